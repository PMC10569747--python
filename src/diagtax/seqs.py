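"""Small sequence utilities shared across modules."""
from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> tuple[str, bool]:
    """Canonical form of a k-mer.

    Returns (canonical_kmer, is_forward) where is_forward is True when the
    input k-mer itself is the canonical (lexicographically smaller) strand.
    """
    rc = revcomp(kmer)
    if kmer <= rc:
        return kmer, True
    return rc, False


def validate_alphabet(seq: str, record_id: str, source: str = "") -> None:
    """Raise ValueError naming the record if seq leaves {A,C,G,T,N}."""
    bad = set(seq) - VALID_BASES
    if bad:
        where = f" in {source}" if source else ""
        raise ValueError(
            f"record {record_id!r}{where}: invalid sequence character(s) "
            f"{sorted(bad)!r}; only A,C,G,T,N allowed"
        )
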