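"""Readers and writers for the external formats the pipeline touches.

Formats: FASTA, FASTQ (Sanger/+33), BLAST tabular outfmt 6 (12 columns, or 13
with a trailing ``staxids`` column), and the per-rank profile TSV dialect.
Gzip input is sniffed by the ``.gz`` extension. Internally all coordinates are
0-based half-open; BLAST's 1-based inclusive coordinates are converted by the
alignment layer, not here — the parser reports fields verbatim.
"""
from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

from .seqs import validate_alphabet


@dataclass
class SeqRecord:
    """One read or contig; qualities are PHRED integers when present."""

    id: str
    sequence: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be nonempty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be nonempty")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Blast6Hit:
    """One row of BLAST tabular output (outfmt 6, optionally with staxids).

    Coordinates are kept exactly as BLAST prints them: 1-based inclusive,
    with sstart > send on minus-strand subject hits.
    """

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    staxids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"pident {self.pident} outside [0, 100]")
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")
        if self.qstart > self.qend:
            raise ValueError("qstart must be <= qend")


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> Iterator[SeqRecord]:
    """Stream records from a FASTA file (multi-line sequences concatenated).

    The header token up to the first whitespace becomes the id; sequences are
    uppercased; characters outside {A,C,G,T,N} raise with the record named.
    An empty file yields nothing.
    """
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            seq = str(rec.seq).upper()
            validate_alphabet(seq, rec.id, str(path))
            yield SeqRecord(rec.id, seq)


def read_fastq(path: str | Path) -> Iterator[SeqRecord]:
    """Stream records from a Sanger-encoded FASTQ file."""
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                seq = str(rec.seq).upper()
                validate_alphabet(seq, rec.id, str(path))
                yield SeqRecord(rec.id, seq, rec.letter_annotations["phred_quality"])
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write single-line-sequence FASTA (so read/write round-trips bytewise)."""
    with _open_text(path, "wt") as out:
        for rec in records:
            out.write(f">{rec.id}\n{rec.sequence}\n")


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as out:
        for rec in records:
            if rec.qualities is None:
                raise ValueError(f"record {rec.id!r}: cannot write FASTQ without qualities")
            qual = "".join(chr(q + 33) for q in rec.qualities)
            out.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


_BLAST6_NUMERIC = {
    "pident": float, "length": int, "mismatch": int, "gapopen": int,
    "qstart": int, "qend": int, "sstart": int, "send": int,
    "evalue": float, "bitscore": float,
}


def parse_blast6(path: str | Path, has_staxids: bool | None = None) -> Iterator[Blast6Hit]:
    """Parse BLAST outfmt-6 tabular output.

    ``has_staxids=None`` autodetects from the first data line (13 columns =>
    trailing ';'-separated staxids). Wrong column counts and non-numeric
    numeric fields raise with the offending line number.
    """
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if has_staxids is None:
                has_staxids = len(fields) == 13
            expected = 13 if has_staxids else 12
            if len(fields) != expected:
                raise ValueError(
                    f"{path}:{lineno}: expected {expected} tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                kwargs = {
                    "qseqid": fields[0],
                    "sseqid": fields[1],
                    **{
                        name: conv(fields[i + 2])
                        for i, (name, conv) in enumerate(_BLAST6_NUMERIC.items())
                    },
                }
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field ({exc})") from exc
            staxids: list[int] = []
            if has_staxids and fields[12]:
                try:
                    staxids = [int(t) for t in fields[12].split(";") if t]
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: bad staxids field") from exc
            yield Blast6Hit(staxids=staxids, **kwargs)


def _fmt_float(x: float) -> str:
    # repr round-trips through float(); trim trailing ".0" noise for ints
    return format(x, "g")


def write_blast6(hits: Iterable[Blast6Hit], path: str | Path) -> None:
    """Write hits in the 13-column staxids dialect; inverse of parse_blast6."""
    with _open_text(path, "wt") as out:
        for h in hits:
            out.write(
                "\t".join([
                    h.qseqid, h.sseqid, _fmt_float(h.pident), str(h.length),
                    str(h.mismatch), str(h.gapopen), str(h.qstart), str(h.qend),
                    str(h.sstart), str(h.send), _fmt_float(h.evalue),
                    _fmt_float(h.bitscore), ";".join(str(t) for t in h.staxids),
                ]) + "\n"
            )


PROFILE_COLUMNS = (
    "taxid", "name", "rank", "read_count", "locus_count",
    "mean_depth_per_locus", "percent_reads", "uncultured_flag",
)


def write_profile(profiles: Mapping[str, "RankProfile"], outdir: str | Path) -> dict[str, Path]:
    """Write one TSV per rank under outdir; returns {rank: path}.

    Rows are sorted by descending read_count, then taxid. Numeric columns are
    written at full precision so the matching reader round-trips losslessly.
    """
    from .profiling import RankProfile  # noqa: F401  (type only; avoids cycle at import time)

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for rank, profile in profiles.items():
        path = outdir / f"profile_{rank}.tsv"
        with open(path, "w") as out:
            out.write("\t".join(PROFILE_COLUMNS) + "\n")
            rows = sorted(
                profile.rows.items(),
                key=lambda kv: (-kv[1].read_count, kv[0]),
            )
            for taxid, row in rows:
                out.write(
                    "\t".join([
                        str(taxid), row.name, rank, str(row.read_count),
                        str(row.locus_count), repr(row.mean_depth),
                        repr(row.percent_reads), str(int(row.uncultured)),
                    ]) + "\n"
                )
        paths[rank] = path
    return paths


def read_profile(path: str | Path) -> "RankProfile":
    """Read one per-rank profile TSV written by write_profile."""
    from .profiling import ProfileRow, RankProfile

    rank = None
    rows = {}
    with _open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != PROFILE_COLUMNS:
            raise ValueError(f"{path}: unexpected profile header {header}")
        for line in handle:
            f = line.rstrip("\n").split("\t")
            rank = f[2]
            rows[int(f[0])] = ProfileRow(
                read_count=int(f[3]), locus_count=int(f[4]),
                mean_depth=float(f[5]), percent_reads=float(f[6]),
                uncultured=bool(int(f[7])), name=f[1],
            )
    if rank is None:
        rank = Path(path).stem.replace("profile_", "")
    return RankProfile(rank=rank, rows=rows)
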