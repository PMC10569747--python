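"""Exact and near-exact read-to-reference matching over a k-mer index.

The classifier only ever consumes 100%-identity, (near-)full-coverage hits,
so a desk-scale seed-and-extend matcher over a 32-mer index is behaviorally
equivalent to a full MegaBLAST run for binning purposes. The 32-mer seed
length equals the minimum diagnostic-sequence length, so no qualifying hit
can lack a seed. BLAST tabular output from a real MegaBLAST run remains a
supported input via :func:`blast6_to_hits`.

Also implemented here: the burn-in database reduction (greedy read
clustering, relaxed 90%-identity search with the representatives, then
shrinking the reference to the subjects of every taxon hit) and an exact
k-mer host-read filter.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .io_formats import Blast6Hit, SeqRecord
from .seqs import canonical, revcomp

K = 32  # seed length == minimum diagnostic length


@dataclass
class AlignmentHit:
    """One query-subject local alignment, 0-based half-open coordinates.

    Exact hits have identity 100, zero mismatches/gapopens, and
    ``aln_len == q_end - q_start``. ``s_start/s_end`` are always plus-strand
    subject coordinates; ``strand`` records the query orientation.
    """

    query_id: str
    subject_accession: str
    subject_taxid: int
    identity: float
    aln_len: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str = "+"
    mismatches: int = 0
    gapopens: int = 0


class ReferenceIndex:
    """Subject sequences plus a canonical 32-mer seed map."""

    def __init__(self, subjects: Mapping[str, tuple[str, int]], k: int = K):
        self.k = k
        self.subjects: dict[str, tuple[str, int]] = dict(subjects)
        self.kmer_map: dict[str, list[tuple[str, int, bool]]] = {}
        for acc, (seq, _taxid) in self.subjects.items():
            if len(seq) < k:
                warnings.warn(f"subject {acc!r} shorter than {k} bp: no seeds indexed")
                continue
            for off in range(len(seq) - k + 1):
                kmer = seq[off:off + k]
                if "N" in kmer:
                    continue
                canon, is_fwd = canonical(kmer)
                self.kmer_map.setdefault(canon, []).append((acc, off, is_fwd))

    @property
    def taxids(self) -> set[int]:
        return {taxid for _, taxid in self.subjects.values()}

    def subset_by_taxids(self, taxids: set[int]) -> "ReferenceIndex":
        kept = {acc: st for acc, st in self.subjects.items() if st[1] in taxids}
        return ReferenceIndex(kept, k=self.k)


def build_reference_index(
    genomes: Iterable[SeqRecord], taxid_map: Mapping[str, int], k: int = K
) -> ReferenceIndex:
    """Index reference genomes; every accession must map to a taxid."""
    subjects: dict[str, tuple[str, int]] = {}
    for rec in genomes:
        if rec.id in subjects:
            raise ValueError(f"duplicate accession {rec.id!r}")
        if rec.id not in taxid_map:
            raise ValueError(f"accession {rec.id!r} has no taxid mapping")
        subjects[rec.id] = (rec.sequence, taxid_map[rec.id])
    return ReferenceIndex(subjects, k=k)


def _seed_locations(index: ReferenceIndex, kmer: str):
    """Plus-strand subject locations whose k-mer equals ``kmer`` verbatim."""
    canon, query_is_canon = canonical(kmer)
    for acc, off, subject_is_canon in index.kmer_map.get(canon, ()):
        if subject_is_canon == query_is_canon:
            yield acc, off


def _extend_exact(read: str, sseq: str, q_pos: int, s_pos: int) -> tuple[int, int]:
    """Maximal exact run through the aligned position; N never matches."""
    left = 0
    while (
        q_pos - left - 1 >= 0 and s_pos - left - 1 >= 0
        and read[q_pos - left - 1] == sseq[s_pos - left - 1]
        and read[q_pos - left - 1] != "N"
    ):
        left += 1
    right = 0
    n_q, n_s = len(read), len(sseq)
    while (
        q_pos + right < n_q and s_pos + right < n_s
        and read[q_pos + right] == sseq[s_pos + right]
        and read[q_pos + right] != "N"
    ):
        right += 1
    return q_pos - left, q_pos - left + left + right  # q interval of the run


def exact_search(
    read: SeqRecord,
    index: ReferenceIndex,
    min_len: int = K,
    qcov: float = 1.0,
) -> list[AlignmentHit]:
    """All subjects containing an exact substring match of the read.

    A hit requires a contiguous, mismatch- and gap-free match of length >=
    max(min_len, ceil(qcov * len(read))) on either strand; qcov=1.0 demands
    the entire read. Every matching subject is reported — the classifier
    needs the full hit set, not a best hit. Reads shorter than min_len
    return an empty list (callers count them as "too short").
    """
    n = len(read.sequence)
    if n < min_len:
        return []
    required = max(min_len, math.ceil(qcov * n))
    hits: list[AlignmentHit] = []
    seen: set[tuple[str, int, str]] = set()
    for strand, rseq in (("+", read.sequence), ("-", revcomp(read.sequence))):
        for i in range(n - index.k + 1):
            kmer = rseq[i:i + index.k]
            if "N" in kmer:
                continue
            for acc, off in _seed_locations(index, kmer):
                diag = off - i
                key = (acc, diag, strand)
                if key in seen:
                    continue
                seen.add(key)
                sseq = index.subjects[acc][0]
                q_lo, q_hi = _extend_exact(rseq, sseq, i, off)
                run = q_hi - q_lo
                if run < required:
                    continue
                s_lo, s_hi = q_lo + diag, q_hi + diag
                if strand == "-":
                    oq_lo, oq_hi = n - q_hi, n - q_lo
                else:
                    oq_lo, oq_hi = q_lo, q_hi
                hits.append(AlignmentHit(
                    query_id=read.id, subject_accession=acc,
                    subject_taxid=index.subjects[acc][1],
                    identity=100.0, aln_len=run,
                    q_start=oq_lo, q_end=oq_hi, s_start=s_lo, s_end=s_hi,
                    strand=strand,
                ))
    return hits


def approx_search(
    read: SeqRecord,
    index: ReferenceIndex,
    min_identity: float = 90.0,
    min_cov: float = 0.95,
) -> list[AlignmentHit]:
    """Relaxed ungapped search: seed, then score the full read on the diagonal.

    Reports subjects where identity >= min_identity over at least
    ``min_cov`` of the read. Used by the burn-in reduction; contains
    exact_search's results whenever min_identity allows.
    """
    n = len(read.sequence)
    if n < index.k:
        return []
    required_cov = math.ceil(min_cov * n)
    best: dict[str, AlignmentHit] = {}
    seen: set[tuple[str, int, str]] = set()
    for strand, rseq in (("+", read.sequence), ("-", revcomp(read.sequence))):
        for i in range(n - index.k + 1):
            kmer = rseq[i:i + index.k]
            if "N" in kmer:
                continue
            for acc, off in _seed_locations(index, kmer):
                diag = off - i
                key = (acc, diag, strand)
                if key in seen:
                    continue
                seen.add(key)
                sseq = index.subjects[acc][0]
                q_lo = max(0, -diag)
                q_hi = min(n, len(sseq) - diag)
                overlap = q_hi - q_lo
                if overlap < required_cov:
                    continue
                matches = sum(
                    1 for j in range(q_lo, q_hi)
                    if rseq[j] == sseq[j + diag] and rseq[j] != "N"
                )
                identity = 100.0 * matches / overlap
                if identity < min_identity:
                    continue
                if strand == "-":
                    oq_lo, oq_hi = n - q_hi, n - q_lo
                else:
                    oq_lo, oq_hi = q_lo, q_hi
                hit = AlignmentHit(
                    query_id=read.id, subject_accession=acc,
                    subject_taxid=index.subjects[acc][1],
                    identity=identity, aln_len=overlap,
                    q_start=oq_lo, q_end=oq_hi,
                    s_start=q_lo + diag, s_end=q_hi + diag,
                    strand=strand, mismatches=overlap - matches,
                )
                if acc not in best or hit.identity > best[acc].identity:
                    best[acc] = hit
    return list(best.values())


def _ungapped_identity(a: str, b: str, k: int = 16) -> float:
    """Best ungapped identity over the shorter sequence, seed-screened."""
    if len(a) < len(b):
        a, b = b, a  # a is the longer
    short = len(b)
    if short < k:
        return 0.0
    a_kmers: dict[str, list[int]] = {}
    for i in range(len(a) - k + 1):
        a_kmers.setdefault(a[i:i + k], []).append(i)
    diags: set[int] = set()
    for j in range(0, short - k + 1, k):
        for i in a_kmers.get(b[j:j + k], ()):
            diags.add(i - j)
    best = 0.0
    for diag in diags:
        lo = max(0, -diag)
        hi = min(short, len(a) - diag)
        matches = sum(1 for j in range(lo, hi) if b[j] == a[j + diag])
        best = max(best, matches / short)
    return best


def cluster_representatives(
    reads: Sequence[SeqRecord], identity: float = 0.95
) -> list[SeqRecord]:
    """Greedy incremental clustering, longest sequence first.

    A read joins the first existing representative with which it shares at
    least ``identity`` over the shorter sequence's length (ungapped); else it
    becomes a new representative. This is the classic greedy clustering
    convention (identity computed over the shorter sequence).
    """
    if not reads:
        raise ValueError("reads must be nonempty")
    # identical sequences trivially share one cluster: collapse them up front
    unique: dict[str, SeqRecord] = {}
    for read in reads:
        unique.setdefault(read.sequence, read)
    ordered = sorted(unique.values(), key=lambda r: -len(r.sequence))
    reps: list[SeqRecord] = []
    seed_index: dict[str, set[int]] = {}
    k = 16
    for read in ordered:
        candidates: set[int] = set()
        for j in range(0, max(1, len(read.sequence) - k + 1), k):
            candidates |= seed_index.get(read.sequence[j:j + k], set())
        joined = False
        for rep_i in sorted(candidates):
            if _ungapped_identity(reps[rep_i].sequence, read.sequence, k) >= identity:
                joined = True
                break
        if not joined:
            rep_i = len(reps)
            reps.append(read)
            for j in range(len(read.sequence) - k + 1):
                seed_index.setdefault(read.sequence[j:j + k], set()).add(rep_i)
    return reps


def burn_in_reduce(
    reads: Sequence[SeqRecord],
    index: ReferenceIndex,
    batch_size: int,
    identity: float = 90.0,
    cluster_identity: float = 0.95,
    min_cov: float = 0.95,
) -> ReferenceIndex:
    """Shrink the reference before the exact search.

    batch_size == 0 disables the burn-in and returns the index unchanged
    (the default). Otherwise: cluster the reads at 95% identity, run the
    relaxed search with each representative (processed in batches of
    ``batch_size``), and keep **all** subjects of every taxon hit — not just
    the hit subjects — so the exact phase can still find a better subject
    within a confirmed taxon.
    """
    if batch_size < 0:
        raise ValueError("batch_size must be >= 0")
    if batch_size == 0:
        return index
    reps = cluster_representatives(reads, identity=cluster_identity)
    hit_taxids: set[int] = set()
    for start in range(0, len(reps), batch_size):
        for rep in reps[start:start + batch_size]:
            for hit in approx_search(rep, index, min_identity=identity, min_cov=min_cov):
                hit_taxids.add(hit.subject_taxid)
    return index.subset_by_taxids(hit_taxids)


def host_filter(
    reads: Iterable[SeqRecord],
    host_index: ReferenceIndex,
    k: int = K,
    max_shared_frac: float = 0.5,
) -> list[SeqRecord]:
    """Remove reads sharing >= max_shared_frac of their k-mers with the host.

    An exact canonical-k-mer screen standing where a host-genome aligner
    would run in a cluster deployment; idempotent by construction.
    """
    kept = []
    for read in reads:
        n_kmers = len(read.sequence) - k + 1
        if n_kmers <= 0:
            kept.append(read)
            continue
        shared = 0
        for i in range(n_kmers):
            kmer = read.sequence[i:i + k]
            if "N" in kmer:
                continue
            canon, _ = canonical(kmer)
            if canon in host_index.kmer_map:
                shared += 1
        if shared / n_kmers >= max_shared_frac:
            continue
        kept.append(read)
    return kept


def blast6_to_hits(
    rows: Iterable[Blast6Hit], taxid_of_subject: Mapping[str, int] | None = None
) -> list[AlignmentHit]:
    """Convert BLAST tabular rows to internal hits.

    1-based inclusive coordinates become 0-based half-open; minus-strand
    subject hits (sstart > send) are normalized to plus-strand subject
    coordinates with strand '-'. The taxid comes from the row's staxids
    (first entry) or from ``taxid_of_subject``.
    """
    hits = []
    for row in rows:
        if row.staxids:
            taxid = row.staxids[0]
        elif taxid_of_subject and row.sseqid in taxid_of_subject:
            taxid = taxid_of_subject[row.sseqid]
        else:
            raise ValueError(f"no taxid for subject {row.sseqid!r}")
        if row.sstart <= row.send:
            s_start, s_end, strand = row.sstart - 1, row.send, "+"
        else:
            s_start, s_end, strand = row.send - 1, row.sstart, "-"
        hits.append(AlignmentHit(
            query_id=row.qseqid, subject_accession=row.sseqid, subject_taxid=taxid,
            identity=row.pident, aln_len=row.length,
            q_start=row.qstart - 1, q_end=row.qend,
            s_start=s_start, s_end=s_end, strand=strand,
            mismatches=row.mismatch, gapopens=row.gapopen,
        ))
    return hits
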