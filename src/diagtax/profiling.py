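"""Abundance profiles and benchmarking metrics.

A taxon's abundance estimate is its mean read depth per locus: assigned
reads divided by the number of loci they cover, where a locus is a maximal
merged run of overlapping subject intervals on one reference accession.
That denominator makes the estimate comparable across samples for both
reduced-representation fragments (each restriction fragment is one locus)
and shotgun pileups (contiguous coverage islands), with no annotation files.
The percent-of-total-reads estimate is also emitted but, being a share of a
composition, is not usable for cross-sample relative abundance.

Benchmarking against a known community: precision = TP/(TP+FP) over
reported taxa, recall = TP/(TP+FN) over community taxa, and the Pearson
correlation between true relative abundances and either estimate over the
recovered taxa.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .align import AlignmentHit
from .binning import RankAssignment
from .taxonomy import TaxonomyTree


@dataclass
class ProfileRow:
    read_count: int
    locus_count: int
    mean_depth: float
    percent_reads: float
    uncultured: bool = False
    name: str = ""


@dataclass
class RankProfile:
    rank: str
    rows: dict[int, ProfileRow] = field(default_factory=dict)

    @property
    def taxa(self) -> set[int]:
        return set(self.rows)


@dataclass
class BenchmarkResult:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0


def _best_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit:
    """A read's representative hit: longest alignment, then leftmost subject
    interval, then accession order."""
    return min(hits, key=lambda h: (-h.aln_len, h.s_start, h.subject_accession))


def merge_loci(hits_for_taxon: Iterable[AlignmentHit]) -> list[tuple[str, int, int]]:
    """Merge overlapping subject intervals per accession into loci."""
    by_acc: dict[str, list[tuple[int, int]]] = {}
    for hit in hits_for_taxon:
        by_acc.setdefault(hit.subject_accession, []).append((hit.s_start, hit.s_end))
    loci: list[tuple[str, int, int]] = []
    for acc in sorted(by_acc):
        intervals = sorted(by_acc[acc])
        cur_start, cur_end = intervals[0]
        for start, end in intervals[1:]:
            if start <= cur_end:  # overlap or abutment within the same locus
                cur_end = max(cur_end, end)
            else:
                loci.append((acc, cur_start, cur_end))
                cur_start, cur_end = start, end
        loci.append((acc, cur_start, cur_end))
    return loci


def compute_profile(
    assignments: Sequence[RankAssignment],
    rank: str,
    total_reads: int,
    tree: TaxonomyTree,
) -> RankProfile:
    """Aggregate one rank's assignments into an abundance profile.

    ``total_reads`` is the full sample size (classified + unclassified); it
    is the denominator of percent_reads only.
    """
    if total_reads == 0:
        raise ValueError("total_reads must be > 0")
    chosen: dict[int, list[AlignmentHit]] = {}
    counts: dict[int, int] = {}
    for a in assignments:
        if not a.assigned:
            continue
        counts[a.taxid] = counts.get(a.taxid, 0) + 1
        if a.supporting_hits:
            chosen.setdefault(a.taxid, []).append(_best_hit(a.supporting_hits))
    rows = {}
    for taxid, read_count in counts.items():
        loci = merge_loci(chosen.get(taxid, []))
        locus_count = max(1, len(loci))
        rows[taxid] = ProfileRow(
            read_count=read_count,
            locus_count=locus_count,
            mean_depth=read_count / locus_count,
            percent_reads=100.0 * read_count / total_reads,
            uncultured=tree.is_uncultured(taxid),
            name=tree.name_of(taxid),
        )
    return RankProfile(rank=rank, rows=rows)


def truth_taxa_at_rank(
    truth_strains: Iterable[int], rank: str, tree: TaxonomyTree
) -> set[int]:
    """Project community strain taxids to the given rank (dropping gaps)."""
    out = set()
    for taxid in truth_strains:
        ancestor = tree.lineage_of(taxid, rank)
        if ancestor is not None:
            out.add(ancestor)
    return out


def precision_recall(
    profile: RankProfile,
    truth_taxa: set[int],
) -> BenchmarkResult:
    """TP/FP/FN over taxon sets; formulas TP/(TP+FP) and TP/(TP+FN)."""
    if not truth_taxa:
        raise ValueError("truth taxa set is empty")
    reported = profile.taxa
    tp = len(reported & truth_taxa)
    return BenchmarkResult(tp=tp, fp=len(reported - truth_taxa), fn=len(truth_taxa - reported))


def abundance_correlation(
    profile: RankProfile,
    truth_abundances: Mapping[int, float],
    tree: TaxonomyTree,
    mode: str = "depth",
    log10: bool = False,
    include_missing: bool = False,
) -> float | None:
    """Pearson r between true and estimated abundances at the profile's rank.

    Truth abundances (strain taxid -> relative abundance) are summed over
    each taxon's rank ancestor. By default only recovered taxa enter the
    correlation (pairwise-complete); ``include_missing`` zero-fills false
    negatives instead. Returns None when fewer than 3 taxa overlap.
    """
    if mode not in ("depth", "percent"):
        raise ValueError(f"unknown abundance mode {mode!r}")
    truth_at_rank: dict[int, float] = {}
    for strain, ab in truth_abundances.items():
        ancestor = tree.lineage_of(strain, profile.rank)
        if ancestor is not None:
            truth_at_rank[ancestor] = truth_at_rank.get(ancestor, 0.0) + ab
    taxa = sorted(truth_at_rank) if include_missing else sorted(
        set(truth_at_rank) & profile.taxa
    )
    if len(taxa) < 3:
        return None
    est = []
    for t in taxa:
        row = profile.rows.get(t)
        if row is None:
            est.append(0.0)
        else:
            est.append(row.mean_depth if mode == "depth" else row.percent_reads)
    truth_vec = [truth_at_rank[t] for t in taxa]
    if log10:
        import math

        floor = min(x for x in est if x > 0) / 2 if any(x > 0 for x in est) else 1.0
        est = [math.log10(max(x, floor)) for x in est]
        truth_vec = [math.log10(x) for x in truth_vec]
    r, _p = stats.pearsonr(truth_vec, est)
    return float(r)


def write_benchmark(
    results: Mapping[str, tuple[BenchmarkResult, float | None, float | None]], path
) -> None:
    """Benchmark TSV: rank, tp, fp, fn, precision, recall, pearson (both modes)."""
    with open(path, "w") as out:
        out.write("rank\ttp\tfp\tfn\tprecision\trecall\tpearson_depth\tpearson_percent\n")
        for rank, (bench, r_depth, r_percent) in results.items():
            out.write(
                f"{rank}\t{bench.tp}\t{bench.fp}\t{bench.fn}\t"
                f"{bench.precision!r}\t{bench.recall!r}\t"
                f"{'' if r_depth is None else repr(r_depth)}\t"
                f"{'' if r_percent is None else repr(r_percent)}\n"
            )
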