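"""Diagnostic-read classification, independently at each taxonomic rank.

The rule: a read's qualifying hits (100% identity, >= 32 bp, and — when
full-query-length alignment is required — covering the whole read at strain
rank or >= ``qcov`` of it at species-to-phylum ranks) are projected to the
rank being profiled. If they all land on a single taxon the read is
*diagnostic* and assigned to it; if they span two or more taxa the read is
discarded. There is no lowest-common-ancestor fallback, no best-hit choice
and no score tie-breaking: ambiguity always discards. That trades recall for
a structural precision guarantee — an error-free read is a verbatim
substring of its source genome, so the true taxon is always in the hit set,
and a single-taxon hit set therefore cannot name a wrong taxon.

Each rank is classified independently over the same hit sets; a finer-rank
assignment therefore always implies the corresponding coarser-rank
assignment (rank monotonicity). Finer-rank profiles are afterwards validated
against the phylum profile (cross-rank validation).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .align import AlignmentHit, ReferenceIndex, exact_search
from .io_formats import SeqRecord
from .taxonomy import RANKS, TaxonomyTree, rank_order

VERDICTS = ("ambiguous_discard", "no_hit", "too_short")


@dataclass
class BinningConfig:
    """Classification thresholds, named after the pipeline's parameters."""

    fullqlen_alignment: bool = True
    qcov: float = 0.97            # species-to-phylum coverage; strain always 1.0
    min_diagnostic_len: int = 32
    ranks: tuple[str, ...] = RANKS

    def __post_init__(self) -> None:
        if self.fullqlen_alignment and not 0.95 <= self.qcov <= 0.99:
            raise ValueError(f"qcov {self.qcov} outside the supported 0.95–0.99 range")


@dataclass
class RankAssignment:
    """Per-read, per-rank classification outcome."""

    read_id: str
    rank: str
    taxid: int | None = None
    verdict: str | None = None
    supporting_hits: list[AlignmentHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.taxid is None) == (self.verdict is None):
            raise ValueError("exactly one of taxid/verdict must be set")
        if self.verdict is not None and self.verdict not in VERDICTS:
            raise ValueError(f"unknown verdict {self.verdict!r}")

    @property
    def assigned(self) -> bool:
        return self.taxid is not None


def rank_hit_filter(
    hits: Sequence[AlignmentHit],
    rank: str,
    cfg: BinningConfig,
    read_len: int,
) -> list[AlignmentHit]:
    """Keep the hits that qualify a read as potentially diagnostic at a rank.

    Always required: identity 100, no mismatches or gap opens, alignment
    length >= min_diagnostic_len. With full-query-length alignment enabled,
    additionally: query coverage 1.0 at strain rank, >= qcov at coarser
    ranks.
    """
    kept = []
    for hit in hits:
        if hit.identity < 100.0 or hit.mismatches or hit.gapopens:
            continue
        if hit.aln_len < cfg.min_diagnostic_len:
            continue
        if cfg.fullqlen_alignment:
            needed = read_len if rank == "strain" else math.ceil(cfg.qcov * read_len)
            if hit.aln_len < needed:
                continue
        kept.append(hit)
    return kept


def diagnostic_classify(
    filtered_hits: Sequence[AlignmentHit],
    rank: str,
    tree: TaxonomyTree,
    read_id: str | None = None,
) -> RankAssignment:
    """Assign a read at one rank by the single-taxon rule.

    Subject taxids are rolled up to the rank via the taxonomy; subjects whose
    lineage lacks the rank are ignored (they cannot participate in the
    within-rank uniqueness they have no taxon for). Hit-taxon set of size 1
    => assigned; 0 => no_hit; >= 2 => ambiguous_discard.
    """
    if read_id is None:
        read_id = filtered_hits[0].query_id if filtered_hits else "?"
    projected: dict[int, list[AlignmentHit]] = {}
    for hit in filtered_hits:
        ancestor = tree.lineage_of(hit.subject_taxid, rank)
        if ancestor is None:
            continue
        projected.setdefault(ancestor, []).append(hit)
    if len(projected) == 1:
        ((taxid, supporting),) = projected.items()
        return RankAssignment(read_id, rank, taxid=taxid, supporting_hits=supporting)
    if len(projected) == 0:
        return RankAssignment(read_id, rank, verdict="no_hit")
    return RankAssignment(read_id, rank, verdict="ambiguous_discard")


@dataclass
class BinResult:
    assignments: dict[str, list[RankAssignment]]  # rank -> one entry per read
    summary: dict[str, dict[str, int]]            # rank -> verdict/assigned counts


def bin_sample(
    reads: Sequence[SeqRecord],
    index_or_hits: ReferenceIndex | Mapping[str, Sequence[AlignmentHit]],
    tree: TaxonomyTree,
    ranks: Sequence[str] | None = None,
    cfg: BinningConfig | None = None,
) -> BinResult:
    """Classify every read at every rank over one shared hit set per read.

    Hits come either from the internal exact matcher (pass a ReferenceIndex)
    or from a pre-computed mapping read_id -> hits (e.g. parsed BLAST
    tabular output). Identical read sequences share one search. The search
    itself uses the loosest coverage any rank needs; per-rank coverage is
    then enforced by :func:`rank_hit_filter`.
    """
    cfg = cfg or BinningConfig()
    ranks = tuple(ranks or cfg.ranks)
    precomputed = not isinstance(index_or_hits, ReferenceIndex)
    if precomputed:
        read_ids = {r.id for r in reads}
        stray = set(index_or_hits) - read_ids
        if stray:
            raise ValueError(
                f"hits reference reads absent from input (e.g. {sorted(stray)[:3]})"
            )
    search_qcov = cfg.qcov if cfg.fullqlen_alignment else 0.0
    cache: dict[str, list[AlignmentHit]] = {}
    assignments: dict[str, list[RankAssignment]] = {rank: [] for rank in ranks}
    for read in reads:
        if len(read.sequence) < cfg.min_diagnostic_len:
            for rank in ranks:
                assignments[rank].append(RankAssignment(read.id, rank, verdict="too_short"))
            continue
        if precomputed:
            hits = list(index_or_hits.get(read.id, ()))
        else:
            if read.sequence in cache:
                hits = [replace(h, query_id=read.id) for h in cache[read.sequence]]
            else:
                hits = exact_search(
                    read, index_or_hits, min_len=cfg.min_diagnostic_len, qcov=search_qcov
                )
                cache[read.sequence] = hits
        for rank in ranks:
            filtered = rank_hit_filter(hits, rank, cfg, len(read.sequence))
            assignments[rank].append(diagnostic_classify(filtered, rank, tree, read.id))
    summary = {
        rank: {
            "assigned": sum(1 for a in assignments[rank] if a.assigned),
            **{
                v: sum(1 for a in assignments[rank] if a.verdict == v)
                for v in VERDICTS
            },
        }
        for rank in ranks
    }
    return BinResult(assignments, summary)


@dataclass
class RankValidation:
    fpr: float          # percent of lower-rank taxa not projecting into the baseline
    sensitivity: float  # percent of baseline taxa covered by the lower rank
    flagged_taxa: set[int] = field(default_factory=set)


@dataclass
class ValidationReport:
    baseline_rank: str
    per_rank: dict[str, RankValidation]


def cross_rank_validate(
    rank_profiles: Mapping[str, "RankProfile"],
    tree: TaxonomyTree,
    baseline: str = "phylum",
    remove_flagged: bool = False,
) -> ValidationReport:
    """Validate finer-rank profiles against a coarser baseline (phylum).

    For lower rank L against baseline H: every taxon in L is projected to its
    H-ancestor. FPR(L) = 100 x |{t in L : ancestor_H(t) not in H}| / |L|;
    sensitivity(L) = 100 x |{h in H : some t in L projects to h}| / |H|.
    Taxa failing projection are flagged and, with ``remove_flagged``, dropped
    from the profile in place.
    """
    if baseline not in rank_profiles or not rank_profiles[baseline].rows:
        warnings.warn(f"empty {baseline} profile: cross-rank validation skipped")
        return ValidationReport(baseline, {})
    baseline_taxa = set(rank_profiles[baseline].rows)
    report: dict[str, RankValidation] = {}
    for rank, profile in rank_profiles.items():
        if rank == baseline or rank_order(rank) > rank_order(baseline):
            continue
        lower = set(profile.rows)
        if not lower:
            warnings.warn(f"empty {rank} profile: FPR undefined, reported as 0")
            report[rank] = RankValidation(0.0, 0.0)
            continue
        flagged = {
            t for t in lower if tree.lineage_of(t, baseline) not in baseline_taxa
        }
        covered = {
            tree.lineage_of(t, baseline) for t in lower - flagged
        } & baseline_taxa
        report[rank] = RankValidation(
            fpr=100.0 * len(flagged) / len(lower),
            sensitivity=100.0 * len(covered) / len(baseline_taxa),
            flagged_taxa=flagged,
        )
        if remove_flagged:
            for t in flagged:
                del profile.rows[t]
    return ValidationReport(baseline, report)


def write_assignments(bin_result: BinResult, path) -> None:
    """Assignments TSV: read_id, rank, taxid or verdict."""
    with open(path, "w") as out:
        out.write("read_id\trank\tassignment\n")
        for rank, assignments in bin_result.assignments.items():
            for a in assignments:
                label = str(a.taxid) if a.assigned else a.verdict
                out.write(f"{a.read_id}\t{rank}\t{label}\n")


def write_validation(report: ValidationReport, path) -> None:
    with open(path, "w") as out:
        out.write("rank\tfpr\tsensitivity\tn_flagged\n")
        for rank, val in report.per_rank.items():
            out.write(f"{rank}\t{val.fpr!r}\t{val.sensitivity!r}\t{len(val.flagged_taxa)}\n")
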