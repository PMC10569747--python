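"""End-to-end orchestration: simulate -> filter -> align/bin -> profile.

Stages run in a fixed order and write their outputs under ``outdir``. Three
checkpoints (simulate, filter, classify) are cached: each writes a key file
derived from the checksums of its inputs and the relevant configuration, and
a rerun with unchanged inputs reloads the cached outputs instead of
recomputing. A manifest (JSON) records the config snapshot, input checksums,
per-stage read counts and wall-clock, and is written even on failure with
the failing stage marked.
"""
from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .align import (ReferenceIndex, blast6_to_hits, build_reference_index,
                    burn_in_reduce, host_filter)
from .binning import (BinningConfig, BinResult, ValidationReport, bin_sample,
                      cross_rank_validate, write_assignments, write_validation)
from .config import Config
from .io_formats import (SeqRecord, parse_blast6, read_fasta, read_fastq,
                         write_fastq, write_profile)
from .profiling import (RankProfile, abundance_correlation, compute_profile,
                        precision_recall, truth_taxa_at_rank, write_benchmark)
from .simulate import (CommunityMember, CommunitySpec, Enzyme, load_truth,
                       quality_filter, simulate_reads, write_fragments,
                       write_truth)
from .taxonomy import TaxonomyTree, load_taxonomy


@dataclass
class StageRecord:
    status: str = "pending"   # ran | cached | failed | skipped
    seconds: float = 0.0
    reads_in: int | None = None
    reads_out: int | None = None


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    input_checksums: dict[str, str] = field(default_factory=dict)
    stages: dict[str, StageRecord] = field(default_factory=dict)
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        payload = {
            "version": self.version,
            "config": self.config,
            "input_checksums": self.input_checksums,
            "stages": {k: asdict(v) for k, v in self.stages.items()},
            "failed_stage": self.failed_stage,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_key(parts: Sequence[str]) -> str:
    return hashlib.sha256("\n".join(parts).encode()).hexdigest()


class _Cache:
    """Checkpoint cache: a stage is valid when its key file matches and all
    its output files exist."""

    def __init__(self, outdir: Path):
        self.dir = outdir / ".cache"
        self.dir.mkdir(parents=True, exist_ok=True)

    def fresh(self, stage: str, key: str, outputs: Sequence[Path]) -> bool:
        marker = self.dir / f"{stage}.key"
        return (
            marker.exists()
            and marker.read_text() == key
            and all(p.exists() for p in outputs)
        )

    def mark(self, stage: str, key: str) -> None:
        (self.dir / f"{stage}.key").write_text(key)


def load_community_spec(path: str | Path) -> CommunitySpec:
    """Community TSV: genome_fasta_path <tab> taxid <tab> relative_abundance.

    Relative paths are resolved against the TSV's directory.
    """
    base = Path(path).resolve().parent
    members = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields_ = line.split("\t")
            if len(fields_) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            if lineno == 1:
                try:
                    float(fields_[2])
                except ValueError:
                    continue  # header
            genome_path = Path(fields_[0])
            if not genome_path.is_absolute():
                genome_path = base / genome_path
            members.append(CommunityMember(
                list(read_fasta(genome_path)), int(fields_[1]), float(fields_[2])
            ))
    return CommunitySpec(members)


def load_taxid_map(path: str | Path) -> dict[str, int]:
    out = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            acc, taxid = line.split("\t")[:2]
            if not taxid.isdigit():
                continue  # header
            out[acc] = int(taxid)
    return out


@dataclass
class AnalysisResult:
    bin_result: BinResult
    profiles: dict[str, RankProfile]
    validation: ValidationReport


def classify_and_profile(
    reads: Sequence[SeqRecord],
    index_or_hits,
    tree: TaxonomyTree,
    cfg: BinningConfig | None = None,
    total_reads: int | None = None,
    remove_flagged: bool = False,
) -> AnalysisResult:
    """Bin every read at every rank, build profiles, cross-rank validate."""
    cfg = cfg or BinningConfig()
    total = total_reads if total_reads is not None else len(reads)
    bin_result = bin_sample(reads, index_or_hits, tree, cfg=cfg)
    profiles = {
        rank: compute_profile(assignments, rank, total, tree)
        for rank, assignments in bin_result.assignments.items()
    }
    validation = cross_rank_validate(profiles, tree, remove_flagged=remove_flagged)
    return AnalysisResult(bin_result, profiles, validation)


def _read_any(path: str) -> list[SeqRecord]:
    name = Path(path).name.lower()
    if any(tag in name for tag in (".fastq", ".fq")):
        return list(read_fastq(path))
    return list(read_fasta(path))


def run_pipeline(config: Config) -> RunManifest:
    """Execute the whole pipeline as configured; returns the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=asdict(config))
    cache = _Cache(outdir)
    manifest_path = outdir / "manifest.json"

    for name in ("reads", "genomes", "taxid_map", "taxonomy", "hits", "host",
                 "community", "truth"):
        value = getattr(config, name)
        if value:
            manifest.input_checksums[name] = _checksum(value)

    enzymes = tuple(Enzyme(e["name"], e["motif"], e["cut_offset"])
                    for e in config.enzymes)

    try:
        # -- simulate ------------------------------------------------------
        stage = StageRecord()
        manifest.stages["simulate"] = stage
        reads_path = Path(config.reads) if config.reads else outdir / "simulated.fastq"
        truth_path = Path(config.truth) if config.truth else outdir / "truth.tsv"
        if config.reads is None:
            if config.community is None:
                raise ValueError("provide either reads or a community spec to simulate")
            t0 = time.perf_counter()
            sim_cfg = json.dumps({
                "community": manifest.input_checksums["community"],
                "method": config.sim_method, "total_reads": config.total_reads,
                "read_length": config.read_length, "error_rate": config.error_rate,
                "scheme": config.scheme, "min_fragment_len": config.min_fragment_len,
                "partial_p": config.partial_p, "enzymes": config.enzymes,
                "seed": config.seed,
            }, sort_keys=True)
            key = _stage_key([sim_cfg])
            outputs = [reads_path, truth_path, outdir / "fragments.tsv"]
            if cache.fresh("simulate", key, outputs):
                stage.status = "cached"
            else:
                community = load_community_spec(config.community)
                sim = simulate_reads(
                    community, config.sim_method, total_reads=config.total_reads,
                    read_length=config.read_length, error_rate=config.error_rate,
                    enzymes=enzymes, partial_p=config.partial_p,
                    scheme=config.scheme, min_fragment_len=config.min_fragment_len,
                    seed=config.seed,
                )
                write_fastq(sim.reads, reads_path)
                write_truth(sim.truth, truth_path)
                write_fragments(sim.fragments.values(), outdir / "fragments.tsv")
                stage.reads_out = len(sim.reads)
                cache.mark("simulate", key)
                stage.status = "ran"
            stage.seconds = time.perf_counter() - t0
        else:
            stage.status = "skipped"

        reads = _read_any(str(reads_path))

        # -- filter (host mask + quality) ----------------------------------
        stage = StageRecord(reads_in=len(reads))
        manifest.stages["filter"] = stage
        t0 = time.perf_counter()
        filtered_path = outdir / "filtered.fastq"
        key = _stage_key([
            _checksum(reads_path),
            manifest.input_checksums.get("host", ""),
            f"{config.quality_q}:{config.quality_max_frac}:{config.host_max_shared_frac}",
        ])
        if cache.fresh("filter", key, [filtered_path]):
            stage.status = "cached"
            reads = list(read_fastq(filtered_path))
        else:
            if config.host:
                host_genomes = list(read_fasta(config.host))
                host_index = ReferenceIndex(
                    {rec.id: (rec.sequence, 0) for rec in host_genomes}
                )
                reads = host_filter(
                    reads, host_index, max_shared_frac=config.host_max_shared_frac
                )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                reads = quality_filter(
                    reads, q=config.quality_q, max_frac=config.quality_max_frac
                )
            if all(r.qualities is not None for r in reads):
                write_fastq(reads, filtered_path)
                cache.mark("filter", key)
            stage.status = "ran"
        stage.reads_out = len(reads)
        stage.seconds = time.perf_counter() - t0

        # -- align + bin + validate + profile + benchmark ------------------
        stage = StageRecord(reads_in=len(reads))
        manifest.stages["classify"] = stage
        t0 = time.perf_counter()
        if config.taxonomy is None:
            raise ValueError("taxonomy path is required")
        tree = load_taxonomy(config.taxonomy)
        bin_cfg = BinningConfig(
            fullqlen_alignment=config.fullqlen_alignment, qcov=config.qcov,
            min_diagnostic_len=config.min_diagnostic_len,
            ranks=tuple(config.ranks),
        )
        key = _stage_key([
            _checksum(filtered_path) if filtered_path.exists() else str(len(reads)),
            manifest.input_checksums.get("genomes", ""),
            manifest.input_checksums.get("hits", ""),
            manifest.input_checksums.get("taxonomy", ""),
            json.dumps({
                "fullqlen": config.fullqlen_alignment, "qcov": config.qcov,
                "min_len": config.min_diagnostic_len,
                "burn_in": config.reads_per_megablast_burn_in,
                "ranks": config.ranks, "remove_flagged": config.remove_flagged,
            }, sort_keys=True),
        ])
        profile_paths = [outdir / f"profile_{r}.tsv" for r in config.ranks]
        classify_outputs = [outdir / "assignments.tsv", outdir / "validation.tsv",
                            *profile_paths]
        if cache.fresh("classify", key, classify_outputs):
            stage.status = "cached"
        else:
            if config.hits:
                rows = list(parse_blast6(config.hits))
                taxid_map = load_taxid_map(config.taxid_map) if config.taxid_map else None
                hit_list = blast6_to_hits(rows, taxid_map)
                hits_by_read: dict[str, list] = {}
                for h in hit_list:
                    hits_by_read.setdefault(h.query_id, []).append(h)
                index_or_hits = hits_by_read
            else:
                if not config.genomes or not config.taxid_map:
                    raise ValueError("need genomes + taxid_map, or pre-computed hits")
                genomes = list(read_fasta(config.genomes))
                taxid_map = load_taxid_map(config.taxid_map)
                index = build_reference_index(genomes, taxid_map)
                if config.reads_per_megablast_burn_in > 0:
                    index = burn_in_reduce(
                        reads, index, config.reads_per_megablast_burn_in,
                        identity=config.burn_in_identity,
                        cluster_identity=config.cluster_identity,
                    )
                index_or_hits = index
            result = classify_and_profile(
                reads, index_or_hits, tree, bin_cfg,
                remove_flagged=config.remove_flagged,
            )
            write_assignments(result.bin_result, outdir / "assignments.tsv")
            write_validation(result.validation, outdir / "validation.tsv")
            write_profile(result.profiles, outdir)

            if truth_path.exists():
                truth = load_truth(truth_path)
                truth_strains = set(truth.values())
                # member read counts give true relative abundances
                counts: dict[int, int] = {}
                for taxid in truth.values():
                    counts[taxid] = counts.get(taxid, 0) + 1
                total_truth = sum(counts.values())
                truth_ab = {t: c / total_truth for t, c in counts.items()}
                bench = {}
                for rank, profile in result.profiles.items():
                    truth_taxa = truth_taxa_at_rank(truth_strains, rank, tree)
                    if not truth_taxa:
                        continue
                    bench[rank] = (
                        precision_recall(profile, truth_taxa),
                        abundance_correlation(profile, truth_ab, tree, mode="depth"),
                        abundance_correlation(profile, truth_ab, tree, mode="percent"),
                    )
                write_benchmark(bench, outdir / "benchmark.tsv")
            cache.mark("classify", key)
            stage.status = "ran"
        stage.seconds = time.perf_counter() - t0
    except Exception:
        for name, record in manifest.stages.items():
            if record.status == "pending":
                record.status = "failed"
                manifest.failed_stage = name
                break
        manifest.write(manifest_path)
        raise
    manifest.write(manifest_path)
    return manifest
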