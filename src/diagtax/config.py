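"""Run configuration: one YAML file, defaults applied, typos rejected.

Parameter names mirror the pipeline's own vocabulary (``fullqlen_alignment``,
``reads_per_megablast_burn_in``, ...) so a run is described in the same terms
the method is.
"""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .taxonomy import RANKS


@dataclass
class Config:
    # paths
    reads: str | None = None          # FASTQ/FASTA query reads
    genomes: str | None = None        # reference FASTA
    taxid_map: str | None = None      # TSV accession -> taxid
    taxonomy: str | None = None       # taxonomy TSV
    hits: str | None = None           # pre-computed BLAST outfmt-6(+staxids) hits
    host: str | None = None           # host genome FASTA for read masking
    community: str | None = None      # community spec TSV (genome path, taxid, abundance)
    truth: str | None = None          # truth TSV (read_id, taxid) for benchmarking
    outdir: str = "diagtax_out"

    # classification parameters
    fullqlen_alignment: bool = True
    qcov: float = 0.97                # species-to-phylum query coverage
    min_diagnostic_len: int = 32
    reads_per_megablast_burn_in: int = 0   # 0 = no burn-in; recommended 1000
    cluster_identity: float = 0.95
    burn_in_identity: float = 90.0
    ranks: list[str] = field(default_factory=lambda: list(RANKS))
    remove_flagged: bool = False

    # read filtering
    quality_q: int = 20
    quality_max_frac: float = 0.20
    host_max_shared_frac: float = 0.5

    # simulation
    sim_method: str = "complete_digest"
    total_reads: int = 100_000
    read_length: int | None = None
    error_rate: float = 0.0
    scheme: str | None = "RE1::RE2"
    min_fragment_len: int = 64
    partial_p: float = 0.5
    enzymes: list[dict] = field(default_factory=lambda: [
        {"name": "NsiI", "motif": "ATGCAT", "cut_offset": 5},
        {"name": "NlaIII", "motif": "CATG", "cut_offset": 4},
    ])

    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.95 <= self.qcov <= 0.99:
            raise ValueError(
                f"qcov {self.qcov} outside the supported 95–99% query-coverage range"
            )
        if self.reads_per_megablast_burn_in < 0:
            raise ValueError("reads_per_megablast_burn_in must be >= 0")
        if not 0 < self.quality_max_frac < 1:
            raise ValueError("quality_max_frac must be in (0, 1)")


_FIELD_NAMES = {f.name for f in fields(Config)}


def load_config(path: str | Path) -> Config:
    """Load YAML config; unknown keys are an error; paths resolved absolute."""
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(data) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    cfg = Config(**data)
    base = Path(path).resolve().parent
    for name in ("reads", "genomes", "taxid_map", "taxonomy", "hits",
                 "host", "community", "truth", "outdir"):
        value = getattr(cfg, name)
        if value is not None and not Path(value).is_absolute():
            setattr(cfg, name, str(base / value))
    return cfg
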