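"""Mock-community read simulation with in-silico restriction digestion.

Generates ground-truthed reads from a defined community of genomes by one of
four fragmentation methods:

* ``shotgun`` — mechanical shearing: uniform starts, truncated-normal lengths;
* ``complete_digest`` — every restriction cut realized;
* ``partial_digest`` — each cut realized independently with probability p;
* ``shotgun_then_digest`` — shear first, then completely digest each read
  (how reduced-representation subsampling is applied to shotgun data).

Digest fragments carry flank annotations (which enzyme bounded each end) so
they can be subsampled by flanking-motif scheme: ``RE1::RE2`` keeps fragments
bounded by one cut of each enzyme, ``RE1/2::RE1/2`` keeps any combination.
Fragments shorter than 64 bp are dropped by default — too short to contain a
diagnostic sequence worth classifying.

Default enzymes are NsiI (ATGCA^T) and NlaIII (CATG^), the double-digest used
for quantitative reduced-representation libraries. Both motifs are palindromic
so a single-strand scan finds every site; non-palindromic motifs are
additionally scanned on the reverse complement.

The module also builds the synthetic study community used throughout the test
suite: ten 50-kb genomes of known lineage, three congeneric pairs at ~95%
identity, five sister-taxon decoy genomes, and a relative-abundance spectrum
log-spaced over three orders of magnitude.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import SeqRecord
from .seqs import revcomp
from .taxonomy import TaxonomyNode, TaxonomyTree


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme: recognition motif plus cut offset within it."""

    name: str
    motif: str
    cut_offset: int  # 0..len(motif); cut placed motif_start + cut_offset

    def __post_init__(self) -> None:
        if len(self.motif) < 4:
            raise ValueError("motif length must be >= 4")
        if not 0 <= self.cut_offset <= len(self.motif):
            raise ValueError("cut_offset outside motif")

    @property
    def palindromic(self) -> bool:
        return self.motif == revcomp(self.motif)


NSI_I = Enzyme("NsiI", "ATGCAT", 5)    # ATGCA^T
NLA_III = Enzyme("NlaIII", "CATG", 4)  # CATG^
DEFAULT_ENZYMES = (NSI_I, NLA_III)


@dataclass
class Fragment:
    """A digest/shear fragment with its provenance interval and flanks."""

    source_id: str
    start: int  # 0-based half-open on the source
    end: int
    sequence: str
    left_flank: str | None = None   # enzyme name bounding the start, None at terminus
    right_flank: str | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence) or len(self.sequence) < 1:
            raise ValueError("fragment interval/sequence length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class CommunityMember:
    records: list[SeqRecord]
    taxid: int
    abundance: float


@dataclass
class CommunitySpec:
    """Ground-truth community: genomes, taxids and relative abundances."""

    members: list[CommunityMember]

    def __post_init__(self) -> None:
        total = sum(m.abundance for m in self.members)
        if any(m.abundance <= 0 for m in self.members):
            raise ValueError("abundances must be > 0")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {total})")

    @property
    def taxids(self) -> list[int]:
        return [m.taxid for m in self.members]

    @property
    def abundances(self) -> dict[int, float]:
        return {m.taxid: m.abundance for m in self.members}


def _find_cut_sites(seq: str, enzymes: Sequence[Enzyme]) -> dict[int, str]:
    """Map cut position -> enzyme name over all motif occurrences, both strands.

    Palindromic motifs are counted once. When two enzymes would cut at the
    same coordinate the earlier enzyme in the list wins (deterministic).
    Cuts at position 0 or len(seq) would create empty fragments and are
    dropped.
    """
    cuts: dict[int, str] = {}
    n = len(seq)
    for enz in enzymes:
        motifs = [(enz.motif, enz.cut_offset)]
        if not enz.palindromic:
            motifs.append((revcomp(enz.motif), len(enz.motif) - enz.cut_offset))
        for motif, offset in motifs:
            start = seq.find(motif)
            while start != -1:
                pos = start + offset
                if 0 < pos < n and pos not in cuts:
                    cuts[pos] = enz.name
                start = seq.find(motif, start + 1)
    return cuts


def digest_sequence(
    seq: SeqRecord,
    enzymes: Sequence[Enzyme] = DEFAULT_ENZYMES,
    mode: str = "complete",
    p: float | None = None,
    seed: int | None = None,
) -> list[Fragment]:
    """In-silico digestion of one sequence.

    ``mode="complete"`` realizes every cut; ``mode="partial"`` realizes each
    cut independently with probability ``p`` (seeded). Fragments are the
    intervals between consecutive realized cuts plus the two terminal
    intervals; each fragment records the enzyme of its bounding cut(s).
    """
    if not enzymes:
        raise ValueError("enzymes must be nonempty")
    cuts = _find_cut_sites(seq.sequence, enzymes)
    positions = sorted(cuts)
    if mode == "partial":
        if p is None or not 0 < p <= 1:
            raise ValueError("partial digestion requires 0 < p <= 1")
        rng = np.random.default_rng(seed)
        keep = rng.random(len(positions)) < p
        positions = [pos for pos, k in zip(positions, keep) if k]
    elif mode != "complete":
        raise ValueError(f"unknown digestion mode {mode!r}")

    bounds = [0, *positions, len(seq.sequence)]
    fragments = []
    for left, right in zip(bounds[:-1], bounds[1:]):
        fragments.append(
            Fragment(
                source_id=seq.id,
                start=left,
                end=right,
                sequence=seq.sequence[left:right],
                left_flank=cuts.get(left) if left > 0 else None,
                right_flank=cuts.get(right) if right < len(seq.sequence) else None,
            )
        )
    return fragments


def shear_sequence(
    seq: SeqRecord,
    n_fragments: int,
    length_mean: float,
    length_sd: float,
    seed: int | None = None,
) -> list[Fragment]:
    """Mechanical-shearing model: uniform starts, truncated-normal lengths.

    Lengths are drawn Normal(length_mean, length_sd) and clamped to
    [32, len(seq)]; a fragment is shifted left if it would overrun the 3' end.
    """
    n = len(seq.sequence)
    if n < 32:
        raise ValueError(f"sequence {seq.id!r} shorter than 32 bp cannot be sheared")
    if n_fragments < 1 or length_mean < 1:
        raise ValueError("n_fragments and length_mean must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = np.clip(
        np.rint(rng.normal(length_mean, length_sd, size=n_fragments)).astype(int), 32, n
    )
    fragments = []
    for length in lengths:
        start = int(rng.integers(0, n - length + 1))
        fragments.append(
            Fragment(seq.id, start, start + length, seq.sequence[start:start + length])
        )
    return fragments


def subsample_by_motif(
    fragments: Iterable[Fragment | SeqRecord],
    re1: Enzyme = NSI_I,
    re2: Enzyme = NLA_III,
    scheme: str = "RE1::RE2",
    min_len: int = 64,
) -> list[Fragment]:
    """Keep fragments by flanking-enzyme scheme and minimum length.

    ``RE1::RE2``: flank set exactly {re1, re2} (either orientation).
    ``RE1/2::RE1/2``: both flanks present and each in {re1, re2}.
    Inputs without flank annotations (plain reads) are completely digested in
    place and their interior sub-fragments classified instead.
    """
    if scheme not in ("RE1::RE2", "RE1/2::RE1/2"):
        raise ValueError(f"unknown subsampling scheme {scheme!r}")
    names = {re1.name, re2.name}
    kept: list[Fragment] = []
    for item in fragments:
        if isinstance(item, SeqRecord):
            candidates = digest_sequence(item, (re1, re2), mode="complete")
        else:
            candidates = [item]
        for frag in candidates:
            if len(frag) < min_len:
                continue
            flanks = (frag.left_flank, frag.right_flank)
            if any(f is None or f not in names for f in flanks):
                continue
            if scheme == "RE1::RE2" and set(flanks) != names:
                continue
            kept.append(frag)
    return kept


def quality_filter(
    reads: Iterable[SeqRecord], q: int = 20, max_frac: float = 0.20
) -> list[SeqRecord]:
    """Drop reads with more than ``max_frac`` of bases below quality ``q``.

    Both comparisons are strict: a base at exactly Q20 is not low-quality and
    a read at exactly 20% low-quality bases is kept. Reads without qualities
    pass through with a warning.
    """
    kept = []
    warned = False
    for read in reads:
        if read.qualities is None:
            if not warned:
                warnings.warn("reads without qualities pass the quality filter unchecked")
                warned = True
            kept.append(read)
            continue
        n_low = sum(1 for qual in read.qualities if qual < q)
        if n_low / len(read) > max_frac:
            continue
        kept.append(read)
    return kept


@dataclass
class ReadSimulation:
    """Simulated reads plus the ground truth needed for benchmarking."""

    reads: list[SeqRecord]
    truth: dict[str, int]                      # read_id -> source strain taxid
    fragments: dict[str, Fragment]             # read_id -> originating fragment
    member_counts: dict[int, int] = field(default_factory=dict)  # taxid -> reads emitted


def _phred_for_error_rate(e: float) -> int:
    if e <= 0:
        return 40
    return max(2, min(40, round(-10.0 * math.log10(e))))


def _apply_errors(seq: str, e: float, rng: np.random.Generator) -> str:
    if e <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < e)[0]
    if hit.size:
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for i in hit:
            choices = bases[bases != arr[i]]
            arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _member_fragments(
    member: CommunityMember,
    method: str,
    *,
    enzymes: Sequence[Enzyme],
    partial_p: float,
    partial_rounds: int,
    shear_mean: float,
    shear_sd: float,
    n_shear: int,
    rng: np.random.Generator,
) -> list[Fragment]:
    frags: list[Fragment] = []
    for rec in member.records:
        if method == "shotgun":
            frags.extend(
                shear_sequence(rec, n_shear, shear_mean, shear_sd,
                               seed=int(rng.integers(2**31)))
            )
        elif method == "complete_digest":
            frags.extend(digest_sequence(rec, enzymes, mode="complete"))
        elif method == "partial_digest":
            # pool several independent realizations: across molecules a partial
            # digest yields overlapping fragments, not one fixed tiling
            for _ in range(partial_rounds):
                frags.extend(
                    digest_sequence(rec, enzymes, mode="partial", p=partial_p,
                                    seed=int(rng.integers(2**31)))
                )
        elif method == "shotgun_then_digest":
            for sheared in shear_sequence(rec, n_shear, shear_mean, shear_sd,
                                          seed=int(rng.integers(2**31))):
                as_rec = SeqRecord(rec.id, sheared.sequence)
                for sub in digest_sequence(as_rec, enzymes, mode="complete"):
                    # lift coordinates back onto the genome
                    frags.append(Fragment(
                        rec.id, sheared.start + sub.start, sheared.start + sub.end,
                        sub.sequence, sub.left_flank, sub.right_flank,
                    ))
        else:
            raise ValueError(f"unknown simulation method {method!r}")
    return frags


def simulate_reads(
    community: CommunitySpec,
    method: str = "complete_digest",
    *,
    total_reads: int = 100_000,
    read_length: int | None = None,
    error_rate: float = 0.0,
    enzymes: Sequence[Enzyme] = DEFAULT_ENZYMES,
    partial_p: float = 0.5,
    partial_rounds: int = 10,
    scheme: str | None = None,
    min_fragment_len: int = 64,
    shear_mean: float = 150.0,
    shear_sd: float = 30.0,
    seed: int = 0,
) -> ReadSimulation:
    """Simulate a FASTQ read set from a defined community.

    Per-member read counts are round(total_reads x relative_abundance); reads
    are drawn uniformly with replacement from the member's fragment pool
    (after optional motif-scheme subsampling), truncated to ``read_length``
    from the 5' end when longer, and substitution errors applied at rate
    ``error_rate`` with matching PHRED qualities. Deterministic under seed.
    """
    rng = np.random.default_rng(seed)
    reads: list[SeqRecord] = []
    truth: dict[str, int] = {}
    frag_of: dict[str, Fragment] = {}
    member_counts: dict[int, int] = {}
    n_nonzero = sum(1 for m in community.members if m.abundance > 0)
    if total_reads < n_nonzero:
        warnings.warn("total_reads is below the number of community members")
    counter = 0
    for member in community.members:
        n_reads = round(total_reads * member.abundance)
        member_counts[member.taxid] = 0
        if n_reads == 0:
            continue
        pool = _member_fragments(
            member, method, enzymes=enzymes, partial_p=partial_p,
            partial_rounds=partial_rounds, shear_mean=shear_mean,
            shear_sd=shear_sd, n_shear=n_reads, rng=rng,
        )
        if scheme is not None:
            pool = subsample_by_motif(pool, enzymes[0], enzymes[1],
                                      scheme=scheme, min_len=min_fragment_len)
        if not pool:
            warnings.warn(f"member {member.taxid}: no fragments pass subsampling")
            continue
        if method in ("shotgun", "shotgun_then_digest"):
            # shearing already produced one fragment pool sized to the member;
            # emit it directly (digestion may have changed the count)
            chosen = pool if method == "shotgun_then_digest" else pool[:n_reads]
        else:
            idx = rng.integers(0, len(pool), size=n_reads)
            chosen = [pool[i] for i in idx]
        for frag in chosen:
            seq = frag.sequence
            if read_length is not None and len(seq) > read_length:
                seq = seq[:read_length]
            seq = _apply_errors(seq, error_rate, rng)
            qual = [_phred_for_error_rate(error_rate)] * len(seq)
            read_id = f"read{counter:07d}"
            counter += 1
            reads.append(SeqRecord(read_id, seq, qual))
            truth[read_id] = member.taxid
            frag_of[read_id] = frag
            member_counts[member.taxid] += 1
    return ReadSimulation(reads, truth, frag_of, member_counts)


def write_truth(truth: dict[str, int], path) -> None:
    with open(path, "w") as out:
        out.write("read_id\ttaxid\n")
        for read_id, taxid in truth.items():
            out.write(f"{read_id}\t{taxid}\n")


def load_truth(path) -> dict[str, int]:
    truth = {}
    with open(path) as handle:
        next(handle)
        for line in handle:
            read_id, taxid = line.rstrip("\n").split("\t")
            truth[read_id] = int(taxid)
    return truth


def write_fragments(fragments: Iterable[Fragment], path) -> None:
    """BED-like fragment table: source, interval, flanking enzymes."""
    with open(path, "w") as out:
        out.write("source_id\tstart\tend\tleft_flank\tright_flank\n")
        for f in fragments:
            out.write(
                f"{f.source_id}\t{f.start}\t{f.end}\t"
                f"{f.left_flank or '.'}\t{f.right_flank or '.'}\n"
            )


# ---------------------------------------------------------------------------
# Synthetic study community
# ---------------------------------------------------------------------------

def random_genome(length: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def mutate_sequence(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Per-base substitution at the given rate (expected identity 1-divergence)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < divergence)[0]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


@dataclass
class MockCommunity:
    """A ground-truthed community plus decoy genomes and their taxonomy."""

    community: CommunitySpec
    decoy_records: list[SeqRecord]
    taxid_map: dict[str, int]     # accession -> strain taxid (community + decoys)
    tree: TaxonomyTree

    @property
    def all_records(self) -> list[SeqRecord]:
        recs = [r for m in self.community.members for r in m.records]
        return recs + self.decoy_records


def make_mock_community(
    seed: int = 0,
    n_genomes: int = 10,
    genome_length: int = 50_000,
    n_congeneric_pairs: int = 3,
    pair_divergence: float = 0.05,
    n_decoys: int = 5,
    decoy_divergence: float = 0.07,
    abundance_span_orders: float = 3.0,
) -> MockCommunity:
    """Build the synthetic study community.

    Ten genomes across seven genera (three congeneric pairs at ~95% identity
    plus four singletons), two phyla, a full strain-to-phylum lineage for every
    genome, five sister-taxon decoy strains (~93% identity to a community
    genome, absent from the community), and relative abundances log-spaced
    over ``abundance_span_orders`` orders of magnitude.
    """
    if n_genomes < 2 * n_congeneric_pairs:
        raise ValueError("not enough genomes for the requested congeneric pairs")
    rng = np.random.default_rng(seed)
    n_genera = n_genomes - n_congeneric_pairs
    genus_of_genome: list[int] = []
    for g in range(n_congeneric_pairs):
        genus_of_genome += [g, g]
    genus_of_genome += list(range(n_congeneric_pairs, n_genera))

    # taxonomy scaffold: two phyla; one class/order per phylum; one family per genus
    nodes = [TaxonomyNode(1, 1, "root", "root")]
    phylum_ids, class_ids, order_ids = [], [], []
    for p in range(2):
        phylum_ids.append(10 + p)
        class_ids.append(20 + p)
        order_ids.append(30 + p)
        nodes.append(TaxonomyNode(10 + p, 1, "phylum", f"Phylum_{p}"))
        nodes.append(TaxonomyNode(20 + p, 10 + p, "class", f"Class_{p}"))
        nodes.append(TaxonomyNode(30 + p, 20 + p, "order", f"Order_{p}"))
    genus_ids, family_ids = [], []
    for g in range(n_genera):
        phylum = 0 if g < (n_genera + 1) // 2 else 1
        family_ids.append(400 + g)
        genus_ids.append(500 + g)
        nodes.append(TaxonomyNode(400 + g, order_ids[phylum], "family", f"Family_{g}"))
        nodes.append(TaxonomyNode(500 + g, 400 + g, "genus", f"Genus_{g}"))

    members: list[CommunityMember] = []
    sequences: list[str] = []
    base_of_genus: dict[int, str] = {}
    for i in range(n_genomes):
        g = genus_of_genome[i]
        species_id = 5000 + i
        strain_id = 50000 + i
        nodes.append(TaxonomyNode(species_id, genus_ids[g], "species",
                                  f"Genus_{g} species_{i}"))
        nodes.append(TaxonomyNode(strain_id, species_id, "strain",
                                  f"Genus_{g} species_{i} strain_{i}"))
        if g in base_of_genus:
            seq = mutate_sequence(base_of_genus[g], pair_divergence, rng)
        else:
            seq = random_genome(genome_length, rng)
            base_of_genus[g] = seq
        sequences.append(seq)
        members.append(CommunityMember([SeqRecord(f"G{i:02d}", seq)], strain_id, 0.0))

    # abundances: log-spaced spectrum, assigned in genome order
    raw = np.power(10.0, -np.linspace(0, abundance_span_orders, n_genomes))
    raw = raw / raw.sum()
    for member, ab in zip(members, raw):
        member.abundance = float(ab)

    decoy_records = []
    taxid_map = {m.records[0].id: m.taxid for m in members}
    for d in range(n_decoys):
        g = d % n_genera
        donor = genus_of_genome.index(g)
        species_id = 6000 + d
        strain_id = 60000 + d
        nodes.append(TaxonomyNode(species_id, genus_ids[g], "species",
                                  f"Genus_{g} decoy_species_{d}"))
        nodes.append(TaxonomyNode(strain_id, species_id, "strain",
                                  f"Genus_{g} decoy_species_{d} strain"))
        seq = mutate_sequence(sequences[donor], decoy_divergence, rng)
        rec = SeqRecord(f"D{d:02d}", seq)
        decoy_records.append(rec)
        taxid_map[rec.id] = strain_id

    community = CommunitySpec(members)
    return MockCommunity(community, decoy_records, taxid_map, TaxonomyTree(nodes))


def planted_hub_compositions(
    n_samples: int = 50,
    n_strains: int = 20,
    hub_size: int = 5,
    factor_sd: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
):
    """Multi-sample strain abundances with one planted correlated hub.

    Strains are organized two-per-genus across four phyla. The hub members
    are one strain from each of ``hub_size`` distinct genera (the genera
    rotating through the phyla, so the hub spans several phylum-level
    groups) and share a latent log-abundance factor; all other strains are
    independent log-normal noise. Returns (DataFrame samples x strain taxids
    of relative abundances, tree, hub strain taxids).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n_genera = n_strains // 2
    n_phyla = 4
    nodes = [TaxonomyNode(1, 1, "root", "root")]
    for p in range(n_phyla):
        nodes.append(TaxonomyNode(10 + p, 1, "phylum", f"Phylum_{p}"))
    strain_ids = []
    for g in range(n_genera):
        phylum = 10 + g % n_phyla
        nodes.append(TaxonomyNode(500 + g, phylum, "genus", f"Genus_{g}"))
        for s in range(2):
            sid = 5000 + 2 * g + s
            tid = 50000 + 2 * g + s
            nodes.append(TaxonomyNode(sid, 500 + g, "species", f"sp_{g}_{s}"))
            nodes.append(TaxonomyNode(tid, sid, "strain", f"st_{g}_{s}"))
            strain_ids.append(tid)
    tree = TaxonomyTree(nodes)

    # one strain per genus; consecutive genera already rotate through the
    # phyla, so the hub spans several phylum-level groups
    hub = [50000 + 2 * g for g in range(hub_size)]
    log_ab = rng.normal(0.0, noise_sd, size=(n_samples, n_strains))
    factor = rng.normal(0.0, factor_sd, size=n_samples)
    cols = {tid: i for i, tid in enumerate(strain_ids)}
    for tid in hub:
        log_ab[:, cols[tid]] += factor
    ab = np.exp(log_ab)
    ab = ab / ab.sum(axis=1, keepdims=True)
    df = pd.DataFrame(ab, columns=strain_ids,
                      index=[f"sample{i}" for i in range(n_samples)])
    return df, tree, hub
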