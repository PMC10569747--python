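# Methods

## Classification model

The engine classifies one read at one taxonomic rank from the set of its
*qualifying* alignment hits, then repeats independently for every rank of the
ladder strain → species → genus → family → order → class → phylum.

A hit qualifies when it is an exact local alignment — 100% identity, zero
mismatches, zero gap opens — of length ≥ `min_diagnostic_len` (32 bp), and,
when `fullqlen_alignment` is on (default), covers the entire read at strain
rank or at least `qcov` of it at coarser ranks. Each qualifying hit's subject
taxid is rolled up to the rank being profiled via the taxonomy; subjects
whose lineage lacks that rank are ignored there (they have no taxon to vote
for). The read is then:

* **assigned** if the projected taxon set has exactly one element
  (a *diagnostic read*);
* **no_hit** if the set is empty;
* **ambiguous_discard** if it has two or more elements.

There is deliberately no best-hit selection, no score tie-breaking, and no
lowest-common-ancestor fallback. Discarding ambiguity is the method: with
error-free reads whose source genomes are present in the reference, the true
taxon is always in the hit set (a read is a substring of its source), so an
assignment can never be wrong — precision is structural, and decoy genomes
can only convert assignments into discards, never into false positives.
The cost is recall in conserved regions, which shrinks as the rank coarsens
because congeneric subjects collapse into one taxon.

Because all ranks are classified from the same hit sets, the assigned-read
sets are nested finest ⊆ coarsest and coarse assignments equal the ancestors
of fine ones. This holds whenever every subject taxid carries a full
strain-to-phylum lineage (true for references built from strain genomes,
as here). A database mixing strain- and species-level subject taxids can
break the nesting: a species-level subject is ignored at strain rank but
votes at species rank. The engine accepts such databases; the nesting is
then a per-database property, not a theorem.

## Parameters

| name | default | meaning |
|---|---|---|
| `min_diagnostic_len` | 32 bp | minimum qualifying alignment length; also the seed k-mer size |
| `fullqlen_alignment` | true | require (near-)full query coverage |
| `qcov` | 0.97 | species-to-phylum coverage fraction; accepted range 0.95–0.99, the midpoint of which is the default since no single value is canonical |
| `reads_per_megablast_burn_in` | 0 | burn-in batch size; 0 disables, 1000 recommended when the reference is large |
| `cluster_identity` | 0.95 | greedy read-clustering threshold for burn-in representatives |
| `burn_in_identity` | 90% | relaxed identity of the burn-in screen (over ≥ 95% of the read — the coverage fraction is not canonical and is exposed as `min_cov`) |
| quality filter | Q20 / 20% | drop a read iff strictly more than 20% of bases are strictly below Q20 |
| `min_fragment_len` | 64 bp | digest fragments shorter than this are never retained |
| host filter | k=32, 50% | remove a read iff ≥ 50% of its canonical 32-mers occur in the host genome |

## Alignment

Matching is seed-and-extend over a canonical 32-mer index of the reference,
both strands, ungapped. The seed length equals the minimum diagnostic length,
so no qualifying hit can lack a seed, and the exact phase is equivalent to a
substring scan (verified against a naive oracle in the tests). Gapped
alignments are not searched: a gapped hit cannot be a 100%-identity
full-coverage hit, so nothing qualifying is lost; for the 90% burn-in screen
this is a documented simplification (ungapped identity only). `N` never
matches anything. Pre-computed hits in BLAST tabular format (12 columns, or
13 with `staxids`) are accepted in place of the internal matcher; subject
coordinates are normalized to plus-strand 0-based half-open intervals at
conversion.

The burn-in reduction clusters reads greedily (longest first, identity over
the shorter sequence), searches each representative at relaxed identity, and
keeps **all subjects of every taxon hit** — not only the hit subjects — so
the exact phase can still find a better subject inside a confirmed taxon.
On communities whose members all exceed the 90% screen the reduced and full
references yield identical profiles (asserted in the acceptance tests).

## Abundance profiles

A taxon's *locus* set is the union of maximal merged overlapping subject
intervals, per reference accession, over each assigned read's representative
hit (longest alignment, ties broken by leftmost interval then accession).
Mean depth per locus = assigned reads / locus count. This operationalizes
"read depth per locus" identically for restriction fragments (each fragment
is one locus) and shotgun pileups (coverage islands), with no annotation.
Percent-of-reads (share of the whole sample, classified + unclassified) is
also reported but is compositional and unusable across samples.

Benchmarking against a known community uses taxon sets at each rank:
precision = TP/(TP+FP), recall = TP/(TP+FN), and Pearson correlation between
true relative abundance and either estimate. False negatives are excluded
from the correlation (pairwise-complete) rather than zero-filled — recall
below 100% should not mechanically depress the abundance accuracy of the
taxa that were recovered; zero-filling is available via `include_missing`.
All arithmetic is full-precision; rounding happens only at presentation.

## Cross-rank validation

The phylum profile (coarsest, most reliable) serves as the baseline. Every
taxon of a finer profile is projected to its phylum ancestor; the FPR proxy
of rank L is the percentage of L's taxa whose ancestor is absent from the
phylum profile, and sensitivity is the percentage of phylum taxa covered by
L's projections. Flagged taxa are reported and optionally removed. On a
single consistent run with full lineages the FPR is 0 and sensitivity 100 at
every rank, which the acceptance tests assert exactly.

## Simulator

The simulator emulates defined mock-community sequencing:

* **shotgun** — uniform fragment starts, Normal(150, 30) lengths truncated to
  [32, genome length];
* **complete digest** — every restriction cut realized; fragments tile the
  genome exactly;
* **partial digest** — each cut realized independently with probability `p`
  (default 0.5 — no canonical value exists); fragments are pooled over 10
  independent realizations per genome, since across molecules a partial
  digest yields overlapping fragments rather than one fixed tiling;
* **shotgun + digest** — shear first, completely digest each read, keep the
  interior sub-fragments (how reduced-representation subsampling applies to
  experimental shotgun reads).

Default enzymes are NsiI (ATGCA^T) and NlaIII (CATG^), per REBASE; both
palindromic, so one-strand scanning finds every site (non-palindromic motifs
are additionally scanned on the reverse complement). Digest fragments carry
flank annotations and can be subsampled by scheme: `RE1::RE2` (one cut of
each enzyme) or `RE1/2::RE1/2` (any combination); fragments < 64 bp are
dropped. Reads are drawn per member in proportion to relative abundance
(round(total × abundance)), truncated 5′ to the read length when one is set,
and given uniform substitution errors at rate *e* with constant PHRED
qualities matching *e*. Ground truth (read → strain taxid) is emitted
alongside. One master seed drives child seeds for every stochastic step, so
outputs are byte-reproducible.

The standard study community is ten 50-kb i.i.d.-random genomes across seven
genera — three congeneric pairs mutated to ~95% identity, four singletons —
under two phyla with full seven-rank lineages, plus five decoy strains at
~93% identity to a community genome placed in sister species, and relative
abundances log-spaced over three orders of magnitude. 50 000 reads are used
for the headline precision/recall runs and 200 000 for abundance recovery;
these sizes give every member ≥ ~25 reads over its ~20 retained fragments
while keeping a run in seconds on one core.

**What the simulator does not emulate** — and what passing tests therefore do
not show about real data: indels and chimeric reads, PCR and GC bias, copy-
number variation, real genome repeat structure and horizontal transfer
(random genomes have no repeats, so diagnostic fragments are more abundant
than in real congenerics), database mis-annotation, and incomplete reference
assemblies. The precision guarantee specifically assumes error-free reads
and complete source genomes in the database; with sequencing errors,
precision decays with base-calling quality, which is why the stringent
quality filter sits in front of the classifier.

## Correlation networks

Profiles across samples are closed to relative abundances (mean depth per
locus per taxon), prevalence-filtered, and CLR-transformed — log of each
component over the row geometric mean — with zeros replaced by half the
sample's smallest nonzero value (multiplicative replacement available).
Pairwise Pearson on CLR columns, two-sided t-test p-values, Benjamini–
Hochberg across all pairs; an edge survives iff q ≤ `fdr` (0.05) and
|r| ≥ `r_min` (0.5). Bootstrap resampling of samples attaches an edge
stability fraction. *Hubs* are connected components of the positive-edge
subgraph with ≥ 3 members — the simplest reproducible formalization of
mutually co-occurring taxon groups; the sign summary (within-hub positive
fraction, between-hub negative fraction) is attached to the graph.

A latent-covariance compositional estimator (CCLasso-style) is intentionally
not implemented; the interface (abundance matrix in, network out) is
estimator-agnostic so one can be plugged in. Known artifact of the CLR +
Pearson stand-in: closure induces a baseline correlation of −1/(p−1) between
components, which slightly inflates the family-wise false-edge rate above
the nominal BH level in small-p panels and makes two-component compositions
degenerate (r ≡ −1); the planted-hub analyses therefore use panels with at
least four aggregated groups.

## Numerical and degenerate-input conventions

All internal coordinates are 0-based half-open; BLAST's 1-based inclusive
coordinates are converted at the boundary, minus-strand subject hits
normalized to plus-strand with a strand flag. Sequences are uppercased on
ingest; only {A,C,G,T,N} is accepted. Reads shorter than 32 bp are counted
`too_short`, not errors. Empty profiles validate to FPR 0 / sensitivity 0
with a warning; an empty phylum baseline skips validation. Abundance
correlations need ≥ 3 overlapping taxa, else they are reported missing.
Enzyme cut-coordinate collisions are resolved deterministically by enzyme
order; cuts at sequence termini are dropped (empty fragments cannot exist).
Ties in representative-hit choice break by leftmost subject interval, then
accession. The pipeline caches three checkpoints (simulate / filter /
classify) keyed by input checksums and the relevant configuration; reruns
with unchanged inputs are byte-identical and reported as cached.

## Known limitations

* Strain-level recall depends on isolate sequencing depth of the clade; taxa
  whose only distinguishing sites fall in unsequenced regions are
  systematically discarded (more species than strains will be recovered).
* The exact matcher is desk-scale: a hash-map 32-mer index over tens of
  megabases, not a production aligner; for large references, run a real
  MegaBLAST and feed the tabular output in via `--hits`.
* Ungapped burn-in identity underestimates similarity of indel-rich pairs;
  a genuinely present taxon diverged by indels could be dropped by the
  reduction (it would also not produce qualifying exact hits).
* The network stand-in estimates marginal CLR correlations, not direct
  interactions; hub membership is sensitive to `r_min` near the closure
  baseline −1/(p−1).
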