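# diagtax

Exact-match, diagnostic-read taxonomic binning and strain-level profiling of
metagenomes — with a built-in mock-community simulator (shotgun shearing and
complete/partial in-silico restriction digestion) so the whole pipeline can be
exercised and benchmarked without downloading anything.

## Who this is for

Microbiome and metagenomics researchers who need **strain-level** community
profiles from shotgun, amplicon, or reduced-representation (GBS/RADseq-style)
sequencing, and who care more about *not reporting wrong taxa* than about
squeezing out every last read. Mainstream read classifiers resolve multi-taxon
hits with best-hit scoring or lowest-common-ancestor (LCA) coarsening; the
first inflates false positives, the second destroys strain resolution. This
package takes the third road: discard the ambiguous reads entirely.

## The method

**Diagnostic reads.** A read is classified at a rank r ∈ {strain, species,
genus, family, order, class, phylum} only from *qualifying* hits: 100%
identity, no gaps, alignment length ≥ 32 bp, and — with full-query-length
matching on (the default) — covering 100% of the read at strain rank or ≥ 97%
(configurable within 95–99%) at coarser ranks. The hits' subject taxa are
rolled up to rank r; if they collapse to a **single** taxon the read is
*diagnostic* and counted for it, otherwise it is discarded. Each rank is
profiled independently over the same hit sets, so

  assigned(strain) ⊆ assigned(species) ⊆ … ⊆ assigned(phylum),

and each read's coarse assignment is the ancestor of its fine one.

**The precision guarantee.** An error-free read is a verbatim substring of
its source genome, so when the source is in the database the true taxon is
always in the hit-taxon set. A single-taxon hit set therefore can never name a
wrong taxon — precision is structurally 100% no matter how many near-identical
decoy genomes the database contains. Recall is what is traded: reads landing
in conserved regions are discarded as ambiguous.

**Abundance.** A taxon's abundance is its *mean read depth per locus*:
assigned reads divided by the number of merged subject intervals they cover.
Unlike percent-of-total-reads, this estimate supports relative abundance
across samples.

**Everything around the core:** burn-in database reduction (greedy 95%
clustering of reads → relaxed 90%-identity search with representatives → keep
all subjects of every taxon hit), exact k-mer host-read masking, PHRED
quality filtering (drop reads with > 20% of bases below Q20), cross-rank
validation of finer profiles against the phylum profile, precision/recall/
Pearson benchmarking against a known community, and CLR-based compositional
correlation networks with hub detection.

## Worked example

Build the standard synthetic study community — ten 50-kb genomes across seven
genera (three congeneric pairs at ~95% identity), five ~93%-identical
sister-taxon decoys, abundances log-spaced over three orders of magnitude —
simulate an error-free complete NsiI+NlaIII double digest keeping RE1::RE2
fragments ≥ 64 bp, and classify against community + decoys:

```python
from diagtax import build_reference_index, classify_and_profile
from diagtax.simulate import make_mock_community, simulate_reads
from diagtax.profiling import (precision_recall, truth_taxa_at_rank,
                               abundance_correlation)

mock = make_mock_community(seed=1)
sim = simulate_reads(mock.community, "complete_digest", total_reads=50_000,
                     scheme="RE1::RE2", min_fragment_len=64, seed=2)
index = build_reference_index(mock.all_records, mock.taxid_map)
result = classify_and_profile(sim.reads, index, mock.tree)

for rank in ("strain", "species", "genus", "phylum"):
    truth = truth_taxa_at_rank(set(sim.truth.values()), rank, mock.tree)
    pr = precision_recall(result.profiles[rank], truth)
    r = abundance_correlation(result.profiles[rank], mock.community.abundances,
                              mock.tree, mode="depth")
    r_txt = f"{r:.3f}" if r is not None else "n/a"
    print(f"{rank:8s} precision={pr.precision:5.1f}%  recall={pr.recall:5.1f}%  "
          f"pearson_depth={r_txt}")
print("strain-rank verdicts:", result.bin_result.summary["strain"])
```

prints

```
strain   precision=100.0%  recall=100.0%  pearson_depth=0.988
species  precision=100.0%  recall=100.0%  pearson_depth=0.988
genus    precision=100.0%  recall=100.0%  pearson_depth=0.997
phylum   precision=100.0%  recall=100.0%  pearson_depth=n/a
strain-rank verdicts: {'assigned': 49410, 'ambiguous_discard': 589, 'no_hit': 0, 'too_short': 0}
```

Reading it: every reported strain is a true community member (the decoys
attract zero assignments — the 589 reads whose fragments are shared with a
decoy or a congeneric partner are discarded, not misassigned); all ten
strains and species are recovered; depth-per-locus estimates track the true
three-orders-of-magnitude abundance spectrum at r ≈ 0.99. The phylum
correlation is undefined because only two phyla exist (fewer than three
points). The same run is available from the shell:

```bash
diagtax run -c config.yaml        # simulate → filter → bin → validate → profile → benchmark
diagtax simulate --community community.tsv --scheme RE1::RE2 --out reads.fastq
diagtax network --profiles out_s1 --profiles out_s2 ... --rank strain --outdir net/
```

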