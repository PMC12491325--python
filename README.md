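# thymosig

Signatures of thymic selection in T-cell receptor (TCR) repertoires.

During T-cell development, V(D)J recombination generates a vast diversity of
CDR3 loops; thymic selection then removes a large fraction of them before
they ever reach the periphery. Comparing a **pre-selection** repertoire
(random productive rearrangements from a generative model) with a
**post-selection** one (naive or singleton clonotypes) reveals what
selection keeps and what it discards: amino-acid and 3-mer composition
shifts, depletion of N-glycosylation sequons (N-X-[S/T], X ≠ P) and of
cysteine-bearing loops, coordinated shifts in Kidera factors per V/J pair,
charge/length/hydrophobicity changes, dense CDR3 similarity-graph clusters
enriched or depleted after selection, and — across individuals — an
HLA-haplotype imprint on which clusters survive.

`thymosig` is a tested, self-contained reimplementation of that analysis
for repertoire immunologists and methods developers. Because the original
cohorts are external, the package ships a first-class synthetic module: a
simplified V(D)J rearrangement simulator with exact junction bookkeeping
and a configurable survival filter that imposes *known* selection effects,
so every statistic can be validated by recovering what was imposed.

## What it computes

* **Neighbor enrichment (TCRNET-style).** For each CDR3 `x` with `d_fg`
  Hamming-distance-1 neighbors in the sample and `d_bg` in a control:

  `E[d] = d_bg · |fg|/|bg|`,  `log2FC = log2((d_fg+ψ)/(E[d]+ψ))`,
  `p = P[X ≥ d_fg]`, `X ~ Binomial(|fg|, max(d_bg,1)/|bg|)` (exact tail).

  Depletion is the same test with foreground and background swapped.
* **Motif clusters.** Connected components of the single-substitution graph
  over the top enriched CDR3s, with per-cluster position-weight matrices,
  consensus sequences and a TSV motif database.
* **Physicochemistry.** Per-CDR3 Kidera factors (10 published descriptors,
  not z-scored), Henderson–Hasselbalch net charge at pH 7 (Lehninger pKa,
  termini excluded), Kyte–Doolittle hydrophobicity; per-V/J-pair Welch
  t-tests with Cohen's *d* and the "selection force" (post/pre fraction
  ratio of the pair).
* **Motif scanning** with somatic-origin attribution: each sequon or
  sulfation-motif hit is mapped to the V, NDN or J nucleotide segment by a
  codon-majority rule (ground truth in simulated data).
* **Cohort divergence.** Subsample–pool–enrich–cluster, per-sample cluster
  occupancy, pairwise Jensen–Shannon divergence (base 2, in [0,1]) and a
  label-permutation test of within-pair vs between-pair distances.
* **Single-cell phenotype association.** Two-tailed Fisher exact tests of
  cluster membership × phenotype with Benjamini–Hochberg correction.
* **Loop geometry.** Backbone phi/psi from the four-atom torsion
  definition, Ramachandran-region classification (default: the mirror
  polyproline-II rectangle, phi ∈ [45°, 180°], psi ∈ [−180°, −90°]),
  5 Å CDR3β–peptide contact filtering, Cα PCA loop shapes, and the CD4/CD8
  conformation contrast (frequency ratio + Fisher p).

## Worked example

```python
import thymosig as ts
from thymosig import simulate as sim, stats as st

params = sim.default_params("TRB")                       # 20 V, 2 D, 12 J toy model
pre  = sim.generate_pre_selection(params, 20000, seed=42)
post = sim.generate_post_selection(params, sim.physchem_selection_spec(),
                                   20000, seed=43)

for prop in ("charge", "length", "hydrophobicity"):
    s = st.distribution_summary(pre, post, prop)
    print(f"{prop:15s} mean {s.mean_pre:7.3f} -> {s.mean_post:7.3f} "
          f"d = {s.cohen_d:+.3f}  tail mass {s.tail_mass_pre:.3f} -> {s.tail_mass_post:.3f}")
```

prints

```
charge          mean  -0.190 ->  -0.567 d = -0.390  tail mass 0.092 -> 0.075
length          mean  14.363 ->  13.439 d = -0.460  tail mass 0.070 -> 0.063
hydrophobicity  mean  -0.299 ->  -0.030 d = +0.515  tail mass 0.100 -> 0.122
```

i.e. the imposed selection filter is recovered with the signature seen in
real repertoires: net charge drops, the long-length tail is trimmed
(post-selection mass outside the pre-selection 5–95% band falls from 7.0%
to 6.3%), and mean hydrophobicity rises. The per-V/J Kidera-factor-4
volcano on the same pair gives 200 testable VJ pairs, 100% of them with
Cohen's d < 0 (median −0.61) — the downward shift is shared across every
pair, not driven by gene usage.

A command-line interface mirrors the library
(`thymosig simulate|io|compare|enrich|cluster|cohort|phenotype|structure|run`);
`thymosig run --stages simulate,compare,enrich,cluster --seed 0` executes
the end-to-end pipeline and writes a manifest that makes the run
bit-reproducible.

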