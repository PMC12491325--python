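# Methods

## The comparison being modelled

Thymic selection is treated as a black-box filter between two observable
repertoires: the productive output of V(D)J recombination (pre-selection)
and the naive peripheral pool (post-selection). Every analysis in the
package is a two-sample comparison across that filter — of feature
frequencies, physicochemical distributions, local similarity-graph density,
or cluster occupancy across donors. No parametric model of selection is
fitted; instead a synthetic filter with known parameters is used to verify
that each statistic recovers what was imposed.

## The rearrangement simulator

`thymosig.simulate` draws V, (D,) and J segments by usage probability,
trims each junction-facing end by a geometric deletion length
(`Geom(p) − 1`, so zero deletions have positive mass), inserts untemplated
nucleotides with a geometric length and a biased base composition, and
keeps junctions that are in frame, stop-free, start with the conserved Cys
and end with Phe/Trp. Rejection sampling (not reweighting) mirrors how
generative tools emit productive-only sequences. The V/NDN/J nucleotide
intervals of every junction are recorded exactly, which makes somatic-origin
attribution of motifs a ground-truth quantity rather than an inference.

The shipped toy parameter set (20 V, 2 D, 12 J for TRB; 20 V, 12 J for TRA)
uses real human terminal segment sequences where short enough, usage
probabilities of realistic unevenness, trimming parameters `p = 0.35–0.45`
(mean 1.2–1.9 nt deleted per end) and insertion parameter `p = 0.28`
(mean ≈ 2.6 nt per zone, G/C-biased composition). At these settings the
simulated TRB CDR3 length distribution (mean ≈ 14.4 aa, range 5–27) and
residue composition (N 3.2%, S 12.3%, G 13.7%) are close to published
repertoire statistics. These defaults are deliberately simplified — they
trade the position-dependent trimming tables of full generative models for
transparency and exact NDN bookkeeping; users can supply their own
parameters through the same JSON schema.

## The selection filter

A clonotype survives independently with probability

    base_rate · Π motif multipliers · Π sigmoid(−w·KF_i) · window(L) · tilt(V,J)

with all multipliers in [0, 1]. Motif penalties are regular expressions
applied once per sequence. A positive Kidera weight `w` penalizes sequences
with a high mean value of that factor (weight 6 on factor 4 moves the
post-selection mean by ≈ −0.5 pooled SD). The length window is a product of
two logistic edges; in the standard physicochemical spec the lower edge (5)
sits below the shortest productive junction so the window acts purely on
the long tail — winsorizing length rather than shifting it (an earlier
window overlapping the length mode shifted the distribution and inflated
the short tail, defeating its purpose). V/J tilts multiply a pair-,
V- or J-specific factor, used as a stand-in for haplotype-dependent
selection.

## Neighbor enrichment

The Hamming-1 neighbor index hashes each sequence once per position with
that position wildcarded; two same-length sequences differing at exactly
one position share exactly one key, so neighbor counts are exact in
O(N·L) without an all-pairs scan. The enrichment p-value is the exact
binomial tail `P[X ≥ d_fg]` with `X ~ Binomial(|fg|, max(d_bg, 1)/|bg|)`
over unique-sequence counts. The control rate is floored at one observable
neighbor: a control showing zero neighbors cannot witness a rate below
`1/|bg|`, and the unfloored plug-in rate declares every chance foreground
neighbor infinitely significant, destroying calibration under the null
(verified: with the floor, 20/20 neutral runs at n = 10⁴ produce zero
sequences passing log2FC > 2 and −log10 p > 12; without it, hundreds pass).
The fold-change pseudocount is 0.5; p-values never use pseudocounts.
Exact binomial p-values on small discrete counts are conservative and
non-uniform (large mass at p = 1) — calibration is therefore asserted at
the decision thresholds, not via a uniformity test.

## Clusters, occupancy, divergence

Clusters are connected components of the single-substitution graph over the
top-enriched sequences (ties in the top-N selection broken by larger fold
change, then lexicographic CDR3). Components are length-pure by
construction; singletons are discarded; numbering is by decreasing size
with lexicographic tie-break. PWMs have no pseudocount, so each position's
distribution sums to exactly 1.

Cluster occupancy counts the clonotypes of a sample falling in each cluster
(exact match by default; a Hamming-1 mode also counts neighbors). Samples
are compared by base-2 Jensen–Shannon divergence of their occupancy
distributions, and pair structure is tested by label permutation of the
(between − within) mean-JSD gap, add-one corrected.

## Study conditions for the synthetic cohort analyses

Simulations are sized so the whole battery runs on one CPU in minutes;
each condition was chosen once, as follows.

* **Sequon knockout:** survival multiplier 0.2 on `N[^P][ST]`, n = 50,000
  pre and matched post.
* **Physicochemical spec:** `[KR]` multiplier 0.4, Kidera-4 weight 6,
  length window (5, 16, 1.5), n = 20,000.
* **Neutral calibration:** 20 independent foreground/background pairs at
  n = 10⁴, thresholds log2FC > 2 and −log10 p > 12.
* **Twin cohort:** 3 pairs × 3 replicates of 15,000 post-selection CDR3s
  against a 100,000-sequence no-selection control. All pairs share a
  selection backbone (glycine-bearing CDR3s at multiplier 0.08; three
  common J-germline suffix motifs EAF/EQ/TQY at 0.08) — the shared part is
  what creates clusters detectable in the pooled cohort, since pool-level
  enrichment cancels effects that differ across samples. Each pair
  additionally down-tilts one third of the J genes (multiplier 0.15), a
  stand-in for a shared HLA haplotype, which leaves cluster detection
  nearly untouched but imprints pair-specific occupancy. Cluster thresholds
  for this analysis are depth-scaled to (log2FC > 1, −log10 p > 8, > 10
  members): the headline thresholds assume pools of ~3×10⁵ sequences per
  sample, where binomial tails reach 10⁻¹², while at 15k-deep samples the
  attainable tails are shallower; the neutral calibration above confirms
  nothing passes even (1, 6) under the null at comparable depth. Three
  replicates per pair (not two) are the minimum for a permutation p below
  0.01: with 2 replicates the permutations equivalent to the identity
  labelling are 48/720 ≈ 7% of the orbit, bounding p above 0.067.
  Occupancy of depleted clusters is counted over the Hamming-1
  neighborhood, because depleted members are by construction (nearly)
  absent from the samples themselves.
* **Structure cohort:** 80 + 74 synthetic loops (the scale of a curated
  TCR:pMHC structure set), background dihedrals in the β region, one
  region residue planted at 45% (CD8) vs 15% (CD4) frequency.

## What the generator does and does not emulate

It reproduces the *structure* of junctional diversity (segment choice,
trimming, insertion, productivity filtering, realistic length and
composition), which is what the comparison statistics consume. It does not
reproduce position-dependent trimming profiles, P(generation) of individual
sequences, donor-specific generation biases (exposed as parameter jitter,
off by default), sequencing error, or clonal expansion (all clonotypes are
singletons by design). Consequently, passing recoveries show that the
statistics detect imposed selection effects of realistic magnitude at
realistic diversity — not that the toy model is a calibrated human model.

One power limitation matters and is deliberate: N-glycosylation sequons in
TCR junctions are almost exclusively somatic (germline J regions contain
Asn but never N-X-[S/T]), so sequon-bearing junctions live in the sparsest
part of the similarity graph. At desk-scale sample sizes (5×10⁴ vs the
study-scale 10⁶–10⁷) several sequon 3-mers have single-digit counts and
sequon-bearing sequences have too few Hamming neighbors for the
per-sequence depletion test — the sequon signal is recovered as frequency
fold changes of supported 3-mers and as positional log-odds, not as
neighbor-graph depletion. This is a sample-size regime, not an estimator
choice; no parameter setting of this generator family escapes it.

## Numerical and convention choices

* Kidera factors: the published 10 × 20 table, means over residues, never
  z-scored. Shipped as versioned TSV; each factor is standardized over the
  20 residues (column means 0, SD 1), which the tests verify.
* Charge: Henderson–Hasselbalch over side chains only (the CDR3 is an
  internal loop), Lehninger pKa set, pH 7.0; EMBOSS pKa set and terminal
  contributions available as options.
* Hydrophobicity: Kyte–Doolittle by default; Hopp–Woods shipped.
* Frequency comparisons: pseudocount 1/|feature universe| by default.
* Welch t-test (unequal variances); Cohen's d with pooled SD; groups
  flagged degenerate (no p-value) only when both are constant.
* VJ-pair tests require ≥ 30 sequences per group per pair.
* Codon-majority rule (≥ 2 of 3 nt) maps a residue to V/NDN/J; boundary
  codons split 1/1/1 are "unknown".
* Torsions follow the IUPAC sign convention; the synthetic backbone
  builder uses ideal Engh–Huber geometry and trans peptide bonds, and
  round-trips prescribed (phi, psi) to < 10⁻¹³ degrees (1° tolerance is
  asserted, covering coordinate rounding in PDB files).
* PCA loop axes are sign-fixed (first loading ≥ 0) for comparability.
* Seeds: one global seed fanned out per stage through
  `SeedSequence(seed, spawn_key=(stage_id,))`; stage ids are frozen so
  adding a stage never reshuffles another stage's stream.

## Known limitations

* The toy generative model is not the calibrated human recombination
  model; absolute frequencies (e.g. sequon prevalence 0.6% of CDR3β) sit
  at the low end of published estimates.
* Sequon depletion via the neighbor-graph test needs study-scale sample
  sizes (see above).
* Exact-match occupancy is sparse for strongly depleted clusters; the
  Hamming-1 mode trades specificity for counts.
* The Ramachandran region rectangle is a configurable default; published
  analyses define the region graphically, not numerically.
* Logo rendering is a minimal matplotlib letter-stack, intended for quick
  inspection; the tested artifact is the PWM.
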