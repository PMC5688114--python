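# Methods

This note documents the models, conventions and numerical choices behind
`paleomt`, and what the synthetic-data tests do and do not establish about
real ancient-DNA data.

## Coordinates, windows and the reference

All positions are rCRS, 1-based; windows are inclusive on both ends. Three
HVS-I windows recur in serial mtDNA studies and are per-analysis
configuration here: 16048–16410 (diversity indices), 16056–16390 (the
default, used for distance and sharing analyses) and 16068–16365 (for
comparisons against heterogeneous modern datasets). The data model is
substitution-only: indels and heteroplasmies are ignored because every
statistic in the package operates on substitution haplotypes; positions read
as N or gap are tracked as *missing* and handled by pairwise deletion.

The packaged reference segment (`paleomt.reference`) is a **synthetic
stand-in** in rCRS coordinates: every position referenced by a motif, panel
diagnostic or standard variant token carries the genuine rCRS allele, the
rest is deterministic filler. Since all statistics operate on variant sets
relative to the reference (or on pairwise differences), the filler bases
never affect a result; the stand-in only needs internal consistency, which a
fixed generation seed guarantees.

## Haplogroup typing

The classifier scores a haplotype against each node of a compact haplogroup
tree with standard HVS-I motifs ("phylotree-lite", ~40 nodes covering the
25 analysis categories plus the H-PLEX17 H-subclades; JSON, fully
config-replaceable). The score of a node is computed on its cumulative
root-path motif: +1 per motif variant present, −1 per motif variant expected
but absent (missing positions are not penalised), private variants 0. The
call is the maximum-score node; ties break to the deeper node, then
lexicographically, so calls are deterministic and invariant under variant
permutation and addition of private variants. A haplotype with no positive
motif evidence — including the reference-identical haplotype — receives the
conventional `H-rCRS` fallback, which is uninformative below haplogroup H
without coding data.

Coding-SNP panels refine or contradict the HVS-I call: a panel-supported
subclade replaces a compatible ancestor (H → H1 on derived G3010A); support
on a different root-path sets the consistency flag false. The G3010A → H1
reading carries a recorded caveat (the variant also occurs in minor H
subclades per current builds of the mtDNA phylogeny). Panel *contents* are
editable configuration: only the T-Plex SNPs (C12633A→T1, A11812G→T2) and
G3010A→H1 are fixed by the source protocols; the remaining GenoCoRe22 /
H-PLEX17 / U-Plex entries packaged here are plausible standard diagnostics,
not a reprint of the assays.

## Frequency-based statistics

* **Frequency table.** Individuals roll up to a 25-category scheme via tree
  ancestry (U5 → U\*, N → N\*, unknown → `other`); the scheme is
  configuration.
* **PCA** is centered and *unscaled* on relative-frequency rows — the
  conventional default when the source configuration is unstated. Sign
  convention: the largest-magnitude loading of each component is made
  positive, so results are deterministic and invariant (up to sign) under
  category reordering. Scaling categories to unit variance would weight rare
  haplogroups up and can shift variance proportions; it is deliberately not
  done.
* **Ward clustering** uses Euclidean distances between frequency rows.
  Bootstrap support is the *plain* bootstrap proportion of replicate trees
  (categories resampled with replacement) containing each node's leaf set.
  Multiscale-bootstrap AU p-values are out of scope; plain support is
  systematically more conservative for small tables, which is the documented
  divergence from pvclust-style reports.
* **Fisher's exact test**: 2×2 tables use the exact two-sided hypergeometric
  test; r×c tables use margin-preserving Monte-Carlo (Patefield sampling via
  `scipy.stats.random_table`), `p = (1 + #{P(sim) ≤ P(obs)})/(B + 1)`,
  default B = 10⁵. Exact r×c enumeration is infeasible at the table sizes
  these studies use. A 1e−9 relative tolerance guards the ≤ comparison of
  table probabilities against floating-point ties.
* **Diversity**: Nei's unbiased Hd over distinct window-clipped haplotypes;
  π as mean pairwise proportion of differing sites with pairwise deletion;
  S as the count of positions with ≥2 observed bases.

## Test of population continuity

The null: two temporally successive samples come from one population whose
haplogroup frequencies changed only by drift. Per replicate the founding
frequency vector is drawn as `Multinomial(Ne, f̂_A)/Ne` — propagating the
sampling uncertainty of the earlier sample — then drifts
`t = round(years_gap / generation_time)` Wright–Fisher generations at
haploid effective size Ne (mtDNA is maternally inherited, so Ne is the
maternal effective size; default grid {1000, 10000}, generation time 25 y,
both configurable), and a sample of size `n_B` is drawn. The statistic is a
Nei-type G\_ST on haplogroup counts: `1 − H_S/H_T`, H\_S the mean unbiased
within-sample gene diversity, H\_T the gene diversity of mean frequencies.
The test statistic and founding layer are this package's concrete,
documented choices (the published protocol this emulates does not reprint
its statistic); both are swappable.

Numerical choice that matters: the *reported* G\_ST is clipped at 0, but the
p-value compares **raw** (unclipped) values between the observed pair and
the null replicates. Clipping creates a tie atom at 0 that makes the
Monte-Carlo p conservative — measured empirical level ≈ 0.012 at nominal
α = 0.05; with raw comparison the level is 0.038–0.054 across the
(Ne, t) calibration grid. p carries the +1 correction and is never exactly
0. Calibration is validated by generating the later sample with the *same*
drift-and-sample process the null simulates; power is validated on
full-replacement (fixation-flip) pairs.

## Shared-haplotype analyses

Two individuals share a lineage iff their variant sets clipped to the common
overlap window (intersection of all windows involved; default 16056–16390)
are identical; empty clipped sets are additionally qualified by the basal
haplogroup (H, V, HV kept distinct; other clades collapse to their
letter-level root), because an rCRS-like HVS-I sequence is compatible with
several clades and only coding data separates them. The plain SHA matrix
uses **column-group denominators** — entry (X, Y) is the percentage of Y's
individuals found in X's lineage set — the orientation under which every
entry is an integer multiple of 100/n\_column; individuals, not distinct
haplotypes, are the counting unit. The ancestral SHA credits each individual
to the earliest-ranked group containing their lineage; the diagonal is the
percentage of new lineages, and each row sums to 100.

Consistency caveat: the sum of a row's earlier-group credits equals the
percentage of its individuals whose lineage occurs in the *union* of earlier
lineage sets. This reduces to the plain-SHA entry of the immediately
preceding group only when older shared lineages are nested in that group —
published tables that mix pairwise-specific overlap windows can violate the
reduction, so the union identity is what the package tests.

## Sequence distances, ΦST, MDS, AMOVA

TN93 separates A↔G and C↔T transitions from transversions with
frequency-dependent coefficients; gamma rate heterogeneity replaces each
−ln(x) with `α(x^{−1/α} − 1)`. Shape α defaults to 0.117, the conventional
control-region value; 0.177 is selectable for mixed ancient/modern
comparisons (both values circulate for this marker; the package does not
adjudicate). Base frequencies are estimated from all sequences in the
comparison unless supplied. Degenerate compositions (a base class absent)
drop the corresponding terms; genuinely saturated pairs return a flagged
ceiling distance (10.0) rather than NaN. In the equal-frequency,
no-rate-variation limit the distance reduces to Jukes–Cantor
`−(3/4)ln(1 − (4/3)p)` (tested to <1e−6 relative error).

ΦST comes from the two-level squared-distance variance decomposition;
negative estimates are floored at 0 for reporting but retained raw
internally. Permutations reshuffle individuals between the two groups on the
fixed distance matrix (distances are not re-estimated per permutation);
p-values carry the +1 correction and are BH-adjusted across all pairs.
Three-level AMOVA uses the standard unequal-size coefficients; permutation
schemes are: whole populations among clusters (F\_CT), individuals among
populations within clusters (F\_SC), individuals among all populations
(F\_ST). A one-cluster partition falls back to the two-level decomposition.
The moment estimators' component sum equals the direct mean squared-distance
total only in expectation, not identically — the exact check is against
independent sum-of-squares arithmetic.

MDS: classical Torgerson double-centering is the default (deterministic,
exact for Euclidean input); Kruskal nonmetric scaling (stress-1, monotone
regression, seeded) is provided because published workflows differ and often
do not state their configuration. Negative input entries are floored at 0;
an all-zero matrix yields coincident points. Per-population subsampling
(default cap 140 sequences, seeded, without replacement) balances grossly
unequal sample sizes in large comparisons.

## Synthetic serial transect

The generator emulates the structure the analyses assume: a U-dominated
hunter-gatherer pool (U5b/U5a/U4/U2), a farmer pool (K/J/T2/H/N1a/V/X/HV/U3),
drift-derived later groups (via the same Wright–Fisher kernel the continuity
test uses, Ne = 1000 between periods in the packaged config), and lineage
transmission: each individual either copies a complete haplotype from a
realized member of an earlier group (with configured probability — the
signal SHA measures) or is drawn fresh from the group's haplogroup
frequency vector. Fresh individuals get the cumulative HVS-I motif of their
haplogroup plus Poisson(λ) private transitions (transitions only, matching
the control region's strong transition bias; default λ = 0.8, chosen to
give the many-singleton haplotype spectra and Hd ≈ 0.92–0.97 typical of
these datasets) at uniformly chosen non-motif window positions, and a
coding-SNP profile consistent with the haplogroup. Group sizes in the
packaged config (35/27/74/118/16) follow the serial sampling the analyses
target. Output is byte-identical under a fixed seed.

What the generator does **not** emulate: post-mortem damage and sequencing
error, heteroplasmy, indels, back-mutation and recurrent mutation at motif
positions (private mutations deliberately avoid all motif positions so
classification accuracy is measurable), within-group geographic
substructure, and realistic coalescent genealogies. Passing tests therefore
demonstrate the *statistical machinery* is correct and calibrated under the
stated model, not that classification or sharing estimates are robust to
aDNA damage or phylogenetic noise in real data.

## Degenerate inputs and tie-breaks (summary)

* Empty haplotype → `H-rCRS`; score ties → deeper node, then lexicographic.
* All-equal frequency rows → PCA returns zero variance proportions.
* Identical groups → Ward merges at height 0 (scipy's deterministic order).
* Zero-sum Fisher categories dropped; a table left with one row or column
  is fully determined by its margins → p = 1.
* G\_ST with both samples monomorphic in the same category (H\_T = 0) → 0.
* Saturated TN93 pairs → flagged ceiling, never NaN.
* ΦST of identical multisets ≤ 0 → reported 0; p near 1.

## Known limitations

* The motif tree is deliberately compact; haplotypes outside its coverage
  resolve to coarse categories or `other`. It is a configuration file, not a
  full phylogeny parser.
* Panel definitions are representative, editable approximations of the
  published multiplex assays.
* Bootstrap support values are plain proportions, not AU p-values.
* The continuity test conditions on the earlier sample and tests each Ne
  separately; it is not a likelihood or coalescent inference and does not
  estimate Ne.
* Geospatial interpolation/mapping of distances to modern populations is
  out of scope; the distance computation itself (window 16068–16365,
  α = 0.177, cap 140) is supported.
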