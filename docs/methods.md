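# Methods

`repadapt` tests whether distantly related plant species repeatedly reuse
the same gene families when adapting to climate. It implements the full
statistical chain from population allele frequencies to repeatedly
associated orthogroups (RAOs) and their gene-family properties, plus a
synthetic-data generator that reproduces the statistical structure each
stage assumes.

## 1. Climate variables

Each sampling site carries 19 bioclim-style summaries plus two *recent
change* variables. For each site, monthly maximum-temperature and
precipitation values pooled over the 1960s are compared with the 2010s by a
Mann–Whitney rank-sum test; the effect size

    r = |Z_W| / sqrt(n1 + n2)

(normal approximation with tie correction, **no** continuity correction)
is attached as `tmax_clim_change` / `prec_clim_change`. Pooling all 120
monthly values per decade (rather than matching calendar months) was an
open choice; we pool, because the rank-sum framework has no natural pairing
and the effect size is meant to summarise the whole distribution shift.
`r` is rank-based, hence invariant to monotone transforms and symmetric in
the decades. Sites missing a decade are skipped with a warning.

## 2. Genotype–environment association (GEA)

Per-site alternate-allele frequencies (from TSV, or computed from a VCF +
population map as alt-dosage / called alleles) are filtered on folded mean
frequency > 0.05 (and minor-allele count > 5 where counts exist). SNPs are
assigned to every gene whose interval, extended by 500 bp flanks, contains
them; a SNP in two overlapping flanked genes contributes to both
(the treatment of such SNPs is not settled in the field; the multimap is
this package's choice and is consistent between assignment and scoring).

Associations are Kendall tau-b correlations of frequency against each
climate variable separately, deliberately without population-structure
correction. P-values: exact enumeration (scipy) for n ≤ 9 tie-free sites,
tie-corrected normal approximation otherwise — sampling designs start at 5
sites, where the approximation alone would be poor. Constant inputs are
flagged degenerate with p = 1. P-values are then converted to empirical
p-values (rank/N, average ranks on ties) **within each (dataset, variable)
over the SNPs assigned to genes only**, so the uniform marginal the later
stages rely on holds on exactly the analysed SNP set. Because the largest
rank gives eP = 1 (unusable in a normal-quantile transform), eP is clamped
symmetrically into [1/(2N), 1 − 1/(2N)]; ranks are preserved.

## 3. Gene-level weighted-Z scores (WZA)

SNP eP values combine within a gene (plus flanks) as

    z_raw = Σ w_i Φ⁻¹(1 − eP_i) / sqrt(Σ w_i²),   w_i = p̄_i (1 − p̄_i),

weighting each SNP by its expected heterozygosity (the factor 2 cancels —
`z_raw` is invariant to uniform weight rescaling). Real genes differ in
SNP count, which makes the null variance of `z_raw` drift with gene length;
we remove this by robust standardisation within ~25 equal-occupancy
SNP-count bins (median, 1.4826·MAD; zero-MAD bins fall back to the global
scale; < 2 bins of genes falls back to global standardisation) with linear
interpolation of location and scale between bin centres. This binned
correction is distribution-free and is validated by calibration: on a
heteroscedastic null (variance ∝ SNP count) the corrected upper-tail p is
uniform and per-bin SDs return to ≈1. Anyone comparing intermediate
numbers against other implementations should note that a parametric
correction (e.g. a spline of variance on SNP count) would differ in detail
while targeting the same invariance. Species with several independent,
spatially non-overlapping datasets have per-gene p-values merged by
Fisher's method (χ² with 2k df) and re-ranked into a fresh empirical p.

## 4. Orthogroup repeatability (PicMin)

Orthogroup maps are filtered to ≤ 10 paralogues per species and ≥ 20
species (configurable; 19 is permitted to mirror the one-variable
exception in the original design). Per (orthogroup, species, variable) the
strongest paralogue signal is kept with a Dunn–Šidák correction,
`eP' = 1 − (1 − min eP)^k`, which is exactly uniform under a null of
independent-uniform paralogue scores.

The repeatability test on the n per-species values: sort, drop the
minimum (the null allows adaptation in ≤ 1 species), and score each
remaining order statistic `p_(a+1)` against the CDF of the a-th order
statistic of n − 1 uniforms, `q_a = I_{p_(a+1)}(a, n − a)`. The minimum
over a is Tippett-combined, `raw_p = 1 − (1 − min_a q_a)^n_eff`, where
`n_eff` is the effective number of independent tests estimated per
species-count configuration from the eigenvalues of the simulated
q-vector correlation matrix (Σ min(λ_i, 1), clipped to [1, n − 1]). Order
statistics are positively correlated, so `n_eff` ≪ n − 1 (≈ 7.4 at
n = 22). Any residual miscalibration of this choice is absorbed by the
next step, which makes the final p-values calibration-exact by
construction: `raw_p` is conservatively biased upward under the null
(mean ≈ 0.72 at n = 22–23), so each configuration's observed values are
re-ranked against 10⁶ simulated null orthogroups,
`calibrated_p = (1 + #{null ≤ raw}) / (1 + N_null)`. Benjamini–Hochberg
runs within each climate variable; q < 0.5 flags a RAO — deliberately
lenient, matched by permutation analysis of the total count. Ties in the
minimising index are broken toward the smallest rank (fewest species):
conservative attribution.

The minimising rank `a_star` estimates the number of contributing species
(`a_star + 1`, counting the dropped minimum); the contributing set is the
species with the `a_star + 1` smallest collapsed eP values (boundary ties
enlarge the set, logged). **Limitation:** when contributing species carry
extremely heavy-tailed-low eP values (e.g. Beta(0.1, 1), i.e. U¹⁰), the
Tippett minimum almost always lands at small a — the first order
statistics are astronomically small — so `a_star + 1` systematically
underestimates the true number of contributing species (≈ 4 estimated for
8 implanted in our recovery harness). Detection (sensitivity, FDR) is
unaffected; only the count estimate is biased. This is inherent to the
argmin-rank estimator, not a defect of the implementation.

Permutation enrichment regenerates i.i.d. uniform eP values over the fixed
orthogroup structure (regeneration and reshuffling of observed values are
equivalent only if observed ePs are exactly uniform; both interpretations
exist, regeneration is the default), reruns test → calibration → BH, and
counts flagged orthogroup-variable pairs; `p = (1 + #{null ≥ obs})/(1 +
n_perm)`. Totals count duplicates across variables; unique-orthogroup
counts are reported alongside. Leave-one-out reruns the full scan with
each species removed (orthogroups falling under the species floor drop
out for that rerun).

## 5. Functional enrichment

*Interactions.* To measure interactions **between** orthogroups, one random
gene per RAO orthogroup is drawn (within-orthogroup edges can never be
counted); edges with support > 0.4 among the drawn genes are counted, and
the observed statistic is the mean over 1,000 draws. The null draws
random non-RAO orthogroup sets of equal size (one gene-draw each; 10,000
sets), unmatched on orthogroup size — a size-matched mode is available.
Edge lists are consumed as generic weighted TSVs; no live database access.

*GO terms.* Each orthogroup's annotation is the deduplicated union of its
reference-species members' GO terms (no ancestor propagation — the
analysis is agnostic about which paralogue carries the relevant term).
Enrichment is the one-tailed upper hypergeometric p of RAO carriers given
background carriers, BH-corrected across terms, reported at FDR < 0.1.

## 6. Gene-family properties

*Tissue specificity.* Expression tables (gene × tissue × stage ×
subtissue TPM) are averaged over stages/subtissues; τ = Σ(1 − x_i)/(n − 1)
on max-scaled profiles (0 = broad/pleiotropic, 1 = single-tissue).
All-zero profiles are excluded with a warning.

*Centrality.* Co-expression edges with −5 < Z < 2.33 are discarded
(both retained signs contribute |Z| to strength and equally to paths).
Degree and strength are direct; closeness is 1/Σ(shortest-path distances
to reachable nodes) and betweenness the unweighted pass-through count
(networkx), isolated nodes scoring 0. Whether the original analyses
weighted path metrics is not documented; unweighted is the default, with a
1/|Z|-distance mode behind a flag.

*Orthogroup Z.* Per-gene values → rank eP oriented so the
most-pleiotropic extreme (low τ; high centrality) gets the lowest eP →
min over paralogues with Dunn–Šidák → rank-based inverse-normal transform
across orthogroups, explicitly standardised to mean 0/SD 1. Orthogroups
are grouped into deciles by their strongest repeatability evidence
(minimum PicMin p across variables; ties broken by orthogroup id for
determinism) and each decile is Stouffer-combined (Σz/√k, two-sided
normal p). A per-variable mode selects orthogroups with PicMin p < 0.005
within one variable instead.

*Duplications.* Events with node support > 0.7 whose species set overlaps
the GEA-contributing species are counted per orthogroup, separately
tallying species-specific events (all tips from one genome); per-decile
means are reported. Gene-tree inference itself is upstream and consumed
as a table.

## 7. Synthetic data

The generator produces every input file the readers consume, with the
structure the analysis assumes — not a population-genetic simulation
(no coalescent, no sequence reads; spatial structure is a shared per-site
random effect, one scalar per site weighted by `drift_sd`, because the
analysis only consumes frequency–climate covariance).

* Climate: one latent gradient per site; variables are
  √ρ·gradient + √(1−ρ)·noise, hitting pairwise correlation ≈ ρ
  (`climate_corr`, default 0.5 — correlated variables are the regime the
  multiple-variable bookkeeping must survive). Monthly decade series get
  site-specific 2010s shifts so the change variables vary across sites.
* Frequencies: logit-scale; base frequency clamped to [0.01, 0.99]
  before noise so MAF filtering does not annihilate loci. Adaptive SNPs
  add `effect_size` (default 2.0, logit slope per SD of climate) times the
  standardised coupled variable.
* Implants: a fraction of orthogroups (default 2.5%) gets
  `n_contributing_species` (default 8) species with one adaptive
  paralogue each; the gene-level eP generator instead draws contributing
  species' values from Beta(0.1, 1) (heavy mass near 0, continuous).
* Gene properties: Dirichlet expression profiles whose concentration
  (breadth) and network-degree propensity shift by `repeatability_link`
  for flagged orthogroups; one GO term is implanted in flagged
  orthogroups; duplication events scale with paralogue count.
* Defaults mirror the study shape where it is fixed (21 variables, 20–25
  species per orthogroup, ≤ 10 paralogues, ≥ 5 sites — we default to 20
  sites, a mid-range design) and otherwise sit at values a pooled-GEA
  study would call realistic (mean 6 SNPs/gene, drift SD 1.0 on the logit
  scale). The true effect-size regime of real adaptive loci is unknown;
  these are calibration choices, not estimates.

What passing synthetic tests do **not** show: robustness to genuine
population structure, linkage beyond gene boundaries, ascertainment in SNP
panels, or climate measurement error — none of which the generator
emulates.

## 8. Numerical and design choices

* Dunn–Šidák computed as `-expm1(k·log1p(-p))`; p = 1 handled; collapsed
  eP floored at the smallest positive double.
* Internal coordinates 0-based half-open; GFF3/VCF 1-based on disk.
* The empirical null store is seeded, persisted (`.npz`) and re-used;
  calibration is a binary search into the sorted store.
* BH is a vectorised step-up (oracle-checked against statsmodels); in null
  permutations only the rejection count is materialised.
* All generators take a single integer seed (or a `numpy` Generator);
  identical seeds give byte-identical output files.
* Problem sizes in the analysis drivers and test harnesses (500–8,470
  orthogroups, 10⁵–10⁶-row calibration nulls, 200–300 permutation
  replicates) were chosen so every stage's Monte-Carlo error is small
  against the tolerance it is checked to; the full-scale null expectation
  uses the same 8,470 × 21 × 20–25 geometry and 10⁶ calibration null as
  the real study.

## 9. Known limitations

* The SNP-count correction is a validated stand-in for an undocumented
  parametric correction; intermediate z-scores need not match other
  implementations numerically (final calibrated quantities are the
  comparable ones).
* The contributing-species count estimator underestimates under extreme
  implant distributions (see §4).
* GEA power varies with site count and allele-frequency resolution; the
  pipeline reports but does not model these.
* No phylogenetic weighting: repeatability treats species exchangeably;
  closely related species can in principle share signal through descent.
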