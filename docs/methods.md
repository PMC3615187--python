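# Methods

## Scope and data model

`tetralink` implements a community-ecology workflow that couples three
layers of observation on geothermal springs: aqueous chemistry (pH,
temperature, nine analytes), membrane-lipid composition (relative
abundances of the fourteen canonical isoprenoid tetraethers, measured
separately in the core and intact-polar fractions, with total and
archaeol concentrations in ng per g dry sediment), and archaeal
community structure (an ultrametric OTU phylogeny plus a site × OTU
relative-abundance table).  All between-sample inference flows through
labelled distance matrices (`skbio.DistanceMatrix`): Euclidean distances
for chemistry and lipid composition, Rao quadratic-entropy
dissimilarity for communities.

The packaged fixtures are the printed tables of a 27-spring Yellowstone
survey.  Two springs (E13, E23) yielded no lipids and are absent from
the lipid tables, so lipid analyses run on n = 25 and chemistry-only
analyses on n = 27; analyses drop springs per-layer rather than
restricting every layer to the common subset.

## Ring Index

RI = (Σ species weight × percent abundance) / 100, the denominator being
the literal constant 100 of the published formula rather than the row
sum — printed rows sum to 98–102 because of rounding, and only the
constant-100 convention reproduces the printed per-sample RI values.
Weights equal ring counts; the 4′/5′ regioisomers count 4/5.  Two
variants handle crenarchaeol (four cyclopentyl plus one cyclohexyl
ring): `as_published` excludes it, matching the published formula text,
while `cren_weight5` counts it and its isomer at five.  The printed
per-sample RI column is consistent with `cren_weight5` in 49 of 50 rows
at one printed decimal, with the 50th (polar E19) recomputing to exactly
2.75 from the rounded abundances — precisely half a printed unit from
the printed 2.7.  Because the inputs are themselves rounded to one
decimal, reproduction is asserted as |recomputed − printed| ≤ 0.05
rather than by re-rounding.  `cren_weight5` is the default; RI–pH
correlations are computed with `as_published`, which matches the
published formula and reproduces the printed correlations (−0.82 core,
−0.71 polar) within ±0.02, where the printed RI column itself does not.
The printed column is retained on parse (`ri_printed`) but never used in
computation.

## Below-detection substitution

Analytes recorded below detection are flagged on ingest and substituted
before distance construction.  The instrument limits are not recoverable
from the available record, so the default (`auto`) limit per analyte is
the smallest positive value observed for that analyte across the table —
deterministic from the data and of the right order of magnitude;
explicit limits can be supplied and must cover every flagged analyte.

## Mantel tests and model ranking

The Mantel r correlates the n(n−1)/2 lower-triangle entries; the null
permutes one matrix's rows and columns jointly; the test is two-sided on
|r| with the add-one estimator.  Both product-moment and rank (Spearman)
forms are implemented; the rank form ranks the condensed entries once
and permutes the ranks, which is exact because the entry multiset is
permutation-invariant.  The product-moment form is the contract default.
The reproduction pipeline uses the rank form: on the packaged data it
yields r² = 0.347 (core) and 0.173 (polar) against |ΔpH| and r = 0.730
between the core and polar matrices, matching the printed 0.36 / 0.17 /
0.73, whereas the product-moment form gives 0.313 / 0.159 / 0.725 and
misses the first.  The original analysis names its software but not the
correlation form; as with the Ring-Index variants, both are exposed and
the one the printed record reflects is used for reproduction.

AICc uses a Gaussian OLS likelihood on the unfolded pairs with
m = n(n−1)/2 treated as the sample size and k = 3 (intercept, slope,
error variance).  This is the conventional distance-regression
construction, but the original likelihood is unstated and pairs are not
independent, so ΔAICc values are meaningful as an ordering, not
digit-for-digit (recomputed core NO₂⁻ ΔAICc is 71.4 against a printed
95.9; the ordering and the support categories agree).  Support follows
ΔAICc < 2 (strong) and ΔAICc > 10 or p > 0.05 (none), the p-rule taking
precedence.  A perfect fit (RSS ≈ 0) reports AICc = −∞ with a warning.
Per-predictor permutation streams are derived from the seed and the
predictor name, so rankings and p-values are invariant to predictor
input order.

## Rao dissimilarity and ordination

D_kl = Σ_ij p_ik p_jl d_ij with d the patristic distance matrix
(dendropy); the returned dissimilarity is the discriminant form
H_kl = D_kl − (D_kk + D_ll)/2, zero on the diagonal and non-negative on
ultrametric trees; the raw D is exposed behind `form="raw"` since
community-phylogenetics programs differ in which they print.  Abundance
weighting is the default; a presence/absence mode substitutes uniform
weights over observed OTUs.  Tree tips absent from the community table
are pruned with a logged count; table OTUs absent from the tree are an
error.  Ultrametricity is checked within a relative tolerance of 1e-3
(rate-smoothed trees carry numerical slack) and violations warn rather
than fail; negative H beyond −1e-12 of the tree scale warns, and small
negatives are clipped to zero.

PCO Gower-centres −½D², eigendecomposes, scales positive-eigenvalue
eigenvectors by √λ, and reports percent variance over the positive
eigenvalues only; negative eigenvalues are reported, never corrected.
Each axis is oriented so its largest-magnitude coordinate is positive,
making output stable across eigensolvers.  The survey's printed PCO
figures (68.1 % on axis 1) depend on an undeposited community table and
are therefore exercised by round-trip and cross-library properties, not
by value.

## Synthetic data

The generator emulates the survey's structure, not its numbers.  Springs
draw pH and temperature uniformly on (2, 9.6) and (16, 87) °C; on the
log scale ammonium and ferrous iron fall with pH and nitrite rises
(slopes 0.35, 0.30, 0.35 per pH unit, lognormal noise SD 1.0, sized so
the pH–ln NH₄⁺ correlation sits near −0.6); other analytes are
independent lognormals at field-plausible scales.  Lipids follow a
target RI = 5.2 − 0.35·pH + N(0, 0.25) clipped to [0, 8] — slope and
spread chosen to bracket the fixtures' observed RI range of roughly
1.7–4.1 — spread over ring classes 0–8 as a discretised Gaussian
(SD 1.1 rings) and drawn from a Dirichlet (concentration 200) so
compositions live on the simplex by construction; the crenarchaeol share
of the five-ring class rises logistically with pH
(`cren_ph_strength = 0` flattens it, giving a clean null).  The polar
composition is a Dirichlet redraw centred on the realised core
composition with concentration set by `core_polar_coupling = 0.85`.
Trees are pure-birth with 31 tips rescaled to unit height; tip pH optima
evolve by Brownian motion (rate 1.5) and map affinely onto the pH range;
site abundances follow a Gaussian pH niche kernel (breadth 1 pH unit;
infinite breadth disables filtering).  amoA gene copies track
(carrier-OTU abundance × crenarchaeol concentration) with lognormal
noise plus a lognormal baseline; the carrier defaults to the deepest
tip.  Every stage draws from an independent stream derived from
(seed, stage name), so outputs are pure functions of the config.

What the generator does not emulate: sequencing noise and compositional
read-count artifacts, detection limits and censoring in the simulated
chemistry, spatial or temporal autocorrelation among springs, and any
lipid–community coupling beyond their shared pH driver.  Passing
recovery tests therefore show that the inference machinery detects the
planted structure at realistic n and noise — not that real surveys carry
that structure.

## Numerical and testing choices

Simulation sizes in the test-suite recovery checks: 100 seeds at the
default 27 springs for end-to-end model selection (pH selected for both
lipid and Rao responses in ≥ 95/100; a null with zero RI slope, flat
crenarchaeol, and no niche filtering selects pH within the central
99.9 % binomial band of the 1/11 chance rate), and n = 50 springs for
single-correlation null checks, where the sampling SD of r (~0.14)
sits well inside the 0.3 acceptance band.  Oracle comparisons use
explicit brute-force constructions (double-sum Rao, path-walk patristic
distances, exhaustive ≤ 6-site Mantel enumeration, normal-equations
OLS) at tolerances 1e-10 to 1e-8.  Permutation p-values with 999
permutations are compared to exhaustive enumeration within four
Monte-Carlo standard deviations.

## Known limitations

The AICc magnitudes and the Rao/PCO absolute values of the original
survey are not reproducible from the printed record (unstated
likelihood; undeposited community table) and are deliberately not
asserted.  Two internal inconsistencies of the printed record are
resolved in favour of the reproducible numbers and documented here: the
Ring-Index crenarchaeol treatment (text excludes it; printed values
include it at weight 5) and the total-lipid ratio correlation (the text
labels the ratio polar:core, but the printed correlations with pH
(−0.47) and temperature (+0.47) reproduce only with the core:polar
orientation; `polar_to_core_ratio` keeps the literal P:C contract and
the reproduction report computes both directions).
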