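# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limits of what the test suite demonstrates.

## Data model

A reaction record is one azole × amine amide coupling identified by
`(azole_id, amine_id)`, with the product SMILES and an optional LCAP yield on
the 0–100 percent scale. Missing labels are an explicit absent value, never
0, because 0 is a legal measured yield. Product SMILES supplied by the user
always take precedence; `assemble_product_smiles` is a convenience that bonds
the azole C2 (the ring CH between the two heteroatoms, located by the SMARTS
`[cH;r5](:[n;r5]):[o,s,nX3;r5]`) to a carbonyl carbon and on to the first
N–H nitrogen of the amine.

## Descriptors

* **Property vector**: the full RDKit `Descriptors.descList` registry (210
  descriptors in the pinned RDKit build); non-finite entries are flagged, not
  silently dropped.
* **Fingerprints**: MACCS (167 keys), RDK bond-path fingerprint (2048 bits,
  paths of up to seven bonds), Morgan (2048 bits, radius 2). RDK and Morgan
  fingerprints carry provenance: each on bit maps to the list of substructure
  occurrences (ordered bond-index tuples) that set it, extracted from the
  generator's bit-info map. Morgan radius-0 environments are single atoms;
  they carry an empty bond tuple and are excluded from bond attribution (their
  importance is routed to the heat's warning channel instead of being lost).
* **Coulomb matrix**: diagonal ½·Z^2.4, off-diagonal Z_i Z_j / r_ij with r in
  Å; the feature is the eigenvalue spectrum sorted by descending absolute
  value and zero-padded, which makes it invariant under isometries and atom
  reindexing. The diagonal exponent is the standard atomic-energy convention
  and is exposed as a module constant.
* **F2B (two-body forces)**: one feature per unordered element pair, the sum
  of inverse distances over all atom pairs with those elements (order-1
  Coulomb form). Pairs absent from a structure contribute 0.
* **MBTR**: concatenated Gaussian-smeared histograms of atomic numbers (k=1),
  pairwise inverse distances (k=2, a raw-distance toggle is provided since
  either axis convention is defensible) and triple-angle cosines (k=3), each
  on a fixed reference axis normalized to [0,1] (Z/100, (1/r)/2 Å⁻¹,
  (cos θ+1)/2) with 20 grid points per element combination, unit weighting
  and width 0.1. The grid extends four widths beyond the normalized axis so
  that the k=1 segment integrates to the per-element atom count to better
  than 1e-3 — fixed axes keep spectra comparable across molecules, which a
  per-structure axis range would break.
* **QM descriptors**: ingested, never computed — HOMO/LUMO energies, dipole,
  and the product-formation ΔG come from an external table;
  electronegativity χ = −(ε_HOMO+ε_LUMO)/2 and hardness
  η = (ε_LUMO−ε_HOMO)/2 are the Koopmans-style finite-difference forms (the
  conventional choice where only frontier energies are available). The
  solvent-mixture calculator is volume-fraction-weighted arithmetic averaging
  of pure-component dielectric constants and refractive indices, e.g. the 1:4
  DME/EtOAc blend gives ε = 6.26 and n = 1.374.
* Geometry provenance (force-field vs QM-optimized) is metadata, not
  enforced: the many-body descriptors accept any coordinates.

## Models

All families are scikit-learn estimators behind one `ModelConfig` surface.
Hyperparameters not fixed by the protocol stay at library defaults but are
frozen in `yieldmap/data/model_defaults.yaml` so results survive library
upgrades; two deliberate choices are the MLP solver (`lbfgs`, which converges
reliably at a few hundred samples where adam does not) and the Gaussian
process kernel (constant × Matérn + white noise, ≥5 optimizer restarts,
normalized targets). Seeds for stochastic families are part of the config and
default to a fixed constant.

Negative raw predictions are clipped to 0 in everything the package reports;
training objectives never see clipped values, and there is no clipping at
100. Metrics are computed on clipped predictions. Zero-variance feature
columns are retained (regularized families handle them; a warning lists
them) so feature indices always align with fingerprint bits.

The linear families (least squares, lasso, Bayesian ridge) expose a
`LinearFit` view — coefficients, intercept, noise variance, posterior
covariance — which is what the attribution mapper and the coefficient-shift
analysis consume. Bayesian ridge predictive standard deviations come from the
posterior predictive (reported pre-clipping).

## Evaluation protocols

* Metrics: AE50 (median absolute error; even counts take the midpoint of the
  central pair), MAE, RMSE, AEmax, and R² = 1 − SS_res/SS_tot with the sample
  mean in SS_tot. Constant-truth inputs make R² undefined; it is reported as
  NaN with a flag, and the error metrics are still returned.
* LOO refits n models, one per held-out record; per-fit failures are
  tolerated up to 10 % of records and reported, beyond which the run aborts.
* k-fold CV uses shuffled nearly-equal folds from a seeded permutation
  (k ≥ 2 enforced); the summary table appends mean/std rows across folds.
* The train/test split is seeded; the stratified option allocates test
  records proportionally over up to ten yield-quantile strata, approximating
  a representative test set.
* LOCO holds out every record involving one azole (or one amine), grouped by
  compound id — stereoisomer duplicates must carry distinct ids. Sorting the
  results by R² ranks compounds by out-of-sample predictability, and
  `coefficient_shift` ranks on-bit coefficient changes |ω_full − ω_loco| to
  explain failures.

## Synthetic data: what it emulates and what it does not

The generator draws azoles from a fragment grammar (thiazole / oxazole /
imidazole cores, a free C2–H, and halogen / alkyl / CF₃ / nitrile / aryl /
TMS substituents) and amines from a panel of secondary amines, assembles all
products combinatorially, and labels them with a planted linear model in
product-fingerprint space:

    yield = clip(ω₀ + Σ_{n ∈ active} ωₙ xₙ + ε, 0, 100),  ε ~ N(0, σ²).

Defaults: 40 active bits with library frequency in [0.1, 0.9], coefficients
~N(0, 3²) yield-percent per bit, intercept 50 %, σ = 3 % — a mid-scale
library with per-motif effects comparable to the noise, which keeps clipping
rare while leaving recovery non-trivial. Ground truth (active bits,
coefficients, noiseless yields) is written to a separate file so tests
cannot leak it into features.

**Identifiability.** Hashed fingerprint columns of a combinatorial library
are heavily aliased: duplicate columns (distinct substructures that always
co-occur) and nested bond paths make individual coefficients unrecoverable
in principle — a ridge fit splits a planted coefficient over its aliases by
data-dependent factors. The default bit selection therefore restricts active
bits to columns whose on/off pattern is unique in the library, and the
quantitative coefficient-recovery benchmark uses an independent Bernoulli
design with p = 128 < n = 200 where recovery is well-posed (the coefficient
scale was fixed by a power analysis of that design). On the molecular
library, recovery is asserted at the levels that are identifiable there:
prediction error (LOO MAE approaching σ·√(2/π)) and the correlation between
fitted and ground-truth bond heats.

Two stress fixtures reproduce known failure modes of substructure models:

* **Unseen motif**: one azole carries a TMS group found nowhere else, with a
  large planted coefficient on a bit unique to it. Azole-wise LOCO then has
  no training evidence for the motif and that compound's R² is strongly
  negative, while amine-wise LOCO (whose yield variation is driven by
  azole-level bits present in training) stays accurate — the qualitative
  signature of out-of-sample failure on unseen reactants.
* **Property cliff**: two azoles differing only in the ring heteroatom
  receive opposite yield offsets applied outside the planted linear
  structure, so no fingerprint bit explains them; LOO error on those records
  degrades relative to the rest.

Passing these tests shows the machinery behaves correctly under a linear
generative model with additive Gaussian noise. Real campaign data differ in
ways the generator does not emulate: non-additive motif interactions,
heteroscedastic and non-Gaussian LCAP noise, yield distributions massed near
0, and chemistry outside the toy grammar. Synthetic results say nothing
about the accuracy attainable on any real dataset.

## Attribution heat maps

Bond weights sum the full importance of every occurrence of every on bit
over the occurrence's bonds (an occurrence with k bonds contributes the
importance to each of its k bonds; a config switch divides by k instead).
This makes the brute-force identity exact: the total over bonds equals
Σₙ ωₙ × (bond multiplicity of n's occurrences). Bits with no usable
provenance — MACCS keys, collision-lost bits, atom-only environments — are
accumulated as warnings, never dropped silently; requesting bond attribution
for MACCS raises a capability error outright.

Color normalization is zero-anchored and asymmetric: negative weights are
scaled by the dataset minimum, positive ones by the dataset maximum, so zero
weight is always the neutral color even when the weight distribution is
one-sided (the one-sided branch falls back to unit slope). This is an
interpretive choice: normalizing to raw dataset extremes without an anchor
would let a nonzero weight appear neutral.

The SHAP backend computes exact interventional SHAP values for linear
models, φₙ = ωₙ(xₙ − mean background xₙ), which satisfy additivity to
machine precision and reduce to coefficient attribution up to the per-bit
background shift; the test suite cross-checks it against full 2⁶ Shapley
coalition enumeration.

**Limits of sign interpretation.** For a *fitted* model, the split of
predicted-yield mass between the intercept and the coefficient vector is
arbitrary, and aliasing spreads planted mass across correlated bits; both
inject a molecule-wide offset into bond weights (observed all-bond mean
weights ranged from −4 to +2 across planted seeds). The absolute sign of a
single fitted bond weight is therefore not reliable evidence of a motif's
direction — what is recoverable is the relative ordering, which the tests
assert as a strong correlation between fitted and ground-truth bond heats.
Heat maps should be read comparatively (which bonds are redder/bluer than
the rest of the dataset), which is exactly what the dataset-wide color
normalization presents. Fingerprint collisions add a second caveat: a bit
set by several distinct substructures cannot be attributed unambiguously,
and the collision report quantifies this per bit.

## Screening

External libraries are standardized (largest organic fragment; molecules
with metals, isotopes or MW > 900 Da rejected), filtered by the six
azole-amide SMARTS patterns, featurized from SMILES alone (geometry- and
QM-based descriptors are rejected for screening), and predicted with
uncertainties. The sixth pattern is shipped verbatim even though its
four-membered aromatic ring can match nothing; a `symmetrized` panel
substitutes the pattern consistent with its N-acyl counterpart, and the
choice is explicit at the call site. The chemical-space PCA standardizes
seven interpretable descriptors (MW, logP, TPSA, H-bond donors/acceptors,
rotatable bonds, aromatic rings — a documented assumption, configurable) on
the labeled reference set and projects query molecules into that basis, so
coverage is always judged relative to the training data. `design_variant`
performs a single-site motif replacement and guarantees only toolkit
sanitization, not synthesizability.

## Problem sizes and determinism

The shipped tests and the acceptance script run entirely on generated data:
a 20 × 10 library (n = 200) for recovery and LOO, 24 × 12 (minus one amine,
n = 264) for combinatorial bookkeeping, 12 × 5 panels with 32-bit
fingerprints for the cross-model grid comparison, and a p = 128 planted
design for coefficient recovery. These sizes were chosen so the full suite
and the acceptance script each complete in a few minutes on a single CPU
while keeping every statistical margin wide. All randomness flows from
explicit seeds; reruns with the same seed are bit-identical, including the
rendered SVG heat maps.

## Known limitations

* Quantum-chemistry outputs are ingested, never computed; there is no
  conformer search or thermochemistry.
* `assemble_product_smiles` picks the first matching C2/N–H site;
  polyfunctional reactants should come with curated product SMILES.
* The RDK-fingerprint hash is toolkit-internal: provenance soundness is
  tested (re-hashing an extracted substructure reproduces its bit), but bit
  indices are not portable across RDKit versions.
* LOCO grouping is by compound id, not structural identity.
* The MLP and tree families have no uncertainty and no attribution path;
  they exist for the model comparison only.
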