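# yieldmap

Interpretable reaction-yield prediction for C2-carboxylated 1,3-azole amides,
with bond-level attribution heat maps for rational molecular design.

## The problem

High-throughput coupling campaigns pair panels of 1,3-azoles (imidazoles,
oxazoles, thiazoles) carboxylated at C2 — the ring carbon between the two
heteroatoms — with secondary amines, and report LCAP yields
(liquid-chromatography area percent, 0–100 %) for each azole × amine product.
Synthetic chemists planning the next campaign want three things from such
data: a yield prediction for an untested product, an uncertainty on that
prediction, and an explanation — *which structural motif is helping or
hurting the yield?*

`yieldmap` covers that pipeline end to end:

* **chemdata** — reaction tables (CSV), combinatorial azole × amine datasets,
  amide-product assembly from reactant SMILES, XYZ geometry I/O;
* **descriptors** — RDKit property vectors, MACCS/RDK/Morgan fingerprints with
  *bit provenance* (every "on" bit mapped to the bond paths that set it),
  Coulomb-matrix eigenspectra, two-body-force (F2B) and MBTR many-body
  descriptors, QM-property ingestion, and the solvent-mixture parameter
  calculator;
* **modeling** — seven regression families (least squares, lasso, Bayesian
  ridge, random forest, Gaussian process, gradient boosting, MLP) with yield
  clipping at 0, posterior predictive uncertainties, and a descriptor × model
  grid search;
* **evaluation** — AE50/MAE/RMSE/AEmax/R² metrics, seeded train/test splits,
  leave-one-out (LOO), 5-fold CV, leave-one-compound-out (LOCO), and
  coefficient-shift analysis;
* **pixie** — the attribution heat mapper: per-bond weights obtained by
  summing the importances (linear-model coefficients or SHAP values) of all
  on-bit substructures containing that bond, with dataset-wide color
  normalization, fingerprint-collision diagnostics and SVG rendering;
* **screening** — SMARTS-filtered screening of external SMILES libraries with
  predictions, uncertainties, heat maps and PCA chemical-space coverage;
* **synthetic** — a combinatorial library generator whose yields are a planted
  linear function of fingerprint bits, so every stage is testable without any
  external download.

## The model

For a product molecule with fingerprint bits {xₙ} a linear model predicts

    ŷ = ω₀ + Σₙ ωₙ xₙ ,        ŷ ← max(ŷ, 0)

and each coefficient ωₙ is the yield contribution (in percent) of the
substructure that sets bit n. The heat mapper assigns every bond *b* the
weight

    w(b) = Σₙ Σ_{o ∈ occ(n)} ωₙ · 1[b ∈ bonds(o)]

— the sum of importances of all on-bit substructure occurrences containing
that bond — and renders weights as a diverging blue–white–red map (red:
motif raises predicted yield; blue: lowers it). Bayesian ridge regression is
the default family: it is linear (interpretable coefficients) and yields
posterior predictive standard deviations. Because hashed fingerprints
collide, a collision report counts how many distinct substructures share
each bit across a dataset.

## Worked example

Simulate a labeled 8 × 6 combinatorial library, grid-search two descriptors
against two linear families with LOO validation, and render heat maps:

```bash
yieldmap simulate   --outdir sim  --seed 5 --n-azoles 8 --n-amines 6
yieldmap gridsearch --table sim/reactions.csv --outdir grid --seed 5 \
    --descriptor rdk --descriptor morgan --model bayesian_ridge --model lasso
yieldmap heatmap    --table sim/reactions.csv --outdir heat --seed 5 --limit 2
```

which prints

```
wrote 48 labeled reactions to sim/reactions.csv
wrote 4-row grid table to grid/grid_search.csv
rendered 2 heat maps (scale -6.75 .. 24.26)
```

and `grid/grid_search.csv` contains one row per descriptor × model pair
(values in yield percent):

| descriptor | model          | AE50 | MAE  | RMSE | AEmax | R²   |
|------------|----------------|------|------|------|-------|------|
| rdk        | bayesian_ridge | 2.75 | 3.63 | 4.56 | 13.42 | 0.58 |
| rdk        | lasso          | 3.61 | 4.23 | 5.26 | 13.28 | 0.44 |
| morgan     | bayesian_ridge | 2.88 | 3.74 | 4.79 | 13.03 | 0.53 |
| morgan     | lasso          | 4.61 | 5.46 | 6.81 | 16.58 | 0.06 |

The simulated labels carry Gaussian noise of σ = 3 %, so a LOO MAE of ~3.6 %
for Bayesian ridge on RDK fingerprints is close to the irreducible error
σ·√(2/π) ≈ 2.4 %; the heat-map scale line reports the smallest and largest
bond weights across the rendered set, which anchor the blue and red ends of
the color bar. Each command also writes a `manifest.json` (seed, config
hash, library versions) so identical manifests imply identical outputs.

To use measured data instead of simulations, supply your own reaction table
(`azole_id, amine_id, product_smiles, yield_lcap` — arbitrary headers via a
column map) to the same commands, and a one-SMILES-per-line library file to
`yieldmap screen`.

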