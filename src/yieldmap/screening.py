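"""Substructure-filtered library screening with predictions, uncertainties,
heat maps, and PCA chemical-space coverage.

An external SMILES library is standardized (largest organic fragment, no
metals/isotopes, MW <= 900), filtered to 1,3-azole amides by a fixed SMARTS
panel, featurized, and pushed through a fitted model; optional bond heat maps
accompany each retained molecule.  A PCA fitted on the labeled reference set
places library molecules in the training chemical space to judge coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski, rdMolDescriptors
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from .chemdata import ReactionDataset, ReactionRecord
from .descriptors import SMILES_ONLY_KINDS, featurize_dataset
from .exceptions import AmbiguityError, CapabilityError, ConfigurationError, ValidationError
from .modeling import FitResult, predict, predict_with_uncertainty
from .pixie import BondHeat, bond_weights, fit_color_scale

__all__ = [
    "AZOLE_AMIDE_SMARTS",
    "AZOLE_AMIDE_SMARTS_SYMMETRIZED",
    "ScreenResult",
    "ChemSpaceProjection",
    "standardize_library",
    "substructure_filter",
    "screen_library",
    "pca_projection",
    "design_variant",
]

#: the six azole-amide SMARTS, verbatim; note the last imidazole pattern is
#: written with a 4-membered ring and matches nothing aromatic — kept as-is for
#: fidelity, with a symmetrized alternative below.
AZOLE_AMIDE_SMARTS = (
    "O=C(N)c1nccs1",
    "O=C(n)c1nccs1",
    "O=C(N)c1ncco1",
    "O=C(n)c1ncco1",
    "O=C(N)c1nccn1",
    "O=C(n)c1ncn1",
)
#: same panel with the last pattern rewritten to mirror its N-acyl counterpart
AZOLE_AMIDE_SMARTS_SYMMETRIZED = AZOLE_AMIDE_SMARTS[:5] + ("O=C(n)c1nccn1",)

MAX_LIBRARY_MW = 900.0

#: default descriptor subset for chemical-space PCA.  The choice of seven
#: interpretable size/polarity/flexibility descriptors is an assumption of this
#: package, exposed as a parameter.
PCA_DESCRIPTOR_NAMES = (
    "MolWt",
    "MolLogP",
    "TPSA",
    "NumHDonors",
    "NumHAcceptors",
    "NumRotatableBonds",
    "NumAromaticRings",
)

_PCA_DESCRIPTOR_FNS = {
    "MolWt": Descriptors.MolWt,
    "MolLogP": Crippen.MolLogP,
    "TPSA": rdMolDescriptors.CalcTPSA,
    "NumHDonors": Lipinski.NumHDonors,
    "NumHAcceptors": Lipinski.NumHAcceptors,
    "NumRotatableBonds": Lipinski.NumRotatableBonds,
    "NumAromaticRings": rdMolDescriptors.CalcNumAromaticRings,
}


@dataclass
class ScreenResult:
    smiles: str
    matched_smarts: tuple[str, ...]
    predicted_yield: float
    uncertainty: float | None = None
    heat: BondHeat | None = None


@dataclass
class ChemSpaceProjection:
    loadings: np.ndarray
    reference_scores: np.ndarray
    query_scores: np.ndarray | None
    explained_variance_ratio: np.ndarray
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray


def standardize_library(smiles_list: Sequence[str]) -> list[str]:
    """Keep the largest organic fragment; reject metals, isotopes, MW > 900."""
    organic = {1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 34, 35, 53}
    kept: list[str] = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        frags = Chem.GetMolFrags(mol, asMols=True)
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
        atoms = list(mol.GetAtoms())
        if any(a.GetAtomicNum() not in organic for a in atoms):
            continue
        if any(a.GetIsotope() != 0 for a in atoms):
            continue
        if Descriptors.MolWt(mol) > MAX_LIBRARY_MW:
            continue
        kept.append(Chem.MolToSmiles(mol))
    return kept


def substructure_filter(
    smiles_list: Sequence[str], smarts_patterns: Sequence[str] = AZOLE_AMIDE_SMARTS
) -> list[tuple[str, tuple[str, ...]]]:
    """Retain molecules matching >= 1 pattern; record all matching patterns."""
    compiled = []
    for patt in smarts_patterns:
        q = Chem.MolFromSmarts(patt)
        if q is None:
            raise ConfigurationError(f"SMARTS pattern {patt!r} does not parse")
        compiled.append((patt, q))
    retained = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        hits = tuple(patt for patt, q in compiled if mol.HasSubstructMatch(q))
        if hits:
            retained.append((smi, hits))
    return retained


def _library_dataset(smiles: Sequence[str]) -> ReactionDataset:
    records = [
        ReactionRecord(azole_id=f"lib{i}", amine_id="0", product_smiles=s)
        for i, s in enumerate(smiles)
    ]
    return ReactionDataset(records, provenance="screening library")


def screen_library(
    fit: FitResult,
    smiles_list: Sequence[str],
    descriptor_kind: str,
    descriptor_options: dict | None = None,
    smarts_patterns: Sequence[str] = AZOLE_AMIDE_SMARTS,
    with_heatmaps: bool = False,
    standardize: bool = True,
) -> tuple[list[ScreenResult], dict[str, float]]:
    """Filter -> featurize -> predict (with uncertainty when available).

    Only SMILES-computable descriptor kinds are allowed; geometry- or
    QM-table-based kinds cannot be evaluated on a bare SMILES library.
    """
    if descriptor_kind not in SMILES_ONLY_KINDS:
        raise CapabilityError(
            f"descriptor {descriptor_kind!r} needs geometries or QM tables; "
            f"screening supports {SMILES_ONLY_KINDS}"
        )
    pool = standardize_library(smiles_list) if standardize else list(smiles_list)
    matched = substructure_filter(pool, smarts_patterns)
    if not matched:
        return [], {}
    dataset = _library_dataset([s for s, _ in matched])
    matrix = featurize_dataset(dataset, descriptor_kind, descriptor_options)
    try:
        means, stds = predict_with_uncertainty(fit, matrix.values)
        stds_list: list[float | None] = list(map(float, stds))
    except CapabilityError:
        means = predict(fit, matrix.values)
        stds_list = [None] * len(means)

    heats: list[BondHeat | None] = [None] * len(means)
    if with_heatmaps:
        if matrix.fingerprints is None or fit.linear_view is None:
            raise CapabilityError("heat maps need a fingerprint descriptor and a linear fit")
        heats = [
            bond_weights(fp, fit.linear_view.coefficients) for fp in matrix.fingerprints
        ]
    results = [
        ScreenResult(
            smiles=smi,
            matched_smarts=hits,
            predicted_yield=float(m),
            uncertainty=s,
            heat=h,
        )
        for (smi, hits), m, s, h in zip(matched, means, stds_list, heats)
    ]
    summary = {
        "n_retained": float(len(results)),
        "yield_min": float(np.min(means)),
        "yield_max": float(np.max(means)),
    }
    defined = [s for s in stds_list if s is not None]
    if defined:
        summary["uncertainty_min"] = float(np.min(defined))
        summary["uncertainty_max"] = float(np.max(defined))
    return results, summary


def _pca_features(smiles: Sequence[str], names: Sequence[str]) -> np.ndarray:
    rows = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValidationError(f"SMILES {smi!r} does not parse")
        rows.append([float(_PCA_DESCRIPTOR_FNS[n](mol)) for n in names])
    return np.array(rows)


def pca_projection(
    reference_smiles: Sequence[str],
    query_smiles: Sequence[str] | None = None,
    n_components: int = 2,
    feature_subset: Sequence[str] = PCA_DESCRIPTOR_NAMES,
) -> ChemSpaceProjection:
    """PCA fitted on the standardized reference set; queries projected in its basis.

    Constant features are dropped with a warning before standardization.
    """
    unknown = set(feature_subset) - set(_PCA_DESCRIPTOR_FNS)
    if unknown:
        raise ConfigurationError(f"unknown PCA descriptors {sorted(unknown)}")
    names = list(feature_subset)
    ref = _pca_features(reference_smiles, names)
    keep = ref.std(axis=0) > 0
    if not np.all(keep):
        import warnings

        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping constant PCA features {dropped}", stacklevel=2)
        names = [n for n, k in zip(names, keep) if k]
        ref = ref[:, keep]
    if n_components > min(ref.shape):
        raise ConfigurationError("n_components exceeds min(rows, selected features)")
    scaler = StandardScaler().fit(ref)
    pca = PCA(n_components=n_components, random_state=0).fit(scaler.transform(ref))
    query_scores = None
    if query_smiles is not None:
        query = _pca_features(query_smiles, names)
        query_scores = pca.transform(scaler.transform(query))
    return ChemSpaceProjection(
        loadings=pca.components_,
        reference_scores=pca.transform(scaler.transform(ref)),
        query_scores=query_scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        feature_names=names,
        scaler_mean=scaler.mean_,
        scaler_scale=scaler.scale_,
    )


def design_variant(base_smiles: str, remove_motif: str, insert_fragment: str) -> str:
    """Replace a uniquely matched motif with a fragment (attached via its first atom).

    No chemical-feasibility claim is made beyond toolkit sanitization.
    """
    mol = Chem.MolFromSmiles(base_smiles)
    if mol is None:
        raise ValidationError(f"SMILES {base_smiles!r} does not parse")
    query = Chem.MolFromSmarts(remove_motif)
    if query is None:
        raise ConfigurationError(f"SMARTS {remove_motif!r} does not parse")
    matches = mol.GetSubstructMatches(query)
    if len(matches) != 1:
        raise AmbiguityError(
            f"motif {remove_motif!r} matched {len(matches)} sites in {base_smiles!r}; need exactly 1"
        )
    replacement = Chem.MolFromSmiles(insert_fragment)
    if replacement is None:
        raise ConfigurationError(f"fragment {insert_fragment!r} does not parse")
    products = AllChem.ReplaceSubstructs(mol, query, replacement, replaceAll=False)
    if not products:
        raise AmbiguityError("substructure replacement produced no product")
    product = products[0]
    try:
        Chem.SanitizeMol(product)
    except Exception as exc:
        raise ValidationError(f"edited molecule failed sanitization: {exc}") from exc
    return Chem.MolToSmiles(product)
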