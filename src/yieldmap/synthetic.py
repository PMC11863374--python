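"""Synthetic combinatorial reaction libraries with planted linear structure.

A fragment grammar over thiazole/oxazole/imidazole cores and secondary amines
generates azole and amine panels; products are assembled and labeled by a
planted linear model in fingerprint space,

    yield_i = clip(intercept + sum_{n in active} w_n x_{i,n} + eps_i, 0, 100),

with seeded Gaussian noise.  Ground truth (active bits, coefficients,
noiseless yields) is exported separately so tests cannot leak it into
features.  Beyond the standard generator, two stress fixtures reproduce known
failure modes of substructure-based yield models: an azole carrying a motif
absent from the rest of the library (out-of-sample LOCO failure) and a
property-cliff pair of near-identical azoles with opposite yield offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .chemdata import ReactionDataset, build_combinatorial_dataset
from .descriptors import compute_fingerprint
from .exceptions import CapacityError, PlantingError, ValidationError

__all__ = [
    "PlantedModel",
    "generate_panels",
    "make_planted_model",
    "plant_and_label",
    "planted_binary_design",
    "loco_stress_fixture",
    "property_cliff_fixture",
    "AZOLE_CORE_SMARTS",
]

# azole cores with a free C2-H; substituent prefixed on C5
_CORES = ("c1cscn1", "c1cocn1", "c1c[nH]cn1")
_SUBSTITUENTS = (
    "",
    "F",
    "Cl",
    "Br",
    "C",
    "CC",
    "C(C)C",
    "C(C)(C)C",
    "CO",
    "FC(F)(F)",
    "N#C",
    "c2ccccc2",
    "c2ccncc2",
    "c2ccoc2",
    "c2ccsc2",
)
_AMINES = (
    "CNC",
    "CCNCC",
    "C1CCNC1",
    "C1CCNCC1",
    "C1COCCN1",
    "CNc1ccccc1",
    "CCNc1ccccc1",
    "CNCc1ccccc1",
    "CCCNC",
    "CNC1CCCCC1",
    "CC1CCNCC1",
    "C1CSCCN1",
    "C1CNC1",
    "CNCC(C)C",
    "CNCCO",
    "CNCC#N",
    "CC(C)NC(C)C",
    "C1CCNC1C",
)

#: classification patterns for the three 1,3-azole cores
AZOLE_CORE_SMARTS = {
    "thiazole": "c1cscn1",
    "oxazole": "c1cocn1",
    "imidazole": "c1c[nH]cn1",
}

#: default planted-model study conditions
DEFAULT_N_ACTIVE = 40
DEFAULT_COEF_SD = 3.0  # yield percent per bit
DEFAULT_INTERCEPT = 50.0
DEFAULT_NOISE_SD = 3.0


@dataclass
class PlantedModel:
    """Ground truth of a planted linear yield model in fingerprint space."""

    active_bits: np.ndarray
    planted_coefficients: np.ndarray
    intercept: float = DEFAULT_INTERCEPT
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0
    fingerprint_kind: str = "rdk"
    fingerprint_length: int = 2048
    fingerprint_radius: int = 2
    #: optional extra coefficient on a deliberately rare, compound-unique bit
    #: (used by the LOCO stress fixture; exempt from the frequency band)
    motif_bit: int | None = None
    motif_coefficient: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        self.active_bits = np.asarray(self.active_bits, dtype=int)
        self.planted_coefficients = np.asarray(self.planted_coefficients, dtype=float)
        if len(self.active_bits) != len(self.planted_coefficients):
            raise ValidationError("active bits and coefficients differ in length")


def _grammar_azoles() -> list[str]:
    out = []
    for sub in _SUBSTITUENTS:
        for core in _CORES:
            mol = Chem.MolFromSmiles(sub + core)
            if mol is not None:
                out.append(Chem.MolToSmiles(mol))
    return list(dict.fromkeys(out))


def generate_panels(
    n_azoles: int, n_amines: int, seed: int = 0
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Draw distinct azole and amine panels from the fragment grammar."""
    if n_azoles < 1 or n_amines < 1:
        raise ValidationError("panel sizes must be at least 1")
    azole_pool = _grammar_azoles()
    amine_pool = [Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in _AMINES]
    if n_azoles > len(azole_pool):
        raise CapacityError(f"grammar offers {len(azole_pool)} azoles, {n_azoles} requested")
    if n_amines > len(amine_pool):
        raise CapacityError(f"grammar offers {len(amine_pool)} amines, {n_amines} requested")
    rng = np.random.default_rng(seed)
    azoles = [str(s) for s in rng.choice(azole_pool, n_azoles, replace=False)]
    amines = [str(s) for s in rng.choice(amine_pool, n_amines, replace=False)]
    return (
        [(f"A{i + 1}", s) for i, s in enumerate(azoles)],
        [(f"N{i + 1}", s) for i, s in enumerate(amines)],
    )


def _fingerprint_matrix(dataset: ReactionDataset, planted: PlantedModel) -> np.ndarray:
    fps = [
        compute_fingerprint(
            r.product_smiles,
            planted.fingerprint_kind,
            planted.fingerprint_length,
            planted.fingerprint_radius,
        )
        for r in dataset
    ]
    return np.array([fp.bits for fp in fps], dtype=float)


def make_planted_model(
    dataset: ReactionDataset,
    n_active: int = DEFAULT_N_ACTIVE,
    coef_sd: float = DEFAULT_COEF_SD,
    intercept: float = DEFAULT_INTERCEPT,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    fingerprint_kind: str = "rdk",
    fingerprint_length: int = 2048,
    fingerprint_radius: int = 2,
    identifiable: bool = True,
) -> PlantedModel:
    """Choose active bits from the library's fingerprints and draw coefficients.

    Active bits are restricted to the frequency band [0.1, 0.9].  With
    ``identifiable=True`` (default) they are additionally restricted to bits
    whose on/off column is unique across the library, so the planted
    coefficient is not split over aliased duplicate columns.
    """
    planted = PlantedModel(
        active_bits=np.array([], dtype=int),
        planted_coefficients=np.array([]),
        intercept=intercept,
        noise_sd=noise_sd,
        seed=seed,
        fingerprint_kind=fingerprint_kind,
        fingerprint_length=fingerprint_length,
        fingerprint_radius=fingerprint_radius,
    )
    X = _fingerprint_matrix(dataset, planted)
    freq = X.mean(axis=0)
    candidates = np.flatnonzero((freq >= 0.1) & (freq <= 0.9))
    if identifiable:
        groups: dict[bytes, list[int]] = {}
        for j in candidates:
            groups.setdefault(X[:, j].tobytes(), []).append(int(j))
        candidates = np.array(sorted(g[0] for g in groups.values() if len(g) == 1))
    if len(candidates) < n_active:
        raise PlantingError(
            f"only {len(candidates)} plantable bits available, {n_active} requested"
        )
    rng = np.random.default_rng(seed)
    planted.active_bits = np.sort(rng.choice(candidates, n_active, replace=False))
    planted.planted_coefficients = rng.normal(0.0, coef_sd, n_active)
    return planted


def plant_and_label(
    dataset: ReactionDataset,
    planted: PlantedModel,
    ground_truth_path: str | Path | None = None,
) -> tuple[ReactionDataset, pd.DataFrame]:
    """Label an unlabeled dataset with the planted model plus clipped noise.

    Returns the labeled dataset and the ground-truth table (also written to
    ``ground_truth_path`` when given, separately from the reaction table).
    """
    if not all(r.yield_lcap is None for r in dataset):
        raise ValidationError("dataset is already labeled")
    X = _fingerprint_matrix(dataset, planted)
    absent = [int(b) for b in planted.active_bits if X[:, b].sum() == 0]
    if planted.motif_bit is not None and X[:, planted.motif_bit].sum() == 0:
        absent.append(int(planted.motif_bit))
    if absent:
        raise PlantingError(f"active bits {absent} absent from every molecule")
    noiseless = planted.intercept + X[:, planted.active_bits] @ planted.planted_coefficients
    if planted.motif_bit is not None:
        noiseless = noiseless + planted.motif_coefficient * X[:, planted.motif_bit]
    rng = np.random.default_rng(planted.seed)
    noise = rng.normal(0.0, planted.noise_sd, len(noiseless))
    yields = np.clip(noiseless + noise, 0.0, 100.0)
    labeled = dataset.with_yields(yields)

    truth_rows = [
        {"kind": "bit", "bit": int(b), "coefficient": float(w), "record": ""}
        for b, w in zip(planted.active_bits, planted.planted_coefficients)
    ]
    if planted.motif_bit is not None:
        truth_rows.append(
            {
                "kind": "motif_bit",
                "bit": int(planted.motif_bit),
                "coefficient": float(planted.motif_coefficient),
                "record": "",
            }
        )
    truth_rows += [
        {"kind": "noiseless_yield", "bit": -1, "coefficient": float(v), "record": r.key}
        for v, r in zip(noiseless, dataset)
    ]
    truth = pd.DataFrame(truth_rows)
    if ground_truth_path is not None:
        truth.to_csv(ground_truth_path, index=False)
    return labeled, truth


def planted_binary_design(
    n: int = 200,
    p: int = 128,
    n_active: int = DEFAULT_N_ACTIVE,
    coef_sd: float = DEFAULT_COEF_SD,
    intercept: float = DEFAULT_INTERCEPT,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Identifiable planted benchmark: independent Bernoulli bits, p < n.

    On hashed fingerprints of a combinatorial library individual coefficients
    are aliased (duplicate/nested columns) and coefficient-space recovery is
    ill-posed; this design isolates the estimator's recovery behaviour where
    recovery is possible.  Returns (X, active_bits, coefficients, yields).
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.1, 0.9, p)
    X = (rng.random((n, p)) < freqs).astype(float)
    active = np.sort(rng.choice(p, n_active, replace=False))
    w = rng.normal(0.0, coef_sd, n_active)
    y = np.clip(intercept + X[:, active] @ w + rng.normal(0.0, noise_sd, n), 0.0, 100.0)
    return X, active, w, y


def _azole_level_bits(X: np.ndarray, azole_ids: list[str]) -> np.ndarray:
    """Bits whose value is constant across amines for every azole."""
    ids = np.asarray(azole_ids)
    ok = np.ones(X.shape[1], dtype=bool)
    for az in dict.fromkeys(azole_ids):
        block = X[ids == az]
        ok &= (block == block[0]).all(axis=0)
    return np.flatnonzero(ok)


def loco_stress_fixture(
    seed: int = 0,
    n_azoles: int = 20,
    n_amines: int = 10,
    motif_coefficient: float = -25.0,
) -> tuple[ReactionDataset, PlantedModel]:
    """Library in which one azole carries a trimethylsilyl motif found nowhere else.

    The planted model places its active coefficients on azole-level bits shared
    across the library plus one large coefficient on a bit unique to the TMS
    azole.  Holding that azole out in LOCO removes the only evidence for the
    motif, so its out-of-sample predictions are systematically offset, while
    amine-wise LOCO (yield variation driven by azole-level bits seen in
    training) remains accurate.
    """
    azoles, amines = generate_panels(n_azoles - 1, n_amines, seed=seed)
    tms = Chem.MolToSmiles(Chem.MolFromSmiles("C[Si](C)(C)c1cscn1"))
    if any(s == tms for _, s in azoles):  # pragma: no cover - grammar excludes TMS
        raise PlantingError("TMS azole unexpectedly present in the random panel")
    azoles = azoles + [("A_TMS", tms)]
    dataset = build_combinatorial_dataset(azoles, amines)

    probe = PlantedModel(np.array([], dtype=int), np.array([]), seed=seed)
    X = _fingerprint_matrix(dataset, probe)
    azole_ids = [r.azole_id for r in dataset]
    freq = X.mean(axis=0)
    level = _azole_level_bits(X, azole_ids)
    tms_rows = np.array([i for i, a in enumerate(azole_ids) if a == "A_TMS"])
    other_rows = np.array([i for i, a in enumerate(azole_ids) if a != "A_TMS"])
    unique_motif = [
        int(j)
        for j in level
        if X[tms_rows, j].all() and not X[other_rows, j].any()
    ]
    if not unique_motif:
        raise PlantingError("no bit unique to the TMS azole found")
    shared = np.array(
        [j for j in level if 0.1 <= freq[j] <= 0.9 and not (X[tms_rows, j].all() and not X[other_rows, j].any())]
    )
    rng = np.random.default_rng(seed)
    n_active = min(DEFAULT_N_ACTIVE, len(shared))
    active = np.sort(rng.choice(shared, n_active, replace=False))
    planted = PlantedModel(
        active_bits=active,
        planted_coefficients=rng.normal(0.0, DEFAULT_COEF_SD, n_active),
        seed=seed,
        motif_bit=unique_motif[0],
        motif_coefficient=motif_coefficient,
    )
    labeled, _ = plant_and_label(dataset, planted)
    return labeled, planted


def property_cliff_fixture(
    seed: int = 0, offset: float = 15.0, n_amines: int = 10
) -> tuple[ReactionDataset, PlantedModel, list[int]]:
    """Two azoles differing only in the ring heteroatom get opposite yield offsets.

    The offsets are applied to the labels directly, outside the planted linear
    structure, emulating a property cliff the fingerprint model cannot resolve
    consistently.  Returns the labeled dataset, the planted model and the
    indices of the cliff records.
    """
    azoles, amines = generate_panels(14, n_amines, seed=seed)
    pair = [Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in ("Cc1cscn1", "Cc1cocn1")]
    azoles = [(i, s) for i, s in azoles if s not in pair]
    azoles += [("A_CLIFF_S", pair[0]), ("A_CLIFF_O", pair[1])]
    dataset = build_combinatorial_dataset(azoles, amines)
    planted = make_planted_model(dataset, seed=seed)
    labeled, _ = plant_and_label(dataset, planted)
    y = labeled.yields
    cliff: list[int] = []
    for i, r in enumerate(labeled):
        if r.azole_id == "A_CLIFF_S":
            y[i] = float(np.clip(y[i] + offset, 0, 100))
            cliff.append(i)
        elif r.azole_id == "A_CLIFF_O":
            y[i] = float(np.clip(y[i] - offset, 0, 100))
            cliff.append(i)
    return labeled.with_yields(y), planted, cliff
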