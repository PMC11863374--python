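"""Featurizations: property vectors, fingerprints with bit provenance, many-body
descriptors, QM-property ingestion, and the solvent-mixture property calculator.

Fingerprints carry *provenance*: for every "on" bit, the list of substructure
occurrences (ordered bond-index tuples) that set it.  This is the information
the bond-attribution heat mapper consumes.  MACCS keys have no bond-path
provenance and ship with an empty map.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors, MACCSkeys

from .chemdata import ReactionDataset, Structure3D
from .exceptions import (
    ConfigurationError,
    DescriptorAvailabilityError,
    SingularGeometryError,
    ValidationError,
)

__all__ = [
    "FingerprintResult",
    "DescriptorMatrix",
    "QMPropertyRecord",
    "SolventMixture",
    "compute_property_descriptors",
    "compute_fingerprint",
    "coulomb_matrix_eigenvalues",
    "two_body_forces",
    "mbtr_spectrum",
    "derive_conceptual_dft",
    "mixture_property",
    "read_qm_table",
    "featurize_dataset",
    "DESCRIPTOR_REGISTRY",
]

FINGERPRINT_KINDS = ("maccs", "rdk", "morgan")

#: diagonal convention of the Coulomb matrix, 0.5 * Z**CM_DIAGONAL_EXPONENT
CM_DIAGONAL_EXPONENT = 2.4

# Fixed MBTR axis references so spectra are comparable across molecules:
# k=1 atomic number, k=2 inverse distance (1/Angstrom), k=3 cosine of angle.
MBTR_AXIS_RANGES = {1: (0.0, 100.0), 2: (0.0, 2.0), 3: (-1.0, 1.0)}
MBTR_DEFAULT_WIDTH = 0.1  # on axes normalized to [0, 1]
_MBTR_PAD_SIGMAS = 4.0  # grid extends this many widths beyond the normalized axis


@dataclass
class FingerprintResult:
    """Bit vector plus bit -> substructure-occurrence provenance.

    Each occurrence is an ordered tuple of bond indices of the matched
    substructure in the source molecule.  Morgan radius-0 environments (single
    atoms) carry an empty tuple.
    """

    kind: str
    length: int
    bits: np.ndarray
    provenance: dict[int, list[tuple[int, ...]]]
    smiles: str = ""

    @property
    def on_bits(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


@dataclass
class DescriptorMatrix:
    """records x features matrix with stable column order."""

    feature_names: list[str]
    values: np.ndarray
    descriptor_kind: str
    fingerprints: list[FingerprintResult] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValidationError("descriptor matrix shape does not match feature names")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


@dataclass(frozen=True)
class QMPropertyRecord:
    """Electronic-structure descriptors of one product (energies in Hartree)."""

    homo_energy: float
    lumo_energy: float
    dipole: float  # Debye
    electronegativity: float  # Hartree
    hardness: float  # Hartree
    delta_g: float  # kcal/mol, product-formation step

    def __post_init__(self) -> None:
        if self.lumo_energy < self.homo_energy:
            raise ValidationError("LUMO energy below HOMO energy")
        if self.hardness < 0:
            raise ValidationError("hardness must be non-negative")

    @classmethod
    def from_frontier(
        cls, homo_energy: float, lumo_energy: float, dipole: float, delta_g: float
    ) -> "QMPropertyRecord":
        chi, eta = derive_conceptual_dft(homo_energy, lumo_energy)
        return cls(homo_energy, lumo_energy, dipole, chi, eta, delta_g)

    def as_vector(self) -> np.ndarray:
        return np.array(
            [
                self.homo_energy,
                self.lumo_energy,
                self.dipole,
                self.electronegativity,
                self.hardness,
                self.delta_g,
            ]
        )


QM_FEATURE_NAMES = ["homo", "lumo", "dipole", "electronegativity", "hardness", "delta_g"]


@dataclass(frozen=True)
class SolventMixture:
    """Volume fractions plus pure-component dielectric constants / refractive indices."""

    components: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        fracs = np.array([c[0] for c in self.components])
        if np.any(fracs <= 0):
            raise ValidationError("volume fractions must be positive")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValidationError(f"volume fractions sum to {fracs.sum()}, expected 1")


def derive_conceptual_dft(homo_energy: float, lumo_energy: float) -> tuple[float, float]:
    """Koopmans-style electronegativity and hardness from frontier energies.

    chi = -(eps_HOMO + eps_LUMO)/2, eta = (eps_LUMO - eps_HOMO)/2.
    """
    if lumo_energy < homo_energy:
        raise ValidationError("inverted HOMO/LUMO gap")
    return -(homo_energy + lumo_energy) / 2.0, (lumo_energy - homo_energy) / 2.0


def mixture_property(mixture: SolventMixture, prop: str) -> float:
    """Volume-fraction-weighted arithmetic mean of a pure-component property."""
    idx = {"dielectric": 1, "refractive_index": 2}.get(prop)
    if idx is None:
        raise ConfigurationError(f"unknown mixture property {prop!r}")
    return float(sum(c[0] * c[idx] for c in mixture.components))


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValidationError(f"SMILES {smiles!r} does not parse")
    return mol


def compute_property_descriptors(smiles: str) -> tuple[list[str], np.ndarray]:
    """Full RDKit property-descriptor vector (stable, alphabetical-by-registry order)."""
    mol = _mol_from_smiles(smiles)
    names = [name for name, _ in Descriptors.descList]
    values = np.empty(len(names))
    for i, (_, fn) in enumerate(Descriptors.descList):
        try:
            values[i] = float(fn(mol))
        except Exception:
            values[i] = np.nan
    return names, values


def _morgan_env_bonds(mol: Chem.Mol, atom: int, radius: int) -> tuple[int, ...]:
    if radius == 0:
        return ()
    bonds = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom)
    return tuple(bonds)


def compute_fingerprint(
    smiles: str, kind: str, length: int = 2048, radius: int = 2
) -> FingerprintResult:
    """Hashed fingerprint with bit->substructure provenance.

    * ``rdk``: bond-path fingerprint, paths of up to seven bonds; provenance is
      the bond-index tuple of each hashed path.
    * ``morgan``: circular fingerprint; each (center atom, radius) environment
      is converted to its bond set.
    * ``maccs``: 167 structural keys, no provenance.
    """
    if kind not in FINGERPRINT_KINDS:
        raise ConfigurationError(f"unknown fingerprint kind {kind!r}; expected {FINGERPRINT_KINDS}")
    mol = _mol_from_smiles(smiles)
    provenance: dict[int, list[tuple[int, ...]]] = {}
    if kind == "maccs":
        fp = MACCSkeys.GenMACCSKeys(mol)
        bits = np.zeros(fp.GetNumBits(), dtype=np.uint8)
        bits[list(fp.GetOnBits())] = 1
        return FingerprintResult("maccs", fp.GetNumBits(), bits, {}, smiles=smiles)
    if kind == "rdk":
        bit_info: dict[int, list[list[int]]] = {}
        fp = Chem.RDKFingerprint(mol, fpSize=length, bitInfo=bit_info)
        for bit, paths in bit_info.items():
            provenance[bit] = [tuple(p) for p in paths]
    else:  # morgan
        bit_info = {}
        fp = AllChem.GetMorganFingerprintAsBitVect(mol, radius, nBits=length, bitInfo=bit_info)
        for bit, envs in bit_info.items():
            provenance[bit] = [_morgan_env_bonds(mol, atom, rad) for atom, rad in envs]
    bits = np.zeros(length, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return FingerprintResult(kind, length, bits, provenance, smiles=smiles)


def _pairwise_distances(structure: Structure3D) -> np.ndarray:
    coords = structure.coordinates
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    n = len(structure.elements)
    if n > 1:
        off = dist[~np.eye(n, dtype=bool)]
        if np.any(off < 1e-8):
            raise SingularGeometryError("coincident nuclei in structure")
    return dist


def coulomb_matrix_eigenvalues(structure: Structure3D, n_max: int) -> np.ndarray:
    """Eigenvalues of the Coulomb matrix, sorted by descending |value|, zero-padded.

    Diagonal 0.5 * Z_i**2.4, off-diagonal Z_i Z_j / |R_i - R_j| (distances in
    Angstrom).  Invariant under rigid isometries and atom reindexing.
    """
    n = len(structure.elements)
    if n > n_max:
        raise ConfigurationError(f"structure has {n} atoms but n_max={n_max}")
    z = structure.atomic_numbers
    dist = _pairwise_distances(structure)
    with np.errstate(divide="ignore"):
        cm = np.where(dist > 0, np.outer(z, z) / np.where(dist > 0, dist, 1.0), 0.0)
    np.fill_diagonal(cm, 0.5 * z**CM_DIAGONAL_EXPONENT)
    eig = np.linalg.eigvalsh(cm)
    eig = eig[np.argsort(-np.abs(eig), kind="stable")]
    out = np.zeros(n_max)
    out[:n] = eig
    return out


def _normalize_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def two_body_forces(
    structure: Structure3D,
    element_pairs: Sequence[tuple[str, str]],
    strict: bool = False,
) -> np.ndarray:
    """One inverse-distance feature per unordered element pair.

    Feature for {A, B} is the sum of 1/r_ij over atom pairs i<j with elements
    {A, B}; pairs absent from the structure get 0.
    """
    pairs = [_normalize_pair(*p) for p in element_pairs]
    if len(set(pairs)) != len(pairs):
        raise ConfigurationError("duplicate element pair after normalization")
    index = {p: k for k, p in enumerate(pairs)}
    covered = {e for p in pairs for e in p}
    missing = set(structure.elements) - covered
    if strict and missing:
        raise ConfigurationError(f"elements {sorted(missing)} not covered by element_pairs")
    dist = _pairwise_distances(structure)
    out = np.zeros(len(pairs))
    n = len(structure.elements)
    for i in range(n):
        for j in range(i + 1, n):
            key = _normalize_pair(structure.elements[i], structure.elements[j])
            k = index.get(key)
            if k is not None:
                out[k] += 1.0 / dist[i, j]
    return out


def _mbtr_grid(width: float, grid_points: int) -> tuple[np.ndarray, float]:
    lo, hi = -_MBTR_PAD_SIGMAS * width, 1.0 + _MBTR_PAD_SIGMAS * width
    return np.linspace(lo, hi, grid_points), (hi - lo) / (grid_points - 1)


def _gauss_sum(grid: np.ndarray, centers: np.ndarray, width: float) -> np.ndarray:
    if centers.size == 0:
        return np.zeros_like(grid)
    z = (grid[:, None] - centers[None, :]) / width
    return (np.exp(-0.5 * z**2) / (width * np.sqrt(2 * np.pi))).sum(axis=1)


def mbtr_layout(elements: Sequence[str], grid_points: int = 20) -> list[tuple[str, ...]]:
    """Deterministic segment layout: k1 per element, k2 per sorted pair, k3 per
    (flank, center, flank) triple with flanks sorted."""
    els = sorted(set(elements))
    segs: list[tuple[str, ...]] = [(e,) for e in els]
    segs += [tuple(p) for p in itertools.combinations_with_replacement(els, 2)]
    for center in els:
        for a, b in itertools.combinations_with_replacement(els, 2):
            segs.append((a, center, b))
    return segs


def mbtr_spectrum(
    structure: Structure3D,
    elements: Sequence[str] | None = None,
    grid_points: int = 20,
    widths: Mapping[int, float] | None = None,
    k2_inverse: bool = True,
) -> tuple[list[str], np.ndarray]:
    """Concatenated k=1/2/3 Gaussian-smeared histograms on fixed normalized axes.

    k=1 smears atomic numbers, k=2 the (by default inverse) pairwise distances,
    k=3 the cosines of all bond-free triples, each on its own per-element-
    combination segment of ``grid_points`` bins.  Unit weighting throughout.
    """
    w = {1: MBTR_DEFAULT_WIDTH, 2: MBTR_DEFAULT_WIDTH, 3: MBTR_DEFAULT_WIDTH}
    if widths:
        w.update(widths)
    if any(v <= 0 for v in w.values()):
        raise ConfigurationError("smearing widths must be positive")
    els = sorted(set(elements if elements is not None else structure.elements))
    unknown = set(structure.elements) - set(els)
    if unknown:
        raise ConfigurationError(f"structure elements {sorted(unknown)} not in element list")
    segs = mbtr_layout(els, grid_points)
    z = structure.atomic_numbers
    dist = _pairwise_distances(structure)
    n = len(structure.elements)

    # collect scalar geometry values per segment key
    values: dict[tuple[str, ...], list[float]] = {s: [] for s in segs}
    for i in range(n):
        values[(structure.elements[i],)].append(z[i])
    for i in range(n):
        for j in range(i + 1, n):
            key = tuple(sorted((structure.elements[i], structure.elements[j])))
            values[key].append(1.0 / dist[i, j] if k2_inverse else dist[i, j])
    coords = structure.coordinates
    for j in range(n):  # center atom
        for i in range(n):
            for k in range(i + 1, n):
                if i == j or k == j:
                    continue
                a, b = coords[i] - coords[j], coords[k] - coords[j]
                cos = float(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b)))
                flanks = sorted((structure.elements[i], structure.elements[k]))
                values[(flanks[0], structure.elements[j], flanks[1])].append(
                    np.clip(cos, -1.0, 1.0)
                )

    names: list[str] = []
    chunks: list[np.ndarray] = []
    for seg in segs:
        k = len(seg)
        lo, hi = MBTR_AXIS_RANGES[k]
        grid, _ = _mbtr_grid(w[k], grid_points)
        centers = (np.array(values[seg]) - lo) / (hi - lo)
        chunks.append(_gauss_sum(grid, centers, w[k]))
        names += [f"mbtr_k{k}_{'-'.join(seg)}_{g}" for g in range(grid_points)]
    return names, np.concatenate(chunks)


def read_qm_table(path: str | Path) -> dict[str, QMPropertyRecord]:
    """CSV with columns: record id ('id' or 'key'), homo, lumo, dipole, delta_g."""
    df = pd.read_csv(path)
    id_col = "id" if "id" in df.columns else "key"
    required = {id_col, "homo", "lumo", "dipole", "delta_g"}
    if not required <= set(df.columns):
        raise ConfigurationError(f"QM table missing columns {sorted(required - set(df.columns))}")
    return {
        str(row[id_col]): QMPropertyRecord.from_frontier(
            float(row["homo"]), float(row["lumo"]), float(row["dipole"]), float(row["delta_g"])
        )
        for _, row in df.iterrows()
    }


# ---------------------------------------------------------------------------
# dataset-level featurization registry


def _feat_properties(dataset: ReactionDataset, options: dict) -> DescriptorMatrix:
    rows, names = [], None
    for r in dataset:
        names, vec = compute_property_descriptors(r.product_smiles)
        rows.append(vec)
    values = np.array(rows) if rows else np.zeros((0, len(names or [])))
    return DescriptorMatrix(names or [], values, "rdkit_properties")


def _feat_fingerprint(kind: str):
    def inner(dataset: ReactionDataset, options: dict) -> DescriptorMatrix:
        length = int(options.get("length", 2048))
        radius = int(options.get("radius", 2))
        fps = [compute_fingerprint(r.product_smiles, kind, length, radius) for r in dataset]
        width = fps[0].length if fps else (167 if kind == "maccs" else length)
        values = (
            np.array([fp.bits for fp in fps], dtype=float) if fps else np.zeros((0, width))
        )
        names = [f"{kind}_bit_{i}" for i in range(width)]
        return DescriptorMatrix(names, values, kind, fingerprints=fps)

    return inner


def _require_geometries(dataset: ReactionDataset, options: dict) -> dict[str, Structure3D]:
    geometries = options.get("geometries")
    if geometries is None:
        raise DescriptorAvailabilityError("geometry-based descriptor requested without geometries")
    missing = [r.key for r in dataset if r.key not in geometries]
    if missing:
        raise DescriptorAvailabilityError(f"no geometry for records {missing}")
    return geometries


def _feat_cm(dataset: ReactionDataset, options: dict) -> DescriptorMatrix:
    geometries = _require_geometries(dataset, options)
    n_max = int(
        options.get("n_max", max((len(geometries[r.key].elements) for r in dataset), default=1))
    )
    values = np.array([coulomb_matrix_eigenvalues(geometries[r.key], n_max) for r in dataset])
    if len(dataset) == 0:
        values = np.zeros((0, n_max))
    return DescriptorMatrix([f"cm_eig_{i}" for i in range(n_max)], values, "coulomb_eigen")


def _feat_f2b(dataset: ReactionDataset, options: dict) -> DescriptorMatrix:
    geometries = _require_geometries(dataset, options)
    pairs = options.get("element_pairs")
    if pairs is None:
        els = sorted({e for r in dataset for e in geometries[r.key].elements})
        pairs = list(itertools.combinations_with_replacement(els, 2))
    values = np.array([two_body_forces(geometries[r.key], pairs) for r in dataset])
    if len(dataset) == 0:
        values = np.zeros((0, len(pairs)))
    return DescriptorMatrix([f"f2b_{a}-{b}" for a, b in pairs], values, "f2b")


def _feat_mbtr(dataset: ReactionDataset, options: dict) -> DescriptorMatrix:
    geometries = _require_geometries(dataset, options)
    elements = options.get("elements")
    if elements is None:
        elements = sorted({e for r in dataset for e in geometries[r.key].elements})
    grid_points = int(options.get("grid_points", 20))
    names: list[str] = []
    rows = []
    for r in dataset:
        names, vec = mbtr_spectrum(
            geometries[r.key],
            elements=elements,
            grid_points=grid_points,
            widths=options.get("widths"),
            k2_inverse=bool(options.get("k2_inverse", True)),
        )
        rows.append(vec)
    values = np.array(rows) if rows else np.zeros((0, len(names)))
    return DescriptorMatrix(names, values, "mbtr")


def _feat_qm(dataset: ReactionDataset, options: dict) -> DescriptorMatrix:
    table = options.get("qm_table")
    if table is None:
        raise DescriptorAvailabilityError("QM descriptor requested without a QM property table")
    missing = [r.key for r in dataset if r.key not in table]
    if missing:
        raise DescriptorAvailabilityError(f"no QM property row for records {missing}")
    values = np.array([table[r.key].as_vector() for r in dataset])
    if len(dataset) == 0:
        values = np.zeros((0, len(QM_FEATURE_NAMES)))
    return DescriptorMatrix(list(QM_FEATURE_NAMES), values, "qm")


DESCRIPTOR_REGISTRY: dict[str, Callable[[ReactionDataset, dict], DescriptorMatrix]] = {
    "rdkit_properties": _feat_properties,
    "maccs": _feat_fingerprint("maccs"),
    "rdk": _feat_fingerprint("rdk"),
    "morgan": _feat_fingerprint("morgan"),
    "coulomb_eigen": _feat_cm,
    "f2b": _feat_f2b,
    "mbtr": _feat_mbtr,
    "qm": _feat_qm,
}

#: descriptor kinds computable from SMILES alone (usable for library screening)
SMILES_ONLY_KINDS = ("rdkit_properties", "maccs", "rdk", "morgan")


def featurize_dataset(
    dataset: ReactionDataset, descriptor_kind: str, options: dict | None = None
) -> DescriptorMatrix:
    """Featurize every record; row order matches record order."""
    fn = DESCRIPTOR_REGISTRY.get(descriptor_kind)
    if fn is None:
        raise ConfigurationError(
            f"unknown descriptor kind {descriptor_kind!r}; known: {sorted(DESCRIPTOR_REGISTRY)}"
        )
    return fn(dataset, options or {})
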