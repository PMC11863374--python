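"""Data model and I/O for combinatorial reaction datasets, structures and geometries.

The central object is a :class:`ReactionDataset`: an ordered list of azole x amine
amide couplings, each optionally labeled with an LCAP yield on the 0-100 percent
scale.  Yields are always stored on that scale; a missing label is ``None``,
never 0 (0 is a legal measured yield).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .exceptions import AssemblyError, ConfigurationError, FormatError, ValidationError

__all__ = [
    "ReactionRecord",
    "ReactionDataset",
    "Structure3D",
    "read_reaction_table",
    "write_reaction_table",
    "build_combinatorial_dataset",
    "assemble_product_smiles",
    "read_xyz",
    "write_xyz",
]

#: canonical column names of the reaction-table CSV dialect
TABLE_COLUMNS = ("azole_id", "amine_id", "azole_smiles", "amine_smiles", "product_smiles", "yield_lcap")

# C2 of a 1,3-azole: aromatic CH in a 5-ring between pyridine-type N and O/S/pyrrole-type N
_C2_SMARTS = Chem.MolFromSmarts("[cH;r5](:[n;r5]):[o,s,nX3;r5]")
# secondary/primary amine N-H that is not an amide or imine nitrogen
_NH_SMARTS = Chem.MolFromSmarts("[NX3;H1,H2;!$(N=*);!$(NC=[O,S])]")


@dataclass(frozen=True)
class ReactionRecord:
    """One azole x amine amide coupling, optionally labeled with an LCAP yield."""

    azole_id: str
    amine_id: str
    azole_smiles: str = ""
    amine_smiles: str = ""
    product_smiles: str = ""
    yield_lcap: float | None = None

    @property
    def key(self) -> str:
        return f"{self.azole_id}-{self.amine_id}"

    def __post_init__(self) -> None:
        if self.yield_lcap is not None and not (0.0 <= self.yield_lcap <= 100.0):
            raise ValidationError(
                f"record {self.key}: yield {self.yield_lcap!r} outside [0, 100] percent"
            )


@dataclass
class ReactionDataset:
    """Ordered collection of :class:`ReactionRecord` with a provenance tag."""

    records: list[ReactionRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def yields(self) -> np.ndarray:
        """Labels as float array; missing labels become NaN."""
        return np.array(
            [np.nan if r.yield_lcap is None else r.yield_lcap for r in self.records], dtype=float
        )

    @property
    def product_smiles(self) -> list[str]:
        return [r.product_smiles for r in self.records]

    def subset(self, indices: Sequence[int], provenance: str | None = None) -> "ReactionDataset":
        return ReactionDataset(
            [self.records[i] for i in indices],
            provenance if provenance is not None else self.provenance,
        )

    def with_yields(self, yields: Sequence[float]) -> "ReactionDataset":
        if len(yields) != len(self.records):
            raise ValidationError("yield vector length does not match record count")
        return ReactionDataset(
            [replace(r, yield_lcap=float(y)) for r, y in zip(self.records, yields)],
            self.provenance,
        )

    def validate_unique_pairs(self) -> None:
        seen: set[tuple[str, str]] = set()
        for r in self.records:
            pair = (r.azole_id, r.amine_id)
            if pair in seen:
                raise ValidationError(f"duplicate (azole_id, amine_id) pair {pair}")
            seen.add(pair)


@dataclass
class Structure3D:
    """Element symbols plus Cartesian coordinates in Angstrom."""

    elements: list[str]
    coordinates: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float).reshape(-1, 3)
        if len(self.elements) != self.coordinates.shape[0]:
            raise ValidationError(
                f"structure {self.label!r}: {len(self.elements)} elements but "
                f"{self.coordinates.shape[0]} coordinate rows"
            )
        if len(self.elements) < 1:
            raise ValidationError("structure must contain at least one atom")

    @property
    def atomic_numbers(self) -> np.ndarray:
        table = Chem.GetPeriodicTable()
        return np.array([table.GetAtomicNumber(e) for e in self.elements], dtype=float)


def _parse_yield(raw, row: int) -> float | None:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return None
    try:
        value = float(raw)
    except (TypeError, ValueError):
        raise ValidationError(f"row {row}: yield {raw!r} is not numeric") from None
    if not (0.0 <= value <= 100.0):
        raise ValidationError(f"row {row}: yield {value} outside [0, 100] percent")
    return value


def read_reaction_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> ReactionDataset:
    """Read a reaction-table CSV (UTF-8, header required) into a dataset.

    ``column_map`` maps canonical names (see :data:`TABLE_COLUMNS`) to the
    headers actually present in the file.  Rows with unparsable product SMILES
    are rejected with their row numbers.
    """
    colmap = {c: c for c in TABLE_COLUMNS}
    if column_map:
        colmap.update(column_map)
    df = pd.read_csv(path, dtype={colmap["azole_id"]: str, colmap["amine_id"]: str})
    for canonical in ("azole_id", "amine_id", "product_smiles"):
        if colmap[canonical] not in df.columns:
            raise ConfigurationError(
                f"required column {colmap[canonical]!r} (for {canonical!r}) missing from {path}"
            )

    records: list[ReactionRecord] = []
    bad_rows: list[int] = []
    for i, row in df.iterrows():
        smi = str(row[colmap["product_smiles"]])
        if Chem.MolFromSmiles(smi) is None:
            bad_rows.append(int(i) + 2)  # 1-based, after the header line
            continue
        records.append(
            ReactionRecord(
                azole_id=str(row[colmap["azole_id"]]),
                amine_id=str(row[colmap["amine_id"]]),
                azole_smiles=str(row.get(colmap["azole_smiles"], "") or ""),
                amine_smiles=str(row.get(colmap["amine_smiles"], "") or ""),
                product_smiles=smi,
                yield_lcap=_parse_yield(row.get(colmap["yield_lcap"]), int(i) + 2),
            )
        )
    if bad_rows:
        raise ValidationError(f"unparsable product SMILES in file rows {bad_rows}")
    dataset = ReactionDataset(records, provenance=str(path))
    dataset.validate_unique_pairs()
    return dataset


def write_reaction_table(dataset: ReactionDataset, path: str | Path) -> None:
    """Write the canonical CSV dialect; round-trips through :func:`read_reaction_table`."""
    rows = [
        {
            "azole_id": r.azole_id,
            "amine_id": r.amine_id,
            "azole_smiles": r.azole_smiles,
            "amine_smiles": r.amine_smiles,
            "product_smiles": r.product_smiles,
            "yield_lcap": "" if r.yield_lcap is None else r.yield_lcap,
        }
        for r in dataset.records
    ]
    pd.DataFrame(rows, columns=list(TABLE_COLUMNS)).to_csv(path, index=False, encoding="utf-8")


def assemble_product_smiles(azole_smiles: str, amine_smiles: str) -> str:
    """Assemble the amide product: azole C2 - C(=O) - amine N, canonicalized.

    This is a convenience for libraries without curated product SMILES; supplied
    product SMILES always take precedence in the pipeline.
    """
    azole = Chem.MolFromSmiles(azole_smiles)
    if azole is None:
        raise AssemblyError(f"azole SMILES {azole_smiles!r} does not parse")
    amine = Chem.MolFromSmiles(amine_smiles)
    if amine is None:
        raise AssemblyError(f"amine SMILES {amine_smiles!r} does not parse")

    c2_matches = azole.GetSubstructMatches(_C2_SMARTS)
    if not c2_matches:
        raise AssemblyError(f"no unsubstituted C2-H between ring heteroatoms in {azole_smiles!r}")
    nh_matches = amine.GetSubstructMatches(_NH_SMARTS)
    if not nh_matches:
        raise AssemblyError(f"no amine N-H found in {amine_smiles!r}")
    c2 = c2_matches[0][0]
    n_idx = nh_matches[0][0] + azole.GetNumAtoms()

    combo = Chem.RWMol(Chem.CombineMols(azole, amine))
    carbonyl_c = combo.AddAtom(Chem.Atom(6))
    carbonyl_o = combo.AddAtom(Chem.Atom(8))
    combo.AddBond(c2, carbonyl_c, Chem.BondType.SINGLE)
    combo.AddBond(carbonyl_c, carbonyl_o, Chem.BondType.DOUBLE)
    combo.AddBond(carbonyl_c, n_idx, Chem.BondType.SINGLE)
    product = combo.GetMol()
    try:
        Chem.SanitizeMol(product)
    except Exception as exc:  # pragma: no cover - defensive
        raise AssemblyError(f"assembled product failed sanitization: {exc}") from exc
    return Chem.MolToSmiles(product)


def build_combinatorial_dataset(
    azoles: Sequence[tuple[str, str]],
    amines: Sequence[tuple[str, str]],
    excluded_amine_ids: Iterable[str] = (),
) -> ReactionDataset:
    """One unlabeled record per (azole, amine) pair, minus excluded amines."""
    for name, panel in (("azole", azoles), ("amine", amines)):
        ids = [i for i, _ in panel]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate id in {name} panel")
    excluded = set(excluded_amine_ids)
    records = [
        ReactionRecord(
            azole_id=az_id,
            amine_id=am_id,
            azole_smiles=az_smi,
            amine_smiles=am_smi,
            product_smiles=assemble_product_smiles(az_smi, am_smi),
        )
        for az_id, az_smi in azoles
        for am_id, am_smi in amines
        if am_id not in excluded
    ]
    return ReactionDataset(records, provenance="combinatorial")


def read_xyz(path: str | Path) -> Structure3D:
    """Read a standard XYZ file (count line, comment line, element x y z rows)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        count = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError(f"{path}: first line is not an atom count") from None
    body = [ln for ln in lines[2 : 2 + count]]
    atom_rows = [ln.split() for ln in body if ln.strip()]
    if len(atom_rows) != count:
        raise FormatError(f"{path}: count line says {count} atoms, found {len(atom_rows)} rows")
    elements, coords = [], []
    for row in atom_rows:
        if len(row) < 4:
            raise FormatError(f"{path}: malformed atom row {row}")
        elements.append(row[0])
        coords.append([float(x) for x in row[1:4]])
    label = lines[1].strip() if len(lines) > 1 else ""
    return Structure3D(elements, np.array(coords), label=label)


def write_xyz(structure: Structure3D, path: str | Path) -> None:
    lines = [str(len(structure.elements)), structure.label]
    for el, (x, y, z) in zip(structure.elements, structure.coordinates):
        lines.append(f"{el} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")
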