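"""Bond-level attribution heat maps from fingerprint-bit importances.

Every "on" bit of a provenance-bearing fingerprint corresponds to one or more
substructure occurrences (bond sets).  The weight of a bond is the sum of the
importances of all on bits over all of their occurrences containing that bond;
importances are either linear-model coefficients or SHAP values, both on the
yield-percent-per-bit scale.  Weights are rendered as a diverging blue-white-red
map: red bonds push the predicted yield up, blue bonds push it down.

Because hashed fingerprints collide (one bit set by several distinct
substructures), attribution can be ambiguous; :func:`collision_report`
quantifies this per bit across a dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.Draw import rdMolDraw2D

from .descriptors import FingerprintResult
from .exceptions import (
    CapabilityError,
    ConfigurationError,
    DepictionError,
    ValidationError,
)
from .modeling import FitResult

__all__ = [
    "BondHeat",
    "ColorScale",
    "CollisionReport",
    "bond_weights",
    "fit_color_scale",
    "apply_color_scale",
    "shap_importances",
    "render_heatmap",
    "collision_report",
]

# fixed rendering constants for byte-reproducible output
CANVAS = (420, 360)
NEGATIVE_COLOR = (0.0, 0.0, 1.0)  # pure blue at color value -1
POSITIVE_COLOR = (1.0, 0.0, 0.0)  # pure red at color value +1


@dataclass
class BondHeat:
    """Per-bond summed importances for one molecule."""

    smiles: str
    weights: np.ndarray  # signed, indexed by bond index
    backend: str = "coefficient"  # "coefficient" | "shap"
    color_values: np.ndarray | None = None  # in [-1, 1] once a scale is applied
    warnings: list[str] = field(default_factory=list)

    @property
    def n_bonds(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class ColorScale:
    """Zero-anchored piecewise-linear map from weights to [-1, 1].

    Negative weights are scaled by the dataset minimum, positive ones by the
    dataset maximum, so zero weight is always the neutral color.  A one-sided
    dataset falls back to unit slope on the empty branch.
    """

    w_min: float
    w_max: float

    def map(self, weights: np.ndarray) -> np.ndarray:
        w = np.asarray(weights, dtype=float)
        neg_scale = abs(self.w_min) if self.w_min < 0 else 1.0
        pos_scale = self.w_max if self.w_max > 0 else 1.0
        out = np.where(w < 0, w / neg_scale, w / pos_scale)
        return np.clip(out, -1.0, 1.0)


@dataclass
class CollisionReport:
    """Distinct-substructure counts per bit, aggregated over a dataset."""

    counts: dict[int, int]
    substructures: dict[int, set[str]]

    @property
    def flagged_bits(self) -> set[int]:
        return {bit for bit, c in self.counts.items() if c > 1}


def bond_weights(
    fp: FingerprintResult,
    importances: Sequence[float],
    backend: str = "coefficient",
    share_across_bonds: bool = False,
) -> BondHeat:
    """Sum per-bit importances onto the bonds of their substructure occurrences.

    Each occurrence of an on bit contributes the full bit importance to each of
    its bonds (``share_across_bonds=True`` divides the importance by the
    occurrence's bond count instead).  Bonds untouched by any occurrence get
    weight exactly 0.  On bits with nonzero importance but no usable provenance
    (MACCS, or atom-only radius-0 environments) are accumulated as warnings,
    never dropped silently.
    """
    if fp.kind == "maccs":
        raise CapabilityError("MACCS keys carry no bond-path provenance; cannot attribute bonds")
    importances = np.asarray(importances, dtype=float)
    if len(importances) != fp.length:
        raise ValidationError("importances must be indexed like the fingerprint bits")
    mol = Chem.MolFromSmiles(fp.smiles)
    if mol is None:
        raise ValidationError(f"fingerprint source SMILES {fp.smiles!r} does not parse")
    weights = np.zeros(mol.GetNumBonds())
    warning_list: list[str] = []
    for bit in fp.on_bits:
        imp = importances[bit]
        occurrences = fp.provenance.get(int(bit))
        if occurrences is None:
            if imp != 0:
                warning_list.append(f"bit {bit}: importance {imp:+.4g} has no provenance")
            continue
        for occ in occurrences:
            if not occ:
                if imp != 0:
                    warning_list.append(
                        f"bit {bit}: atom-only environment, importance {imp:+.4g} not bond-attributable"
                    )
                continue
            contribution = imp / len(occ) if share_across_bonds else imp
            for bond in occ:
                weights[bond] += contribution
    return BondHeat(smiles=fp.smiles, weights=weights, backend=backend, warnings=warning_list)


def fit_color_scale(heats: Sequence[BondHeat]) -> ColorScale:
    """Normalize to the largest and smallest bond weights across the dataset."""
    all_w = np.concatenate([h.weights for h in heats]) if heats else np.array([])
    if all_w.size == 0:
        raise ValidationError("need at least one heat with at least one bond")
    return ColorScale(w_min=float(min(all_w.min(), 0.0)), w_max=float(max(all_w.max(), 0.0)))


def apply_color_scale(heat: BondHeat, scale: ColorScale) -> BondHeat:
    heat.color_values = scale.map(heat.weights)
    return heat


def shap_importances(fit: FitResult, X_background: np.ndarray, x: Sequence[float]) -> np.ndarray:
    """Exact SHAP values for a linear model under feature independence.

    phi_n = omega_n * (x_n - mean background x_n); the attributions sum to
    prediction(x) - mean background prediction exactly.
    """
    if fit.linear_view is None:
        raise CapabilityError("SHAP backend implemented for linear-family fits only")
    bg = np.asarray(getattr(X_background, "values", X_background), dtype=float)
    if bg.ndim != 2 or bg.shape[0] == 0:
        raise ConfigurationError("background must be a nonempty 2-D matrix")
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != bg.shape[1]:
        raise ValidationError("query row and background have different widths")
    return fit.linear_view.coefficients * (x - bg.mean(axis=0))


def _diverging_rgb(v: float) -> tuple[float, float, float]:
    # blue (-1) -> white (0) -> red (+1)
    v = float(np.clip(v, -1.0, 1.0))
    if v < 0:
        t = -v
        return (1 - t * (1 - NEGATIVE_COLOR[0]), 1 - t, 1 - t * (1 - NEGATIVE_COLOR[2]))
    t = v
    return (1 - t * (1 - POSITIVE_COLOR[0]), 1 - t, 1 - t * (1 - POSITIVE_COLOR[2]))


def _legend_svg(scale: ColorScale, width: int, height: int) -> str:
    bar_w, bar_h, x0 = 200, 12, (width - 200) // 2
    y0 = height - 34
    steps = 40
    rects = []
    for i in range(steps):
        v = -1.0 + 2.0 * (i + 0.5) / steps
        r, g, b = _diverging_rgb(v)
        rects.append(
            f"<rect x='{x0 + i * bar_w / steps:.1f}' y='{y0}' width='{bar_w / steps + 0.5:.1f}' "
            f"height='{bar_h}' fill='rgb({int(r * 255)},{int(g * 255)},{int(b * 255)})'/>"
        )
    labels = (
        f"<text x='{x0}' y='{y0 + bar_h + 12}' font-size='10' text-anchor='middle'>{scale.w_min:.2f}</text>"
        f"<text x='{x0 + bar_w / 2:.0f}' y='{y0 + bar_h + 12}' font-size='10' text-anchor='middle'>0</text>"
        f"<text x='{x0 + bar_w}' y='{y0 + bar_h + 12}' font-size='10' text-anchor='middle'>{scale.w_max:.2f}</text>"
    )
    return "".join(rects) + labels


def render_heatmap(
    heat: BondHeat, scale: ColorScale, path: str | Path, size: tuple[int, int] = CANVAS
) -> Path:
    """Write an SVG with bonds colored by the diverging map plus a legend.

    Output bytes are deterministic for fixed inputs and canvas settings.
    """
    mol = Chem.MolFromSmiles(heat.smiles)
    if mol is None:
        raise DepictionError(f"cannot depict {heat.smiles!r}")
    try:
        AllChem.Compute2DCoords(mol)
    except Exception as exc:  # pragma: no cover
        raise DepictionError(f"2D depiction failed for {heat.smiles!r}: {exc}") from exc
    colors = scale.map(heat.weights)
    bond_colors = {i: _diverging_rgb(v) for i, v in enumerate(colors)}
    drawer = rdMolDraw2D.MolDraw2DSVG(size[0], size[1])
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer,
        mol,
        highlightAtoms=[],
        highlightBonds=list(range(mol.GetNumBonds())),
        highlightBondColors=bond_colors,
    )
    drawer.FinishDrawing()
    svg = drawer.GetDrawingText()
    svg = svg.replace("</svg>", _legend_svg(scale, size[0], size[1]) + "</svg>")
    out = Path(path)
    out.write_text(svg)
    return out


def heat_sidecar(heat: BondHeat, scale: ColorScale) -> "pd.DataFrame":
    """CSV-ready table: bond index, atom pair, weight, color value."""
    import pandas as pd

    mol = Chem.MolFromSmiles(heat.smiles)
    colors = scale.map(heat.weights)
    rows = []
    for bond in mol.GetBonds():
        i = bond.GetIdx()
        rows.append(
            {
                "bond": i,
                "begin_atom": bond.GetBeginAtomIdx(),
                "end_atom": bond.GetEndAtomIdx(),
                "weight": heat.weights[i],
                "color_value": colors[i],
            }
        )
    return pd.DataFrame(rows)


def _occurrence_smiles(mol: Chem.Mol, occ: tuple[int, ...]) -> str | None:
    if not occ:
        return None
    try:
        frag = Chem.PathToSubmol(mol, list(occ))
        return Chem.MolToSmiles(frag, canonical=True)
    except Exception:
        return None


def collision_report(fps: Sequence[FingerprintResult]) -> CollisionReport:
    """Count distinct canonical substructures per bit across the dataset.

    A bit observed with more than one distinct substructure is flagged: its
    coefficient cannot be attributed to a unique motif.
    """
    substructures: dict[int, set[str]] = {}
    for fp in fps:
        mol = Chem.MolFromSmiles(fp.smiles)
        if mol is None:
            raise ValidationError(f"fingerprint source SMILES {fp.smiles!r} does not parse")
        for bit, occurrences in fp.provenance.items():
            for occ in occurrences:
                smi = _occurrence_smiles(mol, occ)
                if smi is not None:
                    substructures.setdefault(int(bit), set()).add(smi)
    counts = {bit: len(s) for bit, s in substructures.items()}
    return CollisionReport(counts=counts, substructures=substructures)
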