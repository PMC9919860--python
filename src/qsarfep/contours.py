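"""STDEV*COEFF contour grids from a fitted PLS model, with iso-level
selection and OpenDX export.

Each surviving descriptor column contributes stdev_j(X) * coefficient_j --
the activity change associated with one standard deviation of field
variation at that grid point -- scattered back to its spatial location
(dropped columns contribute zero).  Favored/disfavored iso-levels default to
the 80th percentile of the positive values and the 20th percentile of the
negative values per field kind, the classic contouring convention; viewers
then render the super-level sets as favored (green/blue/purple) and the
sub-level sets as disfavored (yellow/red/cyan) polyhedra.

Grids are exported as OpenDX scalar fields (one file per kind) readable by
common molecular viewers; data are written in the standard DX order (C order
over the grid axes, last axis fastest).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParameterError
from .fields import FieldBlock, GridSpec
from .pls import PLSModel

KIND_NAMES = {
    "S": "steric",
    "E": "electrostatic",
    "H": "hydrophobic",
    "A": "acceptor",
    "D": "donor",
}


@dataclass
class ContourSet:
    """Per-kind stdev*coeff grids (flat arrays over the grid's points)."""

    values: dict[str, np.ndarray]
    grid: GridSpec
    levels: dict[str, tuple[float, float]] = field(default_factory=dict)


def stdev_coeff(model: PLSModel, block: FieldBlock) -> ContourSet:
    """Scatter stdev_j * coefficient_j back onto the grid, per field kind."""
    if model.column_meta is None or model.column_meta != block.column_meta:
        raise ParameterError("model was not fitted on this block's columns")
    sd = block.matrix.std(axis=0, ddof=1)
    contrib = sd * model.coefficients
    values = {k: np.zeros(block.grid.n_points) for k in block.kinds}
    for j, (kind, gidx) in enumerate(block.column_meta):
        values[kind][gidx] = contrib[j]
    return ContourSet(values=values, grid=block.grid)


def iso_levels(
    cset: ContourSet,
    favored_pct: float = 80.0,
    disfavored_pct: float = 20.0,
) -> dict[str, tuple[float, float]]:
    """Contour levels per kind: (favored, disfavored).

    The favored level is the ``favored_pct`` percentile of the positive
    contributions; the disfavored level is the ``disfavored_pct`` percentile
    of the negative contributions.
    """
    levels: dict[str, tuple[float, float]] = {}
    for kind, vals in cset.values.items():
        pos = vals[vals > 0]
        neg = vals[vals < 0]
        if pos.size == 0 and neg.size == 0:
            raise ParameterError(f"no contours: field kind '{kind}' is all zero")
        fav = float(np.percentile(pos, favored_pct)) if pos.size else 0.0
        dis = float(np.percentile(neg, disfavored_pct)) if neg.size else 0.0
        levels[kind] = (fav, dis)
    cset.levels = levels
    return levels


def field_fraction_check(cset: ContourSet) -> dict[str, float]:
    """Per-kind percentage of total |stdev*coeff| mass (sums to 100)."""
    totals = {k: float(np.abs(v).sum()) for k, v in cset.values.items()}
    denom = sum(totals.values())
    if denom <= 0:
        raise ParameterError("all-zero contour set")
    return {k: 100.0 * v / denom for k, v in totals.items()}


# ---------------------------------------------------------------------------
# OpenDX scalar grid I/O
# ---------------------------------------------------------------------------

def write_dx(values: np.ndarray, grid: GridSpec, path) -> None:
    """Write one flat value array as an OpenDX regular scalar grid."""
    nx, ny, nz = grid.dims
    n = nx * ny * nz
    v = np.asarray(values, dtype=float).ravel()
    if v.size != n:
        raise ParameterError(f"{v.size} values for a {nx}x{ny}x{nz} grid")
    d = grid.spacing
    ox, oy, oz = grid.origin
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {ox:.6f} {oy:.6f} {oz:.6f}\n")
        fh.write(f"delta {d:.6f} 0.000000 0.000000\n")
        fh.write(f"delta 0.000000 {d:.6f} 0.000000\n")
        fh.write(f"delta 0.000000 0.000000 {d:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {n} data follows\n")
        for i in range(0, n, 3):  # %.17g preserves doubles exactly
            fh.write(" ".join(f"{x:.17g}" for x in v[i:i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_dx(path) -> tuple[np.ndarray, GridSpec]:
    """Read an OpenDX regular scalar grid written by :func:`write_dx`."""
    dims = None
    origin = None
    deltas = []
    values: list[float] = []
    n_items = None
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[:4] == ["object", "1", "class", "gridpositions"]:
                dims = tuple(int(x) for x in tok[-3:])
            elif tok[0] == "origin":
                origin = np.array([float(x) for x in tok[1:4]])
            elif tok[0] == "delta":
                deltas.append([float(x) for x in tok[1:4]])
            elif tok[0] == "object" and "data" in tok and "follows" in tok:
                n_items = int(tok[tok.index("items") + 1])
            elif n_items is not None and len(values) < n_items:
                try:
                    values.extend(float(x) for x in tok)
                except ValueError:
                    break
    if dims is None or origin is None or n_items is None or len(values) < n_items:
        raise ParameterError(f"not a regular OpenDX scalar grid: {path}")
    spacing = float(deltas[0][0])
    return np.array(values[:n_items]), GridSpec(origin=origin, spacing=spacing, dims=dims)


def export_grid(cset: ContourSet, out_dir, format: str = "dx") -> list[Path]:
    """Write one OpenDX file per field kind (steric.dx, electrostatic.dx, ...)."""
    if format != "dx":
        raise ParameterError(f"unsupported export format '{format}'")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for kind, vals in cset.values.items():
        p = out / f"{KIND_NAMES.get(kind, kind.lower())}.dx"
        write_dx(vals, cset.grid, p)
        paths.append(p)
    return paths
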