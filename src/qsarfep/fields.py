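"""CoMFA / CoMSIA molecular field computation on a shared rectilinear grid.

CoMFA probes every grid intersection with an sp3 carbon atom carrying a +1
charge.  The steric interaction is a 12-6 Lennard-Jones energy built from a
small embedded class table (r_min, epsilon) combined with Lorentz-Berthelot
mixing; the electrostatic interaction is a Coulomb term with a
distance-dependent dielectric eps(r) = r.  Both are truncated at +/-30
kcal/mol by default, and electrostatic values at grid points buried inside
the molecule (steric value at the cap) are replaced by the column mean over
the unburied compounds, following long-standing CoMFA practice.

CoMSIA replaces the hard LJ/Coulomb functional forms with Gaussian-attenuated
similarity indices: field_k(g) = -sum_i w_ik exp(-alpha r_ig^2), where w_ik is
the atom-i physicochemical property for field kind k (steric volume proxy,
partial charge, hydrophobicity, H-bond donor or acceptor flag) and the probe
has weight +1.  The Gaussian is bounded, so no truncation is needed.

The embedded parameter tables are part of this package's contract; they are
deliberately small and documented rather than a reproduction of any
proprietary force field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import COULOMB_KCAL
from .errors import ParameterError
from .structures import Molecule, MoleculeSet

# ---------------------------------------------------------------------------
# Embedded atom parameter tables
# ---------------------------------------------------------------------------

#: Lennard-Jones parameters per vdW class: (r_min/2 in Angstrom, epsilon in
#: kcal/mol).  Tripos-like values; combined with Lorentz-Berthelot mixing.
VDW_PARAMS: dict[str, tuple[float, float]] = {
    "C.3": (1.70, 0.107),
    "C.2": (1.70, 0.107),
    "C.ar": (1.70, 0.107),
    "N.3": (1.55, 0.095),
    "N.2": (1.55, 0.095),
    "N.ar": (1.55, 0.095),
    "O.3": (1.52, 0.116),
    "O.2": (1.52, 0.116),
    "S.3": (1.80, 0.314),
    "F": (1.47, 0.109),
    "Cl": (1.75, 0.314),
    "Br": (1.85, 0.434),
    "H": (1.20, 0.042),
}

#: sp3 carbon probe used for both CoMFA fields (class, charge).
PROBE_CLASS = "C.3"
PROBE_CHARGE = 1.0

#: CoMSIA per-element property table.  ``steric`` is a van der Waals volume
#: proxy (r_vdw^3, Angstrom^3); hydrophobicity is a coarse +1/-1 scale; donor
#: and acceptor are element-level flags (no bond graph is available).
COMSIA_ATOM_PROPS: dict[str, dict[str, float]] = {
    "C": {"steric": 4.91, "hydrophobic": 1.0, "donor": 0.0, "acceptor": 0.0},
    "N": {"steric": 3.72, "hydrophobic": -1.0, "donor": 1.0, "acceptor": 1.0},
    "O": {"steric": 3.51, "hydrophobic": -1.0, "donor": 0.0, "acceptor": 1.0},
    "S": {"steric": 5.83, "hydrophobic": 1.0, "donor": 0.0, "acceptor": 0.0},
    "F": {"steric": 3.18, "hydrophobic": 0.0, "donor": 0.0, "acceptor": 1.0},
    "Cl": {"steric": 5.36, "hydrophobic": 1.0, "donor": 0.0, "acceptor": 0.0},
    "Br": {"steric": 6.33, "hydrophobic": 1.0, "donor": 0.0, "acceptor": 0.0},
    "H": {"steric": 1.73, "hydrophobic": 0.0, "donor": 0.0, "acceptor": 0.0},
}

COMFA_KINDS = ("S", "E")
COMSIA_KINDS = ("S", "E", "H", "A", "D")
#: Default CoMSIA field combination (steric, electrostatic, H-bond donor).
COMSIA_DEFAULT_KINDS = ("S", "E", "D")

DEFAULT_ENERGY_CAP = 30.0  # kcal/mol
DEFAULT_ALPHA = 0.3  # CoMSIA attenuation, 1/Angstrom^2
DEFAULT_MIN_SIGMA = 2.0  # CoMFA column filter, kcal/mol


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Axis-aligned rectilinear grid: origin, uniform spacing, point counts."""

    origin: np.ndarray  # 3-vector, Angstrom
    spacing: float  # Angstrom
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.dims = tuple(int(d) for d in self.dims)
        if self.spacing <= 0:
            raise ParameterError("grid spacing must be positive")
        if any(d < 2 for d in self.dims):
            raise ParameterError("grid needs at least 2 points per axis")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All grid points as an (N, 3) array in C order (z varies fastest)."""
        axes = [self.origin[k] + self.spacing * np.arange(self.dims[k]) for k in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    def point(self, flat_index: int) -> np.ndarray:
        nx, ny, nz = self.dims
        i, rem = divmod(int(flat_index), ny * nz)
        j, k = divmod(rem, nz)
        return self.origin + self.spacing * np.array([i, j, k], dtype=float)


def make_grid(mset: MoleculeSet, spacing: float = 1.0, margin: float = 4.0) -> GridSpec:
    """Build the grid enclosing every aligned molecule plus a margin.

    The box covers the union bounding box extended by ``margin`` on every
    side; dims = ceil(extent / spacing) + 1 per axis.
    """
    if len(mset) == 0:
        raise ParameterError("cannot build a grid around an empty molecule set")
    coords = mset.all_coords()
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    extent = hi - lo
    dims = tuple(int(np.ceil(e / spacing - 1e-9)) + 1 for e in extent)
    return GridSpec(origin=lo, spacing=float(spacing), dims=dims)


# ---------------------------------------------------------------------------
# CoMFA fields
# ---------------------------------------------------------------------------

def _lj_parameters(classes: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom LJ A, C coefficients against the sp3 carbon probe."""
    rp, ep = VDW_PARAMS[PROBE_CLASS]
    A = np.empty(len(classes))
    C = np.empty(len(classes))
    for i, cls in enumerate(classes):
        if cls not in VDW_PARAMS:
            raise ParameterError(f"unknown vdW class '{cls}' (no LJ parameters)")
        ri, ei = VDW_PARAMS[cls]
        rmin = ri + rp  # Lorentz mixing on radii
        eps = np.sqrt(ei * ep)  # Berthelot mixing
        A[i] = eps * rmin ** 12
        C[i] = 2.0 * eps * rmin ** 6
    return A, C


def comfa_fields(
    mol: Molecule, grid: GridSpec, cap: float = DEFAULT_ENERGY_CAP
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CoMFA steric and electrostatic field vectors for one molecule.

    Returns ``(steric, electrostatic, buried)`` where ``buried`` marks grid
    points whose untruncated steric energy reached the cap (probe inside the
    molecule).  Electrostatics at buried points are *not* substituted here --
    that is a column-wise operation done in :func:`assemble_block` once all
    compounds are known.
    """
    pts = grid.points()
    diff = mol.coords[:, None, :] - pts[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=2))
    np.maximum(r, 1e-6, out=r)  # guard probe-on-atom singularities
    A, C = _lj_parameters(mol.vdw_classes)
    inv_r6 = r ** -6
    steric_raw = np.sum(A[:, None] * inv_r6 * inv_r6 - C[:, None] * inv_r6, axis=0)
    buried = steric_raw >= cap
    steric = np.clip(steric_raw, -cap, cap)
    # Coulomb with distance-dependent dielectric eps(r) = r  ->  q/r^2
    elec = COULOMB_KCAL * PROBE_CHARGE * np.sum(mol.charges[:, None] / (r * r), axis=0)
    elec = np.clip(elec, -cap, cap)
    return steric, elec, buried


# ---------------------------------------------------------------------------
# CoMSIA fields
# ---------------------------------------------------------------------------

def _comsia_weights(mol: Molecule, kind: str) -> np.ndarray:
    if kind == "E":
        return mol.charges.astype(float)
    key = {"S": "steric", "H": "hydrophobic", "A": "acceptor", "D": "donor"}[kind]
    w = np.empty(mol.n_atoms)
    for i, el in enumerate(mol.elements):
        if el not in COMSIA_ATOM_PROPS:
            raise ParameterError(f"no CoMSIA property entry for element '{el}'")
        w[i] = COMSIA_ATOM_PROPS[el][key]
    return w


def comsia_fields(
    mol: Molecule,
    grid: GridSpec,
    alpha: float = DEFAULT_ALPHA,
    kinds: tuple[str, ...] = COMSIA_KINDS,
) -> dict[str, np.ndarray]:
    """Gaussian-attenuated similarity fields for one molecule.

    field_k(g) = -sum_i w_ik exp(-alpha r_ig^2); the probe weight is +1 and
    alpha defaults to 0.3 A^-2.
    """
    for k in kinds:
        if k not in COMSIA_KINDS:
            raise ParameterError(f"unknown CoMSIA field kind '{k}'")
    pts = grid.points()
    diff = mol.coords[:, None, :] - pts[None, :, :]
    gauss = np.exp(-alpha * np.sum(diff * diff, axis=2))
    return {k: -(_comsia_weights(mol, k)[None, :] @ gauss)[0] for k in kinds}


# ---------------------------------------------------------------------------
# Descriptor block assembly
# ---------------------------------------------------------------------------

@dataclass
class FieldBlock:
    """Compounds x grid-columns descriptor matrix with column provenance.

    ``column_meta[j]`` is ``(field_kind, flat_grid_index)`` for matrix column
    j; ``dropped_columns`` records the filtered-out columns with reasons;
    ``scaling[kind]`` is the CoMFA-STD divisor applied to that field kind.
    """

    matrix: np.ndarray  # (n_compounds, n_columns)
    column_meta: list[tuple[str, int]]
    ids: list[str]
    grid: GridSpec
    method: str  # 'comfa' | 'comsia'
    dropped_columns: list[tuple[str, int, str]] = field(default_factory=list)
    scaling: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.column_meta):
            raise ParameterError("column_meta length must equal column count")
        if not np.all(np.isfinite(self.matrix)):
            raise ParameterError("field block contains non-finite values")

    @property
    def kinds(self) -> list[str]:
        seen: list[str] = []
        for k, _ in self.column_meta:
            if k not in seen:
                seen.append(k)
        return seen

    def rows(self, ids: list[str]) -> np.ndarray:
        index = {cid: i for i, cid in enumerate(self.ids)}
        return self.matrix[[index[c] for c in ids]]


def assemble_block(
    mset: MoleculeSet,
    grid: GridSpec,
    method: str = "comfa",
    kinds: tuple[str, ...] | None = None,
    min_sigma: float = DEFAULT_MIN_SIGMA,
    cap: float = DEFAULT_ENERGY_CAP,
    alpha: float = DEFAULT_ALPHA,
    block_scaling: bool = True,
) -> FieldBlock:
    """Compute fields for every molecule and assemble the descriptor matrix.

    Columns are ordered by (field kind, flat grid index).  Columns whose
    standard deviation across compounds falls below ``min_sigma`` are dropped
    and recorded.  With ``block_scaling`` (CoMFA-STD) each surviving field
    kind is divided by its pooled column standard deviation so that every
    kind enters the PLS with equal overall variance.
    """
    if len(mset) == 0:
        raise ParameterError("empty molecule set")
    if method not in ("comfa", "comsia"):
        raise ParameterError(f"unknown method '{method}'")
    if kinds is None:
        kinds = COMFA_KINDS if method == "comfa" else COMSIA_DEFAULT_KINDS
    if len(kinds) == 0:
        raise ParameterError("at least one field kind required")

    per_kind: dict[str, np.ndarray] = {}
    if method == "comfa":
        for k in kinds:
            if k not in COMFA_KINDS:
                raise ParameterError(f"CoMFA supports kinds {COMFA_KINDS}, got '{k}'")
        ster_rows, elec_rows, buried_rows = [], [], []
        for mol in mset:
            s, e, b = comfa_fields(mol, grid, cap=cap)
            ster_rows.append(s)
            elec_rows.append(e)
            buried_rows.append(b)
        steric = np.vstack(ster_rows)
        elec = np.vstack(elec_rows)
        buried = np.vstack(buried_rows)
        # electrostatics inside the steric envelope carry no information:
        # replace by the column mean over unburied compounds
        for j in np.nonzero(buried.any(axis=0))[0]:
            mask = buried[:, j]
            elec[mask, j] = elec[~mask, j].mean() if not mask.all() else 0.0
        if "S" in kinds:
            per_kind["S"] = steric
        if "E" in kinds:
            per_kind["E"] = elec
    else:
        rows: dict[str, list[np.ndarray]] = {k: [] for k in kinds}
        for mol in mset:
            fv = comsia_fields(mol, grid, alpha=alpha, kinds=tuple(kinds))
            for k in kinds:
                rows[k].append(fv[k])
        per_kind = {k: np.vstack(rows[k]) for k in kinds}

    kept_cols: list[np.ndarray] = []
    meta: list[tuple[str, int]] = []
    dropped: list[tuple[str, int, str]] = []
    scaling: dict[str, float] = {}
    for k in kinds:
        M = per_kind[k]
        sd = M.std(axis=0, ddof=1) if M.shape[0] > 1 else np.zeros(M.shape[1])
        keep = sd >= min_sigma
        for j in np.nonzero(~keep)[0]:
            dropped.append((k, int(j), f"sigma {sd[j]:.4g} below {min_sigma}"))
        Mk = M[:, keep]
        if block_scaling and Mk.shape[1] > 0:
            pooled = float(np.sqrt(np.mean(Mk.var(axis=0, ddof=1))))
            if pooled > 0:
                Mk = Mk / pooled
                scaling[k] = pooled
            else:
                scaling[k] = 1.0
        else:
            scaling[k] = 1.0
        kept_cols.append(Mk)
        meta.extend((k, int(j)) for j in np.nonzero(keep)[0])

    matrix = (np.hstack(kept_cols) if kept_cols else np.empty((len(mset), 0)))
    return FieldBlock(
        matrix=matrix,
        column_meta=meta,
        ids=mset.ids,
        grid=grid,
        method=method,
        dropped_columns=dropped,
        scaling=scaling,
    )
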