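"""Synthetic inputs for every pipeline stage.

Three generators stand in for data that would otherwise require laboratory
assays or molecular-dynamics sampling:

* :func:`generate_ligand_series` builds a congeneric series -- a rigid common
  core shared bit-identically by all compounds, decorated at a few R-group
  sites.  Each site carries a small per-seed library of discrete substituent
  variants (0-3 atoms from a C/N/O/Cl palette placed at jittered radii of
  1.2-2.5 A around the site), and every compound draws one variant per site,
  with a small positional jitter per compound.  Sharing substituents across
  compounds is what real congeneric series do, and it gives the descriptor
  matrix the redundant, low-rank structure that field-based QSAR relies on.
  Activities are planted as a baseline plus a linear model over actual CoMFA
  steric field values at chosen grid columns plus Gaussian noise, so the
  structure-activity signal is recoverable by construction (exactly, in the
  noiseless limit).

* :func:`generate_energy_series` emits i.i.d. Gaussian per-frame end-state
  energy terms with planted means and spreads, emulating the per-frame output
  of an MM-PB/GBSA post-processor.

* :func:`generate_work_samples` emits Gaussian forward/reverse energy
  differences for each adjacent lambda-window pair.  Means are placed at
  +/-dG + beta sigma^2 / 2 with common sigma, which satisfies the Crooks
  fluctuation relation exactly, so the analytic free energy of each pair
  equals the planted value.

All randomness flows through numpy's PCG64 ``default_rng``; one seed per
artifact is split into independent child streams (per compound / replicate /
window) with ``SeedSequence.spawn``, making outputs bit-reproducible across
runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import KB_KCAL
from .errors import ParameterError
from .fields import DEFAULT_MIN_SIGMA, assemble_block, make_grid
from .structures import Molecule, MoleculeSet

#: (element, vdW class, charge range) palette for R-group decoration atoms
_RGROUP_PALETTE = (
    ("C", "C.3", (-0.10, 0.10)),
    ("N", "N.3", (-0.45, -0.15)),
    ("O", "O.3", (-0.55, -0.25)),
    ("Cl", "Cl", (-0.20, 0.00)),
)

_KNOWN_ENERGY_TERMS = frozenset({"VDWAALS", "EEL", "EGB", "EPB", "ESURF"})


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSeriesSpec:
    """Congeneric-series recipe with a planted linear activity model.

    ``effect_weights`` maps R-group site index -> weight in pIC50 units per
    (scaled) field unit; ``noise_sd`` is the activity noise in pIC50 units.
    ``baseline`` shifts activities into a realistic potency range (pIC50 of
    active kinase inhibitors clusters around 6-9).  ``n_variants`` sets the
    size of each site's substituent library and ``jitter`` the per-compound
    positional noise (Angstrom) on decoration atoms.
    """

    n_compounds: int = 40
    core_atoms: int = 8
    rgroup_sites: int = 3
    effect_weights: dict[int, float] = field(
        default_factory=lambda: {0: 1.0, 1: -0.8, 2: 0.6}
    )
    noise_sd: float = 0.2
    baseline: float = 7.0
    n_variants: int = 6
    jitter: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_compounds < 8:
            raise ParameterError("n_compounds must be >= 8")
        if self.core_atoms < 3:
            raise ParameterError("core_atoms must be >= 3")
        if self.rgroup_sites < 1:
            raise ParameterError("rgroup_sites must be >= 1")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not self.effect_weights:
            raise ParameterError("effect_weights must not be empty")
        for s, w in self.effect_weights.items():
            if not (0 <= s < self.rgroup_sites):
                raise ParameterError(f"effect weight site {s} out of range")
            if not np.isfinite(w):
                raise ParameterError("effect weights must be finite")
        if self.n_variants < 2:
            raise ParameterError("n_variants must be >= 2")
        if self.jitter < 0:
            raise ParameterError("jitter must be >= 0")


@dataclass
class SyntheticEnergySpec:
    """Gaussian per-frame energy series recipe (kcal/mol)."""

    n_frames: int = 1000
    term_means: dict[str, float] = field(
        default_factory=lambda: {"VDWAALS": -58.85, "EEL": -16.96,
                                 "EGB": 29.54, "ESURF": -6.49}
    )
    term_sds: dict[str, float] = field(
        default_factory=lambda: {"VDWAALS": 3.0, "EEL": 2.0,
                                 "EGB": 2.0, "ESURF": 0.5}
    )
    residue_means: dict[str, float] | None = None
    residue_sds: dict[str, float] | None = None
    temperature: float = 300.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        unknown = set(self.term_means) - _KNOWN_ENERGY_TERMS
        if unknown:
            raise ParameterError(f"unknown energy term names: {sorted(unknown)}")
        for name in self.term_means:
            if self.term_sds.get(name, 0.0) < 0:
                raise ParameterError(f"negative sd for term {name}")
        if self.temperature <= 0:
            raise ParameterError("temperature must be positive")


@dataclass
class SyntheticWorkSpec:
    """Gaussian bidirectional work samples with analytically known dG.

    ``delta_g_true`` is the free energy difference per adjacent lambda pair
    (a scalar applied to every pair, or one value per pair), in kcal/mol.
    """

    delta_g_true: float | list[float] = 0.5
    work_sd: float = 1.0
    n_samples: int = 5000
    n_windows: int = 12
    n_replicates: int = 3
    temperature: float = 300.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_windows < 2:
            raise ParameterError("n_windows must be >= 2")
        if self.n_samples < 10:
            raise ParameterError("n_samples must be >= 10")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")
        if self.temperature <= 0:
            raise ParameterError("temperature must be positive")
        if self.work_sd < 0:
            raise ParameterError("work_sd must be >= 0")

    def per_pair_dg(self) -> np.ndarray:
        n_pairs = self.n_windows - 1
        dg = np.asarray(self.delta_g_true, dtype=float)
        if dg.ndim == 0:
            return np.full(n_pairs, float(dg))
        if dg.shape != (n_pairs,):
            raise ParameterError(f"delta_g_true must be scalar or length {n_pairs}")
        return dg


# ---------------------------------------------------------------------------
# Ligand series
# ---------------------------------------------------------------------------

def _site_centers(core_centroid: np.ndarray, n_sites: int, radius: float = 3.5) -> np.ndarray:
    angles = 2.0 * np.pi * np.arange(n_sites) / max(n_sites, 1)
    z = 0.4 * np.where(np.arange(n_sites) % 2 == 0, 1.0, -1.0)
    dirs = np.column_stack([np.cos(angles), np.sin(angles), z])
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return core_centroid + radius * dirs


def generate_ligand_series(
    spec: SyntheticSeriesSpec,
    spacing: float = 1.0,
    margin: float = 4.0,
    min_sigma: float = DEFAULT_MIN_SIGMA,
) -> tuple[MoleculeSet, pd.DataFrame]:
    """Generate an aligned congeneric series and its planted activity table.

    Returns ``(molecules, activities)``.  The activity DataFrame carries the
    planting metadata in ``activities.attrs``: the descriptor-column indices
    (``planted_columns``), the flat grid indices (``planted_grid_indices``),
    the R-group site centers and the field-engine settings used, so tests and
    downstream checks can locate the signal.

    Activities are pIC50_i = baseline + sum_s w_s X_i[col_s] + eps_i where X
    is the CoMFA descriptor block assembled with the same defaults the
    analysis pipeline uses (so noiseless activities are exactly linear in
    surviving steric columns) and eps ~ N(0, noise_sd^2).
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(2 + spec.n_compounds)
    core_rng = np.random.default_rng(children[0])
    noise_rng = np.random.default_rng(children[1])

    core_coords = core_rng.normal(0.0, 1.2, size=(spec.core_atoms, 3))
    core_charges = core_rng.uniform(-0.2, 0.2, size=spec.core_atoms)
    centers = _site_centers(core_coords.mean(axis=0), spec.rgroup_sites)

    # substituent library: n_variants discrete R-groups per site (possibly
    # empty = unsubstituted), shared by all compounds
    library: list[list[list[tuple[str, str, np.ndarray, float]]]] = []
    for s in range(spec.rgroup_sites):
        variants = []
        for _v in range(spec.n_variants):
            atoms = []
            for _ in range(int(core_rng.integers(0, 4))):
                el, cls, (qlo, qhi) = _RGROUP_PALETTE[int(core_rng.integers(len(_RGROUP_PALETTE)))]
                direction = core_rng.normal(size=3)
                direction /= np.linalg.norm(direction)
                pos = centers[s] + core_rng.uniform(1.2, 2.5) * direction
                atoms.append((el, cls, pos, float(core_rng.uniform(qlo, qhi))))
            variants.append(atoms)
        library.append(variants)

    mols = []
    width = max(2, len(str(spec.n_compounds)))
    for i in range(spec.n_compounds):
        rng = np.random.default_rng(children[2 + i])
        elements = ["C"] * spec.core_atoms
        classes = ["C.3"] * spec.core_atoms
        coords = [core_coords]
        charges = [core_charges]
        for s in range(spec.rgroup_sites):
            variant = library[s][int(rng.integers(spec.n_variants))]
            for el, cls, pos, qv in variant:
                coords.append((pos + rng.normal(0.0, spec.jitter, 3))[None, :])
                charges.append(np.array([qv]))
                elements.append(el)
                classes.append(cls)
        mols.append(Molecule(
            id=f"C{i + 1:0{width}d}",
            elements=elements,
            vdw_classes=classes,
            coords=np.vstack(coords),
            charges=np.concatenate(charges),
        ))
    mset = MoleculeSet(mols)

    grid = make_grid(mset, spacing=spacing, margin=margin)
    block = assemble_block(mset, grid, method="comfa", min_sigma=min_sigma)

    # pick, per planted site, the surviving steric column with the largest
    # spread among grid points near the site center
    pts = grid.points()
    steric_cols = [(j, g) for j, (k, g) in enumerate(block.column_meta) if k == "S"]
    col_sd = block.matrix.std(axis=0, ddof=1)
    planted_cols: dict[int, int] = {}
    for s, w in spec.effect_weights.items():
        for reach in (2.5, 4.0, 6.0):
            near = [j for j, g in steric_cols
                    if np.linalg.norm(pts[g] - centers[s]) <= reach]
            if near:
                break
        if not near:
            raise ParameterError(
                f"no surviving steric column near planted site {s}; "
                "lower min_sigma or enlarge the series"
            )
        planted_cols[s] = int(max(near, key=lambda j: col_sd[j]))

    y = np.full(spec.n_compounds, spec.baseline)
    for s, w in spec.effect_weights.items():
        y += w * block.matrix[:, planted_cols[s]]
    y += noise_rng.normal(0.0, spec.noise_sd, size=spec.n_compounds)

    for mol, v in zip(mset, y):
        mol.pic50 = float(v)
    activities = pd.DataFrame({"id": mset.ids, "pIC50": y})
    activities.attrs.update({
        "planted_columns": [planted_cols[s] for s in sorted(planted_cols)],
        "planted_grid_indices": [block.column_meta[planted_cols[s]][1]
                                 for s in sorted(planted_cols)],
        "site_centers": centers,
        "spacing": spacing,
        "margin": margin,
        "min_sigma": min_sigma,
    })
    return mset, activities


# ---------------------------------------------------------------------------
# Energy series
# ---------------------------------------------------------------------------

def generate_energy_series(spec: SyntheticEnergySpec):
    """Planted-Gaussian per-frame end-state energy terms.

    Returns an :class:`~qsarfep.mmgbsa.EnergyTermSeries`; each term is an
    i.i.d. normal series with the requested mean and spread.
    """
    from .mmgbsa import EnergyTermSeries  # local import to avoid a cycle

    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    names = sorted(spec.term_means)
    res_names = sorted(spec.residue_means) if spec.residue_means else []
    children = ss.spawn(len(names) + len(res_names))
    terms = {}
    for name, child in zip(names, children):
        rng = np.random.default_rng(child)
        terms[name] = rng.normal(spec.term_means[name],
                                 spec.term_sds.get(name, 0.0), size=spec.n_frames)
    per_residue = None
    if res_names:
        per_residue = {}
        for name, child in zip(res_names, children[len(names):]):
            rng = np.random.default_rng(child)
            sd = (spec.residue_sds or {}).get(name, 0.0)
            per_residue[name] = rng.normal(spec.residue_means[name], sd,
                                           size=spec.n_frames)
    return EnergyTermSeries(terms=terms, per_residue=per_residue,
                            temperature=spec.temperature)


# ---------------------------------------------------------------------------
# Work samples
# ---------------------------------------------------------------------------

def generate_work_samples(spec: SyntheticWorkSpec, system: str = "complex"):
    """Gaussian forward/reverse work samples per lambda pair and replicate.

    Forward samples ~ N(dG + beta sigma^2 / 2, sigma^2) and reverse samples
    ~ N(-dG + beta sigma^2 / 2, sigma^2), which satisfies the Crooks relation
    so the analytic free energy per pair equals the planted dG exactly.
    Returns a :class:`~qsarfep.rbfe.WorkSampleSet`.
    """
    from .rbfe import WorkSampleSet  # local import to avoid a cycle

    spec.validate()
    beta = 1.0 / (KB_KCAL * spec.temperature)
    dg = spec.per_pair_dg()
    offset = beta * spec.work_sd**2 / 2.0
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_replicates * (spec.n_windows - 1))
    data = {}
    idx = 0
    for rep in range(spec.n_replicates):
        for pair in range(spec.n_windows - 1):
            rng = np.random.default_rng(children[idx])
            idx += 1
            fwd = rng.normal(dg[pair] + offset, spec.work_sd, size=spec.n_samples)
            rev = rng.normal(-dg[pair] + offset, spec.work_sd, size=spec.n_samples)
            data[(pair, rep)] = (fwd, rev)
    return WorkSampleSet(data=data, temperature=spec.temperature, system=system)
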