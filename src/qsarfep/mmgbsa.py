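"""MM-PB/GBSA end-state bookkeeping: term aggregation, interaction entropy,
per-residue decomposition and the ligand contact shell.

This module sits downstream of the (external) molecular-dynamics and PB/GB
solvers: its input is a per-frame series of energy terms -- gas-phase van der
Waals (VDWAALS) and electrostatic (EEL) contributions plus polar (EGB or EPB)
and non-polar (ESURF) solvation terms, all in kcal/mol.  The binding energy
is composed as

    dG_bind = dTOTAL + (-T dS),      dTOTAL = <VDW> + <EEL> + <polar> + <SASA>

with the entropic penalty estimated by the interaction-entropy formula

    -T dS = (1/beta) ln < exp(beta (E_int - <E_int>)) >,

an exponential average of interaction-energy fluctuations (E_int = VDWAALS +
EEL by default).  By Jensen's inequality this is non-negative for any
fluctuating series.  The exponential is evaluated through log-sum-exp to stay
finite for large fluctuations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, KB_KCAL
from .errors import ParameterError
from .structures import Molecule

GAS_TERMS = ("VDWAALS", "EEL")
POLAR_TERMS = ("EGB", "EPB")
REQUIRED_TERMS = ("VDWAALS", "EEL", "ESURF")  # plus one of EGB/EPB
DEFAULT_ENTROPY_TERMS = ("VDWAALS", "EEL")


@dataclass
class EnergyTermSeries:
    """Per-frame energy terms (kcal/mol) with optional per-residue series."""

    terms: dict[str, np.ndarray]
    per_residue: dict[str, np.ndarray] | None = None
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.terms = {k: np.asarray(v, dtype=float) for k, v in self.terms.items()}
        lengths = {v.size for v in self.terms.values()}
        if len(lengths) > 1:
            raise ParameterError(f"unequal frame counts across terms: {lengths}")
        if self.per_residue is not None:
            self.per_residue = {k: np.asarray(v, dtype=float)
                                for k, v in self.per_residue.items()}
        if self.temperature <= 0:
            raise ParameterError("temperature must be positive")

    @property
    def frames(self) -> int:
        return next(iter(self.terms.values())).size if self.terms else 0


@dataclass
class BindingEnergyReport:
    """Aggregated binding-energy summary (kcal/mol)."""

    term_means: dict[str, float]
    delta_total: float
    minus_t_delta_s: float
    delta_g_bind: float


def _aggregation_terms(series: EnergyTermSeries) -> list[str]:
    missing = [t for t in REQUIRED_TERMS if t not in series.terms]
    polar = [t for t in POLAR_TERMS if t in series.terms]
    if missing or not polar:
        need = list(missing) + ([] if polar else ["EGB or EPB"])
        raise ParameterError(f"missing required energy terms: {need}")
    return ["VDWAALS", "EEL", polar[0], "ESURF"]


def aggregate(series: EnergyTermSeries) -> tuple[dict[str, float], float]:
    """Arithmetic mean per term and their sum (dTOTAL) over the four
    gas-phase + solvation terms."""
    if series.frames < 2:
        raise ParameterError("need at least 2 frames")
    use = _aggregation_terms(series)
    means = {t: float(series.terms[t].mean()) for t in series.terms}
    delta_total = float(sum(means[t] for t in use))
    return means, delta_total


def interaction_entropy(
    series: EnergyTermSeries,
    terms: tuple[str, ...] = DEFAULT_ENTROPY_TERMS,
) -> float:
    """-T dS from the exponential average of interaction-energy fluctuations.

    ``terms`` selects the components summed into E_int per frame (default
    gas-phase VDWAALS + EEL).  Computed via log-sum-exp; raises if the result
    still overflows (wildly fluctuating or far-too-short series).
    """
    for t in terms:
        if t not in series.terms:
            raise ParameterError(f"term '{t}' absent from series")
    e_int = np.sum([series.terms[t] for t in terms], axis=0)
    n = e_int.size
    if n < 2:
        raise ParameterError("need at least 2 frames")
    beta = 1.0 / (KB_KCAL * series.temperature)
    fluct = beta * (e_int - e_int.mean())
    value = (logsumexp(fluct) - np.log(n)) / beta
    if not np.isfinite(value):
        raise ParameterError("interaction entropy overflowed; sample more frames")
    return float(value)


def binding_report(
    series: EnergyTermSeries,
    entropy_terms: tuple[str, ...] = DEFAULT_ENTROPY_TERMS,
) -> BindingEnergyReport:
    """Full composition: term means, dTOTAL, -T dS and dG_bind."""
    means, delta_total = aggregate(series)
    tds = interaction_entropy(series, entropy_terms)
    return BindingEnergyReport(
        term_means=means,
        delta_total=delta_total,
        minus_t_delta_s=tds,
        delta_g_bind=delta_total + tds,
    )


def per_residue_rank(series: EnergyTermSeries, top_n: int | None = None) -> list[tuple[str, float]]:
    """Mean per-residue contribution, most favorable (lowest) first.

    Ties are broken by residue id.
    """
    if not series.per_residue:
        raise ParameterError("series has no per-residue decomposition")
    ranked = sorted(
        ((rid, float(v.mean())) for rid, v in series.per_residue.items()),
        key=lambda kv: (kv[1], kv[0]),
    )
    return ranked[:top_n] if top_n is not None else ranked


def contact_shell(
    protein_coords: dict[str, np.ndarray],
    ligand: Molecule,
    cutoff: float = 4.0,
) -> list[str]:
    """Residues with at least one atom strictly within ``cutoff`` Angstrom of
    any ligand atom, in residue-id order."""
    if not protein_coords or ligand.n_atoms == 0:
        raise ParameterError("empty protein or ligand input")
    if cutoff <= 0:
        return []
    tree = cKDTree(ligand.coords)
    hits = []
    for rid, coords in protein_coords.items():
        d, _ = tree.query(np.atleast_2d(np.asarray(coords, dtype=float)), k=1)
        if np.min(d) < cutoff:
            hits.append(rid)
    return sorted(hits)


# ---------------------------------------------------------------------------
# CSV I/O (gmx_MMPBSA-style per-frame tables)
# ---------------------------------------------------------------------------

def read_energy_series(path, temperature: float = DEFAULT_TEMPERATURE) -> EnergyTermSeries:
    """Read a per-frame CSV (columns: frame, term names, optional ``R:<id>``
    per-residue columns)."""
    import pandas as pd

    df = pd.read_csv(path)
    terms = {c: df[c].to_numpy(float) for c in df.columns
             if c != "frame" and not c.startswith("R:")}
    residues = {c[2:]: df[c].to_numpy(float) for c in df.columns if c.startswith("R:")}
    return EnergyTermSeries(terms=terms, per_residue=residues or None,
                            temperature=temperature)


def write_energy_series(series: EnergyTermSeries, path) -> None:
    import pandas as pd

    data = {"frame": np.arange(series.frames)}
    data.update({k: v for k, v in series.terms.items()})
    if series.per_residue:
        data.update({f"R:{k}": v for k, v in series.per_residue.items()})
    pd.DataFrame(data).to_csv(path, index=False)
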