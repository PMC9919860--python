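"""Relative binding free energy bookkeeping: BAR estimation over lambda
windows, replicate aggregation, the thermodynamic cycle, and correlation with
experiment.

The alchemical transformation of ligand A into ligand B is sampled in both
the protein complex and in solution across a schedule of lambda windows
(default: 12 uniformly spaced states).  For each adjacent window pair the
free energy difference is estimated with the Bennett acceptance ratio (BAR):
dG solves the self-consistency condition

    sum_F f(beta w_F - beta dG + M)  =  sum_R f(beta w_R + beta dG - M),

where f is the Fermi function 1/(1 + e^x), w_F are forward energy differences
(U_{i+1} - U_i sampled at lambda_i), w_R reverse differences (U_i - U_{i+1}
at lambda_{i+1}) and M = ln(n_F / n_R).  The root is bracketed within +/-100
kcal/mol and polished to machine precision; the asymptotic standard error
uses Bennett's variance estimator.  Chaining the per-pair estimates along the
schedule gives the leg totals dG_COM and dG_LIG, and the cycle closes as

    ddG_RBFE(A->B) = dG_COM(A->B) - dG_LIG(A->B).

Experimental references come from activities: dG_EXP = -RT ln(10) pIC50, and
ddG_EXP(A->B) = dG_EXP(B) - dG_EXP(A).  Computed and experimental relative
affinities are compared by Pearson correlation and an ordinary least-squares
line (ddG_EXP regressed on ddG_RBFE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp
from scipy.stats import linregress, pearsonr

from .constants import DEFAULT_TEMPERATURE, KB_KCAL, LN10
from .errors import InsufficientOverlapError, ParameterError

_BRACKET = 100.0  # kcal/mol search window for the BAR root


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class LambdaSchedule:
    """Ordered lambda values in [0, 1] with exact endpoints."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 2:
            raise ParameterError("schedule needs at least 2 lambda values")
        if self.values[0] != 0.0 or self.values[-1] != 1.0:
            raise ParameterError("schedule endpoints must be exactly 0 and 1")
        if np.any(np.diff(self.values) <= 0):
            raise ParameterError("lambda values must be strictly increasing")

    @classmethod
    def uniform(cls, n_windows: int = 12) -> "LambdaSchedule":
        return cls(np.linspace(0.0, 1.0, n_windows))

    @property
    def n_windows(self) -> int:
        return self.values.size

    @property
    def n_pairs(self) -> int:
        return self.values.size - 1


@dataclass
class WorkSampleSet:
    """Forward/reverse energy-difference samples per (pair, replicate).

    ``data[(pair_index, replicate)] = (forward, reverse)`` in kcal/mol.
    """

    data: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]
    temperature: float = DEFAULT_TEMPERATURE
    system: str = "complex"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ParameterError("temperature must be positive")
        for key, (f, r) in self.data.items():
            f, r = np.asarray(f, float), np.asarray(r, float)
            if f.size < 1 or r.size < 1:
                raise ParameterError(f"empty sample set at (pair, replicate)={key}")
            self.data[key] = (f, r)

    @property
    def replicates(self) -> list[int]:
        return sorted({rep for _, rep in self.data})

    @property
    def pairs(self) -> list[int]:
        return sorted({pair for pair, _ in self.data})


@dataclass
class BarResult:
    delta_g: float  # kcal/mol
    stderr: float  # asymptotic, kcal/mol


@dataclass
class ChainResult:
    """Per-replicate leg totals and their aggregate."""

    per_replicate: np.ndarray  # total dG per replicate
    mean: float
    sd: float  # across replicates (0 if single replicate)
    stderr: float  # aggregate asymptotic stderr of the replicate mean
    system: str = "complex"


@dataclass
class TransformationResult:
    """One A->B transformation through the closed thermodynamic cycle."""

    pair: tuple[str, str]
    delta_g_com: float
    com_sd: float
    delta_g_lig: float
    lig_sd: float
    ddg_rbfe: float
    ddg_sd: float  # quadrature of the leg SDs


@dataclass
class AffinityRecord:
    """Experimental potency and the derived binding free energy."""

    compound_id: str
    pic50: float
    delta_g_exp: float

    @classmethod
    def from_pic50(cls, compound_id: str, pic50: float,
                   temperature: float = DEFAULT_TEMPERATURE) -> "AffinityRecord":
        return cls(compound_id, float(pic50), pic50_to_dg(pic50, temperature))


# ---------------------------------------------------------------------------
# BAR
# ---------------------------------------------------------------------------

def _log_fermi_sum(x: np.ndarray) -> float:
    # log sum_i 1/(1 + exp(x_i)), evaluated stably
    return float(logsumexp(-np.logaddexp(0.0, x)))


def bar_pair(forward, reverse, temperature: float = DEFAULT_TEMPERATURE) -> BarResult:
    """BAR free energy difference for one adjacent lambda pair.

    Solves the Fermi-function self-consistency equation by bracketed root
    finding within +/-100 kcal/mol; raises
    :class:`~qsarfep.errors.InsufficientOverlapError` when no sign change
    exists in the bracket (distributions too far apart).
    """
    wf = np.asarray(forward, dtype=float)
    wr = np.asarray(reverse, dtype=float)
    if wf.size == 0 or wr.size == 0:
        raise ParameterError("forward and reverse sample sets must be non-empty")
    beta = 1.0 / (KB_KCAL * temperature)
    M = np.log(wf.size / wr.size)

    def residual(dg: float) -> float:
        lhs = _log_fermi_sum(beta * wf - beta * dg + M)
        rhs = _log_fermi_sum(beta * wr + beta * dg - M)
        return lhs - rhs

    lo, hi = -_BRACKET, _BRACKET
    r_lo, r_hi = residual(lo), residual(hi)
    if r_lo == 0.0:
        dg = lo
    elif r_hi == 0.0:
        dg = hi
    elif np.sign(r_lo) == np.sign(r_hi):
        raise InsufficientOverlapError(
            "no BAR solution within +/-100 kcal/mol: insufficient overlap"
        )
    else:
        dg = brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16)

    # Bennett's asymptotic variance at the solution
    ff = 1.0 / (1.0 + np.exp(np.clip(beta * wf - beta * dg + M, -700, 700)))
    fr = 1.0 / (1.0 + np.exp(np.clip(beta * wr + beta * dg - M, -700, 700)))
    var = ((np.mean(ff**2) / np.mean(ff) ** 2 - 1.0) / wf.size
           + (np.mean(fr**2) / np.mean(fr) ** 2 - 1.0) / wr.size)
    return BarResult(delta_g=float(dg), stderr=float(np.sqrt(max(var, 0.0)) / beta))


def chain_windows(samples: WorkSampleSet, schedule: LambdaSchedule) -> ChainResult:
    """Sum per-pair BAR estimates along the schedule, per replicate.

    Every adjacent pair of the schedule must be present for every replicate.
    The replicate totals are reported with their mean, the SD across
    replicates, and an aggregate asymptotic standard error of the mean.
    """
    reps = samples.replicates
    totals = np.zeros(len(reps))
    variances = np.zeros(len(reps))
    for i, rep in enumerate(reps):
        for pair in range(schedule.n_pairs):
            if (pair, rep) not in samples.data:
                raise ParameterError(
                    f"missing samples for lambda pair "
                    f"({schedule.values[pair]:.3f}, {schedule.values[pair + 1]:.3f})"
                    f" in replicate {rep}"
                )
            fwd, rev = samples.data[(pair, rep)]
            res = bar_pair(fwd, rev, samples.temperature)
            totals[i] += res.delta_g
            variances[i] += res.stderr**2
    mean = float(totals.mean())
    sd = float(totals.std(ddof=1)) if len(reps) > 1 else 0.0
    stderr = float(np.sqrt(variances.sum()) / len(reps))
    return ChainResult(per_replicate=totals, mean=mean, sd=sd, stderr=stderr,
                       system=samples.system)


# ---------------------------------------------------------------------------
# Thermodynamic cycle and experimental references
# ---------------------------------------------------------------------------

def cycle_ddg(
    com: tuple[float, float] | ChainResult,
    lig: tuple[float, float] | ChainResult,
    pair: tuple[str, str] = ("A", "B"),
) -> TransformationResult:
    """Close the cycle: ddG_RBFE = dG_COM - dG_LIG, SDs in quadrature."""
    cg, cs = (com.mean, com.sd) if isinstance(com, ChainResult) else com
    lg, ls = (lig.mean, lig.sd) if isinstance(lig, ChainResult) else lig
    return TransformationResult(
        pair=pair,
        delta_g_com=float(cg), com_sd=float(cs),
        delta_g_lig=float(lg), lig_sd=float(ls),
        ddg_rbfe=float(cg - lg),
        ddg_sd=float(np.hypot(cs, ls)),
    )


def pic50_to_dg(pic50: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """dG_EXP = -RT ln(10) pIC50, kcal/mol."""
    return -KB_KCAL * temperature * LN10 * pic50


def dg_to_pic50(delta_g: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Inverse of :func:`pic50_to_dg`."""
    return -delta_g / (KB_KCAL * temperature * LN10)


def ddg_exp(record_a: AffinityRecord, record_b: AffinityRecord) -> float:
    """Experimental relative binding free energy dG_EXP(B) - dG_EXP(A)."""
    return float(record_b.delta_g_exp - record_a.delta_g_exp)


def protocol_total_ns(
    n_windows: int = 12,
    ns_per_window: float = 1.0,
    n_replicates: int = 3,
    n_systems: int = 2,
) -> float:
    """Total sampling per transformation: windows x length x replicates x
    systems (complex + solvent legs)."""
    return float(n_windows * ns_per_window * n_replicates * n_systems)


def correlate(ddg_exp_values, ddg_rbfe_values) -> tuple[float, float, float, float]:
    """Pearson r, r^2 and the OLS line ddG_EXP = slope * ddG_RBFE + intercept."""
    x = np.asarray(ddg_rbfe_values, dtype=float)
    y = np.asarray(ddg_exp_values, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ParameterError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ParameterError("zero variance in one of the series")
    r = float(pearsonr(x, y).statistic)
    fit = linregress(x, y)
    return r, r * r, float(fit.slope), float(fit.intercept)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def write_work_samples(samples: WorkSampleSet, path) -> None:
    """Long-format CSV: system, replicate, pair_index, direction, delta_u."""
    rows = []
    for (pair, rep), (fwd, rev) in sorted(samples.data.items()):
        for v in fwd:
            rows.append((samples.system, rep, pair, "forward", v))
        for v in rev:
            rows.append((samples.system, rep, pair, "reverse", v))
    pd.DataFrame(rows, columns=["system", "replicate", "pair_index",
                                "direction", "delta_u"]).to_csv(path, index=False)


def read_work_samples(path, temperature: float = DEFAULT_TEMPERATURE) -> dict[str, WorkSampleSet]:
    """Read the long-format work CSV; returns one WorkSampleSet per system."""
    df = pd.read_csv(path)
    out: dict[str, WorkSampleSet] = {}
    for system, sys_df in df.groupby("system"):
        data = {}
        for (pair, rep), g in sys_df.groupby(["pair_index", "replicate"]):
            fwd = g.loc[g["direction"] == "forward", "delta_u"].to_numpy(float)
            rev = g.loc[g["direction"] == "reverse", "delta_u"].to_numpy(float)
            data[(int(pair), int(rep))] = (fwd, rev)
        out[str(system)] = WorkSampleSet(data=data, temperature=temperature,
                                         system=str(system))
    return out
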