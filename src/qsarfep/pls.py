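"""Partial least squares (PLS1) regression for field-based QSAR.

The single-response NIPALS algorithm is used: at each step the weight vector
is the (normalized) covariance X'y, scores are t = Xw, and X and y are
deflated by the extracted component.  For one response variable each
component is closed-form, so the fit is exact and deterministic; tolerance
and iteration-cap parameters are retained for interface stability.  Data are
mean-centered but columns are not autoscaled -- field-kind block scaling
happens upstream in the descriptor assembly, following CoMFA convention.

Model quality is summarized by r^2 / SEE / F on the training fit and by the
leave-one-out cross-validated q^2 (PRESS-based) used to select the optimal
number of latent components (ONC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ColumnMismatchError, ParameterError
from .fields import FieldBlock

_RANK_TOL = 1e-12


def _as_matrix(X) -> tuple[np.ndarray, list | None]:
    if isinstance(X, FieldBlock):
        return X.matrix, X.column_meta
    return np.asarray(X, dtype=float), None


@dataclass
class PLSModel:
    """A fitted PLS1 model in the original (centered) column space."""

    n_components: int
    x_weights: np.ndarray  # (p, c)
    x_loadings: np.ndarray  # (p, c)
    y_loadings: np.ndarray  # (c,)
    x_scores: np.ndarray  # (n, c)
    coefficients: np.ndarray  # (p,), pIC50 per (scaled) field unit
    intercept: float
    x_mean: np.ndarray  # (p,)
    y_mean: float
    r2: float
    see: float
    f_value: float
    rss: float
    fitted: np.ndarray  # (n,)
    column_meta: list | None = None
    training_ids: list[str] | None = None
    field_fractions: dict[str, float] | None = None

    @property
    def rotations(self) -> np.ndarray:
        """R = W (P'W)^-1 : projects centered X onto the latent scores."""
        return self.x_weights @ np.linalg.inv(self.x_loadings.T @ self.x_weights)

    def transform(self, X) -> np.ndarray:
        """Latent-space scores for new rows."""
        M, _ = _as_matrix(X)
        return (M - self.x_mean) @ self.rotations


@dataclass
class CVResult:
    """Leave-one-out cross-validation trace and the statistics at ``onc``."""

    q2_per_component: np.ndarray
    press_per_component: np.ndarray
    onc: int
    q2: float
    sep: float  # sqrt(PRESS / (n - c - 1)), pIC50 units
    press: float


def _pls1_components(Xc: np.ndarray, yc: np.ndarray, n_components: int,
                     tol: float = 1e-12, max_iter: int = 500):
    """Extract PLS1 weights/loadings/scores with deflation.

    ``tol``/``max_iter`` bound the (degenerate for PLS1, single-pass)
    iteration; extraction stops with an error if the requested number of
    components exceeds the effective rank.
    """
    n, p = Xc.shape
    X = Xc.copy()
    y = yc.copy()
    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    q = np.empty(n_components)
    T = np.empty((n, n_components))
    y_scale = max(float(np.abs(yc).max()), 1.0)
    for k in range(n_components):
        w = X.T @ y
        nw = float(np.linalg.norm(w))
        if nw <= _RANK_TOL * y_scale:
            raise ParameterError(
                f"n_components={n_components} exceeds the effective rank ({k})"
            )
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= _RANK_TOL:
            raise ParameterError(
                f"n_components={n_components} exceeds the effective rank ({k})"
            )
        p_vec = X.T @ t / tt
        q_k = float(y @ t) / tt
        X -= np.outer(t, p_vec)
        y = y - q_k * t
        W[:, k], P[:, k], q[k], T[:, k] = w, p_vec, q_k, t
    return W, P, q, T


def fit_pls(X, y, n_components: int, training_ids: list[str] | None = None) -> PLSModel:
    """Fit a PLS1 model on centered data.

    Training statistics follow the QSAR conventions: r^2 = 1 - RSS/SS_tot,
    SEE = sqrt(RSS / (n - c - 1)), F = (r^2/c) / ((1 - r^2)/(n - c - 1)).
    When ``X`` is a :class:`~qsarfep.fields.FieldBlock`, per-kind field
    fractions are computed from the summed |coefficient * column stdev| and
    normalized to 100%.
    """
    M, meta = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    n, p = M.shape
    if yv.shape != (n,):
        raise ParameterError("y must be one value per row of X")
    if n_components < 1:
        raise ParameterError("n_components must be >= 1")
    if n < n_components + 2:
        raise ParameterError("need at least n_components + 2 training rows")
    x_mean = M.mean(axis=0)
    y_mean = float(yv.mean())
    W, P, q, T = _pls1_components(M - x_mean, yv - y_mean, n_components)
    coef = W @ np.linalg.solve(P.T @ W, q)
    intercept = y_mean - float(x_mean @ coef)
    fitted = M @ coef + intercept
    rss = float(np.sum((yv - fitted) ** 2))
    ss_tot = float(np.sum((yv - y_mean) ** 2))
    if ss_tot <= 0:
        raise ParameterError("zero variance in y")
    r2 = 1.0 - rss / ss_tot
    dof = n - n_components - 1
    see = float(np.sqrt(rss / dof)) if dof > 0 else float("nan")
    f_value = (
        (r2 / n_components) / ((1.0 - r2) / dof) if dof > 0 and r2 < 1.0 else float("inf")
    )
    fractions = None
    if meta is not None:
        sd = M.std(axis=0, ddof=1)
        contrib: dict[str, float] = {}
        for j, (kind, _) in enumerate(meta):
            contrib[kind] = contrib.get(kind, 0.0) + abs(coef[j] * sd[j])
        total = sum(contrib.values())
        if total > 0:
            fractions = {k: 100.0 * v / total for k, v in contrib.items()}
    return PLSModel(
        n_components=n_components,
        x_weights=W,
        x_loadings=P,
        y_loadings=q,
        x_scores=T,
        coefficients=coef,
        intercept=intercept,
        x_mean=x_mean,
        y_mean=y_mean,
        r2=r2,
        see=see,
        f_value=f_value,
        rss=rss,
        fitted=fitted,
        column_meta=meta,
        training_ids=list(training_ids) if training_ids is not None else None,
        field_fractions=fractions,
    )


def predict(model: PLSModel, X) -> np.ndarray:
    """Predict activities: yhat = X . coefficients + intercept."""
    M, meta = _as_matrix(X)
    if meta is not None and model.column_meta is not None and meta != model.column_meta:
        model_set = set(map(tuple, model.column_meta))
        new_set = set(map(tuple, meta))
        raise ColumnMismatchError(
            f"block columns do not match the model: "
            f"missing={sorted(model_set - new_set)[:5]} "
            f"extra={sorted(new_set - model_set)[:5]}"
        )
    if M.shape[1] != model.coefficients.shape[0]:
        raise ColumnMismatchError(
            f"{M.shape[1]} columns given, model has {model.coefficients.shape[0]}"
        )
    return M @ model.coefficients + model.intercept


def _loo_press(M: np.ndarray, yv: np.ndarray, max_components: int) -> np.ndarray:
    """PRESS per component count from n single-left-out PLS1 refits.

    Each fold extracts components incrementally, accumulating the left-out
    prediction at every component count; if the fold's rank is exhausted the
    last attainable prediction is carried forward.
    """
    n = len(yv)
    press = np.zeros(max_components)
    for i in range(n):
        idx = np.arange(n) != i
        Xi, yi = M[idx], yv[idx]
        xm, ym = Xi.mean(axis=0), float(yi.mean())
        X = Xi - xm
        y = yi - ym
        x_out = M[i] - xm
        pred = ym
        for k in range(max_components):
            w = X.T @ y
            nw = float(np.linalg.norm(w))
            if nw <= _RANK_TOL:
                press[k:] += (yv[i] - pred) ** 2
                break
            w /= nw
            t = X @ w
            tt = float(t @ t)
            if tt <= _RANK_TOL:
                press[k:] += (yv[i] - pred) ** 2
                break
            p_vec = X.T @ t / tt
            q_k = float(y @ t) / tt
            t_out = float(x_out @ w)
            pred += q_k * t_out
            x_out = x_out - t_out * p_vec
            X -= np.outer(t, p_vec)
            y = y - q_k * t
            press[k] += (yv[i] - pred) ** 2
    return press


def loo_q2(X, y, n_components: int) -> CVResult:
    """Leave-one-out q^2 = 1 - PRESS/SS_tot at a fixed component count."""
    M, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if n < n_components + 2:
        raise ParameterError("need at least n_components + 2 rows for LOO")
    ss_tot = float(np.sum((yv - yv.mean()) ** 2))
    if ss_tot <= 0:
        raise ParameterError("zero variance in y")
    press = _loo_press(M, yv, n_components)
    q2 = 1.0 - press / ss_tot
    c = n_components
    sep = float(np.sqrt(press[c - 1] / (n - c - 1))) if n - c - 1 > 0 else float("nan")
    return CVResult(
        q2_per_component=q2,
        press_per_component=press,
        onc=c,
        q2=float(q2[c - 1]),
        sep=sep,
        press=float(press[c - 1]),
    )


def select_onc(X, y, max_components: int = 10) -> tuple[int, CVResult]:
    """Scan 1..max_components by LOO and return the q^2-maximizing count.

    Ties (including a flat trace) break toward the smaller component count.
    """
    if max_components < 1:
        raise ParameterError("max_components must be >= 1")
    M, _ = _as_matrix(X)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    max_c = min(max_components, n - 2)
    cv = loo_q2(M, yv, max_c)
    onc = int(np.argmax(cv.q2_per_component)) + 1  # argmax -> first max -> parsimony
    c = onc
    sep = float(np.sqrt(cv.press_per_component[c - 1] / (n - c - 1))) if n - c - 1 > 0 else float("nan")
    return onc, CVResult(
        q2_per_component=cv.q2_per_component,
        press_per_component=cv.press_per_component,
        onc=onc,
        q2=float(cv.q2_per_component[c - 1]),
        sep=sep,
        press=float(cv.press_per_component[c - 1]),
    )
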