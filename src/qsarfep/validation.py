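"""Train/test splitting, the QSAR validation-statistics battery, threshold
gating and the leverage-based applicability domain (Williams plot).

The external battery follows the Golbraikh-Tropsha conventions: through-origin
regressions with predicted values on the abscissa define r0^2 (the primed
variant swaps axes), rm^2 = r^2 (1 - sqrt(|r^2 - r0^2|)), and the predictive
squared correlation r_pred^2 = QF1^2 uses the training-mean reference.  QF2^2
replaces that reference with the test mean and QF3^2 compares mean squared
errors normalized by the training variance.  Q_ccc is Lin's concordance
correlation coefficient between observed and predicted activities.

chi^2 is computed as sum (y - yhat)^2 / |yhat| by default (the denominator is
switchable to the observed values), since the QSAR-metrics literature uses
both conventions.

The applicability domain uses leverages computed in the PLS latent space on
the intercept-augmented score matrix; the warning leverage is
h* = 3 (c + 1) / n_train and compounds with |standardized residual| > 3 or
h > h* are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .errors import ParameterError
from .fields import FieldBlock, GridSpec, assemble_block, make_grid
from .pls import CVResult, PLSModel, fit_pls, predict, select_onc
from .structures import MoleculeSet


# ---------------------------------------------------------------------------
# Stratified splitting
# ---------------------------------------------------------------------------

@dataclass
class SplitAssignment:
    """Activity-class labels and train/test roles per compound."""

    class_label: dict[str, str]  # id -> {'high','medium','low'}
    role: dict[str, str]  # id -> {'train','test'}
    seed: int
    boundaries: tuple[float, float]

    @property
    def train_ids(self) -> list[str]:
        return [i for i, r in self.role.items() if r == "train"]

    @property
    def test_ids(self) -> list[str]:
        return [i for i, r in self.role.items() if r == "test"]


def stratified_split(
    activities: pd.DataFrame,
    ratio: int = 3,
    seed: int = 0,
    boundaries: tuple[float, float] | None = None,
) -> SplitAssignment:
    """Split compounds into train/test at ``ratio``:1 within activity classes.

    Compounds are first binned into low/medium/high classes at the two pIC50
    cut points (default: terciles of the observed activities).  Within each
    class, round(n_class / (1 + ratio)) compounds are drawn without
    replacement into the test set with a seeded generator; the remainder
    train.
    """
    ids = activities["id"].astype(str).to_numpy()
    y = activities["pIC50"].astype(float).to_numpy()
    if boundaries is None:
        b1, b2 = np.quantile(y, [1.0 / 3.0, 2.0 / 3.0])
    else:
        b1, b2 = sorted(boundaries)
    labels = np.where(y < b1, "low", np.where(y < b2, "medium", "high"))
    rng = np.random.default_rng(seed)
    role = {}
    for cls in ("low", "medium", "high"):
        members = ids[labels == cls]
        if len(members) < 4:
            raise ParameterError(
                f"activity class '{cls}' has only {len(members)} compounds; "
                "adjust the class boundaries"
            )
        n_test = int(np.floor(len(members) / (1.0 + ratio) + 0.5))  # half rounds up
        test = rng.choice(members, size=n_test, replace=False)
        for cid in members:
            role[cid] = "test" if cid in set(test) else "train"
    class_label = {cid: lab for cid, lab in zip(ids, labels)}
    role = {cid: role[cid] for cid in ids}  # restore input order
    return SplitAssignment(class_label=class_label, role=role, seed=seed,
                           boundaries=(float(b1), float(b2)))


# ---------------------------------------------------------------------------
# Statistics battery
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """All model statistics; unset entries stay None.

    Train-side: q2/onc/sep from LOO, r2/see/f_value/rss from the fit,
    bootstrap bs_r2/bs_sd, error measures chi2/rmse/mae and the
    Golbraikh-Tropsha slopes/regressions with the ``_train`` suffix.
    Test-side: the ``_test``-suffixed analogues plus the predictive
    coefficients r_pred_2 (= qf1_2), qf2_2, qf3_2 and Lin's concordance
    q_ccc_2.
    """

    q2: float | None = None
    onc: int | None = None
    sep: float | None = None
    r2: float | None = None
    see: float | None = None
    f_value: float | None = None
    bs_r2: float | None = None
    bs_sd: float | None = None
    chi2: float | None = None
    rmse: float | None = None
    mae: float | None = None
    rss: float | None = None
    k_train: float | None = None
    k_prime_train: float | None = None
    r0_2_train: float | None = None
    r0_2_prime_train: float | None = None
    delta_r0_2_train: float | None = None
    rm_2_train: float | None = None
    rm_2_prime_train: float | None = None
    r2_test: float | None = None
    k_test: float | None = None
    k_prime_test: float | None = None
    r0_2_test: float | None = None
    r0_2_prime_test: float | None = None
    delta_r0_2_test: float | None = None
    rm_2_test: float | None = None
    rm_2_prime_test: float | None = None
    r_pred_2: float | None = None
    qf1_2: float | None = None
    qf2_2: float | None = None
    qf3_2: float | None = None
    q_ccc_2: float | None = None
    chi2_test: float | None = None
    rmse_test: float | None = None
    mae_test: float | None = None
    rss_test: float | None = None
    field_fractions: dict[str, float] | None = None
    pass_flags: dict[str, bool] | None = None

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _gt_statistics(y: np.ndarray, yhat: np.ndarray) -> dict[str, float]:
    """Golbraikh-Tropsha slope/through-origin statistics for one (y, yhat) set."""
    sxy = float(np.sum(y * yhat))
    k = sxy / float(np.sum(yhat**2))
    k_prime = sxy / float(np.sum(y**2))
    ss_y = float(np.sum((y - y.mean()) ** 2))
    ss_yhat = float(np.sum((yhat - yhat.mean()) ** 2))
    if ss_y <= 0:
        raise ParameterError("zero variance in observed activities")
    # observed regressed through the origin on predicted (predicted abscissa)
    r0_2 = 1.0 - float(np.sum((y - k * yhat) ** 2)) / ss_y
    if ss_yhat <= 0:
        # constant predictions: correlation-based statistics are undefined
        r2 = r0_2_prime = rm_2 = rm_2_prime = float("nan")
    else:
        r = float(np.corrcoef(y, yhat)[0, 1])
        r2 = r * r
        # primed variant: axes swapped
        r0_2_prime = 1.0 - float(np.sum((yhat - k_prime * y) ** 2)) / ss_yhat
        rm_2 = r2 * (1.0 - np.sqrt(abs(r2 - r0_2)))
        rm_2_prime = r2 * (1.0 - np.sqrt(abs(r2 - r0_2_prime)))
    return {
        "r2": r2,
        "k": k,
        "k_prime": k_prime,
        "r0_2": r0_2,
        "r0_2_prime": r0_2_prime,
        "delta_r0_2": abs(r0_2 - r0_2_prime),
        "rm_2": rm_2,
        "rm_2_prime": rm_2_prime,
    }


def _error_measures(y: np.ndarray, yhat: np.ndarray, chi2_denominator: str) -> dict[str, float]:
    resid = y - yhat
    denom = np.abs(yhat) if chi2_denominator == "predicted" else np.abs(y)
    if np.any(denom <= 0):
        chi2 = float("nan")
    else:
        chi2 = float(np.sum(resid**2 / denom))
    return {
        "rss": float(np.sum(resid**2)),
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "mae": float(np.mean(np.abs(resid))),
        "chi2": chi2,
    }


def concordance_ccc(y: np.ndarray, yhat: np.ndarray) -> float:
    """Lin's concordance correlation coefficient between y and yhat."""
    my, mp = y.mean(), yhat.mean()
    sy = np.mean((y - my) ** 2)
    sp = np.mean((yhat - mp) ** 2)
    syp = np.mean((y - my) * (yhat - mp))
    return float(2.0 * syp / (sy + sp + (my - mp) ** 2))


def external_metrics(
    y_test,
    yhat_test,
    y_train_mean: float,
    y_train_ss: float,
    n_train: int,
    chi2_denominator: str = "predicted",
) -> dict[str, float]:
    """Test-set statistics battery.

    ``y_train_ss`` is the training sum of squares about the training mean
    (used by r_pred^2/QF1^2 only through the mean, and by QF3^2 through the
    per-compound variance SS_train / n_train).
    """
    y = np.asarray(y_test, dtype=float)
    yhat = np.asarray(yhat_test, dtype=float)
    if y.shape != yhat.shape or y.size < 3:
        raise ParameterError("need matching y/yhat with at least 3 test compounds")
    press = float(np.sum((y - yhat) ** 2))
    ss_about_train_mean = float(np.sum((y - y_train_mean) ** 2))
    ss_about_test_mean = float(np.sum((y - y.mean()) ** 2))
    out = _gt_statistics(y, yhat)
    out.update(_error_measures(y, yhat, chi2_denominator))
    r_pred_2 = 1.0 - press / ss_about_train_mean
    out["r_pred_2"] = r_pred_2
    out["qf1_2"] = r_pred_2  # identical formula by construction
    out["qf2_2"] = 1.0 - press / ss_about_test_mean
    out["qf3_2"] = 1.0 - (press / y.size) / (y_train_ss / n_train)
    out["q_ccc_2"] = concordance_ccc(y, yhat)
    return out


def bootstrap_r2(X, y, onc: int, n_boot: int = 100, seed: int = 0) -> tuple[float, float]:
    """Mean and SD of the training r^2 over bootstrap refits.

    Rows are resampled with replacement and the PLS refitted each time.
    Degenerate resamples (zero y variance or rank below ``onc``) are redrawn,
    at most 10 times each.
    """
    M = X.matrix if isinstance(X, FieldBlock) else np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if n < 10:
        raise ParameterError("bootstrap needs at least 10 compounds")
    rng = np.random.default_rng(seed)
    r2s = []
    for _ in range(n_boot):
        for _attempt in range(10):
            idx = rng.integers(0, n, size=n)
            if np.ptp(yv[idx]) <= 0:
                continue
            try:
                model = fit_pls(M[idx], yv[idx], onc)
            except ParameterError:
                continue
            r2s.append(model.r2)
            break
        else:
            raise ParameterError("bootstrap resampling degenerate 10 times in a row")
    arr = np.asarray(r2s)
    return float(arr.mean()), float(arr.std(ddof=1))


#: Gate definitions: (flag key, threshold description)
GATES = (
    "q2 > 0.5",
    "r2 > 0.6",
    "0.85 <= k or k' <= 1.15",
    "r0^2 - r'0^2 < 0.3",
    "rm^2 or r'm^2 > 0.5",
    "r_pred^2 > 0.6",
    "chi^2 < 1.0",
    "RMSE < 0.5",
)


def threshold_gate(report: ValidationReport) -> dict[str, bool]:
    """Apply the acceptance thresholds and return one flag per criterion.

    The slope (k/k'), r0^2 difference and rm^2 criteria are evaluated on the
    external test set; chi^2 and RMSE on the training fit.  ``overall`` is
    the conjunction of all gates.  All comparisons are strict.
    """
    flags = {
        "q2 > 0.5": report.q2 is not None and report.q2 > 0.5,
        "r2 > 0.6": report.r2 is not None and report.r2 > 0.6,
        "0.85 <= k or k' <= 1.15": (
            (report.k_test is not None and 0.85 <= report.k_test <= 1.15)
            or (report.k_prime_test is not None and 0.85 <= report.k_prime_test <= 1.15)
        ),
        "r0^2 - r'0^2 < 0.3": (
            report.delta_r0_2_test is not None and report.delta_r0_2_test < 0.3
        ),
        "rm^2 or r'm^2 > 0.5": (
            (report.rm_2_test is not None and report.rm_2_test > 0.5)
            or (report.rm_2_prime_test is not None and report.rm_2_prime_test > 0.5)
        ),
        "r_pred^2 > 0.6": report.r_pred_2 is not None and report.r_pred_2 > 0.6,
        "chi^2 < 1.0": report.chi2 is not None and report.chi2 < 1.0,
        "RMSE < 0.5": report.rmse is not None and report.rmse < 0.5,
    }
    flags["overall"] = all(flags.values())
    report.pass_flags = flags
    return flags


# ---------------------------------------------------------------------------
# Applicability domain
# ---------------------------------------------------------------------------

@dataclass
class ADResult:
    """Williams-plot data: leverages, standardized residuals, outliers."""

    leverages: dict[str, float]
    std_residuals: dict[str, float]
    h_star: float
    outliers: list[str]
    roles: dict[str, str] = field(default_factory=dict)


def williams_ad(
    train_scores: np.ndarray,
    test_scores: np.ndarray | None,
    std_residuals_train,
    std_residuals_test,
    onc: int,
    train_ids: list[str] | None = None,
    test_ids: list[str] | None = None,
) -> ADResult:
    """Leverage-based applicability domain in the PLS latent space.

    h_i = z_i' (Z'Z)^-1 z_i on the intercept-augmented score matrix Z of the
    training set; test compounds are projected with the same matrix.  The
    warning leverage is h* = 3 (onc + 1) / n_train; compounds beyond h* or
    with |standardized residual| > 3 are flagged as outliers.
    """
    T = np.asarray(train_scores, dtype=float)
    n_train = T.shape[0]
    Z = np.column_stack([np.ones(n_train), T])
    gram = Z.T @ Z
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise ParameterError("singular score matrix: leverage undefined")
    G = np.linalg.inv(gram)
    if train_ids is None:
        train_ids = [f"train{i}" for i in range(n_train)]
    lev = {cid: float(z @ G @ z) for cid, z in zip(train_ids, Z)}
    roles = {cid: "train" for cid in train_ids}
    res = dict(zip(train_ids, np.asarray(std_residuals_train, dtype=float)))
    if test_scores is not None and len(test_scores) > 0:
        Tt = np.asarray(test_scores, dtype=float)
        Zt = np.column_stack([np.ones(Tt.shape[0]), Tt])
        if test_ids is None:
            test_ids = [f"test{i}" for i in range(Tt.shape[0])]
        lev.update({cid: float(z @ G @ z) for cid, z in zip(test_ids, Zt)})
        res.update(zip(test_ids, np.asarray(std_residuals_test, dtype=float)))
        roles.update({cid: "test" for cid in test_ids})
    h_star = 3.0 * (onc + 1) / n_train
    outliers = [cid for cid in lev if lev[cid] > h_star or abs(res[cid]) > 3.0]
    return ADResult(leverages=lev, std_residuals=res, h_star=h_star,
                    outliers=outliers, roles=roles)


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    grid: GridSpec
    block: FieldBlock
    split: SplitAssignment
    model: PLSModel
    cv: CVResult
    report: ValidationReport
    ad: ADResult
    predictions: pd.DataFrame  # id, role, pIC50, predicted


def qsar_pipeline(
    molecules: MoleculeSet,
    activities: pd.DataFrame,
    method: str = "comfa",
    kinds: tuple[str, ...] | None = None,
    seed: int = 0,
    max_components: int = 6,
    spacing: float = 1.0,
    margin: float = 4.0,
    min_sigma: float = 2.0,
    alpha: float = 0.3,
    ratio: int = 3,
    boundaries: tuple[float, float] | None = None,
    n_boot: int = 100,
) -> PipelineResult:
    """Aligned molecules -> fields -> ONC scan -> fit -> full validation report.

    The descriptor block is assembled once on the full set (column filtering
    and block scaling are thus fixed before splitting, mirroring classic
    CoMFA workflows); the stratified 3:1 split then selects training rows for
    the LOO scan and fit, and the held-out rows for external validation and
    the Williams applicability domain.
    """
    grid = make_grid(molecules, spacing=spacing, margin=margin)
    block = assemble_block(molecules, grid, method=method, kinds=kinds,
                           min_sigma=min_sigma, alpha=alpha)
    split = stratified_split(activities, ratio=ratio, seed=seed, boundaries=boundaries)
    act = dict(zip(activities["id"].astype(str), activities["pIC50"].astype(float)))
    train_ids, test_ids = split.train_ids, split.test_ids
    X_train = block.rows(train_ids)
    X_test = block.rows(test_ids)
    y_train = np.array([act[c] for c in train_ids])
    y_test = np.array([act[c] for c in test_ids])

    onc, cv = select_onc(X_train, y_train, max_components)
    meta_block = FieldBlock(matrix=X_train, column_meta=block.column_meta,
                            ids=train_ids, grid=grid, method=block.method,
                            scaling=block.scaling)
    model = fit_pls(meta_block, y_train, onc, training_ids=train_ids)
    yhat_train = model.fitted
    yhat_test = predict(model, X_test)

    train_gt = _gt_statistics(y_train, yhat_train)
    train_err = _error_measures(y_train, yhat_train, "predicted")
    test_stats = external_metrics(y_test, yhat_test, float(y_train.mean()),
                                  float(np.sum((y_train - y_train.mean()) ** 2)),
                                  len(y_train))
    bs_r2, bs_sd = bootstrap_r2(X_train, y_train, onc, n_boot=n_boot, seed=seed)

    report = ValidationReport(
        q2=cv.q2, onc=onc, sep=cv.sep,
        r2=model.r2, see=model.see, f_value=model.f_value,
        bs_r2=bs_r2, bs_sd=bs_sd,
        chi2=train_err["chi2"], rmse=train_err["rmse"], mae=train_err["mae"],
        rss=train_err["rss"],
        k_train=train_gt["k"], k_prime_train=train_gt["k_prime"],
        r0_2_train=train_gt["r0_2"], r0_2_prime_train=train_gt["r0_2_prime"],
        delta_r0_2_train=train_gt["delta_r0_2"],
        rm_2_train=train_gt["rm_2"], rm_2_prime_train=train_gt["rm_2_prime"],
        r2_test=test_stats["r2"], k_test=test_stats["k"],
        k_prime_test=test_stats["k_prime"], r0_2_test=test_stats["r0_2"],
        r0_2_prime_test=test_stats["r0_2_prime"],
        delta_r0_2_test=test_stats["delta_r0_2"],
        rm_2_test=test_stats["rm_2"], rm_2_prime_test=test_stats["rm_2_prime"],
        r_pred_2=test_stats["r_pred_2"], qf1_2=test_stats["qf1_2"],
        qf2_2=test_stats["qf2_2"], qf3_2=test_stats["qf3_2"],
        q_ccc_2=test_stats["q_ccc_2"],
        chi2_test=test_stats["chi2"], rmse_test=test_stats["rmse"],
        mae_test=test_stats["mae"], rss_test=test_stats["rss"],
        field_fractions=model.field_fractions,
    )
    threshold_gate(report)

    train_rmse = train_err["rmse"]
    ad = williams_ad(
        model.x_scores, model.transform(X_test),
        (y_train - yhat_train) / train_rmse, (y_test - yhat_test) / train_rmse,
        onc, train_ids=train_ids, test_ids=test_ids,
    )
    pred_df = pd.DataFrame({
        "id": train_ids + test_ids,
        "role": ["train"] * len(train_ids) + ["test"] * len(test_ids),
        "pIC50": np.concatenate([y_train, y_test]),
        "predicted": np.concatenate([yhat_train, yhat_test]),
    })
    return PipelineResult(grid=grid, block=block, split=split, model=model,
                          cv=cv, report=report, ad=ad, predictions=pred_df)
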