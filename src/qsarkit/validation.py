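"""The QSAR validation battery.

Internal validation: leave-one-out (LOO) cross-validation (Q², RMSE_LOO,
MAE_LOO), Roy's r²m metrics on the LOO predictions, and a Y-randomization
(response-scrambling) test summarised by cRp².  External validation: r²test,
the predictive Q²(F2), and the Golbraikh–Tropsha checklist.

Conventions that differ between publications, and the choices made here:

* **Q²_LOO** uses the full-training-set mean in the denominator (SST of the
  training activities), and ``RMSE_LOO = sqrt(PRESS / n)``.
* **r²m metrics.**  r²m = r²·(1 − sqrt(r² − r0²)) with r0² the
  determination coefficient of the through-origin regression of *predicted
  on observed*; the primed variant reverses the axes.  Following Roy's
  later recommendation the metrics are computed on min–max scaled vectors
  by default (``scale=True``); the slopes k, k′ are always reported on the
  raw vectors.
* **cRp²** = R·sqrt(R² − (average Rr)²), where R and R² come from the
  unpermuted fit and "average Rr" is the mean correlation of the
  randomized models (``average="r"``, the published form).  Averaging the
  randomized R² values instead is available with ``average="r2"``.
* **r²test** is the squared Pearson correlation between observed and
  predicted test activities; the alternative predictive form
  (1 − SSE_test / deviance about the training mean) is reported separately
  as Q²(F2).  Both appear in the literature under the name "R²test".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .datasets import QSARDataset
from .regression import LinearModel, _design, fit, predict

__all__ = [
    "LOOResult",
    "RmMetrics",
    "YRandResult",
    "ExternalValidation",
    "ValidationReport",
    "loo_cv",
    "rm_metrics",
    "y_randomization",
    "external_validation",
    "validation_report",
]


# ---------------------------------------------------------------------------
# Leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class LOOResult:
    """Per-compound LOO predictions and their summary statistics."""

    loo_predictions: dict[str, float]
    q2_loo: float
    rmse_loo: float
    mae_loo: float


def loo_cv(ds: QSARDataset, subset: str = "train") -> LOOResult:
    """Leave-one-out cross-validation by explicit refitting.

    Each training compound is held out in turn, the model is refitted on
    the remaining n−1 compounds and the held-out activity predicted.
    Q² = 1 − PRESS/SST with SST about the full training mean.
    """
    sub = ds.subset(subset) if subset != "all" else ds
    names = list(ds.descriptor_names)
    n, p = len(sub), len(names)
    if n < p + 3:
        raise ValueError(f"need at least p+3={p + 3} records for LOO, have {n}")
    A = _design(sub, names)
    y = sub.activities()
    ids = sub.ids

    loo = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Ai = A[mask]
        if np.linalg.matrix_rank(Ai) < Ai.shape[1]:
            raise ValueError(
                f"LOO subfit holding out {ids[i]!r} is rank-deficient"
            )
        beta, *_ = np.linalg.lstsq(Ai, y[mask], rcond=None)
        loo[i] = A[i] @ beta

    press = float(np.sum((y - loo) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return LOOResult(
        loo_predictions=dict(zip(ids, loo.tolist())),
        q2_loo=1.0 - press / sst,
        rmse_loo=float(np.sqrt(press / n)),
        mae_loo=float(np.mean(np.abs(y - loo))),
    )


# ---------------------------------------------------------------------------
# Roy's r²m metrics
# ---------------------------------------------------------------------------

@dataclass
class RmMetrics:
    """Roy's modified determination coefficients and through-origin slopes."""

    r2: float
    r0_2: float
    r0p_2: float
    k: float
    k_prime: float
    rm2: float
    rm2_prime: float
    rm2_mean: float
    delta_rm2: float


def _minmax(v: np.ndarray) -> np.ndarray:
    span = v.max() - v.min()
    return (v - v.min()) / span if span > 0 else np.zeros_like(v)


def rm_metrics(y_obs, y_pred, *, scale: bool = True) -> RmMetrics:
    """Roy's r²m metrics between observed and predicted activity vectors.

    r² is the squared Pearson correlation.  k = Σ(obs·pred)/Σ(pred²) and
    k′ = Σ(obs·pred)/Σ(obs²) are the through-origin slopes on the raw
    vectors.  r0² (predicted regressed on observed through the origin) and
    its axis-reversed counterpart r0′² are computed on min–max scaled
    vectors when ``scale`` is true (the default, following Roy's scaled
    variant).  Then r²m = r²·(1 − sqrt(|r² − r0²|)), symmetrically for the
    primed form; Δr²m = |r²m − r²m′| should stay below 0.2 and the mean
    above 0.5 for an acceptable model.

    Swapping the arguments swaps (k, r²m) with (k′, r²m′).
    """
    yo = np.asarray(y_obs, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if yo.shape != yp.shape or yo.ndim != 1:
        raise ValueError("y_obs and y_pred must be 1-d vectors of equal length")
    if len(yo) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(yo) == 0 or np.ptp(yp) == 0:
        raise ValueError("constant vector: r²m metrics undefined")

    r2 = float(np.corrcoef(yo, yp)[0, 1] ** 2)
    k = float(np.sum(yo * yp) / np.sum(yp**2))
    k_prime = float(np.sum(yo * yp) / np.sum(yo**2))

    wo, wp = (_minmax(yo), _minmax(yp)) if scale else (yo, yp)
    # slopes of the through-origin regressions on the working vectors
    c = np.sum(wo * wp) / np.sum(wo**2)  # predicted on observed
    c_prime = np.sum(wo * wp) / np.sum(wp**2)  # observed on predicted
    r0_2 = float(1.0 - np.sum((wp - c * wo) ** 2) / np.sum((wp - wp.mean()) ** 2))
    r0p_2 = float(1.0 - np.sum((wo - c_prime * wp) ** 2) / np.sum((wo - wo.mean()) ** 2))

    rm2 = r2 * (1.0 - np.sqrt(abs(r2 - r0_2)))
    rm2_prime = r2 * (1.0 - np.sqrt(abs(r2 - r0p_2)))
    return RmMetrics(
        r2=r2,
        r0_2=r0_2,
        r0p_2=r0p_2,
        k=k,
        k_prime=k_prime,
        rm2=float(rm2),
        rm2_prime=float(rm2_prime),
        rm2_mean=float((rm2 + rm2_prime) / 2.0),
        delta_rm2=float(abs(rm2 - rm2_prime)),
    )


# ---------------------------------------------------------------------------
# Y-randomization
# ---------------------------------------------------------------------------

@dataclass
class YRandResult:
    """Response-scrambling runs and the chance-correlation summary cRp²."""

    runs: list[tuple[float, float, float]]  # (R, R², Q²) per run
    avg_r: float
    avg_r2: float
    avg_q2: float
    crp2: float
    seed: int | None
    n_runs: int


def y_randomization(
    ds: QSARDataset,
    n_runs: int = 100,
    seed: int = 0,
    *,
    average: str = "r",
    permutations: Sequence[np.ndarray] | None = None,
) -> YRandResult:
    """Refit after randomly permuting the training activities.

    Each run permutes the activity vector over the training compounds,
    refits the linear model on the original descriptors and records
    R = corr(permuted y, fitted y), R², and the LOO Q² of the permuted fit.
    A robust model shows near-zero random R² and negative random Q².

    cRp² = R·sqrt(R² − a), where R, R² describe the unpermuted fit and
    ``a`` is ``(mean random R)²`` for ``average="r"`` (default) or
    ``mean random R²`` for ``average="r2"``.  When R² < a the statistic is
    undefined and NaN is returned.

    ``permutations`` overrides the random draws with explicit index arrays
    (e.g. the identity permutation reproduces the original fit exactly);
    otherwise ``n_runs`` permutations are drawn from a generator seeded
    with ``seed``, so equal seeds give identical runs.
    """
    if average not in ("r", "r2"):
        raise ValueError(f"unknown averaging convention {average!r}")
    train = ds.train
    names = list(ds.descriptor_names)
    n = len(train)
    if permutations is None:
        if n_runs < 10:
            raise ValueError("n_runs must be at least 10")
        rng = np.random.default_rng(seed)
        permutations = [rng.permutation(n) for _ in range(n_runs)]

    A = _design(train, names)
    y = train.activities()
    # hat diagonal is permutation-invariant: compute once, reuse per run
    h = np.einsum("ij,jk,ik->i", A, np.linalg.inv(A.T @ A), A)

    runs = []
    for perm in permutations:
        yp = y[np.asarray(perm)]
        beta, *_ = np.linalg.lstsq(A, yp, rcond=None)
        fitted = A @ beta
        R = float(np.corrcoef(yp, fitted)[0, 1])
        loo = yp - (yp - fitted) / (1.0 - h)
        sst = np.sum((yp - yp.mean()) ** 2)
        q2 = float(1.0 - np.sum((yp - loo) ** 2) / sst)
        runs.append((R, R * R, q2))

    arr = np.asarray(runs)
    avg_r, avg_r2, avg_q2 = arr.mean(axis=0)

    beta0, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted0 = A @ beta0
    r2_orig = float(np.corrcoef(y, fitted0)[0, 1] ** 2)
    r_orig = float(np.sqrt(r2_orig))
    a = avg_r**2 if average == "r" else avg_r2
    crp2 = r_orig * np.sqrt(r2_orig - a) if r2_orig >= a else float("nan")

    return YRandResult(
        runs=[tuple(map(float, run)) for run in runs],
        avg_r=float(avg_r),
        avg_r2=float(avg_r2),
        avg_q2=float(avg_q2),
        crp2=float(crp2),
        seed=seed if permutations is None else None,
        n_runs=len(runs),
    )


# ---------------------------------------------------------------------------
# External validation
# ---------------------------------------------------------------------------

@dataclass
class ExternalValidation:
    """Test-set predictivity: r²test, Q²(F2) and the Golbraikh–Tropsha checks."""

    r2_test: float
    q2_f2: float
    gt_checklist: dict[str, dict]
    observed: dict[str, float] = field(default_factory=dict)
    predicted: dict[str, float] = field(default_factory=dict)


def external_validation(model: LinearModel, ds: QSARDataset) -> ExternalValidation:
    """Predict the test set and evaluate every external-validation criterion.

    The Golbraikh–Tropsha checklist contains exactly four conditions:

    1. ``q2_loo > 0.5`` (internal LOO Q² of the training set);
    2. ``r2_test > 0.6``;
    3. through-origin closeness: ``(r² − r0²)/r² < 0.1`` with
       ``0.85 ≤ k ≤ 1.15``, or the same for the axis-reversed (primed)
       quantities;
    4. ``|r0² − r0′²| < 0.3``.

    The r0² values here follow the original unscaled convention.
    """
    test = ds.test
    if len(test) == 0:
        raise ValueError("test subset is empty; assign split labels first")
    y_obs = test.activities()
    preds = predict(model, test)
    y_pred = np.array([preds[i] for i in test.ids])
    y_train = ds.train.activities()

    r2_test = float(np.corrcoef(y_obs, y_pred)[0, 1] ** 2)
    q2_f2 = float(
        1.0
        - np.sum((y_obs - y_pred) ** 2)
        / np.sum((y_obs - y_train.mean()) ** 2)
    )

    m = rm_metrics(y_obs, y_pred, scale=False)
    q2_loo = loo_cv(ds).q2_loo

    gap = (m.r2 - m.r0_2) / m.r2
    gap_prime = (m.r2 - m.r0p_2) / m.r2
    slope_ok = (gap < 0.1 and 0.85 <= m.k <= 1.15) or (
        gap_prime < 0.1 and 0.85 <= m.k_prime <= 1.15
    )
    checklist = {
        "q2_loo": {"passed": q2_loo > 0.5, "value": q2_loo, "threshold": "> 0.5"},
        "r2_test": {"passed": r2_test > 0.6, "value": r2_test, "threshold": "> 0.6"},
        "origin_slope": {
            "passed": bool(slope_ok),
            "value": {
                "k": m.k,
                "k_prime": m.k_prime,
                "gap": float(gap),
                "gap_prime": float(gap_prime),
            },
            "threshold": "(r²−r0²)/r² < 0.1 with 0.85 ≤ k ≤ 1.15 (either axis)",
        },
        "r0_difference": {
            "passed": abs(m.r0_2 - m.r0p_2) < 0.3,
            "value": float(abs(m.r0_2 - m.r0p_2)),
            "threshold": "< 0.3",
        },
    }
    return ExternalValidation(
        r2_test=r2_test,
        q2_f2=q2_f2,
        gt_checklist=checklist,
        observed=dict(zip(test.ids, y_obs.tolist())),
        predicted=dict(zip(test.ids, y_pred.tolist())),
    )


# ---------------------------------------------------------------------------
# Combined report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Everything the validation battery produces, in one object."""

    loo: LOOResult
    rm_loo: RmMetrics
    y_randomization: YRandResult
    external: ExternalValidation
    rm_test: RmMetrics


def validation_report(
    ds: QSARDataset, *, n_runs: int = 100, seed: int = 0
) -> ValidationReport:
    """Run the full battery (LOO, r²m, Y-randomization, external) on a
    split dataset, refitting the model on the training subset."""
    model = fit(ds)
    loo = loo_cv(ds)
    y_train = ds.train.activities()
    loo_pred = np.array([loo.loo_predictions[i] for i in ds.train.ids])
    rm_loo = rm_metrics(y_train, loo_pred)
    yrand = y_randomization(ds, n_runs=n_runs, seed=seed)
    ext = external_validation(model, ds)
    rm_test = rm_metrics(
        np.array([ext.observed[i] for i in ds.test.ids]),
        np.array([ext.predicted[i] for i in ds.test.ids]),
    )
    return ValidationReport(
        loo=loo, rm_loo=rm_loo, y_randomization=yrand, external=ext, rm_test=rm_test
    )
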