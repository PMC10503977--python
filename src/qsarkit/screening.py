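"""Pre-model descriptor reduction: variance, response-correlation and
multicollinearity (tolerance / variance-inflation factor) screening.

VIF for descriptor j is 1/(1 − r²_j), where r²_j is the coefficient of
determination of descriptor j regressed (with intercept) on the remaining
descriptors; tolerance is its reciprocal.  Descriptors with VIF above 5 are
conventionally considered too collinear to keep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import QSARDataset

__all__ = ["ScreenReport", "correlation_matrix", "vif", "screen"]

#: VIF above which a descriptor pair is considered strongly collinear.
DEFAULT_MAX_VIF = 5.0

_ACTIVITY = "pIC50"


@dataclass
class ScreenReport:
    """Outcome of descriptor screening.

    Attributes
    ----------
    kept : list of str
        Surviving descriptors, in the dataset's order.
    dropped : dict
        Name → reason; reasons are ``zero-variance``,
        ``low-response-correlation`` or ``high-VIF`` (the first rule each
        descriptor violated).
    correlation_matrix : DataFrame
        Pearson correlations over the kept descriptors plus the activity.
    vif, tolerance : dict
        Per kept descriptor; ``tolerance[name] == 1 / vif[name]``.
    """

    kept: list[str]
    dropped: dict[str, str] = field(default_factory=dict)
    correlation_matrix: pd.DataFrame | None = None
    vif: dict[str, float] = field(default_factory=dict)
    tolerance: dict[str, float] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        """True when screening removed every descriptor."""
        return not self.kept


def _subset_arrays(ds: QSARDataset, subset: str, names=None):
    sub = ds.subset(subset) if subset != "all" else ds
    if len(sub) == 0:
        raise ValueError(
            f"subset {subset!r} is empty; pass subset='all' for unlabelled data"
        )
    X = sub.descriptor_matrix(names)
    return sub, X


def correlation_matrix(
    ds: QSARDataset, subset: str = "train", *, include_activity: bool = True
) -> pd.DataFrame:
    """Pearson correlations between descriptors (and optionally the activity).

    Computed on the chosen subset (default ``train``, since screening belongs
    to model building).  Constant columns yield NaN correlations — undefined,
    reported as absent rather than guessed.
    """
    sub, X = _subset_arrays(ds, subset)
    if len(sub) < 3:
        raise ValueError("need at least 3 records to estimate correlations")
    cols = list(ds.descriptor_names)
    data = {name: X[:, j] for j, name in enumerate(cols)}
    if include_activity:
        data[_ACTIVITY] = sub.activities()
        cols = cols + [_ACTIVITY]
    return pd.DataFrame(data, columns=cols).corr()


def _vif_one(X: np.ndarray, j: int) -> float:
    """VIF of column j by the auxiliary-regression definition."""
    others = np.delete(np.arange(X.shape[1]), j)
    A = np.column_stack([np.ones(X.shape[0]), X[:, others]])
    coef, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
    resid = X[:, j] - A @ coef
    sst = np.sum((X[:, j] - X[:, j].mean()) ** 2)
    if sst == 0:
        return np.inf
    r2 = 1.0 - np.sum(resid**2) / sst
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def vif(ds: QSARDataset, subset: str = "train") -> dict[str, float]:
    """Variance-inflation factor for every descriptor on the chosen subset.

    A rank-deficient descriptor matrix yields ``inf`` for the dependent
    column(s) rather than an exception, so the caller can see which columns
    are redundant.
    """
    sub, X = _subset_arrays(ds, subset)
    p = X.shape[1]
    if p < 2:
        return {name: 1.0 for name in ds.descriptor_names}
    if len(sub) < p + 2:
        raise ValueError(
            f"need at least p+2={p + 2} records for VIF, have {len(sub)}"
        )
    return {name: _vif_one(X, j) for j, name in enumerate(ds.descriptor_names)}


def screen(
    ds: QSARDataset,
    *,
    min_variance: float = 0.0,
    min_abs_response_corr: float = 0.0,
    max_vif: float = DEFAULT_MAX_VIF,
    subset: str = "train",
) -> ScreenReport:
    """Three-stage descriptor screen: variance, response correlation, VIF.

    1. Drop constant descriptors (sample variance ``<= min_variance``).
    2. Drop descriptors with ``|corr(x, activity)| < min_abs_response_corr``.
    3. Iteratively drop the highest-VIF descriptor until all VIF
       ``<= max_vif`` (ties broken toward the later name in dataset order,
       so the screen is deterministic).

    ``dropped`` records the first rule each descriptor violated.  Screening
    is idempotent: re-screening a kept set drops nothing.  If everything is
    dropped the report's ``is_empty`` flag is set — no silent success.
    """
    if min_variance < 0 or min_abs_response_corr < 0 or max_vif < 0:
        raise ValueError("screening thresholds must be non-negative")
    sub, X = _subset_arrays(ds, subset)
    y = sub.activities()
    names = list(ds.descriptor_names)
    dropped: dict[str, str] = {}

    variances = X.var(axis=0, ddof=1)
    kept = []
    for j, name in enumerate(names):
        if variances[j] <= min_variance:
            dropped[name] = "zero-variance"
        else:
            kept.append(name)

    if kept:
        Xk = sub.descriptor_matrix(kept)
        corr = np.array(
            [np.corrcoef(Xk[:, j], y)[0, 1] for j in range(len(kept))]
        )
        survivors = []
        for j, name in enumerate(kept):
            if abs(corr[j]) < min_abs_response_corr:
                dropped[name] = "low-response-correlation"
            else:
                survivors.append(name)
        kept = survivors

    while len(kept) >= 2:
        Xk = sub.descriptor_matrix(kept)
        vifs = np.array([_vif_one(Xk, j) for j in range(len(kept))])
        if np.all(vifs <= max_vif):
            break
        # drop the single worst column; on ties prefer the later one
        worst = max(range(len(kept)), key=lambda j: (vifs[j], j))
        dropped[kept[worst]] = "high-VIF"
        kept = [n for i, n in enumerate(kept) if i != worst]

    report = ScreenReport(kept=kept, dropped=dropped)
    if kept:
        Xk = sub.descriptor_matrix(kept)
        data = {name: Xk[:, j] for j, name in enumerate(kept)}
        data[_ACTIVITY] = y
        report.correlation_matrix = pd.DataFrame(
            data, columns=kept + [_ACTIVITY]
        ).corr()
        if len(kept) >= 2 and len(sub) >= len(kept) + 2:
            vifs = {n: _vif_one(Xk, j) for j, n in enumerate(kept)}
        else:
            vifs = {n: 1.0 for n in kept}
        report.vif = vifs
        report.tolerance = {
            n: (0.0 if np.isinf(v) else 1.0 / v) for n, v in vifs.items()
        }
    return report
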