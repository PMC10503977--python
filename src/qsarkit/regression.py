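"""Linear activity model and its goodness-of-fit statistics.

The model is the multiple linear regression

    pIC50 = a0 + a1·x1 + ... + ap·xp

fitted by ordinary least squares on the training subset.  (The study this
package reproduces fitted by PLS; with all latent components retained PLS
and OLS coincide, and OLS is deterministic and exact, so OLS is the
estimator here.)

Degrees-of-freedom conventions matter for matching published numbers:

* ``r²_adj = ((n−1)·r² − p) / (n − 1 − p)``
* fit RMSE defaults to the residual-standard-error form
  ``sqrt(SSE / (n − p − 1))``; the plain ``sqrt(SSE / n)`` form is
  selectable via ``rmse_convention="mean"``.
* ``F = ((SST − SSE)/p) / (SSE/(n − p − 1))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datasets import QSARDataset

__all__ = ["LinearModel", "FitStats", "fit", "predict", "fit_statistics"]


@dataclass
class LinearModel:
    """Fitted linear QSAR model: intercept a0 and one slope per descriptor."""

    intercept: float
    coefficients: dict[str, float]
    descriptor_names: list[str]
    n_train: int

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(self.descriptor_names):
            raise ValueError("coefficient names must match descriptor_names")

    def predict_one(self, descriptors: dict[str, float], compound_id: str = "?") -> float:
        val = self.intercept
        for name in self.descriptor_names:
            if name not in descriptors:
                raise ValueError(
                    f"compound {compound_id!r} is missing descriptor {name!r}"
                )
            val += self.coefficients[name] * descriptors[name]
        return val


@dataclass
class FitStats:
    """Goodness-of-fit summary of a linear model on its training subset."""

    r2: float
    r2_adj: float
    rmse: float
    mae: float
    f_stat: float
    sse: float
    sst: float
    n: int
    p: int
    coef_p_values: dict[str, float] = field(default_factory=dict)


def _design(ds: QSARDataset, names) -> np.ndarray:
    X = ds.descriptor_matrix(names)
    return np.column_stack([np.ones(len(ds)), X])


def _collinear_columns(A: np.ndarray, names) -> list[str]:
    """Names whose removal restores full rank (diagnostic only)."""
    full = np.linalg.matrix_rank(A)
    out = []
    for j, name in enumerate(names):
        sub = np.delete(A, j + 1, axis=1)  # +1 skips the intercept column
        if np.linalg.matrix_rank(sub) == full:
            out.append(name)
    return out


def fit(ds: QSARDataset, subset: str = "train") -> LinearModel:
    """Ordinary least-squares fit on the chosen subset (default train).

    Requires more records than descriptors plus intercept and a full-rank
    descriptor matrix; a rank-deficient matrix raises an error naming the
    collinear columns.
    """
    sub = ds.subset(subset) if subset != "all" else ds
    names = list(ds.descriptor_names)
    n, p = len(sub), len(names)
    if n <= p + 1:
        raise ValueError(f"need more than p+1={p + 1} records to fit, have {n}")
    A = _design(sub, names)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError(
            "descriptor matrix is rank-deficient; collinear columns: "
            f"{_collinear_columns(A, names)}"
        )
    y = sub.activities()
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return LinearModel(
        intercept=float(beta[0]),
        coefficients={name: float(b) for name, b in zip(names, beta[1:])},
        descriptor_names=names,
        n_train=n,
    )


def predict(model: LinearModel, ds: QSARDataset, subset: str = "all") -> dict[str, float]:
    """Predicted activity per compound id: a0 + Σ aj·xj."""
    sub = ds.subset(subset) if subset != "all" else ds
    return {
        rec.id: model.predict_one(rec.descriptors, rec.id) for rec in sub.records
    }


def fit_statistics(
    model: LinearModel,
    ds: QSARDataset,
    subset: str = "train",
    *,
    rmse_convention: str = "residual-se",
) -> FitStats:
    """r², adjusted r², RMSE, MAE, F, and two-sided coefficient p-values.

    ``rmse_convention`` selects the denominator: ``"residual-se"`` →
    sqrt(SSE/(n−p−1)) (default, the regression residual standard error);
    ``"mean"`` → sqrt(SSE/n).
    """
    if rmse_convention not in ("residual-se", "mean"):
        raise ValueError(f"unknown rmse_convention {rmse_convention!r}")
    sub = ds.subset(subset) if subset != "all" else ds
    if len(sub) == 0:
        raise ValueError(f"subset {subset!r} is empty")
    names = model.descriptor_names
    n, p = len(sub), len(names)
    y = sub.activities()
    A = _design(sub, names)
    beta = np.concatenate(
        [[model.intercept], [model.coefficients[name] for name in names]]
    )
    yhat = A @ beta
    resid = y - yhat
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("activity is constant on this subset; r² undefined")
    r2 = 1.0 - sse / sst
    dof = n - p - 1
    r2_adj = ((n - 1) * r2 - p) / dof if dof > 0 else np.nan
    rmse = float(np.sqrt(sse / (dof if rmse_convention == "residual-se" else n)))
    mae = float(np.mean(np.abs(resid)))
    f_stat = ((sst - sse) / p) / (sse / dof) if dof > 0 else np.nan

    # classical OLS coefficient t-tests
    p_values: dict[str, float] = {}
    if dof > 0:
        XtX_inv = np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(XtX_inv) * sse / dof)
        tvals = beta / se
        pv = 2.0 * stats.t.sf(np.abs(tvals), dof)
        p_values = {name: float(v) for name, v in zip(names, pv[1:])}

    return FitStats(
        r2=float(r2),
        r2_adj=float(r2_adj),
        rmse=rmse,
        mae=mae,
        f_stat=float(f_stat),
        sse=sse,
        sst=sst,
        n=n,
        p=p,
        coef_p_values=p_values,
    )
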