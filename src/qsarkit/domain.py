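"""Leverage-based applicability domain (Williams plot).

A prediction is trusted only for compounds that resemble the training set.
The leverage of a compound with descriptor row x is

    h = x̃ᵀ (X̃ᵀX̃)⁻¹ x̃,

where X̃ is the intercept-augmented training descriptor matrix and x̃ the
intercept-augmented query row.  The warning threshold is h* = 3(d+1)/n for
d descriptors and n training compounds.  Compounds are classified on the
Williams plot: leverage above h* marks a structural outlier; a standardized
residual beyond ±σ_mult (default 2) marks a response outlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import QSARDataset
from .regression import LinearModel, _design, fit_statistics, predict

__all__ = ["ADResult", "leverages", "williams_classify", "applicability_domain"]

LABELS = ("inside", "structural-outlier", "response-outlier", "both")


@dataclass
class ADResult:
    """Leverages, threshold, standardized residuals and domain labels."""

    leverages: dict[str, float]
    h_star: float
    std_residuals: dict[str, float] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)


def leverages(train: QSARDataset, query: QSARDataset | None = None) -> ADResult:
    """Hat values for the training compounds and any query compounds.

    Training leverages lie in [1/n, 1] and sum to d+1 (the trace of the hat
    matrix with intercept); a query at the training centroid has h = 1/n.
    """
    names = list(train.descriptor_names)
    Xt = _design(train.subset("all"), names)
    n, d = len(train), len(names)
    gram = Xt.T @ Xt
    if np.linalg.matrix_rank(gram) < gram.shape[0]:
        raise ValueError("XᵀX is singular; drop collinear descriptors first")
    gram_inv = np.linalg.inv(gram)

    result: dict[str, float] = {}
    for ids, dataset in ((train.ids, train), (query.ids if query else [], query)):
        if dataset is None:
            continue
        Xq = _design(dataset.subset("all"), names)
        h = np.einsum("ij,jk,ik->i", Xq, gram_inv, Xq)
        result.update(zip(ids, h.tolist()))
    return ADResult(leverages=result, h_star=3.0 * (d + 1) / n)


def williams_classify(ad: ADResult, residual_sigma_mult: float = 2.0) -> ADResult:
    """Assign Williams-plot labels from leverages and standardized residuals.

    ``inside`` iff h ≤ h* and |standardized residual| ≤ the multiplier;
    otherwise ``structural-outlier``, ``response-outlier`` or ``both``.
    """
    if not ad.std_residuals:
        raise ValueError("std_residuals must be populated before classification")
    labels = {}
    for cid, h in ad.leverages.items():
        high_lev = h > ad.h_star
        high_res = abs(ad.std_residuals[cid]) > residual_sigma_mult
        labels[cid] = (
            "both"
            if high_lev and high_res
            else "structural-outlier"
            if high_lev
            else "response-outlier"
            if high_res
            else "inside"
        )
    return replace(ad, labels=labels)


def applicability_domain(
    model: LinearModel,
    ds: QSARDataset,
    *,
    residual_sigma_mult: float = 2.0,
) -> ADResult:
    """Full Williams-plot analysis of every train/test compound.

    Leverages use the training descriptor matrix; residuals are
    (observed − predicted) divided by the training residual standard error
    sqrt(SSE/(n−p−1)), consistent with the fit RMSE convention.
    """
    train, test = ds.train, ds.test
    ad = leverages(train, test if len(test) else None)
    sigma = fit_statistics(model, ds).rmse
    preds = predict(model, ds)
    std_res = {}
    for rec in list(train.records) + list(test.records):
        std_res[rec.id] = (rec.activity - preds[rec.id]) / sigma
    ad.std_residuals = std_res
    return williams_classify(ad, residual_sigma_mult)
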