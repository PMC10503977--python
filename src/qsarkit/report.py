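"""Post-model structure–activity analyses.

Two complementary views of a finished model: how well independent docking
binding affinities track the measured activities, and which descriptors
carry the model.  Raw regression coefficients are incomparable across
descriptors with different units, so contributions use standardized
coefficient magnitudes |aj|·sd(xj), normalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datasets import QSARDataset
from .regression import LinearModel

__all__ = [
    "CorrelationReport",
    "affinity_activity_correlation",
    "descriptor_contributions",
]


@dataclass
class CorrelationReport:
    """Pearson correlation summary with the least-squares line."""

    r: float
    r2: float
    n: int
    slope: float
    intercept: float


def affinity_activity_correlation(ds: QSARDataset) -> CorrelationReport:
    """Correlate docking binding affinity (kcal/mol) with pIC50.

    Uses every compound carrying both an activity and a binding affinity
    (at least 3 required).  Affinities are negative (more negative =
    stronger predicted binding), so a useful docking protocol gives a
    strongly negative r against pIC50; r² is reported as the headline
    agreement measure.
    """
    pairs = [
        (rec.activity, rec.binding_affinity)
        for rec in ds.records
        if rec.activity is not None and rec.binding_affinity is not None
    ]
    if len(pairs) < 3:
        raise ValueError(
            f"need at least 3 compounds with both activity and affinity, have {len(pairs)}"
        )
    y = np.array([p[0] for p in pairs])
    x = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant column: correlation undefined")
    res = stats.linregress(x, y)
    return CorrelationReport(
        r=float(res.rvalue),
        r2=float(res.rvalue**2),
        n=len(pairs),
        slope=float(res.slope),
        intercept=float(res.intercept),
    )


def descriptor_contributions(
    model: LinearModel, ds: QSARDataset, subset: str = "train"
) -> dict[str, float]:
    """Relative descriptor importance: |aj|·sd(xj), normalized to sum to 1.

    Standard deviations are taken over the chosen subset (default train),
    making the ranking invariant to descriptor unit changes.  A
    zero-variance descriptor contributes 0.
    """
    sub = ds.subset(subset) if subset != "all" else ds
    X = sub.descriptor_matrix(model.descriptor_names)
    sds = X.std(axis=0, ddof=1)
    raw = np.array(
        [abs(model.coefficients[name]) for name in model.descriptor_names]
    ) * sds
    total = raw.sum()
    if total == 0:
        raise ValueError("all contributions are zero")
    return {
        name: float(val / total)
        for name, val in zip(model.descriptor_names, raw)
    }
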