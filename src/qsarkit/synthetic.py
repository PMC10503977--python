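"""Synthetic QSAR datasets with known ground truth.

Generates compound tables with the statistical structure the analysis
pipeline assumes: p correlated Gaussian descriptors and a linear activity
with Gaussian noise, split 80/20 into train/test.  The defaults mirror the
packaged chalcone dataset's regime — 25 compounds, the four-descriptor
correlation structure and column scales of its training set, the fitted
model coefficients as ground truth, and a noise SD equal to the fit's
residual standard error — so synthetic runs exercise the pipeline in the
same corner of parameter space as the real data.

``generate_null`` decouples the activity from the descriptors entirely
(activity drawn i.i.d. with the same marginal mean and variance), giving
the chance-correlation regime that Y-randomization probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import CompoundRecord, QSARDataset, split_dataset

__all__ = ["SyntheticSpec", "generate", "generate_null"]

# Training-set summary statistics of the packaged chalcone dataset,
# in the order (BCUT_SMR_2, logP(o/w), SlogP_VSA4, vsurf_IW3).
_DEFAULT_NAMES = ["BCUT_SMR_2", "logP(o/w)", "SlogP_VSA4", "vsurf_IW3"]
_DEFAULT_MEANS = [0.8298, 4.3781, 16.7906, 1.8713]
_DEFAULT_SDS = [0.0435, 0.3929, 13.5542, 0.7820]
_DEFAULT_CORR = [
    [1.0000, -0.4640, -0.5413, 0.2441],
    [-0.4640, 1.0000, 0.0986, -0.5042],
    [-0.5413, 0.0986, 1.0000, 0.1923],
    [0.2441, -0.5042, 0.1923, 1.0000],
]
_DEFAULT_COEFS = [8.469, 0.636, 0.057, -0.442]
_DEFAULT_INTERCEPT = -3.754
_DEFAULT_NOISE_SD = 0.29


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic generator; defaults emulate the packaged
    chalcone training set (n=25, p=4 correlated descriptors, linear pIC50)."""

    n: int = 25
    descriptor_names: list[str] = field(default_factory=lambda: list(_DEFAULT_NAMES))
    means: list[float] = field(default_factory=lambda: list(_DEFAULT_MEANS))
    sds: list[float] = field(default_factory=lambda: list(_DEFAULT_SDS))
    correlation: list[list[float]] = field(
        default_factory=lambda: [row[:] for row in _DEFAULT_CORR]
    )
    coefficients: list[float] = field(default_factory=lambda: list(_DEFAULT_COEFS))
    intercept: float = _DEFAULT_INTERCEPT
    noise_sd: float = _DEFAULT_NOISE_SD
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        p = len(self.descriptor_names)
        if self.n < 8:
            raise ValueError("need n >= 8")
        if not (len(self.means) == len(self.sds) == len(self.coefficients) == p):
            raise ValueError("means, sds and coefficients must have length p")
        C = np.asarray(self.correlation, dtype=float)
        if C.shape != (p, p) or not np.allclose(C, C.T):
            raise ValueError("correlation must be a symmetric p×p matrix")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        try:
            np.linalg.cholesky(C)
        except np.linalg.LinAlgError as exc:
            raise ValueError("correlation matrix is not positive definite") from exc
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _draw_descriptors(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    C = np.asarray(spec.correlation)
    L = np.linalg.cholesky(C)
    Z = rng.standard_normal((spec.n, len(spec.descriptor_names)))
    return np.asarray(spec.means) + (Z @ L.T) * np.asarray(spec.sds)


def _assemble(spec: SyntheticSpec, X: np.ndarray, y: np.ndarray) -> QSARDataset:
    width = len(str(spec.n))
    records = [
        CompoundRecord(
            id=f"C{i + 1:0{width}d}",
            descriptors=dict(zip(spec.descriptor_names, X[i])),
            activity=float(y[i]),
        )
        for i in range(spec.n)
    ]
    ds = QSARDataset(records, list(spec.descriptor_names))
    return split_dataset(ds, spec.train_fraction, spec.seed)


def generate(spec: SyntheticSpec | None = None) -> QSARDataset:
    """Draw a dataset with a genuine linear descriptor–activity relationship.

    Descriptors come from the specified multivariate normal; the activity
    is intercept + Σ aj·xj + N(0, noise_sd²).  The same seed always yields
    the identical dataset, including the train/test assignment.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    X = _draw_descriptors(spec, rng)
    y = spec.intercept + X @ np.asarray(spec.coefficients)
    y = y + rng.normal(0.0, spec.noise_sd, size=spec.n)
    return _assemble(spec, X, y)


def generate_null(spec: SyntheticSpec | None = None) -> QSARDataset:
    """Draw a dataset whose activity is independent of the descriptors.

    The activity is sampled i.i.d. normal with the same marginal mean and
    variance the structural model would produce (aᵀΣa + noise²), so any
    apparent fit is pure chance correlation — the regime a Y-randomization
    test emulates.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    X = _draw_descriptors(spec, rng)
    a = np.asarray(spec.coefficients)
    sds = np.asarray(spec.sds)
    cov = np.asarray(spec.correlation) * np.outer(sds, sds)
    mu = spec.intercept + float(np.asarray(spec.means) @ a)
    sigma = float(np.sqrt(a @ cov @ a + spec.noise_sd**2))
    y = rng.normal(mu, sigma, size=spec.n)
    return _assemble(spec, X, y)
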