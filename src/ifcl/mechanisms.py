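"""Per-node causal mechanisms: regression fit, residual extraction, noise KDE.

Under the additive noise model each variable satisfies

    X_i = F_i(X_{P_i}) + E_i,

with E_i independent of the parents X_{P_i}. The causal function F_i is
estimated by regression (ordinary least squares on the parent columns by
default, optionally a polynomial basis), the residuals stand in for the
noise draws, and the noise density is approximated by a Gaussian-kernel
density estimate. The per-sample log noise densities are the building
block of the structure score: the likelihood of the data under a causal
structure equals the likelihood of the residuals under the noise
densities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.preprocessing import PolynomialFeatures

from .dataio import Dataset
from .errors import ConfigurationError, NumericalError, StructuralError

__all__ = ["GaussianKDE", "NodeMechanism", "fit_mechanism", "kde_fit", "noise_loglik"]

logger = logging.getLogger(__name__)

#: Supported regression families and the polynomial degree each implies.
FAMILIES = {"linear": 1, "poly2": 2, "poly3": 3}

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: Relative bandwidth floor: fraction of the residual scale (or absolute
#: value when the residuals are numerically constant).
BANDWIDTH_FLOOR = 1e-3


class GaussianKDE:
    """Gaussian-kernel density estimate evaluated in log space.

    Bandwidth follows Silverman's rule of thumb,

        h = 0.9 * min(sd, IQR / 1.34) * m^(-1/5),

    with a positive floor so that degenerate (near-constant) residual
    vectors still yield a finite log-density. Evaluation uses a stable
    log-sum-exp over kernel centers, chunked to bound memory.
    """

    def __init__(self, samples: np.ndarray, bandwidth: float | None = None):
        samples = np.asarray(samples, dtype=float).ravel()
        if samples.size < 2:
            raise ConfigurationError("KDE requires at least 2 samples")
        self.samples = samples
        self.m = samples.size
        self.bandwidth = float(bandwidth) if bandwidth else _silverman(samples)

    def logpdf(self, x: np.ndarray, chunk: int = 1024) -> np.ndarray:
        """Log density at each point of ``x``."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.empty(x.size)
        h = self.bandwidth
        const = math.log(self.m) + math.log(h) + _LOG_SQRT_2PI
        for lo in range(0, x.size, chunk):
            block = x[lo : lo + chunk, None]
            z = -0.5 * ((block - self.samples[None, :]) / h) ** 2
            out[lo : lo + chunk] = logsumexp(z, axis=1) - const
        return out

    def logpdf_loo(self, chunk: int = 1024) -> np.ndarray:
        """Leave-one-out log density at the fitting samples.

        Each sample is scored under the KDE built from the other m-1
        samples: the kernel centered on the evaluated point never
        contributes.
        """
        h = self.bandwidth
        const = math.log(self.m - 1) + math.log(h) + _LOG_SQRT_2PI
        out = np.empty(self.m)
        for lo in range(0, self.m, chunk):
            hi = min(lo + chunk, self.m)
            z = -0.5 * ((self.samples[lo:hi, None] - self.samples[None, :]) / h) ** 2
            idx = np.arange(lo, hi)
            z[idx - lo, idx] = -np.inf
            out[lo:hi] = logsumexp(z, axis=1) - const
        return out


def _silverman(samples: np.ndarray) -> float:
    """Silverman rule-of-thumb bandwidth with a degeneracy floor."""
    m = samples.size
    sd = float(np.std(samples, ddof=1))
    q75, q25 = np.percentile(samples, [75, 25])
    iqr = float(q75 - q25)
    spread = min(x for x in (sd, iqr / 1.34) if x > 0) if (sd > 0 or iqr > 0) else 0.0
    h = 0.9 * spread * m ** (-0.2)
    floor = BANDWIDTH_FLOOR * sd if sd > 0 else BANDWIDTH_FLOOR
    if h < floor:
        logger.warning(
            "near-degenerate residuals (sd=%.3g): bandwidth floored at %.3g", sd, floor
        )
        h = floor
    return h


def kde_fit(residuals: np.ndarray) -> GaussianKDE:
    """Fit a Gaussian KDE to a residual vector (Silverman bandwidth)."""
    return GaussianKDE(residuals)


@dataclass(frozen=True)
class NodeMechanism:
    """A fitted causal function for one node plus its noise model.

    Attributes
    ----------
    node : index of the modelled variable.
    parents : sorted tuple of parent indices (possibly empty).
    family : regression family tag ('linear', 'poly2', 'poly3').
    coefficients : fitted parameter vector (intercept first).
    residuals : length-m noise estimates o_{j,i} - F_i(o_{j,P_i}).
    kde : Gaussian KDE over the residuals.
    loglik : sum over samples of the in-sample log noise density.
    """

    node: int
    parents: tuple[int, ...]
    family: str
    coefficients: np.ndarray
    residuals: np.ndarray
    kde: GaussianKDE
    loglik: float

    @property
    def d(self) -> int:
        """Number of fitted coefficients d_i (intercept included)."""
        return len(self.coefficients)

    @property
    def m(self) -> int:
        return len(self.residuals)

    @property
    def bandwidth(self) -> float:
        return self.kde.bandwidth

    def to_dict(self) -> dict:
        return {
            "node": self.node,
            "parents": list(self.parents),
            "family": self.family,
            "coefficients": [float(c) for c in self.coefficients],
            "d": self.d,
            "bandwidth": self.bandwidth,
            "loglik": self.loglik,
        }


def _design_matrix(data: Dataset, parents: tuple[int, ...], family: str) -> np.ndarray:
    X = data.O[:, list(parents)]
    degree = FAMILIES[family]
    if degree == 1:
        return np.column_stack([np.ones(data.m), X])
    poly = PolynomialFeatures(degree=degree, include_bias=True)
    return poly.fit_transform(X)


def fit_mechanism(
    data: Dataset,
    node: int,
    parents,
    family: str = "linear",
    loo: bool = False,
) -> NodeMechanism:
    """Fit F_i for ``node`` given ``parents`` and estimate its noise density.

    With an empty parent set F_i is the constant sample mean (d_i = 1).
    For the linear family with k parents, d_i = k + 1 (intercept plus one
    slope per parent). ``loo`` scores the residuals by leave-one-out KDE
    instead of in-sample evaluation.
    """
    parents = tuple(sorted(int(p) for p in parents))
    if family not in FAMILIES:
        raise ConfigurationError(f"unknown regression family {family!r}")
    if node in parents:
        raise StructuralError(f"node {node} cannot be its own parent")
    if not all(0 <= p < data.n for p in parents) or not 0 <= node < data.n:
        raise StructuralError("node/parent index out of range")

    y = data.column(node)
    if not parents:
        coef = np.array([y.mean()])
        residuals = y - coef[0]
    else:
        A = _design_matrix(data, parents, family)
        rank = np.linalg.matrix_rank(A)
        if rank < A.shape[1]:
            raise NumericalError(
                f"singular design matrix for node {node} with parents {parents}"
            )
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        residuals = y - A @ coef

    kde = kde_fit(residuals)
    logdens = kde.logpdf_loo() if loo else kde.logpdf(residuals)
    return NodeMechanism(
        node=node,
        parents=parents,
        family=family,
        coefficients=np.asarray(coef),
        residuals=residuals,
        kde=kde,
        loglik=float(np.sum(logdens)),
    )


def noise_loglik(mech: NodeMechanism, loo: bool = False) -> np.ndarray:
    """Per-sample log noise densities log P(E_i = o_{j,i} - F_i(o_{j,P_i}))."""
    if loo:
        return mech.kde.logpdf_loo()
    return mech.kde.logpdf(mech.residuals)
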