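"""Stage-2 sensitivity machinery: numerically centered one-variable kernels,
a first-order additive expansion fitted by support-vector regression, and the
covariance decomposition of the score variance into structural and
correlative indices.

Kernel centering works without knowing the input distribution.  For a raw
one-variable kernel matrix ``K`` at the sample points, the marginal integrals
are Monte-Carlo approximated by the row means ``r`` and the grand mean ``g``,
giving the centered kernel

    ``K0[j, k] = K[j, k] - r[j] * r[k] / g``

whose every row mean vanishes identically at the sample points.  A regressor
trained with the composite kernel ``c + sum_i K0_i`` therefore decomposes into
a constant plus zero-mean one-variable component functions, read directly off
the dual coefficients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr
from sklearn.svm import SVR

from .datasets import FeatureTable
from .errors import ConfigurationError, DataError, KernelError
from .scoring import ScoreSet

__all__ = [
    "FeatureKernel",
    "KernelBank",
    "HDMRModel",
    "SCSAIndices",
    "center_kernel_matrix",
    "build_kernel_bank",
    "fit_svr_hdmr",
    "compute_scsa",
    "influence_patterns",
    "component_grid",
]


def center_kernel_matrix(raw: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Center a symmetric raw kernel matrix to zero Monte-Carlo expectation.

    Returns ``(K0, row_means, grand_mean)``.  Raises :class:`KernelError` when
    the grand mean is not strictly positive (the centering denominator).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != raw.shape[1]:
        raise ConfigurationError("raw kernel matrix must be square")
    r = raw.mean(axis=1)
    g = float(raw.mean())
    if g <= 0.0:
        raise KernelError(
            "kernel grand mean is not positive; choose a positive-valued "
            "kernel family (e.g. rbf)"
        )
    k0 = raw - np.outer(r, r) / g
    return k0, r, g


def _rbf(a: np.ndarray, b: np.ndarray, bandwidth: float) -> np.ndarray:
    d = a[:, None] - b[None, :]
    return np.exp(-(d**2) / (2.0 * bandwidth**2))


def _poly(a: np.ndarray, b: np.ndarray, degree: int) -> np.ndarray:
    return (1.0 + a[:, None] * b[None, :]) ** degree


@dataclass
class FeatureKernel:
    """One feature's centered kernel plus everything needed to evaluate it
    at new points (interpolated row-mean correction)."""

    name: str
    x: np.ndarray  # sample values
    family: str
    bandwidth: float
    k0: np.ndarray  # (N, N) centered matrix
    row_means: np.ndarray
    grand_mean: float
    knots_x: np.ndarray  # unique sorted sample values
    knots_r: np.ndarray  # row means averaged over duplicate x

    def raw_cross(self, x_new: np.ndarray) -> np.ndarray:
        x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
        if self.family == "rbf":
            return _rbf(x_new, self.x, self.bandwidth)
        return _poly(x_new, self.x, int(self.bandwidth))

    def centered_cross(self, x_new: np.ndarray) -> np.ndarray:
        """Centered kernel between new points (rows) and the samples (cols).

        The marginal-integral correction at a new point is linearly
        interpolated from the sample row means, with constant extrapolation
        beyond the observed range.
        """
        x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
        raw = self.raw_cross(x_new)
        r_new = np.interp(x_new, self.knots_x, self.knots_r)
        return raw - np.outer(r_new, self.row_means) / self.grand_mean


@dataclass
class KernelBank:
    """Centered one-variable kernels for a feature subset, plus the additive
    constant ``c`` of the composite kernel."""

    kernels: list[FeatureKernel]
    c: float

    @property
    def feature_names(self) -> list[str]:
        return [k.name for k in self.kernels]

    @property
    def n_samples(self) -> int:
        return self.kernels[0].k0.shape[0]

    def composite(self) -> np.ndarray:
        gram = np.full((self.n_samples, self.n_samples), self.c)
        for k in self.kernels:
            gram += k.k0
        return gram


def build_kernel_bank(
    table: FeatureTable,
    feature_subset=None,
    family: str = "rbf",
    bandwidth="median",
    c: float = 1.0,
) -> KernelBank:
    """Build centered one-variable kernels for each selected feature.

    ``bandwidth`` is either a positive number or ``"median"`` (median of the
    nonzero pairwise absolute differences of that feature's values).  For the
    polynomial family the bandwidth slot carries the degree.
    """
    if family not in ("rbf", "polynomial"):
        raise ConfigurationError(f"unknown kernel family: {family!r}")
    if c < 0:
        raise ConfigurationError("kernel constant c must be nonnegative")
    sub = table if feature_subset is None else table.subset(list(feature_subset))
    if sub.n_samples < 5:
        raise DataError("need at least 5 samples to center kernels")
    kernels = []
    for j, name in enumerate(sub.feature_names):
        x = sub.values[:, j]
        if family == "rbf":
            if bandwidth == "median":
                diffs = np.abs(x[:, None] - x[None, :])[np.triu_indices(len(x), k=1)]
                nz = diffs[diffs > 0]
                if nz.size == 0:
                    raise DataError(f"constant column {name!r}: kernel bandwidth undefined")
                bw = float(np.median(nz))
            else:
                bw = float(bandwidth)
                if bw <= 0:
                    raise ConfigurationError("rbf bandwidth must be positive")
            raw = _rbf(x, x, bw)
        else:
            bw = 3.0 if bandwidth == "median" else float(bandwidth)
            raw = _poly(x, x, int(bw))
        k0, r, g = center_kernel_matrix(raw)
        order = np.argsort(x, kind="stable")
        xs, rs = x[order], r[order]
        # duplicate sample values collapse to one interpolation knot
        knots_x, inverse = np.unique(xs, return_inverse=True)
        knots_r = np.bincount(inverse, weights=rs) / np.bincount(inverse)
        kernels.append(
            FeatureKernel(
                name=name, x=x, family=family, bandwidth=bw, k0=k0,
                row_means=r, grand_mean=g, knots_x=knots_x, knots_r=knots_r,
            )
        )
    return KernelBank(kernels=kernels, c=float(c))


@dataclass
class HDMRModel:
    """Fitted first-order additive expansion of the score function.

    ``f0 + sum_i components[:, i]`` equals the regressor's fitted value at
    every sample; each component has (numerically) zero sample mean.
    """

    bank: KernelBank
    beta: np.ndarray  # dual coefficients (alpha - alpha*) over all samples
    intercept: float
    f0: float
    components: np.ndarray  # (N, k) component values at the samples
    fitted: np.ndarray
    r_squared: float
    settings: dict = field(default_factory=dict)

    @property
    def feature_names(self) -> list[str]:
        return self.bank.feature_names

    def component_index(self, name: str) -> int:
        return self.feature_names.index(name)

    def evaluate_component(self, name: str, x_new: np.ndarray) -> np.ndarray:
        """Evaluate one component function at arbitrary points."""
        k = self.bank.kernels[self.component_index(name)]
        return k.centered_cross(x_new) @ self.beta

    def predict(self, table: FeatureTable) -> np.ndarray:
        total = np.full(table.n_samples, self.f0)
        for name in self.feature_names:
            total += self.evaluate_component(name, table.column(name))
        return total


def fit_svr_hdmr(
    bank: KernelBank,
    scores,
    epsilon: float | None = None,
    cost: float = 10.0,
    r2_floor: float = 0.5,
    tol: float = 1e-8,
) -> HDMRModel:
    """Fit epsilon-insensitive SVR with the composite kernel and decompose it.

    The dual coefficients act on each centered one-variable kernel separately,
    so the fit splits exactly into a constant ``f0`` plus zero-mean one-variable
    component functions.
    """
    y = scores.scores if isinstance(scores, ScoreSet) else np.asarray(scores, dtype=float)
    n = bank.n_samples
    if len(y) != n:
        raise ConfigurationError("kernel bank and scores disagree on sample count")
    if epsilon is None:
        epsilon = 0.1 * float(np.std(y))
    gram = bank.composite()
    svr = SVR(kernel="precomputed", C=cost, epsilon=epsilon, tol=tol, max_iter=2_000_000)
    svr.fit(gram, y)
    if getattr(svr, "fit_status_", 0) != 0:
        raise DataError(
            f"SVR did not converge (C={cost}, epsilon={epsilon}); adjust settings"
        )
    beta = np.zeros(n)
    beta[svr.support_] = svr.dual_coef_[0]
    intercept = float(svr.intercept_[0])
    f0 = intercept + bank.c * float(beta.sum())
    components = np.column_stack([k.k0 @ beta for k in bank.kernels])
    fitted = f0 + components.sum(axis=1)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    if r2 < r2_floor:
        warnings.warn(
            f"first-order expansion fits the scores poorly (R^2={r2:.3f} < "
            f"{r2_floor}); a first-order truncation may be inadequate",
            stacklevel=2,
        )
    return HDMRModel(
        bank=bank,
        beta=beta,
        intercept=intercept,
        f0=f0,
        components=components,
        fitted=fitted,
        r_squared=r2,
        settings={"epsilon": float(epsilon), "cost": float(cost), "c": bank.c},
    )


@dataclass
class SCSAIndices:
    """Structural/correlative decomposition of the score variance.

    ``sb_matrix[i, j]`` is the normalized covariance of components i and j;
    its diagonal is the structural index ``sa``, its off-diagonal row sums the
    correlative index ``sb``, and its row sums the total index ``s_total``.
    """

    feature_names: list[str]
    sa: np.ndarray
    sb: np.ndarray
    s_total: np.ndarray
    sb_matrix: np.ndarray
    sum_total: float
    output_variance: float

    def as_table(self) -> list[dict]:
        order = np.argsort(-self.sa, kind="stable")
        return [
            {
                "feature": self.feature_names[i],
                "sa": float(self.sa[i]),
                "sb": float(self.sb[i]),
                "s_total": float(self.s_total[i]),
            }
            for i in order
        ]

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "sa": self.sa.tolist(),
            "sb": self.sb.tolist(),
            "s_total": self.s_total.tolist(),
            "sb_matrix": self.sb_matrix.tolist(),
            "sum_total": self.sum_total,
            "output_variance": self.output_variance,
        }


def compute_scsa(model: HDMRModel, scores) -> SCSAIndices:
    """Covariance decomposition of the score variance over the sample points."""
    y = scores.scores if isinstance(scores, ScoreSet) else np.asarray(scores, dtype=float)
    n = len(y)
    var = float(np.mean((y - y.mean()) ** 2))
    if var == 0.0:
        raise DataError("constant classifier score: output variance is zero")
    f = model.components
    sb_matrix = (f.T @ f) / (n * var)
    sb_matrix = 0.5 * (sb_matrix + sb_matrix.T)  # enforce exact symmetry
    sa = np.diag(sb_matrix).copy()
    s_total = sb_matrix.sum(axis=1)
    sb = s_total - sa
    return SCSAIndices(
        feature_names=list(model.feature_names),
        sa=sa,
        sb=sb,
        s_total=s_total,
        sb_matrix=sb_matrix,
        sum_total=float(s_total.sum()),
        output_variance=var,
    )


def influence_patterns(
    model: HDMRModel, threshold: float = 0.3
) -> dict[str, dict]:
    """Classify each component's trend against its own feature values.

    Spearman rank correlation of ``f_i(x_i)`` with ``x_i`` over the samples:
    ``enhancing`` at or above +threshold, ``inhibiting`` at or below
    -threshold, otherwise ``non-monotone``.  A constant component reports
    correlation 0.
    """
    out: dict[str, dict] = {}
    for i, name in enumerate(model.feature_names):
        f_vals = model.components[:, i]
        x_vals = model.bank.kernels[i].x
        if np.ptp(f_vals) == 0 or np.ptp(x_vals) == 0:
            rho = 0.0
        else:
            rho = float(spearmanr(x_vals, f_vals).statistic)
            if not np.isfinite(rho):
                rho = 0.0
        if rho >= threshold:
            label = "enhancing"
        elif rho <= -threshold:
            label = "inhibiting"
        else:
            label = "non-monotone"
        out[name] = {"trend": label, "rank_correlation": rho}
    return out


def component_grid(model: HDMRModel, n_points: int = 100) -> dict[str, np.ndarray]:
    """Evaluate every component on a uniform grid over its observed range
    (for plotting/CSV export): returns ``{name: array[(x, f(x))...]}``."""
    grids: dict[str, np.ndarray] = {}
    for i, name in enumerate(model.feature_names):
        x = model.bank.kernels[i].x
        gx = np.linspace(float(x.min()), float(x.max()), n_points)
        gy = model.evaluate_component(name, gx)
        grids[name] = np.column_stack([gx, gy])
    return grids
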