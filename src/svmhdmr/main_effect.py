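"""Stage-1 sensitivity: empirical probability-integral transform, per-feature
component regression, and the variance-based main-effect index.

Each feature is mapped through its empirical CDF to a value ``z`` in (0, 1)
(midpoint plotting position, average ranks for ties), the centered classifier
score is regressed on a low-order polynomial in ``z``, and the main effect is
the mean squared fitted value divided by the population variance of the score.
The index depends on the feature only through ranks, so it is invariant under
any strictly increasing transform of the raw measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .datasets import FeatureTable
from .errors import ConfigurationError, DataError
from .scoring import ScoreSet

__all__ = [
    "CDFTransform",
    "ComponentFit",
    "MainEffectResult",
    "ecdf_transform",
    "fit_component_regression",
    "main_effect_index",
    "compute_main_effects",
    "rank_by_main_effect",
]


@dataclass
class CDFTransform:
    """Empirical-CDF values of every feature: ``z[s, i] = F_i(x_i^(s))``."""

    z: np.ndarray  # (N, n) values in (0, 1)
    feature_names: list[str]
    sorted_values: list[np.ndarray] = field(default_factory=list)
    plotting_position: str = "midpoint"

    def column(self, name_or_index) -> np.ndarray:
        if isinstance(name_or_index, str):
            idx = self.feature_names.index(name_or_index)
        else:
            idx = int(name_or_index)
        return self.z[:, idx]


def ecdf_transform(table: FeatureTable) -> CDFTransform:
    """Per-feature empirical CDF transform with midpoint plotting positions.

    ``z = (rank - 0.5) / N`` with average ranks for ties keeps all values
    strictly inside (0, 1), avoiding boundary atoms the right-continuous step
    ECDF would place at the maximum.
    """
    if table.n_samples < 3:
        raise DataError("need at least 3 samples for an empirical CDF transform")
    n = table.n_samples
    z = np.column_stack(
        [(rankdata(table.values[:, j], method="average") - 0.5) / n
         for j in range(table.n_features)]
    )
    return CDFTransform(
        z=z,
        feature_names=list(table.feature_names),
        sorted_values=[np.sort(table.values[:, j]) for j in range(table.n_features)],
    )


def _as_scores(scores) -> np.ndarray:
    if isinstance(scores, ScoreSet):
        return np.asarray(scores.scores, dtype=float)
    return np.asarray(scores, dtype=float)


@dataclass
class ComponentFit:
    """Least-squares polynomial fit of the centered score against one z-column."""

    coef: np.ndarray  # intercept first, then powers 1..degree
    degree: int
    fitted: np.ndarray  # fitted values at the training z points

    def __call__(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        design = np.vander(z, self.degree + 1, increasing=True)
        return design @ self.coef


def fit_component_regression(z_i: np.ndarray, scores, degree: int = 3) -> ComponentFit:
    """Regress the centered score on polynomials of one transformed feature.

    Returns the fitted one-variable component function; its sample mean over
    the training points is zero (within rounding) because the regression runs
    on centered scores with an intercept.
    """
    y = _as_scores(scores)
    z_i = np.asarray(z_i, dtype=float)
    n = len(y)
    if degree < 1:
        raise ConfigurationError("regression degree must be >= 1")
    if degree + 1 >= n:
        raise ConfigurationError(f"basis degree {degree} too large for N={n}")
    yc = y - y.mean()
    design = np.vander(z_i, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(design, yc, rcond=None)
    return ComponentFit(coef=coef, degree=degree, fitted=design @ coef)


def main_effect_index(fit: ComponentFit, scores) -> float:
    """Main effect: mean of the squared component values over the samples,
    divided by the population variance of the score."""
    y = _as_scores(scores)
    var = float(np.mean((y - y.mean()) ** 2))
    if var == 0.0:
        raise DataError("constant classifier score: output variance is zero")
    return float(np.mean(fit.fitted**2)) / var


@dataclass
class MainEffectResult:
    """Main-effect indices for all analyzed features plus their ranking."""

    s_hat: dict[str, float]
    fitted_components: dict[str, ComponentFit]
    output_variance: float
    ranking: list[str]
    ties: list[tuple[str, str]] = field(default_factory=list)


def compute_main_effects(
    table: FeatureTable, scores, degree: int = 3
) -> MainEffectResult:
    """ECDF-transform every feature, fit its component regression, and index it."""
    y = _as_scores(scores)
    if len(y) != table.n_samples:
        raise ConfigurationError("scores and table disagree on sample count")
    transform = ecdf_transform(table)
    var = float(np.mean((y - y.mean()) ** 2))
    if var == 0.0:
        raise DataError("constant classifier score: output variance is zero")
    s_hat: dict[str, float] = {}
    fits: dict[str, ComponentFit] = {}
    for j, name in enumerate(table.feature_names):
        fit = fit_component_regression(transform.z[:, j], y, degree=degree)
        fits[name] = fit
        s_hat[name] = float(np.mean(fit.fitted**2)) / var
    ranking, ties = rank_by_main_effect(s_hat)
    return MainEffectResult(
        s_hat=s_hat,
        fitted_components=fits,
        output_variance=var,
        ranking=ranking,
        ties=ties,
    )


def rank_by_main_effect(s_hat: dict[str, float]) -> tuple[list[str], list[tuple[str, str]]]:
    """Order features by decreasing index; exact ties break lexicographically
    by name and are reported as flagged pairs."""
    order = sorted(s_hat, key=lambda name: (-s_hat[name], name))
    ties = [
        (a, b)
        for a, b in zip(order, order[1:])
        if s_hat[a] == s_hat[b]
    ]
    return order, ties
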