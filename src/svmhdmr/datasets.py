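"""Labeled feature tables: loading, group filtering, [-1, 1] normalization,
and synthetic fixtures with planted informative structure.

The central object is :class:`FeatureTable`: an ``N x n`` matrix of continuous
measurements with feature names and binary labels encoded as -1/+1.  Loading
drops rows with missing values (no imputation) and restricts the table to
exactly two study groups.  Normalization maps every column affinely onto
``[-1, 1]`` so that each column attains both endpoints.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "FeatureTable",
    "SyntheticSpec",
    "METABOLITE_PANEL",
    "canonical_name",
    "load_feature_table",
    "normalize_features",
    "generate_synthetic",
    "save_feature_table",
]

#: Default feature profile: the 24 one-carbon-metabolism / transsulfuration
#: metabolite measurements, in their conventional x1..x24 order.
METABOLITE_PANEL: tuple[str, ...] = (
    "Methionine",
    "SAM",
    "SAH",
    "SAM/SAH",
    "% DNA methylation",
    "8-OHG",
    "Adenosine",
    "Homocysteine",
    "Cysteine",
    "Glu.-Cys.",
    "Cys.-Gly.",
    "tGSH",
    "fGSH",
    "GSSG",
    "fGSH/GSSG",
    "tGSH/GSSG",
    "Chlorotyrosine",
    "Nitrotyrosine",
    "Tyrosine",
    "Tryptophan",
    "fCystine",
    "fCysteine",
    "fCystine/fCysteine",
    "% oxidized glutathione",
)


def canonical_name(name: str) -> str:
    """Canonicalize a column name: lowercase, all punctuation/whitespace stripped.

    ``"fGSH/GSSG"`` and ``"fGSH_GSSG"`` map to the same key, so CSV dialects
    that mangle separators still match the profile.
    """
    return re.sub(r"[^0-9a-z]+", "", name.lower())


@dataclass
class FeatureTable:
    """An ``N x n`` labeled numeric table.

    ``labels`` take exactly the two values -1 and +1; ``group_names`` maps the
    codes back to the original group strings.  When ``normalized`` is true every
    column lies in ``[-1, 1]`` and attains both endpoints, and ``norm_params``
    stores the per-column ``(min, max)`` used so new data can be mapped
    consistently.
    """

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray
    group_names: dict[int, str] = field(
        default_factory=lambda: {-1: "NEU", +1: "ASD"}
    )
    normalized: bool = False
    norm_params: dict[str, tuple[float, float]] | None = None
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise DataError("feature values must be a 2-D matrix")
        if self.values.shape[0] != self.labels.shape[0]:
            raise DataError("labels and values disagree on sample count")
        if self.values.shape[1] != len(self.feature_names):
            raise DataError("feature_names and values disagree on feature count")
        if not np.all(np.isfinite(self.values)):
            raise DataError("feature values contain missing/non-finite entries")
        uniq = set(np.unique(self.labels).tolist())
        if not uniq <= {-1, 1}:
            raise DataError(f"labels must be encoded -1/+1, got {sorted(uniq)}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> dict[int, int]:
        return {int(v): int(c) for v, c in zip(*np.unique(self.labels, return_counts=True))}

    def feature_index(self, name: str) -> int:
        canon = {canonical_name(f): i for i, f in enumerate(self.feature_names)}
        key = canonical_name(name)
        if key not in canon:
            raise ConfigurationError(f"unknown feature column: {name!r}")
        return canon[key]

    def subset(self, names: list[str] | tuple[str, ...]) -> "FeatureTable":
        """Restrict to the given feature columns (canonical-name matched)."""
        if len(names) == 0:
            raise ConfigurationError("feature subset must be non-empty")
        idx = [self.feature_index(n) for n in names]
        params = None
        if self.norm_params is not None:
            params = {self.feature_names[i]: self.norm_params[self.feature_names[i]] for i in idx}
        return replace(
            self,
            values=self.values[:, idx],
            feature_names=[self.feature_names[i] for i in idx],
            norm_params=params,
        )

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_index(name)]

    def to_frame(self, label_column: str = "Group") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df[label_column] = [self.group_names[int(v)] for v in self.labels]
        return df


def load_feature_table(
    path,
    label_column: str,
    positive_label: str,
    negative_label: str,
    drop_groups: tuple[str, ...] = (),
    feature_columns: tuple[str, ...] | None = None,
) -> FeatureTable:
    """Read a CSV into a :class:`FeatureTable` restricted to two groups.

    Parameters
    ----------
    path : str or file-like
        CSV with a header row; one row per participant.
    label_column : str
        Name of the group-label column (canonical-name matched).
    positive_label, negative_label : str
        Group values mapped to +1 and -1 respectively.
    drop_groups : tuple of str
        Group values to discard entirely (e.g. a sibling cohort).
    feature_columns : tuple of str, optional
        Explicit whitelist of feature columns; default: every numeric
        column except the label column.

    Rows with a missing value in any selected feature column are dropped and
    counted in ``n_dropped``.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    canon_cols = {canonical_name(c): c for c in df.columns}
    label_key = canonical_name(label_column)
    if label_key not in canon_cols:
        raise ConfigurationError(
            f"label column {label_column!r} not found among {list(df.columns)}"
        )
    label_col = canon_cols[label_key]

    groups = df[label_col].astype(str).str.strip()
    present = set(groups.unique())
    for g in (positive_label, negative_label):
        if g not in present:
            raise DataError(f"requested group {g!r} absent from data (found {sorted(present)})")
    keep = groups.isin([positive_label, negative_label])
    dropped_groups = present - {positive_label, negative_label}
    unexpected = dropped_groups - set(drop_groups)
    # Unlisted extra groups are still excluded from a two-class table; they are
    # only worth surfacing, not fatal.
    df = df.loc[keep].reset_index(drop=True)
    groups = groups.loc[keep].reset_index(drop=True)

    if feature_columns is not None:
        cols = []
        for want in feature_columns:
            key = canonical_name(want)
            if key not in canon_cols:
                raise ConfigurationError(f"feature column {want!r} not found in CSV header")
            cols.append(canon_cols[key])
        names = list(feature_columns)
    else:
        numeric = df.drop(columns=[label_col]).apply(
            lambda s: pd.to_numeric(s, errors="coerce")
        )
        cols = [c for c in numeric.columns if numeric[c].notna().any()]
        names = cols
    if len(cols) < 2:
        raise ConfigurationError("need at least 2 numeric feature columns")

    values = df[cols].apply(lambda s: pd.to_numeric(s, errors="coerce")).to_numpy(dtype=float)
    row_ok = np.isfinite(values).all(axis=1)
    n_dropped = int((~row_ok).sum())
    values = values[row_ok]
    groups = groups[row_ok].reset_index(drop=True)

    labels = np.where(groups == positive_label, 1, -1)
    counts = {g: int((groups == g).sum()) for g in (negative_label, positive_label)}
    if min(counts.values()) < 2:
        raise DataError(f"fewer than 2 samples per group after filtering: {counts}")

    return FeatureTable(
        values=values,
        feature_names=[str(n) for n in names],
        labels=labels,
        group_names={-1: negative_label, +1: positive_label},
        n_dropped=n_dropped,
    )


def normalize_features(table: FeatureTable) -> FeatureTable:
    """Map every feature column affinely onto ``[-1, 1]``.

    Each column is transformed by ``x -> 2 (x - min) / (max - min) - 1`` using
    that column's min/max over all retained samples, so the endpoints -1 and +1
    are attained exactly.  The ``(min, max)`` pairs are stored for applying the
    same map to new data.
    """
    if table.normalized:
        raise ConfigurationError("table is already normalized")
    lo = table.values.min(axis=0)
    hi = table.values.max(axis=0)
    const = np.nonzero(hi == lo)[0]
    if const.size:
        bad = table.feature_names[const[0]]
        raise DataError(f"constant column cannot be normalized: {bad!r}")
    scaled = 2.0 * (table.values - lo) / (hi - lo) - 1.0
    params = {name: (float(a), float(b)) for name, a, b in zip(table.feature_names, lo, hi)}
    return replace(table, values=scaled, normalized=True, norm_params=params)


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic labeled table with planted informative features.

    Features are drawn from a zero-mean multivariate normal with the given
    correlation matrix; a latent score ``s = sum_j w_j x_j`` over the
    informative subset produces labels ``sign(s)``, then each label is flipped
    independently with probability ``label_noise``.
    """

    n_samples: int
    n_features: int
    informative: tuple[int, ...]
    effect_weights: tuple[float, ...] | None = None
    correlation: np.ndarray | None = None
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_features < 1:
            raise ConfigurationError("need n_samples >= 2 and n_features >= 1")
        self.informative = tuple(int(i) for i in self.informative)
        if not set(self.informative) <= set(range(self.n_features)):
            raise ConfigurationError("informative indices must lie in [0, n_features)")
        if self.effect_weights is None:
            self.effect_weights = tuple(1.0 for _ in self.informative)
        self.effect_weights = tuple(float(w) for w in self.effect_weights)
        if len(self.effect_weights) != len(self.informative):
            raise ConfigurationError("effect_weights must match informative subset")
        if not 0.0 <= self.label_noise < 0.5:
            raise ConfigurationError("label_noise must lie in [0, 0.5)")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            if c.shape != (self.n_features, self.n_features):
                raise ConfigurationError("correlation matrix has wrong shape")
            if not np.allclose(c, c.T, atol=1e-12):
                raise ConfigurationError("correlation matrix must be symmetric")
            if not np.allclose(np.diag(c), 1.0, atol=1e-12):
                raise ConfigurationError("correlation matrix must have unit diagonal")
            if np.linalg.eigvalsh(c).min() < -1e-10:
                raise ConfigurationError("correlation matrix is not positive semi-definite")
            self.correlation = c

    def to_json(self) -> str:
        d = {
            "n_samples": self.n_samples,
            "n_features": self.n_features,
            "informative": list(self.informative),
            "effect_weights": list(self.effect_weights),
            "correlation": None
            if self.correlation is None
            else np.asarray(self.correlation).tolist(),
            "label_noise": self.label_noise,
            "seed": self.seed,
        }
        return json.dumps(d, indent=1)


def generate_synthetic(spec: SyntheticSpec) -> FeatureTable:
    """Draw a :class:`FeatureTable` from a :class:`SyntheticSpec` (seeded)."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.n_features
    if spec.correlation is None:
        x = rng.standard_normal((n, p))
    else:
        # eigh factorization tolerates a singular PSD correlation matrix
        w, v = np.linalg.eigh(spec.correlation)
        w = np.clip(w, 0.0, None)
        x = rng.standard_normal((n, p)) @ (v * np.sqrt(w)) @ v.T
    score = np.zeros(n)
    for j, wgt in zip(spec.informative, spec.effect_weights):
        score += wgt * x[:, j]
    labels = np.where(score >= 0, 1, -1)
    if spec.label_noise > 0:
        flips = rng.random(n) < spec.label_noise
        labels = np.where(flips, -labels, labels)
    names = [f"x{j + 1}" for j in range(p)]
    return FeatureTable(values=x, feature_names=names, labels=labels,
                        group_names={-1: "NEG", +1: "POS"})


def save_feature_table(table: FeatureTable, path, label_column: str = "Group") -> None:
    """Write the table as CSV with full float precision (round-trip safe)."""
    table.to_frame(label_column).to_csv(path, index=False, float_format="%.17g")
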