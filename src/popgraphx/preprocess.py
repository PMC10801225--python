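"""Cohort cleaning, partitioning and standardization.

Cleaning follows the cohort-preparation recipe: per class and per
continuous feature, values outside the [5th, 95th] percentile band and
missing values are replaced by a centered moving mean (window length 8:
four rows either side, in stored order, clean cells only); missing
categoricals take the class mode.  The train/validation/test split is
stratified by class and happens *before* standardization; continuous
features are then z-scored with train-partition statistics only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import CATEGORICAL_FEATURES, CLASSES, CONTINUOUS_FEATURES

PARTITIONS = ("train", "validation", "test")


@dataclass
class SplitAssignment:
    """Row-wise partition labels plus the fractions and seed that made them."""

    assignment: pd.Series  # index-aligned with the table; values in PARTITIONS
    fractions: tuple[float, float, float]
    seed: int

    def mask(self, partition: str) -> np.ndarray:
        if partition not in PARTITIONS:
            raise ValueError(f"unknown partition {partition!r}")
        return (self.assignment == partition).to_numpy()

    def to_json(self) -> str:
        return json.dumps({
            "fractions": list(self.fractions),
            "seed": self.seed,
            "assignment": self.assignment.tolist(),
        })

    @classmethod
    def from_json(cls, text: str) -> "SplitAssignment":
        d = json.loads(text)
        return cls(pd.Series(d["assignment"]), tuple(d["fractions"]), d["seed"])


@dataclass
class ScalerStats:
    """Train-partition mean/SD per continuous feature (for inverse
    transforms and for displaying explanations in original units)."""

    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)

    def inverse(self, feature: str, z: float) -> float:
        return z * self.sd[feature] + self.mean[feature]

    def to_json(self) -> str:
        return json.dumps({"mean": self.mean, "sd": self.sd})

    @classmethod
    def from_json(cls, text: str) -> "ScalerStats":
        d = json.loads(text)
        return cls(mean=d["mean"], sd=d["sd"])


def _moving_mean_fill(values: np.ndarray, bad: np.ndarray, window: int) -> np.ndarray:
    """Replace flagged cells by the mean of clean cells within a centered
    window (window//2 rows either side), widening when the window holds
    no clean cell."""
    out = values.astype(float).copy()
    n = len(values)
    clean_idx = np.flatnonzero(~bad)
    if clean_idx.size == 0:
        raise ValueError("all cells flagged")
    half = window // 2
    for i in np.flatnonzero(bad):
        w = half
        while True:
            lo, hi = max(0, i - w), min(n, i + w + 1)
            sel = clean_idx[(clean_idx >= lo) & (clean_idx < hi)]
            if sel.size:
                out[i] = values[sel].mean()
                break
            w *= 2
    return out


def clean_features(table: pd.DataFrame, lower: float = 0.05, upper: float = 0.95,
                   window: int = 8) -> pd.DataFrame:
    """Single-pass class-wise outlier/missing replacement.

    Percentile bands are computed per class per feature on the original
    values (one pass, no iteration).  Flagged cells are excluded from
    the moving means that replace them.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    if not 0.0 <= lower < upper <= 1.0:
        raise ValueError("need 0 <= lower < upper <= 1")
    out = table.copy()
    for c, class_index in out.groupby("label", observed=True).groups.items():
        idx = np.asarray(class_index)
        for f in CONTINUOUS_FEATURES:
            vals = out.loc[idx, f].to_numpy(dtype=float)
            finite = np.isfinite(vals)
            if not finite.any():
                raise ValueError(f"feature {f!r} entirely missing in class {c!r}")
            p_lo, p_hi = np.percentile(vals[finite], [100 * lower, 100 * upper])
            bad = ~finite | (vals < p_lo) | (vals > p_hi)
            if bad.any():
                out.loc[idx, f] = _moving_mean_fill(vals, bad, window)
        for f in CATEGORICAL_FEATURES:
            vals = out.loc[idx, f].to_numpy(dtype=float)
            missing = ~np.isfinite(vals)
            if missing.all():
                raise ValueError(f"feature {f!r} entirely missing in class {c!r}")
            if missing.any():
                codes, counts = np.unique(vals[~missing], return_counts=True)
                vals[missing] = codes[np.argmax(counts)]
                out.loc[idx, f] = vals
    return out


def split_dataset(table: pd.DataFrame, fractions=(0.8, 0.1, 0.1),
                  seed: int = 0) -> SplitAssignment:
    """Stratified-by-class random assignment into train/validation/test."""
    fractions = tuple(float(x) for x in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions) \
            or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be 3 nonnegative values summing to 1")
    n_parts = sum(f > 0 for f in fractions)
    rng = np.random.default_rng(seed)
    assignment = pd.Series(index=table.index, dtype=object)
    for c, class_index in table.groupby("label", observed=True).groups.items():
        idx = np.asarray(class_index)
        if len(idx) < n_parts:
            raise ValueError(
                f"class {c!r} has {len(idx)} rows; cannot populate {n_parts} partitions")
        perm = rng.permutation(idx)
        n = len(perm)
        n_tr = int(round(fractions[0] * n))
        n_va = int(round(fractions[1] * n))
        # guarantee at least one row in every nonempty partition
        if fractions[1] > 0:
            n_va = max(n_va, 1)
        if fractions[2] > 0:
            n_tr = min(n_tr, n - n_va - 1)
        n_tr = max(n_tr, 1 if fractions[0] > 0 else 0)
        assignment.loc[perm[:n_tr]] = "train"
        assignment.loc[perm[n_tr:n_tr + n_va]] = "validation"
        assignment.loc[perm[n_tr + n_va:]] = "test"
    return SplitAssignment(assignment=assignment, fractions=fractions, seed=seed)


def standardize(table: pd.DataFrame,
                split: SplitAssignment) -> tuple[pd.DataFrame, ScalerStats]:
    """Z-score all 13 model features using train-partition statistics only.

    Categorical codes (1/2 and +1/-1) are standardized like any other
    column: centering them makes "value omitted" coincide with "value at
    the train mean", so feature occlusion measures a deviation from the
    population rather than an extrapolation to a nonexistent code 0.
    Original-unit values stay available in the cleaned table for
    display.
    """
    from .features import FEATURES
    out = table.copy()
    train = table.loc[split.mask("train")]
    stats = ScalerStats()
    for f in FEATURES:
        mu = float(train[f].mean())
        sd = float(train[f].std(ddof=0))
        if not sd > 0:
            raise ValueError(f"zero train-partition SD for feature {f!r}")
        stats.mean[f] = mu
        stats.sd[f] = sd
        out[f] = (out[f] - mu) / sd
    return out, stats


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """The N x 13 feature matrix X in canonical column order."""
    from .features import FEATURES
    return table[list(FEATURES)].to_numpy(dtype=float)


def label_codes(table: pd.DataFrame) -> np.ndarray:
    """Integer class labels (NC=0, MCI=1, AD=2)."""
    mapping = {c: i for i, c in enumerate(CLASSES)}
    return table["label"].map(mapping).to_numpy(dtype=int)
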