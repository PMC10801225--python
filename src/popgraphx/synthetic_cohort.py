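"""Synthetic multimodal cohort generator.

Emulates a multimodal dementia cohort: class-conditional truncated-normal
continuous features and Bernoulli categoricals, parameterized by the
published per-class means/SDs, category counts and sample sizes
(NC=754, MCI=1095, AD=363).  Downstream stages (cleaning, graph
construction, GCN training, explanation) are all exercisable on these
cohorts without access to the restricted real data.

Truncated sampling is moment-matched: the parent normal's location and
scale are solved so that the *truncated* distribution reproduces the
target mean and SD (plain truncation of N(mean, sd) would bias both
whenever a bound sits within a couple of SDs, e.g. MMSE near its
30-point ceiling).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .features import (
    BOUNDS,
    CATEGORY_CODES,
    CLASSES,
    CONTINUOUS_FEATURES,
    CSV_HEADER,
    FEATURES,
)

# Per-class (NC, MCI, AD) mean and SD for each continuous feature.
_CONTINUOUS_PARAMS: dict[str, tuple[tuple[float, float], ...]] = {
    "age": ((75.6, 6.7), (73.7, 7.5), (75.1, 7.9)),
    "mem": ((0.93, 0.41), (0.33, 0.50), (-0.84, 0.39)),
    "lan": ((0.88, 0.36), (0.56, 0.38), (-0.24, 0.47)),
    "exf": ((0.85, 0.41), (0.53, 0.42), (-0.41, 0.63)),
    "gds": ((7.1, 1.34), (8.3, 2.09), (9.2, 2.63)),
    "moca": ((26.3, 2.57), (23.2, 3.36), (14.8, 3.48)),
    "mmse": ((29.1, 1.07), (28.1, 1.76), (22.4, 3.32)),
    "mct": ((2.84, 0.10), (2.78, 0.15), (2.49, 0.19)),
    "thv": ((6.54, 0.56), (6.34, 0.70), (5.42, 0.72)),
    "phs": ((0.007, 0.49), (0.29, 0.65), (0.84, 0.64)),
}

# Published category counts per class: gender as (F, M); biomarkers as
# printed column pairs whose orientation is configurable (see below).
_GENDER_FM: tuple[tuple[int, int], ...] = ((399, 355), (458, 637), (160, 203))
_ABETA_PAIRS: tuple[tuple[int, int], ...] = ((441, 313), (493, 602), (31, 332))
_TAU_PAIRS: tuple[tuple[int, int], ...] = ((312, 442), (344, 751), (7, 356))

_DEFAULT_N: tuple[int, int, int] = (754, 1095, 363)


@dataclass
class CohortSpec:
    """Class-conditional generative parameters for a synthetic cohort.

    Attributes
    ----------
    n : dict
        Subject count per class.
    continuous : dict
        ``feature -> class -> (mean, sd)``.
    categorical : dict
        ``feature -> class -> probability of the *first* encoded
        category`` (gender: female; biomarkers: positive).
    bounds : dict
        ``feature -> (lo, hi)`` truncation bounds (None = unbounded).
    correlation : ndarray, optional
        Within-class correlation matrix over the continuous features
        (Gaussian copula); identity (independent features) by default.
    biomarker_counts_positive_first : bool
        Orientation of the published amyloid/tau count pairs.  The
        default ``False`` reads them as (negative, positive), which
        makes AD cases predominantly biomarker-positive — the clinically
        plausible reading.
    """

    n: dict[str, int] = field(default_factory=dict)
    continuous: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    categorical: dict[str, dict[str, float]] = field(default_factory=dict)
    bounds: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)
    correlation: np.ndarray | None = None
    biomarker_counts_positive_first: bool = False

    def validate(self) -> None:
        for c in CLASSES:
            if self.n.get(c, 0) < 1:
                raise ValueError(f"class {c} needs n >= 1")
        for f, per_class in self.continuous.items():
            for c, (mu, sd) in per_class.items():
                if not sd > 0:
                    raise ValueError(f"sd must be > 0 for {f}/{c}")
        for f, per_class in self.categorical.items():
            for c, p in per_class.items():
                if not 0.0 < p < 1.0:
                    raise ValueError(f"category probability for {f}/{c} not in (0,1)")
        if self.correlation is not None:
            k = len(CONTINUOUS_FEATURES)
            corr = np.asarray(self.correlation, dtype=float)
            if corr.shape != (k, k):
                raise ValueError(f"correlation must be {k}x{k}")
            if not np.allclose(corr, corr.T):
                raise ValueError("correlation must be symmetric")

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "n": self.n,
            "continuous": self.continuous,
            "categorical": self.categorical,
            "bounds": {f: list(b) for f, b in self.bounds.items()},
            "correlation": None if self.correlation is None
            else np.asarray(self.correlation).tolist(),
            "biomarker_counts_positive_first": self.biomarker_counts_positive_first,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        d = json.loads(text)
        return cls(
            n={c: int(v) for c, v in d["n"].items()},
            continuous={
                f: {c: tuple(v) for c, v in per.items()}
                for f, per in d["continuous"].items()
            },
            categorical=d["categorical"],
            bounds={f: tuple(None if x is None else float(x) for x in b)
                    for f, b in d["bounds"].items()},
            correlation=None if d.get("correlation") is None
            else np.asarray(d["correlation"], dtype=float),
            biomarker_counts_positive_first=bool(
                d.get("biomarker_counts_positive_first", False)
            ),
        )


def default_spec(*, biomarker_counts_positive_first: bool = False) -> CohortSpec:
    """The published cohort parameters: per-class means/SDs, category
    proportions, and sample sizes 754/1095/363."""
    continuous = {
        f: {c: _CONTINUOUS_PARAMS[f][i] for i, c in enumerate(CLASSES)}
        for f in _CONTINUOUS_PARAMS
    }
    categorical: dict[str, dict[str, float]] = {"gender": {}, "abeta": {}, "tau": {}}
    for i, c in enumerate(CLASSES):
        f_cnt, m_cnt = _GENDER_FM[i]
        categorical["gender"][c] = f_cnt / (f_cnt + m_cnt)
        for feat, pairs in (("abeta", _ABETA_PAIRS), ("tau", _TAU_PAIRS)):
            a, b = pairs[i]
            pos = a if biomarker_counts_positive_first else b
            categorical[feat][c] = pos / (a + b)
    spec = CohortSpec(
        n={c: _DEFAULT_N[i] for i, c in enumerate(CLASSES)},
        continuous=continuous,
        categorical=categorical,
        bounds={f: BOUNDS[f] for f in CONTINUOUS_FEATURES},
        biomarker_counts_positive_first=biomarker_counts_positive_first,
    )
    spec.validate()
    return spec


def _censored_moments(loc: float, scale: float, lo: float, hi: float):
    """Mean and SD of clip(N(loc, scale), lo, hi)."""
    a = (lo - loc) / scale if np.isfinite(lo) else -np.inf
    b = (hi - loc) / scale if np.isfinite(hi) else np.inf
    Fa, Fb = stats.norm.cdf(a), stats.norm.cdf(b)
    fa, fb = stats.norm.pdf(a), stats.norm.pdf(b)
    m = loc * (Fb - Fa) - scale * (fb - fa)
    m2 = (loc**2) * (Fb - Fa) + 2 * loc * scale * (fa - fb) \
        + scale**2 * ((Fb - Fa) + (a * fa if np.isfinite(a) else 0.0)
                      - (b * fb if np.isfinite(b) else 0.0))
    if np.isfinite(lo):
        m += lo * Fa
        m2 += lo**2 * Fa
    if np.isfinite(hi):
        m += hi * (1 - Fb)
        m2 += hi**2 * (1 - Fb)
    return m, np.sqrt(max(m2 - m * m, 0.0))


def _matched_sampler(mu: float, sd: float, lo: float | None, hi: float | None):
    """Parent (loc, scale, censored?) whose bounded version has mean mu, SD sd.

    Tries a moment-matched truncated normal first; when no truncated
    normal can reach the printed moments (a ceiling-hugging feature like
    MMSE in cognitively normal subjects), falls back to a moment-matched
    *censored* normal, whose probability mass at the instrument bound is
    exactly the ceiling pile-up such scores show.
    """
    lo_ = -np.inf if lo is None else float(lo)
    hi_ = np.inf if hi is None else float(hi)
    if not np.isfinite(lo_) and not np.isfinite(hi_):
        return mu, sd, False
    # If the bounds are > 4 SDs away the correction is negligible.
    if (mu - lo_) / sd > 4.0 and (hi_ - mu) / sd > 4.0:
        return mu, sd, False

    def trunc_residual(params):
        loc, log_scale = params
        scale = float(np.exp(log_scale))
        a, b = (lo_ - loc) / scale, (hi_ - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mu, np.sqrt(v) - sd]

    sol = optimize.root(trunc_residual, x0=[mu, np.log(sd)], method="hybr")
    if sol.success and max(np.abs(trunc_residual(sol.x))) < 1e-8:
        return sol.x[0], float(np.exp(sol.x[1])), False

    def cens_residual(params):
        loc, log_scale = params
        m, s = _censored_moments(loc, float(np.exp(log_scale)), lo_, hi_)
        return [m - mu, s - sd]

    sol = optimize.root(cens_residual, x0=[mu, np.log(sd)], method="hybr")
    if not sol.success or max(np.abs(cens_residual(sol.x))) > 1e-8:
        raise RuntimeError(f"moment matching failed for mu={mu}, sd={sd}, "
                           f"bounds=({lo_}, {hi_})")
    return sol.x[0], float(np.exp(sol.x[1])), True


def generate_cohort(spec: CohortSpec, seed: int,
                    n_override: dict[str, int] | None = None) -> pd.DataFrame:
    """Draw a labeled cohort table from a :class:`CohortSpec`.

    Continuous features come from moment-matched truncated normals,
    categoricals from per-class Bernoulli draws; optionally a Gaussian
    copula imposes within-class correlation on the continuous block.
    Deterministic for a given (spec, seed).
    """
    spec.validate()
    n_per_class = dict(spec.n)
    if n_override is not None:
        n_per_class.update(n_override)
    rng = np.random.default_rng(seed)

    frames = []
    offset = 0
    for c in CLASSES:
        n_c = int(n_per_class[c])
        cols: dict[str, np.ndarray] = {}
        if spec.correlation is not None:
            z = rng.multivariate_normal(
                np.zeros(len(CONTINUOUS_FEATURES)), spec.correlation, size=n_c,
                method="cholesky")
            u_block = stats.norm.cdf(z)
        else:
            u_block = rng.random((n_c, len(CONTINUOUS_FEATURES)))
        cont_idx = {f: j for j, f in enumerate(CONTINUOUS_FEATURES)}
        for f in FEATURES:
            if f in spec.continuous:
                mu, sd = spec.continuous[f][c]
                lo, hi = spec.bounds.get(f, (None, None))
                loc, scale, censored = _matched_sampler(mu, sd, lo, hi)
                u = u_block[:, cont_idx[f]]
                if censored:
                    lo_ = -np.inf if lo is None else lo
                    hi_ = np.inf if hi is None else hi
                    cols[f] = np.clip(stats.norm.ppf(u, loc=loc, scale=scale),
                                      lo_, hi_)
                else:
                    lo_ = -np.inf if lo is None else lo
                    hi_ = np.inf if hi is None else hi
                    a, b = (lo_ - loc) / scale, (hi_ - loc) / scale
                    cols[f] = stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)
            else:
                p_first = spec.categorical[f][c]
                first, second = CATEGORY_CODES[f]
                cols[f] = np.where(rng.random(n_c) < p_first, first, second)
        df = pd.DataFrame(cols)
        df.insert(0, "label", c)
        df.insert(0, "id", np.arange(offset, offset + n_c))
        offset += n_c
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    return table[list(CSV_HEADER)]


def inject_artifacts(table: pd.DataFrame, missing_rate: float,
                     outlier_rate: float, seed: int) -> pd.DataFrame:
    """Corrupt a cohort with missing cells and class-wise outliers.

    Randomly chosen continuous cells are set to NaN (missing) or
    displaced outside the class-wise [5th, 95th] percentile interval
    (outliers), reproducibly from ``seed``.  Rates are fractions of the
    continuous cells, each in [0, 0.5].
    """
    for name, rate in (("missing_rate", missing_rate), ("outlier_rate", outlier_rate)):
        if not 0.0 <= rate <= 0.5:
            raise ValueError(f"{name} must be in [0, 0.5], got {rate}")
    out = table.copy()
    rng = np.random.default_rng(seed)
    n_rows = len(out)
    cells = [(i, f) for f in CONTINUOUS_FEATURES for i in range(n_rows)]
    n_cells = len(cells)
    n_missing = int(round(missing_rate * n_cells))
    n_outlier = int(round(outlier_rate * n_cells))
    picked = rng.choice(n_cells, size=n_missing + n_outlier, replace=False)

    # Class-wise percentile bands of the clean columns, for displacement.
    bands: dict[tuple[str, str], tuple[float, float]] = {}
    for f in CONTINUOUS_FEATURES:
        for c, grp in out.groupby("label", observed=True)[f]:
            v = grp.to_numpy(dtype=float)
            bands[(f, c)] = (np.nanpercentile(v, 5), np.nanpercentile(v, 95))

    for k, flat in enumerate(picked):
        i, f = cells[flat]
        if k < n_missing:
            out.loc[out.index[i], f] = np.nan
        else:
            c = out.iloc[i]["label"]
            p5, p95 = bands[(f, c)]
            span = max(p95 - p5, 1e-9)
            shift = span * rng.uniform(0.25, 1.0)
            if rng.random() < 0.5:
                out.loc[out.index[i], f] = p95 + shift
            else:
                out.loc[out.index[i], f] = p5 - shift
    return out


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(CSV_HEADER) - set(table.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return table[list(CSV_HEADER)]
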