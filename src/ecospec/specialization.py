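"""Gini-based specialization indices per species and trait bundle.

The degree of specialization of a species within one bundle of binary
traits is the Gini inequality coefficient of its trait vector,

    G = sum_i sum_j |x_i - x_j| / (2 n^2 x̄),

which is 0 when every trait has the same value (perfect evenness, a
generalist) and approaches 1 when a single trait carries all the weight
(a specialist).  For a binary vector the uncorrected maximum is
(n-1)/n, so the bias-corrected variant G * n/(n-1) — which attains
exactly 1 for a one-hot vector — is the default, matching the convention
of the DescTools Gini routine.

An *overall* specialization index aggregates the per-bundle indices per
species (mean by default; max or min optionally) and min–max standardizes
the aggregate across species to [0, 1].
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .traits_io import TraitTable, TraitTableError

__all__ = [
    "gini",
    "bundle_indices",
    "overall_index",
    "classify",
    "index_correlations",
    "IndexCorrelationMatrix",
]


def gini(x, corrected: bool = True) -> float:
    """Gini coefficient of a non-negative vector.

    Parameters
    ----------
    x : array-like of non-negative numbers, length >= 2, positive mean.
    corrected : multiply by n/(n-1) so the maximum (one positive entry,
        rest zero) is exactly 1.  Default True.

    Uses the sorted-rank form  G = sum_i (2i - n - 1) x_(i) / (n^2 x̄),
    algebraically equal to the pairwise double sum over |x_i - x_j|.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be one-dimensional")
    n = x.size
    if n < 2:
        raise ValueError(f"need at least 2 values, got {n}")
    if np.any(x < 0):
        raise ValueError("negative values are not allowed")
    total = x.sum()
    if total <= 0:
        raise ValueError("mean of x is zero: Gini undefined")
    xs = np.sort(x)
    ranks = 2.0 * np.arange(1, n + 1) - n - 1.0
    g = float(ranks @ xs) / (n * total)
    if corrected:
        g *= n / (n - 1)
    return g


def bundle_indices(table: TraitTable, corrected: bool = True) -> pd.DataFrame:
    """Per-species Gini index for every bundle of a trait table.

    Returns a DataFrame indexed by species id with one column per bundle,
    each value the Gini coefficient of that species' trait row within the
    bundle.  All-zero rows raise with species/bundle context.
    """
    out = {}
    for bundle in table.bundle_names:
        sub = table.bundle_matrix(bundle).to_numpy(dtype=float)
        n = sub.shape[1]
        totals = sub.sum(axis=1)
        if np.any(totals == 0):
            bad = table.values.index[totals == 0][0]
            raise TraitTableError(
                f"species {bad!r}, bundle {bundle!r}: all-zero trait row, Gini undefined"
            )
        # vectorized sorted-rank Gini, one row at a time across the bundle
        xs = np.sort(sub, axis=1)
        ranks = 2.0 * np.arange(1, n + 1) - n - 1.0
        g = (xs @ ranks) / (n * totals)
        if corrected:
            g *= n / (n - 1)
        out[bundle] = g
    return pd.DataFrame(out, index=table.values.index)


def overall_index(
    profiles: pd.DataFrame,
    bundles: list[str] | None = None,
    aggregator: str = "mean",
) -> pd.Series:
    """Aggregate per-bundle indices and standardize across species to [0,1].

    ``aggregator`` is one of ``mean``, ``max``, ``min``, applied per species
    over the chosen ``bundles`` (default: all columns of ``profiles``).  The
    aggregate is then min–max standardized over species, so the least
    specialized species scores 0 and the most specialized scores 1.
    """
    if aggregator not in ("mean", "max", "min"):
        raise ValueError(f"aggregator must be mean, max or min, got {aggregator!r}")
    cols = list(profiles.columns) if bundles is None else list(bundles)
    missing = [b for b in cols if b not in profiles.columns]
    if missing:
        raise KeyError(f"unknown bundle(s) {missing}")
    agg = getattr(profiles[cols], aggregator)(axis=1)
    lo, hi = float(agg.min()), float(agg.max())
    if math.isclose(lo, hi, rel_tol=0.0, abs_tol=0.0) or lo == hi:
        raise ValueError("all species aggregates identical: standardization degenerate")
    return ((agg - lo) / (hi - lo)).rename(f"overall_{aggregator}")


def classify(
    profiles: pd.DataFrame, bundle: str, threshold: float
) -> tuple[pd.Series, dict[str, int]]:
    """Label species specialist/generalist on one bundle's index.

    A species is a *specialist* iff its index is >= ``threshold``.  Returns
    the per-species labels and the counts of each label.
    """
    if not 0.0 < threshold < 1.0 + 1e-12:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    if bundle not in profiles.columns:
        raise KeyError(f"unknown bundle {bundle!r}")
    labels = pd.Series(
        np.where(profiles[bundle] >= threshold, "specialist", "generalist"),
        index=profiles.index,
        name=f"{bundle}_class",
    )
    counts = labels.value_counts().to_dict()
    counts.setdefault("specialist", 0)
    counts.setdefault("generalist", 0)
    return labels, counts


@dataclass
class IndexCorrelationMatrix:
    """Spearman correlations among specialization indices.

    ``rho`` and ``p`` are symmetric DataFrames over the bundle names;
    ``normality_p`` holds the Shapiro–Wilk p-value per index (the paper-style
    motivation for using a rank correlation in the first place).
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    normality_p: pd.Series


def _spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with a two-sided p-value.

    t-approximation for n > 10; exact enumeration of all rank permutations
    for n <= 10 (feasible: at most 10! statistics, evaluated in chunks).
    """
    n = x.size
    if n > 10:
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = math.sqrt(float(rx_c @ rx_c) * float(ry_c @ ry_c))
    if denom == 0:
        return math.nan, math.nan
    obs = float(rx_c @ ry_c) / denom
    count = 0
    total = 0
    chunk: list[tuple] = []

    def flush(chunk):
        perms = np.array(chunk)
        rhos = (ry_c[perms] @ rx_c) / denom
        return int(np.count_nonzero(np.abs(rhos) >= abs(obs) - 1e-12))

    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        total += 1
        if len(chunk) == 200_000:
            count += flush(chunk)
            chunk = []
    if chunk:
        count += flush(chunk)
    return obs, count / total


def index_correlations(profiles: pd.DataFrame) -> IndexCorrelationMatrix:
    """Pairwise Spearman correlations among all bundle indices.

    Requires at least 4 species.  A constant index yields undefined
    correlations for its pairs: they are reported as NaN with a warning,
    and its Shapiro–Wilk p is NaN.
    """
    if len(profiles.index) < 4:
        raise ValueError("need at least 4 species for correlations")
    names = list(profiles.columns)
    k = len(names)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    norm_p = {}
    for name in names:
        v = profiles[name].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            warnings.warn(f"index {name!r} is constant: correlations undefined")
            norm_p[name] = math.nan
        else:
            norm_p[name] = float(stats.shapiro(v).pvalue)
    for i in range(k):
        for j in range(i + 1, k):
            xi = profiles[names[i]].to_numpy(dtype=float)
            xj = profiles[names[j]].to_numpy(dtype=float)
            if np.ptp(xi) == 0 or np.ptp(xj) == 0:
                r, p = math.nan, math.nan
            else:
                r, p = _spearman(xi, xj)
            rho[i, j] = rho[j, i] = r
            pmat[i, j] = pmat[j, i] = p
    return IndexCorrelationMatrix(
        rho=pd.DataFrame(rho, index=names, columns=names),
        p=pd.DataFrame(pmat, index=names, columns=names),
        normality_p=pd.Series(norm_p, name="shapiro_p"),
    )
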