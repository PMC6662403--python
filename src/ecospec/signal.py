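"""Phylogenetic signal statistics: Blomberg's K and K*, Moran's I correlograms.

Blomberg's K compares the variance of a tip trait about its (phylogenetic)
mean with the generalized-least-squares error given the phylogenetic
covariance matrix C, scaled by the ratio expected under Brownian motion:

    MSE0 = (x - â)'(x - â) / (n - 1)          (K; â = GLS phylogenetic mean)
    MSE0* = (x - x̄)'(x - x̄) / (n - 1)         (K*; x̄ = arithmetic mean)
    MSE  = (x - â)' C⁻¹ (x - â) / (n - 1)
    E[MSE0/MSE] = (tr C - n / (1'C⁻¹1)) / (n - 1)
    K    = (MSE0 / MSE) / E[MSE0/MSE]          (K* analogously with MSE0*)

K ≈ 1 is consistent with Brownian-motion evolution on the tree; K ≈ 0 means
no phylogenetic signal.  Significance comes from permuting trait values
across tips: signal shows up as a smaller GLS error than random tip
assignment, so the one-tailed p counts permutations with MSE ≤ observed.

Moran's I is computed per patristic-distance class to form a phylogenetic
correlogram; positive I in the shortest-distance class means close relatives
have similar trait values (the correlogram analog of high K).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .phylo import DistanceMatrix, VCVMatrix

__all__ = [
    "SignalResult",
    "Correlogram",
    "align_trait",
    "blomberg_k",
    "k_permutation_test",
    "morans_i",
    "phylo_correlogram",
]


@dataclass
class SignalResult:
    """Point estimates (and optionally permutation p-values) for K and K*."""

    K: float
    K_star: float
    mse0: float
    mse0_star: float
    mse: float
    expected_ratio: float
    n: int
    p_K: float | None = None
    p_K_star: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "K_star": self.K_star,
            "p_K": self.p_K,
            "p_K_star": self.p_K_star,
            "n": self.n,
            "n_permutations": self.n_permutations,
            "MSE0": self.mse0,
            "MSE0_star": self.mse0_star,
            "MSE": self.mse,
            "expected_ratio": self.expected_ratio,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }


@dataclass
class Correlogram:
    """Moran's I per patristic-distance class with bootstrap 95% CIs."""

    class_midpoints: np.ndarray
    class_edges: np.ndarray
    I: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    significance: list[str]
    expected_i: float
    n_bootstrap: int
    seed: int | None = None
    warnings_: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_mid": self.class_midpoints,
                "I": self.I,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "significance": self.significance,
            }
        )


def align_trait(values: pd.Series, tip_labels: list[str]) -> np.ndarray:
    """Reorder a species-indexed trait series to a tree's tip order."""
    missing = [t for t in tip_labels if t not in values.index]
    if missing:
        raise KeyError(f"trait values missing for tips: {missing}")
    x = values.reindex(tip_labels).to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trait vector contains non-finite values")
    return x


def _gls_pieces(C: np.ndarray):
    cf = cho_factor(C)
    one = np.ones(C.shape[0])
    Cinv_one = cho_solve(cf, one)
    denom = float(one @ Cinv_one)  # 1'C⁻¹1
    return cf, Cinv_one, denom


def blomberg_k(
    x: np.ndarray, vcv: VCVMatrix | np.ndarray, tip_labels: list[str] | None = None
) -> SignalResult:
    """Blomberg's K and K* for one trait vector on one tree.

    ``x`` must be ordered like the VCV's tips (use :func:`align_trait`).  A
    constant trait has no variance to partition: K = K* = 0 is returned
    with ``degenerate=True``.
    """
    C = vcv.C if isinstance(vcv, VCVMatrix) else np.asarray(vcv, dtype=float)
    x = np.asarray(x, dtype=float)
    n = x.size
    if C.shape != (n, n):
        raise ValueError(f"C is {C.shape}, trait vector has length {n}")
    if n < 4:
        raise ValueError("need at least 4 tips")
    try:
        cf, Cinv_one, denom = _gls_pieces(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "phylogenetic covariance matrix is singular (identical tips or "
            "zero-length branches); resolve the tree rather than jittering"
        ) from exc
    expected_ratio = (float(np.trace(C)) - n / denom) / (n - 1)
    a_hat = float(Cinv_one @ x) / denom
    resid = x - a_hat
    mse0 = float(resid @ resid) / (n - 1)
    centred = x - x.mean()
    mse0_star = float(centred @ centred) / (n - 1)
    mse = float(resid @ cho_solve(cf, resid)) / (n - 1)
    if mse0_star == 0.0:  # constant trait
        return SignalResult(
            K=0.0, K_star=0.0, mse0=0.0, mse0_star=0.0, mse=0.0,
            expected_ratio=expected_ratio, n=n, degenerate=True,
        )
    K = (mse0 / mse) / expected_ratio
    K_star = (mse0_star / mse) / expected_ratio
    return SignalResult(
        K=K, K_star=K_star, mse0=mse0, mse0_star=mse0_star, mse=mse,
        expected_ratio=expected_ratio, n=n,
    )


def k_permutation_test(
    x: np.ndarray,
    vcv: VCVMatrix | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> SignalResult:
    """Permutation test of phylogenetic signal for K and K*.

    Trait values are shuffled across tips; the test statistic is the GLS
    mean-squared error, and the one-tailed add-one p-value is
    (1 + #{permutations with MSE <= observed}) / (n_perm + 1).  Because the
    total trait variance is unchanged by permutation, this is equivalent to
    the upper tail of the permuted K* distribution; the same p is reported
    for K.  Deterministic given ``seed``.
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    C = vcv.C if isinstance(vcv, VCVMatrix) else np.asarray(vcv, dtype=float)
    x = np.asarray(x, dtype=float)
    res = blomberg_k(x, C)
    res.n_permutations = n_perm
    res.seed = seed
    if res.degenerate:
        warnings.warn("constant trait vector: permutation test degenerate, p = 1")
        res.p_K = res.p_K_star = 1.0
        return res
    cf, Cinv_one, denom = _gls_pieces(C)
    n = x.size
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(x) for _ in range(n_perm)])  # (n_perm, n)
    # batched GLS MSE: (x-â1)'C⁻¹(x-â1) = x'C⁻¹x - (1'C⁻¹x)² / (1'C⁻¹1)
    CinvX = cho_solve(cf, perms.T).T
    quad = np.einsum("ij,ij->i", CinvX, perms)
    s = perms @ Cinv_one
    mse_perm = (quad - s**2 / denom) / (n - 1)
    p = (1 + int(np.count_nonzero(mse_perm <= res.mse * (1 + 1e-12)))) / (n_perm + 1)
    res.p_K = res.p_K_star = p
    return res


def morans_i(x: np.ndarray, W: np.ndarray) -> float:
    """Moran's I autocorrelation of ``x`` under weight matrix ``W``.

    I = (n / S0) * [ΣΣ w_ij (x_i-x̄)(x_j-x̄)] / Σ(x_i-x̄)² with S0 = ΣΣ w_ij.
    ``W`` must be non-negative with a zero diagonal and at least one
    positive weight; ``x`` must be non-constant.
    """
    x = np.asarray(x, dtype=float)
    W = np.asarray(W, dtype=float)
    n = x.size
    if W.shape != (n, n):
        raise ValueError(f"W is {W.shape}, x has length {n}")
    if np.any(W < 0):
        raise ValueError("weights must be non-negative")
    if np.any(np.diag(W) != 0):
        raise ValueError("W must have a zero diagonal")
    s0 = W.sum()
    if s0 == 0:
        raise ValueError("all weights are zero")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("x is constant: Moran's I undefined")
    return float(n / s0 * (z @ W @ z) / denom)


def _bin_weights(D: np.ndarray, edges: np.ndarray, k: int) -> np.ndarray:
    """0/1 weight matrix for distance class k; last class closed above."""
    lo, hi = edges[k], edges[k + 1]
    if k == len(edges) - 2:
        W = (D >= lo) & (D <= hi)
    else:
        W = (D >= lo) & (D < hi)
    W = W.astype(float)
    np.fill_diagonal(W, 0.0)
    return W


def phylo_correlogram(
    x: np.ndarray,
    dist: DistanceMatrix | np.ndarray,
    n_classes: int = 10,
    n_boot: int = 100,
    seed: int | None = None,
) -> Correlogram:
    """Moran's I phylogenetic correlogram with bootstrap confidence bands.

    The patristic-distance range is split into ``n_classes`` equal-width
    bins; within each bin the binary weight matrix links exactly the tip
    pairs whose distance falls in the bin.  95% CIs come from ``n_boot``
    bootstrap resamples of tips (the same resampled indices applied to both
    the trait vector and the distance matrix; duplicated tips produce
    zero-distance pairs, which are dropped from the weights along with the
    diagonal).  A class is significantly positive if its lower CI bound
    exceeds the permutation-null expectation E[I] = -1/(n-1), negative if
    the upper bound is below it.
    """
    D = dist.D if isinstance(dist, DistanceMatrix) else np.asarray(dist, dtype=float)
    x = np.asarray(x, dtype=float)
    n = x.size
    if D.shape != (n, n):
        raise ValueError(f"D is {D.shape}, x has length {n}")
    if n_classes < 2:
        raise ValueError("need at least 2 distance classes")
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    off = D[~np.eye(n, dtype=bool)]
    edges = np.linspace(off.min(), off.max(), n_classes + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    expected = -1.0 / (n - 1)
    notes: list[str] = []

    def all_classes(xv: np.ndarray, Dv: np.ndarray) -> np.ndarray:
        out = np.full(n_classes, np.nan)
        for k in range(n_classes):
            W = _bin_weights(Dv, edges, k)
            # drop zero-distance duplicate pairs created by resampling
            W[Dv == 0] = 0.0
            if W.sum() == 0 or np.ptp(xv) == 0:
                continue
            out[k] = morans_i(xv, W)
        return out

    obs = all_classes(x, D)
    for k in range(n_classes):
        if np.isnan(obs[k]):
            notes.append(f"distance class {k}: empty, Moran's I undefined")
            warnings.warn(notes[-1])

    rng = np.random.default_rng(seed)
    boot = np.full((n_boot, n_classes), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boot[b] = all_classes(x[idx], D[np.ix_(idx, idx)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN classes
        ci_low = np.nanpercentile(boot, 2.5, axis=0)
        ci_high = np.nanpercentile(boot, 97.5, axis=0)
    sig = []
    for k in range(n_classes):
        if np.isnan(ci_low[k]) or np.isnan(ci_high[k]) or np.isnan(obs[k]):
            sig.append("none")
        elif ci_low[k] > expected:
            sig.append("positive")
        elif ci_high[k] < expected:
            sig.append("negative")
        else:
            sig.append("none")
    return Correlogram(
        class_midpoints=mids,
        class_edges=edges,
        I=obs,
        ci_low=ci_low,
        ci_high=ci_high,
        significance=sig,
        expected_i=expected,
        n_bootstrap=n_boot,
        seed=seed,
        warnings_=notes,
    )
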