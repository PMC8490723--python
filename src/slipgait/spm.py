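"""One-dimensional statistics over stance (statistical parametric mapping).

Node-wise t statistics over the 101 stance nodes with family-wise error
controlled nonparametrically: the critical threshold is the (1 - alpha)
quantile of the permutation distribution of the maximum |t| across nodes
(sign-flip permutations for paired contrasts, group-label permutations for
two-sample contrasts; exhaustive enumeration when feasible).  Supra-
threshold clusters are reported as % stance intervals, and per-participant
region-of-interest (ROI) averages over a cluster feed the correlation
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .signal_prep import N_NODES

__all__ = [
    "SPMResult",
    "spm_t_curve",
    "permutation_threshold",
    "find_clusters",
    "roi_average",
    "spm_contrast",
]

_ZERO_VAR_SENTINEL = 1e12


@dataclass
class SPMResult:
    stat_curve: np.ndarray
    threshold: float
    alpha: float
    clusters: list[tuple[int, int]]
    n_permutations: int
    seed: int | None = None
    channel: str = ""
    contrast: str = ""
    zero_variance_nodes: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=int)
    )


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """Node-wise one-sample t on paired differences (n x nodes)."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / se
    t = np.where(se == 0, np.sign(mean) * _ZERO_VAR_SENTINEL, t)
    return np.where((se == 0) & (mean == 0), 0.0, t)


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    se = sp * np.sqrt(1.0 / na + 1.0 / nb)
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t = np.where(se == 0, np.sign(diff) * _ZERO_VAR_SENTINEL, t)
    return np.where((se == 0) & (diff == 0), 0.0, t)


def spm_t_curve(
    curves_a: np.ndarray, curves_b: np.ndarray, paired: bool
) -> np.ndarray:
    """Node-wise paired or two-sample t statistic at each of the 101 nodes.

    Zero-variance nodes receive a large signed sentinel value so they always
    exceed any permutation threshold (and are flagged by ``spm_contrast``).
    """
    a = np.atleast_2d(np.asarray(curves_a, dtype=float))
    b = np.atleast_2d(np.asarray(curves_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("curve sets must share the node dimension")
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired contrast requires matched shapes")
        if a.shape[0] < 3:
            raise ValueError("need at least 3 pairs")
        return _paired_t(a - b)
    if a.shape[0] < 3 or b.shape[0] < 3:
        raise ValueError("need at least 3 curves per group")
    return _two_sample_t(a, b)


def permutation_threshold(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    paired: bool,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> float:
    """(1 - alpha) quantile of the permutation distribution of max |t|.

    Paired designs use sign-flip permutations of the within-pair
    differences; independent designs permute group labels.  When the total
    number of distinct permutations does not exceed ``n_perm`` they are
    enumerated exhaustively (reproducible without a seed).
    """
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    a = np.atleast_2d(np.asarray(curves_a, dtype=float))
    b = np.atleast_2d(np.asarray(curves_b, dtype=float))
    if paired:
        d = a - b
        n = d.shape[0]
        if 2**n <= n_perm:
            signs = np.array(
                [[1 if (m >> i) & 1 else -1 for i in range(n)]
                 for m in range(2**n)],
                dtype=float,
            )
        else:
            signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
            signs[0] = 1.0  # include the observed labelling
        # sign flips leave d**2 unchanged, so the whole permutation set
        # vectorises: only the node means depend on the signs
        sumsq = np.sum(d * d, axis=0)
        means = signs @ d / n
        var = (sumsq - n * means**2) / (n - 1)
        var = np.clip(var, 0.0, None)
        se = np.sqrt(var / n)
        with np.errstate(divide="ignore", invalid="ignore"):
            tmat = np.abs(means) / se
        tmat = np.where(se == 0, np.where(means == 0, 0.0, _ZERO_VAR_SENTINEL),
                        tmat)
        maxima = tmat.max(axis=1)
    else:
        pooled = np.vstack([a, b])
        na, ntot = a.shape[0], a.shape[0] + b.shape[0]
        from math import comb

        if comb(ntot, na) <= n_perm:
            idx_sets = list(combinations(range(ntot), na))
        else:
            idx_sets = [tuple(rng.permutation(ntot)[:na]) for _ in range(n_perm)]
            idx_sets[0] = tuple(range(na))
        maxima = np.empty(len(idx_sets))
        for i, ia in enumerate(idx_sets):
            mask = np.zeros(ntot, dtype=bool)
            mask[list(ia)] = True
            maxima[i] = np.max(np.abs(_two_sample_t(pooled[mask], pooled[~mask])))
    if alpha == 1.0:
        return float(np.min(maxima))
    return float(np.quantile(maxima, 1.0 - alpha))


def find_clusters(stat_curve: np.ndarray, threshold: float) -> list[tuple[int, int]]:
    """Maximal runs of consecutive nodes with |stat| > threshold, as
    (start %, end %) of the first and last node of each run."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = np.abs(np.asarray(stat_curve, dtype=float)) > threshold
    clusters = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            clusters.append((start, i - 1))
            start = None
    if start is not None:
        clusters.append((start, len(above) - 1))
    return clusters


def roi_average(curve: np.ndarray, cluster: tuple[int, int]) -> float:
    """Arithmetic mean of a 101-node curve over cluster nodes, inclusive."""
    start, end = cluster
    if not (0 <= start <= end <= N_NODES - 1):
        raise ValueError("cluster must lie within 0..100 with start <= end")
    curve = np.asarray(curve, dtype=float)
    return float(np.mean(curve[start : end + 1]))


def spm_contrast(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    paired: bool,
    alpha: float,
    n_perm: int = 1000,
    seed: int | None = None,
    channel: str = "",
    contrast: str = "",
) -> SPMResult:
    """Full 1D contrast: t curve, permutation threshold and clusters."""
    t = spm_t_curve(curves_a, curves_b, paired)
    thr = permutation_threshold(curves_a, curves_b, paired, alpha, n_perm, seed)
    # a non-positive threshold can only arise from a fully degenerate
    # contrast (identical curve sets); nothing can be declared significant
    clusters = find_clusters(t, thr) if thr > 0 else []
    return SPMResult(
        stat_curve=t,
        threshold=thr,
        alpha=alpha,
        clusters=clusters,
        n_permutations=n_perm,
        seed=seed,
        channel=channel,
        contrast=contrast,
        zero_variance_nodes=np.flatnonzero(np.abs(t) >= _ZERO_VAR_SENTINEL),
    )
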