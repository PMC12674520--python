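"""Cross-group comparisons: overlap regions, profile similarity, PCA,
and a bootstrap null for the overlap counts.

Overlap regions are the exclusive Venn/Euler cells of the per-group
detection calls. The bootstrap null resamples each group's detection
indicator as an independent Bernoulli draw at the group's observed
detection rate, preserving per-group totals in expectation while
destroying cross-group association — so a significantly larger observed
intersection indicates biological similarity rather than chance.
"""

from __future__ import annotations

from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA

from .containers import (
    BootstrapResult,
    CtMatrix,
    DetectionMatrix,
    OverlapResult,
    SimilarityScore,
)
from .diffexp import bh_adjust

__all__ = ["overlap_regions", "profile_similarity", "pca", "bootstrap_overlap"]


def _nonempty_subsets(groups: Sequence[str]):
    for k in range(1, len(groups) + 1):
        yield from combinations(groups, k)


def overlap_regions(
    detection: DetectionMatrix, groups: Sequence[str] | None = None
) -> OverlapResult:
    """Exclusive region counts for every nonempty subset of ``groups``.

    Region S counts the miRNAs detected in exactly the groups of S; the
    counts partition the union (miRNAs detected in >= 1 chosen group).
    """
    groups = list(groups) if groups is not None else list(detection.groups)
    unknown = [g for g in groups if g not in detection.groups]
    if unknown:
        raise ValueError(f"unknown group(s): {unknown}")
    if len(groups) < 2:
        raise ValueError("overlap needs at least two groups")
    det = detection.detected[groups].to_numpy(bool)
    counts: dict[tuple[str, ...], int] = {
        tuple(sorted(s)): 0 for s in _nonempty_subsets(groups)
    }
    # encode each miRNA's membership pattern as a bitmask
    weights = 1 << np.arange(len(groups))
    codes = det @ weights
    binc = np.bincount(codes, minlength=1 << len(groups))
    for code in range(1, 1 << len(groups)):
        if binc[code]:
            s = tuple(sorted(g for i, g in enumerate(groups) if code >> i & 1))
            counts[s] = int(binc[code])
    universe = int((codes > 0).sum())
    return OverlapResult(counts, universe, groups=tuple(groups))


def profile_similarity(
    values_a: pd.Series, values_b: pd.Series, min_common: int = 3
) -> SimilarityScore:
    """Pearson r and MSE between two per-miRNA expression profiles.

    Computed over the miRNAs with a value in both profiles (the
    common-detected set). A constant profile leaves r undefined (NaN);
    the MSE is still reported.
    """
    a, b = values_a.align(values_b, join="inner")
    mask = a.notna() & b.notna()
    a, b = a[mask].to_numpy(float), b[mask].to_numpy(float)
    n = len(a)
    if n < min_common:
        raise ValueError(f"only {n} common miRNAs (< {min_common})")
    mse = float(np.mean((a - b) ** 2))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(a, b).statistic)
    return SimilarityScore(pearson_r=r, mse=mse, n_common=n)


def pca(matrix: CtMatrix, n_components: int | None = None):
    """Principal components of the complete-row submatrix.

    Samples are observations and miRNAs variables; variables are
    mean-centred, not scaled. Returns per-sample scores (DataFrame) and
    the variance-explained fractions (non-increasing, summing to <= 1).
    A matrix of identical samples yields zero scores and zero shares.
    """
    values = matrix.values
    complete = values.notna().all(axis=1)
    X = values.loc[complete].to_numpy(float).T  # samples x miRNAs
    n_samples = X.shape[0]
    if n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    k = min(n_samples, X.shape[1]) if n_components is None else n_components
    centered = X - X.mean(axis=0)
    if np.allclose(centered, 0):
        scores = np.zeros((n_samples, k))
        ratios = np.zeros(k)
    else:
        model = _SkPCA(n_components=k, svd_solver="full")
        scores = model.fit_transform(X)
        ratios = model.explained_variance_ratio_
        k = scores.shape[1]
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=values.columns, columns=cols),
        np.asarray(ratios, dtype=float),
    )


def bootstrap_overlap(
    detection: DetectionMatrix,
    n_iter: int = 1000,
    seed: int = 0,
    groups: Sequence[str] | None = None,
    universe: str = "detected",
    n_assays: int | None = None,
) -> BootstrapResult:
    """Bootstrap null for the overlap region counts.

    Each iteration redraws, for every miRNA of the universe and every
    group g, an independent Bernoulli(p_g) presence indicator, where
    ``p_g`` is group g's observed detection count divided by the universe
    size M. ``universe="detected"`` (default) takes M = miRNAs detected
    in >= 1 compared group; ``universe="assayed"`` uses ``n_assays``
    (e.g., the full panel size). Two-sided empirical p-values use the
    add-one rule on absolute deviation from the null median, with a BH
    pass across regions.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    groups = list(groups) if groups is not None else list(detection.groups)
    observed = overlap_regions(detection, groups)
    if universe == "detected":
        M = observed.universe_size
    elif universe == "assayed":
        M = int(n_assays) if n_assays is not None else len(detection.mirna_ids)
    else:
        raise ValueError(f"unknown universe {universe!r}")
    G = len(groups)
    p_g = np.array([detection.n_detected(g) / M for g in groups])
    rng = np.random.default_rng(seed)
    weights = 1 << np.arange(G)
    regions = [tuple(sorted(s)) for s in _nonempty_subsets(groups)]
    region_code = {
        s: sum(w for g, w in zip(groups, weights) if g in s) for s in regions
    }
    null = {s: np.empty(n_iter, dtype=np.int64) for s in regions}
    # miRNA-major draw order, one generator per call: platform-stable
    for it in range(n_iter):
        draws = rng.random((M, G)) < p_g
        codes = draws @ weights
        binc = np.bincount(codes, minlength=1 << G)
        for s in regions:
            null[s][it] = binc[region_code[s]]
    medians = {s: float(np.median(null[s])) for s in regions}
    emp_p = {}
    for s in regions:
        obs_dev = abs(observed.region_counts.get(s, 0) - medians[s])
        n_extreme = int((np.abs(null[s] - medians[s]) >= obs_dev).sum())
        emp_p[s] = (1 + n_extreme) / (n_iter + 1)
    adj = bh_adjust(np.array([emp_p[s] for s in regions]))
    return BootstrapResult(
        n_iter=n_iter,
        seed=seed,
        observed={s: observed.region_counts.get(s, 0) for s in regions},
        null_counts=null,
        null_median=medians,
        empirical_p=emp_p,
        p_adjusted={s: float(a) for s, a in zip(regions, adj)},
        universe_size=M,
    )
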