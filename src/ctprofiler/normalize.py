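"""Quantile normalization of Ct matrices and relative-expression measures.

Quantile normalization forces all samples to share one value
distribution, computed on the rows measured in every sample; rows with
missing cells keep their raw values and are flagged in the provenance.
Relative expression is ``35 − mean Ct`` (a linear proxy for
log-abundance on the plate's dynamic range), and the ΔΔCt method yields
fold changes normalized by a per-sample geometric-mean Ct.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CtMatrix, DetectionMatrix, GroupDesign, NormalizedMatrix

__all__ = ["quantile_normalize", "relative_expression", "ddct"]

#: Upper edge of the quantifiable Ct window; expression = CT_MAX − Ct.
CT_MAX = 35.0


def quantile_normalize(matrix: CtMatrix) -> NormalizedMatrix:
    """Rank-based quantile normalization over the complete-row submatrix.

    For each sample, the k-th smallest value is replaced by the mean of
    the k-th smallest values across samples; tied values receive the mean
    of the reference values they span (average-rank convention). Rows
    with any missing cell do not participate and keep their raw values.

    Raises
    ------
    ValueError
        If no row is complete across all samples.
    """
    values = matrix.values
    complete = values.notna().all(axis=1)
    n_complete = int(complete.sum())
    if n_complete == 0:
        raise ValueError("quantile normalization needs >= 1 complete row")
    sub = values.loc[complete]
    arr = sub.to_numpy(dtype=float)
    # Reference distribution: mean of per-sample order statistics.
    ref = np.sort(arr, axis=0).mean(axis=1)
    out_sub = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # Ties: replace by the mean reference value over the tied span.
        out_sub[:, j] = (
            pd.Series(assigned).groupby(pd.Series(col), sort=False).transform("mean")
        ).to_numpy()
    normalized = values.copy()
    normalized.loc[complete] = out_sub
    provenance = {
        "method": "quantile",
        "n_complete_rows": n_complete,
        "n_raw_rows": int((~complete).sum()),
        "raw_rows": [str(i) for i in values.index[~complete]],
    }
    return NormalizedMatrix(normalized, matrix.sample_groups.copy(), provenance)


def relative_expression(
    matrix: CtMatrix,
    design: GroupDesign,
    detection: DetectionMatrix | None = None,
    ct_max: float = CT_MAX,
) -> pd.DataFrame:
    """Per-(miRNA, group) relative expression, defined as ``ct_max − mean Ct``.

    The mean runs over the group's non-missing replicates. Pairs not
    detected (when a detection matrix is supplied) are NaN.
    """
    cols = {}
    for g in design.groups:
        samples = [s for s in design.members[g] if s in matrix.values.columns]
        cols[g] = ct_max - matrix.values[samples].mean(axis=1, skipna=True)
    out = pd.DataFrame(cols, columns=design.groups)
    if detection is not None:
        mask = detection.detected.reindex(
            index=out.index, columns=out.columns, fill_value=False
        )
        out = out.where(mask)
    return out


def ddct(
    matrix: CtMatrix,
    design: GroupDesign,
    reference_group: str,
    detection: DetectionMatrix | None = None,
    center: str = "geometric",
) -> pd.DataFrame:
    """Fold changes by the ΔΔCt method with global-mean normalization.

    Each sample's Ct values are centred by subtracting G(s), a global
    normalizer over all detected-miRNA Cts in that sample; ΔΔCt is the
    difference of group-mean ΔCt from the reference group and the fold
    change is ``2^(−ΔΔCt)``. MiRNAs without complete reference-group
    measurements get a missing fold change.

    ``center="geometric"`` takes G(s) as the geometric mean of the Ct
    values themselves. ``center="arithmetic"`` uses the arithmetic mean
    Ct — i.e., the geometric mean on the abundance (2^−Ct) scale, the
    usual global-mean normalization for qPCR panels — under which an
    additive shift of a whole sample cancels exactly.
    """
    if reference_group not in design.members:
        raise ValueError(f"reference group {reference_group!r} not in design")
    values = matrix.values
    if detection is not None:
        # restrict the normalizer to detected assays per sample's group
        det_cols = {
            s: detection.detected[design.group_of(s)].reindex(
                values.index, fill_value=False
            )
            for s in values.columns
        }
        norm_input = values.where(pd.DataFrame(det_cols))
    else:
        norm_input = values
    if center == "geometric":
        # geometric mean over non-missing Cts (Ct > 0 by invariant)
        g = np.exp(np.log(norm_input).mean(axis=0, skipna=True))
    elif center == "arithmetic":
        g = norm_input.mean(axis=0, skipna=True)
    else:
        raise ValueError(f"unknown center {center!r}")
    dct = values.sub(g, axis=1)
    group_means = {}
    for grp in design.groups:
        samples = [s for s in design.members[grp] if s in values.columns]
        group_means[grp] = dct[samples].mean(axis=1, skipna=False)
    gm = pd.DataFrame(group_means, columns=design.groups)
    dd = gm.sub(gm[reference_group], axis=0)
    return 2.0 ** (-dd)
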