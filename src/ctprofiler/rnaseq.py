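"""Harmonization of miRNA-seq counts onto the qPCR Ct scale.

Counts are filtered (strictly more than ``min_count`` reads in every
sample), standardized to log2 counts per million with an offset for
zeros, then mapped by a decreasing affine transform onto the
quantifiable Ct window (10–35): the most abundant miRNA lands at Ct 10,
the least at Ct 35, matching the inverse relation between abundance and
cycle threshold. The converted profiles are merged with qPCR matrices by
harmonized miRNA name and jointly quantile-normalized.
"""

from __future__ import annotations

import difflib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix, CtMatrix, HarmonizedMatrix, NormalizedMatrix
from .normalize import quantile_normalize

__all__ = [
    "filter_counts",
    "log_cpm",
    "to_ct_scale",
    "harmonize_name",
    "merge_platforms",
]

#: Species prefixes stripped during cross-platform name harmonization.
SPECIES_PREFIXES = ("hsa-", "mmu-", "rno-")


def filter_counts(
    counts: CountMatrix, min_count: int = 10, require_all: bool = True
) -> CountMatrix:
    """Keep miRNAs with count strictly above ``min_count``.

    With ``require_all`` (default) the threshold must hold in every
    sample ("present in all samples"); otherwise one sample suffices.
    """
    above = counts.counts > min_count
    keep = above.all(axis=1) if require_all else above.any(axis=1)
    return CountMatrix(counts.counts.loc[keep])


def log_cpm(counts: CountMatrix, prior: float = 2.0) -> pd.DataFrame:
    """log2 counts per million with a library-size-scaled prior count.

    The prior count is scaled by each library's size in millions and
    added to the counts (twice to the library sizes), so zero counts
    stay finite and doubling every count and library size leaves the
    result exactly unchanged. For a 1e6-read library the offset equals
    ``prior`` counts: count 1000 at prior 2 gives
    log2((1000+2)/(1e6+4) * 1e6) ~= 9.97.
    """
    lib = counts.library_sizes.to_numpy(float)
    if (lib <= 0).any():
        raise ValueError("every library size must be > 0")
    prior_scaled = prior * lib / 1e6
    adj_lib = lib + 2.0 * prior_scaled
    vals = counts.counts.to_numpy(float) + prior_scaled[None, :]
    out = np.log2(vals / adj_lib[None, :] * 1e6)
    return pd.DataFrame(out, index=counts.counts.index, columns=counts.counts.columns)


def to_ct_scale(
    logcpm: pd.DataFrame,
    ct_low: float = 10.0,
    ct_high: float = 35.0,
    invert: bool = True,
) -> pd.DataFrame:
    """Affine map of log-CPM values onto the Ct window [ct_low, ct_high].

    The default orientation is decreasing (``invert=True``): the global
    maximum log-CPM maps to ``ct_low`` and the minimum to ``ct_high``,
    because abundance and Ct are inversely related. Anchors are global
    over the whole matrix so relative abundances across samples are
    preserved.
    """
    x = logcpm.to_numpy(float)
    lo, hi = float(np.nanmin(x)), float(np.nanmax(x))
    if hi == lo:
        raise ValueError("log-CPM matrix is constant: Ct scale undefined")
    frac = (x - lo) / (hi - lo)
    if invert:
        ct = ct_high - (ct_high - ct_low) * frac
    else:
        ct = ct_low + (ct_high - ct_low) * frac
    return pd.DataFrame(ct, index=logcpm.index, columns=logcpm.columns)


def harmonize_name(
    name: str,
    strip_prefixes: Sequence[str] = SPECIES_PREFIXES,
    casefold: bool = True,
    aliases: Mapping[str, str] | None = None,
) -> str:
    """Canonical cross-platform form of a miRNA name."""
    out = name.strip()
    if aliases and out in aliases:
        out = aliases[out]
    for pref in strip_prefixes:
        if out.lower().startswith(pref.lower()):
            out = out[len(pref):]
            break
    return out.casefold() if casefold else out


def merge_platforms(
    qpcr: CtMatrix,
    seq_ct: pd.DataFrame,
    seq_group: str = "seq",
    strip_prefixes: Sequence[str] = SPECIES_PREFIXES,
    casefold: bool = True,
    aliases: Mapping[str, str] | None = None,
) -> HarmonizedMatrix:
    """Merge qPCR and Ct-converted sequencing profiles, then jointly
    quantile-normalize.

    MiRNA names are harmonized (species prefixes stripped, case folded,
    optional alias table) and the matrices inner-joined on the
    harmonized names; the merged matrix is quantile-normalized so both
    platforms share one value distribution. ``mapping_log`` records
    every rename and every unmatched name.

    Raises
    ------
    ValueError
        If no name is shared after harmonization (with nearest-name
        suggestions).
    """

    def _harmonize_index(idx) -> tuple[dict[str, str], list[str]]:
        mapping, order = {}, []
        for name in idx:
            h = harmonize_name(name, strip_prefixes, casefold, aliases)
            mapping[str(name)] = h
            order.append(h)
        return mapping, order

    q_map, q_names = _harmonize_index(qpcr.values.index)
    s_map, s_names = _harmonize_index(seq_ct.index)
    common = sorted(set(q_names) & set(s_names))
    if not common:
        suggestions = {
            n: difflib.get_close_matches(n, q_names, n=1)
            for n in s_names[:10]
        }
        raise ValueError(
            "no shared miRNA names after harmonization; nearest qPCR matches "
            f"for the first sequencing names: {suggestions}"
        )
    q_vals = qpcr.values.copy()
    q_vals.index = q_names
    s_vals = seq_ct.copy()
    s_vals.index = s_names
    # drop harmonization collisions (same canonical name twice on one side)
    q_vals = q_vals[~q_vals.index.duplicated(keep="first")]
    s_vals = s_vals[~s_vals.index.duplicated(keep="first")]
    merged = pd.concat([q_vals.loc[common], s_vals.loc[common]], axis=1)
    q_groups = qpcr.sample_groups
    groups = pd.Series(
        {**{s: q_groups[s] for s in qpcr.values.columns},
         **{s: seq_group for s in seq_ct.columns}},
        dtype=object,
    ).reindex(merged.columns)
    normalized = quantile_normalize(CtMatrix(merged, groups))
    platforms = pd.Series(
        {**{s: "qpcr" for s in qpcr.values.columns},
         **{s: "seq" for s in seq_ct.columns}},
        dtype=object,
    ).reindex(merged.columns)
    mapping_log = {
        "renamed_qpcr": {k: v for k, v in q_map.items() if k != v},
        "renamed_seq": {k: v for k, v in s_map.items() if k != v},
        "unmatched_qpcr": sorted(set(q_names) - set(common)),
        "unmatched_seq": sorted(set(s_names) - set(common)),
        "n_common": len(common),
    }
    return HarmonizedMatrix(
        values=normalized.values,
        sample_groups=groups,
        platforms=platforms,
        mapping_log=mapping_log,
    )
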