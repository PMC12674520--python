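"""Shared domain containers for qPCR Ct-matrix analysis.

The central object is the :class:`CtMatrix` — a miRNA-by-sample matrix of
cycle-threshold (Ct) values with missing cells for wells that did not
amplify or failed quality control. Lower Ct means higher template
abundance. Group structure (cell types, three replicates each in the
reference design) lives in a :class:`GroupDesign`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WellRecord",
    "GroupDesign",
    "CtMatrix",
    "NormalizedMatrix",
    "DetectionMatrix",
    "OverlapResult",
    "BootstrapResult",
    "SimilarityScore",
    "CountMatrix",
    "HarmonizedMatrix",
    "SyntheticTruth",
    "region_key",
    "parse_region_key",
]


@dataclass(frozen=True)
class WellRecord:
    """One well of a qPCR array export.

    Parameters
    ----------
    sample_id, group, mirna_id
        Identity of the measurement.
    ct
        Cycle threshold in PCR cycles, or ``None`` for wells where the
        instrument reported no quantification ("Undetermined").
    amp_score
        Amplification-curve quality score (platform metric, unitless).
    cq_conf
        Quantification-cycle confidence in [0, 1].
    """

    sample_id: str
    group: str
    mirna_id: str
    ct: float | None
    amp_score: float
    cq_conf: float

    def __post_init__(self) -> None:
        if self.ct is not None:
            if not math.isfinite(self.ct) or self.ct <= 0:
                raise ValueError(
                    f"ct must be finite and > 0 or None, got {self.ct!r} "
                    f"for ({self.sample_id}, {self.mirna_id})"
                )
        if not 0.0 <= self.cq_conf <= 1.0:
            raise ValueError(
                f"cq_conf must lie in [0, 1], got {self.cq_conf!r} "
                f"for ({self.sample_id}, {self.mirna_id})"
            )


class GroupDesign:
    """Assignment of samples to groups (cell types) with replicate structure.

    Every sample belongs to exactly one group and each group is nonempty.
    """

    def __init__(
        self,
        members: Mapping[str, Sequence[str]],
        control_group: str | None = None,
    ) -> None:
        self.members: dict[str, list[str]] = {
            str(g): [str(s) for s in ss] for g, ss in members.items()
        }
        if not self.members:
            raise ValueError("design must contain at least one group")
        seen: dict[str, str] = {}
        for g, ss in self.members.items():
            if not ss:
                raise ValueError(f"group {g!r} has no samples")
            for s in ss:
                if s in seen:
                    raise ValueError(
                        f"sample {s!r} assigned to both {seen[s]!r} and {g!r}"
                    )
                seen[s] = g
        if control_group is not None and control_group not in self.members:
            raise ValueError(f"control group {control_group!r} not in design")
        self.control_group = control_group

    @classmethod
    def from_sample_groups(
        cls, sample_groups: Mapping[str, str] | pd.Series, control_group: str | None = None
    ) -> "GroupDesign":
        """Build a design from a sample -> group mapping (order-preserving)."""
        if isinstance(sample_groups, pd.Series):
            items = list(sample_groups.items())
        else:
            items = list(sample_groups.items())
        members: dict[str, list[str]] = {}
        for s, g in items:
            members.setdefault(str(g), []).append(str(s))
        return cls(members, control_group=control_group)

    @property
    def groups(self) -> list[str]:
        return list(self.members)

    @property
    def sample_ids(self) -> list[str]:
        return [s for ss in self.members.values() for s in ss]

    @property
    def sample_to_group(self) -> dict[str, str]:
        return {s: g for g, ss in self.members.items() for s in ss}

    def group_of(self, sample_id: str) -> str:
        return self.sample_to_group[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.sample_to_group

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        sizes = ", ".join(f"{g}={len(ss)}" for g, ss in self.members.items())
        return f"GroupDesign({sizes}, control={self.control_group!r})"


@dataclass
class CtMatrix:
    """miRNA-by-sample matrix of Ct values (NaN = missing).

    ``values`` is a float DataFrame indexed by miRNA ID with sample-ID
    columns; ``sample_groups`` maps each column to its group label and is
    kept aligned with the columns.
    """

    values: pd.DataFrame
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate miRNA IDs in matrix index")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample IDs in matrix columns")
        self.sample_groups = pd.Series(self.sample_groups, dtype=object)
        missing = [s for s in self.values.columns if s not in self.sample_groups.index]
        if missing:
            raise ValueError(f"samples without group labels: {missing}")
        self.sample_groups = self.sample_groups.reindex(self.values.columns)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def design(self, control_group: str | None = None) -> GroupDesign:
        return GroupDesign.from_sample_groups(self.sample_groups, control_group)

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_groups[s] == group]

    def copy(self) -> "CtMatrix":
        return CtMatrix(self.values.copy(), self.sample_groups.copy())

    def equals(self, other: "CtMatrix") -> bool:
        return (
            self.values.equals(other.values)
            and list(self.sample_groups) == list(other.sample_groups)
            and list(self.sample_groups.index) == list(other.sample_groups.index)
        )


@dataclass
class NormalizedMatrix(CtMatrix):
    """A CtMatrix after normalization, with a provenance record.

    ``provenance`` carries the method tag and its parameters (for a
    quantile normalization: how many complete rows defined the reference
    distribution, and which rows were left on the raw scale).
    """

    provenance: dict = field(default_factory=dict)


@dataclass
class DetectionMatrix:
    """Boolean miRNA-by-group detection calls."""

    detected: pd.DataFrame  # bool, index miRNA, columns group

    def __post_init__(self) -> None:
        self.detected = self.detected.astype(bool)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.detected.index)

    @property
    def groups(self) -> list[str]:
        return list(self.detected.columns)

    def n_detected(self, group: str) -> int:
        return int(self.detected[group].sum())

    def union_size(self, groups: Sequence[str] | None = None) -> int:
        sub = self.detected if groups is None else self.detected[list(groups)]
        return int(sub.any(axis=1).sum())


def region_key(groups: Iterable[str]) -> str:
    """Serialize a subset of groups as a '+'-joined sorted key."""
    return "+".join(sorted(groups))


def parse_region_key(key: str) -> tuple[str, ...]:
    return tuple(sorted(key.split("+")))


@dataclass
class OverlapResult:
    """Exclusive region counts of a Venn/Euler decomposition.

    ``region_counts`` maps each nonempty subset of the compared groups
    (as a sorted tuple) to the number of miRNAs detected in exactly those
    groups; the counts partition the union of detected miRNAs.
    """

    region_counts: dict[tuple[str, ...], int]
    universe_size: int
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        total = sum(self.region_counts.values())
        if total != self.universe_size:
            raise ValueError(
                f"region counts sum to {total}, expected universe {self.universe_size}"
            )

    def count(self, *groups: str) -> int:
        return self.region_counts.get(tuple(sorted(groups)), 0)

    def to_json_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "universe_size": self.universe_size,
            "regions": {region_key(k): v for k, v in self.region_counts.items()},
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "OverlapResult":
        return cls(
            region_counts={parse_region_key(k): int(v) for k, v in d["regions"].items()},
            universe_size=int(d["universe_size"]),
            groups=tuple(d.get("groups", ())),
        )


@dataclass
class BootstrapResult:
    """Null distributions and empirical p-values for overlap region counts.

    Null counts come from binomial resampling of per-group detection at
    the observed per-group detection rates; ``empirical_p`` is a two-sided
    add-one empirical p-value per region (distance from the null median).
    """

    n_iter: int
    seed: int
    observed: dict[tuple[str, ...], int]
    null_counts: dict[tuple[str, ...], np.ndarray]
    null_median: dict[tuple[str, ...], float]
    empirical_p: dict[tuple[str, ...], float]
    p_adjusted: dict[tuple[str, ...], float]
    universe_size: int

    def __post_init__(self) -> None:
        for k, v in self.null_counts.items():
            if len(v) != self.n_iter:
                raise ValueError(f"null_counts[{k}] has length {len(v)} != {self.n_iter}")
        lo = 1.0 / (self.n_iter + 1)
        for k, p in self.empirical_p.items():
            if not lo - 1e-12 <= p <= 1.0 + 1e-12:
                raise ValueError(f"empirical p for {k} out of range: {p}")

    def to_json_dict(self, include_null: bool = False) -> dict:
        d = {
            "n_iter": self.n_iter,
            "seed": self.seed,
            "universe_size": self.universe_size,
            "observed": {region_key(k): int(v) for k, v in self.observed.items()},
            "null_median": {region_key(k): float(v) for k, v in self.null_median.items()},
            "empirical_p": {region_key(k): float(v) for k, v in self.empirical_p.items()},
            "p_adjusted": {region_key(k): float(v) for k, v in self.p_adjusted.items()},
        }
        if include_null:
            d["null_counts"] = {
                region_key(k): [int(x) for x in v] for k, v in self.null_counts.items()
            }
        return d


@dataclass
class SimilarityScore:
    """Pearson correlation and mean squared error between two profiles."""

    pearson_r: float
    mse: float
    n_common: int


@dataclass
class CountMatrix:
    """miRNA-by-sample matrix of nonnegative integer sequencing counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if vals.size and (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        if vals.size and not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integral")
        self.counts = self.counts.astype(np.int64)
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate IDs in count matrix")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass
class HarmonizedMatrix:
    """qPCR and sequencing profiles merged on the Ct scale.

    ``platforms`` tags each sample column as ``"qpcr"`` or ``"seq"``;
    ``mapping_log`` records every miRNA-name harmonization applied and
    every name left unmatched on either side.
    """

    values: pd.DataFrame
    sample_groups: pd.Series
    platforms: pd.Series
    mapping_log: dict

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SyntheticTruth:
    """Latent parameters behind a simulated plate, for recovery tests."""

    detect_prob: pd.DataFrame  # miRNA x group, in [0, 1]
    baseline_ct: pd.Series  # per miRNA
    effect: pd.DataFrame  # miRNA x group, ΔCt shift (0 = no effect)
    sigma_ct: float
    qc_fail_prob: float
    detected: pd.DataFrame | None = None  # realized detection (miRNA x group)
    de_mirnas: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        dp = self.detect_prob.to_numpy()
        if ((dp < 0) | (dp > 1)).any():
            raise ValueError("detection probabilities must lie in [0, 1]")
        if self.sigma_ct < 0:
            raise ValueError("sigma_ct must be >= 0")
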