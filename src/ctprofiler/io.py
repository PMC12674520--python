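"""Readers and writers for the tabular formats the pipeline touches.

Well-level exports are long format (one row per well), matching how
array-style qPCR instruments export data. Matrices, differential
expression tables and overlap results round-trip through CSV/JSON.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    BootstrapResult,
    CountMatrix,
    CtMatrix,
    GroupDesign,
    OverlapResult,
    WellRecord,
)

__all__ = [
    "read_well_records",
    "write_well_records",
    "records_to_matrix",
    "read_ct_matrix",
    "write_ct_matrix",
    "read_count_matrix",
    "write_count_matrix",
    "read_annotation_list",
    "write_de_table",
    "read_de_table",
    "write_overlap",
    "read_overlap",
    "write_bootstrap",
    "DEFAULT_ALIASES",
    "MISSING_CT_TOKENS",
]

REQUIRED_COLUMNS = ("sample_id", "group", "mirna_id", "ct", "amp_score", "cq_conf")

#: Column-name aliases accepted on ingestion (case-insensitive, spaces and
#: underscores interchangeable). Instruments vary: "Crt" is a relative Ct,
#: "Amp Score"/"Cq Conf" appear in OpenArray-style exports.
DEFAULT_ALIASES: dict[str, str] = {
    "sample": "sample_id",
    "sample_name": "sample_id",
    "cell_type": "group",
    "condition": "group",
    "mirna": "mirna_id",
    "assay": "mirna_id",
    "assay_name": "mirna_id",
    "target": "mirna_id",
    "crt": "ct",
    "cq": "ct",
    "ampscore": "amp_score",
    "amp_score": "amp_score",
    "cqconf": "cq_conf",
    "cq_conf": "cq_conf",
}

#: Tokens treated as a missing Ct measurement.
MISSING_CT_TOKENS = {"", "undetermined", "na", "nan", "n/a", "null"}


def _canonical_column(name: str, aliases: Mapping[str, str]) -> str:
    key = name.strip().lower().replace(" ", "_")
    if key in REQUIRED_COLUMNS:
        return key
    return aliases.get(key, key)


def _parse_ct(token: object) -> float | None:
    if token is None:
        return None
    if isinstance(token, float) and math.isnan(token):
        return None
    s = str(token).strip()
    if s.lower() in MISSING_CT_TOKENS:
        return None
    try:
        return float(s)
    except ValueError:
        return None


def read_well_records(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
    sep: str = ",",
) -> list[WellRecord]:
    """Read long-format well records from a CSV export.

    The header must name the five required columns
    (``sample_id, group, mirna_id, ct, amp_score, cq_conf``), possibly
    through aliases. Unparseable Ct tokens ("Undetermined", empty, "NA")
    become missing measurements; the row count is preserved.

    Raises
    ------
    ValueError
        If a required column is absent, or if a (sample, miRNA) pair
        occurs more than once.
    """
    alias_map = dict(DEFAULT_ALIASES)
    if aliases:
        alias_map.update(
            {k.strip().lower().replace(" ", "_"): v for k, v in aliases.items()}
        )
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [_canonical_column(c, alias_map) for c in df.columns]
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(
            f"{path}: missing required column(s) {missing_cols}; "
            f"found {list(df.columns)} (configure aliases if names differ)"
        )
    dup_mask = df.duplicated(subset=["sample_id", "mirna_id"], keep=False)
    if dup_mask.any():
        first = df.loc[dup_mask, ["sample_id", "mirna_id"]].iloc[0]
        raise ValueError(
            f"{path}: duplicate (sample, miRNA) pair "
            f"({first['sample_id']!r}, {first['mirna_id']!r})"
        )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            WellRecord(
                sample_id=str(row.sample_id).strip(),
                group=str(row.group).strip(),
                mirna_id=str(row.mirna_id).strip(),
                ct=_parse_ct(row.ct),
                amp_score=float(row.amp_score),
                cq_conf=float(row.cq_conf),
            )
        )
    return records


def write_well_records(records: Iterable[WellRecord], path: str | Path) -> None:
    """Write well records as CSV with the canonical header."""
    rows = [
        {
            "sample_id": r.sample_id,
            "group": r.group,
            "mirna_id": r.mirna_id,
            "ct": "" if r.ct is None else repr(r.ct),
            "amp_score": r.amp_score,
            "cq_conf": r.cq_conf,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)).to_csv(path, index=False)


def records_to_matrix(
    records: Sequence[WellRecord], design: GroupDesign
) -> CtMatrix:
    """Pivot well records into a miRNA-by-sample Ct matrix.

    Cells with no passing record stay missing. Axis orders are
    deterministic (lexicographic), so row-shuffled inputs yield
    identical matrices.
    """
    orphans = sorted({r.sample_id for r in records if r.sample_id not in design})
    if orphans:
        raise ValueError(f"samples absent from design: {orphans}")
    mirnas = sorted({r.mirna_id for r in records})
    samples = sorted(design.sample_ids)
    values = pd.DataFrame(np.nan, index=mirnas, columns=samples, dtype=float)
    for r in records:
        if r.ct is not None:
            values.at[r.mirna_id, r.sample_id] = r.ct
    groups = pd.Series({s: design.group_of(s) for s in samples}, dtype=object)
    return CtMatrix(values, groups.reindex(samples))


_GROUPS_PREFIX = "# groups:"


def write_ct_matrix(matrix: CtMatrix, path: str | Path) -> None:
    """Write a Ct matrix as wide CSV with a group-annotation comment line."""
    path = Path(path)
    header = _GROUPS_PREFIX + " " + ";".join(
        f"{s}={g}" for s, g in matrix.sample_groups.items()
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df = matrix.values.copy()
        df.index.name = "mirna_id"
        df.to_csv(fh)


def read_ct_matrix(path: str | Path) -> CtMatrix:
    """Read a wide Ct-matrix CSV written by :func:`write_ct_matrix`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(_GROUPS_PREFIX):
            raise ValueError(
                f"{path}: missing group annotation line ({_GROUPS_PREFIX!r} ...)"
            )
        pairs = first[len(_GROUPS_PREFIX):].strip()
        groups = {}
        if pairs:
            for item in pairs.split(";"):
                s, g = item.split("=", 1)
                groups[s] = g
        df = pd.read_csv(fh, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return CtMatrix(df, pd.Series(groups, dtype=object).reindex(df.columns))


def read_count_matrix(path: str | Path, sep: str = "\t") -> CountMatrix:
    """Read a miRNA-by-sample count TSV (first column ``mirna_id``)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountMatrix(df)


def write_count_matrix(counts: CountMatrix, path: str | Path, sep: str = "\t") -> None:
    df = counts.counts.copy()
    df.index.name = "mirna_id"
    df.to_csv(path, sep=sep)


def read_annotation_list(path: str | Path) -> list[str]:
    """Read a plain-text miRNA name list (one per line, ``#`` comments)."""
    names = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            names.append(line)
    return names


def write_de_table(result, path: str | Path) -> None:
    """Write a differential-expression results table as CSV."""
    df = result.to_frame() if hasattr(result, "to_frame") else result
    df = df.copy()
    df.index.name = "mirna_id"
    df.to_csv(path)


def read_de_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return df


def write_overlap(result: OverlapResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(result.to_json_dict(), indent=2) + "\n")


def read_overlap(path: str | Path) -> OverlapResult:
    return OverlapResult.from_json_dict(json.loads(Path(path).read_text()))


def write_bootstrap(
    result: BootstrapResult, path: str | Path, include_null: bool = False
) -> None:
    Path(path).write_text(
        json.dumps(result.to_json_dict(include_null=include_null), indent=2) + "\n"
    )
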