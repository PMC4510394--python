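"""Reading, validating, normalizing and writing spot-volume tables.

The canonical in-memory form is long format: one record per
(spot, group, replicate) with a non-negative volume.  Wide tables (spots
as rows, ``group:replicate`` columns) are converted on read.  Volumes are
kept in the units of the input — for the packaged reference fixture that
is the x10^-2 display scale of the source data, stored verbatim.

Missing cells are errors, never silently imputed as zeros: an absent spot
must be recorded as explicit zeros by the instrument export, because
all-zero groups carry meaning downstream (qualitative change, N/A bias).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SpotVolumeTable",
    "GroupMeanFixture",
    "FixtureRow",
    "StructuralError",
    "TableParseError",
    "DegenerateGelError",
    "read_volume_table",
    "write_volume_table",
    "normalize_total_density",
    "load_table1_fixture",
    "write_report",
    "read_report",
]

LONG_COLUMNS = ["spot_id", "protein", "group", "replicate", "volume"]


class StructuralError(ValueError):
    """Table violates a structural invariant (groups, replicates, signs)."""


class TableParseError(ValueError):
    """A cell could not be parsed; the message names row and column."""


class DegenerateGelError(ValueError):
    """A gel has zero total density over the validated spots."""


@dataclass(frozen=True)
class SpotVolumeTable:
    """Validated long-format spot-volume table.

    ``data`` has columns spot_id, protein, group, replicate, volume;
    ``group_labels`` is the ordered (reference, treatment) pair.
    """

    data: pd.DataFrame
    group_labels: tuple[str, str]

    def __post_init__(self):
        _validate_long(self.data, self.group_labels)

    @property
    def spot_ids(self) -> list[str]:
        """Spot ids in first-appearance order."""
        return list(dict.fromkeys(self.data["spot_id"]))

    def protein_label(self, spot_id: str) -> str:
        sub = self.data.loc[self.data["spot_id"] == spot_id, "protein"]
        return "" if sub.empty or pd.isna(sub.iloc[0]) else str(sub.iloc[0])

    def group_values(self, spot_id: str, group: str) -> np.ndarray:
        mask = (self.data["spot_id"] == spot_id) & (self.data["group"] == group)
        return self.data.loc[mask, "volume"].to_numpy(dtype=np.float64)


def _validate_long(df: pd.DataFrame, group_labels: tuple[str, str]) -> None:
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise StructuralError(f"missing columns: {missing}")
    groups = sorted(set(df["group"].astype(str)))
    if len(groups) != 2:
        raise StructuralError(f"expected exactly 2 group labels, found {groups}")
    if sorted(group_labels) != groups:
        raise StructuralError(
            f"declared group labels {group_labels} do not match table groups {groups}"
        )
    if group_labels[0] == group_labels[1]:
        raise StructuralError("reference and treatment group labels must differ")
    vol = df["volume"]
    if vol.isna().any():
        row = int(vol.index[vol.isna()][0])
        raise TableParseError(f"missing/invalid volume at row {row}")
    if (vol < 0).any():
        row = int(vol.index[vol < 0][0])
        raise StructuralError(f"negative volume at row {row}")
    dup = df.duplicated(subset=["spot_id", "group", "replicate"])
    if dup.any():
        key = df.loc[dup.idxmax(), ["spot_id", "group", "replicate"]].tolist()
        raise StructuralError(f"duplicate (spot, group, replicate) record: {key}")
    counts = df.groupby(["spot_id", "group"], sort=False).size().unstack(fill_value=0)
    for spot_id, row in counts.iterrows():
        if len(row) != 2 or row.iloc[0] != row.iloc[1] or (row == 0).any():
            raise StructuralError(
                f"spot {spot_id!r}: unequal replicate counts across groups "
                f"({dict(row)})"
            )


def _coerce_numeric(series: pd.Series, colname: str) -> pd.Series:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna()
    if bad.any():
        row = int(bad.index[bad][0])
        raise TableParseError(
            f"malformed numeric cell at row {row}, column {colname!r}: "
            f"{series[bad].iloc[0]!r}"
        )
    return out


def read_volume_table(
    path,
    layout: str = "long",
    delimiter: str = "\t",
    group_labels: tuple[str, str] | None = None,
) -> SpotVolumeTable:
    """Read a delimited spot-volume table.

    ``layout='long'`` expects columns spot_id, protein, group, replicate,
    volume; ``layout='wide'`` expects spot_id, optionally protein, then
    one ``<group>:<replicate>`` column per gel measurement.  If
    ``group_labels`` is omitted the two labels found are ordered
    lexicographically, reference first.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, comment="#")
    if layout == "long":
        if "protein" not in df.columns:
            df["protein"] = ""
        long = df.loc[:, LONG_COLUMNS].copy()
        long["volume"] = _coerce_numeric(long["volume"], "volume")
    elif layout == "wide":
        long = _wide_to_long(df)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    long["spot_id"] = long["spot_id"].astype(str)
    long["group"] = long["group"].astype(str)
    long["replicate"] = long["replicate"].astype(str)
    if group_labels is None:
        found = sorted(set(long["group"]))
        if len(found) != 2:
            raise StructuralError(f"expected exactly 2 group labels, found {found}")
        group_labels = (found[0], found[1])
    return SpotVolumeTable(data=long.reset_index(drop=True), group_labels=tuple(group_labels))


def _wide_to_long(df: pd.DataFrame) -> pd.DataFrame:
    if "spot_id" not in df.columns:
        raise StructuralError("wide layout requires a 'spot_id' column")
    meta = ["spot_id"] + (["protein"] if "protein" in df.columns else [])
    value_cols = [c for c in df.columns if c not in meta]
    if not value_cols:
        raise StructuralError("wide layout has no '<group>:<replicate>' columns")
    records = []
    for col in value_cols:
        if ":" not in col:
            raise StructuralError(
                f"wide column {col!r} is not of the form '<group>:<replicate>'"
            )
        group, replicate = col.split(":", 1)
        vals = _coerce_numeric(df[col], col)
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise TableParseError(f"missing cell at row {row}, column {col!r}")
        for i in df.index:
            records.append(
                {
                    "spot_id": df.loc[i, "spot_id"],
                    "protein": df.loc[i, "protein"] if "protein" in df.columns else "",
                    "group": group,
                    "replicate": replicate,
                    "volume": float(vals[i]),
                }
            )
    return pd.DataFrame.from_records(records, columns=LONG_COLUMNS)


def write_volume_table(table: SpotVolumeTable, path, delimiter: str = "\t") -> None:
    """Write a table in canonical long format."""
    table.data.to_csv(path, sep=delimiter, index=False)


def normalize_total_density(
    table: SpotVolumeTable, validated_ids=None, scale: float = 100.0
) -> SpotVolumeTable:
    """Total-density normalization of every gel.

    Each gel is one (group, replicate) pair; every volume on a gel is
    divided by the gel's total volume over the validated spots and
    multiplied by ``scale``, so validated volumes on each gel sum to
    ``scale`` afterwards.  ``validated_ids=None`` validates all spots.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    df = table.data.copy()
    if validated_ids is None:
        validated = pd.Series(True, index=df.index)
    else:
        validated = df["spot_id"].isin(set(validated_ids))
        if not validated.any():
            raise ValueError("no validated spots present in the table")
    totals = df.loc[validated].groupby(["group", "replicate"])["volume"].sum()
    for (group, replicate), total in totals.items():
        if total <= 0.0:
            raise DegenerateGelError(
                f"gel (group={group!r}, replicate={replicate!r}) has zero total "
                "density over validated spots"
            )
    keys = pd.MultiIndex.from_frame(df[["group", "replicate"]])
    df["volume"] = df["volume"].to_numpy() / totals.reindex(keys).to_numpy() * scale
    return SpotVolumeTable(data=df, group_labels=table.group_labels)


# ---------------------------------------------------------------------------
# Reference fixture: ten differentially abundant spots, group mean +- SE and
# bootstrap bias per group, in x10^-2 volume units.  N/A bias marks a spot
# absent from the group (mean exactly 0.00).


@dataclass(frozen=True)
class FixtureRow:
    spot_id: str
    mean_control: float
    se_control: float | None
    bias_control: float | None
    mean_dfd: float
    se_dfd: float | None
    bias_dfd: float | None


class GroupMeanFixture:
    """Per-spot group means, standard errors and bootstrap biases."""

    def __init__(self, rows: list[FixtureRow]):
        self._rows = {r.spot_id: r for r in rows}
        self.spot_ids = [r.spot_id for r in rows]

    def __getitem__(self, spot_id: str) -> FixtureRow:
        return self._rows[spot_id]

    def __len__(self) -> int:
        return len(self._rows)

    def __iter__(self):
        return iter(self._rows.values())


def load_table1_fixture() -> GroupMeanFixture:
    """Load the packaged ten-spot reference fixture.

    Values are stored exactly as printed in the source table (x10^-2
    volume units); a spot absent from a group has mean 0.00 and N/A for
    both SE and bias.
    """
    with resources.files("spotboot.data").joinpath("table1.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)

    def opt(v):
        return None if v == "N/A" else float(v)

    rows = [
        FixtureRow(
            spot_id=r["spot_id"],
            mean_control=float(r["mean_control"]),
            se_control=opt(r["se_control"]),
            bias_control=opt(r["bias_control"]),
            mean_dfd=float(r["mean_dfd"]),
            se_dfd=opt(r["se_dfd"]),
            bias_dfd=opt(r["bias_dfd"]),
        )
        for _, r in df.iterrows()
    ]
    fixture = GroupMeanFixture(rows)
    for r in fixture:
        if (r.bias_control is None) != (r.mean_control == 0.0) or (
            r.bias_dfd is None
        ) != (r.mean_dfd == 0.0):
            raise StructuralError(
                f"fixture row {r.spot_id}: N/A bias must coincide with zero mean"
            )
    return fixture


# ---------------------------------------------------------------------------
# Analysis report


def _fmt(v) -> str:
    if v is None:
        return "N/A"
    if isinstance(v, float):
        if math.isnan(v):
            return "N/A"
        if math.isinf(v):
            return "+Inf" if v > 0 else "-Inf"
        return format(v, ".12g")
    return str(v)


def _parse_cell(s: str):
    if s == "N/A":
        return None
    if s == "+Inf":
        return math.inf
    if s == "-Inf":
        return -math.inf
    try:
        return float(s)
    except ValueError:
        return s


def write_report(rows: pd.DataFrame, path, header: dict | None = None) -> None:
    """Write the per-spot analysis report as TSV.

    ``header`` entries are echoed as ``# key: value`` comment lines so a
    run is reproducible from the report alone.  Floats are written to 12
    significant digits; infinities as ``+Inf``/``-Inf``; missing values
    (N/A bias for absent spots) as ``N/A``.
    """
    if rows.empty:
        raise ValueError("report must contain at least one spot")
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write("\t".join(rows.columns) + "\n")
        for _, r in rows.iterrows():
            fh.write("\t".join(_fmt(v) for v in r) + "\n")


def read_report(path) -> tuple[pd.DataFrame, dict]:
    """Read a report written by :func:`write_report`.

    Returns the data frame (infinity/N-A literals decoded) and the header
    dict.
    """
    header: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# "):
            key, _, value = line[2:].partition(": ")
            header[key] = value
            body_start = i + 1
        else:
            break
    columns = lines[body_start].split("\t")
    records = [
        [_parse_cell(c) for c in line.split("\t")] for line in lines[body_start + 1 :] if line
    ]
    return pd.DataFrame(records, columns=columns), header
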