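"""Reading and writing feature tables.

Two dialects are supported: a flat CSV/TSV with metadata columns plus
FreeSurfer-style feature columns (``lh_bankssts_area``), and the
three-table output of FreeSurfer's ``aparcstats2table`` (one table per
measure).  Matrices are always subjects-in-rows; after load, features are
reordered into the canonical sorted (hemisphere, region, measure) order.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ConfigurationError,
    DataError,
    FeatureDescriptor,
    FeatureTable,
    SubjectRecord,
    canonical_feature_order,
)

logger = logging.getLogger(__name__)

#: default column-name pattern: <hemi>_<region>_<measure>
DEFAULT_FEATURE_PATTERN = re.compile(
    r"^(?P<hemi>lh|rh)_(?P<region>[A-Za-z0-9.]+)_(?P<measure>area|thickness|volume)$"
)

_HEMI_CODES = {"lh": "left", "rh": "right"}

DEFAULT_METADATA_COLUMNS: Mapping[str, str] = {
    "subject_id": "subject_id",
    "site": "site",
    "group": "group",
    "age": "age",
    "sex": "sex",
}

#: aparcstats2table aggregate columns excluded by default (whole-hemisphere
#: summaries and volume proxies, not regional measures).
AGGREGATE_COLUMN_MARKERS = (
    "WhiteSurfArea", "MeanThickness", "BrainSegVolNotVent", "eTIV",
    "SupraTentorialVol", "CortexVol",
)


def parse_feature_column(
    name: str, pattern: re.Pattern[str] = DEFAULT_FEATURE_PATTERN
) -> FeatureDescriptor | None:
    """Parse a column name into a descriptor; None if it does not match."""
    m = pattern.match(name)
    if m is None:
        return None
    return FeatureDescriptor(
        region_name=m.group("region"),
        hemisphere=_HEMI_CODES[m.group("hemi")],
        measure=m.group("measure"),
    )


def _build_records(df: pd.DataFrame, cols: Mapping[str, str]) -> list[SubjectRecord]:
    for canonical, actual in cols.items():
        if actual not in df.columns:
            raise ConfigurationError(f"metadata column {actual!r} (for {canonical!r}) not in file")
    ids = df[cols["subject_id"]].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise DataError(f"duplicate subject_id {dup!r}")
    records = []
    for _, row in df.iterrows():
        age = row.get(cols.get("age", "age"))
        sex = row.get(cols.get("sex", "sex"))
        records.append(
            SubjectRecord(
                subject_id=str(row[cols["subject_id"]]),
                site_id=str(row[cols["site"]]),
                group=str(row[cols["group"]]),
                age=float(age) if age is not None and not pd.isna(age) else None,
                sex=str(sex) if sex is not None and not pd.isna(sex) else None,
            )
        )
    return records


def read_feature_table(
    path: str | Path,
    metadata_columns: Mapping[str, str] = DEFAULT_METADATA_COLUMNS,
    feature_pattern: re.Pattern[str] = DEFAULT_FEATURE_PATTERN,
    sep: str | None = None,
    impute: bool = False,
) -> FeatureTable:
    """Load a flat delimited table with metadata and feature columns.

    Parameters
    ----------
    metadata_columns
        Mapping from canonical metadata names (subject_id, site, group,
        age, sex) to the actual column names in the file.
    feature_pattern
        Regex with ``hemi``, ``region`` and ``measure`` groups used to
        recognise feature columns; non-matching, non-metadata columns are
        ignored with a log message.
    impute
        If True, missing feature cells are filled with the per-feature
        median; by default a missing cell is a hard error naming the cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    records = _build_records(df, metadata_columns)

    meta_names = set(metadata_columns.values()) | {"headache_frequency"}
    descriptors: list[FeatureDescriptor] = []
    columns: list[str] = []
    for name in df.columns:
        if name in meta_names:
            continue
        desc = parse_feature_column(name, feature_pattern)
        if desc is None:
            logger.info("ignoring unrecognised column %r", name)
            continue
        descriptors.append(desc)
        columns.append(name)

    values = np.empty((len(df), len(columns)), dtype=float)
    for j, name in enumerate(columns):
        col = pd.to_numeric(df[name], errors="coerce")
        bad = col.isna() & df[name].notna()
        if bad.any():
            i = int(np.nonzero(bad.to_numpy())[0][0])
            raise DataError(
                f"non-numeric feature cell at row {i} "
                f"(subject {records[i].subject_id!r}), column {name!r}"
            )
        values[:, j] = col.to_numpy()

    if np.isnan(values).any():
        if impute:
            med = np.nanmedian(values, axis=0)
            idx = np.nonzero(np.isnan(values))
            values[idx] = np.take(med, idx[1])
            logger.info("imputed %d missing cells with per-feature medians", len(idx[0]))
        else:
            i, j = (int(a[0]) for a in np.nonzero(np.isnan(values)))
            raise DataError(
                f"missing value for subject {records[i].subject_id!r}, "
                f"column {columns[j]!r} (imputation disabled)"
            )

    order = canonical_feature_order(descriptors)
    return FeatureTable(
        subjects=records,
        features=[descriptors[i] for i in order],
        values=values[:, order],
    )


def write_feature_table(table: FeatureTable, path: str | Path, sep: str = ",") -> None:
    """Write the dialect :func:`read_feature_table` reads."""
    table.to_frame().to_csv(path, sep=sep, index=False)


def read_aparc_tables(
    area_path: str | Path,
    thickness_path: str | Path,
    volume_path: str | Path,
    metadata: Sequence[SubjectRecord],
    drop_aggregates: bool = True,
) -> FeatureTable:
    """Merge per-measure ``aparcstats2table`` TSVs into one FeatureTable.

    The three tables must cover the same subjects (any row order; rows are
    joined on the first column, the subject ID).  FreeSurfer aggregate
    columns (eTIV, MeanThickness, WhiteSurfArea, ...) are dropped by
    default.  Region labels outside the Desikan-Killiany atlas are kept
    with a warning, so other parcellations still load.
    """
    paths = {"area": Path(area_path), "thickness": Path(thickness_path), "volume": Path(volume_path)}
    frames: dict[str, pd.DataFrame] = {}
    for measure, p in paths.items():
        df = pd.read_csv(p, sep="\t")
        df = df.rename(columns={df.columns[0]: "subject_id"})
        df["subject_id"] = df["subject_id"].astype(str)
        frames[measure] = df.set_index("subject_id")

    id_sets = {m: set(f.index) for m, f in frames.items()}
    common = set.intersection(*id_sets.values())
    for measure, ids in id_sets.items():
        extra_missing = set.union(*(o for m, o in id_sets.items() if m != measure)) - ids
        if extra_missing:
            raise DataError(
                f"{measure} table is missing subjects {sorted(extra_missing)}"
            )

    by_id = {r.subject_id: r for r in metadata}
    missing_meta = common - set(by_id)
    if missing_meta:
        raise DataError(f"no metadata for subjects {sorted(missing_meta)}")
    # keep the area-table row order for determinism
    subject_order = [s for s in frames["area"].index if s in common]
    records = [by_id[s] for s in subject_order]

    descriptors: list[FeatureDescriptor] = []
    blocks: list[np.ndarray] = []
    from .datamodel import DESIKAN_KILLIANY_REGIONS

    for measure, df in frames.items():
        for name in df.columns:
            if drop_aggregates and any(marker in name for marker in AGGREGATE_COLUMN_MARKERS):
                continue
            desc = parse_feature_column(name)
            if desc is None or desc.measure != measure:
                logger.info("ignoring column %r in %s table", name, measure)
                continue
            if desc.region_name not in DESIKAN_KILLIANY_REGIONS:
                logger.warning("unknown region label %r; retaining", desc.region_name)
            descriptors.append(desc)
            col = pd.to_numeric(df.loc[subject_order, name], errors="coerce").to_numpy()
            blocks.append(col)

    values = np.column_stack(blocks)
    order = canonical_feature_order(descriptors)
    return FeatureTable(
        subjects=records,
        features=[descriptors[i] for i in order],
        values=values[:, order],
    )


def split_by(table: FeatureTable, key: str) -> dict[str, FeatureTable]:
    """Partition a table by ``site`` or ``group``; row order preserved."""
    if key not in ("site", "group"):
        raise ConfigurationError("key must be 'site' or 'group'")
    attr = "site_id" if key == "site" else "group"
    out: dict[str, FeatureTable] = {}
    labels = [getattr(s, attr) for s in table.subjects]
    for label in dict.fromkeys(labels):  # first-appearance order
        rows = [i for i, l in enumerate(labels) if l == label]
        out[label] = table.take(rows)
    return out


@dataclass
class Standardization:
    """Per-feature affine transform record; allows exact inversion."""

    feature_names: list[str]
    mean: np.ndarray
    scale: np.ndarray
    dropped: list[str] = field(default_factory=list)

    def invert(self, table: FeatureTable) -> FeatureTable:
        if table.feature_names != self.feature_names:
            raise DataError("feature set does not match the standardization record")
        return table.with_values(table.values * self.scale + self.mean)


def standardize(
    table: FeatureTable,
    reference: FeatureTable | str = "self",
    on_zero_variance: str = "error",
) -> tuple[FeatureTable, Standardization]:
    """Center/scale each feature to reference mean 0 and SD 1.

    ``reference`` may be another table (e.g. pooled healthy controls) whose
    per-feature statistics define the transform, or ``"self"``.
    ``on_zero_variance``: ``"error"`` (default) or ``"drop"`` (remove the
    constant feature and log it).
    """
    ref = table if reference == "self" else reference
    if ref.feature_names != table.feature_names:
        raise DataError("reference features do not match the table")
    mean = ref.values.mean(axis=0)
    scale = ref.values.std(axis=0, ddof=0)
    zero = scale == 0.0
    if zero.any():
        names = [table.features[j].column_name for j in np.nonzero(zero)[0]]
        if on_zero_variance == "drop":
            logger.warning("dropping zero-variance features: %s", names)
            keep = np.nonzero(~zero)[0]
            sub = table.select_features(keep)
            record = Standardization(
                feature_names=sub.feature_names,
                mean=mean[keep],
                scale=scale[keep],
                dropped=names,
            )
            out = sub.with_values((sub.values - mean[keep]) / scale[keep])
            return out, record
        raise DataError(f"zero-variance features: {names}")
    record = Standardization(feature_names=table.feature_names, mean=mean, scale=scale)
    return table.with_values((table.values - mean) / scale), record
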