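"""Core data model: subject-by-feature morphometry tables.

A :class:`FeatureTable` holds an ``n_subjects x n_features`` matrix of
cortical morphometric measurements (surface area in mm^2, cortical
thickness in mm, gray-matter volume in mm^3 per atlas region and
hemisphere) together with per-subject metadata (site, diagnostic group,
age, sex).  The full Desikan-Killiany table has 204 feature columns:
34 regions x 2 hemispheres x 3 measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HEMISPHERES = ("left", "right")
MEASURES = ("area", "thickness", "volume")
GROUPS = ("HC", "EM", "CM")

#: measure -> physical units; the mapping is bijective.
MEASURE_UNITS: Mapping[str, str] = {"area": "mm2", "thickness": "mm", "volume": "mm3"}

#: Desikan-Killiany cortical parcellation labels (34 per hemisphere).
DESIKAN_KILLIANY_REGIONS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
)


class DataError(ValueError):
    """Raised when input data violate the table contract."""


class ConfigurationError(ValueError):
    """Raised when a reader/operation is configured inconsistently."""


@dataclass(frozen=True)
class FeatureDescriptor:
    """One feature column: an (atlas region, hemisphere, measure) triple."""

    region_name: str
    hemisphere: str
    measure: str

    def __post_init__(self) -> None:
        if self.hemisphere not in HEMISPHERES:
            raise ConfigurationError(
                f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}"
            )
        if self.measure not in MEASURES:
            raise ConfigurationError(
                f"measure must be one of {MEASURES}, got {self.measure!r}"
            )

    @property
    def units(self) -> str:
        return MEASURE_UNITS[self.measure]

    @property
    def column_name(self) -> str:
        """FreeSurfer-style column name, e.g. ``lh_bankssts_area``."""
        hemi = "lh" if self.hemisphere == "left" else "rh"
        return f"{hemi}_{self.region_name}_{self.measure}"


@dataclass(frozen=True)
class SubjectRecord:
    """Per-subject metadata attached to a table row."""

    subject_id: str
    site_id: str
    group: str
    age: float | None = None
    sex: str | None = None
    headache_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DataError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.age is not None and not self.age > 0:
            raise DataError(f"age must be positive, got {self.age}")
        if self.sex is not None and self.sex not in ("F", "M"):
            raise DataError(f"sex must be 'F' or 'M', got {self.sex!r}")


def canonical_feature_order(features: Sequence[FeatureDescriptor]) -> list[int]:
    """Indices sorting features by (hemisphere, region, measure)."""
    return sorted(
        range(len(features)),
        key=lambda i: (features[i].hemisphere, features[i].region_name, features[i].measure),
    )


def default_desikan_features() -> list[FeatureDescriptor]:
    """All 204 Desikan-Killiany features in canonical order."""
    feats = [
        FeatureDescriptor(region, hemi, measure)
        for hemi in HEMISPHERES
        for region in DESIKAN_KILLIANY_REGIONS
        for measure in MEASURES
    ]
    order = canonical_feature_order(feats)
    return [feats[i] for i in order]


@dataclass
class FeatureTable:
    """Ordered subjects, ordered feature descriptors, and a value matrix.

    Rows are subjects, columns are features.  The matrix must be complete
    (no NaN) and dimensions must match the metadata lists.
    """

    subjects: list[SubjectRecord]
    features: list[FeatureDescriptor]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be a 2-D matrix")
        if self.values.shape != (len(self.subjects), len(self.features)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.subjects)} subjects x {len(self.features)} features"
            )
        if np.isnan(self.values).any():
            rows, cols = np.nonzero(np.isnan(self.values))
            sid = self.subjects[rows[0]].subject_id
            col = self.features[cols[0]].column_name
            raise DataError(f"missing value at subject {sid!r}, feature {col!r}")
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise DataError(f"duplicate subject_id {dup!r}")
        triples = [(f.region_name, f.hemisphere, f.measure) for f in self.features]
        if len(set(triples)) != len(triples):
            raise DataError("duplicate (region, hemisphere, measure) feature")

    # -- basic views -------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]

    @property
    def feature_names(self) -> list[str]:
        return [f.column_name for f in self.features]

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "site": [s.site_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
                "headache_frequency": [s.headache_frequency for s in self.subjects],
            }
        )

    def to_frame(self) -> pd.DataFrame:
        """Metadata columns followed by feature columns, one row per subject."""
        meta = self.metadata_frame()
        feats = pd.DataFrame(self.values, columns=self.feature_names)
        return pd.concat([meta.reset_index(drop=True), feats], axis=1)

    # -- selection ---------------------------------------------------------

    def take(self, rows: Iterable[int]) -> "FeatureTable":
        """New table containing the given rows, in the given order."""
        rows = list(rows)
        return FeatureTable(
            subjects=[self.subjects[i] for i in rows],
            features=list(self.features),
            values=self.values[rows, :],
        )

    def select_subjects(self, subject_ids: Iterable[str]) -> "FeatureTable":
        """Rows for the given subject IDs, preserving table row order."""
        wanted = set(subject_ids)
        missing = wanted - set(self.subject_ids)
        if missing:
            raise DataError(f"unknown subject IDs: {sorted(missing)}")
        return self.take(i for i, s in enumerate(self.subjects) if s.subject_id in wanted)

    def select_features(self, cols: Iterable[int]) -> "FeatureTable":
        cols = list(cols)
        return FeatureTable(
            subjects=list(self.subjects),
            features=[self.features[j] for j in cols],
            values=self.values[:, cols],
        )

    def measure_columns(self, measure: str) -> list[int]:
        """Column indices belonging to one measure family (area/thickness/volume)."""
        if measure not in MEASURES:
            raise ConfigurationError(f"unknown measure {measure!r}")
        return [j for j, f in enumerate(self.features) if f.measure == measure]

    def with_values(self, values: np.ndarray) -> "FeatureTable":
        return FeatureTable(list(self.subjects), list(self.features), values)


def concat_tables(tables: Sequence[FeatureTable]) -> FeatureTable:
    """Stack tables sharing an identical feature list."""
    if not tables:
        raise DataError("cannot concatenate zero tables")
    ref = tables[0].features
    for t in tables[1:]:
        if t.features != ref:
            raise DataError("tables have differing feature lists")
    return FeatureTable(
        subjects=[s for t in tables for s in t.subjects],
        features=list(ref),
        values=np.vstack([t.values for t in tables]),
    )
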