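"""Synthetic two-site morphometry studies with planted structure.

The generator emulates the situation the method targets: two imaging
sites whose feature distributions differ by a broad, weak mean shift
(scanner/protocol effect), disease groups (episodic and chronic migraine)
with mean effects on a subset of features, and a healthy-control pool in
which only a fraction ``core_fraction`` of subjects per site is drawn
from a shared "core" distribution — the remaining HCs carry an additional
site-specific off-core shift.  Every planted quantity is recorded in a
truth table so downstream selection can be scored against ground truth.

Features are multivariate Gaussian: baseline + site shift + group effect
(+ off-core shift for non-core HCs) + low-rank correlated noise.  The
low-rank factor structure models the strong inter-regional correlation of
cortical morphometrics while keeping generation O(n * D).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    ConfigurationError,
    FeatureDescriptor,
    FeatureTable,
    SubjectRecord,
    default_desikan_features,
)
from .io import write_feature_table

#: per-measure baseline mean and SD (units of the measure).  SDs are set so
#: that the average |mean difference| between disjoint 21-subject subsets of
#: one site falls in the observed range for FreeSurfer regional measures
#: (tens of mm^2 for area, ~0.04 mm for thickness, hundreds of mm^3 for
#: volume); see calibrate_to_paper_scales for the closed-form mapping.
DEFAULT_BASELINE_MEAN = {"area": 2500.0, "thickness": 2.5, "volume": 7000.0}
DEFAULT_BASELINE_SD = {"area": 326.0, "thickness": 0.177, "volume": 1038.0}

DEFAULT_GROUP_SIZES: Mapping[str, Mapping[str, int]] = {
    "DS1": {"HC": 54, "EM": 51, "CM": 15},
    "DS2": {"HC": 42, "EM": 8, "CM": 26},
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the two-site generator.

    Magnitudes expressed "in SD units" are multiplied by the per-feature
    baseline SD, so a shift of 1.0 moves a feature by one marginal SD.
    """

    n_features: int = 204
    baseline_mean: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE_MEAN))
    baseline_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINE_SD))
    #: per-measure SD of the random per-feature site mean shift (SD units);
    #: a scalar applies to every measure.
    site_shift_sd: float | Mapping[str, float] = 0.1
    #: fraction of features carrying a site shift (1.0 = broad weak shift).
    site_shift_sparsity: float = 1.0
    disease_effect_em: float = 0.35
    disease_effect_cm: float = 0.5
    #: fraction of features affected by disease.
    affected_fraction: float = 0.3
    #: fraction of each site's HCs drawn from the shared core distribution.
    core_fraction: float = 0.5
    #: mean offset of non-core HCs, SD units, site-specific random direction.
    offcore_shift: float = 2.0
    #: fraction of the chronic-disease effect vector added to the off-core
    #: shift: heterogeneous HCs partially resemble patients (latent,
    #: not-yet-manifest disease), which is what makes HC heterogeneity
    #: harmful to cross-site classification.
    offcore_disease_overlap: float = 0.7
    n_factors: int = 10
    #: fraction of marginal variance carried by shared low-rank factors.
    factor_strength: float = 0.5
    group_sizes: Mapping[str, Mapping[str, int]] = field(
        default_factory=lambda: {s: dict(g) for s, g in DEFAULT_GROUP_SIZES.items()}
    )
    #: per-site probability that a subject is female.
    sex_balance: Mapping[str, float] = field(default_factory=lambda: {"DS1": 0.72, "DS2": 0.45})
    age_mean: Mapping[str, float] = field(default_factory=lambda: {"DS1": 33.0, "DS2": 36.0})
    age_sd: float = 11.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ConfigurationError("core_fraction must be in [0, 1]")
        if len(self.group_sizes) != 2:
            raise ConfigurationError("exactly two sites are required")
        for site, groups in self.group_sizes.items():
            for g, n in groups.items():
                if n < 0:
                    raise ConfigurationError(f"negative group size {site}/{g}")
        if self.disease_effect_cm < self.disease_effect_em:
            raise ConfigurationError(
                "chronic-migraine effect must be >= episodic effect "
                "(CM is the more severe state)"
            )
        if self.core_fraction < 1.0:
            for site, groups in self.group_sizes.items():
                if groups.get("HC", 0) == 0:
                    raise ConfigurationError(
                        f"core_fraction < 1 requires HC subjects at site {site}"
                    )
        if not 0.0 <= self.site_shift_sparsity <= 1.0:
            raise ConfigurationError("site_shift_sparsity must be in [0, 1]")
        if not 0.0 <= self.factor_strength < 1.0:
            raise ConfigurationError("factor_strength must be in [0, 1)")


@dataclass
class SyntheticStudy:
    """Generated tables plus the planted ground truth."""

    tables: dict[str, FeatureTable]
    #: one row per subject: subject_id, site, group, is_core_hc
    truth: pd.DataFrame
    #: realized planted vectors, length n_features each
    site_shift_vector: np.ndarray
    em_effect_vector: np.ndarray
    cm_effect_vector: np.ndarray
    offcore_vectors: dict[str, np.ndarray]
    affected_features: np.ndarray
    config: SyntheticConfig

    @property
    def sites(self) -> list[str]:
        return list(self.tables)

    def core_subject_ids(self) -> set[str]:
        t = self.truth
        return set(t.loc[t["is_core_hc"], "subject_id"])

    def write(self, directory: str | Path) -> None:
        """One CSV per site (datamodel_io dialect) plus a truth sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for site, table in self.tables.items():
            write_feature_table(table, directory / f"{site}.csv")
        self.truth.to_csv(directory / "truth.csv", index=False)


def _feature_descriptors(n_features: int) -> list[FeatureDescriptor]:
    full = default_desikan_features()
    if n_features > len(full):
        raise ConfigurationError(f"n_features may not exceed {len(full)}")
    if n_features == len(full):
        return full
    # keep a units-balanced subset: take whole regions in canonical order
    return full[:n_features]


def _per_measure(value: float | Mapping[str, float], measure: str) -> float:
    if isinstance(value, Mapping):
        return float(value[measure])
    return float(value)


def generate_two_site_study(config: SyntheticConfig) -> SyntheticStudy:
    """Draw a deterministic two-site study from the planted model."""
    config.validate()
    rng_structure = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))

    features = _feature_descriptors(config.n_features)
    D = len(features)
    mean = np.array([config.baseline_mean[f.measure] for f in features])
    sd = np.array([config.baseline_sd[f.measure] for f in features])

    # shared low-rank loadings: fraction factor_strength of each marginal
    # variance lives in n_factors shared directions
    k = config.n_factors
    if k > 0 and config.factor_strength > 0:
        raw = rng_structure.standard_normal((D, k))
        raw /= np.linalg.norm(raw, axis=1, keepdims=True)
        loadings = raw * (sd * np.sqrt(config.factor_strength))[:, None]
    else:
        loadings = np.zeros((D, max(k, 1)))
    resid_sd = sd * np.sqrt(1.0 - config.factor_strength)

    # planted site shift: random per-feature magnitude and direction
    shift_scale = np.array([_per_measure(config.site_shift_sd, f.measure) for f in features])
    site_shift = rng_structure.standard_normal(D) * shift_scale * sd
    if config.site_shift_sparsity < 1.0:
        n_shifted = int(round(config.site_shift_sparsity * D))
        keep = rng_structure.choice(D, size=n_shifted, replace=False)
        mask = np.zeros(D, dtype=bool)
        mask[keep] = True
        site_shift = np.where(mask, site_shift, 0.0)

    n_aff = int(round(config.affected_fraction * D))
    affected = np.sort(rng_structure.choice(D, size=n_aff, replace=False))
    direction = np.zeros(D)
    direction[affected] = rng_structure.choice([-1.0, 1.0], size=n_aff)
    em_effect = direction * config.disease_effect_em * sd
    cm_effect = direction * config.disease_effect_cm * sd

    sites = list(config.group_sizes)
    # off-core shift: site-specific random direction with per-feature RMS
    # magnitude of offcore_shift SD units — same per-feature convention as
    # the site shift and disease effects
    offcore_vectors = {}
    for site in sites:
        u = rng_structure.standard_normal(D)
        u /= np.sqrt(np.mean(u**2))  # RMS-normalize per feature
        offcore_vectors[site] = (
            u * config.offcore_shift * sd
            + config.offcore_disease_overlap * cm_effect
        )

    tables: dict[str, FeatureTable] = {}
    truth_rows: list[dict] = []
    for s_idx, site in enumerate(sites):
        groups = config.group_sizes[site]
        records: list[SubjectRecord] = []
        rows: list[np.ndarray] = []
        for g_idx, (group, n) in enumerate(groups.items()):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 1 + s_idx, g_idx])
            )
            if n == 0:
                continue
            base = mean.copy()
            if s_idx == 1:
                base = base + site_shift
            if group == "EM":
                base = base + em_effect
            elif group == "CM":
                base = base + cm_effect

            is_core = np.zeros(n, dtype=bool)
            if group == "HC":
                n_core = int(round(config.core_fraction * n))
                core_idx = rng.choice(n, size=n_core, replace=False)
                is_core[core_idx] = True

            factors = rng.standard_normal((n, loadings.shape[1]))
            noise = rng.standard_normal((n, D)) * resid_sd
            X = base + factors @ loadings.T + noise
            offcore_rows = (~is_core) if group == "HC" else np.zeros(n, dtype=bool)
            X[offcore_rows] += offcore_vectors[site]

            sexes = np.where(
                rng.random(n) < config.sex_balance.get(site, 0.5), "F", "M"
            )
            ages = np.clip(
                rng.normal(config.age_mean.get(site, 35.0), config.age_sd, n), 18, 65
            )
            for i in range(n):
                sid = f"{site}_{group}_{i:03d}"
                records.append(
                    SubjectRecord(
                        subject_id=sid,
                        site_id=site,
                        group=group,
                        age=float(round(ages[i], 1)),
                        sex=str(sexes[i]),
                    )
                )
                truth_rows.append(
                    {
                        "subject_id": sid,
                        "site": site,
                        "group": group,
                        "is_core_hc": bool(is_core[i]) if group == "HC" else False,
                    }
                )
            rows.append(X)
        tables[site] = FeatureTable(
            subjects=records, features=list(features), values=np.vstack(rows)
        )

    return SyntheticStudy(
        tables=tables,
        truth=pd.DataFrame(truth_rows),
        site_shift_vector=site_shift,
        em_effect_vector=em_effect,
        cm_effect_vector=cm_effect,
        offcore_vectors=offcore_vectors,
        affected_features=affected,
        config=config,
    )


def calibrate_to_paper_scales(
    config: SyntheticConfig | None = None,
    within: Mapping[str, float] | None = None,
    cross: Mapping[str, float] | None = None,
    n_sub: int = 21,
) -> SyntheticConfig:
    """Preset whose 21-vs-21 average |mean difference| statistics land on
    realistic multi-site scales.

    For disjoint subsets of size ``n_sub`` from one Gaussian site, the
    per-feature mean difference is N(0, 2*sigma^2/n_sub), so the expected
    absolute difference is ``w = sqrt(4*sigma^2/(pi*n_sub))``; inverting
    gives the per-measure sigma.  Across sites an additional random shift
    with per-feature SD ``s`` inflates it to ``c = sqrt(2*(2*sigma^2/n_sub
    + s^2)/pi)``, giving ``s = sqrt(pi*(c^2 - w^2)/2)``.  Defaults for
    ``within``/``cross`` are typical FreeSurfer regional scales (tens of
    mm^2 area, ~0.04 mm thickness, hundreds of mm^3 volume within site,
    with a clearly larger cross-site value).  This is a convenience preset
    for realistic magnitudes, not a fitted model.
    """
    if config is None:
        config = SyntheticConfig()
    within = dict(within or {"area": 80.24, "thickness": 0.0437, "volume": 255.61})
    cross = dict(cross or {"area": 102.27, "thickness": 0.0481, "volume": 275.58})
    baseline_sd = {}
    shift_sd = {}
    for measure, w in within.items():
        sigma = w * np.sqrt(np.pi * n_sub) / 2.0
        c = cross[measure]
        if c < w:
            raise ConfigurationError("cross-site value must be >= within-site value")
        s_abs = np.sqrt(np.pi * (c**2 - w**2) / 2.0)
        baseline_sd[measure] = float(sigma)
        shift_sd[measure] = float(s_abs / sigma)
    return replace(config, baseline_sd=baseline_sd, site_shift_sd=shift_sd)
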