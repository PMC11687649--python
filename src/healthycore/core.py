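"""Healthy-core selection: distribution-matched HC subsets across sites.

Even stringently screened healthy-control cohorts are heterogeneous, and
two sites' HC pools differ by scanner, protocol and population effects.
The healthy core is the subset of HCs, drawn from both sites, whose
site-wise feature distributions are statistically indistinguishable
under MMD evaluated in GFK space.  The reference algorithm is greedy
backward elimination: starting from the full pools, repeatedly remove
the single subject (from either site) whose removal most lowers the
cross-site MMD^2, until a stopping rule fires — a target core size, a
permutation p-value exceeding a level alpha, or an MMD^2 threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .datamodel import ConfigurationError, DataError, FeatureTable
from .gfk import choose_subspace_dim, gfk_matrix, pca_subspace
from .mmd import KernelSpec, mmd2_from_gram

STOP_RULES = ("target_size", "mmd_pvalue", "mmd_threshold")


@dataclass
class CoreConfig:
    """Configuration of the greedy core search."""

    kernel: KernelSpec | None = None  # None: build linear GFK from the HC pools
    estimator: str = "unbiased"
    strategy: str = "greedy_backward"
    stop_rule: str = "mmd_pvalue"
    target_size: int | None = None  # total retained, both sites, for target_size
    alpha: float = 0.10  # for mmd_pvalue
    tau: float | None = None  # for mmd_threshold
    n_permutations: int = 500
    min_core_per_site: int = 2
    refit_gfk_every: int | str = "never"
    #: z-score features with pooled-HC statistics before subspace fitting
    standardize: bool = True
    subspace_dim: int | None = None  # None: smallest d explaining var_target
    var_target: float = 0.9
    seed: int = 0

    def validate(self, total_pool: int) -> None:
        if self.strategy not in ("greedy_backward", "greedy_forward"):
            raise ConfigurationError(f"unknown strategy {self.strategy!r}")
        if self.stop_rule not in STOP_RULES:
            raise ConfigurationError(f"unknown stop_rule {self.stop_rule!r}")
        if self.min_core_per_site < 2:
            raise ConfigurationError("min_core_per_site must be >= 2")
        if self.stop_rule == "target_size":
            if self.target_size is None:
                raise ConfigurationError("target_size stop rule needs target_size")
            if not 2 * self.min_core_per_site <= self.target_size <= total_pool:
                raise ConfigurationError(
                    f"target_size {self.target_size} outside "
                    f"[{2 * self.min_core_per_site}, {total_pool}]"
                )
        if self.stop_rule == "mmd_threshold" and self.tau is None:
            raise ConfigurationError("mmd_threshold stop rule needs tau")


@dataclass
class CoreSelection:
    """Result of a core search: retained IDs, trajectory, diagnostics."""

    retained: dict[str, list[str]]
    removed_order: list[tuple[str, float]]
    initial_mmd2: float
    final_mmd2: float
    final_p: float | None
    iterations: int
    stop_rule: str
    stopped_early: bool = False  # stop rule unreachable before min_core_per_site
    #: (total retained pool size, mmd2) at each accepted state, starting full
    trajectory: list[tuple[int, float]] = field(default_factory=list)
    #: per-site pool sizes at the start of the search
    initial_pool: dict[str, int] = field(default_factory=dict)

    @property
    def core_size(self) -> int:
        return sum(len(v) for v in self.retained.values())

    def core_ids(self) -> set[str]:
        return {sid for ids in self.retained.values() for sid in ids}

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "retained": self.retained,
            "removed_order": self.removed_order,
            "initial_mmd2": self.initial_mmd2,
            "final_mmd2": self.final_mmd2,
            "final_p": self.final_p,
            "iterations": self.iterations,
            "stop_rule": self.stop_rule,
            "stopped_early": self.stopped_early,
            "trajectory": self.trajectory,
            "initial_pool": self.initial_pool,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "CoreSelection":
        d = json.loads(text)
        return cls(
            retained=d["retained"],
            removed_order=[tuple(t) for t in d["removed_order"]],
            initial_mmd2=d["initial_mmd2"],
            final_mmd2=d["final_mmd2"],
            final_p=d["final_p"],
            iterations=d["iterations"],
            stop_rule=d["stop_rule"],
            stopped_early=d["stopped_early"],
            trajectory=[tuple(t) for t in d["trajectory"]],
            initial_pool=d.get("initial_pool", {}),
        )


def _check_hc_only(table: FeatureTable, name: str) -> None:
    bad = [s.subject_id for s in table.subjects if s.group != "HC"]
    if bad:
        raise DataError(f"{name} contains non-HC subjects: {bad[:5]}")


def build_hc_kernel(
    hc_A: FeatureTable, hc_B: FeatureTable, config: CoreConfig
) -> tuple[KernelSpec, np.ndarray, np.ndarray]:
    """Linear GFK kernel spec from the two HC pools, plus the (optionally
    pooled-standardized) data matrices used for the search."""
    XA, XB = hc_A.values, hc_B.values
    if config.standardize:
        pooled = np.vstack([XA, XB])
        mu, sd = pooled.mean(axis=0), pooled.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise DataError("zero-variance feature in the pooled HC data")
        XA, XB = (XA - mu) / sd, (XB - mu) / sd
    if config.kernel is not None:
        return config.kernel, XA, XB
    D = XA.shape[1]
    d_cap = min(XA.shape[0] - 1, XB.shape[0] - 1, max(D // 2, 1))
    probe = pca_subspace(XA, d=d_cap, label="site_A")
    d = config.subspace_dim or choose_subspace_dim(
        probe.explained_variance, XA.shape[0], XB.shape[0], D, config.var_target
    )
    sub_A = pca_subspace(XA, d=d, label="site_A")
    sub_B = pca_subspace(XB, d=d, label="site_B")
    kernel = gfk_matrix(sub_A, sub_B)
    return KernelSpec(family="linear_gfk", gfk=kernel), XA, XB


def _permutation_p(
    K: np.ndarray, m: int, estimator: str, n_permutations: int, rng: np.random.Generator
) -> float:
    observed = mmd2_from_gram(K, m, estimator)
    N = K.shape[0]
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(N)
        if mmd2_from_gram(K[np.ix_(perm, perm)], m, estimator) >= observed:
            count += 1
    return (1 + count) / (1 + n_permutations)


class _GreedyState:
    """Incremental MMD^2 bookkeeping over a fixed pooled Gram matrix."""

    def __init__(self, K: np.ndarray, mask_A: np.ndarray, mask_B: np.ndarray):
        self.K = K
        self.mask_A = mask_A.copy()
        self.mask_B = mask_B.copy()
        self.r_toA = K[:, self.mask_A].sum(axis=1)
        self.r_toB = K[:, self.mask_B].sum(axis=1)
        diag = np.diag(K)
        self.Sxx = self.r_toA[self.mask_A].sum()
        self.Syy = self.r_toB[self.mask_B].sum()
        self.Sxy = self.r_toB[self.mask_A].sum()
        self.diagX = diag[self.mask_A].sum()
        self.diagY = diag[self.mask_B].sum()

    @property
    def m(self) -> int:
        return int(self.mask_A.sum())

    @property
    def n(self) -> int:
        return int(self.mask_B.sum())

    def current(self, estimator: str) -> float:
        m, n = self.m, self.n
        if estimator == "biased":
            return self.Sxx / m**2 + self.Syy / n**2 - 2 * self.Sxy / (m * n)
        return (
            (self.Sxx - self.diagX) / (m * (m - 1))
            + (self.Syy - self.diagY) / (n * (n - 1))
            - 2 * self.Sxy / (m * n)
        )

    def candidate_values(self, site: str, estimator: str) -> tuple[np.ndarray, np.ndarray]:
        """(candidate pool indices, mmd2 after removing each) for one site."""
        K, diag = self.K, np.diag(self.K)
        if site == "A":
            idx = np.nonzero(self.mask_A)[0]
            m, n = self.m - 1, self.n
            Sxx = self.Sxx - 2 * self.r_toA[idx] + diag[idx]
            dX = self.diagX - diag[idx]
            Sxy = self.Sxy - self.r_toB[idx]
            Syy, dY = self.Syy, self.diagY
        else:
            idx = np.nonzero(self.mask_B)[0]
            m, n = self.m, self.n - 1
            Syy = self.Syy - 2 * self.r_toB[idx] + diag[idx]
            dY = self.diagY - diag[idx]
            Sxy = self.Sxy - self.r_toA[idx]
            Sxx, dX = self.Sxx, self.diagX
        if estimator == "biased":
            vals = Sxx / m**2 + Syy / n**2 - 2 * Sxy / (m * n)
        else:
            vals = (
                (Sxx - dX) / (m * (m - 1))
                + (Syy - dY) / (n * (n - 1))
                - 2 * Sxy / (m * n)
            )
        return idx, vals

    def remove(self, pool_index: int, site: str) -> None:
        col = self.K[:, pool_index]
        diag_val = self.K[pool_index, pool_index]
        if site == "A":
            self.Sxx += -2 * self.r_toA[pool_index] + diag_val
            self.Sxy -= self.r_toB[pool_index]
            self.diagX -= diag_val
            self.mask_A[pool_index] = False
            self.r_toA -= col
        else:
            self.Syy += -2 * self.r_toB[pool_index] + diag_val
            self.Sxy -= self.r_toA[pool_index]
            self.diagY -= diag_val
            self.mask_B[pool_index] = False
            self.r_toB -= col

    def active_gram(self) -> tuple[np.ndarray, int]:
        keep = np.nonzero(self.mask_A | self.mask_B)[0]
        # order: A rows first, then B rows
        a = np.nonzero(self.mask_A)[0]
        b = np.nonzero(self.mask_B)[0]
        order = np.concatenate([a, b])
        del keep
        return self.K[np.ix_(order, order)], len(a)


def select_healthy_core(
    hc_A: FeatureTable, hc_B: FeatureTable, config: CoreConfig
) -> CoreSelection:
    """Greedy search for the healthy core across two HC pools.

    Deterministic given ``config`` (the seed only drives permutation
    tests and tie-breaking).  Returns the full removal trajectory so the
    stopping behaviour can be audited.
    """
    _check_hc_only(hc_A, "hc_A")
    _check_hc_only(hc_B, "hc_B")
    total = hc_A.n_subjects + hc_B.n_subjects
    config.validate(total)
    for t, name in ((hc_A, "hc_A"), (hc_B, "hc_B")):
        if t.n_subjects < config.min_core_per_site + 1:
            raise DataError(f"{name} needs at least min_core_per_site + 1 subjects")

    if config.strategy == "greedy_forward":
        return _select_forward(hc_A, hc_B, config)

    spec, XA, XB = build_hc_kernel(hc_A, hc_B, config)
    site_A = hc_A.subjects[0].site_id
    site_B = hc_B.subjects[0].site_id
    ids = hc_A.subject_ids + hc_B.subject_ids
    mA = len(XA)

    from .mmd import _pooled_gram

    K = _pooled_gram(XA, XB, spec)
    mask_A = np.zeros(total, dtype=bool)
    mask_A[:mA] = True
    mask_B = ~mask_A
    state = _GreedyState(K, mask_A, mask_B)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    priority = rng.permutation(total)  # seeded shuffle for tie-breaking
    perm_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))

    removed_order: list[tuple[str, float]] = []
    current = state.current(config.estimator)
    initial = current
    trajectory: list[tuple[int, float]] = [(total, current)]
    final_p: float | None = None
    stopped_early = False

    while True:
        # stop-rule check on the current retained state
        if config.stop_rule == "target_size":
            if state.m + state.n <= config.target_size:
                break
        elif config.stop_rule == "mmd_threshold":
            if current <= config.tau:
                break
        else:  # mmd_pvalue
            Ksub, m_sub = state.active_gram()
            final_p = _permutation_p(
                Ksub, m_sub, config.estimator, config.n_permutations, perm_rng
            )
            if final_p > config.alpha:
                break

        can_A = state.m > config.min_core_per_site
        can_B = state.n > config.min_core_per_site
        if not can_A and not can_B:
            stopped_early = True
            break

        best_idx, best_val, best_site = -1, np.inf, ""
        for site, allowed in (("A", can_A), ("B", can_B)):
            if not allowed:
                continue
            idx, vals = state.candidate_values(site, config.estimator)
            order = np.lexsort((priority[idx], vals))
            cand = idx[order[0]]
            val = vals[order[0]]
            if (val, priority[cand]) < (best_val, priority[best_idx] if best_idx >= 0 else np.inf):
                best_idx, best_val, best_site = cand, val, site

        state.remove(best_idx, best_site)
        current = best_val
        removed_order.append((ids[best_idx], float(current)))
        trajectory.append((state.m + state.n, float(current)))

    retained = {
        site_A: [ids[i] for i in np.nonzero(state.mask_A)[0]],
        site_B: [ids[i] for i in np.nonzero(state.mask_B)[0]],
    }
    return CoreSelection(
        retained=retained,
        removed_order=removed_order,
        initial_mmd2=float(initial),
        final_mmd2=float(current),
        final_p=final_p,
        iterations=len(removed_order),
        stop_rule=config.stop_rule,
        stopped_early=stopped_early,
        trajectory=trajectory,
        initial_pool={site_A: mA, site_B: total - mA},
    )


def _select_forward(
    hc_A: FeatureTable, hc_B: FeatureTable, config: CoreConfig
) -> CoreSelection:
    """Greedy forward variant: grow the core from the best-matched seeds.

    Starts with the ``min_core_per_site`` best-matched subjects per site
    (greedily chosen to minimize biased MMD^2), then repeatedly adds the
    subject whose inclusion keeps MMD^2 lowest until the stop rule fires.
    """
    spec, XA, XB = build_hc_kernel(hc_A, hc_B, config)
    site_A = hc_A.subjects[0].site_id
    site_B = hc_B.subjects[0].site_id
    ids = hc_A.subject_ids + hc_B.subject_ids
    mA, nB = len(XA), len(XB)
    total = mA + nB

    from .mmd import _pooled_gram

    K = _pooled_gram(XA, XB, spec)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    priority = rng.permutation(total)
    perm_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 31]))

    in_A = np.zeros(total, dtype=bool)
    in_B = np.zeros(total, dtype=bool)

    def biased_value(a_idx: np.ndarray, b_idx: np.ndarray) -> float:
        Ka = K[np.ix_(a_idx, a_idx)]
        Kb = K[np.ix_(b_idx, b_idx)]
        Kab = K[np.ix_(a_idx, b_idx)]
        return float(Ka.mean() + Kb.mean() - 2 * Kab.mean())

    # seed the core with the best-matched subjects, alternating sites
    a_pool = list(range(mA))
    b_pool = list(range(mA, total))
    first_a, first_b, best = -1, -1, np.inf
    for a in a_pool:
        for b in b_pool:
            v = K[a, a] + K[b, b] - 2 * K[a, b]
            if (v, priority[a] + priority[b]) < (best, np.inf):
                if v < best:
                    first_a, first_b, best = a, b, v
    sel_a, sel_b = [first_a], [first_b]
    while len(sel_a) < config.min_core_per_site or len(sel_b) < config.min_core_per_site:
        side = "A" if len(sel_a) <= len(sel_b) else "B"
        pool = a_pool if side == "A" else b_pool
        chosen = pool if side == "A" else pool
        cands = [i for i in chosen if i not in (sel_a if side == "A" else sel_b)]
        vals = [
            biased_value(
                np.array(sel_a + ([c] if side == "A" else [])),
                np.array(sel_b + ([c] if side == "B" else [])),
            )
            for c in cands
        ]
        j = int(np.lexsort((priority[np.array(cands)], np.array(vals)))[0])
        (sel_a if side == "A" else sel_b).append(cands[j])
    in_A[np.array(sel_a)] = True
    in_B[np.array(sel_b)] = True

    added: list[tuple[str, float]] = []
    current = biased_value(np.nonzero(in_A)[0], np.nonzero(in_B)[0])
    trajectory: list[tuple[int, float]] = [(int(in_A.sum() + in_B.sum()), current)]
    final_p: float | None = None
    stopped_early = False

    def current_p() -> float:
        a = np.nonzero(in_A)[0]
        b = np.nonzero(in_B)[0]
        order = np.concatenate([a, b])
        return _permutation_p(
            K[np.ix_(order, order)], len(a), config.estimator,
            config.n_permutations, perm_rng,
        )

    while True:
        size = int(in_A.sum() + in_B.sum())
        if config.stop_rule == "target_size" and size >= config.target_size:
            break
        if size >= total:
            stopped_early = config.stop_rule != "target_size"
            break
        # best candidate addition from either site
        best_idx, best_val, best_site = -1, np.inf, ""
        a_now, b_now = np.nonzero(in_A)[0], np.nonzero(in_B)[0]
        for site, pool, mask in (("A", a_pool, in_A), ("B", b_pool, in_B)):
            cands = [i for i in pool if not mask[i]]
            if not cands:
                continue
            vals = [
                biased_value(
                    np.append(a_now, c) if site == "A" else a_now,
                    np.append(b_now, c) if site == "B" else b_now,
                )
                for c in cands
            ]
            j = int(np.lexsort((priority[np.array(cands)], np.array(vals)))[0])
            if vals[j] < best_val:
                best_idx, best_val, best_site = cands[j], vals[j], site
        if config.stop_rule == "mmd_threshold" and best_val > config.tau:
            break
        (in_A if best_site == "A" else in_B)[best_idx] = True
        current = best_val
        added.append((ids[best_idx], float(current)))
        trajectory.append((int(in_A.sum() + in_B.sum()), float(current)))
        if config.stop_rule == "mmd_pvalue":
            final_p = current_p()
            if final_p <= config.alpha:
                # adding heterogeneity made the sets distinguishable; back off
                (in_A if best_site == "A" else in_B)[best_idx] = False
                added.pop()
                trajectory.pop()
                break

    retained = {
        site_A: [ids[i] for i in np.nonzero(in_A)[0]],
        site_B: [ids[i] for i in np.nonzero(in_B)[0]],
    }
    return CoreSelection(
        retained=retained,
        removed_order=added,
        initial_mmd2=float(trajectory[0][1]),
        final_mmd2=float(current),
        final_p=final_p,
        iterations=len(added),
        stop_rule=config.stop_rule,
        stopped_early=stopped_early,
        trajectory=trajectory,
        initial_pool={site_A: mA, site_B: nB},
    )


def mmd_trajectory(selection: CoreSelection) -> list[tuple[int, float]]:
    """The (pool size, MMD^2) sequence recorded during the search."""
    return list(selection.trajectory)


@dataclass
class CoreQualityReport:
    """Diagnostics of a core selection, optionally scored against truth."""

    per_site_retention: dict[str, float]
    core_size: int
    initial_mmd2: float
    final_mmd2: float
    final_p: float | None
    precision: float | None = None
    recall: float | None = None
    f1: float | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "CoreQualityReport":
        return cls(**json.loads(text))


def core_quality_report(
    selection: CoreSelection,
    pool_sizes: Mapping[str, int] | None = None,
    truth: Mapping[str, bool] | None = None,
) -> CoreQualityReport:
    """Retention fractions, final MMD diagnostics and, when planted-core
    truth flags are supplied, precision/recall/F1 of core membership."""
    removed = {sid for sid, _ in selection.removed_order}
    if pool_sizes is None:
        if not selection.initial_pool:
            raise DataError("pool sizes unavailable; pass pool_sizes explicitly")
        pool_sizes = selection.initial_pool
    retention = {
        site: len(selection.retained[site]) / pool_sizes[site] for site in selection.retained
    }
    report = CoreQualityReport(
        per_site_retention=retention,
        core_size=selection.core_size,
        initial_mmd2=selection.initial_mmd2,
        final_mmd2=selection.final_mmd2,
        final_p=selection.final_p,
    )
    if truth is not None:
        all_ids = selection.core_ids() | removed
        unknown = all_ids - set(truth)
        if unknown:
            raise DataError(f"truth flags missing for subjects {sorted(unknown)[:5]}")
        selected = selection.core_ids()
        positives = {sid for sid in all_ids if truth[sid]}
        tp = len(selected & positives)
        report.precision = tp / len(selected) if selected else 0.0
        report.recall = tp / len(positives) if positives else 0.0
        denom = (report.precision or 0) + (report.recall or 0)
        report.f1 = 2 * report.precision * report.recall / denom if denom else 0.0
    return report
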