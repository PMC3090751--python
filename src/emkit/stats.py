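"""Sensor groups, regional/global measures, pointwise tests, factorial
repeated-measures ANOVA, permutation tests, spatiotemporal post-hoc
filtering, PCA and import transforms.

The ANOVA engine runs point-by-point over arbitrary trailing data axes
(sensors × time, sources × time, or a single ROI value) and handles up
to six crossed within-subject factors and up to three between-subject
factors.  Every within effect (and its interactions with between
effects) is tested against its own subject-interaction error term;
between effects are tested against subjects-within-groups.  Unbalanced
between groups are handled by unweighted (harmonic-mean) cell means.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .containers import SensorLayout

logger = logging.getLogger(__name__)

__all__ = [
    "SensorGroup",
    "Design",
    "StatMap",
    "AnovaResult",
    "mirror_group",
    "regional_summary",
    "global_measures",
    "global_dissimilarity",
    "pointwise_ttest",
    "rm_anova",
    "permutation_test",
    "sensor_adjacency",
    "posthoc_spatiotemporal_filter",
    "pca",
    "import_transform",
]


# ---------------------------------------------------------------------------
# Sensor groups and summary measures


@dataclass
class SensorGroup:
    name: str
    members: list[str]
    mirror_of: str | None = None
    is_midline: bool = False

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a sensor group cannot be empty")


def mirror_group(
    group: SensorGroup, layout: SensorLayout, tolerance_fraction: float = 0.1
) -> SensorGroup:
    """Mirror a sensor group across the sagittal (x = 0) plane.

    Each member position is reflected (left-right coordinate negated)
    and mapped to the nearest sensor.  A nearest distance above
    ``tolerance_fraction`` of the head radius is an error; a group that
    maps onto itself is returned flagged as midline.
    """
    radius = layout.head_radius
    mirrored = []
    for name in group.members:
        pos = layout.positions[layout.index(name)].copy()
        pos[0] = -pos[0]
        dists = np.linalg.norm(layout.positions - pos, axis=1)
        j = int(dists.argmin())
        if dists[j] > tolerance_fraction * radius:
            raise ValueError(
                f"no sensor within {tolerance_fraction:.0%} of head radius of the "
                f"mirror position of {name!r} (closest: {layout.names[j]!r} at "
                f"{dists[j]:.2f} cm)"
            )
        mirrored.append(layout.names[j])
    is_midline = set(mirrored) == set(group.members)
    if is_midline:
        warnings.warn(f"group {group.name!r} is its own mirror (midline group)")
    return SensorGroup(
        name=f"{group.name}_mirror",
        members=mirrored,
        mirror_of=group.name,
        is_midline=is_midline,
    )


def regional_summary(
    data: np.ndarray, group: SensorGroup, layout: SensorLayout, measure: str = "mean"
) -> np.ndarray:
    """Collapse the channel axis over a sensor group.

    ``measure``: ``mean``, ``rms`` (root of the mean square) or
    ``power`` (mean square, the regional power).  The channel axis is
    the second-to-last axis.
    """
    idx = [layout.index(n) for n in group.members]
    x = np.take(np.asarray(data, dtype=float), idx, axis=-2)
    if measure == "mean":
        return x.mean(axis=-2)
    if measure == "power":
        return (x**2).mean(axis=-2)
    if measure == "rms":
        return np.sqrt((x**2).mean(axis=-2))
    raise ValueError(f"unknown measure {measure!r}")


def global_measures(data: np.ndarray) -> dict[str, np.ndarray]:
    """Global power, RMS and mean over channels per time point."""
    data = np.asarray(data, dtype=float)
    gp = (data**2).mean(axis=-2)
    return {"global_power": gp, "global_rms": np.sqrt(gp), "global_mean": data.mean(axis=-2)}


def global_dissimilarity(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Scale-free topography difference of two average-referenced maps.

    Each map is average-referenced and scaled to unit RMS; the result is
    the RMS of their difference (0 for identical shapes, 2 for exactly
    inverted ones).
    """
    out = []
    for m in (map_a, map_b):
        m = np.asarray(m, dtype=float)
        m = m - m.mean()
        rms = np.sqrt((m**2).mean())
        if rms == 0:
            raise ValueError("cannot normalize a zero-RMS map")
        out.append(m / rms)
    return float(np.sqrt(((out[0] - out[1]) ** 2).mean()))


# ---------------------------------------------------------------------------
# Pointwise t tests


@dataclass
class StatMap:
    """Statistic map for one effect: values, dfs, p values, optional mask."""

    effect: str
    stat: np.ndarray
    df: tuple
    p: np.ndarray
    kind: str = "t"
    mask: np.ndarray | None = None
    degenerate: np.ndarray | None = None  # e.g. zero-variance points


def _t_to_p(t: np.ndarray, df: float) -> np.ndarray:
    return 2.0 * scipy.stats.t.sf(np.abs(t), df)


def pointwise_ttest(
    data_a: np.ndarray, data_b: np.ndarray, paired: bool = False
) -> StatMap:
    """t test at every point of subjects × (...) arrays.

    Zero-variance points (e.g. constant paired differences) are
    deterministic rather than NaN: nonzero effect → ``t = ±inf`` with
    ``p = 0`` and a degenerate flag; zero effect → ``t = 0, p = 1``.
    """
    a = np.asarray(data_a, dtype=float)
    b = np.asarray(data_b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise ValueError("paired test requires matched shapes")
        n = a.shape[0]
        if n < 2:
            raise ValueError("need at least 2 subjects")
        d = a - b
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=1)
        df = n - 1
        denom = sd / np.sqrt(n)
    else:
        na, nb = a.shape[0], b.shape[0]
        if na < 2 or nb < 2:
            raise ValueError("need at least 2 subjects per group")
        mean = a.mean(axis=0) - b.mean(axis=0)
        sp2 = (
            (na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)
        ) / (na + nb - 2)
        df = na + nb - 2
        denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    degenerate = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(degenerate, np.sign(mean) * np.inf, mean / np.where(degenerate, 1, denom))
    t = np.where(degenerate & (mean == 0), 0.0, t)
    p = np.where(np.isinf(t), 0.0, np.where(np.isnan(t), 1.0, _t_to_p(np.where(np.isfinite(t), t, 0), df)))
    p = np.where(degenerate & (mean == 0), 1.0, p)
    return StatMap(
        effect="paired_t" if paired else "independent_t",
        stat=np.asarray(t),
        df=(df,),
        p=np.asarray(p),
        kind="t",
        degenerate=degenerate if np.any(degenerate) else None,
    )


# ---------------------------------------------------------------------------
# Repeated-measures / mixed factorial ANOVA


@dataclass
class Design:
    """Factorial design: crossed within factors, between-subject groups.

    ``within``: ordered (name, n_levels) pairs, matching the data axes
    after the subject axis.  ``between``: (name, labels) with one label
    per subject.  Up to six within and three between factors.
    """

    within: list[tuple[str, int]] = field(default_factory=list)
    between: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.within) > 6:
            raise ValueError("at most six within factors are supported")
        if len(self.between) > 3:
            raise ValueError("at most three between factors are supported")
        self.between = [(n, np.asarray(v)) for n, v in self.between]
        if self.between:
            lengths = {len(v) for _, v in self.between}
            if len(lengths) != 1:
                raise ValueError("between-factor label arrays must share length")

    @property
    def within_shape(self) -> tuple[int, ...]:
        return tuple(n for _, n in self.within)


def _marginal_means(C: np.ndarray, keep: tuple[int, ...], n_factors: int) -> np.ndarray:
    """Mean of C over all factor axes not in ``keep`` (axes 0..n_factors-1),
    keeping dims for broadcasting."""
    drop = tuple(ax for ax in range(n_factors) if ax not in keep)
    return C.mean(axis=drop, keepdims=True) if drop else C


def _effect_estimate(C: np.ndarray, subset: tuple[int, ...], n_factors: int) -> np.ndarray:
    """Inclusion–exclusion effect estimate for a factor subset,
    broadcast over the full cell-mean grid."""
    est = np.zeros(C.shape)
    for r in range(len(subset) + 1):
        for sub in itertools.combinations(subset, r):
            sign = (-1) ** (len(subset) - r)
            est = est + sign * _marginal_means(C, sub, n_factors)
    return est


def rm_anova(
    data: np.ndarray,
    design: Design,
    roi: bool = False,
    gg: bool = False,
) -> "AnovaResult":
    """Point-by-point mixed factorial ANOVA.

    Parameters
    ----------
    data
        ``(n_subjects, L1, ..., Lk, *points)`` with one axis per within
        factor, in the order declared in the design.  Trailing axes are
        treated as independent points (sensors, time, ...).
    design
        Factor structure.  The within part must be fully crossed and
        balanced (it is, by construction of the data array); between
        groups may be unbalanced, in which case unweighted (harmonic
        mean) cell means are used — the Type III-style analysis.
    roi
        When the data carry no point axes, also return cell means and
        Bonferroni-corrected pairwise paired-t contrasts per within
        factor.
    gg
        Report the Greenhouse–Geisser epsilon per within effect
        (uncorrected p values are always reported).

    Returns
    -------
    AnovaResult with one :class:`StatMap` per main effect and
    interaction.
    """
    data = np.asarray(data, dtype=float)
    k = len(design.within)
    m = len(design.between)
    n_subj = data.shape[0]
    wshape = design.within_shape
    if data.shape[1 : 1 + k] != wshape:
        raise ValueError(
            f"data within-axes {data.shape[1:1 + k]} do not match design {wshape}"
        )
    pshape = data.shape[1 + k :]
    n_wcells = int(np.prod(wshape)) if k else 1

    # between-group structure
    if m:
        blevels = []
        bindex = np.zeros((m, n_subj), dtype=int)
        for j, (_name, labels) in enumerate(design.between):
            uniq, inv = np.unique(labels, return_inverse=True)
            blevels.append(len(uniq))
            bindex[j] = inv
        bshape = tuple(blevels)
        group_id = np.ravel_multi_index(bindex, bshape)
        n_groups = int(np.prod(bshape))
        counts = np.bincount(group_id, minlength=n_groups)
        if np.any(counts == 0):
            missing = [np.unravel_index(g, bshape) for g in np.nonzero(counts == 0)[0]]
            raise ValueError(f"between design not fully crossed; empty cells {missing}")
        n_harm = n_groups / np.sum(1.0 / counts)
    else:
        bshape = ()
        group_id = np.zeros(n_subj, dtype=int)
        n_groups = 1
        counts = np.array([n_subj])
        n_harm = float(n_subj)

    # unweighted group-by-within cell means C[b..., w..., points...]
    Y = data.reshape((n_subj,) + wshape + pshape)
    C = np.zeros(bshape + wshape + pshape)
    Cg = np.zeros((n_groups,) + wshape + pshape)
    for g in range(n_groups):
        Cg[g] = Y[group_id == g].mean(axis=0)
    C = Cg.reshape(bshape + wshape + pshape)

    n_factors = m + k
    factor_names = [n for n, _ in design.between] + [n for n, _ in design.within]
    factor_sizes = list(bshape) + list(wshape)

    # subject deviation profiles (for within error terms)
    D = Y - Cg[group_id]

    # error terms per within subset
    def within_error(vsub: tuple[int, ...]) -> tuple[float, float]:
        """SS and df of the (within-subset x subject-within-group) term."""
        # vsub indexes within factors 0..k-1 -> data axes 1..k
        keep_axes = tuple(1 + v for v in vsub)
        est = np.zeros((n_subj,) + wshape + pshape)
        nax = 1 + k  # subject + within axes
        for r in range(len(vsub) + 1):
            for sub in itertools.combinations(keep_axes, r):
                sign = (-1) ** (len(vsub) - r)
                drop = tuple(ax for ax in range(1, nax) if ax not in sub)
                est = est + sign * (
                    D.mean(axis=drop, keepdims=True) if drop else D
                )
        # summing the broadcast estimate over the full subject x within grid
        # already carries the per-cell observation multiplicity
        ss = (est**2).sum(axis=tuple(range(1 + k)))
        df = (n_subj - n_groups) * int(
            np.prod([wshape[v] - 1 for v in vsub]) if vsub else 1
        )
        return ss, df

    error_cache: dict[tuple, tuple] = {}
    maps: list[StatMap] = []
    eps_gg: dict[str, np.ndarray] = {}

    for size in range(1, n_factors + 1):
        for subset in itertools.combinations(range(n_factors), size):
            bpart = tuple(f for f in subset if f < m)
            wpart = tuple(f - m for f in subset if f >= m)
            est = _effect_estimate(C, subset, n_factors)
            # full-grid sum times the (harmonic-mean) subjects per group
            ss = n_harm * (est**2).sum(axis=tuple(range(n_factors)))
            df_eff = int(np.prod([factor_sizes[f] - 1 for f in subset]))
            if wpart:
                if wpart not in error_cache:
                    error_cache[wpart] = within_error(wpart)
                ss_err, df_err = error_cache[wpart]
            else:
                if "between" not in error_cache:
                    subj_mean = Y.mean(axis=tuple(range(1, 1 + k))) if k else Y
                    dev = subj_mean - (
                        Cg.mean(axis=tuple(range(1, 1 + k))) if k else Cg
                    )[group_id]
                    ss_b = n_wcells * (dev**2).sum(axis=0)
                    error_cache["between"] = (ss_b, n_subj - n_groups)
                ss_err, df_err = error_cache["between"]
            with np.errstate(divide="ignore", invalid="ignore"):
                F = (ss / df_eff) / (ss_err / df_err)
            F = np.where(np.isnan(F), 0.0, F)
            p = scipy.stats.f.sf(F, df_eff, df_err)
            name = " x ".join(factor_names[f] for f in subset)
            maps.append(
                StatMap(
                    effect=name,
                    stat=np.asarray(F),
                    df=(df_eff, df_err),
                    p=np.asarray(p),
                    kind="F",
                )
            )
            if gg and wpart and not bpart:
                eps_gg[name] = _gg_epsilon(Y, wpart, group_id, wshape, k)

    result = AnovaResult(maps=maps, design=design, gg_epsilon=eps_gg or None)
    if roi and not pshape:
        result.cell_means = C
        result.posthoc = _roi_posthoc(Y, design)
    return result


def _gg_epsilon(Y, wpart, group_id, wshape, k):
    """Greenhouse–Geisser epsilon of a within effect's error covariance."""
    axes_keep = tuple(1 + v for v in wpart)
    drop = tuple(ax for ax in range(1, 1 + k) if ax not in axes_keep)
    P = Y.mean(axis=drop) if drop else Y  # (n_subj, effect cells..., points)
    mcells = int(np.prod([wshape[v] for v in wpart]))
    P = P.reshape((P.shape[0], mcells) + P.shape[1 + len(wpart):])
    # center within groups
    for g in np.unique(group_id):
        P[group_id == g] -= P[group_id == g].mean(axis=0, keepdims=True)
    flat = P.reshape(P.shape[0], mcells, -1)
    eps = np.empty(flat.shape[2])
    for pt in range(flat.shape[2]):
        S = np.cov(flat[:, :, pt], rowvar=False)
        S = np.atleast_2d(S)
        mean_diag = np.trace(S) / mcells
        num = mcells**2 * (mean_diag - S.mean()) ** 2
        den = (mcells - 1) * (
            (S**2).sum() - 2 * mcells * (S.mean(axis=0) ** 2).sum() + mcells**2 * S.mean() ** 2
        )
        eps[pt] = 1.0 if den == 0 else float(np.clip(num / den, 1.0 / (mcells - 1), 1.0))
    return eps.reshape(P.shape[2:])


def _roi_posthoc(Y, design: Design):
    """Bonferroni-corrected pairwise paired-t contrasts per within factor."""
    import pandas as pd

    rows = []
    k = len(design.within)
    for axis, (name, levels) in enumerate(design.within):
        drop = tuple(ax for ax in range(1, 1 + k) if ax != 1 + axis)
        marg = Y.mean(axis=drop) if drop else Y  # (n_subj, levels)
        n_pairs = levels * (levels - 1) // 2
        for i, j in itertools.combinations(range(levels), 2):
            res = pointwise_ttest(marg[:, i], marg[:, j], paired=True)
            rows.append(
                {
                    "factor": name,
                    "level_a": i,
                    "level_b": j,
                    "t": float(res.stat),
                    "df": res.df[0],
                    "p_uncorrected": float(res.p),
                    "p_bonferroni": min(1.0, float(res.p) * n_pairs),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class AnovaResult:
    maps: list[StatMap]
    design: Design
    gg_epsilon: dict | None = None
    cell_means: np.ndarray | None = None
    posthoc: object | None = None

    def __iter__(self):
        return iter(self.maps)

    def __getitem__(self, effect: str) -> StatMap:
        for m in self.maps:
            if m.effect == effect:
                return m
        raise KeyError(effect)


# ---------------------------------------------------------------------------
# Permutation tests


def _paired_t_stat(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d.mean(axis=0) / (sd / np.sqrt(n))
    return np.where(np.isnan(t), 0.0, t)


def _independent_stat(x: np.ndarray, groups: np.ndarray, kind: str) -> np.ndarray:
    levels = np.unique(groups)
    if kind == "independent_t":
        a, b = x[groups == levels[0]], x[groups == levels[1]]
        na, nb = a.shape[0], b.shape[0]
        sp2 = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (
            na + nb - 2
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1 / na + 1 / nb))
        return np.where(np.isnan(t), 0.0, t)
    # one-way F
    grand = x.mean(axis=0)
    ss_b = np.zeros(x.shape[1:])
    ss_w = np.zeros(x.shape[1:])
    for lv in levels:
        xi = x[groups == lv]
        ss_b += xi.shape[0] * (xi.mean(axis=0) - grand) ** 2
        ss_w += ((xi - xi.mean(axis=0, keepdims=True)) ** 2).sum(axis=0)
    df_b, df_w = len(levels) - 1, x.shape[0] - len(levels)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_b / df_b) / (ss_w / df_w)
    return np.where(np.isnan(F), 0.0, F)


def permutation_test(
    data: np.ndarray,
    statistic: str = "paired_t",
    groups: np.ndarray | None = None,
    n_perm: int | None = 1000,
    exact: bool = False,
    seed: int | None = None,
    tail: str = "two-sided",
    exact_cap: int = 200_000,
) -> dict:
    """Nonparametric permutation (rerandomization or exact) test.

    ``paired_t`` operates on paired differences (subjects × points) with
    a sign-flip null; ``independent_t`` and ``anova_F`` relabel group
    membership.  Exact mode enumerates the full null when its size does
    not exceed ``exact_cap``; Monte-Carlo mode draws ``n_perm``
    rerandomizations from a seeded generator and uses the add-one
    estimator ``p = (1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    x = np.asarray(data, dtype=float)
    n = x.shape[0]
    if statistic == "paired_t":
        stat_fn = lambda d: _paired_t_stat(d)
        observed = stat_fn(x)
        n_total = 2**n
    elif statistic in ("independent_t", "anova_F"):
        if groups is None:
            raise ValueError("independent statistics need group labels")
        groups = np.asarray(groups)
        stat_fn = lambda g: _independent_stat(x, g, statistic)
        observed = stat_fn(groups)
        from math import factorial

        _, cnt = np.unique(groups, return_counts=True)
        n_total = factorial(n)
        for c in cnt:
            n_total //= factorial(c)
    else:
        raise ValueError(f"unknown permutation statistic {statistic!r}")

    def compare(val: np.ndarray) -> np.ndarray:
        if statistic == "anova_F":
            return val >= observed - 1e-12
        if tail == "two-sided":
            return np.abs(val) >= np.abs(observed) - 1e-12
        if tail == "greater":
            return val >= observed - 1e-12
        return val <= observed + 1e-12

    if exact:
        if n_total > exact_cap:
            raise ValueError(
                f"exact test would need {n_total} permutations (> cap {exact_cap}); "
                f"use the Monte-Carlo mode with n_perm"
            )
        count = np.zeros(observed.shape)
        if statistic == "paired_t":
            for signs in itertools.product((1.0, -1.0), repeat=n):
                val = stat_fn(x * np.asarray(signs)[(slice(None),) + (None,) * (x.ndim - 1)])
                count += compare(val)
        else:
            seen = set()
            for perm in itertools.permutations(range(n)):
                key = tuple(groups[list(perm)])
                if key in seen:
                    continue
                seen.add(key)
                count += compare(stat_fn(np.asarray(key)))
        p = count / n_total
        return {"p": p, "observed": observed, "n_permutations": n_total, "exact": True}

    if n_perm is None or n_perm < 1:
        raise ValueError("Monte-Carlo mode needs n_perm >= 1")
    rng = np.random.default_rng(seed)
    count = np.zeros(observed.shape)
    for _ in range(n_perm):
        if statistic == "paired_t":
            signs = rng.choice([1.0, -1.0], size=n)
            val = stat_fn(x * signs[(slice(None),) + (None,) * (x.ndim - 1)])
        else:
            val = stat_fn(rng.permutation(groups))
        count += compare(val)
    p = (1.0 + count) / (1.0 + n_perm)
    return {"p": p, "observed": observed, "n_permutations": n_perm, "exact": False}


# ---------------------------------------------------------------------------
# Post-hoc spatiotemporal filtering


def sensor_adjacency(layout: SensorLayout, factor: float = 1.3) -> np.ndarray:
    """Sensor neighbor matrix: within ``factor`` × median nearest-neighbor
    distance.  Symmetric boolean matrix with a False diagonal."""
    pos = layout.positions
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    nn = np.median(d.min(axis=1))
    adj = d <= factor * nn
    return adj


def posthoc_spatiotemporal_filter(
    p: np.ndarray | StatMap,
    alpha: float,
    min_time_points: int,
    min_adjacent_sensors: int,
    adjacency: np.ndarray,
) -> np.ndarray:
    """Remove isolated significant points from a sensors × time p map.

    A point survives iff it belongs to a run of at least
    ``min_time_points`` consecutive significant samples on its sensor
    AND at that time at least ``min_adjacent_sensors`` sensors among the
    sensor itself and its graph neighbors are significant.
    """
    if isinstance(p, StatMap):
        pvals = p.p
    else:
        pvals = np.asarray(p)
    sig = pvals < alpha
    n_sens, n_time = sig.shape

    # temporal run length per point
    runs = np.zeros_like(sig, dtype=int)
    for s in range(n_sens):
        count = 0
        for t in range(n_time):
            count = count + 1 if sig[s, t] else 0
            runs[s, t] = count
        # propagate run length backwards over each run
        for t in range(n_time - 2, -1, -1):
            if sig[s, t] and sig[s, t + 1]:
                runs[s, t] = runs[s, t + 1]
    temporal_ok = runs >= min_time_points

    inclusive = adjacency | np.eye(n_sens, dtype=bool)
    neighbor_counts = inclusive.astype(int) @ sig.astype(int)
    spatial_ok = neighbor_counts >= min_adjacent_sensors

    mask = sig & temporal_ok & spatial_ok
    if isinstance(p, StatMap):
        p.mask = mask
    return mask


# ---------------------------------------------------------------------------
# PCA and import transforms


@dataclass
class PCAResult:
    components: np.ndarray  # (n_components, n_channels), orthonormal
    scores: np.ndarray  # (n_observations, n_components)
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    mean: np.ndarray


def pca(data: np.ndarray) -> PCAResult:
    """Principal components of observations × channels data (SVD-based)."""
    X = np.asarray(data, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D array with at least 2 observations")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (X.shape[0] - 1)
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    return PCAResult(
        components=Vt,
        scores=U * s,
        explained_variance=var,
        explained_variance_ratio=ratio,
        mean=mean,
    )


def import_transform(
    data: np.ndarray,
    steps: list,
    fs: float | None = None,
    times: np.ndarray | None = None,
    layout: SensorLayout | None = None,
    is_statistic: bool = False,
    log: list | None = None,
) -> np.ndarray:
    """Apply an ordered list of data transformations at import time.

    Each step is ``(name, params)`` with names: ``rectify``,
    ``interval_mean`` (params: ``t_min``, ``t_max``), ``group_mean``
    (params: ``group``), ``baseline`` (params: ``t_min``, ``t_max``),
    ``temporal_filter`` (params: ``spec`` FilterSpec), ``spatial_smooth``
    (params: ``lam``).  Order matters (rectify-then-average differs from
    average-then-rectify), hence the explicit list.  Applying a baseline
    to statistical values is almost always a mistake and triggers a
    warning.  Every applied step is appended to ``log`` when given.
    """
    x = np.asarray(data, dtype=float)
    for step in steps:
        name, params = step if isinstance(step, tuple) else (step, {})
        if name == "rectify":
            x = np.abs(x)
        elif name == "interval_mean":
            if times is None:
                raise ValueError("interval_mean needs a time axis")
            sel = (times >= params["t_min"]) & (times <= params["t_max"])
            x = x[..., sel].mean(axis=-1)
        elif name == "group_mean":
            x = regional_summary(x, params["group"], layout, "mean")
        elif name == "baseline":
            if is_statistic:
                warnings.warn(
                    "baseline correction of statistical values is rarely "
                    "meaningful; check the analysis order"
                )
            if times is None:
                raise ValueError("baseline needs a time axis")
            sel = (times >= params["t_min"]) & (times <= params["t_max"])
            x = x - x[..., sel].mean(axis=-1, keepdims=True)
        elif name == "temporal_filter":
            import scipy.signal as _sig

            from .preprocessing import design_filter

            filt = design_filter(params["spec"], fs)
            if filt.is_fir:
                x = _sig.filtfilt(filt.taps, [1.0], x, axis=-1)
            else:
                x = _sig.sosfiltfilt(filt.sos, x, axis=-1)
        elif name == "spatial_smooth":
            from .inverse import InterpolationOperator

            op = InterpolationOperator(layout, lam=params.get("lam", 0.1))
            flat = x.reshape(-1, x.shape[-2], x.shape[-1]) if x.ndim > 2 else x[None]
            out = np.stack([op.interpolate(f) for f in flat])
            x = out.reshape(x.shape)
        else:
            raise ValueError(f"unknown transform {name!r}")
        if log is not None:
            log.append({"transform": name, "params": {k: v for k, v in params.items() if k != "group"}})
    return x
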