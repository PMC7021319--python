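"""Statistics of sex differences: ANOVA on PC scores and centroid size,
Cohen's d with achieved power, allometry (Pearson correlation with lnCS and
per-group multivariate regression on lnCS), and the permutation test on
angles and lengths of allometric trajectories.

Conventions: Cohen's d is (female mean - male mean) / pooled SD, so the
usual male-larger size dimorphism comes out negative. A group's allometric
trajectory is the OLS slope vector of its shape/form variables on lnCS;
trajectory "length" is the predicted shape-change magnitude across the
group's observed size range, ||slope|| * (max lnCS - min lnCS), with the
raw slope norm available behind ``length="norm"``. Pairwise trajectory
comparisons are tested by permuting group labels (group sizes preserved)
and recomputing trajectories, with the +1-corrected p-value
(count of permuted >= observed + 1) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.stats

from .errors import TalogmError

__all__ = [
    "DimorphismStats",
    "AllometricTrajectory",
    "TrajectoryComparison",
    "anova_two_group",
    "cohens_d",
    "power_two_sample",
    "pearson_r",
    "fit_trajectory",
    "trajectory_angle",
    "permutation_trajectory_test",
    "sex_dimorphism_stats",
]


@dataclass
class DimorphismStats:
    variable: str
    F_statistic: float
    df: tuple[int, int]
    p_value: float
    cohens_d: float | None = None
    achieved_power: float | None = None
    pearson_r_vs_lncs: float | None = None
    pearson_p_vs_lncs: float | None = None


@dataclass
class AllometricTrajectory:
    group: str
    coefficient_vector: np.ndarray
    length: float
    lncs_range: tuple[float, float]
    n: int


@dataclass
class TrajectoryComparison:
    group_pair: tuple[str, str]
    angle_deg: float
    angle_p: float
    length_diff: float
    length_p: float
    n_permutations: int
    seed: int


def _two_groups(values: np.ndarray, labels: np.ndarray):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = sorted(set(labels.tolist()))
    if len(levels) != 2:
        raise TalogmError(f"expected exactly two groups, got {levels}")
    a = values[labels == levels[0]]
    b = values[labels == levels[1]]
    if min(len(a), len(b)) < 2:
        raise TalogmError("each group needs at least 2 observations")
    return a, b, levels


def anova_two_group(values, labels, variable: str = "") -> DimorphismStats:
    """One-way ANOVA between two groups; df = (1, n-2). For two groups F is
    identically the square of the equal-variance t statistic."""
    a, b, _ = _two_groups(values, labels)
    f, p = scipy.stats.f_oneway(a, b)
    return DimorphismStats(
        variable=variable,
        F_statistic=float(f),
        df=(1, len(a) + len(b) - 2),
        p_value=float(p),
    )


def cohens_d(group_a, group_b) -> float:
    """(mean_a - mean_b) / pooled SD (n-1 denominators); by convention
    group_a is the female sample, so male-larger traits give negative d."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if min(len(a), len(b)) < 2:
        raise TalogmError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 <= 0:
        raise TalogmError("zero pooled variance; d undefined")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def power_two_sample(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample equal-variance t-test at effect
    size |d|, via the noncentral t distribution."""
    if not (0.0 < alpha < 1.0):
        raise TalogmError(f"alpha must be in (0,1), got {alpha}")
    if min(n1, n2) < 2:
        raise TalogmError("need n >= 2 per group")
    nu = n1 + n2 - 2
    nc = abs(d) * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = scipy.stats.t.ppf(1 - alpha / 2, nu)
    upper = scipy.stats.nct.sf(tcrit, nu, nc)
    lower = scipy.stats.nct.cdf(-tcrit, nu, nc)
    if np.isnan(lower):  # scipy underflows this tail at large noncentrality
        lower = 0.0
    return float(np.clip(upper + lower, 0.0, 1.0))


def pearson_r(scores, lncs) -> tuple[float, float]:
    """Product-moment correlation of a variable with lnCS (static allometry
    screen), with its two-sided p-value."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(lncs, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise TalogmError("need two equal-length vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise TalogmError("zero variance: correlation undefined")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def sex_dimorphism_stats(
    values, sex_labels, lncs=None, variable: str = "", alpha: float = 0.05
) -> DimorphismStats:
    """Full univariate report for one variable: ANOVA F/p, Cohen's d
    (F minus M), achieved power at the realized d, and optionally the
    Pearson correlation with lnCS."""
    values = np.asarray(values, dtype=float)
    sex = np.asarray(sex_labels)
    f_stat = anova_two_group(values, sex, variable=variable)
    females = values[sex == "F"]
    males = values[sex == "M"]
    d = cohens_d(females, males)
    power = power_two_sample(d, len(females), len(males), alpha=alpha)
    r = p_r = None
    if lncs is not None:
        r, p_r = pearson_r(values, lncs)
    return DimorphismStats(
        variable=variable,
        F_statistic=f_stat.F_statistic,
        df=f_stat.df,
        p_value=f_stat.p_value,
        cohens_d=d,
        achieved_power=power,
        pearson_r_vs_lncs=r,
        pearson_p_vs_lncs=p_r,
    )


def _group_slope(x: np.ndarray, z: np.ndarray) -> np.ndarray:
    zc = z - z.mean()
    ss = float(zc @ zc)
    if ss <= 0:
        raise TalogmError("lnCS constant within a group; slope undefined")
    return (x - x.mean(axis=0)).T @ zc / ss


def fit_trajectory(
    variables: np.ndarray,
    lncs: np.ndarray,
    groups: np.ndarray,
    length: str = "range",
) -> dict[str, AllometricTrajectory]:
    """Per-group multivariate OLS regression of the variables on lnCS.

    The coefficient vector is the intragroup allometric trajectory;
    ``length="range"`` (default) scales its norm by the group's observed
    lnCS range, ``length="norm"`` reports the raw norm.
    """
    x = np.asarray(variables, dtype=float)
    z = np.asarray(lncs, dtype=float)
    g = np.asarray(groups)
    if length not in ("range", "norm"):
        raise TalogmError(f"unknown length convention {length!r}")
    out: dict[str, AllometricTrajectory] = {}
    for level in sorted(set(g.tolist())):
        mask = g == level
        if mask.sum() < 3:
            raise TalogmError(f"group {level!r} has < 3 specimens")
        slope = _group_slope(x[mask], z[mask])
        zr = (float(z[mask].min()), float(z[mask].max()))
        norm = float(np.linalg.norm(slope))
        out[level] = AllometricTrajectory(
            group=str(level),
            coefficient_vector=slope,
            length=norm * (zr[1] - zr[0]) if length == "range" else norm,
            lncs_range=zr,
            n=int(mask.sum()),
        )
    return out


def trajectory_angle(a: AllometricTrajectory, b: AllometricTrajectory) -> float:
    """Angle in degrees ([0, 180]) between two trajectory directions."""
    va, vb = a.coefficient_vector, b.coefficient_vector
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na <= 0 or nb <= 0:
        raise TalogmError("zero-norm trajectory; angle undefined")
    cos = np.clip(va @ vb / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def permutation_trajectory_test(
    variables: np.ndarray,
    lncs: np.ndarray,
    group_labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    length: str = "range",
) -> list[TrajectoryComparison]:
    """Permutation test on pairwise trajectory angles and length differences.

    Specimens are randomly reassigned to groups (sizes preserved) and the
    trajectories recomputed; one-sided p for angles (permuted angle >=
    observed) and absolute-difference p for lengths, both +1-corrected so
    p is in (0, 1]. Deterministic given the seed.
    """
    x = np.asarray(variables, dtype=float)
    z = np.asarray(lncs, dtype=float)
    g = np.asarray(group_labels)
    levels = sorted(set(g.tolist()))
    if len(levels) < 2:
        raise TalogmError("need at least two groups")
    obs = fit_trajectory(x, z, g, length=length)
    pairs = [
        (levels[i], levels[j])
        for i in range(len(levels))
        for j in range(i + 1, len(levels))
    ]
    obs_angle = {p: trajectory_angle(obs[p[0]], obs[p[1]]) for p in pairs}
    obs_ldiff = {p: abs(obs[p[0]].length - obs[p[1]].length) for p in pairs}

    rng = np.random.default_rng(seed)
    ge_angle = {p: 0 for p in pairs}
    ge_ldiff = {p: 0 for p in pairs}
    for _ in range(n_perm):
        gp = rng.permutation(g)
        try:
            perm = fit_trajectory(x, z, gp, length=length)
        except TalogmError:
            # degenerate permutation (constant lnCS in a group): count as
            # extreme, keeping the test conservative
            for p in pairs:
                ge_angle[p] += 1
                ge_ldiff[p] += 1
            continue
        for p in pairs:
            if trajectory_angle(perm[p[0]], perm[p[1]]) >= obs_angle[p]:
                ge_angle[p] += 1
            if abs(perm[p[0]].length - perm[p[1]].length) >= obs_ldiff[p]:
                ge_ldiff[p] += 1

    return [
        TrajectoryComparison(
            group_pair=p,
            angle_deg=obs_angle[p],
            angle_p=(ge_angle[p] + 1) / (n_perm + 1),
            length_diff=obs_ldiff[p],
            length_p=(ge_ldiff[p] + 1) / (n_perm + 1),
            n_permutations=n_perm,
            seed=seed,
        )
        for p in pairs
    ]
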