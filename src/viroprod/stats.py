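"""Comparative statistics: rank correlations, rank tests, and partial RDA.

All tests are non-parametric, matching the small, tied, strongly non-normal
samples typical of incubation studies.  Values below the detection limit are
carried through parsing as missing-with-flag and only substituted (default:
zero) at analysis time, so raw "n.d."/"<x" markers survive round-tripping.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .series import DuplicateSummary

__all__ = [
    "EnvSample",
    "VariationPartition",
    "resolve_below_detection",
    "spearman",
    "mann_whitney",
    "kruskal_wallis",
    "range_overlap_difference",
    "rda_variation_partition",
]

#: Sentinel used in numeric arrays for below-detection values before the
#: nd-policy is applied.
BELOW_DETECTION = float("nan")


@dataclass(frozen=True)
class EnvSample:
    """One depth-zone record of physicochemistry plus standing stocks.

    Nutrient/gas fields are in uM and may be None when below the detection
    limit (kept distinct from a measured zero).  ``vpr`` defaults to the
    ratio of the two abundances when both are present.
    """

    station: str
    zone: str
    depth: float
    temperature: float
    salinity: float
    turbidity: float
    PO4: float | None
    NO2: float | None
    NO3: float | None
    NH4: float | None
    O2: float | None
    H2S: float | None
    prok_abundance: float | None = None
    viral_abundance: float | None = None
    vpr: float | None = None

    def __post_init__(self) -> None:
        if (
            self.vpr is None
            and self.prok_abundance
            and self.viral_abundance is not None
        ):
            object.__setattr__(
                self, "vpr", self.viral_abundance / self.prok_abundance
            )


@dataclass(frozen=True)
class VariationPartition:
    """Variance decomposition from (partial) redundancy analysis.

    Fractions of the total variance of the centered response matrix:

    * ``unique_explanatory`` — explained by X after removing Z,
    * ``shared``             — jointly attributable to X and Z,
    * ``conditional``        — explained by Z alone (unique to Z),
    * ``residual``           — unexplained;

    these four sum to 1.  ``total_explained`` is the fraction explained by
    X and Z together.  ``p_total`` is the permutation p-value for the
    (partial) explanatory fraction.  Raw R^2 fractions by default; when
    ``adjusted`` is set the fractions are Ezekiel-adjusted and individual
    components may be negative.
    """

    total_explained: float
    unique_explanatory: float
    shared: float
    conditional: float
    residual: float
    p_total: float
    n_permutations: int
    seed: int
    adjusted: bool = False
    rank_deficient: bool = False

    def fractions_sum(self) -> float:
        return (
            self.unique_explanatory + self.shared + self.conditional + self.residual
        )


def resolve_below_detection(
    values: Sequence[float | None], nd_policy: str = "zero"
) -> np.ndarray:
    """Substitute below-detection entries (None/NaN) according to policy.

    Policies: ``"zero"`` (default, as in redox-gradient studies where n.d.
    means absent-or-trace) or ``"drop"`` (return NaN, caller masks).
    """
    arr = np.array(
        [np.nan if v is None else float(v) for v in values], dtype=float
    )
    if nd_policy == "zero":
        return np.nan_to_num(arr, nan=0.0)
    if nd_policy == "drop":
        return arr
    raise ValueError(f"unknown nd policy: {nd_policy!r}")


def _exact_spearman_p(rank_x: np.ndarray, rank_y: np.ndarray, r_obs: float) -> float:
    """Two-sided exact p by full enumeration of rank permutations (n <= 9)."""
    n = len(rank_x)
    perms = np.array(list(itertools.permutations(range(n))))
    permuted = rank_y[perms]  # (n!, n)
    rx = rank_x - rank_x.mean()
    ry = permuted - permuted.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx**2).sum() * (ry**2).sum(axis=1))
    r_all = (ry @ rx) / denom
    return float(np.mean(np.abs(r_all) >= abs(r_obs) - 1e-12))


def spearman(
    x: Sequence[float | None],
    y: Sequence[float | None],
    nd_policy: str = "zero",
    exact: bool = False,
) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    Below-detection markers (None/NaN) are resolved by ``nd_policy`` before
    ranking.  The p-value uses the t-approximation (scipy); with
    ``exact=True`` and n <= 9, the two-sided p is computed by exhaustive
    enumeration of all rank permutations instead.

    Returns
    -------
    (r, p)
    """
    xv = resolve_below_detection(x, nd_policy)
    yv = resolve_below_detection(y, nd_policy)
    if len(xv) != len(yv):
        raise ValueError("x and y must have equal length")
    mask = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[mask], yv[mask]
    if len(xv) < 3:
        raise ValueError("need at least 3 paired observations")
    res = sps.spearmanr(xv, yv)
    r = float(res.statistic)
    if exact:
        if len(xv) > 9:
            raise ValueError("exact enumeration limited to n <= 9")
        p = _exact_spearman_p(sps.rankdata(xv), sps.rankdata(yv), r)
    else:
        p = float(res.pvalue)
    return r, p


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float  # classical statistic, min(U_a, U_b)
    z: float  # tie-corrected normal approximation
    p_value: float

    def __iter__(self):
        yield self.U
        yield self.p_value


def mann_whitney(
    a: Sequence[float], b: Sequence[float]
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with tie correction.

    Returns the classical U (the smaller of the two group statistics), the
    tie-corrected standard-normal z, and the two-sided p-value (exact where
    scipy's auto policy permits, otherwise asymptotic).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    u_a = float(res.statistic)
    n1, n2 = len(a), len(b)
    u = min(u_a, n1 * n2 - u_a)
    # tie-corrected normal approximation
    all_vals = np.concatenate([a, b])
    _, counts = np.unique(all_vals, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    mu = n1 * n2 / 2.0
    z = (u_a - mu) / np.sqrt(sigma2) if sigma2 > 0 else 0.0
    return MannWhitneyResult(U=u, z=float(z), p_value=float(res.pvalue))


@dataclass(frozen=True)
class KruskalResult:
    H: float
    p_value: float
    posthoc: tuple[tuple[int, int, MannWhitneyResult], ...]


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H test with pairwise post-hoc U tests.

    The post-hoc entries are (i, j, MannWhitneyResult) for every group pair,
    mirroring the use of the U test as a non-parametric post-hoc.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups")
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if any(len(g) == 0 for g in arrays):
        raise ValueError("groups must be non-empty")
    try:
        h, p = sps.kruskal(*arrays)
    except ValueError:  # scipy rejects all-identical data; H is 0 there
        h, p = 0.0, 1.0
    posthoc = tuple(
        (i, j, mann_whitney(arrays[i], arrays[j]))
        for i, j in itertools.combinations(range(len(arrays)), 2)
    )
    return KruskalResult(H=float(h), p_value=float(p), posthoc=posthoc)


def range_overlap_difference(a: DuplicateSummary, b: DuplicateSummary) -> bool:
    """Relevant-difference rule for duplicate incubations.

    True iff the closed ranges [a.low, a.high] and [b.low, b.high] are
    disjoint; touching endpoints count as overlapping (no difference).
    """
    return not a.overlaps(b)


def _center(m: np.ndarray) -> np.ndarray:
    return m - m.mean(axis=0, keepdims=True)


def _explained_fraction(Y: np.ndarray, X: np.ndarray) -> tuple[float, bool]:
    """R^2 of the multivariate least-squares projection of Y on X.

    Uses lstsq (pseudo-inverse on rank deficiency); returns (fraction,
    rank_deficient flag).  Y and X must already be centered.
    """
    if X.size == 0:
        return 0.0, False
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ coef
    total = float((Y**2).sum())
    if total == 0:
        return 0.0, rank < X.shape[1]
    return float((fitted**2).sum()) / total, rank < X.shape[1]


def rda_variation_partition(
    Y,
    X,
    Z=None,
    n_perm: int = 10_000,
    seed: int = 0,
    adjusted: bool = False,
    bootstrap: bool = False,
) -> VariationPartition:
    """Redundancy analysis with variation partitioning and a permutation test.

    The response matrix Y is column-centered and projected onto the centered
    explanatory matrix X; with a conditional matrix Z, the partial RDA first
    residualizes both Y and X on Z.  Variance fractions (raw R^2 by default):

    * unique_explanatory = R^2(X+Z) - R^2(Z)
    * conditional        = R^2(X+Z) - R^2(X)
    * shared             = R^2(X) + R^2(Z) - R^2(X+Z)
    * residual           = 1 - R^2(X+Z)

    The permutation test permutes the rows of the Z-residualized response
    (without replacement; ``bootstrap=True`` resamples rows with
    replacement) and compares the partial explanatory fraction.

    Returns
    -------
    VariationPartition
    """
    Y = _center(np.atleast_2d(np.asarray(Y, dtype=float)))
    X = _center(np.atleast_2d(np.asarray(X, dtype=float)))
    if Y.shape[0] != X.shape[0]:
        raise ValueError("Y and X must have the same number of rows")
    has_z = Z is not None and np.size(Z) > 0
    if has_z:
        Z = _center(np.atleast_2d(np.asarray(Z, dtype=float)))
        if Z.shape[0] != Y.shape[0]:
            raise ValueError("Z must have the same number of rows as Y")

    rank_deficient = False
    if has_z:
        r2_z, rd1 = _explained_fraction(Y, Z)
        r2_x, rd2 = _explained_fraction(Y, X)
        r2_xz, rd3 = _explained_fraction(Y, np.hstack([X, Z]))
        rank_deficient = rd1 or rd2 or rd3
        unique = r2_xz - r2_z
        conditional = r2_xz - r2_x
        shared = r2_x + r2_z - r2_xz
        residual = 1.0 - r2_xz
        total = r2_xz
        # residualize for the permutation test (partial RDA)
        coef_y, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        coef_x, *_ = np.linalg.lstsq(Z, X, rcond=None)
        Yr = Y - Z @ coef_y
        Xr = X - Z @ coef_x
        stat_obs, _ = _explained_fraction(Yr, Xr)
    else:
        r2_x, rank_deficient = _explained_fraction(Y, X)
        unique, conditional, shared = r2_x, 0.0, 0.0
        residual = 1.0 - r2_x
        total = r2_x
        Yr, Xr = Y, X
        stat_obs = r2_x

    n = Y.shape[0]
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        idx = (
            rng.integers(0, n, size=n) if bootstrap else rng.permutation(n)
        )
        stat_perm, _ = _explained_fraction(_center(Yr[idx]), Xr)
        if stat_perm >= stat_obs - 1e-12:
            exceed += 1
    p_total = (exceed + 1) / (n_perm + 1)

    if adjusted:
        # Ezekiel adjustment per component, via adjusted R^2 of each model
        def adj(r2: float, m: int) -> float:
            if n - m - 1 <= 0:
                return np.nan
            return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)

        if has_z:
            a_z = adj(r2_z, Z.shape[1])
            a_x = adj(r2_x, X.shape[1])
            a_xz = adj(r2_xz, X.shape[1] + Z.shape[1])
            unique = a_xz - a_z
            conditional = a_xz - a_x
            shared = a_x + a_z - a_xz
            residual = 1.0 - a_xz
            total = a_xz
        else:
            total = adj(r2_x, X.shape[1])
            unique = total
            residual = 1.0 - total

    return VariationPartition(
        total_explained=total,
        unique_explanatory=unique,
        shared=shared,
        conditional=conditional,
        residual=residual,
        p_total=float(p_total),
        n_permutations=n_perm,
        seed=seed,
        adjusted=adjusted,
        rank_deficient=rank_deficient,
    )
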