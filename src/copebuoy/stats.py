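"""Statistical layer: depth-effect tests on lipid content and body density.

The centrepiece is a stratified (restricted-permutation) ANOVA: the depth
effect is tested by the sequential-SS F statistic for depth entered after
sampling date in an additive linear model, and its null distribution is
built by permuting the response *within* date strata — exact exchangeability
under the null given additive date effects.  When the stratified
permutation space is small the test enumerates it exhaustively and reports
the exact p; otherwise it Monte-Carlo samples with the add-one rule
p = (1 + #{F* >= F_obs}) / (1 + iterations).

Also here: the step-down Holm-Bonferroni adjustment applied across species
within one response family, the tie-corrected Kruskal-Wallis test used for
prosome-length comparisons, an additive two-way ANOVA (depth x stage), and
the prosome-length vs absolute-lipid-area regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Sequence

import numpy as np
from scipy import linalg as sla
from scipy import stats as sps
from sympy.utilities.iterables import multiset_permutations

logger = logging.getLogger(__name__)

__all__ = [
    "DepthTestResult",
    "RankTestResult",
    "permutation_anova",
    "holm_bonferroni",
    "kruskal_wallis",
    "two_way_anova",
    "length_lipid_regression",
    "count_stratified_arrangements",
]

_RSS_TOL = 1e-12


@dataclass(frozen=True)
class DepthTestResult:
    """Outcome of one species' stratified permutation ANOVA."""

    species_label: str
    response: str
    F_obs: float
    df_depth: int
    df_resid: int
    iterations: int  # permutations actually evaluated (exact count if exhaustive)
    p_raw: float
    seed: int | None
    exact: bool = False
    n: int = 0
    p_adjusted: float | None = None
    dropped_strata: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not 0.0 < self.p_raw <= 1.0:
            raise ValueError(f"p_raw {self.p_raw} outside (0, 1]")
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-15:
            raise ValueError("adjusted p below raw p")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class RankTestResult:
    """Kruskal-Wallis outcome (chi-square approximation)."""

    H: float
    df: int
    p: float
    tie_corrected: bool

    def __post_init__(self) -> None:
        if self.H < 0:
            raise ValueError("H must be non-negative")


def _dummies(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Drop-first treatment dummies for an integer-coded factor."""
    out = np.zeros((codes.size, max(n_levels - 1, 0)))
    for lev in range(1, n_levels):
        out[codes == lev, lev - 1] = 1.0
    return out


def _orth_bases(depth_codes, date_codes, n_depth, n_date):
    """Orthonormal bases for the date-only and date+depth design spaces."""
    n = depth_codes.size
    intercept = np.ones((n, 1))
    x_red = np.hstack([intercept, _dummies(date_codes, n_date)])
    x_full = np.hstack([x_red, _dummies(depth_codes, n_depth)])
    q_red = sla.orth(x_red)
    q_full = sla.orth(x_full)
    return q_red, q_full


def _f_from_columns(Y, q_red, q_full, df_depth, df_resid):
    """Sequential-SS F for depth-after-date, vectorised over columns of Y."""
    ss_red = np.sum((q_red.T @ Y) ** 2, axis=0)
    ss_full = np.sum((q_full.T @ Y) ** 2, axis=0)
    yy = np.sum(Y * Y, axis=0)
    ss_extra = np.maximum(ss_full - ss_red, 0.0)
    rss = np.maximum(yy - ss_full, 0.0)
    scale = np.maximum(yy, 1.0)
    degenerate = rss <= _RSS_TOL * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_extra / df_depth) / (rss / df_resid)
    # perfect fit: infinite F if depth explains anything, else 0
    f = np.where(degenerate, np.where(ss_extra > _RSS_TOL * scale, np.inf, 0.0), f)
    return f


def count_stratified_arrangements(depth_codes, date_codes) -> int:
    """Number of distinct within-stratum assignments of depth labels."""
    total = 1
    for stratum in np.unique(date_codes):
        labels = depth_codes[date_codes == stratum]
        n_s = labels.size
        count = math.factorial(n_s)
        for lev in np.unique(labels):
            count //= math.factorial(int(np.sum(labels == lev)))
        total *= count
    return total


def _stratified_permutation_indices(date_codes, rng, iterations):
    """(iterations, n) index arrays permuting positions within date strata."""
    n = date_codes.size
    idx = np.tile(np.arange(n), (iterations, 1))
    for stratum in np.unique(date_codes):
        pos = np.nonzero(date_codes == stratum)[0]
        sub = np.tile(pos, (iterations, 1))
        idx[:, pos] = rng.permuted(sub, axis=1)
    return idx


def _exhaustive_assignments(y, depth_codes, date_codes):
    """All distinct stratified reassignments of y to depth cells.

    Enumerates, per date stratum, every distinct arrangement of that
    stratum's depth-label multiset; an arrangement moves the y-values
    labelled `level` under the arrangement into the cell that the original
    design labels `level` (F depends on cell membership only).
    """
    strata = np.unique(date_codes)
    per_stratum = []
    for stratum in strata:
        pos = np.nonzero(date_codes == stratum)[0]
        labels = depth_codes[pos]
        arrangements = list(multiset_permutations(list(labels)))
        per_stratum.append((pos, labels, arrangements))
    columns = []
    for combo in product(*[a for _, _, a in per_stratum]):
        y_perm = y.copy()
        for (pos, labels, _), arr in zip(per_stratum, combo):
            arr = np.asarray(arr)
            for lev in np.unique(labels):
                y_perm[pos[labels == lev]] = y[pos[arr == lev]]
        columns.append(y_perm)
    return np.column_stack(columns)


def permutation_anova(
    y: Sequence[float],
    depth: Sequence,
    date: Sequence | None = None,
    iterations: int = 5000,
    seed: int | None = None,
    *,
    exhaustive_limit: int = 20_000,
    species_label: str = "",
    response: str = "",
) -> DepthTestResult:
    """Test the depth-layer effect on a response, with date as a covariate.

    Parameters
    ----------
    y
        Response values (e.g. % lipid area), one per individual.
    depth
        Depth-layer labels (categorical).
    date
        Sampling-date labels defining permutation strata; ``None`` means a
        single stratum.  Strata containing fewer than two depth levels are
        dropped with a logged warning.
    iterations
        Monte-Carlo permutation count (used when the stratified arrangement
        space exceeds ``exhaustive_limit``).
    seed
        RNG seed for the Monte-Carlo path; recorded in the result.
    """
    y = np.asarray(y, dtype=float)
    depth = np.asarray(depth)
    date = np.full(y.size, "all") if date is None else np.asarray(date)
    if not (y.size == depth.size == date.size):
        raise ValueError("y, depth and date must have equal length")
    if y.size == 0:
        raise ValueError("empty data")

    # drop strata lacking depth contrast
    dropped: list[str] = []
    keep = np.ones(y.size, dtype=bool)
    for stratum in np.unique(date):
        mask = date == stratum
        if np.unique(depth[mask]).size < 2:
            dropped.append(str(stratum))
            keep &= ~mask
            logger.warning(
                "permutation_anova[%s/%s]: dropping date stratum %r "
                "(single depth level, %d records)",
                species_label, response, stratum, int(mask.sum()),
            )
    y, depth, date = y[keep], depth[keep], date[keep]
    if y.size == 0:
        raise ValueError("no stratum contains more than one depth level")

    depth_levels, depth_codes = np.unique(depth, return_inverse=True)
    date_levels, date_codes = np.unique(date, return_inverse=True)
    if depth_levels.size < 2:
        raise ValueError("need at least two depth levels")

    q_red, q_full = _orth_bases(depth_codes, date_codes, depth_levels.size, date_levels.size)
    df_depth = q_full.shape[1] - q_red.shape[1]
    df_resid = y.size - q_full.shape[1]
    if df_depth < 1:
        raise ValueError("depth effect confounded with date (zero df)")
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    f_obs = float(_f_from_columns(y[:, None], q_red, q_full, df_depth, df_resid)[0])

    # ties in the null distribution count as hits; F is compared with a
    # tolerance relative to its magnitude to absorb float noise
    f_tol = 1e-9 * max(1.0, abs(f_obs))
    n_arrangements = count_stratified_arrangements(depth_codes, date_codes)
    if n_arrangements <= exhaustive_limit:
        Y = _exhaustive_assignments(y, depth_codes, date_codes)
        f_null = _f_from_columns(Y, q_red, q_full, df_depth, df_resid)
        hits = int(np.sum(f_null >= f_obs - f_tol))
        p_raw = hits / n_arrangements  # identity arrangement included => p > 0
        used, exact = n_arrangements, True
    else:
        if iterations < 1:
            raise ValueError("iterations must be >= 1")
        rng = np.random.default_rng(seed)
        idx = _stratified_permutation_indices(date_codes, rng, iterations)
        f_null = _f_from_columns(y[idx].T, q_red, q_full, df_depth, df_resid)
        hits = int(np.sum(f_null >= f_obs - f_tol))
        p_raw = (1 + hits) / (1 + iterations)
        used, exact = iterations, False

    return DepthTestResult(
        species_label=species_label,
        response=response,
        F_obs=f_obs,
        df_depth=df_depth,
        df_resid=df_resid,
        iterations=used,
        p_raw=p_raw,
        seed=seed,
        exact=exact,
        n=int(y.size),
        dropped_strata=tuple(dropped),
    )


def holm_bonferroni(p_values: Sequence[float]) -> list[float]:
    """Step-down Holm adjustment, returned in input order and capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        running_max = max(running_max, (m - rank) * p[idx])
        adjusted[idx] = min(running_max, 1.0)
    return adjusted.tolist()


def attach_holm(results: Sequence[DepthTestResult]) -> list[DepthTestResult]:
    """Holm-adjust a family of depth tests (one family per response)."""
    adj = holm_bonferroni([r.p_raw for r in results])
    return [replace(r, p_adjusted=a) for r, a in zip(results, adj)]


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H test on midranks.

    H = 12/(N(N+1)) * sum n_i * Rbar_i^2 - 3(N+1), divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N); p from chi-square with k-1 df.
    All values tied gives H = 0, p = 1.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    if n_total < 3:
        raise ValueError("need total n >= 3")
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + a.size]
        h += a.size * r.mean() ** 2
        start += a.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    tie_corrected = tie_term > 0
    if correction <= 0:  # every value identical
        return RankTestResult(H=0.0, df=len(arrays) - 1, p=1.0, tie_corrected=True)
    h /= correction
    h = max(h, 0.0)
    df = len(arrays) - 1
    p = float(sps.chi2.sf(h, df)) if h > 0 else 1.0
    return RankTestResult(H=float(h), df=df, p=p, tie_corrected=tie_corrected)


def two_way_anova(y: Sequence[float], depth: Sequence, stage: Sequence) -> dict:
    """Additive two-way ANOVA (depth + stage), sequential (type-I) SS.

    Each factor's F is reported with that factor entered *after* the other,
    so the two entries coincide only for balanced (orthogonal) designs.
    Returns ``{"depth": {"F", "df", "p"}, "stage": {...}}``.
    """
    import pandas as pd
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm

    y = np.asarray(y, dtype=float)
    depth = np.asarray(depth).astype(str)
    stage = np.asarray(stage).astype(str)
    if np.unique(depth).size < 2 or np.unique(stage).size < 2:
        raise ValueError("both factors need at least two levels")
    df = pd.DataFrame({"y": y, "depth": depth, "stage": stage})
    if float(np.var(y)) == 0.0:
        return {
            "depth": {"F": 0.0, "df": np.unique(depth).size - 1, "p": 1.0},
            "stage": {"F": 0.0, "df": np.unique(stage).size - 1, "p": 1.0},
        }
    out = {}
    for factor, formula in (
        ("depth", "y ~ C(stage) + C(depth)"),
        ("stage", "y ~ C(depth) + C(stage)"),
    ):
        fit = ols(formula, data=df).fit()
        if fit.df_resid < 1:
            raise ValueError("rank-deficient design: no residual df")
        table = anova_lm(fit, typ=1)
        row = table.loc[f"C({factor})"]
        out[factor] = {
            "F": float(row["F"]),
            "df": int(row["df"]),
            "p": float(row["PR(>F)"]),
        }
    return out


def length_lipid_regression(
    lengths: Sequence[float], lipid_areas: Sequence[float]
) -> dict:
    """OLS of absolute lipid area on prosome length: slope, intercept, R², p."""
    x = np.asarray(lengths, dtype=float)
    yv = np.asarray(lipid_areas, dtype=float)
    if x.size != yv.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if float(np.var(x)) == 0.0:
        raise ValueError("zero variance in prosome length")
    res = sps.linregress(x, yv)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p": float(res.pvalue),
        "stderr": float(res.stderr),
        "n": int(x.size),
    }
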