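"""Community statistics: PERMANOVA on Bray-Curtis, KW/Dunn, sign test.

The multivariate workflow mirrors the standard community-ecology chain:
arcsine-square-root transform of proportion covers, removal of OTUs seen
in fewer than 5% of transects, Bray-Curtis dissimilarity, one-way
permutational MANOVA (pseudo-F from the distance-based sums of squares,
p by label permutation) with pairwise post-hocs, plus the nonparametric
univariate tests (tie-corrected Kruskal-Wallis with Dunn's z post-hocs,
and the exact two-sided paired sign test).

All permutation machinery is implemented here; library routines are used
only for rank assignment, binomial tail masses and multiple-testing
adjustment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PermanovaResult",
    "PairwiseResult",
    "KWDunnResult",
    "SignTestResult",
    "arcsine_transform",
    "filter_rare_otus",
    "bray_curtis",
    "permanova",
    "pairwise_permanova",
    "kruskal_wallis_dunn",
    "sign_test",
]

_META_COLS = ("site_id", "area", "survey_id", "transect")


@dataclass(frozen=True)
class PermanovaResult:
    factor: str
    df_between: int
    df_resid: int
    ss_between: float
    ss_resid: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int | None

    def summary(self) -> str:
        return (
            f"PERMANOVA [{self.factor}]: pseudo-F({self.df_between},{self.df_resid})"
            f" = {self.pseudo_f:.2f}, p = {self.p_value:.4g}"
            f" ({self.n_permutations} permutations)"
        )


@dataclass(frozen=True)
class PairwiseResult:
    factor: str
    table: pd.DataFrame  # group_a, group_b, pseudo_f, p_raw, p_adjusted
    adjust: str


@dataclass(frozen=True)
class KWDunnResult:
    h_statistic: float  # tie-corrected
    df: int
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, z, p_raw, p_adjusted
    adjust: str


@dataclass(frozen=True)
class SignTestResult:
    """Exact two-sided paired sign test.

    ``s`` counts positive differences x - y among the ``n_effective``
    untied pairs; the p-value doubles the smaller exact Binomial(n, 1/2)
    tail, capped at 1.
    """

    s: int
    n_effective: int
    p_value: float
    direction: str = "x_minus_y"


def _values(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    value_cols = [c for c in matrix.columns if c not in _META_COLS]
    return matrix[value_cols], value_cols


def arcsine_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Arcsine-square-root transform, arcsin(sqrt(v)), on proportions in [0, 1]."""
    vals, cols = _values(matrix)
    arr = vals.to_numpy(dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("arcsine transform requires proportions in [0, 1]")
    out = matrix.copy()
    out[cols] = np.arcsin(np.sqrt(arr))
    return out


def filter_rare_otus(matrix: pd.DataFrame, min_prevalence: float = 0.05) -> pd.DataFrame:
    """Drop OTU columns present (value > 0) in fewer than 5% of rows.

    The cut is strict: prevalence exactly at ``min_prevalence`` is kept.
    Applied to the full pooled transect set before any subsetting.
    """
    vals, cols = _values(matrix)
    prevalence = (vals > 0).mean(axis=0)
    keep = [c for c in cols if prevalence[c] >= min_prevalence]
    if not keep:
        raise ValueError("rare-OTU filter removed every column")
    meta = [c for c in matrix.columns if c in _META_COLS]
    return matrix[meta + keep]


def bray_curtis(matrix: pd.DataFrame) -> np.ndarray:
    """Bray-Curtis dissimilarity matrix between rows.

    d(i,j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk); a semimetric in
    [0, 1] for nonnegative data. All-zero rows are rejected (d undefined).
    """
    vals, _ = _values(matrix)
    x = vals.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("Bray-Curtis requires nonnegative values")
    zero_rows = np.flatnonzero(x.sum(axis=1) == 0)
    if zero_rows.size:
        raise ValueError(f"all-zero rows (undefined distance): {zero_rows.tolist()}")
    num = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    den = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    return num / den


def _ss_partition(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(ss_between, ss_within) from squared distances and group labels."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)  # (1/N) sum_{i<j} d^2
    ss_within = 0.0
    for g in np.unique(labels):
        idx = labels == g
        ng = int(idx.sum())
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * ng)
    return ss_total - ss_within, ss_within


def _pseudo_f_many(d2: np.ndarray, label_codes: np.ndarray, perms: np.ndarray) -> np.ndarray:
    """Pseudo-F for each row of permuted label assignments (vectorised).

    ``perms``: (m, N) integer array, each row a permutation of the group
    codes. Returns the m pseudo-F values up to the constant df ratio,
    i.e. actual F values.
    """
    n = d2.shape[0]
    groups = np.unique(label_codes)
    a = groups.size
    ss_total = d2.sum() / (2 * n)
    ss_within = np.zeros(perms.shape[0])
    for g in groups:
        mask = (perms == g).astype(float)  # (m, N)
        ng = mask.sum(axis=1)
        # sum over i,j in group of d2_ij = 1_g' D2 1_g
        quad = ((mask @ d2) * mask).sum(axis=1)
        ss_within += quad / (2 * ng)
    ss_between = ss_total - ss_within
    return (ss_between / (a - 1)) / (ss_within / (n - a))


def permanova(
    dist: np.ndarray,
    labels,
    *,
    n_perm: int = 9999,
    seed: int | None = None,
    factor: str = "group",
    exact: bool = False,
) -> PermanovaResult:
    """One-way permutational MANOVA on a distance matrix.

    SS are partitioned from squared distances (SS_total = (1/N) sum_{i<j}
    d2_ij; SS_within summed per group with 1/n_g weights); pseudo-F =
    (SS_between/(a-1)) / (SS_within/(N-a)). The p-value is the
    add-one permutation estimate (1 + #{F_perm >= F_obs}) / (1 + n_perm)
    under random relabelling with the given seed, so p is never zero.

    ``exact=True`` enumerates every distinct label arrangement instead
    (feasible only for small N); p is then #{F >= F_obs} / #arrangements,
    the identity arrangement included.
    """
    d = np.asarray(dist, dtype=float)
    codes, uniques = pd.factorize(np.asarray(labels))
    n = d.shape[0]
    if codes.shape[0] != n:
        raise ValueError("labels do not align with the distance matrix")
    a = uniques.size
    if a < 2:
        raise ValueError("need at least two groups")
    if np.all(np.bincount(codes) == 1):
        raise ValueError("every group is a singleton; no within-group variation")
    d2 = d**2

    ss_between, ss_within = _ss_partition(d2, codes)
    df_b, df_r = a - 1, n - a
    f_obs = (ss_between / df_b) / (ss_within / df_r)
    if not np.isfinite(f_obs):
        raise ValueError("non-finite pseudo-F (degenerate distance matrix)")

    if exact:
        perms = np.array(sorted({p for p in itertools.permutations(codes)}))
        f_perm = _pseudo_f_many(d2, codes, perms)
        p = int(np.sum(f_perm >= f_obs - 1e-12)) / perms.shape[0]
        n_perm = perms.shape[0]
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
        f_perm = _pseudo_f_many(d2, codes, perms)
        p = (1 + int(np.sum(f_perm >= f_obs - 1e-12))) / (1 + n_perm)
    return PermanovaResult(
        factor=factor, df_between=df_b, df_resid=df_r,
        ss_between=ss_between, ss_resid=ss_within,
        pseudo_f=float(f_obs), p_value=float(p),
        n_permutations=n_perm, seed=seed,
    )


def pairwise_permanova(
    dist: np.ndarray,
    labels,
    *,
    n_perm: int = 9999,
    seed: int | None = None,
    adjust: str = "BH",
    factor: str = "group",
) -> PairwiseResult:
    """PERMANOVA on every group pair's submatrix, with p adjustment.

    ``adjust``: "BH" (Benjamini-Hochberg, default), "bonferroni", "holm"
    or "none".
    """
    d = np.asarray(dist, dtype=float)
    lab = np.asarray(labels)
    groups = pd.unique(lab)
    rng = np.random.default_rng(seed)
    rows = []
    for ga, gb in itertools.combinations(groups, 2):
        idx = np.flatnonzero((lab == ga) | (lab == gb))
        sub = d[np.ix_(idx, idx)]
        res = permanova(
            sub, lab[idx], n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)), factor=f"{ga} vs {gb}",
        )
        rows.append({"group_a": ga, "group_b": gb,
                     "pseudo_f": res.pseudo_f, "p_raw": res.p_value})
    table = pd.DataFrame(rows)
    if adjust == "none":
        table["p_adjusted"] = table["p_raw"]
    else:
        method = {"BH": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}[adjust]
        table["p_adjusted"] = multipletests(table["p_raw"], method=method)[1]
    return PairwiseResult(factor=factor, table=table, adjust=adjust)


def kruskal_wallis_dunn(
    groups: dict[str, np.ndarray], *, adjust: str = "none"
) -> KWDunnResult:
    """Tie-corrected Kruskal-Wallis H with Dunn's pairwise z tests.

    H = (12/(N(N+1))) sum n_i (Rbar_i - Rbar)^2, divided by the tie
    correction 1 - sum(t^3 - t)/(N^3 - N); p from chi-square with a-1 df.
    Dunn's z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with T = sum(t^3 - t)/(12(N-1)); two-sided normal p per pair,
    unadjusted by default.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for k, arr in zip(names, arrays):
        if arr.size == 0:
            raise ValueError(f"group {k!r} has no observations")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)  # midranks for ties
    sizes = np.array([a.size for a in arrays])
    bounds = np.cumsum(sizes)
    rank_groups = np.split(ranks, bounds[:-1])
    mean_ranks = np.array([r.mean() for r in rank_groups])

    grand = (n_total + 1) / 2
    h = 12.0 / (n_total * (n_total + 1)) * np.sum(sizes * (mean_ranks - grand) ** 2)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    # correction hits 0 only when every observation is identical: no evidence
    h_corrected = h / correction if correction > 0 else 0.0
    df = len(arrays) - 1
    p = float(sps.chi2.sf(h_corrected, df)) if correction > 0 else 1.0

    t_tie = tie_term / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - t_tie
    rows = []
    for i, j in itertools.combinations(range(len(names)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        rows.append({"group_a": names[i], "group_b": names[j],
                     "z": float(z), "p_raw": float(2 * sps.norm.sf(abs(z)))})
    pairwise = pd.DataFrame(rows)
    if adjust == "none":
        pairwise["p_adjusted"] = pairwise["p_raw"]
    else:
        method = {"BH": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm"}[adjust]
        pairwise["p_adjusted"] = multipletests(pairwise["p_raw"], method=method)[1]
    return KWDunnResult(
        h_statistic=float(h_corrected), df=df, p_value=p,
        pairwise=pairwise, adjust=adjust,
    )


def sign_test(x, y, *, direction: str = "x_minus_y") -> SignTestResult:
    """Exact two-sided paired sign test.

    Differences d = x - y (or y - x with ``direction="y_minus_x"``); zero
    differences are dropped; S counts d > 0 among the n untied pairs and
    p = min(1, 2 * min(P(X <= S), P(X >= S))) for X ~ Binomial(n, 1/2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    d = x - y if direction == "x_minus_y" else y - x
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all pairs are tied; sign test undefined")
    s = int(np.sum(d > 0))
    p = 2 * min(sps.binom.cdf(s, n, 0.5), sps.binom.sf(s - 1, n, 0.5))
    return SignTestResult(s=s, n_effective=n, p_value=float(min(1.0, p)),
                          direction=direction)
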