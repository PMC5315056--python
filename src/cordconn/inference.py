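"""Permutation-based group inference.

One-sample effects are tested by sign-flipping per-subject values (valid
under symmetry of the subject distribution), with family-wise error (FWE)
control by the max-statistic over synchronized flips.  Joint inference
across many analyses uses either the average-across-analyses test or
non-parametric combination (NPC) with the Fisher combining function.
Repeated-measures ANOVA main effects use the Greenhouse-Geisser
degrees-of-freedom correction for non-sphericity.

P-value conventions: two-tailed via |t|; the observed statistic is included
in the null set (add-one convention), so p is always in (0, 1]; exact
enumeration of all 2^n sign patterns replaces random sampling whenever
2^n <= n_flips; degenerate (zero-variance) statistics map to t = 0, p = 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class InferenceError(ValueError):
    pass


@dataclass
class PermResult:
    """Observed statistic with uncorrected and FWE-corrected two-tailed p."""

    stat: float
    p_uncorrected: float
    p_fwe: float
    n_resamples: int
    seed: object = None
    exhaustive: bool = False

    def __post_init__(self):
        if not (0 < self.p_uncorrected <= 1 and 0 < self.p_fwe <= 1):
            raise InferenceError("p-values must lie in (0, 1]")
        if self.p_fwe < self.p_uncorrected - 1e-12:
            raise InferenceError("corrected p cannot undercut uncorrected p")


# ---------------------------------------------------------------------------
# sign-flip machinery
# ---------------------------------------------------------------------------

def _flip_matrix(n: int, n_flips: int, rng) -> tuple:
    """(flips, exhaustive): all 2^n sign patterns when feasible, else a
    random sample of ``n_flips`` patterns."""
    if 2 ** n <= n_flips:
        bits = (np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]) & 1
        return bits * 2.0 - 1.0, True
    flips = rng.integers(0, 2, size=(n_flips, n)) * 2.0 - 1.0
    return flips, False


def _t_null(values: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """One-sample t statistics of sign-flipped columns, shape (B, k).

    Exploits that the flipped sum of squares equals the unflipped one.
    """
    n = values.shape[0]
    sums = flips @ values                      # (B, k)
    mean = sums / n
    ss = (values ** 2).sum(axis=0)             # (k,)
    var = (ss[None, :] - n * mean ** 2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    # zero variance: nonzero mean -> infinite t (sign kept); zero mean -> 0
    t[np.isnan(t)] = 0.0
    return t


def fwe_family(values, n_flips: int = 10000, seed=None, flips=None) -> list:
    """Synchronized sign-flip tests over a family of k one-sample effects.

    ``values`` is (n, k); the same flips are applied to every column and
    the FWE-corrected p for column j counts flips whose max_i |t*_i|
    reaches |t_j|.  Returns one :class:`PermResult` per column.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.ndim != 2:
        raise InferenceError("values must be (n, k)")
    n, k = values.shape
    if n < 2:
        raise InferenceError("need at least 2 subjects")
    rng = np.random.default_rng(seed)
    if flips is None:
        flips, exhaustive = _flip_matrix(n, n_flips, rng)
    else:
        flips = np.asarray(flips, dtype=float)
        exhaustive = flips.shape[0] == 2 ** n
    tnull = _t_null(values, flips)             # (B, k)
    tobs = _t_null(values, np.ones((1, n)))[0]  # (k,)
    abs_null = np.abs(tnull)
    max_null = abs_null.max(axis=1)
    B = flips.shape[0]
    results = []
    for j in range(k):
        if np.all(values[:, j] == 0):
            results.append(PermResult(stat=0.0, p_uncorrected=1.0, p_fwe=1.0,
                                      n_resamples=B, seed=seed,
                                      exhaustive=exhaustive))
            continue
        cnt_u = int(np.sum(abs_null[:, j] >= abs(tobs[j]) - 1e-12))
        cnt_f = int(np.sum(max_null >= abs(tobs[j]) - 1e-12))
        if exhaustive:
            p_u, p_f = cnt_u / B, cnt_f / B
        else:
            p_u, p_f = (1 + cnt_u) / (1 + B), (1 + cnt_f) / (1 + B)
        results.append(PermResult(stat=float(tobs[j]), p_uncorrected=p_u,
                                  p_fwe=max(p_f, p_u), n_resamples=B,
                                  seed=seed, exhaustive=exhaustive))
    return results


def signflip_one_sample(values, n_flips: int = 10000, seed=None) -> PermResult:
    """Two-tailed one-sample sign-flip test of mean zero (statistic: t)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise InferenceError("values must be 1-dimensional")
    return fwe_family(values[:, None], n_flips=n_flips, seed=seed)[0]


def paired_permutation(values_a, values_b, n_flips: int = 10000,
                       seed=None) -> list:
    """Permutation analogue of the paired t-test on per-subject differences.

    ``values_a``/``values_b`` are (n,) or (n, k) with paired rows; with k
    contrasts the FWE correction spans the family of k tests.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise InferenceError("paired samples must have equal shape")
    d = a - b
    if d.ndim == 1:
        return [signflip_one_sample(d, n_flips=n_flips, seed=seed)]
    return fwe_family(d, n_flips=n_flips, seed=seed)


def average_across_analyses_test(values, n_flips: int = 10000, seed=None) -> PermResult:
    """Sign-flip test of the per-subject average across J analyses.

    ``values`` is (n, J); the null hypothesis is that the average effect is
    zero.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return signflip_one_sample(values.mean(axis=1), n_flips=n_flips, seed=seed)


# ---------------------------------------------------------------------------
# non-parametric combination
# ---------------------------------------------------------------------------

def _npc_stats(values: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """Fisher combining statistic S_b = -2 sum_j ln p_jb per flip.

    Within-flip per-analysis p-values are computed by ranking each flip's
    |t| against the full flip distribution of that analysis (row 0 is the
    identity flip = observed data).
    """
    tnull = np.abs(_t_null(values, flips))     # (B, J)
    B, J = tnull.shape
    p = np.empty_like(tnull)
    for j in range(J):
        order = np.sort(tnull[:, j])
        # count of flips with |t| >= this flip's |t| (self included)
        p[:, j] = (B - np.searchsorted(order, tnull[:, j] - 1e-12,
                                       side="left")) / B
    return -2.0 * np.log(p).sum(axis=1)


def npc_fisher(values, n_flips: int = 10000, seed=None, flips=None) -> PermResult:
    """Joint NPC test across J analyses with the Fisher combining function.

    ``values`` is (n, J); sign flips are synchronized across analyses; the
    null hypothesis is that all J effects are zero.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n, J = values.shape
    if J == 0:
        raise InferenceError("need at least one analysis for NPC")
    rng = np.random.default_rng(seed)
    if flips is None:
        flips, exhaustive = _flip_matrix(n, n_flips, rng)
        if not exhaustive:
            flips = np.vstack([np.ones((1, n)), flips])  # identity first
    S = _npc_stats(values, flips)
    # locate the identity flip (observed data)
    id_row = np.nonzero(np.all(flips == 1.0, axis=1))[0][0]
    s_obs = S[id_row]
    B = flips.shape[0]
    p = float(np.sum(S >= s_obs - 1e-12) / B)
    return PermResult(stat=float(s_obs), p_uncorrected=p, p_fwe=p,
                      n_resamples=B, seed=seed)


def npc_fisher_family(values_by_test: dict, n_flips: int = 10000, seed=None) -> dict:
    """NPC per test with FWE over the family via the max combining statistic."""
    names = list(values_by_test)
    first = np.asarray(values_by_test[names[0]], dtype=float)
    n = first.shape[0]
    rng = np.random.default_rng(seed)
    flips, exhaustive = _flip_matrix(n, n_flips, rng)
    if not exhaustive:
        flips = np.vstack([np.ones((1, n)), flips])
    S = {name: _npc_stats(np.asarray(values_by_test[name], dtype=float), flips)
         for name in names}
    id_row = np.nonzero(np.all(flips == 1.0, axis=1))[0][0]
    S_max = np.max(np.stack([S[name] for name in names]), axis=0)
    B = flips.shape[0]
    out = {}
    for name in names:
        s_obs = S[name][id_row]
        p_u = float(np.sum(S[name] >= s_obs - 1e-12) / B)
        p_f = float(np.sum(S_max >= s_obs - 1e-12) / B)
        out[name] = PermResult(stat=float(s_obs), p_uncorrected=p_u,
                               p_fwe=max(p_f, p_u), n_resamples=B, seed=seed)
    return out


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Main effect of one within-subject factor with GG correction."""

    factor: str
    F: float
    df1: int
    df2: int
    epsilon: float
    df1_gg: float
    df2_gg: float
    p: float


def _gg_epsilon(Y: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the subject x level matrix."""
    k = Y.shape[1]
    if k == 2:
        return 1.0
    S = np.cov(Y, rowvar=False)
    Jc = np.eye(k) - np.ones((k, k)) / k
    Sc = Jc @ S @ Jc
    num = np.trace(Sc) ** 2
    den = (k - 1) * np.trace(Sc @ Sc)
    if den <= 0:
        return 1.0
    return float(np.clip(num / den, 1.0 / (k - 1), 1.0))


def rm_anova_main_effects(values: np.ndarray, factor_names,
                          factor_levels=None) -> pd.DataFrame:
    """Main effects of a complete within-subject factorial design.

    ``values`` has shape (n_subjects, l1, l2, ...); for each factor the
    grid is collapsed (averaged) over the other factors and the one-way
    repeated-measures F statistic is computed with Greenhouse-Geisser
    corrected degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != len(factor_names) + 1:
        raise InferenceError("values must be (subjects, level_1, ..., level_m)")
    if not np.all(np.isfinite(values)):
        raise InferenceError("incomplete grid (non-finite cells)")
    n = values.shape[0]
    rows = []
    for fi, fname in enumerate(factor_names):
        other = tuple(ax for ax in range(1, values.ndim) if ax != fi + 1)
        Y = values.mean(axis=other) if other else values  # (n, k)
        k = Y.shape[1]
        grand = Y.mean()
        subj_mean = Y.mean(axis=1, keepdims=True)
        lvl_mean = Y.mean(axis=0, keepdims=True)
        ss_lvl = n * ((lvl_mean - grand) ** 2).sum()
        resid = Y - subj_mean - lvl_mean + grand
        ss_err = (resid ** 2).sum()
        df1, df2 = k - 1, (k - 1) * (n - 1)
        if ss_err <= 1e-30:
            F = 0.0
            p = 1.0
            eps = 1.0
        else:
            F = (ss_lvl / df1) / (ss_err / df2)
            eps = _gg_epsilon(Y)
            p = float(stats.f.sf(F, eps * df1, eps * df2))
        rows.append(AnovaResult(factor=fname, F=float(F), df1=df1, df2=df2,
                                epsilon=eps, df1_gg=eps * df1, df2_gg=eps * df2,
                                p=p))
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("factor")


# ---------------------------------------------------------------------------
# fingerprints and descriptive summaries
# ---------------------------------------------------------------------------

SEGMENT_PAIRS = {
    1: [("C6", "C7"), ("C7", "C8"), ("C8", "T1")],
    2: [("C6", "C8"), ("C7", "T1")],
    3: [("C6", "T1")],
}


def fingerprint_similarity(profiles: dict, n_flips: int = 10000,
                           seed=None) -> pd.DataFrame:
    """Similarity of intra-segmental connectivity patterns vs distance.

    ``profiles`` maps segment name -> (n_subjects, 4) array of the four
    intra-segmental indices.  Per subject and segment pair, the Pearson
    correlation of the two 4-vectors is computed; pairs are averaged within
    inter-segmental distance class (3, 2, 1 pairs for distances 1, 2, 3),
    and each distance's group mean is tested by sign-flip with FWE over the
    three distances.
    """
    segs = list(profiles)
    n = np.asarray(profiles[segs[0]]).shape[0]
    per_distance = {}
    for dist, pairs in SEGMENT_PAIRS.items():
        vals = np.full((n, len(pairs)), np.nan)
        for pj, (a, b) in enumerate(pairs):
            A = np.asarray(profiles[a], dtype=float)
            B = np.asarray(profiles[b], dtype=float)
            for i in range(n):
                if A[i].std() == 0 or B[i].std() == 0:
                    warnings.warn(f"constant pattern for subject {i} "
                                  f"pair {a}-{b}; skipped")
                    continue
                vals[i, pj] = np.corrcoef(A[i], B[i])[0, 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_distance[dist] = np.nanmean(vals, axis=1)
    mat = np.column_stack([per_distance[d] for d in sorted(per_distance)])
    valid = np.all(np.isfinite(mat), axis=1)
    if not valid.all():
        warnings.warn(f"{int((~valid).sum())} subject(s) without a valid "
                      "similarity at some distance; dropped from inference")
    results = fwe_family(mat[valid], n_flips=n_flips, seed=seed)
    rows = []
    for j, dist in enumerate(sorted(per_distance)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean_r = float(np.nanmean(per_distance[dist]))
        rows.append({"distance": dist, "n_pairs": len(SEGMENT_PAIRS[dist]),
                     "mean_r": mean_r,
                     "t": results[j].stat,
                     "p_uncorrected": results[j].p_uncorrected,
                     "p_fwe": results[j].p_fwe})
    return pd.DataFrame(rows).set_index("distance")


def percent_positive(values) -> float:
    """Percentage of subjects with a strictly positive value."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise InferenceError("need at least one value")
    return float(100.0 * np.count_nonzero(values > 0) / values.size)
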