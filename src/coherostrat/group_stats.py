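"""Group formation and inference: MEP median split, two-sample tests,
electrode-pair maps with Benjamini-Hochberg FDR, the mixed three-way
ANOVA on Total Coherence, and Duncan's multiple range post hoc.

Design conventions
------------------
* The median split sends amplitudes strictly below the sample median to
  L-MEP and everything else (including median ties) to H-MEP.
* FDR families are per band: all electrode pairs of one band form one
  family, so each band reports its own adjusted threshold.
* The ANOVA is the univariate mixed model with Group between subjects and
  ROI, Band within; each within-subject effect is tested against its own
  subject-interaction error stratum, with no sphericity correction.
* Duncan's test protects the comparison of ``p`` ordered means at level
  1 - (1-alpha)^(p-1), using the studentized range distribution, with the
  usual no-crossing (containment) rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .spectral_coherence import CoherenceSet

__all__ = [
    "median_split",
    "t_test_two_sample",
    "t_from_summary",
    "chi_square_2x2",
    "pearson_r",
    "fdr_bh",
    "PairwiseTestMap",
    "pairwise_map_test",
    "AnovaTable",
    "mixed_anova_totcoh",
    "duncan_mrt",
    "duncan_group_by_cell",
]


# ---------------------------------------------------------------------------
# stratification and elementary tests

def median_split(cohort: pd.DataFrame) -> pd.DataFrame:
    """Assign L-MEP / H-MEP by the sample median of ``mep_amplitude``.

    Amplitudes strictly below the median go to L-MEP; values at or above
    it to H-MEP, so median ties land in the high group.
    """
    if len(cohort) < 4:
        raise ValueError("need at least four subjects to split")
    amps = cohort["mep_amplitude"].to_numpy(dtype=float)
    if np.ptp(amps) == 0:
        raise ValueError("all MEP amplitudes identical; split undefined")
    med = float(np.median(amps))
    out = cohort.copy()
    out["group"] = np.where(amps < med, "L-MEP", "H-MEP")
    return out


def t_test_two_sample(a, b, variant: str = "pooled") -> tuple[float, float, float]:
    """Two-tailed unpaired t-test; returns (t, df, p).

    ``variant`` is ``"pooled"`` (Student, equal variances — the default) or
    ``"welch"``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.var() + b.var() == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("degenerate zero-variance groups with unequal means")
    if variant == "pooled":
        res = stats.ttest_ind(a, b, equal_var=True)
        df = len(a) + len(b) - 2
    elif variant == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        df = float(res.df)
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    return float(res.statistic), float(df), float(res.pvalue)


def t_from_summary(m1: float, se1: float, n1: int,
                   m2: float, se2: float, n2: int) -> tuple[float, float, float]:
    """Pooled two-sample t reconstructed from printed summaries
    (means, standard errors, group sizes); returns (t, df, p)."""
    s1sq = n1 * se1 ** 2
    s2sq = n2 * se2 ** 2
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1sq + (n2 - 1) * s2sq) / df
    t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi_square_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with two-tailed p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need n >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# FDR and pairwise maps

def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over one family.

    Returns (rejection mask in input order, adjusted threshold p_FDR).
    p_FDR is the largest raw p that is still rejected — the per-family
    "corrected threshold" convention — and 0.0 when nothing is rejected.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    ks = np.flatnonzero(sorted_p <= (np.arange(1, m + 1) * q / m))
    if ks.size == 0:
        return np.zeros(m, dtype=bool), 0.0
    p_fdr = float(sorted_p[ks[-1]])
    return p <= p_fdr, p_fdr


@dataclass
class PairwiseTestMap:
    """Per-band electrode-pair test results.

    ``table`` columns: band, ch_i, ch_j, t, p_raw, diff (mean L - mean H),
    significant. ``p_fdr`` maps band -> the family's adjusted threshold.
    """

    table: pd.DataFrame
    p_fdr: dict[str, float]
    q: float
    labels: list[str]


def pairwise_map_test(coh_l: list[CoherenceSet], coh_h: list[CoherenceSet],
                      bands: list[str] | None = None, q: float = 0.05,
                      variant: str = "pooled") -> PairwiseTestMap:
    """Mass-univariate two-sample t over electrode pairs, FDR per band.

    ``coh_l`` / ``coh_h`` are the per-subject band coherence sets of the
    two groups (identical channel sets required). The signed difference is
    mean(L) - mean(H), so negative values mean lower coherence in the
    low-excitability group.
    """
    if len(coh_l) < 2 or len(coh_h) < 2:
        raise ValueError("each group needs at least two subjects")
    labels = coh_l[0].labels
    for cs in coh_l + coh_h:
        if cs.labels != labels:
            raise ValueError("channel sets differ across subjects")
    if bands is None:
        bands = coh_l[0].bands
    n = len(labels)
    pairs = list(combinations(range(n), 2))
    rows = []
    p_fdr: dict[str, float] = {}
    for band in bands:
        stack_l = np.stack([cs[band] for cs in coh_l])   # subjects x n x n
        stack_h = np.stack([cs[band] for cs in coh_h])
        i_idx = np.array([i for i, _ in pairs])
        j_idx = np.array([j for _, j in pairs])
        a = stack_l[:, i_idx, j_idx]                     # subjects x pairs
        b = stack_h[:, i_idx, j_idx]
        res = stats.ttest_ind(a, b, axis=0, equal_var=(variant == "pooled"))
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        p = np.where(np.isnan(p), 1.0, p)                # zero-variance pairs
        t = np.where(np.isnan(t), 0.0, t)
        mask, thr = fdr_bh(p, q)
        p_fdr[band] = thr
        diff = a.mean(axis=0) - b.mean(axis=0)
        for k, (i, j) in enumerate(pairs):
            rows.append({"band": band, "ch_i": labels[i], "ch_j": labels[j],
                         "t": t[k], "p_raw": p[k], "diff": diff[k],
                         "significant": bool(mask[k])})
    table = pd.DataFrame(rows, columns=["band", "ch_i", "ch_j", "t", "p_raw",
                                        "diff", "significant"])
    return PairwiseTestMap(table=table, p_fdr=p_fdr, q=q, labels=list(labels))


# ---------------------------------------------------------------------------
# mixed three-way ANOVA

@dataclass
class AnovaTable:
    """Mixed-design ANOVA results: one row per effect with its error stratum."""

    table: pd.DataFrame   # effect, df_num, df_den, ss, ms, ms_error, F, p, stratum

    def effect(self, name: str) -> pd.Series:
        rows = self.table[self.table["effect"] == name]
        if rows.empty:
            raise KeyError(f"no effect {name!r}")
        return rows.iloc[0]

    def stratum_error(self, name: str) -> tuple[float, float]:
        """(mean-square error, df) of the stratum an effect is tested in."""
        row = self.effect(name)
        return float(row["ms_error"]), float(row["df_den"])


def mixed_anova_totcoh(tot: pd.DataFrame, groups: pd.DataFrame | dict,
                       value: str = "value") -> AnovaTable:
    """Three-way mixed ANOVA on TotCoh: Group (between) x ROI x Band (within).

    ``tot`` is the long TotCoh table (subject, band, scope, value) with the
    global scope ignored; ``groups`` maps subject id -> "L-MEP"/"H-MEP"
    (a dict or a cohort table with id/group columns). Requires a complete
    subject x ROI x band grid. Sums of squares are formed by the exact
    orthogonal stratum decomposition (subject means, within-subject ROI and
    band deviations and their interaction), each within-subject effect
    tested against its subject-interaction stratum.
    """
    if isinstance(groups, pd.DataFrame):
        gmap = dict(zip(groups["id"], groups["group"]))
    else:
        gmap = dict(groups)
    df = tot[tot["scope"] != "global"].copy()
    df["grp"] = df["subject"].map(gmap)
    if df["grp"].isna().any():
        missing = sorted(df.loc[df["grp"].isna(), "subject"].unique())
        raise ValueError(f"subjects without group assignment: {missing}")

    cube = df.pivot_table(index="subject", columns=["scope", "band"],
                          values=value, aggfunc="first")
    if cube.isna().any().any():
        raise ValueError("incomplete subject x ROI x band grid")
    rois = sorted(df["scope"].unique())
    bands = sorted(df["band"].unique())
    subjects = list(cube.index)
    r, b, N = len(rois), len(bands), len(subjects)
    g_labels = [gmap[s] for s in subjects]
    levels = sorted(set(g_labels))
    g = len(levels)
    if g < 2:
        raise ValueError("need at least two groups")
    y = cube.loc[:, [(roi, band) for roi in rois for band in bands]]\
        .to_numpy().reshape(N, r, b)

    grp_idx = np.array([levels.index(x) for x in g_labels])
    n_k = np.bincount(grp_idx, minlength=g)
    if (n_k < 2).any():
        raise ValueError("every group needs at least two subjects")

    grand = y.mean()
    subj_mean = y.mean(axis=(1, 2))                       # N
    grp_mean = np.array([subj_mean[grp_idx == k].mean() for k in range(g)])

    rows = []

    def add(effect, ss, dfn, ss_err, dfd, stratum):
        ms = ss / dfn
        mse = ss_err / dfd
        F = ms / mse
        p = stats.f.sf(F, dfn, dfd)
        rows.append({"effect": effect, "df_num": int(dfn), "df_den": int(dfd),
                     "ss": ss, "ms": ms, "ms_error": mse, "F": float(F),
                     "p": float(p), "stratum": stratum})

    # between-subject stratum
    ss_a = r * b * float(np.sum(n_k * (grp_mean - grand) ** 2))
    ss_s = r * b * float(np.sum((subj_mean - grp_mean[grp_idx]) ** 2))
    add("Group", ss_a, g - 1, ss_s, N - g, "subjects(Group)")

    # one within factor at a time: deviations of factor means from subject mean
    def within_stratum(factor_means, n_levels, mult, name):
        # factor_means: N x n_levels (already averaged over the other factor)
        d = factor_means - subj_mean[:, None]
        overall = d.mean(axis=0)                          # main effect curve
        ss_main = mult * N * float(np.sum(overall ** 2))
        ss_int = 0.0
        for k in range(g):
            dk = d[grp_idx == k].mean(axis=0)
            ss_int += mult * n_k[k] * float(np.sum((dk - overall) ** 2))
        resid = d - overall[None, :] \
            - (np.array([d[grp_idx == k].mean(axis=0) for k in range(g)])[grp_idx]
               - overall[None, :])
        ss_err = mult * float(np.sum(resid ** 2))
        dfd = (N - g) * (n_levels - 1)
        add(name, ss_main, n_levels - 1, ss_err, dfd, f"{name} x subjects(Group)")
        add(f"Group x {name}", ss_int, (g - 1) * (n_levels - 1), ss_err, dfd,
            f"{name} x subjects(Group)")

    within_stratum(y.mean(axis=2), r, b, "ROI")
    within_stratum(y.mean(axis=1), b, r, "Band")

    # ROI x Band stratum
    e = y - y.mean(axis=2, keepdims=True) - y.mean(axis=1, keepdims=True) \
        + subj_mean[:, None, None]
    overall = e.mean(axis=0)                              # r x b
    ss_rb = N * float(np.sum(overall ** 2))
    ss_grb = 0.0
    grp_dev = np.zeros((g, r, b))
    for k in range(g):
        grp_dev[k] = e[grp_idx == k].mean(axis=0) - overall
        ss_grb += n_k[k] * float(np.sum(grp_dev[k] ** 2))
    resid = e - overall[None] - grp_dev[grp_idx]
    ss_err = float(np.sum(resid ** 2))
    dfd = (N - g) * (r - 1) * (b - 1)
    add("ROI x Band", ss_rb, (r - 1) * (b - 1), ss_err, dfd,
        "ROI x Band x subjects(Group)")
    add("Group x ROI x Band", ss_grb, (g - 1) * (r - 1) * (b - 1), ss_err, dfd,
        "ROI x Band x subjects(Group)")

    table = pd.DataFrame(rows, columns=["effect", "df_num", "df_den", "ss",
                                        "ms", "ms_error", "F", "p", "stratum"])
    return AnovaTable(table=table)


# ---------------------------------------------------------------------------
# Duncan's multiple range test

import functools


@functools.lru_cache(maxsize=4096)
def _duncan_crit(p_span: int, df: float, alpha: float) -> float:
    """Duncan critical studentized range for a span of p ordered means:
    the (1 - alpha_p) quantile with protection level
    alpha_p = 1 - (1 - alpha)^(p - 1)."""
    alpha_p = 1.0 - (1.0 - alpha) ** (p_span - 1)
    return float(stats.studentized_range.ppf(1.0 - alpha_p, p_span, df))


def duncan_mrt(means, n_per_cell, ms_error: float, df_error: float,
               alpha: float = 0.05, labels: list[str] | None = None,
               nominal_p: bool = True) -> pd.DataFrame:
    """Duncan's multiple range test over a set of cell means.

    ``n_per_cell`` is the per-cell sample size (scalar, or per-cell array in
    which case the harmonic mean is used for each comparison span). Returns
    one row per mean pair: labels, span p, observed range, critical range,
    nominal p (observed tail probability converted back through the
    protection level), and the decision after the no-crossing rule.
    ``nominal_p=False`` skips the per-pair tail probabilities (the
    studentized-range survival function is costly) and reports NaN there;
    decisions are unaffected.
    """
    means = np.asarray(means, dtype=float)
    k = means.size
    if k < 2:
        raise ValueError("need at least two means")
    if ms_error <= 0:
        raise ValueError("ms_error must be positive")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    n = np.broadcast_to(np.asarray(n_per_cell, dtype=float), (k,))
    if labels is None:
        labels = [f"cell{i}" for i in range(k)]

    order = np.argsort(means, kind="stable")
    sm = means[order]

    # step-down: sweep spans from widest to narrowest; a span inside an
    # already-retained homogeneous span is never tested (containment /
    # no-crossing rule), and a non-significant span is retained whole
    homogeneous = np.zeros((k, k), dtype=bool)

    def se_for(i, j):
        inv = 1.0 / n[order[i:j + 1]]
        nh = (j - i + 1) / inv.sum()
        return np.sqrt(ms_error / nh)

    def contained(i, j):
        return any(homogeneous[a, b]
                   for a in range(0, i + 1) for b in range(j, k))

    for p_span in range(k, 1, -1):
        for i in range(0, k - p_span + 1):
            j = i + p_span - 1
            if contained(i, j):
                continue
            rng_obs = sm[j] - sm[i]
            crit = _duncan_crit(p_span, df_error, alpha) * se_for(i, j)
            if rng_obs <= crit:
                homogeneous[i, j] = True

    rows = []
    for a_pos in range(k):
        for b_pos in range(a_pos + 1, k):
            inside = any(homogeneous[i, j]
                         for i in range(0, a_pos + 1)
                         for j in range(b_pos, k))
            p_span = b_pos - a_pos + 1
            rng_obs = sm[b_pos] - sm[a_pos]
            se = se_for(a_pos, b_pos)
            crit = _duncan_crit(p_span, df_error, alpha) * se
            if nominal_p:
                tail = float(stats.studentized_range.sf(rng_obs / se, p_span,
                                                        df_error))
                tail = min(max(tail, 0.0), 1.0)
                p_nom = 1.0 - (1.0 - tail) ** (1.0 / (p_span - 1)) \
                    if p_span > 1 else tail
            else:
                p_nom = float("nan")
            rows.append({
                "cell_a": labels[order[a_pos]], "cell_b": labels[order[b_pos]],
                "span": p_span, "range": rng_obs, "critical_range": crit,
                "significant": bool(not inside), "p_nominal": float(p_nom),
            })
    return pd.DataFrame(rows, columns=["cell_a", "cell_b", "span", "range",
                                       "critical_range", "significant",
                                       "p_nominal"])


def duncan_group_by_cell(tot: pd.DataFrame, groups, anova: AnovaTable,
                         alpha: float = 0.05, error_effect: str = "Group x ROI",
                         nominal_p: bool = True) -> pd.DataFrame:
    """Duncan post hoc over the Group x ROI x Band cell means of a TotCoh
    table, using the error stratum of ``error_effect`` from the fitted
    ANOVA. Returns the full pairwise table with cells labelled
    ``group|roi|band``; the L-vs-H rows within one ROI x band cell are the
    ones the group comparison reads off.
    """
    if isinstance(groups, pd.DataFrame):
        gmap = dict(zip(groups["id"], groups["group"]))
    else:
        gmap = dict(groups)
    df = tot[tot["scope"] != "global"].copy()
    df["grp"] = df["subject"].map(gmap)
    cells = df.groupby(["grp", "scope", "band"])[
        "value"].agg(["mean", "count"]).reset_index()
    labels = [f"{r.grp}|{r.scope}|{r.band}" for r in cells.itertuples()]
    ms_error, df_error = anova.stratum_error(error_effect)
    return duncan_mrt(cells["mean"].to_numpy(), cells["count"].to_numpy(),
                      ms_error, df_error, alpha=alpha, labels=labels,
                      nominal_p=nominal_p)
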