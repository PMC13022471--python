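"""Stratification and inference: median split, t/chi-square/Pearson, BH-FDR,
the mixed three-way ANOVA and Duncan's multiple range test — each checked
against an independently coded oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from coherostrat import (CoherenceSet, chi_square_2x2, duncan_mrt, fdr_bh,
                         median_split, mixed_anova_totcoh, pairwise_map_test,
                         pearson_r, t_from_summary, t_test_two_sample)
from coherostrat.group_stats import _duncan_crit


def cohort_frame(amps):
    n = len(amps)
    return pd.DataFrame({
        "id": [f"S{i}" for i in range(n)], "mep_amplitude": amps,
        "age": 65.0, "sex": "F", "education": 12.0, "cmmse": 29.0,
        "grip": 28.0, "group": "unassigned"})


class TestMedianSplit:
    def test_median_value_goes_high(self):
        out = median_split(cohort_frame([1, 2, 3, 4, 5]))
        assert list(out["group"]) == ["L-MEP"] * 2 + ["H-MEP"] * 3

    def test_87_subjects_with_two_median_ties_split_42_45(self, rng):
        # 42 below the median, two subjects tied at it, 43 above
        low = np.linspace(0.2, 0.79, 42)
        high = np.linspace(0.81, 2.5, 43)
        amps = np.concatenate([low, [0.8, 0.8], high])
        rng.shuffle(amps)
        out = median_split(cohort_frame(amps))
        counts = out["group"].value_counts()
        assert counts["L-MEP"] == 42 and counts["H-MEP"] == 45

    def test_identical_amplitudes_rejected(self):
        with pytest.raises(ValueError, match="split undefined"):
            median_split(cohort_frame([1.0, 1.0, 1.0, 1.0]))


class TestTTest:
    def test_identical_groups_null(self):
        t, df, p = t_test_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_summary_reconstruction_of_cognitive_contrast(self):
        # printed group summaries: 28.89 +/- 0.19 (n=42) vs 29.40 +/- 0.15
        # (n=45) reproduce t = -2.134 within rounding of the summaries
        t, df, _ = t_from_summary(28.89, 0.19, 42, 29.40, 0.15, 45)
        assert df == 85
        assert abs(t - (-2.134)) < 0.05

    def test_matches_textbook_formula(self, rng):
        for _ in range(100):
            n1, n2 = rng.integers(3, 30, size=2)
            a, b = rng.normal(size=n1), rng.normal(1.0, 2.0, size=n2)
            t, df, p = t_test_two_sample(a, b)
            sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) \
                / (n1 + n2 - 2)
            t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(2 * sps.t.sf(abs(t_ref), n1 + n2 - 2),
                                      abs=1e-10)

    def test_welch_variant_differs_under_heteroscedasticity(self, rng):
        a = rng.normal(size=10)
        b = rng.normal(0.5, 5.0, size=40)
        _, df_p, _ = t_test_two_sample(a, b, "pooled")
        _, df_w, _ = t_test_two_sample(a, b, "welch")
        assert df_w != df_p


class TestChiSquare:
    def test_reference_gender_table_p_rounds_to_057(self):
        chi2, p = chi_square_2x2([[18, 24], [22, 23]])
        assert round(p, 2) == 0.57

    def test_proportional_table_is_exact_independence(self):
        chi2, p = chi_square_2x2([[10, 20], [20, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_brute_force_expected_counts(self, rng):
        for _ in range(50):
            t = rng.integers(1, 40, size=(2, 2)).astype(float)
            chi2, _ = chi_square_2x2(t)
            exp = np.outer(t.sum(1), t.sum(0)) / t.sum()
            assert chi2 == pytest.approx(((t - exp) ** 2 / exp).sum(),
                                         abs=1e-10)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_2x2([[0, 0], [5, 3]])


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_matches_covariance_formula(self, rng):
        for _ in range(50):
            x, y = rng.normal(size=(2, 20))
            r, _ = pearson_r(x, y)
            ref = np.cov(x, y)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
            assert r == pytest.approx(ref, abs=1e-12)

    def test_null_correlation_small_at_large_n(self):
        hits = 0
        for seed in range(100):
            r_ = np.random.default_rng(seed)
            r, _ = pearson_r(r_.normal(size=1000), r_.normal(size=1000))
            hits += abs(r) < 0.1
        assert hits >= 95

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def fdr_oracle(p, q):
    """Brute force: largest k with p(k) <= k q / m, then threshold."""
    p = np.asarray(p, dtype=float)
    m = p.size
    s = np.sort(p)
    best = 0.0
    for k in range(1, m + 1):
        if s[k - 1] <= k * q / m:
            best = s[k - 1]
    return p <= best if best > 0 else np.zeros(m, bool), best


class TestFDR:
    def test_step_up_example(self):
        mask, thr = fdr_bh([0.001, 0.01, 0.02, 0.03, 0.5], 0.05)
        assert mask.tolist() == [True, True, True, True, False]
        assert thr == pytest.approx(0.03)

    def test_single_p_reduces_to_raw_threshold(self):
        mask, thr = fdr_bh([0.01], 0.05)
        assert mask.tolist() == [True]
        assert thr == pytest.approx(0.01)

    def test_no_admissible_k(self):
        mask, thr = fdr_bh([0.9, 0.8], 0.05)
        assert not mask.any()
        assert thr == 0.0

    def test_matches_brute_force_on_random_families(self):
        for seed in range(300):
            r = np.random.default_rng(seed)
            m = r.integers(1, 40)
            p = r.random(m) ** r.uniform(0.5, 3.0)
            q = r.uniform(0.01, 0.2)
            mask, thr = fdr_bh(p, q)
            mask_o, thr_o = fdr_oracle(p, q)
            assert mask.tolist() == mask_o.tolist()
            assert thr == pytest.approx(thr_o, abs=1e-15)

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        for _ in range(20):
            p = rng.random(25)
            mask, _ = fdr_bh(p, 0.05)
            ref = multipletests(p, 0.05, method="fdr_bh")[0]
            assert mask.tolist() == ref.tolist()


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 10_000))
def test_fdr_monotone_in_q_and_order_invariant(seed):
    r = np.random.default_rng(seed)
    p = r.random(r.integers(2, 30))
    m1, _ = fdr_bh(p, 0.01)
    m2, _ = fdr_bh(p, 0.10)
    assert set(np.flatnonzero(m1)) <= set(np.flatnonzero(m2))
    perm = r.permutation(p.size)
    mp, _ = fdr_bh(p[perm], 0.05)
    m, _ = fdr_bh(p, 0.05)
    assert mp.tolist() == m[perm].tolist()


# ---------------------------------------------------------------------------
# mixed ANOVA

def totcoh_frame(y, rois, bands, subjects):
    rows = []
    for si, s in enumerate(subjects):
        for ri, roi in enumerate(rois):
            for bi, band in enumerate(bands):
                rows.append({"subject": s, "band": band, "scope": roi,
                             "value": y[si, ri, bi], "n_pairs": 1})
    return pd.DataFrame(rows)


def balanced_anova_oracle(y, grp_idx, g):
    """Textbook balanced-case sums of squares for 1-between, 2-within."""
    N, r, b = y.shape
    n = N // g
    grand = y.mean()
    A = np.array([y[grp_idx == k].mean() for k in range(g)])
    S = y.mean(axis=(1, 2))
    B = y.mean(axis=(0, 2))
    C = y.mean(axis=(0, 1))
    AB = np.array([y[grp_idx == k].mean(axis=(0, 2)) for k in range(g)])
    AC = np.array([y[grp_idx == k].mean(axis=(0, 1)) for k in range(g)])
    BC = y.mean(axis=0)
    ABC = np.array([y[grp_idx == k].mean(axis=0) for k in range(g)])
    SB = y.mean(axis=2)
    SC = y.mean(axis=1)
    out = {}
    out["Group"] = n * r * b * ((A - grand) ** 2).sum()
    out["S(A)"] = r * b * ((S - A[grp_idx]) ** 2).sum()
    out["ROI"] = N * b * ((B - grand) ** 2).sum()
    out["Group x ROI"] = n * b * ((AB - A[:, None] - B[None] + grand) ** 2).sum()
    out["ROIxS"] = b * ((SB - S[:, None] - AB[grp_idx] + A[grp_idx, None]) ** 2).sum()
    out["Band"] = N * r * ((C - grand) ** 2).sum()
    out["Group x Band"] = n * r * ((AC - A[:, None] - C[None] + grand) ** 2).sum()
    out["BandxS"] = r * ((SC - S[:, None] - AC[grp_idx] + A[grp_idx, None]) ** 2).sum()
    out["ROI x Band"] = N * ((BC - B[:, None] - C[None] + grand) ** 2).sum()
    out["Group x ROI x Band"] = n * ((
        ABC - AB[:, :, None] - AC[:, None, :] - BC[None]
        + A[:, None, None] + B[None, :, None] + C[None, None, :] - grand
    ) ** 2).sum()
    resid = (y - SB[:, :, None] - SC[:, None, :] + S[:, None, None]
             - ABC[grp_idx] + AB[grp_idx][:, :, None] + AC[grp_idx][:, None, :]
             - A[grp_idx][:, None, None])
    out["RBxS"] = (resid ** 2).sum()
    return out


class TestMixedAnova:
    def test_reference_design_df_4_340(self, rng):
        subjects = [f"S{i}" for i in range(87)]
        groups = {s: ("L-MEP" if i < 42 else "H-MEP")
                  for i, s in enumerate(subjects)}
        y = rng.normal(size=(87, 5, 2))
        tot = totcoh_frame(y, ["Frontal", "Central", "Parietal", "Occipital",
                               "Temporal"], ["Alpha 2", "Beta 1"], subjects)
        res = mixed_anova_totcoh(tot, groups)
        row = res.effect("Group x ROI")
        assert (row["df_num"], row["df_den"]) == (4, 340)
        grp = res.effect("Group")
        assert (grp["df_num"], grp["df_den"]) == (1, 85)

    def test_matches_balanced_textbook_oracle(self, rng):
        N, g, r, b = 12, 2, 4, 3
        grp_idx = np.repeat([0, 1], N // g)
        y = rng.normal(size=(N, r, b)) + 0.3 * grp_idx[:, None, None]
        subjects = [f"S{i}" for i in range(N)]
        groups = {s: ("L-MEP" if grp_idx[i] == 0 else "H-MEP")
                  for i, s in enumerate(subjects)}
        tot = totcoh_frame(y, [f"R{i}" for i in range(r)],
                           [f"B{i}" for i in range(b)], subjects)
        res = mixed_anova_totcoh(tot, groups)
        oracle = balanced_anova_oracle(y, grp_idx, g)
        pairs = [("Group", "Group", "S(A)"),
                 ("ROI", "ROI", "ROIxS"),
                 ("Group x ROI", "Group x ROI", "ROIxS"),
                 ("Band", "Band", "BandxS"),
                 ("Group x Band", "Group x Band", "BandxS"),
                 ("ROI x Band", "ROI x Band", "RBxS"),
                 ("Group x ROI x Band", "Group x ROI x Band", "RBxS")]
        for effect, ss_key, err_key in pairs:
            row = res.effect(effect)
            assert row["ss"] == pytest.approx(oracle[ss_key], rel=1e-10)
            assert row["ms_error"] * row["df_den"] == \
                pytest.approx(oracle[err_key], rel=1e-10)

    def test_missing_cell_rejected(self, rng):
        subjects = [f"S{i}" for i in range(6)]
        groups = {s: ("L-MEP" if i < 3 else "H-MEP")
                  for i, s in enumerate(subjects)}
        y = rng.normal(size=(6, 3, 2))
        tot = totcoh_frame(y, list("PQR"), list("xy"), subjects)
        tot = tot.drop(index=5)
        with pytest.raises(ValueError, match="incomplete"):
            mixed_anova_totcoh(tot, groups)


# ---------------------------------------------------------------------------
# Duncan

_oracle_q_cache: dict = {}


def _oracle_q(width, df_error, alpha):
    key = (width, df_error, alpha)
    if key not in _oracle_q_cache:
        alpha_p = 1 - (1 - alpha) ** (width - 1)
        _oracle_q_cache[key] = sps.studentized_range.ppf(1 - alpha_p, width,
                                                         df_error)
    return _oracle_q_cache[key]


def duncan_oracle_subsets(means, n, ms_error, df_error, alpha):
    """Independently coded marking-style range algorithm: walk spans from
    widest to narrowest, skip spans inside retained homogeneous spans, and
    return the significance verdict per sorted-position pair."""
    k = len(means)
    order = np.argsort(means, kind="stable")
    sm = np.asarray(means)[order]
    retained = []                      # list of (i, j) homogeneous spans
    for width in range(k, 1, -1):
        for i in range(0, k - width + 1):
            j = i + width - 1
            if any(a <= i and j <= b for a, b in retained):
                continue
            q = _oracle_q(width, df_error, alpha)
            if sm[j] - sm[i] <= q * np.sqrt(ms_error / n):
                retained.append((i, j))
    verdict = {}
    for a in range(k):
        for b in range(a + 1, k):
            inside = any(i <= a and b <= j for i, j in retained)
            verdict[(order[a], order[b])] = not inside
    return verdict


class TestDuncan:
    def test_two_means_reduce_to_t_test(self, rng):
        for seed in range(30):
            r = np.random.default_rng(seed)
            means = r.normal(size=2)
            mse, df, n = r.uniform(0.5, 2.0), 20, 8
            table = duncan_mrt(means, n, mse, df, alpha=0.05)
            t_obs = abs(means[0] - means[1]) / np.sqrt(2 * mse / n)
            t_sig = t_obs > sps.t.ppf(0.975, df)
            assert bool(table["significant"][0]) == bool(t_sig)

    def test_identical_means_form_one_subset(self):
        table = duncan_mrt([1.0, 1.0, 1.0], 5, 0.5, 12)
        assert not table["significant"].any()

    def test_matches_independent_range_oracle(self):
        for seed in range(200):
            r = np.random.default_rng(seed)
            k = int(r.integers(3, 7))
            means = r.normal(scale=r.uniform(0.2, 2.0), size=k)
            mse = r.uniform(0.2, 2.0)
            df = int(r.choice([5, 10, 20, 40]))
            n = int(r.integers(2, 12))
            table = duncan_mrt(means, n, mse, df, alpha=0.05,
                               labels=[str(i) for i in range(k)],
                               nominal_p=False)
            oracle = duncan_oracle_subsets(means, n, mse, df, 0.05)
            for row in table.itertuples():
                key = (int(row.cell_a), int(row.cell_b))
                key = key if key in oracle else (key[1], key[0])
                assert oracle[key] == row.significant, (seed, key)

    def test_containment_consistency(self):
        # a pair inside a retained homogeneous span is never significant:
        # if sorted neighbours (a, c) are equal, (a, b) and (b, c) are too
        for seed in range(300):
            r = np.random.default_rng(10_000 + seed)
            k = int(r.integers(3, 7))
            means = np.sort(r.normal(scale=r.uniform(0.2, 2.0), size=k))
            table = duncan_mrt(means, 6, float(r.uniform(0.2, 2.0)),
                               int(r.choice([10, 30])), nominal_p=False,
                               labels=[str(i) for i in range(k)])
            sig = {(int(t.cell_a), int(t.cell_b)): t.significant
                   for t in table.itertuples()}
            for (a, b), s in sig.items():
                if not s:
                    for (c, d), s2 in sig.items():
                        if a <= c and d <= b:
                            assert not s2

    def test_protection_level_reduces_to_alpha_for_two(self):
        assert _duncan_crit(2, 30, 0.05) == pytest.approx(
            sps.studentized_range.ppf(0.95, 2, 30))

    def test_nonpositive_ms_error_rejected(self):
        with pytest.raises(ValueError, match="ms_error"):
            duncan_mrt([1.0, 2.0], 5, 0.0, 10)


# ---------------------------------------------------------------------------
# pairwise maps

def sets_from_stack(stack, band="Alpha 2"):
    labels = [f"e{i}" for i in range(stack.shape[1])]
    out = []
    for m in stack:
        mm = (m + m.T) / 2
        np.fill_diagonal(mm, 1.0)
        out.append(CoherenceSet(matrices={band: mm}, labels=labels, K=10))
    return out


class TestPairwiseMap:
    def test_identical_groups_all_null(self, rng):
        stack = rng.random((4, 6, 6))
        a = sets_from_stack(stack)
        b = sets_from_stack(stack.copy())
        res = pairwise_map_test(a, b, bands=["Alpha 2"])
        assert not res.table["significant"].any()
        np.testing.assert_allclose(res.table["t"], 0.0, atol=1e-10)
        assert res.p_fdr["Alpha 2"] == 0.0

    def test_null_family_false_rejections_controlled(self):
        # both groups from one distribution: families with any rejection
        # should not exceed q by more than 3 Monte-Carlo SEs
        q, fams_hit, n_fam = 0.05, 0, 60
        for seed in range(n_fam):
            r = np.random.default_rng(seed)
            stack = 0.3 + 0.05 * r.standard_normal((24, 8, 8))
            sets = sets_from_stack(np.clip(stack, 0, 1))
            res = pairwise_map_test(sets[:12], sets[12:], bands=["Alpha 2"],
                                    q=q)
            fams_hit += res.table["significant"].any()
        se = np.sqrt(q * (1 - q) / n_fam)
        assert fams_hit / n_fam <= q + 3 * se

    def test_planted_pairs_detected(self, rng):
        base = 0.3 + 0.03 * rng.standard_normal((40, 6, 6))
        eff = base.copy()
        eff[:20, 1, 2] += 0.2
        eff[:20, 2, 1] += 0.2
        sets = sets_from_stack(np.clip(eff, 0, 1))
        res = pairwise_map_test(sets[:20], sets[20:], bands=["Alpha 2"])
        sig = res.table[res.table["significant"]]
        assert {("e1", "e2")} == set(zip(sig["ch_i"], sig["ch_j"]))
        assert (sig["diff"] > 0).all()

    def test_channel_mismatch_rejected(self, rng):
        a = sets_from_stack(rng.random((3, 4, 4)))
        b = sets_from_stack(rng.random((3, 5, 5)))
        with pytest.raises(ValueError, match="channel sets"):
            pairwise_map_test(a, b)
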