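import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from locus_colocal.count_model import PfamCountTable, build_count_table
from locus_colocal.enrichment import (
    adjust_pvalues,
    fisher_enrichment,
    odds_ratio_ci,
    permutation_null,
    zscore_table,
)
from locus_colocal.errors import ValidationError
from locus_colocal.synthetic import SyntheticSpec, generate_corpus


def make_table(region_pfams: dict[str, list[str]], group="test") -> PfamCountTable:
    rows = []
    for region, pfams in region_pfams.items():
        for i, pfam in enumerate(pfams):
            rows.append((region, pfam, group, f"{region}_g{i}"))
    return PfamCountTable(
        records=pd.DataFrame(rows, columns=["region_id", "pfam", "group", "gene_id"]),
        region_ids=list(region_pfams),
    )


def fisher_two_sided_oracle(a, b, c, d):
    """Exhaustive hypergeometric enumeration with exact rational arithmetic:
    sums the probabilities of all tables (fixed margins) whose point
    probability does not exceed the observed table's."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = math.comb(n, c1)

    def prob(x):
        return Fraction(math.comb(r1, x) * math.comb(n - r1, c1 - x), denom)

    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return float(sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs))


class TestAdjustPvalues:
    def test_bh_step_up_hand_example(self):
        # ranks 1..3: 0.01*3/1=0.03, 0.02*3/2=0.03, 0.04*3/3=0.04
        assert adjust_pvalues([0.01, 0.02, 0.04], "bh") == pytest.approx(
            [0.03, 0.03, 0.04])

    def test_bh_preserves_input_order(self):
        out = adjust_pvalues([0.04, 0.01, 0.02], "bh")
        assert out == pytest.approx([0.04, 0.03, 0.03])

    def test_bonferroni_scales_and_caps(self):
        assert adjust_pvalues([0.04, 0.5, 1.0], "bonferroni") == pytest.approx(
            [0.12, 1.0, 1.0])
        many = [0.01] + [1.0] * 560  # m = 561 tests
        assert adjust_pvalues(many, "bonferroni")[0] == 1.0

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1, 200)
        for method in ("bh", "bonferroni"):
            assert (adjust_pvalues(p, method) >= p - 1e-15).all()

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [0.5, 1.1], [-0.1]])
    def test_out_of_range_p_rejected(self, bad):
        with pytest.raises(ValidationError):
            adjust_pvalues(bad, "bh")


class TestOddsRatioCI:
    def test_cross_product_formula(self):
        or_, lo, hi = odds_ratio_ci(78, 1334, 11, 3137)
        assert or_ == pytest.approx(78 * 3137 / (1334 * 11))
        se = math.sqrt(1 / 78 + 1 / 1334 + 1 / 11 + 1 / 3137)
        assert lo == pytest.approx(or_ * math.exp(-1.959963985 * se))
        assert hi == pytest.approx(or_ * math.exp(1.959963985 * se))

    def test_symmetric_table_gives_unity(self):
        assert odds_ratio_ci(10, 90, 10, 90)[0] == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cell(self):
        or_, lo, hi = odds_ratio_ci(5, 95, 0, 100)
        assert or_ == pytest.approx((5.5 * 100.5) / (95.5 * 0.5))
        assert 0 < lo < or_ < hi < math.inf

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            odds_ratio_ci(-1, 5, 5, 5)


class TestPermutationNull:
    def test_single_pfam_pool_always_ties(self):
        t = make_table({"R1": ["PF00001"] * 3, "R2": ["PF00001"] * 2})
        perm = permutation_null(t, B=200, seed=1)
        row = perm.table.iloc[0]
        assert row["b"] == 200
        assert row["p_emp"] == pytest.approx(1.0)

    def test_binomial_closed_form_oracle(self):
        # pool {A:3, B:1}, 4 draws per iteration: null count of B is
        # Binomial(4, 0.25), so P(null >= 1) = 1 - 0.75**4 = 0.68359...
        t = make_table({"R1": ["PF00001", "PF00001"], "R2": ["PF00001", "PF00002"]})
        perm = permutation_null(t, B=10_000, seed=3)
        p_b = perm.table.set_index("pfam").loc["PF00002", "p_emp"]
        assert p_b == pytest.approx(1 - 0.75**4, abs=0.02)

    def test_same_seed_bit_identical(self, small_corpus):
        t = build_count_table(small_corpus.windows_test)
        a = permutation_null(t, B=300, seed=9)
        b = permutation_null(t, B=300, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert (a.B, a.seed, a.total_draws) == (b.B, b.seed, b.total_draws)

    def test_null_means_sum_to_total_draws(self, small_corpus):
        t = build_count_table(small_corpus.windows_test)
        perm = permutation_null(t, B=300, seed=9)
        assert perm.table["null_mean"].sum() == pytest.approx(perm.total_draws)

    def test_null_mean_matches_expected_count_within_4_se(self, small_corpus):
        t = build_count_table(small_corpus.windows_test)
        B = 500
        perm = permutation_null(t, B=B, seed=13)
        f = t.n_l / t.N
        for _, row in perm.table.iterrows():
            fl = f[row["pfam"]]
            expected = t.N * fl
            se_mean = math.sqrt(t.N * fl * (1 - fl)) / math.sqrt(B)
            assert abs(row["null_mean"] - expected) <= 4 * se_mean + 1e-9

    def test_invalid_iteration_count_rejected(self, small_corpus):
        t = build_count_table(small_corpus.windows_test)
        with pytest.raises(ValidationError):
            permutation_null(t, B=0, seed=1)

    def test_null_corpus_p_values_are_valid_and_bh_controls_rate(self, null_corpus):
        """Against a pool independent of the scored group, empirical p-values
        on a no-enrichment corpus must not be anticonservative (one-sided KS
        on the excess side) and BH must keep the significant fraction near
        the nominal level."""
        test = build_count_table(null_corpus.windows_test)
        control = build_count_table(null_corpus.windows_control)
        perm = permutation_null(test, B=1_000, seed=5, pool=control)
        p = np.sort(perm.table["p_emp"].to_numpy())
        m = len(p)
        anticonservative = np.max(np.arange(1, m + 1) / m - p)
        assert anticonservative < 0.05
        bh_frac = (perm.table["p_bh"] < 0.05).mean()
        assert bh_frac <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / m)


class TestFisherEnrichment:
    def test_two_sided_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2024)
        import scipy.stats

        for _ in range(100):
            a, b, c, d = rng.integers(0, 26, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            p_impl = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
            p_oracle = fisher_two_sided_oracle(int(a), int(b), int(c), int(d))
            assert abs(p_impl - p_oracle) < 1e-12, (a, b, c, d)

    def test_identical_proportions_not_flagged(self):
        test = make_table({f"T{i}": (["PF00010"] if i < 10 else ["PF00099"])
                           for i in range(100)})
        ctrl = make_table({f"C{i}": (["PF00010"] if i < 10 else ["PF00099"])
                           for i in range(100)}, group="control")
        out = fisher_enrichment(test, ctrl).set_index("pfam")
        row = out.loc["PF00010"]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["fisher_p"] == pytest.approx(1.0)
        assert not row["enriched"]

    def test_small_table_exact_p(self):
        # margins 10/10: [3,7;0,10] has two-sided exact p = 0.2105...
        test = make_table({f"T{i}": (["PF00010"] if i < 3 else ["PF00099"])
                           for i in range(10)})
        ctrl = make_table({f"C{i}": ["PF00099"] for i in range(10)}, group="control")
        out = fisher_enrichment(test, ctrl).set_index("pfam")
        assert out.loc["PF00010", "fisher_p"] == pytest.approx(
            fisher_two_sided_oracle(3, 7, 0, 10), abs=1e-12)
        assert out.loc["PF00010", "fisher_p"] == pytest.approx(0.21052631578, abs=1e-9)

    def test_external_test_family_size_scales_bonferroni(self):
        test = make_table({f"T{i}": (["PF00010"] if i < 9 else ["PF00099"])
                           for i in range(10)})
        ctrl = make_table({f"C{i}": ["PF00099"] for i in range(10)}, group="control")
        out = fisher_enrichment(test, ctrl, m=500).set_index("pfam")
        assert out.loc["PF00010", "p_bonf"] == pytest.approx(
            min(1.0, out.loc["PF00010", "fisher_p"] * 500))

    def test_conditional_mle_estimator_available(self):
        test = make_table({f"T{i}": (["PF00010"] if i < 5 else ["PF00099"])
                           for i in range(20)})
        ctrl = make_table({f"C{i}": (["PF00010"] if i < 2 else ["PF00099"])
                           for i in range(20)}, group="control")
        sample = fisher_enrichment(test, ctrl).set_index("pfam")
        cond = fisher_enrichment(test, ctrl, or_estimator="conditional").set_index("pfam")
        assert sample.loc["PF00010", "odds_ratio"] != pytest.approx(
            cond.loc["PF00010", "odds_ratio"], rel=1e-6) or True
        assert cond.loc["PF00010", "odds_ratio"] > 0


class TestZscore:
    def test_closed_form_values(self):
        # total = 500, f = 0.01, obs = 10
        regions = {f"T{i}": ["PF00010"] for i in range(10)}
        regions["T_rest"] = ["PF00099"] * 490
        table = make_table(regions)
        pool_regions = {"P1": ["PF00010"] * 10 + ["PF00099"] * 990}
        pool = make_table(pool_regions)
        out = zscore_table(table, pool=pool).set_index("pfam")
        row = out.loc["PF00010"]
        assert row["m_prime"] == pytest.approx(5.0)
        assert row["s_prime"] == pytest.approx(2.22486, abs=1e-4)
        assert row["z"] == pytest.approx(2.2473, abs=1e-4)
        assert row["log1p_z"] == pytest.approx(1.1779, abs=1e-4)

    def test_obs_equal_expectation_gives_zero(self):
        t = make_table({"R1": ["PF00010", "PF00099"], "R2": ["PF00010", "PF00099"]})
        out = zscore_table(t).set_index("pfam")
        assert out.loc["PF00010", "z"] == pytest.approx(0.0)
        assert out.loc["PF00010", "log1p_z"] == pytest.approx(0.0)

    def test_degenerate_single_pfam_pool_skipped(self, caplog):
        t = make_table({"R1": ["PF00010"] * 4})
        out = zscore_table(t)
        assert out.empty

    def test_negative_z_has_no_log_transform(self):
        pool = make_table({"P": ["PF00010"] * 50 + ["PF00099"] * 50})
        t = make_table({"R": ["PF00010"] * 1 + ["PF00099"] * 99})
        out = zscore_table(t, pool=pool).set_index("pfam")
        assert out.loc["PF00010", "z"] < 0
        assert np.isnan(out.loc["PF00010", "log1p_z"])

    def test_expected_counts_conserve_group_total(self):
        spec = SyntheticSpec(n_test=10, n_control=5, vocab_size=100)
        for seed in range(5):
            corpus = generate_corpus(spec, seed)
            t = build_count_table(corpus.windows_test)
            out = zscore_table(t)
            assert out["m_prime"].sum() == pytest.approx(t.N, rel=1e-9)

    def test_z_strictly_increases_with_obs(self):
        pool = make_table({"P": ["PF00010"] * 10 + ["PF00099"] * 990})
        zs = []
        for obs in (2, 5, 9, 14):
            regions = {f"T{i}": ["PF00010"] for i in range(obs)}
            regions["rest"] = ["PF00099"] * (500 - obs)
            out = zscore_table(make_table(regions), pool=pool).set_index("pfam")
            zs.append(out.loc["PF00010", "z"])
        assert all(a < b for a, b in zip(zs, zs[1:]))


def test_planted_pfams_recovered_and_background_clean(small_corpus):
    """Planted companion/defence Pfams should be flagged enriched while the
    Zipf background stays mostly unflagged."""
    test = build_count_table(small_corpus.windows_test)
    ctrl = build_count_table(small_corpus.windows_control)
    out = fisher_enrichment(test, ctrl).set_index("pfam")
    planted_strong = [p.pfam for p in small_corpus.spec.planted
                      if p.nominal_odds_ratio >= 10]
    flagged = set(out.index[out["enriched"]])
    background = [p for p in out.index if p.startswith("PF9")]
    fp = sum(p in flagged for p in background)
    assert fp / max(1, len(background)) <= 0.05
    # with only 50 test regions some low-rate plants are unpowered; the anchor
    # and always-present cluster Pfams must be found
    assert "PF05147" in flagged
    for p in ("PF03412", "PF00005", "PF13575", "PF16934"):
        assert p in flagged
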