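"""CPM, prevalence filter, TMM, dispersion, exact NB test, adjustment, DE driver.

TMM factors and exact-test p-values are cross-checked against reference
values computed with Bioconductor edgeR (calcNormFactors method="TMM" and
exactTest rejection.region="smallp") on small fixed matrices, keeping the
native implementation and the reference route independent.
"""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trnaquant.destats import (
    DesignInfo,
    adjust_pvalues,
    cpm,
    estimate_common_dispersion,
    exact_nb_test,
    filter_low_counts,
    run_de,
    tmm_factors,
)
from trnaquant.quantify import CountTable

DATA = Path(__file__).parent / "data"


def _design(n1, n2, prefix="s"):
    return DesignInfo(
        samples=tuple(f"{prefix}{i}" for i in range(n1 + n2)),
        groups=("A",) * n1 + ("B",) * n2,
    )


def _nb(rng, mu, phi, size):
    if phi == 0:
        return rng.poisson(mu, size)
    r = 1 / phi
    return rng.negative_binomial(r, r / (r + mu), size)


class TestCpm:
    def test_values(self):
        frame = pd.DataFrame({"s": [1, 0, 551]})
        out = cpm(frame, lib_sizes=[1e6])
        assert out["s"].tolist() == [1.0, 0.0, 551.0]
        out2 = cpm(frame, lib_sizes=[2e6])
        assert out2["s"].iloc[2] == pytest.approx(275.5)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            cpm(pd.DataFrame({"s": [0, 0]}), lib_sizes=[0.0])


class TestFilter:
    def _table(self, per_sample_cpm_hits, n=10):
        # entity passes CPM >= 1 in `per_sample_cpm_hits` of n samples
        lib = 1_000_000
        rows = {}
        for hits in per_sample_cpm_hits:
            vals = [2 if j < hits else 0 for j in range(n)]
            rows[f"g{hits}"] = vals
        frame = pd.DataFrame(rows, index=[f"s{j}" for j in range(n)]).T
        # pad library to 1e6 with a ballast entity
        ballast = lib - frame.sum(axis=0)
        frame.loc["ballast"] = ballast
        return CountTable("individual", frame)

    def test_ceil_boundary_nine_of_ten_kept_eight_removed(self):
        table = self._table([10, 9, 8])
        kept, removed = filter_low_counts(table, min_cpm=1, min_fraction=0.9)
        assert "g10" in kept.entities and "g9" in kept.entities
        assert "g8" in removed

    def test_partition(self):
        table = self._table([10, 5, 0])
        kept, removed = filter_low_counts(table)
        assert set(kept.entities) | set(removed) == set(table.entities)
        assert not set(kept.entities) & set(removed)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(50, 200)
        frame = pd.DataFrame({"a": col, "b": col})
        assert np.allclose(tmm_factors(frame), [1.0, 1.0])

    def test_global_rescaling_absorbed_by_library_size(self):
        rng = np.random.default_rng(2)
        col = rng.poisson(50, 200) + 1
        frame = pd.DataFrame({"a": col, "b": 2 * col})
        assert np.allclose(tmm_factors(frame), [1.0, 1.0])

    def test_toy_spiked_gene_matches_reference(self):
        # 4 genes, 2 samples, one spiked gene; expected factors from edgeR
        frame = pd.DataFrame({"s1": [1000, 2000, 3000, 4000],
                              "s2": [1000, 2000, 3000, 40000]})
        f = tmm_factors(frame)
        assert np.allclose(f, [2.1447610590, 0.4662524041], atol=1e-8)

    def test_random_nb_matrix_matches_reference(self):
        frame = pd.read_csv(DATA / "synthetic_nb_counts.tsv", sep="\t", header=None)
        frame.columns = ["s1", "s2", "s3", "s4"]
        f = tmm_factors(frame)
        expected = [0.9403395790, 1.0452985344, 1.0306434380, 0.9871121557]
        assert np.allclose(f, expected, atol=1e-8)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(
            {f"s{i}": rng.poisson(rng.uniform(20, 80), 300) for i in range(5)}
        )
        f = tmm_factors(frame).to_numpy()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_fewer_than_two_samples_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            tmm_factors(pd.DataFrame({"s": [1, 2, 3]}))


class TestDispersion:
    def test_poisson_counts_estimate_near_zero(self):
        rng = np.random.default_rng(10)
        mu = rng.lognormal(4, 1, 200)
        frame = pd.DataFrame({f"s{i}": _nb(rng, mu, 0.0, 200) for i in range(6)})
        phi = estimate_common_dispersion(frame, _design(3, 3))
        assert phi < 0.05

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(11)
        mu = rng.lognormal(4, 1, 500)
        frame = pd.DataFrame({f"s{i}": _nb(rng, mu, 0.4, 500) for i in range(6)})
        phi = estimate_common_dispersion(frame, _design(3, 3))
        assert 0.25 <= phi <= 0.6

    def test_identical_replicates_hit_lower_bound(self):
        # no within-group variability -> no overdispersion signal
        frame = pd.DataFrame({"s0": [10, 20, 30], "s1": [10, 20, 30],
                              "s2": [12, 25, 33], "s3": [12, 25, 33]})
        phi = estimate_common_dispersion(frame, _design(2, 2))
        assert phi == pytest.approx(1e-6, abs=1e-6)

    def test_all_zero_rejected(self):
        frame = pd.DataFrame({"s0": [0, 0], "s1": [0, 0]})
        with pytest.raises(ValueError, match="zero"):
            estimate_common_dispersion(frame, _design(1, 1))


class TestExactTest:
    def test_equal_sums_equal_sizes_is_modal(self):
        assert exact_nb_test(40, 40, 3, 3, 0.2) == 1.0

    def test_symmetry(self):
        assert exact_nb_test(50, 30, 3, 3, 0.2) == pytest.approx(
            exact_nb_test(30, 50, 3, 3, 0.2)
        )

    def test_binomial_limit_matches_enumeration(self):
        for t, a in [(30, 9), (50, 20), (12, 2)]:
            probs = stats.binom.pmf(np.arange(t + 1), t, 0.5)
            expected = probs[probs <= probs[a] * (1 + 1e-10)].sum()
            assert exact_nb_test(a, t - a, 4, 4, 0.0) == pytest.approx(expected)

    def test_matches_reference_smallp(self):
        # edgeR exactTest(dispersion=0.1, rejection.region="smallp"),
        # equal library sizes, 3 vs 3
        assert exact_nb_test(31, 93, 3, 3, 0.1) == pytest.approx(
            0.0011010024, abs=1e-9
        )
        assert exact_nb_test(60, 63, 3, 3, 0.1) == pytest.approx(
            0.9181138146, abs=1e-9
        )

    def test_zero_total_is_one(self):
        assert exact_nb_test(0, 0, 3, 3, 0.2) == 1.0

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            exact_nb_test(1, 2, 3, 3, -0.1)

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b = int(rng.integers(0, 200)), int(rng.integers(0, 200))
            p = exact_nb_test(a, b, 3, 4, float(rng.uniform(0, 2)))
            assert 0 < p <= 1


class TestAdjust:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.02], "bh")[0] == pytest.approx(0.02)
        assert adjust_pvalues([0.02], "bonferroni")[0] == pytest.approx(0.02)

    def test_bh_hand_worked_vector(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_bonferroni_caps_at_one(self):
        assert adjust_pvalues([0.3, 0.3, 0.3, 0.3], "bonferroni")[0] == 1.0

    def test_order_preserved_and_dominance(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, 40)
        bh = adjust_pvalues(p, "bh")
        bonf = adjust_pvalues(p, "bonferroni")
        assert (bh <= bonf + 1e-12).all()
        assert (bh >= p - 1e-12).all()
        # order preservation: adjusting a permutation permutes the output
        perm = rng.permutation(40)
        assert np.allclose(adjust_pvalues(p[perm], "bh"), bh[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([1.2], "bh")


class TestRunDe:
    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(123)
        mu = rng.lognormal(4, 1, 500)
        frame = pd.DataFrame({f"s{i}": _nb(rng, mu, 0.2, 500) for i in range(10)})
        de = run_de(CountTable("individual", frame), _design(5, 5))
        frac = (de.table["p_raw"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_planted_upregulation_detected(self):
        rng = np.random.default_rng(124)
        mu = rng.lognormal(4, 1, 500)
        frame = pd.DataFrame({f"s{i}": _nb(rng, mu, 0.2, 500) for i in range(10)})
        test_cols = [f"s{i}" for i in range(5, 10)]
        planted = np.arange(50)
        frame.loc[planted, test_cols] = _nb(
            rng, np.tile(mu[planted] * 4, (5, 1)).T, 0.2, (50, 5)
        )
        de = run_de(CountTable("individual", frame), _design(5, 5))
        hit = de.table.iloc[planted]
        assert hit["significant"].mean() >= 0.8
        assert hit["p_bh"].median() < de.table["p_bh"].median()

    def test_label_swap_negates_fold_change(self):
        rng = np.random.default_rng(125)
        frame = pd.DataFrame({f"s{i}": rng.poisson(100, 80) for i in range(6)})
        table = CountTable("individual", frame)
        d1 = _design(3, 3)
        d2 = DesignInfo(samples=d1.samples, groups=("B",) * 3 + ("A",) * 3)
        t1 = run_de(table, d1).table
        t2 = run_de(table, d2).table
        assert np.allclose(t1["log2_fc"], -t2["log2_fc"])
        assert np.allclose(t1["p_raw"], t2["p_raw"])

    def test_zero_count_group_rejected(self):
        frame = pd.DataFrame({"s0": [0, 0], "s1": [0, 0], "s2": [5, 5], "s3": [5, 5]})
        design = DesignInfo(samples=("s0", "s1", "s2", "s3"),
                            groups=("A", "A", "B", "B"))
        with pytest.raises(ValueError, match="zero total"):
            run_de(CountTable("individual", frame), design)

    def test_adjusted_columns_dominate_raw(self):
        rng = np.random.default_rng(126)
        frame = pd.DataFrame({f"s{i}": rng.poisson(60, 100) for i in range(6)})
        de = run_de(CountTable("individual", frame), _design(3, 3)).table
        assert (de["p_bh"] <= de["p_bonferroni"] + 1e-12).all()
        assert (de["p_raw"] <= de["p_bh"] + 1e-12).all()
        assert de[["p_raw", "p_bonferroni", "p_bh"]].le(1).all().all()
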