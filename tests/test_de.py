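"""FPKM filter, normalization, NB testing, BH adjustment, class aggregation."""

import numpy as np
import pandas as pd
import pytest

from introshift.de import (
    aggregate_repeat_classes,
    bh_adjust,
    filter_low_expression,
    fpkm,
    nb_test,
    size_factors,
)
from introshift.quantify import CountMatrix
from introshift.simulate import SimulationConfig, simulate_counts


def make_cm(counts: dict, lengths=None, lib=None):
    df = pd.DataFrame(counts)
    lengths = pd.Series(lengths if lengths is not None else [1000] * len(df), index=df.index)
    lib = pd.Series(lib) if lib is not None else df.sum(axis=0) + 1000
    return CountMatrix(df.astype(np.int64), lengths, lib)


class TestFpkm:
    def test_unit_case(self):
        cm = make_cm({"s1": [10, 0]}, lengths=[1000, 500], lib={"s1": 1_000_000})
        x = fpkm(cm)
        assert x.iloc[0, 0] == pytest.approx(10.0)
        assert x.iloc[1, 0] == 0.0

    def test_matches_elementwise_formula_on_random_matrix(self, rng):
        counts = rng.integers(0, 500, size=(30, 6))
        lengths = rng.integers(200, 5000, size=30)
        lib = rng.integers(10_000, 1_000_000, size=6)
        cm = CountMatrix(
            pd.DataFrame(counts, index=[f"f{i}" for i in range(30)],
                         columns=[f"s{j}" for j in range(6)]),
            pd.Series(lengths, index=[f"f{i}" for i in range(30)]),
            pd.Series(lib, index=[f"s{j}" for j in range(6)]),
        )
        x = fpkm(cm).to_numpy()
        for i in range(30):
            for j in range(6):
                expect = counts[i, j] / ((lengths[i] / 1e3) * (lib[j] / 1e6))
                assert x[i, j] == pytest.approx(expect)

    def test_zero_library_size_is_an_error(self):
        cm = make_cm({"s1": [1]}, lib={"s1": 10})
        cm.library_sizes["s1"] = 0
        with pytest.raises(ValueError, match="library sizes"):
            fpkm(cm)


class TestLowExpressionFilter:
    def build(self, fpkm_per_sample):
        """One feature per row; length 1000, library 1e6 -> count == FPKM."""
        n_samples = len(fpkm_per_sample[0])
        counts = {f"s{j}": [row[j] for row in fpkm_per_sample] for j in range(n_samples)}
        return make_cm(counts, lengths=[1000] * len(fpkm_per_sample),
                       lib={f"s{j}": 1_000_000 for j in range(n_samples)})

    def test_threshold_boundaries_at_80_percent(self):
        low8 = [1] * 8 + [10] * 2   # FPKM < 5 in 8 of 10 -> excluded
        low7 = [1] * 7 + [10] * 3   # FPKM < 5 in 7 of 10 -> retained
        high = [10] * 10
        cm = self.build([low8, low7, high])
        kept = filter_low_expression(cm)
        assert list(kept.counts.index) == [1, 2]

    def test_mean_mode_reading(self):
        # mean FPKM 4.5 < 5 -> excluded under mean mode, retained per-sample
        # (below 5 in only 75% of samples)
        borderline = [1, 1, 1, 15]
        cm = self.build([borderline])
        assert len(filter_low_expression(cm, mode="mean").counts) == 0
        assert len(filter_low_expression(cm, mode="per_sample").counts) == 1


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        cm = make_cm({"s1": [10, 20, 30], "s2": [10, 20, 30]})
        f = size_factors(cm)
        assert f.tolist() == pytest.approx([1.0, 1.0])

    def test_doubled_sample_scales_proportionally(self):
        cm = make_cm({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        f = size_factors(cm)
        assert f["s2"] / f["s1"] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_matches_brute_force_median_of_ratios(self, rng):
        counts = rng.integers(1, 1000, size=(50, 4))
        df = pd.DataFrame(counts, index=[f"f{i}" for i in range(50)],
                          columns=list("abcd"))
        got = size_factors(df)
        geo = np.exp(np.mean(np.log(counts), axis=1))
        for j, s in enumerate("abcd"):
            expect = np.median(counts[:, j] / geo)
            assert got[s] == pytest.approx(expect)

    def test_upper_quartile_fallback_when_no_common_feature(self, caplog):
        cm = make_cm({"s1": [10, 0], "s2": [0, 10]})
        f = size_factors(cm)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)


class TestBhAdjust:
    def test_single_and_stepup_example(self):
        assert bh_adjust([0.04]).tolist() == [0.04]
        # step-up: q_i = min over j>=i of p_(j) * n / j, all equal 0.04 here
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx([0.04] * 4)

    def test_q_dominates_p_and_is_order_stable(self, rng):
        p = rng.random(200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()
        # permutation equivariance
        perm = rng.permutation(200)
        assert bh_adjust(p[perm]) == pytest.approx(q[perm])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])


class TestNbTest:
    def design(self, n=5):
        return {f"S{j}_{c}": c for c in ("T0", "T1") for j in range(n)}

    def test_identical_counts_are_ns_with_zero_lfc(self):
        cm = make_cm({f"S{j}_{c}": [50, 200] for c in ("T0", "T1") for j in range(3)})
        res = nb_test(cm, self.design(3))
        assert res["log2FC"].tolist() == pytest.approx([0.0, 0.0])
        assert (res["call"] == "NS").all()

    def test_all_zero_feature_is_ns_with_p_one(self):
        counts = {f"S{j}_{c}": [0, 100] for c in ("T0", "T1") for j in range(3)}
        cm = make_cm(counts)
        res = nb_test(cm, self.design(3)).set_index("feature_id")
        assert res.loc[0, "p_value"] == 1.0
        assert res.loc[0, "log2FC"] == 0.0
        assert res.loc[0, "call"] == "NS"

    def test_null_simulation_controls_false_positives(self):
        """2000 null NB features, dispersion 0.1, 5 vs 5: the q<0.05 fraction
        stays at or below the nominal level (3 seeds)."""
        for seed in (11, 12, 13):
            cfg = SimulationConfig(seed=seed, nb_dispersion=0.1, de_fraction=0.0)
            cm, truth, design = simulate_counts(cfg, [f"f{i}" for i in range(2000)])
            res = nb_test(cm, design)
            frac = (res["q_value"] < 0.05).mean()
            assert frac <= 0.05, f"seed {seed}: {frac}"

    def test_strong_effects_are_recovered(self):
        """|log2FC| = 2 at mean >= 100, dispersion 0.05: >= 90% called."""
        for seed in (21, 22, 23):
            cfg = SimulationConfig(seed=seed, nb_dispersion=0.05,
                                   baseline_log_mean=float(np.log(300)), baseline_log_sd=0.3)
            ids = [f"f{i}" for i in range(1200)]
            lfc = {f: (2.0 if i < 200 else 0.0) for i, f in enumerate(ids)}
            cm, truth, design = simulate_counts(cfg, ids, true_log2fc=lfc)
            res = nb_test(cm, design).set_index("feature_id")
            up_rate = (res.loc[[f for f in ids if lfc[f] == 2.0], "call"] == "UP").mean()
            assert up_rate >= 0.90, f"seed {seed}: {up_rate}"

    def test_lfc_estimates_are_nearly_unbiased(self):
        """Balanced up/down effects (the generator's sign convention): the
        median signed estimation error over DE features stays within 0.2."""
        cfg = SimulationConfig(seed=31, nb_dispersion=0.1,
                               baseline_log_mean=float(np.log(200)), baseline_log_sd=0.5)
        ids = [f"f{i}" for i in range(1500)]
        lfc = {f: (2.0 if i < 150 else -2.0 if i < 300 else 0.0) for i, f in enumerate(ids)}
        cm, truth, design = simulate_counts(cfg, ids, true_log2fc=lfc)
        res = nb_test(cm, design).set_index("feature_id")
        de_ids = [f for f in ids if lfc[f] != 0.0]
        err = res.loc[de_ids, "log2FC"] - pd.Series({f: lfc[f] for f in de_ids})
        assert abs(float(err.median())) <= 0.2

    def test_scale_invariance_after_normalization(self):
        """Scaling one sample's counts leaves log2FC unchanged on
        dispersion-free data."""
        rng = np.random.default_rng(5)
        base = rng.integers(50, 500, size=20)
        counts = {f"S{j}_{c}": (base * (2 if c == "T1" else 1)).tolist()
                  for c in ("T0", "T1") for j in range(3)}
        cm1 = make_cm(counts)
        counts_scaled = dict(counts)
        counts_scaled["S0_T0"] = (np.array(counts["S0_T0"]) * 7).tolist()
        cm2 = make_cm(counts_scaled)
        r1 = nb_test(cm1, self.design(3))
        r2 = nb_test(cm2, self.design(3))
        assert r2["log2FC"].to_numpy() == pytest.approx(r1["log2FC"].to_numpy(), abs=1e-6)

    def test_paired_mode_uses_subject_ratios(self):
        cfg = SimulationConfig(seed=41, nb_dispersion=0.05)
        ids = [f"f{i}" for i in range(300)]
        lfc = {f: (2.0 if i < 60 else 0.0) for i, f in enumerate(ids)}
        cm, truth, design = simulate_counts(cfg, ids, true_log2fc=lfc)
        res = nb_test(cm, design, paired=True).set_index("feature_id")
        assert (res.loc[[f for f in ids if lfc[f] == 2.0], "call"] == "UP").mean() >= 0.8

    def test_call_thresholds_are_inclusive_on_lfc(self):
        # log2FC exactly +1 with tiny q must be UP (inclusive >=)
        res = pd.DataFrame({"feature_id": ["a"], "log2FC": [1.0], "q_value": [0.01]})
        from introshift.de import _calls
        assert _calls(res["log2FC"].to_numpy(), res["q_value"].to_numpy(), 1.0, 0.05)[0] == "UP"


class TestRepeatClassAggregation:
    def test_fraction_tally(self):
        de = pd.DataFrame(
            {
                "feature_id": [f"r{i}" for i in range(12)],
                "call": ["UP"] * 5 + ["DOWN"] * 3 + ["UP"] * 2 + ["NS"] * 2,
            }
        )
        classes = {f"r{i}": "LINE" for i in range(5)}
        classes.update({f"r{i}": "SINE" for i in range(5, 8)})
        classes.update({f"r{i}": "DNA" for i in range(8, 10)})
        summ = aggregate_repeat_classes(de, classes)
        f = summ.fractions()
        assert f["LINE"] == pytest.approx(0.5)
        assert f["SINE"] == pytest.approx(0.3)
        assert f["DNA"] == pytest.approx(0.2)
        assert f.sum() == pytest.approx(1.0)

    def test_zero_modulated_gives_empty_summary(self):
        de = pd.DataFrame({"feature_id": ["a"], "call": ["NS"]})
        assert aggregate_repeat_classes(de, {"a": "LINE"}).table.empty

    def test_missing_metadata_is_unknown_and_matches_brute_force(self, rng):
        n = 200
        calls = rng.choice(["UP", "DOWN", "NS"], size=n)
        classes = {f"r{i}": rng.choice(["LINE", "SINE", "LTR", "DNA"]) for i in range(n - 20)}
        de = pd.DataFrame({"feature_id": [f"r{i}" for i in range(n)], "call": calls})
        summ = aggregate_repeat_classes(de, classes)
        mod = [i for i in range(n) if calls[i] != "NS"]
        expected = {}
        for i in mod:
            c = classes.get(f"r{i}", "Unknown")
            expected[c] = expected.get(c, 0) + 1
        got = summ.table.set_index("repeat_class")["n_modulated"].to_dict()
        assert got == expected
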