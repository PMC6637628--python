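import itertools

import numpy as np
import pandas as pd
import pytest

from microtraj import (
    KOProfile,
    ModuleMap,
    SimConfig,
    ko_differential,
    module_abundance,
    module_log2fc,
    read_ko_profile,
    read_module_map,
    simulate_cohort,
    wilcoxon_rank_sum,
    write_ko_profile,
    write_module_map,
)
from microtraj.kegg import KeggError
from microtraj.profiles import SampleMetadata


def exact_rank_sum_p(a, b):
    """Enumeration oracle: two-sided p of the rank sum of group a (no ties)."""
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    n1 = len(a)
    w_obs = ranks[:n1].sum()
    mean_w = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            count += 1
    return count / total


class TestWilcoxon:
    def test_textbook_small_case(self):
        res = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert res.w == 3.0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.direction == -1
        assert res.method == "exact"

    def test_matches_enumeration_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(15):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 13 - n1))
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            res = wilcoxon_rank_sum(a, b)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(exact_rank_sum_p(a, b), abs=1e-12)

    def test_identical_groups_give_p_one_direction_zero(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)
        assert res.direction == 0

    def test_large_shift_seven_vs_seven(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=7)
        b = a + 100.0
        res = wilcoxon_rank_sum(a, b)
        assert res.p_value < 0.01 and res.direction == -1

    def test_w_within_analytic_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n1, n2 = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            res = wilcoxon_rank_sum(rng.normal(size=n1), rng.normal(size=n2))
            lo = n1 * (n1 + 1) / 2
            assert lo <= res.w <= lo + n1 * n2

    def test_exact_and_normal_p_agree_for_seven_vs_seven(self):
        rng = np.random.default_rng(3)
        import scipy.stats

        for _ in range(10):
            a, b = rng.normal(size=7), rng.normal(size=7)
            approx = wilcoxon_rank_sum(a, b)  # 14 samples -> normal approximation
            assert approx.method == "normal"
            exact_p = scipy.stats.mannwhitneyu(a, b, method="exact").pvalue
            assert abs(approx.p_value - exact_p) < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(KeggError):
            wilcoxon_rank_sum([], [1.0])


class TestModuleAbundance:
    def test_single_ko_module_equals_that_ko(self):
        ko = KOProfile(pd.DataFrame({"K1": [1.0, 2.0], "K2": [3.0, 4.0]}, index=["a", "b"]))
        mmap = ModuleMap({"M1": ("K1",)})
        out = module_abundance(ko, mmap)
        np.testing.assert_allclose(out["M1"], [1.0, 2.0])

    def test_three_ko_module_mean_by_hand(self):
        ko = KOProfile(
            pd.DataFrame(
                {"K1": [3.0], "K2": [6.0], "K3": [9.0], "K4": [1.0]}, index=["a"]
            )
        )
        out = module_abundance(ko, ModuleMap({"M1": ("K1", "K2", "K3")}))
        assert out.loc["a", "M1"] == pytest.approx(6.0)
        out_sum = module_abundance(ko, ModuleMap({"M1": ("K1", "K2", "K3")}), agg="sum")
        assert out_sum.loc["a", "M1"] == pytest.approx(18.0)

    def test_absent_module_dropped_with_warning(self):
        ko = KOProfile(pd.DataFrame({"K1": [1.0]}, index=["a"]))
        mmap = ModuleMap({"M1": ("K1",), "M2": ("K9",)})
        with pytest.warns(UserWarning, match="dropped"):
            out = module_abundance(ko, mmap)
        assert list(out.columns) == ["M1"]

    def test_ko_order_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.random((3, 6))
        kos = [f"K{i}" for i in range(6)]
        ko = KOProfile(pd.DataFrame(vals, index=list("abc"), columns=kos))
        shuffled = KOProfile(ko.data[kos[::-1]])
        mmap = ModuleMap({"M1": ("K0", "K3", "K5")})
        pd.testing.assert_frame_equal(
            module_abundance(ko, mmap), module_abundance(shuffled, mmap)
        )

    def test_empty_map_rejected(self):
        with pytest.raises(KeggError):
            ModuleMap({})


class TestModuleLog2FC:
    @staticmethod
    def _setup(factor=4.0):
        samples = [f"g1_r{r}_{tp}" for r in range(3) for tp in ("TP1", "TP5")]
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "rat_id": [s.rsplit("_", 1)[0] for s in samples],
                    "group": "g1",
                    "timepoint": [s.rsplit("_", 1)[1] for s in samples],
                }
            )
        )
        base = np.array([10.0, 5.0])
        rows = []
        for s in samples:
            v = base.copy()
            if s.endswith("TP5"):
                v = v * [factor, 1.0]
            rows.append(v)
        modules = pd.DataFrame(rows, index=samples, columns=["M1", "M2"])
        return modules, meta

    def test_equal_means_give_zero_and_fourfold_gives_two(self):
        modules, meta = self._setup()
        fc = module_log2fc(modules, meta, eps=0.0)
        assert fc.loc["M1", "g1"] == pytest.approx(2.0)
        assert fc.loc["M2", "g1"] == pytest.approx(0.0)

    def test_antisymmetry_under_swapped_contrast(self):
        modules, meta = self._setup()
        fwd = module_log2fc(modules, meta, tp_num="TP5", tp_den="TP1", eps=0.0)
        rev = module_log2fc(modules, meta, tp_num="TP1", tp_den="TP5", eps=0.0)
        np.testing.assert_allclose(fwd.to_numpy(), -rev.to_numpy(), atol=1e-12)

    def test_unknown_contrast_rejected(self):
        modules, meta = self._setup()
        with pytest.raises(KeggError, match="TP9"):
            module_log2fc(modules, meta, tp_num="TP9")

    def test_planted_module_shift_recovered(self):
        # modest KO noise so recovery error is dominated by the planted shift
        cfg = SimConfig(seed=42, ko_noise_sd=0.05)
        _, meta, ko, truth = simulate_cohort(cfg)
        modules = module_abundance(ko, truth.module_map)
        fc = module_log2fc(modules, meta, eps=0.0)  # all-positive table
        up = truth.ko_shifts[0]
        down = truth.ko_shifts[1]
        assert fc.loc[up.module, up.group] == pytest.approx(np.log2(up.factor), abs=0.2)
        assert fc.loc[down.module, down.group] == pytest.approx(
            np.log2(down.factor), abs=0.2
        )
        untouched = [m for m in fc.index if m not in (up.module, down.module)]
        assert fc.loc[untouched, "model"].abs().max() < 0.2

    def test_planted_shift_detected_by_rank_sum(self, default_cohort):
        profile, meta, ko, truth = default_cohort
        up = truth.ko_shifts[0]
        tests = ko_differential(ko, meta, "model", "normal", timepoint="TP5")
        member = list(truth.module_map.members[up.module])
        assert (tests.loc[member, "p_value"] < 0.05).all()
        assert (tests.loc[member, "direction"] == 1).all()


class TestKoIO:
    def test_roundtrip(self, tmp_path, default_cohort):
        ko = default_cohort[2]
        path = tmp_path / "ko.tsv"
        write_ko_profile(ko, path)
        back = read_ko_profile(path)
        assert back.ko_ids == ko.ko_ids
        np.testing.assert_allclose(back.values, ko.values, atol=1e-12)

    def test_module_map_roundtrip(self, tmp_path, default_cohort):
        mmap = default_cohort[3].module_map
        path = tmp_path / "map.tsv"
        write_module_map(mmap, path)
        back = read_module_map(path)
        assert back.members == mmap.members
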