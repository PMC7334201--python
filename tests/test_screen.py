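import numpy as np
import pytest
from scipy import stats

import reelscreen as rs
from reelscreen.screen import ScreenError, _ttest_rows
from tests.conftest import build_count_matrix


class TestAlleleRatio:
    def test_basic_ratio(self):
        assert rs.allele_ratio(50, 25) == 2.0

    def test_symmetric_counts(self):
        assert rs.allele_ratio(7, 7) == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ScreenError):
            rs.allele_ratio(3, 0)


class TestTtest:
    def test_frozen_reference_value(self):
        # oracle: classic pooled-variance t with df=8, p from the t CDF
        p = rs.ttest_cycle10((1.0, 1.1, 0.9, 1.0, 1.0), (2.0, 2.1, 1.9, 2.0, 2.0))
        assert p == pytest.approx(1.6924559265e-08, rel=1e-6)

    def test_identical_groups(self):
        assert rs.ttest_cycle10((1.0, 1.1, 0.9, 1.0, 1.0), (1.0, 1.1, 0.9, 1.0, 1.0)) \
            == pytest.approx(1.0, abs=1e-12)

    def test_two_tailed_symmetry(self):
        a, b = (1.0, 1.2, 0.8, 1.1, 0.9), (2.0, 2.3, 1.8, 2.2, 1.7)
        assert rs.ttest_cycle10(a, b) == pytest.approx(rs.ttest_cycle10(b, a))

    def test_matches_scipy_student(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = rng.normal(size=5), rng.normal(0.5, 1.2, size=5)
            expected = stats.ttest_ind(a, b, equal_var=True).pvalue
            assert rs.ttest_cycle10(a, b) == pytest.approx(expected, rel=1e-10)

    def test_scale_invariance(self):
        a, b = (1.0, 1.2, 0.8, 1.1, 0.9), (2.0, 2.3, 1.8, 2.2, 1.7)
        assert rs.ttest_cycle10(a, b) == pytest.approx(
            rs.ttest_cycle10(tuple(3 * x for x in a), tuple(3 * x for x in b))
        )

    def test_zero_variance_sentinels(self):
        assert rs.ttest_cycle10((1.0,) * 5, (1.0,) * 5) == 1.0
        assert rs.ttest_cycle10((1.0,) * 5, (2.0,) * 5) == 0.0

    def test_vectorized_rows_match_scalar(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(10, 5))
        b = rng.normal(0.3, 1.0, size=(10, 5))
        rowwise = _ttest_rows(a, b)
        for i in range(10):
            assert rowwise[i] == pytest.approx(rs.ttest_cycle10(a[i], b[i]), rel=1e-10)
        welch = _ttest_rows(a, b, welch=True)
        for i in range(10):
            assert welch[i] == pytest.approx(
                stats.ttest_ind(a[i], b[i], equal_var=False).pvalue, rel=1e-8
            )


class TestNormalizedTrajectory:
    def test_identical_conditions_give_unity(self):
        cm = build_count_matrix([("rs1", "C"), ("rs1", "T")], fill=10)
        traj = rs.normalized_trajectory(cm, "rs1", ("C", "T"))
        assert np.allclose(traj, 1.0)

    def test_cyclewise_arithmetic(self):
        # sample ratio means (2,2,2,2); control ratio means (1,2,4,8)
        overrides = {}
        for cyc, ctrl_num in zip((1, 4, 7, 10), (10, 20, 40, 80)):
            for rep in range(1, 6):
                overrides[("rs1", "C", cyc, "sample", rep)] = 20
                overrides[("rs1", "T", cyc, "sample", rep)] = 10
                overrides[("rs1", "C", cyc, "control", rep)] = ctrl_num
                overrides[("rs1", "T", cyc, "control", rep)] = 10
        cm = build_count_matrix(overrides)
        traj = rs.normalized_trajectory(cm, "rs1", ("C", "T"))
        assert np.allclose(traj, [2.0, 1.0, 0.5, 0.25])

    def test_missing_cycle_is_clean_error(self):
        cm = build_count_matrix([("rs1", "C"), ("rs1", "T")], cycles=(1, 4, 7))
        with pytest.raises(ScreenError, match="cycle 10"):
            rs.normalized_trajectory(cm, "rs1", ("C", "T"))


class TestFitSlope:
    def test_exact_linear(self):
        assert rs.fit_slope((1.0, 1.3, 1.6, 1.9)) == pytest.approx(0.1)

    def test_constant_trajectory(self):
        assert rs.fit_slope((1.5, 1.5, 1.5, 1.5)) == 0.0

    def test_antisymmetry(self):
        assert rs.fit_slope((1.9, 1.6, 1.3, 1.0)) == pytest.approx(-0.1)

    def test_linearity_in_input(self):
        rng = np.random.default_rng(5)
        y1, y2 = rng.normal(size=4), rng.normal(size=4)
        s = rs.fit_slope(2 * y1 + 3 * y2)
        assert s == pytest.approx(2 * rs.fit_slope(y1) + 3 * rs.fit_slope(y2))

    def test_matches_scipy_linregress(self):
        y = (0.9, 0.5, 0.3, 0.2)
        expected = stats.linregress([1, 4, 7, 10], y).slope
        assert rs.fit_slope(y) == pytest.approx(expected, rel=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ScreenError):
            rs.fit_slope((1.0, np.nan, 1.0, 1.0))


class TestClassify:
    @pytest.mark.parametrize(
        "p,slope,expected",
        [
            (0.01, 0.10, "candidate"),
            (0.01, -0.10, "candidate"),
            (0.01, 0.02, "putative"),
            (0.01, -0.02, "putative"),
            (0.20, 0.30, "non_fSNP"),
            (0.05, 0.10, "non_fSNP"),   # p boundary is strict
            (0.01, 0.05, "putative"),   # slope boundary is strict
            (0.01, -0.05, "putative"),
            (0.049999, 0.050001, "candidate"),
            (0.0, 0.0, "putative"),
            (1.0, 1.0, "non_fSNP"),
        ],
    )
    def test_cutoff_partition(self, p, slope, expected):
        assert rs.classify(p, slope) == expected

    def test_custom_thresholds(self):
        assert rs.classify(0.08, 0.2, alpha=0.1, slope_cut=0.3) == "putative"


class TestReplicateCorrelation:
    def test_duplicated_replicates_give_unity(self, small_lib):
        rng = np.random.default_rng(6)
        rows = small_lib.sequence_index()
        cm = build_count_matrix(rows, fill=10)
        base = rng.integers(5, 100, size=len(rows))
        for rep in range(1, 6):  # same counts in every replicate
            for (s, a), v in zip(rows, base):
                cm.df.loc[(s, a), (10, "sample", rep)] = v
        r2 = rs.replicate_correlation(cm, small_lib, cycle=10)
        assert all(v == pytest.approx(1.0) for v in r2.values())

    def test_independent_noise_gives_low_r2(self):
        lib = rs.random_library(300, seed=12)
        rng = np.random.default_rng(13)
        rows = lib.sequence_index()
        cm = build_count_matrix(rows, fill=50)
        for rep in range(1, 6):
            noise = rng.integers(20, 200, size=len(rows))
            for (s, a), v in zip(rows, noise):
                cm.df.loc[(s, a), (10, "sample", rep)] = v
        r2 = rs.replicate_correlation(cm, lib, cycle=10)
        assert all(v < 0.1 for v in r2.values())

    def test_r2_increases_with_depth(self):
        # shared biological truth + multinomial sampling: deeper sequencing
        # means better replicate agreement
        lib = rs.random_library(200, seed=14)
        out = {}
        for depth in (2000, 200_000):
            cfg = rs.SimulationConfig(n_snps=200, fraction_functional=0.3,
                                      delta_p=0.2, pcr_noise_sd=0.2,
                                      depth=depth, seed=15)
            cm, _ = rs.simulate_screen(lib, cfg)
            retained, _ = rs.qc_complete(cm)
            r2 = rs.replicate_correlation(retained, lib, cycle=10)
            out[depth] = np.mean(list(r2.values()))
        assert out[200_000] > out[2000]


class TestRunScreen:
    def test_empty_matrix_gives_empty_report(self, small_lib):
        cm = build_count_matrix(small_lib.sequence_index(), fill=0)
        rep = rs.run_screen(cm, small_lib)
        assert rep.n_analyzed == 0
        assert rep.results.empty
        assert sum(rep.class_counts.values()) == 0

    def test_class_counts_partition_analyzed_snps(self):
        lib = rs.random_library(100, seed=16)
        cfg = rs.SimulationConfig(n_snps=100, fraction_functional=0.2,
                                  delta_p=0.2, depth=20000, seed=17)
        cm, _ = rs.simulate_screen(lib, cfg)
        rep = rs.run_screen(cm, lib)
        assert sum(rep.class_counts.values()) == rep.n_analyzed
        assert rep.n_analyzed + len(rep.dropped) == 100

    def test_effects_rank_by_slope_magnitude(self):
        # larger allele difference in shift probability -> larger |slope|,
        # within the moderate-effect regime where the trajectory has not yet
        # saturated near zero (|slope| peaks around delta_p ~ 0.2 and the
        # ordering inverts beyond it)
        lib = rs.random_library(6, seed=18)
        import pandas as pd

        p = {}
        deltas = [0.0, 0.03, 0.06, 0.09, 0.12, 0.15]
        for rec, d in zip(lib.records, deltas):
            for a in rec.alleles:
                p[(rec.snp_id, a)] = 0.1
            p[(rec.snp_id, rec.risk_allele)] = 0.1 + d
        s = pd.Series(p)
        s.index = pd.MultiIndex.from_tuples(s.index)
        model = rs.AlleleShiftModel(p_sample=s)
        cfg = rs.SimulationConfig(n_snps=6, mode="deterministic", depth=1e6, seed=0)
        cm, _ = rs.simulate_screen(lib, cfg, model=model)
        rep = rs.run_screen(cm, lib, min_count=0.0)
        slopes = rep.results.set_index("snp_id")["slope"]
        ordered = [abs(slopes[rec.snp_id]) for rec in lib.records]
        assert ordered == sorted(ordered)

    def test_counts_file_round_trip_preserves_analysis(self, tmp_path):
        # the analysis is reproducible from the long-format counts TSV alone
        lib = rs.random_library(60, seed=19)
        cfg = rs.SimulationConfig(n_snps=60, fraction_functional=0.2,
                                  delta_p=0.25, depth=30000, seed=20)
        cm, _ = rs.simulate_screen(lib, cfg)
        rep_mem = rs.run_screen(cm, lib)
        path = tmp_path / "counts.tsv"
        cm.to_long(path)
        rep_disk = rs.run_screen(rs.CountMatrix.from_long(path), lib)
        assert rep_mem.class_counts == rep_disk.class_counts
        a = rep_mem.results.sort_values(["snp_id", "nonrisk_allele"]).reset_index(drop=True)
        b = rep_disk.results.sort_values(["snp_id", "nonrisk_allele"]).reset_index(drop=True)
        assert np.allclose(a["p_value"], b["p_value"])
        assert np.allclose(a["slope"], b["slope"])

    def test_missing_cycle_named_in_error(self):
        cm = build_count_matrix([("rs1", "C"), ("rs1", "T")], cycles=(1, 4, 7))
        lib = rs.LibraryDefinition(records=[
            rs.SnpRecord("rs1", "L", ("C", "T"), "C", "A" * 15, "G" * 15)
        ])
        with pytest.raises(ScreenError, match="cycle 10"):
            rs.run_screen(cm, lib, cycles=(1, 4, 7, 10))
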