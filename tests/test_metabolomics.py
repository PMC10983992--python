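import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mobnet.config import AnalysisConfig
from mobnet.metabolomics import (DELTA_13C, DELTA_15N, MetaboliteDiff,
                                 ReferenceMass, Trace, diff_metabolites,
                                 extract_xic, heavy_mz, integrate_auc,
                                 mz_window, parse_formula, quantify,
                                 quantify_all, read_reference_masses)
from mobnet.synthetic import PeakSpec, gen_traces

from _oracles import gaussian_area


class TestMzWindow:
    def test_75ppm_at_300(self):
        lo, hi = mz_window(300.0, 75)
        assert lo == pytest.approx(299.9775, abs=1e-9)
        assert hi == pytest.approx(300.0225, abs=1e-9)

    def test_zero_width(self):
        assert mz_window(100.0, 0) == (100.0, 100.0)

    def test_pyruvate_mass_direct_arithmetic(self):
        mz = 87.0088
        lo, hi = mz_window(mz, 75)
        assert lo == pytest.approx(mz - mz * 75 / 1e6)
        assert hi == pytest.approx(mz + mz * 75 / 1e6)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            mz_window(0.0, 75)

    @settings(max_examples=100, derandomize=True)
    @given(mz=st.floats(50, 1100), ppm1=st.floats(0, 200), ppm2=st.floats(0, 200))
    def test_symmetric_and_monotone(self, mz, ppm1, ppm2):
        lo, hi = mz_window(mz, ppm1)
        assert hi - mz == pytest.approx(mz - lo)
        lo2, hi2 = mz_window(mz, ppm2)
        if ppm2 >= ppm1:
            assert lo2 <= lo and hi2 >= hi


class TestHeavyMz:
    def test_no_labelable_atoms(self):
        assert heavy_mz("H2O", 17.0027) == pytest.approx(17.0027)

    def test_pyruvate_three_carbons(self):
        # independent oracle: shift from the atomic-mass table directly
        shift = 3 * (13.00335484 - 12.0)
        assert heavy_mz("C3H4O3", 87.0088) == pytest.approx(87.0088 + shift, abs=1e-6)

    def test_glutamine_carbon_and_nitrogen(self):
        shift = 5 * (13.00335484 - 12.0) + 2 * (15.00010890 - 14.00307401)
        assert heavy_mz("C5H10N2O3", 145.0619) == pytest.approx(
            145.0619 + shift, abs=1e-6)

    def test_formula_parsing(self):
        assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}
        assert parse_formula({"C": 4, "N": 4}) == {"C": 4, "N": 4}
        with pytest.raises(ValueError):
            parse_formula("C6H12o6")


def point_trace(rows):
    return Trace(sample="S1", points=pd.DataFrame(
        rows, columns=["rt_s", "mz", "intensity"]))


class TestExtractXic:
    def test_all_points_outside_window(self):
        t = point_trace([(1.0, 200.0, 5.0)])
        xic = extract_xic(t, (100.0, 101.0), (0.0, 10.0))
        assert xic.empty

    def test_single_point_inside(self):
        t = point_trace([(1.0, 100.5, 5.0)])
        xic = extract_xic(t, (100.0, 101.0), (0.0, 10.0))
        assert xic["intensity"].tolist() == [5.0]

    def test_matches_brute_force_filter_and_sum(self):
        rng = np.random.default_rng(9)
        rows = [(float(rng.uniform(0, 100)), float(rng.uniform(99, 103)),
                 float(rng.uniform(0, 10))) for _ in range(500)]
        t = point_trace(rows)
        window, rt_win = (100.0, 101.5), (20.0, 80.0)
        xic = extract_xic(t, window, rt_win)
        expected = {}
        for rt, mz, inten in rows:
            if 100.0 <= mz <= 101.5 and 20.0 <= rt <= 80.0:
                expected[rt] = expected.get(rt, 0.0) + inten
        got = dict(zip(xic["rt_s"], xic["intensity"]))
        assert got == pytest.approx(expected)
        # conservation bound: XIC total never exceeds trace total
        assert xic["intensity"].sum() <= t.points["intensity"].sum() + 1e-9


class TestIntegrateAuc:
    def test_rectangle(self):
        xic = pd.DataFrame({"rt_s": np.arange(0, 11, 1.0), "intensity": 1.0})
        assert integrate_auc(xic) == pytest.approx(10.0)

    def test_degenerate_inputs(self):
        assert integrate_auc(pd.DataFrame({"rt_s": [], "intensity": []})) == 0.0
        assert integrate_auc(pd.DataFrame({"rt_s": [1.0], "intensity": [5.0]})) == 0.0

    def test_unsorted_rejected(self):
        xic = pd.DataFrame({"rt_s": [2.0, 1.0], "intensity": [1.0, 1.0]})
        with pytest.raises(ValueError, match="sorted"):
            integrate_auc(xic)

    def test_gaussian_closed_form(self):
        """Trapezoid on a sigma/10 grid recovers A*s*sqrt(2*pi) within 1%."""
        A, s = 50.0, 4.0
        t = np.arange(-5 * s, 5 * s + s / 20, s / 10)
        xic = pd.DataFrame({"rt_s": t + 100, "intensity": A * np.exp(-t**2 / (2 * s**2))})
        assert integrate_auc(xic) == pytest.approx(gaussian_area(A, s), rel=0.01)


class TestQuantify:
    def ref(self, **kw):
        base = dict(metabolite="pyruvate", formula={"C": 3, "H": 4, "O": 3},
                    mz_light=87.0088, rt_window=(160.0, 200.0))
        base.update(kw)
        return ReferenceMass(**base)

    def trace_for(self, area_light, area_heavy, noise_sd=0.0, seed=0):
        spec = PeakSpec(metabolite="pyruvate", formula="C3H4O3",
                        true_area_light=area_light, true_area_heavy=area_heavy,
                        rt_center=180.0, rt_sigma=4.0, mz_light=87.0088,
                        sampling_dt=0.4, noise_sd=noise_sd)
        traces, _ = gen_traces([spec], seed)
        return Trace(sample="S1", points=traces[["rt_s", "mz", "intensity"]])

    def test_equal_channels_ratio_one(self, config):
        q = quantify(self.trace_for(100.0, 100.0), self.ref(), config)
        assert q.ratio == pytest.approx(1.0, rel=1e-6)

    def test_two_to_one(self, config):
        q = quantify(self.trace_for(200.0, 100.0), self.ref(), config)
        assert q.ratio == pytest.approx(2.0, rel=0.01)

    def test_area_recovery_within_one_percent(self, config):
        q = quantify(self.trace_for(200.0, 100.0), self.ref(), config)
        assert q.auc_light == pytest.approx(200.0, rel=0.01)
        assert q.auc_heavy == pytest.approx(100.0, rel=0.01)

    def test_scale_equivariance(self, config):
        """Multiplying light intensities by k multiplies the ratio by k."""
        t = self.trace_for(100.0, 100.0)
        q1 = quantify(t, self.ref(), config)
        scaled = t.points.copy()
        light = scaled["mz"] < 88  # light channel points
        scaled.loc[light, "intensity"] *= 3.0
        q2 = quantify(Trace(sample="S1", points=scaled), self.ref(), config)
        assert q2.ratio == pytest.approx(3.0 * q1.ratio, rel=1e-9)

    def test_empty_heavy_channel_flagged(self, config):
        t = self.trace_for(100.0, 100.0)
        no_heavy = t.points[t.points["mz"] < 88]
        q = quantify(Trace(sample="S1", points=no_heavy), self.ref(), config)
        assert q.ratio is None

    def test_noisy_recovery_unbiased(self, config):
        """Mean recovered ratio over 100 seeds within 3 SE of truth."""
        ratios = []
        for seed in range(100):
            q = quantify(self.trace_for(200.0, 100.0, noise_sd=0.2, seed=seed),
                         self.ref(), config)
            ratios.append(q.ratio)
        mean, se = np.mean(ratios), np.std(ratios, ddof=1) / 10
        assert abs(mean - 2.0) < 3 * max(se, 1e-4)


class TestDiffMetabolites:
    def quants(self, treated, control, metabolite="m1"):
        rows = [(f"treated_{i}", metabolite, "treated", r)
                for i, r in enumerate(treated)]
        rows += [(f"control_{i}", metabolite, "control", r)
                 for i, r in enumerate(control)]
        return pd.DataFrame(rows, columns=["sample", "metabolite", "condition", "ratio"])

    def test_allantoin_style_8fold_retained(self, config):
        """~8-fold accumulation with tight replicates passes the 24 h filter."""
        q = self.quants([8.1, 7.9, 8.0], [1.0, 1.05, 0.95], "allantoin")
        (d,) = diff_metabolites(q, "24h", config)
        assert d.fold_change == pytest.approx(8.0, rel=0.01)
        assert d.p_value < 0.05 and d.retained

    def test_below_6h_threshold_not_retained(self, config):
        q = self.quants([1.4, 1.41, 1.39], [1.0, 1.0, 1.0])
        (d,) = diff_metabolites(q, "6h", config)
        assert d.fold_change == pytest.approx(1.4, rel=0.01)
        assert not d.retained

    def test_fails_p_not_retained(self, config):
        q = self.quants([3.0, 0.5, 5.5], [1.0, 2.0, 0.2])
        (d,) = diff_metabolites(q, "6h", config)
        assert d.p_value > 0.05 and not d.retained

    def test_decrease_direction_symmetric(self, config):
        """fold 1/2.5 is retained at the 2-fold cutoff iff fold 2.5 is."""
        up = self.quants([2.5, 2.52, 2.48], [1.0, 1.01, 0.99])
        down = self.quants([1 / 2.5, 1 / 2.52, 1 / 2.48], [1.0, 1.01, 0.99])
        (du,) = diff_metabolites(up, "24h", config)
        (dd,) = diff_metabolites(down, "24h", config)
        assert du.retained and dd.retained
        mid = self.quants([1 / 1.8, 1 / 1.81, 1 / 1.79], [1.0, 1.01, 0.99])
        (dm,) = diff_metabolites(mid, "24h", config)
        assert not dm.retained  # 1.8-fold decrease misses the 2-fold cutoff

    def test_missing_control_group_rejected(self, config):
        q = self.quants([2.0, 2.0], [1.0, 1.0]).query("condition == 'treated'")
        with pytest.raises(ValueError, match="control"):
            diff_metabolites(q, "6h", config)

    def test_single_replicate_excluded(self, config):
        q = self.quants([2.0], [1.0, 1.0])
        assert diff_metabolites(q, "6h", config) == []

    def test_welch_p_matches_scipy_on_known_input(self, config):
        from scipy import stats

        t, c = [2.0, 2.2, 1.9], [1.0, 1.1, 0.9]
        q = self.quants(t, c)
        (d,) = diff_metabolites(q, "6h", config)
        assert d.p_value == pytest.approx(
            stats.ttest_ind(t, c, equal_var=False).pvalue)


def test_reference_mass_reader_and_heavy_derivation(tmp_path):
    p = tmp_path / "refs.tsv"
    p.write_text(
        "metabolite\tformula\tmz_light\trt_start\trt_end\n"
        "pyruvate\tC3H4O3\t87.0088\t160\t200\n"
    )
    (ref,) = read_reference_masses(p)
    assert ref.mz_heavy == pytest.approx(87.0088 + 3 * DELTA_13C)


def test_quantify_all_end_to_end(config):
    specs = [
        PeakSpec(metabolite="allantoin", formula="C4H6N4O3",
                 true_area_light=800.0, true_area_heavy=100.0,
                 rt_center=300.0, rt_sigma=4.0, mz_light=157.0367,
                 sampling_dt=0.4, sample="t1"),
    ]
    traces, refs = gen_traces(specs, 0)
    refs_objs = [ReferenceMass(metabolite=r.metabolite,
                               formula=parse_formula(r.formula),
                               mz_light=r.mz_light,
                               rt_window=(r.rt_start, r.rt_end))
                 for r in refs.itertuples(index=False)]
    out = quantify_all(traces, refs_objs, config)
    assert out.iloc[0]["ratio"] == pytest.approx(8.0, rel=0.01)
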