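import numpy as np
import pandas as pd
import pytest

from thermoresp.errors import NoBreakpointError, ValidationError
from thermoresp import thermal as th


def heating_trace(
    psi=45.0, noise=0.0, rng=None, slow=0.001, fast=0.05, t_hi=65.0,
    sample_id="t1", direction="heating", peak=None,
):
    t = np.arange(20.0, t_hi, 0.05)
    f = 1.0 + slow * (t - 20.0)
    if peak is None:
        f = f + fast * np.clip(t - psi, 0, None)
    else:
        f = f + fast * np.clip(np.minimum(t, peak) - psi, 0, None)
        f = f - 0.08 * np.clip(t - peak, 0, None)
    if noise and rng is not None:
        f = f + rng.normal(0, noise, t.size)
    return th.FluorescenceTrace(sample_id, "sp", "control", direction, t, f)


class TestQc:
    def test_duplicates_averaged_and_sorted(self):
        tr = th.FluorescenceTrace(
            "a", "sp", "control", "heating",
            np.array([21.0, 20.0, 20.0] + list(np.linspace(22, 60, 30))),
            np.array([1.0, 0.5, 1.5] + [1.0] * 30),
        )
        out = th.qc_trace(tr)
        assert out.temperature[0] == 20.0 and out.f0[0] == 1.0  # averaged
        assert np.all(np.diff(out.temperature) > 0)

    def test_cooling_stored_chronologically(self):
        t = np.linspace(20, -10, 40)
        tr = th.FluorescenceTrace("a", "sp", "control", "cooling", t, np.ones(40))
        out = th.qc_trace(tr)
        assert out.temperature[0] == 20.0 and out.temperature[-1] == -10.0

    def test_too_few_points_rejected(self):
        tr = th.FluorescenceTrace(
            "a", "sp", "control", "heating", np.arange(10.0), np.ones(10)
        )
        with pytest.raises(ValidationError):
            th.qc_trace(tr)


class TestTcrit:
    def test_noiseless_breakpoint_to_grid_resolution(self):
        fit = th.fit_tcrit(heating_trace(psi=45.0))
        assert fit.tcrit == pytest.approx(45.0, abs=0.1)
        assert fit.slope_fast > fit.slope_slow
        assert not fit.fast_not_steeper

    def test_straight_line_has_no_breakpoint(self):
        tr = heating_trace(psi=100.0)  # breakpoint outside range: pure line
        with pytest.raises(NoBreakpointError):
            th.fit_tcrit(tr)

    def test_noisy_recovery_within_half_degree(self):
        rng = np.random.default_rng(21)
        errors = [
            abs(th.fit_tcrit(heating_trace(45.0, 0.02, rng)).tcrit - 45.0)
            for _ in range(20)
        ]
        assert np.mean(np.array(errors) < 0.5) >= 0.95

    def test_consistency_as_noise_vanishes(self):
        rng = np.random.default_rng(5)
        errs = []
        for sd in (0.05, 0.01, 0.001):
            e = [
                abs(th.fit_tcrit(heating_trace(40.0, sd, rng)).tcrit - 40.0)
                for _ in range(5)
            ]
            errs.append(np.mean(e))
        assert errs[2] <= errs[0] + 0.05 and errs[2] < 0.15

    def test_shift_equivariance(self):
        tr = heating_trace(psi=45.0)
        shifted = th.FluorescenceTrace(
            "t1", "sp", "control", "heating", tr.temperature + 3.0, tr.f0
        )
        a = th.fit_tcrit(tr).tcrit
        b = th.fit_tcrit(shifted).tcrit
        assert b - a == pytest.approx(3.0, abs=1e-6)

    def test_grid_refinement_never_raises_rss(self):
        rng = np.random.default_rng(2)
        tr = heating_trace(43.3, 0.02, rng)
        coarse = th.fit_tcrit(tr, grid_step=0.2)
        fine = th.fit_tcrit(tr, grid_step=0.1)
        assert fine.rss <= coarse.rss + 1e-9

    def test_cooling_breakpoint_on_negated_axis(self):
        t = np.arange(20.0, -25.0, -0.05)
        x = -t
        f = 1.0 + 0.001 * (x + 20.0) + 0.05 * np.clip(x - 8.0, 0, None)
        tr = th.FluorescenceTrace("c1", "sp", "control", "cooling", t, f)
        fit = th.fit_tcrit(tr)
        assert fit.tcrit == pytest.approx(-8.0, abs=0.1)


class TestTmax:
    def test_planted_peak_recovered(self):
        tr = heating_trace(psi=45.0, peak=55.0)
        tmax, flag = th.extract_tmax(tr)
        assert tmax == pytest.approx(55.0, abs=0.1)
        assert not flag

    def test_tie_resolves_to_tcrit_side(self):
        t = np.linspace(20, 65, 200)
        f = np.ones(200)
        i54 = int(np.argmin(np.abs(t - 54.0)))
        i56 = int(np.argmin(np.abs(t - 56.0)))
        f[i54 - 2 : i54 + 3] = 2.0
        f[i56 - 2 : i56 + 3] = 2.0
        tr = th.FluorescenceTrace("a", "sp", "control", "heating", t, f)
        tmax, _ = th.extract_tmax(tr)
        assert tmax == pytest.approx(t[i54 - 2], abs=0.5)
        assert tmax < 55.0

    def test_monotone_trace_flags_endpoint(self):
        tr = heating_trace(psi=45.0)  # rises to the final point
        _, flag = th.extract_tmax(tr)
        assert flag


class TestAcclimation:
    def traits(self, rows):
        return pd.DataFrame(
            rows,
            columns=["sample_id", "species_id", "treatment", "direction", "tcrit", "tmax"],
        ).assign(fast_not_steeper=False, tmax_at_endpoint=False)

    def test_hot_delta_sign_convention(self):
        tr = self.traits(
            [
                ("a", "sp", "control", "heating", 45.0, 53.0),
                ("b", "sp", "hot", "heating", 48.0, 55.0),
            ]
        )
        out = th.acclimation_deltas(tr).set_index("species_id")
        assert out.loc["sp", "Tcrit_hot"] == 3.0  # gained heat tolerance
        assert out.loc["sp", "Tmax_hot"] == 2.0

    def test_cold_delta_worsening_is_positive(self):
        tr = self.traits(
            [
                ("a", "sp", "control", "cooling", -9.0, -15.0),
                ("b", "sp", "cold", "cooling", -6.0, -12.0),
            ]
        )
        out = th.acclimation_deltas(tr).set_index("species_id")
        assert out.loc["sp", "Tcrit_cold"] == 3.0  # toward 0: worse performance

    def test_equal_means_give_zero_and_missing_arm_is_nan(self):
        tr = self.traits(
            [
                ("a", "spA", "control", "heating", 45.0, 53.0),
                ("b", "spA", "hot", "heating", 45.0, 53.0),
            ]
        )
        out = th.acclimation_deltas(tr).set_index("species_id")
        assert out.loc["spA", "Tcrit_hot"] == 0.0
        assert np.isnan(out.loc["spA", "Tcrit_cold"])  # no cooling traces


def test_planted_trace_parameters_recovered(small_bundle):
    """End-to-end: the trace generator's breakpoints and deltas round-trip
    through Tcrit extraction and the acclimation computation."""
    truth = small_bundle.truth
    traits = th.trace_traits(small_bundle.traces)
    deltas = th.acclimation_deltas(traits).set_index("species_id")
    planted = pd.DataFrame(truth.thermal_deltas).T
    for trait in ("Tcrit_hot", "Tcrit_cold"):
        err = (deltas[trait] - planted[trait]).abs()
        assert err.max() < 0.8  # plant-level jitter with 3 plants per arm
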