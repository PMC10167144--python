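"""Objective function, synthetic traces, and parameter recovery."""

import numpy as np
import pytest

from bayliss.errors import ParameterError
from bayliss.fitting import (
    DiameterTrace,
    FitSpec,
    fit,
    forward_trace,
    generate_synthetic_trace,
    objective,
    simulate_passive_trace,
)
from bayliss.params import MaterialParams
from bayliss.protocols import ScenarioSpec, build_staircase
from bayliss.ring import RingConfiguration

# small, fast setup shared by the fitting tests
RING = RingConfiguration(n_elem=2)
PROTO = build_staircase(levels=(40.0, 80.0, 120.0), hold=30.0, pre_hold=30.0, dt=5.0)
SAMPLE_T = np.array([25.0, 55.0, 85.0, 115.0])


def _trace(t, d, scenario="passive"):
    return DiameterTrace(t=np.asarray(t, float), d=np.asarray(d, float), scenario=scenario)


class TestObjective:
    def test_perfect_match(self):
        tr = _trace([0, 1, 2], [200, 210, 220])
        assert objective([tr], [tr]) == 0.0

    def test_single_point(self):
        te = _trace([0.0], [200.0])
        ts = _trace([0.0], [198.0])
        assert objective([te], [ts]) == pytest.approx(0.01)

    def test_three_four_five(self):
        te = _trace([0.0, 1.0], [100.0, 100.0])
        ts = _trace([0.0, 1.0], [97.0, 96.0])  # relative errors 0.03 and 0.04
        assert objective([te], [ts]) == pytest.approx(0.05)

    def test_order_invariance(self):
        a_e, a_s = _trace([0, 1], [100, 100]), _trace([0, 1], [99, 98])
        b_e, b_s = _trace([0, 1], [200, 200]), _trace([0, 1], [195, 190])
        z1 = objective([a_e, b_e], [a_s, b_s])
        z2 = objective([b_e, a_e], [b_s, a_s])
        assert z1 == pytest.approx(z2, rel=1e-15)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            objective([], [])


class TestSyntheticTraces:
    def test_zero_noise_is_exact_forward_model(self, params):
        clean = forward_trace(RING, PROTO, ScenarioSpec.passive(), params, sample_t=SAMPLE_T)
        synth = generate_synthetic_trace(
            RING, PROTO, ScenarioSpec.passive(), params, noise_sd_rel=0.0, seed=7, sample_t=SAMPLE_T
        )
        assert np.array_equal(clean.d, synth.d)

    def test_seed_determinism(self, params):
        kw = dict(noise_sd_rel=0.02, seed=11, sample_t=SAMPLE_T)
        a = generate_synthetic_trace(RING, PROTO, ScenarioSpec.passive(), params, **kw)
        b = generate_synthetic_trace(RING, PROTO, ScenarioSpec.passive(), params, **kw)
        assert np.array_equal(a.d, b.d)

    def test_noise_amplitude_statistics(self, params):
        """Empirical relative SD of the multiplicative noise lies in
        [0.008, 0.012] for a nominal 1% over >= 500 samples."""
        t_many = np.linspace(1.0, PROTO.total_duration, 600)
        clean = simulate_passive_trace(RING, PROTO, params, t_many)
        noisy = generate_synthetic_trace(
            RING, PROTO, ScenarioSpec.passive(), params,
            noise_sd_rel=0.01, seed=3, sample_t=t_many,
        )
        rel = noisy.d / clean.d - 1.0
        assert 0.008 < rel.std() < 0.012

    def test_csv_roundtrip(self, params, tmp_path):
        tr = _trace([1.0, 2.0], [200.0, 201.0], scenario="passive")
        path = tmp_path / "trace.csv"
        tr.to_csv(path)
        back = DiameterTrace.from_csv(path)
        assert np.array_equal(back.t, tr.t)
        assert np.array_equal(back.d, tr.d)
        assert back.scenario == "passive"


class TestFit:
    def test_point_bounds_return_direct_evaluation(self, params):
        truth = generate_synthetic_trace(
            RING, PROTO, ScenarioSpec.passive(), params, sample_t=SAMPLE_T
        )
        spec = FitSpec(
            stage="passive",
            free={"alpha1": (11.52507, 11.52507), "phi": (38.923, 38.923)},
            traces=[truth],
            ring=RING,
            protocol=PROTO,
        )
        res = fit(spec)
        assert res.nfev == 1
        assert res.z == pytest.approx(0.0, abs=1e-10)

    def test_passive_recovery_noiseless(self, params):
        """Fitting alpha1 and the opening angle against a noiseless
        synthetic passive trace reproduces the trace to < 0.1%
        (parameters themselves may trade off)."""
        truth = generate_synthetic_trace(
            RING, PROTO, ScenarioSpec.passive(), params, sample_t=SAMPLE_T
        )
        spec = FitSpec(
            stage="passive",
            free={"alpha1": (8.0, 16.0), "phi": (20.0, 55.0)},
            traces=[truth],
            ring=RING,
            protocol=PROTO,
            popsize=4,
            maxiter=8,
            seed=1,
            tol=1e-10,
        )
        res = fit(spec)
        # forward-model error per point implied by the pooled objective
        assert res.z / np.sqrt(len(SAMPLE_T)) < 1e-3

    def test_recovery_with_one_percent_noise(self, params):
        """With 1% trace noise the refit forward trace stays within 1%
        RMS relative diameter of the noise-free truth."""
        clean = forward_trace(RING, PROTO, ScenarioSpec.passive(), params, sample_t=SAMPLE_T)
        noisy = generate_synthetic_trace(
            RING, PROTO, ScenarioSpec.passive(), params,
            noise_sd_rel=0.01, seed=5, sample_t=SAMPLE_T,
        )
        spec = FitSpec(
            stage="passive",
            free={"alpha1": (8.0, 16.0), "phi": (20.0, 55.0)},
            traces=[noisy],
            ring=RING,
            protocol=PROTO,
            popsize=4,
            maxiter=6,
            seed=2,
        )
        res = fit(spec)
        from bayliss.fitting import _build_setup

        fitted_params, fitted_ring = _build_setup(MaterialParams(), RING, res.params)
        refit = forward_trace(fitted_ring, PROTO, ScenarioSpec.passive(), fitted_params, sample_t=SAMPLE_T)
        rms = np.sqrt(np.mean(((refit.d - clean.d) / clean.d) ** 2))
        assert rms < 0.01

    def test_invalid_stage_params(self, params):
        with pytest.raises(ParameterError):
            FitSpec(
                stage="passive",
                free={"kappa": (1.0, 2.0)},
                traces=[_trace([0.0], [200.0])],
                ring=RING,
                protocol=PROTO,
            )
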