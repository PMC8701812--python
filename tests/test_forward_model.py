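"""Forward signal model, classical relaxometry curves, and panel generation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import relaxprint as rp
from relaxprint.errors import DomainError, InvalidSampleError
from relaxprint.forward_model import (
    DEFAULT_BRAND_COUNTS,
    DEFAULT_SPECIES_LIBRARY,
    MonoExpFit,
    fit_monoexponential,
)


def single(t2=0.100, t1=0.200, a=1.0):
    return rp.OilSample("x", (rp.RelaxationComponent(a, t1, t2),))


class TestComponentInvariants:
    def test_t2_must_not_exceed_t1(self):
        with pytest.raises(DomainError):
            rp.RelaxationComponent(1.0, t1=0.1, t2=0.2)

    @pytest.mark.parametrize("kwargs", [
        dict(amplitude=-0.1, t1=0.2, t2=0.1),
        dict(amplitude=1.0, t1=0.0, t2=0.1),
        dict(amplitude=1.0, t1=0.2, t2=-0.1),
    ])
    def test_nonphysical_parameters_rejected(self, kwargs):
        with pytest.raises(DomainError):
            rp.RelaxationComponent(**kwargs)

    def test_sample_needs_components_with_signal(self):
        with pytest.raises(InvalidSampleError):
            rp.OilSample("empty", ())
        with pytest.raises(InvalidSampleError):
            rp.OilSample("dark", (rp.RelaxationComponent(0.0, 0.2, 0.1),))


class TestSimulateSignal:
    def test_closed_form_single_component(self):
        # 2 n tau1 = 0.1 s = T2 -> exp(-1)
        s = rp.simulate_signal(single(t2=0.100), tau1=250e-6, n=200, tau2=0.0)
        assert s == pytest.approx(math.exp(-1), abs=1e-12)

    def test_no_decay_gives_unity(self):
        sample = DEFAULT_SPECIES_LIBRARY["FO"]
        assert rp.simulate_signal(sample, tau1=250e-6, n=0, tau2=0.0) == pytest.approx(1.0)

    def test_closed_form_two_components(self):
        sample = rp.OilSample(
            "two",
            (
                rp.RelaxationComponent(1.0, 1.0, 0.050),
                rp.RelaxationComponent(1.0, 1.0, 0.100),
            ),
        )
        s = rp.simulate_signal(sample, tau1=250e-6, n=200, tau2=0.0)
        assert s == pytest.approx((math.exp(-2) + math.exp(-1)) / 2, abs=1e-12)

    def test_tau2_applies_t1_modulation(self):
        s = rp.simulate_signal(single(t2=0.1, t1=0.2), tau1=250e-6, n=0, tau2=0.2)
        assert s == pytest.approx(math.exp(-1), abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            rp.simulate_signal(single(), tau1=0.0, n=10, tau2=0.0)
        with pytest.raises(DomainError):
            rp.simulate_signal(single(), tau1=1e-4, n=-1, tau2=0.0)

    @given(
        tau1=st.sampled_from([100e-6, 250e-6, 500e-6]),
        n1=st.integers(1, 1000),
        n2=st.integers(1, 1000),
    )
    def test_noiseless_signal_decreasing_in_n(self, tau1, n1, n2):
        sample = DEFAULT_SPECIES_LIBRARY["PO"]
        s1 = rp.simulate_signal(sample, tau1, min(n1, n2), 0.1)
        s2 = rp.simulate_signal(sample, tau1, max(n1, n2), 0.1)
        if n1 != n2:
            assert s1 > s2
        assert 0.0 < s2 <= s1 <= 1.0

    @given(n=st.integers(1, 2500))
    def test_noiseless_signal_decreasing_in_tau1(self, n):
        sample = DEFAULT_SPECIES_LIBRARY["OL"]
        vals = [rp.simulate_signal(sample, t, n, 0.1) for t in (1e-4, 2e-4, 5e-4)]
        assert vals[0] > vals[1] > vals[2] > 0


class TestSurface:
    def test_noiseless_surface_matches_pointwise_signal(self):
        proto = rp.AcquisitionProtocol(noise_sigma=0.0)
        sample = DEFAULT_SPECIES_LIBRARY["CO"]
        surf = rp.simulate_surface(sample, proto)
        for i, t1 in enumerate(proto.tau1_schedule[::3]):
            for j, n in enumerate(proto.n_schedule[::5]):
                assert surf.values[3 * i, 5 * j] == pytest.approx(
                    rp.simulate_signal(sample, t1, n, proto.tau2), abs=1e-15
                )

    def test_default_grid_has_126_cells(self, default_grid):
        assert default_grid.shape == (7, 18)
        assert default_grid.n_cells == 126

    def test_seeded_surfaces_reproducible(self):
        proto = rp.AcquisitionProtocol(noise_sigma=1e-3, seed=42)
        sample = DEFAULT_SPECIES_LIBRARY["SFO"]
        a = rp.simulate_surface(sample, proto)
        b = rp.simulate_surface(sample, proto)
        np.testing.assert_array_equal(a.values, b.values)


class TestMakeBrand:
    def test_zero_jitter_is_identity(self):
        t = DEFAULT_SPECIES_LIBRARY["FO"]
        b = rp.make_brand(t, 0.0, seed=1)
        assert b.components == t.components

    def test_seeded_brand_reproducible(self):
        t = DEFAULT_SPECIES_LIBRARY["SO"]
        assert rp.make_brand(t, 0.05, seed=7) == rp.make_brand(t, 0.05, seed=7)

    def test_negative_jitter_rejected(self):
        with pytest.raises(DomainError):
            rp.make_brand(DEFAULT_SPECIES_LIBRARY["SO"], -0.1, seed=0)

    def test_lognormal_jitter_centred_on_template(self):
        # Unit-median lognormal: sample means stay within 3 SE of template.
        t = single(t2=0.080, t1=0.200, a=2.0)
        rng = np.random.default_rng(0)
        draws = [rp.make_brand(t, 0.05, rng) for _ in range(1000)]
        for attr, ref in [("t1", 0.200), ("t2", 0.080), ("amplitude", 2.0)]:
            vals = np.array([getattr(b.components[0], attr) for b in draws])
            se = vals.std(ddof=1) / math.sqrt(len(vals))
            # lognormal(median=1, cv=0.05) has mean exp(sigma^2/2) ~ 1.00125
            assert abs(vals.mean() - ref) < 3 * se + 0.002 * ref

    def test_t2_clipped_to_t1(self):
        # A component with t2 == t1 can only stay physical by clipping.
        t = rp.OilSample("edge", (rp.RelaxationComponent(1.0, 0.1, 0.1),))
        for seed in range(20):
            b = rp.make_brand(t, 0.2, seed=seed)
            assert b.components[0].t2 <= b.components[0].t1


class TestMix:
    @pytest.mark.parametrize("v,which", [(0.0, "base"), (1.0, "adulterant")])
    def test_endpoints_reproduce_parents(self, v, which):
        base = DEFAULT_SPECIES_LIBRARY["FO"]
        adult = DEFAULT_SPECIES_LIBRARY["SO"]
        m = rp.mix(base, adult, v)
        parent = base if which == "base" else adult
        for tau1, n in [(1e-4, 10), (250e-6, 200), (5e-4, 900)]:
            assert rp.simulate_signal(m, tau1, n, 0.1) == pytest.approx(
                rp.simulate_signal(parent, tau1, n, 0.1), abs=1e-12
            )

    @given(v=st.floats(0.0, 1.0))
    def test_mixture_signal_affine_in_v(self, v):
        base = DEFAULT_SPECIES_LIBRARY["FO"]
        adult = DEFAULT_SPECIES_LIBRARY["SO"]
        m = rp.mix(base, adult, v)
        for tau1, n in [(1e-4, 40), (3e-4, 500)]:
            expected = (1 - v) * rp.simulate_signal(base, tau1, n, 0.1) + v * (
                rp.simulate_signal(adult, tau1, n, 0.1)
            )
            assert rp.simulate_signal(m, tau1, n, 0.1) == pytest.approx(
                expected, abs=1e-12
            )

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(DomainError):
            rp.mix(DEFAULT_SPECIES_LIBRARY["FO"], DEFAULT_SPECIES_LIBRARY["SO"], 1.2)


class TestClassicCurvesAndFits:
    def test_ir_null_point(self):
        t1 = 0.180
        m = rp.simulate_classic_curves(single(t1=t1, t2=0.1), [t1 * math.log(2)], "IR")
        assert m[0] == pytest.approx(0.0, abs=1e-12)

    def test_ir_full_recovery(self):
        m = rp.simulate_classic_curves(single(), [100.0], "IR")
        assert m[0] == pytest.approx(1.0, abs=1e-12)

    def test_cpmg_e_folding(self):
        m = rp.simulate_classic_curves(single(t2=0.120), [0.120], "CPMG")
        assert m[0] == pytest.approx(math.exp(-1), abs=1e-12)

    def test_empty_delays_rejected(self):
        with pytest.raises(DomainError):
            rp.simulate_classic_curves(single(), [], "IR")

    @pytest.mark.parametrize(
        "kind,tgen", [("CPMG", 0.120), ("IR", 0.180)]
    )
    def test_monoexponential_fit_recovers_generator(self, kind, tgen):
        sample = single(t1=0.180, t2=0.120)
        t = np.linspace(0.01, 0.8, 40)
        y = rp.simulate_classic_curves(sample, t, kind)
        fit = rp.fit_monoexponential(t, y, kind)
        assert isinstance(fit, MonoExpFit)
        assert fit.time_constant == pytest.approx(tgen, rel=1e-6)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-6)

    def test_effective_t2_brackets_two_component_mixture(self):
        sample = rp.OilSample(
            "two",
            (
                rp.RelaxationComponent(1.0, 0.3, 0.050),
                rp.RelaxationComponent(1.0, 0.3, 0.150),
            ),
        )
        t = np.linspace(0.005, 0.5, 60)
        y = rp.simulate_classic_curves(sample, t, "CPMG")
        fit = rp.fit_monoexponential(t, y, "CPMG")
        assert 0.050 < fit.time_constant < 0.150

    def test_too_few_points_rejected(self):
        with pytest.raises(DomainError):
            rp.fit_monoexponential([0.1, 0.2], [0.5, 0.3], "CPMG")


class TestPanel:
    def test_study_inventory_counts(self, default_panel):
        assert len(default_panel.pure) == 28
        per_species = {}
        for r in default_panel.pure:
            per_species[r.species] = per_species.get(r.species, 0) + 1
        assert per_species == DEFAULT_BRAND_COUNTS

    def test_mixture_series_ratios(self, default_panel):
        cal = sorted(r.ratio for r in default_panel.mixtures("calibration"))
        val = sorted(r.ratio for r in default_panel.mixtures("validation"))
        assert cal == [0.10, 0.20, 0.30, 0.50, 0.70, 0.90]
        assert val == [0.20, 0.30, 0.40, 0.50, 0.70, 0.80]

    def test_panel_deterministic_under_seed(self):
        a = rp.generate_panel(rp.PanelConfig(seed=11))
        b = rp.generate_panel(rp.PanelConfig(seed=11))
        assert [r.label for r in a.records] == [r.label for r in b.records]
        for ra, rb in zip(a.records, b.records):
            np.testing.assert_array_equal(ra.surface.values, rb.surface.values)

    def test_unknown_mixture_species_rejected(self):
        with pytest.raises(rp.ConfigError):
            rp.PanelConfig(
                mixture_series=(rp.MixtureSeries("FO", "XX", (0.5,)),)
            )
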