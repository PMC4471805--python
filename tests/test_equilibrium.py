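"""Unit tests for assembly schemes, equilibrium solutions and association fits."""

import numpy as np
import pytest

from oligomass.equilibrium import (
    OutOfRangeError,
    ValidationError,
    apparent_kd_from_inflection,
    build_scheme,
    dimer_tetramer_hexamer,
    fit_association,
    kd3_for_apparent_kd,
    monomer_trimer,
    predict_binding_curve,
    solve_equilibrium,
    species_molar_ratio,
    weight_average_mw,
)
from oligomass.simulate import SeriesDesign, simulate_binding_series


class TestBuildScheme:
    def test_coiled_coil_species_masses(self):
        s = build_scheme("cc", 12.5, 0.0, "monomer", [(3, 1.0)])
        assert s.orders == (1, 3)
        np.testing.assert_allclose(s.species_masses, [12.5, 37.5])

    def test_tagged_obligate_dimer_masses(self):
        s = build_scheme("flex", 46.0, 16.0, "obligate_dimer", [(4, 1.0), (6, 2.0)])
        np.testing.assert_allclose(s.species_masses, [124.0, 248.0, 372.0])

    def test_single_species_scheme_rejected(self):
        with pytest.raises(ValidationError, match="two species"):
            build_scheme("imp-dimer", 6.5, 0.0, "obligate_dimer", [])

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(protomer_mass=-1.0), "protomer_mass"),
            (dict(protomer_mass=12.5, tag_mass=-0.1), "tag_mass"),
            (dict(protomer_mass=12.5, steps=[(3, -1.0)]), "kd"),
            (dict(protomer_mass=12.5, steps=[(3, 1.0), (2, 1.0)]), "strictly increasing"),
        ],
    )
    def test_invalid_fields_named(self, kwargs, match):
        kwargs.setdefault("steps", [(3, 1.0)])
        with pytest.raises(ValidationError, match=match):
            build_scheme("bad", **kwargs)


class TestSolveEquilibrium:
    def test_monomer_trimer_hand_solution(self):
        # kd3 = [M]^3/[T] = 1 μM², c_total = 4 μM → [M] = [T] = 1 μM
        dist = solve_equilibrium(monomer_trimer(12.5, 1.0), 4.0)
        np.testing.assert_allclose(dist.concentrations, [1.0, 1.0], rtol=1e-9)

    def test_hexamer_chain_hand_solution(self):
        # equal stepwise kds of 3 μM, c_total = 36 μM → [D]=[T]=[H]=3 μM
        dist = solve_equilibrium(dimer_tetramer_hexamer(46.0, 16.0, 3.0, 3.0), 36.0)
        np.testing.assert_allclose(dist.concentrations, [3.0, 3.0, 3.0], rtol=1e-9)

    def test_zero_concentration_gives_empty_system(self, cc_scheme):
        dist = solve_equilibrium(cc_scheme, 0.0)
        np.testing.assert_array_equal(dist.concentrations, 0.0)

    def test_mass_conservation_random_schemes(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            base = rng.choice(["monomer", "obligate_dimer"])
            base_order = 2 if base == "obligate_dimer" else 1
            n_steps = rng.integers(1, 4)
            orders, kds = [], []
            prev = base_order
            for j in range(n_steps):
                jump = int(rng.integers(1, 4)) if j == 0 else 1
                prev += jump * base_order
                orders.append(prev)
                kds.append(10.0 ** rng.uniform(-2, 2))
            scheme = build_scheme("rand", 10.0 ** rng.uniform(0.5, 2), 0.0, base, list(zip(orders, kds)))
            c_total = 10.0 ** rng.uniform(-3, 3)
            dist = solve_equilibrium(scheme, c_total)
            total = float(np.dot(scheme.orders, dist.concentrations))
            assert abs(total - c_total) / c_total <= 1e-9

    def test_agrees_with_bisection_oracle(self):
        """Independent fixed-iteration bisection on the free-monomer concentration."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            kds = [10.0 ** rng.uniform(-2, 2), 10.0 ** rng.uniform(-2, 2)]
            scheme = build_scheme("s", 12.5, 0.0, "monomer", [(2, kds[0]), (3, kds[1])])
            c_total = 10.0 ** rng.uniform(-3, 3)

            def total(m):
                d = m * m / kds[0]
                t = d * m / kds[1]
                return m + 2 * d + 3 * t

            lo, hi = 0.0, c_total
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if total(mid) > c_total:
                    hi = mid
                else:
                    lo = mid
            dist = solve_equilibrium(scheme, c_total)
            assert dist.concentrations[0] == pytest.approx(0.5 * (lo + hi), rel=1e-8)


class TestWeightAverageMW:
    def test_single_species_limit(self, cc_scheme):
        dist = solve_equilibrium(cc_scheme, 1e-9)
        assert weight_average_mw(dist) == pytest.approx(12.5, rel=1e-6)

    def test_hand_arithmetic_equal_molar(self):
        # [M] = [T] = 1 μM: (12.5² + 37.5²)/(12.5 + 37.5) = 31.25
        dist = solve_equilibrium(monomer_trimer(12.5, 1.0), 4.0)
        assert weight_average_mw(dist) == pytest.approx(31.25, rel=1e-9)

    def test_equal_mass_fractions_give_midpoint(self):
        # equal mass fractions of 12.5 and 37.5 kDa → 25.0 by definition
        from oligomass.equilibrium import SpeciesDistribution

        scheme = monomer_trimer(12.5, 1.0)
        dist = SpeciesDistribution(scheme, 6.0, np.array([3.0, 1.0]))  # 3·12.5 = 1·37.5 mass units
        assert weight_average_mw(dist) == pytest.approx(25.0)

    def test_undefined_at_zero_concentration(self, cc_scheme):
        with pytest.raises(ValidationError):
            weight_average_mw(solve_equilibrium(cc_scheme, 0.0))


class TestBindingCurvePrediction:
    def test_limits_and_monotonicity(self, cc_scheme):
        grid = np.logspace(-4, 5, 60)
        curve = predict_binding_curve(cc_scheme, grid)
        assert curve.provenance == "model"
        assert curve.mw[0] == pytest.approx(12.5, rel=1e-3)
        assert curve.mw[-1] == pytest.approx(37.5, rel=1e-2)
        assert np.all(np.diff(curve.mw) > 0)
        assert np.all((curve.mw >= 12.5) & (curve.mw <= 37.5))

    def test_empty_grid_rejected(self, cc_scheme):
        with pytest.raises(ValidationError):
            predict_binding_curve(cc_scheme, [])


class TestSpeciesRatio:
    def test_hexamer_tetramer_ratio(self, hexamer_scheme):
        dist = solve_equilibrium(hexamer_scheme, 36.0)
        assert species_molar_ratio(dist, 6, 4) == pytest.approx(1.0, rel=1e-9)

    def test_identity_ratio(self, hexamer_scheme):
        dist = solve_equilibrium(hexamer_scheme, 10.0)
        assert species_molar_ratio(dist, 4, 4) == 1.0

    def test_higher_orders_vanish_on_dilution(self, hexamer_scheme):
        ratios = [
            species_molar_ratio(solve_equilibrium(hexamer_scheme, c), 6, 4) for c in (10.0, 1.0, 0.01)
        ]
        assert ratios[0] > ratios[1] > ratios[2]
        assert ratios[2] < 1e-2

    def test_absent_species_and_zero_denominator(self, hexamer_scheme):
        dist = solve_equilibrium(hexamer_scheme, 10.0)
        with pytest.raises(KeyError):
            species_molar_ratio(dist, 8, 4)
        with pytest.raises(ZeroDivisionError):
            species_molar_ratio(solve_equilibrium(hexamer_scheme, 0.0), 6, 4)


class TestApparentKd:
    def test_closed_form_monomer_trimer(self):
        # midpoint where [M] = 3[T]: [M]² = kd3/3, c_mid = 2[M] = 2/√3 for kd3 = 1
        kd = apparent_kd_from_inflection(monomer_trimer(12.5, 1.0))
        assert kd == pytest.approx(2.0 / np.sqrt(3.0), rel=1e-9)

    def test_kd3_helper_inverts_midpoint(self):
        assert apparent_kd_from_inflection(monomer_trimer(12.5, kd3_for_apparent_kd(3.0))) == pytest.approx(
            3.0, rel=1e-9
        )

    def test_scale_invariance_of_mass_action(self):
        from oligomass.equilibrium import monomer_dimer_trimer

        # stepwise (single-base-unit) kds in μM: scaling both by f scales the midpoint by f
        base = apparent_kd_from_inflection(monomer_dimer_trimer(12.5, 1.0, 1.0))
        for f in (0.1, 10.0, 250.0):
            scaled = apparent_kd_from_inflection(monomer_dimer_trimer(12.5, f, f))
            assert scaled == pytest.approx(f * base, rel=1e-8)
        # the overall μM² constant of a direct trimerization scales as f² for the same dilation
        base3 = apparent_kd_from_inflection(monomer_trimer(12.5, 1.0))
        assert apparent_kd_from_inflection(monomer_trimer(12.5, 4.0)) == pytest.approx(2 * base3, rel=1e-8)

    def test_second_derivative_estimator_close_to_midpoint(self, cc_scheme):
        mid = apparent_kd_from_inflection(cc_scheme)
        infl = apparent_kd_from_inflection(cc_scheme, method="second_derivative")
        assert infl == pytest.approx(mid, rel=0.5)

    def test_particle_scale_below_protomer_scale(self, cc_scheme):
        assert apparent_kd_from_inflection(cc_scheme, scale="particle") < apparent_kd_from_inflection(cc_scheme)

    def test_measured_curve_midpoint(self, cc_scheme):
        curve = predict_binding_curve(cc_scheme, np.logspace(-3, 4, 40))
        kd = apparent_kd_from_inflection(curve, mw_limits=(12.5, 37.5))
        assert kd == pytest.approx(3.0, rel=1e-3)

    def test_monomer_limit_only_is_out_of_range(self, cc_scheme):
        curve = predict_binding_curve(cc_scheme, np.logspace(-4, -2, 10))
        with pytest.raises(OutOfRangeError, match="wider"):
            apparent_kd_from_inflection(curve, mw_limits=(12.5, 37.5))


class TestFitAssociation:
    def test_noiseless_self_consistency(self, cc_scheme):
        curve = simulate_binding_series(cc_scheme, SeriesDesign(152.0, 11, 1, 0.0, 0))
        fit = fit_association(curve, monomer_trimer(12.5, 0.5))
        assert fit.converged
        assert fit.scheme.kds[0] == pytest.approx(6.75, rel=1e-6)
        assert fit.rss < 1e-12

    def test_noisy_recovery_within_30_percent(self, cc_scheme):
        curve = simulate_binding_series(cc_scheme, SeriesDesign(152.0, 11, 3, 0.03, 7))
        fit = fit_association(curve, monomer_trimer(12.5, 1.0))
        assert fit.converged
        assert fit.apparent_kd == pytest.approx(3.0, rel=0.30)

    def test_median_recovery_within_20_percent(self, cc_scheme):
        kds = []
        for seed in range(50):
            curve = simulate_binding_series(cc_scheme, SeriesDesign(152.0, 11, 3, 0.03, seed))
            kds.append(fit_association(curve, monomer_trimer(12.5, 1.0)).apparent_kd)
        assert np.median(kds) == pytest.approx(3.0, rel=0.20)

    def test_bootstrap_interval_brackets_estimate(self, cc_scheme):
        curve = simulate_binding_series(cc_scheme, SeriesDesign(152.0, 11, 3, 0.03, 7))
        fit = fit_association(curve, monomer_trimer(12.5, 1.0), bootstrap=50, seed=1729)
        lo, hi = fit.apparent_kd_ci
        assert lo <= fit.apparent_kd <= hi

    def test_flat_curve_hits_boundary(self):
        from oligomass.equilibrium import BindingCurve

        c = np.logspace(-1, 2, 8)
        flat = BindingCurve(c, np.full_like(c, 12.5))
        fit = fit_association(flat, monomer_trimer(12.5, 1.0))
        assert not fit.converged

    def test_too_few_points_rejected(self, cc_scheme):
        from oligomass.equilibrium import BindingCurve

        curve = BindingCurve([1.0, 2.0], [13.0, 14.0])
        with pytest.raises(ValidationError):
            fit_association(curve, cc_scheme)

    def test_tag_shifts_masses_not_kds(self):
        untagged = monomer_trimer(12.5, 6.75)
        tagged = build_scheme("cc-tag", 12.5, 16.0, "monomer", [(3, 6.75)])
        d_u = simulate_binding_series(untagged, SeriesDesign(152.0, 11, 1, 0.0, 0))
        d_t = simulate_binding_series(tagged, SeriesDesign(152.0, 11, 1, 0.0, 0))
        kd_u = fit_association(d_u, monomer_trimer(12.5, 1.0)).scheme.kds[0]
        kd_t = fit_association(d_t, build_scheme("cc-tag", 12.5, 16.0, "monomer", [(3, 1.0)])).scheme.kds[0]
        assert kd_t == pytest.approx(kd_u, rel=1e-6)
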