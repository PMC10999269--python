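"""Dynamical core: niche response, interactions, dispersal, integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sedadyn import (
    DriverSeries,
    MetacommunityParams,
    NicheParams,
    dispersal_flux,
    functional_response,
    niche_response,
    per_capita_growth,
    simulate,
)


def make_params(S=2, L=2, **over):
    base = dict(
        n_species=S,
        n_sites=L,
        growth=NicheParams(
            r=np.ones(S), mu=np.zeros(S), sigma=np.ones(S), b0=np.zeros(S)
        ),
        alpha=np.zeros((S, S)),
    )
    base.update(over)
    return MetacommunityParams(**base)


class TestNicheResponse:
    def test_maximum_at_optimum(self):
        p = make_params(
            S=1, L=1,
            growth=NicheParams(r=[1.0], mu=[10.0], sigma=[2.0], b0=[0.0]),
        )
        assert niche_response(p, 0, 10.0) == pytest.approx(1.0)
        # one niche breadth from the optimum
        assert niche_response(p, 0, 12.0) == pytest.approx(np.exp(-0.5))
        assert niche_response(p, 0, 12.0) < niche_response(p, 0, 10.0)

    def test_zero_amplitude_returns_baseline(self):
        p = make_params(
            S=1, L=1,
            growth=NicheParams(r=[0.0], mu=[10.0], sigma=[2.0], b0=[0.37]),
        )
        for u in (-5.0, 10.0, 40.0):
            assert niche_response(p, 0, u) == pytest.approx(0.37)

    def test_bad_species_index(self):
        p = make_params(S=2, L=1)
        with pytest.raises(IndexError):
            niche_response(p, 5, 0.0)


class TestFunctionalResponse:
    def test_no_trophic_links(self):
        p = make_params(S=3, L=1)
        assert np.array_equal(
            functional_response(p, np.ones(3)), np.zeros((3, 3))
        )

    def test_linear_limit_and_saturation(self):
        attack = np.zeros((2, 2))
        attack[0, 1] = 0.5
        p_lin = make_params(S=2, L=1, attack=attack, handling=np.inf)
        F = functional_response(p_lin, np.array([0.0, 2.0]))
        assert F[0, 1] == pytest.approx(0.5)
        p_sat = make_params(S=2, L=1, attack=attack, handling=1.0)
        F = functional_response(p_sat, np.array([0.0, 2.0]))
        # 0.5 / (1 + 0.5*2/1) = 0.25
        assert F[0, 1] == pytest.approx(0.25)

    def test_negative_abundance_rejected(self):
        p = make_params(S=2, L=1)
        with pytest.raises(ValueError):
            functional_response(p, np.array([-0.1, 1.0]))


class TestPerCapitaGrowth:
    def test_all_zero_parameters(self):
        p = make_params(
            S=3, L=1,
            growth=NicheParams(
                r=np.zeros(3), mu=np.zeros(3), sigma=np.ones(3), b0=np.zeros(3)
            ),
        )
        assert np.allclose(per_capita_growth(p, np.array([1.0, 2.0, 3.0]), 0.0), 0)

    def test_logistic_equilibrium(self):
        r, K = 0.7, 2.5
        p = make_params(
            S=1, L=1,
            growth=NicheParams(r=[r], mu=[0.0], sigma=[1.0], b0=[0.0]),
            alpha=[[r / K]],
        )
        assert per_capita_growth(p, np.array([K]), 0.0)[0] == pytest.approx(0.0)

    def test_two_species_arithmetic(self):
        p = make_params(
            S=2, L=1,
            growth=NicheParams(
                r=[1.0, 0.5], mu=[0.0, 0.0], sigma=[1.0, 1.0], b0=[0.0, 0.0]
            ),
            alpha=[[0.1, 0.05], [0.02, 0.1]],
        )
        g = per_capita_growth(p, np.array([2.0, 3.0]), 0.0)
        assert g == pytest.approx([0.65, 0.16])

    def test_shape_mismatch(self):
        p = make_params(S=2, L=1)
        with pytest.raises(ValueError):
            per_capita_growth(p, np.ones(3), 0.0)


class TestDispersalFlux:
    def test_zero_rates(self):
        p = make_params(S=1, L=3)
        assert np.allclose(dispersal_flux(p, 0, np.array([1.0, 2.0, 3.0])), 0)

    def test_two_box_exchange(self):
        m = np.full((1, 2, 2), 0.1)
        p = make_params(S=1, L=2, dispersal=m)
        flux = dispersal_flux(p, 0, np.array([4.0, 0.0]))
        assert flux == pytest.approx([-0.4, 0.4])

    def test_symmetric_equal_abundance(self):
        m = np.full((1, 3, 3), 0.2)
        p = make_params(S=1, L=3, dispersal=m)
        assert np.allclose(dispersal_flux(p, 0, np.full(3, 1.7)), 0)

    @settings(max_examples=50, deadline=None)
    @given(
        n=st.lists(
            st.floats(0, 100, allow_nan=False), min_size=3, max_size=3
        ),
        m=st.lists(
            st.floats(0, 5, allow_nan=False), min_size=9, max_size=9
        ),
    )
    def test_mass_conservation_property(self, n, m):
        """Dispersal fluxes always cancel when summed across sites."""
        p = make_params(S=1, L=3, dispersal=np.array(m).reshape(1, 3, 3))
        flux = dispersal_flux(p, 0, np.array(n))
        assert abs(flux.sum()) <= 1e-9 * max(1.0, np.abs(flux).max())


class TestSimulate:
    def test_zero_model_constant(self):
        p = make_params(
            S=2, L=2,
            growth=NicheParams(
                r=np.zeros(2), mu=np.zeros(2), sigma=np.ones(2), b0=np.zeros(2)
            ),
        )
        drivers = [DriverSeries([0, 10], [0, 0], site=f"s{k}") for k in range(2)]
        n0 = np.array([[1.0, 2.0], [3.0, 4.0]])
        traj = simulate(p, n0, drivers, (0, 10), np.linspace(0, 10, 11))
        assert np.allclose(traj.abundance, n0[:, :, None])

    def test_logistic_closed_form(self, logistic_params, flat_driver):
        grid = np.linspace(0, 10, 201)
        traj = simulate(logistic_params, [[0.1]], flat_driver, (0, 10), grid)
        exact = 1.0 / (1.0 + 9.0 * np.exp(-grid))
        rel = np.abs(traj.abundance[0, 0] - exact) / exact
        assert rel.max() < 1e-6
        # spot value: N(1) = 1/(1+9 e^-1)
        n1 = traj.abundance[0, 0, 20]
        assert n1 == pytest.approx(1.0 / (1.0 + 9.0 * np.exp(-1.0)), abs=1e-6)

    def test_pure_dispersal_conserves_totals(self):
        rng = np.random.default_rng(42)
        m = rng.uniform(0, 0.05, (2, 3, 3))
        p = make_params(
            S=2, L=3,
            growth=NicheParams(
                r=np.zeros(2), mu=np.zeros(2), sigma=np.ones(2), b0=np.zeros(2)
            ),
            dispersal=m,
        )
        drivers = [DriverSeries([0, 1e4], [0, 0], site=f"s{k}") for k in range(3)]
        n0 = rng.uniform(0.5, 2.0, (2, 3))
        grid = np.linspace(0, 1e4, 101)
        traj = simulate(p, n0, drivers, (0, 1e4), grid)
        totals = traj.abundance.sum(axis=1)
        rel_err = np.abs(totals - totals[:, [0]]) / totals[:, [0]]
        assert rel_err.max() < 1e-8

    def test_nonnegativity(self):
        # strong mortality drives abundances toward zero; never below
        p = make_params(
            S=2, L=1,
            growth=NicheParams(
                r=np.zeros(2), mu=np.zeros(2), sigma=np.ones(2),
                b0=[-0.5, -1.0],
            ),
            alpha=0.3 * np.ones((2, 2)),
        )
        drivers = [DriverSeries([0, 100], [0, 0])]
        traj = simulate(p, np.full((2, 1), 1.0), drivers, (0, 100),
                        np.linspace(0, 100, 51))
        assert np.all(traj.abundance >= 0)

    def test_competition_monotonicity(self):
        """Raising alpha_12 never raises species 1's trajectory."""
        def run(a12):
            p = make_params(
                S=2, L=1,
                growth=NicheParams(
                    r=[0.5, 0.5], mu=[0.0, 0.0], sigma=[1.0, 1.0],
                    b0=[0.0, 0.0],
                ),
                alpha=np.array([[1.0, a12], [0.0, 1.0]]),
            )
            drivers = [DriverSeries([0, 50], [0, 0])]
            return simulate(
                p, np.full((2, 1), 0.1), drivers, (0, 50),
                np.linspace(0, 50, 26),
            ).abundance[0, 0]

        prev = run(0.0)
        for a12 in (0.2, 0.5, 1.0):
            cur = run(a12)
            assert np.all(cur <= prev + 1e-9)
            prev = cur

    def test_grid_refinement(self, trio_data):
        """Halving tolerances barely changes the 3-species fixture output."""
        sc, _, _ = trio_data
        kw = dict(rtol=1e-8, atol=1e-10)
        a = simulate(sc.params, sc.initial_abundance, sc.drivers, sc.t_span,
                     sc.output_grid, **kw).abundance
        b = simulate(sc.params, sc.initial_abundance, sc.drivers, sc.t_span,
                     sc.output_grid, rtol=5e-9, atol=5e-11).abundance
        scale = np.maximum(np.abs(a), 1e-6)
        assert np.max(np.abs(a - b) / scale) < 1e-5

    def test_invalid_inputs(self, logistic_params, flat_driver):
        with pytest.raises(ValueError):
            simulate(logistic_params, [[-0.1]], flat_driver, (0, 10),
                     np.linspace(0, 10, 5))
        with pytest.raises(ValueError):
            simulate(logistic_params, [[0.1]], flat_driver, (0, 5),
                     np.linspace(0, 10, 5))


class TestParamsContainer:
    def test_yaml_round_trip(self, two_species_params):
        text = two_species_params.to_yaml()
        back = MetacommunityParams.from_yaml(text)
        assert back == two_species_params

    def test_yaml_round_trip_infinite_handling(self):
        p = make_params(S=2, L=2, handling=np.inf,
                        dispersal=np.full((2, 2, 2), 0.1))
        back = MetacommunityParams.from_yaml(p.to_yaml())
        assert back == p
        assert np.isinf(back.handling)

    def test_dispersal_diagonal_zeroed(self):
        p = make_params(S=1, L=2, dispersal=np.ones((1, 2, 2)))
        assert p.dispersal[0, 0, 0] == 0.0
        assert p.dispersal[0, 1, 1] == 0.0

    @pytest.mark.parametrize(
        "field,value",
        [
            ("epsilon", 1.5),
            ("attack", -np.ones((2, 2))),
            ("handling", -1.0),
        ],
    )
    def test_invariants_enforced(self, field, value):
        with pytest.raises(ValueError):
            make_params(S=2, L=2, **{field: value})

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            NicheParams(r=[1.0], mu=[0.0], sigma=[0.0], b0=[0.0])


class TestDriverSeries:
    def test_interpolation_and_extrapolation(self):
        d = DriverSeries([0.0, 10.0], [1.0, 3.0])
        assert d(5.0) == pytest.approx(2.0)
        assert d(-100.0) == pytest.approx(1.0)
        assert d(100.0) == pytest.approx(3.0)

    def test_bp_conversion(self):
        d = DriverSeries([11700.0, 0.0], [-2.0, 6.0], site="lakeX")
        m = d.to_model_time(11700.0)
        assert m.times[0] == 0.0
        assert m(0.0) == pytest.approx(-2.0)
        assert m(11700.0) == pytest.approx(6.0)

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            DriverSeries([0.0, 5.0, 5.0], [1.0, 2.0, 3.0])
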