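"""Mesh construction, PDE integration, and the fluid-mixing operator."""

import numpy as np
import pytest

from follisim.geometry import FollicleGeometry, GrowthLaw
from follisim.kinetics import SPECIES, species_index
from follisim.parameters import ParameterSet
from follisim.solver import (
    DAY,
    FieldState,
    Mesh,
    build_mesh,
    initial_state,
    mix_fluid,
    run_simulation,
)

TINY = 1e-300


def inert_params(**overrides):
    """All reactions essentially switched off; growth/diffusion remain."""
    off = dict(
        k_on=TINY, delta_F=TINY, delta_L=TINY, delta_A=TINY, delta_E=TINY,
        delta_RF=TINY, delta_RL=TINY, delta_RE=TINY, delta_CF=TINY,
        delta_CL=TINY, delta_CE=TINY, delta_I=TINY,
        rho_RF=TINY, rho_RL=TINY, rho_RE=TINY, rho_I=TINY, rho_E=TINY,
        rho_F=TINY, rho_L=TINY, rho_A=TINY, Delta=TINY, I0_frac=TINY,
    )
    off.update(overrides)
    return ParameterSet(**off)


class TestMesh:
    @pytest.mark.parametrize("variant", ["two_compartment", "antrum"])
    def test_resolves_every_layer(self, variant):
        geom = FollicleGeometry(variant=variant)
        mesh = build_mesh(geom)
        for layer, intervals in geom.layer_bounds().items():
            for lo, hi in intervals:
                inside = (mesh.nodes > lo) & (mesh.nodes < hi)
                assert inside.sum() >= 8, f"{layer} [{lo},{hi}] under-resolved"

    def test_boundaries_are_nodes(self):
        geom = FollicleGeometry(variant="antrum")
        mesh = build_mesh(geom)
        bounds = {b for ivs in geom.layer_bounds().values() for ab in ivs for b in ab}
        for b in bounds:
            assert np.any(np.isclose(mesh.nodes, b, atol=1e-12))

    def test_cell_widths_sum_to_domain(self):
        mesh = build_mesh(FollicleGeometry(variant="antrum"))
        assert mesh.cell_widths.sum() == pytest.approx(2.0)

    def test_rejects_unsorted_nodes(self):
        geom = FollicleGeometry()
        with pytest.raises(ValueError):
            Mesh(nodes=np.array([-1.0, 0.5, 0.2, 1.0]),
                 labels=np.array(["a"] * 4, dtype=object), geometry=geom)


class TestInitialState:
    def test_igf_preloaded_in_theca_only(self, params):
        geom = FollicleGeometry(variant="antrum")
        mesh = build_mesh(geom)
        state = initial_state(params, geom, mesh)
        theca = mesh.mask("theca")
        i_row = state.species("I")
        assert np.all(i_row[theca] == pytest.approx(0.3 * params.K_I))
        assert np.all(i_row[~theca] == 0.0)
        # theca sits at both ends, so the profile is even in xi
        np.testing.assert_allclose(i_row, i_row[::-1])

    def test_everything_else_zero(self, params):
        geom = FollicleGeometry(variant="two_compartment")
        mesh = build_mesh(geom)
        state = initial_state(params, geom, mesh)
        for name in SPECIES:
            if name != "I":
                assert np.all(state.species(name) == 0.0)


class TestRunSimulation:
    def test_zero_sources_give_zero_solution(self):
        geom = FollicleGeometry(variant="two_compartment")
        res = run_simulation(inert_params(), geom,
                             output_times=[0, DAY, 2 * DAY])
        assert np.max(np.abs(res.states)) < 1e-12

    def test_growth_dilution_closed_form(self):
        """With transport and reactions off, every concentration decays as
        Lambda(0)/Lambda(t) under uniform domain growth."""
        p = inert_params(I0_frac=0.3, D_I=TINY)
        geom = FollicleGeometry(variant="two_compartment")
        mesh = build_mesh(geom)
        times = [0, 2 * DAY, 5 * DAY]
        res = run_simulation(p, geom, mesh, times, rtol=1e-8, atol=1e-10)
        law = GrowthLaw(p.Lambda0, p.v)
        i0 = res.states[0, species_index("I")]
        for k, t in enumerate(times):
            expected = i0 * law.length(0) / law.length(t)
            np.testing.assert_allclose(res.states[k, species_index("I")],
                                       expected, rtol=1e-5, atol=1e-12)

    def test_static_uniform_profile_is_steady(self):
        """No growth, no reactions: diffusion leaves a constant alone."""
        p = inert_params(v=0.0)
        geom = FollicleGeometry(variant="two_compartment")
        mesh = build_mesh(geom)
        conc = np.zeros((len(SPECIES), mesh.n_nodes))
        conc[species_index("F")] = 1.7
        res = run_simulation(p, geom, mesh, [0, DAY],
                             initial=FieldState(conc, 0.0))
        np.testing.assert_allclose(res.states[-1, species_index("F")], 1.7, rtol=1e-6)

    def test_mass_conservation_without_sources(self):
        """v = 0 and all gain/loss terms off: the spatial integral of
        ligand + complex is an invariant of binding plus diffusion."""
        p = inert_params(v=0.0, k_on=1e-3)
        geom = FollicleGeometry(variant="two_compartment")
        mesh = build_mesh(geom)
        rng = np.random.default_rng(5)
        conc = np.zeros((len(SPECIES), mesh.n_nodes))
        for name in ("F", "Rf", "Cf", "L", "Rl", "Cl"):
            smooth = np.interp(mesh.nodes, np.linspace(-1, 1, 9), rng.uniform(0, 5, 9))
            conc[species_index(name)] = smooth
        res = run_simulation(p, geom, mesh, [0, DAY], initial=FieldState(conc, 0.0))
        w = mesh.cell_widths
        for lig, cpx in (("F", "Cf"), ("L", "Cl")):
            total = (res.species(lig) + res.species(cpx)) @ w
            assert total[-1] == pytest.approx(total[0], rel=1e-6)

    def test_two_compartment_solution_stays_even(self, two_comp_result):
        """Symmetric geometry and initial data: c(xi) = c(-xi) at all times."""
        res = two_comp_result
        assert np.allclose(res.mesh.nodes, -res.mesh.nodes[::-1])
        flipped = res.states[..., ::-1]
        scale = np.abs(res.states).max(axis=-1, keepdims=True) + 1e-12
        assert np.max(np.abs(res.states - flipped) / scale) < 1e-3

    def test_first_state_is_initial_condition(self, antrum_result, params):
        geom = antrum_result.geometry
        expected = initial_state(params, geom, antrum_result.mesh)
        np.testing.assert_array_equal(antrum_result.states[0], expected.concentrations)

    def test_deterministic_rerun(self, params):
        geom = FollicleGeometry(variant="antrum")
        mesh = build_mesh(geom, nodes_per_unit=40, min_layer_nodes=8)
        a = run_simulation(params, geom, mesh, [0, DAY])
        b = run_simulation(params, geom, mesh, [0, DAY])
        np.testing.assert_array_equal(a.states, b.states)

    def test_concentrations_essentially_nonnegative(self, antrum_result):
        assert antrum_result.states.min() >= -100 * antrum_result.diagnostics["atol"]

    def test_bad_initial_shape_rejected(self, params):
        geom = FollicleGeometry(variant="antrum")
        mesh = build_mesh(geom)
        with pytest.raises(ValueError):
            run_simulation(params, geom, mesh,
                           initial=FieldState(np.zeros((11, 3)), 0.0))


class TestMixFluid:
    @pytest.fixture()
    def setup(self, params):
        geom = FollicleGeometry(variant="antrum_mixed")
        mesh = build_mesh(geom)
        return geom, mesh

    def test_uniform_fluid_unchanged(self, setup, params):
        geom, mesh = setup
        conc = np.zeros((len(SPECIES), mesh.n_nodes))
        conc[species_index("F")] = 2.0
        state = FieldState(conc, 0.0)
        out = mix_fluid(state, mesh, geom)
        np.testing.assert_array_almost_equal(out.concentrations, conc)

    def test_idempotent_and_conservative(self, setup, params):
        geom, mesh = setup
        rng = np.random.default_rng(1)
        conc = rng.uniform(0, 10, size=(len(SPECIES), mesh.n_nodes))
        state = FieldState(conc, 0.0)
        once = mix_fluid(state, mesh, geom)
        twice = mix_fluid(once, mesh, geom)
        np.testing.assert_allclose(once.concentrations, twice.concentrations, rtol=1e-13)
        fluid = mesh.mask("fluid")
        w = mesh.cell_widths
        for name in ("F", "L", "A", "E"):
            i = species_index(name)
            assert (once.concentrations[i] * w)[fluid].sum() == pytest.approx(
                (conc[i] * w)[fluid].sum(), rel=1e-12)

    def test_receptors_untouched(self, setup, params):
        geom, mesh = setup
        rng = np.random.default_rng(2)
        conc = rng.uniform(0, 10, size=(len(SPECIES), mesh.n_nodes))
        out = mix_fluid(FieldState(conc, 0.0), mesh, geom)
        for name in ("Rf", "Rl", "Re", "Cf", "Cl", "Ce", "I"):
            i = species_index(name)
            np.testing.assert_array_equal(out.concentrations[i], conc[i])

    def test_empty_fluid_rejected(self, params):
        geom = FollicleGeometry(variant="two_compartment")
        mesh = build_mesh(geom)
        conc = np.zeros((len(SPECIES), mesh.n_nodes))
        with pytest.raises(ValueError):
            mix_fluid(FieldState(conc, 0.0), mesh, geom)

    def test_mixed_run_has_flat_fluid_profiles(self, params):
        geom = FollicleGeometry(variant="antrum_mixed")
        mesh = build_mesh(geom, nodes_per_unit=40, min_layer_nodes=8)
        res = run_simulation(params, geom, mesh, [0, DAY],
                            mix_substep=3600.0)
        fluid = mesh.mask("fluid")
        f_end = res.states[-1, species_index("F"), fluid]
        assert np.ptp(f_end) <= 1e-9 * max(f_end.max(), 1e-12)
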