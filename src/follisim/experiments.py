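"""Scenario presets, the parameter-noise robustness analysis, and config I/O.

Each scenario reproduces one figure-level computation: hormone-gradient
profiles on the growing or scaled domain, steroid production and fluid
levels, receptor-field panels, the four expression time courses, and the
thick-theca sensitivity variant.  All scenarios run the default five-day
horizon with daily outputs.

Robustness bands follow the published protocol: an ensemble of simulations
with every kinetic parameter multiplied by independent Gaussian factors
(mean 1, relative SD 0.2), summarised as per-time mean and standard
deviation of each scenario observable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import FollicleGeometry, GrowthLaw, physical_coordinate
from .observables import (
    ObservableSeries,
    compartment_average,
    expression_timecourses,
    export_csv,
    fluid_average,
    receptor_fields,
    steroid_production_fields,
)
from .parameters import NoiseSpec, ParameterSet, default_parameters, sample_noisy_parameters
from .solver import DAY, SimulationResult, build_mesh, run_simulation

__all__ = [
    "Scenario",
    "SCENARIOS",
    "RobustnessResult",
    "SolverConfig",
    "load_config",
    "resolve_config",
    "run_scenario",
    "scenario_observables",
    "robustness_bands",
    "run_seed",
]


@dataclass(frozen=True)
class Scenario:
    """A named figure-level computation."""

    name: str
    variant: str
    description: str
    geometry_overrides: dict = field(default_factory=dict)
    parameter_overrides: dict = field(default_factory=dict)


SCENARIOS: dict[str, Scenario] = {
    s.name: s
    for s in [
        Scenario("fig3_timecourses", "two_compartment",
                 "Expression time courses of LH/FSH receptors and aromatase"),
        Scenario("fig4_growing", "two_compartment",
                 "FSH and LH gradients plotted on the growing domain"),
        Scenario("fig4_scaled", "two_compartment",
                 "FSH and LH gradients on the scaled (stationary) domain"),
        Scenario("fig4_antrum", "antrum",
                 "FSH and LH gradients with the fluid-filled antrum"),
        Scenario("fig4_mixed", "antrum_mixed",
                 "FSH and LH gradients with rapid mixing in the antrum"),
        Scenario("fig5_steroids", "antrum",
                 "Steroid production fields and fluid-average time courses"),
        Scenario("fig6_receptors", "antrum",
                 "Receptor production, free/bound receptors, and activities"),
        Scenario("supp_thick_theca", "antrum",
                 "Steroid outputs with a 20% thicker theca",
                 geometry_overrides={"theca_scale": 1.2}),
    ]
}


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings shared by all scenarios."""

    nodes_per_unit: float = 120.0
    min_layer_nodes: int = 10
    rtol: float = 1e-6
    atol: float = 1e-8
    mix_substep: float = 600.0
    mix_mode: str = "split"
    output_days: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0)

    @property
    def output_times(self) -> tuple[float, ...]:
        return tuple(d * DAY for d in self.output_days)

    def fast(self) -> "SolverConfig":
        """Coarser profile for quick runs: half the grid, looser tolerance."""
        return SolverConfig(nodes_per_unit=self.nodes_per_unit / 2,
                            min_layer_nodes=8, rtol=1e-5, atol=1e-7,
                            mix_substep=max(self.mix_substep, 3600.0),
                            mix_mode=self.mix_mode,
                            output_days=self.output_days)


def load_config(path) -> dict:
    """Read a YAML configuration with sections parameters/geometry/solver/noise."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    unknown = set(cfg) - {"parameters", "geometry", "solver", "noise"}
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    return cfg


def resolve_config(
    scenario: Scenario, config: dict | None = None
) -> tuple[ParameterSet, FollicleGeometry, SolverConfig, dict]:
    """Merge scenario presets with a configuration dict.

    Precedence: config file values override scenario presets, which override
    package defaults.  Unknown parameter keys raise.
    """
    config = config or {}
    params = default_parameters().replace(**{
        **scenario.parameter_overrides, **config.get("parameters", {})
    })
    geo_kwargs = {"variant": scenario.variant,
                  **scenario.geometry_overrides, **config.get("geometry", {})}
    geom = FollicleGeometry(**geo_kwargs)
    solver_cfg = SolverConfig(**config.get("solver", {}))
    noise_cfg = config.get("noise", {})
    return params, geom, solver_cfg, noise_cfg


def _simulate(params: ParameterSet, geom: FollicleGeometry,
              solver: SolverConfig) -> SimulationResult:
    mesh = build_mesh(geom, solver.nodes_per_unit, solver.min_layer_nodes)
    return run_simulation(
        params, geom, mesh, solver.output_times,
        rtol=solver.rtol, atol=solver.atol,
        mix_substep=solver.mix_substep, mix_mode=solver.mix_mode,
    )


def scenario_observables(name: str, result: SimulationResult) -> dict[str, ObservableSeries]:
    """Scalar time courses summarising a scenario (used for noise bands)."""
    if name in ("fig3_timecourses", "fig6_receptors"):
        return expression_timecourses(result)
    if name in ("fig5_steroids", "supp_thick_theca"):
        return {"A_fluid": fluid_average(result, "A"),
                "E_fluid": fluid_average(result, "E")}
    # gradient scenarios: track compartment-average hormone levels
    comp = "granulosa" if result.geometry.variant == "two_compartment" else "fluid"
    return {f"F_{comp}": compartment_average(result, "F", comp),
            f"L_{comp}": compartment_average(result, "L", comp)}


def _write_profiles(result: SimulationResult, species_names, out: Path,
                    stem: str, scaled: bool) -> None:
    """Per-day concentration profiles, one CSV per species."""
    law = result.growth_law
    for name in species_names:
        traj = result.species(name)
        cols: dict[str, np.ndarray] = {"xi": result.mesh.nodes}
        for i, t in enumerate(result.times):
            day = t / DAY
            if not scaled:
                cols[f"x_mm_day{day:g}"] = np.asarray(physical_coordinate(
                    result.mesh.nodes, float(t), result.geometry, law))
            cols[f"{name}_nM_day{day:g}"] = traj[i]
        export_csv(cols, out / f"{stem}_{name}.csv", index_name="xi")


def run_scenario(
    name: str,
    config: dict | None = None,
    out_dir=None,
    fast: bool = False,
) -> SimulationResult:
    """Run a named scenario; optionally write its observable files.

    Writes (under ``out_dir``): the full solution as ``solution.csv``, the
    scenario's characteristic CSVs, and ``manifest.json`` with the resolved
    configuration.
    """
    if name not in SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    scenario = SCENARIOS[name]
    params, geom, solver_cfg, _ = resolve_config(scenario, config)
    if fast:
        solver_cfg = solver_cfg.fast()
    result = _simulate(params, geom, solver_cfg)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.save_csv(out / "solution.csv")
        if name == "fig3_timecourses":
            export_csv(expression_timecourses(result), out / "timecourses.csv")
        elif name.startswith("fig4"):
            _write_profiles(result, ("F", "L"), out, "profile",
                            scaled=name != "fig4_growing")
        elif name in ("fig5_steroids", "supp_thick_theca"):
            export_csv({"time_s": result.times,
                        "A_fluid_nM": fluid_average(result, "A").values,
                        "E_fluid_nM": fluid_average(result, "E").values},
                       out / "fluid_steroids.csv")
            _write_profiles(result, ("A", "E"), out, "profile", scaled=True)
            prod = steroid_production_fields(result)
            for key, field_arr in prod.items():
                cols = {"xi": result.mesh.nodes}
                for i, t in enumerate(result.times):
                    cols[f"{key}_day{t / DAY:g}"] = field_arr[i]
                export_csv(cols, out / f"{key}.csv", index_name="xi")
        elif name == "fig6_receptors":
            fields = receptor_fields(result)
            for rec, panels in fields.items():
                for panel, arr in panels.items():
                    arr = np.broadcast_to(arr, (result.times.size, result.mesh.n_nodes))
                    cols = {"xi": result.mesh.nodes}
                    for i, t in enumerate(result.times):
                        cols[f"{rec}_{panel}_day{t / DAY:g}"] = arr[i]
                    export_csv(cols, out / f"receptor_{rec}_{panel}.csv",
                               index_name="xi")
        manifest = {
            "scenario": name,
            "parameters": params.to_dict(),
            "geometry": {
                "variant": geom.variant, "xi_theta": geom.xi_theta,
                "xi_phi1": geom.xi_phi1, "xi_phi2": geom.xi_phi2,
                "theca_scale": geom.theca_scale,
                "length_convention": geom.length_convention,
            },
            "solver": {"nodes_per_unit": solver_cfg.nodes_per_unit,
                       "rtol": solver_cfg.rtol, "atol": solver_cfg.atol,
                       "n_nodes": result.mesh.n_nodes},
            "diagnostics": result.diagnostics,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def run_seed(master_seed: int, i: int) -> int:
    """Counter-based per-run seed derived from the master seed."""
    return int((master_seed * 1_000_003 + i) % (2**31 - 1))


@dataclass(frozen=True)
class RobustnessResult:
    """Ensemble mean and SD bands of scenario observables under noise."""

    scenario: str
    noise: NoiseSpec
    times: np.ndarray
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    run_seeds: tuple[int, ...]
    n_failed: int = 0

    def save_csv(self, path) -> None:
        cols: dict[str, np.ndarray] = {"time_s": self.times}
        for key in self.mean:
            cols[f"{key}_mean"] = self.mean[key]
            cols[f"{key}_sd"] = self.sd[key]
        export_csv(cols, path, index_name="time_s")


def robustness_bands(
    scenario_name: str,
    noise: NoiseSpec,
    config: dict | None = None,
    fast: bool = False,
) -> RobustnessResult:
    """Run the Gaussian-noise ensemble for a scenario.

    Each run perturbs all kinetic parameters once (the perturbation is held
    constant in time) with a per-run seed derived from ``noise.seed``.
    Failed integrations are excluded; more than 20% failures is an error.
    """
    if scenario_name not in SCENARIOS:
        raise KeyError(f"unknown scenario {scenario_name!r}")
    scenario = SCENARIOS[scenario_name]
    params, geom, solver_cfg, _ = resolve_config(scenario, config)
    if fast:
        solver_cfg = solver_cfg.fast()

    seeds = tuple(run_seed(noise.seed, i) for i in range(noise.n_runs))
    per_obs: dict[str, list[np.ndarray]] = {}
    times = None
    n_failed = 0
    for s in seeds:
        one = NoiseSpec(relative_sd=noise.relative_sd, n_runs=1, seed=s,
                        perturbed_fields=noise.perturbed_fields)
        noisy = sample_noisy_parameters(params, one)[0]
        try:
            result = _simulate(noisy, geom, solver_cfg)
        except RuntimeError:
            n_failed += 1
            continue
        obs = scenario_observables(scenario_name, result)
        times = result.times
        for key, series in obs.items():
            per_obs.setdefault(key, []).append(series.values)
    if n_failed > 0.2 * noise.n_runs:
        raise RuntimeError(
            f"{n_failed}/{noise.n_runs} ensemble runs failed to integrate")
    mean = {k: np.mean(np.stack(v), axis=0) for k, v in per_obs.items()}
    sd = {k: np.std(np.stack(v), axis=0, ddof=0) for k, v in per_obs.items()}
    return RobustnessResult(scenario_name, noise, times, mean, sd, seeds, n_failed)
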