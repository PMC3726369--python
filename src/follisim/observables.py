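"""Reduction of simulation results to reported quantities.

Provides compartment-averaged time courses (receptor expression, fluid
steroid levels), pointwise production and activity fields, and CSV export.
All averages are length-weighted on the 1D mesh; "total receptor" means
free plus ligand-bound, since bound LH receptor is heavily internalized and
free-only averages would misrepresent the theca time course.  The aromatase
observable is the dimensionless regulation factor
sigma_I * (1 + sigma_E*sigma_G) * (1 + sigma_G), the quantity that scales
estradiol production, evaluated per point or compartment-averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import catalysis_rate, regulatory_state, species_index
from .solver import SimulationResult

__all__ = [
    "ObservableSeries",
    "compartment_average",
    "fluid_average",
    "expression_timecourses",
    "receptor_fields",
    "steroid_production_fields",
    "aromatase_activity",
    "export_csv",
]


@dataclass(frozen=True)
class ObservableSeries:
    """A named scalar time course with units and provenance."""

    name: str
    times: np.ndarray
    values: np.ndarray
    units: str = "nM"
    compartment: str = ""
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have the same length")

    def normalized_to_max(self) -> "ObservableSeries":
        """Rescale to a maximum of 1 (no-op for an all-zero series)."""
        peak = float(np.max(np.abs(self.values)))
        vals = self.values / peak if peak > 0 else self.values
        return ObservableSeries(self.name, self.times, vals, "relative",
                                self.compartment, True)


def _weights(result: SimulationResult, compartment: str) -> np.ndarray:
    mask = result.mesh.mask(compartment)
    if not mask.any():
        raise ValueError(f"compartment {compartment!r} is empty on this mesh")
    w = np.where(mask, result.mesh.cell_widths, 0.0)
    return w / w.sum()


def compartment_average(
    result: SimulationResult,
    species_or_field,
    compartment: str,
    name: str | None = None,
    units: str = "nM",
) -> ObservableSeries:
    """Length-weighted mean over a compartment at each output time.

    ``species_or_field`` is a species name, or a (n_times, n_nodes) array of
    any per-node quantity (a production rate, an activity, a sum of species).
    """
    if isinstance(species_or_field, str):
        field = result.species(species_or_field)
        name = name or species_or_field
    else:
        field = np.asarray(species_or_field, dtype=float)
        if field.shape != (result.times.size, result.mesh.n_nodes):
            raise ValueError("field must have shape (n_times, n_nodes)")
        name = name or "field"
    w = _weights(result, compartment)
    values = field @ w
    return ObservableSeries(f"{name}_{compartment}", result.times, values,
                            units, compartment)


def fluid_average(result: SimulationResult, species: str) -> ObservableSeries:
    """Average concentration of a soluble species in the follicular fluid."""
    return compartment_average(result, species, "fluid")


def _total(result: SimulationResult, free: str, bound: str) -> np.ndarray:
    return result.species(free) + result.species(bound)


def _conc(result: SimulationResult, name: str) -> np.ndarray:
    """Species trajectory with sub-tolerance negative excursions clipped."""
    return np.maximum(result.species(name), 0.0)


def _regulation(result: SimulationResult):
    return regulatory_state(_conc(result, "Cf"), _conc(result, "Cl"),
                            _conc(result, "Ce"), _conc(result, "I"),
                            result.params)


def aromatase_activity(result: SimulationResult) -> np.ndarray:
    """Aromatase regulation factor sigma_I*(1+sigma_E*sigma_G)*(1+sigma_G)
    per time and node (dimensionless)."""
    reg = _regulation(result)
    return reg.sigma_I * (1.0 + reg.sigma_E * reg.sigma_G) * (1.0 + reg.sigma_G)


def expression_timecourses(
    result: SimulationResult, normalize: bool = False
) -> dict[str, ObservableSeries]:
    """The four expression time courses: total LH receptor in theca and
    granulosa, total FSH receptor in granulosa, and the aromatase regulation
    factor in the granulosa.

    For the two-compartment geometry "granulosa" averages cover the whole
    cellular interior; for antrum variants they cover the mural granulosa
    strip.
    """
    gran = "granulosa"
    lhr = _total(result, "Rl", "Cl")
    fshr = _total(result, "Rf", "Cf")
    series = {
        "lhr_theca": compartment_average(result, lhr, "theca", name="total_LHR"),
        "lhr_granulosa": compartment_average(result, lhr, gran, name="total_LHR"),
        "fshr_granulosa": compartment_average(result, fshr, gran, name="total_FSHR"),
        "aromatase_granulosa": compartment_average(
            result, aromatase_activity(result), gran,
            name="aromatase", units="dimensionless"),
    }
    if normalize:
        series = {k: s.normalized_to_max() for k, s in series.items()}
    return series


def receptor_fields(result: SimulationResult) -> dict[str, dict[str, np.ndarray]]:
    """Per-receptor field sets: production rate, free receptor, bound
    complex, and pointwise signalling activity, each (n_times, n_nodes)."""
    p = result.params
    _, gamma, phi = result.mesh.indicator_fields()
    cells = 1.0 - phi
    reg = _regulation(result)
    sE, sI = reg.sigma_E, reg.sigma_I
    return {
        "fsh": {
            "production": p.rho_RF * (gamma * p.theta + sI * (1.0 + sE)) * cells,
            "free": result.species("Rf"),
            "bound": result.species("Cf"),
            "activity": reg.sigma_F,
        },
        "lh": {
            "production": p.rho_RL * sI * (1.0 + sE) * cells,
            "free": result.species("Rl"),
            "bound": result.species("Cl"),
            "activity": reg.sigma_L,
        },
        "estrogen": {
            "production": p.rho_RE * (1.0 + sE) * (1.0 - sI) * cells,
            "free": result.species("Re"),
            "bound": result.species("Ce"),
            "activity": sE,
        },
    }


def steroid_production_fields(result: SimulationResult) -> dict[str, np.ndarray]:
    """Androgen delivery/production and estradiol (aromatase) production
    rate fields, nM/s, per time and node."""
    p = result.params
    theta, gamma, _ = result.mesh.indicator_fields()
    reg = _regulation(result)
    androgen = p.rho_A * (1.0 + reg.sigma_G) * p.Delta * theta
    estradiol = catalysis_rate(_conc(result, "A"), _conc(result, "I"),
                               reg.sigma_E, reg.sigma_G, gamma, p)
    return {"androgen_production": androgen, "estradiol_production": estradiol}


def export_csv(series, path, index_name: str = "time_s") -> None:
    """Write observable series (or xi-indexed fields) to a CSV file.

    ``series`` maps column names to ObservableSeries, or to plain arrays
    sharing one index passed as ``("index", array)`` in the mapping under
    the key of ``index_name``.  A metadata comment records units.
    """
    import pandas as pd

    if not series:
        with open(path, "w") as fh:
            fh.write(f"{index_name}\n")
        return
    cols: dict[str, np.ndarray] = {}
    units: dict[str, str] = {}
    index = None
    for key, s in series.items():
        if isinstance(s, ObservableSeries):
            if index is None:
                index = np.asarray(s.times, dtype=float)
            elif not np.array_equal(index, s.times):
                raise ValueError("all series must share the same time grid")
            cols[key] = s.values
            units[key] = s.units
        else:
            arr = np.asarray(s, dtype=float)
            if key == index_name:
                index = arr
            else:
                cols[key] = arr
                units[key] = ""
    if index is None:
        raise ValueError(f"no index column {index_name!r} provided")
    df = pd.DataFrame({index_name: index, **cols})
    with open(path, "w") as fh:
        unit_note = ", ".join(f"{k}: {u}" for k, u in units.items() if u)
        if unit_note:
            fh.write(f"# units -- {unit_note}\n")
        df.to_csv(fh, index=False)
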