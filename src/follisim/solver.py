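"""Method-of-lines integration of the growing-domain reaction-diffusion system.

The PDE for each species on the stationary frame xi in [-1, 1] reads

    dc/dt + (v / Lambda(t)) c = (D / l(t)^2) d2c/dxi2 + R(c),

where the (v/Lambda) term is the dilution caused by uniform domain growth and
l(t) is the physical length per unit xi (Lambda/2 under the default
``half_length`` convention, Lambda under ``as_printed``).  Zero-flux boundary
conditions hold at xi = +-1.

Space is discretized with a conservative finite-volume scheme on a
non-uniform mesh graded toward the thin theca and granulosa layers; time
integration uses an implicit adaptive stiff method (scipy BDF) with a sparse
Jacobian pattern.  Rapid mixing of the follicular fluid (variant
``antrum_mixed``) is applied by operator splitting: after each accepted
substep the soluble species are replaced by their mass-conserving average
over the fluid; alternatively a large effective fluid diffusivity can be
used (``mix_mode="diffusive"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.integrate import solve_ivp

from .geometry import FollicleGeometry, GrowthLaw, indicators
from .kinetics import (
    SPECIES,
    diffusion_coefficients,
    reaction_jacobian,
    reaction_rates,
    species_index,
)
from .parameters import ParameterSet

__all__ = [
    "Mesh",
    "FieldState",
    "SimulationResult",
    "build_mesh",
    "initial_state",
    "run_simulation",
    "mix_fluid",
    "DAY",
    "DEFAULT_OUTPUT_TIMES",
]

DAY = 86400.0
DEFAULT_OUTPUT_TIMES = tuple(float(d) * DAY for d in range(6))

#: Soluble hormones subject to fluid mixing.
SOLUBLE = ("F", "L", "A", "E")


@dataclass(frozen=True)
class Mesh:
    """Non-uniform spatial mesh on xi in [-1, 1] with compartment labels."""

    nodes: np.ndarray            # sorted xi values incl. -1, 1, boundaries
    labels: np.ndarray           # per-node layer name
    geometry: FollicleGeometry

    def __post_init__(self) -> None:
        if np.any(np.diff(self.nodes) <= 0):
            raise ValueError("mesh nodes must be strictly increasing")
        if self.nodes[0] != -1.0 or self.nodes[-1] != 1.0:
            raise ValueError("mesh must span [-1, 1]")

    @property
    def n_nodes(self) -> int:
        return self.nodes.size

    @property
    def cell_widths(self) -> np.ndarray:
        """Finite-volume control widths (xi measure), summing to 2."""
        x = self.nodes
        w = np.empty_like(x)
        w[1:-1] = 0.5 * (x[2:] - x[:-2])
        w[0] = 0.5 * (x[1] - x[0])
        w[-1] = 0.5 * (x[-1] - x[-2])
        return w

    def mask(self, compartment: str) -> np.ndarray:
        """Boolean node mask; 'gamma' means granulosa plus cell block."""
        if compartment == "gamma":
            return np.isin(self.labels, ("granulosa", "cell_block"))
        if compartment not in ("theca", "granulosa", "cell_block", "fluid"):
            raise ValueError(f"unknown compartment {compartment!r}")
        return self.labels == compartment

    def indicator_fields(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return indicators(self.nodes, self.geometry)


@dataclass(frozen=True)
class FieldState:
    """Concentrations (nM) of all species on the mesh at one time."""

    concentrations: np.ndarray   # (n_species, n_nodes)
    time: float

    def __post_init__(self) -> None:
        if self.concentrations.shape[0] != len(SPECIES):
            raise ValueError(f"expected {len(SPECIES)} species rows")

    def species(self, name: str) -> np.ndarray:
        return self.concentrations[species_index(name)]


@dataclass(frozen=True)
class SimulationResult:
    """Full space-time solution plus everything needed to reproduce it."""

    times: np.ndarray            # (n_times,), s
    states: np.ndarray           # (n_times, n_species, n_nodes), nM
    mesh: Mesh
    geometry: FollicleGeometry
    params: ParameterSet
    diagnostics: dict = field(default_factory=dict)

    def species(self, name: str) -> np.ndarray:
        """(n_times, n_nodes) trajectory of one species."""
        return self.states[:, species_index(name), :]

    def state_at(self, i: int) -> FieldState:
        return FieldState(self.states[i], float(self.times[i]))

    @property
    def growth_law(self) -> GrowthLaw:
        return GrowthLaw(self.params.Lambda0, self.params.v)

    def to_dataframe(self):
        """Long-format table: time_s, xi, x_mm, species, conc_nM."""
        import pandas as pd

        from .geometry import physical_coordinate

        frames = []
        for i, t in enumerate(self.times):
            x_mm = physical_coordinate(self.mesh.nodes, float(t), self.geometry, self.growth_law)
            for s, name in enumerate(SPECIES):
                frames.append(pd.DataFrame({
                    "time_s": float(t),
                    "xi": self.mesh.nodes,
                    "x_mm": x_mm,
                    "species": name,
                    "conc_nM": self.states[i, s],
                }))
        return pd.concat(frames, ignore_index=True)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def build_mesh(
    geom: FollicleGeometry,
    nodes_per_unit: float = 120.0,
    min_layer_nodes: int = 10,
) -> Mesh:
    """Boundary-fitted mesh with at least ``min_layer_nodes`` intervals per
    layer and Chebyshev-style grading inside wide segments.

    Every compartment boundary is a mesh node; thin layers (theca,
    granulosa) are resolved regardless of the global density.
    """
    bounds = sorted({lo for ivs in geom.layer_bounds().values() for lo, _ in ivs}
                    | {hi for ivs in geom.layer_bounds().values() for _, hi in ivs})
    nodes = [bounds[0]]
    for a, b in zip(bounds[:-1], bounds[1:]):
        width = b - a
        n = max(min_layer_nodes, int(round(width * nodes_per_unit)))
        if width > 0.1:
            # cosine grading: cluster toward both segment ends
            s = 0.5 * (1.0 - np.cos(np.linspace(0.0, np.pi, n + 1)))
        else:
            s = np.linspace(0.0, 1.0, n + 1)
        nodes.extend((a + s[1:] * width).tolist())
    arr = np.array(nodes)
    arr[-1] = 1.0
    return Mesh(nodes=arr, labels=geom.layer_of(arr), geometry=geom)


def initial_state(params: ParameterSet, geom: FollicleGeometry, mesh: Mesh) -> FieldState:
    """Zero everywhere except the IGF complex, pre-loaded in the theca.

    I(0) = I0_frac * K_I on theca nodes reflects the early presence of
    IGF-2/IGF-receptor complexes in the vascularised theca; everything else
    starts at zero so the spatial patterns emerge from the regulation alone.
    """
    conc = np.zeros((len(SPECIES), mesh.n_nodes))
    theta, _, _ = mesh.indicator_fields()
    conc[species_index("I")] = params.I0_frac * params.K_I * theta
    return FieldState(concentrations=conc, time=0.0)


def _diffusion_operator(nodes: np.ndarray, d_field: np.ndarray) -> sp.csr_matrix:
    """Conservative flux-form second-derivative operator with zero-flux ends.

    ``d_field`` is the per-node diffusion coefficient; interface values use
    the harmonic mean.  For constant ``d_field`` this reduces to the standard
    central stencil on a non-uniform grid.
    """
    n = nodes.size
    h = np.diff(nodes)                       # interval widths, (n-1,)
    dl, dr = d_field[:-1], d_field[1:]
    d_face = np.where(dl + dr > 0, 2.0 * dl * dr / np.maximum(dl + dr, 1e-300), 0.0)
    g = d_face / h                           # face conductances
    w = np.empty(n)
    w[1:-1] = 0.5 * (nodes[2:] - nodes[:-2])
    w[0] = 0.5 * h[0]
    w[-1] = 0.5 * h[-1]

    main = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    main[:-1] -= g / w[:-1]
    upper += g / w[:-1]
    main[1:] -= g / w[1:]
    lower += g / w[1:]
    return sp.diags([lower, main, upper], [-1, 0, 1], format="csr")


def mix_fluid(state: FieldState, mesh: Mesh, geom: FollicleGeometry) -> FieldState:
    """Replace soluble species in the follicular fluid by their average.

    The average is length-weighted over the fluid nodes, so the total amount
    of each species in the fluid is conserved to machine precision; receptor
    species and the IGF complex are untouched.  Idempotent.
    """
    fluid = mesh.mask("fluid")
    if not fluid.any():
        raise ValueError("geometry has an empty fluid compartment")
    w = mesh.cell_widths[fluid]
    conc = state.concentrations.copy()
    for name in SOLUBLE:
        i = species_index(name)
        conc[i, fluid] = np.average(conc[i, fluid], weights=w)
    return FieldState(concentrations=conc, time=state.time)


def _jac_sparsity(n_nodes: int) -> sp.csr_matrix:
    """Jacobian pattern: dense species coupling per node, nearest-neighbour
    coupling within each species (node-major ordering)."""
    ns = len(SPECIES)
    ones = sp.csr_matrix(np.ones((ns, ns)))
    neigh = sp.diags([np.ones(n_nodes - 1)] * 2, [-1, 1], format="csr")
    return (sp.kron(sp.eye(n_nodes), ones) + sp.kron(neigh, sp.eye(ns))).tocsr()


def run_simulation(
    params: ParameterSet,
    geom: FollicleGeometry,
    mesh: Mesh | None = None,
    output_times=None,
    *,
    initial: FieldState | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    method: str = "BDF",
    mix_substep: float = 600.0,
    mix_mode: str = "split",
    mix_diffusivity: float = 10.0,
) -> SimulationResult:
    """Integrate the full system and return the solution at ``output_times``.

    ``output_times`` defaults to daily outputs over 5 days; time zero is
    always included so the first stored state is the initial condition.
    Raises ``RuntimeError`` on integrator failure or if any concentration
    drops below -100 * atol.
    """
    if mesh is None:
        mesh = build_mesh(geom)
    if output_times is None:
        output_times = DEFAULT_OUTPUT_TIMES
    t_out = np.asarray(sorted(set(float(t) for t in output_times) | {0.0}))
    if np.any(t_out < 0):
        raise ValueError("output times must be non-negative")

    law = GrowthLaw(params.Lambda0, params.v)
    inds = mesh.indicator_fields()
    d_coeffs = diffusion_coefficients(params)
    n_nodes = mesh.n_nodes
    ns = len(SPECIES)

    mixing = geom.variant == "antrum_mixed"
    fluid = mesh.mask("fluid")

    ops = []
    for i, name in enumerate(SPECIES):
        d_field = np.full(n_nodes, d_coeffs[i])
        if mixing and mix_mode == "diffusive" and name in SOLUBLE:
            d_field[fluid] += mix_diffusivity
        ops.append(_diffusion_operator(mesh.nodes, d_field))

    half = 2.0 if geom.length_convention == "half_length" else 1.0

    # constant-pattern diffusion operator over the full state vector
    # (node-major layout); time dependence enters only through 1/l(t)^2
    diff_template = sp.csr_matrix((ns * n_nodes, ns * n_nodes))
    for i in range(ns):
        unit = sp.csr_matrix(([1.0], ([i], [i])), shape=(ns, ns))
        diff_template = diff_template + sp.kron(ops[i], unit)
    diff_template = diff_template.tocsr()
    identity = sp.identity(ns * n_nodes, format="csr")

    n_rhs = 0

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        nonlocal n_rhs
        n_rhs += 1
        c = y.reshape(n_nodes, ns).T
        c_pos = np.maximum(c, 0.0)          # clip only inside the reactions
        L = law.length(t)
        ell2 = (L / half) ** 2
        dc = reaction_rates(c_pos, inds, params)
        dc -= (params.v / L) * c
        for i in range(ns):
            dc[i] += (ops[i] @ c[i]) / ell2
        return dc.T.ravel()

    block_idx = np.arange(n_nodes)

    def jac(t: float, y: np.ndarray):
        c = y.reshape(n_nodes, ns).T
        c_pos = np.maximum(c, 0.0)
        L = law.length(t)
        ell2 = (L / half) ** 2
        Jr = reaction_jacobian(c_pos, inds, params)
        # clipped entries contribute nothing through the reactions
        Jr *= (c >= 0.0).T[:, None, :]
        Jbsr = sp.bsr_matrix((Jr, block_idx, np.arange(n_nodes + 1)),
                             shape=(ns * n_nodes, ns * n_nodes))
        return Jbsr + diff_template / ell2 - (params.v / L) * identity
    if initial is None:
        initial = initial_state(params, geom, mesh)
    if initial.concentrations.shape != (ns, n_nodes):
        raise ValueError("initial state does not match the mesh")
    y0 = initial.concentrations
    t_end = float(t_out[-1])

    states = np.empty((t_out.size, ns, n_nodes))
    states[0] = y0
    if t_out.size == 1 or t_end == 0.0:
        return SimulationResult(t_out, states[: 1], mesh, geom, params,
                                {"n_rhs": 0, "rtol": rtol, "atol": atol})

    def integrate(y_start, t0, t1, t_eval):
        kwargs = ({"jac": jac} if method in ("BDF", "Radau")
                  else {"jac_sparsity": _jac_sparsity(n_nodes)})
        sol = solve_ivp(
            rhs, (t0, t1), y_start, method=method, t_eval=t_eval,
            rtol=rtol, atol=atol, **kwargs,
        )
        if not sol.success:
            worst = np.nan
            if sol.y.size:
                worst = float(sol.t[-1])
            raise RuntimeError(
                f"integration failed at t={worst}: {sol.message}"
            )
        return sol

    if mixing and mix_mode == "split":
        # operator splitting: integrate in substeps, mix the fluid after each
        breaks = np.unique(np.concatenate([
            np.arange(0.0, t_end, mix_substep), t_out, [t_end]
        ]))
        y = y0.T.ravel()
        out_idx = 1
        for t0, t1 in zip(breaks[:-1], breaks[1:]):
            sol = integrate(y, t0, t1, [t1])
            y = sol.y[:, -1]
            c = y.reshape(n_nodes, ns).T
            mixed = mix_fluid(FieldState(c, t1), mesh, geom)
            y = mixed.concentrations.T.ravel()
            if out_idx < t_out.size and np.isclose(t1, t_out[out_idx]):
                states[out_idx] = mixed.concentrations
                out_idx += 1
        if out_idx != t_out.size:
            raise RuntimeError("internal error: missed an output time")
    else:
        sol = integrate(y0.T.ravel(), 0.0, t_end, t_out[1:])
        for j in range(1, t_out.size):
            states[j] = sol.y[:, j - 1].reshape(n_nodes, ns).T

    if states.min() < -100.0 * atol:
        i_t, i_s, _ = np.unravel_index(states.argmin(), states.shape)
        raise RuntimeError(
            f"solver produced negative concentrations: species {SPECIES[i_s]} "
            f"reached {states.min():.3e} nM at t={t_out[i_t]:.0f} s"
        )

    diagnostics = {"n_rhs": n_rhs, "rtol": rtol, "atol": atol,
                   "n_nodes": n_nodes, "method": method}
    return SimulationResult(t_out, states, mesh, geom, params, diagnostics)
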