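"""Reaction terms of the follicle signalling network.

Eleven species are tracked: the gonadotropins FSH (F) and LH (L), androgens
(A), estradiol (E), the free receptors of FSH/LH/estradiol (Rf, Rl, Re),
their ligand-bound complexes (Cf, Cl, Ce), and the active IGF-receptor
complex (I) which lumps the IGF/IGFBP/PAPP-A axis into a single variable.

Regulatory influences enter through Hill activities sigma_i of the bound
complexes; combined gonadotropin activity is the plain sum
sigma_G = sigma_F + sigma_L, reflecting the shared intracellular machinery
of the two receptors.

Compartment restriction is expressed through the indicator fields
(Theta, Gamma, Phi): blood exchange and androgen delivery act only in the
theca (Theta), aromatase catalysis only in the cellular block (Gamma), and
soluble hormones are not degraded in the cell-free follicular fluid (Phi),
implemented as a (1 - Phi) factor on their linear decay.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "SPECIES",
    "species_index",
    "diffusion_coefficients",
    "RegulatoryState",
    "hill",
    "hill_derivative",
    "regulatory_state",
    "catalysis_rate",
    "reaction_rates",
    "reaction_jacobian",
]

#: Ordered species identifiers; array axes follow this order everywhere.
SPECIES: tuple[str, ...] = ("F", "L", "A", "E", "Rf", "Rl", "Re", "Cf", "Cl", "Ce", "I")

_DIFF_FIELD = {
    "F": "D_H", "L": "D_H",
    "A": "D_S", "E": "D_S",
    "Rf": "D_R", "Rl": "D_R", "Re": "D_R", "Cf": "D_R", "Ce": "D_R",
    "Cl": "D_CL",
    "I": "D_I",
}


def species_index(name: str) -> int:
    try:
        return SPECIES.index(name)
    except ValueError:
        raise KeyError(f"unknown species {name!r}") from None


def diffusion_coefficients(params: ParameterSet) -> np.ndarray:
    """Per-species diffusion coefficients (mm^2/s) in ``SPECIES`` order.

    Gonadotropins share D_H, steroids D_S; the ligand-bound LH receptor has
    its own measured coefficient D_CL, all other receptors and complexes use
    the generic membrane coefficient D_R, and the IGF complex D_I.
    """
    return np.array([getattr(params, _DIFF_FIELD[s]) for s in SPECIES])


def hill(c, K: float, n: float):
    """Activating Hill function c^n / (c^n + K^n), in [0, 1).

    ``c`` may be a scalar or array of non-negative concentrations (nM).
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    if K <= 0:
        raise ValueError("Hill constant K must be positive")
    if n < 1:
        raise ValueError("Hill coefficient n must be >= 1")
    # computed as 1/(1 + (K/c)^n): stable for concentrations many orders of
    # magnitude above K, where c^n would overflow
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(c > 0, K / np.where(c > 0, c, 1.0), np.inf)
        out = 1.0 / (1.0 + ratio ** n)
    return out if out.ndim else float(out)


def hill_derivative(c, K: float, n: float):
    """d/dc of the activating Hill function, n * s * (1 - s) / c."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    s = np.asarray(hill(c, K, n))
    out = np.where(c > 0, n * s * (1.0 - s) / np.where(c > 0, c, 1.0),
                   0.0 if n > 1 else 1.0 / K)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class RegulatoryState:
    """Hill activities of the bound complexes at one or more points."""

    sigma_F: np.ndarray
    sigma_L: np.ndarray
    sigma_E: np.ndarray
    sigma_I: np.ndarray

    @property
    def sigma_G(self) -> np.ndarray:
        """Combined gonadotropin activity sigma_F + sigma_L, in [0, 2)."""
        return self.sigma_F + self.sigma_L


def regulatory_state(Cf, Cl, Ce, I, params: ParameterSet) -> RegulatoryState:
    """Evaluate all Hill activities from the bound-complex concentrations."""
    n = params.n_hill
    return RegulatoryState(
        sigma_F=hill(Cf, params.K_F, n),
        sigma_L=hill(Cl, params.K_L, n),
        sigma_E=hill(Ce, params.K_E, n),
        sigma_I=hill(I, params.K_I, n),
    )


def catalysis_rate(A, I, sigma_E, sigma_G, Gamma, params: ParameterSet):
    """Aromatase conversion rate of androgens into estradiol, nM/s.

    Michaelis-Menten in the androgen substrate, proportional to the IGF
    complex level I (the proxy for aromatase expression) and enhanced by
    estrogen and gonadotropin signalling; restricted to the cellular block
    by Gamma.
    """
    A = np.asarray(A, dtype=float)
    sat = A / (A + params.K_M)
    rate = params.rho_E * np.asarray(Gamma) * sat * np.asarray(I) \
        * (1.0 + np.asarray(sigma_E) * np.asarray(sigma_G)) * (1.0 + np.asarray(sigma_G))
    return rate if np.ndim(rate) else float(rate)


def reaction_rates(
    state: np.ndarray,
    indicators: tuple[np.ndarray, np.ndarray, np.ndarray],
    params: ParameterSet,
    granulosa: np.ndarray | None = None,
) -> np.ndarray:
    """Pointwise reaction rates R(c) for all species, nM/s.

    ``state`` has shape (11, ...) in ``SPECIES`` order; ``indicators`` is the
    (Theta, Gamma, Phi) triple evaluated at the same points.  ``granulosa``
    is the indicator of the mural granulosa layer, where the testosterone
    receptor resides and drives gonadotropin-independent FSH-receptor
    expression (the theta term); it defaults to Gamma, which is exact for
    the two-compartment layout.  Negative inputs raise; callers who
    integrate the system clip small negative excursions before evaluating.
    """
    state = np.asarray(state, dtype=float)
    if state.shape[0] != len(SPECIES):
        raise ValueError(f"state must have leading dimension {len(SPECIES)}")
    if np.any(state < 0):
        raise ValueError("state must be non-negative componentwise")
    Theta, Gamma, Phi = (np.asarray(ind, dtype=float) for ind in indicators)
    Gmur = Gamma if granulosa is None else np.asarray(granulosa, dtype=float)
    F, L, A, E, Rf, Rl, Re, Cf, Cl, Ce, I = state
    p = params

    reg = regulatory_state(Cf, Cl, Ce, I, p)
    sE, sI, sG = reg.sigma_E, reg.sigma_I, reg.sigma_G

    exch = p.Delta * Theta           # blood exchange, theca only
    decay_on = 1.0 - Phi             # no degradation of solubles in the fluid

    bind_F = p.k_on * F * Rf - p.k_off_F * Cf
    bind_L = p.k_on * L * Rl - p.k_off_L * Cl
    bind_E = p.k_on * E * Re - p.k_off_E * Ce
    cat = catalysis_rate(A, I, sE, sG, Gamma, p)

    R = np.empty_like(state)
    R[0] = (p.rho_F - F) * exch - bind_F - p.delta_F * F * decay_on
    R[1] = (p.rho_L - L) * exch - bind_L - p.delta_L * L * decay_on
    R[2] = (p.rho_A * (1.0 + sG) - A) * exch - p.delta_A * A * decay_on - cat
    R[3] = -E * exch - bind_E - p.delta_E * E * decay_on + cat
    cells = 1.0 - Phi                # receptors are made by cells only
    R[4] = p.rho_RF * (Gmur * p.theta + sI * (1.0 + sE)) * cells - bind_F - p.delta_RF * Rf
    R[5] = p.rho_RL * sI * (1.0 + sE) * cells - bind_L - p.delta_RL * Rl
    R[6] = p.rho_RE * (1.0 + sE) * (1.0 - sI) * cells - bind_E - p.delta_RE * Re
    R[7] = bind_F - p.delta_CF * Cf
    R[8] = bind_L - p.delta_CL * Cl
    R[9] = bind_E - p.delta_CE * Ce
    R[10] = p.rho_I * sG - p.delta_I * I
    return R


def reaction_jacobian(
    state: np.ndarray,
    indicators: tuple[np.ndarray, np.ndarray, np.ndarray],
    params: ParameterSet,
) -> np.ndarray:
    """Pointwise Jacobian dR_i/dc_j of the reaction terms.

    ``state`` has shape (11, n_points); the result has shape
    (n_points, 11, 11) with J[k, i, j] = dR_i/dc_j at point k.
    """
    state = np.asarray(state, dtype=float)
    n_pts = state.shape[1]
    Theta, Gamma, Phi = (np.broadcast_to(np.asarray(ind, dtype=float), (n_pts,))
                         for ind in indicators)
    F, L, A, E, Rf, Rl, Re, Cf, Cl, Ce, I = state
    p = params
    n = p.n_hill

    sF = hill(Cf, p.K_F, n)
    sL = hill(Cl, p.K_L, n)
    sE = hill(Ce, p.K_E, n)
    sI = hill(I, p.K_I, n)
    sG = sF + sL
    dsF = hill_derivative(Cf, p.K_F, n)
    dsL = hill_derivative(Cl, p.K_L, n)
    dsE = hill_derivative(Ce, p.K_E, n)
    dsI = hill_derivative(I, p.K_I, n)

    exch = p.Delta * Theta
    dec = 1.0 - Phi
    cells = 1.0 - Phi

    sat = A / (A + p.K_M)
    dsat = p.K_M / (A + p.K_M) ** 2
    reg_cat = (1.0 + sE * sG) * (1.0 + sG)
    base = p.rho_E * Gamma
    cat_A = base * dsat * I * reg_cat
    cat_I = base * sat * reg_cat
    # d reg_cat/d sG = sE (1 + sG) + (1 + sE sG); chain through sF or sL
    dreg_dsG = sE * (1.0 + sG) + (1.0 + sE * sG)
    cat_Cf = base * sat * I * dreg_dsG * dsF
    cat_Cl = base * sat * I * dreg_dsG * dsL
    cat_Ce = base * sat * I * sG * (1.0 + sG) * dsE

    iF, iL, iA, iE, iRf, iRl, iRe, iCf, iCl, iCe, iI = range(11)
    J = np.zeros((n_pts, 11, 11))

    J[:, iF, iF] = -exch - p.k_on * Rf - p.delta_F * dec
    J[:, iF, iRf] = -p.k_on * F
    J[:, iF, iCf] = p.k_off_F

    J[:, iL, iL] = -exch - p.k_on * Rl - p.delta_L * dec
    J[:, iL, iRl] = -p.k_on * L
    J[:, iL, iCl] = p.k_off_L

    J[:, iA, iA] = -exch - p.delta_A * dec - cat_A
    J[:, iA, iCf] = p.rho_A * exch * dsF - cat_Cf
    J[:, iA, iCl] = p.rho_A * exch * dsL - cat_Cl
    J[:, iA, iCe] = -cat_Ce
    J[:, iA, iI] = -cat_I

    J[:, iE, iE] = -exch - p.k_on * Re - p.delta_E * dec
    J[:, iE, iRe] = -p.k_on * E
    J[:, iE, iA] = cat_A
    J[:, iE, iCf] = cat_Cf
    J[:, iE, iCl] = cat_Cl
    J[:, iE, iCe] = p.k_off_E + cat_Ce
    J[:, iE, iI] = cat_I

    J[:, iRf, iF] = -p.k_on * Rf
    J[:, iRf, iRf] = -p.k_on * F - p.delta_RF
    J[:, iRf, iCf] = p.k_off_F
    J[:, iRf, iCe] = p.rho_RF * cells * sI * dsE
    J[:, iRf, iI] = p.rho_RF * cells * dsI * (1.0 + sE)

    J[:, iRl, iL] = -p.k_on * Rl
    J[:, iRl, iRl] = -p.k_on * L - p.delta_RL
    J[:, iRl, iCl] = p.k_off_L
    J[:, iRl, iCe] = p.rho_RL * cells * sI * dsE
    J[:, iRl, iI] = p.rho_RL * cells * dsI * (1.0 + sE)

    J[:, iRe, iE] = -p.k_on * Re
    J[:, iRe, iRe] = -p.k_on * E - p.delta_RE
    J[:, iRe, iCe] = p.k_off_E + p.rho_RE * cells * dsE * (1.0 - sI)
    J[:, iRe, iI] = -p.rho_RE * cells * (1.0 + sE) * dsI

    J[:, iCf, iF] = p.k_on * Rf
    J[:, iCf, iRf] = p.k_on * F
    J[:, iCf, iCf] = -(p.k_off_F + p.delta_CF)

    J[:, iCl, iL] = p.k_on * Rl
    J[:, iCl, iRl] = p.k_on * L
    J[:, iCl, iCl] = -(p.k_off_L + p.delta_CL)

    J[:, iCe, iE] = p.k_on * Re
    J[:, iCe, iRe] = p.k_on * E
    J[:, iCe, iCe] = -(p.k_off_E + p.delta_CE)

    J[:, iI, iCf] = p.rho_I * dsF
    J[:, iI, iCl] = p.rho_I * dsL
    J[:, iI, iI] = -p.delta_I
    return J
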