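"""Model parameters, unit conversions, and Gaussian-noise sampling.

The internal unit system is nanomolar (nM) for concentrations, seconds for
time and millimetres for length.  Cell volumes only appear at conversion
boundaries and are given in cubic micrometres.

Membrane receptors (FSH- and LH-receptor) react in a thin shell under the
plasma membrane whose volume is roughly 500-fold smaller than the granulosa
cell volume; the affected production rates and Hill constants therefore carry
a 500x factor relative to the whole-cell figures, and this factor is stored
as data (``membrane_factor``) rather than recomputed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "ParameterSet",
    "NoiseSpec",
    "AVOGADRO",
    "default_parameters",
    "receptors_per_cell_to_nM",
    "per_cell_rate_to_nM_per_s",
    "iu_per_l_to_nM",
    "mass_conc_to_nM",
    "gradient_length",
    "sample_noisy_parameters",
    "PERTURBABLE_FIELDS",
    "GRANULOSA_CELL_VOLUME_UM3",
]

AVOGADRO = 6.02214076e23  # molecules per mole

#: Measured volume of a granulosa cell, cubic micrometres.
GRANULOSA_CELL_VOLUME_UM3 = 1140.0


@dataclass(frozen=True)
class ParameterSet:
    """All rate, transport, affinity and regulation constants of the model.

    Units: diffusion coefficients mm^2/s, first-order rates 1/s, the
    association rate ``k_on`` 1/(nM s), production rates nM/s (except
    ``rho_E``, a catalytic turnover in 1/s, and the delivery levels
    ``rho_F``, ``rho_L``, ``rho_A`` in nM), Hill and Michaelis constants nM.
    """

    # Domain growth
    Lambda0: float = 5.0          # initial domain size, mm
    v: float = 2.3e-5             # growth speed, mm/s (~10 mm in 5 days)

    # Diffusion coefficients, mm^2/s
    D_H: float = 6.7e-5           # gonadotropins F, L
    D_S: float = 1.0e-4           # steroids A, E
    D_CL: float = 2.0e-8          # LH-bound receptor complex
    D_R: float = 1.0e-7           # other receptors and complexes
    D_I: float = 4.0e-9           # IGF-receptor complex

    # Binding kinetics
    k_on: float = 1.0e-3          # 1/(nM s)
    k_off_F: float = 5.0e-4       # K_D = 0.5 nM
    k_off_L: float = 1.0e-2       # K_D = 10 nM
    k_off_E: float = 1.0e-4       # K_D = 0.1 nM

    # Decay / turnover rates, 1/s
    delta_F: float = 1.0e-5
    delta_L: float = 5.0e-4
    delta_RF: float = 3.0e-5
    delta_RL: float = 3.0e-5
    delta_RE: float = 6.4e-5
    delta_CF: float = 6.4e-5
    delta_CL: float = 7.5e-4
    delta_CE: float = 6.4e-5
    delta_A: float = 6.4e-5
    delta_E: float = 6.4e-5
    delta_I: float = 1.2e-6

    # Production / delivery
    rho_RF: float = 0.25          # nM/s; 500 x 0.5 pM/s (membrane volume)
    rho_RL: float = 0.25          # nM/s
    rho_RE: float = 1.25e-3       # nM/s (1.25 pM/s, cytoplasmic receptor)
    rho_F: float = 2.0            # nM, serum FSH level delivered via theca
    rho_L: float = 0.8            # nM, 40% of FSH
    rho_A: float = 100.0          # nM, androgen precursor level
    rho_E: float = 0.06           # 1/s, aromatase k_cat
    rho_I: float = 2.8 * 5000.0 * 1.2e-6   # nM/s = 2.8 * K_I * delta_I
    K_M: float = 44.0             # nM, Michaelis constant of aromatase

    # Hill regulation
    K_F: float = 1500.0           # nM; 500 x 3 nM (membrane volume)
    K_L: float = 5.0              # nM; 500 x 10 pM (membrane volume)
    K_E: float = 35.0             # nM
    K_I: float = 5000.0           # nM (5 uM)
    n_hill: float = 2.0
    theta: float = 0.2            # gonadotropin-independent FSH-receptor drive

    # Blood exchange and initial condition
    Delta: float = 1.0            # 1/s
    I0_frac: float = 0.3          # I(0) = I0_frac * K_I on the theca
    membrane_factor: float = 500.0

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not np.isfinite(value):
                raise ValueError(f"{f.name} must be finite, got {value!r}")
            if f.name == "v":
                if value < 0:
                    raise ValueError("growth speed v must be non-negative")
            elif value <= 0:
                raise ValueError(f"{f.name} must be strictly positive, got {value!r}")
        if self.n_hill < 1:
            raise ValueError("Hill coefficient n_hill must be >= 1")

    def replace(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the given fields overridden.

        Unknown field names raise ``ValueError`` so that configuration typos
        do not silently fall back to defaults.
        """
        known = {f.name for f in fields(self)}
        unknown = set(overrides) - known
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Fields subject to the multiplicative-noise robustness analysis: every
#: kinetic, affinity and diffusion constant.  Geometry/growth (Lambda0, v),
#: the Hill coefficient, the stored membrane factor and the initial-condition
#: fraction are excluded.
PERTURBABLE_FIELDS: tuple[str, ...] = tuple(
    f.name
    for f in fields(ParameterSet)
    if f.name not in ("Lambda0", "v", "n_hill", "membrane_factor", "I0_frac")
)


@dataclass(frozen=True)
class NoiseSpec:
    """Specification of the Gaussian parameter-noise ensemble."""

    relative_sd: float = 0.2
    n_runs: int = 100
    seed: int = 0
    perturbed_fields: tuple[str, ...] = field(default=PERTURBABLE_FIELDS)

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be >= 0")
        if self.relative_sd >= 1:
            # factor ~ N(1, sd) truncated positive degenerates for sd >= 1
            raise ValueError("relative_sd >= 1 is rejected (degenerate truncation)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        unknown = set(self.perturbed_fields) - {f.name for f in fields(ParameterSet)}
        if unknown:
            raise ValueError(f"unknown perturbed field(s): {sorted(unknown)}")


def default_parameters() -> ParameterSet:
    """Return the default parameter set in internal units (nM, s, mm)."""
    return ParameterSet()


def receptors_per_cell_to_nM(count: float, cell_volume: float = GRANULOSA_CELL_VOLUME_UM3) -> float:
    """Convert a receptor copy number per cell into a nM concentration.

    Parameters
    ----------
    count : molecules per cell (>= 0)
    cell_volume : cell volume in cubic micrometres (> 0)
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    if cell_volume <= 0:
        raise ValueError("cell_volume must be positive")
    litres = cell_volume * 1e-15  # 1 um^3 = 1e-15 l
    molar = count / (litres * AVOGADRO)
    return molar * 1e9


def per_cell_rate_to_nM_per_s(rate: float, cell_volume: float = GRANULOSA_CELL_VOLUME_UM3) -> float:
    """Convert a production rate in molecules/cell/min into nM/s."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    return receptors_per_cell_to_nM(rate, cell_volume) / 60.0


def iu_per_l_to_nM(iu: float, ug_per_iu: float, mw: float) -> float:
    """Convert a gonadotropin level in IU/l into nM.

    ``ug_per_iu`` is the mass equivalent of one international unit in
    micrograms (about 46 for FSH, 23 for LH); ``mw`` the molecular weight
    in kDa.
    """
    if iu <= 0 or ug_per_iu <= 0 or mw <= 0:
        raise ValueError("all arguments must be positive")
    grams_per_l = iu * ug_per_iu * 1e-6
    molar = grams_per_l / (mw * 1e3)
    return molar * 1e9


def mass_conc_to_nM(conc: float, mw: float) -> float:
    """Convert a mass concentration in ng/ml into nM given the weight in kDa."""
    if conc < 0:
        raise ValueError("conc must be non-negative")
    if mw <= 0:
        raise ValueError("mw must be positive")
    grams_per_l = conc * 1e-6  # ng/ml == ug/l
    return grams_per_l / (mw * 1e3) * 1e9


def gradient_length(D: float, half_life: float) -> float:
    """Characteristic length sqrt(D/k) of a diffusion-degradation gradient.

    ``D`` in mm^2/s, ``half_life`` in seconds; the first-order removal rate
    is k = ln(2)/half_life.  Returns millimetres.
    """
    if D <= 0 or half_life <= 0:
        raise ValueError("D and half_life must be positive")
    k = math.log(2.0) / half_life
    return math.sqrt(D / k)


def sample_noisy_parameters(base: ParameterSet, spec: NoiseSpec) -> list[ParameterSet]:
    """Draw ``spec.n_runs`` parameter sets with multiplicative Gaussian noise.

    Each perturbed field is multiplied by an independent draw from
    Normal(1, relative_sd), redrawn until positive; all other fields are
    left unchanged.  Reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    out: list[ParameterSet] = []
    for _ in range(spec.n_runs):
        overrides: dict[str, float] = {}
        for name in spec.perturbed_fields:
            factor = rng.normal(1.0, spec.relative_sd)
            while factor <= 0.0:
                factor = rng.normal(1.0, spec.relative_sd)
            overrides[name] = getattr(base, name) * factor
        out.append(base.replace(**overrides))
    return out
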