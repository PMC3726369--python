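"""Follicle cross-section geometry on the stationary coordinate xi in [-1, 1].

The growing follicle is modelled as a uniformly expanding 1D cross-section of
length Lambda(t) = Lambda(0) + v*t.  On the stationary frame the compartment
boundaries are fixed: the vascularised theca occupies |xi| >= xi_theta at both
ends of the domain; in the antrum variants a cellular block (mural granulosa
plus cumulus-oocyte complex) sits at [xi_phi1, xi_phi2) on one side and the
follicular fluid fills the rest.

Two length conventions are supported.  Under ``half_length`` (the default)
Lambda denotes the follicle diameter spanned by xi in [-1, 1], so physical
positions are x = (Lambda/2) * xi; this is the convention that makes the
boundary arithmetic (xi_theta = 1 - 2*0.1/20 for a 100 um theca at a 20 mm
follicle, a 12.5 um granulosa at 5 mm) come out exactly.  ``as_printed``
instead uses x = Lambda * xi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthLaw",
    "FollicleGeometry",
    "VARIANTS",
    "LAYERS",
    "domain_length",
    "indicators",
    "layer_thickness",
    "physical_coordinate",
]

VARIANTS = ("two_compartment", "antrum", "antrum_mixed")
LAYERS = ("theca", "granulosa", "cell_block", "fluid")


@dataclass(frozen=True)
class GrowthLaw:
    """Linear domain growth Lambda(t) = Lambda0 + v*t (mm, mm/s)."""

    Lambda0: float = 5.0
    v: float = 2.3e-5

    def __post_init__(self) -> None:
        if self.Lambda0 <= 0:
            raise ValueError("Lambda0 must be positive")
        if self.v < 0:
            raise ValueError("v must be non-negative")

    def length(self, t: float) -> float:
        if np.any(np.asarray(t) < 0):
            raise ValueError("t must be non-negative")
        return self.Lambda0 + self.v * t


@dataclass(frozen=True)
class FollicleGeometry:
    """Compartment layout of the follicle cross-section.

    ``variant`` selects between the plain two-compartment layout
    (theca/granulosa), the antrum layout with a fluid-filled cavity, and the
    antrum layout with instantaneous mixing of soluble species in the fluid.

    ``theca_scale`` thickens the theca by moving xi_theta inward, as used by
    the sensitivity variant with a 20% thicker theca (theca_scale = 1.2).
    The cellular block rides on the theca's basal lamina: its boundaries
    slide inward by the same amount, so granulosa and COC keep their
    thickness and their distance to the theca.
    ``granulosa_width`` is the xi-width of the mural granulosa strip at the
    theca-side edge of the cellular block (antrum variants only).
    """

    variant: str = "antrum"
    xi_theta: float = 0.99
    xi_phi1: float = -0.985
    xi_phi2: float = -0.835
    theca_scale: float = 1.0
    granulosa_width: float = 0.005
    length_convention: str = "half_length"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.length_convention not in ("half_length", "as_printed"):
            raise ValueError("length_convention must be 'half_length' or 'as_printed'")
        if not 0 < self.xi_theta < 1:
            raise ValueError("xi_theta must lie in (0, 1)")
        if self.theca_scale <= 0:
            raise ValueError("theca_scale must be positive")
        if not 0 < self.xi_theta_eff < 1:
            raise ValueError("scaled theca boundary left the domain")
        if self.variant != "two_compartment":
            if not (-1 < self.xi_phi1_eff < self.xi_phi2_eff < self.xi_theta_eff):
                raise ValueError(
                    "need -1 < xi_phi1 < xi_phi2 < xi_theta (after theca scaling)"
                )
            if not 0 < self.granulosa_width <= self.xi_phi2 - self.xi_phi1:
                raise ValueError("granulosa_width must fit inside the cellular block")

    @property
    def xi_theta_eff(self) -> float:
        """Theca boundary after applying ``theca_scale``."""
        return 1.0 - self.theca_scale * (1.0 - self.xi_theta)

    @property
    def _shift(self) -> float:
        """Inward displacement of the cellular block under theca scaling."""
        return self.xi_theta_eff - self.xi_theta

    @property
    def xi_phi1_eff(self) -> float:
        return self.xi_phi1 + self._shift

    @property
    def xi_phi2_eff(self) -> float:
        return self.xi_phi2 + self._shift

    @property
    def has_antrum(self) -> bool:
        return self.variant != "two_compartment"

    def layer_bounds(self) -> dict[str, list[tuple[float, float]]]:
        """xi-intervals of each layer (half-open, closed at the lower bound)."""
        xt = self.xi_theta_eff
        theca = [(-1.0, -xt), (xt, 1.0)]
        if not self.has_antrum:
            return {
                "theca": theca,
                "granulosa": [(-xt, xt)],
                "cell_block": [],
                "fluid": [],
            }
        p1, p2 = self.xi_phi1_eff, self.xi_phi2_eff
        g0, g1 = p1, p1 + self.granulosa_width
        fluid = [(p2, xt)]
        if p1 > -xt:
            # sliver between the theca and the cellular block is fluid
            fluid.insert(0, (-xt, p1))
        return {
            "theca": theca,
            "granulosa": [(g0, g1)],
            "cell_block": [(g1, p2)],
            "fluid": fluid,
        }

    def layer_of(self, xi: np.ndarray) -> np.ndarray:
        """Layer name for each xi (boundaries belong to the lower-bound side
        of the half-open intervals; +1 closes the right theca)."""
        xi = np.atleast_1d(np.asarray(xi, dtype=float))
        if np.any(xi < -1) or np.any(xi > 1):
            raise ValueError("xi must lie in [-1, 1]")
        out = np.empty(xi.shape, dtype=object)
        out[:] = "fluid" if self.has_antrum else "granulosa"
        for name, intervals in self.layer_bounds().items():
            for lo, hi in intervals:
                mask = (xi >= lo) & (xi < hi)
                out[mask] = name
        out[xi >= 1.0] = "theca"
        out[np.abs(xi) >= self.xi_theta_eff] = "theca"
        return out


def domain_length(t: float, law: GrowthLaw) -> float:
    """Domain length Lambda(t) in mm."""
    return law.length(t)


def _half_scale(geom: FollicleGeometry, law: GrowthLaw, t: float) -> float:
    """Physical length per unit xi: Lambda/2 or Lambda, by convention."""
    L = law.length(t)
    return L / 2.0 if geom.length_convention == "half_length" else L


def indicators(
    xi: np.ndarray | float, geom: FollicleGeometry
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compartment indicator functions (Theta, Gamma, Phi) at xi.

    Theta marks the theca (both domain ends), Gamma the cellular block
    (granulosa + COC; the whole interior for the two-compartment variant),
    Phi the follicular fluid.  Exactly one of the three is 1 at every xi.
    """
    xi_arr = np.asarray(xi, dtype=float)
    if np.any(xi_arr < -1) or np.any(xi_arr > 1):
        raise ValueError("xi must lie in [-1, 1]")
    layer = geom.layer_of(np.atleast_1d(xi_arr))
    theta = (layer == "theca").astype(float)
    gamma = ((layer == "granulosa") | (layer == "cell_block")).astype(float)
    phi = (layer == "fluid").astype(float)
    if xi_arr.ndim == 0:
        return float(theta[0]), float(gamma[0]), float(phi[0])
    return theta, gamma, phi


def layer_thickness(
    geom: FollicleGeometry, law: GrowthLaw, layer: str, t: float
) -> float:
    """Physical thickness of a layer at time t, in mm.

    The theca thickness sums both ends of the domain; layer thicknesses of
    all four layers sum to the physical extent of the domain.
    """
    if layer not in LAYERS:
        raise ValueError(f"unknown layer {layer!r}; expected one of {LAYERS}")
    width = sum(hi - lo for lo, hi in geom.layer_bounds()[layer])
    return width * _half_scale(geom, law, t)


def physical_coordinate(
    xi: np.ndarray | float, t: float, geom: FollicleGeometry, law: GrowthLaw
) -> np.ndarray | float:
    """Physical position x (mm) of stationary coordinate xi at time t."""
    xi_arr = np.asarray(xi, dtype=float)
    if np.any(xi_arr < -1) or np.any(xi_arr > 1):
        raise ValueError("xi must lie in [-1, 1]")
    return xi_arr * _half_scale(geom, law, t)
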