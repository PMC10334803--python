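"""Worm-like-chain (WLC) entropic-spring mathematics.

The Marko–Siggia interpolation gives the restoring force of a semiflexible
polymer stretched to end-to-end extension ``x`` below its contour length
``L_C``::

    F(x) = (kBT / lp) * [ 1/4 (1 - x/L_C)^-2 + x/L_C - 1/4 ]

For an unfolded polypeptide the persistence length per residue is
lp = 0.38 nm, so a chain of ``n`` residues has contour length
``L_C = n * lp``.  Closed-form integration of ``F`` yields the elastic
energy stored between two extensions, and differentiation the local
spring constant.  These three quantities — force (pN), energy (kBT) and
stiffness (pN/nm) — are the primitives for the gating analysis.

Canonical internal units are nm / pN / pN·nm.  Interfaces also accept
ångström via :class:`Extension` or the :func:`angstrom` helper, since
structural coordinates are in Å.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.optimize import brentq

__all__ = [
    "BOLTZMANN_PN_NM_PER_K",
    "Extension",
    "NearContourWarning",
    "WLCDomainError",
    "WLCParams",
    "angstrom",
    "contour_length",
    "wlc_energy",
    "wlc_force",
    "wlc_inverse_force",
    "wlc_stiffness",
]

#: Boltzmann constant in pN·nm per Kelvin.
BOLTZMANN_PN_NM_PER_K = 0.0138065

#: Fraction of the contour length above which results carry a warning.
NEAR_CONTOUR_FRACTION = 0.98


class WLCDomainError(ValueError):
    """Raised for extensions or parameters outside the model's domain."""


class NearContourWarning(UserWarning):
    """Extension within 2% of the contour length: force nearly diverges."""


@dataclass(frozen=True)
class WLCParams:
    """Physical constants of one entropic spring.

    Parameters
    ----------
    persistence_length : float
        Persistence length per chain unit, nm.  0.38 nm for amino acids.
    thermal_energy : float
        kBT in pN·nm.  4.114 pN·nm near room temperature.
    n_units : int
        Number of chain units (residues) in the unfolded segment.
    """

    persistence_length: float = 0.38
    thermal_energy: float = 4.114
    n_units: int = 16

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise WLCDomainError("persistence_length must be > 0")
        if self.thermal_energy <= 0:
            raise WLCDomainError("thermal_energy must be > 0")
        if self.n_units < 1:
            raise WLCDomainError("n_units must be >= 1")

    @property
    def contour_length(self) -> float:
        """Contour length L_C = n_units × persistence_length, nm."""
        return self.n_units * self.persistence_length

    @classmethod
    def from_temperature(cls, temperature_k: float, **kwargs) -> "WLCParams":
        """Build params with kBT derived from a temperature in Kelvin."""
        if temperature_k <= 0:
            raise WLCDomainError("temperature must be > 0 K")
        return cls(thermal_energy=BOLTZMANN_PN_NM_PER_K * temperature_k, **kwargs)

    def with_delta_residues(self, delta: int) -> "WLCParams":
        """Copy with the chain-unit count changed by ``delta`` residues."""
        return WLCParams(self.persistence_length, self.thermal_energy,
                         self.n_units + delta)


@dataclass(frozen=True)
class Extension:
    """End-to-end extension tagged with its unit ('nm' or 'A')."""

    value: float
    unit: str = "nm"

    def __post_init__(self) -> None:
        if self.unit not in ("nm", "A"):
            raise WLCDomainError(f"unknown length unit {self.unit!r}")

    @property
    def nm(self) -> float:
        return self.value * 0.1 if self.unit == "A" else self.value

    @property
    def angstrom(self) -> float:
        return self.value if self.unit == "A" else self.value * 10.0


def angstrom(value: float) -> Extension:
    """Shorthand for an :class:`Extension` given in Å."""
    return Extension(value, "A")


def _as_nm(x: "Extension | float") -> float:
    return x.nm if isinstance(x, Extension) else float(x)


def contour_length(n_units: int, persistence_length: float = 0.38) -> float:
    """Contour length in nm of a chain of ``n_units`` units."""
    if n_units < 1 or persistence_length <= 0:
        raise WLCDomainError("n_units >= 1 and persistence_length > 0 required")
    return n_units * persistence_length


def _check_extension(x_nm: float, params: WLCParams, *, allow_equal: bool = False) -> float:
    lc = params.contour_length
    if x_nm < 0:
        raise WLCDomainError(f"extension {x_nm} nm is negative")
    if x_nm >= lc and not (allow_equal and x_nm == lc):
        raise WLCDomainError(
            f"extension {x_nm:.4g} nm >= contour length {lc:.4g} nm: force diverges")
    if x_nm > NEAR_CONTOUR_FRACTION * lc:
        warnings.warn(
            f"extension {x_nm:.4g} nm is within 2% of the contour length "
            f"{lc:.4g} nm", NearContourWarning, stacklevel=3)
    return x_nm


def wlc_force(x: "Extension | float", params: WLCParams = WLCParams()) -> float:
    """Marko–Siggia restoring force in pN at extension ``x`` (nm or Å-tagged).

    Strictly increasing in x with F(0) = 0; diverges as x → L_C.
    """
    x_nm = _check_extension(_as_nm(x), params)
    t = x_nm / params.contour_length
    bracket = 0.25 * (1.0 - t) ** -2 + t - 0.25
    return params.thermal_energy / params.persistence_length * bracket


def _energy_primitive(t: float) -> float:
    # Antiderivative of the Marko-Siggia bracket w.r.t. t = x/L_C.
    return 0.25 / (1.0 - t) + 0.5 * t * t - 0.25 * t


def wlc_energy(x_from: "Extension | float", x_to: "Extension | float",
               params: WLCParams = WLCParams()) -> float:
    """Elastic energy, in kBT, stored stretching the chain from x_from to x_to.

    Closed-form integral of :func:`wlc_force`; positive for x_to > x_from
    (energy loaded into the spring), additive over subintervals.
    """
    a = _check_extension(_as_nm(x_from), params)
    b = _check_extension(_as_nm(x_to), params)
    if a > b:
        raise WLCDomainError(f"reversed bounds: {a} nm > {b} nm")
    ta, tb = a / params.contour_length, b / params.contour_length
    # (kBT * L_C / lp) * [g(tb) - g(ta)] in pN·nm, reported in kBT multiples:
    return params.contour_length / params.persistence_length * (
        _energy_primitive(tb) - _energy_primitive(ta))


def wlc_stiffness(x: "Extension | float", params: WLCParams = WLCParams()) -> float:
    """Local spring constant dF/dx in pN/nm at extension ``x``."""
    x_nm = _check_extension(_as_nm(x), params)
    lc = params.contour_length
    t = x_nm / lc
    return params.thermal_energy / params.persistence_length * (
        0.5 / lc * (1.0 - t) ** -3 + 1.0 / lc)


def wlc_inverse_force(target_force: float, params: WLCParams = WLCParams()) -> Extension:
    """Extension (nm) at which the chain exerts ``target_force`` pN.

    Monotonicity of the force law makes the root unique; solved by
    bracketed root finding to 1e-9 pN.
    """
    if target_force < 0:
        raise WLCDomainError("target force must be >= 0")
    if target_force == 0:
        return Extension(0.0, "nm")
    lc = params.contour_length
    hi = lc * (1.0 - 1e-9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", NearContourWarning)
        if wlc_force(hi, params) < target_force:
            raise WLCDomainError(f"force {target_force} pN unreachable below L_C")
        x = brentq(lambda v: wlc_force(v, params) - target_force, 0.0, hi,
                   xtol=1e-15, rtol=8.9e-16)
    return Extension(float(x), "nm")
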