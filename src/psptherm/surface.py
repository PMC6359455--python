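"""Acid/base decomposition of surface energy and contact-angle prediction.

The surface tension of a pure compound splits into a nonhydrogen-bonding
part gamma_VES (dispersion + refractivity + polarity; practically the
dispersive surface energy measured by alkane-probe IGC) and a
hydrogen-bonding part gamma_hb = 2*sqrt(gamma_a*gamma_b).  The acidic and
basic components are proportional to the A and B descriptors:

    gamma_a / A = gamma_b / B = gamma_VES / (3.1*Vx + E + S)

so gamma_tot = gamma_VES * (D + 2*sqrt(A*B)) / D with D = 3.1*Vx + E + S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import DISPERSION_VX_COEFF
from .descriptors import LSERDescriptors
from .exceptions import DomainError

__all__ = [
    "SurfaceComponents",
    "components_from_dispersive",
    "components_from_total",
    "contact_angle",
]


@dataclass(frozen=True)
class SurfaceComponents:
    """Surface-tension components of one compound, mJ/m^2."""

    gamma_VES: float
    gamma_a: float
    gamma_b: float

    @property
    def gamma_hb(self) -> float:
        return 2.0 * math.sqrt(self.gamma_a * self.gamma_b)

    @property
    def gamma_tot(self) -> float:
        return self.gamma_VES + self.gamma_hb


def _descriptor_denominator(lser: LSERDescriptors) -> float:
    D = DISPERSION_VX_COEFF * lser.Vx + lser.E + lser.S
    if D <= 0:
        raise DomainError(f"3.1*Vx + E + S must be positive, got {D}")
    return D


def components_from_dispersive(gamma_d: float, lser: LSERDescriptors) -> SurfaceComponents:
    """Surface components from the dispersive surface energy gamma_d (mJ/m^2).

    gamma_d is identified with the nonhydrogen-bonding component gamma_VES;
    the acid/base components follow from the proportionality to A and B.
    """
    if gamma_d < 0:
        raise DomainError(f"gamma_d must be nonnegative, got {gamma_d}")
    D = _descriptor_denominator(lser)
    k = gamma_d / D
    return SurfaceComponents(gamma_VES=gamma_d, gamma_a=k * lser.A, gamma_b=k * lser.B)


def components_from_total(gamma_tot: float, lser: LSERDescriptors) -> SurfaceComponents:
    """Surface components from a measured total surface tension (mJ/m^2).

    Inverse of :func:`components_from_dispersive`:
    gamma_VES = gamma_tot * D / (D + 2*sqrt(A*B)).
    """
    if gamma_tot < 0:
        raise DomainError(f"gamma_tot must be nonnegative, got {gamma_tot}")
    D = _descriptor_denominator(lser)
    gamma_ves = gamma_tot * D / (D + 2.0 * math.sqrt(lser.A * lser.B))
    return components_from_dispersive(gamma_ves, lser)


def contact_angle(solid: SurfaceComponents, liquid: SurfaceComponents,
                  gamma_L: float | None = None) -> float:
    """Contact angle (degrees) of a liquid on a solid from their components.

    cos(theta) = 2*(sqrt(gVES_L*gVES_S) + sqrt(ga_L*gb_S) + sqrt(ga_S*gb_L))
                 / gamma_L - 1,
    clamped to [-1, 1] (complete wetting / dewetting).

    Parameters
    ----------
    gamma_L : total surface tension of the liquid; defaults to
        ``liquid.gamma_tot``.
    """
    if gamma_L is None:
        gamma_L = liquid.gamma_tot
    if not gamma_L > 0:
        raise DomainError(f"liquid surface tension must be positive, got {gamma_L}")
    work = (math.sqrt(liquid.gamma_VES * solid.gamma_VES)
            + math.sqrt(liquid.gamma_a * solid.gamma_b)
            + math.sqrt(solid.gamma_a * liquid.gamma_b))
    cos_theta = min(1.0, max(-1.0, 2.0 * work / gamma_L - 1.0))
    return math.degrees(math.acos(cos_theta))
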