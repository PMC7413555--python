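"""Axisymmetric rigid probe geometries for Hertzian-type contact.

The elastic force-indentation law is ``F = C_geom * E * delta^n`` with

=========  ===  =======================
shape       n   C_geom
=========  ===  =======================
cylinder    1   2 R_cyl
sphere     1.5  (4/3) sqrt(R)
cone        2   (2/pi) tan(alpha_cone)
=========  ===  =======================

Two Poisson-ratio conventions are in circulation: the constants above
("results" mode, the default, so that fitted moduli reproduce quoted
figure values directly) and the same constants divided by
``1 - nu^2`` ("methods" mode, the convention used when comparing with
experiments on nearly incompressible samples).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = ["ProbeGeometry", "make_probe"]

_SHAPES = ("cylinder", "sphere", "cone")


@dataclass(frozen=True)
class ProbeGeometry:
    shape: str
    dimension: float  # R_cyl [m] | R [m] | alpha_cone [rad]
    n: float  # Hertzian exponent
    C_geom: float  # F = C_geom * E * delta^n
    nu: float = 0.0
    nu_divisor_applied: bool = False

    def check_depth(self, delta_max: float) -> None:
        """Warn when a spherical contact leaves the parabolic regime."""
        if self.shape == "sphere" and delta_max > 0.1 * self.dimension:
            warnings.warn(
                f"delta_max = {delta_max:g} m exceeds 10% of the sphere radius "
                f"{self.dimension:g} m; the parabolic contact approximation degrades",
                stacklevel=2,
            )


def make_probe(shape: str, dimension: float, nu: float = 0.0, nu_mode: str = "results") -> ProbeGeometry:
    """Construct a probe from its shape and dimension.

    Parameters
    ----------
    shape : {'cylinder', 'sphere', 'cone'}
    dimension : float
        Cylinder radius [m], sphere radius [m], or cone half-angle [rad].
    nu : float
        Sample Poisson's ratio; only used when ``nu_mode='methods'``.
    nu_mode : {'results', 'methods'}
        'results' leaves ``C_geom`` bare; 'methods' divides by
        ``1 - nu^2``.
    """
    if shape not in _SHAPES:
        raise ValueError(f"unknown probe shape {shape!r}; choose from {_SHAPES}")
    if not (dimension > 0):
        raise ValueError("probe dimension must be positive")
    if shape == "cone" and not dimension < math.pi / 2:
        raise ValueError("cone half-angle must be below pi/2 rad")
    if nu_mode not in ("results", "methods"):
        raise ValueError("nu_mode must be 'results' or 'methods'")
    if shape == "cylinder":
        n, C = 1.0, 2.0 * dimension
    elif shape == "sphere":
        n, C = 1.5, 4.0 * math.sqrt(dimension) / 3.0
    else:
        n, C = 2.0, 2.0 * math.tan(dimension) / math.pi
    applied = nu_mode == "methods"
    if applied:
        if not -1.0 < nu <= 0.5:
            raise ValueError("Poisson's ratio must lie in (-1, 0.5]")
        C /= 1.0 - nu * nu
    return ProbeGeometry(shape, float(dimension), n, C, float(nu), applied)
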