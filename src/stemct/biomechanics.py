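"""Euler-Bernoulli beam properties of stem internodes.

An internode is treated as a slender beam with a solid circular
cross-section.  From its geometry and a three-point bending test (specimen
supported at two points a span L_in apart, loaded centrally) the module
computes:

* slenderness ratio          lambda = L / D                (dimensionless)
* second moment of area      I = pi D^4 / 64               (mm^4)
* section modulus            Z = I / r                     (mm^3)
* Young's (elastic) modulus  E = F_i L_in^3 / (48 B_i I)   (MPa)
* maximum bending stress     sigma_max = F_u L_in r / (4 I) (MPa)
* flexural rigidity          EI = E * I                    (N mm^2)

Units are mm for lengths, N for forces, MPa (= N/mm^2) for stresses.  Plant
stems are composite materials, so E and EI are spatially averaged
("effective") properties of the whole heterogeneous section; results carry
that label in their metadata.  Euler-Bernoulli theory assumes a slender
beam: specimens with lambda <= 10 are flagged rather than rejected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "BendingTest",
    "MechanicalProperties",
    "SlendernessWarning",
    "slenderness",
    "second_moment",
    "section_modulus",
    "youngs_modulus",
    "max_stress",
    "rigidity",
    "compute_properties",
]


class SlendernessWarning(UserWarning):
    """Specimen too stocky for the slender-beam assumption (lambda <= 10)."""


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be strictly positive, got {value}")


@dataclass
class BendingTest:
    """One three-point bending measurement of an internode.

    ``force_n`` is the force F_i needed to reach the lateral displacement
    ``displacement_mm`` (B_i) within the elastic range; ``failure_force_n``
    (F_u) is the force at which structural integrity is lost.
    """

    internode_key: str
    span_length_mm: float
    force_n: float
    displacement_mm: float
    failure_force_n: float

    def __post_init__(self) -> None:
        _require_positive(
            span_length_mm=self.span_length_mm,
            force_n=self.force_n,
            displacement_mm=self.displacement_mm,
            failure_force_n=self.failure_force_n,
        )


@dataclass
class MechanicalProperties:
    internode_key: str
    slenderness: float
    second_moment_mm4: float
    section_modulus_mm3: float
    youngs_modulus_mpa: float
    max_stress_mpa: float
    rigidity_n_mm2: float
    slenderness_ok: bool
    notes: list[str] = field(
        default_factory=lambda: ["spatially averaged / effective properties"]
    )


def slenderness(length_mm: float, diameter_mm: float) -> float:
    """Slenderness ratio lambda = L / D; warns when lambda <= 10."""
    _require_positive(length_mm=length_mm, diameter_mm=diameter_mm)
    lam = length_mm / diameter_mm
    if lam <= 10:
        warnings.warn(
            f"slenderness ratio {lam:.3g} <= 10; Euler-Bernoulli assumptions weak",
            SlendernessWarning,
            stacklevel=2,
        )
    return lam


def second_moment(diameter_mm: float) -> float:
    """Second moment of area of a solid circular section, I = pi D^4 / 64."""
    _require_positive(diameter_mm=diameter_mm)
    return math.pi * diameter_mm**4 / 64.0


def section_modulus(second_moment_mm4: float, radius_mm: float) -> float:
    """Section modulus Z = I / r."""
    _require_positive(second_moment_mm4=second_moment_mm4, radius_mm=radius_mm)
    return second_moment_mm4 / radius_mm


def youngs_modulus(
    force_n: float,
    span_length_mm: float,
    displacement_mm: float,
    second_moment_mm4: float,
) -> float:
    """Effective Young's modulus from a three-point bending test,
    E = F L^3 / (48 B I), in MPa."""
    _require_positive(
        force_n=force_n,
        span_length_mm=span_length_mm,
        displacement_mm=displacement_mm,
        second_moment_mm4=second_moment_mm4,
    )
    return force_n * span_length_mm**3 / (48.0 * displacement_mm * second_moment_mm4)


def max_stress(
    failure_force_n: float,
    span_length_mm: float,
    radius_mm: float,
    second_moment_mm4: float,
) -> float:
    """Maximum bending stress at failure, sigma_max = F_u L r / (4 I), MPa.

    Equivalent to M / Z with the central bending moment M = F_u L / 4.
    """
    _require_positive(
        failure_force_n=failure_force_n,
        span_length_mm=span_length_mm,
        radius_mm=radius_mm,
        second_moment_mm4=second_moment_mm4,
    )
    return failure_force_n * span_length_mm * radius_mm / (4.0 * second_moment_mm4)


def rigidity(youngs_modulus_mpa: float, second_moment_mm4: float) -> float:
    """Flexural rigidity EI in N mm^2."""
    _require_positive(
        youngs_modulus_mpa=youngs_modulus_mpa, second_moment_mm4=second_moment_mm4
    )
    return youngs_modulus_mpa * second_moment_mm4


def compute_properties(test: BendingTest, diameter_mm: float) -> MechanicalProperties:
    """All beam properties for one internode from its bending test and
    diameter."""
    _require_positive(diameter_mm=diameter_mm)
    r = diameter_mm / 2.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SlendernessWarning)
        lam = slenderness(test.span_length_mm, diameter_mm)
    i_mm4 = second_moment(diameter_mm)
    e_mpa = youngs_modulus(
        test.force_n, test.span_length_mm, test.displacement_mm, i_mm4
    )
    return MechanicalProperties(
        internode_key=test.internode_key,
        slenderness=lam,
        second_moment_mm4=i_mm4,
        section_modulus_mm3=section_modulus(i_mm4, r),
        youngs_modulus_mpa=e_mpa,
        max_stress_mpa=max_stress(
            test.failure_force_n, test.span_length_mm, r, i_mm4
        ),
        rigidity_n_mm2=rigidity(e_mpa, i_mm4),
        slenderness_ok=lam > 10,
    )
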