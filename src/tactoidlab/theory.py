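"""Hard-rod tactoid free-energy model.

A tactoid is a spindle-shaped nematic droplet of aligned rod-like particles
(here filamentous phages held together by depletion attraction).  Its shape
is set by a competition between the interfacial free energy, which favours
compact droplets, and the Frank elastic energy of the curved director field,
which favours elongation.  In the one-constant approximation, and with the
droplet area and volume approximated as ``A ~ R*r`` and ``V ~ R*r**2``
(major axis R, minor axis r), the free energy reads

    F = gamma * A + K * V / R**2

Minimising F over (r, R) at fixed volume gives the equilibrium shape

    R = (4 K / gamma)**(2/5) * V**(1/5)
    R/r = (4 K / gamma)**(3/5) * V**(-1/5)

so the aspect ratio falls off as the -1/5 power of droplet volume.  The
material constants are in turn approximated from the rod geometry (length
``b``, width ``a``, in-droplet packing fraction ``rho``) by their values at
the homogeneous-bipolar transition, K ~ rho*b/a**2 and gamma ~ 1/(a*b).
Only ratios and exponents are meaningful: all hidden proportionality
prefactors are fixed to 1, and predictions are made as ratios between two
rod species so that unknown common factors (including the rod width, equal
for the two phages considered) cancel.

All quantities are in consistent user-supplied units; no unit conversion is
performed internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "TactoidShape",
    "MaterialProps",
    "PhageGeometry",
    "WettingParams",
    "NoWettingSolutionError",
    "ConvergenceError",
    "free_energy",
    "equilibrium_shape_closed_form",
    "minimize_shape",
    "material_props_from_phage",
    "predict_prefactor_ratio",
    "contact_angle",
]


class NoWettingSolutionError(ValueError):
    """Raised when the Young-Laplace balance has no contact-angle solution.

    Carries ``side``: ``"complete wetting"`` when cos(theta) > 1 (the droplet
    spreads fully over the cell) or ``"complete dewetting"`` when
    cos(theta) < -1.
    """

    def __init__(self, cos_theta: float):
        self.cos_theta = cos_theta
        self.side = "complete wetting" if cos_theta > 1 else "complete dewetting"
        super().__init__(
            f"cos(theta) = {cos_theta:.6g} outside [-1, 1]: {self.side}"
        )


class ConvergenceError(RuntimeError):
    """Numeric minimisation failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate: "TactoidShape | None" = None):
        super().__init__(message)
        self.last_iterate = last_iterate


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0):
            raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class TactoidShape:
    """Geometry of one tactoid: major axis R, minor axis r (same length unit).

    ``volume`` is optional; when omitted it is derivable from the model's
    V ~ R*r**2 proxy (:meth:`model_volume`) or, for measured objects, from
    the prolate-spheroid rule in the morphometry module.  ``outside_validity``
    flags shapes where the scaling solution gave R < r, i.e. parameters
    outside the elongated regime the relation is valid in.
    """

    major_axis: float
    minor_axis: float
    volume: float | None = None
    outside_validity: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        _require_positive(major_axis=self.major_axis, minor_axis=self.minor_axis)
        if not self.outside_validity and self.major_axis < self.minor_axis:
            raise ValueError(
                f"major_axis ({self.major_axis}) < minor_axis ({self.minor_axis}); "
                "tactoids are elongated along the director"
            )
        if self.volume is not None:
            _require_positive(volume=self.volume)

    @property
    def aspect_ratio(self) -> float:
        return self.major_axis / self.minor_axis

    def model_volume(self) -> float:
        """Volume under the scaling model's proxy V = R*r**2."""
        return self.major_axis * self.minor_axis**2


@dataclass(frozen=True)
class MaterialProps:
    """Tactoid material constants: Frank constant K and surface tension gamma."""

    frank_constant: float
    surface_tension: float

    def __post_init__(self) -> None:
        _require_positive(
            frank_constant=self.frank_constant,
            surface_tension=self.surface_tension,
        )


@dataclass(frozen=True)
class PhageGeometry:
    """One phage species: length b, width a, in-tactoid packing fraction rho.

    Packing fractions above 1 are rejected here; naive cylinder occupancies
    exceeding 1 are the packing module's business and are reported there with
    an overlap flag.
    """

    length: float
    width: float
    packing_fraction: float

    def __post_init__(self) -> None:
        _require_positive(length=self.length, width=self.width)
        if not (self.length > self.width):
            raise ValueError(
                f"length ({self.length}) must exceed width ({self.width})"
            )
        if not (0 < self.packing_fraction <= 1):
            raise ValueError(
                f"packing_fraction must be in (0, 1], got {self.packing_fraction}"
            )


@dataclass(frozen=True)
class WettingParams:
    """Pairwise surface tensions at a bacterium-tactoid-medium contact line.

    ``gamma_bacteria_tactoid`` and ``gamma_bacteria_medium`` are the tensions
    of the cell against the droplet and against the crowding-polymer medium;
    ``gamma_medium_tactoid`` is the droplet-medium tension (the gamma of the
    free-energy model).
    """

    gamma_bacteria_tactoid: float
    gamma_bacteria_medium: float
    gamma_medium_tactoid: float

    def __post_init__(self) -> None:
        _require_positive(gamma_medium_tactoid=self.gamma_medium_tactoid)


def free_energy(shape: TactoidShape, props: MaterialProps) -> float:
    """Free energy F = gamma*(R*r) + K*(R*r**2)/R**2 of a tactoid.

    Area and volume are taken from the axes via the model proxies A = R*r and
    V = R*r**2; a ``volume`` stored on the shape is ignored so that the
    energy, the closed form and the numeric minimiser are mutually consistent.
    """
    R, r = shape.major_axis, shape.minor_axis
    K, gamma = props.frank_constant, props.surface_tension
    return gamma * R * r + K * (R * r**2) / R**2


def equilibrium_shape_closed_form(props: MaterialProps, volume: float) -> TactoidShape:
    """Analytic minimiser of :func:`free_energy` at fixed volume V = R*r**2.

    Returns the shape with R = (4K/gamma)**(2/5) * V**(1/5) and
    r = sqrt(V/R).  When the parameters put the solution outside the
    elongated regime (R < r), the shape is returned flagged
    ``outside_validity`` rather than raising: the scaling relation is only
    valid for r << R, and callers may want to see where it breaks.
    """
    _require_positive(volume=volume)
    k_over_g = props.frank_constant / props.surface_tension
    R = (4.0 * k_over_g) ** 0.4 * volume**0.2
    r = math.sqrt(volume / R)
    return TactoidShape(R, r, volume=volume, outside_validity=R < r)


def minimize_shape(
    props: MaterialProps, volume: float, tolerance: float = 1e-10
) -> TactoidShape:
    """Numeric constrained minimisation of the tactoid free energy.

    The volume constraint is eliminated by substituting r = sqrt(V/R), which
    reduces the Lagrange-multiplier system to a 1-D minimisation of
    F(R) = gamma*sqrt(V*R) + K*V/R**2 over R, solved by bounded scalar
    minimisation in log R.  Agrees with
    :func:`equilibrium_shape_closed_form` to within ``tolerance`` (relative).
    """
    from scipy.optimize import minimize_scalar

    _require_positive(volume=volume, tolerance=tolerance)
    K, gamma = props.frank_constant, props.surface_tension

    def objective(logR: float) -> float:
        R = math.exp(logR)
        return gamma * math.sqrt(volume * R) + K * volume / R**2

    # The analytic optimum sits at log R = 0.4*log(4K/g) + 0.2*log V; bracket
    # it generously so the bound never binds for sane parameters.
    center = 0.4 * math.log(4.0 * K / gamma) + 0.2 * math.log(volume)
    res = minimize_scalar(
        objective,
        bounds=(center - 20.0, center + 20.0),
        method="bounded",
        options={"xatol": tolerance / 10.0},
    )
    R = math.exp(res.x)
    r = math.sqrt(volume / R)
    shape = TactoidShape(R, r, volume=volume, outside_validity=R < r)
    if not res.success:
        raise ConvergenceError(
            f"shape minimisation did not converge: {res.message}", last_iterate=shape
        )
    return shape


def material_props_from_phage(geom: PhageGeometry) -> MaterialProps:
    """Material constants from rod geometry: K = rho*b/a**2, gamma = 1/(a*b).

    These are the homogeneous-bipolar-transition approximations with the
    hidden proportionality constants set to 1, so absolute values carry no
    meaning — only ratios between species do.
    """
    a, b, rho = geom.width, geom.length, geom.packing_fraction
    return MaterialProps(frank_constant=rho * b / a**2, surface_tension=1.0 / (a * b))


def predict_prefactor_ratio(geom_a: PhageGeometry, geom_b: PhageGeometry) -> float:
    """Predicted ratio of aspect-ratio prefactors C_A/C_B of two rod species.

    From R/r ~ (rho * b**2 / a)**(3/5) * V**(-1/5), the prefactor ratio is
    (rho_A b_A**2 / a_A)**(3/5) / (rho_B b_B**2 / a_B)**(3/5).  Invariant
    under a common rescaling of the rod widths.
    """
    def c53(g: PhageGeometry) -> float:
        return g.packing_fraction * g.length**2 / g.width

    return (c53(geom_a) / c53(geom_b)) ** 0.6


def contact_angle(w: WettingParams) -> float:
    """Interior Young-Laplace contact angle (degrees) of a tactoid on a cell.

    cos(theta) = (gamma_bacteria_tactoid - gamma_bacteria_medium) / gamma.
    A higher droplet-medium tension gamma pushes theta toward 90 degrees,
    i.e. reduced wetting.  Raises :class:`NoWettingSolutionError` when the
    balance has no solution (complete wetting or dewetting).
    """
    cos_theta = (
        w.gamma_bacteria_tactoid - w.gamma_bacteria_medium
    ) / w.gamma_medium_tactoid
    if abs(cos_theta) > 1:
        raise NoWettingSolutionError(cos_theta)
    return math.degrees(math.acos(cos_theta))
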