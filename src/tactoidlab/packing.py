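"""Filament packing fractions in cubic tomogram sub-boxes.

The in-tactoid packing fraction rho of a phage species is estimated from a
cubic box cropped out of a tomogram, either by a manual filament count
(weakly ordered species) or from the lattice spacing read off a Fourier
transform (regularly packed species).  Filaments are modelled as parallel
cylinders of radius ``r_f`` spanning the box edge ``E``, so the occupancy is
the naive ``n * pi * r_f**2 / E**2`` with no overlap correction — exactly
the worked-example arithmetic, which for tightly packed lattices can exceed
what hard cylinders could actually achieve.  A separate flag reports when
the configuration is geometrically impossible (cylinder diameter larger
than the lattice spacing, or occupancy beyond 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "FilamentBoxModel",
    "OverlapWarning",
    "cylinder_packing_fraction",
    "lattice_filament_count",
    "box_volume",
]


class OverlapWarning(UserWarning):
    """The reported occupancy assumes overlapping cylinders."""


@dataclass(frozen=True)
class FilamentBoxModel:
    """A cubic tomogram sub-box with cylindrical filaments spanning it.

    Exactly one of ``filament_count`` (manual count) or ``lattice_spacing``
    (Fourier-transform spacing, square lattice assumed) drives the occupancy.
    All lengths in nm.
    """

    edge: float
    filament_radius: float
    filament_count: int | None = None
    lattice_spacing: float | None = None

    def __post_init__(self) -> None:
        if not (self.edge > 0):
            raise ValueError(f"edge must be > 0, got {self.edge}")
        if not (self.filament_radius > 0):
            raise ValueError(f"filament_radius must be > 0, got {self.filament_radius}")
        if (self.filament_count is None) == (self.lattice_spacing is None):
            raise ValueError(
                "exactly one of filament_count or lattice_spacing must be given"
            )
        if self.filament_count is not None and self.filament_count < 0:
            raise ValueError(f"filament_count must be >= 0, got {self.filament_count}")
        if self.lattice_spacing is not None and not (self.lattice_spacing > 0):
            raise ValueError(
                f"lattice_spacing must be > 0, got {self.lattice_spacing}"
            )

    @property
    def overlapping(self) -> bool:
        """True when the stated geometry forces cylinders to overlap."""
        if self.lattice_spacing is not None:
            return 2 * self.filament_radius > self.lattice_spacing
        frac = (
            self.filament_count * math.pi * self.filament_radius**2 / self.edge**2
        )
        return frac > 1


def box_volume(box: FilamentBoxModel) -> float:
    """Volume E**3 of the cubic box (nm**3); 89.72**3 = 722217.15."""
    return box.edge**3


def lattice_filament_count(box: FilamentBoxModel) -> int:
    """Filament count for a square lattice at the stated spacing.

    The per-edge count is the nearest integer to E/s (89.72/6 -> 15) and the
    box count is its square (15**2 = 225).  Requires s < E.
    """
    s = box.lattice_spacing
    if s is None:
        raise ValueError("lattice_filament_count needs lattice_spacing")
    if s >= box.edge:
        raise ValueError(
            f"lattice_spacing ({s}) >= edge ({box.edge}): fewer than one filament per edge"
        )
    per_edge = round(box.edge / s)
    return per_edge**2


def cylinder_packing_fraction(box: FilamentBoxModel) -> float:
    """Naive volume fraction occupied by n box-spanning cylinders.

    n * pi * r_f**2 * E / E**3 = n * pi * r_f**2 / E**2.  In lattice mode
    n is derived via :func:`lattice_filament_count`.  No overlap correction
    is applied; an :class:`OverlapWarning` is emitted when the configuration
    is geometrically impossible, so that naive occupancies near or above
    close packing are not mistaken for true volume fractions.
    """
    if box.filament_count is not None:
        n = box.filament_count
    else:
        n = lattice_filament_count(box)
    frac = n * math.pi * box.filament_radius**2 / box.edge**2
    if box.overlapping:
        warnings.warn(
            f"occupancy {frac:.4f} assumes overlapping cylinders "
            f"(radius {box.filament_radius} nm)",
            OverlapWarning,
            stacklevel=2,
        )
    return frac
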