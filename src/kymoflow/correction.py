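"""Closed-form corrections for scanner-motion bias in line-scan velocimetry.

A laser line-scan acquires pixels sequentially at the focal-spot speed
``v_scan``, so the dark shadow an unlabeled red blood cell (RBC) leaves on a
space-time image is stretched or compressed depending on whether the scanner
moves with the flow (anterograde) or against it (retrograde).  The functions
here map between the *real* RBC size/velocity and the *apparent* quantities
read off the image, and provide the consistency identity that couples the
anterograde and retrograde apparent speeds of the same cell.

Units are fixed project-wide: lengths in micrometres, speeds in mm/s and
times in milliseconds.  Since 1 mm/s = 1 um/ms, no conversion constants
appear in the formulas.  All speeds are stored as magnitudes; the scan
direction is an explicit enum, with the flow direction defining the positive
vessel axis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "Direction",
    "ScanParameters",
    "RBCState",
    "ApparentObservation",
    "BidirectionalPair",
    "SingularityError",
    "InconsistentObservationError",
    "time_to_scan_rbc",
    "apparent_size",
    "real_size",
    "apparent_velocity",
    "apparent_velocity_from_geometry",
    "apparent_velocity_from_angle",
    "real_velocity",
    "bidirectional_residual",
    "vaa_from_var",
    "relative_error",
]

#: Inputs within this relative distance of a pole are treated as at the pole.
POLE_RTOL = 1e-6


class Direction(str, enum.Enum):
    """Scan direction relative to blood flow."""

    ANTEROGRADE = "anterograde"  # focal spot moves with the flow
    RETROGRADE = "retrograde"  # focal spot moves against the flow

    @classmethod
    def coerce(cls, value: "Direction | str") -> "Direction":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"direction must be 'anterograde' or 'retrograde', got {value!r}"
            ) from None


class SingularityError(ValueError):
    """Anterograde scanning cannot overtake an RBC at or above scan speed."""


class InconsistentObservationError(ValueError):
    """The observation cannot arise from any real velocity under the model."""


@dataclass(frozen=True)
class ScanParameters:
    """Acquisition geometry and timing of a line-scan.

    Parameters
    ----------
    v_scan : float
        Focal-spot speed magnitude along the vessel axis, mm/s.
    direction : Direction or str
        Sweep direction relative to blood flow.
    t_line : float
        Full line repetition period in ms, including fly-back and any dead
        time outside the analysed segment.
    x_pixel : float
        Spatial pixel size along the scan axis, um.
    n_pixels : int
        Number of pixels per sweep of the analysed segment.
    """

    v_scan: float
    direction: Direction
    t_line: float
    x_pixel: float
    n_pixels: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", Direction.coerce(self.direction))
        if not self.v_scan > 0:
            raise ValueError(f"v_scan must be > 0, got {self.v_scan}")
        if not self.x_pixel > 0:
            raise ValueError(f"x_pixel must be > 0, got {self.x_pixel}")
        if int(self.n_pixels) != self.n_pixels or self.n_pixels < 2:
            raise ValueError(f"n_pixels must be an integer >= 2, got {self.n_pixels}")
        if not self.t_line > 0:
            raise ValueError(f"t_line must be > 0, got {self.t_line}")
        # the sweep itself cannot take longer than the full line period
        if self.t_line < self.n_pixels * self.t_pixel * (1 - 1e-9):
            raise ValueError(
                f"t_line={self.t_line} ms is shorter than the sweep time "
                f"{self.n_pixels * self.t_pixel} ms (n_pixels * x_pixel / v_scan)"
            )

    @property
    def t_pixel(self) -> float:
        """Dwell step between successive pixels, ms (= x_pixel / v_scan)."""
        return self.x_pixel / self.v_scan

    @property
    def sweep_time(self) -> float:
        """Time to sweep the analysed segment once, ms."""
        return self.n_pixels * self.t_pixel

    @property
    def segment_length(self) -> float:
        """Length of the analysed segment, um."""
        return self.n_pixels * self.x_pixel

    def with_direction(self, direction: "Direction | str") -> "ScanParameters":
        return ScanParameters(
            self.v_scan, Direction.coerce(direction), self.t_line, self.x_pixel, self.n_pixels
        )


@dataclass(frozen=True)
class RBCState:
    """Ground-truth RBC extent and speed along the vessel axis.

    ``v_real`` is a magnitude; the flow direction defines the positive axis
    and the scan direction is carried by :class:`ScanParameters`.
    """

    d_real: float  # um
    v_real: float = 0.0  # mm/s

    def __post_init__(self) -> None:
        if self.d_real < 0:
            raise ValueError(f"d_real must be >= 0, got {self.d_real}")
        if self.v_real < 0:
            raise ValueError(f"v_real must be >= 0, got {self.v_real}")


@dataclass(frozen=True)
class ApparentObservation:
    """Measured shadow properties on a space-time image."""

    d_app: float | None = None  # um
    v_app: float | None = None  # mm/s
    alpha: float | None = None  # stripe angle vs horizontal, rad, in (0, pi/2)
    dx_mov: float | None = None  # per-line apparent displacement, um
    t_rbc: float | None = None  # scanner transit time over one RBC, ms

    def __post_init__(self) -> None:
        if self.d_app is not None and self.d_app < 0:
            raise ValueError("d_app must be >= 0")
        if self.v_app is not None and self.v_app < 0:
            raise ValueError("v_app must be >= 0")
        if self.alpha is not None and not (0 < self.alpha < math.pi / 2):
            raise ValueError("alpha must lie in (0, pi/2)")


@dataclass(frozen=True)
class BidirectionalPair:
    """Matched anterograde/retrograde apparent speeds at a common scan speed."""

    v_aa: float  # anterograde apparent speed, mm/s
    v_ar: float  # retrograde apparent speed, mm/s
    v_scan: float  # mm/s

    def __post_init__(self) -> None:
        if self.v_aa < 0 or self.v_ar < 0:
            raise ValueError("apparent speeds must be >= 0")
        if not self.v_scan > 0:
            raise ValueError("v_scan must be > 0")


def _check_anterograde_pole(v_real: float, v_scan: float) -> None:
    if v_real >= v_scan * (1 - POLE_RTOL):
        raise SingularityError(
            f"anterograde scanning at v_scan={v_scan} mm/s cannot overtake an "
            f"RBC moving at v_real={v_real} mm/s; the apparent size/velocity "
            "diverge at v_real = v_scan (scan retrograde instead)"
        )


def time_to_scan_rbc(rbc: RBCState, scan: ScanParameters) -> float:
    """Time for the focal spot to traverse one RBC, ms.

    The transit time is the real extent divided by the scanner-RBC closing
    speed: ``d_real / (v_scan - v_real)`` anterograde (same direction, so the
    scanner must overtake), ``d_real / (v_scan + v_real)`` retrograde.
    """
    if scan.direction is Direction.ANTEROGRADE:
        _check_anterograde_pole(rbc.v_real, scan.v_scan)
        return rbc.d_real / (scan.v_scan - rbc.v_real)
    return rbc.d_real / (scan.v_scan + rbc.v_real)


def apparent_size(rbc: RBCState, scan: ScanParameters) -> float:
    """Apparent shadow extent on the image, um.

    The shadow is written at scan speed for the duration of the transit, so
    ``d_app = v_scan * t_rbc``: stretched anterograde, compressed retrograde,
    equal to ``d_real`` only for a stationary cell.
    """
    return scan.v_scan * time_to_scan_rbc(rbc, scan)


def real_size(d_app: float, v_real: float, scan: ScanParameters) -> float:
    """Invert the apparent-size model given the (corrected) real velocity."""
    if d_app < 0:
        raise ValueError(f"d_app must be >= 0, got {d_app}")
    if scan.direction is Direction.ANTEROGRADE:
        _check_anterograde_pole(v_real, scan.v_scan)
        return d_app * (scan.v_scan - v_real) / scan.v_scan
    return d_app * (scan.v_scan + v_real) / scan.v_scan


def apparent_velocity_from_geometry(dx_mov: float, scan: ScanParameters) -> float:
    """Camera-model apparent speed: per-line displacement over line period."""
    if dx_mov < 0:
        raise ValueError(f"dx_mov must be >= 0, got {dx_mov}")
    return dx_mov / scan.t_line


def apparent_velocity_from_angle(alpha: float, scan: ScanParameters) -> float:
    """Apparent speed from the stripe angle ``alpha`` vs the horizontal.

    ``v_app = (x_pixel / t_line) / tan(alpha)`` once the image axes are
    scaled to grid units (one column = ``x_pixel`` um, one row = ``t_line``
    ms); with unit axis scaling this is the classical ``1/tan(alpha)``.
    """
    if not 0 < alpha < math.pi / 2:
        raise ValueError(f"alpha must lie in (0, pi/2), got {alpha}")
    return (scan.x_pixel / scan.t_line) / math.tan(alpha)


def apparent_velocity(v_real: float, scan: ScanParameters) -> float:
    """Forward bias model: apparent speed magnitude for a given real speed.

    Anterograde: ``v_scan * v_real / (v_scan - v_real)`` (overestimate,
    diverging at the pole ``v_real = v_scan``); retrograde:
    ``v_scan * v_real / (v_scan + v_real)`` (underestimate, bounded by
    ``v_scan``).
    """
    if v_real < 0:
        raise ValueError(f"v_real must be >= 0, got {v_real}")
    if scan.direction is Direction.ANTEROGRADE:
        _check_anterograde_pole(v_real, scan.v_scan)
        return scan.v_scan * v_real / (scan.v_scan - v_real)
    return scan.v_scan * v_real / (scan.v_scan + v_real)


def real_velocity(v_app: float, scan: ScanParameters) -> float:
    """Correct an apparent speed for scanner motion.

    Inverse of :func:`apparent_velocity`: ``v_scan*v_app/(v_scan + v_app)``
    anterograde, ``v_scan*v_app/(v_scan - v_app)`` retrograde.  A retrograde
    apparent speed can never reach ``v_scan`` under the model, so such an
    observation is rejected as inconsistent.
    """
    if v_app < 0:
        raise ValueError(f"v_app must be >= 0, got {v_app}")
    if scan.direction is Direction.ANTEROGRADE:
        return scan.v_scan * v_app / (scan.v_scan + v_app)
    if v_app >= scan.v_scan * (1 - POLE_RTOL):
        raise InconsistentObservationError(
            f"retrograde apparent speed {v_app} mm/s >= v_scan={scan.v_scan} "
            "mm/s cannot arise from any real velocity"
        )
    return scan.v_scan * v_app / (scan.v_scan - v_app)


def bidirectional_residual(pair: BidirectionalPair) -> float:
    """Consistency residual ``1/v_ar - 1/v_aa - 2/v_scan`` (s/mm; == ms/um).

    Zero (to tolerance) exactly when the two apparent speeds are explained by
    a single underlying real velocity at the stated scan speed.
    """
    if pair.v_ar <= 0 or pair.v_aa <= 0:
        raise ValueError("v_aa and v_ar must be > 0 to form the residual")
    return 1.0 / pair.v_ar - 1.0 / pair.v_aa - 2.0 / pair.v_scan


def vaa_from_var(v_ar: float, v_scan: float) -> float:
    """Predicted anterograde apparent speed from the retrograde one.

    ``v_aa = v_scan * v_ar / (v_scan - 2 v_ar)`` — the single-parameter model
    used to recover ``v_scan`` from paired bidirectional measurements.  The
    pole at ``v_ar = v_scan/2`` corresponds to ``v_real = v_scan``.
    """
    if v_ar < 0:
        raise ValueError(f"v_ar must be >= 0, got {v_ar}")
    if not v_scan > 0:
        raise ValueError(f"v_scan must be > 0, got {v_scan}")
    if v_ar >= 0.5 * v_scan * (1 - POLE_RTOL):
        raise SingularityError(
            f"v_ar={v_ar} mm/s is at or beyond the pole v_scan/2="
            f"{0.5 * v_scan} mm/s (implies v_real >= v_scan)"
        )
    return v_scan * v_ar / (v_scan - 2.0 * v_ar)


def relative_error(v_real: float, scan: ScanParameters) -> float:
    """Relative error of reporting the apparent instead of the real speed.

    ``(v_real - v_app) / v_real``: negative anterograde (overestimate),
    positive retrograde (underestimate), and vanishing when
    ``v_real << v_scan``.
    """
    if not v_real > 0:
        raise ValueError(f"v_real must be > 0, got {v_real}")
    return (v_real - apparent_velocity(v_real, scan)) / v_real
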