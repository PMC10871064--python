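"""Tracking-beam sequence construction and interleaved pulse timing.

Four tracking families are supported:

* ``pw`` -- a single 0-degree plane-wave transmit per frame;
* ``pwc`` -- coherent plane-wave compounding over n steered transmits
  (3-degree spacing, symmetric about 0);
* ``rxpar`` -- one focused transmit per frame (Tx F/2.6 ... F/5) with all
  lines of the group beamformed in parallel on receive;
* ``txrxpar`` -- two focused transmits per frame, offset laterally by
  +/- 0.2 mm about the line-group center, beamformed independently and
  combined laterally.

Each 500-us pulse interval interleaves a 70-us FUS excitation burst, an idle
gap for the FUS interference to decay (90 us, shortened to 40 us when five
compounding angles must fit), and the pulse-echo tracking events, yielding a
2-kHz tracking frame rate.  Reconstruction covers a 3.2 mm (axial) x 1.2 mm
(lateral) patch around the focus, with lines at half-wavelength pitch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SPEED_OF_SOUND
from .mechanics import AMEnvelope, FOCUS_DEPTH_MM

__all__ = [
    "PATCH_AXIAL_MM",
    "PATCH_LATERAL_MM",
    "LINE_PITCH_MM",
    "N_LINES",
    "TXRX_OFFSET_MM",
    "PWC_ANGLE_STEP_DEG",
    "TransmitSpec",
    "TrackingSequence",
    "PulseTimeline",
    "RasterGrid",
    "make_transmits",
    "build_timeline",
    "min_tx_fnumber",
    "raster_grid",
]

#: Reconstructed patch around the focus (axial x lateral), mm.
PATCH_AXIAL_MM = 3.2
PATCH_LATERAL_MM = 1.2
#: Beamformed line pitch: half a wavelength at the 7.8-MHz imaging frequency.
LINE_PITCH_MM = SPEED_OF_SOUND / 7.8 / 2
#: Lines per group: 13 lines at lambda/2 pitch tile the 1.2-mm group span.
N_LINES = 13
#: Lateral offset of each Tx-Rx parallel transmit about the group center (mm).
TXRX_OFFSET_MM = 0.2
#: Angle difference between consecutive compounding plane waves (degrees).
PWC_ANGLE_STEP_DEG = 3.0
#: Default full aperture / focus of the imaging array (mm).
_FULL_APERTURE_MM = 11.81

#: End of the recorded channel-data window (mm); sets the per-event
#: round-trip time used by the timing validator.
ACQUISITION_DEPTH_MM = 55.0

#: Round-trip tracking pulse length (us): 2 cycles at 7.8 MHz.
_PULSE_LEN_US = 2 / 7.8


@dataclass(frozen=True)
class TransmitSpec:
    """One tracking transmit: a steered plane wave or a focused beam."""

    mode: str  # "plane" | "focused"
    steer_angle: float = 0.0  # degrees (plane waves)
    focus_depth: float = FOCUS_DEPTH_MM  # mm (focused)
    tx_fnumber: float | None = None  # focused
    active_aperture: float | None = None  # mm (focused; clipped to full)
    lateral_offset: float = 0.0  # mm, transmit center re line-group center

    def __post_init__(self):
        if self.mode not in ("plane", "focused"):
            raise ValueError(f"unknown transmit mode {self.mode!r}")
        if self.mode == "focused" and (self.active_aperture is None
                                       or self.active_aperture <= 0):
            raise ValueError("focused transmit requires a positive aperture")


@dataclass(frozen=True)
class TrackingSequence:
    """Declarative description of one tracking mode."""

    family: str  # "pw" | "pwc" | "rxpar" | "txrxpar"
    transmits: tuple[TransmitSpec, ...]
    rx_fnumber: float = 2.6
    compounding_angles: tuple[float, ...] = ()
    line_pitch: float = LINE_PITCH_MM
    n_lines: int = N_LINES

    def __post_init__(self):
        if self.family in ("pw", "rxpar") and len(self.transmits) != 1:
            raise ValueError(f"{self.family} uses exactly one transmit per frame")
        if self.family == "txrxpar" and len(self.transmits) != 2:
            raise ValueError("txrxpar uses exactly two transmits per frame")
        if self.family == "pwc":
            a = np.asarray(self.compounding_angles)
            if len(a) < 2 or not np.allclose(a + a[::-1], 0) or not np.allclose(
                np.diff(a), PWC_ANGLE_STEP_DEG
            ):
                raise ValueError(
                    "pwc angles must be symmetric about 0 with 3-degree spacing"
                )

    @property
    def events_per_frame(self) -> int:
        return len(self.transmits)

    def line_positions(self, center: float = 0.0) -> np.ndarray:
        """Lateral positions (mm) of the beamformed line group."""
        idx = np.arange(self.n_lines) - (self.n_lines - 1) / 2.0
        return center + idx * self.line_pitch

    @property
    def label(self) -> str:
        if self.family == "pw":
            return "PW"
        if self.family == "pwc":
            return f"PWC{len(self.compounding_angles)}"
        f = self.transmits[0].tx_fnumber
        return ("RxPar" if self.family == "rxpar" else "TxRxPar") + f" F/{f:g}"


def min_tx_fnumber(focus_depth: float, aperture: float = _FULL_APERTURE_MM) -> float:
    """Smallest achievable transmit F-number, to one decimal (depth/aperture)."""
    if focus_depth <= 0 or aperture <= 0:
        raise ValueError("focus depth and aperture must be positive")
    return round(focus_depth / aperture, 1)


def _focused_transmit(tx_fnumber, focus_depth, aperture, lateral_offset=0.0):
    geo_min = min_tx_fnumber(focus_depth, aperture)
    if tx_fnumber + 1e-9 < geo_min:
        raise ValueError(
            f"Tx F/{tx_fnumber:g} below the geometric minimum F/{geo_min:g} "
            f"({aperture:g}-mm aperture focused at {focus_depth:g} mm)"
        )
    active = min(focus_depth / tx_fnumber, aperture)
    return TransmitSpec("focused", focus_depth=focus_depth,
                        tx_fnumber=tx_fnumber, active_aperture=active,
                        lateral_offset=lateral_offset)


def make_transmits(
    family: str,
    n_angles: int | None = None,
    tx_fnumber: float | None = None,
    focus_depth: float = FOCUS_DEPTH_MM,
    aperture: float = _FULL_APERTURE_MM,
    rx_fnumber: float = 2.6,
) -> TrackingSequence:
    """Build the transmit list for one tracking family.

    ``pwc`` needs ``n_angles`` (odd; 3-degree spacing symmetric about 0);
    ``rxpar``/``txrxpar`` need ``tx_fnumber``.  Focused transmits use an
    active aperture of ``focus_depth / tx_fnumber`` clipped to the full
    aperture; an F-number below the geometric minimum is rejected.
    """
    family = family.lower()
    if family == "pw":
        return TrackingSequence("pw", (TransmitSpec("plane"),), rx_fnumber)
    if family == "pwc":
        if n_angles is None or n_angles < 2:
            raise ValueError("pwc requires n_angles >= 2")
        angles = (np.arange(n_angles) - (n_angles - 1) / 2.0) * PWC_ANGLE_STEP_DEG
        tx = tuple(TransmitSpec("plane", steer_angle=a) for a in angles)
        return TrackingSequence("pwc", tx, rx_fnumber,
                                compounding_angles=tuple(angles))
    if family == "rxpar":
        if tx_fnumber is None:
            raise ValueError("rxpar requires tx_fnumber")
        tx = _focused_transmit(tx_fnumber, focus_depth, aperture)
        return TrackingSequence("rxpar", (tx,), rx_fnumber)
    if family == "txrxpar":
        if tx_fnumber is None:
            raise ValueError("txrxpar requires tx_fnumber")
        tx = tuple(
            _focused_transmit(tx_fnumber, focus_depth, aperture, off)
            for off in (-TXRX_OFFSET_MM, +TXRX_OFFSET_MM)
        )
        return TrackingSequence("txrxpar", tx, rx_fnumber)
    raise ValueError(f"unknown sequence family {family!r} "
                     "(expected pw, pwc, rxpar or txrxpar)")


@dataclass(frozen=True)
class PulseTimeline:
    """Timing of one interleaved HMI pulse train."""

    pulse_interval: float  # us
    fus_burst: float  # us
    idle_after_fus: float  # us
    tracking_window: float  # us
    frame_rate: float  # Hz
    n_pulses: int


def build_timeline(
    pulse_interval: float,
    fus_burst: float,
    idle: float,
    sequence: TrackingSequence,
    am: AMEnvelope,
    acquisition_depth: float = ACQUISITION_DEPTH_MM,
    in_silico: bool = False,
) -> PulseTimeline:
    """Validate and build the interleaved pulse timeline.

    Each pulse interval must accommodate the FUS burst, the idle gap, and
    one round-trip tracking event per transmit (round trip to the end of the
    recorded depth window plus the pulse length).  Hardware-infeasible
    combinations (e.g. 7-angle compounding within the 430-us window) are
    rejected with the computed deficit unless ``in_silico=True``, where the
    time window is unconstrained.
    """
    if pulse_interval <= 0 or fus_burst < 0 or idle < 0:
        raise ValueError("invalid timing parameters")
    tracking_window = pulse_interval - fus_burst
    per_event = 2 * acquisition_depth / SPEED_OF_SOUND + _PULSE_LEN_US
    needed = idle + sequence.events_per_frame * per_event
    if needed > tracking_window and not in_silico:
        raise ValueError(
            f"{sequence.events_per_frame} tracking event(s) of {per_event:.1f} us "
            f"plus {idle:g}-us idle exceed the {tracking_window:g}-us tracking "
            f"window by {needed - tracking_window:.1f} us"
        )
    frame_rate = 1e6 / pulse_interval
    if frame_rate < 2 * am.am_frequency:
        raise ValueError("pulse interval violates Nyquist for the AM frequency")
    n_pulses = int(round(am.duration * 1e3 / pulse_interval))
    return PulseTimeline(pulse_interval, fus_burst, idle, tracking_window,
                         frame_rate, n_pulses)


@dataclass(frozen=True)
class RasterGrid:
    """2-D point-by-point raster scan positions (mechanical translation)."""

    lateral_step: float  # mm
    axial_step: float  # mm
    n_lateral: int
    n_axial: int
    center: tuple[float, float] = (0.0, FOCUS_DEPTH_MM)

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) focus positions (x, z) mm, row-major from shallow-left."""
        xs = (np.arange(self.n_lateral) - (self.n_lateral - 1) / 2.0) \
            * self.lateral_step + self.center[0]
        zs = (np.arange(self.n_axial) - (self.n_axial - 1) / 2.0) \
            * self.axial_step + self.center[1]
        out = [(x, z) for z in zs for x in xs]
        return np.asarray(out)

    def __len__(self) -> int:
        return self.n_lateral * self.n_axial


def raster_grid(
    fov_lateral: float,
    fov_axial: float,
    step_lateral: float = 0.8,
    step_axial: float = 2.0,
    center: tuple[float, float] = (0.0, FOCUS_DEPTH_MM),
) -> RasterGrid:
    """Raster grid covering the FOV; counts are round(fov / step) per axis."""
    if step_lateral <= 0 or step_axial <= 0:
        raise ValueError("raster steps must be positive")
    if fov_lateral <= 0 or fov_axial <= 0:
        raise ValueError("field of view must be positive")
    n_lat = int(np.floor(fov_lateral / step_lateral + 0.5 + 1e-9))
    n_ax = int(np.floor(fov_axial / step_axial + 0.5 + 1e-9))
    return RasterGrid(step_lateral, step_axial, n_lat, n_ax, center)
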