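"""FEM-surrogate phantom mechanics: oscillatory displacement fields and scatterers.

The amplitude-modulated FUS beam exerts a radiation force proportional to the
local acoustic intensity.  Instead of a full elastodynamic FEM solve, the
workbench uses a quasi-static Kelvin-Voigt surrogate:

* the displacement amplitude field is ``gain * smooth(I(r) / E(r))`` where
  ``I`` is the (peak-normalized) intensity, ``E`` the local Young's modulus,
  and ``smooth`` a Gaussian shear-coupling kernel whose width defaults to a
  quarter of the background shear wavelength at the AM frequency (shear
  modulus ``G = E / 3``, density 1000 kg/m^3);
* the temporal response is the causal first-order Kelvin-Voigt response
  (time constant ``eta / E``) to the raised-cosine AM envelope, so the
  steady-state oscillation sits at the AM frequency with a small viscous
  phase lag.

The surrogate's contract is qualitative: amplitude inversely proportional to
stiffness in the zero-smoothing limit, linear in intensity, and contrast that
decreases monotonically with the smoothing width.  It does not reproduce
inertia or shear-wave propagation.

Displacement fields live on a 2-D (x, z) grid in the imaging plane (0.1 mm
spacing by default) and are treated as uniform over the small elevation
extent of the scatterer slab.  Axial ``z`` increases away from the array;
the FUS focus sits at z = 31 mm in array coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import SPEED_OF_SOUND, IntensityField

__all__ = [
    "RESOLUTION_CELL_MM3",
    "FOCUS_DEPTH_MM",
    "PhantomModel",
    "AMEnvelope",
    "DisplacementField",
    "ScattererField",
    "am_envelope",
    "shear_wavelength_mm",
    "solve_harmonic_displacement",
    "generate_scatterers",
    "displace_scatterers",
]

#: Depth of the confocal FUS / imaging focus in array coordinates (mm).
FOCUS_DEPTH_MM = 31.0

# Resolution cell used for scatterer density: axial pulse length (2 cycles at
# 7.8 MHz) x lateral -6 dB beamwidth at the focus (~ lambda * F/2.6) x an
# equal elevation extent.
_LAMBDA_IMG = SPEED_OF_SOUND / 7.8
_PULSE_LEN_MM = 2 * _LAMBDA_IMG
_BEAMWIDTH_MM = _LAMBDA_IMG * 2.6
RESOLUTION_CELL_MM3 = _PULSE_LEN_MM * _BEAMWIDTH_MM**2


@dataclass(frozen=True)
class PhantomModel:
    """Inclusion phantom: a stiff sphere/cylinder in a softer background.

    ``region`` is the scatterer slab in array coordinates, given as
    ``((xmin, xmax), (ymin, ymax), (zmin, zmax))`` in mm with z the depth.
    """

    background_E: float = 5.3  # kPa
    inclusion_E: float = 56.0  # kPa
    inclusion_shape: str = "sphere"  # sphere | cylinder | none
    inclusion_diameter: float = 3.6  # mm
    inclusion_center: tuple[float, float] = (0.0, FOCUS_DEPTH_MM)  # (x, z) mm
    viscosity: float = 0.6  # Pa s (Kelvin-Voigt damping)
    region: tuple[tuple[float, float], ...] = (
        (-6.0, 6.0),
        (-0.5, 0.5),
        (FOCUS_DEPTH_MM - 6.0, FOCUS_DEPTH_MM + 6.0),
    )

    def __post_init__(self):
        if self.background_E <= 0 or self.inclusion_E <= 0:
            raise ValueError("Young's moduli must be positive")
        if self.inclusion_shape not in ("sphere", "cylinder", "none"):
            raise ValueError(f"unknown inclusion shape {self.inclusion_shape!r}")
        if self.viscosity < 0:
            raise ValueError("viscosity must be non-negative")

    def youngs_modulus(self, x: np.ndarray, z: np.ndarray) -> np.ndarray:
        """Young's modulus (kPa) at in-plane points; broadcasts x against z."""
        x = np.asarray(x, dtype=float)
        z = np.asarray(z, dtype=float)
        E = np.full(np.broadcast(x, z).shape, self.background_E)
        if self.inclusion_shape != "none":
            cx, cz = self.inclusion_center
            r2 = (x - cx) ** 2 + (z - cz) ** 2
            E[r2 <= (self.inclusion_diameter / 2) ** 2] = self.inclusion_E
        return E


@dataclass
class AMEnvelope:
    """Normalized radiation-force envelope: e(t) = (1 - cos(2 pi f_am t)) / 2."""

    am_frequency: float  # Hz
    duration: float  # ms
    frame_rate: float  # Hz
    samples: np.ndarray = field(repr=False)  # type: ignore[assignment]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.frame_rate

    @property
    def n_cycles(self) -> float:
        return self.duration * 1e-3 * self.am_frequency


def am_envelope(f_am: float, duration: float, frame_rate: float) -> AMEnvelope:
    """Raised-cosine AM envelope sampled at the tracking frame rate.

    Parameters: ``f_am`` in Hz (200/300/600/800 in the study conditions),
    ``duration`` in ms, ``frame_rate`` in Hz.  Rejects sub-Nyquist frame
    rates (``frame_rate < 2 * f_am``).
    """
    if f_am <= 0 or duration <= 0 or frame_rate <= 0:
        raise ValueError("f_am, duration and frame_rate must be positive")
    if frame_rate < 2 * f_am:
        raise ValueError(
            f"frame rate {frame_rate} Hz is below Nyquist (2 x {f_am} Hz) "
            "for the AM frequency"
        )
    n = int(round(duration * 1e-3 * frame_rate))
    t = np.arange(n) / frame_rate
    e = 0.5 * (1.0 - np.cos(2 * np.pi * f_am * t))
    return AMEnvelope(float(f_am), float(duration), float(frame_rate), e)


def shear_wavelength_mm(E_kpa: float, f_am: float, density: float = 1000.0) -> float:
    """Shear wavelength (mm) at ``f_am`` Hz for Young's modulus ``E_kpa``.

    Uses G = E / 3 (incompressible elastic solid) and c_s = sqrt(G / rho).
    """
    cs = np.sqrt(E_kpa * 1e3 / 3.0 / density)  # m/s
    return cs / f_am * 1e3  # mm


@dataclass
class DisplacementField:
    """Time-resolved axial particle displacement on an (x, z) grid.

    ``u`` has shape (nx, nz, nt) in micrometers; ``times_us`` are the frame
    times in microseconds.  u(:, :, 0) is zero (motion starts from rest).
    """

    x: np.ndarray  # mm
    z: np.ndarray  # mm (depth)
    times_us: np.ndarray
    u: np.ndarray  # um

    def __post_init__(self):
        if self.u.shape != (len(self.x), len(self.z), len(self.times_us)):
            raise ValueError("displacement array shape mismatch")

    def amplitude(self) -> np.ndarray:
        """Steady-state half peak-to-peak amplitude map (um)."""
        half = self.u.shape[2] // 2
        tail = self.u[:, :, half:]
        return (tail.max(axis=2) - tail.min(axis=2)) / 2.0


def _kelvin_voigt_response(t_s: np.ndarray, f_am: float, tau_s: float) -> np.ndarray:
    """Causal response of tau u' + u = e(t) to the raised-cosine envelope."""
    w = 2 * np.pi * f_am
    if tau_s <= 0:
        return 0.5 * (1 - np.cos(w * t_s))
    H = 1.0 / np.sqrt(1 + (w * tau_s) ** 2)
    phi = np.arctan(w * tau_s)
    decay = np.exp(-t_s / tau_s)
    return 0.5 * (1 - decay) - 0.5 * H * np.cos(w * t_s - phi) + 0.5 * H * np.cos(phi) * decay


def solve_harmonic_displacement(
    phantom: PhantomModel,
    intensity: IntensityField,
    envelope: AMEnvelope,
    focus: tuple[float, float] = (0.0, FOCUS_DEPTH_MM),
    smoothing_sigma: float | None = None,
    drive_gain: float = 240.0,
) -> DisplacementField:
    """Solve the surrogate for the FUS focus placed at ``focus`` (x, z) mm.

    ``intensity`` is a peak-normalized (x, z) field centered on the focus
    (coordinates relative to the focus, uniform spacing).  ``smoothing_sigma``
    is the Gaussian shear-coupling width in mm; ``None`` selects the default
    of one quarter of the background shear wavelength at the AM frequency.
    ``drive_gain`` converts normalized intensity over stiffness into
    micrometers (um kPa); the default yields ~1 um amplitude (~2 um peak-to-
    peak) at the focus of a homogeneous 5.3-kPa background at 200-Hz AM,
    typical of the micron-level displacements HMI reports.
    """
    if intensity.axes != ("x", "z"):
        raise ValueError("intensity field must be on (x, z) axes")
    xi, zi = intensity.coords
    dx = np.diff(xi)
    dz = np.diff(zi)
    if len(dx) and len(dz) and not (
        np.allclose(dx, dx[0], rtol=1e-6) and np.allclose(dz, dz[0], rtol=1e-6)
        and np.isclose(dx[0], dz[0], rtol=1e-6)
    ):
        raise ValueError("intensity grid must have uniform, equal x/z spacing")
    spacing = float(dx[0]) if len(dx) else 0.1

    x = xi + focus[0]
    z = zi + focus[1]
    E = phantom.youngs_modulus(x[:, None], z[None, :])
    drive = intensity.values / E  # 1/kPa, peak-normalized intensity

    if smoothing_sigma is None:
        smoothing_sigma = shear_wavelength_mm(phantom.background_E,
                                              envelope.am_frequency) / 4.0
    if smoothing_sigma > 0:
        drive = gaussian_filter(drive, sigma=smoothing_sigma / spacing,
                                mode="nearest")
    amp = drive_gain * drive  # um

    t_s = envelope.times_s
    u = np.empty(amp.shape + (len(t_s),))
    for E_val in np.unique(E):
        tau_s = phantom.viscosity / (E_val * 1e3)  # s
        g = _kelvin_voigt_response(t_s, envelope.am_frequency, tau_s)
        mask = E == E_val
        u[mask, :] = amp[mask][:, None] * g[None, :]
    return DisplacementField(x, z, t_s * 1e6, u)


@dataclass
class ScattererField:
    """Random point scatterers: positions (N, 3) as (x, y, z) mm, reflectivities."""

    positions: np.ndarray
    amplitudes: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3) as (x, y, z)")
        if len(self.amplitudes) != len(self.positions):
            raise ValueError("one amplitude per scatterer required")


def generate_scatterers(
    region: tuple[tuple[float, float], ...],
    density: float = 20.0,
    cell_volume: float = RESOLUTION_CELL_MM3,
    seed: int | None = None,
    poisson: bool = False,
) -> ScattererField:
    """Uniform random scatterers at ``density`` per resolution cell.

    ``region`` is ``((xmin, xmax), (ymin, ymax), (zmin, zmax))`` in mm.  The
    count is ``round(density * volume / cell_volume)`` (deterministic) or
    Poisson-distributed with that mean when ``poisson=True``.  Reflectivities
    are standard normal.  The same seed reproduces the identical field.
    """
    if density <= 0:
        raise ValueError("scatterer density must be positive")
    spans = [hi - lo for lo, hi in region]
    if len(region) != 3 or any(s <= 0 for s in spans):
        raise ValueError("region must be a non-empty (x, y, z) box")
    volume = spans[0] * spans[1] * spans[2]
    rng = np.random.default_rng(seed)
    mean_n = density * volume / cell_volume
    n = int(rng.poisson(mean_n)) if poisson else int(round(mean_n))
    pos = np.column_stack(
        [rng.uniform(lo, hi, n) for lo, hi in region]
    )
    amps = rng.standard_normal(n)
    return ScattererField(pos, amps, seed)


def displace_scatterers(
    scat: ScattererField, disp: DisplacementField, t_us: float
) -> ScattererField:
    """Move scatterers axially by the displacement field at time ``t_us``.

    Displacement is interpolated linearly in time and bilinearly in (x, z);
    the field is taken as uniform over elevation (y).  Scatterers outside the
    solved grid do not move.
    """
    times = disp.times_us
    if t_us < times[0] - 1e-9 or t_us > times[-1] + 1e-9:
        raise ValueError(f"time {t_us} us outside solved range "
                         f"[{times[0]}, {times[-1]}]")
    it = int(np.clip(np.searchsorted(times, t_us) - 1, 0, len(times) - 2))
    f = (t_us - times[it]) / (times[it + 1] - times[it])
    u_t = (1 - f) * disp.u[:, :, it] + f * disp.u[:, :, it + 1]  # (nx, nz) um

    x, z = scat.positions[:, 0], scat.positions[:, 2]
    ux = _bilinear(disp.x, disp.z, u_t, x, z)
    new_pos = scat.positions.copy()
    new_pos[:, 2] += ux * 1e-3  # um -> mm, axial shift
    return ScattererField(new_pos, scat.amplitudes.copy(), scat.seed)


def _bilinear(gx, gz, vals, x, z):
    """Bilinear interpolation of vals[nx, nz] at points (x, z); 0 outside."""
    out = np.zeros(len(x))
    inside = (x >= gx[0]) & (x <= gx[-1]) & (z >= gz[0]) & (z <= gz[-1])
    if not np.any(inside):
        return out
    xi = np.clip(np.searchsorted(gx, x[inside]) - 1, 0, len(gx) - 2)
    zi = np.clip(np.searchsorted(gz, z[inside]) - 1, 0, len(gz) - 2)
    fx = (x[inside] - gx[xi]) / (gx[xi + 1] - gx[xi])
    fz = (z[inside] - gz[zi]) / (gz[zi + 1] - gz[zi])
    v = (
        vals[xi, zi] * (1 - fx) * (1 - fz)
        + vals[xi + 1, zi] * fx * (1 - fz)
        + vals[xi, zi + 1] * (1 - fx) * fz
        + vals[xi + 1, zi + 1] * fx * fz
    )
    out[inside] = v
    return out
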