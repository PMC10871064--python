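"""Transducer geometry and continuous-wave focal-field simulation.

The workbench models two transducers: a phased imaging array (104 elements,
7.8 MHz center frequency, 11.81 mm aperture) used for RF speckle tracking, and
an annular spherically focused FUS bowl (4.5 MHz, 80 mm outer diameter, 41 mm
central opening, 76 mm radius of curvature) that delivers the amplitude-
modulated acoustic radiation force.

The bowl's continuous-wave pressure field is computed with a Rayleigh-
Sommerfeld integral over the spherical cap, discretized into surface patches
no larger than ``lambda / 6``.  Conventions: the geometric focus is the origin
of the field coordinates, ``z`` is the beam (axial) direction, ``x`` and ``y``
are transverse; lengths in mm, frequencies in MHz, time in microseconds, so
the speed of sound is 1.54 mm/us (soft tissue).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import numba as nb

#: Speed of sound used everywhere in the package (mm/us; soft tissue).
SPEED_OF_SOUND = 1.54

__all__ = [
    "SPEED_OF_SOUND",
    "ImagingArrayGeometry",
    "FUSBowlGeometry",
    "PressureField",
    "IntensityField",
    "build_imaging_array",
    "simulate_bowl_field",
    "simulate_focal_intensity_xz",
    "beam_width",
    "pressure_to_intensity",
]


@dataclass(frozen=True)
class ImagingArrayGeometry:
    """Linear/phased imaging array lying along ``x`` at ``z = 0``."""

    n_elements: int
    pitch: float  # mm
    center_frequency: float  # MHz
    bandwidth: tuple[float, float] = (5.0, 12.0)  # MHz

    @property
    def aperture_width(self) -> float:
        """Full aperture in mm (n_elements * pitch)."""
        return self.n_elements * self.pitch

    @property
    def element_positions(self) -> np.ndarray:
        """Lateral element centers (mm), evenly spaced and centered at 0."""
        idx = np.arange(self.n_elements)
        return (idx - (self.n_elements - 1) / 2.0) * self.pitch

    @property
    def wavelength(self) -> float:
        """Wavelength at the center frequency (mm)."""
        return SPEED_OF_SOUND / self.center_frequency


def build_imaging_array(
    n_elements: int = 104,
    pitch: float = 11.81 / 104,
    fc: float = 7.8,
    bandwidth: tuple[float, float] = (5.0, 12.0),
) -> ImagingArrayGeometry:
    """Construct the imaging-array geometry (defaults: the P12-5 style array)."""
    if n_elements < 2:
        raise ValueError("imaging array needs at least 2 elements")
    if pitch <= 0:
        raise ValueError(f"element pitch must be positive, got {pitch}")
    if fc <= 0:
        raise ValueError(f"center frequency must be positive, got {fc}")
    return ImagingArrayGeometry(int(n_elements), float(pitch), float(fc), bandwidth)


@dataclass(frozen=True)
class FUSBowlGeometry:
    """Annular spherically focused bowl (single-element FUS transducer)."""

    center_frequency: float = 4.5  # MHz
    outer_diameter: float = 80.0  # mm
    opening_diameter: float = 41.0  # mm
    radius_of_curvature: float = 76.0  # mm

    def __post_init__(self):
        if not (0 <= self.opening_diameter < self.outer_diameter):
            raise ValueError("opening diameter must lie in [0, outer diameter)")
        if self.radius_of_curvature <= self.outer_diameter / 2:
            raise ValueError("radius of curvature must exceed the aperture radius")

    @property
    def wavelength(self) -> float:
        return SPEED_OF_SOUND / self.center_frequency


@dataclass
class PressureField:
    """Complex pressure sampled on a rectilinear grid (arbitrary units)."""

    axes: tuple[str, ...]
    coords: tuple[np.ndarray, ...]
    values: np.ndarray  # complex, shape = tuple(len(c) for c in coords)
    frequency: float  # MHz

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != tuple(len(c) for c in self.coords):
            raise ValueError("values shape does not match coordinate lengths")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pressure field contains non-finite values")
        for name, c in zip(self.axes, self.coords):
            if len(c) > 1 and not np.all(np.diff(c) > 0):
                raise ValueError(f"grid axis {name!r} must be strictly increasing")


@dataclass
class IntensityField:
    """Time-averaged acoustic intensity on a rectilinear grid (values >= 0)."""

    axes: tuple[str, ...]
    coords: tuple[np.ndarray, ...]
    values: np.ndarray
    frequency: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("intensity must be non-negative")


@nb.njit(cache=True, fastmath=True)
def _rayleigh_sum(src, areas, pts, k):  # pragma: no cover - numba kernel
    m = pts.shape[0]
    n = src.shape[0]
    out_re = np.zeros(m)
    out_im = np.zeros(m)
    for i in range(m):
        px, py, pz = pts[i, 0], pts[i, 1], pts[i, 2]
        acc_re = 0.0
        acc_im = 0.0
        for j in range(n):
            dx = px - src[j, 0]
            dy = py - src[j, 1]
            dz = pz - src[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            ph = k * d
            a = areas[j] / d
            acc_re += a * np.cos(ph)
            acc_im += a * np.sin(ph)
        out_re[i] = acc_re
        out_im[i] = acc_im
    return out_re + 1j * out_im


def _mesh_bowl(geom: FUSBowlGeometry, patch: float):
    """Mesh the annular spherical cap into patches of size <= ``patch`` mm.

    The bowl is a cap of the sphere of radius R centered at the focus
    (origin), occupying z < 0.  Returns (points (N, 3), areas (N,)).
    """
    R = geom.radius_of_curvature
    sin_out = (geom.outer_diameter / 2.0) / R
    sin_in = (geom.opening_diameter / 2.0) / R
    th_out = np.arcsin(sin_out)
    th_in = np.arcsin(sin_in)
    n_th = max(2, int(np.ceil(R * (th_out - th_in) / patch)))
    edges = np.linspace(th_in, th_out, n_th + 1)
    pts_list = []
    area_list = []
    for a, b in zip(edges[:-1], edges[1:]):
        th = 0.5 * (a + b)
        ring_len = 2 * np.pi * R * np.sin(th)
        n_phi = max(4, int(np.ceil(ring_len / patch)))
        phi = (np.arange(n_phi) + 0.5) * (2 * np.pi / n_phi)
        r_t = R * np.sin(th)
        x = r_t * np.cos(phi)
        y = r_t * np.sin(phi)
        z = np.full(n_phi, -R * np.cos(th))
        # exact ring strip area split evenly over its patches
        strip_area = 2 * np.pi * R * R * (np.cos(a) - np.cos(b))
        pts_list.append(np.column_stack([x, y, z]))
        area_list.append(np.full(n_phi, strip_area / n_phi))
    return np.concatenate(pts_list), np.concatenate(area_list)


def simulate_bowl_field(
    geom: FUSBowlGeometry,
    grid: dict[str, np.ndarray],
    c: float = SPEED_OF_SOUND,
    mesh_patch: float | None = None,
) -> PressureField:
    """Continuous-wave Rayleigh-integral field of the focused bowl.

    Parameters
    ----------
    grid
        Mapping from axis names (subset of ``x``, ``y``, ``z``) to 1-D
        coordinate arrays in mm, relative to the geometric focus.  Omitted
        axes are fixed at 0 (so ``{"x": xs}`` is the transverse focal line).
    mesh_patch
        Source-patch size in mm; defaults to ``lambda / 6``.
    """
    lam = c / geom.center_frequency
    axes = tuple(a for a in ("x", "y", "z") if a in grid)
    if not axes:
        raise ValueError("grid must provide at least one of x, y, z")
    coords = tuple(np.atleast_1d(np.asarray(grid[a], dtype=float)) for a in axes)
    for name, arr in zip(axes, coords):
        if name in ("x", "y") and len(arr) > 1:
            step = np.max(np.diff(arr))
            if step > lam / 4 + 1e-12:
                raise ValueError(
                    f"transverse grid spacing {step:.4g} mm exceeds lambda/4 = "
                    f"{lam / 4:.4g} mm"
                )
        if arr.min() > 0 or arr.max() < 0:
            warnings.warn(
                f"grid axis {name!r} does not span the geometric focus (0)",
                stacklevel=2,
            )
    patch = lam / 6 if mesh_patch is None else float(mesh_patch)
    src, areas = _mesh_bowl(geom, patch)

    mesh = np.meshgrid(*coords, indexing="ij")
    full = {a: m.ravel() for a, m in zip(axes, mesh)}
    npts = mesh[0].size
    pts = np.column_stack(
        [full.get(a, np.zeros(npts)) for a in ("x", "y", "z")]
    )
    k = 2 * np.pi * geom.center_frequency / c
    vals = _rayleigh_sum(src, areas, pts, k).reshape(mesh[0].shape)
    return PressureField(axes, coords, vals, geom.center_frequency)


def simulate_focal_intensity_xz(
    geom: FUSBowlGeometry,
    x: np.ndarray,
    z: np.ndarray,
    c: float = SPEED_OF_SOUND,
    mesh_patch: float | None = None,
) -> IntensityField:
    """Separable (x, z) intensity model of the focal region, peak-normalized.

    The full 2-D Rayleigh evaluation is expensive, and the radiation-force
    surrogate only needs the focal-region shape, so the intensity is modeled
    as the outer product of the exact transverse focal-line profile and the
    exact on-axis profile: ``I(x, z) = T(x) * A(z)``, each from the Rayleigh
    integral, normalized to peak 1.  Exact on both axes through the focus.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    lam = c / geom.center_frequency
    # The transverse profile is simulated on a lambda/8 line (the Rayleigh
    # solver requires <= lambda/4 transverse sampling) and interpolated onto
    # the requested grid; intensity varies smoothly at that scale.
    xf = np.arange(x.min(), x.max() + lam / 8, lam / 8)
    tr = simulate_bowl_field(geom, {"x": xf}, c=c, mesh_patch=mesh_patch)
    ax = simulate_bowl_field(geom, {"z": z}, c=c, mesh_patch=mesh_patch)
    t = np.interp(x, xf, np.abs(tr.values) ** 2)
    a = np.abs(ax.values) ** 2
    vals = np.outer(t / t.max(), a / a.max())
    return IntensityField(("x", "z"), (x, ax.coords[0]), vals,
                          geom.center_frequency)


def beam_width(field: PressureField, axis: str, level_db: float = 6.0) -> float:
    """Full width of ``|p|`` at ``level_db`` below its maximum, in mm.

    ``axis`` is ``"transverse"``/``"x"``/``"y"`` or ``"axial"``/``"z"``.  The
    width is measured on the 1-D profile through the global maximum of the
    field, with linear interpolation between samples.  ``level_db`` is the
    positive number of dB down from the peak (6 -> half amplitude).
    """
    name = {"transverse": "x", "axial": "z"}.get(axis, axis)
    if name not in field.axes:
        raise ValueError(f"field has no axis {axis!r} (axes: {field.axes})")
    level_db = float(abs(level_db))
    if level_db == 0.0:
        return 0.0
    mag = np.abs(field.values)
    peak_idx = np.unravel_index(np.argmax(mag), mag.shape)
    ax_i = field.axes.index(name)
    sl = list(peak_idx)
    sl[ax_i] = slice(None)
    profile = mag[tuple(sl)]
    coord = field.coords[ax_i]
    ipk = int(np.argmax(profile))
    target = profile[ipk] * 10 ** (-level_db / 20.0)

    def _cross(idx_range):
        prev = ipk
        for i in idx_range:
            if profile[i] <= target:
                # linear interpolation between samples i and prev
                f = (profile[prev] - target) / (profile[prev] - profile[i])
                return coord[prev] + f * (coord[i] - coord[prev])
            prev = i
        raise ValueError(
            f"-{level_db} dB level never crossed along axis {axis!r} within grid"
        )

    right = _cross(range(ipk + 1, len(profile)))
    left = _cross(range(ipk - 1, -1, -1))
    return float(right - left)


def pressure_to_intensity(
    field: PressureField, rho: float = 1.0, c: float = SPEED_OF_SOUND
) -> IntensityField:
    """Convert complex pressure to time-averaged intensity |p|^2 / (2 rho c)."""
    vals = np.abs(field.values) ** 2 / (2.0 * rho * c)
    return IntensityField(field.axes, field.coords, vals, field.frequency)
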