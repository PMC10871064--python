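"""Linear scattering simulation: per-element RF channel data synthesis.

Each scatterer contributes one echo per receive element, delayed by the
transmit wavefront arrival plus the return path and weighted by reflectivity,
the transmit beam amplitude at the scatterer, a hard-baffle sinc element
directivity (element width 0.95 x pitch), and 1/r spreading on receive.

Transmit delay models:

* plane wave steered by theta: arrival time (z cos(theta) + x sin(theta)) / c,
  referenced to the wavefront passing the array center;
* focused beam: virtual-source convention -- a spherical wave converging on
  the focus before it and diverging from it beyond, referenced so the focus
  is reached at ``focus_depth / c``.

The focused transmit amplitude uses an hourglass beam envelope: a Gaussian
lateral profile whose width is the -6 dB focal width (lambda x F/#) grown
geometrically away from the focus, with 1/sqrt(width) amplitude conservation.

Channel data is synthesized directly at the stored sampling rate (>= 4x the
imaging center frequency, 31.2 MHz by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import numba as nb
from scipy.signal import butter, filtfilt

from .geometry import SPEED_OF_SOUND, ImagingArrayGeometry
from .mechanics import ScattererField
from .sequences import TransmitSpec

__all__ = [
    "PulseModel",
    "ChannelData",
    "synthesize_channel_data",
    "add_band_limited_noise",
    "inject_fus_interference",
    "transmit_arrival_times",
]

_SIGMA_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # -6 dB envelope width / sigma

#: Elevation lens of the imaging array: aperture and fixed focus (mm).
ELEV_APERTURE_MM = 4.5
ELEV_FOCUS_MM = 31.0


@dataclass(frozen=True)
class PulseModel:
    """Gaussian-windowed tracking pulse (round-trip wavelet)."""

    center_frequency: float = 7.8  # MHz
    n_cycles: float = 2.0

    @property
    def duration(self) -> float:
        """-6 dB envelope duration in us (n_cycles periods)."""
        return self.n_cycles / self.center_frequency

    @property
    def sigma(self) -> float:
        """Gaussian envelope sigma in us."""
        return self.duration / _SIGMA_FACTOR

    @property
    def half_support(self) -> float:
        """Truncation half-width in us (3 sigma)."""
        return 3.0 * self.sigma

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Pulse amplitude at times ``t`` (us), centered at t = 0."""
        t = np.asarray(t, dtype=float)
        w = np.cos(2 * np.pi * self.center_frequency * t) * np.exp(
            -0.5 * (t / self.sigma) ** 2
        )
        return np.where(np.abs(t) <= self.half_support, w, 0.0)


@dataclass
class ChannelData:
    """Per-element RF time samples for one transmit-receive event."""

    samples: np.ndarray  # (n_elements, n_samples)
    sampling_rate: float  # MHz
    transmit: TransmitSpec
    t0: float  # us, time of the first sample

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be (n_elements, n_samples)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("channel data contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.shape[1]) / self.sampling_rate


def transmit_arrival_times(
    tx: TransmitSpec, positions: np.ndarray, c: float = SPEED_OF_SOUND,
    wavelength: float = SPEED_OF_SOUND / 7.8,
) -> np.ndarray:
    """Transmit wavefront arrival time (us) at (x, y, z) scatterer positions.

    Plane waves: the steered wavefront referenced to the array center.
    Focused beams: a virtual source at the focus (spherical wave converging
    before it, diverging beyond), with the lateral term faded in over the
    Rayleigh range so the wavefront is planar through the focal zone --
    the naive ``sign(z - z_f) |r - r_f|`` form is discontinuous across the
    focal plane for off-axis points.
    """
    x, y, z = positions[:, 0], positions[:, 1], positions[:, 2]
    if tx.mode == "plane":
        th = np.deg2rad(tx.steer_angle)
        return (z * np.cos(th) + x * np.sin(th)) / c
    xc = tx.lateral_offset
    zf = tx.focus_depth
    dz = z - zf
    rho2 = (x - xc) ** 2 + y**2
    z_r = 0.785 * wavelength * tx.tx_fnumber**2  # Rayleigh range (pi w0^2 / lambda)
    d = np.sqrt(dz**2 + rho2 * dz**2 / (dz**2 + z_r**2))
    return (zf + np.sign(dz) * d) / c


def _tx_amplitude(
    tx: TransmitSpec, positions: np.ndarray, wavelength: float,
    aperture: float = 11.81,
) -> np.ndarray:
    """Transmit beam amplitude at the scatterer positions.

    Plane waves carry the Fresnel near-field ripple of the finite transmit
    aperture (a perfectly uniform plane wave would flatter PW tracking);
    focused beams use the hourglass model below.
    """
    from scipy.special import fresnel

    x, y, z = positions[:, 0], positions[:, 1], positions[:, 2]
    # fixed elevation lens, common to every transmit mode (the array focuses
    # electronically in x only): Gaussian slice with a sidelobe shoulder
    sig_el = wavelength * (ELEV_FOCUS_MM / ELEV_APERTURE_MM) / _SIGMA_FACTOR
    elev = (np.exp(-0.5 * y**2 / sig_el**2)
            + 0.2 * np.exp(-0.5 * y**2 / (3 * sig_el) ** 2)) / 1.2
    if tx.mode == "plane":
        th = np.deg2rad(tx.steer_angle)
        xi = x * np.cos(th) - z * np.sin(th)  # transverse beam coordinate
        zeta = np.maximum(x * np.sin(th) + z * np.cos(th), 1e-6)
        half = aperture * np.cos(th) / 2.0
        u = np.sqrt(2.0 / (wavelength * zeta))
        s2, c2 = fresnel(u * (xi + half))
        s1, c1 = fresnel(u * (xi - half))
        return elev * np.hypot(c2 - c1, s2 - s1) / np.sqrt(2.0)
    w_focal = wavelength * tx.tx_fnumber  # -6 dB focal beamwidth
    sig_f = w_focal / _SIGMA_FACTOR
    cone = tx.active_aperture * np.abs(z - tx.focus_depth) / tx.focus_depth
    sig = np.sqrt(sig_f**2 + (cone / _SIGMA_FACTOR) ** 2)
    r2 = (x - tx.lateral_offset) ** 2
    # 1/sqrt(width) lateral energy conservation referenced to the aperture
    # plane, where the beam is aperture-wide with unit amplitude -- so a
    # focused transmit carries its focusing gain relative to a plane wave.
    sig_0 = np.sqrt(sig_f**2 + (tx.active_aperture / _SIGMA_FACTOR) ** 2)
    # Gaussian mainlobe plus a wide shoulder (~ -17 dB off-axis), standing in
    # for the sidelobe skirt of a uniformly apodized aperture; a pure
    # Gaussian underestimates off-axis transmit energy by tens of dB.
    lobe = (np.exp(-0.5 * r2 / sig**2)
            + 0.2 * np.exp(-0.5 * r2 / (3 * sig) ** 2)) / 1.2
    return elev * np.sqrt(sig_0 / sig) * lobe


@nb.njit(cache=True, fastmath=True)
def _accumulate_echoes(
    out, elem_x, pos, amp, tau_tx, t0, dt, lut, lut_dt, half_sup, dir_width, c
):  # pragma: no cover - numba kernel
    n_elem = elem_x.shape[0]
    n_scat = pos.shape[0]
    n_samp = out.shape[1]
    n_lut = lut.shape[0]
    for e in range(n_elem):
        xe = elem_x[e]
        for j in range(n_scat):
            dx = pos[j, 0] - xe
            dy = pos[j, 1]
            dz = pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            tau = tau_tx[j] + r / c
            # hard-baffle sinc directivity on the lateral angle
            s = np.sqrt(dx * dx + dy * dy) / r
            arg = dir_width * s
            if arg < 1e-9:
                direct = 1.0
            else:
                pa = np.pi * arg
                direct = np.sin(pa) / pa
            a = amp[j] * direct / r
            i0 = int(np.ceil((tau - half_sup - t0) / dt))
            i1 = int(np.floor((tau + half_sup - t0) / dt))
            if i0 < 0:
                i0 = 0
            if i1 >= n_samp:
                i1 = n_samp - 1
            for n in range(i0, i1 + 1):
                # pulse waveform via fine lookup table (linear interpolation)
                u = (t0 + n * dt - tau + half_sup) / lut_dt
                iu = int(u)
                if iu < 0 or iu + 1 >= n_lut:
                    continue
                f = u - iu
                out[e, n] += a * (lut[iu] * (1.0 - f) + lut[iu + 1] * f)


def synthesize_channel_data(
    scat: ScattererField,
    array: ImagingArrayGeometry,
    tx: TransmitSpec,
    pulse: PulseModel | None = None,
    fs: float = 31.2,
    t0: float | None = None,
    n_samples: int | None = None,
    c: float = SPEED_OF_SOUND,
) -> ChannelData:
    """Synthesize one transmit-receive event of RF channel data.

    ``t0``/``n_samples`` fix the record window (us / samples); when omitted
    they are chosen to cover all echoes.  Deterministic given its inputs.
    """
    pulse = pulse or PulseModel(center_frequency=array.center_frequency)
    if fs < 4 * pulse.center_frequency - 1e-9:
        raise ValueError(
            f"sampling rate {fs} MHz below 4x the pulse center frequency"
        )
    pos = scat.positions
    if np.any(pos[:, 2] <= 0):
        raise ValueError("scatterers must lie in front of the array (z > 0)")

    lam = c / pulse.center_frequency
    tau_tx = transmit_arrival_times(tx, pos, c)
    amp = scat.amplitudes * _tx_amplitude(tx, pos, lam,
                                          aperture=array.aperture_width)

    elem_x = array.element_positions
    r_max = np.sqrt((np.abs(pos[:, 0]).max() + array.aperture_width / 2) ** 2
                    + pos[:, 2].max() ** 2)
    if t0 is None:
        t0 = max(0.0, tau_tx.min() + pos[:, 2].min() / c - 2 * pulse.half_support)
    if n_samples is None:
        t_end = tau_tx.max() + r_max / c + 2 * pulse.half_support
        n_samples = int(np.ceil((t_end - t0) * fs))

    out = np.zeros((array.n_elements, n_samples))
    # pulse waveform tabulated at 1/64 of the sample interval
    lut_dt = 1.0 / (fs * 64)
    tt = np.arange(-pulse.half_support, pulse.half_support + lut_dt, lut_dt)
    lut = pulse.waveform(tt)
    _accumulate_echoes(
        out, elem_x, pos, amp, tau_tx, t0, 1.0 / fs, lut, lut_dt,
        pulse.half_support, 0.95 * array.pitch / lam, c,
    )
    return ChannelData(out, fs, tx, t0)


def inject_fus_interference(
    ch: ChannelData,
    amplitude: float,
    fus_fc: float = 4.5,
    harmonics: tuple[int, ...] = (1, 2, 3),
    seed: int | None = None,
) -> ChannelData:
    """Add FUS leakage tones (fundamental + harmonics) to the channel data.

    The co-firing FUS transducer leaks narrow-band tones at 4.5 / 9 /
    13.5 MHz into the imaging receive band; the notch-filter bank in the
    motion-estimation chain exists to suppress them.  Tones above the
    record's Nyquist are skipped; per-element random phases come from
    ``seed``.  ``amplitude`` is the per-tone amplitude in channel units
    (off by default throughout the pipeline).
    """
    if amplitude == 0:
        return ch
    rng = np.random.default_rng(seed)
    t = ch.times[None, :]
    out = ch.samples.copy()
    n_elem = out.shape[0]
    for h in harmonics:
        f0 = h * fus_fc
        if f0 >= ch.sampling_rate / 2:
            continue
        phase = rng.uniform(0, 2 * np.pi, n_elem)[:, None]
        out += amplitude * np.cos(2 * np.pi * f0 * t + phase)
    return ChannelData(out, ch.sampling_rate, ch.transmit, ch.t0)


def add_band_limited_noise(
    ch: ChannelData,
    snr_db: float | None = 30.0,
    band: tuple[float, float] = (5.0, 12.0),
    seed: int | None = None,
    reference_power: float | None = None,
) -> ChannelData:
    """Add band-limited Gaussian noise at the given channel SNR.

    White Gaussian noise is band-pass filtered to ``band`` (MHz) and scaled
    so that the measured ``10 log10(P_signal / P_noise)`` over the full
    record equals ``snr_db`` exactly.  ``snr_db=None`` (or infinity) returns
    the input unchanged.  Reproducible given ``seed``.

    ``reference_power`` fixes the signal power the SNR refers to (the DAQ
    noise floor does not depend on the transmit sequence, so cross-sequence
    comparisons reference a common -- conventionally plane-wave -- event);
    when None, the power of ``ch`` itself is used.
    """
    if snr_db is None or np.isinf(snr_db):
        return ch
    p_signal = float(np.mean(ch.samples**2)) if reference_power is None \
        else float(reference_power)
    if p_signal <= 0:
        raise ValueError("cannot set an SNR on a zero-power signal")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(ch.samples.shape)
    nyq = ch.sampling_rate / 2
    b, a = butter(4, [band[0] / nyq, band[1] / nyq], btype="bandpass")
    noise = filtfilt(b, a, noise, axis=1)
    p_noise = np.mean(noise**2)
    noise *= np.sqrt(p_signal / (10 ** (snr_db / 10)) / p_noise)
    return ChannelData(ch.samples + noise, ch.sampling_rate, ch.transmit, ch.t0)
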