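"""Harmonic displacement estimation from beamformed RF frames.

The chain mirrors standard HMI post-processing:

1. second-order Butterworth notch filters suppress the FUS fundamental and
   harmonics (4.5 / 9 / 13.5 MHz) in the RF lines;
2. interframe axial displacements are estimated per line with 1-D normalized
   cross-correlation (window 4 lambda = 0.79 mm, 95% overlap) and refined to
   subsample precision with cosine interpolation of the correlation peak;
3. interframe estimates are accumulated into cumulative traces, band-pass
   filtered around the AM frequency with a zero-phase 48th-order FIR, and
   reduced to the mean peak-to-peak (P2P) displacement over complete AM
   cycles.

Zero-variance correlation windows yield NaN estimates (flagged, never a
silent 0) and are excluded from P2P statistics downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import numba as nb
from scipy.signal import filtfilt, firwin, iirnotch

from .geometry import SPEED_OF_SOUND
from .beamform import RFFrame

__all__ = [
    "NCC_WINDOW_MM",
    "NCC_OVERLAP",
    "InterframeDisplacement",
    "HarmonicTrace",
    "notch_filter_fus",
    "ncc_displacement",
    "cosine_subsample",
    "extract_harmonic",
    "track_interframe",
    "p2p_patch",
]

#: Tracking window: 4 wavelengths at the 7.8-MHz imaging frequency (mm).
NCC_WINDOW_MM = 4 * SPEED_OF_SOUND / 7.8
NCC_OVERLAP = 0.95


@dataclass
class InterframeDisplacement:
    """Per-window interframe axial displacement estimates.

    ``values`` has shape (n_pairs, n_lines, n_windows) in micrometers; NaN
    marks windows where the estimate is undefined (zero variance).
    """

    values: np.ndarray
    window_length: float  # mm
    window_overlap: float
    frame_rate: float  # Hz
    lines: np.ndarray  # mm
    depth_centers: np.ndarray  # mm


@dataclass
class HarmonicTrace:
    """Cumulative and AM-band filtered displacement for one location."""

    cumulative: np.ndarray  # um
    filtered: np.ndarray  # um
    p2p: float  # um


def notch_filter_fus(
    frame: RFFrame,
    fus_fc: float = 4.5,
    harmonics: tuple[int, ...] = (1, 2, 3),
    bw: float = 0.5,
    imaging_fc: float = 7.8,
) -> RFFrame:
    """Suppress FUS interference tones in the RF lines (zero-phase notches).

    One second-order notch per requested harmonic of ``fus_fc`` (MHz);
    centers at or above the Nyquist of the stored rate are skipped.  The
    notch bandwidth must stay clear of the imaging center frequency.  The
    0.5-MHz default width matters on short records: a tone windowed to a
    few microseconds spreads spectrally by ~1/T, so narrower notches leak
    interference even though the tone itself is a spectral line.
    """
    fs = frame.sampling_rate
    out = frame.samples.copy()
    for h in harmonics:
        f0 = h * fus_fc
        if f0 >= fs / 2:
            continue
        if bw >= abs(f0 - imaging_fc):
            raise ValueError(
                f"notch bandwidth {bw} MHz reaches the imaging center "
                f"frequency from the {f0}-MHz notch"
            )
        b, a = iirnotch(f0, f0 / bw, fs=fs)
        out = filtfilt(b, a, out, axis=1)
    return RFFrame(frame.lines.copy(), frame.depths.copy(), out,
                   frame.sampling_rate, frame.frame_time)


def cosine_subsample(y_minus: float, y_zero: float, y_plus: float) -> float:
    """Fractional lag of the correlation peak from three samples around it.

    Fits ``cos(w (t - d))`` through the samples at t = -1, 0, +1 and returns
    ``d`` in (-0.5, 0.5).  Exact for pure cosines.  Falls back to parabolic
    interpolation (with a warning) when the cosine fit is infeasible.
    """
    if y_zero <= 0 or y_zero < max(y_minus, y_plus):
        raise ValueError("y_zero must be the positive maximum of the triplet")
    arg = (y_minus + y_plus) / (2.0 * y_zero)
    if not -1.0 < arg < 1.0:
        warnings.warn("cosine fit infeasible; using parabolic interpolation",
                      stacklevel=2)
        denom = y_minus - 2.0 * y_zero + y_plus
        if denom == 0:
            return 0.0
        d = 0.5 * (y_minus - y_plus) / denom
        return float(np.clip(d, -0.5, 0.5))
    w = np.arccos(arg)
    theta = np.arctan2(y_minus - y_plus, 2.0 * y_zero * np.sin(w))
    return float(np.clip(-theta / w, -0.5, 0.5))


@nb.njit(cache=True, fastmath=True)
def _ncc_lines(ref, cmp, starts, wlen, maxlag):  # pragma: no cover
    """NCC shifts (samples, NaN if undefined) for one line pair."""
    n = ref.shape[0]
    W = starts.shape[0]
    shifts = np.empty(W)
    nl = 2 * maxlag + 1
    rho = np.empty(nl)
    for wi in range(W):
        s = starts[wi]
        e_ref = 0.0
        for i in range(s, s + wlen):
            e_ref += ref[i] * ref[i]
        if e_ref <= 0.0:
            shifts[wi] = np.nan
            continue
        best = -2.0
        besti = 0
        any_var = False
        for il in range(nl):
            lag = il - maxlag
            lo = s + lag
            if lo < 0 or lo + wlen > n:
                rho[il] = -2.0
                continue
            num = 0.0
            e_cmp = 0.0
            for i in range(wlen):
                a = ref[s + i]
                b = cmp[lo + i]
                num += a * b
                e_cmp += b * b
            if e_cmp <= 0.0:
                rho[il] = -2.0
                continue
            any_var = True
            rho[il] = num / np.sqrt(e_ref * e_cmp)
        if not any_var:
            shifts[wi] = np.nan
            continue
        # integer peak, ties broken toward zero lag
        for dist in range(maxlag + 1):
            il = maxlag - dist
            if rho[il] > best:
                best = rho[il]
                besti = il
            if dist > 0:
                il = maxlag + dist
                if rho[il] > best:
                    best = rho[il]
                    besti = il
        delta = 0.0
        if best >= 1.0 - 1e-9:
            pass  # bit-exact match: integer shift, no subsample refinement
        elif 0 < besti < nl - 1 and rho[besti - 1] > -2.0 \
                and rho[besti + 1] > -2.0 and best > 0.0:
            ym, y0, yp = rho[besti - 1], best, rho[besti + 1]
            arg = (ym + yp) / (2.0 * y0)
            if -1.0 < arg < 1.0:
                w = np.arccos(arg)
                theta = np.arctan2(ym - yp, 2.0 * y0 * np.sin(w))
                delta = -theta / w
            else:
                denom = ym - 2.0 * y0 + yp
                if denom != 0.0:
                    delta = 0.5 * (ym - yp) / denom
            if delta > 0.5:
                delta = 0.5
            elif delta < -0.5:
                delta = -0.5
        shifts[wi] = (besti - maxlag) + delta
    return shifts


def _window_grid(n_samples: int, wlen: int, step: int, maxlag: int):
    starts = np.arange(maxlag, n_samples - wlen - maxlag + 1, step)
    if len(starts) == 0:
        raise ValueError("RF line too short for the tracking window and lag range")
    return starts


def ncc_displacement(
    ref: np.ndarray,
    cmp: np.ndarray,
    window: float = NCC_WINDOW_MM,
    overlap: float = NCC_OVERLAP,
    fs: float = 124.8,
    c: float = SPEED_OF_SOUND,
    max_lag: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """1-D NCC interframe displacement for a single RF line pair.

    ``ref``/``cmp`` are depth series sampled at ``fs`` (MHz, the upsampled
    rate), so one sample corresponds to c / (2 fs) of axial displacement.
    Returns ``(shifts_um, window_center_indices)``; NaN marks windows with
    zero variance.  The lag search spans +/- a quarter window, ties at the
    integer peak break toward zero lag.
    """
    ref = np.asarray(ref, dtype=float)
    cmp = np.asarray(cmp, dtype=float)
    if ref.shape != cmp.shape or ref.ndim != 1:
        raise ValueError("ref and cmp must be 1-D arrays of equal length")
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    pitch_um = c / (2 * fs) * 1e3  # um per sample
    wlen = max(2, int(round(window / (pitch_um * 1e-3))))
    if max_lag is None:
        max_lag = max(1, wlen // 4)
    step = max(1, int(round(wlen * (1 - overlap))))
    starts = _window_grid(len(ref), wlen, step, max_lag)
    shifts = _ncc_lines(ref, cmp, starts, wlen, max_lag)
    return shifts * pitch_um, starts + wlen // 2


def track_interframe(
    frames: list[RFFrame],
    frame_rate: float,
    window: float = NCC_WINDOW_MM,
    overlap: float = NCC_OVERLAP,
    c: float = SPEED_OF_SOUND,
    max_lag: int | None = None,
) -> InterframeDisplacement:
    """NCC tracking of consecutive frame pairs for every line."""
    if len(frames) < 2:
        raise ValueError("need at least two frames to track")
    f0 = frames[0]
    fs = f0.sampling_rate
    pitch_um = c / (2 * fs) * 1e3
    wlen = max(2, int(round(window / (pitch_um * 1e-3))))
    if max_lag is None:
        max_lag = max(1, wlen // 4)
    step = max(1, int(round(wlen * (1 - overlap))))
    starts = _window_grid(len(f0.depths), wlen, step, max_lag)
    n_lines = len(f0.lines)
    out = np.empty((len(frames) - 1, n_lines, len(starts)))
    for p in range(len(frames) - 1):
        a, b = frames[p], frames[p + 1]
        for li in range(n_lines):
            out[p, li] = _ncc_lines(a.samples[li], b.samples[li], starts,
                                    wlen, max_lag)
    return InterframeDisplacement(
        out * pitch_um, window, overlap, frame_rate,
        f0.lines.copy(), f0.depths[starts + wlen // 2],
    )


def _bandpass_taps(f_am: float, frame_rate: float, fir_order: int, n: int):
    ntaps = fir_order + 1
    if ntaps % 2 == 0:
        ntaps += 1
    if ntaps > n - 1:
        ntaps = max(5, (n - 2) | 1)
        warnings.warn(
            f"trace of {n} samples too short for a {fir_order}th-order FIR; "
            f"using {ntaps - 1}th order", stacklevel=3,
        )
    h = firwin(ntaps, [0.75 * f_am, 1.25 * f_am], pass_zero=False,
               fs=frame_rate)
    # normalize so the forward-backward (squared) response is unity at f_am
    k = np.arange(ntaps)
    resp = np.abs(np.sum(h * np.exp(-2j * np.pi * f_am / frame_rate * k)))
    return h / resp


def _zero_phase_bandpass(x: np.ndarray, taps: np.ndarray, frame_rate: float,
                         f_am: float, axis: int = -1) -> np.ndarray:
    """Apply the FIR band-pass with zero phase (magnitude-squared response).

    The trace is first detrended by jointly fitting an affine trend plus a
    sinusoid at ``f_am`` and subtracting only the trend part (a plain linear
    fit is biased by the oscillation itself and its residual ramp would leak
    into the passband).  The detrended trace is then filtered circularly in
    the frequency domain with ``|H(f)|^2``, the forward-backward response of
    the linear-phase FIR.  Circular application avoids the edge transients a
    49-tap kernel would smear across the short cumulative traces; the
    tracking trains hold an integer number of AM cycles, so wrap-around
    seams are negligible after detrending.
    """
    x = np.asarray(x, dtype=float)
    x = np.moveaxis(x, axis, -1)
    n = x.shape[-1]
    t = np.arange(n) / frame_rate
    A = np.column_stack([np.ones(n), t,
                         np.sin(2 * np.pi * f_am * t),
                         np.cos(2 * np.pi * f_am * t)])
    coef, *_ = np.linalg.lstsq(A, x.reshape(-1, n).T, rcond=None)
    trend = (A[:, :2] @ coef[:2]).T.reshape(x.shape)
    x = np.moveaxis(x - trend, -1, axis)
    n = x.shape[axis]
    freqs = np.fft.rfftfreq(n, d=1.0 / frame_rate)
    m = np.arange(len(taps))
    H = np.abs(np.exp(-2j * np.pi * np.outer(freqs / frame_rate, m)) @ taps) ** 2
    X = np.fft.rfft(x, axis=axis)
    shape = [1] * x.ndim
    shape[axis] = len(freqs)
    return np.fft.irfft(X * H.reshape(shape), n=n, axis=axis)


def _p2p_per_cycle(filtered: np.ndarray, f_am: float, frame_rate: float,
                   upsample: int = 8):
    """Mean peak-to-peak over complete AM cycles along the last axis.

    The band-limited trace is upsampled (FFT resampling, matching the
    circular filtering) before taking per-cycle extrema so the peak-to-peak
    value does not depend on where the tracking frames fall within the AM
    cycle.
    """
    from scipy.signal import resample

    n = filtered.shape[-1]
    period = frame_rate / f_am
    m = int(n / period + 1e-9)
    if m < 1:
        raise ValueError("trace shorter than one AM cycle")
    if upsample > 1:
        filtered = resample(filtered, n * upsample, axis=-1)
        period *= upsample
    edges = np.round(np.arange(m + 1) * period).astype(int)
    p2ps = [
        filtered[..., lo:hi].max(axis=-1) - filtered[..., lo:hi].min(axis=-1)
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    return np.mean(p2ps, axis=0)


def extract_harmonic(
    interframe: np.ndarray,
    f_am: float,
    frame_rate: float,
    fir_order: int = 48,
) -> HarmonicTrace:
    """Harmonic P2P displacement from a 1-D interframe displacement trace.

    The interframe estimates are accumulated (cumulative sum, starting from
    rest), band-pass filtered around ``f_am`` (0.75-1.25 x, linear-phase FIR
    applied with zero phase), and summarized as the mean peak-to-peak
    amplitude over complete AM cycles.  Requires at least two complete
    cycles; shorter traces are rejected with the needed minimum.
    """
    interframe = np.asarray(interframe, dtype=float)
    if interframe.ndim != 1:
        raise ValueError("expected a 1-D interframe displacement trace")
    cumulative = np.concatenate([[0.0], np.cumsum(interframe)])
    n = len(cumulative)
    min_n = int(np.ceil(2 * frame_rate / f_am))
    if n < min_n:
        raise ValueError(
            f"trace of {n} samples covers fewer than 2 AM cycles; "
            f"need at least {min_n}"
        )
    taps = _bandpass_taps(f_am, frame_rate, fir_order, n)
    filtered = _zero_phase_bandpass(cumulative, taps, frame_rate, f_am)
    p2p = float(_p2p_per_cycle(filtered, f_am, frame_rate))
    return HarmonicTrace(cumulative, filtered, p2p)


def p2p_patch(
    frames: list[RFFrame],
    f_am: float,
    frame_rate: float,
    fir_order: int = 48,
    notch: bool = True,
    window: float = NCC_WINDOW_MM,
    overlap: float = NCC_OVERLAP,
    max_lag: int | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full per-patch chain: notch -> NCC -> cumulative -> FIR -> P2P.

    Returns ``(p2p, lines, depth_centers)`` where ``p2p`` has shape
    (n_lines, n_windows) in micrometers with NaN where tracking failed.
    """
    if notch:
        frames = [notch_filter_fus(f) for f in frames]
    disp = track_interframe(frames, frame_rate, window, overlap,
                            max_lag=max_lag)
    inter = disp.values  # (n_pairs, n_lines, n_windows)
    cumulative = np.concatenate(
        [np.zeros((1,) + inter.shape[1:]), np.cumsum(inter, axis=0)], axis=0
    )
    n = cumulative.shape[0]
    min_n = int(np.ceil(2 * frame_rate / f_am))
    if n < min_n:
        raise ValueError(f"need at least {min_n} frames for 2 AM cycles")
    bad = ~np.all(np.isfinite(cumulative), axis=0)  # (n_lines, n_windows)
    cumulative[:, bad] = 0.0
    taps = _bandpass_taps(f_am, frame_rate, fir_order, n)
    filtered = _zero_phase_bandpass(cumulative, taps, frame_rate, f_am, axis=0)
    p2p = _p2p_per_cycle(np.moveaxis(filtered, 0, -1), f_am, frame_rate)
    p2p[bad] = np.nan
    return p2p, disp.lines, disp.depth_centers
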