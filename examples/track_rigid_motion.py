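"""Recover an imposed harmonic motion through the full tracking chain.

A speckle phantom oscillates rigidly with 5-um amplitude at 200 Hz; RF
channel data is synthesized per frame (2-kHz frame rate, 30-dB channel
noise), beamformed, and run through the displacement-estimation chain
(notch filters -> NCC -> AM-band FIR -> peak-to-peak).  The recovered P2P
should be 10 um.
"""

import numpy as np

from harmotrack import (SPEED_OF_SOUND, PulseModel, ScattererField,
                        add_band_limited_noise, build_imaging_array,
                        das_beamform, generate_scatterers, make_transmits,
                        p2p_patch, synthesize_channel_data)

array = build_imaging_array()
pulse = PulseModel()
tx = make_transmits("pw").transmits[0]
scat = generate_scatterers(((-1.5, 1.5), (-0.4, 0.4), (28.5, 33.5)), seed=11)

fs = 31.2
lines = (np.arange(13) - 6) * array.wavelength / 2
depths = np.arange(29.4, 32.6, SPEED_OF_SOUND / (2 * 4 * fs))
t0 = 2 * 27.0 / SPEED_OF_SOUND
n_samp = int(np.ceil((2 * 35.5 / SPEED_OF_SOUND + 1 - t0) * fs))

frames = []
for k in range(60):  # 30 ms at 2 kHz
    u = 5.0 * np.sin(2 * np.pi * 200.0 * k / 2000.0)  # um
    pos = scat.positions.copy()
    pos[:, 2] += u * 1e-3
    ch = synthesize_channel_data(ScattererField(pos, scat.amplitudes), array,
                                 tx, pulse, fs, t0=t0, n_samples=n_samp)
    ch = add_band_limited_noise(ch, 30.0, seed=500 + k)
    frames.append(das_beamform(ch, lines, depths, array=array))

p2p, _, _ = p2p_patch(frames, 200.0, 2000.0)
print(f"median P2P displacement: {np.nanmedian(p2p):.3f} um (expected 10.0)")
print(f"P2P spread across the patch: {np.nanstd(p2p):.3f} um")
print("The chain recovers the imposed 10-um peak-to-peak motion; the spread")
print("is speckle/noise-induced estimation jitter.")
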