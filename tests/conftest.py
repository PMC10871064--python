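"""Shared fixtures: geometry objects and a few pre-simulated RF frame sets."""

from __future__ import annotations

import numpy as np
import pytest

from harmotrack.geometry import SPEED_OF_SOUND, build_imaging_array
from harmotrack.mechanics import ScattererField, generate_scatterers
from harmotrack.rf import PulseModel, add_band_limited_noise, \
    synthesize_channel_data
from harmotrack.beamform import UPSAMPLE, das_beamform
from harmotrack.sequences import make_transmits

FS_MHZ = 31.2
FS_UP = FS_MHZ * UPSAMPLE
DEPTH_PITCH_MM = SPEED_OF_SOUND / (2 * FS_UP)


def exhaustive_permutation_pvalue(table):
    """Independent Friedman oracle: enumerate all within-row permutations;
    the statistic for each comes from scipy's implementation."""
    import itertools
    from scipy import stats as sps

    obs = sps.friedmanchisquare(*table.T).statistic
    n, k = table.shape
    perms = list(itertools.permutations(range(k)))
    count = total = 0
    for assign in itertools.product(perms, repeat=n):
        permuted = np.vstack([table[i, list(p)] for i, p in enumerate(assign)])
        total += 1
        if sps.friedmanchisquare(*permuted.T).statistic >= obs - 1e-12:
            count += 1
    return count / total


@pytest.fixture(scope="session")
def array():
    return build_imaging_array()


@pytest.fixture(scope="session")
def pulse():
    return PulseModel()


@pytest.fixture(scope="session")
def pw_transmit():
    return make_transmits("pw").transmits[0]


def beamform_speckle_frames(
    scat: ScattererField,
    displacements_um,
    array,
    pulse,
    tx=None,
    lines=None,
    snr_db=30.0,
    seed0=500,
):
    """Synthesize + beamform one frame per rigid axial displacement (um)."""
    tx = tx or make_transmits("pw").transmits[0]
    if lines is None:
        lines = (np.arange(13) - 6) * (SPEED_OF_SOUND / 7.8 / 2)
    depths = np.arange(31.0 - 1.6, 31.0 + 1.6, DEPTH_PITCH_MM)
    t0 = 2 * 27.0 / SPEED_OF_SOUND
    n = int(np.ceil((2 * 35.5 / SPEED_OF_SOUND + 1 - t0) * FS_MHZ))
    frames = []
    for k, u in enumerate(displacements_um):
        pos = scat.positions.copy()
        pos[:, 2] += u * 1e-3
        ch = synthesize_channel_data(ScattererField(pos, scat.amplitudes),
                                     array, tx, pulse, FS_MHZ,
                                     t0=t0, n_samples=n)
        if snr_db is not None:
            ch = add_band_limited_noise(ch, snr_db, seed=seed0 + k)
        frames.append(das_beamform(ch, lines, depths, array=array))
    return frames


@pytest.fixture(scope="session")
def speckle():
    """A modest speckle field around the focus."""
    return generate_scatterers(((-1.5, 1.5), (-0.4, 0.4), (28.5, 33.5)),
                               seed=11)


@pytest.fixture(scope="session")
def rigid_sine_frames(speckle, array, pulse):
    """60 frames (6 cycles of 200-Hz AM at 2 kHz) of rigid 5-um sinusoidal
    motion with 30-dB channel noise -- the imposed-motion oracle."""
    t = np.arange(60) / 2000.0
    u = 5.0 * np.sin(2 * np.pi * 200.0 * t)
    return beamform_speckle_frames(speckle, u, array, pulse)


@pytest.fixture(scope="session")
def static_frame_pair(speckle, array, pulse):
    """Two frames of the same static speckle, independent 30-dB noise."""
    return beamform_speckle_frames(speckle, [0.0, 0.0], array, pulse,
                                   seed0=900)
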