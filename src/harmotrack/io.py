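"""HDF5 persistence for simulation products (chunked arrays with metadata).

Channel data, displacement fields, scatterer fields and HMI maps round-trip
through a single HDF5 container; axis coordinates and units travel as
attributes/datasets alongside the arrays.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .beamform import RFFrame
from .geometry import IntensityField, PressureField
from .mechanics import DisplacementField, ScattererField
from .metrics import HMIMap
from .rf import ChannelData
from .sequences import TransmitSpec

__all__ = [
    "save_channel_data", "load_channel_data",
    "save_displacement_field", "load_displacement_field",
    "save_scatterers", "load_scatterers",
    "save_map", "load_map",
    "save_frames", "load_frames",
    "save_field", "load_field",
]

_CHUNK = True  # h5py auto-chunking


def _tx_to_json(tx: TransmitSpec) -> str:
    return json.dumps({
        "mode": tx.mode, "steer_angle": tx.steer_angle,
        "focus_depth": tx.focus_depth, "tx_fnumber": tx.tx_fnumber,
        "active_aperture": tx.active_aperture,
        "lateral_offset": tx.lateral_offset,
    })


def _tx_from_json(s: str) -> TransmitSpec:
    return TransmitSpec(**json.loads(s))


def save_channel_data(path, ch: ChannelData, group: str = "channel_data"):
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        d = g.create_dataset("samples", data=ch.samples, chunks=_CHUNK)
        d.attrs["units"] = "arbitrary"
        g.attrs["sampling_rate_MHz"] = ch.sampling_rate
        g.attrs["t0_us"] = ch.t0
        g.attrs["transmit"] = _tx_to_json(ch.transmit)


def load_channel_data(path, group: str = "channel_data") -> ChannelData:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        return ChannelData(g["samples"][()], float(g.attrs["sampling_rate_MHz"]),
                           _tx_from_json(g.attrs["transmit"]),
                           float(g.attrs["t0_us"]))


def save_displacement_field(path, disp: DisplacementField,
                            group: str = "displacement"):
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("u_um", data=disp.u, chunks=_CHUNK)
        g.create_dataset("x_mm", data=disp.x)
        g.create_dataset("z_mm", data=disp.z)
        g.create_dataset("times_us", data=disp.times_us)


def load_displacement_field(path, group: str = "displacement") -> DisplacementField:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        return DisplacementField(g["x_mm"][()], g["z_mm"][()],
                                 g["times_us"][()], g["u_um"][()])


def save_scatterers(path, scat: ScattererField, group: str = "scatterers"):
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("positions_mm", data=scat.positions, chunks=_CHUNK)
        g.create_dataset("amplitudes", data=scat.amplitudes)
        g.attrs["seed"] = -1 if scat.seed is None else int(scat.seed)


def load_scatterers(path, group: str = "scatterers") -> ScattererField:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        seed = int(g.attrs["seed"])
        return ScattererField(g["positions_mm"][()], g["amplitudes"][()],
                              None if seed < 0 else seed)


def save_map(path, hmi: HMIMap, group: str = "hmi_map"):
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("values", data=hmi.values, chunks=_CHUNK)
        g.create_dataset("x_mm", data=hmi.x)
        g.create_dataset("z_mm", data=hmi.z)
        g.attrs["normalized"] = bool(hmi.normalized)
        g.attrs["provenance"] = json.dumps(hmi.provenance)


def load_map(path, group: str = "hmi_map") -> HMIMap:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        return HMIMap(g["x_mm"][()], g["z_mm"][()], g["values"][()],
                      bool(g.attrs["normalized"]),
                      json.loads(g.attrs["provenance"]))


def save_field(path, field: PressureField | IntensityField,
               group: str = "field"):
    """Persist a pressure (complex) or intensity (real) field with axes."""
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("values", data=field.values, chunks=_CHUNK)
        g.attrs["kind"] = ("pressure" if np.iscomplexobj(field.values)
                           else "intensity")
        g.attrs["axes"] = list(field.axes)
        g.attrs["frequency_MHz"] = field.frequency
        g.attrs["units"] = "mm"
        for name, coord in zip(field.axes, field.coords):
            g.create_dataset(f"coord_{name}", data=coord)


def load_field(path, group: str = "field"):
    with h5py.File(path, "r") as fh:
        g = fh[group]
        axes = tuple(str(a) for a in g.attrs["axes"])
        coords = tuple(g[f"coord_{a}"][()] for a in axes)
        values = g["values"][()]
        freq = float(g.attrs["frequency_MHz"])
        if g.attrs["kind"] == "pressure":
            return PressureField(axes, coords, values, freq)
        return IntensityField(axes, coords, values, freq)


def save_frames(path, frames: list[RFFrame], group: str = "rf_frames"):
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("samples", data=np.stack([f.samples for f in frames]),
                         chunks=_CHUNK)
        g.create_dataset("lines_mm", data=frames[0].lines)
        g.create_dataset("depths_mm", data=frames[0].depths)
        g.create_dataset("frame_times_us",
                         data=np.array([f.frame_time for f in frames]))
        g.attrs["sampling_rate_MHz"] = frames[0].sampling_rate


def load_frames(path, group: str = "rf_frames") -> list[RFFrame]:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        samples = g["samples"][()]
        lines = g["lines_mm"][()]
        depths = g["depths_mm"][()]
        times = g["frame_times_us"][()]
        fs = float(g.attrs["sampling_rate_MHz"])
        return [RFFrame(lines.copy(), depths.copy(), s, fs, float(t))
                for s, t in zip(samples, times)]
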