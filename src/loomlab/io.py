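"""File formats: TIFF movies with JSON sidecars, event CSV, SWC morphology,
HDF5 simulation results, JSON energy reports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .imaging import FluorMovie, Timeline
from .neuron_model import Morphology, SimResult
from .stimulus import StimulusMovie

_SWC_REGION_CODE = {"trunk": 5, "SIZ": 6, "axon": 2, "A": 3, "B": 4, "C": 7}
_SWC_CODE_REGION = {v: k for k, v in _SWC_REGION_CODE.items()}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_stimulus_movie(movie: StimulusMovie, path) -> None:
    """Write a luminance movie as 16-bit multi-frame TIFF + JSON sidecar."""
    path = Path(path)
    data = np.clip(movie.frames, 0.0, 1.0)
    tifffile.imwrite(path, (data * 65535).astype(np.uint16))
    meta = {"frame_rate": movie.frame_rate, "pixel_pitch": movie.pixel_pitch,
            "t_start": movie.t_start, "luminance_scale": 65535,
            "coarse_pixel_deg": movie.coarse_pixel_deg}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_stimulus_movie(path) -> StimulusMovie:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    frames = tifffile.imread(path).astype(np.float32)
    frames /= meta.get("luminance_scale", 65535)
    return StimulusMovie(frames, meta["frame_rate"], meta["pixel_pitch"],
                         t_start=meta.get("t_start", 0.0),
                         coarse_pixel_deg=meta.get("coarse_pixel_deg"))


def save_fluor_movie(movie: FluorMovie, path) -> None:
    """Write a fluorescence stack as TIFF (float32) + JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    meta = {"frame_rate": movie.frame_rate, "pixel_size": movie.pixel_size}
    if movie.timeline is not None:
        meta["timeline"] = {"stim_start": movie.timeline.stim_start,
                            "stim_end": movie.timeline.stim_end,
                            "flash_time": movie.timeline.flash_time}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def load_fluor_movie(path) -> FluorMovie:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    tl = meta.get("timeline")
    timeline = Timeline(**tl) if tl else None
    return FluorMovie(tifffile.imread(path).astype(np.float64),
                      frame_rate=meta["frame_rate"],
                      pixel_size=meta["pixel_size"], timeline=timeline)


def save_morphology_swc(morph: Morphology, path) -> None:
    """SWC-style text with an extra region-label column."""
    lines = ["# id type x y z radius parent region"]
    for i in range(morph.n):
        x, y, z = morph.position[i]
        lines.append(
            f"{i + 1} {_SWC_REGION_CODE[morph.region[i]]} "
            f"{x:.2f} {y:.2f} {z:.2f} {morph.diam[i] / 2:.3f} "
            f"{morph.parent[i] + 1 if morph.parent[i] >= 0 else -1} "
            f"{morph.region[i]}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_morphology_swc(path, cm: float = 1.0, g_leak: float = 1.25e-4,
                        e_leak: float = -66.0,
                        axial_resistivity: float = 60.0,
                        compartment_length: float = 20.0) -> Morphology:
    """Read an SWC-style file written by :func:`save_morphology_swc`.

    SWC stores point radii, not cylinder lengths; compartment lengths are
    the distance to the parent point (``compartment_length`` at the root).
    """
    ids, parents, regions, pos, radii = [], [], [], [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        ids.append(int(parts[0]))
        regions.append(parts[7] if len(parts) > 7
                       else _SWC_CODE_REGION.get(int(parts[1]), "trunk"))
        pos.append([float(parts[2]), float(parts[3]), float(parts[4])])
        radii.append(float(parts[5]))
        parents.append(int(parts[6]))
    order = np.argsort(ids)
    remap = {ids[i]: rank for rank, i in enumerate(order)}
    pos = np.asarray(pos)[order]
    parent = np.asarray([remap.get(parents[i], -1) if parents[i] > 0 else -1
                         for i in order], dtype=np.int64)
    length = np.full(parent.size, compartment_length)
    has_par = parent >= 0
    length[has_par] = np.linalg.norm(pos[has_par] - pos[parent[has_par]],
                                     axis=1)
    length[length <= 0] = compartment_length
    m = Morphology(parent=parent, length=length,
                   diam=2.0 * np.asarray(radii)[order],
                   region=np.asarray(regions, dtype=object)[order],
                   position=pos,
                   axial_resistivity=np.full(parent.size, axial_resistivity),
                   cm=cm, g_leak=g_leak, e_leak=e_leak)
    m.validate()
    return m


def save_sim_result(result: SimResult, path) -> None:
    """HDF5 with Vm traces plus spike times and run metadata."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("t_s", data=result.t_s)
        fh.create_dataset("vm_mv", data=result.vm_mv)
        fh.create_dataset("rec_comps", data=result.rec_comps)
        fh.create_dataset("spike_times_s", data=result.spike_times_s)
        fh.attrs["total_excitatory_charge_nc"] = \
            result.total_excitatory_charge_nc
        fh.attrs["dt_ms"] = result.dt_ms


def load_sim_result(path) -> SimResult:
    with h5py.File(path, "r") as fh:
        return SimResult(
            t_s=fh["t_s"][:], vm_mv=fh["vm_mv"][:],
            rec_comps=fh["rec_comps"][:],
            spike_times_s=fh["spike_times_s"][:],
            total_excitatory_charge_nc=float(
                fh.attrs["total_excitatory_charge_nc"]),
            dt_ms=float(fh.attrs["dt_ms"]))


def save_energy_report(report, path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))
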