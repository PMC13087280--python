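"""HDF5 container for paired RF/B-mode samples and parametric maps.

Layout per sample file: ``/rf`` (float32), ``/bmode`` (uint8), ``/roi``
(uint8 mask), attributes ``sampling_rate_mhz``, ``speed_of_sound_mps``,
``lateral_pitch_mm``, ``provenance``, ``class_label`` and a JSON-serialized
``scene_ground_truth``. A raw ``.bin`` + JSON sidecar dialect is
read-compatible.
"""

from __future__ import annotations

import json
import os
from typing import Optional

import h5py
import numpy as np

from .qus import MAP_NAMES, ParametricMapSet
from .types import BModeImage, RFFrame

__all__ = ["save_sample", "load_sample", "save_maps", "load_maps"]


def _scene_ground_truth(sample) -> dict:
    scene = sample.scene
    return {
        "class_label": sample.class_label,
        "lesion_id": sample.lesion_id,
        "plane_id": sample.plane_id,
        "roi_geometry_mm": list(sample.roi_geometry),
        "seed": scene.seed,
        "regions": [
            {"a_eff_um": r.a_eff_um, "density_per_mm2": r.density_per_mm2,
             "amplitude_variance": r.amplitude_variance,
             "attenuation_db_mhz_cm": r.attenuation_db_mhz_cm,
             "geometry": list(r.geometry) if r.geometry else None}
            for r in scene.regions],
    }


def save_sample(path: str, rf: RFFrame, bmode: Optional[BModeImage] = None,
                roi: Optional[np.ndarray] = None,
                class_label: Optional[str] = None,
                ground_truth: Optional[dict] = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rf", data=rf.samples.astype(np.float32))
        if bmode is not None:
            f.create_dataset("bmode",
                             data=np.round(bmode.pixels * 255).astype(np.uint8))
            f.attrs["bmode_dynamic_range_db"] = bmode.dynamic_range_db
        if roi is not None:
            f.create_dataset("roi", data=roi.astype(np.uint8))
        f.attrs["sampling_rate_mhz"] = rf.sampling_rate_mhz
        f.attrs["speed_of_sound_mps"] = rf.speed_of_sound_mps
        f.attrs["lateral_pitch_mm"] = rf.lateral_pitch_mm
        f.attrs["provenance"] = rf.provenance
        if class_label is not None:
            f.attrs["class_label"] = class_label
        if ground_truth is not None:
            f.attrs["scene_ground_truth"] = json.dumps(ground_truth)
        if rf.calibration:
            f.attrs["calibration"] = json.dumps(rf.calibration)


def load_sample(path: str):
    """Load a sample from HDF5 or from the raw binary + JSON sidecar dialect.

    Returns ``(RFFrame, bmode array or None, roi array or None, attrs)``.
    """
    if path.endswith(".bin"):
        return _load_raw_sidecar(path)
    with h5py.File(path, "r") as f:
        attrs = dict(f.attrs)
        rf = RFFrame(
            samples=f["rf"][()].astype(np.float64),
            sampling_rate_mhz=float(attrs["sampling_rate_mhz"]),
            speed_of_sound_mps=float(attrs["speed_of_sound_mps"]),
            lateral_pitch_mm=float(attrs["lateral_pitch_mm"]),
            provenance=str(attrs.get("provenance", "original")),
            calibration=json.loads(attrs["calibration"])
            if "calibration" in attrs else {})
        bmode = f["bmode"][()] / 255.0 if "bmode" in f else None
        roi = f["roi"][()].astype(bool) if "roi" in f else None
    if "scene_ground_truth" in attrs:
        attrs["scene_ground_truth"] = json.loads(attrs["scene_ground_truth"])
    return rf, bmode, roi, attrs


def _load_raw_sidecar(path: str):
    meta_path = os.path.splitext(path)[0] + ".json"
    with open(meta_path) as fh:
        meta = json.load(fh)
    data = np.fromfile(path, dtype=np.dtype(meta.get("dtype", "float32")))
    samples = data.reshape(meta["shape"])
    rf = RFFrame(samples=samples.astype(np.float64),
                 sampling_rate_mhz=meta["sampling_rate_mhz"],
                 speed_of_sound_mps=meta["speed_of_sound_mps"],
                 lateral_pitch_mm=meta["lateral_pitch_mm"],
                 provenance=meta.get("provenance", "original"),
                 calibration=meta.get("calibration", {}))
    return rf, None, None, meta


def save_maps(path: str, maps: ParametricMapSet) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("maps")
        for name in MAP_NAMES:
            g.create_dataset(name, data=maps.maps[name].astype(np.float32))
        g.create_dataset("valid", data=maps.valid.astype(np.uint8))
        g.create_dataset("region", data=maps.region.astype(np.int8))
        g.attrs["window_mm"] = maps.window_mm
        g.attrs["overlap"] = maps.overlap
        g.attrs["band_mhz"] = list(maps.band)
        if maps.ace is not None:
            g.attrs["ace_db_mhz_cm"] = maps.ace.ace_db_mhz_cm


def load_maps(path: str) -> ParametricMapSet:
    with h5py.File(path, "r") as f:
        g = f["maps"]
        maps = {name: g[name][()].astype(np.float64) for name in MAP_NAMES}
        mapset = ParametricMapSet(
            maps=maps, valid=g["valid"][()].astype(bool),
            region=g["region"][()],
            center_depth_cm=np.full(maps["MBF"].shape, np.nan),
            center_lateral_mm=np.full(maps["MBF"].shape, np.nan),
            window_mm=float(g.attrs["window_mm"]),
            overlap=float(g.attrs["overlap"]),
            band=tuple(g.attrs["band_mhz"]))
    return mapset
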