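"""Standard-format I/O: TIFF/OME-TIFF images, YAML stain/config files,
JSON transforms, CSV/GeoJSON object tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml
from shapely.geometry import mapping, shape

from .phenotype import DetectedObject, PathologyObject
from .registration import ChannelStack, Transform
from .stain import CalibratedImage, DensityMap, StainMatrix, StainVector

__all__ = [
    "read_rgb_tiff", "write_rgb_tiff",
    "read_density_tiff", "write_density_tiff",
    "write_stack_ome_tiff", "read_stack_ome_tiff",
    "load_stain_matrix", "save_stain_matrix",
    "save_transform", "load_transform",
    "objects_to_geojson",
]


def _resolution_tags(mpp: float) -> dict:
    # TIFF resolution is pixels per unit; store pixels-per-centimeter
    px_per_cm = 1e4 / mpp
    return {"resolution": (px_per_cm, px_per_cm), "resolutionunit": "CENTIMETER"}


def write_rgb_tiff(path: str | Path, img: CalibratedImage) -> None:
    data = np.asarray(img.pixels)
    if data.dtype not in (np.uint8, np.uint16):
        data = np.clip(np.rint(data), 0, 255).astype(np.uint8)
    tifffile.imwrite(
        path, data, photometric="rgb",
        metadata={"microns_per_pixel": img.microns_per_pixel,
                  "round_id": img.round_id},
        **_resolution_tags(img.microns_per_pixel),
    )


def read_rgb_tiff(path: str | Path, microns_per_pixel: float | None = None,
                  round_id: str = "") -> CalibratedImage:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if microns_per_pixel is None:
            meta = tf.shaped_metadata or tf.imagej_metadata
            if meta:
                m = meta[0] if isinstance(meta, (list, tuple)) else meta
                microns_per_pixel = m.get("microns_per_pixel")
                round_id = round_id or m.get("round_id", "")
    if microns_per_pixel is None:
        raise ValueError(f"{path}: no micron calibration found; pass microns_per_pixel")
    return CalibratedImage(data, float(microns_per_pixel), round_id,
                           modality="brightfield_rgb")


def write_density_tiff(path: str | Path, d: DensityMap) -> None:
    tifffile.imwrite(
        path, d.values.astype(np.float32),
        metadata={"microns_per_pixel": d.microns_per_pixel, "stain": d.stain},
        **_resolution_tags(d.microns_per_pixel),
    )


def read_density_tiff(path: str | Path,
                      microns_per_pixel: float | None = None) -> DensityMap:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata
        stain = ""
        if meta:
            m = meta[0]
            microns_per_pixel = microns_per_pixel or m.get("microns_per_pixel")
            stain = m.get("stain", "")
    if microns_per_pixel is None:
        raise ValueError(f"{path}: no micron calibration found")
    return DensityMap(data.astype(float), float(microns_per_pixel), stain)


def write_stack_ome_tiff(path: str | Path, stack: ChannelStack) -> None:
    """Multi-channel OME-TIFF with channel names in the OME metadata."""
    names = stack.channel_names
    data = np.stack([stack.channels[n] for n in names]).astype(np.float32)
    mpp = stack.microns_per_pixel
    tifffile.imwrite(
        path, data, ome=True,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": mpp, "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": mpp, "PhysicalSizeYUnit": "µm",
        },
    )
    # validity mask rides alongside (mask pixels are not OME channels)
    tifffile.imwrite(str(path) + ".validity.tif",
                     stack.validity.astype(np.uint8))


def read_stack_ome_tiff(path: str | Path) -> ChannelStack:
    import xml.etree.ElementTree as ET

    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        ome = tf.ome_metadata
    root = ET.fromstring(ome)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    channels = root.findall(".//ome:Channel", ns)
    names = [c.get("Name") for c in channels]
    pixels = root.find(".//ome:Pixels", ns)
    mpp = float(pixels.get("PhysicalSizeX", "1.0"))
    vpath = Path(str(path) + ".validity.tif")
    validity = (tifffile.imread(vpath).astype(bool) if vpath.exists()
                else np.ones(data.shape[-2:], dtype=bool))
    counterstain = "hematoxylin" if "hematoxylin" in names else names[-1]
    return ChannelStack({n: data[i].astype(float) for i, n in enumerate(names)},
                        mpp, validity, counterstain_name=counterstain)


def save_stain_matrix(path: str | Path, m: StainMatrix) -> None:
    payload = {"stains": [{"name": v.name, "od_rgb": list(v.od_rgb)}
                          for v in m.vectors]}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_stain_matrix(path: str | Path) -> StainMatrix:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return StainMatrix(tuple(
        StainVector.from_raw(s["name"], s["od_rgb"]) for s in payload["stains"]
    ))


def save_transform(path: str | Path, t: Transform) -> None:
    with open(path, "w") as fh:
        json.dump(t.to_dict(), fh, indent=2)
    if t.displacement_field is not None:
        tifffile.imwrite(str(path) + ".field.tif",
                         t.displacement_field.astype(np.float32))


def load_transform(path: str | Path) -> Transform:
    with open(path) as fh:
        t = Transform.from_dict(json.load(fh))
    fpath = Path(str(path) + ".field.tif")
    if fpath.exists():
        t.displacement_field = tifffile.imread(fpath).astype(float)
    return t


def objects_to_geojson(
    objects: Sequence[DetectedObject | PathologyObject]) -> dict:
    features = []
    for o in objects:
        props: dict = {"id": o.id}
        if isinstance(o, DetectedObject):
            props.update({"label": o.label, "area_um2": o.area_um2,
                          **{f"{m}_pos": bool(v) for m, v in o.marker_vector.items()}})
        else:
            props.update({"kind": o.kind, "area_um2": o.area_um2})
        features.append({"type": "Feature", "geometry": mapping(o.boundary),
                         "properties": props})
    return {"type": "FeatureCollection", "features": features}
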