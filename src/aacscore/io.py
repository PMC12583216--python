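"""Model checkpoints, 16-bit PNG working format, and DICOM ingest.

Checkpoints are ``.npz`` archives of named parameter arrays with a JSON
sidecar recording the model configuration, so a saved model can be rebuilt
and its weights restored exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .regression import CNNRegressor, RegressorConfig, build_regressor
from .segmentation import SegConfig, SegmenterModel, UNet

__all__ = [
    "save_segmenter",
    "load_segmenter",
    "save_regressor",
    "load_regressor",
    "read_image",
    "write_image_png16",
    "read_dicom",
]


def _tupled(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def save_segmenter(model: SegmenterModel, path: str | Path) -> Path:
    """Write a segmenter checkpoint (``<path>.npz`` + ``<path>.json``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for i, net in enumerate(model.nets):
        for k, v in net.state().items():
            arrays[f"net{i}/{k}"] = v
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"kind": "segmenter", "n_folds": len(model.nets),
               "config": dataclasses.asdict(model.config)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npz")


def load_segmenter(path: str | Path) -> SegmenterModel:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if sidecar.get("kind") != "segmenter":
        raise ValueError(f"{path} is not a segmenter checkpoint")
    config = SegConfig(**_tupled(sidecar["config"]))
    data = np.load(path.with_suffix(".npz"))
    nets = []
    for i in range(sidecar["n_folds"]):
        net = UNet(config, rng=np.random.default_rng(0))
        prefix = f"net{i}/"
        net.load_state({k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)})
        nets.append(net)
    return SegmenterModel(nets=nets, config=config)


def save_regressor(model: CNNRegressor, path: str | Path) -> Path:
    """Write a regressor checkpoint (``<path>.npz`` + ``<path>.json``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **model.state())
    sidecar = {"kind": "regressor", "config": dataclasses.asdict(model.config)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npz")


def load_regressor(path: str | Path) -> CNNRegressor:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if sidecar.get("kind") != "regressor":
        raise ValueError(f"{path} is not a regressor checkpoint")
    model = build_regressor(RegressorConfig(**_tupled(sidecar["config"])))
    data = np.load(path.with_suffix(".npz"))
    model.load_state({k: data[k] for k in data.files})
    return model


def write_image_png16(image: np.ndarray, path: str | Path) -> Path:
    """Write a float image in [0, 1] as 16-bit grayscale PNG."""
    path = Path(path)
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    iio.imwrite(path, (arr * 65535).round().astype(np.uint16))
    return path


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF (8 or 16 bit) or DICOM file as float32 in [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        return read_dicom(path)[0]
    arr = iio.imread(path)
    if arr.ndim == 3:  # RGB(A) -> luminance
        arr = arr[..., :3].mean(axis=-1)
    arr = arr.astype(np.float32)
    scale = 65535.0 if arr.max() > 255 else 255.0
    return arr / scale


def read_dicom(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a DICOM radiograph into the float [0, 1] working format.

    Returns ``(image, metadata)`` with pixel spacing (mm/pixel) and
    laterality when present.  MONOCHROME1 images are inverted so higher
    values always mean brighter (more attenuating) structures.
    """
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float32)
    lo, hi = float(arr.min()), float(arr.max())
    arr = (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        arr = 1.0 - arr
    meta: dict = {}
    spacing = getattr(ds, "ImagerPixelSpacing", None) or getattr(ds, "PixelSpacing", None)
    if spacing is not None:
        meta["pixel_spacing_mm"] = [float(s) for s in spacing]
    for tag in ("Laterality", "ImageLaterality", "PatientOrientation"):
        if getattr(ds, tag, None):
            meta[tag.lower()] = str(getattr(ds, tag))
    return arr, meta
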