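"""Bundle I/O: named arrays in HDF5 with a JSON metadata sidecar, TIFF export."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .metrics import EnvelopeImage

__all__ = [
    "write_bundle",
    "read_bundle",
    "write_envelope_bundle",
    "read_envelope_bundle",
    "export_tiff",
    "REQUIRED_META",
]

#: Metadata keys every envelope bundle must carry.
REQUIRED_META = ("dz", "dx", "seed", "label")


def write_bundle(path, arrays: dict[str, np.ndarray], meta: dict) -> Path:
    """Write named arrays to ``path`` (HDF5) and metadata to ``path + '.json'``."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name, arr in arrays.items():
            f.create_dataset(name, data=np.asarray(arr))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(meta, indent=2, default=_jsonable))
    return path


def _jsonable(obj):
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)!r}")


def read_bundle(path) -> tuple[dict[str, np.ndarray], dict]:
    """Read back arrays and sidecar metadata written by :func:`write_bundle`."""
    path = Path(path)
    arrays = {}
    with h5py.File(path, "r") as f:
        for name in f:
            arrays[name] = f[name][()]
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return arrays, meta


def write_envelope_bundle(
    path, img: EnvelopeImage, seed: int, extra_arrays: dict | None = None, extra_meta: dict | None = None
) -> Path:
    """Store an envelope image plus provenance in one bundle."""
    arrays = {"envelope": img.pixels}
    if extra_arrays:
        arrays.update(extra_arrays)
    meta = {"dz": img.dz, "dx": img.dx, "seed": seed, "label": img.label}
    if extra_meta:
        meta.update(extra_meta)
    return write_bundle(path, arrays, meta)


def read_envelope_bundle(path) -> tuple[EnvelopeImage, dict[str, np.ndarray], dict]:
    """Load an envelope bundle, validating the required metadata keys."""
    arrays, meta = read_bundle(path)
    missing = [k for k in REQUIRED_META if k not in meta]
    if missing:
        raise KeyError(f"bundle metadata missing required keys: {missing}")
    if "envelope" not in arrays:
        raise KeyError("bundle is missing the 'envelope' array")
    img = EnvelopeImage(arrays.pop("envelope"), dz=meta["dz"], dx=meta["dx"], label=meta["label"])
    return img, arrays, meta


def export_tiff(img: EnvelopeImage, path) -> Path:
    """Write the envelope as a float32 TIFF (values preserved, no scaling)."""
    path = Path(path)
    tifffile.imwrite(path, img.pixels.astype(np.float32))
    return path
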