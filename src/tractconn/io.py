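"""File-format plumbing: TrackVis .trk, NIfTI, CSV and JSON artefacts.

Streamline coordinates are kept in mm world space (RAS) via the
volume's affine; voxel indices are 0-based throughout; matrices are
written as CSV with ROI ids as header so round trips are lossless at
CSV precision.  Every numeric artefact written by the pipeline embeds
the run seed and a config hash (CSV: a leading ``#`` comment line;
JSON: top-level keys).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd
from nibabel.streamlines import Tractogram as NibTractogram
from nibabel.streamlines.trk import TrkFile

from .atlas import Parcellation
from .connectome import ConnectionMatrix
from .tracking import Streamline, Tractogram, TensorVolume

__all__ = [
    "save_trk",
    "load_trk",
    "save_tensor_volume",
    "load_tensor_volume",
    "save_label_volume",
    "load_label_volume",
    "save_matrix_csv",
    "load_matrix_csv",
    "config_hash",
]

_TENSOR_COMPONENTS = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]


def config_hash(config: dict) -> str:
    """Short stable hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ----------------------------------------------------------------------
# TrackVis


def save_trk(path: str | Path, tractogram: Tractogram, retained_only: bool = True) -> None:
    """Write streamlines to TrackVis .trk (RAS mm coordinates).

    The header records the source volume's voxel size and dimensions.
    """
    sls = tractogram.retained if retained_only else tractogram.streamlines
    points = [np.asarray(s.points, dtype=np.float32) for s in sls if len(s.points) >= 2]
    affine = np.eye(4)
    nt = NibTractogram(points, affine_to_rasmm=affine)
    header = {
        "voxel_sizes": np.asarray(tractogram.voxel_size, dtype=np.float32),
        "dimensions": np.asarray(tractogram.dimensions, dtype=np.int16),
        "voxel_to_rasmm": np.diag(list(tractogram.voxel_size) + [1.0]).astype(np.float32),
        "voxel_order": "RAS",
    }
    TrkFile(nt, header=header).save(str(path))


def load_trk(path: str | Path) -> Tractogram:
    """Read a .trk file; all streamlines come back flagged retained."""
    trk = TrkFile.load(str(path))
    header = trk.header
    tg = Tractogram(
        voxel_size=tuple(float(v) for v in header["voxel_sizes"]),
        dimensions=tuple(int(d) for d in header["dimensions"]),
    )
    for pts in trk.tractogram.streamlines:
        tg.streamlines.append(Streamline(points=np.asarray(pts, dtype=float), retained=True))
    return tg


# ----------------------------------------------------------------------
# NIfTI


def save_tensor_volume(vol: TensorVolume, prefix: str | Path) -> dict[str, Path]:
    """Write tensors (6-component symmetric image), white and grey masks.

    Returns the written paths keyed by artefact name.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    comp = np.stack(
        [vol.tensors[..., i, j] for i, j in _TENSOR_COMPONENTS], axis=-1
    ).astype(np.float32)
    aff = vol.affine
    paths = {}
    for name, data in (
        ("tensors", comp),
        ("white_mask", vol.white_mask.astype(np.uint8)),
        ("grey_mask", vol.grey_mask.astype(np.uint8)),
    ):
        p = prefix.parent / f"{prefix.name}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(data, aff), str(p))
        paths[name] = p
    return paths


def load_tensor_volume(prefix: str | Path) -> TensorVolume:
    prefix = Path(prefix)
    imgs = {
        name: nib.load(str(prefix.parent / f"{prefix.name}_{name}.nii.gz"))
        for name in ("tensors", "white_mask", "grey_mask")
    }
    comp = np.asarray(imgs["tensors"].dataobj, dtype=float)
    shape = comp.shape[:3]
    tensors = np.zeros(shape + (3, 3))
    for c, (i, j) in enumerate(_TENSOR_COMPONENTS):
        tensors[..., i, j] = comp[..., c]
        tensors[..., j, i] = comp[..., c]
    aff = imgs["tensors"].affine
    voxel_size = tuple(float(v) for v in np.abs(np.diag(aff)[:3]))
    return TensorVolume(
        tensors=tensors,
        white_mask=np.asarray(imgs["white_mask"].dataobj).astype(bool),
        grey_mask=np.asarray(imgs["grey_mask"].dataobj).astype(bool),
        voxel_size=voxel_size,
    )


def save_label_volume(
    labels: np.ndarray, path: str | Path, voxel_size: tuple[float, float, float] = (1, 1, 1)
) -> None:
    aff = np.diag(list(voxel_size) + [1.0])
    aff[:3, 3] = 0.5 * np.asarray(voxel_size)
    nib.save(nib.Nifti1Image(labels.astype(np.int16), aff), str(path))


def load_label_volume(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj).astype(int)


# ----------------------------------------------------------------------
# CSV / JSON


def save_matrix_csv(
    cm: ConnectionMatrix,
    parcellation: Parcellation,
    path: str | Path,
    which: str = "count",
    meta: Optional[dict] = None,
) -> None:
    ids = parcellation.roi_table["id"].to_list()
    frame = pd.DataFrame(getattr(cm, which), index=ids, columns=ids)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if meta:
            fh.write(f"# {json.dumps(meta, sort_keys=True)}\n")
        frame.to_csv(fh, float_format="%.10g")


def load_matrix_csv(path: str | Path, which: str = "count") -> np.ndarray:
    frame = pd.read_csv(path, index_col=0, comment="#")
    arr = frame.to_numpy(dtype=float)
    if which == "count":
        arr = arr.astype(np.int64)
    return arr


def write_json(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, Path):
        return str(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")
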