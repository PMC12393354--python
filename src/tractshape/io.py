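"""Standard-format I/O: TRK/TCK tractograms, CSV/JSON matrices, transforms.

Tractogram files go through nibabel's streamlines API.  TCK stores points
in world RAS mm directly; TRK stores voxmm coordinates and carries the
voxel-to-RAS affine in its header, so a reference affine (normally the
phantom volume's) is required when writing TRK.  Reading auto-detects the
format from the magic bytes and always returns world-mm RAS points.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import nibabel as nib
from nibabel.streamlines import Field
from nibabel.streamlines.tck import TckFile
from nibabel.streamlines.trk import TrkFile

from .metrics import SimilarityMatrix
from .tracking import Tractogram

__all__ = [
    "save_tractogram",
    "load_tractogram",
    "save_similarity_matrix",
    "load_similarity_matrix",
    "write_json",
    "read_json",
]


def save_tractogram(
    path,
    streamlines: Sequence[np.ndarray],
    affine: Optional[np.ndarray] = None,
    grid_shape: Optional[tuple] = None,
) -> None:
    """Write streamlines (world-mm RAS) to .trk or .tck by file suffix.

    TRK requires ``affine`` (voxel-to-RAS) and ``grid_shape`` so that the
    header can define the voxmm convention; TCK ignores both.
    """
    path = Path(path)
    sls = [np.asarray(s, dtype=np.float64) for s in streamlines]
    tg = nib.streamlines.Tractogram(sls, affine_to_rasmm=np.eye(4))
    suffix = path.suffix.lower()
    if suffix == ".tck":
        nib.streamlines.save(tg, str(path))
    elif suffix == ".trk":
        if affine is None:
            affine = np.eye(4)
        if grid_shape is None:
            raise ValueError("TRK output requires grid_shape for its header")
        header = {
            Field.VOXEL_TO_RASMM: np.asarray(affine, dtype=np.float64),
            Field.VOXEL_SIZES: np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0)),
            Field.DIMENSIONS: np.asarray(grid_shape, dtype=np.int16),
        }
        nib.streamlines.save(tg, str(path), header=header)
    else:
        raise ValueError(f"unsupported tractogram suffix {path.suffix!r} (use .trk or .tck)")


def load_tractogram(path) -> Tractogram:
    """Read a TRK or TCK file (format auto-detected) into world-mm RAS."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not (TrkFile.is_correct_format(str(path)) or TckFile.is_correct_format(str(path))):
        raise ValueError(f"{path}: not a recognizable TRK or TCK file (bad magic bytes)")
    tfile = nib.streamlines.load(str(path))
    sls = [np.asarray(s, dtype=np.float64) for s in tfile.streamlines]
    return Tractogram(streamlines=sls, provenance={"source": str(path)})


def save_similarity_matrix(csv_path, M: SimilarityMatrix) -> None:
    """Matrix as CSV (header row/column = subject ids) + JSON sidecar."""
    csv_path = Path(csv_path)
    df = pd.DataFrame(M.scores, index=M.subject_ids, columns=M.subject_ids)
    df.to_csv(csv_path, float_format="%.10g")
    sidecar = {
        "method": M.method,
        "theta_mm": M.theta,
        "empty_subjects": M.empty_subjects,
    }
    write_json(csv_path.with_suffix(".json"), sidecar)


def load_similarity_matrix(csv_path) -> SimilarityMatrix:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path, index_col=0)
    meta_path = csv_path.with_suffix(".json")
    meta = read_json(meta_path) if meta_path.exists() else {}
    return SimilarityMatrix(
        scores=df.to_numpy(),
        subject_ids=[str(c) for c in df.columns],
        method=meta.get("method", ""),
        theta=float(meta.get("theta_mm", 0.0)),
        empty_subjects=list(meta.get("empty_subjects", [])),
    )


def write_json(path, obj) -> None:
    """Deterministically formatted JSON (sorted keys, fixed indentation)."""
    with open(path, "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
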