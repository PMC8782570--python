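"""HDF5 containers and CSV exports for pipeline artifacts."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import (
    EigenSpectrum,
    FormatError,
    IntensityMatrix,
    ModeBasis,
    SkeletonMap,
)


def save_matrix(
    path: str | Path, mat: IntensityMatrix, skel: SkeletonMap | None = None
) -> None:
    """Write an intensity matrix (and optionally its skeleton) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=mat.values)
        f.attrs["dt"] = mat.dt
        f.attrs["stage"] = mat.stage
        if skel is not None:
            f.create_dataset("pixels", data=skel.pixels)


def load_matrix(path: str | Path) -> tuple[IntensityMatrix, SkeletonMap | None]:
    with h5py.File(path, "r") as f:
        if "values" not in f:
            raise FormatError(f"{path}: missing 'values' dataset")
        mat = IntensityMatrix(
            values=f["values"][...], dt=float(f.attrs["dt"]), stage=str(f.attrs["stage"])
        )
        skel = None
        if "pixels" in f:
            pixels = f["pixels"][...]
            from .imaging import _skeleton_pixels_and_adjacency

            img = np.zeros(
                (pixels[:, 0].max() + 1, pixels[:, 1].max() + 1), dtype=bool
            )
            img[pixels[:, 0], pixels[:, 1]] = True
            skel = _skeleton_pixels_and_adjacency(img)
    return mat, skel


def save_modes(path: str | Path, basis: ModeBasis) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("modes", data=basis.modes)
        f.create_dataset("eigenvalues", data=basis.eigenvalues)
        f.create_dataset("coefficients", data=basis.coefficients)
        f.create_dataset("temporal_mean", data=basis.temporal_mean)
        f.attrs["dt"] = basis.dt


def load_modes(path: str | Path) -> ModeBasis:
    with h5py.File(path, "r") as f:
        return ModeBasis(
            modes=f["modes"][...],
            eigenvalues=f["eigenvalues"][...],
            coefficients=f["coefficients"][...],
            temporal_mean=f["temporal_mean"][...],
            dt=float(f.attrs["dt"]),
        )


def spectrum_to_csv(path: str | Path, spectrum: EigenSpectrum) -> None:
    pd.DataFrame(
        {
            "rank": spectrum.ranks,
            "relative_eigenvalue_percent": spectrum.relative_eigenvalues,
        }
    ).to_csv(path, index=False)


def matrix_to_csv(path: str | Path, mat: IntensityMatrix) -> None:
    """Long-format export (pixel_id, t_index, value)."""
    P, T = mat.values.shape
    df = pd.DataFrame(
        {
            "pixel_id": np.repeat(np.arange(P), T),
            "t_index": np.tile(np.arange(T), P),
            "value": mat.values.ravel(),
        }
    )
    df.to_csv(path, index=False)


class RunLog:
    """Append-only JSON-lines run log."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    def write(self, **record) -> None:
        with self.path.open("a") as f:
            f.write(json.dumps(record, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
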