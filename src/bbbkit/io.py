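"""File-format plumbing: TIFF stacks, NIfTI volumes, CSV tables, manifests.

All writers are deterministic (no timestamps) so identical inputs and seeds
produce bit-identical artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .angiography import AngioSeries
from .ecog import ECoGTrace
from .exceptions import InvalidInputError
from .mri import DCESeries, Volume3D

__all__ = [
    "write_angio",
    "read_angio",
    "write_ecog",
    "read_ecog",
    "write_volume",
    "read_volume",
    "write_dce",
    "read_dce",
    "write_json",
    "read_json",
]


def write_json(path: Path | str, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: Path | str) -> dict:
    return json.loads(Path(path).read_text())


def write_angio(path: Path | str, series: AngioSeries, manifest: dict | None = None) -> None:
    """Write a multi-page grayscale TIFF stack plus a sidecar JSON manifest."""
    path = Path(path)
    tifffile.imwrite(path, series.frames.astype(np.float32))
    sidecar = {
        "frame_rate": series.frame_rate,
        "tracer_mode": series.tracer_mode,
        "times_s": [float(t) for t in series.times],
    }
    if manifest:
        sidecar["manifest"] = manifest
    write_json(path.with_suffix(".json"), sidecar)


def read_angio(path: Path | str) -> AngioSeries:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise InvalidInputError(f"missing sidecar manifest {sidecar_path}")
    frames = tifffile.imread(path)
    sidecar = read_json(sidecar_path)
    return AngioSeries(
        frames=np.asarray(frames, dtype=float),
        times=np.asarray(sidecar["times_s"], dtype=float),
        frame_rate=float(sidecar["frame_rate"]),
        tracer_mode=sidecar["tracer_mode"],
    )


def write_ecog(path: Path | str, trace: ECoGTrace) -> None:
    """Write a two-column (time_s, uV) CSV."""
    t = np.arange(trace.samples.size) / trace.fs
    header = f"time_s,uv  # fs={trace.fs}"
    np.savetxt(path, np.column_stack([t, trace.samples]), delimiter=",",
               header=header, comments="# ", fmt="%.6f")


def read_ecog(path: Path | str, fs: float | None = None) -> ECoGTrace:
    """Read a (time_s, uV) CSV; sampling rate inferred from the time column
    unless given explicitly."""
    data = np.loadtxt(path, delimiter=",", comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise InvalidInputError("expected a two-column (time, uV) table")
    if fs is None:
        dt = np.diff(data[:, 0])
        if not np.allclose(dt, dt[0], rtol=1e-3):
            raise InvalidInputError("irregular time base; pass fs explicitly")
        fs = 1.0 / float(dt[0])
    return ECoGTrace(samples=data[:, 1], fs=fs)


def _nifti(vol: np.ndarray) -> nib.Nifti1Image:
    img = nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine=np.eye(4))
    return img


def write_volume(path: Path | str, volume: Volume3D) -> None:
    nib.save(_nifti(volume.voxels), str(path))


def read_volume(path: Path | str, hemisphere_split: int | None = None) -> Volume3D:
    img = nib.load(str(path))
    vox = np.asarray(img.get_fdata(), dtype=float)
    if hemisphere_split is None:
        hemisphere_split = vox.shape[2] // 2
    return Volume3D(voxels=vox, hemisphere_split=hemisphere_split)


def write_dce(directory: Path | str, series: DCESeries, manifest: dict | None = None) -> list[Path]:
    """Write a DCE series as ordered NIfTI scans plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(series.scans.shape[0]):
        # uncompressed NIfTI: gzip embeds a modification time, which would
        # break bit-identical reruns
        p = directory / f"scan_{i:02d}.nii"
        nib.save(_nifti(series.scans[i]), str(p))
        paths.append(p)
    if series.muscle_mask is not None:
        nib.save(_nifti(series.muscle_mask.astype(np.float32)),
                 str(directory / "muscle_mask.nii"))
    meta = {
        "scans": [p.name for p in paths],
        "times": [float(t) for t in series.times],
        "contrast_index": series.contrast_index,
        "muscle_mask": "muscle_mask.nii" if series.muscle_mask is not None else None,
    }
    if manifest:
        meta["manifest"] = manifest
    write_json(directory / "dce_manifest.json", meta)
    return paths


def read_dce(directory: Path | str) -> DCESeries:
    directory = Path(directory)
    meta = read_json(directory / "dce_manifest.json")
    scans = np.stack([
        np.asarray(nib.load(str(directory / name)).get_fdata(), dtype=float)
        for name in meta["scans"]
    ])
    muscle = None
    if meta.get("muscle_mask"):
        muscle = np.asarray(
            nib.load(str(directory / meta["muscle_mask"])).get_fdata()
        ) > 0.5
    return DCESeries(
        scans=scans,
        times=np.asarray(meta["times"], dtype=float),
        contrast_index=int(meta["contrast_index"]),
        muscle_mask=muscle,
    )
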