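"""NIfTI / TSV / JSON input-output with BIDS-style naming."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .motion import MotionTrace
from .series import MultiEchoSeries

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_run",
    "load_run",
    "save_motion_tsv",
    "load_motion_tsv",
    "save_matrix_tsv",
    "save_json",
]

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return aff


def save_nifti(data: np.ndarray, path: Path | str, voxel_size: float = 2.0) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(data), _affine(voxel_size)), str(path))
    return path


def load_nifti(path: Path | str) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    voxel = float(img.header.get_zooms()[0])
    return np.asarray(img.get_fdata()), voxel


def save_motion_tsv(motion: MotionTrace, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(motion.as_array(), columns=MOTION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return path


def load_motion_tsv(path: Path | str, tr: float) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    arr = df[MOTION_COLUMNS].to_numpy()
    return MotionTrace(translations=arr[:, :3], rotations=arr[:, 3:], tr=tr)


def save_matrix_tsv(matrix: np.ndarray, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(np.asarray(matrix)).to_csv(
        path, sep="\t", index=False, header=False
    )
    return path


def save_json(obj: dict, path: Path | str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=_default))
    return path


def save_run(
    series: MultiEchoSeries,
    motion: MotionTrace,
    out_dir: Path | str,
    subject: str = "01",
    run: int = 1,
) -> Path:
    """Write a run as per-echo magnitude/phase NIfTI plus a motion TSV.

    Filenames follow ``sub-X_run-Y_echo-N_part-{mag,phase}_bold.nii.gz``;
    acquisition metadata is stored in a JSON sidecar.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"sub-{subject}_run-{run}"
    for e in range(series.n_echoes):
        save_nifti(
            series.magnitude[e],
            out_dir / f"{stem}_echo-{e + 1}_part-mag_bold.nii.gz",
            series.voxel_size,
        )
        if series.phase is not None:
            save_nifti(
                series.phase[e],
                out_dir / f"{stem}_echo-{e + 1}_part-phase_bold.nii.gz",
                series.voxel_size,
            )
    save_motion_tsv(motion, out_dir / f"{stem}_motion.tsv")
    save_json(
        {
            "EchoTimes_ms": list(series.echo_times),
            "RepetitionTime_s": series.tr,
            "NumNoiseFrames": series.n_noise_frames,
            "VoxelSize_mm": series.voxel_size,
            "HasPhase": series.phase is not None,
        },
        out_dir / f"{stem}_bold.json",
    )
    return out_dir


def load_run(
    data_dir: Path | str, subject: str = "01", run: int = 1
) -> tuple[MultiEchoSeries, MotionTrace]:
    """Read back a run written by :func:`save_run`."""
    data_dir = Path(data_dir)
    stem = f"sub-{subject}_run-{run}"
    meta = json.loads((data_dir / f"{stem}_bold.json").read_text())
    echo_times = meta["EchoTimes_ms"]
    mags, phases = [], []
    for e in range(len(echo_times)):
        m, voxel = load_nifti(data_dir / f"{stem}_echo-{e + 1}_part-mag_bold.nii.gz")
        mags.append(m)
        if meta["HasPhase"]:
            p, _ = load_nifti(
                data_dir / f"{stem}_echo-{e + 1}_part-phase_bold.nii.gz"
            )
            phases.append(p)
    series = MultiEchoSeries(
        magnitude=np.stack(mags),
        phase=np.stack(phases) if phases else None,
        echo_times=tuple(echo_times),
        tr=meta["RepetitionTime_s"],
        n_noise_frames=meta["NumNoiseFrames"],
        voxel_size=meta["VoxelSize_mm"],
    )
    motion = load_motion_tsv(
        data_dir / f"{stem}_motion.tsv", tr=meta["RepetitionTime_s"]
    )
    return series, motion
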