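"""On-disk formats: NIfTI series and masks, JSON time sidecars, CSV tables.

A subject directory contains::

    series.nii.gz            4D HU volume, time as the 4th dimension
    times.json               frame times in seconds (sidecar; NIfTI time
                             metadata is unreliable across tools)
    mask_<region>.nii.gz     one binary label image per region
    aif_true.csv             the noise-free simulated AIF (synthetic data)
    ground_truth.csv         per-tissue true blood flow (synthetic data)

Series round-trip bit-identically in HU values and times.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .perfusion import Curve, DynamicSeries, PerfusionMap, ROIMask
from .synthetic import SyntheticSubject

MASK_NAMES = (
    "aorta",
    "carcinoma_circular",
    "carcinoma_polygonal",
    "parenchyma_circular",
    "parenchyma_polygonal",
)

__all__ = [
    "MASK_NAMES",
    "write_series",
    "read_series",
    "write_subject",
    "read_subject",
    "write_map",
    "write_cohort",
    "read_cohort",
]


def _nifti(data: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(data, affine=np.eye(4))


def write_series(series: DynamicSeries, directory: str | Path) -> None:
    """Write a dynamic series as 4D NIfTI plus a JSON time sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    # (t, row, col) -> (row, col, 1, t): spatial dims first, time fourth
    data = np.transpose(series.voxels, (1, 2, 0))[:, :, None, :]
    nib.save(_nifti(data.astype(np.float64)), directory / "series.nii.gz")
    (directory / "times.json").write_text(
        json.dumps({"frame_times_s": series.times.tolist()}, indent=1)
    )


def read_series(directory: str | Path) -> DynamicSeries:
    directory = Path(directory)
    img = nib.load(directory / "series.nii.gz")
    data = np.asarray(img.dataobj, dtype=np.float64)
    voxels = np.transpose(data[:, :, 0, :], (2, 0, 1))
    times = np.asarray(json.loads((directory / "times.json").read_text())["frame_times_s"])
    return DynamicSeries(voxels, times)


def _mask_path(directory: Path, name: str) -> Path:
    return directory / f"mask_{name}.nii.gz"


def write_subject(subject: SyntheticSubject, directory: str | Path) -> None:
    """Write one synthetic subject (series, masks, true AIF, ground truth)."""
    directory = Path(directory)
    write_series(subject.series, directory)
    for name, roi in subject.masks.items():
        nib.save(_nifti(roi.mask[:, :, None].astype(np.uint8)), _mask_path(directory, name))
    pd.DataFrame(
        {"time_s": subject.aif_true.times, "hu": subject.aif_true.values}
    ).to_csv(directory / "aif_true.csv", index=False)
    (directory / "aif_meta.json").write_text(
        json.dumps({"baseline_hu": subject.aif_true.baseline, "seed": subject.seed})
    )
    pd.DataFrame(
        [{"tissue": k, "bf_true": v} for k, v in sorted(subject.ground_truth.items())]
    ).to_csv(directory / "ground_truth.csv", index=False)


def read_subject(directory: str | Path) -> SyntheticSubject:
    directory = Path(directory)
    series = read_series(directory)
    masks: dict[str, ROIMask] = {}
    for name in MASK_NAMES:
        path = _mask_path(directory, name)
        if not path.exists():
            raise FileNotFoundError(f"missing mask file: {path.name}")
        mask = np.asarray(nib.load(path).dataobj)[:, :, 0].astype(bool)
        kind = "circular" if ("circular" in name or name == "aorta") else "polygonal"
        masks[name] = ROIMask(mask, name, kind)

    aif_df = pd.read_csv(directory / "aif_true.csv")
    meta = json.loads((directory / "aif_meta.json").read_text())
    aif = Curve(aif_df["time_s"].to_numpy(), aif_df["hu"].to_numpy(),
                baseline=float(meta["baseline_hu"]))
    gt_df = pd.read_csv(directory / "ground_truth.csv")
    return SyntheticSubject(
        subject_id=directory.name,
        series=series,
        masks=masks,
        aif_true=aif,
        ground_truth=dict(zip(gt_df["tissue"], gt_df["bf_true"])),
        seed=int(meta["seed"]),
    )


def write_map(pmap: PerfusionMap, path: str | Path) -> None:
    """Write a perfusion map as NIfTI; provenance goes to a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(_nifti(pmap.bf[:, :, None]), path)
    sidecar = path.with_name(path.name.replace(".nii.gz", "") + "_meta.json")
    sidecar.write_text(
        json.dumps(
            {
                "method": pmap.method,
                "timing": pmap.timing,
                "n_floored": pmap.n_floored,
                "provenance": pmap.provenance,
            },
            indent=1,
        )
    )


def write_cohort(cohort: list[SyntheticSubject], directory: str | Path) -> None:
    """Write all subjects plus a cohort manifest CSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for subject in cohort:
        write_subject(subject, directory / subject.subject_id)
        row = {"subject_id": subject.subject_id, "seed": subject.seed}
        row.update({f"bf_true_{k}": v for k, v in sorted(subject.ground_truth.items())})
        rows.append(row)
    pd.DataFrame(rows).to_csv(directory / "manifest.csv", index=False)


def read_cohort(directory: str | Path) -> list[SyntheticSubject]:
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv in {directory}")
    ids = pd.read_csv(manifest)["subject_id"].tolist()
    if not ids:
        raise ValueError("empty cohort manifest")
    return [read_subject(directory / sid) for sid in ids]
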