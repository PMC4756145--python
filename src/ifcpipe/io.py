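"""Disk round trips: NIfTI volumes, SPM-style motion files, manifests.

A simulated cohort can be written out subject by subject (4-D NIfTI plus
6-column motion text) with a TSV manifest and a JSON ground-truth sidecar,
and read back into the in-memory objects the pipeline stages consume.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import Grid
from .preprocess import MotionTrace, VolumeSeries
from .simulate import GroundTruth


def write_volume_series(series: VolumeSeries, path: Path) -> None:
    vol = series.data.reshape(*series.grid.shape, series.n_volumes)
    img = nib.Nifti1Image(np.asarray(vol, np.float32), series.grid.affine)
    img.header.set_zooms((*series.grid.voxel_size_mm, series.tr_seconds))
    nib.save(img, str(path))


def read_volume_series(path: Path, subject_id: str = "") -> VolumeSeries:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D image")
    grid = Grid(data.shape[:3], img.affine)
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return VolumeSeries(
        data=data.reshape(-1, data.shape[3]),
        grid=grid,
        tr_seconds=tr,
        subject_id=subject_id or Path(path).stem,
    )


def write_motion(trace: MotionTrace, path: Path) -> None:
    np.savetxt(path, trace.to_spm_array(), fmt="%.8e")


def write_cohort(
    series: list[VolumeSeries],
    motions: list[MotionTrace],
    truth: GroundTruth,
    out_dir: str | Path,
) -> Path:
    """Write one subject per NIfTI/motion pair plus manifest and ground truth.

    Returns the manifest path. The manifest flags the cohort as synthetic:
    every distributional choice in the generator is a stand-in, not an
    empirical model of scanner data.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for s, m, grp in zip(series, motions, truth.group_labels):
        bold = out / f"{s.subject_id}_bold.nii"
        rp = out / f"rp_{s.subject_id}.txt"
        write_volume_series(s, bold)
        write_motion(m, rp)
        rows.append(
            {
                "subject": s.subject_id,
                "group": grp,
                "bold": bold.name,
                "motion": rp.name,
                "synthetic": True,
            }
        )
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)

    maps_img = nib.Nifti1Image(
        truth.latent_network_maps.T.reshape(
            *truth.grid.shape, truth.latent_network_maps.shape[0]
        ).astype(np.float32),
        truth.grid.affine,
    )
    nib.save(maps_img, str(out / "network_maps.nii"))
    gt = {
        "group_labels": truth.group_labels,
        "roi_names": truth.roi_names,
        "home_networks": truth.home_networks,
        "planted_coupling": [b.tolist() for b in truth.planted_coupling],
        "gm_mask": truth.gm_mask.tolist(),
        "wm_mask": truth.wm_mask.tolist(),
        "csf_mask": truth.csf_mask.tolist(),
        "note": "synthetic cohort; all distributional choices are stand-ins",
    }
    (out / "ground_truth.json").write_text(json.dumps(gt))
    return manifest


def read_cohort(manifest_path: str | Path) -> tuple[list[VolumeSeries], list[MotionTrace], list[str]]:
    """Read back the per-subject series, motion traces and group labels."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    base = manifest_path.parent
    series, motions = [], []
    for _, row in df.iterrows():
        series.append(read_volume_series(base / row["bold"], subject_id=str(row["subject"])))
        motions.append(MotionTrace.from_spm_file(base / row["motion"]))
    return series, motions, list(df["group"].astype(str))
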