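"""NIfTI volume I/O, phantom-case persistence, run configs and evaluation.

Volumes live on disk as NIfTI-1 with an RAS affine carrying the voxel spacing;
in memory they are (z, y, x)-ordered arrays (see :mod:`ctfree_gfr.volume`).
A phantom case is a directory of six volumes plus a JSON sidecar with the
scalar ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .metrics import MetricReport, aggregate_reports
from .phantom import PhantomCase
from .volume import LabelMap, Volume3D

__all__ = [
    "read_volume",
    "write_volume",
    "save_case",
    "load_case",
    "save_config",
    "load_config",
    "evaluate_run",
]

_CASE_VOLUMES = {
    "mu_map": "mu.nii.gz",
    "activity": "activity.nii.gz",
    "labels": "labels.nii.gz",
    "primary_spect": "primary.nii.gz",
    "scatter_spect": "scatter.nii.gz",
    "quantitative_spect": "quant.nii.gz",
}


def _to_nifti(volume: Volume3D) -> nib.Nifti1Image:
    # internal (z, y, x) -> NIfTI (x, y, z)
    data = np.ascontiguousarray(volume.data.transpose(2, 1, 0))
    affine = np.diag([*volume.spacing_mm[::-1], 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.spacing_mm[::-1])
    return img


def write_volume(volume: Volume3D, path: str | Path) -> Path:
    """Write a volume as NIfTI-1; read_volume inverts exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(_to_nifti(volume), str(path))
    return path


def read_volume(path: str | Path, as_labels: bool = False) -> Volume3D:
    """Read a 3D NIfTI volume into the internal (z, y, x) convention."""
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3D volume, got shape {img.shape} in {path}")
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    if as_labels:
        return LabelMap(np.rint(data).astype(np.int16), spacing)
    return Volume3D(np.asarray(data), spacing)


def save_case(case: PhantomCase, out_dir: str | Path) -> Path:
    """Write a phantom case as six NIfTI volumes plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for attr, fname in _CASE_VOLUMES.items():
        write_volume(getattr(case, attr), out_dir / fname)
    sidecar = {
        "injected_activity_MBq": case.injected_activity_MBq,
        "true_pct_id": {str(k): v for k, v in case.true_pct_id.items()},
        "category": case.category,
        "side": case.side,
        "seed": case.seed,
    }
    (out_dir / "case.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir


def load_case(case_dir: str | Path) -> PhantomCase:
    """Inverse of :func:`save_case`."""
    case_dir = Path(case_dir)
    meta = json.loads((case_dir / "case.json").read_text())
    vols = {
        attr: read_volume(case_dir / fname, as_labels=(attr == "labels"))
        for attr, fname in _CASE_VOLUMES.items()
    }
    return PhantomCase(
        **vols,
        injected_activity_MBq=float(meta["injected_activity_MBq"]),
        true_pct_id={int(k): float(v) for k, v in meta["true_pct_id"].items()},
        category=meta["category"],
        side=meta["side"],
        seed=int(meta["seed"]),
    )


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def save_config(config, path: str | Path) -> Path:
    """Serialize a (dataclass or dict) run configuration to YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))
    return path


def load_config(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def evaluate_run(pred_dir: str | Path, truth_dir: str | Path):
    """Score predicted label maps against ground truth, case by case.

    Both directories hold ``<case_id>.nii.gz`` label maps (or case
    subdirectories containing ``labels.nii.gz``).  Case IDs must match
    exactly; any mismatch is reported with the offending IDs.

    Returns ``(per_case_reports, aggregate_table)``.
    """
    pred_dir, truth_dir = Path(pred_dir), Path(truth_dir)

    def index(d: Path) -> dict[str, Path]:
        out = {}
        for p in sorted(d.glob("*.nii.gz")):
            out[p.name.removesuffix(".nii.gz")] = p
        for p in sorted(d.glob("*/labels.nii.gz")):
            out[p.parent.name] = p
        return out

    preds, truths = index(pred_dir), index(truth_dir)
    if set(preds) != set(truths):
        missing = sorted(set(truths) - set(preds))
        extra = sorted(set(preds) - set(truths))
        raise ValueError(
            f"case ID mismatch: missing predictions {missing}, unmatched {extra}"
        )
    reports = []
    for cid in sorted(preds):
        pred = read_volume(preds[cid], as_labels=True)
        truth = read_volume(truths[cid], as_labels=True)
        reports.append(MetricReport.from_segmentation(cid, pred, truth))
    return reports, aggregate_reports(reports)
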