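"""Evaluation metrics: segmentation overlap and u-map agreement.

Segmentation is scored with the Dice similarity coefficient (DSC) and the
signed volume difference VD = ground-truth volume - predicted volume (mL);
negative VD means over-segmentation.  Synthetic attenuation maps are scored
against ground truth with R^2, mean squared error, and the normalized mean
absolute error in percent (%NMAE), all over a body mask.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .volume import LEFT_KIDNEY, RIGHT_KIDNEY, LabelMap, Volume3D

__all__ = [
    "dsc",
    "dsc_report",
    "volume_difference",
    "mumap_agreement",
    "MetricReport",
    "aggregate_reports",
]

_KIDNEY_CLASSES = (RIGHT_KIDNEY, LEFT_KIDNEY)


def _as_array(labels: LabelMap | np.ndarray) -> np.ndarray:
    return labels.data if isinstance(labels, LabelMap) else np.asarray(labels)


def _class_mask(labels: LabelMap | np.ndarray, class_id) -> np.ndarray:
    arr = _as_array(labels)
    if class_id == "total":
        return np.isin(arr, _KIDNEY_CLASSES)
    if class_id not in (0, *_KIDNEY_CLASSES):
        raise ValueError(f"unknown class id {class_id!r}")
    return arr == class_id


def dsc(
    pred: LabelMap | np.ndarray,
    truth: LabelMap | np.ndarray,
    class_id: int | str = "total",
) -> float:
    """Dice similarity coefficient 2|A n B| / (|A| + |B|) for one class.

    ``class_id='total'`` treats the union of both kidney classes as the
    foreground.  Two empty masks agree perfectly (DSC 1); empty-vs-nonempty
    is 0, matching the failure mode where one side predicts no kidney.
    """
    a = _class_mask(pred, class_id)
    b = _class_mask(truth, class_id)
    if a.shape != b.shape:
        raise ValueError("prediction and truth must share the grid")
    size = int(a.sum()) + int(b.sum())
    if size == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(a & b)) / size


def dsc_report(pred: LabelMap, truth: LabelMap) -> dict[str, float]:
    """DSC for total (union foreground), left and right kidney."""
    return {
        "total": dsc(pred, truth, "total"),
        "left": dsc(pred, truth, LEFT_KIDNEY),
        "right": dsc(pred, truth, RIGHT_KIDNEY),
    }


def volume_difference(
    pred: LabelMap,
    truth: LabelMap,
    voxel_size_mm: float | None = None,
) -> dict[str, float]:
    """Signed volume difference (truth - prediction) in mL per class and total."""
    if _as_array(pred).shape != _as_array(truth).shape:
        raise ValueError("prediction and truth must share the grid")
    if voxel_size_mm is None:
        vox_ml = truth.voxel_volume_ml if isinstance(truth, LabelMap) else None
        if vox_ml is None:
            raise ValueError("voxel_size_mm required for bare arrays")
    else:
        vox_ml = float(voxel_size_mm) ** 3 / 1000.0

    out = {}
    for name, cls in (("total", "total"), ("left", LEFT_KIDNEY), ("right", RIGHT_KIDNEY)):
        nt = int(_class_mask(truth, cls).sum())
        np_ = int(_class_mask(pred, cls).sum())
        out[name] = (nt - np_) * vox_ml
    return out


def mumap_agreement(
    pred_mu: Volume3D,
    true_mu: Volume3D,
    mask: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """(R^2, MSE, %NMAE) between a synthetic and a reference attenuation map.

    The comparison runs over ``mask``, defaulting to the body contour of the
    reference map (voxels with positive attenuation).  %NMAE normalizes the
    mean absolute error by the dynamic range of the reference within the mask.
    """
    if not pred_mu.same_grid(true_mu):
        raise ValueError("attenuation maps must share the grid")
    if mask is None:
        mask = true_mu.data > 0
    t = np.asarray(true_mu.data, dtype=np.float64)[mask]
    p = np.asarray(pred_mu.data, dtype=np.float64)[mask]
    if t.size == 0:
        raise ValueError("empty evaluation mask")
    ss_tot = float(((t - t.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("reference map is constant within the mask; R^2 undefined")
    diff = p - t
    r2 = 1.0 - float((diff**2).sum()) / ss_tot
    mse = float((diff**2).mean())
    t_range = float(t.max() - t.min())
    nmae_pct = 100.0 * float(np.abs(diff).mean()) / t_range
    return r2, mse, nmae_pct


@dataclass
class MetricReport:
    """Per-case metric row; u-map fields stay None for segmentation-only runs."""

    case_id: str
    dsc_total: float | None = None
    dsc_left: float | None = None
    dsc_right: float | None = None
    vd_total_ml: float | None = None
    vd_left_ml: float | None = None
    vd_right_ml: float | None = None
    r2: float | None = None
    mse: float | None = None
    nmae_pct: float | None = None

    @classmethod
    def from_segmentation(
        cls, case_id: str, pred: LabelMap, truth: LabelMap
    ) -> "MetricReport":
        d = dsc_report(pred, truth)
        v = volume_difference(pred, truth)
        return cls(
            case_id=case_id,
            dsc_total=d["total"], dsc_left=d["left"], dsc_right=d["right"],
            vd_total_ml=v["total"], vd_left_ml=v["left"], vd_right_ml=v["right"],
        )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def aggregate_reports(reports: list[MetricReport]) -> pd.DataFrame:
    """Mean, sample SD and min-max range per metric column over cases."""
    if not reports:
        raise ValueError("no reports to aggregate")
    df = pd.DataFrame([r.to_dict() for r in reports]).set_index("case_id")
    df = df.dropna(axis=1, how="all").astype(float)
    agg = df.agg(["mean", "std", "min", "max"])
    agg.index.name = "statistic"
    return agg
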