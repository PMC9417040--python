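"""Sorted-volume quality reporting and comparative-study statistics.

Quality of a sorted 4DCT is quantified by the normalised boundary indices
(N-NCC, N-RMSD) evaluated inside a central region of interest at every
couch-position boundary of every phase bin, aggregated per sorting method.
Weight sweeps rerun the full-cost sorter over a grid of phase : amplitude :
RMA weight ratios. Pearson correlation (against ordinal operator scores)
and linearly weighted kappa (inter-rater agreement) support replaying the
observer-study statistics on arbitrary score vectors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import cohen_kappa_score

from . import sorting
from .errors import CineSortError, ConfigError, MaskError
from .indices import (
    DEFAULT_BODY_THRESHOLD,
    BoundaryContext,
    IndexTable,
    body_mask,
    normalised_index,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TABLE_RATIOS",
    "roi_mask",
    "volume_boundary_frame",
    "quality_report",
    "weight_sweep",
    "pearson_r",
    "weighted_kappa",
]

#: Default weight-ratio grid (phase : amplitude : rma).
TABLE_RATIOS = [
    (1, 1, 1), (0, 1, 1), (1, 0, 1), (1, 1, 2), (2, 1, 1),
    (1, 2, 1), (0, 1, 2), (0, 2, 1), (1, 0, 2), (2, 0, 1),
]

DEFAULT_ROI_WIDTH = 200


def roi_mask(image: np.ndarray, width: int = DEFAULT_ROI_WIDTH,
             threshold: float = DEFAULT_BODY_THRESHOLD) -> np.ndarray:
    """Central vertical band of ``width`` pixels intersected with the body mask.

    A width at least the image width reduces to the body mask itself.
    """
    rows, cols = image.shape
    c0 = max(0, (cols - width) // 2)
    c1 = min(cols, c0 + width)
    band = np.zeros((rows, cols), dtype=bool)
    band[:, c0:c1] = True
    roi = band & body_mask(image, threshold)
    if not roi.any():
        raise MaskError("ROI band contains no body pixels")
    return roi


def volume_boundary_frame(volume: sorting.SortedVolume,
                          index_names=("n_ncc", "n_rmsd"),
                          roi_width: int = DEFAULT_ROI_WIDTH,
                          threshold: float = DEFAULT_BODY_THRESHOLD) -> pd.DataFrame:
    """Normalised boundary indices of one sorted volume, within the ROI band.

    One row per couch boundary and index; failed entries get NaN values.
    """
    s = volume.slices_per_block
    n = volume.n_couch
    rows = []
    for b in range(n - 1):
        ctx = BoundaryContext(
            upper_penultimate=volume.data[b * s + s - 2],
            upper_last=volume.data[b * s + s - 1],
            lower_first=volume.data[(b + 1) * s],
            lower_second=volume.data[(b + 1) * s + 1],
        )
        for name in index_names:
            base = name.removeprefix("n_")
            try:
                roi = roi_mask(ctx.upper_last, roi_width, threshold)
                val = normalised_index(ctx, base=base, roi=roi, threshold=threshold)
            except CineSortError as exc:
                logger.debug("boundary %d %s failed: %s", b, name, exc)
                val = np.nan
            rows.append({
                "method": volume.method,
                "bin": volume.bin_index,
                "boundary": b,
                "index": name,
                "value": val,
            })
    return pd.DataFrame(rows)


def quality_report(volumes_by_method: dict[str, list[sorting.SortedVolume]],
                   index_names=("n_ncc", "n_rmsd"),
                   roi_width: int = DEFAULT_ROI_WIDTH,
                   threshold: float = DEFAULT_BODY_THRESHOLD,
                   baseline: str = "phase") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-boundary index table plus per-method aggregates.

    Returns ``(per_boundary, summary)``. The summary holds mean and standard
    deviation per method and index and, when the baseline method is present,
    the relative improvement ``(mean_baseline - mean_method)/mean_baseline``
    (positive means the method beats the baseline for error-type indices
    such as N-RMSD; for similarity-type indices the sign is inverted in
    interpretation, not in the formula).
    """
    if not volumes_by_method:
        raise ConfigError("no sorted volumes supplied")
    frames = []
    for method, vols in volumes_by_method.items():
        for vol in vols:
            df = volume_boundary_frame(vol, index_names, roi_width, threshold)
            df["method"] = method
            frames.append(df)
    per_boundary = pd.concat(frames, ignore_index=True)
    grouped = per_boundary.groupby(["method", "index"])["value"]
    summary = grouped.agg(mean="mean", std="std", n="count").reset_index()
    if baseline in volumes_by_method:
        base_means = summary[summary["method"] == baseline].set_index("index")["mean"]
        summary["relative_improvement"] = summary.apply(
            lambda r: ((base_means[r["index"]] - r["mean"]) / base_means[r["index"]]
                       if base_means.get(r["index"], 0) else np.nan),
            axis=1,
        )
    return per_boundary, summary


def weight_sweep(study, table: IndexTable, ratios=None,
                 n_bins: int | None = None, K: int = 2,
                 roi_width: int = DEFAULT_ROI_WIDTH,
                 index_names=("n_rmsd",)) -> pd.DataFrame:
    """Quality of the full-cost sorter over a grid of weight ratios.

    Each ratio is (phase, amplitude, rma), renormalised to sum 1. Returns
    one row per ratio and index with the mean/std of the boundary values
    over all bins. Deterministic given the study.
    """
    if ratios is None:
        ratios = TABLE_RATIOS
    rows = []
    inputs = sorting.prepare_inputs(study, K=K)
    for ratio in ratios:
        if len(ratio) != 3:
            raise ConfigError(f"ratio {ratio} must have three entries")
        if sum(ratio) <= 0:
            raise ConfigError("all-zero weight ratio")
        w = sorting.WeightConfig.from_ratio(*ratio)
        sels = sorting.amp_sim_w_sort(study, table, w=w, n_bins=n_bins,
                                      inputs=inputs)
        vols = [sorting.assemble_volume(study, s) for s in sels]
        df = pd.concat([volume_boundary_frame(v, index_names, roi_width)
                        for v in vols], ignore_index=True)
        for name, grp in df.groupby("index"):
            rows.append({
                "phase_ratio": ratio[0],
                "amplitude_ratio": ratio[1],
                "rma_ratio": ratio[2],
                "index": name,
                "mean": grp["value"].mean(),
                "std": grp["value"].std(),
            })
    return pd.DataFrame(rows)


_PEARSON_BANDS = [(0.7, "high"), (0.3, "moderate"), (0.1, "low"), (0.0, "negligible")]


def pearson_r(x, y) -> tuple[float, float, str]:
    """Sample Pearson correlation with two-sided p and a strength band.

    Bands on |r|: >= 0.7 high, 0.3-0.7 moderate, 0.1-0.3 low, < 0.1
    negligible.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ConfigError("need equal-length vectors of >= 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ConfigError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    band = next(label for thr, label in _PEARSON_BANDS if abs(r) >= thr)
    return r, p, band


def _kappa_band(kappa: float) -> str:
    if kappa < 0.20:
        return "Poor"
    if kappa <= 0.40:
        return "Fair"
    if kappa <= 0.60:
        return "Moderate"
    if kappa <= 0.80:
        return "Good"
    return "Very Good"


def weighted_kappa(rater1, rater2, weights: str = "linear",
                   categories=(1, 2, 3, 4)) -> tuple[float, str]:
    """Weighted kappa between two ordinal score vectors, with agreement band.

    Linear disagreement weights by default (quadratic available). Bands:
    < 0.20 Poor, 0.20-0.40 Fair, 0.41-0.60 Moderate, 0.61-0.80 Good,
    0.81-1.00 Very Good.
    """
    a = np.asarray(rater1, dtype=int)
    b = np.asarray(rater2, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigError("score vectors must be 1-D and equal length")
    cats = set(categories)
    if not (set(a) <= cats and set(b) <= cats):
        raise ConfigError(f"scores must lie in {sorted(cats)}")
    if len(set(a) | set(b)) < 2:
        raise ConfigError("a single category in both raters: kappa undefined")
    if np.array_equal(a, b):
        # chance-corrected agreement of identical ratings is exactly 1;
        # avoids 0/0 when the raters also agree by construction
        return 1.0, _kappa_band(1.0)
    kappa = float(cohen_kappa_score(a, b, weights=weights,
                                    labels=sorted(categories)))
    return kappa, _kappa_band(kappa)
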