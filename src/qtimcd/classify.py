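"""ROI statistics and ROC-based voxel classification.

The statistical back end of the analysis: per-ROI intensity samples are
extracted and (for the structural contrasts) normalized by a reference-ROI
mean; per-class intensity distributions are averaged across ROIs with equal
ROI weight; a receiver operating characteristic (ROC) swept over the
common histogram bins of the normal-cortex and normal-white-matter
distributions yields, per contrast, an optimal threshold (Youden's J) and
an AUC; lesion voxels are then classified as cortex-like or
white-matter-like against that threshold, and per-lesion white-matter-like
percentages (WM%) are tabulated with per-type mean (SD) aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RoiSample",
    "AveragedDistribution",
    "ThresholdResult",
    "extract_roi",
    "normalize_intensity",
    "histogram_edges",
    "average_distributions",
    "roc_threshold",
    "classify_wm_percent",
    "build_report",
]

# contrasts whose intensities are in arbitrary units and must be normalized
NORMALIZED_CONTRASTS = ("T1w", "FLAIR")


@dataclass(frozen=True)
class RoiSample:
    """Per-ROI intensity sample for one contrast."""

    roi_id: str
    lesion_type: str  # PH | SH | FCD | PMG | cortex | WM
    contrast: str  # T1w | FLAIR | FA | MKA
    values: np.ndarray
    reference_id: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        if v.size == 0:
            raise ValueError(f"ROI {self.roi_id!r} has no voxels")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"ROI {self.roi_id!r} contains non-finite values")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class AveragedDistribution:
    """Equal-ROI-weight average of per-ROI normalized histograms."""

    contrast: str
    tissue_class: str
    bin_edges: np.ndarray
    density: np.ndarray
    n_rois: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        e = np.asarray(self.bin_edges, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if len(e) != len(d) + 1:
            raise ValueError("bin_edges must have one more entry than density")
        if np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(d < 0):
            raise ValueError("densities must be non-negative")
        mass = float(np.sum(d * np.diff(e)))
        if abs(mass - 1.0) > 1e-9:
            raise ValueError(f"density must integrate to 1, got {mass}")
        object.__setattr__(self, "bin_edges", e)
        object.__setattr__(self, "density", d)

    @property
    def bin_masses(self) -> np.ndarray:
        return self.density * np.diff(self.bin_edges)


@dataclass(frozen=True)
class ThresholdResult:
    """ROC-derived decision rule for one contrast."""

    contrast: str
    threshold: float
    polarity: str  # "high": WM-like above threshold; "low": below
    auc: float

    def __post_init__(self) -> None:
        if self.polarity not in ("high", "low"):
            raise ValueError(f"polarity must be 'high' or 'low', got {self.polarity!r}")
        if not 0.5 - 1e-12 <= self.auc <= 1.0 + 1e-12:
            raise ValueError(f"AUC must lie in [0.5, 1], got {self.auc}")


def extract_roi(
    volume: np.ndarray,
    roi_mask: np.ndarray,
    roi_id: str,
    lesion_type: str,
    contrast: str,
) -> RoiSample:
    """Extract per-voxel intensities of one ROI (mask order)."""
    volume = np.asarray(volume, dtype=float)
    roi_mask = np.asarray(roi_mask).astype(bool)
    if volume.shape != roi_mask.shape:
        raise ValueError(f"ROI grid {roi_mask.shape} does not match volume {volume.shape}")
    if not roi_mask.any():
        raise ValueError(f"ROI {roi_id!r} is empty")
    return RoiSample(roi_id, lesion_type, contrast, volume[roi_mask])


def normalize_intensity(sample: RoiSample, reference: RoiSample) -> RoiSample:
    """Divide a structural sample by the mean of its reference ROI.

    FA and MK_A samples are dimensionless and pass through unchanged (with
    no reference recorded).
    """
    if sample.contrast not in NORMALIZED_CONTRASTS:
        return sample
    ref_mean = float(np.mean(reference.values))
    if ref_mean <= 0:
        raise ValueError(
            f"reference ROI {reference.roi_id!r} has nonpositive mean {ref_mean}"
        )
    return replace(
        sample, values=sample.values / ref_mean, reference_id=reference.roi_id
    )


def histogram_edges(
    samples: Iterable[RoiSample], n_bins: int = 64
) -> np.ndarray:
    """Common bin edges spanning the pooled 1st-99th percentile of samples.

    Used across tissue classes of one contrast so their averaged
    distributions share a binning.
    """
    pooled = np.concatenate([s.values for s in samples])
    lo, hi = np.percentile(pooled, [1.0, 99.0])
    if hi <= lo:  # degenerate range: single-bin fallback
        pad = max(abs(lo), 1.0) * 1e-6
        return np.array([lo - pad, hi + pad])
    return np.linspace(lo, hi, n_bins + 1)


def average_distributions(
    samples: Sequence[RoiSample],
    n_bins: int = 64,
    bin_edges: np.ndarray | None = None,
    tissue_class: str | None = None,
) -> AveragedDistribution:
    """Average the normalized histograms of several ROIs with equal weight.

    Each ROI contributes its own density estimate regardless of its voxel
    count (ROIs are the sampling unit, not voxels).  Values outside the bin
    range are clipped into the edge bins so every ROI keeps unit mass.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("need at least one ROI sample")
    contrasts = {s.contrast for s in samples}
    if len(contrasts) > 1:
        raise ValueError(f"samples mix contrasts: {sorted(contrasts)}")
    degenerate = False
    if bin_edges is None:
        bin_edges = histogram_edges(samples, n_bins)
        degenerate = len(bin_edges) == 2
    bin_edges = np.asarray(bin_edges, dtype=float)
    widths = np.diff(bin_edges)
    densities = []
    for s in samples:
        v = np.clip(s.values, bin_edges[0], bin_edges[-1])
        counts, _ = np.histogram(v, bins=bin_edges)
        densities.append(counts / (counts.sum() * widths))
    mean_density = np.mean(densities, axis=0)
    mean_density = mean_density / np.sum(mean_density * widths)
    return AveragedDistribution(
        contrast=samples[0].contrast,
        tissue_class=tissue_class or samples[0].lesion_type,
        bin_edges=bin_edges,
        density=mean_density,
        n_rois=len(samples),
        degenerate=degenerate,
    )


def roc_threshold(
    cortex_dist: AveragedDistribution, wm_dist: AveragedDistribution
) -> ThresholdResult:
    """ROC analysis of white matter (positive class) against cortex.

    The threshold sweeps the common bin edges; polarity (which side of the
    threshold is white-matter-like) is resolved automatically so the AUC is
    >= 0.5.  The operating point maximizes Youden's J = TPR - FPR, and the
    AUC is the trapezoidal area under the swept ROC curve.
    """
    if not np.array_equal(cortex_dist.bin_edges, wm_dist.bin_edges):
        raise ValueError("distributions must share bin edges")
    edges = cortex_dist.bin_edges
    wm_mass = wm_dist.bin_masses
    ctx_mass = cortex_dist.bin_masses
    # P(value > edge_k) for each of the len(edges) candidate thresholds
    tail_wm = np.concatenate(([1.0], 1.0 - np.cumsum(wm_mass)))
    tail_ctx = np.concatenate(([1.0], 1.0 - np.cumsum(ctx_mass)))

    best = None
    for polarity in ("high", "low"):
        if polarity == "high":
            # traverse thresholds descending so FPR and TPR both increase
            tpr, fpr = tail_wm[::-1], tail_ctx[::-1]
        else:
            tpr, fpr = 1.0 - tail_wm, 1.0 - tail_ctx
        auc = float(np.trapezoid(tpr, fpr))
        j = tpr - fpr
        k = int(np.argmax(j))
        edge_idx = len(edges) - 1 - k if polarity == "high" else k
        cand = (auc, polarity, float(edges[edge_idx]))
        if best is None or cand[0] > best[0]:
            best = cand
    auc, polarity, tau = best
    auc = min(max(auc, 0.5), 1.0)
    return ThresholdResult(
        contrast=cortex_dist.contrast, threshold=tau, polarity=polarity, auc=auc
    )


def classify_wm_percent(
    sample: RoiSample, threshold: ThresholdResult
) -> tuple[float, np.ndarray]:
    """Classify lesion voxels against the ROC threshold.

    A voxel is white-matter-like when it lies strictly on the WM side of the
    threshold (ties count as cortex-like).  Returns the percentage in
    [0, 100] and the per-voxel boolean labels.
    """
    if sample.values.size == 0:
        raise ValueError("empty sample")
    if threshold.polarity == "high":
        wm_like = sample.values > threshold.threshold
    else:
        wm_like = sample.values < threshold.threshold
    pct = 100.0 * float(wm_like.sum()) / float(wm_like.size)
    return pct, wm_like


def build_report(
    lesion_rows: Sequence[dict],
    contrasts: Sequence[str] = ("T1w", "FLAIR", "FA", "MKA"),
) -> pd.DataFrame:
    """Tabulate per-lesion WM% and per-type mean (SD) aggregates.

    ``lesion_rows`` hold ``lesion_id``, ``lesion_type``, ``n_voxels`` and
    one WM% entry per contrast.  Aggregate rows (one per lesion type, id
    ``M (SD)``) carry the mean with the sample standard deviation (ddof=1;
    0 for singleton types).  Percentages are kept at full precision here;
    rounding to integers happens only when the table is rendered.
    """
    if not lesion_rows:
        raise ValueError("need at least one lesion")
    df = pd.DataFrame(lesion_rows)
    out_rows = list(lesion_rows)
    for ltype, grp in df.groupby("lesion_type", sort=False):
        agg = {"lesion_id": "M (SD)", "lesion_type": ltype, "n_voxels": float(grp["n_voxels"].mean())}
        for c in contrasts:
            m = float(grp[c].mean())
            sd = float(grp[c].std(ddof=1)) if len(grp) > 1 else 0.0
            agg[c] = m
            agg[f"{c}_sd"] = sd
        out_rows.append(agg)
    return pd.DataFrame(out_rows)
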