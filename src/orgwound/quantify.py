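"""Per-organoid readouts: diameter morphometry, proliferation and migration maps.

Three readouts mirror the repair phenotypes of interest: (1) the mean
organoid diameter over time, normalized to the pre-ablation size (growth);
(2) the EdU-positive fraction overall and per 30-µm arc-distance bin
(proliferation); (3) the mean per-cell migration distance overall and per
bin (motility).  Per-bin values are aggregated across organoids — each
organoid contributes one value per bin — matching a design where n counts
organoids, not cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from . import geometry, imaging
from .geometry import AblationSite, CircleModel, DEFAULT_BIN_WIDTH_UM
from .imaging import ProjectedImage, segment_organoid
from .synthgen import ConfigurationError
from .tracking import Track


@dataclass
class DiameterSeries:
    """Mean organoid diameter per timepoint and its normalized time course."""

    mean_diameter_um: np.ndarray
    rel_diameter_pct: np.ndarray
    n_slices_used: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "timepoint": np.arange(len(self.mean_diameter_um)),
            "mean_diameter_um": self.mean_diameter_um,
            "rel_diameter_pct": self.rel_diameter_pct,
            "n_slices_used": self.n_slices_used,
        })


@dataclass
class ProliferationResult:
    """EdU-positive fraction, overall and per arc-distance bin."""

    overall_rate: float
    per_bin_rate: dict[int, float]
    per_bin_counts: dict[int, tuple[int, int]]  # bin -> (edu_pos, total)
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM
    threshold: float | None = None


@dataclass
class MigrationResult:
    """Mean migration distance, overall and per arc-distance bin."""

    overall_mean_um: float
    per_bin_mean_um: dict[int, float]
    per_bin_n: dict[int, int]
    metric: str = "path_length_um"
    bin_width_um: float = DEFAULT_BIN_WIDTH_UM


# ---------------------------------------------------------------------------
# morphometry
# ---------------------------------------------------------------------------

def mask_axes_um(mask: np.ndarray, pixel_size_um: float) -> tuple[float, float]:
    """Minor and major axis lengths (µm) of the mask's second-moment ellipse."""
    from skimage.measure import regionprops

    props = regionprops(mask.astype(np.uint8))
    if not props:
        raise ValueError("empty mask")
    p = props[0]
    return (p.axis_minor_length * pixel_size_um, p.axis_major_length * pixel_size_um)


def slice_diameter_um(img: ProjectedImage, smooth_sigma_um: float = 2.0,
                      closing_radius_um: float = 10.0) -> float:
    """Diameter of one z-slice: mean of the mask's minor and major axes."""
    mask = segment_organoid(img, smooth_sigma_um=smooth_sigma_um,
                            closing_radius_um=closing_radius_um)
    minor, major = mask_axes_um(mask.mask, img.pixel_size_um)
    return 0.5 * (minor + major)


def diameter_series(stacks, channel: int = 0, pixel_size_um: float = 1.0,
                    smooth_sigma_um: float = 2.0,
                    closing_radius_um: float = 10.0) -> DiameterSeries:
    """Mean organoid diameter per timepoint, normalized to timepoint 0 = 100 %.

    ``stacks`` is a (T, Z, C, Y, X) array or a list of per-timepoint
    (Z, C, Y, X)/(Z, Y, X) stacks.  Per slice the organoid is segmented and
    its diameter taken as (minor + major)/2 of the second-moment ellipse;
    the timepoint diameter is the mean over slices.  Slices whose
    segmentation fails are skipped with a warning; a timepoint where every
    slice fails is an error.
    """
    if isinstance(stacks, np.ndarray) and stacks.ndim == 5:
        stacks = list(stacks)
    diameters, n_used = [], []
    for t, stack in enumerate(stacks):
        planes = stack[:, channel] if stack.ndim == 4 else stack
        vals = []
        for iz in range(planes.shape[0]):
            img = ProjectedImage(pixels=planes[iz], channel=channel, mode="max",
                                 pixel_size_um=pixel_size_um, frame=t)
            try:
                vals.append(slice_diameter_um(img, smooth_sigma_um=smooth_sigma_um,
                                              closing_radius_um=closing_radius_um))
            except ValueError as exc:
                warnings.warn(f"timepoint {t} slice {iz}: {exc}; slice skipped",
                              stacklevel=2)
        if not vals:
            raise ValueError(f"no slice of timepoint {t} could be segmented")
        diameters.append(float(np.mean(vals)))
        n_used.append(len(vals))
    diameters = np.asarray(diameters)
    return DiameterSeries(mean_diameter_um=diameters,
                          rel_diameter_pct=100.0 * diameters / diameters[0],
                          n_slices_used=np.asarray(n_used))


# ---------------------------------------------------------------------------
# proliferation
# ---------------------------------------------------------------------------

def edu_threshold(intensities: np.ndarray, strategy: str = "otsu",
                  fixed_value: float | None = None, mad_k: float = 3.0) -> float:
    """Per-organoid EdU positivity threshold on per-nucleus mean intensities.

    ``otsu`` assumes a bimodal positive/negative intensity mixture;
    ``fixed`` uses an absolute value; ``mad`` uses median + k·MAD.
    """
    x = np.asarray(intensities, float)
    if strategy == "otsu":
        from skimage.filters import threshold_otsu
        return float(threshold_otsu(x, nbins=256))
    if strategy == "fixed":
        if fixed_value is None:
            raise ConfigurationError("fixed strategy requires fixed_value")
        return float(fixed_value)
    if strategy == "mad":
        med = float(np.median(x))
        mad = float(np.median(np.abs(x - med)))
        return med + mad_k * mad
    raise ConfigurationError(f"unknown threshold strategy {strategy!r}")


def proliferation_map(detections: pd.DataFrame, site_xy_um,
                      circle: CircleModel | None = None,
                      threshold_strategy: str = "otsu",
                      fixed_value: float | None = None, mad_k: float = 3.0,
                      labels: np.ndarray | None = None,
                      bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
                      distance_metric: str = "arc") -> ProliferationResult:
    """EdU-positive fraction overall and per arc-distance bin.

    ``detections`` needs x_um/y_um and — unless explicit boolean ``labels``
    are supplied (bypass mode) — a mean_intensity_ch1 column from which
    positivity is called by the configured threshold strategy.  Empty bins
    are absent from the result, never reported as zero.
    """
    if len(detections) == 0:
        raise ValueError("no detections")
    xy = detections[["x_um", "y_um"]].to_numpy(float)
    thr = None
    if labels is None:
        inten = detections["mean_intensity_ch1"].to_numpy(float)
        thr = edu_threshold(inten, threshold_strategy, fixed_value, mad_k)
        labels = inten > thr
    labels = np.asarray(labels, bool)
    if len(labels) != len(xy):
        raise ConfigurationError("labels length mismatch")

    dist, circle, _site = geometry.cell_distances(xy, site_xy_um, circle,
                                                  metric=distance_metric)
    bins = geometry.bin_indices(dist, bin_width_um)
    per_bin_rate, per_bin_counts = {}, {}
    for b in np.unique(bins):
        sel = bins == b
        pos, tot = int(labels[sel].sum()), int(sel.sum())
        per_bin_counts[int(b)] = (pos, tot)
        per_bin_rate[int(b)] = pos / tot
    return ProliferationResult(
        overall_rate=float(labels.mean()), per_bin_rate=per_bin_rate,
        per_bin_counts=per_bin_counts, bin_width_um=bin_width_um, threshold=thr)


# ---------------------------------------------------------------------------
# migration
# ---------------------------------------------------------------------------

def migration_map(tracks: list[Track], site_xy_um,
                  circle: CircleModel | None = None,
                  metric: str = "path_length_um",
                  reference_frame: int = 0, n_frames: int | None = None,
                  min_duration_frac: float = 0.5,
                  bin_width_um: float = DEFAULT_BIN_WIDTH_UM,
                  distance_metric: str = "arc") -> MigrationResult:
    """Mean migration distance overall and per arc-distance bin.

    Each retained track is binned by its arc distance from the wound at the
    reference frame (tracks not covering that frame use their first
    position).  Tracks spanning fewer than ``min_duration_frac`` of the
    movie's frames are excluded — partial tracks bias distance sums.  The
    migration metric is configurable; total path length is the default
    headline metric.
    """
    if n_frames is None:
        n_frames = 1 + max((int(t.frames[-1]) for t in tracks if t.n_points), default=0)
    retained = [t for t in tracks if t.n_points >= min_duration_frac * n_frames]
    if not retained:
        raise ValueError("no tracks retained for migration statistics")

    ref_xy = []
    for t in retained:
        hit = np.where(t.frames == reference_frame)[0]
        ref_xy.append(t.xy_um[hit[0]] if len(hit) else t.xy_um[0])
    ref_xy = np.asarray(ref_xy)
    if circle is None:
        circle = geometry.fit_circle(ref_xy)
    dist, circle, _site = geometry.cell_distances(ref_xy, site_xy_um, circle,
                                                  metric=distance_metric)
    bins = geometry.bin_indices(dist, bin_width_um)
    values = np.array([t.metric(metric) for t in retained])

    per_bin_mean, per_bin_n = {}, {}
    for b in np.unique(bins):
        sel = bins == b
        per_bin_mean[int(b)] = float(values[sel].mean())
        per_bin_n[int(b)] = int(sel.sum())
    return MigrationResult(overall_mean_um=float(values.mean()),
                           per_bin_mean_um=per_bin_mean, per_bin_n=per_bin_n,
                           metric=metric, bin_width_um=bin_width_um)


# ---------------------------------------------------------------------------
# cross-organoid aggregation
# ---------------------------------------------------------------------------

def aggregate_condition(results: list, bin_width_um: float | None = None) -> pd.DataFrame:
    """Mean ± SEM across organoids, per bin and overall.

    ``results`` are ProliferationResult or MigrationResult objects from one
    condition; each organoid contributes one value per bin, and organoids
    lacking a bin are excluded from that bin (absence is not a zero).
    Returns a tidy frame: bin_index, bin_lo_um, bin_hi_um, mean, sem,
    n_organoids (bin_index = -1 marks the overall row).
    """
    from .stats import sem as _sem

    if len(results) < 2:
        raise ValueError("need >= 2 organoids for a condition summary")
    if bin_width_um is None:
        bin_width_um = results[0].bin_width_um

    def _values(res):
        if isinstance(res, ProliferationResult):
            return res.overall_rate, res.per_bin_rate
        if isinstance(res, MigrationResult):
            return res.overall_mean_um, res.per_bin_mean_um
        raise ConfigurationError(f"cannot aggregate {type(res).__name__}")

    overall, per_bin = [], {}
    for res in results:
        o, pb = _values(res)
        overall.append(o)
        for b, v in pb.items():
            per_bin.setdefault(b, []).append(v)

    rows = [{"bin_index": -1, "bin_lo_um": np.nan, "bin_hi_um": np.nan,
             "mean": float(np.mean(overall)), "sem": _sem(overall),
             "n_organoids": len(overall)}]
    for b in sorted(per_bin):
        vals = per_bin[b]
        rows.append({"bin_index": b, "bin_lo_um": b * bin_width_um,
                     "bin_hi_um": (b + 1) * bin_width_um,
                     "mean": float(np.mean(vals)),
                     "sem": _sem(vals) if len(vals) >= 2 else np.nan,
                     "n_organoids": len(vals)})
    return pd.DataFrame(rows)
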