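"""Projection, nucleus detection, intensity readout and organoid segmentation.

The analysis works on 2D representations of the z-stacks: maximum-intensity
projections for tracking, sum projections for EdU quantification.  Nuclei are
found with a deterministic Laplacian-of-Gaussian blob detector — blob-like
fluorescent nuclei at a known scale need no trained model, and every
downstream stage also accepts externally supplied point tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthgen import ConfigurationError

DETECTION_COLUMNS = ["frame", "cell_index", "x_um", "y_um", "radius_um",
                     "mean_intensity_ch0", "mean_intensity_ch1"]


@dataclass(frozen=True)
class ProjectedImage:
    """A 2D projection of one frame/channel of a z-stack."""

    pixels: np.ndarray
    channel: int
    mode: str
    pixel_size_um: float
    frame: int = 0


@dataclass
class NucleusDetection:
    """One detected nucleus in one frame; positions in µm (image frame)."""

    cell_index: int
    x_um: float
    y_um: float
    radius_um: float
    mean_intensity: dict[int, float] = field(default_factory=dict)
    border_clipped: bool = False


@dataclass(frozen=True)
class OrganoidMask:
    """Binary whole-organoid mask with its area and centroid."""

    mask: np.ndarray
    area_um2: float
    centroid_xy_um: tuple[float, float]
    pixel_size_um: float


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project(stack: np.ndarray, channel: int = 0, mode: str = "max",
            z_window: tuple[int, int] | None = None, frame: int = 0,
            pixel_size_um: float = 1.0) -> ProjectedImage:
    """Project a stack to 2D by per-pixel max or sum over selected z-slices.

    ``stack`` may be (T, Z, C, Y, X), (Z, C, Y, X) or (Z, Y, X);
    ``z_window`` is a half-open slice-index range (default: all slices).
    """
    if mode not in ("max", "sum"):
        raise ConfigurationError(f"unknown projection mode {mode!r}")
    if stack.ndim == 5:
        sub = stack[frame, :, channel]
    elif stack.ndim == 4:
        sub = stack[:, channel]
    elif stack.ndim == 3:
        sub = stack
    else:
        raise ConfigurationError(f"expected 3-5D stack, got {stack.ndim}D")
    if z_window is not None:
        lo, hi = z_window
        sub = sub[lo:hi]
    if sub.shape[0] == 0:
        raise ConfigurationError("empty z window")
    pixels = sub.max(axis=0) if mode == "max" else sub.sum(axis=0, dtype=np.float64)
    return ProjectedImage(pixels=np.asarray(pixels), channel=channel, mode=mode,
                          pixel_size_um=pixel_size_um, frame=frame)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def detect_nuclei(img: ProjectedImage, sigma_um: float = 1.0,
                  min_separation_um: float = 2.0, rel_threshold: float = 0.15,
                  exclusion_center_um: tuple[float, float] | None = None,
                  exclusion_radius_um: float = 0.0) -> list[NucleusDetection]:
    """Detect nuclei as scale-normalized Laplacian-of-Gaussian maxima.

    Local maxima of the LoG response at scale ``sigma_um`` exceeding
    ``rel_threshold`` × the peak response and separated by at least
    ``min_separation_um`` are kept; subpixel positions come from the
    intensity-weighted centroid of the positive response in a 2σ window.
    An optional exclusion disc around a declared ablation site suppresses
    detections inside the autofluorescent scar.
    """
    if sigma_um <= 0:
        raise ConfigurationError("sigma_um must be > 0")
    px = img.pixel_size_um
    sigma_px = sigma_um / px
    data = np.asarray(img.pixels, dtype=np.float64)
    # scale-normalized negative LoG: bright blobs become positive peaks
    resp = -(sigma_px ** 2) * ndimage.gaussian_laplace(data, sigma_px)

    hi = float(resp.max())
    if hi <= 0:
        return []
    threshold = rel_threshold * hi
    min_sep_px = max(1, int(round(min_separation_um / px)))
    footprint = np.ones((2 * min_sep_px + 1, 2 * min_sep_px + 1), bool)
    local_max = (resp == ndimage.maximum_filter(resp, footprint=footprint))
    peaks = np.argwhere(local_max & (resp > threshold) & (resp > 0))

    half = max(1, int(round(2 * sigma_px)))
    h, w = resp.shape
    out: list[NucleusDetection] = []
    pos = np.clip(resp, 0, None)
    for i, (r, c) in enumerate(peaks):
        r0, r1 = max(r - half, 0), min(r + half + 1, h)
        c0, c1 = max(c - half, 0), min(c + half + 1, w)
        win = pos[r0:r1, c0:c1]
        tot = win.sum()
        if tot > 0:
            yy, xx = np.mgrid[r0:r1, c0:c1]
            y_px = float((win * yy).sum() / tot)
            x_px = float((win * xx).sum() / tot)
        else:
            y_px, x_px = float(r), float(c)
        x_um, y_um = x_px * px, y_px * px
        if exclusion_center_um is not None and exclusion_radius_um > 0:
            ex, ey = exclusion_center_um
            if (x_um - ex) ** 2 + (y_um - ey) ** 2 <= exclusion_radius_um ** 2:
                continue
        out.append(NucleusDetection(cell_index=len(out), x_um=x_um, y_um=y_um,
                                    radius_um=np.sqrt(2) * sigma_um))
    return out


def measure_intensity(detections: list[NucleusDetection],
                      img_by_channel: dict[int, ProjectedImage],
                      aperture_um: float) -> list[NucleusDetection]:
    """Fill ``mean_intensity`` per channel: mean over a disc of radius ``aperture_um``.

    Discs clipped by the image border are measured over the clipped area and
    flagged via ``border_clipped``.
    """
    if aperture_um <= 0:
        raise ConfigurationError("aperture_um must be > 0")
    for det in detections:
        for ch, img in img_by_channel.items():
            px = img.pixel_size_um
            data = np.asarray(img.pixels, dtype=np.float64)
            h, w = data.shape
            r_px = aperture_um / px
            cx, cy = det.x_um / px, det.y_um / px
            x0, x1 = int(np.floor(cx - r_px)), int(np.ceil(cx + r_px)) + 1
            y0, y1 = int(np.floor(cy - r_px)), int(np.ceil(cy + r_px)) + 1
            clipped = x0 < 0 or y0 < 0 or x1 > w or y1 > h
            x0c, x1c = max(x0, 0), min(x1, w)
            y0c, y1c = max(y0, 0), min(y1, h)
            yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
            disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px ** 2
            if disc.sum() == 0:
                det.mean_intensity[ch] = 0.0
            else:
                det.mean_intensity[ch] = float(data[y0c:y1c, x0c:x1c][disc].mean())
            if clipped:
                det.border_clipped = True
    return detections


def detections_to_frame(detections: list[NucleusDetection], frame: int = 0) -> pd.DataFrame:
    """Tabulate detections with the standard CSV schema."""
    return pd.DataFrame({
        "frame": frame,
        "cell_index": [d.cell_index for d in detections],
        "x_um": [d.x_um for d in detections],
        "y_um": [d.y_um for d in detections],
        "radius_um": [d.radius_um for d in detections],
        "mean_intensity_ch0": [d.mean_intensity.get(0, np.nan) for d in detections],
        "mean_intensity_ch1": [d.mean_intensity.get(1, np.nan) for d in detections],
    }, columns=DETECTION_COLUMNS)


# ---------------------------------------------------------------------------
# organoid segmentation
# ---------------------------------------------------------------------------

def segment_organoid(img: ProjectedImage, smooth_sigma_um: float = 2.0,
                     closing_radius_um: float = 10.0,
                     min_snr: float = 5.0) -> OrganoidMask:
    """Segment the whole organoid: Gaussian smooth, Otsu threshold,
    morphological closing, keep the largest connected component, fill holes.

    The closing (disc radius ``closing_radius_um``) bridges the gaps between
    neighbouring nuclei so the epithelial ring encloses the lumen before
    hole filling; being a dilation followed by an erosion it leaves the
    outer boundary position unbiased to first order.
    """
    from skimage.filters import threshold_otsu

    data = np.asarray(img.pixels, dtype=np.float64)
    if data.size == 0:
        raise ConfigurationError("empty image")
    px = img.pixel_size_um
    smooth = ndimage.gaussian_filter(data, smooth_sigma_um / px)
    if smooth.max() <= smooth.min():
        raise ValueError("no organoid found")
    fg = smooth > threshold_otsu(smooth)
    if not fg.any() or fg.all():
        raise ValueError("no organoid found")
    # reject slices without real signal (e.g. z-planes beyond the organoid):
    # Otsu splits pure noise at ~2-3 noise SDs of separation
    bg = smooth[~fg]
    bg_sd = float(bg.std())
    if bg_sd > 0 and (float(smooth[fg].mean()) - float(bg.mean())) < min_snr * bg_sd:
        raise ValueError("no organoid found")
    if closing_radius_um > 0:
        # exact Euclidean closing via two distance transforms (fast for
        # large radii): dilation = dist-to-foreground <= r, erosion of the
        # dilated set = dist-to-its-background > r
        r = closing_radius_um / px
        dilated = ndimage.distance_transform_edt(~fg) <= r
        fg = ndimage.distance_transform_edt(dilated) > r
    lab, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    mask = ndimage.binary_fill_holes(lab == (1 + int(np.argmax(sizes))))
    cy, cx = ndimage.center_of_mass(mask)
    return OrganoidMask(mask=mask, area_um2=float(mask.sum()) * px * px,
                        centroid_xy_um=(float(cx * px), float(cy * px)),
                        pixel_size_um=px)
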