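"""Synthetic organoid time-lapse generator.

Airway organoids are nearly centrosymmetric epithelial spheres; a confocal
section through the ablation plane shows the epithelium as a ring of nuclei.
The generator therefore models an organoid as a 2D ring of cells (static
radial jitter, tangential motion only) and renders it into multi-channel,
multi-timepoint z-stacks.  Every simulated quantity — positions, EdU labels,
ablated cells, circle geometry — is recorded in a ground-truth table so that
detection, tracking, geometry and rate estimation can be scored exactly.

Coordinates are micrometres with the origin at the image top-left corner and
y increasing downward; angles are radians in [-pi, pi) measured from the +x
axis with positive angles toward +y.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

TRUTH_COLUMNS = ["frame", "cell_id", "x_um", "y_um", "angle_rad", "edu_label", "ablated"]


class ConfigurationError(ValueError):
    """A generator or pipeline parameter is out of its valid range."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrganoidSpec:
    """Geometry and timing of one simulated organoid.

    Defaults follow the imaging design of the study this package emulates:
    ~148-µm organoids (radius 74 µm), frames every 30 min over 6 h, z-stacks
    of ±8 µm at 2-µm steps, and ~6 % diameter growth per 24 h
    (``growth_rate_per_h`` is the relative diameter increase per hour).
    """

    n_cells: int = 100
    radius_um: float = 74.0
    radial_jitter_um: float = 2.0
    angle_jitter_frac: float = 0.1  # SD of angular jitter, fraction of cell spacing
    nucleus_sigma_um: float = 1.0
    growth_rate_per_h: float = 0.0025
    frame_interval_min: float = 30.0
    n_frames: int = 13
    z_range_um: float = 8.0
    z_step_um: float = 2.0
    pixel_size_um: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 3:
            raise ConfigurationError("n_cells must be >= 3")
        for name in ("radius_um", "z_step_um", "pixel_size_um", "nucleus_sigma_um"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("radial_jitter_um", "angle_jitter_frac", "frame_interval_min",
                     "z_range_um"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if self.growth_rate_per_h < 0:
            raise ConfigurationError("growth_rate_per_h must be >= 0")

    @property
    def z_positions_um(self) -> np.ndarray:
        n = int(round(self.z_range_um / self.z_step_um))
        return np.arange(-n, n + 1) * self.z_step_um

    @property
    def duration_h(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_min / 60.0


@dataclass(frozen=True)
class MotionSpec:
    """Tangential random walk plus optional wound-directed drift.

    ``sigma_tangential_um`` is the per-frame SD of the tangential step;
    ``drift_speed_um_per_frame`` is added toward the wound for cells whose
    arc distance from it is below ``drift_range_um``.
    """

    sigma_tangential_um: float = 0.8
    drift_speed_um_per_frame: float = 0.0
    drift_range_um: float = 60.0

    def validate(self) -> None:
        for name in ("sigma_tangential_um", "drift_speed_um_per_frame", "drift_range_um"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass(frozen=True)
class LabelSpec:
    """Distance-dependent EdU labeling probabilities.

    Each cell is labeled independently with probability
    ``baseline_rate + bin_boosts.get(bin_index, 0)`` where the bin index is
    derived from the cell's arc distance to the wound.  ``channel_contrast``
    is the EdU-channel mean-intensity ratio of labeled to unlabeled nuclei.
    """

    baseline_rate: float = 0.13
    bin_boosts: dict[int, float] = field(default_factory=dict)
    channel_contrast: float = 5.0

    def validate(self) -> None:
        if not 0.0 <= self.baseline_rate <= 1.0:
            raise ConfigurationError("baseline_rate must be in [0, 1]")
        for b, boost in self.bin_boosts.items():
            p = self.baseline_rate + boost
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"bin_boosts[{b}] yields probability {p:.3f} outside [0, 1]")
        if self.channel_contrast <= 0:
            raise ConfigurationError("channel_contrast must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated organoid.

    ``cells`` holds one row per (frame, cell): frame, cell_id, x_um, y_um,
    angle_rad, edu_label, ablated.  Ablated cells have rows only up to and
    including the ablation frame.  The circle centre is fixed; the radius
    follows the growth law and is recorded per frame.
    """

    cells: pd.DataFrame
    circle_center_xy_um: tuple[float, float]
    circle_radius_um_per_frame: np.ndarray
    fov_um: float
    spec: OrganoidSpec
    radial_offset_um: np.ndarray  # per-cell static offset from the shell radius
    ablation_center_xy_um: tuple[float, float] | None = None
    ablation_frame: int | None = None
    ablation_theta_rad: float | None = None

    def frame_table(self, frame: int) -> pd.DataFrame:
        return self.cells[self.cells["frame"] == frame].reset_index(drop=True)

    @property
    def n_frames_present(self) -> int:
        if len(self.cells) == 0:
            return 1
        return int(self.cells["frame"].max()) + 1


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def _wrap_angle(theta):
    """Wrap to [-pi, pi)."""
    return np.mod(np.asarray(theta) + np.pi, 2 * np.pi) - np.pi


def make_organoid(spec: OrganoidSpec) -> SyntheticTruth:
    """Place ``spec.n_cells`` on a jittered ring; return frame-0 ground truth.

    Angles are equally spaced with Gaussian jitter of SD
    ``angle_jitter_frac`` × spacing plus a random global rotation; each
    cell's radius is drawn once from N(radius_um, radial_jitter_um²) and the
    offset is kept fixed for the whole time-lapse (cells stay in the shell).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    spacing = 2 * np.pi / n
    theta = np.arange(n) * spacing + rng.uniform(0, 2 * np.pi)
    theta = _wrap_angle(theta + rng.normal(0, spec.angle_jitter_frac * spacing, n))
    radial_offset = rng.normal(0.0, spec.radial_jitter_um, n)

    # field of view sized for the fully grown organoid plus a rendering margin
    r_final = spec.radius_um * (1 + spec.growth_rate_per_h * spec.duration_h)
    margin = 4 * spec.radial_jitter_um + 8 * spec.nucleus_sigma_um + 5.0
    fov = 2 * (r_final + margin)
    cx = cy = fov / 2.0

    r = spec.radius_um + radial_offset
    df = pd.DataFrame({
        "frame": 0,
        "cell_id": np.arange(n),
        "x_um": cx + r * np.cos(theta),
        "y_um": cy + r * np.sin(theta),
        "angle_rad": theta,
        "edu_label": False,
        "ablated": False,
    })
    return SyntheticTruth(
        cells=df,
        circle_center_xy_um=(cx, cy),
        circle_radius_um_per_frame=np.array([spec.radius_um]),
        fov_um=fov,
        spec=spec,
        radial_offset_um=radial_offset,
    )


def apply_ablation(truth: SyntheticTruth, k: int, frame: int = 0,
                   seed: int | None = None) -> SyntheticTruth:
    """Mark ``k`` angularly contiguous cells as ablated at ``frame``.

    The ablation site is the circular mean of the victims' angles, mapped to
    the shell circle.  Ablated cells keep their rows up to the ablation frame
    and are removed from all later frames by :func:`simulate_timelapse`.
    """
    n = truth.spec.n_cells
    if not 1 <= k < n:
        raise ConfigurationError(f"k must satisfy 1 <= k < n_cells, got {k}")
    rng = np.random.default_rng(truth.spec.seed + 1 if seed is None else seed)

    frame0 = truth.frame_table(0)
    order = np.argsort(frame0["angle_rad"].to_numpy())
    start = int(rng.integers(n))
    victims = frame0["cell_id"].to_numpy()[order[(start + np.arange(k)) % n]]

    cells = truth.cells.copy()
    cells.loc[cells["cell_id"].isin(victims), "ablated"] = True

    ang = frame0.set_index("cell_id").loc[victims, "angle_rad"].to_numpy()
    theta0 = float(np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang))))
    cx, cy = truth.circle_center_xy_um
    r = float(truth.circle_radius_um_per_frame[min(frame, len(truth.circle_radius_um_per_frame) - 1)])
    site = (cx + r * np.cos(theta0), cy + r * np.sin(theta0))

    return dataclasses.replace(
        truth, cells=cells, ablation_center_xy_um=site,
        ablation_frame=frame, ablation_theta_rad=theta0)


def simulate_timelapse(truth: SyntheticTruth, motion: MotionSpec) -> SyntheticTruth:
    """Propagate frame-0 truth through all frames of ``truth.spec``.

    Per frame each surviving cell's angle advances by N(0, (σ_t/R)²); cells
    within ``drift_range_um`` arc distance of the wound take an extra step of
    ``drift_speed_um_per_frame`` toward the wound angle, clamped so they stop
    at the wound rather than overshooting.  The shell radius follows
    R(t) = R0·(1 + g·t_hours); per-cell radial offsets are static.
    """
    motion.validate()
    spec = truth.spec
    rng = np.random.default_rng(spec.seed + 2)
    dt_h = spec.frame_interval_min / 60.0

    frame0 = truth.frame_table(0)
    cell_ids = frame0["cell_id"].to_numpy()
    theta = frame0["angle_rad"].to_numpy().astype(float)
    ablated = frame0["ablated"].to_numpy()
    labels = frame0["edu_label"].to_numpy()
    offsets = truth.radial_offset_um
    cx, cy = truth.circle_center_xy_um
    abl_frame = truth.ablation_frame if truth.ablation_frame is not None else -1

    radii = spec.radius_um * (1 + spec.growth_rate_per_h * dt_h * np.arange(spec.n_frames))

    rows = [frame0.assign(frame=0)]
    for f in range(1, spec.n_frames):
        R = radii[f]
        step = rng.normal(0.0, motion.sigma_tangential_um / R, size=len(theta))
        if (motion.drift_speed_um_per_frame > 0 and truth.ablation_theta_rad is not None
                and f > abl_frame):
            dtheta = _wrap_angle(truth.ablation_theta_rad - theta)
            in_range = np.abs(dtheta) * R <= motion.drift_range_um
            drift = np.sign(dtheta) * np.minimum(
                motion.drift_speed_um_per_frame / R, np.abs(dtheta))
            step = step + np.where(in_range, drift, 0.0)
        theta = _wrap_angle(theta + step)
        alive = ~ablated if f > abl_frame and abl_frame >= 0 else np.ones(len(theta), bool)
        r = R + offsets[alive]
        rows.append(pd.DataFrame({
            "frame": f,
            "cell_id": cell_ids[alive],
            "x_um": cx + r * np.cos(theta[alive]),
            "y_um": cy + r * np.sin(theta[alive]),
            "angle_rad": theta[alive],
            "edu_label": labels[alive],
            "ablated": ablated[alive],
        }))

    cells = pd.concat(rows, ignore_index=True)
    return dataclasses.replace(truth, cells=cells, circle_radius_um_per_frame=radii)


def assign_edu_labels(truth: SyntheticTruth, labels: LabelSpec,
                      bin_width_um: float = 30.0,
                      seed: int | None = None) -> SyntheticTruth:
    """Label each surviving cell EdU-positive with a distance-dependent probability.

    The cell's bin is computed from its arc distance to the wound at the last
    simulated frame (the EdU readout is a single fixed timepoint).  With no
    ablation only ``baseline_rate`` applies and ``bin_boosts`` must be empty.
    """
    labels.validate()
    if labels.bin_boosts and truth.ablation_theta_rad is None:
        raise ConfigurationError("bin_boosts require an ablation site")
    rng = np.random.default_rng(truth.spec.seed + 3 if seed is None else seed)

    last = truth.n_frames_present - 1
    tbl = truth.frame_table(last)
    p = np.full(len(tbl), labels.baseline_rate)
    if truth.ablation_theta_rad is not None:
        R = float(truth.circle_radius_um_per_frame[min(last, len(truth.circle_radius_um_per_frame) - 1)])
        dtheta = np.abs(_wrap_angle(tbl["angle_rad"].to_numpy() - truth.ablation_theta_rad))
        dist = R * np.minimum(dtheta, 2 * np.pi - dtheta)
        bins = np.floor(dist / bin_width_um).astype(int)
        for b, boost in labels.bin_boosts.items():
            p = np.where(bins == b, p + boost, p)
    flags = rng.random(len(tbl)) < p
    lab_by_id = dict(zip(tbl["cell_id"], flags))

    cells = truth.cells.copy()
    cells["edu_label"] = cells["cell_id"].map(lambda c: bool(lab_by_id.get(c, False)))
    return dataclasses.replace(truth, cells=cells)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderSpec:
    """Photometry of the rendered stacks (arbitrary photon-count units)."""

    nuclear_amplitude: float = 150.0
    edu_negative_amplitude: float = 30.0
    axial_sigma_um: float = 3.0
    background: float = 5.0
    read_noise_sd: float = 2.0
    noise: bool = True
    scar_frames: int = 4
    scar_sigma_um: float = 4.0
    scar_amplitude: float = 400.0


def _paint_gaussians(plane: np.ndarray, xs_px, ys_px, amps, sigma_px: float) -> None:
    """Add 2D Gaussians onto ``plane`` in-place, each on a ±4σ patch."""
    h, w = plane.shape
    half = max(1, int(np.ceil(4 * sigma_px)))
    for x, y, a in zip(xs_px, ys_px, amps):
        x0, x1 = int(np.floor(x)) - half, int(np.floor(x)) + half + 1
        y0, y1 = int(np.floor(y)) - half, int(np.floor(y)) + half + 1
        x0c, x1c, y0c, y1c = max(x0, 0), min(x1, w), max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        gx = np.exp(-0.5 * ((np.arange(x0c, x1c) - x) / sigma_px) ** 2)
        gy = np.exp(-0.5 * ((np.arange(y0c, y1c) - y) / sigma_px) ** 2)
        plane[y0c:y1c, x0c:x1c] += a * np.outer(gy, gx)


def render_stack(truth: SyntheticTruth, spec: OrganoidSpec | None = None,
                 labels: LabelSpec | None = None,
                 render: RenderSpec | None = None,
                 frames: list[int] | None = None) -> np.ndarray:
    """Render the truth into a (frames, z, channel, y, x) float32 stack.

    Channel 0 is the nuclear label (every cell), channel 1 the EdU channel
    (labeled cells brighter by ``labels.channel_contrast``).  Nuclei are 3D
    Gaussians (lateral σ = ``nucleus_sigma_um``, Gaussian axial attenuation)
    in the z = 0 plane.  An ablation scar — a bright static blob mimicking
    wound autofluorescence — is drawn in both channels for
    ``render.scar_frames`` frames after ablation and is absent from the
    ground truth.  Poisson shot noise plus Gaussian read noise are applied
    when ``render.noise`` is set.  ``frames`` restricts rendering to the
    listed frame indices (e.g. only the fixed EdU imaging timepoint).
    """
    spec = spec or truth.spec
    labels = labels or LabelSpec()
    render = render or RenderSpec()
    px = spec.pixel_size_um
    side = int(np.ceil(truth.fov_um / px))
    zs = spec.z_positions_um
    frame_list = list(range(truth.n_frames_present)) if frames is None else list(frames)

    r_max = float(np.max(truth.circle_radius_um_per_frame)) + 4 * spec.radial_jitter_um
    if 2 * r_max > truth.fov_um:
        raise ConfigurationError(
            f"field of view ({truth.fov_um:.0f} µm) smaller than organoid "
            f"({2 * r_max:.0f} µm)")

    rng = np.random.default_rng(spec.seed + 4)
    sigma_px = spec.nucleus_sigma_um / px
    stack = np.zeros((len(frame_list), len(zs), 2, side, side), dtype=np.float32)

    abl_frame = truth.ablation_frame if truth.ablation_frame is not None else None
    for out_f, f in enumerate(frame_list):
        tbl = truth.frame_table(f)
        xs = tbl["x_um"].to_numpy() / px
        ys = tbl["y_um"].to_numpy() / px
        lab = tbl["edu_label"].to_numpy()
        amp_nuc = np.full(len(tbl), render.nuclear_amplitude)
        amp_edu = np.where(lab, labels.channel_contrast, 1.0) * render.edu_negative_amplitude
        for iz, z in enumerate(zs):
            att = float(np.exp(-0.5 * (z / render.axial_sigma_um) ** 2))
            _paint_gaussians(stack[out_f, iz, 0], xs, ys, amp_nuc * att, sigma_px)
            _paint_gaussians(stack[out_f, iz, 1], xs, ys, amp_edu * att, sigma_px)
        if (abl_frame is not None and truth.ablation_center_xy_um is not None
                and abl_frame < f + 1 and f - abl_frame < render.scar_frames):
            sx, sy = truth.ablation_center_xy_um
            for iz, z in enumerate(zs):
                att = float(np.exp(-0.5 * (z / (2 * render.axial_sigma_um)) ** 2))
                for c in range(2):
                    _paint_gaussians(stack[out_f, iz, c], [sx / px], [sy / px],
                                     [render.scar_amplitude * att],
                                     render.scar_sigma_um / px)

    stack += render.background
    if render.noise:
        stack = rng.poisson(stack).astype(np.float32)
        stack += rng.normal(0.0, render.read_noise_sd, stack.shape).astype(np.float32)
        np.clip(stack, 0, None, out=stack)
    return stack


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def write_stack(path, stack: np.ndarray, spec: OrganoidSpec) -> None:
    """Write a (T, Z, C, Y, X) stack as TIFF with axes and pixel-size metadata."""
    tifffile.imwrite(
        path, stack, imagej=False,
        metadata={"axes": "TZCYX", "pixel_size_um": spec.pixel_size_um,
                  "z_step_um": spec.z_step_um,
                  "frame_interval_min": spec.frame_interval_min})


def read_stack(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack; returns (array, metadata dict).

    Falls back to assuming (T, Z, C, Y, X) axis order when the file carries
    no axes metadata.
    """
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    meta = dict(meta) if meta else {}
    meta.setdefault("axes", "TZCYX"[-arr.ndim:] if arr.ndim <= 5 else "TZCYX")
    return arr, meta


def write_truth(path, truth: SyntheticTruth) -> None:
    truth.cells.to_csv(path, index=False, columns=TRUTH_COLUMNS)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["edu_label"] = df["edu_label"].astype(bool)
    df["ablated"] = df["ablated"].astype(bool)
    return df
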