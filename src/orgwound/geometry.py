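"""Shell geometry: circle fitting, wound localization and arc distances.

All cells of an organoid section lie near a circle (the epithelial shell);
every spatial readout is expressed as the geodesic distance along that
fitted circle from the ablation site, binned into 30-µm intervals.  Arc
length, not chord length, is used: on a ~150-µm organoid the chordal
distance can never exceed the diameter, while arc distance reaches half the
circumference (~235 µm), which is what distance bins beyond 180 µm require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthgen import ConfigurationError

DEFAULT_BIN_WIDTH_UM = 30.0


@dataclass(frozen=True)
class CircleModel:
    """Least-squares circle through the cell positions."""

    cx_um: float
    cy_um: float
    r_um: float
    rms_residual_um: float

    @property
    def center(self) -> np.ndarray:
        return np.array([self.cx_um, self.cy_um])


@dataclass(frozen=True)
class AblationSite:
    """The wound reference point and its angle on the fitted circle."""

    x_um: float
    y_um: float
    theta0_rad: float


@dataclass(frozen=True)
class DistanceBin:
    """Half-open arc-distance interval [lo_um, hi_um)."""

    index: int
    lo_um: float
    hi_um: float

    def __str__(self) -> str:
        return f"{self.lo_um:g}-{self.hi_um:g} um"


# ---------------------------------------------------------------------------
# circle fitting
# ---------------------------------------------------------------------------

def fit_circle(points: np.ndarray) -> CircleModel:
    """Algebraic least-squares circle (Kåsa fit).

    Solves the linear system minimizing Σ (x² + y² + D·x + E·y + F)² and
    converts to centre/radius; exact on noiseless circles and on any three
    non-collinear points.  ``rms_residual_um`` is the RMS of the geometric
    residuals |dist − r|.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ConfigurationError("need at least 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([x, y, np.ones_like(x)])
    b = x * x + y * y
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise ConfigurationError("points are collinear or degenerate")
    cx, cy = sol[0] / 2.0, sol[1] / 2.0
    r2 = sol[2] + cx * cx + cy * cy
    if r2 <= 0:
        raise ConfigurationError("degenerate circle fit")
    r = float(np.sqrt(r2))
    resid = np.hypot(x - cx, y - cy) - r
    return CircleModel(cx_um=float(cx), cy_um=float(cy), r_um=r,
                       rms_residual_um=float(np.sqrt(np.mean(resid ** 2))))


def refine_circle(circle: CircleModel, points: np.ndarray, tol: float = 1e-8,
                  max_iter: int = 50) -> CircleModel:
    """Gauss–Newton refinement of the geometric (orthogonal) residuals.

    Optional: the algebraic fit is already exact on noiseless rings; the
    refinement matters only for strongly non-uniform angular coverage.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    p = np.array([circle.cx_um, circle.cy_um, circle.r_um])
    for _ in range(max_iter):
        dx = pts[:, 0] - p[0]
        dy = pts[:, 1] - p[1]
        d = np.hypot(dx, dy)
        d = np.where(d == 0, 1e-12, d)
        r_vec = d - p[2]
        J = np.column_stack([-dx / d, -dy / d, -np.ones_like(d)])
        step, *_ = np.linalg.lstsq(J, -r_vec, rcond=None)
        p = p + step
        if np.linalg.norm(step) < tol:
            break
    dx = pts[:, 0] - p[0]
    dy = pts[:, 1] - p[1]
    resid = np.hypot(dx, dy) - p[2]
    return CircleModel(cx_um=float(p[0]), cy_um=float(p[1]), r_um=float(p[2]),
                       rms_residual_um=float(np.sqrt(np.mean(resid ** 2))))


# ---------------------------------------------------------------------------
# angles and distances
# ---------------------------------------------------------------------------

def project_angle(point, circle: CircleModel) -> float:
    """Angle of the centre-to-point ray, in [-pi, pi)."""
    x, y = np.asarray(point, float)
    if x == circle.cx_um and y == circle.cy_um:
        raise ConfigurationError("point coincides with circle centre")
    theta = float(np.arctan2(y - circle.cy_um, x - circle.cx_um))
    return -np.pi if theta == np.pi else theta


def locate_site(point, circle: CircleModel) -> AblationSite:
    """Project a declared ablation position onto the fitted circle."""
    theta0 = project_angle(point, circle)
    return AblationSite(x_um=float(point[0]), y_um=float(point[1]),
                        theta0_rad=theta0)


def arc_distance(theta, site: AblationSite, circle: CircleModel):
    """Geodesic distance r·Δθ along the circle, Δθ = min(|θ−θ0|, 2π−|θ−θ0|)."""
    dtheta = np.abs(np.asarray(theta, float) - site.theta0_rad) % (2 * np.pi)
    dtheta = np.minimum(dtheta, 2 * np.pi - dtheta)
    out = circle.r_um * dtheta
    return float(out) if np.isscalar(theta) else out


def assign_bin(distance_um: float, bin_width_um: float = DEFAULT_BIN_WIDTH_UM) -> DistanceBin:
    """Half-open 30-µm (default) distance bin: index = floor(d / width)."""
    if distance_um < 0:
        raise ConfigurationError("distance must be >= 0")
    if bin_width_um <= 0:
        raise ConfigurationError("bin_width_um must be > 0")
    idx = int(np.floor(distance_um / bin_width_um))
    return DistanceBin(index=idx, lo_um=idx * bin_width_um,
                       hi_um=(idx + 1) * bin_width_um)


def bin_indices(distances_um, bin_width_um: float = DEFAULT_BIN_WIDTH_UM) -> np.ndarray:
    """Vectorized bin assignment."""
    d = np.asarray(distances_um, float)
    if (d < 0).any():
        raise ConfigurationError("distances must be >= 0")
    return np.floor(d / bin_width_um).astype(int)


def cell_distances(xy_um: np.ndarray, site_xy_um, circle: CircleModel | None = None,
                   metric: str = "arc"):
    """Arc (default) or chordal distances of cells from the ablation site.

    Fits the circle to ``xy_um`` when none is given; both the cells and the
    site are projected onto the circle for the arc metric.
    """
    xy = np.atleast_2d(np.asarray(xy_um, float))
    if circle is None:
        circle = fit_circle(xy)
    site = locate_site(site_xy_um, circle)
    if metric == "chord":
        d = np.hypot(xy[:, 0] - site.x_um, xy[:, 1] - site.y_um)
    elif metric == "arc":
        theta = np.arctan2(xy[:, 1] - circle.cy_um, xy[:, 0] - circle.cx_um)
        d = arc_distance(theta, site, circle)
    else:
        raise ConfigurationError(f"unknown distance metric {metric!r}")
    return d, circle, site
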