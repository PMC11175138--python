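"""Pupil-centre tracking: mask -> boundary -> ellipse -> 1D gaze trace.

The horizontal position of the pupil centre is the sole feature the
downstream nystagmus detector sees, so this module turns per-frame binary
pupil masks into a validated, gap-free 1D time series:

1. the outer boundary of the largest connected mask component is extracted;
2. a direct least-squares ellipse (stable Halir & Flusser formulation of
   the Fitzgibbon algebraic fit) gives the sub-pixel centre;
3. implausible detections (tiny/huge masks, large inter-frame jumps,
   degenerate fits) are flagged invalid, and a guard band around every
   invalid frame is invalidated too, since neighbouring frames of a failed
   detection are themselves suspect;
4. gaps are bridged by carrying the last detected position forward —
   deliberately NOT by linear interpolation, which would fabricate the very
   slow-phase ramps the detector is trained to find.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "EllipseFit", "GazeTrace",
    "extract_boundary", "fit_ellipse", "track", "flag_invalid", "bridge",
    "DEFAULT_GUARD", "DEFAULT_AREA_MIN", "DEFAULT_AREA_MAX_FRAC",
    "DEFAULT_JUMP_MAX",
]

# plausibility gates, tuned for 320x240 preprocessed eye images; callers
# working at other resolutions scale them (see pipeline)
DEFAULT_AREA_MIN = 50.0          # px^2
DEFAULT_AREA_MAX_FRAC = 0.3      # fraction of image area
DEFAULT_JUMP_MAX = 40.0          # px from the last valid centre
DEFAULT_GUARD = 5                # frames invalidated on each side


@dataclass
class EllipseFit:
    """Least-squares ellipse: centre (px), semi-axes (px), angle (deg)."""

    center_x: float = np.nan
    center_y: float = np.nan
    semi_major: float = np.nan
    semi_minor: float = np.nan
    angle: float = np.nan  # major-axis angle from +x, degrees in [0, 180)
    valid: bool = False


@dataclass
class GazeTrace:
    """Per-frame horizontal pupil-centre positions with validity flags."""

    x: np.ndarray
    valid: np.ndarray
    fps: float = 30.0
    eye: str = "left"
    source: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.x.shape != self.valid.shape:
            raise ValueError("x and valid must have equal length")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def usable(self) -> bool:
        """False when no frame has a valid detection."""
        return bool(self.valid.any())

    def copy(self) -> "GazeTrace":
        return replace(self, x=self.x.copy(), valid=self.valid.copy())


# ---------------------------------------------------------------------------
# boundary extraction and ellipse fitting
# ---------------------------------------------------------------------------

def extract_boundary(mask: np.ndarray) -> np.ndarray:
    """Outer boundary of the largest connected foreground component.

    Returns an ordered ``(n, 2)`` array of sub-pixel (x, y) points from the
    0.5-level contour; an empty ``(0, 2)`` array for an empty mask. Smaller
    components (e.g. mask fragments split off by a specular glint) are
    ignored.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.empty((0, 2))
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:  # pragma: no cover - nonempty mask always has one
        return np.empty((0, 2))
    boundary = max(contours, key=len)
    return boundary[:, ::-1]  # (row, col) -> (x, y)


def fit_ellipse(points: np.ndarray) -> EllipseFit:
    """Direct least-squares conic fit constrained to an ellipse.

    Uses the numerically stable Halir & Flusser partitioning of the
    Fitzgibbon algebraic fit (the ellipse-specific constraint
    ``4ac - b^2 = 1``), then converts the conic to geometric parameters via
    the eigen-decomposition of its quadratic part. Exact for noise-free
    conic samples. Degenerate inputs (< 5 points, (near-)collinear points,
    or a non-elliptical conic) return ``valid=False``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 5:
        return EllipseFit()
    x, y = pts[:, 0], pts[:, 1]
    # centre/scale for conditioning; fold back at the end
    mx, my = x.mean(), y.mean()
    s = max(x.std(), y.std(), 1e-12)
    xs, ys = (x - mx) / s, (y - my) / s

    d1 = np.column_stack([xs * xs, xs * ys, ys * ys])
    d2 = np.column_stack([xs, ys, np.ones_like(xs)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError:
        return EllipseFit()
    m = s1 + s2 @ t
    # premultiply by inv(C1), C1 the ellipse-constraint matrix
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    try:
        eigval, eigvec = np.linalg.eig(m)
    except np.linalg.LinAlgError:
        return EllipseFit()
    # the ellipse solution is the eigenvector with 4ac - b^2 > 0
    ev = np.real(eigvec)
    cond = 4.0 * ev[0] * ev[2] - ev[1] ** 2
    good = np.where(np.isreal(eigval) & (cond > 0))[0]
    if len(good) == 0:
        return EllipseFit()
    a1 = np.real(eigvec[:, good[0]])
    coeffs = np.concatenate([a1, t @ a1])  # A, B, C, D, E, F (scaled frame)

    fit = _conic_to_ellipse(coeffs)
    if fit is None:
        return EllipseFit()
    cx, cy, smaj, smin, angle = fit
    return EllipseFit(center_x=cx * s + mx, center_y=cy * s + my,
                      semi_major=smaj * s, semi_minor=smin * s,
                      angle=angle, valid=True)


def _conic_to_ellipse(coeffs: np.ndarray):
    """Convert conic Ax^2+Bxy+Cy^2+Dx+Ey+F=0 to centre/axes/angle."""
    a, b, c, d, e, f = coeffs
    m2 = np.array([[a, b / 2.0], [b / 2.0, c]])
    try:
        center = np.linalg.solve(m2, [-d / 2.0, -e / 2.0])
    except np.linalg.LinAlgError:
        return None
    f0 = f + (d * center[0] + e * center[1]) / 2.0
    lam, vec = np.linalg.eigh(m2)
    radii_sq = -f0 / lam
    if not np.all(np.isfinite(radii_sq)) or np.any(radii_sq <= 0):
        return None
    radii = np.sqrt(radii_sq)
    major = int(np.argmax(radii))
    angle = np.degrees(np.arctan2(vec[1, major], vec[0, major])) % 180.0
    return (center[0], center[1], radii.max(), radii.min(), angle)


# ---------------------------------------------------------------------------
# per-frame tracking and gap handling
# ---------------------------------------------------------------------------

def track(masks: np.ndarray, fps: float = 30.0, eye: str = "left",
          source: str = "", area_min: float = DEFAULT_AREA_MIN,
          area_max_frac: float = DEFAULT_AREA_MAX_FRAC,
          jump_max: float = DEFAULT_JUMP_MAX) -> GazeTrace:
    """Convert a per-frame pupil-mask stack into a raw horizontal gaze trace.

    A frame is marked invalid when its largest mask component is smaller
    than ``area_min`` or larger than ``area_max_frac`` of the image, when
    the ellipse fit is degenerate, when the fitted centre lies outside the
    image, or when the centre jumps more than ``jump_max`` px from the last
    valid frame — all symptoms of a blink or a mis-segmentation rather than
    a real eye movement.
    """
    masks = np.asarray(masks)
    if masks.ndim != 3 or masks.shape[0] == 0:
        raise ValueError("masks must be a nonempty (T, H, W) stack")
    n, h, w = masks.shape
    area_max = area_max_frac * h * w
    x = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    last = None
    for t in range(n):
        mask = masks[t] > 0
        area = float(mask.sum())
        if not (area_min <= area <= area_max):
            continue
        fit = fit_ellipse(extract_boundary(mask))
        if not fit.valid:
            continue
        if not (0 <= fit.center_x < w and 0 <= fit.center_y < h):
            continue
        if last is not None and abs(fit.center_x - last) > jump_max:
            continue
        x[t] = fit.center_x
        valid[t] = True
        last = fit.center_x
    return GazeTrace(x=x, valid=valid, fps=fps, eye=eye, source=source)


def flag_invalid(trace: GazeTrace, guard: int = DEFAULT_GUARD) -> GazeTrace:
    """Dilate invalid runs by ``guard`` frames on each side.

    Frames adjacent to a failed detection are unreliable (the eye is
    half-closed, the mask partial), so each invalid frame invalidates its
    +/- guard neighbourhood. ``guard=0`` is the identity.
    """
    if guard < 0:
        raise ValueError("guard must be >= 0")
    out = trace.copy()
    if guard == 0 or out.valid.all():
        return out
    bad = ndimage.binary_dilation(~out.valid, structure=np.ones(2 * guard + 1))
    out.valid = ~bad
    out.x[bad] = np.nan
    return out


def bridge(trace: GazeTrace) -> GazeTrace:
    """Fill every gap with the last detected position (fill-forward).

    Linear interpolation across a gap can manufacture a slow linear drift —
    exactly the slow-phase signature of nystagmus — so gaps are instead held
    at the position detected immediately before them. Leading frames with no
    prior detection take the first valid value. A trace with no valid frame
    at all is returned unchanged (``usable`` stays False); callers must
    check :attr:`GazeTrace.usable`.

    Idempotent, never changes a valid sample, and introduces no new extrema.
    """
    out = trace.copy()
    if not trace.usable:
        return out
    idx = np.where(out.valid, np.arange(len(out)), -1)
    idx = np.maximum.accumulate(idx)
    first = int(np.argmax(out.valid))
    idx[idx < 0] = first
    out.x = out.x[idx]
    out.valid = np.ones(len(out), dtype=bool)
    return out
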