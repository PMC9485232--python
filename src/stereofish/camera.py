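"""Pinhole stereo-rig geometry.

Models the vertical-baseline stereo camera used for parallax-based fish
sizing: two identical pinhole cameras separated by an 8-cm vertical
baseline.  Provides projection, Brown radial distortion, pixel disparity
("translation") between the stereo frames, and the analytic
disparity-to-scale relationship that the empirical chessboard calibration
approximates.

Conventions
-----------
Pixel coordinates are 0-based with the origin at the top-left corner,
``u`` increasing rightward and ``v`` increasing downward.  World
coordinates are expressed in the frame of camera *a* (the upper camera):
``x`` rightward, ``y`` downward, ``z`` along the optical axis (metres,
``z > 0`` in front of the lens).  Camera *b* sits ``baseline`` metres
below camera *a*.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "CameraIntrinsics",
    "RadialDistortion",
    "StereoRig",
    "PixelPoint",
    "WorldPoint",
    "default_rig",
    "project",
    "apply_distortion",
    "undistort",
    "disparity",
    "ideal_scale_from_disparity",
    "load_rig",
    "save_rig",
]


@dataclass(frozen=True)
class PixelPoint:
    """A point in image coordinates (pixels, origin top-left)."""

    u: float
    v: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.u) and math.isfinite(self.v)):
            raise ValueError(f"pixel coordinates must be finite, got ({self.u}, {self.v})")

    def as_array(self) -> np.ndarray:
        return np.array([self.u, self.v], dtype=float)


@dataclass(frozen=True)
class WorldPoint:
    """A point in the camera-a frame (metres); z is distance along the optical axis."""

    x: float
    y: float
    z: float


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics.

    ``focal_px`` is the focal length expressed in pixels per axis
    (f_x = F / p_x, f_y = F / p_y, where F is the focal length and
    p_x, p_y the pixel pitch).  ``skew`` is f_x * tan(alpha) and is zero
    for perpendicular sensor axes.  When only the field of view is known
    (as for the study rig), use :meth:`from_fov`.
    """

    focal_px: tuple[float, float]
    principal_point: tuple[float, float]
    sensor_resolution: tuple[int, int]
    skew: float = 0.0
    field_of_view: tuple[float, float] | None = None
    focal_length_mm: float | None = None
    pixel_size_mm: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        fx, fy = self.focal_px
        if fx <= 0 or fy <= 0:
            raise ValueError("focal_px components must be positive")
        w, h = self.sensor_resolution
        cx, cy = self.principal_point
        if not (0 <= cx < w and 0 <= cy < h):
            raise ValueError("principal point must lie inside the sensor")

    @classmethod
    def from_fov(
        cls,
        resolution: tuple[int, int],
        fov_deg: tuple[float, float],
        skew: float = 0.0,
        square_pixels: bool = False,
    ) -> "CameraIntrinsics":
        """Derive pixel focal lengths from the field of view.

        f = (extent / 2) / tan(FOV / 2), applied independently to each
        axis; the principal point defaults to the sensor centre.  With
        ``square_pixels=True`` the horizontal FOV alone sets a common
        focal length for both axes — nominal datasheet FOVs are rounded
        and deriving the axes independently would imply a spurious ~2%
        pixel anisotropy on a square-pixel sensor.
        """
        w, h = resolution
        fh, fv = fov_deg
        fx = (w / 2) / math.tan(math.radians(fh) / 2)
        fy = fx if square_pixels else (h / 2) / math.tan(math.radians(fv) / 2)
        return cls(
            focal_px=(fx, fy),
            principal_point=(w / 2, h / 2),
            sensor_resolution=(w, h),
            skew=skew,
            field_of_view=(fh, fv),
        )


@dataclass(frozen=True)
class RadialDistortion:
    """Two-coefficient Brown radial distortion; (0, 0) is the identity."""

    k1: float = 0.0
    k2: float = 0.0

    @property
    def is_identity(self) -> bool:
        return self.k1 == 0.0 and self.k2 == 0.0


@dataclass(frozen=True)
class StereoRig:
    """Two identical cameras on a vertical baseline.

    ``medium_index`` is an empirical refractive scaling applied to the
    pixel focal lengths (1.0 in air, ~1.33 as a flat-port water
    approximation); it is a synthetic-data knob, not a ray-traced
    refraction model — the field calibration absorbs refraction
    empirically.
    """

    camera_a: CameraIntrinsics
    camera_b: CameraIntrinsics
    baseline: float = 0.08
    distortion: RadialDistortion = field(default_factory=RadialDistortion)
    medium_index: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        if self.camera_a.sensor_resolution != self.camera_b.sensor_resolution:
            raise ValueError("both cameras must share sensor resolution")

    def camera(self, which: Literal["a", "b"]) -> CameraIntrinsics:
        if which == "a":
            return self.camera_a
        if which == "b":
            return self.camera_b
        raise ValueError(f"which_camera must be 'a' or 'b', got {which!r}")

    def effective_focal(self, which: Literal["a", "b"] = "a") -> tuple[float, float]:
        """Pixel focal lengths scaled by the medium index."""
        fx, fy = self.camera(which).focal_px
        return fx * self.medium_index, fy * self.medium_index


def default_rig(
    baseline: float = 0.08,
    distortion: RadialDistortion | None = None,
    medium_index: float = 1.0,
) -> StereoRig:
    """The study rig: 3280x2464 sensors, 54 deg H x 41 deg V nominal FOV,
    8-cm vertical baseline, square pixels (f = 3218.7 px from the
    horizontal FOV)."""
    cam = CameraIntrinsics.from_fov((3280, 2464), (54.0, 41.0), square_pixels=True)
    return StereoRig(
        camera_a=cam,
        camera_b=cam,
        baseline=baseline,
        distortion=distortion or RadialDistortion(),
        medium_index=medium_index,
    )


def project(point: WorldPoint, rig: StereoRig, which_camera: Literal["a", "b"]) -> PixelPoint:
    """Project a world point into one of the two cameras.

    Camera b is displaced ``baseline`` metres down the y (image-vertical)
    axis, so the point's y coordinate is shifted by -baseline in its
    frame; an on-axis target therefore appears higher in frame b, giving
    a positive vertical disparity f_y * B / z.  Radial distortion, if
    any, is applied after the pinhole projection.
    """
    if point.z <= 0:
        raise ValueError(f"cannot project a point with z <= 0 (got z={point.z})")
    cam = rig.camera(which_camera)
    fx, fy = rig.effective_focal(which_camera)
    cx, cy = cam.principal_point
    y = point.y - (rig.baseline if which_camera == "b" else 0.0)
    u = fx * (point.x / point.z) + cam.skew * (y / point.z) + cx
    v = fy * (y / point.z) + cy
    p = PixelPoint(u, v)
    if not rig.distortion.is_identity:
        p = apply_distortion(p, cam, rig.distortion)
    return p


def _normalize(p: PixelPoint, cam: CameraIntrinsics) -> tuple[float, float]:
    fx, fy = cam.focal_px
    cx, cy = cam.principal_point
    return (p.u - cx) / fx, (p.v - cy) / fy


def _denormalize(x: float, y: float, cam: CameraIntrinsics) -> PixelPoint:
    fx, fy = cam.focal_px
    cx, cy = cam.principal_point
    return PixelPoint(x * fx + cx, y * fy + cy)


def apply_distortion(p: PixelPoint, cam: CameraIntrinsics, d: RadialDistortion) -> PixelPoint:
    """Apply the Brown radial model on normalized coordinates.

    x_d = x_u * (1 + k1 r^2 + k2 r^4) with r^2 = x_u^2 + y_u^2; this
    produces the barrel (k1 < 0) or pincushion (k1 > 0) warping the
    chessboard calibration is designed to absorb.
    """
    if d.is_identity:
        return p
    x, y = _normalize(p, cam)
    r2 = x * x + y * y
    factor = 1.0 + d.k1 * r2 + d.k2 * r2 * r2
    return _denormalize(x * factor, y * factor, cam)


def undistort(
    p: PixelPoint,
    cam: CameraIntrinsics,
    d: RadialDistortion,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> PixelPoint:
    """Invert the radial distortion by fixed-point iteration.

    Starts from the distorted point and repeatedly divides by the radial
    factor evaluated at the current estimate; converges for moderate
    distortion (|k1| <= ~0.3 within the unit normalized radius).
    """
    if d.is_identity:
        return p
    xd, yd = _normalize(p, cam)
    x, y = xd, yd
    for _ in range(max_iter):
        r2 = x * x + y * y
        factor = 1.0 + d.k1 * r2 + d.k2 * r2 * r2
        if factor <= 0:
            raise ArithmeticError(
                f"radial factor became non-positive (r2={r2:.4g}, k1={d.k1}, k2={d.k2}); "
                "distortion too strong to invert at this radius"
            )
        x_new, y_new = xd / factor, yd / factor
        if abs(x_new - x) < tol and abs(y_new - y) < tol:
            x, y = x_new, y_new
            break
        x, y = x_new, y_new
    else:
        raise ArithmeticError(
            f"undistortion failed to converge after {max_iter} iterations "
            f"(point=({p.u:.2f}, {p.v:.2f}), k1={d.k1}, k2={d.k2})"
        )
    return _denormalize(x, y, cam)


def disparity(p_a: PixelPoint, p_b: PixelPoint) -> float:
    """Euclidean pixel distance between corresponding points in the two frames.

    For this vertical-baseline rig the disparity is dominated by the
    vertical component; the Euclidean norm also captures any residual
    horizontal offset from noise or misalignment.
    """
    return float(np.hypot(p_a.u - p_b.u, p_a.v - p_b.v))


def vertical_disparity(p_a: PixelPoint, p_b: PixelPoint) -> float:
    """Vertical-only disparity (config alternative to the Euclidean norm)."""
    return abs(p_a.v - p_b.v)


def ideal_scale_from_disparity(rig: StereoRig, d: float) -> float:
    """Analytic micron/pixel scale implied by a disparity, for an aligned rig.

    From v_a - v_b = f_y B / z and the vertical metric scale z / f_y
    (m/pixel), the scale is B * 1e6 / d micron/pixel — independent of
    the focal length.  This is the parallax oracle the empirical
    chessboard calibration curve approximates.
    """
    if d <= 0:
        raise ValueError(f"disparity must be positive, got {d}")
    return rig.baseline * 1e6 / d


def disparity_at_distance(rig: StereoRig, z: float) -> float:
    """Noiseless vertical disparity f_y * B / z of a target at depth z."""
    if z <= 0:
        raise ValueError("distance must be positive")
    _, fy = rig.effective_focal("a")
    return fy * rig.baseline / z


def distance_for_disparity(rig: StereoRig, d: float) -> float:
    """Depth z at which an on-axis target shows disparity d (inverse of the above)."""
    if d <= 0:
        raise ValueError("disparity must be positive")
    _, fy = rig.effective_focal("a")
    return fy * rig.baseline / d


# ---------------------------------------------------------------------------
# serialization


def _rig_to_dict(rig: StereoRig) -> dict:
    return {
        "camera_a": asdict(rig.camera_a),
        "camera_b": asdict(rig.camera_b),
        "baseline": rig.baseline,
        "distortion": asdict(rig.distortion),
        "medium_index": rig.medium_index,
    }


def _intrinsics_from_dict(d: dict) -> CameraIntrinsics:
    return CameraIntrinsics(
        focal_px=tuple(d["focal_px"]),
        principal_point=tuple(d["principal_point"]),
        sensor_resolution=tuple(d["sensor_resolution"]),
        skew=d.get("skew", 0.0),
        field_of_view=tuple(d["field_of_view"]) if d.get("field_of_view") else None,
        focal_length_mm=d.get("focal_length_mm"),
        pixel_size_mm=tuple(d["pixel_size_mm"]) if d.get("pixel_size_mm") else None,
    )


def save_rig(rig: StereoRig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_rig_to_dict(rig), indent=2))


def load_rig(path: str | Path) -> StereoRig:
    d = json.loads(Path(path).read_text())
    return StereoRig(
        camera_a=_intrinsics_from_dict(d["camera_a"]),
        camera_b=_intrinsics_from_dict(d["camera_b"]),
        baseline=d["baseline"],
        distortion=RadialDistortion(**d["distortion"]),
        medium_index=d.get("medium_index", 1.0),
    )
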