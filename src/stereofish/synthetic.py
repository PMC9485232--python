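"""Seeded synthetic stereo scenes with ground truth.

Generates every input the pipeline consumes — chessboard calibration
sessions, silhouette validation batches, and free-swimming fish scenes —
by projecting known geometry through the pinhole stereo rig and adding
pixel-level landmark jitter.  The jitter stands in for the landmark
CNN's localisation error; fish are rendered as their two landmarks (a
horizontal body segment), since no other pixel carries information for
the downstream measurement.

Every generator is driven by a single integer seed and emits a paired
(annotations, truth) set of tables, so every downstream statistic can be
scored exactly without re-deriving the geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .camera import (
    StereoRig,
    WorldPoint,
    default_rig,
    disparity_at_distance,
    distance_for_disparity,
    project,
)
from .calibration import MIN_TRANSLATION_PX, ChessboardSpec

__all__ = [
    "SceneConfig",
    "PopulationConfig",
    "SILHOUETTE_LENGTHS_CM",
    "generate_chessboard_session",
    "generate_silhouette_validation",
    "generate_fish_population",
    "generate_fish_scene",
    "field_scene_config",
]

# Standard lengths (cm) of the four plastic silhouettes used for
# measurement-error validation.
SILHOUETTE_LENGTHS_CM = (22.0, 24.2, 29.0, 33.6)


@dataclass(frozen=True)
class SceneConfig:
    """Acquisition geometry and noise for synthetic scenes.

    ``landmark_jitter_sd`` (pixels) is isotropic Gaussian noise added to
    every projected landmark coordinate, emulating CNN localisation
    error.  ``yaw_sd`` (degrees) rotates fish about the vertical axis,
    foreshortening their projected length by cos(yaw); keep it 0 for
    validation targets and positive for field emulation.
    """

    rig: StereoRig
    distance_range: tuple[float, float] = (0.3, 2.0)
    landmark_jitter_sd: float = 2.0
    yaw_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.distance_range
        if not (0 < lo <= hi):
            raise ValueError("distance_range must be positive and ordered")
        if self.landmark_jitter_sd < 0:
            raise ValueError("landmark_jitter_sd must be >= 0")

    @classmethod
    def for_disparity_range(
        cls,
        rig: StereoRig | None = None,
        min_disparity: float = MIN_TRANSLATION_PX,
        max_disparity: float = 600.0,
        **kwargs,
    ) -> "SceneConfig":
        """Config whose distance range spans the given disparity band on this rig."""
        rig = rig or default_rig()
        z_near = distance_for_disparity(rig, max_disparity)
        z_far = distance_for_disparity(rig, min_disparity)
        return cls(rig=rig, distance_range=(z_near, z_far), **kwargs)


def field_scene_config(rig: StereoRig | None = None, seed: int = 0) -> SceneConfig:
    """Field-emulation preset: wide depth range (0.3-3.6 m, so roughly half
    the fish fall below the 140-px disparity threshold) and 25-degree yaw sd."""
    return SceneConfig(rig=rig or default_rig(), distance_range=(0.3, 3.6), yaw_sd=25.0, seed=seed)


@dataclass(frozen=True)
class PopulationConfig:
    """Fish population model: normal standard lengths, power-law weights.

    Defaults match the field sample of the farmed seabream cage this
    generator emulates: n = 190, SL ~ N(27.1, 1.6^2) cm, and weights
    from W = 0.1342 * SL^2.5465 with multiplicative log-normal noise.
    """

    n: int = 190
    sl_mean_cm: float = 27.1
    sl_sd_cm: float = 1.6
    lwr_a: float = 0.1342
    lwr_b: float = 2.5465
    weight_noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sl_mean_cm <= 0 or self.sl_sd_cm <= 0:
            raise ValueError("sl_mean_cm and sl_sd_cm must be positive")


def _project_segment(
    rig: StereoRig,
    x0: float,
    y0: float,
    z: float,
    length_m: float,
    rng: np.random.Generator,
    jitter_sd: float,
):
    """Project a horizontal segment [x0, x0+length] x {y0} x {z} into both
    frames and jitter each landmark coordinate."""
    pts = {}
    for name, x in (("p1", x0), ("p2", x0 + length_m)):
        for frame in ("a", "b"):
            p = project(WorldPoint(x, y0, z), rig, frame)
            u = p.u + (rng.normal(0, jitter_sd) if jitter_sd > 0 else 0.0)
            v = p.v + (rng.normal(0, jitter_sd) if jitter_sd > 0 else 0.0)
            pts[(name, frame)] = (u, v)
    return pts


def _lateral_bounds(rig: StereoRig, z: float, margin_px: float = 100.0) -> tuple[float, float]:
    """Horizontal world extent (m) visible at depth z, with a pixel margin."""
    fx, _ = rig.effective_focal("a")
    w, _ = rig.camera_a.sensor_resolution
    half = (w / 2 - margin_px) / fx * z
    return -half, half


def generate_chessboard_session(
    n_poses: int = 52,
    pairs_per_pose: int = 4,
    cfg: SceneConfig | None = None,
    spec: ChessboardSpec | None = None,
    session_id: str = "synthetic",
    max_resample: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a chessboard calibration session.

    Calibration sessions deliberately cover the rig's working
    translation range, so pose depths are sampled uniformly in
    *disparity* over the band implied by the config's distance range
    (uniform-in-distance sampling would crowd the low-disparity end and
    leave the near field uncalibrated).  Each of the ``pairs_per_pose``
    landmark pairs spans an integer number of squares horizontally and
    is projected into both frames with landmark jitter.  Poses whose
    projection would leave the image are resampled.

    Returns ``(annotations, truth)``: the calibration annotation table
    (columns ``session_id, pose_id, pair_id, endpoint, frame, u, v,
    squares_spanned``) and a per-pose truth table with the exact
    distance, disparity and micron/pixel scale.
    """
    cfg = cfg or SceneConfig(rig=default_rig())
    spec = spec or ChessboardSpec()
    rng = np.random.default_rng(cfg.seed)
    rig = cfg.rig
    rows: list[dict] = []
    truth: list[dict] = []
    z_lo, z_hi = cfg.distance_range
    d_hi = disparity_at_distance(rig, z_lo)
    d_lo = disparity_at_distance(rig, z_hi)
    max_span = 7 * spec.square_size_mm / 1000.0  # widest landmark pair
    for pose in range(n_poses):
        for attempt in range(max_resample):
            z = distance_for_disparity(rig, rng.uniform(d_lo, d_hi))
            x_min, x_max = _lateral_bounds(rig, z)
            # the board may extend past the frame edge; only the widest
            # landmark pair must remain visible
            if x_max - max_span > x_min:
                break
        else:
            raise RuntimeError(f"could not place pose {pose} inside the image after {max_resample} tries")
        y0 = rng.uniform(-0.05, 0.05) * z
        d_true = disparity_at_distance(rig, z)
        truth.append(
            {
                "session_id": session_id,
                "pose_id": f"pose{pose:03d}",
                "distance_m": z,
                "disparity_px": d_true,
                "scale_micron_per_px": rig.baseline * 1e6 / d_true,
            }
        )
        for pair in range(pairs_per_pose):
            squares = int(rng.integers(3, 8))  # pairs span 3-7 squares
            sep_m = squares * spec.square_size_mm / 1000.0
            px0 = rng.uniform(x_min, x_max - sep_m)
            py0 = y0 + rng.uniform(-0.02, 0.02)
            pts = _project_segment(rig, px0, py0, z, sep_m, rng, cfg.landmark_jitter_sd)
            for (name, frame), (u, v) in pts.items():
                rows.append(
                    {
                        "session_id": session_id,
                        "pose_id": f"pose{pose:03d}",
                        "pair_id": f"pair{pair}",
                        "endpoint": 1 if name == "p1" else 2,
                        "frame": frame,
                        "u": u,
                        "v": v,
                        "squares_spanned": squares,
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(truth)


def generate_silhouette_validation(
    lengths_cm: tuple[float, ...] = SILHOUETTE_LENGTHS_CM,
    n_images: int = 17,
    cfg: SceneConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the plastic-silhouette measurement-error experiment.

    Each of ``n_images`` stereo photos contains all silhouettes placed
    fronto-parallel at a common distance; distances increase linearly
    across images over the config's range.  Returns ``(annotations,
    truth)`` in the fish-annotation dialect; silhouettes whose true
    disparity falls below the 140-px threshold are kept but flagged in
    the truth table (they exercise the QC path downstream).
    """
    cfg = cfg or SceneConfig.for_disparity_range()
    if any(l <= 0 for l in lengths_cm):
        raise ValueError("silhouette lengths must be positive")
    rng = np.random.default_rng(cfg.seed)
    rig = cfg.rig
    z_lo, z_hi = cfg.distance_range
    distances = np.linspace(z_lo, z_hi, n_images)
    rows: list[dict] = []
    truth: list[dict] = []
    for img, z in enumerate(distances):
        d_true = disparity_at_distance(rig, z)
        x_min, x_max = _lateral_bounds(rig, z)
        for k, sl in enumerate(lengths_cm):
            fish_id = f"img{img:02d}_sil{k}"
            length_m = sl / 100.0
            if x_max - length_m <= x_min:
                x0 = x_min
            else:
                x0 = rng.uniform(x_min, x_max - length_m)
            y0 = rng.uniform(-0.1, 0.1) * z
            pts = _project_segment(rig, x0, y0, z, length_m, rng, cfg.landmark_jitter_sd)
            for (name, frame), (u, v) in pts.items():
                rows.append(
                    {
                        "fish_id": fish_id,
                        "frame": frame,
                        "landmark": "snout" if name == "p1" else "caudal",
                        "u": u,
                        "v": v,
                        "confidence": 1.0,
                    }
                )
            truth.append(
                {
                    "fish_id": fish_id,
                    "image_id": img,
                    "true_sl_cm": sl,
                    "distance_m": z,
                    "disparity_px": d_true,
                    "below_threshold": d_true < MIN_TRANSLATION_PX,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(truth)


def generate_fish_population(cfg: PopulationConfig | None = None) -> pd.DataFrame:
    """Draw a fish population with known lengths and weights.

    SL ~ Normal(mean, sd) truncated at > 5 cm; weight = a * SL^b times
    multiplicative log-normal noise with the configured coefficient of
    variation (unit mean).
    """
    cfg = cfg or PopulationConfig()
    rng = np.random.default_rng(cfg.seed)
    sl = np.empty(cfg.n)
    filled = 0
    while filled < cfg.n:
        draw = rng.normal(cfg.sl_mean_cm, cfg.sl_sd_cm, cfg.n - filled)
        draw = draw[draw > 5.0]
        sl[filled : filled + draw.size] = draw
        filled += draw.size
    w = cfg.lwr_a * sl**cfg.lwr_b
    if cfg.weight_noise_cv > 0:
        sigma2 = np.log1p(cfg.weight_noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=cfg.n)
        w = w * noise
    return pd.DataFrame(
        {
            "fish_id": [f"fish{i:04d}" for i in range(cfg.n)],
            "true_sl_cm": sl,
            "true_weight_g": w,
        }
    )


def generate_fish_scene(
    population: pd.DataFrame,
    cfg: SceneConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place a fish population in front of the rig and image it.

    Each fish gets a uniform depth within the config's range and a yaw
    about the vertical axis drawn from N(0, yaw_sd); its projected body
    segment is the true SL foreshortened by cos(yaw).  Returns
    ``(annotations, truth)``; the truth table records the exact depth,
    disparity, yaw and whether the fish should fail the 140-px filter.
    """
    cfg = cfg or field_scene_config()
    rng = np.random.default_rng(cfg.seed)
    rig = cfg.rig
    z_lo, z_hi = cfg.distance_range
    rows: list[dict] = []
    truth: list[dict] = []
    for _, fish in population.iterrows():
        fid = str(fish["fish_id"])
        sl_cm = float(fish["true_sl_cm"])
        z = rng.uniform(z_lo, z_hi)
        yaw = np.radians(rng.normal(0, cfg.yaw_sd)) if cfg.yaw_sd > 0 else 0.0
        proj_len_m = sl_cm / 100.0 * abs(np.cos(yaw))
        x_min, x_max = _lateral_bounds(rig, z)
        x0 = rng.uniform(x_min, max(x_max - proj_len_m, x_min + 1e-9))
        y0 = rng.uniform(-0.15, 0.15) * z
        d_true = disparity_at_distance(rig, z)
        pts = _project_segment(rig, x0, y0, z, proj_len_m, rng, cfg.landmark_jitter_sd)
        for (name, frame), (u, v) in pts.items():
            rows.append(
                {
                    "fish_id": fid,
                    "frame": frame,
                    "landmark": "snout" if name == "p1" else "caudal",
                    "u": u,
                    "v": v,
                    "confidence": 1.0,
                }
            )
        truth.append(
            {
                "fish_id": fid,
                "true_sl_cm": sl_cm,
                "distance_m": z,
                "disparity_px": d_true,
                "yaw_deg": np.degrees(yaw),
                "projected_sl_cm": sl_cm * abs(np.cos(yaw)),
                "below_threshold": d_true < MIN_TRANSLATION_PX,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(truth)
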