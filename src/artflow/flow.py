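"""Synthetic ego-motion optic flow from dot-defined environments.

Simulates an observer translating (and optionally rotating) through a 3D
dot cloud or over a ground plane, and computes the first-order optic flow
(Longuet-Higgins & Prazdny) of every visible dot under a pinhole camera.

Coordinate conventions
----------------------
Camera frame: x right, y up, z forward (optical axis); right-handed.
Image coordinates: pixels relative to the principal point, y up.
Heading azimuth is right-positive about the vertical axis, elevation
up-positive; (0, 0) is straight ahead.  Rotation rates are (pitch, yaw,
roll) about the camera (x, y, z) axes, right-hand rule, in deg/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "CameraModel",
    "EgoMotion",
    "DotScene",
    "FlowFrame",
    "FlowSequence",
    "DatasetSpec",
    "heading_to_translation",
    "make_scene",
    "analytic_flow",
    "advance_scene",
    "render_sequence",
    "generate_dataset",
    "ENVIRONMENTS",
]


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera. Defaults: 512x512 px, 90 deg field of view, 30 fps."""

    width: int = 512
    height: int = 512
    fov: float = 90.0
    fps: float = 30.0
    focal_length_cm: float = 1.74

    @property
    def focal_length_px(self) -> float:
        # fov = 90 deg => f = width / 2
        return (self.width / 2.0) / np.tan(np.deg2rad(self.fov / 2.0))

    @property
    def deg_per_px(self) -> float:
        """Uniform small-angle scale used to convert px/frame to deg/s."""
        return self.fov / self.width

    @property
    def dt(self) -> float:
        return 1.0 / self.fps


@dataclass(frozen=True)
class EgoMotion:
    """Constant instantaneous self-motion: heading angles + rotation rates."""

    heading_azimuth: float = 0.0  # deg, right-positive
    heading_elevation: float = 0.0  # deg, up-positive
    translation_speed: float = 3.0  # m/s
    rotation_rates: tuple[float, float, float] = (0.0, 0.0, 0.0)  # pitch,yaw,roll deg/s

    @property
    def translation(self) -> np.ndarray:
        return heading_to_translation(
            self.heading_azimuth, self.heading_elevation, self.translation_speed
        )

    @property
    def omega_rad(self) -> np.ndarray:
        """Angular velocity about (x, y, z) in rad/s."""
        return np.deg2rad(np.asarray(self.rotation_rates, dtype=float))


def heading_to_translation(azimuth: float, elevation: float, speed: float) -> np.ndarray:
    """Unit heading direction scaled by speed (m/s), camera frame.

    azimuth/elevation in degrees; (0, 0) maps to the optical axis (0, 0, 1).
    """
    az = np.deg2rad(azimuth)
    el = np.deg2rad(elevation)
    return speed * np.array(
        [np.cos(el) * np.sin(az), np.sin(el), np.cos(el) * np.cos(az)]
    )


@dataclass
class DotScene:
    """Set of 3D dots in the camera frame.

    For ground scenes the supporting plane is tracked as ``n . P = -d``
    (initially n = (0, 1, 0), d = eye height), so that dots respawned
    mid-sequence land on the current plane even after camera motion.
    """

    kind: str  # {"cloud", "ground"}
    points: np.ndarray  # (n_dots, 3) metres
    depth_range: tuple[float, float] = (1.0, 50.0)
    eye_height: float = 1.61
    plane_normal: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    plane_offset: float = 1.61  # d in n . P = -d

    @property
    def n_dots(self) -> int:
        return len(self.points)


def _sample_cloud(n: int, camera: CameraModel, depth_range, rng) -> np.ndarray:
    """Dots uniform over the view-frustum cross-section at each depth."""
    f = camera.focal_length_px
    x_img = rng.uniform(-camera.width / 2, camera.width / 2, n)
    y_img = rng.uniform(-camera.height / 2, camera.height / 2, n)
    z = rng.uniform(depth_range[0], depth_range[1], n)
    return np.column_stack([x_img * z / f, y_img * z / f, z])


def _sample_ground(
    n: int, camera: CameraModel, depth_range, normal, offset, rng
) -> np.ndarray:
    """Dots uniform over the image-plane footprint of the visible ground patch.

    Rejection-samples image points whose viewing ray meets the plane at a
    depth inside ``depth_range``.
    """
    f = camera.focal_length_px
    pts = np.empty((0, 3))
    while len(pts) < n:
        m = max(4 * (n - len(pts)), 256)
        x_img = rng.uniform(-camera.width / 2, camera.width / 2, m)
        y_img = rng.uniform(-camera.height / 2, camera.height / 2, m)
        rays = np.column_stack([x_img / f, y_img / f, np.ones(m)])
        denom = rays @ normal
        with np.errstate(divide="ignore", invalid="ignore"):
            t = -offset / denom
        ok = (denom != 0) & (t > 0)
        z = rays[:, 2] * t
        ok &= (z >= depth_range[0]) & (z <= depth_range[1])
        pts = np.vstack([pts, rays[ok] * t[ok, None]])
    return pts[:n]


def make_scene(
    environment: str,
    camera: CameraModel,
    rng: np.random.Generator,
    n_dots: int = 2000,
    depth_range: tuple[float, float] = (1.0, 50.0),
    eye_height: float = 1.61,
) -> DotScene:
    """Draw a fresh dot scene ("cloud" or "ground") for one video sample."""
    kind = "ground" if environment.startswith("ground") else "cloud"
    normal = np.array([0.0, 1.0, 0.0])
    if kind == "cloud":
        pts = _sample_cloud(n_dots, camera, depth_range, rng)
    else:
        pts = _sample_ground(n_dots, camera, depth_range, normal, eye_height, rng)
    return DotScene(
        kind=kind,
        points=pts,
        depth_range=depth_range,
        eye_height=eye_height,
        plane_normal=normal,
        plane_offset=eye_height,
    )


def _project(points: np.ndarray, camera: CameraModel):
    f = camera.focal_length_px
    z = points[:, 2]
    return f * points[:, 0] / z, f * points[:, 1] / z


def analytic_flow(points: np.ndarray, ego: EgoMotion, camera: CameraModel):
    """First-order image motion of 3D points under instantaneous (T, omega).

    Returns ``(x_img, y_img, direction, speed)``: image positions in pixels
    (principal-point origin, y up), flow direction in radians and flow speed
    in deg/s.  The translational term scales with inverse depth; the
    rotational term is depth-independent.

    Raises ValueError if any point lies at or behind the camera (Z <= 0).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    z = points[:, 2]
    if np.any(z <= 0):
        raise ValueError("point behind camera (Z <= 0)")
    f = camera.focal_length_px
    x, y = _project(points, camera)
    tx, ty, tz = ego.translation
    wx, wy, wz = ego.omega_rad
    u = (x * tz - f * tx) / z + (-f * wy + y * wz + x * y * wx / f - x * x * wy / f)
    v = (y * tz - f * ty) / z + (f * wx - x * wz + y * y * wx / f - x * y * wy / f)
    # u, v are px/s; deg/s = px/frame * deg_per_px * fps = px/s * deg_per_px
    speed = np.hypot(u, v) * camera.deg_per_px
    direction = np.arctan2(v, u)
    return x, y, direction, speed


def _in_frustum(points: np.ndarray, camera: CameraModel, depth_range) -> np.ndarray:
    z = points[:, 2]
    ok = (z >= depth_range[0]) & (z <= depth_range[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        x = camera.focal_length_px * points[:, 0] / z
        y = camera.focal_length_px * points[:, 1] / z
    ok &= (np.abs(x) <= camera.width / 2) & (np.abs(y) <= camera.height / 2)
    return ok


def advance_scene(
    scene: DotScene,
    ego: EgoMotion,
    dt: float,
    camera: CameraModel,
    rng: np.random.Generator,
) -> DotScene:
    """Rigidly move the scene into the next camera frame; clip and respawn.

    The camera translates T*dt and rotates by omega*dt, so point coordinates
    transform as ``P' = R(omega dt)^T (P - T dt)``.  Dots leaving the view
    frustum or valid depth range are replaced with fresh draws from the
    scene's generating distribution, keeping the dot count constant.
    """
    t_step = ego.translation * dt
    omega = ego.omega_rad
    pts = scene.points - t_step
    normal = scene.plane_normal
    offset = scene.plane_offset + float(normal @ t_step)
    if np.any(omega):
        rot_inv = Rotation.from_rotvec(omega * dt).inv()
        pts = rot_inv.apply(pts)
        normal = rot_inv.apply(normal)
    ok = _in_frustum(pts, camera, scene.depth_range)
    n_bad = int(np.count_nonzero(~ok))
    if n_bad:
        if scene.kind == "cloud":
            fresh = _sample_cloud(n_bad, camera, scene.depth_range, rng)
        else:
            fresh = _sample_ground(
                n_bad, camera, scene.depth_range, normal, offset, rng
            )
        pts = pts.copy()
        pts[~ok] = fresh
    return replace(
        scene, points=pts, plane_normal=normal, plane_offset=offset,
        eye_height=offset,
    )


@dataclass
class FlowFrame:
    """Sparse flow field of one video frame (zero-speed vectors excluded)."""

    x: np.ndarray  # px, principal-point origin, y up
    y: np.ndarray
    direction: np.ndarray  # rad
    speed: np.ndarray  # deg/s

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class FlowSequence:
    frames: list[FlowFrame]
    labels: EgoMotion

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def render_sequence(
    ego: EgoMotion,
    environment: str,
    camera: CameraModel,
    rng: np.random.Generator,
    n_frames: int = 10,
    n_dots: int = 2000,
    depth_range: tuple[float, float] = (1.0, 50.0),
    eye_height: float = 1.61,
) -> FlowSequence:
    """Render one video sample: ``n_frames`` flow fields along a constant path."""
    scene = make_scene(environment, camera, rng, n_dots, depth_range, eye_height)
    frames = []
    for k in range(n_frames):
        if k:
            scene = advance_scene(scene, ego, camera.dt, camera, rng)
        x, y, direction, speed = analytic_flow(scene.points, ego, camera)
        moving = speed > 0
        frames.append(
            FlowFrame(x[moving], y[moving], direction[moving], speed[moving])
        )
    return FlowSequence(frames=frames, labels=ego)


#: dataset name -> (has_rotation, scene kind, default train/test sizes)
ENVIRONMENTS = {
    "cloud_T": (False, "cloud", 500, 250),
    "ground_T": (False, "ground", 500, 250),
    "cloud_TR": (True, "cloud", 1000, 500),
}


@dataclass(frozen=True)
class DatasetSpec:
    """Sampling conditions for one dot-defined dataset.

    Headings (azimuth and elevation) are Uniform(-45, 45) deg; for the
    translation+rotation environment a rotation magnitude Uniform(1, 10)
    deg/s is applied about an independent uniformly random 3D axis.
    """

    environment: str = "cloud_T"
    n_train: int | None = None
    n_test: int | None = None
    seed: int = 0
    heading_range: tuple[float, float] = (-45.0, 45.0)
    rotation_range: tuple[float, float] = (1.0, 10.0)
    translation_speed: float = 3.0
    n_frames: int = 10
    n_dots: int = 2000
    depth_range: tuple[float, float] = (1.0, 50.0)
    eye_height: float = 1.61

    def __post_init__(self):
        if self.environment not in ENVIRONMENTS:
            raise ValueError(f"unknown environment {self.environment!r}")
        _, _, tr, te = ENVIRONMENTS[self.environment]
        if self.n_train is None:
            object.__setattr__(self, "n_train", tr)
        if self.n_test is None:
            object.__setattr__(self, "n_test", te)

    @property
    def has_rotation(self) -> bool:
        return ENVIRONMENTS[self.environment][0]


def _sample_ego(spec: DatasetSpec, rng: np.random.Generator) -> EgoMotion:
    az, el = rng.uniform(*spec.heading_range, size=2)
    rates = (0.0, 0.0, 0.0)
    if spec.has_rotation:
        mag = rng.uniform(*spec.rotation_range)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        rates = tuple(mag * axis)
    return EgoMotion(az, el, spec.translation_speed, rates)


def _render_split(spec: DatasetSpec, camera: CameraModel, n: int, seed_seq):
    out = []
    for child in seed_seq.spawn(n):
        rng = np.random.default_rng(child)
        ego = _sample_ego(spec, rng)
        out.append(
            render_sequence(
                ego, spec.environment, camera, rng,
                n_frames=spec.n_frames, n_dots=spec.n_dots,
                depth_range=spec.depth_range, eye_height=spec.eye_height,
            )
        )
    return out


def generate_dataset(
    spec: DatasetSpec, camera: CameraModel | None = None
) -> tuple[list[FlowSequence], list[FlowSequence]]:
    """Generate the train and test splits (disjoint seed streams)."""
    camera = camera or CameraModel()
    train_ss, test_ss = np.random.SeedSequence(spec.seed).spawn(2)
    train = _render_split(spec, camera, spec.n_train, train_ss)
    test = _render_split(spec, camera, spec.n_test, test_ss)
    return train, test


def labels_frame(sequences: list[FlowSequence]):
    """Self-motion labels of a split as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for i, seq in enumerate(sequences):
        e = seq.labels
        p, yw, r = e.rotation_rates
        rows.append(
            dict(sample_id=i, azimuth_deg=e.heading_azimuth,
                 elevation_deg=e.heading_elevation,
                 pitch_dps=p, yaw_dps=yw, roll_dps=r)
        )
    return pd.DataFrame(rows)


def label_matrix(sequences: list[FlowSequence], targets: str = "heading") -> np.ndarray:
    """Label array: columns (az, el) or (az, el, pitch, yaw, roll)."""
    lab = np.array(
        [
            [s.labels.heading_azimuth, s.labels.heading_elevation,
             *s.labels.rotation_rates]
            for s in sequences
        ]
    )
    if targets == "heading":
        return lab[:, :2]
    if targets == "heading+rotation":
        return lab
    raise ValueError(f"unknown targets {targets!r}")
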