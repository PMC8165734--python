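"""Head-orientation estimation from labeled 2-D landmarks (perspective-n-point).

Given 4-9 labeled anatomical landmarks in an image, a 3-D head template with
the same labels, and pinhole camera intrinsics, recover the camera-frame
rotation and translation of the head.  The solver follows the EPnP scheme
(four control points, barycentric coordinates, null-space beta cases) and
refines the result by damped Gauss-Newton (Levenberg-Marquardt) minimization
of the full reprojection objective.  Near-planar landmark configurations are
seeded from a homography decomposition instead.

Conventions
-----------
Camera frame: x right, y down, z forward (into the scene).  Head frame: the
bird in left profile faces +x at zero rotation, so its left side faces the
camera.  Rotations decompose intrinsically yaw -> pitch -> roll, with yaw
signed so that -90 deg faces the camera and +90 deg faces away::

    R = R_y(-yaw) @ R_x(pitch) @ R_z(roll)      (angles in radians internally)

Pose quality is summarized by the mean Euclidean reprojection residual in
pixels; poses whose mean residual exceeds a threshold (default 25 px) are
flagged for exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LANDMARK_LABELS",
    "CameraModel",
    "HeadModel3D",
    "LandmarkObservation",
    "PoseEstimate",
    "default_head_template",
    "euler_to_rotation",
    "rotation_to_euler",
    "project_points",
    "solve_pnp",
    "reprojection_residuals",
    "qc_filter",
    "QC_THRESHOLD_PX",
]

#: The nine nameable head landmarks, in canonical order.
LANDMARK_LABELS = (
    "bill_tip",
    "upper_caudal_cyr",
    "lower_caudal_mandible",
    "left_lower_rostral_periorbital",
    "right_lower_rostral_periorbital",
    "left_eye_center",
    "right_eye_center",
    "left_lower_caudal_periorbital",
    "right_lower_caudal_periorbital",
)

#: Default mean-reprojection-residual retention threshold (pixels).
QC_THRESHOLD_PX = 25.0


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics (no distortion terms)."""

    fx: float = 1000.0
    fy: float = 1000.0
    cx: float = 320.0
    cy: float = 240.0
    width: int = 640
    height: int = 480

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx <= self.width and 0 <= self.cy <= self.height):
            raise ValueError("principal point must lie within the sensor")

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )


@dataclass(frozen=True)
class HeadModel3D:
    """3-D head template: landmark label -> (x, y, z) in millimetres, head frame."""

    points: Mapping[str, tuple[float, float, float]]

    def __post_init__(self) -> None:
        unknown = set(self.points) - set(LANDMARK_LABELS)
        if unknown:
            raise ValueError(f"unknown landmark labels: {sorted(unknown)}")
        if len(self.points) < 4:
            raise ValueError("head template needs at least 4 landmarks")
        arr = self.array(sorted(self.points))
        centered = arr - arr.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            raise ValueError("template landmarks are collinear")

    def array(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.points[lab] for lab in labels], dtype=float)

    def scaled(self, factor: float) -> "HeadModel3D":
        return HeadModel3D({k: tuple(factor * c for c in v) for k, v in self.points.items()})


def default_head_template() -> HeadModel3D:
    """A synthetic, plausibly pigeon-scaled head template (millimetres).

    Coordinates are NOT measured from a real specimen; they are a synthetic
    stand-in with realistic proportions (bill ~25 mm beyond the cere, eyes
    ~24 mm apart).  Real-data analyses should supply a species-appropriate
    template.
    """
    return HeadModel3D(
        {
            "bill_tip": (55.0, 8.0, 0.0),
            "upper_caudal_cyr": (30.0, -2.0, 0.0),
            "lower_caudal_mandible": (28.0, 12.0, 0.0),
            "left_lower_rostral_periorbital": (22.0, 4.0, -10.0),
            "right_lower_rostral_periorbital": (22.0, 4.0, 10.0),
            "left_eye_center": (15.0, -4.0, -12.0),
            "right_eye_center": (15.0, -4.0, 12.0),
            "left_lower_caudal_periorbital": (5.0, 4.0, -11.0),
            "right_lower_caudal_periorbital": (5.0, 4.0, 11.0),
        }
    )


@dataclass
class LandmarkObservation:
    """Labeled 2-D pixel coordinates for one frame (4-9 landmarks)."""

    frame_id: str
    landmarks: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if not (4 <= len(self.landmarks) <= 9):
            raise ValueError(
                f"frame {self.frame_id}: expected 4-9 landmarks, got {len(self.landmarks)}"
            )
        unknown = set(self.landmarks) - set(LANDMARK_LABELS)
        if unknown:
            raise ValueError(f"frame {self.frame_id}: unknown labels {sorted(unknown)}")

    @property
    def labels(self) -> list[str]:
        return [lab for lab in LANDMARK_LABELS if lab in self.landmarks]

    def array(self) -> np.ndarray:
        return np.array([self.landmarks[lab] for lab in self.labels], dtype=float)


@dataclass
class PoseEstimate:
    """Recovered head pose for one frame."""

    frame_id: str
    rotation_matrix: np.ndarray
    pitch_deg: float
    yaw_deg: float
    roll_deg: float
    translation: np.ndarray
    mean_residual_px: float
    retained: bool
    gimbal_flag: bool = False
    residuals_px: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# Euler angles
# ---------------------------------------------------------------------------

def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rx(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def euler_to_rotation(pitch_deg: float, yaw_deg: float, roll_deg: float) -> np.ndarray:
    """Rotation matrix from Tait-Bryan angles under the package convention."""
    return _ry(np.deg2rad(-yaw_deg)) @ _rx(np.deg2rad(pitch_deg)) @ _rz(np.deg2rad(roll_deg))


def rotation_to_euler(rotation_matrix: np.ndarray) -> tuple[float, float, float, bool]:
    """Decompose a proper rotation into (pitch, yaw, roll) degrees.

    Returns a fourth ``gimbal`` flag; within ~1e-6 deg of pitch = +/-90 the
    roll is set to 0 by convention and the in-plane angle is assigned to yaw.
    """
    r = np.asarray(rotation_matrix, dtype=float)
    if r.shape != (3, 3):
        raise ValueError("rotation matrix must be 3x3")
    if not np.allclose(r @ r.T, np.eye(3), atol=1e-8) or np.linalg.det(r) < 0:
        raise ValueError("input is not a proper rotation matrix")
    # R = Ry(a) Rx(b) Rz(c) with a = -yaw:
    #   R[1,2] = -sin(b);  R[0,2] = sin(a) cos(b);  R[2,2] = cos(a) cos(b)
    #   R[1,0] = cos(b) sin(c);  R[1,1] = cos(b) cos(c)
    sb = -r[1, 2]
    sb = min(1.0, max(-1.0, sb))
    pitch = np.arcsin(sb)
    cb = np.cos(pitch)
    gimbal = bool(cb < np.deg2rad(1e-6))
    if gimbal:
        # roll := 0; remaining rotation about the vertical goes to yaw.
        # pitch=+90: R[0,:2] = (cos(a-c), sin(a-c)); pitch=-90: (cos(a+c), -sin(a+c))
        a = np.arctan2(r[0, 1], r[0, 0]) * (1.0 if sb > 0 else -1.0)
        c = 0.0
    else:
        a = np.arctan2(r[0, 2], r[2, 2])
        c = np.arctan2(r[1, 0], r[1, 1])
    yaw = -a
    return float(np.rad2deg(pitch)), float(np.rad2deg(yaw)), float(np.rad2deg(c)), gimbal


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------

def project_points(points_3d: np.ndarray, rotation: np.ndarray, translation: np.ndarray,
                   camera: CameraModel) -> np.ndarray:
    """Pinhole projection of head-frame points to pixel coordinates."""
    pc = points_3d @ rotation.T + translation
    z = pc[:, 2]
    if np.any(z <= 0):
        raise ValueError("point behind camera (z <= 0)")
    return np.column_stack(
        (camera.fx * pc[:, 0] / z + camera.cx, camera.fy * pc[:, 1] / z + camera.cy)
    )


# ---------------------------------------------------------------------------
# EPnP
# ---------------------------------------------------------------------------

def _control_points(pts: np.ndarray) -> np.ndarray:
    """Centroid + principal-direction control points (4x3)."""
    c0 = pts.mean(axis=0)
    centered = pts - c0
    cov = centered.T @ centered / len(pts)
    w, v = np.linalg.eigh(cov)
    # scale each axis by sqrt of its variance (avoid zero for planar sets)
    scales = np.sqrt(np.maximum(w, 1e-12 * max(w.max(), 1.0)))
    return np.vstack([c0, c0 + scales[::-1, None] * v.T[::-1]])


def _barycentric(pts: np.ndarray, ctrl: np.ndarray) -> np.ndarray:
    a = np.vstack([ctrl.T, np.ones(4)])
    b = np.vstack([pts.T, np.ones(len(pts))])
    alphas, *_ = np.linalg.lstsq(a, b, rcond=None)
    return alphas.T  # n x 4


def _build_m(alphas: np.ndarray, uv: np.ndarray, cam: CameraModel) -> np.ndarray:
    n = len(uv)
    m = np.zeros((2 * n, 12))
    u = uv[:, 0] - cam.cx
    v = uv[:, 1] - cam.cy
    for j in range(4):
        a = alphas[:, j]
        m[0::2, 3 * j + 0] = a * cam.fx
        m[0::2, 3 * j + 2] = -a * u
        m[1::2, 3 * j + 1] = a * cam.fy
        m[1::2, 3 * j + 2] = -a * v
    return m


def _rho(ctrl: np.ndarray) -> np.ndarray:
    d = []
    for i in range(4):
        for j in range(i + 1, 4):
            d.append(np.sum((ctrl[i] - ctrl[j]) ** 2))
    return np.array(d)


def _dist2_pairs(vec12: np.ndarray) -> np.ndarray:
    c = vec12.reshape(4, 3)
    d = []
    for i in range(4):
        for j in range(i + 1, 4):
            d.append(np.sum((c[i] - c[j]) ** 2))
    return np.array(d)


def _pose_from_betas(betas: np.ndarray, null4: np.ndarray, alphas: np.ndarray,
                     pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Camera-frame control points from betas -> absolute orientation (Kabsch)."""
    cc = (null4 @ betas).reshape(4, 3)
    pc = alphas @ cc
    # enforce cheirality: points must lie in front of the camera
    if pc[:, 2].sum() < 0:
        pc = -pc
    # Kabsch: find R, t minimizing ||R p_world + t - p_cam||
    mu_w = pts.mean(axis=0)
    mu_c = pc.mean(axis=0)
    h = (pts - mu_w).T @ (pc - mu_c)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = mu_c - r @ mu_w
    return r, t


def _epnp_candidates(pts: np.ndarray, uv: np.ndarray, cam: CameraModel):
    """EPnP initial poses: beta cases N = 1, 2, 3 on the null space of M."""
    ctrl = _control_points(pts)
    alphas = _barycentric(pts, ctrl)
    m = _build_m(alphas, uv, cam)
    _, _, vt = np.linalg.svd(m, full_matrices=False)
    null4 = vt[-1:-5:-1].T  # 12 x 4, columns ordered by increasing singular value
    rho = _rho(ctrl)

    candidates = []

    def add(betas):
        r, t = _pose_from_betas(betas, null4, alphas, pts)
        candidates.append((r, t))

    v1 = null4[:, 0]
    # N = 1: single direction, least-squares scale on squared distances
    d1 = _dist2_pairs(v1)
    if np.dot(d1, d1) > 0:
        b1 = np.sqrt(max(np.dot(d1, rho) / np.dot(d1, d1), 0.0))
        add(np.array([b1, 0.0, 0.0, 0.0]))

    # N = 2: unknowns b11, b12, b22
    v2 = null4[:, 1]
    c1 = v1.reshape(4, 3)
    c2 = v2.reshape(4, 3)
    rows = []
    for i in range(4):
        for j in range(i + 1, 4):
            dv1 = c1[i] - c1[j]
            dv2 = c2[i] - c2[j]
            rows.append([dv1 @ dv1, 2 * dv1 @ dv2, dv2 @ dv2])
    l2 = np.array(rows)
    sol, *_ = np.linalg.lstsq(l2, rho, rcond=None)
    b11, b12, b22 = sol
    if b11 >= 0:
        ba = np.sqrt(b11)
        bb = b12 / ba if ba > 1e-12 else (np.sqrt(max(b22, 0.0)))
        add(np.array([ba, bb, 0.0, 0.0]))

    # N = 3: unknowns b11, b12, b13, b22, b23, b33 (6 eqs, 6 unknowns)
    v3 = null4[:, 2]
    c3 = v3.reshape(4, 3)
    rows = []
    for i in range(4):
        for j in range(i + 1, 4):
            d1v = c1[i] - c1[j]
            d2v = c2[i] - c2[j]
            d3v = c3[i] - c3[j]
            rows.append([
                d1v @ d1v, 2 * d1v @ d2v, 2 * d1v @ d3v,
                d2v @ d2v, 2 * d2v @ d3v, d3v @ d3v,
            ])
    l3 = np.array(rows)
    sol, *_ = np.linalg.lstsq(l3, rho, rcond=None)
    b11, b12, b13, b22, b23, b33 = sol
    if b11 >= 0:
        ba = np.sqrt(b11)
        bb = b12 / ba if ba > 1e-12 else 0.0
        bc = b13 / ba if ba > 1e-12 else 0.0
        add(np.array([ba, bb, bc, 0.0]))

    return candidates


def _planarity(pts: np.ndarray) -> float:
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return s[-1] / s[0] if s[0] > 0 else 0.0


def _homography_candidates(pts: np.ndarray, uv: np.ndarray, cam: CameraModel):
    """Pose seeds for (near-)planar landmark sets via homography decomposition."""
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    basis = vt[:2]  # in-plane axes
    plane_xy = centered @ basis.T
    # DLT homography plane -> normalized image coords
    xn = (uv[:, 0] - cam.cx) / cam.fx
    yn = (uv[:, 1] - cam.cy) / cam.fy
    n = len(pts)
    a = np.zeros((2 * n, 9))
    a[0::2, 0:2] = plane_xy
    a[0::2, 2] = 1
    a[0::2, 6:8] = -xn[:, None] * plane_xy
    a[0::2, 8] = -xn
    a[1::2, 3:5] = plane_xy
    a[1::2, 5] = 1
    a[1::2, 6:8] = -yn[:, None] * plane_xy
    a[1::2, 8] = -yn
    _, _, vth = np.linalg.svd(a)
    h = vth[-1].reshape(3, 3)
    cands = []
    for sign in (1.0, -1.0):
        hh = sign * h
        h1, h2, h3 = hh[:, 0], hh[:, 1], hh[:, 2]
        lam = (np.linalg.norm(h1) + np.linalg.norm(h2)) / 2
        if lam < 1e-12:
            continue
        r1 = h1 / lam
        r2 = h2 / lam
        r3 = np.cross(r1, r2)
        q = np.column_stack([r1, r2, r3])
        u, _, vtq = np.linalg.svd(q)
        r_plane = u @ np.diag([1, 1, np.sign(np.linalg.det(u @ vtq))]) @ vtq
        # compose: world frame -> in-plane coords -> camera frame
        r = r_plane @ np.vstack([basis, np.cross(basis[0], basis[1])])
        t_full = h3 / lam + r @ (-pts.mean(axis=0))
        if (pts @ r.T + t_full)[:, 2].mean() > 0:
            cands.append((r, t_full))
    return cands


def _rodrigues(rvec: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(rvec)
    if theta < 1e-12:
        return np.eye(3)
    k = rvec / theta
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * kx + (1 - np.cos(theta)) * (kx @ kx)


def _rvec_from_rotation(r: np.ndarray) -> np.ndarray:
    cos_t = (np.trace(r) - 1) / 2
    cos_t = min(1.0, max(-1.0, cos_t))
    theta = np.arccos(cos_t)
    if theta < 1e-12:
        return np.zeros(3)
    if np.pi - theta < 1e-6:
        # near-pi: extract axis from R + I
        m = (r + np.eye(3)) / 2
        axis = np.sqrt(np.maximum(np.diag(m), 0))
        axis /= np.linalg.norm(axis)
        # fix signs from off-diagonals
        if m[0, 1] < 0:
            axis[1] *= -1
        if m[0, 2] < 0:
            axis[2] *= -1
        return theta * axis
    axis = np.array([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]])
    return theta * axis / (2 * np.sin(theta))


def _refine(r0: np.ndarray, t0: np.ndarray, pts: np.ndarray, uv: np.ndarray,
            cam: CameraModel) -> tuple[np.ndarray, np.ndarray]:
    """Damped Gauss-Newton (LM) refinement of the reprojection objective."""

    def resid(x):
        r = _rodrigues(x[:3])
        pc = pts @ r.T + x[3:]
        z = np.maximum(pc[:, 2], 1e-9)
        u = cam.fx * pc[:, 0] / z + cam.cx
        v = cam.fy * pc[:, 1] / z + cam.cy
        return np.concatenate([u - uv[:, 0], v - uv[:, 1]])

    x0 = np.concatenate([_rvec_from_rotation(r0), t0])
    sol = least_squares(resid, x0, method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15,
                        max_nfev=400)
    return _rodrigues(sol.x[:3]), sol.x[3:]


def solve_pnp(obs: LandmarkObservation, model: HeadModel3D, camera: CameraModel,
              qc_threshold: float = QC_THRESHOLD_PX) -> PoseEstimate:
    """Recover head rotation and translation from one frame's landmarks.

    Raises
    ------
    ValueError
        Fewer than 4 usable correspondences, or degenerate (collinear)
        geometry.
    """
    labels = [lab for lab in obs.labels if lab in model.points]
    if len(labels) < 4:
        raise ValueError(
            f"frame {obs.frame_id}: need >= 4 correspondences, got {len(labels)}"
        )
    pts = model.array(labels)
    uv = np.array([obs.landmarks[lab] for lab in labels], dtype=float)

    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise ValueError(f"frame {obs.frame_id}: landmarks are collinear, pose unsolvable")

    if _planarity(pts) < 1e-3:
        candidates = _homography_candidates(pts, uv, camera)
    else:
        candidates = _epnp_candidates(pts, uv, camera)
        candidates += _homography_candidates(pts, uv, camera)
    # canonical multi-start seeds: near-planar landmark subsets admit a
    # mirrored two-fold ambiguity that can capture every data-driven seed,
    # so always offer the refiner a spread of orientations as well
    depths = [t[2] for _, t in candidates if np.isfinite(t[2]) and t[2] > 0]
    z0 = float(np.median(depths)) if depths else 5.0 * float(
        np.linalg.norm(np.ptp(pts, axis=0))) + 1.0
    for yaw0 in (0.0, 90.0, -90.0, 180.0):
        candidates.append((euler_to_rotation(0.0, yaw0, 0.0),
                           np.array([0.0, 0.0, z0])))

    best = None
    for r0, t0 in candidates:
        if not np.all(np.isfinite(r0)) or not np.all(np.isfinite(t0)):
            continue
        try:
            r, t = _refine(r0, t0, pts, uv, camera)
        except Exception:
            continue
        if (pts @ r.T + t)[:, 2].min() <= 0:
            continue
        proj = project_points(pts, r, t, camera)
        res = float(np.linalg.norm(proj - uv, axis=1).mean())
        if best is None or res < best[2]:
            best = (r, t, res)
    if best is None:
        raise ValueError(f"frame {obs.frame_id}: pose estimation failed to converge")

    r, t, _ = best
    pitch, yaw, roll, gimbal = rotation_to_euler(r)
    residuals = np.linalg.norm(project_points(pts, r, t, camera) - uv, axis=1)
    mean_res = float(residuals.mean())
    return PoseEstimate(
        frame_id=obs.frame_id,
        rotation_matrix=r,
        pitch_deg=pitch,
        yaw_deg=yaw,
        roll_deg=roll,
        translation=t,
        mean_residual_px=mean_res,
        retained=mean_res <= qc_threshold,
        gimbal_flag=gimbal,
        residuals_px=residuals,
    )


def reprojection_residuals(pose: PoseEstimate, obs: LandmarkObservation,
                           model: HeadModel3D, camera: CameraModel):
    """Per-landmark Euclidean pixel residuals and their mean for a given pose."""
    labels = [lab for lab in obs.labels if lab in model.points]
    pts = model.array(labels)
    uv = np.array([obs.landmarks[lab] for lab in labels], dtype=float)
    proj = project_points(pts, pose.rotation_matrix, pose.translation, camera)
    res = np.linalg.norm(proj - uv, axis=1)
    return res, float(res.mean())


def qc_filter(poses: Iterable[PoseEstimate], threshold: float = QC_THRESHOLD_PX):
    """Split poses into retained (mean residual <= threshold) and excluded.

    A mean residual exactly at the threshold is retained; strictly greater is
    excluded.

    Returns
    -------
    (retained, report) : (list[PoseEstimate], dict)
        ``report`` counts exclusions overall and per trial prefix of frame_id.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    retained, excluded = [], []
    for p in poses:
        p.retained = p.mean_residual_px <= threshold
        (retained if p.retained else excluded).append(p)
    report = {
        "threshold_px": threshold,
        "n_input": len(retained) + len(excluded),
        "n_retained": len(retained),
        "n_excluded": len(excluded),
        "excluded_frames": [p.frame_id for p in excluded],
    }
    return retained, report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_landmarks_csv(path: str | Path) -> list[LandmarkObservation]:
    """Read observations from CSV with columns frame_id, label, u_px, v_px."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"frame_id", "label", "u_px", "v_px"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: landmark CSV needs columns {sorted(required)}")
    out = []
    for fid, grp in df.groupby("frame_id", sort=True):
        lm = {row.label: (float(row.u_px), float(row.v_px)) for row in grp.itertuples()}
        out.append(LandmarkObservation(frame_id=str(fid), landmarks=lm))
    return out


def read_head_template(path: str | Path) -> HeadModel3D:
    """Read a head template from CSV (label,x_mm,y_mm,z_mm) or JSON mapping."""
    import json

    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text())
        return HeadModel3D({k: tuple(map(float, v)) for k, v in raw.items()})
    import pandas as pd

    df = pd.read_csv(path)
    return HeadModel3D(
        {r.label: (float(r.x_mm), float(r.y_mm), float(r.z_mm)) for r in df.itertuples()}
    )


def poses_to_dataframe(poses: Sequence[PoseEstimate]):
    """Flatten pose estimates to the output CSV schema."""
    import pandas as pd

    return pd.DataFrame(
        {
            "frame_id": [p.frame_id for p in poses],
            "pitch_deg": [p.pitch_deg for p in poses],
            "yaw_deg": [p.yaw_deg for p in poses],
            "roll_deg": [p.roll_deg for p in poses],
            "tx": [p.translation[0] for p in poses],
            "ty": [p.translation[1] for p in poses],
            "tz": [p.translation[2] for p in poses],
            "mean_residual_px": [p.mean_residual_px for p in poses],
            "retained": [p.retained for p in poses],
        }
    )
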