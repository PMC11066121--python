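"""Point-based rigid registration of tracking space onto image space.

Implements Horn's closed-form absolute-orientation solution: the rotation
that least-squares aligns two corresponded point sets is the unit
quaternion given by the eigenvector of the largest eigenvalue of a 4x4
symmetric matrix built from the point cross-covariance; the translation
then maps centroid onto centroid.  Fiducial registration error (FRE) is
the root-mean-square residual distance between corresponded fiducials
after alignment.  A Monte-Carlo estimator of target registration error
(TRE) propagates fiducial localization noise to an arbitrary target.

The registration direction is tracking -> image: ``apply(result.transform,
moving_i)`` approximates ``fixed_i``.  Rigid only — no scaling — because
the tracked phantom and its image are metrically consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import CountMismatch, DegenerateFiducials, EmptyInput, MalformedRow
from .geometry import Point3, RigidTransform, quat_to_matrix

__all__ = [
    "FiducialPairSet",
    "RegistrationResult",
    "FiducialGeometryDiagnostic",
    "horn_register",
    "compute_fre",
    "check_fiducial_geometry",
    "monte_carlo_tre",
    "monte_carlo_fre",
]

# collinearity threshold: second singular value below this fraction of the
# largest means the constellation does not pin down all rotation axes
_DEGENERACY_RATIO = 1e-6


@dataclass(frozen=True)
class FiducialPairSet:
    """Corresponded fiducial coordinates in two frames, matched by id.

    ``moving`` holds the digitized positions in tracking space, ``fixed``
    the marker centres in image (CT / virtual) space, both ``(N, 3)`` mm.
    """

    ids: tuple
    moving: np.ndarray
    fixed: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        moving = np.atleast_2d(np.asarray(self.moving, dtype=float))
        fixed = np.atleast_2d(np.asarray(self.fixed, dtype=float))
        if len(ids) != len(set(ids)):
            raise CountMismatch(f"duplicate fiducial ids: {ids}")
        if moving.shape != (len(ids), 3) or fixed.shape != (len(ids), 3):
            raise CountMismatch(
                f"need matching (N,3) point arrays for {len(ids)} ids, "
                f"got {moving.shape} and {fixed.shape}"
            )
        if len(ids) < 3:
            raise CountMismatch(f"at least 3 fiducial pairs required, got {len(ids)}")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "moving", moving)
        object.__setattr__(self, "fixed", fixed)

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, ids: Sequence[str]) -> "FiducialPairSet":
        """Restrict to a named subset (e.g. the 3 fiducials actually digitized)."""
        wanted = [str(i) for i in ids]
        missing = [i for i in wanted if i not in self.ids]
        if missing:
            raise CountMismatch(f"unknown fiducial ids: {missing}")
        idx = [self.ids.index(i) for i in wanted]
        return FiducialPairSet(tuple(wanted), self.moving[idx], self.fixed[idx])

    # -- CSV interchange: columns id,space{moving|fixed},x_mm,y_mm,z_mm ----
    def to_csv(self, path) -> None:
        rows = []
        for space, pts in (("moving", self.moving), ("fixed", self.fixed)):
            for i, p in zip(self.ids, pts):
                rows.append({"id": i, "space": space,
                             "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]})
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path) -> "FiducialPairSet":
        df = pd.read_csv(path, dtype={"id": str})
        required = {"id", "space", "x_mm", "y_mm", "z_mm"}
        if not required.issubset(df.columns):
            raise MalformedRow(f"expected columns {sorted(required)} in {path}")
        bad = set(df["space"]) - {"moving", "fixed"}
        if bad:
            raise MalformedRow(f"unknown space label(s) {sorted(bad)} in {path}")
        ids, moving, fixed = [], [], []
        for fid, grp in df.groupby("id", sort=False):
            by_space = {s: g for s, g in grp.groupby("space")}
            if set(by_space) != {"moving", "fixed"}:
                raise MalformedRow(f"fiducial {fid!r} lacks a moving/fixed pair")
            ids.append(fid)
            moving.append(by_space["moving"][["x_mm", "y_mm", "z_mm"]].iloc[0].to_numpy())
            fixed.append(by_space["fixed"][["x_mm", "y_mm", "z_mm"]].iloc[0].to_numpy())
        return cls(tuple(ids), np.array(moving, dtype=float), np.array(fixed, dtype=float))


@dataclass(frozen=True)
class FiducialGeometryDiagnostic:
    """Rank diagnostic of a fiducial constellation."""

    ok: bool
    singular_values: np.ndarray
    ratio: float
    message: str


def check_fiducial_geometry(points) -> FiducialGeometryDiagnostic:
    """Flag collinear or duplicated fiducial constellations.

    Degenerate when the second-largest singular value of the centred
    point matrix falls below ``1e-6`` of the largest (or the spread is
    zero altogether).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3:
        raise CountMismatch("geometry check needs at least 3 points")
    centred = pts - pts.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    if s[0] <= 0.0:
        return FiducialGeometryDiagnostic(False, s, 0.0, "all points coincide")
    ratio = float(s[1] / s[0])
    if ratio < _DEGENERACY_RATIO:
        return FiducialGeometryDiagnostic(
            False, s, ratio, "points are collinear or coincident"
        )
    return FiducialGeometryDiagnostic(True, s, ratio, "ok")


@dataclass(frozen=True)
class RegistrationResult:
    """Fitted tracking->image transform with per-fiducial residuals and FRE.

    ``residuals[i] = fixed_i - transform(moving_i)`` in mm.
    """

    transform: RigidTransform
    residuals: np.ndarray
    fre: float
    ids: tuple = field(default=())

    def to_csv(self, path) -> None:
        """Tidy CSV: one ``transform`` row (quaternion, translation, FRE)
        followed by one ``residual`` row per fiducial."""
        q = self.transform.rotation
        t = self.transform.translation
        rows = [{
            "record": "transform", "id": "",
            "qw": q.w, "qx": q.x, "qy": q.y, "qz": q.z,
            "tx_mm": t.x, "ty_mm": t.y, "tz_mm": t.z,
            "rx_mm": "", "ry_mm": "", "rz_mm": "", "fre_mm": self.fre,
        }]
        ids = self.ids or tuple(str(i) for i in range(len(self.residuals)))
        for fid, r in zip(ids, self.residuals):
            rows.append({
                "record": "residual", "id": fid,
                "qw": "", "qx": "", "qy": "", "qz": "",
                "tx_mm": "", "ty_mm": "", "tz_mm": "",
                "rx_mm": r[0], "ry_mm": r[1], "rz_mm": r[2], "fre_mm": "",
            })
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RegistrationResult":
        df = pd.read_csv(path, dtype={"record": str, "id": str})
        trow = df[df["record"] == "transform"]
        if len(trow) != 1:
            raise MalformedRow(f"expected exactly one transform row in {path}")
        trow = trow.iloc[0]
        from .geometry import UnitQuaternion

        transform = RigidTransform(
            UnitQuaternion(float(trow.qw), float(trow.qx), float(trow.qy), float(trow.qz)),
            Point3(float(trow.tx_mm), float(trow.ty_mm), float(trow.tz_mm)),
        )
        rrows = df[df["record"] == "residual"]
        residuals = rrows[["rx_mm", "ry_mm", "rz_mm"]].to_numpy(dtype=float)
        ids = tuple(rrows["id"].tolist())
        return cls(transform, residuals, float(trow.fre_mm), ids)


def compute_fre(residuals) -> float:
    """Root-mean-square of residual vector norms (mm)."""
    r = np.atleast_2d(np.asarray(residuals, dtype=float))
    if r.size == 0:
        raise EmptyInput("no residuals to summarize")
    return float(np.sqrt(np.mean(np.sum(r * r, axis=-1))))


def _horn_solve(moving: np.ndarray, fixed: np.ndarray):
    """Batched Horn solution.

    ``moving``/``fixed`` are ``(..., N, 3)`` with identical leading shape
    (``fixed`` may broadcast).  Returns ``(R, t)`` with shapes
    ``(..., 3, 3)`` and ``(..., 3)`` such that ``R @ moving_i + t ~ fixed_i``.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.broadcast_to(np.asarray(fixed, dtype=float), moving.shape)
    mc = moving.mean(axis=-2, keepdims=True)
    fc = fixed.mean(axis=-2, keepdims=True)
    m = moving - mc
    f = fixed - fc
    # cross-covariance S_ab = sum_i m_ia f_ib
    S = np.einsum("...ni,...nj->...ij", m, f)
    S00, S01, S02 = S[..., 0, 0], S[..., 0, 1], S[..., 0, 2]
    S10, S11, S12 = S[..., 1, 0], S[..., 1, 1], S[..., 1, 2]
    S20, S21, S22 = S[..., 2, 0], S[..., 2, 1], S[..., 2, 2]
    N = np.empty(S.shape[:-2] + (4, 4), dtype=float)
    N[..., 0, 0] = S00 + S11 + S22
    N[..., 0, 1] = N[..., 1, 0] = S12 - S21
    N[..., 0, 2] = N[..., 2, 0] = S20 - S02
    N[..., 0, 3] = N[..., 3, 0] = S01 - S10
    N[..., 1, 1] = S00 - S11 - S22
    N[..., 1, 2] = N[..., 2, 1] = S01 + S10
    N[..., 1, 3] = N[..., 3, 1] = S02 + S20
    N[..., 2, 2] = -S00 + S11 - S22
    N[..., 2, 3] = N[..., 3, 2] = S12 + S21
    N[..., 3, 3] = -S00 - S11 + S22
    _, vecs = np.linalg.eigh(N)
    q = vecs[..., :, -1]  # eigenvector of the largest eigenvalue
    # canonical hemisphere: non-negative scalar part
    sign = np.where(q[..., 0:1] < 0.0, -1.0, 1.0)
    q = q * sign
    R = quat_to_matrix(q)
    t = fc[..., 0, :] - np.einsum("...ij,...j->...i", R, mc[..., 0, :])
    return R, t


def horn_register(
    pairs: FiducialPairSet, subset: Optional[Sequence[str]] = None
) -> RegistrationResult:
    """Least-squares rigid tracking->image transform by Horn's method.

    Minimizes ``sum_i ||fixed_i - T(moving_i)||^2`` over rigid ``T`` via
    the quaternion eigen-solution.  ``subset`` optionally restricts the
    fit to a named subset of fiducials (>= 3), mirroring a workflow where
    only some registration markers are digitized; residuals and FRE are
    reported for the fiducials actually used.
    """
    if subset is not None:
        pairs = pairs.subset(subset)
    for name, pts in (("moving", pairs.moving), ("fixed", pairs.fixed)):
        diag = check_fiducial_geometry(pts)
        if not diag.ok:
            raise DegenerateFiducials(f"{name} fiducials degenerate: {diag.message}")
    R, t = _horn_solve(pairs.moving, pairs.fixed)
    residuals = pairs.fixed - (pairs.moving @ R.T + t)
    return RegistrationResult(
        RigidTransform.from_rotation_translation(R, t),
        residuals,
        compute_fre(residuals),
        pairs.ids,
    )


def monte_carlo_tre(
    pairs: FiducialPairSet,
    target: Point3,
    sigma: float,
    reps: int,
    seed: int,
) -> float:
    """RMS target registration error under fiducial localization noise.

    Each replicate perturbs the moving fiducials by isotropic per-axis
    Gaussian noise of standard deviation ``sigma`` (mm), re-registers,
    and maps ``target`` (tracking space); the RMS distance to the
    noise-free mapping over ``reps`` replicates is returned.  At the
    fiducial centroid this converges to ``sigma * sqrt(3 / N)``, the
    centroid limit of the standard first-order TRE propagation.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    base = horn_register(pairs)
    true_mapped = base.transform.apply(target).as_array()
    rng = np.random.default_rng(seed)
    noisy = pairs.moving[None, :, :] + rng.normal(0.0, sigma, size=(reps,) + pairs.moving.shape)
    R, t = _horn_solve(noisy, pairs.fixed[None, :, :])
    mapped = np.einsum("rij,j->ri", R, target.as_array()) + t
    d2 = np.sum((mapped - true_mapped) ** 2, axis=-1)
    return float(np.sqrt(np.mean(d2)))


def monte_carlo_fre(pairs: FiducialPairSet, sigma: float, reps: int, seed: int) -> float:
    """RMS of the FRE over ``reps`` noisy registrations.

    Moving fiducials are perturbed per axis by Gaussian noise ``sigma``;
    the expected squared FRE is ``(1 - 2/N) * 3 sigma^2`` to first order.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    noisy = pairs.moving[None, :, :] + rng.normal(0.0, sigma, size=(reps,) + pairs.moving.shape)
    fixed = np.broadcast_to(pairs.fixed, noisy.shape)
    R, t = _horn_solve(noisy, fixed)
    residuals = fixed - (np.einsum("rij,rnj->rni", R, noisy) + t[:, None, :])
    fre2 = np.mean(np.sum(residuals**2, axis=-1), axis=-1)
    return float(np.sqrt(np.mean(fre2)))
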