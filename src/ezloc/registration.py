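"""Rigid intra-subject co-registration by mutual-information maximization.

The registration path is deliberately simple and deterministic: a
multi-resolution pyramid (downsampling factors 4, 2, 1) with a
derivative-free simplex search of the six rigid parameters at each level,
maximizing the joint-histogram mutual information of the overlap region.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .errors import ConvergenceError, DegenerateInputError, GridMismatchError
from .imaging import Volume3D, resample_to

DEFAULT_BINS = 64


@dataclass
class RigidTransform:
    """6-DOF rigid transform: Euler angles (degrees) applied z-y-x about a
    center point, followed by a translation (mm).

    The transform maps a world point ``p`` to ``R (p - c) + c + t``.
    """

    rotation_deg: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float)
        self.translation_mm = np.asarray(self.translation_mm, dtype=float)
        self.center_mm = np.asarray(self.center_mm, dtype=float)

    def rotation_matrix(self) -> np.ndarray:
        az, ay, ax = self.rotation_deg
        # extrinsic z, then y, then x  ->  R = Rx @ Ry @ Rz
        return Rotation.from_euler("zyx", [az, ay, ax], degrees=True).as_matrix()

    def matrix(self) -> np.ndarray:
        """The equivalent 4x4 world-to-world matrix."""
        R = self.rotation_matrix()
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = self.center_mm - R @ self.center_mm + self.translation_mm
        return m

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation_matrix().T
        rot = Rotation.from_matrix(Rinv).as_euler("zyx", degrees=True)
        # translation of the inverse about the same center
        t = -Rinv @ self.translation_mm
        return RigidTransform(
            rotation_deg=np.array([rot[0], rot[1], rot[2]]),
            translation_mm=t,
            center_mm=self.center_mm.copy(),
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        m = self.matrix()
        out = pts @ m[:3, :3].T + m[:3, 3]
        return out[0] if np.asarray(points).ndim == 1 else out

    def save(self, path) -> None:
        """Serialize as a plain-text row-major 4x4 matrix (mm)."""
        np.savetxt(str(path), self.matrix(), fmt="%.10g")

    @staticmethod
    def from_matrix(m: np.ndarray, center_mm=None) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        c = np.zeros(3) if center_mm is None else np.asarray(center_mm, float)
        R = m[:3, :3]
        rot = Rotation.from_matrix(R).as_euler("zyx", degrees=True)
        t = m[:3, 3] - (c - R @ c)
        return RigidTransform(np.array(rot), t, c)

    @staticmethod
    def load(path) -> "RigidTransform":
        return RigidTransform.from_matrix(np.loadtxt(str(path)))


def mutual_information(a: Volume3D, b: Volume3D, bins: int = DEFAULT_BINS) -> float:
    """MI (nats) of the joint intensity histogram over the nonzero overlap.

    ``MI = H(A) + H(B) - H(A,B)`` with the histogram restricted to voxels
    where both volumes are nonzero.
    """
    if a.shape != b.shape:
        raise GridMismatchError(f"shapes differ: {a.shape} vs {b.shape}")
    if bins < 8:
        raise DegenerateInputError("need at least 8 histogram bins")
    av = np.asarray(a.data, dtype=float).ravel()
    bv = np.asarray(b.data, dtype=float).ravel()
    keep = (av != 0) & (bv != 0)
    if not keep.any():
        raise DegenerateInputError("empty overlap region between volumes")
    hist, _, _ = np.histogram2d(av[keep], bv[keep], bins=bins)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)

    def _entropy(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    return _entropy(px) + _entropy(py) - _entropy(pxy.ravel())


def _downsample(vol: Volume3D, factor: int) -> Volume3D:
    if factor == 1:
        return vol
    sm = ndimage.gaussian_filter(vol.data.astype(float), sigma=factor / 2.0)
    data = sm[::factor, ::factor, ::factor]
    aff = vol.affine.copy()
    aff[:3, :3] *= factor
    return Volume3D(data, aff)


def register_rigid(
    moving: Volume3D,
    fixed: Volume3D,
    bins: int = DEFAULT_BINS,
    pyramid=(4, 2, 1),
    max_iter: int = 200,
    tol: float = 1e-5,
) -> RigidTransform:
    """Find the 6-DOF transform (moving world -> fixed world) maximizing MI.

    Deterministic for fixed inputs and settings.  Raises
    :class:`ConvergenceError` (with the best-so-far transform attached as
    ``payload``) if the simplex search exhausts its iteration budget at the
    full-resolution level without converging.
    """
    for v, name in ((moving, "moving"), (fixed, "fixed")):
        if np.ptp(np.asarray(v.data, dtype=float)) == 0:
            raise DegenerateInputError(
                f"{name} volume is flat (single intensity); registration is undefined"
            )
    center = fixed.world_center()
    params = np.zeros(6)  # rz, ry, rx (deg), tx, ty, tz (mm)
    converged = True
    for factor in pyramid:
        mov_l = _downsample(moving, factor)
        fix_l = _downsample(fixed, factor)

        def neg_mi(p):
            t = RigidTransform(p[:3], p[3:], center)
            res = resample_to(mov_l, fix_l, t)
            try:
                return -mutual_information(res, fix_l, bins=bins)
            except DegenerateInputError:
                return 0.0

        # explicit simplex: meaningful perturbations (deg / mm) per level;
        # a restart with a shrunken simplex polishes the finest level, where
        # the default simplex tends to collapse early
        step_sets = [np.full(6, 2.0) * [1, 1, 1, factor, factor, factor]]
        if factor == 1:
            step_sets.append(np.full(6, 0.5))
        for steps in step_sets:
            simplex = np.vstack([params, params + np.diag(steps)])
            res = optimize.minimize(
                neg_mi,
                params,
                method="Nelder-Mead",
                options={
                    "maxiter": max_iter,
                    "xatol": 0.01 * factor,
                    "fatol": tol,
                    "initial_simplex": simplex,
                },
            )
            params = res.x
        converged = bool(res.success) or res.fun < neg_mi(np.zeros(6))
    best = RigidTransform(params[:3], params[3:], center)
    if not converged:
        raise ConvergenceError(
            f"registration did not converge (best MI {-res.fun:.4f})", payload=best
        )
    return best
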