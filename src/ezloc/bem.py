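"""Three-compartment boundary-element forward solver (optional tier).

Constant (face-centroid) collocation on nested closed triangle meshes
(inner skull, outer skull, scalp) with an isolated-skull decomposition to
control the numerical error introduced by the low skull conductivity.
Validated against the analytic concentric-sphere model on spherical
geometry.

Derivation sketch (all discrete identities are exact in the collocated
system): with surface potentials ``v`` and the double-layer (solid angle)
operator ``W``, the surface equations read ``A v = b`` where
``A = diag((s- + s+)/2) - W`` and ``b`` holds the primary (infinite-medium)
potential times the source-compartment conductivity.  Writing
``v = v_hat + c * v0`` with ``v0`` the solution of the isolated
inner-compartment problem and ``c = s1/(s1 - s2)`` turns the source term on
the inner surface into ``-s1*s2/(s1-s2) * v0`` (order s2, small), removing
the large cancellation between inner-skull and scalp potentials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .errors import GeometryError, ParameterError
from .headmodel import (
    CorticalSourceSpace,
    ElectrodeSet,
    Leadfield,
)


def triangle_solid_angles(obs: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Signed solid angles (sr) of triangles viewed from observation points.

    van Oosterom & Strackee formula; sign follows the vertex ordering
    (positive when the triangle normal faces away from the observer).
    Shape: (n_obs, n_tri).
    """
    obs = np.asarray(obs, dtype=float)
    out = np.empty((len(obs), len(tri)))
    chunk = max(1, int(4e7 // (len(tri) * 3)))
    for s in range(0, len(obs), chunk):
        o = obs[s:s + chunk]
        r1 = tri[None, :, 0, :] - o[:, None, :]
        r2 = tri[None, :, 1, :] - o[:, None, :]
        r3 = tri[None, :, 2, :] - o[:, None, :]
        n1 = np.linalg.norm(r1, axis=2)
        n2 = np.linalg.norm(r2, axis=2)
        n3 = np.linalg.norm(r3, axis=2)
        num = np.einsum("ijk,ijk->ij", r1, np.cross(r2, r3))
        den = (
            n1 * n2 * n3
            + np.einsum("ijk,ijk->ij", r1, r2) * n3
            + np.einsum("ijk,ijk->ij", r1, r3) * n2
            + np.einsum("ijk,ijk->ij", r2, r3) * n1
        )
        out[s:s + chunk] = 2.0 * np.arctan2(num, den)
    return out


def _face_centroids(verts, faces):
    return verts[faces].mean(axis=1)


def _check_closed(verts, faces, name):
    """Every edge of a closed orientable triangle mesh is shared by exactly
    two faces with opposite direction."""
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    und = np.sort(edges, axis=1)
    _, counts = np.unique(und, axis=0, return_counts=True)
    if not np.all(counts == 2):
        raise GeometryError(f"surface {name!r} is not a closed manifold mesh")


@dataclass
class BEMModel:
    """Precomputed BEM system for one head geometry."""

    verts: list
    faces: list
    centroids: list          # per-surface face centroids
    conductivities: np.ndarray
    lu: tuple                # LU factorization of the deflated system
    iso_pinv: np.ndarray     # pseudo-inverse of the isolated inner problem
    omega_1k: list           # solid-angle blocks S1 -> S2, S1 -> S3
    n_faces: list
    use_isa: bool

    @property
    def scalp_centroids(self):
        return self.centroids[2]


def _as_mesh(surface):
    if isinstance(surface, CorticalSourceSpace):
        return surface.vertices, surface.faces
    verts, faces = surface
    return np.asarray(verts, dtype=float), np.asarray(faces, dtype=int)


def build_bem(surfaces, conductivities, use_isa: bool = None) -> BEMModel:
    """Assemble and factorize the collocation system.

    ``surfaces``: three nested closed meshes, innermost (inner skull) first.
    ``conductivities``: (brain, skull, scalp) in S/m; outside is 0.
    """
    if len(surfaces) != 3:
        raise ParameterError("exactly three nested surfaces are required")
    cond = np.asarray(conductivities, dtype=float)
    if np.any(cond <= 0):
        raise ParameterError("conductivities must be positive")
    meshes = [_as_mesh(s) for s in surfaces]
    for k, (v, f) in enumerate(meshes):
        _check_closed(v, f, f"S{k + 1}")
    # orient all faces outward (positive enclosed solid angle from inside)
    oriented = []
    for v, f in meshes:
        inner_pt = v.mean(axis=0, keepdims=True)
        tot = triangle_solid_angles(inner_pt, v[f]).sum()
        if tot < 0:
            f = f[:, ::-1]
        oriented.append((v, f))
    meshes = oriented

    cents = [_face_centroids(v, f) for v, f in meshes]
    nf = [len(f) for _, f in meshes]
    ntot = sum(nf)
    offs = np.concatenate([[0], np.cumsum(nf)])

    # solid-angle blocks, observation rows x source-triangle columns
    omega = np.empty((ntot, ntot))
    for k in range(3):
        for l in range(3):
            vl, fl = meshes[l]
            omega[offs[k]:offs[k + 1], offs[l]:offs[l + 1]] = triangle_solid_angles(
                cents[k], vl[fl]
            )

    # geometry sanity + own-surface diagonal consistency (exact constants)
    expected = np.array([[2, 4, 4], [0, 2, 4], [0, 0, 2]]) * np.pi
    for k in range(3):
        for l in range(3):
            block = omega[offs[k]:offs[k + 1], offs[l]:offs[l + 1]]
            if k == l:
                # the singular self term is undefined in the arctan formula
                # (observation point lies in the triangle plane); its true
                # principal value is 0, and the diagonal is then fixed so
                # each row integrates a constant exactly
                d = np.arange(nf[k])
                block[d, d] = 0.0
                block[d, d] = expected[k, l] - block.sum(axis=1)
                continue
            sums = block.sum(axis=1)
            if not np.allclose(sums, expected[k, l], atol=2.0):
                raise GeometryError(
                    f"surfaces S{k + 1}/S{l + 1} do not appear properly nested "
                    f"(mean enclosed solid angle {sums.mean():.2f}, "
                    f"expected {expected[k, l]:.2f}); intersecting surfaces?"
                )

    sig_in = np.array([cond[0], cond[1], cond[2]])
    sig_out = np.array([cond[1], cond[2], 0.0])
    jump = np.repeat((sig_in + sig_out) / 2.0, nf)
    dsig = np.repeat(sig_in - sig_out, nf)
    A = np.diag(jump) - omega * (dsig[None, :] / (4.0 * np.pi))

    # deflation: fix the arbitrary constant via the mean scalp potential
    defl = np.zeros((1, ntot))
    defl[0, offs[2]:offs[3]] = jump.mean() / nf[2]
    A_def = A + np.ones((ntot, 1)) @ defl
    anorm = np.linalg.norm(A_def, 1)
    lu = sla.lu_factor(A_def)
    rcond = _rcond_from_lu(lu, anorm)
    if rcond < 1e-12:
        raise GeometryError(
            f"BEM system is ill-conditioned (reciprocal condition {rcond:.2e})"
        )

    if use_isa is None:
        use_isa = cond[1] < 0.2 * cond[0]
    iso_pinv = None
    omega_1k = None
    if use_isa:
        n1 = nf[0]
        A_iso = cond[0] * (
            np.eye(n1) / 2.0 - omega[:n1, :n1] / (4.0 * np.pi)
        )
        iso_pinv = np.linalg.pinv(A_iso, rcond=1e-10)
        omega_1k = [
            omega[offs[1]:offs[2], :n1],
            omega[offs[2]:offs[3], :n1],
        ]
    return BEMModel(
        verts=[m[0] for m in meshes],
        faces=[m[1] for m in meshes],
        centroids=cents,
        conductivities=cond,
        lu=lu,
        iso_pinv=iso_pinv,
        omega_1k=omega_1k,
        n_faces=nf,
        use_isa=use_isa,
    )


def _rcond_from_lu(lu, anorm):
    from scipy.linalg import lapack

    gecon = lapack.dgecon
    rcond, _ = gecon(lu[0], anorm, norm="1")
    return rcond


def _primary(points: np.ndarray, r0: np.ndarray, m: np.ndarray) -> np.ndarray:
    """sigma * v_infinity: (1/4pi) m.(r - r0)/|r - r0|^3, mm and A*m -> SI."""
    d = (points - r0) * 1e-3
    n = np.linalg.norm(d, axis=1)
    return (d @ m) / (4.0 * np.pi * n ** 3)


def bem_scalp_potential(model: BEMModel, dipole_pos_mm, dipole_moment) -> np.ndarray:
    """Potential (volts per A*m) at the scalp face centroids for one dipole
    inside the innermost compartment."""
    r0 = np.asarray(dipole_pos_mm, dtype=float)
    m = np.asarray(dipole_moment, dtype=float)
    s1, s2 = model.conductivities[0], model.conductivities[1]
    nf = model.n_faces
    offs = np.concatenate([[0], np.cumsum(nf)])
    b = np.concatenate([_primary(c, r0, m) for c in model.centroids])
    if model.use_isa:
        v0 = model.iso_pinv @ b[: nf[0]]
        b_mod = b.copy()
        b_mod[: nf[0]] = -(s1 * s2 / (s1 - s2)) * v0
        b_mod[offs[1]:offs[2]] += (s1 / (4.0 * np.pi)) * (model.omega_1k[0] @ v0)
        b_mod[offs[2]:offs[3]] += (s1 / (4.0 * np.pi)) * (model.omega_1k[1] @ v0)
        v_hat = sla.lu_solve(model.lu, b_mod)
        return v_hat[offs[2]:offs[3]]
    v = sla.lu_solve(model.lu, b)
    return v[offs[2]:offs[3]]


def leadfield_bem3(
    surfaces,
    conductivities,
    elec: ElectrodeSet,
    src: CorticalSourceSpace,
    use_isa: bool = None,
) -> Leadfield:
    """BEM gain matrix (microvolt per nA*m), average-referenced.

    Electrode potentials are taken from the nearest scalp face centroid.
    """
    model = build_bem(surfaces, conductivities, use_isa=use_isa)
    from scipy.spatial import cKDTree

    tree = cKDTree(model.scalp_centroids)
    _, idx = tree.query(elec.positions)
    cols = []
    for pos, ori in zip(src.vertices, src.orientations):
        v = bem_scalp_potential(model, pos, ori)
        cols.append(v[idx])
    gain = np.array(cols).T * 1e6 * 1e-9  # -> microvolt per nA*m
    gain -= gain.mean(axis=0, keepdims=True)
    return Leadfield(
        gain=gain,
        model="bem3",
        electrodes=elec,
        meta=dict(conductivities=list(np.asarray(conductivities, float)),
                  use_isa=model.use_isa, units="uV per nA*m"),
    )
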