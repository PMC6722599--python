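"""Source spaces, electrode montages, and the EEG forward model.

The required forward model is the analytic three-shell concentric-sphere
series; the boundary-element solver in :mod:`ezloc.bem` is an optional tier
validated against it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .errors import FormatError, GeometryError, ParameterError

DEFAULT_RADII_MM = (79.0, 82.0, 88.0)          # brain / outer skull / scalp
DEFAULT_CONDUCTIVITIES = (0.33, 0.0042, 0.33)  # S/m


@dataclass
class CorticalSourceSpace:
    """Triangulated source surface with fixed (normal) dipole orientations."""

    vertices: np.ndarray      # (N, 3) world mm
    faces: np.ndarray         # (F, 3) int
    orientations: np.ndarray  # (N, 3) unit normals
    adjacency: sparse.csr_matrix = None  # symmetric vertex adjacency

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.adjacency is None:
            self.adjacency = vertex_adjacency(len(self.vertices), self.faces)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def graph_rings(self, center: int, max_ring: int = None) -> np.ndarray:
        """Graph distance (in adjacency rings) from ``center`` to every vertex."""
        dist = sparse.csgraph.shortest_path(
            self.adjacency, method="D", unweighted=True, indices=center
        )
        return dist


@dataclass
class ElectrodeSet:
    labels: list
    positions: np.ndarray  # (M, 3) world mm

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if len(set(self.labels)) != len(self.labels):
            raise FormatError("electrode labels must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.labels)


@dataclass
class Leadfield:
    """Average-referenced gain matrix, microvolt per nA*m, fixed orientations."""

    gain: np.ndarray          # (M, N)
    model: str                # "sphere3" | "bem3"
    electrodes: ElectrodeSet
    reference: str = "average"
    meta: dict = field(default_factory=dict)


def vertex_adjacency(n_vertices: int, faces: np.ndarray) -> sparse.csr_matrix:
    """Symmetric 0/1 vertex adjacency from a triangle list."""
    faces = np.asarray(faces, dtype=int)
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [0, 2]]])
    i = np.concatenate([e[:, 0], e[:, 1]])
    j = np.concatenate([e[:, 1], e[:, 0]])
    a = sparse.coo_matrix(
        (np.ones(len(i)), (i, j)), shape=(n_vertices, n_vertices)
    ).tocsr()
    a.data[:] = 1.0
    return a


# ---------------------------------------------------------------------------
# icosphere tessellation

_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        [-1, _ICO_T, 0], [1, _ICO_T, 0], [-1, -_ICO_T, 0], [1, -_ICO_T, 0],
        [0, -1, _ICO_T], [0, 1, _ICO_T], [0, -1, -_ICO_T], [0, 1, -_ICO_T],
        [_ICO_T, 0, -1], [_ICO_T, 0, 1], [-_ICO_T, 0, -1], [-_ICO_T, 0, 1],
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=int,
)


def make_sphere_source_space(subdivisions: int, radius_mm: float) -> CorticalSourceSpace:
    """Icosahedral sphere tessellation; ``10 * 4**s + 2`` vertices, radial
    orientations."""
    if not (1 <= subdivisions <= 5):
        raise ParameterError("subdivisions must be in 1..5")
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    faces = _ICO_FACES.copy()
    for _ in range(subdivisions):
        verts, faces = _subdivide(verts, faces)
        verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    orient = verts.copy()
    return CorticalSourceSpace(verts * radius_mm, faces, orient)


def _subdivide(verts, faces):
    midpoint = {}
    verts = list(map(tuple, verts))

    def _mid(i, j):
        key = (min(i, j), max(i, j))
        if key not in midpoint:
            p = (np.array(verts[i]) + np.array(verts[j])) / 2.0
            verts.append(tuple(p))
            midpoint[key] = len(verts) - 1
        return midpoint[key]

    out = []
    for a, b, c in faces:
        ab, bc, ca = _mid(a, b), _mid(b, c), _mid(c, a)
        out += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
    return np.array(verts, dtype=float), np.array(out, dtype=int)


# ---------------------------------------------------------------------------
# surface I/O

def load_surface(path) -> CorticalSourceSpace:
    """Load a triangle mesh (GIfTI, OFF, or OBJ) as a source space.

    Orientations are area-weighted vertex normals (zero-area faces are
    excluded with a warning); unreferenced vertices are pruned.
    """
    path = str(path)
    if path.endswith(".gii"):
        import nibabel as nib

        img = nib.load(path)
        verts = faces = None
        for arr in img.darrays:
            if arr.data.ndim == 2 and arr.data.shape[1] == 3:
                if np.issubdtype(arr.data.dtype, np.floating):
                    verts = np.asarray(arr.data, dtype=float)
                else:
                    faces = np.asarray(arr.data, dtype=int)
        if verts is None or faces is None:
            raise FormatError(f"{path}: GIfTI file lacks vertex/face arrays")
    elif path.endswith(".off"):
        verts, faces = _read_off(path)
    elif path.endswith(".obj"):
        verts, faces = _read_obj(path)
    else:
        raise FormatError(f"unsupported mesh format: {path}")
    if faces.shape[1] != 3:
        raise FormatError(f"{path}: non-triangular faces (shape {faces.shape})")

    used = np.zeros(len(verts), dtype=bool)
    used[faces.ravel()] = True
    if not used.all():
        warnings.warn(f"{path}: pruning {int((~used).sum())} unreferenced vertices")
        remap = -np.ones(len(verts), dtype=int)
        remap[used] = np.arange(used.sum())
        verts = verts[used]
        faces = remap[faces]

    normals = _vertex_normals(verts, faces)
    return CorticalSourceSpace(verts, faces, normals)


def _read_off(path):
    with open(path) as fh:
        tokens = [t for line in fh
                  if (s := line.split("#")[0].strip())
                  for t in s.split()]
    if tokens[0] != "OFF":
        raise FormatError(f"{path}: missing OFF header")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4
    verts = np.array(tokens[pos:pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    faces = []
    for _ in range(nf):
        k = int(tokens[pos])
        faces.append([int(t) for t in tokens[pos + 1:pos + 1 + k]])
        pos += 1 + k
    lens = {len(f) for f in faces}
    if lens != {3}:
        raise FormatError(f"{path}: non-triangular faces present")
    return verts, np.array(faces, dtype=int)


def _read_obj(path):
    verts, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
                if len(idx) != 3:
                    raise FormatError(f"{path}: non-triangular face {parts}")
                faces.append(idx)
    return np.array(verts, dtype=float), np.array(faces, dtype=int)


def write_surface(src: CorticalSourceSpace, path) -> None:
    """Write as OFF (plain text)."""
    path = str(path)
    if not path.endswith(".off"):
        raise FormatError("only OFF output is supported")
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{src.n_vertices} {len(src.faces)} 0\n")
        for v in src.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in src.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _vertex_normals(verts, faces):
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    fn = np.cross(v1 - v0, v2 - v0)  # 2x area-weighted
    area2 = np.linalg.norm(fn, axis=1)
    degenerate = area2 < 1e-12
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-area face(s) excluded "
                      "from normal computation")
        fn = fn[~degenerate]
        faces = faces[~degenerate]
    normals = np.zeros_like(verts)
    for k in range(3):
        np.add.at(normals, faces[:, k], fn)
    norm = np.linalg.norm(normals, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return normals / norm


# ---------------------------------------------------------------------------
# electrode montages

# unit-sphere positions, RAS (x right, y anterior, z up)
_S18, _C18 = np.sin(np.deg2rad(18)), np.cos(np.deg2rad(18))
_S54, _C54 = np.sin(np.deg2rad(54)), np.cos(np.deg2rad(54))
_MONTAGE_1020 = {
    "Fp1": (-_S18, _C18, 0.0), "Fp2": (_S18, _C18, 0.0),
    "F7": (-_C18, _S18, 0.0), "F8": (_C18, _S18, 0.0),
    "T3": (-1.0, 0.0, 0.0), "T4": (1.0, 0.0, 0.0),
    "T5": (-_C18, -_S18, 0.0), "T6": (_C18, -_S18, 0.0),
    "O1": (-_S18, -_C18, 0.0), "O2": (_S18, -_C18, 0.0),
    "F3": (-0.5455, 0.6731, 0.5), "F4": (0.5455, 0.6731, 0.5),
    "C3": (-np.sqrt(0.5), 0.0, np.sqrt(0.5)), "C4": (np.sqrt(0.5), 0.0, np.sqrt(0.5)),
    "P3": (-0.5455, -0.6731, 0.5), "P4": (0.5455, -0.6731, 0.5),
    "Fz": (0.0, np.sqrt(0.5), np.sqrt(0.5)), "Pz": (0.0, -np.sqrt(0.5), np.sqrt(0.5)),
    "Cz": (0.0, 0.0, 1.0),
}
_MONTAGE_1010_EXTRA = {
    "Fpz": (0.0, 1.0, 0.0), "Oz": (0.0, -1.0, 0.0),
    "FC1": (-0.29, 0.35, 0.89), "FC2": (0.29, 0.35, 0.89),
    "CP1": (-0.29, -0.35, 0.89), "CP2": (0.29, -0.35, 0.89),
    "FC5": (-0.81, 0.31, 0.5), "FC6": (0.81, 0.31, 0.5),
    "CP5": (-0.81, -0.31, 0.5), "CP6": (0.81, -0.31, 0.5),
}
MONTAGES = {
    "10-20": _MONTAGE_1020,
    "10-10-29": {**_MONTAGE_1020, **_MONTAGE_1010_EXTRA},
}


def standard_montage(name: str = "10-20", scalp_radius_mm: float = 88.0) -> ElectrodeSet:
    """Standard angular electrode placement scaled onto a scalp sphere."""
    if name not in MONTAGES:
        raise ParameterError(
            f"unknown montage {name!r}; supported: {sorted(MONTAGES)}"
        )
    table = MONTAGES[name]
    labels = list(table.keys())
    pos = np.array([table[l] for l in labels], dtype=float)
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return ElectrodeSet(labels, pos * scalp_radius_mm)


# ---------------------------------------------------------------------------
# three-shell concentric-sphere forward model

_RADIAL_CACHE: dict = {}


def _shell_radial_coeffs(n_max: int, radii_rel, conductivities) -> np.ndarray:
    """Per-order surface-potential coefficients g_n for a unit source term.

    For harmonic order n the potential in each layer is
    ``A r^n + B r^-(n+1)`` plus, in the innermost layer, the source term
    ``s * r^-(n+1)`` with s = 1.  Continuity of potential and of the radial
    current at each interface plus the zero-current condition at the scalp
    give a 5x5 linear system per order; g_n is the resulting potential
    coefficient evaluated at the (unit) scalp radius.  All radii are
    normalized by the scalp radius for conditioning.
    """
    key = (n_max, tuple(np.round(radii_rel, 12)), tuple(conductivities))
    if key in _RADIAL_CACHE:
        return _RADIAL_CACHE[key]
    r1, r2, r3 = radii_rel  # r3 == 1
    s1, s2, s3 = conductivities
    g = np.zeros(n_max + 1)
    for n in range(1, n_max + 1):
        # unknowns: a1, a2, b2, a3, b3
        A = np.zeros((5, 5))
        rhs = np.zeros(5)
        rp = lambda r: r ** n
        rm = lambda r: r ** -(n + 1)
        dp = lambda r: n * r ** (n - 1)
        dm = lambda r: -(n + 1) * r ** -(n + 2)
        # potential continuity at r1:  a1 rp + s rm = a2 rp + b2 rm
        A[0] = [rp(r1), -rp(r1), -rm(r1), 0, 0]
        rhs[0] = -rm(r1)
        # current continuity at r1
        A[1] = [s1 * dp(r1), -s2 * dp(r1), -s2 * dm(r1), 0, 0]
        rhs[1] = -s1 * dm(r1)
        # potential continuity at r2
        A[2] = [0, rp(r2), rm(r2), -rp(r2), -rm(r2)]
        # current continuity at r2
        A[3] = [0, s2 * dp(r2), s2 * dm(r2), -s3 * dp(r2), -s3 * dm(r2)]
        # zero radial current at scalp (r3 = 1)
        A[4] = [0, 0, 0, s3 * dp(r3), s3 * dm(r3)]
        sol = np.linalg.solve(A, rhs)
        a3, b3 = sol[3], sol[4]
        g[n] = a3 * rp(r3) + b3 * rm(r3)
    _RADIAL_CACHE[key] = g
    return g


def _assoc_legendre1(n_max: int, x: np.ndarray) -> np.ndarray:
    """P_n^1(x) for n = 0..n_max without the Condon-Shortley phase.

    Shape (n_max+1, len(x)).  Recurrence:
    (n - 1) P_n^1 = (2n - 1) x P_{n-1}^1 - n P_{n-2}^1.
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros((n_max + 1, len(x)))
    s = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
    if n_max >= 1:
        out[1] = s
    if n_max >= 2:
        out[2] = 3.0 * x * s
    for n in range(3, n_max + 1):
        out[n] = ((2 * n - 1) * x * out[n - 1] - n * out[n - 2]) / (n - 1)
    return out


def sphere3_potential(
    dipole_pos_mm: np.ndarray,
    dipole_moment: np.ndarray,
    electrode_pos_mm: np.ndarray,
    radii_mm=DEFAULT_RADII_MM,
    conductivities=DEFAULT_CONDUCTIVITIES,
    tol: float = 1e-12,
    n_max: int = 400,
) -> np.ndarray:
    """Scalp potential (volts per A*m of moment) of one dipole.

    Series solution for a current dipole inside three concentric spherical
    shells, truncated when the remaining terms fall below ``tol`` relative.
    Electrodes are radially projected onto the scalp sphere.
    """
    radii = np.asarray(radii_mm, dtype=float)
    cond = np.asarray(conductivities, dtype=float)
    if not (radii[0] < radii[1] < radii[2]):
        raise GeometryError(f"shell radii must increase, got {radii_mm}")
    if np.any(cond <= 0):
        raise ParameterError("conductivities must be positive")
    r0 = np.asarray(dipole_pos_mm, dtype=float)
    m = np.asarray(dipole_moment, dtype=float)
    R = radii[2]
    r0n = np.linalg.norm(r0)
    if r0n >= radii[0]:
        raise GeometryError(
            f"dipole at radius {r0n:.2f} mm is on/outside the innermost shell "
            f"({radii[0]} mm)"
        )
    elec = np.asarray(electrode_pos_mm, dtype=float)
    er = elec / np.linalg.norm(elec, axis=1, keepdims=True)  # on scalp sphere

    b = r0n / R
    if r0n < 1e-9:
        rhat = np.array([0.0, 0.0, 1.0])
        b = 0.0
    else:
        rhat = r0 / r0n
    m_r = float(m @ rhat)
    cosg = np.clip(er @ rhat, -1.0, 1.0)
    # tangent direction at each electrode, in the dipole-electrode plane
    tvec = er - cosg[:, None] * rhat
    tn = np.linalg.norm(tvec, axis=1)
    ok = tn > 1e-12
    that = np.zeros_like(tvec)
    that[ok] = tvec[ok] / tn[ok, None]
    m_t = that @ m  # tangential moment component toward each electrode

    g = _shell_radial_coeffs(n_max, radii / R, cond)
    # choose truncation: term amplitude ~ |g_n| * b^(n-1)
    ns = np.arange(1, n_max + 1)
    amp = np.abs(g[1:]) * np.maximum(b, 1e-3) ** (ns - 1) * ns
    cutoff = np.nonzero(amp < tol * max(amp.max(), 1e-300))[0]
    n_use = int(cutoff[0]) + 1 if len(cutoff) else n_max

    P = np.empty((n_use + 1, len(er)))
    P[0] = 1.0
    if n_use >= 1:
        P[1] = cosg
    for n in range(2, n_use + 1):
        P[n] = ((2 * n - 1) * cosg * P[n - 1] - (n - 1) * P[n - 2]) / n
    P1 = _assoc_legendre1(n_use, cosg)

    scale = 1.0 / (4.0 * np.pi * cond[0] * (R * 1e-3) ** 2)  # SI volts, A*m
    nsu = np.arange(1, n_use + 1)
    bpow = b ** (nsu - 1)
    coef = g[1:n_use + 1] * bpow
    v = scale * (
        (coef * nsu) @ P[1:] * m_r + coef @ P1[1:] * m_t
    )
    return v


def leadfield_sphere3(
    src: CorticalSourceSpace,
    elec: ElectrodeSet,
    radii_mm=DEFAULT_RADII_MM,
    conductivities=DEFAULT_CONDUCTIVITIES,
) -> Leadfield:
    """Average-referenced gain matrix (microvolt per nA*m) for fixed-orientation
    dipoles at the source-space vertices."""
    cols = []
    for pos, ori in zip(src.vertices, src.orientations):
        v = sphere3_potential(pos, ori, elec.positions, radii_mm, conductivities)
        cols.append(v)
    gain = np.array(cols).T  # (M, N), volts per A*m
    gain = gain * 1e6 * 1e-9  # -> microvolt per nA*m
    gain -= gain.mean(axis=0, keepdims=True)
    return Leadfield(
        gain=gain,
        model="sphere3",
        electrodes=elec,
        meta=dict(
            radii_mm=list(radii_mm),
            conductivities=list(conductivities),
            units="uV per nA*m",
        ),
    )
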