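"""Ictal EEG source imaging with multiple sparse priors.

The sensor covariance is modeled as a nonnegative combination of a sensor
noise component and source covariance components (cortical patches, plus
optional components derived from SPECT hyperperfusion clusters).  Component
weights are optimized by restricted-maximum-likelihood ascent on the
variational free energy in log-hyperparameter space, with automatic
relevance determination pruning; the posterior mean current is the standard
Gaussian conditional given the optimized prior covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, GridMismatchError, ParameterError
from .headmodel import CorticalSourceSpace, Leadfield
from .imaging import BinaryMask, Volume3D
from .registration import RigidTransform
from .siscom import ClusterSet


@dataclass
class EEGEpoch:
    """Multichannel EEG segment: (M channels x T samples), microvolts."""

    data: np.ndarray
    srate: float
    labels: list
    window: tuple = (0.0, 0.0)

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] < 2:
            raise ParameterError("epoch must have at least 2 samples")
        if len(self.labels) != self.data.shape[0]:
            raise ParameterError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )

    @property
    def n_channels(self):
        return self.data.shape[0]

    @property
    def n_samples(self):
        return self.data.shape[1]

    def pick(self, labels) -> "EEGEpoch":
        """Reorder/subset channels to match ``labels`` (by name, not index)."""
        index = {l: i for i, l in enumerate(self.labels)}
        missing = [l for l in labels if l not in index]
        if missing:
            raise ParameterError(f"channels missing from epoch: {missing}")
        rows = [index[l] for l in labels]
        return EEGEpoch(self.data[rows], self.srate, list(labels), self.window)


@dataclass
class PriorComponent:
    profile: np.ndarray   # (N,) nonnegative, peak 1
    tag: str              # "patch" | "siscom"
    center: int = -1      # seed vertex (patches)

    def __post_init__(self):
        p = np.asarray(self.profile, dtype=float)
        if p.min() < 0:
            raise ParameterError("component profile must be nonnegative")
        m = p.max()
        if m <= 0:
            raise ParameterError("component profile is identically zero")
        self.profile = p / m


@dataclass
class PriorLibrary:
    components: list

    def __len__(self):
        return len(self.components)

    def __add__(self, other: "PriorLibrary") -> "PriorLibrary":
        return PriorLibrary(list(self.components) + list(other.components))

    @property
    def tags(self):
        return [c.tag for c in self.components]


@dataclass
class MSPResult:
    hyperparameters: np.ndarray    # per component, then noise (last)
    J: np.ndarray                  # (N, T) posterior mean currents
    free_energy_trace: np.ndarray
    active_components: np.ndarray  # indices surviving pruning
    converged: bool
    tags: list = field(default_factory=list)

    def vertex_power(self) -> np.ndarray:
        """Time-mean squared posterior current per vertex."""
        return (self.J ** 2).mean(axis=1)

    def component_weights(self) -> dict:
        out = {"noise": float(self.hyperparameters[-1])}
        for i, tag in enumerate(self.tags):
            out.setdefault(tag, 0.0)
            out[tag] += float(self.hyperparameters[i])
        return out


@dataclass
class EZMap:
    vertex_set: np.ndarray
    volume: BinaryMask
    threshold_rule: str


def average_reference(eeg: EEGEpoch) -> EEGEpoch:
    """Remove the instantaneous channel mean from every sample."""
    if eeg.n_channels < 2:
        raise ParameterError("need at least 2 channels to average-reference")
    data = eeg.data - eeg.data.mean(axis=0, keepdims=True)
    return EEGEpoch(data, eeg.srate, list(eeg.labels), eeg.window)


# ---------------------------------------------------------------------------
# prior construction

def diffusion_kernel(
    src: CorticalSourceSpace, seeds, smoothness: float
) -> np.ndarray:
    """Peak-normalized graph-diffusion profile seeded at ``seeds``.

    ``smoothness`` is the number of diffusion steps of the half-lazy
    normalized-adjacency walk ``v <- (v + A_hat v)/2``; 0 yields a delta
    profile at the seeds.
    """
    n = src.n_vertices
    v = np.zeros(n)
    v[np.atleast_1d(seeds)] = 1.0
    steps = int(round(smoothness))
    if steps <= 0:
        return v
    adj = src.adjacency
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    dinv = sparse.diags(1.0 / deg)
    ahat = dinv @ adj  # row-stochastic
    for _ in range(steps):
        v = 0.5 * (v + ahat @ v)
    return v / v.max()


def build_patch_library(
    src: CorticalSourceSpace,
    n_patches: int = 256,
    smoothness: float = 4,
    seed: int = 0,
) -> PriorLibrary:
    """Patch components at uniformly sampled center vertices.

    Centers are drawn without replacement when ``n_patches < N`` (a
    deterministic permutation given ``seed``), otherwise every vertex is a
    center.
    """
    n = src.n_vertices
    if n_patches > n:
        raise ParameterError(f"n_patches ({n_patches}) exceeds vertex count ({n})")
    if smoothness < 0:
        raise ParameterError("smoothness must be >= 0")
    if n_patches == n:
        centers = np.arange(n)
    else:
        rng = np.random.default_rng(seed)
        centers = np.sort(rng.permutation(n)[:n_patches])
    comps = [
        PriorComponent(diffusion_kernel(src, c, smoothness), "patch", center=int(c))
        for c in centers
    ]
    return PriorLibrary(comps)


def siscom_prior_components(
    clusters: ClusterSet,
    src: CorticalSourceSpace,
    mri_to_head: RigidTransform = None,
    max_dist_mm: float = 15.0,
    smoothness: float = 4,
) -> PriorLibrary:
    """One diffusion-kernel component per hyperperfusion cluster.

    Cluster voxels are mapped through ``mri_to_head`` and attached to their
    nearest source vertices within ``max_dist_mm``.  Clusters with no vertex
    in range produce no component and a warning (deep or extra-cortical
    focus).
    """
    tree = cKDTree(src.vertices)
    comps = []
    for ci, cluster in enumerate(clusters):
        # cluster stores voxel indices; world positions are precomputed only
        # for peak/centroid, so rebuild them from the member voxels
        pts = cluster.centroid_mm[None, :] if cluster.voxels is None else None
        pts = _cluster_world(cluster)
        if mri_to_head is not None:
            pts = mri_to_head.apply(pts)
        d, idx = tree.query(pts)
        near = idx[d <= max_dist_mm]
        if near.size == 0:
            warnings.warn(
                f"cluster {ci} has no source vertex within {max_dist_mm} mm; "
                "skipped (deep or extra-cortical focus)"
            )
            continue
        seeds = np.unique(near)
        profiles = [diffusion_kernel(src, s, smoothness) for s in seeds]
        profile = np.max(profiles, axis=0)
        comps.append(PriorComponent(profile, "siscom", center=int(seeds[0])))
    return PriorLibrary(comps)


def _cluster_world(cluster):
    if getattr(cluster, "world_mm", None) is not None:
        return cluster.world_mm
    raise ParameterError(
        "cluster lacks world coordinates; build clusters via threshold_clusters"
    )


# ---------------------------------------------------------------------------
# inversion

@dataclass
class MSPOptions:
    max_iter: int = 128
    tol: float = 1e-6
    prune_ratio: float = 1e-8
    shrinkage: float = 0.05


def _data_covariance(Y: np.ndarray, shrinkage: float) -> np.ndarray:
    m, t = Y.shape
    C = (Y @ Y.T) / t
    if t < 4 * m:
        C = (1.0 - shrinkage) * C + shrinkage * np.diag(np.diag(C))
    return C


def invert_msp(
    eeg: EEGEpoch, lf: Leadfield, lib: PriorLibrary, opts: MSPOptions = None
) -> MSPResult:
    """ReML / free-energy optimization of the covariance-component weights.

    Damped Fisher-scoring steps in log-hyperparameter space; a step is only
    accepted if it does not decrease the free energy, so the returned trace
    is monotone non-decreasing (within 1e-6).  Components whose weight falls
    below ``prune_ratio`` of the largest are pruned (fixed to zero).
    """
    opts = opts or MSPOptions()
    if len(lib) == 0:
        raise ParameterError("prior library is empty")
    eeg = eeg.pick(lf.electrodes.labels)
    Y = eeg.data
    M, T = Y.shape
    L = lf.gain
    if L.shape[0] != M:
        raise GridMismatchError("EEG channel count does not match leadfield rows")

    C_hat = _data_covariance(Y, opts.shrinkage)
    if not np.isfinite(C_hat).all():
        raise DegenerateInputError("non-finite data covariance")
    scale = np.trace(C_hat) / M
    if scale <= 0:
        raise DegenerateInputError("zero-power epoch")

    K = len(lib)
    # sensor projections a_i = L q_i of the rank-one components q_i q_i^T,
    # scaled to unit mean sensor power so one init fits all
    A_raw = np.column_stack([L @ c.profile for c in lib.components])  # (M, K)
    norms = np.maximum((A_raw ** 2).sum(axis=0) / M, 1e-300)
    A = A_raw / np.sqrt(norms)[None, :]
    nhyp = K + 1  # components + sensor noise (last)

    nu = np.full(nhyp, np.log(scale * 0.5 / max(K, 1)))
    nu[-1] = np.log(scale * 0.5)
    active = np.ones(nhyp, dtype=bool)

    def free_energy(nu_vec, act):
        lam = np.where(act, np.exp(nu_vec), 0.0)
        C = lam[-1] * np.eye(M) + (A * lam[:-1][None, :]) @ A.T
        sign, logdet = np.linalg.slogdet(C)
        if sign <= 0:
            return -np.inf, None, None
        Ci = np.linalg.inv(C)
        f = -0.5 * T * (logdet + np.sum(Ci * C_hat) + M * np.log(2 * np.pi))
        return f, C, Ci

    f_cur, C, Ci = free_energy(nu, active)
    if not np.isfinite(f_cur):
        raise DegenerateInputError("singular initial sensor covariance")
    trace = [f_cur]
    damping = 1.0
    converged = False
    for _ in range(opts.max_iter):
        idx = np.nonzero(active[:-1])[0]
        lam_c = np.exp(nu[idx])
        lam_n = np.exp(nu[-1])
        Ai = A[:, idx]
        CiA = Ci @ Ai                        # (M, k)
        CiChCi = Ci @ C_hat @ Ci
        # gradients in log space: dF/dnu_i = lam_i * dF/dlam_i
        tr_CiP = np.einsum("mk,mk->k", Ai, CiA)
        tr_CiChCiP = np.einsum("mk,mk->k", Ai, CiChCi @ Ai)
        g_c = -0.5 * T * lam_c * (tr_CiP - tr_CiChCiP)
        g_n = -0.5 * T * lam_n * (np.trace(Ci) - np.trace(CiChCi))
        g = np.append(g_c, g_n)
        # expected (Fisher) curvature: tr(Ci P_i Ci P_j) = (a_i^T Ci a_j)^2
        G = Ai.T @ CiA                       # (k, k)
        H = np.empty((len(idx) + 1, len(idx) + 1))
        H[:-1, :-1] = 0.5 * T * np.outer(lam_c, lam_c) * G ** 2
        cross = np.einsum("mk,mk->k", CiA, CiA)      # tr(Ci P_i Ci)
        H[:-1, -1] = H[-1, :-1] = 0.5 * T * lam_c * lam_n * cross
        H[-1, -1] = 0.5 * T * lam_n ** 2 * np.sum(Ci * Ci)
        accepted = False
        f_new = f_cur
        for _try in range(10):
            step = np.linalg.solve(
                H + damping * np.diag(np.maximum(np.diag(H), 1e-12)), g
            )
            step = np.clip(step, -8.0, 8.0)
            nu_new = nu.copy()
            nu_new[idx] += step[:-1]
            nu_new[-1] += step[-1]
            f_new, C_new, Ci_new = free_energy(nu_new, active)
            if np.isfinite(f_new) and f_new >= f_cur - 1e-9 * max(1.0, abs(f_cur)):
                accepted = True
                break
            damping *= 10.0
        if not accepted:
            break
        damping = max(damping / 3.0, 1e-6)
        df = f_new - f_cur
        nu, f_cur, C, Ci = nu_new, f_new, C_new, Ci_new
        trace.append(f_cur)
        # ARD pruning (noise component exempt)
        lam_all = np.where(active, np.exp(nu), 0.0)
        thr = opts.prune_ratio * lam_all.max()
        drop = active & (lam_all < thr)
        drop[-1] = False
        if drop.any():
            active = active & ~drop
            f_cur, C, Ci = free_energy(nu, active)
            trace[-1] = f_cur
        if abs(df) < opts.tol * max(1.0, abs(f_cur)):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"ReML did not converge in {opts.max_iter} iterations "
            f"(last dF {trace[-1] - trace[-2] if len(trace) > 1 else 0:.3g})"
        )

    lam_all = np.where(active, np.exp(nu), 0.0)
    lam_src = lam_all[:-1] / norms  # weights on the un-normalized q_i q_i^T
    # posterior mean J = Gamma L^T Ci Y with Gamma = sum lam_i q_i q_i^T
    CiY = Ci @ Y
    proj = A_raw.T @ CiY                        # (K, T): a_i^T Ci Y
    Q = np.column_stack([c.profile for c in lib.components])  # (N, K)
    J = Q @ (lam_src[:, None] * proj)
    hyper = np.append(lam_src, lam_all[-1])
    act_idx = np.nonzero(active[:-1])[0]
    return MSPResult(
        hyperparameters=hyper,
        J=J,
        free_energy_trace=np.array(trace),
        active_components=act_idx,
        converged=converged,
        tags=list(lib.tags),
    )


def invert_with_siscom_prior(
    eeg: EEGEpoch,
    lf: Leadfield,
    patch_lib: PriorLibrary,
    siscom_components: PriorLibrary,
    opts: MSPOptions = None,
) -> MSPResult:
    """MSP inversion on the patch library augmented with SPECT-derived
    components; with an empty augmentation the result is identical to
    :func:`invert_msp`."""
    if siscom_components is None or len(siscom_components) == 0:
        return invert_msp(eeg, lf, patch_lib, opts)
    return invert_msp(eeg, lf, patch_lib + siscom_components, opts)


def source_to_ez_map(
    res: MSPResult,
    src: CorticalSourceSpace,
    mri: Volume3D,
    frac: float = 0.5,
    render_radius_mm: float = 6.0,
    head_to_mri: RigidTransform = None,
) -> EZMap:
    """Binarize the posterior power map and render it onto the MRI grid.

    Vertices with time-mean squared current >= ``frac * max`` are selected;
    voxels within ``render_radius_mm`` of any selected vertex are marked.
    """
    if not (0 < frac <= 1):
        raise ParameterError("frac must be in (0, 1]")
    power = res.vertex_power()
    pmax = power.max()
    vol = np.zeros(mri.shape, dtype=bool)
    if pmax <= 0:
        warnings.warn("all-zero posterior currents; empty EZ map")
        return EZMap(
            np.array([], dtype=int),
            BinaryMask(vol, mri.affine.copy()),
            f"frac={frac} of max power",
        )
    selected = np.nonzero(power >= frac * pmax)[0]
    pts = src.vertices[selected]
    if head_to_mri is not None:
        pts = head_to_mri.apply(pts)
    vox = mri.world_to_voxel(pts)
    rad_vox = np.ceil(render_radius_mm / mri.voxel_sizes).astype(int)
    shape = np.asarray(mri.shape)
    for center_vox, center_mm in zip(vox, pts):
        lo = np.maximum(np.floor(center_vox - rad_vox - 1).astype(int), 0)
        hi = np.minimum(np.ceil(center_vox + rad_vox + 2).astype(int), shape)
        if np.any(lo >= hi):
            continue
        grid = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        ijk = np.stack([g.ravel() for g in grid], axis=1)
        d = np.linalg.norm(mri.voxel_to_world(ijk) - center_mm, axis=1)
        inside = ijk[d <= render_radius_mm]
        vol[tuple(inside.T)] = True
    return EZMap(
        selected, BinaryMask(vol, mri.affine.copy()), f"frac={frac} of max power"
    )
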