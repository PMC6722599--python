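"""Subtraction ictal-interictal SPECT analysis.

Pipeline: register interictal onto ictal, mask, global-count normalize,
subtract, Gaussian-smooth the difference, z-score over the brain mask,
co-register to the MRI, and extract suprathreshold clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, GridMismatchError, ParameterError
from .imaging import BinaryMask, Volume3D, apply_mask, resample_to
from .registration import RigidTransform, register_rigid

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # sigma = FWHM * this


@dataclass
class ZScoreMap:
    """Standardized ictal-interictal difference image.

    ``zvol`` holds z-values inside ``mask`` and 0 outside; voxels outside the
    mask are excluded from all statistics.
    """

    zvol: Volume3D
    mask: BinaryMask
    mean_diff: float
    sd_diff: float


@dataclass
class Cluster:
    voxels: np.ndarray          # (n, 3) int voxel indices
    size: int
    peak_z: float
    peak_mm: np.ndarray         # world coordinates of the peak voxel
    centroid_mm: np.ndarray
    world_mm: np.ndarray = None  # (n, 3) world coordinates of member voxels


@dataclass
class ClusterSet:
    clusters: list
    threshold: float
    connectivity: int = 26

    def __len__(self):
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def to_mask(self, like: Volume3D | BinaryMask) -> BinaryMask:
        """Render the union of cluster voxels as a mask on ``like``'s grid."""
        out = np.zeros(like.shape, dtype=bool)
        for c in self.clusters:
            out[tuple(c.voxels.T)] = True
        return BinaryMask(out, np.asarray(like.affine).copy())


@dataclass
class SiscomResult:
    zmap: ZScoreMap                  # on the MRI grid
    clusters: ClusterSet
    interictal_to_ictal: RigidTransform
    ictal_to_mri: RigidTransform
    zmap_spect: ZScoreMap = None     # pre-MRI-resampling z-map (audit)
    params: dict = field(default_factory=dict)


def normalize_global(vol: Volume3D, mask: BinaryMask, target: float = 100.0) -> Volume3D:
    """Scale so the mean intensity over ``mask`` equals ``target``."""
    if not vol.same_grid(mask):
        raise GridMismatchError("volume and mask grids differ; resample first")
    m = float(np.asarray(vol.data, dtype=float)[mask.data].mean()) if mask.n_voxels else 0.0
    if m <= 0:
        raise DegenerateInputError(f"nonpositive brain mean ({m}); cannot normalize")
    return Volume3D(vol.data * (target / m), vol.affine.copy())


def subtract(ictal_n: Volume3D, interictal_n: Volume3D) -> Volume3D:
    if not ictal_n.same_grid(interictal_n):
        raise GridMismatchError("ictal and interictal grids differ; resample first")
    return Volume3D(
        np.asarray(ictal_n.data, float) - np.asarray(interictal_n.data, float),
        ictal_n.affine.copy(),
    )


def smooth_gaussian(vol: Volume3D, fwhm_mm: float) -> Volume3D:
    """Mass-preserving Gaussian smoothing with a kernel of given FWHM (mm).

    Anisotropic voxels are honored: per-axis sigma in voxel units is
    ``fwhm * FWHM_TO_SIGMA / voxel_size``.
    """
    if fwhm_mm <= 0:
        raise ParameterError(f"fwhm_mm must be > 0, got {fwhm_mm}")
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vol.voxel_sizes
    out = ndimage.gaussian_filter(np.asarray(vol.data, float), sigma=sigma_vox)
    return Volume3D(out, vol.affine.copy())


def zscore(diff: Volume3D, mask: BinaryMask) -> ZScoreMap:
    """Standardize the difference image by its mean/SD over brain voxels.

    Uses the population SD.  Outside the mask z is set to 0 and excluded
    from statistics.
    """
    if not diff.same_grid(mask):
        raise GridMismatchError("difference and mask grids differ")
    vals = np.asarray(diff.data, float)[mask.data]
    if vals.size == 0:
        raise DegenerateInputError("empty brain mask")
    mean = float(vals.mean())
    sd = float(vals.std())  # population SD
    if sd <= 0:
        raise DegenerateInputError(
            "zero SD of differences over the brain mask (identical scans?)"
        )
    z = np.where(mask.data, (np.asarray(diff.data, float) - mean) / sd, 0.0)
    return ZScoreMap(Volume3D(z, diff.affine.copy()), mask, mean, sd)


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def threshold_clusters(
    zmap: ZScoreMap, z_threshold: float = 2.0, min_size: int = 10
) -> ClusterSet:
    """26-connected components of {z >= threshold} within the brain mask.

    Components smaller than ``min_size`` voxels are dropped; the remainder
    are sorted by descending peak z.  An empty set is a valid result.
    """
    if min_size < 1:
        raise ParameterError("min_size must be >= 1")
    z = np.asarray(zmap.zvol.data, float)
    supra = (z >= z_threshold) & zmap.mask.data
    labels, n = ndimage.label(supra, structure=_STRUCT26)
    clusters = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        if len(vox) < min_size:
            continue
        zs = z[tuple(vox.T)]
        peak_i = int(np.argmax(zs))
        peak_vox = vox[peak_i]
        clusters.append(
            Cluster(
                voxels=vox,
                size=len(vox),
                peak_z=float(zs[peak_i]),
                peak_mm=zmap.zvol.voxel_to_world(peak_vox),
                centroid_mm=zmap.zvol.voxel_to_world(vox.mean(axis=0)),
                world_mm=zmap.zvol.voxel_to_world(vox),
            )
        )
    clusters.sort(key=lambda c: -c.peak_z)
    return ClusterSet(clusters, threshold=float(z_threshold))


def run_siscom(
    ictal: Volume3D,
    interictal: Volume3D,
    mri: Volume3D,
    brain_mask: BinaryMask,
    fwhm_mm: float = 12.0,
    z_threshold: float = 2.0,
    min_cluster_size: int = 10,
    norm_target: float = 100.0,
    do_registration: bool = True,
) -> SiscomResult:
    """Run the full subtraction analysis.

    ``brain_mask`` is expected on the ictal grid.  With
    ``do_registration=False`` (phantoms already aligned) both transforms are
    identity and the registration stages are skipped.
    """
    def _stage(name, fn, *a, **k):
        try:
            return fn(*a, **k)
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    if do_registration:
        t_ii = _stage("register-interictal", register_rigid, interictal, ictal)
    else:
        t_ii = RigidTransform(center_mm=ictal.world_center())
    interictal_r = _stage("resample-interictal", resample_to, interictal, ictal, t_ii)

    ictal_m = _stage("mask", apply_mask, ictal, brain_mask)
    interictal_m = _stage("mask", apply_mask, interictal_r, brain_mask)
    ictal_n = _stage("normalize", normalize_global, ictal_m, brain_mask, norm_target)
    interictal_n = _stage(
        "normalize", normalize_global, interictal_m, brain_mask, norm_target
    )
    diff = _stage("subtract", subtract, ictal_n, interictal_n)
    diff_s = _stage("smooth", smooth_gaussian, diff, fwhm_mm)
    zmap_spect = _stage("zscore", zscore, diff_s, brain_mask)

    if do_registration:
        t_im = _stage("register-mri", register_rigid, ictal, mri)
    else:
        t_im = RigidTransform(center_mm=mri.world_center())
    z_on_mri = _stage("resample-zmap", resample_to, zmap_spect.zvol, mri, t_im)
    mask_on_mri_vol = _stage(
        "resample-mask",
        resample_to,
        Volume3D(brain_mask.data.astype(float), brain_mask.affine),
        mri,
        t_im,
    )
    mask_on_mri = BinaryMask(mask_on_mri_vol.data > 0.5, mri.affine.copy())
    zmap_mri = ZScoreMap(
        Volume3D(np.where(mask_on_mri.data, z_on_mri.data, 0.0), mri.affine.copy()),
        mask_on_mri,
        zmap_spect.mean_diff,
        zmap_spect.sd_diff,
    )
    clusters = _stage(
        "clusters", threshold_clusters, zmap_mri, z_threshold, min_cluster_size
    )
    return SiscomResult(
        zmap=zmap_mri,
        clusters=clusters,
        interictal_to_ictal=t_ii,
        ictal_to_mri=t_im,
        zmap_spect=zmap_spect,
        params=dict(
            fwhm_mm=fwhm_mm,
            z_threshold=z_threshold,
            min_cluster_size=min_cluster_size,
            norm_target=norm_target,
            do_registration=do_registration,
        ),
    )
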