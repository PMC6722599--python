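"""Ground-truth phantom generator.

Produces phantom MRI / SPECT pairs with implanted hyperperfusion blobs,
simulated cortical source activity with matching EEG, and the masks needed
to exercise every pipeline stage with a known answer.  Everything is
deterministic given the scenario seed.

Default desk-scale geometry (shared by all scenarios): 64^3 grid at 2 mm
centered on the origin, head sphere 58 mm, brain sphere 50 mm, cortical
source sphere 44 mm with shells at 50/54/58 mm, 19-channel montage on the
58 mm scalp.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError
from .esi import EEGEpoch, diffusion_kernel
from .eegio import write_eeg_tsv
from .headmodel import (
    CorticalSourceSpace,
    ElectrodeSet,
    Leadfield,
    leadfield_sphere3,
    make_sphere_source_space,
    standard_montage,
    write_surface,
)
from .imaging import BinaryMask, Volume3D, resample_to, write_volume
from .registration import RigidTransform

HEAD_RADIUS_MM = 58.0
BRAIN_RADIUS_MM = 50.0
CORTEX_RADIUS_MM = 44.0
SHELL_RADII_MM = (50.0, 54.0, 58.0)
SHELL_CONDUCTIVITIES = (0.33, 0.0042, 0.33)


@dataclass
class ScenarioSpec:
    """Parameter block fully determining one synthetic dataset."""

    scenario: str = "focal"               # focal | multifocal | discordant
    blob_centers_mm: list = None          # world mm; scenario default if None
    blob_radii_mm: list = None
    blob_increase: float = 0.25           # fractional perfusion increase
    source_directions: list = None        # unit vectors toward active patches
    snr_db: float = 15.0
    noise_sd: float = 0.05                # SPECT noise, fraction of local mean
    misregistration: RigidTransform = None
    seed: int = 0
    shape: tuple = (64, 64, 64)
    voxel_mm: float = 2.0
    subdivisions: int = 3                 # 642-vertex source sphere
    patch_smoothness: float = 4
    srate: float = 250.0
    n_samples: int = 200
    resection_radius_mm: float = 18.0

    def __post_init__(self):
        if self.scenario not in ("focal", "multifocal", "discordant"):
            raise ParameterError(f"unknown scenario {self.scenario!r}")
        if self.blob_increase <= 0:
            raise ParameterError("blob intensity increase must be > 0")
        if not np.isfinite(self.snr_db):
            raise ParameterError("SNR must be finite in a scenario spec")
        defaults = _scenario_defaults(self.scenario)
        if self.blob_centers_mm is None:
            self.blob_centers_mm = defaults["blob_centers"]
        if self.blob_radii_mm is None:
            self.blob_radii_mm = defaults["blob_radii"]
        if self.source_directions is None:
            self.source_directions = defaults["source_directions"]


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _scenario_defaults(scenario):
    d0 = _unit([0.3, 0.6, 0.74])
    if scenario == "focal":
        return dict(
            blob_centers=[(CORTEX_RADIUS_MM * d0).tolist()],
            blob_radii=[12.0],
            source_directions=[d0.tolist()],
        )
    if scenario == "discordant":
        # blob 30 mm posterior to the active source
        src = CORTEX_RADIUS_MM * d0
        blob = src + np.array([0.0, -30.0, 0.0])
        return dict(
            blob_centers=[blob.tolist()],
            blob_radii=[12.0],
            source_directions=[d0.tolist()],
        )
    d1 = _unit([-0.7, 0.5, 0.5])
    d2 = _unit([0.7, -0.4, 0.6])
    return dict(
        blob_centers=[(CORTEX_RADIUS_MM * d1).tolist(),
                      (CORTEX_RADIUS_MM * d2).tolist()],
        blob_radii=[8.0, 8.0],
        source_directions=[d1.tolist(), d2.tolist()],
    )


@dataclass
class GroundTruthBundle:
    mri: Volume3D
    brain_mask: BinaryMask
    ictal: Volume3D
    interictal: Volume3D
    blob_mask: BinaryMask
    source_space: CorticalSourceSpace
    electrodes: ElectrodeSet
    leadfield: Leadfield
    eeg: EEGEpoch
    true_currents: np.ndarray
    active_vertices: np.ndarray
    resection_mask: BinaryMask = None
    spec: ScenarioSpec = None
    files: dict = field(default_factory=dict)


def _grid_affine(shape, voxel_mm):
    aff = np.eye(4)
    aff[:3, :3] *= voxel_mm
    aff[:3, 3] = -voxel_mm * (np.asarray(shape) - 1) / 2.0
    return aff


def _world_radius_grid(shape, affine):
    ii, jj, kk = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    ijk = np.stack([ii, jj, kk], axis=-1).astype(float)
    xyz = ijk @ affine[:3, :3].T + affine[:3, 3]
    return xyz, np.linalg.norm(xyz, axis=-1)


def _smooth_field(shape, rng, sigma_vox=1.5, amplitude=0.35):
    # texture scale chosen so rigid registration is well conditioned in
    # rotation: a coarser field makes the MI optimum degenerate
    noise = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    sm /= max(np.abs(sm).max(), 1e-12)
    return 1.0 + amplitude * sm


def make_phantom_head(shape=(64, 64, 64), voxel_mm=2.0, seed: int = 0):
    """Spherical head/brain phantom MRI plus brain mask."""
    if min(shape) < 32:
        raise ParameterError("grid must be at least 32^3")
    rng = np.random.default_rng(seed)
    affine = _grid_affine(shape, voxel_mm)
    xyz, r = _world_radius_grid(shape, affine)
    brain = r <= BRAIN_RADIUS_MM
    head = r <= HEAD_RADIUS_MM
    mri = np.zeros(shape)
    mri[head] = 40.0
    mri[brain] = (80.0 * _smooth_field(shape, rng))[brain]
    return Volume3D(mri, affine), BinaryMask(brain, affine)


def make_spect_pair(mri: Volume3D, brain_mask: BinaryMask, spec: ScenarioSpec):
    """Ictal / interictal perfusion pair with an implanted hyperperfusion blob.

    interictal = baseline * (1 + noise); ictal = baseline * (1 +
    increase * blob) * (1 + noise); noise is Gaussian with SD proportional
    to the local mean.  The misregistration transform, when set, is applied
    to the interictal volume.
    """
    rng = np.random.default_rng(spec.seed + 1)
    shape = brain_mask.shape
    xyz, r = _world_radius_grid(shape, brain_mask.affine)
    blob = np.zeros(shape, dtype=bool)
    for c, rad in zip(spec.blob_centers_mm, spec.blob_radii_mm):
        c = np.asarray(c, dtype=float)
        if np.linalg.norm(c) + 1e-9 > BRAIN_RADIUS_MM:
            raise GeometryError(
                f"blob center {c} (radius from origin "
                f"{np.linalg.norm(c):.1f} mm) is outside the brain sphere"
            )
        blob |= np.linalg.norm(xyz - c, axis=-1) <= rad
    blob &= brain_mask.data

    baseline = np.zeros(shape)
    baseline[brain_mask.data] = (60.0 * _smooth_field(shape, rng))[brain_mask.data]
    ictal_clean = baseline * (1.0 + spec.blob_increase * blob)
    interictal_clean = baseline

    def _noisy(clean):
        if spec.noise_sd <= 0:
            return clean.copy()
        return clean * (1.0 + spec.noise_sd * rng.standard_normal(shape))

    ictal = Volume3D(_noisy(ictal_clean), brain_mask.affine.copy())
    interictal = Volume3D(_noisy(interictal_clean), brain_mask.affine.copy())
    if spec.misregistration is not None:
        # move the interictal acquisition: resample through the inverse so
        # registration should recover `misregistration`
        interictal = resample_to(
            interictal, interictal, spec.misregistration.inverse()
        )
    return ictal, interictal, BinaryMask(blob, brain_mask.affine.copy())


def default_waveform(n_samples: int, srate: float) -> np.ndarray:
    """Damped 6 Hz oscillation, unit peak."""
    t = np.arange(n_samples) / srate
    return np.exp(-t / (0.4 * n_samples / srate)) * np.sin(2 * np.pi * 6.0 * t)


def simulate_eeg(
    src: CorticalSourceSpace,
    lf: Leadfield,
    active_vertices,
    waveform: np.ndarray,
    snr_db: float,
    seed: int = 0,
    smoothness: float = 4,
    amplitude_nAm: float = 10.0,
):
    """Sensor data = gain x currents + white noise at the requested channel-
    averaged SNR (dB); ``snr_db=inf`` gives noiseless data."""
    active_vertices = np.atleast_1d(np.asarray(active_vertices, dtype=int))
    if active_vertices.size == 0:
        raise ParameterError("empty active vertex set")
    if active_vertices.max() >= src.n_vertices:
        raise ParameterError("active vertex index outside source space")
    profile = diffusion_kernel(src, active_vertices, smoothness)
    waveform = np.asarray(waveform, dtype=float)
    J = amplitude_nAm * np.outer(profile, waveform)  # (N, T) nA*m
    clean = lf.gain @ J                              # microvolts
    if np.isinf(snr_db):
        data = clean
    else:
        rng = np.random.default_rng(seed)
        p_sig = float((clean ** 2).mean())
        p_noise = p_sig / (10.0 ** (snr_db / 10.0))
        data = clean + np.sqrt(p_noise) * rng.standard_normal(clean.shape)
    eeg = EEGEpoch(data, srate=250.0, labels=list(lf.electrodes.labels))
    return eeg, J


def _sphere_mask(like: BinaryMask, center_mm, radius_mm) -> BinaryMask:
    xyz, _ = _world_radius_grid(like.shape, like.affine)
    d = np.linalg.norm(xyz - np.asarray(center_mm, dtype=float), axis=-1)
    return BinaryMask(d <= radius_mm, like.affine.copy())


def build_bundle(spec: ScenarioSpec) -> GroundTruthBundle:
    """Assemble a full in-memory ground-truth bundle for a scenario."""
    mri, brain_mask = make_phantom_head(spec.shape, spec.voxel_mm, spec.seed)
    ictal, interictal, blob_mask = make_spect_pair(mri, brain_mask, spec)

    src = make_sphere_source_space(spec.subdivisions, CORTEX_RADIUS_MM)
    elec = standard_montage("10-20", scalp_radius_mm=HEAD_RADIUS_MM)
    lf = leadfield_sphere3(src, elec, SHELL_RADII_MM, SHELL_CONDUCTIVITIES)

    active = np.array(
        [
            int(np.argmin(np.linalg.norm(src.vertices - CORTEX_RADIUS_MM
                                         * _unit(d), axis=1)))
            for d in spec.source_directions
        ]
    )
    waveform = default_waveform(spec.n_samples, spec.srate)
    eeg, J = simulate_eeg(
        src, lf, active, waveform, spec.snr_db, seed=spec.seed + 2,
        smoothness=spec.patch_smoothness,
    )

    resection = None
    if spec.scenario == "focal":
        resection = _sphere_mask(
            brain_mask, spec.blob_centers_mm[0], spec.resection_radius_mm
        )
    elif spec.scenario == "discordant":
        # resection anterior to (and missing most of) the true focus,
        # mirroring a blown localization with posterior estimates
        src_center = CORTEX_RADIUS_MM * _unit(spec.source_directions[0])
        c = _unit(src_center + np.array([0.0, 60.0, 0.0])) * CORTEX_RADIUS_MM
        resection = _sphere_mask(brain_mask, c, 12.0)

    return GroundTruthBundle(
        mri=mri,
        brain_mask=brain_mask,
        ictal=ictal,
        interictal=interictal,
        blob_mask=blob_mask,
        source_space=src,
        electrodes=elec,
        leadfield=lf,
        eeg=eeg,
        true_currents=J,
        active_vertices=active,
        resection_mask=resection,
        spec=spec,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_dataset(spec: ScenarioSpec, out_dir) -> GroundTruthBundle:
    """Write a bundle to disk in standard formats plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    b = build_bundle(spec)
    files = {}

    def _vol(name, v):
        p = out / f"{name}.nii"
        write_volume(v, p)
        files[name] = p

    _vol("mri", b.mri)
    _vol("brain_mask", b.brain_mask)
    _vol("ictal", b.ictal)
    _vol("interictal", b.interictal)
    _vol("blob_mask", b.blob_mask)
    if b.resection_mask is not None:
        _vol("resection_mask", b.resection_mask)

    p = out / "cortex.off"
    write_surface(b.source_space, p)
    files["cortex"] = p

    p = out / "electrodes.tsv"
    with open(p, "w") as fh:
        fh.write("label\tx_mm\ty_mm\tz_mm\n")
        for lab, pos in zip(b.electrodes.labels, b.electrodes.positions):
            fh.write(f"{lab}\t{pos[0]:.6f}\t{pos[1]:.6f}\t{pos[2]:.6f}\n")
    files["electrodes"] = p

    p = out / "eeg.tsv"
    write_eeg_tsv(b.eeg, p)
    files["eeg"] = p

    p = out / "leadfield.npy"
    np.save(p, b.leadfield.gain)
    files["leadfield"] = p
    (out / "leadfield.json").write_text(json.dumps(b.leadfield.meta, indent=2))

    p = out / "true_currents.npy"
    np.save(p, b.true_currents)
    files["true_currents"] = p

    spec_dict = asdict(spec)
    if spec.misregistration is not None:
        spec_dict["misregistration"] = {
            "rotation_deg": spec.misregistration.rotation_deg.tolist(),
            "translation_mm": spec.misregistration.translation_mm.tolist(),
            "center_mm": spec.misregistration.center_mm.tolist(),
        }
    manifest = dict(
        scenario=spec.scenario,
        seed=spec.seed,
        spec=_jsonable(spec_dict),
        active_vertices=b.active_vertices.tolist(),
        checksums={k: _sha256(v) for k, v in files.items()},
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    b.files = {k: str(v) for k, v in files.items()}
    b.files["manifest"] = str(out / "manifest.json")
    return b


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
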