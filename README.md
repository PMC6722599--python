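# ezloc

Noninvasive epileptogenic-zone (EZ) localization toolkit combining three
functional-imaging readouts of the same seizure:

1. **SISCOM** — subtraction of ictal and interictal perfusion SPECT
   co-registered to MRI: global-count normalization, subtraction, 12-mm
   FWHM smoothing, z-scoring over the brain mask, z ≥ 2 cluster extraction.
2. **Ictal ESI** — EEG source imaging on a cortical source space with a
   multiple-sparse-priors Bayesian inverse (ReML free-energy optimization
   of covariance-component weights with ARD pruning).
3. **ESI + SISCOM priors** — the hyperperfusion clusters from (1) injected
   as additional spatial covariance components into the inverse of (2).

A voxelwise coincidence analysis scores each EZ hypothesis against a
resection mask (sensitivity / specificity), and a synthetic ground-truth
module generates phantom MRI/SPECT/EEG bundles so every stage is testable
end-to-end without patient data.

## Command line

```bash
# synthetic ground-truth bundle (focal | multifocal | discordant)
ezloc simulate --scenario focal --seed 1 --out-dir bundle/

# full methodology: three EZ maps + coincidence table
ezloc run-all --bundle-dir bundle/ --no-register --out-dir out/

# individual stages
ezloc register --moving interictal.nii --fixed ictal.nii --out t.txt
ezloc siscom --ictal ictal.nii --interictal interictal.nii \
             --mri mri.nii --mask brain.nii --fwhm 12 --zthr 2 --out-dir s/
ezloc forward --subdivisions 3 --out leadfield.npy
ezloc invert --eeg eeg.tsv --leadfield leadfield.npy --surface cortex.off \
             --siscom-clusters s/cluster_mask.nii --mri mri.nii --out-dir inv/
ezloc coincide --ez out/ez_esi_siscom.nii --resection resection.nii \
               --region brain.nii --out result.json
```

`run-all` accepts a TOML config (`--config run.toml`) with per-stage tables
(`[siscom]`, `[esi]`, ...); unknown keys are rejected and every run writes
a JSON manifest echoing all parameters.

## Library layout

| module | contents |
|---|---|
| `ezloc.imaging` | `Volume3D`/`BinaryMask`, NIfTI I/O, masking, rigid resampling |
| `ezloc.registration` | mutual information, multi-resolution rigid registration |
| `ezloc.siscom` | normalization, subtraction, smoothing, z-scoring, clustering, `run_siscom` |
| `ezloc.headmodel` | icosphere source spaces, mesh I/O, 10-20 montage, analytic 3-shell sphere leadfield |
| `ezloc.bem` | optional 3-compartment boundary-element leadfield (validated against the sphere) |
| `ezloc.esi` | patch priors, SISCOM prior components, MSP inversion, EZ map rendering |
| `ezloc.coincidence` | confusion counts, sensitivity/specificity, atlas label overlap |
| `ezloc.synthetic` | phantom heads, SPECT pairs, EEG simulation, on-disk bundles |
| `ezloc.eegio` | EEG TSV and minimal EDF read/write |
| `ezloc.cli` | click front end + `run_methodology` driver |

Conventions: world coordinates are RAS millimetres, voxel indices 0-based;
leadfields are average-referenced, µV per nA·m, fixed (normal) dipole
orientations.

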