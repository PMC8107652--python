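# mbqmri — model-based quantitative MRI reconstruction

Estimates physical parameter maps directly from multi-coil radial k-space
data by solving a nonlinear inverse problem (iteratively regularized
Gauss-Newton, IRGNM), or a linear temporal-subspace problem:

- **T1 mapping** from single-shot inversion-recovery radial FLASH
  (maps Mss, M0, R1*; T1 = M0 / (Mss · R1*)),
- **T2 mapping** from multi-echo spin-echo radial data (M0', R2),
- **water/fat separation with R2\* and B0 mapping** from multi-echo
  gradient-echo data (6-peak fat spectrum),
- **phase-contrast flow** (shared anatomy + directly regularized
  phase-difference map; v = Δφ·VENC/π),
- **linear subspace reconstruction** (SVD of a simulated signal
  dictionary or low-order Fourier modes, coefficient-space solve,
  voxel-wise 3-parameter fit; root-sum-squares composites and synthesized
  images for frequency-swept SSFP).

A self-contained, inverse-crime-free phantom simulator generates all test
inputs analytically: closed-form ellipse Fourier transforms, smooth
plane-wave-expansion coil sensitivities (so coil weighting stays
analytic), per-readout signal weighting, and seeded complex Gaussian
noise. No rasterized image is ever re-gridded to synthesize data.

The forward operator factorizes as sampling ∘ NUFFT ∘ coils ∘ signal
model. The NUFFT is a Kaiser-Bessel gridding implementation (oversampled
FFT + precomputed sparse interpolation) with a machine-exact adjoint;
direct-summation DFT oracles back all operator tests.

## CLI

```sh
mbqmri simulate --phantom t1_tubes --out data.h5 --seed 42
mbqmri nlrecon  --model t1 --in data.h5 --out maps.h5
mbqmri subrecon --in data.h5 --out coeffs.h5 --basis svd --coeffs 4 --reg l2:0.1
mbqmri fit      --in data.h5 --coeffs coeffs.h5 --out maps.h5
mbqmri synth    --maps maps.h5 --model t1 --times 40,400,800,4000 --out synth.h5
mbqmri roi      --maps maps.h5 --phantom t1_tubes
mbqmri traj     --n-spokes 1020 --out traj
```

Builtin phantoms: `t1_tubes` (10 tubes, T1 200–2000 ms, background
3000 ms), `t2_tubes` (T2 20–200 ms, background 1000 ms),
`waterfat_liver_toy`, `flow_vessel_toy`. Every command writes a
`<out>.log.json` provenance record (config hash, seed, versions).
K-space and maps are stored in documented HDF5 containers; BART-style
cfl/hdr and NIfTI export are available via `mbqmri.io`.

## Layout

| module | contents |
| --- | --- |
| `signal_models` | analytic signal models + exact partials |
| `trajectories` | (tiny) golden-angle radial trajectories, frame binning |
| `phantom` | analytic ellipse/coil k-space simulation, builtin fixtures |
| `encoding` | NUFFT, coil operators, forward model + Jacobians, Sobolev weights |
| `nlrecon` | IRGNM with CG/FISTA/ADMM inner solvers, end-to-end pipelines |
| `subspace` | dictionaries, SVD/Fourier bases, coefficient solve, pixel fit |
| `metrics`, `io`, `config`, `cli` | ROI/error metrics, file formats, YAML config, CLI |
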