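# maim

Multi-angle interference microscopy: near-surface 3D super-resolution
reconstruction combining TIRF-SIM lateral super-resolution with
multi-angle evanescent-wave depth inversion.

## The problem

Total internal reflection fluorescence (TIRF) confines excitation to an
evanescent field that decays exponentially above the coverslip with a
penetration depth

    d(θ) = λ / (4π √(n₁² sin²θ − n₂²)),

set by the incidence angle θ beyond the critical angle
θ_c = arcsin(n₂/n₁).  Recording a stack of images at K supercritical
angles therefore encodes each fluorophore's depth z in the way its
intensity falls off across angles, I(θ, z) = I₀(θ)·e^(−z/d(θ)).
Separately, structured illumination (SIM) formed by two interfering
evanescent waves doubles the *lateral* resolution from nine raw frames
(3 pattern orientations × 3 phases).  Combining the two gives
near-surface 3D imaging: sub-100-nm laterally, tens of nanometers
axially, over a ~600 nm depth volume — without any axial scanning.

This package implements the complete computational side of that method
for microscopists and method developers:

- **forward physics** — critical angle, penetration depth, s-polarized
  interface intensity, and the K×M angle-by-depth system matrix
  `A[k,m] = I₀(θ_k)·exp(−z_m/d(θ_k))`;
- **synthetic phantoms** — 3D microtubule filaments, surface-labeled
  microspheres resting on the coverslip, line-pair resolution targets,
  rendered into multi-angle ring-TIRF stacks and 9-frame SIM raw sets
  with Gaussian white noise at controlled SNR;
- **TIRF-SIM reconstruction** — band separation, data-driven pattern
  estimation (cross-correlation with sub-pixel zoomed-DFT refinement),
  generalized Wiener combination on a 2× grid with triangular
  apodization;
- **segmentation** — azimuthal ring averaging, SR-derived binary
  masking, guarded local-median background subtraction;
- **depth inversion** — per-pixel non-negative, ℓ1-regularized least
  squares, min ½‖Af − b‖² + μ‖f‖₁ s.t. f ≥ 0, solved by vectorized
  ADMM (projected-gradient and NNLS solvers provided for
  cross-checking), yielding per-pixel axial profiles, the mean depth
  h = Σ z f / Σ f, and assembled z-stacks;
- **validation** — Monte-Carlo depth-RMSE grids over depth × SNR,
  spherical-cap fitting of microsphere depth maps, line-pair/FWHM
  resolution metrics;
- **I/O and CLI** — multi-page float TIFF + JSON sidecars, YAML run
  configuration, color-coded depth rendering, and a `maim` command with
  `simulate / simrecon / depthrecon / pipeline / validate / render`
  subcommands.

## Worked example

Recover the diameter of simulated coverslip-attached, surface-labeled
4.86 μm silica microspheres by running the whole pipeline — render a
20-angle ring-TIRF stack and a SIM raw set at SNR 30, reconstruct the
lateral SR image, mask, subtract background, invert every masked pixel
to a depth profile, and fit the spherical cap h(r) = R − √(R² − r²):

```python
from maim import sphere_recovery_experiment

mean_diam, fits = sphere_recovery_experiment(n_spheres=2, seed=1)
for i, f in enumerate(fits):
    print(f"sphere {i}: diameter {f.diameter_um:.2f} um "
          f"({f.n_pixels} px, residual {f.residual_rms_nm:.0f} nm)")
print(f"mean fitted diameter: {mean_diam:.2f} um (truth 4.86 um)")
```

prints

```
sphere 0: diameter 4.79 um (1925 px, residual 39 nm)
sphere 1: diameter 4.83 um (1873 px, residual 120 nm)
mean fitted diameter: 4.81 um (truth 4.86 um)
```

i.e. the per-pixel depth map reproduces the sphere's lower cap well
enough that the fitted diameter lands within ~1% of ground truth.  The
underlying physics is available directly:

```python
from maim import OpticalConfig, critical_angle, penetration_depth

cfg = OpticalConfig()          # 488 nm, NA 1.49, n1 1.518, n2 1.33, 52 nm px
critical_angle(cfg.n1, cfg.n2) # 61.18 deg
penetration_depth(61.5, cfg)   # 374 nm
penetration_depth(71.0, cfg)   # 72 nm
```

The same pipeline is scriptable from the shell:

```sh
maim simulate --preset sphere --seed 1 --out run/
maim pipeline --simraw run/simraw --matirf run/matirf --out run/out/
```

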