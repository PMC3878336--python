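# attencorr

Two-view variational attenuation correction for confocal microscopy.

Thick specimens attenuate both the excitation and the emission light, so
confocal stacks darken with imaging depth in a tissue-dependent way that
single-view, depth-only corrections cannot undo.  `attencorr` estimates the
attenuation-free intensities `I`, a spatially variant attenuation field
`alpha` (Beer-Lambert coefficient per voxel-length) and an inter-recording
photobleaching factor `beta_2` from **two registered recordings of the same
sample taken from opposite sides** (top/bottom).  It is aimed at people
quantifying fluorescence in whole-mount recordings — zebrafish embryos,
plant roots, thick tissue sections — where the two-view acquisition is
feasible and registration is done upstream.

## Model

The measurement of view *i* at voxel *x* is

```
F_i(x) = beta_i * I(x) * C_i(x)^2          (beta_1 = 1, beta_2 > 0)
C_i(x) = ∫_S s_i(r) * exp(-∫_0^∞ alpha(x + l*r) dl) dr
```

— the transmission of the objective's cone of rays, squared because
excitation and emission traverse the same cone.  The estimate minimizes

```
E = Σ_i Σ_x (I_i - F_i)^2 / (m^2 I_i + σ^2)            data (Poisson-Gaussian weights)
  + λ Σ_x ψ(|∇alpha|^2)                                 smoothness (TM or TV)
  + μ Σ_x sqrt(alpha^2 + ε^2)                           sparsity
```

subject to `alpha >= 0`, `beta_2 > 0`, with box-constrained L-BFGS-B over
`alpha` and closed-form inner updates for `I` and `beta_2`.  See
`docs/methods.md` for discretization, optimization and limitations.

## Worked example

`python examples/reconstruct_sphere.py` simulates a textured absorbing
sphere (absorption 0.006/voxel, core intensity 4094, 20 % bleaching of the
bottom view, Poisson-Gaussian noise) at 48³ and reconstructs it:

```
estimated bleaching factor beta_2 : 0.802   (simulated: 0.800)
rmse of intensities               : 54.3 levels
rmse of attenuation coefficients  : 0.00130 per voxel
energy: 6.72e+07 -> 1.72e+07 over 20 iterations
rmse of the fused direct inversion: 54.5 levels
```

The bleaching factor is recovered to well under the 2 % tolerance one would
expect across noise realizations, and the intensity error is a small
fraction of the 4094-level core intensity.  Other examples: phantom
simulation (`simulate_phantom.py`), the ground-truth-optimal
one-factor-per-slice baseline and why it fails on the sphere interior
(`slicewise_oracle.py`), and prior-weight rules of thumb
(`parameter_rules.py`).

A thin CLI wraps the same functions:

```sh
attencorr simulate --phantom textured_sphere --shape 64 64 64 --seed 1 -o data/
attencorr correct  --top data/view_top.h5 --bottom data/view_bottom.h5 \
                   --reg tm --lambda 1e8 --mu 1e3 --m 0.05 -o out/
attencorr fuse     --top A.h5 --bottom B.h5 --conf-top CA.h5 --conf-bottom CB.h5 -o fused.h5
attencorr evaluate --phantom textured_sphere --reg tm -o table.csv
```

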