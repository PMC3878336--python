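"""Reconstruct intensities, attenuation and the bleaching factor from a
simulated two-view recording of the textured sphere.

Uses Tikhonov-Miller smoothing with the sparsity prior and the
Poisson-Gaussian data weights (model sigma fixed at 1, the usual convention
when the absolute noise scale is unknown).  A short run already recovers the
bleaching factor and most of the intensity range; longer runs refine the
attenuation field.
"""

import attencorr as ac

spec = ac.PhantomSpec(kind="textured_sphere", shape=(48, 48, 48), seed=0)
I_true, alpha_true, recs = ac.make_dataset(
    spec, beta2=0.8, noise=ac.NoiseParams(m=0.05, sigma=10.0, seed=0)
)

state = ac.reconstruct(
    recs,
    reg=ac.RegularizerSpec(kind="tm", lam=1e8, mu=1e3),
    noise=ac.NoiseParams(m=0.05, sigma=1.0),
    solver=ac.SolverConfig(max_outer_iterations=20),
)

print(f"estimated bleaching factor beta_2 : {state.beta2:.3f}   (simulated: 0.800)")
print(f"rmse of intensities               : {ac.rmse(state.I, I_true):.1f} levels")
print(f"rmse of attenuation coefficients  : {ac.rmse(state.alpha, alpha_true):.5f} per voxel")
print(f"energy: {state.energy_trace[0]:.3g} -> {state.energy_trace[-1]:.3g} "
      f"over {state.iteration} iterations")

# fuse the two corrected views weighted by their squared cone transmissions
corr_top = ac.VolumeGrid(recs.top.values / (state.C1.values ** 2 + 1e-12))
corr_bottom = ac.VolumeGrid(
    recs.bottom.values / (state.beta2 * state.C2.values ** 2 + 1e-12)
)
conf1 = ac.VolumeGrid(state.C1.values ** 2)
conf2 = ac.VolumeGrid(state.C2.values ** 2)
fused = ac.fuse_views(corr_top, corr_bottom, conf1, conf2)
print(f"rmse of the fused direct inversion: {ac.rmse(fused, I_true):.1f} levels")
print()
print("beta_2 close to 0.8 means the inter-recording signal loss was identified;")
print("the intensity rmse is a small fraction of the 4094-level core intensity.")
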