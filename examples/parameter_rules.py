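"""Rule-of-thumb starting values for the prior weights.

The smoothness weight lambda and sparsity weight mu are chosen so that each
energy term has roughly the same influence: the data term scales with the
squared expected residual r^2, the smoothness term with the expected
attenuation-gradient magnitude g (TV) or its square (TM), and the sparsity
term with the expected attenuation a.
"""

import attencorr as ac

r = 5.0       # expected residual intensity difference (average noise level)
a = 0.005     # expected attenuation coefficient, per voxel
g = 0.0005    # expected attenuation gradient magnitude, per voxel^2

for kind in ("tm", "tv"):
    lam, mu = ac.suggest_parameters(r, a, g, kind)
    print(f"{kind.upper()}: lambda = r^2/g{'^2' if kind == 'tm' else '':3s} = {lam:.3g}"
          f"    mu = r^2/a = {mu:.3g}")

print()
print("These are starting points for an exponential grid search, not optima;")
print("the best values depend on image content and the Poisson weight m.")
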