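"""Derive state thresholds from opening-event scatter.

Opening events (opening force, opening FRET) fall into three clusters, one
per conformation.  k-means with k = 3 on the standardized scatter finds the
cluster centres; midpoints between adjacent centroid coordinates give the
force thresholds separating F / F' / F'' and the FRET thresholds separating
the APO / WB / SB helix-arm states.
"""

import numpy as np

import forcefret as ff

forces, frets, truth = ff.simulate_opening_events(n_per_class=50, seed=0)
model = ff.derive_thresholds(ff.kmeans_cluster(forces, frets, k=3, n_restarts=20, seed=0))

print("cluster centroids (opening force pN, opening FRET):")
for i, (f, e) in enumerate(model.centroids):
    print(f"  C{i + 1}: {f:5.1f} pN, {e:.3f}")
print(f"FRET thresholds:  {model.fret_thresholds[0]:.3f} / {model.fret_thresholds[1]:.3f}")
print(f"force thresholds: {model.force_thresholds[0]:.2f} / {model.force_thresholds[1]:.2f} pN")

# the same pooled FRET values fitted to a sum of four Gaussians
rng = np.random.default_rng(1)
pooled = np.concatenate([
    rng.normal(0.05, 0.03, 400),  # unfolded baseline
    rng.normal(0.46, 0.06, 800),
    rng.normal(0.73, 0.10, 600),
    rng.normal(0.80, 0.045, 1200),
])
fit = ff.fit_gaussian_sum(pooled, n_components=4, bin_width=0.025)
print("\nGaussian-sum fit of the pooled histogram (bin 0.025):")
for a, m, s in zip(fit.amplitudes, fit.means, fit.sds):
    print(f"  mean {m:.3f}  sd {s:.3f}  amplitude {a:.0f}")
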