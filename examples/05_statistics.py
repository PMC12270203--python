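"""Statistical toolkit: comparing correlations and feature-space diagnostics.

Fisher's Z compares two Pearson correlations across samples; the
silhouette/spectral-entropy pair quantifies how much class structure a
feature space carries (higher silhouette, lower entropy = better).
"""

import numpy as np

import pepgan as pg

res = pg.fisher_z_test(0.5, 103, 0.0, 103)
print(f"Fisher Z for r=0.5 vs r=0.0 (n=103 each): Z={res.statistic:.3f}, p={res.p_value:.2e}")
print("Z near 3.9 says the two correlations differ far beyond sampling noise.\n")

ds = pg.generate_dataset(pg.SyntheticConfig(n_strong=80, n_weak=80, seed=3))
recs = [r for r in ds if r.label in ("strong", "weak")]
seqs = [r.sequence for r in recs]
labels = [r.label for r in recs]

phys = pg.robust_scale(pg.descriptor_frame(seqs)).array
onehot = np.stack([pg.one_hot(s).ravel() for s in seqs])
for name, feats in (("physiochemical", phys), ("sequence one-hot", onehot)):
    corr = pg.sample_correlation_matrix(feats)
    _, med = pg.silhouette_scores(1.0 - corr, labels)
    ent = pg.correlation_entropy(corr)
    print(f"{name:18s} median silhouette {med:+.3f}   spectral entropy {ent:.2f} bits")
print("\nThe physiochemical space concentrates the strong/weak structure into")
print("fewer correlated modes: higher silhouette, lower entropy.")
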