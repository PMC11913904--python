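"""Recover hidden conformational states from a gated synthetic ensemble.

The generator drives tunnel gates and torsion-like angle features with a
hidden 3-state Markov chain.  The state-model stages (torsion featurization,
tICA, k-means microstates, MSM, PCCA+) must rediscover those states from the
angle features alone; the hidden sequence is the ground truth to score
against.
"""

import numpy as np
from scipy.optimize import linear_sum_assignment

import tunnelstates as ts

spec = ts.SyntheticWorldSpec(n_frames=4000, n_trajectories=2, seed=42)
ensemble, truth = ts.generate_gated_ensemble(spec)

features = ts.featurize_torsions(ensemble)
tica = ts.fit_tica(features, lag=50)
print("tICA eigenvalues:", np.round(tica.eigenvalues[:4], 3))

projected = tica.transform(features, n_components=4)
micro = ts.kmeans_discretize(projected, k=50, seed=spec.seed)
model = ts.estimate_msm(micro, lag=20, reversible=True)
print("MSM slowest eigenvalues:", np.round(np.real(model.eigenvalues[:4]), 4))

decomposition = ts.pcca(model, n_macrostates=3)
macro = ts.build_state_trajectories(micro, decomposition)

predicted = np.concatenate(macro)
hidden = truth.all_states()
conf = np.zeros((3, 3))
for p, h in zip(predicted, hidden):
    conf[p, h] += 1
rows, cols = linear_sum_assignment(-conf)
accuracy = conf[rows, cols].sum() / len(hidden)
print(f"hidden-state recovery after label matching: {accuracy:.1%}")
print("values above ~90% mean the kinetic decomposition found the gates'")
print("hidden dynamics rather than noise")
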