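"""Recover a planted weight vector from pairwise comparisons alone.

A linear accelerated-failure-time cohort with known weights w* is
generated; the pairwise logistic fit sees only the comparable-pair
orderings, yet recovers the direction of w* almost exactly, and its
held-out concordance matches the oracle score w*.x.
"""

import numpy as np
import scipy.sparse as sp

from tdrank import build_pairs, c_index, fit_observations, simulate_linear_cohort

X, observations, risk, w_star = simulate_linear_cohort(
    n_patients=2000, n_features=20, seed=11
)
rng = np.random.default_rng(0)
perm = rng.permutation(len(observations))
train, test = perm[:1300], perm[1300:]
obs_train = [observations[i] for i in train]
obs_test = [observations[i] for i in test]

dataset = build_pairs(obs_train)
rows = {o.patient_id: i for i, o in enumerate(observations)}
X_train = X[[rows[o.patient_id] for o in dataset.observations]]
model = fit_observations(dataset, sp.csr_matrix(X_train), lam=1.0)

w = model.weights
cosine = w @ w_star / (np.linalg.norm(w) * np.linalg.norm(w_star))
X_test = X[[rows[o.patient_id] for o in obs_test]]
c_fit = c_index(X_test @ w, obs_test, n_bootstrap=0).value
c_oracle = c_index(X_test @ w_star, obs_test, n_bootstrap=0).value

print(f"training pairs: {dataset.n_pairs}")
print(f"cosine(w_hat, w*): {cosine:.3f}")
print(f"held-out C-index — fitted: {c_fit:.3f}, oracle: {c_oracle:.3f}")
# cosine near 1 means the ranking objective identifies the true risk
# direction; the fitted score concedes almost nothing to the oracle.
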