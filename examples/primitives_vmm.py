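"""Sub-second behavioral primitives and VMM stimulus decoding.

Tiles each trial's response into short windows, clusters the windows into
a small primitive alphabet, trains one PPM variable-order Markov model per
stimulus and decodes held-out trials by maximum likelihood.  Also shows
decoding of pure synthetic Markov chains where the exact Bayes accuracy of
the generators is known.
"""

import numpy as np

import ethopose as ep
from ethopose import synthetic as syn

# --- primitives from the behavior matrix --------------------------------
spec = syn.TrialEnsembleSpec(seed=7)
matrix, _, _ = syn.simulate_trials(spec)
seqs, centroids = ep.extract_primitives(matrix, duration=0.333,
                                        n_primitives=6, seed=0, runs=20)
L = len(seqs[0].symbols) - seqs[0].n_pre
print(f"primitive duration 0.333 s -> {L} symbols per 2 s response "
      f"(+{seqs[0].n_pre} pre-onset context symbols)")

acc = ep.decode_cv(seqs, matrix.stimulus, max_order=1, folds=10, seed=1)
print(f"10-fold VMM decoding accuracy (order 1): {acc:.3f} (chance 0.333)")

# --- known order-1 generators -------------------------------------------
P1 = np.array([[0.9, 0.1], [0.1, 0.9]])
P2 = np.array([[0.1, 0.9], [0.9, 0.1]])
train, ytr = syn.simulate_markov_sequences([P1, P2], 100, 15, seed=2)
test, yte = syn.simulate_markov_sequences([P1, P2], 100, 15, seed=3)
models = [
    ep.train_ppm([ep.PrimitiveSequence(0, s, 0.133, 2)
                  for s, l in zip(train, ytr) if l == c],
                 max_order=1, stimulus=c)
    for c in (0, 1)
]
acc = np.mean([ep.decode_stimulus(models, s)[0] == l
               for s, l in zip(test, yte)])
bayes = syn.bayes_accuracy([P1, P2], 15, n_mc=4000, seed=4)
print(f"two order-1 chains: PPM accuracy = {acc:.2f}, "
      f"generator Bayes accuracy = {bayes:.2f}")
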