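"""Score the four canonical two-locus patterns.

Generates the four archetype measurement pairs (random, constitutive
member, co-occurring, mutually exclusive), scores each for co-occurring
gains, and prints the min-sum M, covariance C and score S = M * C.  Only
the truly co-occurring pair should combine a large shared amplitude with
positive covariance; the constitutively aberrated pair has a large M but C
near zero, so the covariance weight suppresses it.
"""

import numpy as np

from cooccur import ModePair, generate_archetype_pairs, score_matrix

pairs = generate_archetype_pairs(n_samples=50, amplitude=2.0, noise_sd=0.1, seed=7)

print(f"{'archetype':<20} {'M (min-sum)':>12} {'C (cov)':>9} {'S = M*C':>9}")
for name, (u, v) in pairs.items():
    # score for gains: clip negatives as the gain channel does
    sm = score_matrix(
        ModePair("gain-gain", "a_p", "b_q",
                 np.maximum(u, 0)[:, None], np.maximum(v, 0)[:, None])
    )
    print(f"{name:<20} {sm.M[0, 0]:>12.2f} {sm.C[0, 0]:>9.3f} {sm.S[0, 0]:>9.2f}")

print("\nOnly the co-occurring pair earns a high S; the covariance weight")
print("removes the constitutive pair that dominates the min-sum alone.")
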