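"""Why the homogeneous model fails: calibration on a heterogeneous null.

Generates a configuration-model cohort with no dependence between genes
and reports the fraction of significant pairwise tests under both
background models.  A calibrated test should flag at most ~5% of
independent pairs at alpha = 0.05.
"""

import numpy as np

import mecotest as mt

cfg = mt.SimulationConfig(n_genes=250, n_tumors=400, seed=2,
                          min_alterations_tested=25)
X = mt.simulate_null_matrix(cfg)
tested = [g for g, s in zip(X.gene_labels, X.gene_sums)
          if s >= cfg.min_alterations_tested][:60]
print(f"testing all pairs of {len(tested)} genes "
      f"({len(tested) * (len(tested) - 1) // 2} pairs), no real signal")

for name, P in (("heterogeneous", mt.estimate_background(X)),
                ("homogeneous  ", mt.estimate_binomial_background(X))):
    for direction in ("cooccurrence", "exclusivity"):
        res = mt.test_all_pairs(X, P, direction, genes=tested)
        frac = np.mean([r.p_value <= 0.05 for r in res])
        print(f"{name} {direction:13s} fraction p<=0.05: {frac:.3f}")

print()
print("The homogeneous model mistakes shared tumor-load structure for")
print("co-occurrence and flags a large share of independent pairs; the")
print("margin-matched model stays at or below the nominal 5% level.")
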