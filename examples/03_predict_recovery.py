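"""CPM-style LOOCV prediction of recovery with permutation inference.

Builds a 60-participant cohort with a planted interaction effect (30
coherent effect nodes, population R^2 = 0.25 of recovery on the planted
composite feature), forms the interaction features z(V) * z(I), runs the
leave-one-out procedure (per-fold feature selection at p < .05, strength
averaging, simple regression), a 200-permutation test, and reports the
important nodes and their network distribution.
"""

import numpy as np

import varicpm as v

K, C = 30, 0.9
beta = 2.0 * np.sqrt(0.25 / 0.75 / ((1 + (K - 1) * C) / K))
spec = v.CohortSpec(
    effect_nodes=tuple(range(1, K + 1)),
    effect_size_interaction=beta,
    effect_node_correlation=C,
    noise_sd=2.0,
    task_scans=0,
    seed=11,
)
targets = v.draw_variability_targets(spec)
behavior, truth = v.generate_behavior(spec, targets.rest, self_other=targets.self_other)
features = v.interaction_features(targets.rest, truth.interdependence)
y = behavior["recovery"].to_numpy()

cfg = v.ModelConfig(n_permutations=200, permutation_seed=1)
result = v.loocv_predict(features, y, cfg)
for m in ("total", "positive", "negative"):
    print(f"{m:>8} model: r = {result.r[m] if result.valid[m] else None}  "
          f"valid = {result.valid[m]}  ({result.invalid_reason[m] or 'ok'})")

perm = v.permutation_test(features, y, cfg, result)
for m, p in perm.empirical_p.items():
    print(f"{m:>8} model: empirical P = {p:.4f}  "
          f"({perm.n_invalid_permutations[m]} invalid permutations excluded)")

imp = v.important_nodes(result)
planted = set(range(1, K + 1))
found = set(imp["node_id"])
print(f"\nimportant nodes (> 95% of iterations): {len(imp)}; "
      f"Jaccard overlap with the {K} planted nodes: "
      f"{len(found & planted) / len(found | planted):.2f}")

atlas = v.synthetic_atlas(spec.n_nodes, seed=0)
print("\nnetwork breakdown of the important nodes:")
print(v.network_breakdown(imp["node_id"].tolist(), atlas).head(5).to_string(index=False))
print("\nA predictive power r ~ 0.3-0.5 with empirical P < 0.05 mirrors the "
      "regime this analysis is designed for; the permutation null of CPM "
      "predictive power is wide (sd ~ 0.2 at n = 60), which is why the "
      "permutation test, not the parametric p, is the inferential anchor.")
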