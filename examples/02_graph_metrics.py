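"""Build a connectivity matrix and extract sparsity-swept graph metrics.

Shows the small-world profile of one subject's functional network: at each
sparsity level the binarized graph is compared against degree-preserving
rewired nulls, and every metric is summarized across the grid by its area
under the curve.
"""

from connectoclass import (
    CohortSpec,
    compute_fc,
    generate_cohort,
    metric_profile,
    threshold_at_sparsity,
)

cohort = generate_cohort(CohortSpec(n_sites=1, n_patients_per_site=1,
                                    n_controls_per_site=1, seed=3))
fc = compute_fc(cohort[0].timeseries)
print(f"connectivity matrix: {fc.n_regions} x {fc.n_regions}")

g = threshold_at_sparsity(fc, 0.10)
print(f"at sparsity 0.10 the graph keeps {g.n_edges} edges "
      "(identical for every subject by construction)")

profile = metric_profile(fc, n_nulls=20, seed=3)
for s, gm in zip(profile.sparsity_grid[::8], profile.global_metrics[::8]):
    print(f"S={s:.2f}  Cp={gm.Cp:.3f}  Lp={gm.Lp:.3f}  gamma={gm.gamma:.2f}  "
          f"lambda={gm.lam:.2f}  sigma={gm.sigma:.2f}  Eglob={gm.Eglob:.3f}")
print(f"feature vector: {profile.auc_features.size} AUC values "
      "(7 global + 3 nodal metrics x 90 regions)")
print("sigma > 1 indicates a small-world organization: clustered like a "
      "lattice, short paths like a random graph")
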