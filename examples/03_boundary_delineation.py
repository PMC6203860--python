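"""Delineate the benthos/hyporheos boundary from abundance data alone.

Simulates assemblages with a planted compositional turnover at 10 cm
(upwelling) and 15 cm (downwelling), then scans adjacent 5-cm layer pairs
with permutation ANOSIM on Bray-Curtis dissimilarities.  The boundary is
the shallowest pair whose assemblages differ significantly."""

from hyporheic.community import delineate_boundary
from hyporheic.experiments import boundary_study_scenario
from hyporheic.simulate import abundance_table, simulate_community

scenario = boundary_study_scenario(seed=3)
table = abundance_table(simulate_community(scenario))

for condition in ("UW", "DW"):
    sub = table[table.index.get_level_values("condition") == condition]
    res = delineate_boundary(sub, condition=condition, n_permutations=1000,
                             seed=3, holm=True)
    truth = scenario.boundary_depth[condition]
    print(f"\n{condition} (true boundary {truth:.0f} cm):")
    for t in res.pair_tests:
        print(f"  layers {t.upper_layer}-{t.lower_layer} "
              f"(edge {t.boundary_depth_cm:4.0f} cm): "
              f"R = {t.result.r_statistic:+.3f}, p = {t.result.p_value:.4f}, "
              f"between-layer similarity = {t.mean_between_similarity:.2f}")
    print(f"  -> detected boundary interval: layers {res.boundary_interval}, "
          f"edge at {res.boundary_depth_cm} cm")
print("\n(R near 0: assemblages indistinguishable; R near 1: complete "
      "turnover. The DW boundary sits deeper than the UW one.)")
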