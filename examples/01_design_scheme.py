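"""Build combinatorial environment schemes with fixed total carbon.

Constructs the hierarchical design (32 carbon sources paired by
monoculture-yield rank, merged level by level into one 32-source medium)
and the all-subsets design on 5 sources, then prints the environment
counts per complexity level.  Every environment carries the same total
carbon, so complexity varies while energy supply does not.
"""

import envcomplexity as ec

resources = [ec.Resource(i, f"cs{i + 1}", rank_score=float(i + 1)) for i in range(32)]
tree = ec.build_hierarchical_scheme(resources, total_carbon=1.5)

print("hierarchical scheme on 32 resources")
for level in tree.complexity_levels():
    print(f"  complexity {level:2d}: {len(tree.environments_by_complexity(level))} environments")
print(f"  total: {len(tree)} environments, {tree.n_edges} composite->constituent links")

subset = ec.build_full_subset_scheme(resources[:5], total_carbon=1.5)
print(f"\nall-subsets scheme on 5 resources: {len(subset)} environments")

pair = tree.environments_by_complexity(2)[0]
print(f"\nfirst rank-extreme pair {pair.id}: resources {sorted(pair.resources)}, "
      f"{list(pair.concentrations.values())[0]:.3f} carbon units each")
# the pairing puts the lowest-yield source with the highest-yield one, so
# every 2-source medium mixes a "poor" and a "rich" carbon source.
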