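"""How richness and yield scale with environmental complexity.

Runs two small consumer-resource ensembles over the 63-environment
hierarchical scheme: one where every species uses each resource with the
same probability (theta = 0.5), and one mixing generalists and
specialists (theta sampled per species).  Prints mean yield, species
richness and Shannon entropy per complexity level.  Uniform-theta
communities gain species as complexity grows; the generalist-specialist
mix flattens that gain.  (This demo uses 2 replicates to stay quick —
the niche-overlap contrast between the regimes needs a larger ensemble
to resolve.)
"""

import envcomplexity as ec
from envcomplexity.crm import CRMParams

resources = [ec.Resource(i, f"cs{i + 1}", float(i + 1)) for i in range(32)]
tree = ec.build_hierarchical_scheme(resources, total_carbon=1.5)

for label, theta in [
    ("uniform theta = 0.5", ec.ThetaSpec("uniform", 0.5)),
    ("generalists + specialists", ec.ThetaSpec("sampled_range", low=0.15, high=0.95)),
]:
    cfg = ec.EnsembleConfig(
        S=13, scheme=tree, theta=theta,
        n_replicates=2, byproduct_counts=[1, 5, 10], seed=7,
    )
    result = ec.run_ensemble(cfg, CRMParams())
    summary = ec.scaling_summary(result)
    rho = result.rho["rho"].mean()
    print(f"\n{label} (mean niche overlap rho = {rho:.2f})")
    print("  complexity   yield (CFU/mL)   richness S   entropy H (bits)")
    for _, row in summary.iterrows():
        print(f"  {int(row['complexity']):10d}   {row['yield_mean']:.3e}"
              f"        {row['richness_mean']:5.2f}        {row['shannon_mean']:.2f}")
# yield stays roughly constant with complexity (equal total carbon),
# while richness climbs only in the low-overlap regime.
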