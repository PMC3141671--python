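"""Time a gene duplication against the cyclostome-gnathostome split.

Simulates a lamprey-like query gene that diverged from KCNA1 *after* the
tri-gene cluster duplication (scenario II: cluster duplication before the
split), then runs the full pipeline: enumerate the 45 candidate placements
on the constrained gnathostome backbone, score each by maximum likelihood
under JTT+G4, convert log-likelihoods to topology weights, and fold the
weights through the event-timing rule.
"""

import dupetime as dt

spec = dt.SimulationSpec(seed=42, scenario="II", n_sites=1000)
alignment, truth = dt.simulate_family(spec)
print(f"simulated query {truth['query']} on branch {truth['branch_id']} "
      f"({truth['arrangement_id']}); true scenario: {truth['scenario']}")

analysis = dt.place_and_time(
    alignment,
    spec.backbone,
    spec.events,
    model=spec.model,
    optimize="attachment",  # EPA-style: only the graft branches re-fitted
)

table = analysis.placement_table().sort_values("weight", ascending=False)
print("\ntop candidate placements:")
print(table.head(5)[["placement_id", "lnL", "weight", "scenario"]].to_string(index=False))

in_set = table[table["in_1sigma_set"]]
print(f"\n{len(in_set)} topologies within one KH standard error of the best")

s = analysis.summary
print(f"\nP(scenario I)  = {s.p_scenario_i:.3f}   (cluster duplication after the split)")
print(f"P(scenario II) = {s.p_scenario_ii:.3f}   (cluster duplication before the split)")
print(f"N_bef = {s.n_bef:.2f}, N_aft = {s.n_aft:.2f}  (sum = 7 backbone duplication nodes)")
print("\nA P(II) near 1 with N_bef near 7 means the query's lineage split from")
print("the gnathostomes after all seven duplications - the simulated truth.")
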