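"""Retrieve the most similar historical case for a target resident.

Simulates a small screening cohort, learns forest attribute weights, fits
one risk curve per resident, and ranks the case base against one target by
the time-decayed interval similarity.  The best case's similarity
percentage decides the reuse tier of its diagnosis-and-treatment protocol.
"""

from fdacbr import CaseBase, retrieve
from fdacbr.simulate import SimConfig, simulate_cohort
from fdacbr.weights import fit_forest_weights

syn = simulate_cohort(SimConfig(n_residents=60, seed=4))
weights = fit_forest_weights(syn.cohort, n_trees=100, seed=4)
top3 = sorted(zip(weights.values, weights.names), reverse=True)[:3]
print("top forest weights:",
      ", ".join(f"{n}={v:.3f}" for v, n in top3))

protocols = {rid: f"<protocol of {rid}>" for rid in syn.cohort.ids()}
base = CaseBase.from_cohort(syn.cohort, weights, protocols=protocols)

target = base.ids()[0]
outcome = retrieve(target, base, theta=0.6, mu=0.8, k=5)
print(f"\ntarget {target} (archetype {syn.archetypes[target]}); "
      f"{outcome.n_incomparable} cases had no overlapping exam window")
print("rank  case id   similarity%  archetype")
for rank, (cid, pct) in enumerate(outcome.ranked, start=1):
    print(f"{rank:4d}  {cid}  {pct:10.1f}  {syn.archetypes[cid]:9d}")

print(f"\nbest-case tier: {outcome.tier}")
print("(>90% reuse the protocol directly, 70-90% alternative plan,")
print(" 60-70% auxiliary reference, otherwise not used)")
if outcome.best_protocol is not None:
    print("reused protocol payload:", outcome.best_protocol)
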