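"""Maximum-parsimony ancestral states with dependency-aware cost matrices.

Runs the parsimony battery on the synthetic 80-taxon dataset: ACCTRAN (unit
costs) and two Sankoff MPR analyses whose cost matrices encode either
independent characters or switch-on dependency (forbidden steps cost 100).
"""

import numpy as np

import paleoparity as pp

ds = pp.amniote_fixture(seed=21)
space = pp.build_space()
results = pp.parsimony_suite(ds.tree, ds.codings, forbidden_cost=100.0)

root = frozenset(ds.tree.leaf_labels())
for name, res in results.items():
    labels = res.state_labels
    states = ", ".join(labels[s] for s in sorted(res.node_states[root]))
    print(f"{name:12s} total cost {res.total_cost:6.1f}  root state(s): {states}")

mpr = results["MPR_sw"]
freq = mpr.state_freq[root]
print("\nMPR_sw root-state frequencies over all minimal reconstructions:")
for lab, f in zip(space.labels, freq):
    if f > 0:
        print(f"  {lab:14s} {f:.3f}")
print("true simulated root state:",
      space.labels[ds.node_states[root]])
# the MPR frequency summary reports every minimal-cost state rather than
# silently breaking ties; ACCTRAN returns one state by its stated convention
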