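"""Node centrality, predictability and bridge-node selection.

Strength sums absolute incident weights, expected influence (EI) keeps
their signs, closeness/betweenness use shortest paths on distances
1/|w|, and predictability is the share of a node's variance explained
by all other nodes.  Bridge variants restrict to cross-instrument
connections; bridge nodes are those strictly above the 80th percentile.
"""

from netpsych import centrality_table, estimate_network, select_bridge_nodes
from netpsych import study_like_dataset

data = study_like_dataset(n=1019, seed=7)
net = estimate_network(data)
table = centrality_table(net, data)

cols = ["strength", "expected_influence", "closeness", "predictability",
        "bridge_strength", "bridge_expected_influence"]
print(table[cols].round(3).to_string())
print(f"\nmean predictability: {table['predictability'].mean():.2f}")

for index, nodes in select_bridge_nodes(table).items():
    print(f"bridge nodes by {index}: {nodes or '(none above the cutoff)'}")
print("\nA node with high bridge strength channels association between")
print("instruments (e.g. between negative affect and schizotypy).")
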