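"""Copy-number and duplication accounting on a species-labeled gene tree.

Parses a small Newick gene tree whose tip labels are "Species|gene", counts
gene copies per species, and flags duplication nodes with the species-overlap
criterion: an internal node is a duplication if two of its child subtrees
contain the same species.
"""

from nucdup import (
    copy_number_table,
    label_duplications,
    parse_newick_genetree,
    sister_paralog_pairs,
)

NEWICK = "(((Scer|LYS20,Scer|LYS21),(Klac|HCS1,Klac|HCS2)),(Ylip|HCS,Ncra|HCS));"

tree = parse_newick_genetree(NEWICK)
table = copy_number_table(tree)
report = label_duplications(tree)
pairs = sister_paralog_pairs(tree)

print("copies per species:", dict(sorted(table.items())))
print(f"species with >= 2 copies: {report.n_multi_copy}")
print(f"duplication nodes (species-overlap): {report.n_duplications}")
for species, g1, g2 in pairs:
    print(f"within-species sister paralogs: {species}: {g1} / {g2}")

# Two species each hold a within-species cherry, so two duplication events
# are inferred; each cherry is a paralog pair whose closest relative in the
# tree is the other copy.
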