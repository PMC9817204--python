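"""Per-cell PD, PE and WE on a tiny hand-checkable community.

Three species on a 2x2 grid: A only in cell 1, B in cells 1-2, C only in
cell 2.  PE apportions each branch length across the cells its
descendants occupy, so summing PE over the map returns the whole tree
length.
"""

import phyloscape as ps

tree = ps.parse_newick("((A:1,B:1):1,C:2);")
grid = ps.Grid.regular(2, 2)
occ = ps.OccurrenceMatrix.from_records(
    [
        (grid.cell_ids[0], "A"),
        (grid.cell_ids[0], "B"),
        (grid.cell_ids[1], "B"),
        (grid.cell_ids[1], "C"),
    ],
    grid,
    tree,
)

table = ps.diversity_table(tree, occ)
print(table)
print(f"\ntotal tree length      : {tree.total_length}")
print(f"sum of PE over cells   : {table.PE.sum()}  (equals tree length)")
print(f"sum of WE over cells   : {table.WE.sum()}  (equals species count)")
# Cell 1 PE = 1/1 (A's branch, range 1) + 1/2 + 1/2 (B's branch and the
# shared AB stem, each in 2 cells) = 2.0; cell 2 = 1/2 + 1/2 + 2/1 = 3.0.
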