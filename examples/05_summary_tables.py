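"""Bookkeeping reports: duplication table, gene catalog, pooled-sex coverage.

Duplication sizes follow the plain kb-difference convention
(size = end_kb - start_kb); the catalog counts a multicopy locus annotated
under two names once; pooled-sex coverage of the hemizygous Y is
depth x male_fraction / 2.
"""

from ytraffic import report

rows = [
    dict(source_chromosome="E", scaffold="CH964272", start_kb=11_183, end_kb=11_448,
         n_genes=25, n_functional=1, n_pseudogenes=12),
    dict(source_chromosome="C", scaffold="CH963850", start_kb=1_340, end_kb=1_402,
         n_genes=10, n_functional=0, n_pseudogenes=10),
    dict(source_chromosome="B", scaffold="CH963913", start_kb=3_149, end_kb=3_452,
         n_genes=14, n_functional=2, n_pseudogenes=10),
    dict(source_chromosome="B", scaffold="CH963857", start_kb=10_827, end_kb=10_901,
         n_genes=9, n_functional=1, n_pseudogenes=4),
]
table = report.segdup_table(rows)
print(table.to_string(index=False))
print("\nThe totals row sums 704 kb of duplicated sequence carrying 58 genes,")
print("of which only 4 stayed functional and 36 are recognizable pseudogenes")
print("(the remainder disappeared).")

cat = report.catalog(
    ["kl-2", "kl-3", "PRY", "PPrY", "ORY", "CCY", "ARY", "JYalpha"],
    ["GK21041", "GK20609", "GK13929", "GK28041", "GK27472", "YOgnWI030283",
     "GK21220", "YOgnWI000172", "GK27406", "GK28211", "GK18510", "GK20591",
     "YOgnWI018045", ("GK20618", "GK20619")],
)
print(f"\ncatalog: {cat.n_total_y_genes} Y-linked genes "
      f"({cat.n_previously_known} previously known + {cat.n_new} new loci)")

print(f"\nexpected Y coverage from an 8.4x unsexed (50/50) library: "
      f"{report.expected_y_depth(8.4, 0.5)}x")
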