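"""The packaged worked example: from printed tables to one ceRNA triplet.

Filters the candidate sponge-target miRNAs (down-regulated in tumor)
and their predicted target genes (up-regulated in tumor), then closes
the six reported sign-consistent pairs into a lncRNA/miRNA/mRNA triple.
"""

from cernascreen import (
    apply_de_filter,
    assemble_triplets,
    load_consistent_pairs_fixture,
    load_table3_fixture,
    load_table4_fixture,
)

mirnas = load_table3_fixture()
mi_down = apply_de_filter(mirnas, min_abs_log2fc=1.0, max_p=0.05, direction="down")
print(f"candidate miRNAs: {len(mirnas)}; down-regulated (|log2FC|>=1, p<0.05): "
      f"{len(mi_down)}")

targets = load_table4_fixture()
m_up = apply_de_filter([rec for _, rec in targets], 1.0, 0.05, "up")
unique_genes = {r.feature_id for r in m_up}
print(f"predicted target rows: {len(targets)}; unique up-regulated genes: "
      f"{len(unique_genes)}")

pairs = load_consistent_pairs_fixture()
triplets = assemble_triplets(
    [p for p in pairs if p.pair_kind == "lnc-mi"],
    [p for p in pairs if p.pair_kind == "mi-m"],
    [p for p in pairs if p.pair_kind == "lnc-m"],
)
for t in triplets:
    print(f"sign-consistent triplet: {t.lncRNA_id} / {t.miRNA_id} / {t.mRNA_id}")

# the triple's evidence in the printed tables
by_id = {r.feature_id: r for r in mirnas}
print(f"{triplets[0].miRNA_id} log2FC in tumor: {by_id[triplets[0].miRNA_id].log2fc}")
block = {rec.feature_id: rec for mi, rec in targets if mi == triplets[0].miRNA_id}
print(f"{triplets[0].mRNA_id} log2FC in tumor: {block[triplets[0].mRNA_id].log2fc}")

# A triple with negative lncRNA-miRNA and miRNA-mRNA association but a
# positive lncRNA-mRNA association is the expression pattern expected if
# the lncRNA sequesters the miRNA away from its target mRNA.
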