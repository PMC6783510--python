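"""Assemble an antagonistic module pair from annotation + co-expression files.

Builds a miniature positive/negative pair for blood-vessel-diameter
regulation from a toy term→gene table and two co-expression query
exports, showing the filtering rules: co-expression evidence is kept
only with score > 0 and p < 0.01, and any gene appearing in both
candidate modules is removed from both.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from tfgmr import assemble_module_pair, core_genes_for_term, filter_coexpression
from tfgmr.module_builder import read_coexpression_table, write_gmt, write_provenance

ANNOTATIONS = """\
term_id\tgene
GO:0097755\tKNG1
GO:0097755\tNOS3
GO:0097755\tADRB2
GO:0097756\tEDN1
GO:0097756\tAVP
"""

# SEEK-style exports: gene, co-expression score, p-value.
# EDN1 is co-expressed with the positive core but is itself negative core,
# so it lands in both candidate sets and must be removed from both.
COEXP_POS = """\
gene\tscore\tp_value
ADM\t0.81\t0.0004
EDN1\t0.55\t0.0030
CALCRL\t0.12\t0.0500
"""
COEXP_NEG = """\
gene\tscore\tp_value
AGT\t0.66\t0.0011
ACE\t-0.20\t0.0001
"""

with TemporaryDirectory() as d:
    d = Path(d)
    (d / "annotations.tsv").write_text(ANNOTATIONS)
    (d / "coexp_pos.tsv").write_text(COEXP_POS)
    (d / "coexp_neg.tsv").write_text(COEXP_NEG)

    core_pos = core_genes_for_term(d / "annotations.tsv", "GO:0097755")
    core_neg = core_genes_for_term(d / "annotations.tsv", "GO:0097756")
    coexp_pos = filter_coexpression(read_coexpression_table(d / "coexp_pos.tsv"))
    coexp_neg = filter_coexpression(read_coexpression_table(d / "coexp_neg.tsv"))
    print("positive core:", sorted(core_pos))
    print("kept positive co-expression evidence:", sorted(coexp_pos),
          "(CALCRL dropped: p = 0.05 is not < 0.01)")
    print("kept negative co-expression evidence:", sorted(coexp_neg),
          "(ACE dropped: score ≤ 0)")

    pair = assemble_module_pair(core_pos, coexp_pos, core_neg, coexp_neg)
    write_gmt(pair, d / "modules.gmt")
    write_provenance(pair, d / "provenance.tsv")
    for m in (pair.positive, pair.negative):
        print(f"{m.name}: {len(m.members)} members — core {sorted(m.core_genes)}, "
              f"co-expressed {sorted(m.coexpressed_genes)}")
    print("EDN1 appears in neither module: it evidenced both directions.")
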