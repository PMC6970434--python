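"""Confidence-LCA taxonomy voting on tied best references.

When a read ties across α1,3GT genes from several organisms, its taxonomy is
called at the deepest rank supported by at least 90% of the tied lineages.
"""

from galscan.lca import LcaConfig, lca_assign
from galscan.refdb import TaxonomyLineage, lineage_format, lineage_parse

ECOLI = lineage_parse(
    "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacterales;"
    "f__Enterobacteriaceae;g__Escherichia;s__Escherichia coli;t__")
EFERG = lineage_parse(
    "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacterales;"
    "f__Enterobacteriaceae;g__Escherichia;s__Escherichia fergusonii;"
    "t__Escherichia fergusonii ATCC 35469")
HINF = lineage_parse(
    "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Pasteurellales;"
    "f__Pasteurellaceae;g__Haemophilus;s__Haemophilus influenzae;t__")

# nine strain-distinct E. coli lineages against one E. fergusonii:
strains = [TaxonomyLineage(ranks=ECOLI.ranks[:7] + (f"E. coli STR{k:02d}",))
           for k in range(9)]
lin, depth = lca_assign(strains + [EFERG], LcaConfig(confidence=0.90))
print(f"9:1 Escherichia split  -> depth {depth}: {lineage_format(lin, width=depth)}")

# an Enterobacterales / Pasteurellales tie can only be called at class level:
lin, depth = lca_assign([ECOLI, HINF], LcaConfig(confidence=0.90))
print(f"E. coli vs H. influenzae -> depth {depth}: {lineage_format(lin, width=depth)}")

# unanimity (confidence 1.0) is the classical strict LCA:
lin, depth = lca_assign(strains + [EFERG], LcaConfig(confidence=1.0))
print(f"same split, strict LCA  -> depth {depth}: {lineage_format(lin, width=depth)}")
# At 90% confidence a 9/10 species majority is called; requiring unanimity
# retreats to the genus shared by E. coli and E. fergusonii.
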