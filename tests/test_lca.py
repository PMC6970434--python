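"""Confidence-based LCA voting over tied best references."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from galscan.lca import (
    LcaConfig,
    TieMember,
    collapse_ties_by_lineage,
    lca_assign,
)
from galscan.refdb import TaxonomyLineage, lineage_parse

from conftest import TOY_LINEAGES, strict_lca_oracle

ECOLI = lineage_parse(TOY_LINEAGES["ECOLI"])
HINF = lineage_parse(TOY_LINEAGES["HINF"])
EFERG = lineage_parse(
    "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacterales;"
    "f__Enterobacteriaceae;g__Escherichia;s__Escherichia fergusonii;"
    "t__Escherichia fergusonii ATCC 35469")


def _ecoli_strain(k):
    return TaxonomyLineage(ranks=ECOLI.ranks[:7] + (f"Escherichia coli STR{k:02d}",))


class TestLcaAssign:
    def test_singleton_assigns_full_lineage(self):
        lin, depth = lca_assign([_ecoli_strain(1)], LcaConfig())
        assert depth == 8 and lin.ranks == _ecoli_strain(1).ranks

    def test_nine_to_one_escherichia_split_assigns_species_at_90pct(self):
        # nine strain-distinct E. coli lineages vs one E. fergusonii:
        # species support 9/10 = 0.90 >= 0.90; strain support then fails.
        votes = [_ecoli_strain(k) for k in range(9)] + [EFERG]
        lin, depth = lca_assign(votes, LcaConfig(confidence=0.90))
        assert depth == 7
        assert lin.ranks[6] == "Escherichia coli"
        assert lin.ranks[7] == ""

    def test_eight_to_two_split_stops_at_genus(self):
        votes = [_ecoli_strain(k) for k in range(8)] + [EFERG, EFERG]
        lin, depth = lca_assign(votes, LcaConfig(confidence=0.90))
        assert depth == 6 and lin.ranks[5] == "Escherichia"

    def test_enterobacterales_vs_pasteurellales_stops_at_class(self):
        lin, depth = lca_assign([ECOLI, HINF], LcaConfig(confidence=0.90))
        assert depth == 3
        assert lin.ranks[:3] == ("Bacteria", "Proteobacteria", "Gammaproteobacteria")
        assert lin.ranks[3] == ""

    def test_empty_tie_set_is_error(self):
        with pytest.raises(ValueError):
            lca_assign([], LcaConfig())

    def test_empty_reference_labels_cap_assignment_depth(self):
        truncated = lineage_parse("k__Bacteria;p__Proteobacteria")
        lin, depth = lca_assign([truncated, truncated], LcaConfig())
        assert depth == 2

    def test_confidence_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            LcaConfig(confidence=0.5)


_labels = st.sampled_from(["A", "B", "C"])
_rand_lineage = st.builds(
    lambda labs, depth: TaxonomyLineage(ranks=tuple(labs[:depth]) + ("",) * (8 - depth)),
    st.lists(_labels, min_size=8, max_size=8),
    st.integers(min_value=0, max_value=8),
)


class TestProperties:
    @given(st.lists(_rand_lineage, min_size=1, max_size=6))
    def test_confidence_one_reduces_to_strict_lca(self, lineages):
        lin, depth = lca_assign(lineages, LcaConfig(confidence=1.0))
        expected = strict_lca_oracle(lineages)
        assert depth == len(expected)
        assert lin.ranks[:depth] == expected

    @given(st.lists(_rand_lineage, min_size=1, max_size=6),
           st.floats(min_value=0.51, max_value=1.0))
    def test_raising_confidence_never_deepens_assignment(self, lineages, conf):
        _, d_lo = lca_assign(lineages, LcaConfig(confidence=conf))
        _, d_hi = lca_assign(lineages, LcaConfig(confidence=1.0))
        assert d_hi <= d_lo

    @given(st.lists(_rand_lineage, min_size=1, max_size=8),
           st.floats(min_value=0.51, max_value=1.0))
    def test_assigned_prefix_support_recomputed_independently(self, lineages, conf):
        lin, depth = lca_assign(lineages, LcaConfig(confidence=conf))
        for r in range(depth):
            support = sum(l.ranks[: r + 1] == lin.ranks[: r + 1] for l in lineages)
            assert support / len(lineages) >= conf - 1e-9
            assert lin.ranks[r] != ""

    @given(_rand_lineage, st.integers(min_value=1, max_value=5))
    def test_identical_tie_set_assigns_its_own_depth(self, lineage, n):
        lin, depth = lca_assign([lineage] * n, LcaConfig(confidence=1.0))
        assert depth == strict_lca_oracle([lineage]).__len__()
        assert lin.ranks[:depth] == lineage.ranks[:depth]


class TestCollapse:
    def test_identical_lineages_collapse_to_one_vote(self):
        ties = [TieMember("geneA", ECOLI), TieMember("geneB", ECOLI)]
        votes = collapse_ties_by_lineage(ties)
        assert votes == [(ECOLI, 1)]

    def test_per_gene_mode_keeps_multiplicity(self):
        halv = lineage_parse(TOY_LINEAGES["HALV"])
        ties = [TieMember("g1", ECOLI), TieMember("g2", ECOLI), TieMember("g3", halv)]
        votes = dict(collapse_ties_by_lineage(ties, per_gene=True))
        assert votes[ECOLI] == 2 and votes[halv] == 1

    def test_forty_five_duplicate_deposits_count_once_in_collapsed_mode(self):
        halv = lineage_parse(TOY_LINEAGES["HALV"])
        ties = [TieMember(f"dup{k}", ECOLI) for k in range(45)] + [TieMember("h", halv)]
        votes = collapse_ties_by_lineage(ties)
        assert sorted(w for _, w in votes) == [1, 1]

    def test_members_counted_once_per_gene_id(self):
        ties = [TieMember("g1", ECOLI, "+"), TieMember("g1", ECOLI, "-")]
        assert collapse_ties_by_lineage(ties, per_gene=True) == [(ECOLI, 1)]
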