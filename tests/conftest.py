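"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from functools import lru_cache

import pytest
from hypothesis import HealthCheck, settings

from galscan.refdb import N_RANKS, ReferenceGene, lineage_parse

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def oracle_semiglobal(read: str, ref: str) -> tuple[int, int, int]:
    """Exhaustive recursive enumeration of semi-global alignments.

    Enumerates the alignment graph (diagonal / read-gap / ref-gap moves, free
    reference end gaps) by plain recursion with memoisation and returns the
    optimum under the contract's ordering: max score (match +1, mismatch −1,
    gap −1), then max matches, then min columns.  Returns (score, matches,
    columns).  Independent of the packed-integer DP kernel.
    """
    m, n = len(read), len(ref)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple[int, int, int]:
        if i == m:  # remaining reference is a free end gap
            return (0, 0, 0)
        best = None
        if j < n:
            is_match = read[i] == ref[j] and read[i] in "ACGT"
            s, mt, nc = rec(i + 1, j + 1)
            cand = (s + 1, mt + 1, nc - 1) if is_match else (s - 1, mt, nc - 1)
            best = cand
        s, mt, nc = rec(i + 1, j)  # gap in reference, read base consumed
        cand = (s - 1, mt, nc - 1)
        if best is None or cand > best:
            best = cand
        if j < n:  # interior gap in read, reference base consumed
            s, mt, nc = rec(i, j + 1)
            cand = (s - 1, mt, nc - 1)
            if cand > best:
                best = cand
        return best

    score, matches, neg_cols = max(rec(0, s) for s in range(n + 1))
    return score, matches, -neg_cols


def strict_lca_oracle(lineages) -> tuple[str, ...]:
    """Longest common prefix of ranked lineages, stopping at empty labels."""
    prefix = []
    for r in range(N_RANKS):
        labels = {lin.ranks[r] for lin in lineages}
        if len(labels) != 1 or "" in labels:
            break
        prefix.append(next(iter(labels)))
    return tuple(prefix)


TOY_LINEAGES = {
    "ECOLI": "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacterales;"
             "f__Enterobacteriaceae;g__Escherichia;s__Escherichia coli;t__",
    "HINF": "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Pasteurellales;"
            "f__Pasteurellaceae;g__Haemophilus;s__Haemophilus influenzae;t__",
    "HALV": "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacterales;"
            "f__Hafniaceae;g__Hafnia;s__Hafnia alvei;t__Hafnia alvei ATCC 13337",
}


@pytest.fixture
def toy_db():
    """Three distinguishable 200-nt reference genes with Greengenes lineages."""
    import numpy as np

    rng = np.random.default_rng(42)
    bases = "ACGT"
    genes = []
    for gid in ("ECOLI", "HINF", "HALV"):
        seq = "".join(bases[i] for i in rng.integers(0, 4, size=200))
        genes.append(ReferenceGene(gene_id=gid, sequence=seq,
                                   lineage=lineage_parse(TOY_LINEAGES[gid]),
                                   gene_symbol="waaO"))
    return genes


@pytest.fixture
def toy_db_files(tmp_path, toy_db):
    """The toy database written as FASTA + lineage TSV."""
    from galscan.refdb import write_fasta, write_lineage_table

    fasta = tmp_path / "db.fasta"
    tsv = tmp_path / "db.tsv"
    write_fasta(toy_db, fasta)
    write_lineage_table(toy_db, tsv)
    return fasta, tsv
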