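"""Semi-global alignment correctness: DP vs enumeration oracle, screening, strands."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from galscan.align import (
    HAVE_NUMBA,
    ScreenConfig,
    align_semiglobal,
    best_alignment,
    identity_passes,
    reverse_complement,
    screen_read,
)
from galscan.qc import Read

from conftest import oracle_semiglobal

dna = st.text(alphabet="ACGT", min_size=1)


class TestAlignSemiglobal:
    def test_exact_substring_scores_full_identity(self):
        r = align_semiglobal("ACGTACGTAC", "TTTACGTACGTACTTT")
        assert (r.matches, r.columns, r.identity) == (10, 10, 1.0)
        assert (r.ref_start, r.ref_end) == (3, 13)

    def test_single_substitution(self):
        r = align_semiglobal("ACGAACGTAC", "TTTACGTACGTACTTT")
        assert (r.matches, r.columns, r.identity) == (9, 10, 0.9)

    def test_identical_short_sequences(self):
        r = align_semiglobal("ACGT", "ACGT")
        assert r.identity == 1.0 and (r.ref_start, r.ref_end) == (0, 4)

    def test_ambiguity_codes_never_match(self):
        r = align_semiglobal("ACGN", "ACGN")
        assert r.matches == 3

    def test_empty_sequence_is_hard_error(self):
        with pytest.raises(ValueError):
            align_semiglobal("", "ACGT")
        with pytest.raises(ValueError):
            align_semiglobal("ACGT", "")

    def test_invariants_on_result(self):
        r = align_semiglobal("ACGTTGCA", "TTACGTACGGTT")
        assert 0 <= r.matches <= r.columns
        assert r.identity == r.matches / r.columns
        assert r.ref_end - r.ref_start <= r.columns

    @given(dna.filter(lambda s: len(s) <= 8), dna.filter(lambda s: len(s) <= 14))
    def test_dp_equals_enumeration_oracle(self, read, ref):
        got = align_semiglobal(read, ref)
        score, matches, columns = oracle_semiglobal(read, ref)
        assert (got.matches, got.columns) == (matches, columns)
        assert 2 * got.matches - got.columns == score

    @given(st.data())
    def test_read_scores_perfect_identity_on_its_own_source_segment(self, data):
        ref = data.draw(st.text(alphabet="ACGT", min_size=30, max_size=120))
        i = data.draw(st.integers(0, len(ref) - 20))
        r = align_semiglobal(ref[i:i + 20], ref)
        assert r.identity == 1.0

    @pytest.mark.skipif(not HAVE_NUMBA, reason="compiled kernel unavailable")
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=30),
           st.text(alphabet="ACGTN", min_size=1, max_size=60))
    @settings(max_examples=60)
    def test_pure_python_fallback_matches_compiled_kernel(self, read, ref):
        fast = align_semiglobal(read, ref)
        slow = align_semiglobal(read, ref, pure_python=True)
        assert fast == slow


class TestScreenRead:
    def test_verbatim_read_hits_its_source_gene(self, toy_db):
        read = Read(read_id="r", sequence=toy_db[0].sequence[40:140], sample_id="s")
        hit = screen_read(read, toy_db, ScreenConfig(identity_cutoff=0.85))
        assert hit is not None and hit.best_identity == 1.0
        assert any(m.gene_id == "ECOLI" and m.strand == "+" for m in hit.tie_set)

    def test_reverse_complement_read_same_identity_flipped_strand(self, toy_db):
        fwd = Read(read_id="f", sequence=toy_db[0].sequence[40:140], sample_id="s")
        rev = Read(read_id="r", sequence=reverse_complement(fwd.sequence), sample_id="s")
        h_f = screen_read(fwd, toy_db, ScreenConfig())
        h_r = screen_read(rev, toy_db, ScreenConfig())
        assert h_f.best_identity == h_r.best_identity
        flipped = {"+": "-", "-": "+"}
        assert {(m.gene_id, flipped[m.strand]) for m in h_f.tie_set} == \
               {(m.gene_id, m.strand) for m in h_r.tie_set}

    def test_empty_database_is_hard_error(self):
        with pytest.raises(ValueError):
            screen_read(Read(read_id="r", sequence="ACGT" * 25), [])

    def test_divergent_read_retained_only_at_lenient_cutoff(self, toy_db):
        # ~10% substitutions: above 0.85 on average, below 0.935
        rng = np.random.default_rng(0)
        src = toy_db[1].sequence[:100]
        kept85 = kept935 = 0
        n = 40
        for _ in range(n):
            seq = list(src)
            for i in rng.choice(100, size=10, replace=False):
                seq[i] = "ACGT".replace(seq[i], "")[rng.integers(0, 3)]
            read = Read(read_id="r", sequence="".join(seq), sample_id="s")
            m, c, _ = best_alignment(read, toy_db)
            kept85 += identity_passes(m, c, 0.85)
            kept935 += identity_passes(m, c, 0.935)
        assert kept85 > n * 0.8       # nearly all retained at the lenient cutoff
        assert kept935 < n * 0.2      # nearly all rejected at the strict one

    def test_cutoff_nesting_on_fixed_reads(self, toy_db):
        rng = np.random.default_rng(3)
        reads = []
        for i in range(20):
            gene = toy_db[i % 3]
            start = int(rng.integers(0, 100))
            seq = list(gene.sequence[start:start + 80])
            for j in rng.choice(80, size=int(rng.integers(0, 12)), replace=False):
                seq[j] = "ACGT".replace(seq[j], "")[rng.integers(0, 3)]
            reads.append(Read(read_id=f"r{i}", sequence="".join(seq), sample_id="s"))
        hits85 = {r.read_id for r in reads
                  if screen_read(r, toy_db, ScreenConfig(identity_cutoff=0.85))}
        hits935 = {r.read_id for r in reads
                   if screen_read(r, toy_db, ScreenConfig(identity_cutoff=0.935))}
        assert hits935 <= hits85

    def test_boundary_identity_passes_at_its_exact_cutoff(self):
        assert identity_passes(17, 20, 0.85)
        assert not identity_passes(16, 20, 0.85)
        assert identity_passes(187, 200, 0.935)
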