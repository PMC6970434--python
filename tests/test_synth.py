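"""Synthetic-data generator: determinism, ground truth, cutoff evaluation."""

import numpy as np
import pytest

from galscan.align import screen_identities
from galscan.refdb import deduplicate
from galscan.synth import (
    SimConfig,
    SimTruth,
    evaluate_cutoffs,
    simulate_cohort,
    simulate_refdb,
    simulate_sample,
)

SMALL = SimConfig(seed=1, n_refs=6, ref_len_range=(400, 600),
                  reads_per_sample=30, target_fraction=0.5, divergence=0.05,
                  read_len=80, n_samples=3)


class TestRefdbSim:
    def test_seeded_rerun_is_byte_identical(self):
        a = simulate_refdb(SMALL)
        b = simulate_refdb(SMALL)
        assert a == b

    def test_planted_duplicates_are_reported(self):
        genes = simulate_refdb(SMALL, n_duplicates=2)
        _, rep = deduplicate(genes)
        assert rep.n_duplicates == 2

    def test_gene_count_and_lengths(self):
        genes = simulate_refdb(SMALL)
        assert len(genes) == SMALL.n_refs
        assert all(400 <= len(g.sequence) <= 600 for g in genes)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(divergence=1.5)
        with pytest.raises(ValueError):
            simulate_refdb(SimConfig(n_refs=0))


class TestSampleSim:
    def test_every_read_has_exactly_one_truth_record(self):
        genes = simulate_refdb(SMALL)
        reads, truths = simulate_sample(SMALL, genes)
        assert len(reads) == len(truths) == SMALL.reads_per_sample
        assert {r.read_id for r in reads} == {t.read_id for t in truths}

    def test_zero_divergence_reads_screen_at_full_identity(self):
        cfg = SimConfig(seed=2, n_refs=4, ref_len_range=(300, 400),
                        reads_per_sample=10, target_fraction=1.0, divergence=0.0,
                        read_len=60)
        genes = simulate_refdb(cfg)
        reads, truths = simulate_sample(cfg, genes)
        ids = screen_identities(reads, genes)
        assert all(m == c for m, c in ids.values())

    def test_read_longer_than_shortest_gene_is_error(self):
        genes = simulate_refdb(SMALL)
        with pytest.raises(ValueError):
            simulate_sample(SimConfig(read_len=10_000), genes)

    def test_background_reads_rarely_reach_the_lenient_cutoff(self):
        cfg = SimConfig(seed=3, n_refs=4, ref_len_range=(500, 700),
                        reads_per_sample=300, target_fraction=0.0, read_len=100)
        genes = simulate_refdb(cfg)
        reads, truths = simulate_sample(cfg, genes)
        ids = screen_identities(reads, genes)
        table = evaluate_cutoffs(ids, truths, cutoffs=[0.85])
        fp_rate = 1.0 - table.loc[0, "specificity"]
        assert fp_rate < 0.01


class TestEvaluateCutoffs:
    def test_zero_divergence_gives_perfect_sensitivity(self):
        cfg = SimConfig(seed=4, n_refs=4, ref_len_range=(300, 400),
                        reads_per_sample=12, target_fraction=1.0, divergence=0.0,
                        read_len=60)
        genes = simulate_refdb(cfg)
        reads, truths = simulate_sample(cfg, genes)
        table = evaluate_cutoffs(screen_identities(reads, genes), truths,
                                 cutoffs=[0.85, 0.935, 1.0])
        assert (table["sensitivity"] == 1.0).all()

    def test_sensitivity_monotone_in_cutoff_and_divergence(self):
        rows = []
        for div in (0.05, 0.12):
            cfg = SimConfig(seed=5, n_refs=4, ref_len_range=(300, 400),
                            reads_per_sample=60, target_fraction=1.0,
                            divergence=div, read_len=80)
            genes = simulate_refdb(cfg)
            reads, truths = simulate_sample(cfg, genes)
            t = evaluate_cutoffs(screen_identities(reads, genes), truths,
                                 cutoffs=[0.85, 0.935])
            rows.append(t["sensitivity"].tolist())
        assert rows[0][1] <= rows[0][0]         # stricter cutoff detects fewer
        assert rows[1][0] <= rows[0][0]         # higher divergence detects fewer

    def test_missing_truth_is_hard_error(self):
        with pytest.raises(ValueError):
            evaluate_cutoffs({"ghost": (50, 60)},
                             [SimTruth("other", "s", "background", "", -1, -1, 0, 0)])

    def test_empty_truth_is_hard_error(self):
        with pytest.raises(ValueError):
            evaluate_cutoffs({}, [])


class TestCohortSim:
    def test_full_determinism_of_cohort_generation(self):
        a = simulate_cohort(SMALL)
        b = simulate_cohort(SMALL)
        assert a.samples == b.samples
        assert a.antigen.equals(b.antigen)

    def test_antigen_tracks_planted_species_diversity(self):
        cfg = SimConfig(seed=6, n_refs=12, ref_len_range=(300, 400),
                        reads_per_sample=40, target_fraction=0.6,
                        read_len=80, n_samples=24, antigen_sigma=0.01)
        sim = simulate_cohort(cfg)
        df = sim.antigen
        # the linear model is recoverable from the planted diversity
        corr = np.corrcoef(df["n_species_true"], df["antigen"])[0, 1]
        assert corr > 0.95

    def test_truth_index_covers_all_reads(self):
        sim = simulate_cohort(SMALL)
        n_reads = sum(len(reads) for _, reads, _ in sim.samples)
        assert len(sim.truth_by_read) == n_reads
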