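"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators are provided:

* ``simulate_refdb`` — a toy reference gene set: i.i.d. uniform-ACGT genes of
  realistic marker-gene length (900–1500 nt) with lineages drawn from a small
  taxonomy mirroring the taxa that dominate gut α1,3GT carriage
  (Enterobacteriaceae, Pasteurellaceae, lactobacilli, ...), optionally with
  planted exact duplicates.
* ``simulate_curated_refdb`` — a synthetic stand-in for a manually curated
  α1,3GT collection: 193 entries of which 55 are exact nucleotide duplicates,
  45 of those deposited once per E. coli strain and the remaining 10 duplicated
  within a genus except for one cross-genus pair.  All sequences are random;
  only the composition (counts, lineages, duplication structure) is meaningful.
* ``simulate_sample`` / ``simulate_cohort`` — per-sample shotgun read sets
  mixing reads excised from reference genes under a divergence model with
  background reads of i.i.d. random sequence (guaranteed no homology), plus a
  per-sample antigen level depending linearly on the number of distinct
  species planted: antigen = alpha + beta·n_species + Normal(0, sigma²).

Every read carries a ground-truth record, and all randomness derives from a
single master seed through per-purpose child seeds, so outputs are
byte-identical across reruns and adding samples never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .qc import Read
from .refdb import ReferenceGene, TaxonomyLineage, lineage_format, lineage_parse

# A small taxonomy mirroring the species most often carrying α1,3GT genes in
# the human gut (Enterobacteriaceae and Pasteurellaceae dominate, with
# streptococci, lactobacilli and Bacteroidales also represented).
DEFAULT_TAXA: tuple[str, ...] = (
    "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacterales;f__Enterobacteriaceae;g__Escherichia;s__Escherichia coli;t__",
    "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacterales;f__Enterobacteriaceae;g__Escherichia;s__Escherichia fergusonii;t__Escherichia fergusonii ATCC 35469",
    "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Pasteurellales;f__Pasteurellaceae;g__Haemophilus;s__Haemophilus influenzae;t__",
    "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacterales;f__Hafniaceae;g__Hafnia;s__Hafnia alvei;t__Hafnia alvei ATCC 13337",
    "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;f__Streptococcaceae;g__Streptococcus;s__Streptococcus salivarius",
    "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;f__Streptococcaceae;g__Streptococcus;s__Streptococcus pneumoniae",
    "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;f__Lactobacillaceae;g__Pediococcus;s__Pediococcus pentosaceus",
    "k__Bacteria;p__Firmicutes;c__Bacilli;o__Lactobacillales;f__Lactobacillaceae;g__Lactobacillus;s__Lactobacillus delbrueckii;t__Lactobacillus delbrueckii subsp. bulgaricus",
    "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Tannerellaceae;g__Parabacteroides;s__Parabacteroides distasonis;t__",
    "k__Bacteria;p__Bacteroidetes;c__Bacteroidia;o__Bacteroidales;f__Prevotellaceae;g__Prevotella;s__Prevotella sp. P6B1;t__",
    "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Eubacteriaceae;g__Eubacterium;s__Eubacterium eligens;t__Eubacterium eligens ATCC 27750",
    "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacterales;f__Enterobacteriaceae;g__Klebsiella;s__Klebsiella pneumoniae;t__",
)

_GENE_SYMBOLS = ("waaO", "rfaI", "rfaJ", "gspA", "waaI", "ybl158")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohorts.

    Defaults: marker genes of 900–1500 nt, 100 nt reads at constant Q30, 15%
    of reads excised from reference genes at 5% per-base divergence with no
    indels (so expected identity has the closed form 1 − divergence), and an
    antigen model on an ELISA optical-density-like scale.
    """

    seed: int = 0
    n_refs: int = 16
    ref_len_range: tuple[int, int] = (900, 1500)
    taxonomy_spec: tuple[str, ...] = DEFAULT_TAXA
    reads_per_sample: int = 120
    target_fraction: float = 0.15
    divergence: float = 0.05
    indel_prob: float = 0.0
    read_len: int = 100
    n_samples: int = 10
    antigen_alpha: float = 0.2
    antigen_beta: float = 0.15
    antigen_sigma: float = 0.05

    def __post_init__(self) -> None:
        for p in (self.divergence, self.indel_prob):
            if not 0.0 <= p < 1.0:
                raise ValueError(f"probability out of [0, 1): {p}")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ValueError(f"target_fraction out of [0, 1]: {self.target_fraction}")
        if self.read_len < 1 or self.n_samples < 1 or self.reads_per_sample < 1:
            raise ValueError("lengths and counts must be positive")
        if self.ref_len_range[0] > self.ref_len_range[1] or self.ref_len_range[0] < 1:
            raise ValueError(f"bad ref_len_range {self.ref_len_range}")


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth provenance of one simulated read."""

    read_id: str
    sample_id: str
    source: str  # gene_id or "background"
    lineage: str
    start: int
    end: int
    n_substitutions: int
    n_indels: int

    @property
    def is_target(self) -> bool:
        return self.source != "background"


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *tags]))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def simulate_refdb(cfg: SimConfig, n_duplicates: int = 0) -> list[ReferenceGene]:
    """Toy reference database; lineages cycle through the taxonomy spec.

    ``n_duplicates`` plants that many exact copies (fresh ids, same lineage) of
    the first genes, to exercise duplicate detection downstream.
    """
    if cfg.n_refs < 1:
        raise ValueError("n_refs must be >= 1")
    rng = _rng(cfg.seed, 0)
    lo, hi = cfg.ref_len_range
    taxa = [lineage_parse(s) for s in cfg.taxonomy_spec]
    genes = []
    for i in range(cfg.n_refs):
        genes.append(ReferenceGene(
            gene_id=f"SYN{i:03d}",
            sequence=_random_seq(rng, int(rng.integers(lo, hi + 1))),
            lineage=taxa[i % len(taxa)],
            gene_symbol=_GENE_SYMBOLS[i % len(_GENE_SYMBOLS)],
            source="custom",
        ))
    for d in range(n_duplicates):
        src = genes[d % cfg.n_refs]
        genes.append(replace(src, gene_id=f"DUP{d:03d}"))
    return genes


def _strain_lineage(base: str, strain: str) -> TaxonomyLineage:
    lin = lineage_parse(base)
    ranks = lin.ranks[:7] + (strain,)
    return TaxonomyLineage(ranks=ranks, width=8)


def simulate_curated_refdb(seed: int = 0) -> list[ReferenceGene]:
    """Synthetic stand-in for a manually curated α1,3GT gene list.

    The sequences are random; the composition reproduces the shape of a real
    multi-portal curation effort: 193 entries, 138 unique sequences, 55 exact
    duplicates of which 45 are per-strain E. coli deposits and 10 come from
    the remaining groups — all within one genus except a single cross-genus
    pair (Acidaminococcus intestini / Campylobacter lari).
    """
    rng = _rng(seed, 99)
    genes: list[ReferenceGene] = []

    ecoli = "k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Enterobacterales;f__Enterobacteriaceae;g__Escherichia;s__Escherichia coli"

    def add(gene_id, seq, lineage, symbol, source="KEGG"):
        genes.append(ReferenceGene(gene_id=gene_id, sequence=seq, lineage=lineage,
                                   gene_symbol=symbol, source=source))

    # two E. coli genes, each deposited once per strain: 2 kept + 45 duplicates
    seq_a = _random_seq(rng, 1023)
    for k in range(31):
        add(f"ECO_WAAO_{k:02d}", seq_a, _strain_lineage(ecoli, f"Escherichia coli STR{k:03d}"), "waaO")
    seq_b = _random_seq(rng, 987)
    for k in range(16):
        add(f"ECO_RFAI_{k:02d}", seq_b, _strain_lineage(ecoli, f"Escherichia coli STR{100 + k:03d}"), "rfaI")

    # same-genus duplicate groups outside Escherichia (9 removed in total)
    same_genus = [
        ("HIN", DEFAULT_TAXA[2], 3),
        ("SPN", DEFAULT_TAXA[5], 3),
        ("LDE", DEFAULT_TAXA[7], 3),
        ("HAL", DEFAULT_TAXA[3], 3),
        ("PRE", DEFAULT_TAXA[9], 2),
    ]
    for tag, base, n in same_genus:
        seq = _random_seq(rng, int(rng.integers(900, 1501)))
        lin = lineage_parse(base)
        for k in range(n):
            add(f"{tag}_{k:02d}", seq, lin, "gspA", source="UniProt")

    # the one cross-genus identical pair
    seq_x = _random_seq(rng, 1104)
    add("AIN_00", seq_x, lineage_parse(
        "k__Bacteria;p__Firmicutes;c__Negativicutes;o__Acidaminococcales;"
        "f__Acidaminococcaceae;g__Acidaminococcus;s__Acidaminococcus intestini;t__"),
        "gspA", source="UniProt")
    add("CLA_00", seq_x, lineage_parse(
        "k__Bacteria;p__Proteobacteria;c__Epsilonproteobacteria;o__Campylobacterales;"
        "f__Campylobacteraceae;g__Campylobacter;s__Campylobacter lari;t__"),
        "gspA", source="UniProt")

    # 130 unique singleton genes spread over the default taxa plus extra species
    genus_pool = [lineage_parse(t) for t in DEFAULT_TAXA]
    for i in range(130):
        base = genus_pool[i % len(genus_pool)]
        ranks = base.ranks[:6] + (f"{base.ranks[5]} sp{i:03d}", "")
        lin = TaxonomyLineage(ranks=ranks, width=8)
        add(f"UNI_{i:03d}", _random_seq(rng, int(rng.integers(900, 1501))), lin,
            _GENE_SYMBOLS[i % len(_GENE_SYMBOLS)], source=("KEGG", "UniProt", "ExPASy")[i % 3])
    assert len(genes) == 193
    return genes


def _mutate(rng: np.random.Generator, seq: str, divergence: float,
            indel_prob: float) -> tuple[str, int, int]:
    """Apply per-base substitutions and (optionally) indels; returns counts."""
    out = []
    n_sub = 0
    n_indel = 0
    for ch in seq:
        if indel_prob > 0.0:
            u = rng.random()
            if u < indel_prob / 2:  # deletion
                n_indel += 1
                continue
            if u < indel_prob:  # insertion before the base
                out.append("ACGT"[rng.integers(0, 4)])
                n_indel += 1
        if rng.random() < divergence:
            alts = "ACGT".replace(ch, "") if ch in "ACGT" else "ACGT"
            out.append(alts[rng.integers(0, len(alts))])
            n_sub += 1
        else:
            out.append(ch)
    return "".join(out), n_sub, n_indel


def simulate_sample(cfg: SimConfig, refdb: Sequence[ReferenceGene], sample_index: int = 0,
                    allowed_genes: Sequence[ReferenceGene] | None = None,
                    quality: int = 30) -> tuple[list[Read], list[SimTruth]]:
    """One sample's reads: gene-derived targets plus unrelated background.

    Target reads are substrings of reference genes mutated at the configured
    substitution/indel rates (both strands, chosen at random); background
    reads are i.i.d. uniform ACGT.  Each read gets one truth record.
    """
    if not refdb:
        raise ValueError("empty reference database")
    pool = list(allowed_genes) if allowed_genes is not None else list(refdb)
    shortest = min(len(g.sequence) for g in pool)
    if cfg.read_len > shortest:
        raise ValueError(f"read_len {cfg.read_len} exceeds shortest gene ({shortest} nt)")
    rng = _rng(cfg.seed, 1, sample_index)
    sample_id = f"S{sample_index:03d}"
    # per-sample gene-derived read count is binomial, so hit counts disperse
    # across subjects the way real carriage does
    n_target = int(rng.binomial(cfg.reads_per_sample, cfg.target_fraction))
    reads: list[Read] = []
    truths: list[SimTruth] = []
    from .align import reverse_complement  # local import to avoid a cycle

    for i in range(cfg.reads_per_sample):
        rid = f"{sample_id}_r{i:04d}"
        if i < n_target:
            gene = pool[int(rng.integers(0, len(pool)))]
            start = int(rng.integers(0, len(gene.sequence) - cfg.read_len + 1))
            frag = gene.sequence[start:start + cfg.read_len]
            seq, n_sub, n_indel = _mutate(rng, frag, cfg.divergence, cfg.indel_prob)
            if rng.random() < 0.5:
                seq = reverse_complement(seq)
            truths.append(SimTruth(rid, sample_id, gene.gene_id,
                                   lineage_format(gene.lineage), start,
                                   start + cfg.read_len, n_sub, n_indel))
        else:
            seq = _random_seq(rng, cfg.read_len)
            truths.append(SimTruth(rid, sample_id, "background", "", -1, -1, 0, 0))
        reads.append(Read(read_id=rid, sequence=seq,
                          qualities=(quality,) * len(seq), sample_id=sample_id))
    return reads, truths


@dataclass(frozen=True)
class CohortSim:
    refdb: tuple[ReferenceGene, ...]
    samples: tuple[tuple[str, tuple[Read, ...], tuple[SimTruth, ...]], ...]
    antigen: pd.DataFrame  # sample_id, n_species_true, antigen
    truth_by_read: dict = field(repr=False, default_factory=dict)


def simulate_cohort(cfg: SimConfig, refdb: Sequence[ReferenceGene] | None = None) -> CohortSim:
    """A cohort of samples with varying planted species diversity and antigen.

    Each sample draws a random subset of reference species; its target reads
    come only from genes of those species.  The antigen level is linear in the
    number of species actually planted, with Gaussian noise.
    """
    genes = list(refdb) if refdb is not None else simulate_refdb(cfg)
    species = sorted({g.lineage.species_key for g in genes})
    samples = []
    rows = []
    truth_by_read: dict[str, SimTruth] = {}
    for s in range(cfg.n_samples):
        rng = _rng(cfg.seed, 2, s)
        k = int(rng.integers(1, len(species) + 1))
        chosen = {species[i] for i in rng.choice(len(species), size=k, replace=False)}
        allowed = [g for g in genes if g.lineage.species_key in chosen]
        reads, truths = simulate_sample(cfg, genes, sample_index=s, allowed_genes=allowed)
        sid = reads[0].sample_id
        planted = {t.source for t in truths if t.is_target}
        planted_species = {g.lineage.species_key for g in genes if g.gene_id in planted}
        n_species_true = len(planted_species)
        noise = _rng(cfg.seed, 3, s).normal(0.0, cfg.antigen_sigma)
        antigen = cfg.antigen_alpha + cfg.antigen_beta * n_species_true + noise
        rows.append({"sample_id": sid, "n_species_true": n_species_true, "antigen": antigen})
        samples.append((sid, tuple(reads), tuple(truths)))
        for t in truths:
            truth_by_read[t.read_id] = t
    return CohortSim(
        refdb=tuple(genes), samples=tuple(samples),
        antigen=pd.DataFrame(rows), truth_by_read=truth_by_read,
    )


def evaluate_cutoffs(identities: dict[str, tuple[int, int]], truths: Sequence[SimTruth],
                     cutoffs: Sequence[float] = (0.85, 0.935)) -> pd.DataFrame:
    """Sensitivity and specificity of identity cutoffs against ground truth.

    ``identities`` maps read_id → best (matches, columns) from the screen;
    every screened read must have a truth record.
    """
    from .align import identity_passes

    if not truths:
        raise ValueError("empty truth set")
    truth_by_read = {t.read_id: t for t in truths}
    missing = set(identities) - set(truth_by_read)
    if missing:
        raise ValueError(f"reads missing ground truth: {sorted(missing)[:5]}")
    rows = []
    for cutoff in cutoffs:
        tp = fn = fp = tn = 0
        for rid, (m, c) in identities.items():
            detected = m > 0 and identity_passes(m, c, cutoff)
            if truth_by_read[rid].is_target:
                tp += detected
                fn += not detected
            else:
                fp += detected
                tn += not detected
        n_target = tp + fn
        n_bg = fp + tn
        rows.append({
            "cutoff": cutoff,
            "n_target": n_target,
            "n_background": n_bg,
            "sensitivity": tp / n_target if n_target else float("nan"),
            "specificity": tn / n_bg if n_bg else float("nan"),
        })
    return pd.DataFrame(rows)


def write_truth_table(truths: Sequence[SimTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tsample_id\tsource\tlineage\tstart\tend\tn_substitutions\tn_indels\n")
        for t in truths:
            fh.write(f"{t.read_id}\t{t.sample_id}\t{t.source}\t{t.lineage}\t{t.start}"
                     f"\t{t.end}\t{t.n_substitutions}\t{t.n_indels}\n")


def write_antigen_table(antigen: pd.DataFrame, path: str | Path) -> None:
    out = antigen.copy()
    out["antigen"] = out["antigen"].map(lambda v: float(f"{v:.6g}"))
    out.to_csv(path, sep="\t", index=False)
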