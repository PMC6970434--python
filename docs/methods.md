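# Methods

## The screening procedure

`galscan` quantifies carriage of α1,3-galactosyltransferase (α1,3GT) genes in
shotgun metagenomes by direct gene-targeted screening rather than taxonomic
profiling: each read is compared against every curated reference gene and
retained if its best percent identity reaches a threshold. Because α1,3GT
sequences are diverse, divergent homologs matter, and heuristic short-read
mappers tuned for high-identity matches are unreliable in that regime; the
aligner here is therefore exhaustive dynamic programming with no seeding,
banding or statistical approximation.

### Alignment model

Mode is semi-global ("glocal"): the read must align end to end (read end gaps
are penalised) while reference end gaps are free — the natural model for a
~100 nt fragment drawn from a ~1 kb gene. Scoring is match +1, mismatch −1,
gap −1 (linear). The reported quantity is

    identity = matches / alignment columns,

where interior gap columns count against identity and ambiguity codes (N and
the other IUPAC letters) never count as matches — a conservative choice that
cannot inflate identity. Both strands are screened; the tie-set of a read is
every (reference, strand) pair achieving exactly its best identity, compared
as exact rationals (cross-multiplication, never floats).

Among co-optimal alignments the reported one maximises matches, then
minimises columns, then takes the leftmost reference start, then the longest
reference span. The last rule exists because the first four quantities do not
pin down the reference interval: a diagonal mismatch can be exchanged for a
gap pair without changing (score, matches, columns), moving the alignment
end. Preferring the longer reference span prefers substitutions over gap
pairs and makes output byte-stable.

The kernel packs (score, matches, columns) and (start, span) into two 64-bit
integers compared lexicographically, so the whole tie chain is resolved
inside the recurrence; it is JIT-compiled with numba when available, and the
identical pure-Python function is the reference path (cross-checked in the
tests). Sequences are limited to 2·len(read) + len(ref) < 2²¹, far beyond
any gene-screening use.

Identity thresholds: the screening presets are 0.85 (lenient, tolerant of
divergent homologs) and 0.935 (strict). Threshold comparisons are done in
integer arithmetic at 1e-9 resolution so a printed cutoff like 0.935 admits
an identity of exactly 187/200 despite binary floating point representing
neither value exactly.

### Quality control

Reads are 3′-trimmed by a sliding window (default 4 bases, mean Phred < 20):
at the first failing window the cut is placed at the first below-threshold
base inside that window, so a run of good bases immediately before the
quality crash is kept. Leading/trailing N runs are stripped and reads shorter
than 50 nt are dropped. The published pipelines this emulates do not document
their trimming parameters, so these defaults follow common practice; the
trimmed read is always a contiguous substring of the input, and raising the
quality threshold never lengthens it (both property-tested).

### Taxonomy assignment

A read tying across genes from several organisms is assigned by
confidence-LCA voting. Votes are full lineage prefixes in an 8-rank
Greengenes-style taxonomy (kingdom → strain); at each rank the modal prefix
is assigned iff its supporting fraction is ≥ the confidence (default 0.90,
compared at 1e-9 resolution so a 9/10 split passes a 90% bar) and its label
is non-empty. Assignment stops at the first failing rank. Design choices:

* votes are over full prefixes, so homonymous genus names in different
  families cannot pool support;
* identical full lineages collapse to one vote by default — 45 per-strain
  deposits of the same E. coli gene should not outvote everything else — with
  a per-gene mode retained for sensitivity analysis;
* empty reference labels count as non-support, so truncated lineages cap the
  assignable depth;
* confidence 1.0 reduces exactly to the strict LCA (longest common prefix),
  verified against an independent oracle.

### Reference curation

Duplicates are exact equality of the normalised (uppercase, U→T) nucleotide
string; the first occurrence in input order is kept and each group is flagged
when all members share a genus. Deduplication is a curation/reporting step;
the screening database keeps all deposits by default because a read's best
identity is unaffected by duplicates and the LCA collapses identical lineages
anyway (`RunConfig.dedup_db` switches this).

The shipped curated-set generator (`simulate_curated_refdb`) is a synthetic
stand-in: random sequences arranged to the composition of a real
multi-portal curation — 193 deposits, 138 unique, 55 exact duplicates of
which 45 are per-strain E. coli deposits and 10 come from the remaining
groups, with exactly one duplicate pair crossing a genus boundary
(Acidaminococcus intestini / Campylobacter lari).

### Summaries

"Hits" are retained reads (one best hit per read), not read-reference pairs.
A species is counted when a read is assigned at the species rank or deeper;
strain-only differences collapse. Cohort prevalence is the percentage of
subjects with ≥ 1 hit (full precision kept, rounded value also reported);
dispersion is the sample SD (n−1; 0 for a single-sample cohort). The
ranked-taxa table sorts strictly by descending count, ties broken
lexicographically.

### Regression

`stats.linear_regression` is ordinary least squares (backed by
`scipy.stats.linregress`) with R² and a two-sided t-test on the slope (n−2
df). It requires n ≥ 3 and non-constant x. Exactly one regression is in
scope — antigen level against α1,3GT species diversity — so there is no
multiple-testing machinery.

## The synthetic-data generator

`galscan.synth` emulates the study inputs so every stage is testable without
downloads. Defaults (the generator's study conditions, chosen once):

| parameter | default | meaning |
|---|---|---|
| `ref_len_range` | 900–1500 nt | marker-gene length |
| `read_len` | 100 nt | shotgun read length, constant Q30 |
| `n_refs` | 16 | genes in the toy reference set |
| `n_samples` | 10 | subjects per cohort |
| `reads_per_sample` | 120 | reads per subject |
| `target_fraction` | 0.15 | expected share of gene-derived reads |
| `divergence` | 0.05 | per-base substitution probability |
| `indel_prob` | 0.0 | per-base indel probability |
| antigen (α, β, σ) | 0.2, 0.15, 0.05 | OD-like scale per species |

Gene-derived reads are uniform substrings of reference genes mutated at the
divergence rate (half reverse-complemented); with `indel_prob = 0` expected
identity has the closed form 1 − divergence, which the cutoff analyses use.
The per-sample number of gene-derived reads is Binomial(reads_per_sample,
target_fraction), so per-subject hit counts disperse as carriage does.
Background reads are i.i.d. uniform ACGT — a guaranteed no-homology null
(shuffled-gene backgrounds would be a harder negative control and are not the
default). Each sample draws a random subset of reference species; the antigen
level is linear in the number of species actually planted plus Gaussian
noise.

All randomness flows from one master seed through deterministic child seeds
(numpy `SeedSequence([seed, stage, sample])`), so whole-pipeline outputs are
byte-identical across reruns and adding samples never perturbs earlier ones.

What the simulator does **not** emulate: platform error profiles, quality
dropoff along reads, log-normal community abundance structure, paired ends,
real α1,3GT sequence phylogeny (reference genes are random, so inter-gene
identity is ~25%, easier to separate than real homolog families). Passing
tests therefore demonstrate the machinery's correctness and the cutoffs'
behaviour under the stated divergence model, not sensitivity on real gut
communities.

## Problem sizes

The test suite screens small cohorts (hundreds of reads against 4–8 genes of
300–700 nt); the reproduction script screens a default cohort (10 × 120 reads
against 16 genes of 900–1500 nt, one exhaustive pass reused for both
cutoffs), fuzzes the aligner against an enumeration oracle on 500 read/ref
pairs up to 8/14 nt, the LCA against a longest-common-prefix oracle on 1000
tie-sets, and measures antigen-slope 2-SE coverage over 200 replicates of
n = 100 subjects (the t-based 2-SE interval covers ≈ 95% at that size).

## Known limitations

* The exhaustive aligner is O(len(read) × len(ref)) per pair with no
  prefiltering by design; screening millions of reads against large gene sets
  is outside its intended scale.
* The identity definition (gap columns penalise, ambiguity never matches) and
  the semi-global mode are declared contracts; other tools' unstated
  conventions may differ, so absolute identities are comparable only within
  this tool.
* Real cohort-level numbers depend on undocumented trimming parameters and
  subject selection in the source datasets and are not reproducible at desk
  scale; the package reproduces reporting shapes on synthetic cohorts
  instead.
* The confidence-LCA voting semantics (per-unique-lineage votes over full
  prefixes, ≥ comparison) is one declared reading of "90%-confidence LCA";
  per-gene weighting is available but alternative per-rank semantics are not.
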