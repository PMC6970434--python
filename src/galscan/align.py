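"""Exhaustive semi-global alignment of reads against reference genes.

Every read is aligned optimally, by full dynamic programming with no heuristic
seeding or pruning, against every reference gene on both strands.  The mode is
semi-global ("glocal"): the read must be aligned end to end (its end gaps are
penalised) while end gaps on the reference are free, the natural choice for
short fragments screened against full-length genes.

Scoring is match +1, mismatch −1, gap −1 (linear).  The decision variable is
percent identity = matches / alignment columns, where gap columns count against
identity and ambiguity codes (N and the other IUPAC letters) never count as
matches.  Among co-optimal alignments the reported one maximises matches, then
minimises columns, then takes the leftmost reference start, then the longest
reference span — a fixed chain that makes outputs byte-stable.

The DP kernel packs (score, matches, columns) and (start, reference-span) into
two int64 keys compared lexicographically, so the whole tie-break chain is
resolved inside the recurrence.  The identical Python kernel is JIT-compiled
with numba when available; the pure-Python path is the reference
implementation and is cross-checked against the compiled one in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .refdb import ReferenceGene
from .lca import ReadHit, TieMember
from .qc import Read

_SHIFT = 21
_MASK = (1 << _SHIFT) - 1
# key1 packs (score+L | matches | L-columns); all three deltas are additive per move
_D_MATCH = (1 << 42) + (1 << 21) - 1   # score +1, matches +1, columns +1
_D_COST = -(1 << 42) - 1               # score −1, columns +1 (mismatch or gap)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _sg_kernel_py(read: np.ndarray, ref: np.ndarray) -> tuple[int, int]:
    """Semi-global DP over packed int64 keys; returns the best (key1, key2)."""
    m = read.shape[0]
    n = ref.shape[0]
    L = m + n
    k1p = np.empty(n + 1, np.int64)
    k2p = np.empty(n + 1, np.int64)
    k1c = np.empty(n + 1, np.int64)
    k2c = np.empty(n + 1, np.int64)
    base = (np.int64(L) << 42) | np.int64(L)
    for j in range(n + 1):
        k1p[j] = base
        k2p[j] = np.int64(n - j) << 21
    for i in range(m):
        a = read[i]
        k1c[0] = k1p[0] + _D_COST
        k2c[0] = k2p[0]
        for j in range(1, n + 1):
            if a == ref[j - 1] and a < 4:
                b1 = k1p[j - 1] + _D_MATCH
            else:
                b1 = k1p[j - 1] + _D_COST
            b2 = k2p[j - 1] + 1
            u1 = k1p[j] + _D_COST
            u2 = k2p[j]
            if u1 > b1 or (u1 == b1 and u2 > b2):
                b1 = u1
                b2 = u2
            l1 = k1c[j - 1] + _D_COST
            l2 = k2c[j - 1] + 1
            if l1 > b1 or (l1 == b1 and l2 > b2):
                b1 = l1
                b2 = l2
            k1c[j] = b1
            k2c[j] = b2
        k1p, k1c = k1c, k1p
        k2p, k2c = k2c, k2p
    best1 = k1p[0]
    best2 = k2p[0]
    for j in range(1, n + 1):
        if k1p[j] > best1 or (k1p[j] == best1 and k2p[j] > best2):
            best1 = k1p[j]
            best2 = k2p[j]
    return best1, best2


try:  # optional JIT of the identical kernel
    from numba import njit

    _sg_kernel_fast = njit(cache=True, nogil=True)(_sg_kernel_py)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba present in the supported environment
    _sg_kernel_fast = _sg_kernel_py
    HAVE_NUMBA = False


@dataclass(frozen=True)
class AlignmentResult:
    ref_id: str
    strand: str
    matches: int
    columns: int
    identity: float
    ref_start: int
    ref_end: int


@dataclass(frozen=True)
class ScreenConfig:
    """Screening thresholds; the study presets are 0.85 and 0.935 identity."""

    identity_cutoff: float = 0.85
    min_read_len: int = 50
    both_strands: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_cutoff <= 1.0:
            raise ValueError(f"identity_cutoff out of (0, 1]: {self.identity_cutoff}")


PRESET_CUTOFFS = (0.85, 0.935)


def _align_encoded(read: np.ndarray, ref: np.ndarray, pure_python: bool = False):
    m, n = read.shape[0], ref.shape[0]
    if 2 * m + n >= (1 << _SHIFT):
        raise ValueError("sequences too long for the packed DP kernel")
    kern = _sg_kernel_py if pure_python else _sg_kernel_fast
    k1, k2 = kern(read, ref)
    L = m + n
    score = (int(k1) >> 42) - L
    matches = (int(k1) >> _SHIFT) & _MASK
    columns = L - (int(k1) & _MASK)
    start = n - (int(k2) >> _SHIFT)
    span = int(k2) & _MASK
    return score, matches, columns, start, start + span


def align_semiglobal(read_seq: str, ref_seq: str, ref_id: str = "", strand: str = "+",
                     pure_python: bool = False) -> AlignmentResult:
    """Optimal semi-global alignment of the full read against one reference."""
    if not read_seq or not ref_seq:
        raise ValueError("cannot align an empty sequence")
    _, matches, columns, start, end = _align_encoded(
        encode(read_seq.upper()), encode(ref_seq.upper()), pure_python=pure_python
    )
    return AlignmentResult(
        ref_id=ref_id, strand=strand, matches=matches, columns=columns,
        identity=matches / columns, ref_start=start, ref_end=end,
    )


def best_alignment(read: Read, db: Sequence[ReferenceGene],
                   both_strands: bool = True) -> tuple[int, int, list[tuple[ReferenceGene, str]]]:
    """Best identity of a read over all references × strands.

    Returns ``(matches, columns, tie_set)`` where tie_set lists every
    (gene, strand) achieving exactly the best identity; identity comparisons
    are exact rationals (cross-multiplied), never floats.
    """
    if not db:
        raise ValueError("empty reference database")
    fwd = encode(read.sequence)
    rev = encode(reverse_complement(read.sequence)) if both_strands else None
    best_m, best_c = 0, 1
    ties: list[tuple[ReferenceGene, str]] = []
    for gene in db:
        ref = encode(gene.sequence)
        for strand, enc in (("+", fwd), ("-", rev)):
            if enc is None:
                continue
            _, m, c, _, _ = _align_encoded(enc, ref)
            cmp = m * best_c - best_m * c
            if cmp > 0:
                best_m, best_c = m, c
                ties = [(gene, strand)]
            elif cmp == 0 and m > 0:
                ties.append((gene, strand))
    return best_m, best_c, ties


def identity_passes(matches: int, columns: int, cutoff: float) -> bool:
    """Integer test matches/columns >= cutoff at 1e-9 resolution.

    The cutoff is snapped to parts-per-billion so that a printed threshold
    like 0.935 admits an identity of exactly 187/200 despite neither value
    being representable in binary floating point.
    """
    return matches * 10 ** 9 >= round(cutoff * 10 ** 9) * columns


def screen_read(read: Read, db: Sequence[ReferenceGene],
                cfg: ScreenConfig = ScreenConfig()) -> ReadHit | None:
    """Screen one QC-passed read; returns a hit iff best identity >= the cutoff."""
    best_m, best_c, ties = best_alignment(read, db, both_strands=cfg.both_strands)
    if best_m == 0 or not identity_passes(best_m, best_c, cfg.identity_cutoff):
        return None
    tie_set = tuple(
        TieMember(gene_id=g.gene_id, lineage=g.lineage, strand=s) for g, s in ties
    )
    return ReadHit(
        read_id=read.read_id, sample_id=read.sample_id,
        best_identity=best_m / best_c, matches=best_m, columns=best_c,
        tie_set=tie_set,
    )


def screen_sample(reads: Sequence[Read], db: Sequence[ReferenceGene],
                  cfg: ScreenConfig = ScreenConfig()) -> list[ReadHit]:
    """Screen all reads of one sample, skipping reads below the length floor."""
    hits = []
    for read in reads:
        if len(read.sequence) < cfg.min_read_len:
            continue
        hit = screen_read(read, db, cfg)
        if hit is not None:
            hits.append(hit)
    return hits


def screen_identities(reads: Sequence[Read], db: Sequence[ReferenceGene],
                      both_strands: bool = True) -> dict[str, tuple[int, int]]:
    """Best (matches, columns) per read id regardless of any cutoff.

    Used to evaluate several cutoffs from a single screening pass and to score
    sensitivity/specificity against simulator ground truth.
    """
    out: dict[str, tuple[int, int]] = {}
    for read in reads:
        m, c, _ = best_alignment(read, db, both_strands=both_strands)
        out[read.read_id] = (m, c)
    return out
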