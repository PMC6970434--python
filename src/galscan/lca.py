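"""Confidence-based lowest-common-ancestor (LCA) taxonomy assignment.

When a read ties for its best identity across α1,3GT genes from several
reference organisms, its taxonomy is called at the deepest rank supported by at
least a stated supermajority (default 90%) of the tied references.  Votes are
cast over full lineage prefixes, not per-rank labels in isolation, so
homonymous labels in different families cannot pool support; identical full
lineages collapse to a single vote by default (a gene deposited once per strain
should not dominate), with a per-gene voting mode retained for sensitivity
analysis.  At confidence 1.0 the procedure reduces to the classical strict LCA.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .refdb import (
    EMPTY_LINEAGE,
    N_RANKS,
    TaxonomyLineage,
    lineage_from_prefix,
)

_PPB = 10 ** 9  # confidence compared at 1e-9 resolution (90% with 9/10 must pass)


@dataclass(frozen=True)
class TieMember:
    gene_id: str
    lineage: TaxonomyLineage
    strand: str = "+"


@dataclass
class ReadHit:
    """One screened read: best identity, tied best references, assigned lineage."""

    read_id: str
    sample_id: str
    best_identity: float
    matches: int
    columns: int
    tie_set: tuple[TieMember, ...]
    assigned_lineage: TaxonomyLineage = field(default=EMPTY_LINEAGE)
    assigned_depth: int = 0


@dataclass(frozen=True)
class LcaConfig:
    confidence: float = 0.90

    def __post_init__(self) -> None:
        if not 0.5 < self.confidence <= 1.0:
            raise ValueError(f"confidence must be in (0.5, 1], got {self.confidence}")


def collapse_ties_by_lineage(tie_set: Sequence[TieMember],
                             per_gene: bool = False) -> list[tuple[TaxonomyLineage, int]]:
    """Turn a tie-set into weighted lineage votes.

    Members are counted once per unique gene_id.  In the default collapsed mode
    each distinct full lineage contributes one vote; in per-gene mode every
    gene contributes one vote, so duplicated deposits weigh in proportionally.
    """
    seen_genes: dict[str, TieMember] = {}
    for m in tie_set:
        seen_genes.setdefault(m.gene_id, m)
    counts: Counter[tuple[str, ...]] = Counter()
    rep: dict[tuple[str, ...], TaxonomyLineage] = {}
    for m in seen_genes.values():
        key = m.lineage.ranks
        counts[key] += 1
        rep.setdefault(key, m.lineage)
    if per_gene:
        return [(rep[k], c) for k, c in sorted(counts.items())]
    return [(rep[k], 1) for k in sorted(counts)]


def lca_assign(lineages: Sequence[TaxonomyLineage], cfg: LcaConfig = LcaConfig(),
               weights: Sequence[int] | None = None) -> tuple[TaxonomyLineage, int]:
    """Deepest lineage prefix supported by >= confidence of the votes.

    Walks ranks kingdom→strain; at each rank the modal full prefix is assigned
    iff its supporting weight fraction reaches the confidence and its label at
    that rank is non-empty (unresolved reference ranks cannot be assigned).
    Stops at the first failing rank.  Returns (assigned lineage, depth); depth
    0 means unassigned.
    """
    if not lineages:
        raise ValueError("empty tie set")
    if weights is None:
        weights = [1] * len(lineages)
    if len(weights) != len(lineages):
        raise ValueError("weights/lineages length mismatch")
    total = sum(weights)
    conf_ppb = round(cfg.confidence * _PPB)
    assigned: tuple[str, ...] = ()
    depth = 0
    for r in range(N_RANKS):
        votes: Counter[tuple[str, ...]] = Counter()
        for lin, w in zip(lineages, weights):
            votes[lin.ranks[: r + 1]] += w
        # deterministic modal choice: max count, then lexicographically smallest
        count = max(votes.values())
        prefix = min(k for k, v in votes.items() if v == count)
        if not prefix[r]:
            break
        if count * _PPB < conf_ppb * total:
            break
        assigned = prefix
        depth = r + 1
    if depth == 0:
        return EMPTY_LINEAGE, 0
    return lineage_from_prefix(assigned), depth


def assign_hit(hit: ReadHit, cfg: LcaConfig = LcaConfig(), per_gene: bool = False) -> ReadHit:
    """Fill in assigned_lineage/assigned_depth for one hit (returns the hit)."""
    votes = collapse_ties_by_lineage(hit.tie_set, per_gene=per_gene)
    lineage, depth = lca_assign([v[0] for v in votes], cfg, weights=[v[1] for v in votes])
    hit.assigned_lineage = lineage
    hit.assigned_depth = depth
    return hit


def assign_hits(hits: Iterable[ReadHit], cfg: LcaConfig = LcaConfig(),
                per_gene: bool = False) -> list[ReadHit]:
    return [assign_hit(h, cfg, per_gene=per_gene) for h in hits]
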