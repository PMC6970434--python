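"""Per-sample and per-cohort summaries of α1,3GT screening hits.

"Number of hits" means the number of retained reads (one best hit per read),
so the per-subject mean is a mean over reads, not read-reference pairs.
Species counting requires an assignment at the species rank or deeper;
strain-only differences collapse to a single species.  Cohort prevalence is
the percentage of subjects with at least one retained hit.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .lca import ReadHit
from .refdb import lineage_format

SPECIES_DEPTH = 7  # ranks assigned up to and including species


@dataclass(frozen=True)
class SampleSummary:
    sample_id: str
    n_reads_screened: int
    n_hits: int
    n_species: int
    lineage_counts: dict[str, int]


@dataclass(frozen=True)
class CohortSummary:
    n_samples: int
    n_positive: int
    prevalence_pct: float
    mean_hits: float
    sd_hits: float
    min_hits: int
    max_hits: int

    @property
    def prevalence_pct_rounded(self) -> int:
        return round(self.prevalence_pct)


def summarize_sample(hits: Sequence[ReadHit], sample_id: str | None = None,
                     n_reads_screened: int | None = None) -> SampleSummary:
    """Tally one sample's retained hits and its species-or-deeper assignments."""
    sids = {h.sample_id for h in hits}
    if len(sids) > 1:
        raise ValueError(f"hits from multiple samples: {sorted(sids)}")
    if sample_id is None:
        if not sids:
            raise ValueError("sample_id required for an empty hit list")
        sample_id = next(iter(sids))
    elif sids and next(iter(sids)) != sample_id:
        raise ValueError(f"hits belong to {next(iter(sids))!r}, not {sample_id!r}")
    counts: Counter[str] = Counter()
    species: set[tuple[str, ...]] = set()
    for h in hits:
        counts[lineage_format(h.assigned_lineage, width=h.assigned_depth)] += 1
        if h.assigned_depth >= SPECIES_DEPTH:
            species.add(h.assigned_lineage.species_key)
    return SampleSummary(
        sample_id=sample_id,
        n_reads_screened=n_reads_screened if n_reads_screened is not None else len(hits),
        n_hits=len(hits),
        n_species=len(species),
        lineage_counts=dict(counts),
    )


def cohort_stats(samples: Sequence[SampleSummary]) -> CohortSummary:
    """Prevalence, mean, sample SD (n−1) and range of per-sample hit counts."""
    if not samples:
        raise ValueError("empty cohort")
    hits = np.array([s.n_hits for s in samples], dtype=float)
    n = len(samples)
    n_pos = int((hits > 0).sum())
    sd = float(hits.std(ddof=1)) if n > 1 else 0.0
    return CohortSummary(
        n_samples=n,
        n_positive=n_pos,
        prevalence_pct=100.0 * n_pos / n,
        mean_hits=float(hits.mean()),
        sd_hits=sd,
        min_hits=int(hits.min()),
        max_hits=int(hits.max()),
    )


def rank_taxa(hits: Sequence[ReadHit]) -> pd.DataFrame:
    """Ranked table of assigned lineages by descending total hit count.

    Ties break lexicographically on the lineage string, so the table is
    deterministic for a given hit set.
    """
    counts: Counter[str] = Counter(
        lineage_format(h.assigned_lineage, width=h.assigned_depth) for h in hits
    )
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["lineage", "n_hits"])


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_sample_summaries(samples: Sequence[SampleSummary], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tn_reads_screened\tn_hits\tn_species\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.n_reads_screened}\t{s.n_hits}\t{s.n_species}\n")


def write_cohort_json(summary: CohortSummary, path: str | Path) -> None:
    payload = {
        "n_samples": summary.n_samples,
        "n_positive": summary.n_positive,
        "prevalence_pct": float(_fmt(summary.prevalence_pct)),
        "prevalence_pct_rounded": summary.prevalence_pct_rounded,
        "mean_hits": float(_fmt(summary.mean_hits)),
        "sd_hits": float(_fmt(summary.sd_hits)) if math.isfinite(summary.sd_hits) else None,
        "min_hits": summary.min_hits,
        "max_hits": summary.max_hits,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def write_taxa_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def plot_cohort_hits(samples: Sequence[SampleSummary], path: str | Path,
                     title: str = "hits per sample") -> None:
    """Bar plot of per-sample hit counts with the cohort mean as a line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    counts = [s.n_hits for s in samples]
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(counts)), 3))
    ax.bar(range(len(counts)), counts, color="steelblue")
    ax.axhline(np.mean(counts), color="orange", lw=2, label=f"mean = {np.mean(counts):.3g}")
    ax.set_xlabel("sample")
    ax.set_ylabel("retained hits")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
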