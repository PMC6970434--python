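"""End-to-end orchestration: trim → screen → assign taxonomy → summarise.

Every stage writes a plain-text table that the next stage documents as its
input, so stages are independently runnable and testable.  A run manifest
(config echo, package version, input checksums) makes reruns auditable;
rerunning with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .align import ScreenConfig, screen_sample
from .lca import LcaConfig, ReadHit, TieMember, assign_hits
from .qc import QCParams, read_fastx, trim_reads, write_qc_log
from .refdb import deduplicate, lineage_format, lineage_parse, load_references
from .summarize import (
    cohort_stats,
    rank_taxa,
    summarize_sample,
    write_cohort_json,
    write_sample_summaries,
    write_taxa_table,
)


@dataclass(frozen=True)
class RunConfig:
    db_fasta: Path
    lineage_table: Path
    reads: tuple[Path, ...]
    outdir: Path
    screen: ScreenConfig = ScreenConfig()
    lca: LcaConfig = LcaConfig()
    qc: QCParams = QCParams()
    dedup_db: bool = False  # screening keeps all deposits by default
    per_gene_votes: bool = False


def write_hits_table(hits: Sequence[ReadHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tread_id\tbest_identity\tn_tied_refs\ttied_ref_ids"
                 "\ttied_strands\tassigned_lineage\tassigned_depth\n")
        for h in hits:
            fh.write(
                f"{h.sample_id}\t{h.read_id}\t{h.best_identity:.6g}\t{len(h.tie_set)}"
                f"\t{','.join(m.gene_id for m in h.tie_set)}"
                f"\t{','.join(m.strand for m in h.tie_set)}"
                f"\t{lineage_format(h.assigned_lineage, width=h.assigned_depth)}"
                f"\t{h.assigned_depth}\n"
            )


def read_hits_table(path: str | Path, lineage_by_gene: dict[str, str] | None = None) -> list[ReadHit]:
    """Load a hit table; tie-set lineages are resolved via ``lineage_by_gene``."""
    hits: list[ReadHit] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            gene_ids = f[idx["tied_ref_ids"]].split(",") if f[idx["tied_ref_ids"]] else []
            strands = f[idx["tied_strands"]].split(",") if f[idx["tied_strands"]] else []
            tie = []
            for gid, strand in zip(gene_ids, strands):
                if lineage_by_gene is not None:
                    if gid not in lineage_by_gene:
                        raise ValueError(f"no lineage for tied reference {gid!r}")
                    lin = lineage_parse(lineage_by_gene[gid])
                else:
                    lin = lineage_parse("")
                tie.append(TieMember(gene_id=gid, lineage=lin, strand=strand))
            assigned = lineage_parse(f[idx["assigned_lineage"]])
            hits.append(ReadHit(
                read_id=f[idx["read_id"]], sample_id=f[idx["sample_id"]],
                best_identity=float(f[idx["best_identity"]]),
                matches=0, columns=0, tie_set=tuple(tie),
                assigned_lineage=assigned, assigned_depth=int(f[idx["assigned_depth"]]),
            ))
    return hits


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the whole screen on a set of per-sample read files.

    Returns the cohort summary as a dict; all outputs are written under
    ``cfg.outdir``.  Missing inputs raise FileNotFoundError naming the path;
    a cohort where no read survives QC yields a warning and empty-but-valid
    outputs.
    """
    for p in (cfg.db_fasta, cfg.lineage_table, *cfg.reads):
        if not Path(p).exists():
            raise FileNotFoundError(str(p))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    db = load_references(cfg.db_fasta, cfg.lineage_table)
    if cfg.dedup_db:
        db, _ = deduplicate(db)

    all_hits: list[ReadHit] = []
    summaries = []
    qc_entries: dict[str, dict] = {}
    total_kept = 0
    for reads_path in sorted(Path(p) for p in cfg.reads):
        reads = list(read_fastx(reads_path))
        sample_id = reads[0].sample_id if reads else reads_path.stem
        kept, log = trim_reads(reads, cfg.qc)
        qc_entries[sample_id] = log
        total_kept += len(kept)
        hits = screen_sample(kept, db, cfg.screen)
        hits = assign_hits(hits, cfg.lca, per_gene=cfg.per_gene_votes)
        all_hits.extend(hits)
        summaries.append(summarize_sample(hits, sample_id=sample_id,
                                          n_reads_screened=len(kept)))
    if total_kept == 0:
        warnings.warn("no reads survived QC; writing empty outputs", stacklevel=2)

    write_hits_table(all_hits, outdir / "hits.tsv")
    write_sample_summaries(summaries, outdir / "per_sample.tsv")
    cohort = cohort_stats(summaries)
    write_cohort_json(cohort, outdir / "cohort.json")
    write_taxa_table(rank_taxa(all_hits), outdir / "taxa.tsv")
    write_qc_log(qc_entries, outdir / "qc_log.tsv")

    manifest = {
        "tool": "galscan",
        "version": __version__,
        "config": {
            "identity_cutoff": cfg.screen.identity_cutoff,
            "min_read_len": cfg.screen.min_read_len,
            "both_strands": cfg.screen.both_strands,
            "lca_confidence": cfg.lca.confidence,
            "qc": {"window": cfg.qc.window, "min_mean_q": cfg.qc.min_mean_q,
                   "min_len": cfg.qc.min_len},
            "dedup_db": cfg.dedup_db,
            "per_gene_votes": cfg.per_gene_votes,
        },
        "inputs": {
            str(p): _sha256(Path(p))
            for p in [cfg.db_fasta, cfg.lineage_table, *cfg.reads]
        },
        "n_reference_genes": len(db),
        "n_samples": len(summaries),
        "n_hits": len(all_hits),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
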