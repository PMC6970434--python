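"""Reference database of bacterial α1,3-galactosyltransferase (α1,3GT) marker genes.

The screening pipeline works against a curated nucleotide gene set in which every
sequence carries a ranked taxonomy.  Bacterial α1,3GT genes go by many short names
(waaO, waaI, rfaI, rfaJ, gspA, ...), so curation is manual and the database here is
simply a FASTA file plus a tab-separated lineage table in the Greengenes-style
``k__...;p__...;...;t__...`` dialect.

This module loads and validates such a database, detects exact nucleotide
duplicates (a curated list assembled from several portals typically contains many —
e.g. the same operon gene deposited once per sequenced strain), and serialises the
unique set, a duplicate report and a small manifest.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

RANK_PREFIXES = ("k", "p", "c", "o", "f", "g", "s", "t")
RANK_NAMES = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
    "strain",
)
N_RANKS = 8

# Uppercase IUPAC nucleotide codes accepted after normalisation (U is mapped to T).
IUPAC_NT = frozenset("ACGTRYSWKMBDHVN")

SOURCES = ("KEGG", "UniProt", "ExPASy", "custom")


@dataclass(frozen=True)
class TaxonomyLineage:
    """Ranked taxonomy from kingdom to strain; empty labels mark unresolved ranks.

    ``width`` records how many ranks the serialised form carries (truncated
    strings are legal and round-trip); it is presentation metadata and does not
    take part in equality or hashing.
    """

    ranks: tuple[str, ...]
    width: int = field(default=N_RANKS, compare=False)

    def __post_init__(self) -> None:
        if len(self.ranks) != N_RANKS:
            raise ValueError(f"lineage must have exactly {N_RANKS} ranks, got {len(self.ranks)}")
        if not 0 <= self.width <= N_RANKS:
            raise ValueError(f"width out of range: {self.width}")

    @property
    def depth(self) -> int:
        """Index just past the deepest non-empty rank (0 for an all-empty lineage)."""
        d = 0
        for i, label in enumerate(self.ranks):
            if label:
                d = i + 1
        return d

    def prefix(self, depth: int) -> tuple[str, ...]:
        return self.ranks[:depth]

    @property
    def genus(self) -> str:
        return self.ranks[5]

    @property
    def species_key(self) -> tuple[str, ...]:
        """Prefix up to the species rank; strain-only differences collapse."""
        return self.ranks[:7]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return lineage_format(self)


EMPTY_LINEAGE = TaxonomyLineage(ranks=("",) * N_RANKS, width=0)


def lineage_parse(s: str) -> TaxonomyLineage:
    """Parse a Greengenes-style lineage string.

    Truncated strings (fewer than 8 ranks) are allowed; missing trailing ranks
    become empty slots.  Rank prefixes must appear in canonical order
    (k, p, c, o, f, g, s, t); anything else is a hard error.
    """
    s = s.strip()
    if not s:
        return EMPTY_LINEAGE
    parts = [p.strip() for p in s.split(";")]
    if len(parts) > N_RANKS:
        raise ValueError(f"lineage has more than {N_RANKS} ranks: {s!r}")
    labels = []
    for i, part in enumerate(parts):
        expect = RANK_PREFIXES[i] + "__"
        if not part.startswith(expect):
            raise ValueError(
                f"rank {i} of lineage {s!r}: expected prefix {expect!r}, got {part!r}"
            )
        labels.append(part[len(expect):].strip())
    labels.extend([""] * (N_RANKS - len(parts)))
    return TaxonomyLineage(ranks=tuple(labels), width=len(parts))


def lineage_format(lineage: TaxonomyLineage, width: int | None = None) -> str:
    """Serialise a lineage back to the Greengenes-style string.

    By default the lineage's own recorded width is used, so parse∘format is the
    identity on canonical strings (including those that print trailing empty
    ranks such as ``;t__``).
    """
    w = lineage.width if width is None else width
    return ";".join(f"{RANK_PREFIXES[i]}__{lineage.ranks[i]}" for i in range(w))


def lineage_from_prefix(prefix: Sequence[str]) -> TaxonomyLineage:
    """Build a full-width lineage whose leading ranks are ``prefix``."""
    labels = tuple(prefix) + ("",) * (N_RANKS - len(prefix))
    return TaxonomyLineage(ranks=labels, width=N_RANKS)


@dataclass(frozen=True)
class ReferenceGene:
    """One curated α1,3GT nucleotide sequence with its taxonomy."""

    gene_id: str
    sequence: str
    lineage: TaxonomyLineage
    gene_symbol: str = ""
    source: str = "custom"


@dataclass(frozen=True)
class DuplicateGroup:
    kept_id: str
    removed_ids: tuple[str, ...]
    shared_genus: bool


@dataclass(frozen=True)
class DuplicateReport:
    n_input: int
    n_duplicates: int
    n_unique: int
    groups: tuple[DuplicateGroup, ...]


def normalize_sequence(seq: str, gene_id: str = "?") -> str:
    """Uppercase, map U→T, and validate against the IUPAC nucleotide alphabet."""
    s = seq.upper().replace("U", "T")
    for pos, ch in enumerate(s):
        if ch not in IUPAC_NT:
            raise ValueError(
                f"sequence {gene_id}: non-IUPAC character {ch!r} at position {pos}"
            )
    return s


def _read_lineage_table(path: str | Path) -> dict[str, tuple[TaxonomyLineage, str, str]]:
    """Read the two-column (plus optional gene_symbol, source) lineage TSV."""
    table: dict[str, tuple[TaxonomyLineage, str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 tab-separated columns")
            gid, lin = fields[0], fields[1]
            # tolerate a header row
            if lineno == 1 and "__" not in lin and lin.lower() in {"lineage", "taxonomy"}:
                continue
            symbol = fields[2] if len(fields) > 2 else ""
            source = fields[3] if len(fields) > 3 else "custom"
            table[gid] = (lineage_parse(lin), symbol, source)
    return table


def load_references(fasta_path: str | Path, lineage_table_path: str | Path) -> list[ReferenceGene]:
    """Load reference genes from FASTA plus a lineage table.

    Every FASTA id must appear in the table; sequences are uppercased with U→T
    and validated against IUPAC letters.  Errors name the offending id or the
    position of the first bad character.
    """
    table = _read_lineage_table(lineage_table_path)
    genes: list[ReferenceGene] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        gid = rec.id
        if gid in seen:
            raise ValueError(f"duplicate gene_id in FASTA: {gid}")
        seen.add(gid)
        if gid not in table:
            raise ValueError(f"no lineage entry for FASTA id {gid!r} in {lineage_table_path}")
        lineage, symbol, source = table[gid]
        seq = normalize_sequence(str(rec.seq), gene_id=gid)
        if not seq:
            raise ValueError(f"sequence {gid} is empty")
        genes.append(ReferenceGene(gene_id=gid, sequence=seq, lineage=lineage,
                                   gene_symbol=symbol, source=source))
    return genes


def deduplicate(genes: Sequence[ReferenceGene]) -> tuple[list[ReferenceGene], DuplicateReport]:
    """Remove exact nucleotide duplicates, keeping the first occurrence.

    Duplicate means byte-identical normalised sequence; no reverse-complement or
    near-identity collapsing.  Each group is flagged when all of its members
    share the same (non-empty) genus, which distinguishes the common case of
    one gene deposited per strain from rarer cross-genus identical deposits.
    """
    first_by_seq: dict[str, ReferenceGene] = {}
    removed_by_seq: dict[str, list[ReferenceGene]] = {}
    unique: list[ReferenceGene] = []
    for g in genes:
        if g.sequence in first_by_seq:
            removed_by_seq[g.sequence].append(g)
        else:
            first_by_seq[g.sequence] = g
            removed_by_seq[g.sequence] = []
            unique.append(g)
    groups = []
    n_dup = 0
    for kept in unique:
        removed = removed_by_seq[kept.sequence]
        if not removed:
            continue
        n_dup += len(removed)
        genera = {m.lineage.genus for m in [kept, *removed]}
        shared = len(genera) == 1 and "" not in genera
        groups.append(DuplicateGroup(
            kept_id=kept.gene_id,
            removed_ids=tuple(m.gene_id for m in removed),
            shared_genus=shared,
        ))
    report = DuplicateReport(
        n_input=len(genes), n_duplicates=n_dup, n_unique=len(unique), groups=tuple(groups)
    )
    return unique, report


def write_fasta(genes: Iterable[ReferenceGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.sequence), 80):
                fh.write(g.sequence[i:i + 80] + "\n")


def write_lineage_table(genes: Iterable[ReferenceGene], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{lineage_format(g.lineage)}\t{g.gene_symbol}\t{g.source}\n")


def write_duplicate_report(report: DuplicateReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("kept_id\tremoved_ids\tn_removed\tshared_genus\n")
        for grp in report.groups:
            fh.write(
                f"{grp.kept_id}\t{','.join(grp.removed_ids)}\t{len(grp.removed_ids)}"
                f"\t{str(grp.shared_genus).lower()}\n"
            )


def db_manifest(genes: Sequence[ReferenceGene], report: DuplicateReport | None = None) -> dict:
    """Summary of a reference database: counts, per-genus tallies, checksum."""
    h = hashlib.sha256()
    for g in genes:
        h.update(g.gene_id.encode())
        h.update(b"\x00")
        h.update(g.sequence.encode())
        h.update(b"\n")
    genera = Counter(g.lineage.genus or "(unranked)" for g in genes)
    manifest = {
        "n_genes": len(genes),
        "total_nt": sum(len(g.sequence) for g in genes),
        "sha256": h.hexdigest(),
        "genera": dict(sorted(genera.items())),
    }
    if report is not None:
        manifest["dedup"] = {
            "n_input": report.n_input,
            "n_duplicates": report.n_duplicates,
            "n_unique": report.n_unique,
        }
    return manifest


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
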