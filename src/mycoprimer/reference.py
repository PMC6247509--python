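"""Taxonomically annotated reference sequences (SILVA-style) with
fungal/outgroup classification, taxonomy overrides, and dereplication.

A SILVA-dialect FASTA header is ``<accession> <semicolon-separated path>``,
e.g. ``X1 Eukaryota;Opisthokonta;Fungi;Ascomycota;Pezizomycotina;``.  A record
is fungal iff the (configurable) label "Fungi" occurs at any rank; the phylum
is the next rank below it and the subphylum the one after.  Non-fungal
eukaryotes get an outgroup label (the first rank below the supergroup
containers, e.g. Stramenopiles under Eukaryota;SAR;).  Prokaryotes are dropped
at load with a logged count: every coverage denominator in this toolkit is
eukaryote-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .iupac import normalize

logger = logging.getLogger(__name__)

FUNGAL_LABEL = "Fungi"
PROKARYOTE_DOMAINS = frozenset({"Bacteria", "Archaea"})
# supergroup containers skipped when deriving the outgroup label
CONTAINER_LABELS = frozenset({"Eukaryota", "SAR", "TSAR", "Opisthokonta"})


class ReferenceDBError(ValueError):
    pass


class MalformedHeaderError(ReferenceDBError):
    def __init__(self, record_index: int, header: str, reason: str):
        self.record_index = record_index
        super().__init__(
            f"record {record_index}: malformed header {header!r}: {reason}"
        )


@dataclass
class ReferenceRecord:
    id: str
    sequence: str
    taxonomy: list[str]
    is_fungal: bool = False
    phylum: str | None = None
    subphylum: str | None = None
    outgroup: str | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize(self.sequence)
        if not self.sequence:
            raise ReferenceDBError(f"record {self.id!r}: empty sequence")

    @property
    def species(self) -> str:
        """Lowest taxonomy rank; used as the species label for barcode
        metrics."""
        return self.taxonomy[-1]

    @property
    def group_labels(self) -> tuple[str, ...]:
        """Taxon-group labels this record counts toward (phylum and
        subphylum for fungi, outgroup otherwise)."""
        if self.is_fungal:
            labels = [x for x in (self.phylum, self.subphylum) if x]
            return tuple(labels) if labels else (FUNGAL_LABEL,)
        return (self.outgroup,) if self.outgroup else ()


def classify(
    taxonomy: Sequence[str], fungal_label: str = FUNGAL_LABEL
) -> tuple[bool, str | None, str | None, str | None]:
    """(is_fungal, phylum, subphylum, outgroup) from a taxonomy path."""
    path = list(taxonomy)
    if fungal_label in path:
        i = path.index(fungal_label)
        below = path[i + 1:]
        phylum = below[0] if below else None
        subphylum = below[1] if len(below) > 1 else None
        return True, phylum, subphylum, None
    outgroup = next((x for x in path if x not in CONTAINER_LABELS), None)
    return False, None, None, outgroup


def make_record(
    rec_id: str, sequence: str, taxonomy: Sequence[str],
    fungal_label: str = FUNGAL_LABEL,
) -> ReferenceRecord:
    is_fungal, phylum, subphylum, outgroup = classify(taxonomy, fungal_label)
    return ReferenceRecord(
        id=rec_id, sequence=sequence, taxonomy=list(taxonomy),
        is_fungal=is_fungal, phylum=phylum, subphylum=subphylum,
        outgroup=outgroup,
    )


@dataclass
class ReferenceDB:
    records: list[ReferenceRecord] = field(default_factory=list)

    @property
    def fungal_records(self) -> list[ReferenceRecord]:
        return [r for r in self.records if r.is_fungal]

    @property
    def nonfungal_records(self) -> list[ReferenceRecord]:
        return [r for r in self.records if not r.is_fungal]

    @property
    def fungal_count(self) -> int:
        return len(self.fungal_records)

    @property
    def nonfungal_eukaryote_count(self) -> int:
        return len(self.nonfungal_records)

    @property
    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            for g in r.group_labels:
                counts[g] = counts.get(g, 0) + 1
        return counts

    def fungal_group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.fungal_records:
            for g in r.group_labels:
                counts[g] = counts.get(g, 0) + 1
        return counts

    def outgroup_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.nonfungal_records:
            if r.outgroup:
                counts[r.outgroup] = counts.get(r.outgroup, 0) + 1
        return counts

    def subset(self, predicate) -> "ReferenceDB":
        return ReferenceDB([r for r in self.records if predicate(r)])

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _parse_silva_header(description: str) -> tuple[str, list[str]]:
    parts = description.split(None, 1)
    if len(parts) < 2:
        raise ValueError("no taxonomy after accession")
    acc, path = parts
    taxonomy = [x.strip() for x in path.split(";") if x.strip()]
    if not taxonomy:
        raise ValueError("empty taxonomy path")
    return acc, taxonomy


def load_reference_fasta(
    path: str | Path,
    taxonomy_dialect: str = "silva",
    taxonomy_tsv: str | Path | None = None,
    fungal_label: str = FUNGAL_LABEL,
    drop_prokaryotes: bool = True,
) -> ReferenceDB:
    """Load a reference FASTA.

    ``silva`` dialect reads the taxonomy path from the header; ``plain``
    reads it from a two-column sidecar TSV (id <TAB> semicolon path).
    Prokaryotic records are dropped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise ReferenceDBError(f"no such file: {path}")
    taxmap: dict[str, list[str]] = {}
    if taxonomy_dialect == "plain":
        if taxonomy_tsv is None:
            raise ReferenceDBError("plain dialect requires taxonomy_tsv")
        for line in Path(taxonomy_tsv).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            rec_id, _, tax = line.partition("\t")
            taxmap[rec_id.strip()] = [
                x.strip() for x in tax.split(";") if x.strip()
            ]
    elif taxonomy_dialect != "silva":
        raise ReferenceDBError(f"unknown taxonomy dialect {taxonomy_dialect!r}")

    records: list[ReferenceRecord] = []
    dropped = 0
    n_seen = 0
    for i, seqrec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        n_seen += 1
        if taxonomy_dialect == "silva":
            try:
                acc, taxonomy = _parse_silva_header(seqrec.description)
            except ValueError as exc:
                raise MalformedHeaderError(i, seqrec.description, str(exc))
        else:
            acc = seqrec.id
            if acc not in taxmap:
                raise MalformedHeaderError(i, acc, "no taxonomy in sidecar TSV")
            taxonomy = taxmap[acc]
        if drop_prokaryotes and taxonomy and taxonomy[0] in PROKARYOTE_DOMAINS:
            dropped += 1
            continue
        records.append(make_record(acc, str(seqrec.seq), taxonomy, fungal_label))
    if n_seen == 0:
        raise ReferenceDBError(f"empty FASTA: {path}")
    if dropped:
        logger.info("dropped %d prokaryotic records from %s", dropped, path)
    return ReferenceDB(records)


def write_reference_fasta(db: ReferenceDB, path: str | Path) -> None:
    """Write SILVA-dialect FASTA (round-trips with load_reference_fasta)."""
    seqrecs = [
        SeqRecord(
            Seq(r.sequence), id=r.id,
            description=";".join(r.taxonomy) + ";",
        )
        for r in db.records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


@dataclass(frozen=True)
class TaxonomyOverride:
    """Relabel records whose taxonomy starts with a prefix (e.g. moving
    zygomycete fungi onto the revised taxonomy)."""

    match_path_prefix: tuple[str, ...]
    replacement_path: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.match_path_prefix or not self.replacement_path:
            raise ReferenceDBError("override prefix/replacement must be non-empty")

    def matches(self, taxonomy: Sequence[str]) -> bool:
        n = len(self.match_path_prefix)
        return tuple(taxonomy[:n]) == self.match_path_prefix


def load_overrides_tsv(path: str | Path) -> list[TaxonomyOverride]:
    """Two-column TSV: semicolon prefix <TAB> semicolon replacement."""
    overrides = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        prefix, _, repl = line.partition("\t")
        overrides.append(
            TaxonomyOverride(
                tuple(x.strip() for x in prefix.split(";") if x.strip()),
                tuple(x.strip() for x in repl.split(";") if x.strip()),
            )
        )
    return overrides


def apply_overrides(
    db: ReferenceDB,
    overrides: Iterable[TaxonomyOverride],
    fungal_label: str = FUNGAL_LABEL,
) -> ReferenceDB:
    """Relabel matching records; record count is always preserved.

    Two overrides matching the same record is a conflict and raises.
    """
    overrides = list(overrides)
    out: list[ReferenceRecord] = []
    n_applied = 0
    for rec in db.records:
        matching = [o for o in overrides if o.matches(rec.taxonomy)]
        if len(matching) > 1:
            raise ReferenceDBError(
                f"conflicting overrides for record {rec.id!r}: "
                + "; ".join(str(o.match_path_prefix) for o in matching)
            )
        if matching:
            o = matching[0]
            new_tax = list(o.replacement_path) + list(
                rec.taxonomy[len(o.match_path_prefix):]
            )
            out.append(make_record(rec.id, rec.sequence, new_tax, fungal_label))
            n_applied += 1
        else:
            out.append(rec)
    if n_applied:
        logger.info("applied taxonomy overrides to %d records", n_applied)
    return ReferenceDB(out)


def dereplicate(records: Iterable[ReferenceRecord]) -> list[ReferenceRecord]:
    """Collapse exact full-length duplicates within each taxon group,
    keeping the first occurrence (deterministic)."""
    seen: set[tuple[tuple[str, ...], str]] = set()
    out: list[ReferenceRecord] = []
    for rec in records:
        key = (rec.group_labels, rec.sequence)
        if key in seen:
            continue
        seen.add(key)
        out.append(rec)
    return out
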