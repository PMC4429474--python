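"""Reading, validating, deduplicating and indexing proteome FASTA files.

A :class:`ProteomeSet` is the census input unit: protein records with unique
identifiers, a species label each (supplied via a sidecar TSV or defaulted to
the source-file stem), and optional taxon-order metadata.
"""

from __future__ import annotations

import fnmatch
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

# 20 standard residues plus ambiguity codes B, Z, X and the rare U, O.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "BZXUO")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (bad header, illegal residue)."""


class DuplicateIdError(ValueError):
    """Raised when two records share a protein_id."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with identifiers and species metadata."""

    protein_id: str
    species: str
    sequence: str
    description: str = ""
    locus_tag: str | None = None
    taxon_order: str | None = None

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.protein_id}: empty sequence")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            raise FastaParseError(
                f"record {self.protein_id!r}: illegal residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteomeSet:
    """A collection of protein records indexed by id and by species."""

    records: list[ProteinRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.protein_id for r in self.records]
        if len(ids) != len(set(ids)):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise DuplicateIdError(f"duplicate protein ids: {sorted(dups)}")
        self._by_id = {r.protein_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_id

    def get(self, protein_id: str) -> ProteinRecord:
        return self._by_id[protein_id]

    @property
    def species_index(self) -> dict[str, list[str]]:
        idx: dict[str, list[str]] = {}
        for r in self.records:
            idx.setdefault(r.species, []).append(r.protein_id)
        return idx

    @property
    def species(self) -> list[str]:
        return sorted(self.species_index)

    def subset(self, ids) -> "ProteomeSet":
        wanted = set(ids)
        return ProteomeSet(
            records=[r for r in self.records if r.protein_id in wanted],
            provenance=list(self.provenance),
        )


def _read_species_table(path) -> list[tuple[str, str, str | None]]:
    """Sidecar TSV: record_id_or_glob <TAB> species [<TAB> taxon_order]."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FastaParseError(
                    f"{path}:{lineno}: species table needs >= 2 tab-separated columns"
                )
            rows.append((parts[0], parts[1], parts[2] if len(parts) > 2 else None))
    return rows


def _lookup_species(pid: str, table) -> tuple[str | None, str | None]:
    # exact id match wins over glob patterns; first matching row otherwise
    for key, sp, order in table:
        if key == pid:
            return sp, order
    for key, sp, order in table:
        if fnmatch.fnmatchcase(pid, key):
            return sp, order
    return None, None


def read_fasta(path, species_table=None) -> ProteomeSet:
    """Read one proteome FASTA file into a :class:`ProteomeSet`.

    Sequences are uppercased and trailing stop symbols ``*`` stripped.
    Records without a species mapping get the source-file stem as species.

    Parameters
    ----------
    path:
        FASTA file (wrapped or unwrapped).
    species_table:
        Optional sidecar TSV mapping record ids (or glob patterns) to
        species and, optionally, taxon order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = _read_species_table(species_table) if species_table else []
    default_species = path.stem

    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise FastaParseError(f"{path}: record with empty header")
        seq = str(entry.seq).upper().rstrip("*")
        if "*" in seq or "-" in seq or any(c.isspace() for c in seq):
            raise FastaParseError(
                f"record {entry.id!r}: internal stop/gap/whitespace character"
            )
        species, order = _lookup_species(entry.id, table)
        records.append(
            ProteinRecord(
                protein_id=entry.id,
                species=species or default_species,
                taxon_order=order,
                description=entry.description,
                sequence=seq,
            )
        )
    return ProteomeSet(records=records, provenance=[str(path)])


def read_fasta_many(paths, species_table=None) -> ProteomeSet:
    """Read and concatenate several per-species proteome files."""
    records: list[ProteinRecord] = []
    provenance: list[str] = []
    for p in paths:
        ps = read_fasta(p, species_table=species_table)
        records.extend(ps.records)
        provenance.extend(ps.provenance)
    return ProteomeSet(records=records, provenance=provenance)


def write_fasta(ps: ProteomeSet, path) -> None:
    entries = [
        SeqRecord(Seq(r.sequence), id=r.protein_id, description=r.description or "")
        for r in ps.records
    ]
    SeqIO.write(entries, str(path), "fasta")


def write_species_table(ps: ProteomeSet, path) -> None:
    with open(path, "w") as fh:
        for r in ps.records:
            cols = [r.protein_id, r.species]
            if r.taxon_order:
                cols.append(r.taxon_order)
            fh.write("\t".join(cols) + "\n")


def deduplicate_records(ps: ProteomeSet):
    """Collapse byte-identical sequences *within the same species*.

    Cross-species identical sequences are biological signal and are kept.
    The lexicographically smallest protein_id of each group survives.

    Returns
    -------
    (ProteomeSet, dict)
        The deduplicated set and a report mapping each duplicated
        (species, sequence) group to the sorted list of member ids.
    """
    groups: dict[tuple[str, str], list[ProteinRecord]] = {}
    for r in ps.records:
        groups.setdefault((r.species, r.sequence), []).append(r)

    survivors: list[ProteinRecord] = []
    report: dict[str, list[str]] = {}
    surviving_ids = set()
    for (species, seq), members in groups.items():
        keeper = min(members, key=lambda r: r.protein_id)
        surviving_ids.add(keeper.protein_id)
        if len(members) > 1:
            h = hashlib.sha1(f"{species}|{seq}".encode()).hexdigest()[:12]
            report[h] = sorted(r.protein_id for r in members)
    # preserve original record order among survivors
    survivors = [r for r in ps.records if r.protein_id in surviving_ids]
    return ProteomeSet(records=survivors, provenance=list(ps.provenance)), report


def write_dedup_report(report: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_hash\tn_members\tmember_ids\n")
        for h in sorted(report):
            fh.write(f"{h}\t{len(report[h])}\t{','.join(report[h])}\n")
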