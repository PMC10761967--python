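"""Sequence and table IO: FASTA ortholog groups, gene lists, exon maps, site calls.

The screen operates on one representative protein per species per gene.
Representatives are chosen as the longest annotated isoform, mirroring the
common practice of comparing "longest isoform" orthologs across species.
All residue coordinates in this package are 1-based and inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import molecular_weight

from .errors import FastaParseError, MissingOrthologError

#: Canonical amino acids plus the ambiguity letter X.
ALLOWED_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

SITE_CLASSES = ("positive", "negative")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its accession, gene symbol and species tag."""

    accession: str
    gene_symbol: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.accession!r}: empty sequence")
        bad = set(self.sequence) - ALLOWED_RESIDUES
        if bad:
            raise ValueError(
                f"record {self.accession!r}: illegal residue characters "
                f"{sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneList:
    """An ordered, duplicate-free list of uppercase gene symbols."""

    symbols: tuple[str, ...]
    source_name: str = ""

    @staticmethod
    def from_symbols(symbols: Iterable[str], source_name: str = "") -> "GeneList":
        seen: dict[str, None] = {}
        for s in symbols:
            seen.setdefault(s.strip().upper(), None)
        return GeneList(tuple(seen), source_name)

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class OrthologGroup:
    """One gene's representative protein per species (at most one member each)."""

    gene_symbol: str
    members: Mapping[str, ProteinRecord]

    def species(self) -> tuple[str, ...]:
        return tuple(self.members)

    def has_panel(self, panel: Sequence[str]) -> bool:
        return all(sp in self.members for sp in panel)


class SiteCall(NamedTuple):
    """A selected-site call produced by an external selection analysis."""

    position: int  # 1-based residue index
    category: str  # "positive" or "negative"
    method: str  # e.g. MEME, FEL, FUBAR


@dataclass(frozen=True)
class SiteCallSet:
    calls: tuple[SiteCall, ...]
    protein_length: int

    def __post_init__(self) -> None:
        seen = set()
        for call in self.calls:
            if not 1 <= call.position <= self.protein_length:
                raise ValueError(
                    f"site call at position {call.position} outside "
                    f"[1, {self.protein_length}]"
                )
            if call.category not in SITE_CLASSES:
                raise ValueError(
                    f"site call class {call.category!r} not in {SITE_CLASSES}"
                )
            if call in seen:
                raise ValueError(f"duplicate site call {call}")
            seen.add(call)

    def methods(self) -> tuple[str, ...]:
        out: dict[str, None] = {}
        for call in self.calls:
            out.setdefault(call.method, None)
        return tuple(out)


@dataclass(frozen=True)
class ExonPartitionTable:
    """Ordered exon partitions as 1-based inclusive residue intervals.

    Intervals may not overlap across partitions; a residue belongs to at most
    one partition. Residues covered by no partition are legal and reported as
    unassigned downstream.
    """

    partitions: tuple[tuple[str, tuple[tuple[int, int], ...]], ...]
    protein_length: int
    _lookup: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        covered: dict[int, str] = {}
        for label, intervals in self.partitions:
            for start, end in intervals:
                if not (1 <= start <= end <= self.protein_length):
                    raise ValueError(
                        f"partition {label!r}: interval [{start}, {end}] outside "
                        f"[1, {self.protein_length}]"
                    )
                for pos in range(start, end + 1):
                    if pos in covered:
                        raise ValueError(
                            f"position {pos} in overlapping partitions "
                            f"{covered[pos]!r} and {label!r}"
                        )
                    covered[pos] = label
        self._lookup.update(covered)

    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.partitions)

    def length_aa(self, label: str) -> int:
        for lab, intervals in self.partitions:
            if lab == label:
                return sum(end - start + 1 for start, end in intervals)
        raise KeyError(label)

    def partition_of(self, position: int) -> str | None:
        """Label covering ``position``, or None when unassigned."""
        return self._lookup.get(position)


# ---------------------------------------------------------------------------
# FASTA


def _split_header(header: str, lineno_hint: str) -> tuple[str, str, str]:
    parts = header.split("|")
    if len(parts) != 3 or not all(parts):
        raise FastaParseError(
            f"malformed header {header!r} ({lineno_hint}): expected "
            "'accession|gene_symbol|species'"
        )
    return parts[0], parts[1], parts[2]


def read_fasta(
    path,
    dialect: str = "pipe",
    metadata: Mapping[str, tuple[str, str]] | None = None,
) -> list[ProteinRecord]:
    """Read protein records from FASTA.

    dialect "pipe" expects headers ``accession|gene_symbol|species``;
    dialect "plain" expects bare accessions and a ``metadata`` mapping
    accession -> (gene_symbol, species), e.g. from :func:`read_metadata`.
    Sequences are uppercased and a single terminal ``*`` is stripped.
    """
    if dialect not in ("pipe", "plain"):
        raise ValueError(f"unknown FASTA dialect {dialect!r}")
    if dialect == "plain" and metadata is None:
        raise ValueError("dialect 'plain' requires a metadata mapping")
    records: list[ProteinRecord] = []
    seen_accessions: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if dialect == "pipe":
            accession, gene, species = _split_header(rec.id, f"record {i} of {path}")
        else:
            accession = rec.id
            try:
                gene, species = metadata[accession]  # type: ignore[index]
            except KeyError:
                raise FastaParseError(
                    f"accession {accession!r} (record {i} of {path}) missing "
                    "from metadata table"
                ) from None
        if accession in seen_accessions:
            raise FastaParseError(f"duplicate accession {accession!r} in {path}")
        seen_accessions.add(accession)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        try:
            records.append(ProteinRecord(accession, gene, species, seq))
        except ValueError as exc:
            raise FastaParseError(str(exc)) from None
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    """Write records as pipe-dialect FASTA wrapped at ``width`` columns."""
    seq_records = [
        SeqRecord(
            Seq(r.sequence),
            id=f"{r.accession}|{r.gene_symbol}|{r.species}",
            description="",
        )
        for r in records
    ]
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# TSV readers


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring undeclared column(s) {extra}", stacklevel=3)
    return df[list(required)]


def read_metadata(path) -> dict[str, tuple[str, str]]:
    """Sidecar metadata TSV (accession, gene_symbol, species) for plain FASTA."""
    df = _read_tsv(path, ["accession", "gene_symbol", "species"])
    return {
        row.accession: (row.gene_symbol, row.species) for row in df.itertuples()
    }


def read_gene_list(path, source_name: str | None = None) -> GeneList:
    """Gene-list TSV with a single ``symbol`` column."""
    df = _read_tsv(path, ["symbol"])
    return GeneList.from_symbols(
        df["symbol"], source_name or Path(str(path)).stem
    )


def read_exon_map(path, protein_length: int) -> ExonPartitionTable:
    """Exon-partition TSV with columns label, start, end (1-based inclusive)."""
    df = _read_tsv(path, ["label", "start", "end"])
    order: dict[str, list[tuple[int, int]]] = {}
    for idx, row in enumerate(df.itertuples(), start=2):
        try:
            start, end = int(row.start), int(row.end)
        except ValueError:
            raise ValueError(f"{path} row {idx}: non-integer interval bounds") from None
        order.setdefault(row.label, []).append((start, end))
    try:
        return ExonPartitionTable(
            tuple((label, tuple(iv)) for label, iv in order.items()), protein_length
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def read_site_calls(path, protein_length: int) -> SiteCallSet:
    """Selected-site TSV with columns position, class, method."""
    df = _read_tsv(path, ["position", "class", "method"])
    calls = []
    for idx, row in enumerate(df.itertuples(), start=2):
        try:
            pos = int(row.position)
        except ValueError:
            raise ValueError(f"{path} row {idx}: non-integer position") from None
        calls.append(SiteCall(pos, getattr(row, "_2"), row.method))
    try:
        return SiteCallSet(tuple(calls), protein_length)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# Gene-list and isoform operations


def intersect_gene_lists(a: GeneList, b: GeneList) -> GeneList:
    """Symbols present in both lists (case-normalised), in ``a``'s order."""
    in_b = set(b.symbols)
    name = f"{a.source_name}&{b.source_name}" if a.source_name or b.source_name else ""
    return GeneList(tuple(s for s in a.symbols if s in in_b), name)


def select_longest_isoform(
    records: Iterable[ProteinRecord], gene: str, species: str
) -> ProteinRecord:
    """The longest isoform for (gene, species); length ties break to the
    lexicographically smallest accession so the choice is deterministic."""
    gene_u = gene.upper()
    candidates = [
        r
        for r in records
        if r.gene_symbol.upper() == gene_u and r.species == species
    ]
    if not candidates:
        raise MissingOrthologError(gene, species)
    return min(candidates, key=lambda r: (-len(r.sequence), r.accession))


def build_ortholog_group(
    records: Iterable[ProteinRecord], gene: str, panel: Sequence[str]
) -> OrthologGroup:
    """Assemble an OrthologGroup with the longest isoform per panel species."""
    records = list(records)
    missing = []
    members: dict[str, ProteinRecord] = {}
    for species in panel:
        try:
            members[species] = select_longest_isoform(records, gene, species)
        except MissingOrthologError:
            missing.append(species)
    if missing:
        raise MissingOrthologError(gene, missing)
    return OrthologGroup(gene.upper(), members)


# ---------------------------------------------------------------------------
# Protein mass


def protein_mass(sequence: str) -> float:
    """Predicted average molecular mass of a protein sequence, in kDa.

    Sum of average residue masses plus one water; X is rejected because its
    mass is undefined.
    """
    bad = set(sequence) - (ALLOWED_RESIDUES - {"X"})
    if bad:
        raise ValueError(f"mass undefined for residue letter(s) {sorted(bad)!r}")
    return molecular_weight(sequence, seq_type="protein") / 1000.0
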