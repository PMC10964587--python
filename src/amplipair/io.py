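"""Plain-text readers/writers and the core record types the pipeline exchanges.

Formats handled here:

* FASTA (any line wrap on read; 80-column wrap on write),
* tab-separated count tables (features in rows, samples in columns),
* two-column taxonomy tables (``feature_id<TAB>lineage``), where a lineage is
  exactly seven semicolon-separated rank names
  (domain;phylum;class;order;family;genus;species) with trailing empties
  allowed — an empty rank means "unassigned from here on down",
* sample metadata tables (``sample_id  subject  niche  platform``).

Counts are strictly integers; relative abundances are always derived on the
fly and never stored, which prevents silently normalising a table twice.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "FormatError",
    "SequenceRecord",
    "CountTable",
    "Lineage",
    "SampleMetadata",
    "RANKS",
    "NICHES",
    "PLATFORMS",
    "read_fasta",
    "write_fasta",
    "read_count_table",
    "write_count_table",
    "read_taxonomy_table",
    "write_taxonomy_table",
    "read_metadata",
    "write_metadata",
    "setup_logging",
]

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
NICHES = ("saliva", "subgingival", "faeces")
PLATFORMS = ("illumina", "pacbio")

IUPAC_NT = frozenset("ACGTRYSWKMBDHVN")

logger = logging.getLogger("amplipair")


class FormatError(ValueError):
    """A file violated the expected on-disk format or an invariant."""


def setup_logging(verbose: bool = False) -> None:
    """Configure package logging to stderr."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


@dataclass(frozen=True)
class SequenceRecord:
    """One identified nucleotide sequence.

    ``id`` is a whitespace-free token, ``residues`` an uppercase IUPAC
    nucleotide string.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"invalid sequence id {self.id!r}")
        if not self.residues:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - IUPAC_NT
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Lineage:
    """A 7-rank taxonomic lineage with the prefix property.

    ``ranks`` always has length 7; the empty string marks an unassigned rank
    and once a rank is empty every deeper rank must be empty too.
    """

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != 7:
            raise FormatError(f"lineage must have 7 ranks, got {len(self.ranks)}")
        seen_empty = False
        for name in self.ranks:
            if seen_empty and name:
                raise FormatError(
                    f"non-empty rank below an empty rank in {self.ranks!r}"
                )
            if not name:
                seen_empty = True

    @classmethod
    def from_string(cls, text: str) -> "Lineage":
        fields = [f.strip() for f in text.split(";")]
        if len(fields) > 7:
            raise FormatError(f"more than 7 lineage fields in {text!r}")
        fields += [""] * (7 - len(fields))
        return cls(tuple(fields))

    @classmethod
    def empty(cls) -> "Lineage":
        return cls(("",) * 7)

    def to_string(self) -> str:
        return ";".join(self.ranks)

    def get(self, rank: str) -> str:
        return self.ranks[RANKS.index(rank)]

    def truncate(self, depth: int) -> "Lineage":
        """Keep the first ``depth`` ranks (0 keeps nothing)."""
        return Lineage(tuple(self.ranks[:depth]) + ("",) * (7 - depth))

    def with_species(self, species: str) -> "Lineage":
        if not self.ranks[5]:
            raise FormatError("cannot set species below an unassigned genus")
        return Lineage(self.ranks[:6] + (species,))

    @property
    def genus(self) -> str:
        return self.ranks[5]

    @property
    def species(self) -> str:
        return self.ranks[6]

    def depth(self) -> int:
        """Number of assigned leading ranks."""
        d = 0
        for name in self.ranks:
            if not name:
                break
            d += 1
        return d


@dataclass
class CountTable:
    """Non-negative integer feature × sample matrix backed by a DataFrame."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.shape[1] < 1:
            raise FormatError("count table needs at least one sample")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if df.isna().any().any():
            raise FormatError("count table contains missing cells")
        if not all(pd.api.types.is_integer_dtype(t) for t in df.dtypes):
            raise FormatError("counts must be integers")
        if (df.to_numpy() < 0).any():
            raise FormatError("counts must be non-negative")
        self.data = df.astype("int64")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def sample_counts(self, sample_id: str) -> pd.Series:
        return self.data[sample_id]

    def totals(self) -> pd.Series:
        """Per-sample column sums."""
        return self.data.sum(axis=0)

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions (columns sum to 1)."""
        tot = self.data.sum(axis=0)
        if (tot == 0).any():
            zero = list(tot.index[tot == 0])
            raise FormatError(f"zero-sum samples: {zero}")
        return self.data / tot

    def subset_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        return CountTable(self.data[list(sample_ids)].copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass(frozen=True)
class SampleMetadata:
    """One sample's design coordinates: who, where, and on which sequencer."""

    sample_id: str
    subject: str
    niche: str
    platform: str

    def __post_init__(self) -> None:
        for tok in (self.sample_id, self.subject):
            if not tok or any(c.isspace() for c in tok):
                raise FormatError(f"invalid token {tok!r}")
        if self.niche not in NICHES:
            raise FormatError(f"unknown niche {self.niche!r}")
        if self.platform not in PLATFORMS:
            raise FormatError(f"unknown platform {self.platform!r}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into records, preserving order.

    Raises :class:`FormatError` on an empty file or on sequence data that
    appears before the first header.
    """
    path = Path(path)
    with open(path) as handle:
        for line in handle:
            if line.strip():
                if not line.startswith(">"):
                    raise FormatError(
                        f"{path}: sequence line before any FASTA header"
                    )
                break
        else:
            raise FormatError(f"{path}: no records")
    records: list[SequenceRecord] = []
    with open(path) as handle:
        for title, seq in SimpleFastaParser(handle):
            parts = title.split(maxsplit=1)
            rec_id = parts[0] if parts else ""
            desc = parts[1] if len(parts) > 1 else ""
            records.append(
                SequenceRecord(id=rec_id, residues=seq.upper(), description=desc)
            )
    if not records:
        raise FormatError(f"{path}: no records")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, width: int = 80
) -> None:
    """Write records as FASTA, sequence wrapped at ``width`` columns."""
    records = list(records)
    if not records:
        raise FormatError("no records to write")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"duplicate record ids: {dups}")
    with open(path, "w") as handle:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            handle.write(header + "\n")
            for start in range(0, len(rec.residues), width):
                handle.write(rec.residues[start : start + width] + "\n")


# ---------------------------------------------------------------------------
# Count tables


def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV count table (first column feature id, header sample ids)."""
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].tolist()
        raise FormatError(f"{path}: duplicate feature ids {dups}")
    parsed = pd.DataFrame(index=raw.index.astype(str))
    for col in raw.columns:
        values = []
        for feat, cell in raw[col].items():
            if cell is None or (isinstance(cell, float) and pd.isna(cell)):
                raise FormatError(f"{path}: missing cell at row {feat!r}, column {col!r}")
            try:
                v = int(str(cell).strip())
            except ValueError:
                raise FormatError(
                    f"{path}: non-integer cell {cell!r} at row {feat!r}, column {col!r}"
                ) from None
            if v < 0:
                raise FormatError(
                    f"{path}: negative count {v} at row {feat!r}, column {col!r}"
                )
            values.append(v)
        parsed[str(col)] = values
    return CountTable(parsed)


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# Taxonomy tables


def read_taxonomy_table(path: str | Path) -> dict[str, Lineage]:
    """Read a two-column TSV mapping feature id to a 7-rank lineage."""
    path = Path(path)
    out: dict[str, Lineage] = {}
    with open(path) as handle:
        for n, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{n}: expected 2 tab-separated columns")
            feat, lineage_text = parts
            if feat in out:
                raise FormatError(f"{path}:{n}: duplicate feature id {feat!r}")
            try:
                out[feat] = Lineage.from_string(lineage_text)
            except FormatError as exc:
                raise FormatError(f"{path}:{n}: {exc}") from None
    if not out:
        raise FormatError(f"{path}: no taxonomy rows")
    return out


def write_taxonomy_table(lineages: Mapping[str, Lineage], path: str | Path) -> None:
    with open(path, "w") as handle:
        for feat, lin in lineages.items():
            handle.write(f"{feat}\t{lin.to_string()}\n")


# ---------------------------------------------------------------------------
# Sample metadata


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", "subject", "niche", "platform"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    rows = [
        SampleMetadata(
            sample_id=r.sample_id, subject=r.subject, niche=r.niche, platform=r.platform
        )
        for r in df.itertuples()
    ]
    keys = [(m.subject, m.niche, m.platform) for m in rows]
    if len(set(keys)) != len(keys):
        dups = sorted({k for k in keys if keys.count(k) > 1})
        raise FormatError(f"{path}: duplicate (subject, niche, platform): {dups}")
    return rows


def write_metadata(rows: Iterable[SampleMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        [(m.sample_id, m.subject, m.niche, m.platform) for m in rows],
        columns=["sample_id", "subject", "niche", "platform"],
    )
    df.to_csv(path, sep="\t", index=False)
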