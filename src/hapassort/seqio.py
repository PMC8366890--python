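"""Input/output for the pipeline's three external formats.

* aligned FASTA (relaxed: wrapped or single-line) -> :class:`Alignment`
* tab-separated sample metadata -> :class:`MetadataTable`
* Newick clock trees -> :class:`~hapassort.trees.UltrametricTree`

plus the join of alignment and metadata into a validated :class:`Dataset`.

Habitat labels are normalized case-insensitively with spaces and
underscores treated as equivalent; anything outside the three Keys
habitat classes maps to ``other`` with a warning (archival sequence
records without fine-scale locality fall in this bucket and are
excluded from habitat-level tests by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .trees import UltrametricTree

log = logging.getLogger(__name__)

IUPAC_SYMBOLS = frozenset("ACGTN-RYSWKMBDHV")
HABITATS = ("offshore_reef", "inshore_reef", "grass_bed", "other")
LINEAGES = ("northern", "southern")

_HABITAT_ALIASES = {
    "offshore_reef": "offshore_reef",
    "offshore": "offshore_reef",
    "fore_reef": "offshore_reef",
    "inshore_reef": "inshore_reef",
    "patch_reef": "inshore_reef",
    "inshore_patch_reef": "inshore_reef",
    "grass_bed": "grass_bed",
    "inshore_grass_bed": "grass_bed",
    "grass": "grass_bed",
    "other": "other",
}

METADATA_COLUMNS = ("sample_id", "site", "habitat", "region")


class SeqIOError(ValueError):
    """Base class for malformed pipeline inputs."""


class AlignmentLengthError(SeqIOError):
    pass


class DuplicateIdError(SeqIOError):
    pass


class SymbolError(SeqIOError):
    pass


class SchemaError(SeqIOError):
    pass


class EmptyDatasetError(SeqIOError):
    pass


# ----------------------------------------------------------------------
# Alignment


@dataclass(frozen=True)
class Alignment:
    """Fixed-length nucleotide matrix keyed by sample id.

    ``matrix`` is an ``(n_samples, length)`` array of single uppercase
    characters over the IUPAC alphabet plus ``N`` and ``-``.
    """

    sample_ids: tuple[str, ...]
    matrix: np.ndarray  # dtype '<U1'

    def __post_init__(self):
        if len(self.sample_ids) != len(set(self.sample_ids)):
            raise DuplicateIdError("duplicate sample ids in alignment")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.sample_ids):
            raise AlignmentLengthError("matrix shape does not match sample ids")
        if self.matrix.shape[1] < 1:
            raise AlignmentLengthError("alignment must have at least one column")

    @property
    def length(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, sample_id: str) -> str:
        i = self.sample_ids.index(sample_id)
        return "".join(self.matrix[i])

    def sequence_strings(self) -> dict[str, str]:
        return {sid: "".join(r) for sid, r in zip(self.sample_ids, self.matrix)}

    def subset(self, ids: list[str]) -> "Alignment":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in ids]
        return Alignment(tuple(ids), self.matrix[rows])

    @classmethod
    def from_sequences(cls, ids, seqs) -> "Alignment":
        ids = tuple(ids)
        seqs = [s.upper() for s in seqs]
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            offender = next(
                sid for sid, s in zip(ids, seqs) if len(s) != len(seqs[0])
            )
            raise AlignmentLengthError(
                f"ragged alignment: sequence {offender!r} has a different length"
            )
        for sid, s in zip(ids, seqs):
            bad = set(s) - IUPAC_SYMBOLS
            if bad:
                pos = next(i for i, c in enumerate(s) if c in bad)
                raise SymbolError(
                    f"non-IUPAC symbol {s[pos]!r} at position {pos} in {sid!r}"
                )
        matrix = np.array([list(s) for s in seqs], dtype="<U1")
        return cls(ids, matrix)


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file (uppercasing symbols, order preserved)."""
    path = Path(path)
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise DuplicateIdError(f"duplicate sample id {rec.id!r} in {path}")
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise SeqIOError(f"no FASTA records in {path}")
    return Alignment.from_sequences(ids, seqs)


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in alignment.sequence_strings().items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ----------------------------------------------------------------------
# Metadata


def normalize_habitat(label: str) -> str:
    key = str(label).strip().lower().replace(" ", "_").replace("-", "_")
    while "__" in key:
        key = key.replace("__", "_")
    if key in _HABITAT_ALIASES:
        return _HABITAT_ALIASES[key]
    log.warning("unrecognized habitat label %r mapped to 'other'", label)
    return "other"


@dataclass(frozen=True)
class MetadataTable:
    """Per-sample site/habitat/region labels (+ simulated lineage truth)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        missing = [c for c in ("sample_id", "site", "habitat") if c not in self.table]
        if missing:
            raise SchemaError(f"metadata missing required column(s): {missing}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise DuplicateIdError(f"duplicate sample id {dup!r} in metadata")
        bad = set(self.table["habitat"]) - set(HABITATS)
        if bad:
            raise SchemaError(f"non-canonical habitat value(s) {sorted(bad)}")
        if "lineage_truth" in self.table:
            vals = set(self.table["lineage_truth"].dropna())
            if not vals <= set(LINEAGES):
                raise SchemaError(f"bad lineage_truth value(s) {sorted(vals - set(LINEAGES))}")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.table["sample_id"])

    @property
    def has_lineage_truth(self) -> bool:
        return "lineage_truth" in self.table.columns

    def subset(self, ids: list[str]) -> "MetadataTable":
        sub = (
            self.table.set_index("sample_id")
            .loc[list(ids)]
            .reset_index()
        )
        return MetadataTable(sub)

    @classmethod
    def from_records(cls, records: list[dict]) -> "MetadataTable":
        df = pd.DataFrame.from_records(records)
        df["habitat"] = [normalize_habitat(h) for h in df["habitat"]]
        if "region" not in df:
            df["region"] = "unknown"
        return cls(df)


def read_metadata(path: str | Path) -> MetadataTable:
    """Read the tab-separated metadata table, normalizing habitat labels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample_id", "site", "habitat") if c not in df.columns]
    if missing:
        raise SchemaError(f"metadata file {path} missing column(s): {missing}")
    df["habitat"] = [normalize_habitat(h) for h in df["habitat"]]
    if "region" not in df:
        df["region"] = "unknown"
    return MetadataTable(df)


def write_metadata(meta: MetadataTable, path: str | Path) -> None:
    cols = [c for c in (*METADATA_COLUMNS, "lineage_truth") if c in meta.table.columns]
    meta.table.to_csv(path, sep="\t", index=False, columns=cols)


# ----------------------------------------------------------------------
# Dataset


@dataclass(frozen=True)
class Dataset:
    """Validated join of alignment and metadata (identical id sets, same order)."""

    alignment: Alignment
    metadata: MetadataTable

    def __post_init__(self):
        if self.alignment.sample_ids != self.metadata.sample_ids:
            raise SeqIOError("dataset alignment/metadata ids differ; use make_dataset")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.alignment.sample_ids

    @property
    def n_samples(self) -> int:
        return self.alignment.n_samples


def make_dataset(alignment: Alignment, metadata: MetadataTable) -> Dataset:
    """Join on the id intersection, warning about any dropped samples."""
    align_ids = set(alignment.sample_ids)
    meta_ids = set(metadata.sample_ids)
    common = align_ids & meta_ids
    if not common:
        raise EmptyDatasetError("alignment and metadata share no sample ids")
    dropped_a = len(align_ids - common)
    dropped_m = len(meta_ids - common)
    if dropped_a or dropped_m:
        log.warning(
            "make_dataset dropped %d alignment-only and %d metadata-only samples",
            dropped_a,
            dropped_m,
        )
    keep = [s for s in alignment.sample_ids if s in common]
    return Dataset(alignment.subset(keep), metadata.subset(keep))


# ----------------------------------------------------------------------
# Newick trees


def read_newick(path: str | Path) -> UltrametricTree:
    """Read a single rooted clock tree; validates ultrametricity."""
    text = Path(path).read_text()
    return UltrametricTree.from_newick(text)


def write_newick(tree: UltrametricTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick())
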