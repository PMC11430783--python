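"""Reading, validating, splitting and summarizing multi-label mRNA localization data.

A dataset couples nucleotide sequences (FASTA) with per-sequence label sets
over a fixed, ordered universe of subcellular compartments.  Every vector or
matrix in the package that is indexed by compartment shares the ordering of
:class:`CompartmentUniverse`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The nine compartments of the RNALocate-derived multi-label benchmark,
#: in the fixed order used throughout the package.
DEFAULT_COMPARTMENTS: tuple[str, ...] = (
    "exosome",
    "nucleus",
    "nucleoplasm",
    "chromatin",
    "cytoplasm",
    "nucleolus",
    "cytosol",
    "membrane",
    "ribosome",
)

_VALID_CHARS = set("ACGTUN")


@dataclass(frozen=True)
class CompartmentUniverse:
    """Ordered set of compartment names shared by all label-indexed arrays."""

    labels: tuple[str, ...] = DEFAULT_COMPARTMENTS

    def __post_init__(self) -> None:
        if len(self.labels) < 2:
            raise ValueError("universe needs at least two compartments")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("compartment names must be unique")
        if any(not name for name in self.labels):
            raise ValueError("compartment names must be non-empty")

    @property
    def q(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown compartment {label!r}") from None

    def encode(self, label_set: Iterable[str]) -> np.ndarray:
        """Binary indicator row for a label subset."""
        row = np.zeros(self.q, dtype=np.int8)
        for label in label_set:
            row[self.index(label)] = 1
        return row


def canonicalize_sequence(sequence: str, record_id: str = "?") -> str:
    """Uppercase and map RNA (U) onto the internal DNA alphabet (T).

    Ambiguous bases ``N`` are retained (the tokenizer maps k-mers containing
    them to an unknown token); any other character is rejected.
    """
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise ValueError(
            f"record {record_id!r}: invalid characters {sorted(bad)!r} "
            "(expected A/C/G/T/U/N)"
        )
    return seq


@dataclass
class LabeledSequence:
    """One mRNA record: identifier, canonical A/C/G/T(/N) sequence, label set."""

    id: str
    sequence: str
    label_set: frozenset[str]

    def __post_init__(self) -> None:
        if not self.label_set:
            raise ValueError(f"record {self.id!r}: empty label set")


class LocalizationDataset:
    """Records plus the aligned r x q binary label matrix."""

    def __init__(self, universe: CompartmentUniverse, records: Sequence[LabeledSequence]):
        self.universe = universe
        self.records = list(records)
        self.label_matrix = np.array(
            [universe.encode(rec.label_set) for rec in self.records], dtype=np.int8
        ).reshape(len(self.records), universe.q)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    @property
    def sequences(self) -> list[str]:
        return [rec.sequence for rec in self.records]

    def subset(self, indices: Sequence[int]) -> "LocalizationDataset":
        return LocalizationDataset(self.universe, [self.records[i] for i in indices])


@dataclass(frozen=True)
class SplitSpec:
    """Record-level uniform random train/test split."""

    test_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


@dataclass
class DatasetSummary:
    """Counts and composition statistics of a dataset.

    ``cardinality_histogram[c-1]`` is the number of records carrying exactly
    ``c`` labels; ``composition`` rows (one per compartment) are mean
    A/C/G/T fractions over the records carrying that compartment.
    """

    total: int
    cardinality_histogram: np.ndarray
    per_label_counts: np.ndarray
    composition: pd.DataFrame
    universe: CompartmentUniverse = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "total": int(self.total),
            "cardinality_histogram": [int(x) for x in self.cardinality_histogram],
            "per_label_counts": {
                label: int(count)
                for label, count in zip(self.universe.labels, self.per_label_counts)
            },
            "composition": {
                label: {base: float(self.composition.loc[label, base]) for base in "ACGT"}
                for label in self.composition.index
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def read_dataset(
    fasta_path: str | Path,
    labels_path: str | Path,
    universe: CompartmentUniverse | None = None,
) -> LocalizationDataset:
    """Load a FASTA + label-table pair into a validated dataset.

    The label table is tab-separated with an ``id`` column and either the
    wide binary form (one 0/1 column per compartment) or the long form (a
    ``labels`` column holding comma-separated compartment names).  FASTA ids
    and table ids must match one-to-one.
    """
    universe = universe or CompartmentUniverse()
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        sequences[rec.id] = canonicalize_sequence(str(rec.seq), rec.id)

    table = pd.read_csv(labels_path, sep="\t", dtype={"id": str})
    if "id" not in table.columns:
        raise ValueError("label table must contain an 'id' column")
    label_sets = _parse_label_table(table, universe)

    fasta_ids = set(sequences)
    table_ids = set(label_sets)
    if fasta_ids != table_ids:
        missing = sorted(table_ids - fasta_ids)[:5]
        extra = sorted(fasta_ids - table_ids)[:5]
        raise ValueError(
            f"FASTA/label id mismatch: in labels but not FASTA {missing!r}; "
            f"in FASTA but not labels {extra!r}"
        )

    records = [
        LabeledSequence(id=rid, sequence=sequences[rid], label_set=label_sets[rid])
        for rid in table["id"]
    ]
    return LocalizationDataset(universe, records)


def _parse_label_table(
    table: pd.DataFrame, universe: CompartmentUniverse
) -> dict[str, frozenset[str]]:
    if "labels" in table.columns:  # long form
        out: dict[str, frozenset[str]] = {}
        for rid, cell in zip(table["id"], table["labels"]):
            if pd.isna(cell) or not str(cell).strip():
                raise ValueError(f"record {rid!r}: empty label set")
            names = frozenset(part.strip() for part in str(cell).split(","))
            for name in names:
                universe.index(name)  # raises on unknown
            out[str(rid)] = names
        return out

    missing_cols = [label for label in universe.labels if label not in table.columns]
    if missing_cols:
        raise ValueError(f"label table missing compartment columns {missing_cols!r}")
    out = {}
    for _, row in table.iterrows():
        names = frozenset(
            label for label in universe.labels if int(row[label]) == 1
        )
        if not names:
            raise ValueError(f"record {row['id']!r}: empty label set")
        out[str(row["id"])] = names
    return out


def write_dataset(
    ds: LocalizationDataset, fasta_path: str | Path, labels_path: str | Path
) -> None:
    """Persist as FASTA plus the canonical wide binary TSV."""
    records = [
        SeqRecord(Seq(rec.sequence), id=rec.id, description="") for rec in ds.records
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    table = pd.DataFrame(ds.label_matrix, columns=list(ds.universe.labels))
    table.insert(0, "id", ds.ids)
    table.to_csv(labels_path, sep="\t", index=False)


def split_train_test(
    ds: LocalizationDataset, spec: SplitSpec
) -> tuple[LocalizationDataset, LocalizationDataset]:
    """Disjoint, exhaustive record-level split; floor(r*test_fraction) in test."""
    r = len(ds)
    if r < 10:
        raise ValueError("need at least 10 records to split")
    n_test = int(np.floor(r * spec.test_fraction))
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(r)
    test_idx = np.sort(order[:n_test])
    train_idx = np.sort(order[n_test:])
    return ds.subset(train_idx), ds.subset(test_idx)


def summarize(ds: LocalizationDataset) -> DatasetSummary:
    """Cardinality histogram, per-compartment counts and nucleotide composition."""
    q = ds.universe.q
    cardinalities = ds.label_matrix.sum(axis=1)
    hist = np.bincount(cardinalities, minlength=q + 1)[1 : q + 1]
    per_label = ds.label_matrix.sum(axis=0).astype(np.int64)

    # per-record base fractions (N excluded from the denominator)
    fracs = np.zeros((len(ds), 4))
    for i, rec in enumerate(ds.records):
        counts = np.array([rec.sequence.count(base) for base in "ACGT"], dtype=float)
        total = counts.sum()
        if total > 0:
            fracs[i] = counts / total
    comp = np.full((q, 4), np.nan)
    for j in range(q):
        carriers = ds.label_matrix[:, j] == 1
        if carriers.any():
            comp[j] = fracs[carriers].mean(axis=0)
    composition = pd.DataFrame(comp, index=list(ds.universe.labels), columns=list("ACGT"))

    return DatasetSummary(
        total=len(ds),
        cardinality_histogram=hist,
        per_label_counts=per_label,
        composition=composition,
        universe=ds.universe,
    )
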