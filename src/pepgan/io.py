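"""Peptide dataset containers and CSV/FASTA round-trip I/O.

The central objects are :class:`PeptideRecord` (one sequence with an
optional binding score and a strong/weak/unlabeled call) and
:class:`PeptideDataset` (an ordered, id-unique collection with a fixed
length policy).  Binding labels follow the IEDB convention for a single
HLA allele: score >= 0.486 is a strong binder, score <= 0.362 a weak
binder, and anything in the open interval in between is left unlabeled
and excluded from training splits.
"""

from __future__ import annotations

import dataclasses
import io as _io
from pathlib import Path
from typing import Iterable, Iterator, Literal

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import AA_INDEX, PEPTIDE_LENGTH

STRONG_MIN: float = 0.486
WEAK_MAX: float = 0.362

Label = Literal["strong", "weak", "unlabeled"]
Source = Literal["real", "generated"]


@dataclasses.dataclass(frozen=True)
class PeptideRecord:
    """One peptide with provenance and (optional) binding annotation."""

    id: str
    sequence: str
    score: float | None = None
    label: Label = "unlabeled"
    source: Source = "real"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = sorted({c for c in self.sequence if c not in AA_INDEX})
        if bad:
            raise ValueError(f"non-canonical residue(s) {bad} in {self.sequence!r}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclasses.dataclass
class LoadReport:
    """Counts of records dropped while loading/validating a dataset."""

    n_loaded: int = 0
    n_dropped_alphabet: int = 0
    n_dropped_length: int = 0
    n_dropped_duplicate_id: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_dropped_alphabet + self.n_dropped_length + self.n_dropped_duplicate_id


class PeptideDataset:
    """Ordered collection of validated, fixed-length peptide records."""

    def __init__(
        self,
        records: Iterable[PeptideRecord],
        length_policy: int | None = PEPTIDE_LENGTH,
    ) -> None:
        self.length_policy = length_policy
        self.records: list[PeptideRecord] = []
        seen: set[str] = set()
        for rec in records:
            if length_policy is not None and len(rec.sequence) != length_policy:
                raise ValueError(
                    f"record {rec.id!r} has length {len(rec.sequence)}, policy {length_policy}"
                )
            if rec.id in seen:
                raise ValueError(f"duplicate id {rec.id!r}")
            seen.add(rec.id)
            self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PeptideRecord:
        return self.records[i]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def subset(self, label: Label | None = None, source: Source | None = None) -> "PeptideDataset":
        recs = [
            r
            for r in self.records
            if (label is None or r.label == label) and (source is None or r.source == source)
        ]
        return PeptideDataset(recs, length_policy=self.length_policy)

    def counts(self) -> dict[str, int]:
        out = {"strong": 0, "weak": 0, "unlabeled": 0}
        for r in self.records:
            out[r.label] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sequence": self.sequences,
                "score": [r.score for r in self.records],
                "label": [r.label for r in self.records],
                "source": [r.source for r in self.records],
            }
        )


def _records_from_rows(
    rows: Iterable[tuple[str, str, float | None, str, str]],
    length_policy: int | None,
    report: LoadReport,
) -> list[PeptideRecord]:
    out: list[PeptideRecord] = []
    seen: set[str] = set()
    for rid, seq, score, label, source in rows:
        seq = str(seq).strip().upper()
        if not seq or any(c not in AA_INDEX for c in seq):
            report.n_dropped_alphabet += 1
            continue
        if length_policy is not None and len(seq) != length_policy:
            report.n_dropped_length += 1
            continue
        if rid in seen:
            report.n_dropped_duplicate_id += 1
            continue
        seen.add(rid)
        out.append(PeptideRecord(id=rid, sequence=seq, score=score, label=label, source=source))
        report.n_loaded += 1
    return out


def load_dataset(
    path: str | Path,
    format: Literal["csv", "fasta"] = "csv",
    score_column: str | None = "score",
    sequence_column: str = "sequence",
    length_policy: int | None = PEPTIDE_LENGTH,
) -> tuple[PeptideDataset, LoadReport]:
    """Load peptides from CSV or FASTA, dropping invalid records.

    Returns the validated dataset and a :class:`LoadReport` counting the
    records dropped for alphabet, length, or duplicate-id violations.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = LoadReport()
    if format == "csv":
        df = pd.read_csv(path)
        if sequence_column not in df.columns:
            raise ValueError(f"CSV {path} has no {sequence_column!r} column")
        has_score = score_column is not None and score_column in df.columns
        rows = []
        for i, row in df.iterrows():
            rid = str(row["id"]) if "id" in df.columns else f"p{i}"
            score = None
            if has_score and pd.notna(row[score_column]):
                score = float(row[score_column])
            label = str(row["label"]) if "label" in df.columns and pd.notna(row.get("label")) else "unlabeled"
            source = str(row["source"]) if "source" in df.columns and pd.notna(row.get("source")) else "real"
            rows.append((rid, row[sequence_column], score, label, source))
    elif format == "fasta":
        rows = []
        for rec in SeqIO.parse(str(path), "fasta"):
            rid, _, label = rec.id.partition("|")
            rows.append((rid, str(rec.seq), None, label or "unlabeled", "real"))
    else:
        raise ValueError(f"unknown format {format!r}")

    records = _records_from_rows(rows, length_policy, report)
    if not records:
        raise ValueError(f"no valid peptides in {path} after filtering")
    return PeptideDataset(records, length_policy=length_policy), report


def apply_binding_thresholds(
    dataset: PeptideDataset,
    strong_min: float = STRONG_MIN,
    weak_max: float = WEAK_MAX,
) -> PeptideDataset:
    """Assign strong/weak/unlabeled calls from binding scores.

    ``score >= strong_min`` -> strong; ``score <= weak_max`` -> weak; the
    open interval stays unlabeled (kept in the dataset, excluded from
    training splits downstream).  Idempotent and order-independent.
    """
    if strong_min <= weak_max:
        raise ValueError(f"strong_min {strong_min} must exceed weak_max {weak_max}")
    missing = [r.id for r in dataset if r.score is None]
    if missing:
        raise ValueError(f"{len(missing)} record(s) without a score, e.g. {missing[:3]}")
    relabeled = []
    for r in dataset:
        assert r.score is not None
        if r.score >= strong_min:
            label: Label = "strong"
        elif r.score <= weak_max:
            label = "weak"
        else:
            label = "unlabeled"
        relabeled.append(dataclasses.replace(r, label=label))
    return PeptideDataset(relabeled, length_policy=dataset.length_policy)


def write_dataset(
    dataset: PeptideDataset,
    path: str | Path,
    format: Literal["csv", "fasta"] = "csv",
) -> None:
    """Write a dataset; ``load_dataset(write_dataset(d))`` round-trips.

    FASTA headers carry ``id|label``; scores survive only in CSV.
    """
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    if format == "csv":
        dataset.to_frame().to_csv(path, index=False)
    elif format == "fasta":
        recs = [
            SeqRecord(Seq(r.sequence), id=f"{r.id}|{r.label}", description="")
            for r in dataset
        ]
        with open(path, "w") as fh:
            SeqIO.write(recs, fh, "fasta")
    else:
        raise ValueError(f"unknown format {format!r}")


def dataset_from_sequences(
    sequences: Iterable[str],
    prefix: str = "p",
    source: Source = "real",
    length_policy: int | None = PEPTIDE_LENGTH,
) -> PeptideDataset:
    """Convenience: wrap bare sequences into a dataset with generated ids."""
    recs = [
        PeptideRecord(id=f"{prefix}{i}", sequence=s, source=source)
        for i, s in enumerate(sequences)
    ]
    return PeptideDataset(recs, length_policy=length_policy)
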