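"""Readers and writers: peptide tables, FASTA, models, reports, fixtures.

Peptide datasets travel as delimited text with header columns ``sequence``,
``charge`` and (optionally) ``drift_time_ms``; sequence-only input may also
arrive as FASTA with the charge supplied separately.  Trained models are
self-describing JSON documents.  The shipped test-set fixture transcribes
the published table of observed and predicted drift times for 82 peptide
ions from a five-protein tryptic digest, verbatim — including the values
whose aggregates disagree slightly with the prose they accompany.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from . import __version__
from .errors import IntegrityError, ValidationError
from .features import Peptide, validate_sequence
from .ann import ANNModel
from .evaluation import EvaluationReport, PredictionRecord

#: SHA-256 of the shipped test-set fixture, pinned at packaging time
_TABLE3_SHA256 = "4ab7e29b8f0ff042611acdb6297db13091e8571cd9fe39aae76b95f55c309a4c"


def read_peptide_table(path, dialect: str | None = None) -> list[Peptide]:
    """Read a TSV/CSV peptide table into validated records.

    The delimiter is inferred from the extension unless *dialect* ("tsv" or
    "csv") is given.  Errors name the offending row (1-based, excluding the
    header) and field.
    """
    path = Path(path)
    sep = {"tsv": "\t", "csv": ","}.get(dialect or path.suffix.lstrip(".").lower(), "\t")
    # round_trip parsing so write->read preserves drift times bitwise
    df = pd.read_csv(path, sep=sep, dtype={"sequence": str}, float_precision="round_trip")
    required = {"sequence", "charge"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {sorted(missing)}")
    peptides = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        try:
            drift = getattr(row, "drift_time_ms", None)
            drift = None if drift is None or pd.isna(drift) else float(drift)
            peptides.append(
                Peptide(sequence=str(row.sequence).upper(), charge=int(row.charge),
                        drift_time_ms=drift)
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {row_no}: {exc}") from exc
    if not peptides:
        raise ValidationError(f"{path}: no peptide rows found")
    return peptides


def write_peptide_table(peptides: Sequence[Peptide], path) -> None:
    """Write peptides as TSV with the standard three columns."""
    df = pd.DataFrame(
        {
            "sequence": [p.sequence for p in peptides],
            "charge": [p.charge for p in peptides],
            "drift_time_ms": [p.drift_time_ms for p in peptides],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_fasta(path, charge: int) -> list[Peptide]:
    """Read peptide sequences from FASTA, assigning a uniform charge."""
    peptides = []
    for rec_no, record in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(record.seq).upper()
        try:
            validate_sequence(seq)
        except ValidationError as exc:
            raise ValidationError(f"{path}: record {rec_no} ({record.id}): {exc}") from exc
        peptides.append(Peptide(sequence=seq, charge=charge))
    if not peptides:
        raise ValidationError(f"{path}: no FASTA records found")
    return peptides


def save_model(model: ANNModel, path, seed: int | None = None) -> None:
    """Serialize a model to JSON, stamping package version (and seed)."""
    doc = model.to_dict()
    doc["package_version"] = __version__
    if seed is not None:
        doc["metadata"]["seed"] = seed
    Path(path).write_text(json.dumps(doc, indent=2))


def load_model(path) -> ANNModel:
    return ANNModel.from_dict(json.loads(Path(path).read_text()))


def write_report(report: EvaluationReport, path, extra: Mapping | None = None) -> None:
    doc = report.to_dict()
    doc["package_version"] = __version__
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2))


def write_accuracy_curve(report: EvaluationReport, path) -> None:
    """Export the accuracy-vs-threshold curve as two-column TSV."""
    df = pd.DataFrame(
        {"threshold": list(report.accuracy_at), "fraction": list(report.accuracy_at.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def load_table3_fixture() -> dict[int, list[PredictionRecord]]:
    """The published test-set table as prediction records, grouped by charge.

    33 singly-, 38 doubly- and 11 triply-charged peptide ions with observed
    and published-model-predicted drift times; blank table cells carry no
    record.  The file's checksum is verified on every load.
    """
    raw = resources.files("driftnet.data").joinpath("table3_test_set.tsv").read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE3_SHA256:
        raise IntegrityError(
            f"test-set fixture checksum mismatch: expected {_TABLE3_SHA256}, got {digest}"
        )
    df = pd.read_csv(pd.io.common.BytesIO(raw), sep="\t")
    groups: dict[int, list[PredictionRecord]] = {1: [], 2: [], 3: []}
    for row in df.itertuples(index=False):
        peptide = Peptide(sequence=row.sequence, charge=int(row.charge),
                          drift_time_ms=float(row.observed_ms))
        groups[int(row.charge)].append(
            PredictionRecord(peptide=peptide, t_exp=float(row.observed_ms),
                             t_pred=float(row.predicted_ms))
        )
    return groups
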