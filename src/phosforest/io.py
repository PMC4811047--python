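"""Readers/writers for sequences, site annotations, accessibility profiles
and trained model bundles.

Conventions used everywhere in the package:

* residue positions are 1-based, inclusive, on the sanitized sequence;
* sequences are uppercased and non-standard letters (B, Z, J, U, O, ``*``
  and anything else outside the 20-letter alphabet) become the placeholder
  'X', never dropping the protein;
* annotations are a 4-column TSV (protein_id, position, residue, label)
  with a required header; accessibility profiles are a 3-column TSV
  (protein_id, position, asa), one row per residue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from Bio import SeqIO

from ._scales import AMINO_ACIDS
from .features import SCHEMA_VERSION, FeatureSchema

logger = logging.getLogger(__name__)

VALID_RESIDUES = frozenset("STY")
VALID_LABELS = frozenset({"positive", "negative"})

ANNOTATION_COLUMNS = ("protein_id", "position", "residue", "label")
ASA_COLUMNS = ("protein_id", "position", "asa")

MODEL_FORMAT_VERSION = 1


class ParseError(ValueError):
    """A file could not be parsed into the expected records."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence (sanitized, 21-letter alphabet)."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("protein id must be nonempty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS + "X")
        if bad:
            raise ValueError(f"protein {self.id!r} has invalid letters {sorted(bad)}")


@dataclass(frozen=True)
class SiteAnnotation:
    """One labelled candidate site: protein, 1-based position, S/T/Y, label."""

    protein_id: str
    position: int
    residue: str
    label: str

    def __post_init__(self):
        if self.residue not in VALID_RESIDUES:
            raise ValueError(f"residue must be one of S/T/Y, got {self.residue!r}")
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be positive/negative, got {self.label!r}")
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")


@dataclass(frozen=True)
class AsaProfile:
    """Per-residue nonnegative solvent-accessibility values for one protein."""

    protein_id: str
    values: tuple[float, ...] = field(repr=False)


def sanitize_sequence(raw: str) -> tuple[str, int]:
    """Uppercase and map non-standard letters to 'X'; returns (seq, n_mapped)."""
    seq = raw.upper()
    out = []
    mapped = 0
    for ch in seq:
        if ch in AMINO_ACIDS:
            out.append(ch)
        else:
            out.append("X")
            mapped += 1
    return "".join(out), mapped


def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into sanitized :class:`ProteinRecord` objects."""
    path = Path(path)
    text_head = path.read_text()[:1000].lstrip()
    if text_head and not text_head.startswith(">"):
        first = text_head.splitlines()[0]
        raise ParseError(f"{path}: not FASTA, first line {first!r}")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    n_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq, mapped = sanitize_sequence(str(rec.seq))
        n_mapped += mapped
        records.append(ProteinRecord(rec.id, seq))
    if n_mapped:
        logger.info("read_fasta(%s): mapped %d non-standard letters to 'X'", path, n_mapped)
    if not records:
        logger.warning("read_fasta(%s): no sequences found", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def read_annotations(
    path, proteins: Sequence[ProteinRecord]
) -> tuple[list[SiteAnnotation], list[str]]:
    """Read and validate site annotations against their proteins.

    Rows whose stated residue is not S/T/Y or does not match the sequence
    character at that position are rejected (returned in the second
    element, one message per row). Unknown protein ids and out-of-range
    positions are hard errors.
    """
    by_id = {p.id: p for p in proteins}
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    unknown = sorted(set(df["protein_id"]) - set(by_id))
    if unknown:
        raise ParseError(f"{path}: unknown protein ids {unknown}")
    annotations: list[SiteAnnotation] = []
    rejected: list[str] = []
    for row in df.itertuples(index=False):
        prot = by_id[row.protein_id]
        pos = int(row.position)
        if not 1 <= pos <= len(prot.sequence):
            raise ParseError(
                f"{path}: position {pos} out of range for protein "
                f"{prot.id!r} (length {len(prot.sequence)})"
            )
        residue = str(row.residue).upper()
        if residue not in VALID_RESIDUES:
            rejected.append(f"{prot.id}:{pos} residue {residue!r} is not S/T/Y")
            continue
        if prot.sequence[pos - 1] != residue:
            rejected.append(
                f"{prot.id}:{pos} stated residue {residue!r} != sequence "
                f"character {prot.sequence[pos - 1]!r}"
            )
            continue
        label = str(row.label).lower()
        if label not in VALID_LABELS:
            rejected.append(f"{prot.id}:{pos} label {row.label!r} not positive/negative")
            continue
        annotations.append(SiteAnnotation(prot.id, pos, residue, label))
    for msg in rejected:
        logger.warning("read_annotations(%s): rejected row: %s", path, msg)
    return annotations, rejected


def write_annotations(annotations: Iterable[SiteAnnotation], path) -> None:
    df = pd.DataFrame(
        [(a.protein_id, a.position, a.residue, a.label) for a in annotations],
        columns=list(ANNOTATION_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


def read_asa_profiles(path, proteins: Sequence[ProteinRecord]) -> dict[str, AsaProfile]:
    """Read per-residue accessibility profiles, length-checked per protein."""
    by_id = {p.id: p for p in proteins}
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    missing = set(ASA_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if (df["asa"] < 0).any():
        bad = df.loc[df["asa"] < 0].iloc[0]
        raise ParseError(
            f"{path}: negative accessibility for {bad['protein_id']}:{bad['position']}"
        )
    profiles: dict[str, AsaProfile] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        if pid not in by_id:
            raise ParseError(f"{path}: unknown protein id {pid!r}")
        n = len(by_id[pid].sequence)
        grp = grp.sort_values("position")
        if len(grp) != n or list(grp["position"]) != list(range(1, n + 1)):
            raise ParseError(
                f"{path}: profile for {pid!r} has {len(grp)} values, "
                f"sequence has {n} residues"
            )
        profiles[pid] = AsaProfile(pid, tuple(float(v) for v in grp["asa"]))
    return profiles


def write_asa_profiles(profiles: Mapping[str, AsaProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ASA_COLUMNS) + "\n")
        for pid in profiles:
            for i, v in enumerate(profiles[pid].values, start=1):
                fh.write(f"{pid}\t{i}\t{v:.6f}\n")


def save_model(bundle, path) -> None:
    """Persist a trained model bundle (forest + schema + params) to one file."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "schema": bundle.schema.to_dict(),
        "residue": bundle.residue,
        "params": bundle.params,
        "metadata": bundle.metadata,
        "forest": bundle.forest,
    }
    joblib.dump(payload, path)


def load_model(path):
    """Load a bundle saved by :func:`save_model`, guarding schema version."""
    from .model import ModelBundle  # local import to avoid a cycle

    try:
        payload = joblib.load(path)
    except Exception as exc:  # truncated/corrupt file
        raise ParseError(f"{path}: cannot load model bundle ({exc})") from exc
    if not isinstance(payload, dict) or payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ParseError(f"{path}: unrecognized model bundle format")
    schema = FeatureSchema.from_dict(payload["schema"])
    if schema.version != SCHEMA_VERSION:
        raise ParseError(
            f"{path}: model was trained under schema version {schema.version}, "
            f"current is {SCHEMA_VERSION}; retrain instead of reindexing"
        )
    current = FeatureSchema.for_window(schema.window_size)
    if current.names != schema.names:
        raise ParseError(f"{path}: saved schema does not match the current definition")
    return ModelBundle(
        residue=payload["residue"],
        forest=payload["forest"],
        schema=schema,
        params=payload["params"],
        metadata=payload["metadata"],
    )


def write_feature_matrix(X: np.ndarray, windows, schema: FeatureSchema, path) -> None:
    """Feature matrix as TSV with window metadata plus named feature columns."""
    meta = pd.DataFrame(
        {
            "protein_id": [w.protein_id for w in windows],
            "center_position": [w.center_position for w in windows],
            "residue": [w.center_residue for w in windows],
            "label": [w.label for w in windows],
        }
    )
    feats = pd.DataFrame(X, columns=list(schema.names))
    pd.concat([meta, feats], axis=1).to_csv(path, sep="\t", index=False)


def read_feature_matrix(path, schema: FeatureSchema | None = None):
    """Read a matrix written by :func:`write_feature_matrix`.

    Returns (X, y, meta, schema). The schema is reconstructed from the
    column names; a mismatch with the current definition is an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    meta_cols = ["protein_id", "center_position", "residue", "label"]
    feat_cols = [c for c in df.columns if c not in meta_cols]
    if schema is None:
        w = sum(1 for c in feat_cols if c.startswith("ASA_"))
        schema = FeatureSchema.for_window(w)
    if list(schema.names) != feat_cols:
        raise ParseError(f"{path}: feature columns do not match schema names")
    X = df[feat_cols].to_numpy(dtype=float)
    y = (df["label"] == "positive").to_numpy(dtype=int)
    return X, y, df[meta_cols], schema
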