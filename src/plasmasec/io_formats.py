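"""Readers and writers for every external representation the tool touches.

Formats handled:

* multi-record protein FASTA (via :mod:`Bio.SeqIO`);
* PSI-BLAST ASCII PSSM files (the ``-out_ascii_pssm`` dialect);
* PSIPRED vertical ``.ss2`` secondary-structure files, plus a plain
  H/E/C string fallback;
* tab-separated labelled feature tables;
* JSON model files.

All per-residue indexing is 0-based internally; ``.ss2`` row indices
(1-based) are converted on read.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

# PSI-BLAST header order; every 20-column matrix in the package uses it.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_SET = frozenset(AA_ORDER)

# Ambiguity / non-standard residue letters mapped to X on read.
_AMBIGUOUS = frozenset("BZJUO")

SS_STATES = "HEC"

MODEL_SCHEMA_VERSION = "1.0"


def sanitize_sequence(raw: str) -> str:
    """Uppercase a raw sequence and map non-canonical residues to ``X``.

    The letters B, Z, J, U and O (ambiguity codes, selenocysteine,
    pyrrolysine) become ``X``; X itself is kept.  Any other character
    raises ``ValueError``.  Downstream encoders exclude X positions from
    composition denominators and substitution-score sums, so the whole
    feature space stays defined on the 20-letter alphabet.
    """
    seq = raw.strip().upper()
    out = []
    for ch in seq:
        if ch in AA_SET or ch == "X":
            out.append(ch)
        elif ch in _AMBIGUOUS:
            out.append("X")
        else:
            raise ValueError(f"invalid residue character {ch!r}")
    return "".join(out)


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique accession."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: empty sequence")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"{self.id}: sequence must be uppercase")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PSSMProfile:
    """L x 20 log-odds matrix from an iterative profile search.

    Columns follow the PSI-BLAST header order ``A R N D C Q E G H I L K
    M F P S T W Y V``; entry (i, j) scores substitution of residue i by
    amino-acid type j.
    """

    protein_id: str
    scores: np.ndarray
    column_order: str = AA_ORDER

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"{self.protein_id}: PSSM must be L x 20, got {self.scores.shape}"
            )


@dataclass
class SSAnnotation:
    """Per-residue three-state secondary structure, optionally with probabilities.

    ``probs`` rows are ordered (C, H, E) as in PSIPRED output.
    """

    protein_id: str
    states: str
    probs: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        bad = set(self.states) - set(SS_STATES)
        if bad:
            raise ValueError(f"{self.protein_id}: unknown SS state(s) {sorted(bad)}")
        if self.probs is not None:
            self.probs = np.asarray(self.probs, dtype=float)
            if self.probs.shape != (len(self.states), 3):
                raise ValueError(
                    f"{self.protein_id}: probs shape {self.probs.shape} "
                    f"!= ({len(self.states)}, 3)"
                )
            sums = self.probs.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 0.02):
                raise ValueError(f"{self.protein_id}: probability rows do not sum to 1")


@dataclass
class LabeledDataset:
    """Feature matrix with ids, an ordered schema and optional binary labels."""

    ids: list[str]
    X: np.ndarray
    y: Optional[np.ndarray] = None
    schema: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        if self.schema and len(self.schema) != self.X.shape[1]:
            raise ValueError("schema length does not match feature count")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=int)
            if self.y.shape[0] != self.X.shape[0]:
                raise ValueError("label count does not match row count")
            if not set(np.unique(self.y)) <= {0, 1}:
                raise ValueError("labels must be binary 0/1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]


@dataclass
class TrainedModel:
    """A fitted logistic model plus everything needed to re-apply it."""

    weights: np.ndarray
    intercept: float
    selected_indices: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    schema_version: str = MODEL_SCHEMA_VERSION
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if self.weights.shape[0] != self.selected_indices.shape[0]:
            raise ValueError("weights and selected_indices length mismatch")
        if np.any(np.diff(self.selected_indices) <= 0) and self.selected_indices.size > 1:
            raise ValueError("selected_indices must be strictly increasing")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record protein FASTA file.

    Sequences are whitespace-stripped, uppercased and sanitized (see
    :func:`sanitize_sequence`).  Duplicate ids raise; an empty file
    returns an empty list with a warning.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, sanitize_sequence(str(rec.seq))))
    if not records:
        warnings.warn(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def _is_pssm_label_line(tokens: list[str]) -> bool:
    return (
        len(tokens) in (20, 40)
        and all(len(t) == 1 and t in AA_SET for t in tokens)
    )


def read_pssm(path: str | Path, sequence: Optional[str] = None,
              protein_id: Optional[str] = None) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM (``-out_ascii_pssm``) file.

    Only the first 20 numeric columns (the log-odds block) are kept; the
    percentage block and the trailing information-content statistics are
    ignored.  If ``sequence`` is supplied, the residue letter of each
    data row is checked against it.
    """
    path = Path(path)
    pid = protein_id if protein_id is not None else path.stem
    rows: list[list[float]] = []
    residues: list[str] = []
    in_data = False
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not in_data:
                if _is_pssm_label_line(tokens):
                    in_data = True
                continue
            # Data rows: "<index> <residue> <20 log-odds> [<20 pct> ...]".
            if len(tokens) < 22 or not tokens[0].isdigit():
                break
            idx = int(tokens[0])
            if idx != len(rows) + 1:
                raise ValueError(f"{path}: non-consecutive PSSM row index {idx}")
            res = tokens[1].upper()
            if sequence is not None:
                expect = sequence[len(rows)]
                if expect != "X" and res != expect:
                    raise ValueError(
                        f"{path}: residue mismatch at row {len(rows)}: "
                        f"PSSM has {res!r}, sequence has {expect!r}"
                    )
            try:
                vals = [float(t) for t in tokens[2:22]]
            except ValueError as exc:
                raise ValueError(f"{path}: malformed PSSM row {idx}") from exc
            rows.append(vals)
            residues.append(res)
    if not in_data:
        raise ValueError(f"{path}: no PSSM column-label line found (truncated file?)")
    if not rows:
        raise ValueError(f"{path}: PSSM contains no data rows (truncated file?)")
    if sequence is not None and len(rows) != len(sequence):
        raise ValueError(
            f"{path}: PSSM has {len(rows)} rows but sequence length is {len(sequence)}"
        )
    return PSSMProfile(pid, np.array(rows, dtype=float))


def write_pssm(profile: PSSMProfile, path: str | Path,
               sequence: Optional[str] = None) -> None:
    """Write a PSSM in the PSI-BLAST ASCII dialect.

    The percentage block is written as zeros and the two trailing
    per-row statistics as ``0.00`` — readers (including ours) ignore
    them.
    """
    L = profile.scores.shape[0]
    seq = sequence if sequence is not None else "X" * L
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted, "
            "and normalized\n"
        )
        labels = "  ".join(AA_ORDER)
        fh.write("            " + labels + "   " + labels + "\n")
        for i in range(L):
            vals = "".join(f"{int(round(v)):4d}" for v in profile.scores[i])
            pcts = "".join(f"{0:4d}" for _ in range(20))
            fh.write(f"{i + 1:5d} {seq[i]} {vals} {pcts}  0.00 0.00\n")
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1337     0.3157\n")


# ---------------------------------------------------------------------------
# PSIPRED .ss2 (vertical format) and plain-string fallback
# ---------------------------------------------------------------------------

def read_ss2(path: str | Path, protein_id: Optional[str] = None) -> SSAnnotation:
    """Read secondary structure from PSIPRED vertical ``.ss2`` output.

    Rows are ``index residue state pC pH pE``.  A file containing only
    an H/E/C string (optionally wrapped over lines) is accepted as a
    fallback and yields an annotation without probabilities.
    """
    path = Path(path)
    pid = protein_id if protein_id is not None else path.stem
    states: list[str] = []
    probs: list[list[float]] = []
    plain_chunks: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) == 1 and set(tokens[0]) <= set(SS_STATES):
                plain_chunks.append(tokens[0])
                continue
            if len(tokens) < 6:
                raise ValueError(f"{path}:{lineno}: malformed ss2 row")
            idx = int(tokens[0])
            if idx != len(states) + 1:
                raise ValueError(f"{path}:{lineno}: non-monotone ss2 index {idx}")
            state = tokens[2]
            if state not in SS_STATES:
                raise ValueError(f"{path}:{lineno}: unknown SS state {state!r}")
            states.append(state)
            probs.append([float(tokens[3]), float(tokens[4]), float(tokens[5])])
    if plain_chunks:
        if states:
            raise ValueError(f"{path}: mixes ss2 rows with plain H/E/C strings")
        return SSAnnotation(pid, "".join(plain_chunks), None)
    if not states:
        raise ValueError(f"{path}: no secondary-structure content found")
    return SSAnnotation(pid, "".join(states), np.array(probs, dtype=float))


def write_ss2(ss: SSAnnotation, path: str | Path,
              sequence: Optional[str] = None) -> None:
    """Write an annotation in PSIPRED vertical format."""
    L = len(ss.states)
    seq = sequence if sequence is not None else "X" * L
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT (vertical)\n\n")
        for i, state in enumerate(ss.states):
            if ss.probs is not None:
                pc, ph, pe = ss.probs[i]
            else:
                pc, ph, pe = (float(state == s) for s in "CHE")
            fh.write(f"{i + 1:4d} {seq[i]} {state}  {pc:6.3f} {ph:6.3f} {pe:6.3f}\n")


# ---------------------------------------------------------------------------
# Feature tables (TSV)
# ---------------------------------------------------------------------------

def write_feature_table(dataset: LabeledDataset, path: str | Path) -> None:
    """Write a labelled feature table as TSV.

    Header is ``id``, the feature names, then ``label`` (omitted when
    the dataset has no labels).  Floats are written with 17 significant
    digits so that write -> read round-trips exactly.
    """
    if not dataset.schema:
        raise ValueError("dataset has no schema; cannot write a feature table")
    with open(path, "w") as fh:
        cols = ["id", *dataset.schema] + (["label"] if dataset.y is not None else [])
        fh.write("\t".join(cols) + "\n")
        for i, pid in enumerate(dataset.ids):
            row = [pid] + [f"{v:.17g}" for v in dataset.X[i]]
            if dataset.y is not None:
                row.append(str(int(dataset.y[i])))
            fh.write("\t".join(row) + "\n")


def read_feature_table(path: str | Path) -> LabeledDataset:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "id":
            raise ValueError(f"{path}:1: feature table must start with an 'id' column")
        has_label = header[-1] == "label"
        schema = header[1 : -1 if has_label else len(header)]
        ids: list[str] = []
        rows: list[list[float]] = []
        labels: list[int] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} columns, got {len(parts)}"
                )
            ids.append(parts[0])
            if has_label:
                rows.append([float(v) for v in parts[1:-1]])
                labels.append(int(parts[-1]))
            else:
                rows.append([float(v) for v in parts[1:]])
    X = np.array(rows, dtype=float) if rows else np.empty((0, len(schema)))
    y = np.array(labels, dtype=int) if has_label else None
    return LabeledDataset(ids=ids, X=X, y=y, schema=list(schema))


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column ``id<TAB>label`` TSV (header optional)."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            parts = stripped.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            if lineno == 1 and parts[1].lower() == "label":
                continue
            out[parts[0]] = int(parts[1])
    return out


def write_labels(labels: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlabel\n")
        for pid, lab in labels.items():
            fh.write(f"{pid}\t{int(lab)}\n")


# ---------------------------------------------------------------------------
# Model files (JSON)
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    doc = {
        "schema_version": model.schema_version,
        "weights": model.weights.tolist(),
        "intercept": float(model.intercept),
        "selected_indices": model.selected_indices.tolist(),
        "standardization": {
            "center": model.center.tolist(),
            "scale": model.scale.tolist(),
        },
        "provenance": model.provenance,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_model(path: str | Path) -> TrainedModel:
    with open(path) as fh:
        doc = json.load(fh)
    return TrainedModel(
        weights=np.array(doc["weights"], dtype=float),
        intercept=float(doc["intercept"]),
        selected_indices=np.array(doc["selected_indices"], dtype=int),
        center=np.array(doc["standardization"]["center"], dtype=float),
        scale=np.array(doc["standardization"]["scale"], dtype=float),
        schema_version=doc.get("schema_version", MODEL_SCHEMA_VERSION),
        provenance=doc.get("provenance", {}),
    )
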