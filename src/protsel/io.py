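"""Reading and writing labeled protein sequence sets.

Sequences arrive as FASTA, labels either implicitly (one FASTA per class) or
through a tab-separated label map ``sequence_id<TAB>class``. Non-standard
residues (B, J, O, U, X, Z, ``*``, gaps) are handled by a configurable
policy:

``reject``
    abort on the first non-standard residue;
``skip_sequence``
    drop the whole record with a logged warning;
``drop_ngrams`` (default)
    keep the record but flag the offending positions so the encoder excludes
    every window that overlaps them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .errors import DatasetError, FastaParseError, NonStandardResidueError

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetically ordered.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AMINO_ACID_SET = frozenset(AMINO_ACIDS)

RESIDUE_POLICIES = ("reject", "drop_ngrams", "skip_sequence")


@dataclass(frozen=True)
class ProteinSequence:
    """A single protein sequence.

    ``invalid_positions`` holds 0-based indices of residues outside the
    standard alphabet; it is non-empty only under policy ``drop_ngrams``.
    """

    id: str
    residues: str
    invalid_positions: tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_clean(self) -> bool:
        return not self.invalid_positions


@dataclass
class LabeledDataset:
    """Multi-class sequence set: class labels in first-appearance order."""

    classes: list[str]
    sequences: dict[str, list[ProteinSequence]] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {c: len(self.sequences[c]) for c in self.classes}

    @property
    def n_sequences(self) -> int:
        return sum(len(v) for v in self.sequences.values())

    def validate(self) -> None:
        if len(self.classes) < 2:
            raise DatasetError(f"need at least 2 classes, got {len(self.classes)}")
        seen: set[str] = set()
        for c in self.classes:
            seqs = self.sequences.get(c, [])
            if len(seqs) < 2:
                raise DatasetError(
                    f"class {c!r} has {len(seqs)} sequence(s); at least 2 are "
                    "required (the sample variance needs N_i - 1 >= 1)"
                )
            for s in seqs:
                if s.id in seen:
                    raise DatasetError(f"duplicate sequence id {s.id!r} across dataset")
                seen.add(s.id)

    def iter_rows(self):
        """Yield (class_label, ProteinSequence) in class order then input order."""
        for c in self.classes:
            for s in self.sequences[c]:
                yield c, s


def _apply_policy(record_id: str, residues: str, policy: str) -> ProteinSequence | None:
    residues = residues.upper()
    bad = tuple(i for i, ch in enumerate(residues) if ch not in AMINO_ACID_SET)
    if not residues:
        raise FastaParseError(f"record {record_id!r} has an empty sequence")
    if not bad:
        return ProteinSequence(record_id, residues)
    if policy == "reject":
        raise NonStandardResidueError(
            f"record {record_id!r} contains non-standard residue(s) "
            f"{sorted({residues[i] for i in bad})} at position(s) {list(bad)[:5]}"
        )
    if policy == "skip_sequence":
        logger.warning(
            "skipping record %r: %d non-standard residue(s)", record_id, len(bad)
        )
        return None
    if policy == "drop_ngrams":
        logger.info(
            "record %r: %d non-standard residue(s) flagged; overlapping "
            "n-grams will be excluded from encoding",
            record_id,
            len(bad),
        )
        return ProteinSequence(record_id, residues, bad)
    raise ValueError(f"unknown residue policy {policy!r}")


def read_fasta(path: str | Path, residue_policy: str = "drop_ngrams") -> list[ProteinSequence]:
    """Read a FASTA file into validated :class:`ProteinSequence` records.

    Record ids are the first whitespace-delimited token of the header.
    Raises :class:`FastaParseError` on malformed or empty input.
    """
    if residue_policy not in RESIDUE_POLICIES:
        raise ValueError(f"residue_policy must be one of {RESIDUE_POLICIES}")
    path = Path(path)
    # Light syntactic pre-check so errors carry a line number; Bio.SeqIO is
    # permissive about text before the first header.
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"expected FASTA header '>' as first non-blank content in {path}",
                    line=lineno,
                )
            break
        else:
            raise FastaParseError(f"empty FASTA file: {path}")

    out: list[ProteinSequence] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = _apply_policy(record.id, str(record.seq), residue_policy)
        if seq is not None:
            out.append(seq)
    return out


def read_label_map(path: str | Path) -> dict[str, str]:
    """Read a ``sequence_id<TAB>class`` TSV (header row required)."""
    labels: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise DatasetError(f"empty label map: {path}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise DatasetError(f"label map {path} line {lineno}: expected 2 columns")
            sid, cls = parts
            if sid in labels:
                raise DatasetError(f"label map {path}: duplicate sequence id {sid!r}")
            labels[sid] = cls
    return labels


def load_labeled_dataset(
    class_fastas: list[tuple[str, str | Path]] | None = None,
    fasta: str | Path | None = None,
    label_map: str | Path | None = None,
    residue_policy: str = "drop_ngrams",
) -> LabeledDataset:
    """Assemble a :class:`LabeledDataset` from FASTA input.

    Either ``class_fastas`` — a list of (class label, FASTA path) pairs, one
    file per class — or a single ``fasta`` plus a ``label_map`` TSV.
    """
    if (class_fastas is None) == (fasta is None):
        raise ValueError("provide either class_fastas or (fasta, label_map)")

    classes: list[str] = []
    sequences: dict[str, list[ProteinSequence]] = {}
    if class_fastas is not None:
        for label, path in class_fastas:
            seqs = read_fasta(path, residue_policy=residue_policy)
            if label not in sequences:
                classes.append(label)
                sequences[label] = []
            sequences[label].extend(seqs)
    else:
        if label_map is None:
            raise ValueError("a label map is required with a single FASTA")
        labels = read_label_map(label_map)
        seqs = read_fasta(fasta, residue_policy=residue_policy)
        by_id = {s.id: s for s in seqs}
        missing = sorted(set(labels) - set(by_id))
        if missing:
            raise DatasetError(
                f"label map references id(s) missing from FASTA: {missing}"
            )
        for s in seqs:
            if s.id not in labels:
                raise DatasetError(f"sequence {s.id!r} has no entry in the label map")
            cls = labels[s.id]
            if cls not in sequences:
                classes.append(cls)
                sequences[cls] = []
            sequences[cls].append(s)

    ds = LabeledDataset(classes=classes, sequences=sequences)
    ds.validate()
    return ds


def write_fasta(sequences: list[ProteinSequence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sequences:
            fh.write(f">{s.id}\n{s.residues}\n")


def save_matrix_csv(matrix, labels, ids, descriptors, path: str | Path) -> None:
    """Dense CSV: sequence_id, class, then one column per descriptor."""
    import pandas as pd
    import scipy.sparse as sp

    dense = matrix.toarray() if sp.issparse(matrix) else matrix
    df = pd.DataFrame(dense, columns=list(descriptors))
    df.insert(0, "class", list(labels))
    df.insert(0, "sequence_id", list(ids))
    df.to_csv(path, index=False)


def load_matrix_csv(path: str | Path):
    """Inverse of :func:`save_matrix_csv`; returns (matrix, labels, ids, descriptors)."""
    import numpy as np
    import pandas as pd

    df = pd.read_csv(path)
    if df.columns[0] != "sequence_id" or df.columns[1] != "class":
        raise DatasetError(f"{path}: expected 'sequence_id' and 'class' leading columns")
    ids = df["sequence_id"].astype(str).tolist()
    labels = np.asarray(df["class"].astype(str))
    descriptors = list(df.columns[2:])
    matrix = df[df.columns[2:]].to_numpy(dtype=float)
    return matrix, labels, ids, descriptors


def save_matrix_mtx(matrix, labels, ids, descriptors, path: str | Path) -> None:
    """MatrixMarket coordinate file plus sidecar row-label and column files."""
    import scipy.io
    import scipy.sparse as sp

    path = Path(path)
    scipy.io.mmwrite(str(path), sp.coo_matrix(matrix))
    with open(path.with_suffix(".rows.tsv"), "w", encoding="utf-8") as fh:
        fh.write("sequence_id\tclass\n")
        for sid, lab in zip(ids, labels):
            fh.write(f"{sid}\t{lab}\n")
    with open(path.with_suffix(".cols.txt"), "w", encoding="utf-8") as fh:
        fh.write("\n".join(descriptors) + "\n")


def write_dataset(ds: LabeledDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write one FASTA per class plus ``labels.tsv``; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    labels_path = out_dir / "labels.tsv"
    with open(labels_path, "w", encoding="utf-8") as lab:
        lab.write("sequence_id\tclass\n")
        for c in ds.classes:
            safe = "".join(ch if ch.isalnum() or ch in "-_" else "_" for ch in c)
            fasta_path = out_dir / f"{safe}.fasta"
            write_fasta(ds.sequences[c], fasta_path)
            written[c] = fasta_path
            for s in ds.sequences[c]:
                lab.write(f"{s.id}\t{c}\n")
    written["__labels__"] = labels_path
    return written
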