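"""File formats: FASTA, Vienna dot-bracket, annotation/window/report TSV,
and sparse (SVM-light/libSVM) feature files.

User-facing coordinates are 1-based inclusive; they are converted to the
package's internal 0-based half-open convention on read and back on write.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from sklearn.datasets import dump_svmlight_file, load_svmlight_file

from .dataset import LabeledWindow, Precursor

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_dotbracket",
    "write_dotbracket",
    "read_annotation",
    "write_annotation",
    "load_precursors",
    "write_windows",
    "write_features",
    "read_features",
]

ANNOTATION_COLUMNS = [
    "id",
    "mature5p_start",
    "mature5p_end",
    "mature3p_start",
    "mature3p_end",
]


def read_fasta(path) -> dict[str, str]:
    """Sequences by record id."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(precursors, path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.id, description="") for p in precursors
    ]
    SeqIO.write(records, str(path), "fasta")


def read_dotbracket(path) -> dict[str, tuple[str, str]]:
    """Vienna dot-bracket records: ``>id`` / sequence / structure.

    The structure line may carry a trailing free energy in parentheses
    after whitespace (RNAfold output style); it is ignored.
    """
    out: dict[str, tuple[str, str]] = {}
    lines = [ln.rstrip("\n") for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(
                f"{path}: expected '>' header at line {i + 1}, got {lines[i]!r}"
            )
        if i + 2 >= len(lines):
            raise ValueError(f"{path}: truncated record at line {i + 1}")
        rid = lines[i][1:].split()[0]
        seq = lines[i + 1].strip()
        struct = lines[i + 2].split()[0]
        out[rid] = (seq, struct)
        i += 3
    return out


def write_dotbracket(precursors, path) -> None:
    with open(path, "w") as fh:
        for p in precursors:
            fh.write(f">{p.id}\n{p.sequence}\n{p.structure}\n")


def _span_from_row(row, start_col: str, end_col: str) -> tuple[int, int] | None:
    start, end = row[start_col], row[end_col]
    if pd.isna(start) or pd.isna(end):
        return None
    return int(start) - 1, int(end)  # 1-based inclusive -> 0-based half-open


def read_annotation(path) -> dict[str, dict]:
    """Mature-arm spans per precursor id (1-based inclusive in the file)."""
    table = pd.read_csv(path, sep="\t")
    missing = set(ANNOTATION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    out = {}
    for _, row in table.iterrows():
        out[str(row["id"])] = {
            "mature5p": _span_from_row(row, "mature5p_start", "mature5p_end"),
            "mature3p": _span_from_row(row, "mature3p_start", "mature3p_end"),
        }
    return out


def write_annotation(precursors, path) -> None:
    rows = []
    for p in precursors:
        rows.append(
            {
                "id": p.id,
                "mature5p_start": p.mature5p[0] + 1 if p.mature5p else math.nan,
                "mature5p_end": p.mature5p[1] if p.mature5p else math.nan,
                "mature3p_start": p.mature3p[0] + 1 if p.mature3p else math.nan,
                "mature3p_end": p.mature3p[1] if p.mature3p else math.nan,
            }
        )
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def load_precursors(fasta_path, structures_path, annotation_path) -> list[Precursor]:
    """Join FASTA, dot-bracket and annotation files by id into precursors.

    Ids present in one file but not the others are an error (orphans are
    listed); sequence/structure length mismatches are errors too.
    """
    seqs = read_fasta(fasta_path)
    structs = read_dotbracket(structures_path)
    annos = read_annotation(annotation_path)
    ids = set(seqs) | set(structs) | set(annos)
    orphans = sorted(
        i for i in ids if i not in seqs or i not in structs or i not in annos
    )
    if orphans:
        raise ValueError(f"ids not present in all three inputs: {orphans}")
    precursors = []
    for rid in sorted(seqs):
        _, struct = structs[rid]
        precursors.append(
            Precursor(
                id=rid,
                sequence=seqs[rid],
                structure=struct,
                mature5p=annos[rid]["mature5p"],
                mature3p=annos[rid]["mature3p"],
            )
        )
    return precursors


def write_windows(windows, path) -> None:
    """Labeled-window inspection table (tokens rendered A/U/C/G, L<l>, '-')."""
    rows = [
        {
            "id": w.precursor_id,
            "arm": w.arm,
            "label": w.label,
            "center": w.center,
            "armTokens": " ".join(t.render() for t in w.arm_tokens),
            "compTokens": " ".join(t.render() for t in w.comp_tokens),
        }
        for w in windows
    ]
    pd.DataFrame(
        rows, columns=["id", "arm", "label", "center", "armTokens", "compTokens"]
    ).to_csv(path, sep="\t", index=False)


def write_features(X, y, path) -> None:
    """Sparse ASCII feature file (SVM-light/libSVM, 1-based indices, ±1 labels)."""
    X = np.asarray(X)
    y = np.asarray(y)
    with open(path, "wb") as fh:
        dump_svmlight_file(X, y, fh, zero_based=False)


def read_features(path, n_features: int | None = None):
    X, y = load_svmlight_file(str(path), n_features=n_features, zero_based=False)
    return X.toarray(), y.astype(np.int64)


def windows_to_features(windows, scheme):
    """Convenience: encode labeled windows into (X, y) under ``scheme``."""
    from .encoding import encode_windows

    return encode_windows(windows, scheme)
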