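"""Plain-text readers and writers for all pipeline formats.

Everything is TSV or simple line-oriented text: ROI time series (T rows x
R columns, header = ROI labels), parcel->network lookups, word2vec-style
embedding text files, one bracketed tree per line, and the subject table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_matrix_tsv", "read_matrix_tsv",
    "write_networks_tsv", "read_networks_tsv",
    "write_word2vec", "read_word2vec",
    "write_trees", "read_trees",
    "write_subjects", "read_subjects",
    "write_manifest",
]


def write_matrix_tsv(path, values: np.ndarray, columns: list[str]) -> None:
    pd.DataFrame(np.asarray(values), columns=columns).to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float), list(df.columns)


def write_networks_tsv(path, roi_labels: list[str], networks: list[str]) -> None:
    pd.DataFrame({"roi_label": roi_labels, "network": networks}).to_csv(
        path, sep="\t", index=False)


def read_networks_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["roi_label"], df["network"]))


def write_word2vec(path, labels: list[str], vectors: np.ndarray) -> None:
    """word2vec text format: `<n> <dim>` header then `label v1 ... vdim`."""
    v = np.asarray(vectors)
    with open(path, "w") as fh:
        fh.write(f"{v.shape[0]} {v.shape[1]}\n")
        for lab, row in zip(labels, v):
            fh.write(lab + " " + " ".join(f"{x:.8g}" for x in row) + "\n")


def read_word2vec(path) -> tuple[list[str], np.ndarray]:
    with open(path) as fh:
        n, dim = map(int, fh.readline().split())
        labels, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1 : dim + 1]])
    if len(labels) != n:
        raise ValueError(f"word2vec header promised {n} rows, found {len(labels)}")
    return labels, np.asarray(rows)


def write_trees(path, trees: list[str]) -> None:
    Path(path).write_text("".join(t + "\n" for t in trees))


def read_trees(path) -> list[str]:
    return [ln for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_subjects(path, subjects: pd.DataFrame) -> None:
    subjects.to_csv(path, sep="\t", index=False)


def read_subjects(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
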