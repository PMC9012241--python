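"""File formats: FASTA sequences, TSV labels / annotations / reports.

FASTA goes through Biopython (multi-line records, 60-column wrapping,
uppercase coercion on read).  Label files are two-column TSV
``seq_id<TAB>class_label`` (header optional); annotation files are four-column
TSV ``seq_id<TAB>start<TAB>end<TAB>label`` with 0-based half-open coordinates.
A converter is provided for 1-based closed coordinates as used by protein
feature tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .interpretability import MotifAnnotation, MotifMatch


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {id: uppercase sequence}, preserving order."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="")
               for sid, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")  # wraps at 60 columns


def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                     comment=None, skip_blank_lines=True)
    # tolerate an optional header row
    if list(df.iloc[0]) == columns:
        df = df.iloc[1:].reset_index(drop=True)
    if df.shape[1] != len(columns):
        raise ValueError(f"{path}: expected {len(columns)} columns, "
                         f"found {df.shape[1]}")
    df.columns = columns
    return df


def read_labels(path) -> dict[str, str]:
    df = _read_tsv(path, ["seq_id", "class_label"])
    return dict(zip(df.seq_id, df.class_label))


def write_labels(labels: dict[str, object], path) -> None:
    pd.DataFrame({"seq_id": list(labels), "class_label": list(labels.values())}
                 ).to_csv(path, sep="\t", index=False, header=False)


def read_annotations(path, one_based_closed: bool = False) -> list[MotifAnnotation]:
    """Read annotation TSV; set ``one_based_closed`` for feature-table style
    coordinates (converted to 0-based half-open)."""
    df = _read_tsv(path, ["seq_id", "start", "end", "label"])
    anns = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if one_based_closed:
            start, end = start - 1, end
        anns.append(MotifAnnotation(seq_id=row.seq_id, start=start, end=end,
                                    label=row.label))
    return anns


def write_annotations(annotations: list[MotifAnnotation], path) -> None:
    pd.DataFrame([(a.seq_id, a.start, a.end, a.label) for a in annotations],
                 columns=["seq_id", "start", "end", "label"]
                 ).to_csv(path, sep="\t", index=False, header=False)


def write_predictions(seq_ids: list[str], predictions: np.ndarray,
                      probabilities: np.ndarray, class_names: list, path) -> None:
    """Prediction TSV: seq_id, predicted class, full probability vector."""
    rows = []
    for sid, pred, probs in zip(seq_ids, predictions, probabilities):
        rows.append([sid, class_names[int(pred)]] + [f"{p:.6g}" for p in probs])
    cols = ["seq_id", "predicted_class"] + [f"p_{c}" for c in class_names]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_attention(seq_id: str, W: np.ndarray, v: np.ndarray,
                    kernel_sizes: tuple[int, ...], tsv_path,
                    array_path=None) -> None:
    """Serialize a double-scale attention matrix: TSV (position, margin weight,
    per-scale weights) and optionally the dense arrays as .npz."""
    l = v.shape[0]
    data = {"seq_id": [seq_id] * l, "position": np.arange(l), "margin": v}
    for k, size in enumerate(kernel_sizes):
        data[f"w_scale{size}"] = W[k]
    pd.DataFrame(data).to_csv(tsv_path, sep="\t", index=False,
                              float_format="%.8g")
    if array_path is not None:
        np.savez(array_path, W=W, v=v, kernel_sizes=np.array(kernel_sizes))


def write_matches(matches: list[MotifMatch], path) -> None:
    pd.DataFrame(
        [(m.annotation.seq_id, m.annotation.start, m.annotation.end,
          m.annotation.label, m.matched_scale, f"{m.center_weight_ratio:.6g}",
          f"{m.score:.6g}") for m in matches],
        columns=["seq_id", "start", "end", "label", "matched_scale",
                 "center_weight_ratio", "score"]
    ).to_csv(path, sep="\t", index=False)
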