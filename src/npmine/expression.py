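"""Transcript x tissue presence/absence summaries (RT-PCR style calls).

The canonical tissue panel for a decapod expression survey: CG (cerebral
ganglia), EG (eyestalk ganglia), Gi (gill), Hp (hepatopancreas), Ht
(heart), Ms (muscle), Ov (ovary), VG (ventral ganglia), YO (Y-organ).
The CNS aggregate is the OR over CG, EG and VG.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

CANONICAL_TISSUES = ("CG", "EG", "Gi", "Hp", "Ht", "Ms", "Ov", "VG", "YO")
CNS_TISSUES = ("CG", "EG", "VG")


class MatrixParseError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    calls: pd.DataFrame  # boolean, transcripts x tissues

    @property
    def transcripts(self) -> list[str]:
        return list(self.calls.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.calls.columns)


def read_matrix(path: str | Path) -> ExpressionMatrix:
    """Parse a TSV with a tissue-name header row and {0,1} cells.

    Non-canonical tissue names are accepted with a warning; ragged rows,
    non-binary cells, or duplicated labels raise MatrixParseError.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as e:
        raise MatrixParseError(f"{path}: {e}") from e
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise MatrixParseError(f"{path}: duplicated transcript ids {dupes}")
    if df.columns.has_duplicates:
        raise MatrixParseError(f"{path}: duplicated tissue names")
    unknown = [t for t in df.columns if t not in CANONICAL_TISSUES]
    if unknown:
        warnings.warn(f"non-canonical tissue names: {unknown}", stacklevel=2)
    for tid, row in df.iterrows():
        for tissue, cell in row.items():
            if pd.isna(cell) or str(cell) not in ("0", "1"):
                raise MatrixParseError(
                    f"row {tid!r}, tissue {tissue!r}: cell {cell!r} is not 0/1"
                )
    return ExpressionMatrix(calls=df.astype(int).astype(bool))


def count_expressed(m: ExpressionMatrix, tissue: str) -> int:
    """Number of transcripts detected in one tissue."""
    if tissue not in m.calls.columns:
        raise KeyError(
            f"unknown tissue {tissue!r}; available: {list(m.calls.columns)}"
        )
    return int(m.calls[tissue].sum())


def tissue_summary(m: ExpressionMatrix) -> dict:
    """Per-tissue counts, the CNS aggregate, and per-transcript tissue lists."""
    counts = {t: count_expressed(m, t) for t in m.calls.columns}
    cns_cols = [t for t in CNS_TISSUES if t in m.calls.columns]
    cns = int(m.calls[cns_cols].any(axis=1).sum()) if cns_cols else 0
    per_transcript = {
        tid: [t for t in m.calls.columns if m.calls.at[tid, t]]
        for tid in m.calls.index
    }
    return {"per_tissue": counts, "CNS": cns, "per_transcript": per_transcript}
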