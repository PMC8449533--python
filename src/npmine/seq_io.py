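"""Sequence I/O, six-frame translation, and ORF extraction.

Coordinates in all public records are 1-based inclusive on the forward
strand of the source transcript, matching the residue-numbering convention
used in prohormone site labels such as K47R.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

NUCLEOTIDE_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")
STOP = "*"

_CODON_TABLE = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)


class FastaParseError(ValueError):
    """Raised when a FASTA record violates the declared alphabet or format."""


@dataclass
class TranscriptRecord:
    """A nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class ProteinRecord:
    """An amino-acid sequence, optionally tracking its coding origin.

    ``frame`` is in {-3..-1, 1..3}; ``cds_span`` is a 1-based inclusive
    nucleotide interval on the forward strand of ``source_id``. Raw frame
    translations may contain the stop sentinel ``*``; ORF products never do.
    """

    id: str
    seq: str
    source_id: str = "direct"
    frame: Optional[int] = None
    cds_span: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    @property
    def length(self) -> int:
        return len(self.seq)


def _validate(record_id: str, seq: str, alphabet: str) -> None:
    allowed = NUCLEOTIDE_ALPHABET if alphabet == "nucleotide" else PROTEIN_ALPHABET
    bad = set(seq) - allowed
    if bad:
        raise FastaParseError(
            f"record {record_id!r}: illegal {alphabet} characters {sorted(bad)}"
        )


def read_fasta(path: str | Path, alphabet: str = "nucleotide"):
    """Read a FASTA file into TranscriptRecords or ProteinRecords.

    Sequences are uppercased and whitespace-stripped; record order is
    preserved. Illegal characters for the declared alphabet raise
    :class:`FastaParseError` naming the offending record.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"alphabet must be nucleotide or protein, got {alphabet!r}")
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).replace(" ", "").upper()
        _validate(rec.id, seq, alphabet)
        if alphabet == "nucleotide":
            records.append(TranscriptRecord(id=rec.id, seq=seq))
        else:
            records.append(ProteinRecord(id=rec.id, seq=seq))
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _translate(nt: str) -> str:
    """Standard-table translation; trailing partial codon dropped; ambiguous
    codons (containing N) become X; stop codons become ``*``."""
    out = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if codon in _CODON_TABLE:
            out.append(_CODON_TABLE[codon])
        elif codon in _STOP_CODONS:
            out.append(STOP)
        else:
            out.append("X")
    return "".join(out)


def translate_frame(t: TranscriptRecord, frame: int) -> ProteinRecord:
    """Translate one of the six reading frames.

    Negative frames translate the reverse complement. The result is a raw
    frame translation and may contain the stop sentinel ``*``.
    """
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValueError(f"frame must be in +-1..3, got {frame}")
    nt = t.seq if frame > 0 else revcomp(t.seq)
    offset = abs(frame) - 1
    return ProteinRecord(
        id=f"{t.id}|frame{frame:+d}",
        seq=_translate(nt[offset:]),
        source_id=t.id,
        frame=frame,
    )


def find_orfs(
    t: TranscriptRecord,
    min_len_aa: int = 50,
    require_start: bool = True,
) -> list[ProteinRecord]:
    """All maximal ORFs in all six frames with translated length >= min_len_aa.

    With ``require_start`` (the default, matching common ORF-finder
    behaviour) an ORF runs from the first ATG after the previous in-frame
    stop to the next in-frame stop; nested shorter ORFs are suppressed.
    With ``require_start=False`` stop-to-stop open reading is reported
    instead (for partial precursors). Only ORFs terminated by a stop codon
    are reported. ``cds_span`` excludes the stop codon, so the span always
    translates exactly to ``seq``. Output order is deterministic: by
    forward-strand start, then frame.
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    L = len(t.seq)
    found = []
    for frame in (1, 2, 3, -1, -2, -3):
        nt = t.seq if frame > 0 else revcomp(t.seq)
        offset = abs(frame) - 1
        aa = _translate(nt[offset:])
        seg_start = 0  # index in aa of first residue after previous stop
        for i, ch in enumerate(aa):
            if ch != STOP:
                continue
            segment = aa[seg_start:i]
            start_in_seg: Optional[int] = None
            if require_start:
                m = segment.find("M")
                if m >= 0:
                    start_in_seg = m
            elif segment:
                start_in_seg = 0
            if start_in_seg is not None:
                orf_aa = segment[start_in_seg:]
                if len(orf_aa) >= min_len_aa:
                    aa_start = seg_start + start_in_seg
                    # nucleotide coords on the translated strand (0-based)
                    nt_start = offset + 3 * aa_start
                    nt_end = offset + 3 * i - 1  # last coding base, excl. stop
                    if frame > 0:
                        span = (nt_start + 1, nt_end + 1)
                    else:
                        span = (L - nt_end, L - nt_start)
                    found.append(
                        ProteinRecord(
                            id="",
                            seq=orf_aa,
                            source_id=t.id,
                            frame=frame,
                            cds_span=span,
                        )
                    )
            seg_start = i + 1
    found.sort(key=lambda r: (r.cds_span[0], r.frame))
    for n, rec in enumerate(found, start=1):
        rec.id = f"{t.id}|orf{n}"
    return found


def orf_table(orfs: Iterable[ProteinRecord]):
    """ORF report rows: id, source_id, frame, start, end, length_aa."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "id": o.id,
                "source_id": o.source_id,
                "frame": o.frame,
                "start": o.cds_span[0] if o.cds_span else None,
                "end": o.cds_span[1] if o.cds_span else None,
                "length_aa": o.length,
            }
            for o in orfs
        ],
        columns=["id", "source_id", "frame", "start", "end", "length_aa"],
    )
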