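"""Candidate GPCR vetting: length filter, 7-TM detection, family assignment.

A G protein-coupled receptor crosses the membrane seven times; its 7-TM
domain (first to last helix) is the diagnostic, alignable core. Candidates
are vetted in three stages:

1. proteins shorter than 150 aa are deemed too short for reliable vetting;
2. transmembrane helices are called from a Kyte-Doolittle hydropathy
   profile (windowed mean, default window 19, threshold 1.6 -- the classic
   criterion for a membrane-spanning segment) and only candidates whose
   helix count falls in the acceptance band (default exactly 7) pass;
3. the extracted 7-TM domains are placed by global-alignment distance to a
   labelled reference panel (rhodopsin-like A family vs secretin-like B
   family) and, for n >= 3, summarised as a neighbor-joining tree.

Supra-threshold runs of the smoothed profile are narrower than the
underlying helix (the window averages in flanking loop residues), so runs
are widened to the window length before the helix-length bounds are
enforced; this mirrors how a hydropathy plot is read by eye.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .precursor import KYTE_DOOLITTLE
from .seq_io import ProteinRecord

MIN_GPCR_LEN = 150


@dataclass
class HydropathyProfile:
    values: np.ndarray  # one score per residue; edges use shrunken windows
    window: int
    scale: str = "kyte-doolittle"


@dataclass
class TmSegment:
    span: tuple[int, int]  # 1-based inclusive
    mean_score: float


@dataclass
class TmConfig:
    window: int = 19
    threshold: float = 1.6
    min_tm_len: int = 15
    max_tm_len: int = 30
    min_loop_len: int = 5
    min_run_len: int = 5  # raw supra-threshold runs shorter than this are noise
    acceptance_band: tuple[int, ...] = (7,)


@dataclass
class GpcrCandidate:
    protein_id: str
    length: int
    tm_segments: list[TmSegment]
    passes_7tm: bool
    domain_7tm: str
    family: str = "unassigned"
    nearest_ref: Optional[str] = None
    nearest_distance: Optional[float] = None
    margin: Optional[float] = None


def filter_by_length(
    proteins: Sequence[ProteinRecord], min_len: int = MIN_GPCR_LEN
) -> tuple[list[ProteinRecord], list[ProteinRecord]]:
    """Partition into (retained, rejected); retained iff length >= min_len."""
    retained = [p for p in proteins if p.length >= min_len]
    rejected = [p for p in proteins if p.length < min_len]
    return retained, rejected


def hydropathy_profile(p: ProteinRecord, window: int = 19) -> HydropathyProfile:
    """Centered moving-average Kyte-Doolittle profile (X scores 0)."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > p.length:
        raise ValueError(f"window {window} exceeds protein length {p.length}")
    raw = pd.Series([KYTE_DOOLITTLE.get(a, 0.0) for a in p.seq])
    values = raw.rolling(window, center=True, min_periods=1).mean().to_numpy()
    return HydropathyProfile(values=values, window=window)


def predict_tm_segments(
    h: HydropathyProfile, cfg: TmConfig | None = None
) -> list[TmSegment]:
    """Call transmembrane helices from a hydropathy profile.

    Maximal runs above threshold (>= min_run_len) are widened to the
    profile window, merged when separated by less than min_loop_len, split
    when longer than max_tm_len, and finally length-bounded to
    [min_tm_len, max_tm_len].
    """
    cfg = cfg or TmConfig()
    above = h.values > cfg.threshold
    n = len(above)
    runs = []
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        if j - i >= cfg.min_run_len:
            runs.append([i, j - 1])  # 0-based inclusive
        i = j
    # widen each run to at least the window length (centered, clipped)
    for r in runs:
        width = r[1] - r[0] + 1
        if width < h.window:
            pad = h.window - width
            r[0] = max(0, r[0] - pad // 2)
            r[1] = min(n - 1, r[1] + (pad - pad // 2))
    # merge runs separated by short gaps
    merged = []
    for r in runs:
        if merged and r[0] - merged[-1][1] - 1 < cfg.min_loop_len:
            merged[-1][1] = max(merged[-1][1], r[1])
        else:
            merged.append(r)
    # split over-long runs, drop under-length remnants
    segments: list[TmSegment] = []
    for r in merged:
        width = r[1] - r[0] + 1
        if width > cfg.max_tm_len:
            parts = int(np.ceil(width / cfg.max_tm_len))
            bounds = np.linspace(r[0], r[1] + 1, parts + 1).astype(int)
            pieces = [(bounds[k], bounds[k + 1] - 1) for k in range(parts)]
        else:
            pieces = [(r[0], r[1])]
        for a, b in pieces:
            if b - a + 1 >= cfg.min_tm_len:
                segments.append(
                    TmSegment(
                        span=(a + 1, b + 1),
                        mean_score=float(np.mean(h.values[a : b + 1])),
                    )
                )
    return segments


def extract_7tm_domain(p: ProteinRecord, segments: Sequence[TmSegment]) -> str:
    """Substring from the first TM start to the last TM end."""
    if not segments:
        raise ValueError(f"{p.id}: no TM segments, cannot extract a domain")
    return p.seq[segments[0].span[0] - 1 : segments[-1].span[1]]


def triage(p: ProteinRecord, cfg: TmConfig | None = None) -> GpcrCandidate:
    """Profile, call helices, and apply the 7-TM acceptance band."""
    cfg = cfg or TmConfig()
    prof = hydropathy_profile(p, cfg.window)
    segs = predict_tm_segments(prof, cfg)
    return GpcrCandidate(
        protein_id=p.id,
        length=p.length,
        tm_segments=segs,
        passes_7tm=len(segs) in cfg.acceptance_band,
        domain_7tm=extract_7tm_domain(p, segs) if segs else "",
    )


# ---------------------------------------------------------------------------
# alignment distances and trees

# fixed scoring so distances are bit-reproducible: BLOSUM62, gap open -10
# (charged on the first gap residue), gap extend -0.5
_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.substitution_matrix = substitution_matrices.load("BLOSUM62")
_ALIGNER.open_gap_score = -10.0
_ALIGNER.extend_gap_score = -0.5


def pairwise_distance(a: str, b: str) -> float:
    """1 - identities/alignment_length from a global alignment; symmetric."""
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    if a == b:
        return 0.0
    x, y = sorted((a, b))  # symmetry by canonical argument order
    aln = _ALIGNER.align(x, y)[0]
    identities = aln.counts().identities
    return 1.0 - identities / aln.length


def distance_matrix(labelled_domains: dict[str, str]) -> DistanceMatrix:
    """All-pairs alignment distances; labels sorted for determinism."""
    labels = sorted(labelled_domains)
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_distance(labelled_domains[labels[i]], labelled_domains[labels[j]])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=labels)


def nj_tree(d: DistanceMatrix):
    """Neighbor joining with negative branch lengths clamped to zero.

    Labels are taken in sorted order so tie-breaking is deterministic.
    Requires n >= 3.
    """
    if len(d.ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    order = sorted(d.ids)
    d = d.filter(order)
    return _skbio_nj(d, neg_as_zero=True)


def assign_family(
    c: GpcrCandidate, refs: Sequence[tuple[str, str, str]]
) -> GpcrCandidate:
    """Assign A/B family by the nearest labelled reference domain.

    ``refs`` holds (id, family_label, domain) triples. An exact tie between
    the nearest references of two different families leaves the candidate
    unassigned, with both contenders surfaced in the margin report.
    """
    if not refs or not c.domain_7tm:
        c.family = "unassigned"
        return c
    dists = sorted(
        ((pairwise_distance(c.domain_7tm, dom), rid, fam) for rid, fam, dom in refs),
        key=lambda t: (t[0], t[1]),
    )
    best_d, best_id, best_fam = dists[0]
    other = next((t for t in dists if t[2] != best_fam), None)
    if other is not None and abs(other[0] - best_d) < 1e-12:
        c.family = "unassigned"
        c.nearest_ref = f"{best_id}|{other[1]}"
        c.nearest_distance = best_d
        c.margin = 0.0
        return c
    c.family = best_fam
    c.nearest_ref = best_id
    c.nearest_distance = best_d
    c.margin = (other[0] - best_d) if other is not None else None
    return c


def parse_reference_fasta(records: Iterable[ProteinRecord]) -> list[tuple[str, str, str]]:
    """Reference panel from headers of the form ``id|A|annotation``."""
    refs = []
    for r in records:
        parts = r.id.split("|")
        if len(parts) < 2 or parts[1] not in ("A", "B"):
            raise ValueError(
                f"reference header {r.id!r} must look like 'id|A|annotation'"
            )
        refs.append((parts[0], parts[1], r.seq))
    return refs


def candidate_report(cands: Sequence[GpcrCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": c.protein_id,
                "length": c.length,
                "n_tm": len(c.tm_segments),
                "passes_7tm": c.passes_7tm,
                "family": c.family,
                "nearest_ref": c.nearest_ref,
                "distance": c.nearest_distance,
                "margin": c.margin,
            }
            for c in cands
        ],
        columns=[
            "id", "length", "n_tm", "passes_7tm", "family",
            "nearest_ref", "distance", "margin",
        ],
    )
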