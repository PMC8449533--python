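"""Ground-truthed synthetic precursors, transcripts and GPCR-like proteins.

The generator emulates the architecture of secretory neuropeptide
precursors: an N-terminal signal peptide (19-35 aa), an optional
precursor-related peptide, and 1-35 mature-peptide payloads separated by
mono-/di-/tri-basic convertase sites, with amide-donor glycines and
N-terminal glutamines where a family's PTMs call for them. GPCR-like
proteins are built as alternating hydrophobic membrane blocks and polar
loops. Every product carries a complete truth record, and in clean mode
(noise 0) the pipeline's stages reproduce that truth exactly.

Clean-mode payloads never contain K or R (which would create spurious
convertase sites); random filler payloads additionally avoid strongly
hydrophobic residues so the signal-peptide stage stays unambiguous.
Generated signal peptides are canonical by construction -- "MK", a poly-L
hydrophobic core, and an "LSSA" cap whose small -3/-1 residues pin the
heuristic's cleavage call to the planted position.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .seq_io import ProteinRecord, TranscriptRecord, write_fasta

# payload alphabet for clean mode: no K/R (sites), no G (amide donor), no C
CLEAN_ALPHABET = "ADEFHILMNPQSTVWY"
# filler alphabet for random payloads: additionally no hydrophobic-core letters
POLAR_FILLER = "ADENPQSTY"

SITE_RUNS = {"KR": "KR", "RR": "RR", "KK": "KK", "RK": "RK",
             "KKR": "KKR", "RKR": "RKR", "K": "K", "R": "R"}

# unprocessed (amide-donor G retained) clean payloads, keyed by family
FAMILY_PAYLOADS = {
    "AST-A": "AGPYSFGLG",
    "AST-B": "AWSSSSGAWG",
    "kinin": "QAFSAWAG",
    "GSEFLamide": "AGSEFLG",
    "CCHamide": "ACSSYGHSCAGAHG",
    "vasopressin": "CFITNCPPGG",
}

_HYDROPHOBIC = "LIVFA"
_POLAR_LOOP = "DENQSTGKR"

_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_BY_AA:
    _CODONS_BY_AA[aa].sort()
_STOPS = sorted(standard_dna_table.stop_codons)


@dataclass
class PrecursorSpec:
    """Blueprint for one synthetic precursor.

    ``copies`` lists (payload, site_kind) pairs; a payload may be a family
    name from :data:`FAMILY_PAYLOADS` or an explicit unprocessed fragment
    string (amide-donor G included where amidation is intended). Site kinds
    follow the convertase run they plant ("KR", "RKR", ...); monobasic
    kinds are only valid after the final copy (near-terminal cleavage).
    """

    copies: list[tuple[str, Optional[str]]]
    signal_len: Optional[int] = 25
    cprp_len: int = 0
    tail: Optional[str] = None  # C-terminal fragment after the final site
    seed: int = 0


@dataclass
class SyntheticTruth:
    protein: str
    signal_span: Optional[tuple[int, int]]
    sites: list[tuple[int, str]]  # (1-based start of run, run string)
    matures: list[str]  # rendered, in precursor order (CPRP excluded)
    families: list[Optional[str]]
    cprp_span: Optional[tuple[int, int]] = None
    transcript: Optional[str] = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "protein": self.protein,
            "signal_span": self.signal_span,
            "sites": self.sites,
            "matures": self.matures,
            "families": self.families,
            "cprp_span": self.cprp_span,
            "transcript": self.transcript,
            "seed": self.seed,
        }


def _render_truth(payload: str) -> str:
    """Expected rendering of an unprocessed payload (analytic, not via the
    annotator, so truth stays independent of the code under test)."""
    seq = payload.rstrip("KR")
    amide = seq.endswith("G") and len(seq) > 1
    if amide:
        seq = seq[:-1]
    pyro = seq.startswith("Q")
    return ("p" + seq if pyro else seq) + ("amide" if amide else "")


def make_signal(rng: np.random.Generator, length: int) -> str:
    """A canonical signal peptide of the requested length (19-35 aa)."""
    if not 19 <= length <= 35:
        raise ValueError("signal length must be in [19, 35]")
    return "MK" + "L" * (length - 6) + "LSSA"


def generate_precursor(spec: PrecursorSpec, noise: float = 0.0) -> SyntheticTruth:
    """Assemble a precursor protein and its complete truth record."""
    if not spec.copies:
        raise ValueError("a precursor needs at least one payload copy")
    rng = np.random.default_rng(spec.seed)
    parts: list[str] = []
    sites: list[tuple[int, str]] = []
    matures: list[str] = []
    families: list[Optional[str]] = []
    pos = 0

    if spec.signal_len is not None:
        sig = make_signal(rng, spec.signal_len)
        parts.append(sig)
        signal_span = (1, len(sig))
        pos = len(sig)
    else:
        parts.append("M")
        signal_span = None
        pos = 1

    cprp_span = None
    if spec.cprp_len > 0:
        cprp = "".join(rng.choice(list(POLAR_FILLER), size=spec.cprp_len))
        parts.append(cprp)
        cprp_span = (pos + 1, pos + len(cprp))
        pos += len(cprp)
        parts.append("KR")
        sites.append((pos + 1, "KR"))
        pos += 2

    n = len(spec.copies)
    for k, (payload, site_kind) in enumerate(spec.copies):
        family = payload if payload in FAMILY_PAYLOADS else None
        frag = FAMILY_PAYLOADS.get(payload, payload)
        if noise == 0.0 and ("K" in frag or "R" in frag):
            raise ValueError(
                f"clean-mode payload {frag!r} contains a basic residue"
            )
        if noise > 0.0:
            frag = _mutate_payload(frag, noise, rng)
        if signal_span is None and k == 0 and spec.cprp_len == 0:
            frag_in_protein = "M" + frag  # initiator Met retained
            span = (pos, pos + len(frag))
            parts.append(frag)
            pos += len(frag)
            matures.append(_render_truth(frag_in_protein))
        else:
            parts.append(frag)
            span = (pos + 1, pos + len(frag))
            pos += len(frag)
            matures.append(_render_truth(frag))
        families.append(family)
        if site_kind is not None:
            run = SITE_RUNS[site_kind]
            if len(run) == 1 and k != n - 1:
                raise ValueError("monobasic sites are only valid after the final copy")
            parts.append(run)
            sites.append((pos + 1, run))
            pos += len(run)

    if spec.tail:
        if spec.copies[-1][1] is None:
            raise ValueError("a tail fragment requires a site after the final copy")
        if "K" in spec.tail or "R" in spec.tail:
            raise ValueError("tail fragment must not contain basic residues")
        parts.append(spec.tail)
        pos += len(spec.tail)

    return SyntheticTruth(
        protein="".join(parts),
        signal_span=signal_span,
        sites=sites,
        matures=matures,
        families=families,
        cprp_span=cprp_span,
        seed=spec.seed,
    )


def _mutate_payload(frag: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute interior residues, sparing the leading Q and donor G."""
    chars = list(frag)
    start = 1 if chars[0] == "Q" else 0
    end = len(chars) - 1 if chars[-1] == "G" else len(chars)
    for i in range(start, end):
        if rng.random() < rate:
            chars[i] = str(rng.choice(list(CLEAN_ALPHABET)))
    return "".join(chars)


def reverse_translate(protein: str, seed: int = 0) -> str:
    """A transcript whose first in-frame ATG...stop ORF encodes ``protein``.

    Codons are drawn uniformly; UTRs avoid adenine entirely so no upstream
    ATG can pre-empt the planted start. The protein must begin with M.
    """
    if not protein:
        raise ValueError("cannot reverse-translate an empty protein")
    if protein[0] != "M":
        raise ValueError("protein must start with M for an ATG-anchored ORF")
    bad = set(protein) - set(_CODONS_BY_AA)
    if bad:
        raise ValueError(f"cannot reverse-translate residues {sorted(bad)}")
    rng = np.random.default_rng(seed)
    utr_alpha = list("CGT")
    utr5 = "".join(rng.choice(utr_alpha, size=rng.integers(12, 61)))
    utr3 = "".join(rng.choice(utr_alpha, size=rng.integers(12, 61)))
    cds = "".join(str(rng.choice(_CODONS_BY_AA[aa])) for aa in protein)
    stop = str(rng.choice(_STOPS))
    return utr5 + cds + stop + utr3


def generate_gpcr_like(
    n_tm: int, seed: int = 0, noise: float = 0.0
) -> tuple[str, list[tuple[int, int]]]:
    """A membrane-protein-like sequence with ``n_tm`` hydrophobic blocks.

    Blocks are 19-23 aa from {L,I,V,F,A}; loops are >= 12 aa of polar
    residues. Returns (protein, truth TM spans, 1-based inclusive).
    Optional noise substitutes residues uniformly at the given rate.
    """
    if not 0 <= n_tm <= 10:
        raise ValueError("n_tm must be in [0, 10]")
    rng = np.random.default_rng(seed)
    parts = []
    spans = []
    pos = 0

    def loop(min_len=12, max_len=25):
        return "M" * 0 + "".join(
            rng.choice(list(_POLAR_LOOP), size=rng.integers(min_len, max_len + 1))
        )

    first = loop(20, 30) if n_tm else loop(150, 200)
    parts.append("M" + first)
    pos = 1 + len(first)
    for _ in range(n_tm):
        block = "".join(rng.choice(list(_HYDROPHOBIC), size=rng.integers(19, 24)))
        parts.append(block)
        spans.append((pos + 1, pos + len(block)))
        pos += len(block)
        lp = loop()
        parts.append(lp)
        pos += len(lp)
    protein = "".join(parts)
    if n_tm >= 5 and len(protein) < 150:  # pad the tail loop if ever short
        protein += "".join(rng.choice(list(_POLAR_LOOP), size=150 - len(protein)))
    if noise > 0.0:
        chars = list(protein)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for i in range(1, len(chars)):
            if rng.random() < noise:
                chars[i] = str(rng.choice(alphabet))
        protein = "".join(chars)
    return protein, spans


def generate_dataset(
    n_precursors: int,
    n_gpcrs: int,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[list[TranscriptRecord], dict]:
    """A mixed nucleotide dataset plus its truth manifest.

    Precursors cycle through the clean family payload menu with 1-3 copies
    each; receptors alternate between 7-TM positives and 5/6-TM negatives.
    """
    if not 0.0 <= noise <= 0.2:
        raise ValueError("noise must be in [0, 0.2]")
    rng = np.random.default_rng(seed)
    transcripts: list[TranscriptRecord] = []
    manifest: dict = {"precursors": [], "gpcrs": [], "seed": seed, "noise": noise}

    menu = sorted(FAMILY_PAYLOADS)
    for i in range(n_precursors):
        family = menu[i % len(menu)]
        n_copies = int(rng.integers(1, 4))
        copies = [(family, "KR") for _ in range(n_copies)]
        signal_len = int(rng.integers(19, 36))
        cprp_len = int(rng.integers(6, 15)) if i % 3 == 2 else 0
        # keep the precursor comfortably above the 50-aa ORF minimum
        est = signal_len + cprp_len + sum(
            len(FAMILY_PAYLOADS[f]) + 2 for f, _ in copies
        )
        tail_len = max(60 - est, 0) + int(rng.integers(5, 16))
        tail = "".join(rng.choice(list(POLAR_FILLER), size=tail_len))
        spec = PrecursorSpec(
            copies=copies,
            signal_len=signal_len,
            cprp_len=cprp_len,
            tail=tail,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        truth = generate_precursor(spec, noise=noise)
        truth.transcript = reverse_translate(
            truth.protein, seed=int(rng.integers(0, 2**31 - 1))
        )
        tid = f"syn_precursor_{i+1}"
        transcripts.append(TranscriptRecord(id=tid, seq=truth.transcript))
        entry = truth.to_dict()
        entry["id"] = tid
        manifest["precursors"].append(entry)

    for i in range(n_gpcrs):
        n_tm = 7 if i % 2 == 0 else int(rng.choice([5, 6]))
        prot, spans = generate_gpcr_like(
            n_tm, seed=int(rng.integers(0, 2**31 - 1)), noise=noise
        )
        nt = reverse_translate(prot, seed=int(rng.integers(0, 2**31 - 1)))
        tid = f"syn_gpcr_{i+1}"
        transcripts.append(TranscriptRecord(id=tid, seq=nt))
        manifest["gpcrs"].append(
            {
                "id": tid,
                "protein": prot,
                "n_tm": n_tm,
                "tm_spans": spans,
                "expected_pass_7tm": n_tm == 7,
                "transcript": nt,
            }
        )
    return transcripts, manifest


def write_dataset(
    transcripts: Sequence[TranscriptRecord], manifest: dict, outdir: str | Path
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(transcripts, outdir / "dataset.fasta")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
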