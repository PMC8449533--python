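"""Motif-based neuropeptide family classification.

Each neuropeptide family is recognised by a short signature, almost always
at the amidated C-terminus of the mature peptide (e.g. -YXFGLamide for
A-type allatostatins, -RLRFamide for short neuropeptide F). The library
below transcribes the per-family signatures reported for decapod
crustaceans, in a small explicit pattern dialect:

* an uppercase letter matches itself;
* ``X`` matches any single residue (``X`` in a peptide never satisfies a
  fixed position);
* ``[AB]`` matches any residue in the bracket;
* ``X{m,n}`` matches between m and n arbitrary residues (used only for the
  natalisin W...Ramide signature).

A motif's *specificity* is its number of position-restricted (non-``X``)
slots; classification keeps the most specific motif whose anchor and PTM
requirements (amidation, pyroglutamate) are satisfied. The
CHH/MIH/ITP superfamily has no short linear signature and is recognised
instead by its six-cysteine skeleton (a ``cys_skeleton`` motif kind).

Exemplar peptides whose family section reports a signature but no complete
peptide are synthetic instantiations of the motif and are flagged as such.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .precursor import MaturePeptide, PrecursorAnnotation

AA = "ACDEFGHIKLMNPQRSTVWY"

UNCLASSIFIED = "unclassified"


class MotifSyntaxError(ValueError):
    pass


@dataclass
class FamilyMotif:
    family: str
    pattern: str
    anchor: str  # c_terminal | n_terminal | anywhere | full_match
    requires_amide: str  # yes | no | either
    requires_pyroglu: str  # yes | no | either
    kind: str = "linear"  # linear | cys_skeleton
    provenance: str = ""
    exemplars: tuple[str, ...] = ()
    synthetic_exemplar: bool = False
    specificity: int = 0
    _regex: Optional[re.Pattern] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.kind == "linear":
            body, spec = _compile_pattern(self.pattern, self.family)
            if self.anchor == "c_terminal":
                rx = body + "$"
            elif self.anchor == "n_terminal":
                rx = "^" + body
            elif self.anchor == "full_match":
                rx = "^" + body + "$"
            elif self.anchor == "anywhere":
                rx = body
            else:
                raise MotifSyntaxError(f"{self.family}: unknown anchor {self.anchor!r}")
            self._regex = re.compile(rx)
            self.specificity = spec
        elif self.kind == "cys_skeleton":
            self.specificity = 6
        else:
            raise MotifSyntaxError(f"{self.family}: unknown motif kind {self.kind!r}")


def _compile_pattern(pattern: str, family: str) -> tuple[str, int]:
    """Translate the motif dialect to a regex; return (regex, specificity)."""
    if not pattern:
        raise MotifSyntaxError(f"{family}: empty pattern")
    out, spec, i = [], 0, 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "X":
            if i + 1 < len(pattern) and pattern[i + 1] == "{":
                j = pattern.find("}", i)
                if j < 0 or not re.fullmatch(r"X\{\d+,\d+\}", pattern[i : j + 1]):
                    raise MotifSyntaxError(f"{family}: malformed repeat in {pattern!r}")
                out.append("." + pattern[i + 1 : j + 1])
                i = j + 1
            else:
                out.append(".")
                i += 1
        elif ch == "[":
            j = pattern.find("]", i)
            inner = pattern[i + 1 : j] if j > 0 else ""
            if j < 0 or not inner or not set(inner) <= set(AA):
                raise MotifSyntaxError(f"{family}: malformed class in {pattern!r}")
            out.append(f"[{inner}]")
            spec += 1
            i = j + 1
        elif ch in AA:
            out.append(ch)
            spec += 1
            i += 1
        else:
            raise MotifSyntaxError(f"{family}: illegal character {ch!r} in {pattern!r}")
    if spec < 1:
        raise MotifSyntaxError(f"{family}: pattern has no fixed positions")
    return "".join(out), spec


# six-cysteine skeleton acceptance window (CHH-superfamily matures run ~70 aa)
CYS_SKELETON_COUNT = 6
CYS_SKELETON_SPACING = (2, 35)
CYS_SKELETON_LENGTH = (50, 90)

_CHH_EXEMPLAR = (
    "S" * 10 + "C" + "T" * 10 + "C" + "A" * 10 + "C"
    + "D" * 10 + "C" + "N" * 10 + "C" + "E" * 10 + "C" + "S" * 5
)

# family, pattern, anchor, amide, pyroglu, kind, provenance, exemplars, synthetic
_BUILTIN = [
    ("ACP", "QITFSRSWVPQ", "full_match", "yes", "yes", "linear",
     "signature pQITFSRSWVPQamide", ("pQITFSRSWVPQamide",), False),
    ("ALP", "WRSCIRRGGACDHRPNDCCYNSSCRCNLWGTNCRCQRMGIFQQW", "full_match", "yes",
     "either", "linear", "mature WRSC...QQWamide, 8 Cys",
     ("WRSCIRRGGACDHRPNDCCYNSSCRCNLWGTNCRCQRMGIFQQWamide",), False),
    ("AST-A", "XYXFGL", "c_terminal", "yes", "either", "linear",
     "signature XYXFGLamide; exemplar AGPYSFGLamide", ("AGPYSFGLamide",), False),
    ("AST-B", "XWXXXXGXW", "c_terminal", "yes", "either", "linear",
     "signature XWXXXXGXWamide; exemplar AGWSSMRGAWamide", ("AGWSSMRGAWamide",), False),
    ("AST-C", "PISCF", "c_terminal", "no", "either", "linear",
     "signature PISCF free acid; exemplar pQIRYHQCYFNPISCF", ("pQIRYHQCYFNPISCF",), False),
    ("AST-CCC", "SYWKQCAFNAVSCF", "full_match", "yes", "either", "linear",
     "signature SYWKQCAFNAVSCFamide", ("SYWKQCAFNAVSCFamide",), False),
    ("CCAP", "PFCNAFTGC", "full_match", "yes", "either", "linear",
     "signature PFCNAFTGCamide, one disulfide", ("PFCNAFTGCamide",), False),
    ("CCHamide", "XCXX[YF]GHSCXGAH", "c_terminal", "yes", "either", "linear",
     "signature XCXXY/FGHSCXGAHamide, one disulfide", ("ACSSYGHSCAGAHamide",), True),
    ("CHH", "CX6", "anywhere", "either", "either", "cys_skeleton",
     "CHH/MIH/ITP superfamily six-cysteine skeleton", (_CHH_EXEMPLAR,), True),
    ("CNMamide", "VMCHFKICNM", "full_match", "yes", "either", "linear",
     "signature VMCHFKICNMamide, one disulfide", ("VMCHFKICNMamide",), False),
    ("corazonin", "QTFQYSRGWTN", "full_match", "yes", "yes", "linear",
     "signature pQTFQYSRGWTNamide", ("pQTFQYSRGWTNamide",), False),
    ("CRF-like DH44", "NSGLSLSIDASMKVLREALYLEIARKKQRQQLQRAQHNKALLNTI", "full_match",
     "yes", "either", "linear", "45 aa mature NSGLS...LNTIamide",
     ("NSGLSLSIDASMKVLREALYLEIARKKQRQQLQRAQHNKALLNTIamide",), False),
    ("elevenin", "XXXXDCR[KR]FVFAPXCRGIIA", "c_terminal", "no", "either", "linear",
     "signature XXXXDCR-K/R-FVFAPXCRGIIA, one disulfide", ("SSSSDCRKFVFAPSCRGIIA",), True),
    ("ETH", "DAGHFFAETPKHLPRI", "full_match", "yes", "either", "linear",
     "carcikinin/ETH signature DAGHFFAETPKHLPRIamide", ("DAGHFFAETPKHLPRIamide",), False),
    ("GSEFLamide", "XGSEFL", "c_terminal", "yes", "either", "linear",
     "signature XGSEFLamide", ("AGSEFLamide",), True),
    ("HIGSLYRamide", "H[IL]GSL[LY]R", "c_terminal", "yes", "either", "linear",
     "signature H-I/L-GSL-L/Y-Ramide", ("HIGSLYRamide",), True),
    ("kinin", "X[FL][NS]XWA", "c_terminal", "yes", "either", "linear",
     "signature X-F/L-N/S-X-WAamide; exemplars QAFSAWAamide, QALNVWAamide",
     ("QAFSAWAamide", "QALNVWAamide", "SGDSKHGRFSAWAamide"), False),
    ("myosuppressin", "QDLDHVFLRF", "full_match", "yes", "yes", "linear",
     "signature pQDLDHVFLRFamide", ("pQDLDHVFLRFamide",), False),
    ("natalisin", "WX{2,13}R", "c_terminal", "yes", "either", "linear",
     "signature WXXX(n)Ramide", ("WSSSGRamide",), True),
    ("NPF", "RPRF", "c_terminal", "yes", "either", "linear",
     "signature RPRFamide", ("SSRPRFamide",), True),
    ("orcokinin", "NFDEIDRSXFGFX", "c_terminal", "no", "either", "linear",
     "signature NFDEIDRSXFGFX free acid", ("NFDEIDRSSFGFN",), True),
    ("proctolin", "RYLPT", "full_match", "no", "either", "linear",
     "signature RYLPT free acid", ("RYLPT",), False),
    ("pyrokinin", "F[AS]PR[PL]", "c_terminal", "yes", "either", "linear",
     "signature F-A/S-PR-P/Lamide (FXPRLamide); exemplars FAPRPamide, FSPRLamide",
     ("FAPRPamide", "FSPRLamide"), False),
    ("RPCH", "QLNFSPGW", "full_match", "yes", "yes", "linear",
     "signature pQLNFSPGWamide", ("pQLNFSPGWamide",), False),
    ("RYamide", "FYSQRY", "full_match", "yes", "either", "linear",
     "signature FYSQRYamide", ("FYSQRYamide",), False),
    ("SIFamide", "GYRKPPFNGSIF", "full_match", "yes", "either", "linear",
     "signature GYRKPPFNGSIFamide", ("GYRKPPFNGSIFamide",), False),
    ("sNPF", "PXXRLRF", "c_terminal", "yes", "either", "linear",
     "signature PXXRLRFamide; exemplars APPSMRLRFamide, KDARTPALRLRFamide",
     ("APPSMRLRFamide", "KDARTPALRLRFamide"), False),
    ("sulfakinin", "DYGH[ML]RF", "c_terminal", "yes", "either", "linear",
     "signature DYGH-M/L-RFamide; exemplars EFDDYGHMRFamide, GSASDDYQDDYGHLRFamide",
     ("EFDDYGHMRFamide", "GSASDDYQDDYGHLRFamide"), False),
    ("tachykinin", "XPSGFLGMR", "c_terminal", "yes", "either", "linear",
     "signature XPSGFLGMRamide", ("APSGFLGMRamide",), True),
    ("trissin", "STVSCDSCGPECQTACGTKNFRACCFNFL", "full_match", "no", "either",
     "linear", "29 aa mature, 6 Cys, three disulfides",
     ("STVSCDSCGPECQTACGTKNFRACCFNFL",), False),
    ("vasopressin", "CFITNCPPG", "full_match", "yes", "either", "linear",
     "signature CFITNCPPGamide, one disulfide", ("CFITNCPPGamide",), False),
]


def compile_motif_library(user_tsv: str | Path | None = None) -> list[FamilyMotif]:
    """The built-in family library, optionally extended from a user TSV.

    The TSV must carry columns family, pattern, anchor, requires_amide,
    requires_pyroglu (kind and provenance optional). Duplicate family names
    raise ValueError.
    """
    lib = [
        FamilyMotif(
            family=f, pattern=p, anchor=a, requires_amide=am, requires_pyroglu=pg,
            kind=k, provenance=prov, exemplars=ex, synthetic_exemplar=syn,
        )
        for f, p, a, am, pg, k, prov, ex, syn in _BUILTIN
    ]
    if user_tsv is not None:
        df = pd.read_csv(user_tsv, sep="\t")
        for _, row in df.iterrows():
            lib.append(
                FamilyMotif(
                    family=str(row["family"]),
                    pattern=str(row["pattern"]),
                    anchor=str(row["anchor"]),
                    requires_amide=str(row["requires_amide"]),
                    requires_pyroglu=str(row["requires_pyroglu"]),
                    kind=str(row.get("kind", "linear") or "linear"),
                    provenance=str(row.get("provenance", "") or ""),
                )
            )
    names = [m.family for m in lib]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ValueError(f"duplicate family names in motif library: {sorted(dupes)}")
    return lib


def library_tsv(lib: Sequence[FamilyMotif], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "family": m.family, "pattern": m.pattern, "anchor": m.anchor,
                "requires_amide": m.requires_amide,
                "requires_pyroglu": m.requires_pyroglu,
                "kind": m.kind, "specificity": m.specificity,
                "provenance": m.provenance,
            }
            for m in lib
        ]
    ).to_csv(path, sep="\t", index=False)


@dataclass
class FamilyAssignment:
    peptide_ref: str
    family: str
    score: int
    matched_span: Optional[tuple[int, int]]
    competing: list[str] = field(default_factory=list)


def _ptm_ok(requirement: str, flag: bool) -> bool:
    return requirement == "either" or (requirement == "yes") == flag


def _match_motif(motif: FamilyMotif, m: MaturePeptide) -> Optional[tuple[int, int]]:
    if not _ptm_ok(motif.requires_amide, m.amidated):
        return None
    if not _ptm_ok(motif.requires_pyroglu, m.pyroglu):
        return None
    if motif.kind == "cys_skeleton":
        if m.seq.count("C") != CYS_SKELETON_COUNT:
            return None
        if not CYS_SKELETON_LENGTH[0] <= len(m.seq) <= CYS_SKELETON_LENGTH[1]:
            return None
        cys = [i for i, a in enumerate(m.seq) if a == "C"]
        gaps = [b - a for a, b in zip(cys, cys[1:])]
        lo, hi = CYS_SKELETON_SPACING
        if any(g < lo or g > hi for g in gaps):
            return None
        return (1, len(m.seq))
    # fixed positions compile to literals/classes over the 20-letter alphabet,
    # so an unknown residue X can only ever occupy a wildcard slot
    hit = motif._regex.search(m.seq)
    if hit is None:
        return None
    return (hit.start() + 1, hit.end())


def classify_peptide(
    m: MaturePeptide, lib: Sequence[FamilyMotif], peptide_ref: str = ""
) -> FamilyAssignment:
    """Assign one mature peptide to the best-matching family.

    All motifs are tested under their anchor and PTM constraints; the
    winner has the highest specificity, ties broken by longer matched span
    then lexical family order. No match yields "unclassified".
    """
    hits = []
    for motif in lib:
        span = _match_motif(motif, m)
        if span is not None:
            hits.append((motif, span))
    if not hits:
        return FamilyAssignment(peptide_ref, UNCLASSIFIED, 0, None)
    hits.sort(key=lambda h: (-h[0].specificity, -(h[1][1] - h[1][0]), h[0].family))
    winner, span = hits[0]
    return FamilyAssignment(
        peptide_ref=peptide_ref,
        family=winner.family,
        score=winner.specificity,
        matched_span=span,
        competing=[h[0].family for h in hits[1:]],
    )


def classify_all(
    annotations: Iterable[PrecursorAnnotation], lib: Sequence[FamilyMotif]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assignment table (one row per mature peptide) and per-family tally.

    The tally counts distinct precursors and total peptides per family.
    """
    rows = []
    for ann in annotations:
        for k, m in enumerate(ann.matures, start=1):
            ref = f"{ann.protein_id}#{k}"
            asg = classify_peptide(m, lib, peptide_ref=ref)
            rows.append(
                {
                    "precursor_id": ann.protein_id,
                    "peptide_ref": ref,
                    "rendered": m.rendered,
                    "family": asg.family,
                    "score": asg.score,
                    "competing": ";".join(asg.competing),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["precursor_id", "peptide_ref", "rendered", "family", "score", "competing"],
    )
    if table.empty:
        tally = pd.DataFrame(columns=["family", "n_precursors", "n_peptides"])
    else:
        grp = table[table["family"] != UNCLASSIFIED].groupby("family")
        tally = grp.agg(
            n_precursors=("precursor_id", "nunique"), n_peptides=("peptide_ref", "count")
        ).reset_index()
    return table, tally
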