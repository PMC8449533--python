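"""Prohormone precursor annotation.

A secreted neuropeptide precursor is processed in vivo in three steps that
this module models explicitly:

1. the N-terminal signal peptide (15-40 aa) is removed by signal peptidase;
2. prohormone convertases cleave at basic-residue sites -- dibasic pairs
   (KR, RR, KK, RK), tribasic runs (KKR, RKR), and, in restricted contexts,
   single K/R residues -- and carboxypeptidases remove the exposed basics;
3. the liberated fragments are post-translationally modified: a C-terminal
   glycine is consumed to amidate the preceding residue, and an N-terminal
   glutamine (optionally glutamate) cyclizes to pyroglutamate.

The signal-peptide stage is a self-contained three-region heuristic
(charged n-region, hydrophobic h-region, small-residue -3/-1 cleavage
context); externally computed spans can be supplied per record id and are
returned verbatim.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

from .seq_io import ProteinRecord

BASIC = set("KR")
# Kyte-Doolittle hydropathy, shared with the GPCR triage stage.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}
_SMALL = set("AGSCT")  # permitted at the -3 and -1 cleavage positions


class ContractViolation(ValueError):
    """Raised when inputs violate a documented operation contract."""


class RenderingParseError(ValueError):
    """Raised for strings that do not follow the pQ/pE/amide convention."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SignalPeptidePrediction:
    """Signal-peptide call anchored at residue 1 (``span`` absent if none)."""

    span: Optional[tuple[int, int]]
    score: float
    method: str = "heuristic"  # or "external"


@dataclass
class CleavageSite:
    """A convertase site labelled by the 1-based position of its first basic
    residue; the scissile bond lies after ``cut_after``."""

    start: int
    basic_run: str
    kind: str  # monobasic | dibasic | tribasic

    @property
    def cut_after(self) -> int:
        return self.start + len(self.basic_run) - 1


@dataclass
class PeptideFragment:
    span: tuple[int, int]
    seq: str
    role: str = "candidate_mature"  # CPRP | candidate_mature | neurophysin_like | unassigned


@dataclass
class MaturePeptide:
    """A processed peptide with its PTM flags and display rendering."""

    seq: str
    amidated: bool
    pyroglu: bool
    source_span: tuple[int, int]
    cys_count: int
    rendered: str
    bridges: Optional[list[tuple[int, int]]] = None


@dataclass
class PrecursorAnnotation:
    protein_id: str
    signal: SignalPeptidePrediction
    sites: list[CleavageSite]
    fragments: list[PeptideFragment]
    matures: list[MaturePeptide]
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SignalConfig:
    min_len: int = 15
    max_len: int = 40
    h_window: int = 8
    # h-region hydropathy saturates at this mean so that any canonically
    # hydrophobic core scores alike and the cleavage context decides the cut
    h_saturation: float = 3.5
    threshold: float = 0.6
    external: Optional[dict[str, tuple[int, int]]] = None


@dataclass
class CleavageRules:
    dibasic: frozenset[str] = frozenset({"KR", "RR", "KK", "RK"})
    tribasic: frozenset[str] = frozenset({"KKR", "RKR"})
    interior_monobasic: frozenset[str] = frozenset()  # e.g. {"R"} to enable
    terminal_monobasic: bool = True
    terminal_window: int = 4  # monobasic K/R accepted within this many residues of the C-terminus


@dataclass
class PtmRules:
    amidation: bool = True
    pyroglu_from_q: bool = True
    pyroglu_from_e: bool = False
    strip_trailing_basics: bool = True


# ---------------------------------------------------------------------------
# signal peptide


def _signal_component_scores(seq: str, cut: int, cfg: SignalConfig):
    """(n, h, c) component scores for a candidate cleavage after ``cut``."""
    n_score = 1.0 if BASIC & set(seq[1:6]) else 0.4
    lo, hi = 2, cut - 3  # 0-based window bounds for the h-region search
    best = -5.0
    for s in range(lo, max(lo, hi - cfg.h_window + 1) + 1):
        w = seq[s : s + cfg.h_window]
        if len(w) < cfg.h_window:
            break
        best = max(best, sum(KYTE_DOOLITTLE[a] for a in w) / cfg.h_window)
    h_score = min(max(best / cfg.h_saturation, 0.0), 1.0)
    c_score = (0.5 if seq[cut - 1] in _SMALL else 0.0) + (
        0.5 if seq[cut - 3] in _SMALL else 0.0
    )
    return n_score, h_score, c_score


def signal_score(seq: str, cut: int, cfg: SignalConfig) -> float:
    """Combined three-region score in [0,1] for a cleavage after ``cut``."""
    n, h, c = _signal_component_scores(seq, cut, cfg)
    return 0.2 * n + 0.5 * h + 0.3 * c


def predict_signal_peptide(
    p: ProteinRecord, cfg: SignalConfig | None = None
) -> SignalPeptidePrediction:
    """Heuristic signal-peptide call, or an external span returned verbatim.

    The heuristic scans candidate signal lengths in [min_len, max_len],
    scores each with the three-region model, and keeps the best-scoring
    length (ties resolved toward the shortest). Proteins shorter than 30 aa
    (heuristic mode) yield an absent prediction with score 0.
    """
    cfg = cfg or SignalConfig()
    if cfg.external and p.id in cfg.external:
        span = cfg.external[p.id]
        return SignalPeptidePrediction(span=tuple(span), score=1.0, method="external")
    if p.length < 30:
        return SignalPeptidePrediction(span=None, score=0.0)
    best_cut, best_score = None, -1.0
    hi = min(cfg.max_len, p.length - 10)
    for cut in range(cfg.min_len, hi + 1):
        s = signal_score(p.seq, cut, cfg)
        if s > best_score + 1e-12:
            best_cut, best_score = cut, s
    if best_score >= cfg.threshold:
        return SignalPeptidePrediction(span=(1, best_cut), score=round(best_score, 4))
    return SignalPeptidePrediction(span=None, score=round(max(best_score, 0.0), 4))


# ---------------------------------------------------------------------------
# cleavage sites


def find_cleavage_sites(
    p: ProteinRecord,
    rules: CleavageRules | None = None,
    signal: SignalPeptidePrediction | None = None,
) -> list[CleavageSite]:
    """Scan for convertase sites over maximal basic (K/R) runs.

    Within each maximal run, enabled patterns are matched greedily left to
    right, longest first (tribasic > dibasic > monobasic); unmatched basics
    are left to the flanking fragments. Runs lying entirely inside the
    signal span are excluded.
    """
    rules = rules or CleavageRules()
    seq = p.seq
    sig_end = signal.span[1] if signal is not None and signal.span else 0
    sites: list[CleavageSite] = []
    for m in re.finditer(r"[KR]+", seq):
        run_start = m.start() + 1  # 1-based
        run = m.group()
        if run_start + len(run) - 1 <= sig_end:
            continue
        i = 0
        while i < len(run):
            pos = run_start + i
            if pos <= sig_end:  # run straddles the signal boundary
                i += 1
                continue
            chunk3 = run[i : i + 3]
            chunk2 = run[i : i + 2]
            if len(chunk3) == 3 and chunk3 in rules.tribasic:
                sites.append(CleavageSite(pos, chunk3, "tribasic"))
                i += 3
            elif len(chunk2) == 2 and chunk2 in rules.dibasic:
                sites.append(CleavageSite(pos, chunk2, "dibasic"))
                i += 2
            else:
                mono = run[i]
                near_terminal = pos > len(seq) - rules.terminal_window
                if mono in rules.interior_monobasic or (
                    rules.terminal_monobasic and near_terminal
                ):
                    sites.append(CleavageSite(pos, mono, "monobasic"))
                i += 1
    return sites


# ---------------------------------------------------------------------------
# fragment excision


def excise_fragments(
    p: ProteinRecord,
    signal: SignalPeptidePrediction | None,
    sites: Sequence[CleavageSite],
) -> list[PeptideFragment]:
    """Maximal intervals between the signal end, basic runs, and termini.

    The signal span and every matched basic run are consumed; what remains
    tiles the precursor exactly (empty intervals dropped). Overlapping
    sites raise :class:`ContractViolation`.
    """
    covered = [False] * (p.length + 1)  # 1-based occupancy
    if signal is not None and signal.span:
        for i in range(signal.span[0], signal.span[1] + 1):
            covered[i] = True
    for s in sorted(sites, key=lambda s: s.start):
        for i in range(s.start, s.cut_after + 1):
            if covered[i]:
                raise ContractViolation(
                    f"{p.id}: cleavage site at {s.start} overlaps signal or another site"
                )
            covered[i] = True
    fragments = []
    i = 1
    while i <= p.length:
        if covered[i]:
            i += 1
            continue
        j = i
        while j <= p.length and not covered[j]:
            j += 1
        fragments.append(PeptideFragment(span=(i, j - 1), seq=p.seq[i - 1 : j - 1]))
        i = j
    return fragments


# ---------------------------------------------------------------------------
# post-translational modification


def apply_ptm(f: PeptideFragment, rules: PtmRules | None = None) -> MaturePeptide:
    """Process one excised fragment into its mature peptide.

    Trailing basics (if retained by the excision policy) are trimmed, a
    C-terminal amide-donor glycine is consumed to set the amide flag, and a
    leading Q (or E when enabled) sets the pyroglutamate flag. The
    ``rendered`` string uses the pQ/pE prefix and "amide" suffix convention.
    """
    rules = rules or PtmRules()
    if not f.seq:
        raise ContractViolation("cannot process an empty fragment")
    seq = f.seq
    if rules.strip_trailing_basics:
        seq = seq.rstrip("KR")
    amidated = False
    if rules.amidation and seq.endswith("G") and len(seq) > 1:
        seq = seq[:-1]
        amidated = True
    pyroglu = bool(seq) and (
        (rules.pyroglu_from_q and seq[0] == "Q")
        or (rules.pyroglu_from_e and seq[0] == "E")
    )
    return MaturePeptide(
        seq=seq,
        amidated=amidated,
        pyroglu=pyroglu,
        source_span=f.span,
        cys_count=seq.count("C"),
        rendered=render(seq, amidated, pyroglu),
    )


def render(seq: str, amidated: bool, pyroglu: bool) -> str:
    out = ("p" + seq[0] + seq[1:]) if pyroglu else seq
    return out + ("amide" if amidated else "")


def invert_rendering(rendered: str) -> str:
    """Exact inverse of the pQ/pE/amide display convention.

    "amide" suffix restores the donor glycine; a pQ/pE prefix restores the
    plain Q/E. Round-trips with :func:`apply_ptm` on fragments that carry
    no trailing basic residues.
    """
    s = rendered
    amide = s.endswith("amide")
    if amide:
        s = s[: -len("amide")]
    if s.startswith("pQ") or s.startswith("pE"):
        s = s[1:]
    if not s or not set(s) <= set("ACDEFGHIKLMNPQRSTVWYX"):
        raise RenderingParseError(f"not a valid rendered peptide: {rendered!r}")
    return s + ("G" if amide else "")


def count_cysteines(m: MaturePeptide) -> int:
    return m.seq.count("C")


def mature_from_rendered(rendered: str) -> MaturePeptide:
    """Rebuild a MaturePeptide from its pQ/pE/amide display string."""
    frag = invert_rendering(rendered)
    return apply_ptm(PeptideFragment(span=(1, len(frag)), seq=frag))


# ---------------------------------------------------------------------------
# disulfide bookkeeping


@dataclass
class DisulfidePlan:
    cys_count: int
    bridge_count: int
    n_matchings: Optional[int]
    matchings: Optional[list[list[tuple[int, int]]]]
    warning: Optional[str] = None


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def _enumerate_matchings(items: list[int]) -> list[list[tuple[int, int]]]:
    if not items:
        return [[]]
    first, rest = items[0], items[1:]
    out = []
    for k, partner in enumerate(rest):
        remaining = rest[:k] + rest[k + 1 :]
        for sub in _enumerate_matchings(remaining):
            out.append([(first, partner)] + sub)
    return out


def enumerate_disulfide_pairings(cys_count: int, list_limit: int = 12) -> DisulfidePlan:
    """Bridge count and the number of distinct perfect pairings.

    For an even count n there are n/2 bridges and (n-1)!! distinct perfect
    matchings (listed explicitly for n <= ``list_limit``). An odd count is
    flagged as an unpaired-cysteine condition with floor(n/2) bridges.
    """
    if cys_count < 0:
        raise ValueError("cys_count must be >= 0")
    if cys_count % 2:
        return DisulfidePlan(
            cys_count=cys_count,
            bridge_count=cys_count // 2,
            n_matchings=None,
            matchings=None,
            warning=f"odd cysteine count {cys_count}: one cysteine left unpaired",
        )
    listing = (
        _enumerate_matchings(list(range(1, cys_count + 1)))
        if cys_count <= list_limit
        else None
    )
    return DisulfidePlan(
        cys_count=cys_count,
        bridge_count=cys_count // 2,
        n_matchings=_double_factorial(cys_count - 1),
        matchings=listing,
    )


def validate_pairing(
    pairing: Sequence[tuple[int, int]], cys_count: int
) -> tuple[bool, str]:
    """True iff ``pairing`` is a perfect matching of 1..cys_count."""
    used = set()
    for a, b in pairing:
        for idx in (a, b):
            if not 1 <= idx <= cys_count:
                return False, f"cysteine index {idx} out of range 1..{cys_count}"
            if idx in used:
                return False, f"cysteine index {idx} used more than once"
            used.add(idx)
        if a == b:
            return False, f"self-pairing of cysteine {a}"
    if len(used) != cys_count:
        missing = sorted(set(range(1, cys_count + 1)) - used)
        return False, f"unpaired cysteines: {missing}"
    return True, "valid perfect matching"


# ---------------------------------------------------------------------------
# full chain


def annotate_precursor(
    p: ProteinRecord,
    signal_cfg: SignalConfig | None = None,
    cleavage_rules: CleavageRules | None = None,
    ptm_rules: PtmRules | None = None,
    cprp_rule: bool = True,
) -> PrecursorAnnotation:
    """Signal -> cleavage -> excision -> PTM for one precursor.

    Precursors with no detectable signal peptide are annotated with an
    absent signal rather than rejected. With ``cprp_rule`` the first
    post-signal fragment is relabelled CPRP when a later fragment carries a
    six-cysteine CHH-type skeleton. A precursor consisting only of basic
    residues yields zero fragments and a warning.
    """
    warnings: list[str] = []
    signal = predict_signal_peptide(p, signal_cfg)
    sites = find_cleavage_sites(p, cleavage_rules, signal)
    fragments = excise_fragments(p, signal, sites)
    if not fragments:
        warnings.append(f"{p.id}: no fragments remain after excision")
    matures = [apply_ptm(f, ptm_rules) for f in fragments]
    if cprp_rule and signal.span and len(fragments) >= 2:
        later_chh = any(
            m.cys_count == 6 and len(m.seq) >= 50 for m in matures[1:]
        )
        if later_chh and fragments[0].span[0] == signal.span[1] + 1:
            fragments[0].role = "CPRP"
    return PrecursorAnnotation(
        protein_id=p.id,
        signal=signal,
        sites=sites,
        fragments=fragments,
        matures=matures,
        warnings=warnings,
    )
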