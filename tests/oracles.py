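"""Independent oracles used by the test suite.

Each function here re-derives an expected result by a different mechanism
than the implementation under test (regex alternation instead of pointer
scans, exhaustive enumeration instead of closed forms, graph path lengths
instead of agglomeration), so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import itertools
import re

import networkx as nx
import numpy as np

STANDARD_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R", "AGT": "S",
    "AGC": "S", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
STOPS = {"TAA", "TAG", "TGA"}
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def translate(nt: str) -> str:
    out = []
    for i in range(0, len(nt) - 2, 3):
        c = nt[i : i + 3]
        out.append(STANDARD_CODONS.get(c, "*" if c in STOPS else "X"))
    return "".join(out)


def brute_force_orfs(seq: str, min_len_aa: int):
    """Every maximal ATG-to-stop ORF in six frames, as a set of
    (protein, frame, forward_start, forward_end) tuples."""
    L = len(seq)
    out = set()
    for frame in (1, 2, 3, -1, -2, -3):
        nt = seq if frame > 0 else revcomp(seq)
        off = abs(frame) - 1
        # enumerate every ATG; extend to first in-frame stop; then keep
        # only ORFs not contained in a longer ORF ending at the same stop
        hits = []
        for i in range(off, L - 2, 3):
            if nt[i : i + 3] != "ATG":
                continue
            j = i
            while j + 3 <= L and nt[j : j + 3] not in STOPS:
                j += 3
            if j + 3 > L:
                continue  # ran off the end without a stop
            hits.append((i, j))  # coding bases nt[i:j], stop at j
        by_stop = {}
        for i, j in hits:
            by_stop.setdefault(j, []).append(i)
        for j, starts in by_stop.items():
            i = min(starts)  # maximal ORF; nested ones suppressed
            aa = translate(nt[i:j])
            if len(aa) < min_len_aa:
                continue
            if frame > 0:
                span = (i + 1, j)
            else:
                span = (L - j + 1, L - i)
            out.add((aa, frame, span[0], span[1]))
    return out


def regex_scan_cleavage(seq, dibasic, tribasic, interior_mono, terminal_mono,
                        terminal_window=4, signal_end=0):
    """Cleavage sites via a single regex alternation per basic run."""
    alts = sorted(tribasic, reverse=True) + sorted(dibasic, reverse=True)
    mono_ok = set(interior_mono)
    pattern = "|".join(alts) if alts else None
    sites = []
    for run in re.finditer(r"[KR]+", seq):
        text = run.group()
        base = run.start()  # 0-based
        taken = [False] * len(text)
        if pattern:
            i = 0
            while i < len(text):
                m = re.match(pattern, text[i:])
                pos1 = base + i + 1
                if m and pos1 > signal_end:
                    for k in range(i, i + len(m.group())):
                        taken[k] = True
                    sites.append((pos1, m.group()))
                    i += len(m.group())
                else:
                    i += 1
        for i, ch in enumerate(text):
            pos1 = base + i + 1
            if taken[i] or pos1 <= signal_end:
                continue
            if ch in mono_ok or (terminal_mono and pos1 > len(seq) - terminal_window):
                sites.append((pos1, ch))
        # re-sort run-local ordering
    sites.sort()
    return sites


def count_perfect_matchings(n: int) -> int:
    """Number of perfect matchings of n labelled items, by exhaustive
    canonicalised enumeration (n even, small)."""
    items = list(range(1, n + 1))
    if n == 0:
        return 1
    seen = set()
    for perm in itertools.permutations(items):
        pairs = frozenset(
            frozenset(perm[i : i + 2]) for i in range(0, n, 2)
        )
        seen.add(pairs)
    return len(seen)


def random_additive_tree(rng: np.random.Generator, n: int):
    """A random binary tree over n leaves and its exact leaf-to-leaf
    distance matrix (labels sorted)."""
    avail = [str(i) for i in range(n)]
    G = nx.Graph()
    nxt = n
    while len(avail) > 2:
        a, b = sorted(rng.choice(len(avail), 2, replace=False), reverse=True)
        na, nb = avail.pop(int(a)), avail.pop(int(b))
        new = f"i{nxt}"
        nxt += 1
        G.add_edge(na, new, w=float(rng.uniform(0.05, 0.5)))
        G.add_edge(nb, new, w=float(rng.uniform(0.05, 0.5)))
        avail.append(new)
    G.add_edge(avail[0], avail[1], w=float(rng.uniform(0.05, 0.5)))
    labs = sorted(x for x in G.nodes if not x.startswith("i"))
    lengths = dict(nx.all_pairs_dijkstra_path_length(G, weight="w"))
    D = np.array([[lengths[a][b] for b in labs] for a in labs])
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return labs, D, G


def tree_splits_nx(G: nx.Graph, labs) -> set:
    """Non-trivial bipartitions of the leaf set induced by tree edges."""
    leaves = frozenset(labs)
    out = set()
    for e in list(G.edges):
        H = G.copy()
        H.remove_edge(*e)
        comp = next(nx.connected_components(H))
        s = frozenset(x for x in comp if x in leaves)
        if 1 < len(s) < len(leaves) - 1:
            out.add(frozenset([s, leaves - s]))
    return out


def tree_splits_skbio(tree) -> set:
    leaves = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        s = frozenset(t.name for t in node.tips())
        if 1 < len(s) < len(leaves) - 1:
            out.add(frozenset([s, leaves - s]))
    return out


def optimal_global_alignments(a: str, b: str, score_fn, gap_open=-10.0,
                              gap_extend=-0.5):
    """All score-optimal global alignments under affine gaps.

    Returns (optimal_score, set of (identities, alignment_length)).
    Three-state Gotoh DP with full backtracking; intended for short
    sequences only.
    """
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score_fn(a[i - 1], b[j - 1])
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
        for j in range(0, m + 1):
            if i >= 1:
                X[i][j] = max(
                    M[i - 1][j] + gap_open,
                    X[i - 1][j] + gap_extend,
                    Y[i - 1][j] + gap_open,
                )
        for j in range(1, m + 1):
            Y[i][j] = max(
                M[i][j - 1] + gap_open,
                Y[i][j - 1] + gap_extend,
                X[i][j - 1] + gap_open,
            )
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    best = max(M[n][m], X[n][m], Y[n][m])

    results = set()
    tol = 1e-9

    def back(i, j, state, idents, length):
        if i == 0 and j == 0 and state == "M":
            results.add((idents, length))
            return
        if state == "M":
            if i > 0 and j > 0:
                s = score_fn(a[i - 1], b[j - 1])
                ident = 1 if a[i - 1] == b[j - 1] else 0
                for prev in ("M", "X", "Y"):
                    val = {"M": M, "X": X, "Y": Y}[prev][i - 1][j - 1]
                    if abs(val + s - cur_val(i, j, "M")) < tol and val > NEG:
                        back(i - 1, j - 1, prev, idents + ident, length + 1)
        elif state == "X":
            if i > 0:
                v = cur_val(i, j, "X")
                if abs(M[i - 1][j] + gap_open - v) < tol:
                    back(i - 1, j, "M", idents, length + 1)
                if abs(X[i - 1][j] + gap_extend - v) < tol:
                    back(i - 1, j, "X", idents, length + 1)
                if abs(Y[i - 1][j] + gap_open - v) < tol:
                    back(i - 1, j, "Y", idents, length + 1)
        else:
            if j > 0:
                v = cur_val(i, j, "Y")
                if abs(M[i][j - 1] + gap_open - v) < tol:
                    back(i, j - 1, "M", idents, length + 1)
                if abs(Y[i][j - 1] + gap_extend - v) < tol:
                    back(i, j - 1, "Y", idents, length + 1)
                if abs(X[i][j - 1] + gap_open - v) < tol:
                    back(i, j - 1, "X", idents, length + 1)

    def cur_val(i, j, state):
        return {"M": M, "X": X, "Y": Y}[state][i][j]

    for state in ("M", "X", "Y"):
        if abs(cur_val(n, m, state) - best) < tol:
            back(n, m, state, 0, 0)
    return best, results
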