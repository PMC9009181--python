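"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the package's own code paths: the codon table is
written out literally, alignment scores come from direct recursion over
edit scripts, the median closure works on integer bitmasks, and the
breakpoint minimum enumerates every parent-switch assignment.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

# Standard genetic code, written out independently (DNA codons).
ORACLE_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_translate(nt: str) -> tuple[str, bool]:
    """(residues, terminated_early) by direct codon lookup."""
    residues = []
    n_codons = len(nt) // 3
    for i in range(n_codons):
        aa = ORACLE_CODON_TABLE[nt[3 * i : 3 * i + 3]]
        if aa == "*":
            return "".join(residues), i < n_codons - 1
        residues.append(aa)
    return "".join(residues), False


def enumerate_alignment_score(
    a: str, b: str,
    match: float = 2.0, mismatch: float = -3.0,
    gap_open: float = -8.0, gap_extend: float = -1.0,
) -> float:
    """Exhaustive recursion over all global alignments (no memoization).

    The first position of a gap run costs ``gap_open``, each further
    position ``gap_extend``; end gaps are penalized.  Exponential — only
    for tiny inputs.
    """
    NEG = float("-inf")

    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if j < len(b):
            cost = gap_extend if prev == "A" else gap_open
            best = max(best, cost + rec(i, j + 1, "A"))
        if i < len(a):
            cost = gap_extend if prev == "B" else gap_open
            best = max(best, cost + rec(i + 1, j, "B"))
        return best

    return rec(0, 0, "")


def recursive_alignment_score(
    a: str, b: str,
    match: float = 2.0, mismatch: float = -3.0,
    gap_open: float = -8.0, gap_extend: float = -1.0,
) -> float:
    """Same recursion with memoization, for somewhat longer inputs."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = float("-inf")
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if j < len(b):
            cost = gap_extend if prev == "A" else gap_open
            best = max(best, cost + rec(i, j + 1, "A"))
        if i < len(a):
            cost = gap_extend if prev == "B" else gap_open
            best = max(best, cost + rec(i + 1, j, "B"))
        return best

    return rec(0, 0, "")


def bitmask_median_closure(vectors: set[tuple[int, ...]]) -> set[tuple[int, ...]]:
    """Median closure on integer bitmasks: med(a,b,c) = ab | ac | bc."""
    if not vectors:
        return set()
    width = len(next(iter(vectors)))

    def pack(v):
        return sum(bit << k for k, bit in enumerate(v))

    def unpack(x):
        return tuple((x >> k) & 1 for k in range(width))

    closure = {pack(v) for v in vectors}
    changed = True
    while changed:
        changed = False
        snapshot = list(closure)
        for a, b, c in itertools.combinations_with_replacement(snapshot, 3):
            med = (a & b) | (a & c) | (b & c)
            if med not in closure:
                closure.add(med)
                changed = True
    return {unpack(x) for x in closure}


def exhaustive_min_breakpoints(child, parent_a, parent_b) -> int | None:
    """Minimum switches over every active-parent assignment (2^n)."""
    informative = [k for k in range(len(child)) if parent_a[k] != parent_b[k]]
    sites = [
        k for k in informative
        if child[k] == parent_a[k] or child[k] == parent_b[k]
    ]
    if not sites:
        return None
    best = None
    for assignment in itertools.product("AB", repeat=len(sites)):
        ok = all(
            child[k] == (parent_a[k] if who == "A" else parent_b[k])
            for k, who in zip(sites, assignment)
        )
        if not ok:
            continue
        switches = sum(x != y for x, y in zip(assignment, assignment[1:]))
        if best is None or switches < best:
            best = switches
    return best
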