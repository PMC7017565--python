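"""Independent brute-force oracles shared by unit and acceptance tests.

These deliberately avoid the implementation's code paths: alignment
scores come from exhaustive recursion over alignments (no dynamic
programming), and pattern matching from Python regexes compiled
independently of the pattern engine.
"""

import itertools
import re

from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN, GAP_EXTEND = 11, 1  # gap of length k costs open + k*extend


def brute_force_global(a: str, b: str) -> float:
    """Enumerate every affine-gap global alignment recursively."""

    def rec(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        best = -1e9
        if i < len(a) and j < len(b):
            best = max(best, BLOSUM62[a[i], b[j]] + rec(i + 1, j + 1, "m"))
        if i < len(a):
            cost = GAP_EXTEND if state == "a" else GAP_OPEN + GAP_EXTEND
            best = max(best, -cost + rec(i + 1, j, "a"))
        if j < len(b):
            cost = GAP_EXTEND if state == "b" else GAP_OPEN + GAP_EXTEND
            best = max(best, -cost + rec(i, j + 1, "b"))
        return best

    return rec(0, 0, "m")


def brute_force_local(a: str, b: str) -> float:
    """Best score over all substring pairs; empty alignment scores 0."""
    best = 0.0
    for i, k in itertools.combinations(range(len(a) + 1), 2):
        for j, l in itertools.combinations(range(len(b) + 1), 2):
            best = max(best, brute_force_global(a[i:k], b[j:l]))
    return best


def pattern_to_regex(pattern) -> str:
    """Compile a parsed pattern's element list to a Python regex."""
    parts = []
    for el in pattern.elements:
        if el.kind == "x":
            atom = "."
        elif el.kind == "letter":
            atom = next(iter(el.residues))
        elif el.kind == "set":
            atom = "[" + "".join(sorted(el.residues)) + "]"
        else:
            atom = "[^" + "".join(sorted(el.residues)) + "]"
        if (el.min_count, el.max_count) == (1, 1):
            parts.append(atom)
        elif el.min_count == el.max_count:
            parts.append(f"{atom}{{{el.min_count}}}")
        else:
            parts.append(f"{atom}{{{el.min_count},{el.max_count}}}")
    body = "".join(parts)
    if pattern.anchored_start:
        body = "^" + body
    if pattern.anchored_end:
        body += "$"
    return body


def regex_scan(pattern, seq: str):
    """All overlapping (1-based start, matched) pairs via lookahead."""
    rx = re.compile(f"(?=({pattern_to_regex(pattern)}))")
    return [(m.start() + 1, m.group(1)) for m in rx.finditer(seq)]
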