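"""Distance-based protein phylogenetics: progressive alignment,
p-distance/Poisson distances, Saitou-Nei neighbor-joining with
nonparametric bootstrap supports, and Newick I/O.

Alignment defaults mirror the MEGA/Clustal protein setup (Gonnet-250
log-odds matrix, gap opening 10, extension 0.2). Distances use
p-distance with pairwise deletion of gap sites by default; Poisson
correction (-ln(1-p)) is switchable. Negative NJ branch-length
estimates are clamped to zero and flagged.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from .homology import load_matrix
from .seqio import SeqRecord


@dataclass(frozen=True)
class AlignParams:
    matrix_name: str = "GONNET1992"
    gap_open: float = 10.0
    gap_extend: float = 0.2

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are magnitudes, must be >= 0")


@dataclass
class MSA:
    """Aligned rows (equal length, '-' gaps) with parallel labels."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("labels/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("MSA rows must have equal length")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def resample_columns(self, indices: np.ndarray) -> "MSA":
        rows = ["".join(r[i] for i in indices) for r in self.rows]
        return MSA(list(self.labels), rows)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


@dataclass
class TreeNode:
    name: str = ""
    length: float = 0.0
    support: float | None = None
    negative_length_clamped: bool = False
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary trifurcating root."""

    root: TreeNode

    def leaf_labels(self) -> list[str]:
        return sorted(leaf.name for leaf in self.root.leaves())

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized to the side not
        containing the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_labels())
        anchor = min(all_leaves)
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode, is_root: bool) -> None:
            for child in node.children:
                side = frozenset(leaf.name for leaf in child.leaves())
                if 1 < len(side) < len(all_leaves) - 1:
                    canon = side if anchor not in side else all_leaves - side
                    out.add(canon)
                walk(child, False)

        walk(self.root, True)
        return out

    def path_length(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        def find(node: TreeNode, target: str, acc: float, path: list) -> list | None:
            if node.is_leaf and node.name == target:
                return path + [(node, acc)]
            for c in node.children:
                hit = find(c, target, acc + c.length, path + [(node, acc)])
                if hit:
                    return hit
            return None

        pa = find(self.root, a, 0.0, [])
        pb = find(self.root, b, 0.0, [])
        if pa is None or pb is None:
            raise KeyError("leaf not found")
        nodes_a = {id(n): dist for n, dist in pa}
        lca_dist = 0.0
        for n, dist in reversed(pb):
            if id(n) in nodes_a:
                lca_dist = dist
                lca_a = nodes_a[id(n)]
                break
        return (pa[-1][1] - lca_a) + (pb[-1][1] - lca_dist)


# ---------------------------------------------------------------- MSA

def _pairwise_global(
    a: str, b: str, params: AlignParams
) -> tuple[str, str]:
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = load_matrix(params.matrix_name)
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    aligner.mode = "global"
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def progressive_msa(
    seqs: list[SeqRecord], params: AlignParams = AlignParams()
) -> MSA:
    """Guide-tree (UPGMA on pairwise p-distances) progressive alignment.

    Profiles are merged in guide-tree order with a profile-profile DP
    using mean-of-pairs column scores. Input order does not affect the
    result: sequences are canonically sorted by id first.
    """
    if len(seqs) < 2:
        raise ValueError("progressive_msa needs at least 2 sequences")
    seqs = sorted(seqs, key=lambda s: s.id)
    n = len(seqs)

    # pairwise distance estimates for the guide tree
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ra, rb = _pairwise_global(seqs[i].residues, seqs[j].residues, params)
            comp = [(x, y) for x, y in zip(ra, rb) if x != "-" and y != "-"]
            p = (
                sum(1 for x, y in comp if x != y) / len(comp) if comp else 1.0
            )
            dist[i, j] = dist[j, i] = p

    order = _upgma_merge_order(dist)
    matrix = load_matrix(params.matrix_name)

    profiles: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [seqs[i].residues]) for i in range(n)
    }
    next_id = n
    for a_id, b_id in order:
        ids_a, rows_a = profiles.pop(a_id)
        ids_b, rows_b = profiles.pop(b_id)
        rows = _align_profiles(rows_a, rows_b, matrix, params)
        profiles[next_id] = (ids_a + ids_b, rows)
        next_id += 1
    (ids, rows), = profiles.values()
    by_index = dict(zip(ids, rows))
    return MSA(
        [seqs[i].id for i in sorted(by_index)],
        [by_index[i] for i in sorted(by_index)],
    )


def _upgma_merge_order(dist: np.ndarray) -> list[tuple[int, int]]:
    """UPGMA agglomeration order; ties broken by smallest indices."""
    n = dist.shape[0]
    active = {i: ([i], i) for i in range(n)}  # id -> (members, min index)
    d = {
        (i, j): dist[i, j]
        for i in range(n)
        for j in range(i + 1, n)
    }
    order = []
    next_id = n
    while len(active) > 1:
        best = min(
            d.items(),
            key=lambda kv: (kv[1], active[kv[0][0]][1], active[kv[0][1]][1]),
        )[0]
        a, b = best
        mem_a, min_a = active.pop(a)
        mem_b, min_b = active.pop(b)
        members = mem_a + mem_b
        order.append((a, b))
        for k, (mem_k, _) in active.items():
            da = d.pop((min(a, k), max(a, k)))
            db = d.pop((min(b, k), max(b, k)))
            w = (da * len(mem_a) + db * len(mem_b)) / len(members)
            d[(min(next_id, k), max(next_id, k))] = w
        d.pop((a, b), None)
        active[next_id] = (members, min(min_a, min_b))
        next_id += 1
    return order


def _align_profiles(
    rows_a: list[str], rows_b: list[str], matrix, params: AlignParams
) -> list[str]:
    """Global DP (affine gaps) on profile columns, mean-of-pairs score."""
    la, lb = len(rows_a[0]), len(rows_b[0])
    cols_a = ["".join(r[i] for r in rows_a) for i in range(la)]
    cols_b = ["".join(r[i] for r in rows_b) for i in range(lb)]

    def col_score(ca: str, cb: str) -> float:
        total, count = 0.0, 0
        for x in ca:
            for y in cb:
                if x == "-" or y == "-":
                    continue
                total += matrix[x, y]
                count += 1
        return total / count if count else 0.0

    go, ge = params.gap_open + params.gap_extend, params.gap_extend
    neg = -1e30
    M = np.full((la + 1, lb + 1), neg)
    X = np.full((la + 1, lb + 1), neg)  # gap in B (consume A column)
    Y = np.full((la + 1, lb + 1), neg)  # gap in A
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -(go + ge * (i - 1))
    for j in range(1, lb + 1):
        Y[0, j] = -(go + ge * (j - 1))
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = col_score(cols_a[i - 1], cols_b[j - 1])
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            Y[i, j] = max(M[i, j - 1] - go, Y[i, j - 1] - ge, X[i, j - 1] - go)
    # traceback
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            out_a.append(cols_a[i - 1])
            out_b.append(cols_b[j - 1])
            s = col_score(cols_a[i - 1], cols_b[j - 1])
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax(prev))
            i, j = i - 1, j - 1
        elif state == 1 and i > 0:
            out_a.append(cols_a[i - 1])
            out_b.append("-" * len(cols_b[0]))
            opts = [M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go]
            state = int(np.argmax(opts))
            i -= 1
        elif state == 2 and j > 0:
            out_a.append("-" * len(cols_a[0]))
            out_b.append(cols_b[j - 1])
            opts = [M[i, j - 1] - go, Y[i, j - 1] - ge, X[i, j - 1] - go]
            state = [0, 2, 1][int(np.argmax(opts))]
            j -= 1
        elif i > 0:
            state = 1
        else:
            state = 2
    out_a.reverse()
    out_b.reverse()
    na, nb = len(rows_a), len(rows_b)
    merged_a = ["".join(col[k] for col in out_a) for k in range(na)]
    merged_b = ["".join(col[k] for col in out_b) for k in range(nb)]
    return merged_a + merged_b


# ----------------------------------------------------------- distances

def msa_distances(msa: MSA, model: str = "p_distance") -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gapped sites."""
    if model not in ("p_distance", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    n = len(msa.labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = msa.rows[i], msa.rows[j]
            compared = mismatch = 0
            for x, y in zip(ri, rj):
                if x == "-" or y == "-":
                    continue
                compared += 1
                if x != y:
                    mismatch += 1
            p = mismatch / compared if compared else 0.0
            if model == "poisson":
                p = -math.log(max(1.0 - p, 1e-12))
            d[i, j] = d[j, i] = p
    return DistanceMatrix(list(msa.labels), d)


def write_phylip(dm: DistanceMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for label, row in zip(dm.labels, dm.d):
            fh.write(label.ljust(10) + " ".join(f"{x:.6f}" for x in row) + "\n")


# ------------------------------------------------------------------ NJ

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei agglomeration; Q-ties broken by lowest label pair."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=label) for i, label in enumerate(dm.labels)
    }
    rep: dict[int, str] = {i: label for i, label in enumerate(dm.labels)}
    d: dict[tuple[int, int], float] = {
        (i, j): float(dm.d[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n

    def D(i: int, j: int) -> float:
        return d[(min(i, j), max(i, j))]

    while len(nodes) > 3:
        active = sorted(nodes)
        m = len(active)
        r = {i: sum(D(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D(i, j) - r[i] - r[j]
                pair_key = tuple(sorted((rep[i], rep[j])))
                if best is None or (q, pair_key) < (best[0], best[1]):
                    best = (q, pair_key, i, j)
        _, _, i, j = best
        dij = D(i, j)
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        ci, cj = nodes.pop(i), nodes.pop(j)
        ci.length, ci.negative_length_clamped = _clamp(li)
        cj.length, cj.negative_length_clamped = _clamp(lj)
        new = TreeNode(children=[ci, cj])
        for k in list(nodes):
            if k == next_id:
                continue
            dk = (D(i, k) + D(j, k) - dij) / 2
            d[(min(next_id, k), max(next_id, k))] = max(dk, 0.0)
        nodes[next_id] = new
        rep[next_id] = min(rep[i], rep[j])
        next_id += 1

    (a, b, c) = sorted(nodes)
    la = (D(a, b) + D(a, c) - D(b, c)) / 2
    lb = (D(a, b) + D(b, c) - D(a, c)) / 2
    lc = (D(a, c) + D(b, c) - D(a, b)) / 2
    for node_id, length in ((a, la), (b, lb), (c, lc)):
        nodes[node_id].length, nodes[node_id].negative_length_clamped = _clamp(
            length
        )
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root)


def _clamp(length: float) -> tuple[float, bool]:
    return (0.0, True) if length < 0 else (float(length), False)


# ----------------------------------------------------------- bootstrap

def bootstrap(
    msa: MSA,
    reps: int = 1000,
    seed: int = 0,
    model: str = "p_distance",
) -> PhyloTree:
    """Column-resampling bootstrap supports on the full-data NJ tree.

    Support of an internal edge is the percentage of replicate NJ trees
    containing the same bipartition; reproducible under a fixed seed.
    """
    full = neighbor_joining(msa_distances(msa, model))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in full.bipartitions()}
    for _ in range(reps):
        idx = rng.integers(0, msa.n_cols, size=msa.n_cols)
        rep_tree = neighbor_joining(
            msa_distances(msa.resample_columns(idx), model)
        )
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    supports = {bp: 100.0 * c / reps for bp, c in counts.items()}
    _attach_supports(full, supports)
    return full


def _attach_supports(tree: PhyloTree, supports: dict[frozenset[str], float]) -> None:
    all_leaves = frozenset(tree.leaf_labels())
    anchor = min(all_leaves)

    def walk(node: TreeNode) -> None:
        for child in node.children:
            if not child.is_leaf:
                side = frozenset(leaf.name for leaf in child.leaves())
                if 1 < len(side) < len(all_leaves) - 1:
                    canon = side if anchor not in side else all_leaves - side
                    child.support = supports.get(canon, 0.0)
            walk(child)

    walk(tree.root)


# -------------------------------------------------------------- newick

def write_newick(tree: PhyloTree) -> str:
    """Newick string; bootstrap supports appear as internal-node labels."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return f"{node.name}:{node.length:.6g}"
        inner = ",".join(fmt(c) for c in node.children)
        label = "" if node.support is None else f"{node.support:g}"
        return f"({inner}){label}:{node.length:.6g}"

    inner = ",".join(fmt(c) for c in tree.root.children)
    label = "" if tree.root.support is None else f"{tree.root.support:g}"
    return f"({inner}){label};"


_TOKEN = re.compile(r"[(),;]|[^(),;:]+(?::[0-9.eE+-]+)?")


def parse_newick(text: str) -> PhyloTree:
    """Parse the Newick dialect written by write_newick."""
    pos = 0
    s = text.strip()

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if s[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
        # label and/or length
        m = re.match(r"[^(),;:]*", s[pos:])
        label = m.group(0)
        pos += len(label)
        if label:
            if node.children:
                try:
                    node.support = float(label)
                except ValueError:
                    node.name = label
            else:
                node.name = label
        if pos < len(s) and s[pos] == ":":
            m2 = re.match(r":([0-9.eE+-]+)", s[pos:])
            node.length = float(m2.group(1))
            pos += len(m2.group(0))
        return node

    root = parse_node()
    return PhyloTree(root)
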