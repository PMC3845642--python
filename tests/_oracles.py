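"""Independent oracles used by the test suite.

These deliberately re-derive expected values by brute force (exhaustive
enumeration, closed forms, grid search) without reusing the package's
implementation paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

# standard genetic code, transcribed independently for the oracle
_CODE = {}
_BASES = "TCAG"
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, repeat=3)):
    _CODE[_b1 + _b2 + _b3] = _AA[_i]
STOPS = {c for c, a in _CODE.items() if a == "*"}
SENSE_CODONS = sorted(c for c in _CODE if c not in STOPS)


def _is_ts(a: str, b: str) -> bool:
    return {a, b} in ({"A", "G"}, {"C", "T"})


def ng_sites_oracle(codons: list[str], R: float) -> tuple[float, float]:
    """Per-sequence synonymous/nonsynonymous site counts (weighted by R)."""
    S = 0.0
    for codon in codons:
        for pos in range(3):
            wsum = wsyn = 0.0
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                w = R if _is_ts(codon[pos], b) else 1.0
                wsum += w
                neighbor = codon[:pos] + b + codon[pos + 1:]
                if neighbor not in STOPS and _CODE[neighbor] == _CODE[codon]:
                    wsyn += w
            S += wsyn / wsum
    return S, 3.0 * len(codons) - S


def ng_diffs_oracle(c1: str, c2: str) -> tuple[float, float]:
    """Average syn/nonsyn steps over minimal pathways (stop paths excluded)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    all_paths = []
    for order in itertools.permutations(diff):
        cur = c1
        path = [cur]
        for pos in order:
            cur = cur[:pos] + c2[pos] + cur[pos + 1:]
            path.append(cur)
        all_paths.append(path)
    open_paths = [p for p in all_paths
                  if not any(c in STOPS for c in p[1:-1])]
    if not open_paths:
        open_paths = all_paths
    sd = nd = 0.0
    for path in open_paths:
        for a, b in zip(path, path[1:]):
            if a not in STOPS and b not in STOPS and _CODE[a] == _CODE[b]:
                sd += 1
            else:
                nd += 1
    return sd / len(open_paths), nd / len(open_paths)


def ng_pair_oracle(codons1: list[str], codons2: list[str], R: float
                   ) -> dict[str, float]:
    """Whole-pair modified Nei-Gojobori estimate from the oracle pieces."""
    S1, N1 = ng_sites_oracle(codons1, R)
    S2, N2 = ng_sites_oracle(codons2, R)
    S, N = (S1 + S2) / 2.0, (N1 + N2) / 2.0
    Sd = Nd = 0.0
    for a, b in zip(codons1, codons2):
        sd, nd = ng_diffs_oracle(a, b)
        Sd += sd
        Nd += nd
    pS, pN = Sd / S, Nd / N

    def jc(p):
        return math.nan if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)

    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "pS": pS, "pN": pN,
            "dS": jc(pS), "dN": jc(pN)}


def alignment_score_oracle(a: str, b: str, matrix, open_gap: float,
                           extend_gap: float) -> float:
    """Best global affine-gap score by exhaustive enumeration of alignments.

    Enumerates all monotone edit scripts (match/insert/delete op strings)
    and scores gap runs with open + extend * (len - 1). Exponential: only
    for short strings.
    """
    best = -math.inf

    def score(ops: list[str]) -> float:
        total = 0.0
        i = j = 0
        k = 0
        while k < len(ops):
            if ops[k] == "M":
                total += float(matrix[a[i], b[j]])
                i += 1
                j += 1
                k += 1
            else:
                run = 0
                op = ops[k]
                while k < len(ops) and ops[k] == op:
                    run += 1
                    k += 1
                    if op == "D":
                        i += 1
                    else:
                        j += 1
                total -= open_gap + extend_gap * (run - 1)
        return total

    def rec(i: int, j: int, ops: list[str]):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score(ops))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ops + ["M"])
        if i < len(a):
            rec(i + 1, j, ops + ["D"])
        if j < len(b):
            rec(i, j + 1, ops + ["I"])

    rec(0, 0, [])
    return best


def random_additive_tree(rng: np.random.Generator, n: int):
    """A random binary tree topology with branch lengths, plus its exact
    leaf-to-leaf path-distance matrix.

    Returns (newick, labels, matrix).
    """
    labels = [f"T{k}" for k in range(n)]
    # grow by random leaf attachment: maintain nested list structure
    nodes = {0: None}

    class N:
        def __init__(self, label=None):
            self.label = label
            self.children = []  # (child, length)

    root = N()
    leaves = []
    for lbl in labels[:3]:
        leaf = N(lbl)
        root.children.append([leaf, round(float(rng.uniform(0.05, 1.0)), 4)])
        leaves.append(leaf)
    edges = list(root.children)
    for lbl in labels[3:]:
        # pick a random edge, split it, hang the new leaf there
        all_edges = []

        def collect(node):
            for edge in node.children:
                all_edges.append((node, edge))
                collect(edge[0])

        collect(root)
        parent, edge = all_edges[int(rng.integers(len(all_edges)))]
        child, length = edge
        mid = N()
        cut = float(rng.uniform(0.2, 0.8)) * length
        parent.children.remove(edge)
        parent.children.append([mid, round(length - cut, 4)])
        mid.children.append([child, round(cut, 4) + 0.01])
        leaf = N(lbl)
        mid.children.append([leaf, round(float(rng.uniform(0.05, 1.0)), 4)])
        leaves.append(leaf)

    # exact distances by DFS
    dist = {}

    def walk(node, acc):
        if node.label is not None:
            dist[node.label] = acc
        for child, length in node.children:
            walk(child, acc + length)

    import numpy as _np
    mat = _np.zeros((n, n))
    for i, a in enumerate(labels):
        dist = {}
        start = None

        def find(node):
            nonlocal start
            if node.label == a:
                start = node
            for child, _ in node.children:
                find(child)

        find(root)
        # path distances via parent maps
        parents = {}

        def link(node, parent, length):
            parents[id(node)] = (parent, length)
            for child, ln in node.children:
                link(child, node, ln)

        link(root, None, 0.0)

        def depth_path(node):
            path = {}
            d = 0.0
            cur = node
            while cur is not None:
                path[id(cur)] = d
                parent, ln = parents[id(cur)]
                d += ln
                cur = parent
            return path

        pa = depth_path(start)
        for j, b in enumerate(labels):
            if i == j:
                continue
            target = None

            def find_b(node):
                nonlocal target
                if node.label == b:
                    target = node
                for child, _ in node.children:
                    find_b(child)

            find_b(root)
            d = 0.0
            cur = target
            while id(cur) not in pa:
                parent, ln = parents[id(cur)]
                d += ln
                cur = parent
            mat[i, j] = d + pa[id(cur)]

    def to_newick(node):
        if node.label is not None:
            return node.label
        inner = ",".join(f"{to_newick(c)}:{ln:g}" for c, ln in node.children)
        return f"({inner})"

    return to_newick(root) + ";", labels, mat


def grid_search_pi(charge_fn, step: float = 1e-4) -> float:
    """Brute-force pI: the grid pH in [0, 14] whose |charge| is smallest."""
    grid = np.arange(0.0, 14.0 + step, step)
    charges = np.array([charge_fn(ph) for ph in grid])
    return float(grid[int(np.argmin(np.abs(charges)))])
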