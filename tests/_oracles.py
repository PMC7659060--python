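"""Independent brute-force oracles used by the test suite.

These are deliberately written from first principles, separate from the
package's implementations, so agreement is a real cross-check: exhaustive
pathway enumeration for codon-level Ka/Ks counting, grid search for the
isoelectric point, O(n²) window scanning for tandem clusters, subset
enumeration for longest collinear chains, and exhaustive least-squares
topology search for small neighbor-joining problems.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

GENETIC_CODE = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for _i, (_a, _b, _c) in enumerate(itertools.product(_BASES, _BASES, _BASES)):
    GENETIC_CODE[_a + _b + _c] = _AA[_i]
STOPS = {c for c, aa in GENETIC_CODE.items() if aa == "*"}


# ---------------------------------------------------------------------------
# NG86 counting
# ---------------------------------------------------------------------------


def ng86_sites_oracle(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts; stop mutations count nonsyn."""
    syn = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            mut = codon[:pos] + nt + codon[pos + 1 :]
            if mut not in STOPS and GENETIC_CODE[mut] == GENETIC_CODE[codon]:
                syn += 1 / 3
    return syn, 3 - syn


def ng86_diffs_oracle(ca: str, cb: str) -> tuple[float, float]:
    """Equal-weight average over all pathway permutations, skipping stops."""
    pos = [i for i in range(3) if ca[i] != cb[i]]
    if not pos:
        return 0.0, 0.0
    tallies = []
    for order in itertools.permutations(pos):
        current, syn, nonsyn, blocked = ca, 0, 0, False
        for p in order:
            nxt = current[:p] + cb[p] + current[p + 1 :]
            if nxt in STOPS:
                blocked = True
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if not blocked:
            tallies.append((syn, nonsyn))
    if not tallies:  # all pathways cross a stop: count through them
        for order in itertools.permutations(pos):
            current, syn, nonsyn = ca, 0, 0
            for p in order:
                nxt = current[:p] + cb[p] + current[p + 1 :]
                if GENETIC_CODE.get(nxt, "*") == GENETIC_CODE.get(current, "*"):
                    syn += 1
                else:
                    nonsyn += 1
                current = nxt
            tallies.append((syn, nonsyn))
    return (
        sum(t[0] for t in tallies) / len(tallies),
        sum(t[1] for t in tallies) / len(tallies),
    )


def ng86_counts_oracle(seq_a: str, seq_b: str):
    """(S, N, Sd, Nd) for two aligned in-frame sequences."""
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        sa, na = ng86_sites_oracle(ca)
        sb, nb = ng86_sites_oracle(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        ds, dn = ng86_diffs_oracle(ca, cb)
        Sd += ds
        Nd += dn
    return S, N, Sd, Nd


# ---------------------------------------------------------------------------
# isoelectric point grid search
# ---------------------------------------------------------------------------

_PK_POS = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
_PK_NEG = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}


def pi_grid_oracle(sequence: str, step: float = 0.001) -> float:
    """pH (on a fixed grid) with the smallest |net charge|."""

    def charge(ph: float) -> float:
        q = 1 / (1 + 10 ** (ph - _PK_POS["Nterm"]))
        q -= 1 / (1 + 10 ** (_PK_NEG["Cterm"] - ph))
        for aa in sequence:
            if aa in _PK_POS:
                q += 1 / (1 + 10 ** (ph - _PK_POS[aa]))
            elif aa in _PK_NEG:
                q -= 1 / (1 + 10 ** (_PK_NEG[aa] - ph))
        return q

    grid = np.arange(0.0, 14.0 + step, step)
    charges = np.array([charge(p) for p in grid])
    return float(grid[np.argmin(np.abs(charges))])


# ---------------------------------------------------------------------------
# tandem clusters by quadratic window scan
# ---------------------------------------------------------------------------


def tandem_clusters_oracle(ordered_ids, family, max_intervening):
    """All maximal runs of family genes with small gaps, O(n²)."""
    positions = [i for i, g in enumerate(ordered_ids) if g in family]
    clusters, current = [], []
    for p in positions:
        if current and p - current[-1] - 1 > max_intervening:
            if len(current) >= 2:
                clusters.append([ordered_ids[i] for i in current])
            current = []
        current.append(p)
    if len(current) >= 2:
        clusters.append([ordered_ids[i] for i in current])
    return clusters


# ---------------------------------------------------------------------------
# longest strictly-increasing chain by subset enumeration
# ---------------------------------------------------------------------------


def lis_subset_oracle(anchors) -> int:
    best = 0
    n = len(anchors)
    for mask in range(1, 1 << n):
        chosen = sorted(
            anchors[i] for i in range(n) if mask >> i & 1
        )
        if all(
            a1 < a2 and b1 < b2
            for (a1, b1), (a2, b2) in zip(chosen, chosen[1:])
        ):
            best = max(best, len(chosen))
    return best


# ---------------------------------------------------------------------------
# exhaustive least-squares topology search for small trees
# ---------------------------------------------------------------------------


def _all_topologies(labels):
    """All unrooted binary topologies by stepwise leaf addition.

    A topology is a set of edges over nodes; leaves are labels, internal
    nodes are negative integers.  Yields (edges, next_internal) tuples.
    """
    a, b, c = labels[:3]
    base = [frozenset([(a, -1), (b, -1), (c, -1)])]
    topologies = [(edges, -2) for edges in base]
    for leaf in labels[3:]:
        nxt = []
        for edges, next_int in topologies:
            for edge in edges:
                new_node = next_int
                rest = set(edges) - {edge}
                u, v = edge
                rest.add((u, new_node))
                rest.add((v, new_node))
                rest.add((leaf, new_node))
                nxt.append((frozenset(rest), next_int - 1))
        topologies = nxt
    return [edges for edges, _ in topologies]


def _ls_fit(edges, labels, dmat):
    """Least-squares branch lengths for one topology; returns SSE and the
    fitted path-length matrix."""
    adjacency = {}
    for u, v in edges:
        adjacency.setdefault(u, []).append((v, (u, v)))
        adjacency.setdefault(v, []).append((u, (u, v)))
    edge_list = sorted(edges, key=str)
    edge_index = {e: i for i, e in enumerate(edge_list)}

    def path_edges(src, dst):
        stack = [(src, None, [])]
        while stack:
            node, prev, path = stack.pop()
            if node == dst:
                return path
            for nbr, edge in adjacency[node]:
                if nbr != prev:
                    stack.append((nbr, node, path + [edge_index[edge]]))
        raise RuntimeError("disconnected topology")

    n = len(labels)
    rows, target = [], []
    pair_paths = []
    for i in range(n):
        for j in range(i + 1, n):
            row = np.zeros(len(edge_list))
            path = path_edges(labels[i], labels[j])
            row[path] = 1.0
            rows.append(row)
            target.append(dmat[i, j])
            pair_paths.append((i, j, path))
    A = np.array(rows)
    y = np.array(target)
    lengths, *_ = np.linalg.lstsq(A, y, rcond=None)
    fitted = A @ lengths
    sse = float(np.sum((fitted - y) ** 2))
    return sse


def best_topology_splits(labels, dmat):
    """Splits of the minimum-SSE topology over all unrooted topologies."""
    best_sse, best_edges = math.inf, None
    for edges in _all_topologies(list(labels)):
        sse = _ls_fit(edges, list(labels), dmat)
        if sse < best_sse - 1e-12:
            best_sse, best_edges = sse, edges
    return topology_splits(best_edges, list(labels))


def topology_splits(edges, labels):
    """Non-trivial bipartitions of a topology (canonical frozensets)."""
    adjacency = {}
    for u, v in edges:
        adjacency.setdefault(u, []).append(v)
        adjacency.setdefault(v, []).append(u)
    ref = min(labels)
    splits = set()
    for u, v in edges:
        # leaves on the u-side when edge (u, v) is cut
        seen, stack = {v}, [u]
        side = set()
        while stack:
            node = stack.pop()
            if node in seen:
                continue
            seen.add(node)
            if node in labels:
                side.add(node)
            stack.extend(n for n in adjacency[node] if n not in seen)
        if ref in side:
            side = set(labels) - side
        if 2 <= len(side) <= len(labels) - 2:
            splits.add(frozenset(side))
    return splits


def random_additive_matrix(labels, rng):
    """Random unrooted binary tree with positive lengths; returns its
    path-length matrix and the tree's non-trivial splits."""
    # build a random topology by stepwise addition
    a, b, c = labels[:3]
    edges = {(a, -1), (b, -1), (c, -1)}
    next_int = -2
    for leaf in labels[3:]:
        edge = sorted(edges, key=str)[rng.integers(len(edges))]
        edges.remove(edge)
        u, v = edge
        edges.add((u, next_int))
        edges.add((v, next_int))
        edges.add((leaf, next_int))
        next_int -= 1
    lengths = {e: float(rng.uniform(0.05, 1.0)) for e in edges}
    adjacency = {}
    for u, v in edges:
        adjacency.setdefault(u, []).append((v, lengths[(u, v)]))
        adjacency.setdefault(v, []).append((u, lengths[(u, v)]))

    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        # BFS distances from leaf i
        dist = {labels[i]: 0.0}
        stack = [labels[i]]
        while stack:
            node = stack.pop()
            for nbr, w in adjacency[node]:
                if nbr not in dist:
                    dist[nbr] = dist[node] + w
                    stack.append(nbr)
        for j in range(n):
            d[i, j] = dist[labels[j]]
    np.fill_diagonal(d, 0.0)
    return d, topology_splits(edges, list(labels))
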