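"""Stage 3 — distance phylogeny: p-distances, neighbor-joining, bootstrap
supports and clade/group assignment.

The tree is built by the Saitou–Nei neighbor-joining agglomeration from
pairwise p-distances on an aligned peptide matrix.  On exactly additive
distance matrices NJ recovers the generating topology and branch lengths.
Bootstrap supports come from column resampling with replacement; group
labels propagate from exemplar leaves to the smallest enclosing clade.

A star-progressive fallback aligner (pairwise global alignments merged
center-out, "once a gap always a gap") is provided for synthetic data;
pre-computed alignments are accepted everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from famsurvey.io_formats import TreeNode, ValidationError

MSA = list[tuple[str, str]]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.d.shape} does not match "
                f"{n} labels"
            )
        if not np.all(np.isfinite(self.d)):
            raise ValidationError("distance matrix has non-finite entries")
        if np.any(self.d < 0):
            raise ValidationError("distance matrix has negative entries")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValidationError("distance matrix diagonal is not zero")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------


def p_distance(msa: MSA) -> DistanceMatrix:
    """Pairwise p-distance: mismatches / compared columns.

    Columns with a gap ('-') in either sequence of a pair are excluded for
    that pair only.  A pair with zero comparable columns is an error.
    """
    if len(msa) < 2:
        raise ValidationError("need at least two sequences")
    length = len(msa[0][1])
    for label, seq in msa:
        if len(seq) != length:
            raise ValidationError(
                f"{label}: aligned length {len(seq)} != {length}"
            )
    labels = [label for label, _ in msa]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate sequence labels")
    arr = np.array([list(seq.upper()) for _, seq in msa])
    gaps = arr == "-"
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gaps[i] | gaps[j])
            compared = int(ok.sum())
            if compared == 0:
                raise ValidationError(
                    f"no comparable columns between {labels[i]} and {labels[j]}"
                )
            mism = int((arr[i, ok] != arr[j, ok]).sum())
            d[i, j] = d[j, i] = mism / compared
    return DistanceMatrix(labels=labels, d=d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Standard Q-matrix agglomeration with the usual branch-length formulas;
    ties on Q are broken toward the lexicographically smallest label pair
    (internal nodes are keyed by their smallest descendant leaf label).
    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling edge.  The returned root is the final trifurcation
    (unrooted tree in rooted representation).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=label) for label in dm.labels]
    keys: list[str] = list(dm.labels)  # smallest descendant label per node
    d = dm.d.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        row_sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1 :]:
                q = (r - 2) * d[i, j] - row_sums[i] - row_sums[j]
                tie_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = d[i, j] / 2.0 + (row_sums[i] - row_sums[j]) / (2.0 * (r - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = max(li, 0.0)
        nodes[j].length = max(lj, 0.0)
        new_index = len(nodes)
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new_index, k] = d[k, new_index] = (
                d[i, k] + d[j, k] - d[i, j]
            ) / 2.0
        active = [k for k in active if k not in (i, j)] + [new_index]

    a, b, c = active
    la = (d[a, b] + d[a, c] - d[b, c]) / 2.0
    lb = (d[a, b] + d[b, c] - d[a, c]) / 2.0
    lc = (d[a, c] + d[b, c] - d[a, b]) / 2.0
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    for idx, length in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(length, 0.0)
    # deterministic child order for byte-identical output
    root.children.sort(key=lambda child: min(child.leaf_labels()))
    return root


def tree_path_lengths(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (additivity check)."""
    leaves = sorted(tree.leaf_labels())
    index = {label: i for i, label in enumerate(leaves)}
    n = len(leaves)
    d = np.zeros((n, n))

    def below(node: TreeNode) -> list[tuple[str, float]]:
        if node.is_leaf:
            pairs_below = [(node.label or "", 0.0)]
        else:
            child_sets = [below(c) for c in node.children]
            for x in range(len(child_sets)):
                for y in range(x + 1, len(child_sets)):
                    for la, da in child_sets[x]:
                        for lb, db in child_sets[y]:
                            i, j = index[la], index[lb]
                            d[i, j] = d[j, i] = da + db
            pairs_below = [p for s in child_sets for p in s]
        return [(label, dist + (node.length or 0.0)) for label, dist in pairs_below]

    below(tree)
    return DistanceMatrix(labels=leaves, d=d)


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial splits, each canonicalized to the side not containing the
    lexicographically smallest leaf."""
    all_leaves = set(tree.leaf_labels())
    ref = min(all_leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = set(node.leaf_labels())
        if ref in side:
            side = all_leaves - side
        if len(side) >= 2 and len(all_leaves) - len(side) >= 2:
            splits.add(frozenset(side))
    return splits


def bootstrap_support(msa: MSA, replicates: int = 100,
                      seed: int = 0) -> TreeNode:
    """NJ tree from the original alignment with bootstrap supports.

    Alignment columns are resampled with replacement ``replicates`` times;
    the support of each internal bipartition of the original tree is the
    fraction of replicate trees containing it.
    """
    if replicates < 1:
        raise ValidationError("replicates must be ≥ 1")
    tree = nj_tree(p_distance(msa))
    length = len(msa[0][1])
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {s: 0 for s in _bipartitions(tree)}
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        resampled = [(label, "".join(seq[c] for c in cols)) for label, seq in msa]
        rep_splits = _bipartitions(nj_tree(p_distance(resampled)))
        for split in counts:
            if split in rep_splits:
                counts[split] += 1

    all_leaves = set(tree.leaf_labels())
    ref = min(all_leaves)
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = set(node.leaf_labels())
        if ref in side:
            side = all_leaves - side
        key = frozenset(side)
        if key in counts:
            node.support = counts[key] / replicates
    return tree


# ---------------------------------------------------------------------------
# group assignment
# ---------------------------------------------------------------------------

CladeAssignment = dict[str, str]


def assign_groups(tree: TreeNode,
                  reference_members: dict[str, str]) -> CladeAssignment:
    """Propagate group labels from exemplar leaves to all leaves.

    Each unlabeled leaf takes the group of the smallest clade (on the rooted
    representation) that contains it together with at least one exemplar;
    when that clade's exemplars span several groups the leaf is
    "unassigned".  Exemplars keep their own group.
    """
    leaves = set(tree.leaf_labels())
    missing = set(reference_members) - leaves
    if missing:
        raise ValidationError(
            f"exemplars absent from tree: {sorted(missing)[:5]}"
        )
    parent: dict[int, TreeNode] = {}
    for node in tree.walk():
        for child in node.children:
            parent[id(child)] = node
    leaf_nodes = {leaf.label: leaf for leaf in tree.leaves()}

    assignment: CladeAssignment = {}
    for label in sorted(leaves):
        if label in reference_members:
            assignment[label] = reference_members[label]
            continue
        node: TreeNode | None = leaf_nodes[label]
        group = "unassigned"
        while node is not None:
            exemplar_groups = {
                reference_members[l]
                for l in node.leaf_labels()
                if l in reference_members
            }
            if exemplar_groups:
                group = (
                    exemplar_groups.pop()
                    if len(exemplar_groups) == 1
                    else "unassigned"
                )
                break
            node = parent.get(id(node))
        assignment[label] = group
    return assignment


# ---------------------------------------------------------------------------
# fallback star-progressive aligner
# ---------------------------------------------------------------------------


def _pairwise_global(a: str, b: str) -> tuple[str, str]:
    """Global alignment with match 1, mismatch −1, gap −2 (linear)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    alignment = aligner.align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def ensure_alignment(sequences: list[tuple[str, str]]) -> MSA:
    """Return an aligned matrix for arbitrary input sequences.

    Equal-length sequences are taken as already aligned (substitution-only
    divergence, the synthetic generator's regime).  Ragged inputs go through
    :func:`star_align`; for real, indel-rich data supply an external MSA
    instead — a single-center star alignment misplaces gaps between
    sequences that are both distant from the center.
    """
    if len({len(seq) for _, seq in sequences}) <= 1:
        return list(sequences)
    return star_align(sequences)


def star_align(sequences: list[tuple[str, str]]) -> MSA:
    """Star-progressive multiple alignment around the first sequence.

    Every sequence is aligned pairwise to the center; gaps are merged with
    the "once a gap, always a gap" rule.  Intended for synthetic benchmark
    data — use a dedicated MSA tool for real sequences.
    """
    if not sequences:
        raise ValidationError("no sequences to align")
    if len(sequences) == 1:
        return list(sequences)
    center_label, center = sequences[0]
    aligned = [_pairwise_global(center, seq) for _, seq in sequences[1:]]

    # gaps inserted before each center position (index len(center) = at end)
    gap_count = [0] * (len(center) + 1)
    per_alignment_gaps: list[list[int]] = []
    for ac, _ in aligned:
        gaps = [0] * (len(center) + 1)
        ci = 0
        for ch in ac:
            if ch == "-":
                gaps[ci] += 1
            else:
                ci += 1
        per_alignment_gaps.append(gaps)
        for i, g in enumerate(gaps):
            gap_count[i] = max(gap_count[i], g)

    def thread(seq_aln: str, center_aln: str, gaps: list[int]) -> str:
        out: list[str] = []
        ci = 0
        pending = ""
        for cch, sch in zip(center_aln, seq_aln):
            if cch == "-":
                pending += sch
            else:
                out.append(pending + "-" * (gap_count[ci] - len(pending)))
                out.append(sch)
                pending = ""
                ci += 1
        out.append(pending + "-" * (gap_count[len(center)] - len(pending)))
        return "".join(out)

    center_row = "".join(
        "-" * gap_count[i] + (center[i] if i < len(center) else "")
        for i in range(len(center) + 1)
    )
    msa: MSA = [(center_label, center_row)]
    for (label, _), (ac, as_), gaps in zip(
        sequences[1:], aligned, per_alignment_gaps
    ):
        msa.append((label, thread(as_, ac, gaps)))
    width = len(msa[0][1])
    for label, row in msa:
        if len(row) != width:
            raise ValidationError(f"star alignment failed to square up at {label}")
    return msa
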