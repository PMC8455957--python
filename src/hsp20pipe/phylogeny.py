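"""Distance phylogenetics: Poisson correction, neighbor joining, bootstrap.

Distances between aligned protein sequences use the Poisson correction
d = -ln(1 - p) with pairwise deletion: for each sequence pair, only columns
where neither sequence has a gap or unknown residue are compared. Trees are
built with classic neighbor joining (Q-matrix minimization with
Studier-Keppler distance updates, ties broken by the lowest taxon-index
pair); NJ is exact on additive matrices. Bootstrap supports resample
alignment columns with replacement and record, for every internal
bipartition of the full-data tree, the percentage of replicate trees
containing it. Trees are scikit-bio ``TreeNode`` objects, so Newick I/O is
the library's.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

GAP_CHARS = set("-.?Xx*")


@dataclass
class DistanceMatrix:
    ids: list
    matrix: np.ndarray        # symmetric, zero diagonal
    used_sites: np.ndarray    # per-pair compared column counts

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m


def poisson_distance(seq_i: str, seq_j: str) -> tuple[float, int]:
    """Poisson-corrected distance and the number of sites used.

    Columns with a gap/unknown in either sequence are excluded (pairwise
    deletion); p is the mismatch proportion over the remaining sites and
    d = -ln(1 - p).
    """
    if len(seq_i) != len(seq_j):
        raise ValueError("sequences must be aligned to equal length")
    used = 0
    mismatches = 0
    for a, b in zip(seq_i.upper(), seq_j.upper()):
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        used += 1
        if a != b:
            mismatches += 1
    if used == 0:
        raise ValueError("no usable sites for this pair (all gapped/unknown)")
    p = mismatches / used
    if p >= 1.0:  # cannot happen for p<1; guard anyway
        raise ValueError("mismatch proportion reached 1; distance undefined")
    return -np.log(1.0 - p), used


def poisson_distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    """All-pairs Poisson distances (vectorized; pairwise deletion)."""
    ids = list(alignment)
    n = len(ids)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    rows = np.array([list(alignment[t].upper()) for t in ids])
    valid = ~np.isin(rows, sorted(GAP_CHARS))
    pair_valid = valid[:, None, :] & valid[None, :, :]
    used = pair_valid.sum(axis=2)
    if (used == 0).any(axis=None) and n > 1:
        off = used[~np.eye(n, dtype=bool)]
        if (off == 0).any():
            raise ValueError("a sequence pair has no usable sites (all gapped)")
    mism = ((rows[:, None, :] != rows[None, :, :]) & pair_valid).sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(used > 0, mism / np.maximum(used, 1), 0.0)
    off = ~np.eye(n, dtype=bool)
    if (p[off] >= 1.0).any():
        raise ValueError(
            "a sequence pair differs at every usable site; "
            "the Poisson distance is undefined at p = 1"
        )
    mat = -np.log(1.0 - p)
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(ids=ids, matrix=mat, used_sites=used)


def neighbor_joining(dm: DistanceMatrix, clamp_negative: bool = True) -> TreeNode:
    """Classic NJ; returns an unrooted (trifurcating-root) TreeNode."""
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.isfinite(dm.matrix).all():
        raise ValueError("distance matrix contains non-finite entries")
    D = dm.matrix.astype(float).copy()
    nodes = [TreeNode(name=str(t)) for t in dm.ids]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie break: first minimum in row-major order
        i_loc, j_loc = divmod(int(np.argmin(Q)), m)
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = active[i_loc], active[j_loc]
        dij = D[i, j]
        li = 0.5 * dij + (r[i_loc] - r[j_loc]) / (2.0 * (m - 2))
        lj = dij - li
        if clamp_negative:
            li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = float(li), float(lj)
        parent.extend([ci, cj])
        # Studier-Keppler update: distance from the new node to every other
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, new_row])
        D = np.hstack([D, np.append(new_row, 0.0)[:, None]])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # join the last three nodes on a central trifurcation
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = TreeNode()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        child = nodes[k]
        child.length = max(lk, 0.0) if clamp_negative else float(lk)
        root.append(child)
    return root


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions, each as the frozenset of tip names on the
    smaller side (lexicographic tie-break) — orientation-free."""
    tips = frozenset(t.name for t in tree.tips())
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        pick = side if (len(side), sorted(side)) <= (len(other), sorted(other)) else other
        out.add(pick)
    return out


def bootstrap_support(
    alignment: dict[str, str], n_replicates: int = 1000, seed: int = 0
) -> TreeNode:
    """NJ tree from the full alignment with bootstrap supports (in %) stored
    on internal nodes (``node.support`` and as the node name)."""
    if len(alignment) < 3:
        raise ValueError("need at least 3 taxa")
    ncol = len(next(iter(alignment.values())))
    ids = list(alignment)
    rows = np.array([list(alignment[t]) for t in ids])
    tree = neighbor_joining(poisson_distance_matrix(alignment))
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep = {t: "".join(rows[i, cols]) for i, t in enumerate(ids)}
        try:
            rep_tree = neighbor_joining(poisson_distance_matrix(rep))
        except ValueError:  # a pair with no usable resampled sites
            continue
        rep_bps = bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        tips = frozenset(t.name for t in tree.tips())
        other = tips - side
        if len(side) < 2 or len(other) < 2:
            continue
        pick = side if (len(side), sorted(side)) <= (len(other), sorted(other)) else other
        support = 100.0 * counts[pick] / n_replicates
        node.support = support
        node.name = f"{support:.0f}"
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def newick_string(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def assign_subfamilies(
    tree: TreeNode, reference_labels: dict[str, str]
) -> dict[str, str]:
    """Reference-guided subfamily labels: each unlabeled leaf takes the
    label of its nearest labeled reference leaf by patristic distance."""
    tips = [t.name for t in tree.tips()]
    missing = [t for t in reference_labels if t not in tips]
    if missing:
        raise KeyError(f"reference taxa not in tree: {missing}")
    dm = tree.tip_tip_distances()
    out: dict[str, str] = {}
    refs = list(reference_labels)
    for tip in tips:
        if tip in reference_labels:
            out[tip] = reference_labels[tip]
            continue
        nearest = min(refs, key=lambda r: (dm[tip, r], r))
        out[tip] = reference_labels[nearest]
    return out
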