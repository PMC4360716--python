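"""Distance-based tree inference, support handling, clade delineation, and
topology concordance.

Trees are Bio.Phylo objects; bootstrap supports are integer percentages
stored as clade confidences and serialized as internal node labels in
Newick. Tree inference is neighbor joining on p-distances with a
nonparametric (column-resampling) bootstrap; every downstream operation
(support collapsing, outgroup rooting, clade delineation, Robinson-Foulds
comparison) is inference-agnostic, so externally computed Newick trees can
be supplied instead.

The Robinson-Foulds concordance test asks whether two topologies over the
same leaves agree more than chance: the null distribution is RF(t1, t2 with
leaf labels uniformly permuted). Because RF between unrelated topologies is
heavily discrete (most label permutations land at or near the maximum), the
conservative empirical p-value has large point masses; a tie-randomized
p-value (the standard construction for discrete permutation nulls, exactly
uniform under H0) is reported alongside it and the normal approximation.
"""

from __future__ import annotations

import copy
import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import Phylo
from Bio.Phylo.BaseTree import Clade, Tree

from .align import GAP, MSA


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    no_overlap: set[frozenset] = field(default_factory=set)  # flagged pairs


@dataclass
class PermutationResult:
    """Result of the leaf-label permutation test on Robinson-Foulds distance."""

    observed_rf: int
    null_mean: float
    null_sd: float
    p_empirical: float
    p_normal: float
    p_randomized: float
    n_perm: int
    seed: int


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _row_codes(msa: MSA) -> np.ndarray:
    mat = np.frombuffer(
        "".join(seq for _, seq in msa.rows).encode("ascii"), dtype=np.uint8
    ).reshape(len(msa.rows), msa.n_cols)
    codes = mat.astype(np.int16)
    codes[mat == ord(GAP)] = -1
    return codes


def _pdist_from_codes(codes: np.ndarray) -> tuple[np.ndarray, set[tuple[int, int]]]:
    n = codes.shape[0]
    D = np.zeros((n, n))
    flagged = set()
    valid = codes >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            tot = int(both.sum())
            if tot == 0:
                D[i, j] = D[j, i] = 1.0
                flagged.add((i, j))
            else:
                mism = int(((codes[i] != codes[j]) & both).sum())
                D[i, j] = D[j, i] = mism / tot
    return D, flagged


def p_distance_matrix(msa: MSA) -> DistanceMatrix:
    """Pairwise p-distances: mismatches over columns where both rows are
    non-gap; pairs with no shared columns get d = 1.0 and are flagged."""
    if len(msa.rows) < 2:
        raise ValueError("p-distance needs at least 2 rows")
    codes = _row_codes(msa)
    D, flagged = _pdist_from_codes(codes)
    ids = msa.ids
    return DistanceMatrix(
        ids, D, {frozenset((ids[i], ids[j])) for i, j in flagged}
    )


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining. Returns an unrooted tree (trifurcating
    root). Negative branch lengths are clamped to 0; ties in the Q matrix
    break toward the smallest active pair (i, j) in row-major order."""
    D = np.array(dm.matrix, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    nodes: list[Clade] = [Clade(name=i) for i in dm.ids]
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = Q[iu]
        k = int(np.argmin(flat))  # first minimum in row-major upper triangle
        i, j = int(iu[0][k]), int(iu[1][k])
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        nodes[i].branch_length = max(li, 0.0)
        nodes[j].branch_length = max(lj, 0.0)
        joined = Clade(clades=[nodes[i], nodes[j]])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[1:, 1:] = D[np.ix_(keep, keep)]
        D2[0, 1:] = D2[1:, 0] = dnew[keep]
        D2[0, 0] = 0.0
        D = D2
        nodes = [joined] + [nodes[x] for x in keep]
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.branch_length = max(0.5 * (dab + dac - dbc), 0.0)
    b.branch_length = max(0.5 * (dab + dbc - dac), 0.0)
    c.branch_length = max(0.5 * (dac + dbc - dab), 0.0)
    return Tree(root=Clade(clades=[a, b, c]), rooted=False)


# ---------------------------------------------------------------------------
# Bipartitions and Robinson-Foulds
# ---------------------------------------------------------------------------

def leaf_names(tree: Tree) -> list[str]:
    return [t.name for t in tree.get_terminals()]


def _splits(tree: Tree, index: dict[str, int]) -> set[int]:
    """Canonical non-trivial bipartitions as bitmasks over `index` (leaves
    missing from the index are ignored, i.e. the tree is restricted)."""
    n = len(index)
    full = (1 << n) - 1
    out: set[int] = set()

    def walk(clade: Clade) -> int:
        if not clade.clades:
            i = index.get(clade.name)
            return 0 if i is None else (1 << i)
        mask = 0
        for ch in clade.clades:
            mask |= walk(ch)
        size = mask.bit_count()
        if 2 <= size <= n - 2:
            out.add(min(mask, full ^ mask))
        return mask

    for ch in tree.root.clades:
        walk(ch)
    return out


def rf_distance(t1: Tree, t2: Tree) -> int:
    """Robinson-Foulds (symmetric-difference) distance on non-trivial
    unrooted bipartitions; trees with different leaf sets are restricted to
    the intersection (error if fewer than 4 common leaves)."""
    common = sorted(set(leaf_names(t1)) & set(leaf_names(t2)))
    if len(common) < 4:
        raise ValueError(f"only {len(common)} common leaves; need >= 4")
    index = {name: i for i, name in enumerate(common)}
    return len(_splits(t1, index) ^ _splits(t2, index))


def rf_max(n_leaves: int) -> int:
    return 2 * (n_leaves - 3)


def rf_permutation_test(
    t1: Tree, t2: Tree, n_perm: int = 1000, seed: int = 0
) -> PermutationResult:
    """Observed RF(t1, t2) against the null of RF(t1, label-permuted t2)."""
    common = sorted(set(leaf_names(t1)) & set(leaf_names(t2)))
    if len(common) < 4:
        raise ValueError(f"only {len(common)} common leaves; need >= 4")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    index = {name: i for i, name in enumerate(common)}
    n = len(common)
    full = (1 << n) - 1
    s1 = _splits(t1, index)
    s2_members = [
        tuple(i for i in range(n) if mask >> i & 1) for mask in _splits(t2, index)
    ]
    observed = len(s1 ^ _splits(t2, index))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    for p in range(n_perm):
        perm = rng.permutation(n)
        s2p = set()
        for members in s2_members:
            mask = 0
            for i in members:
                mask |= 1 << perm[i]
            s2p.add(min(mask, full ^ mask))
        null[p] = len(s1 ^ s2p)
    mean = float(null.mean())
    sd = float(null.std())
    p_emp = (1 + int((null <= observed).sum())) / (n_perm + 1)
    if sd > 0:
        z = (observed - mean) / sd
        p_norm = 0.5 * math.erfc(-z / math.sqrt(2))  # lower tail
    else:
        p_norm = 1.0 if observed >= mean else 0.0
    less = int((null < observed).sum())
    ties = int((null == observed).sum())
    p_rand = (less + rng.random() * (1 + ties)) / (n_perm + 1)
    return PermutationResult(
        observed_rf=observed,
        null_mean=mean,
        null_sd=sd,
        p_empirical=p_emp,
        p_normal=p_norm,
        p_randomized=p_rand,
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_support(msa: MSA, n_reps: int = 100, seed: int = 0) -> Tree:
    """NJ tree from the full alignment, with internal-edge supports from
    column resampling with replacement (percent of replicates containing the
    same bipartition)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    dm = p_distance_matrix(msa)
    tree = neighbor_joining(dm)
    ids = msa.ids
    index = {name: i for i, name in enumerate(sorted(ids))}
    n = len(index)
    full = (1 << n) - 1
    codes = _row_codes(msa)
    rng = np.random.default_rng(seed)
    counts: dict[int, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, codes.shape[1], codes.shape[1])
        D, _flags = _pdist_from_codes(codes[:, cols])
        rep = neighbor_joining(DistanceMatrix(ids, D))
        for mask in _splits(rep, index):
            counts[mask] = counts.get(mask, 0) + 1

    def walk(clade: Clade) -> int:
        if not clade.clades:
            return 1 << index[clade.name]
        mask = 0
        for ch in clade.clades:
            mask |= walk(ch)
        size = mask.bit_count()
        if 2 <= size <= n - 2:
            canon = min(mask, full ^ mask)
            clade.confidence = round(100 * counts.get(canon, 0) / n_reps)
        return mask

    for ch in tree.root.clades:
        walk(ch)
    return tree


def collapse_low_support(tree: Tree, threshold: int = 50) -> Tree:
    """Contract internal edges whose support is strictly below threshold
    (support exactly at the threshold is retained). The contracted edge's
    length is absorbed into its children."""
    t = copy.deepcopy(tree)

    def walk(clade: Clade) -> None:
        new_children: list[Clade] = []
        for ch in clade.clades:
            walk(ch)
            if ch.clades and ch.confidence is not None and ch.confidence < threshold:
                for gc in ch.clades:
                    if ch.branch_length is not None and gc.branch_length is not None:
                        gc.branch_length += ch.branch_length
                    new_children.append(gc)
            else:
                new_children.append(ch)
        clade.clades = new_children

    walk(t.root)
    return t


# ---------------------------------------------------------------------------
# Rooting and clade delineation
# ---------------------------------------------------------------------------

def _unroot_in_place(tree: Tree) -> None:
    """Collapse a bifurcating root into a trifurcation (unrooted form)."""
    root = tree.root
    if len(root.clades) != 2:
        return
    a, b = root.clades
    internal = a if a.clades else b
    other = b if internal is a else a
    if not internal.clades:
        raise ValueError("cannot unroot a 2-leaf tree")
    other.branch_length = (other.branch_length or 0.0) + (
        internal.branch_length or 0.0
    )
    root.clades = list(internal.clades) + [other]
    root.confidence = None


def root_with_outgroup(tree: Tree, outgroup_ids: Sequence[str]) -> Tree:
    """Root on the edge separating the outgroup from the ingroup, at its
    midpoint. The outgroup must be monophyletic in the unrooted tree."""
    og = set(outgroup_ids)
    leaves = set(leaf_names(tree))
    missing = og - leaves
    if missing:
        raise ValueError(f"outgroup leaves not in tree: {sorted(missing)}")
    if not og or og == leaves:
        raise ValueError("outgroup must be a proper non-empty leaf subset")
    index = {name: i for i, name in enumerate(sorted(leaves))}
    full = (1 << len(index)) - 1
    og_mask = 0
    for name in og:
        og_mask |= 1 << index[name]
    t = copy.deepcopy(tree)
    _unroot_in_place(t)
    found: list[Clade] = []

    def walk(clade: Clade) -> int:
        if not clade.clades:
            m = 1 << index[clade.name]
        else:
            m = 0
            for ch in clade.clades:
                m |= walk(ch)
        if m == og_mask or m == full ^ og_mask:
            found.append(clade)
        return m

    walk(t.root)
    found = [c for c in found if c is not t.root]
    if not found:
        raise ValueError(
            f"outgroup is not monophyletic in the unrooted tree: {sorted(og)}"
        )
    pivot = found[0]
    chain = [t.root] + t.get_path(pivot)  # root ... pivot
    bls = [c.branch_length for c in chain]
    confs = [c.confidence for c in chain]
    half = (pivot.branch_length or 0.0) / 2
    parent = chain[-2]
    parent.clades.remove(pivot)
    pivot.branch_length = half
    parent.branch_length = half
    parent.confidence = confs[-1]  # both root children carry the root edge
    new_root = Clade(clades=[pivot, parent])
    # invert the root->parent path: each ancestor becomes a child of its
    # former child; a node's confidence labels the edge above it, so both
    # the edge length and the support move together during inversion
    for k in range(len(chain) - 2, 0, -1):
        node, old_parent = chain[k], chain[k - 1]
        old_parent.clades.remove(node)
        node.clades.append(old_parent)
        old_parent.branch_length = bls[k]
        old_parent.confidence = confs[k]
    old_root = chain[0]
    if len(old_root.clades) == 1:  # former trifurcation reduced on the path
        only = old_root.clades[0]
        holder = chain[1] if len(chain) > 2 else new_root
        idx = holder.clades.index(old_root)
        only.branch_length = (only.branch_length or 0.0) + (
            old_root.branch_length or 0.0
        )
        holder.clades[idx] = only
    return Tree(root=new_root, rooted=True)


def delineate_clades(
    rooted_tree: Tree, query_ids: Sequence[str], min_support: int = 80
) -> tuple[dict[str, set[str]], set[str]]:
    """Maximal supported subtrees composed purely of query leaves.

    A clade is a rooted subtree with support >= min_support whose >= 2
    leaves are all in query_ids; only maximal such subtrees are reported
    (pre-order, so ids are deterministic). Returns (clades, unassigned
    query leaves)."""
    queries = set(query_ids)
    clades: dict[str, set[str]] = {}
    assigned: set[str] = set()

    def walk(clade: Clade, is_root: bool) -> None:
        if not clade.clades:
            return
        leaves = {l.name for l in clade.get_terminals()}
        if (
            not is_root
            and clade.confidence is not None
            and clade.confidence >= min_support
            and len(leaves) >= 2
            and leaves <= queries
        ):
            clades[f"clade_{len(clades) + 1}"] = leaves
            assigned.update(leaves)
            return
        for ch in clade.clades:
            walk(ch, False)

    walk(rooted_tree.root, True)
    unassigned = {
        l for l in leaf_names(rooted_tree) if l in queries and l not in assigned
    }
    return clades, unassigned


# ---------------------------------------------------------------------------
# Newick IO (supports as integer internal node labels)
# ---------------------------------------------------------------------------

def write_newick(tree: Tree, path: Optional[str | Path] = None) -> str:
    def fmt(clade: Clade) -> str:
        if not clade.clades:
            body = clade.name or ""
        else:
            inner = ",".join(fmt(ch) for ch in clade.clades)
            label = "" if clade.confidence is None else str(int(clade.confidence))
            body = f"({inner}){label}"
        if clade.branch_length is not None:
            body += f":{clade.branch_length:.10g}"
        return body

    text = fmt(tree.root) + ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def read_newick(source: str | Path) -> Tree:
    """Parse Newick; numeric internal node labels are read as supports."""
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    tree = Phylo.read(io.StringIO(text), "newick")
    # Biopython stores numeric internal labels as confidence already; fall
    # back to converting stray string labels.
    for clade in tree.find_clades():
        if clade.clades and clade.name is not None:
            try:
                clade.confidence = int(float(clade.name))
                clade.name = None
            except ValueError:
                pass
    return tree


# ---------------------------------------------------------------------------
# Random trees (used for calibration and by the simulator's consumers)
# ---------------------------------------------------------------------------

def enumerate_topologies(names: Sequence[str]) -> list[Tree]:
    """All distinct unrooted binary topologies on the given leaves, by
    sequential insertion of each new leaf into every edge ((2n-5)!! trees)."""
    names = list(names)
    if len(names) < 4:
        raise ValueError("enumeration needs at least 4 leaves")
    base = Clade(
        clades=[Clade(name=names[0]), Clade(name=names[1]), Clade(name=names[2])]
    )
    roots = [base]
    for name in names[3:]:
        grown = []
        for r in roots:
            n_edges = sum(1 for _ in _edges(r))
            for k in range(n_edges):
                r2 = copy.deepcopy(r)
                parent, child = list(_edges(r2))[k]
                mid = Clade()
                parent.clades[parent.clades.index(child)] = mid
                mid.clades = [child, Clade(name=name)]
                grown.append(r2)
        roots = grown
    return [Tree(root=r, rooted=False) for r in roots]


def _edges(root: Clade):
    stack = [root]
    while stack:
        node = stack.pop()
        for ch in node.clades:
            yield node, ch
            stack.append(ch)


def random_tree(names: Sequence[str], rng: np.random.Generator) -> Tree:
    """Uniform random unrooted binary topology by sequential leaf insertion
    onto a uniformly chosen edge; branch lengths 1."""
    names = list(names)
    if len(names) < 3:
        raise ValueError("need at least 3 leaves")
    root = Clade(
        clades=[Clade(name=names[0], branch_length=1.0),
                Clade(name=names[1], branch_length=1.0),
                Clade(name=names[2], branch_length=1.0)]
    )
    edges: list[tuple[Clade, Clade]] = [(root, ch) for ch in root.clades]
    for name in names[3:]:
        parent, child = edges[rng.integers(0, len(edges))]
        mid = Clade(branch_length=1.0)
        leaf = Clade(name=name, branch_length=1.0)
        parent.clades[parent.clades.index(child)] = mid
        mid.clades = [child, leaf]
        edges.remove((parent, child))
        edges += [(parent, mid), (mid, child), (mid, leaf)]
    return Tree(root=root, rooted=False)
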