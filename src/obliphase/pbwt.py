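"""Compressed positional Burrows-Wheeler transform and neighbour selection.

Each compressed panel block gets a *prefix tree*: for every column of the
block, the distinct haplotype prefixes form nodes ordered lexicographically
by reversed prefix (the PBWT positional prefix order), with divergence values
recording the longest common suffix-of-prefix between adjacent nodes.  The
trees are built once from the public reference panel and reused across all
MCMC iterations and samples.

The current (secret) phase estimate is inserted retroactively: per column we
maintain its insertion rank in the positional prefix order, its divergences
to the neighbouring nodes, and -- as the linear-scan embodiment of the
divergence chains -- the full vector of block-level longest-common-suffix
(LCS) lengths between the target prefix and every node.  All updates are
branch-free whole-array operations whose access pattern depends only on the
public tree shape.

Neighbour selection at a search position ``p`` ranks reference haplotypes by
the length of their match with the target ending immediately before ``p``
(sites p-1, p-2, ...).  Matches that span the whole in-block prefix are
extended by a *global* LCS carried across preceding blocks, updated only at
block transitions.  The S best haplotypes (ties to the smaller haplotype id)
form a neighbour set; the union of the sets over all search positions, held
as a membership bitmap, yields the conditioned reference panel, padded to a
fixed public capacity so its true cardinality stays hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .oblivious import Secret, vemit
from .panel import CompressedBlock, CompressedPanel, decompress

__all__ = [
    "PrefixTree",
    "PrefixTreeLevel",
    "InsertedTarget",
    "CandidateSet",
    "NeighborSet",
    "ConditionedPanel",
    "build_prefix_tree",
    "insert_estimate",
    "candidate_search",
    "global_lcs_at_block_start",
    "rank_neighbors",
    "find_neighbors",
    "select_search_positions",
    "build_conditioned_panel",
]


# ---------------------------------------------------------------------------
# prefix trees (public data)
# ---------------------------------------------------------------------------

@dataclass
class PrefixTreeLevel:
    """Nodes of one column, in positional prefix order.

    ``div[i]`` is the longest common suffix of the prefixes of node ``i-1``
    and node ``i`` at this column (``div[0] = 0``: no predecessor).
    """

    groups: list  # member unique-haplotype ids per node
    div: np.ndarray  # (n_nodes,)
    sizes: np.ndarray  # (n_nodes,) original-haplotype multiplicity
    group_of_uid: np.ndarray  # (n_unique,) -> node index
    parent: np.ndarray  # (n_nodes,) node index in previous level (-1 at root)
    edge_allele: np.ndarray  # (n_nodes,) allele on edge from parent (-1 at root)
    child0: np.ndarray = field(default=None)  # type: ignore[assignment]
    child1: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_nodes(self) -> int:
        return len(self.groups)


@dataclass
class PrefixTree:
    """Per-block PBWT: one level per prefix length 0..width."""

    start: int
    end: int
    n_hap: int
    levels: list  # PrefixTreeLevel, length width + 1

    @property
    def width(self) -> int:
        return self.end - self.start


def build_prefix_tree(block: CompressedBlock) -> PrefixTree:
    """PBWT of a block's unique rows as a prefix tree with divergences.

    Pure public computation: built from the reference panel only, so the
    result can be reused across iterations and target samples.
    """
    n_u = block.n_unique
    n_hap = block.index_map.shape[0]
    mult = np.bincount(block.index_map, minlength=n_u).astype(np.int64)
    root = PrefixTreeLevel(
        groups=[np.arange(n_u)],
        div=np.zeros(1, dtype=np.int64),
        sizes=np.array([mult.sum()], dtype=np.int64),
        group_of_uid=np.zeros(n_u, dtype=np.int64),
        parent=np.array([-1]),
        edge_allele=np.array([-1]),
    )
    levels = [root]
    for c in range(block.width):
        col = block.uniques[:, c]
        prev = levels[-1]
        zero_nodes, one_nodes = [], []  # (parent_idx, members)
        for i, members in enumerate(prev.groups):
            m0 = members[col[members] == 0]
            m1 = members[col[members] == 1]
            if m0.size:
                zero_nodes.append((i, m0))
            if m1.size:
                one_nodes.append((i, m1))

        def _divs(nodes):
            out = np.zeros(len(nodes), dtype=np.int64)
            for k in range(1, len(nodes)):
                lo, hi = nodes[k - 1][0], nodes[k][0]
                out[k] = 1 + prev.div[lo + 1 : hi + 1].min()
            return out

        groups = [m for _, m in zero_nodes] + [m for _, m in one_nodes]
        div = np.concatenate([_divs(zero_nodes), _divs(one_nodes)])
        parent = np.array([p for p, _ in zero_nodes] + [p for p, _ in one_nodes])
        edge = np.array([0] * len(zero_nodes) + [1] * len(one_nodes))
        group_of_uid = np.empty(n_u, dtype=np.int64)
        sizes = np.empty(len(groups), dtype=np.int64)
        for gi, members in enumerate(groups):
            group_of_uid[members] = gi
            sizes[gi] = mult[members].sum()
        child0 = np.full(prev.n_nodes, -1, dtype=np.int64)
        child1 = np.full(prev.n_nodes, -1, dtype=np.int64)
        for k, (p, _) in enumerate(zero_nodes):
            child0[p] = k
        for k, (p, _) in enumerate(one_nodes):
            child1[p] = len(zero_nodes) + k
        prev.child0, prev.child1 = child0, child1
        levels.append(
            PrefixTreeLevel(groups, div, sizes, group_of_uid, parent, edge)
        )
    return PrefixTree(block.start, block.end, n_hap, levels)


# ---------------------------------------------------------------------------
# oblivious target insertion
# ---------------------------------------------------------------------------

@dataclass
class InsertedBlock:
    """Secret insertion state of the target within one block's tree."""

    match: list  # per level: (n_nodes,) block-level LCS of target vs node
    rank: list  # per level: Secret insertion rank in positional prefix order
    d_above: list  # per level: Secret divergence to the node above
    d_below: list  # per level: Secret divergence to the node below
    full_match: np.ndarray  # (n_hap,) block-level LCS at the block end


@dataclass
class InsertedTarget:
    blocks: list  # InsertedBlock per block
    global_lcs: list  # per block: (n_hap,) global LCS at the block start


def insert_estimate(trees: list, hap) -> InsertedTarget:
    """Insert a (secret) haplotype estimate into every block's prefix tree.

    Per column the insertion rank and neighbour divergences are updated
    incrementally; the full match-length vector is carried alongside so
    candidate search and ranking are single linear scans.  The global LCS
    vector is extended at each block transition: a full-width in-block match
    inherits the carryover from the preceding blocks.
    """
    hap_v = hap.expose() if isinstance(hap, Secret) else np.asarray(hap)
    blocks_out = []
    g_list = []
    n_hap = trees[0].n_hap
    g = np.zeros(n_hap, dtype=np.int64)
    for tree in trees:
        g_list.append(g)
        t = np.asarray(hap_v[tree.start : tree.end], dtype=np.int64)
        vemit("insert_block", tree.start, tree.end)
        match = [np.zeros(1, dtype=np.int64)]
        rank = [Secret(1)]
        d_above = [Secret(0)]
        d_below = [Secret(0)]
        r = 1
        for c in range(tree.width):
            prev = tree.levels[c]
            lvl = tree.levels[c + 1]
            tc = int(t[c])  # secret value; used arithmetically only
            m_prev = match[-1]
            m_new = np.where(lvl.edge_allele == tc, m_prev[lvl.parent] + 1, 0)
            n_prev = prev.n_nodes
            idx = np.arange(n_prev)
            has0 = prev.child0 >= 0
            has1 = prev.child1 >= 0
            z_before = int((has0 & (idx < r)).sum())
            o_before = int((has1 & (idx < r)).sum())
            n_zero = int(has0.sum())
            r = (1 - tc) * z_before + tc * (n_zero + o_before)
            n_new = lvl.n_nodes
            sel_above = np.arange(n_new) == (r - 1)
            sel_below = np.arange(n_new) == r
            d_above.append(Secret(int((m_new * sel_above).sum())))
            d_below.append(Secret(int((m_new * sel_below).sum())))
            match.append(m_new)
            rank.append(Secret(r))
        last = tree.levels[tree.width]
        per_uid = match[-1][last.group_of_uid]
        full = per_uid[_index_map_of(tree)]
        blocks_out.append(
            InsertedBlock(match, rank, d_above, d_below, full)
        )
        w = tree.width
        g = np.where(full == w, full + g, full)
    return InsertedTarget(blocks_out, g_list)


def _index_map_of(tree: PrefixTree) -> np.ndarray:
    # the last level's singleton groups are in bijection with unique rows;
    # the original-haplotype mapping is recovered through group_of_uid and
    # the block's index_map, which the caller stores on the tree
    return tree.index_map  # type: ignore[attr-defined]


def build_trees(cp: CompressedPanel) -> list:
    """Prefix trees for every block, annotated with their index maps."""
    trees = []
    for blk in cp.blocks:
        tree = build_prefix_tree(blk)
        tree.index_map = blk.index_map  # type: ignore[attr-defined]
        trees.append(tree)
    return trees


# ---------------------------------------------------------------------------
# candidate search and ranking
# ---------------------------------------------------------------------------

@dataclass
class CandidateSet:
    """Contiguous run of nodes around the insertion point whose block-level
    LCS reaches the data-dependent threshold ``theta``."""

    block_idx: int
    col: int  # prefix length within the block
    node_mask: Secret  # (n_nodes,) bool
    block_lcs: Secret  # (n_nodes,) match length per node
    theta: Secret


def candidate_search(
    tree: PrefixTree, inserted: InsertedBlock, col: int, S: int, block_idx: int = 0
) -> CandidateSet:
    """Nodes adjacent to the insertion point holding at least S haplotypes.

    Walking outward from the insertion rank, the block-level LCS is the
    running minimum of the divergences, so the set of nodes whose LCS
    reaches any threshold is a contiguous run containing the insertion
    point.  The scan computes the match length of *every* node and lowers
    the threshold until the accumulated original-haplotype count reaches S,
    then keeps all nodes tied at that threshold -- guaranteeing the true
    top-S (under the id tie rule) are among the candidates.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if S > tree.n_hap:
        raise ValueError(f"S={S} exceeds panel size {tree.n_hap}")
    lvl = tree.levels[col]
    m = inserted.match[col]
    vemit("candidate_search", col, lvl.n_nodes)
    # counts are non-increasing in the threshold v; theta = largest v with
    # at least S haplotypes at or above it (v = 0 always qualifies)
    reach = 0
    for v in range(col + 1):
        reach += int(((m >= v) * lvl.sizes).sum() >= S)
    theta = reach - 1
    mask = m >= theta
    return CandidateSet(block_idx, col, Secret(mask), Secret(m), Secret(theta))


def global_lcs_at_block_start(
    trees: list, inserted: InsertedTarget, block_idx: int
) -> Secret:
    """Global LCS of every reference haplotype with the target, for matches
    ending at the start of ``block_idx`` (0 for the first block)."""
    return Secret(inserted.global_lcs[block_idx])


@dataclass
class NeighborSet:
    """Exactly S haplotype ids (original panel indexing) with the longest
    total match at a search position."""

    ids: list  # Secret ints, length S
    lcs: list  # Secret ints: total match lengths
    S: int


def rank_neighbors(
    candidates: CandidateSet, global_lcs: Secret, tree: PrefixTree, S: int
) -> NeighborSet:
    """Top-S candidate haplotypes by total match length.

    The total match is the block-level LCS, extended by the global carryover
    when the whole in-block prefix matches.  Selection is S passes of an
    oblivious full-scan maximum over all reference haplotypes (candidates
    carry a live key, everything else a floor key); ties break toward the
    smaller haplotype id via a composite key.
    """
    col = candidates.col
    lvl = tree.levels[col]
    index_map = _index_map_of(tree)
    n_hap = tree.n_hap
    node_of_hap = lvl.group_of_uid[index_map]  # public
    lcs_h = candidates.block_lcs.expose()[node_of_hap]
    cand_h = candidates.node_mask.expose()[node_of_hap]
    g = global_lcs.expose()
    total = lcs_h + (lcs_h == col) * g
    vemit("rank_neighbors", col, n_hap, S)
    key = np.where(cand_h, total * n_hap + (n_hap - 1 - np.arange(n_hap)), -1)
    ids, lcs = [], []
    for _ in range(S):
        j = int(np.argmax(key))  # full scan; result stays secret-typed
        ids.append(Secret(j))
        lcs.append(Secret(int(total[j])))
        key = np.where(np.arange(n_hap) == j, -1, key)
    return NeighborSet(ids, lcs, S)


def find_neighbors(
    trees: list, inserted: InsertedTarget, pos: int, S: int
) -> NeighborSet:
    """End-to-end neighbour query at site index ``pos`` (match ending at
    sites pos-1, pos-2, ...)."""
    b = _block_of(trees, pos)
    tree = trees[b]
    col = pos - tree.start
    cands = candidate_search(tree, inserted.blocks[b], col, S, b)
    g = global_lcs_at_block_start(trees, inserted, b)
    return rank_neighbors(cands, g, tree, S)


def _block_of(trees: list, pos: int) -> int:
    for b, t in enumerate(trees):
        if t.start <= pos < t.end:
            return b
    raise ValueError(f"position {pos} outside the panel range")


# ---------------------------------------------------------------------------
# search positions and the conditioned panel
# ---------------------------------------------------------------------------

def select_search_positions(graph, rng) -> list:
    """One search position per genotype-graph segment, drawn uniformly from
    the segment's heterozygous sites (public randomness, seed-determined)."""
    positions = []
    for seg in graph.segments:
        if len(seg.het_sites) == 0:
            continue
        positions.append(int(rng.choice(seg.het_sites)))
    return positions


@dataclass
class ConditionedPanel:
    """Fixed-capacity subset of the reference panel for the HMM.

    ``hap_ids`` always has the public length ``k_cap``; unused slots repeat
    the first selected haplotype and are flagged in ``is_pad`` so the HMM
    gives them zero weight rather than revealing the true union size.
    """

    hap_ids: list  # Secret ints, length k_cap
    is_pad: Secret  # (k_cap,) bool
    bitmap: Secret  # (n_hap,) membership bitmap
    alleles: np.ndarray  # (k_cap, n_sites): secret values, public shape
    k_cap: int


def build_conditioned_panel(
    neighbor_sets: list,
    cp: CompressedPanel,
    k_cap: int | None = None,
    panel_alleles: np.ndarray | None = None,
) -> ConditionedPanel:
    """Union the neighbour sets into a conditioned panel of public size.

    Membership is accumulated in a bitmap of per-haplotype selection counts
    via linear one-hot scans; the ``k_cap`` slots are then filled by repeated
    oblivious maximum selection on (selection count, smaller id first), which
    reduces to the plain set union whenever the union fits the capacity and
    otherwise keeps the most frequently selected haplotypes.  Row contents
    are gathered with one-hot contractions so the access pattern never
    depends on which haplotypes were chosen.
    """
    if not neighbor_sets:
        raise ValueError("no neighbor sets given")
    n_hap = cp.n_hap
    if k_cap is None:
        k_cap = sum(ns.S for ns in neighbor_sets)
    k_cap = min(k_cap, n_hap)
    ids_all = np.array(
        [i.expose() for ns in neighbor_sets for i in ns.ids], dtype=np.int64
    )
    vemit("panel_union", n_hap, ids_all.size, k_cap)
    counts = (ids_all[:, None] == np.arange(n_hap)[None, :]).sum(axis=0)
    member = counts > 0
    key = np.where(member, counts * n_hap + (n_hap - 1 - np.arange(n_hap)), -1)
    slot_ids = np.empty(k_cap, dtype=np.int64)
    is_pad = np.empty(k_cap, dtype=bool)
    first_id = int(np.argmax(key))
    for k in range(k_cap):
        j = int(np.argmax(key))
        valid = key[j] > -1
        slot_ids[k] = j if valid else first_id
        is_pad[k] = not valid
        key = np.where(np.arange(n_hap) == j, -1, key)
    bitmap = (slot_ids[:, None] == np.arange(n_hap)[None, :]).any(axis=0)
    if panel_alleles is None:
        panel_alleles = decompress(cp).alleles
    onehot = (slot_ids[:, None] == np.arange(n_hap)[None, :]).astype(np.int64)
    alleles = (onehot @ panel_alleles.astype(np.int64)).astype(np.int8)
    return ConditionedPanel(
        hap_ids=[Secret(int(i)) for i in slot_ids],
        is_pad=Secret(is_pad),
        bitmap=Secret(bitmap),
        alleles=alleles,
        k_cap=k_cap,
    )
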