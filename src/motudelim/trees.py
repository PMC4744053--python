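"""Neighbor-joining tree construction, rooting and newick serialization.

Trees are carried as :class:`dendropy.Tree` objects throughout the package.
NJ is implemented directly (Saitou-Nei Q-criterion agglomeration) so that
tie-breaks are deterministic across platforms: when two candidate joins
have equal Q, the pair whose smallest original taxon index is lowest wins.
Negative branch lengths arising from the NJ length equations are set to
zero with the deficit transferred to the sister branch, preserving the
path length through the join.
"""

from __future__ import annotations

import warnings

import dendropy
import numpy as np

from motudelim.distances import DistanceMatrix

__all__ = ["nj_tree", "root_tree", "midpoint_root", "write_newick", "read_newick"]


def _adjust_negative(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb = max(lb + la, 0.0)
        la = 0.0
    if lb < 0:
        la = max(la + lb, 0.0)
        lb = 0.0
    return la, lb


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Unrooted neighbor-joining tree from a distance matrix.

    Standard Saitou-Nei agglomeration: at each step join the pair (i, j)
    minimizing Q_ij = (m-2) d_ij - r_i - r_j. Returns an unrooted tree with
    a trifurcating seed node. Exact on additive matrices.
    """
    n = dm.n
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 sequences")
    if np.isnan(dm.values).any():
        raise ValueError("distance matrix contains undefined entries")
    taxa = dendropy.TaxonNamespace(dm.ids)
    tree = dendropy.Tree(taxon_namespace=taxa)

    nodes: list[dendropy.Node] = []
    for sid in dm.ids:
        nd = dendropy.Node(taxon=taxa.get_taxon(sid))
        nodes.append(nd)
    D = dm.values.astype(float).copy()
    active = list(range(n))
    minmem = {i: i for i in range(n)}
    lengths: dict[int, float] = {}  # pending branch length of slot's edge to its parent
    neg_loss = 0.0

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        best = None
        xi, yj = np.where(Q <= qmin + 1e-12 * max(1.0, abs(qmin)))
        for x, y in zip(xi, yj):
            if x >= y:
                continue
            a, b = active[x], active[y]
            key = tuple(sorted((minmem[a], minmem[b])))
            if best is None or key < best[0]:
                best = (key, x, y)
        _, x, y = best
        a, b = active[x], active[y]
        dij = sub[x, y]
        la = 0.5 * dij + (r[x] - r[y]) / (2.0 * (m - 2))
        lb = dij - la
        la2, lb2 = _adjust_negative(la, lb)
        neg_loss += abs(la - la2) + abs(lb - lb2) - abs((la + lb) - (la2 + lb2))
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = la2
        nodes[b].edge.length = lb2
        # new cluster occupies slot a
        newd = 0.5 * (D[a, :] + D[b, :] - dij)
        D[a, :] = newd
        D[:, a] = newd
        D[a, a] = 0.0
        nodes[a] = parent
        minmem[a] = min(minmem[a], minmem[b])
        active.remove(b)

    # resolve the final three clusters on one (unrooted) seed node
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    seed = tree.seed_node
    for slot, ln in ((a, la), (b, lb), (c, lc)):
        seed.add_child(nodes[slot])
        nodes[slot].edge.length = max(ln, 0.0)
    if min(la, lb, lc) < 0:
        neg_loss += -min(la, lb, lc)
    if neg_loss > 0:
        warnings.warn(f"negative NJ branch lengths adjusted; total length change {neg_loss:.3e}",
                      stacklevel=2)
    tree.is_rooted = False
    return tree


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Root a tree at the midpoint of its longest tip-to-tip path."""
    t = tree.clone(depth=1)
    if len(t.seed_node.child_nodes()) == 2:
        # collapse an existing degree-2 root first; rerooting an already
        # midpoint-rooted tree in place misplaces the new root
        t.deroot()
    t.reroot_at_midpoint(update_bipartitions=True)
    t.is_rooted = True
    return t


def root_tree(
    tree: dendropy.Tree,
    mode: str = "midpoint",
    outgroup_ids: list[str] | None = None,
) -> dendropy.Tree:
    """Root a tree by midpoint or by an outgroup (degree-2 root).

    With ``mode='outgroup'`` the root is placed on the edge above the MRCA
    of ``outgroup_ids`` (or above the single outgroup tip), splitting that
    edge's length equally.
    """
    if mode == "midpoint":
        return midpoint_root(tree)
    if mode != "outgroup":
        raise ValueError(f"mode must be 'midpoint' or 'outgroup', got {mode!r}")
    if not outgroup_ids:
        raise ValueError("outgroup rooting requires outgroup_ids")
    t = tree.clone(depth=1)
    labels = {tx.label for tx in t.taxon_namespace}
    missing = sorted(set(outgroup_ids) - labels)
    if missing:
        raise ValueError(f"outgroup ids not in tree: {missing}")
    if len(outgroup_ids) == 1:
        node = next(lf for lf in t.leaf_node_iter() if lf.taxon.label == outgroup_ids[0])
    else:
        node = t.mrca(taxon_labels=outgroup_ids)
    if node is t.seed_node:
        # outgroup spans the current seed; root on the edge of the complement
        node = next(ch for ch in t.seed_node.child_nodes())
    elen = node.edge.length or 0.0
    t.reroot_at_edge(node.edge, length1=elen / 2.0, length2=elen / 2.0,
                     update_bipartitions=True)
    t.is_rooted = True
    return t


def write_newick(tree: dendropy.Tree, path: str | None = None) -> str:
    """Serialize to newick (10 significant digits); optionally write to a file."""
    # spaces are quoted; underscores stay literal (paired with
    # preserve_underscores=True on the reader) so sample ids round-trip
    text = tree.as_string(
        schema="newick",
        real_value_format_specifier=".10g",
        unquoted_underscores=True,
        preserve_spaces=True,
        suppress_rooting=False,
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(source: str) -> dendropy.Tree:
    """Parse newick text (or a path to a newick file)."""
    import os

    kwargs = dict(schema="newick", preserve_underscores=True)
    if os.path.exists(source):
        return dendropy.Tree.get(path=source, **kwargs)
    return dendropy.Tree.get(data=source, **kwargs)
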