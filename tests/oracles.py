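"""Independent brute-force oracles used by the tests.

These implementations deliberately share no code with the package: distances
are path walks over parent maps, metrics are naive double loops over species
lists, and BLADJ expectations come from explicit dated-to-dated path
enumeration.  They are only ever run on tiny inputs.
"""

from __future__ import annotations

import numpy as np


def _parent_map(ptree):
    """(parents, lengths, tips) from a PhyloTree via its dendropy structure."""
    parents, lengths, tips = {}, {}, {}
    for node in ptree.dendropy_tree.preorder_node_iter():
        parents[node] = node.parent_node
        lengths[node] = node.edge.length
        if node.is_leaf():
            tips[node.taxon.label] = node
    return parents, lengths, tips


def path_walk_distance(ptree, a: str, b: str) -> float:
    """Patristic distance by walking both tips to the root and trimming."""
    parents, lengths, tips = _parent_map(ptree)

    def path(label):
        out, node = [], tips[label]
        while node is not None:
            out.append(node)
            node = parents[node]
        return out

    pa, pb = path(a), path(b)
    common = set(pa) & set(pb)
    d = 0.0
    for node in pa:
        if node in common:
            break
        d += lengths[node]
    for node in pb:
        if node in common:
            break
        d += lengths[node]
    return d


def brute_cophenetic(ptree) -> dict:
    labels = ptree.tip_labels
    return {(a, b): path_walk_distance(ptree, a, b)
            for i, a in enumerate(labels) for b in labels[i + 1:]}


def brute_faith_pd(ptree, species, rooted="mrca") -> float:
    """Sum branch lengths on the union of tip-to-MRCA (or tip-to-root) paths."""
    parents, lengths, tips = _parent_map(ptree)
    paths = []
    for label in species:
        path, node = [], tips[label]
        while node is not None:
            path.append(node)
            node = parents[node]
        paths.append(path)
    shared = set(paths[0])
    for p in paths[1:]:
        shared &= set(p)
    mrca = paths[0][min(paths[0].index(n) for n in shared)]
    edges = set()
    for p in paths:
        for node in p:
            if node is mrca:
                break
            edges.add(node)
    total = sum(lengths[e] for e in edges)
    if rooted == "root":
        node = mrca
        while parents[node] is not None:
            total += lengths[node]
            node = parents[node]
    return total


# -- community metrics, naive double loops ---------------------------------

def brute_mpd(abund: dict, dist, weighted=False) -> float:
    sp = [s for s, v in abund.items() if v > 0]
    if len(sp) < 2:
        return float("nan")
    num = den = 0.0
    for i in sp:
        for j in sp:
            if i == j:
                continue
            w = abund[i] * abund[j] if weighted else 1.0
            num += w * dist.get(i, j)
            den += w
    return num / den


def brute_mntd(abund: dict, dist, weighted=False) -> float:
    sp = [s for s, v in abund.items() if v > 0]
    if len(sp) < 2:
        return float("nan")
    num = den = 0.0
    for i in sp:
        m = min(dist.get(i, j) for j in sp if j != i)
        w = abund[i] if weighted else 1.0
        num += w * m
        den += w
    return num / den


def brute_comdist(abund_a: dict, abund_b: dict, dist, weighted=False) -> float:
    sa = [s for s, v in abund_a.items() if v > 0]
    sb = [s for s, v in abund_b.items() if v > 0]
    ta = sum(abund_a[s] for s in sa)
    tb = sum(abund_b[s] for s in sb)
    num = den = 0.0
    for i in sa:
        for j in sb:
            w = (abund_a[i] / ta) * (abund_b[j] / tb) if weighted else 1.0
            num += w * dist.get(i, j)
            den += w
    return num / den


def brute_comdistnt(abund_a: dict, abund_b: dict, dist, weighted=False) -> float:
    sa = [s for s, v in abund_a.items() if v > 0]
    sb = [s for s, v in abund_b.items() if v > 0]
    mins_a = {i: min(dist.get(i, j) for j in sb) for i in sa}
    mins_b = {j: min(dist.get(i, j) for i in sa) for j in sb}
    if weighted:
        ta = sum(abund_a[s] for s in sa)
        tb = sum(abund_b[s] for s in sb)
        da = sum(abund_a[i] / ta * mins_a[i] for i in sa)
        db = sum(abund_b[j] / tb * mins_b[j] for j in sb)
        return 0.5 * (da + db)
    pooled = list(mins_a.values()) + list(mins_b.values())
    return float(np.mean(pooled))


def bladj_chain_oracle(anchors, n_between) -> list:
    """Ages of undated nodes evenly spaced between two dated anchors.

    ``anchors`` = (older_age, younger_age); ``n_between`` undated nodes sit
    on the path.  Returns their ages from the older side downward.
    """
    hi, lo = anchors
    step = (hi - lo) / (n_between + 1)
    return [hi - step * (k + 1) for k in range(n_between)]
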