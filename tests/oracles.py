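"""Independent brute-force reference implementations used as test oracles.

Everything here is written from first principles (exhaustive scans, DFS path
enumeration, pairwise rank counting) and deliberately shares no code path
with the package implementations it checks.
"""

from __future__ import annotations

from itertools import combinations


def brute_filter(rows, eps_cutoff, p_cutoff):
    """Exhaustive scan: unique canonical pairs passing both inclusive cutoffs."""
    kept = set()
    for a, b, eps, p in rows:
        if eps <= eps_cutoff and p <= p_cutoff:
            kept.add(tuple(sorted((a.upper(), b.upper()))))
    return kept


def brute_translate(pairs, orth_map):
    """Cartesian expansion of yeast pairs through per-gene orthologue sets."""
    out = set()
    untranslatable = 0
    for ya, yb in pairs:
        ha, hb = orth_map.get(ya, set()), orth_map.get(yb, set())
        if not ha or not hb:
            untranslatable += 1
            continue
        produced = {tuple(sorted((x, y))) for x in ha for y in hb if x != y}
        if not produced:
            untranslatable += 1
        out |= produced
    return out, untranslatable


def bfs_distances(adj, start):
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist

def adjacency(edges, nodes):
    adj = {n: set() for n in nodes}
    for a, b in edges:
        if a != b:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def all_simple_paths(adj, s, t):
    """All simple s->t paths by DFS; exponential, for tiny graphs only."""
    paths, stack = [], [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            paths.append(path)
            continue
        for nb in adj[node]:
            if nb not in path:
                stack.append((nb, path + [nb]))
    return paths


def brute_betweenness(adj, nodes):
    """Normalised betweenness via exhaustive shortest-path enumeration."""
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = all_simple_paths(adj, s, t)
        if not paths:
            continue
        min_len = min(len(p) for p in paths)
        shortest = [p for p in paths if len(p) == min_len]
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p)
            bc[v] += through / len(shortest)
    norm = (n - 1) * (n - 2) / 2.0
    return {v: (bc[v] / norm if norm > 0 else 0.0) for v in nodes}


def brute_clustering(adj, nodes):
    out = {}
    for v in nodes:
        nbrs = sorted(adj[v])
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for a, b in combinations(nbrs, 2) if b in adj[a])
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def brute_closeness(adj, nodes):
    """Closeness with the reachable-fraction scaling used for disconnected graphs."""
    n = len(nodes)
    out = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        reachable = len(dist) - 1
        total = sum(dist.values())
        if reachable == 0 or total == 0:
            out[v] = 0.0
        else:
            out[v] = (reachable / total) * (reachable / (n - 1))
    return out


def rank_auc_pairwise(labels, scores):
    """AUC as the pairwise win fraction (Mann-Whitney statistic)."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def brute_clinical_pairs(combos, targets, sl_pairs):
    """Double loop over all drug pairs co-occurring in practice combinations."""
    sl = {frozenset(p) for p in sl_pairs}
    result = {}
    for combo in combos:
        if combo.source != "practice":
            continue
        drugs = sorted(d for d in combo.drugs if d in targets)
        for da, db in combinations(drugs, 2):
            spans = {
                tuple(sorted((ta, tb)))
                for ta in targets[da]
                for tb in targets[db]
                if ta != tb and frozenset((ta, tb)) in sl
            }
            if spans:
                result.setdefault((da, db), set()).update(spans)
    return result


def brute_candidates(combos, targets, sl_pairs, same_indication=True):
    """Double loop over all cross-combination drug pairs, novelty-checked."""
    sl = {frozenset(p) for p in sl_pairs}
    existing = set()
    for combo in combos:
        for pair in combinations(sorted(combo.drugs), 2):
            existing.add(frozenset(pair))
    result = {}
    for cx, cy in combinations(combos, 2):
        if same_indication and cx.indication != cy.indication:
            continue
        for da in cx.drugs:
            for db in cy.drugs:
                if da == db or da not in targets or db not in targets:
                    continue
                if frozenset((da, db)) in existing:
                    continue
                spans = {
                    tuple(sorted((ta, tb)))
                    for ta in targets[da]
                    for tb in targets[db]
                    if ta != tb and frozenset((ta, tb)) in sl
                }
                if spans:
                    result.setdefault(tuple(sorted((da, db))), set()).update(spans)
    return result
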