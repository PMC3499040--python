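"""Independent brute-force oracles shared by unit and acceptance tests."""

import itertools


def _bfs_distances(adj, start):
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _brute_force_metrics(nodes, edges):
    """Independent implementation of every node metric from first principles."""
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    n = len(nodes)
    out = {}
    for v in nodes:
        deg = len(adj[v])
        # clustering
        pairs = list(itertools.combinations(adj[v], 2))
        clust = (sum(1 for a, b in pairs if b in adj[a]) / len(pairs)) if pairs else 0.0
        dist = _bfs_distances(adj, v)
        reach = len(dist) - 1
        total = sum(dist.values())
        closeness = (reach / total) * (reach / (n - 1)) if total > 0 and n > 1 else 0.0
        ecc = max(dist.values()) if reach else 0.0
        status = float(total)
        # ego density
        ego_nodes = adj[v] | {v}
        ego_edges = sum(1 for a, b in itertools.combinations(ego_nodes, 2)
                        if b in adj[a])
        possible = len(ego_nodes) * (len(ego_nodes) - 1) / 2
        ego_density = ego_edges / possible if possible else 0.0
        out[v] = {"degree": float(deg), "clustering": clust, "closeness": closeness,
                  "eccentricity": float(ecc), "status": status,
                  "ego_density": ego_density}
    # betweenness by explicit shortest-path enumeration
    for v in nodes:
        out[v]["betweenness"] = 0.0
    for s, t in itertools.combinations(nodes, 2):
        dist = _bfs_distances(adj, s)
        if t not in dist:
            continue
        # count shortest paths through each node by dynamic programming
        sigma = {u: 0 for u in nodes}
        sigma[s] = 1
        order = sorted([u for u in dist], key=lambda u: dist[u])
        for u in order:
            for w in adj[u]:
                if w in dist and dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
        dist_t = _bfs_distances(adj, t)
        for v in nodes:
            if v in (s, t) or v not in dist or t not in dist:
                continue
            if dist[v] + dist_t.get(v, float("inf")) == dist[t] and sigma[t]:
                sigma_v_t = 0
                # paths through v = sigma[s->v] * sigma[v->t]
                sigma_t_from_v = {u: 0 for u in nodes}
                sigma_t_from_v[v] = 1
                for u in sorted([u for u in dist_t], key=lambda u: dist_t[u]):
                    for w in adj[u]:
                        if w in dist_t and dist_t[w] == dist_t[u] + 1 and \
                                dist.get(u, -1) >= dist[v]:
                            pass
                sigma_v = sigma[v]
                # recompute forward from v
                dv = _bfs_distances(adj, v)
                sig_v = {u: 0 for u in nodes}
                sig_v[v] = 1
                for u in sorted([u for u in dv], key=lambda u: dv[u]):
                    for w in adj[u]:
                        if w in dv and dv[w] == dv[u] + 1:
                            sig_v[w] += sig_v[u]
                sigma_v_t = sig_v.get(t, 0)
                out[v]["betweenness"] += sigma_v * sigma_v_t / sigma[t]
    return out


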