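"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain double loops / exhaustive
enumeration / dense sampling, independent of the library's vectorized code
paths, so that equality against these functions is a genuine cross-check.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np


def min_image_dist(a, b, box, periodic):
    d = np.asarray(b, float) - np.asarray(a, float)
    for k in range(3):
        if periodic[k]:
            d[k] -= box[k] * round(d[k] / box[k])
    return float(np.sqrt((d**2).sum()))


def brute_hbonds(config, topo, dist_cutoff=3.5, angle_cutoff=30.0):
    """All-triples donor/acceptor filter; returns {(donor, acceptor)}."""
    out = set()
    for heavy, hyd in topo.donors:
        for acc in sorted(topo.acceptors):
            if heavy == acc:
                continue
            if topo.molecule_of[heavy] == topo.molecule_of[acc]:
                continue
            d = min_image_dist(
                config.coords[heavy], config.coords[acc], config.box, config.periodic
            )
            if d > dist_cutoff:
                continue
            if hyd is not None:
                hd = np.asarray(config.coords[heavy]) - config.coords[hyd]
                ha = np.asarray(config.coords[acc]) - config.coords[hyd]
                for k in range(3):
                    if config.periodic[k]:
                        hd[k] -= config.box[k] * round(hd[k] / config.box[k])
                        ha[k] -= config.box[k] * round(ha[k] / config.box[k])
                cosang = np.dot(hd, ha) / (np.linalg.norm(hd) * np.linalg.norm(ha))
                dev = 180.0 - np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                if dev > angle_cutoff:
                    continue
            out.add((heavy, acc))
    return out


def brute_gamma(config, topo, cutoff, species3):
    """Explicit per-molecule distance classification and direct counting."""
    prot = topo.protein_molecules()
    assert len(prot) == 1
    pa = topo.atoms_of(prot[0])

    def mol_surface_dist(m):
        best = np.inf
        for a in topo.atoms_of(m):
            for p in pa:
                d = min_image_dist(
                    config.coords[a], config.coords[p], config.box, config.periodic
                ) - topo.radius_of[int(p)]
                best = min(best, d)
        return best

    n3l = n3b = n1l = n1b = 0
    for m, sp in topo.species_of.items():
        if sp == "protein":
            continue
        local = mol_surface_dist(m) <= cutoff
        if sp == species3:
            n3l += local
            n3b += not local
        elif sp == "water":
            n1l += local
            n1b += not local
    if n1b == 0 and n1l == 0:
        return float(n3l)
    return n3l - (n3b / n1b) * n1l


def enumerate_bridge_triplets(bonds_as_mol_pairs, species_of):
    """Exhaustive D-A-D / P-A-D triplet enumeration over a molecule bond list."""
    partners: dict = {}
    for u, v in bonds_as_mol_pairs:
        for a, b in ((u, v), (v, u)):
            if species_of[a] == "anion":
                partners.setdefault(a, set()).add(b)
    dad = set()
    pad = set()
    for anion, ps in partners.items():
        dends = sorted(p for p in ps if species_of[p] == "dendrimer")
        prots = sorted(p for p in ps if species_of[p] == "protein")
        for d1, d2 in combinations(dends, 2):
            dad.add((d1, anion, d2))
        for pr in prots:
            for d in dends:
                pad.add((pr, anion, d))
    return dad, pad


def dfs_components(nodes, edges):
    """Depth-first-search connected components; returns frozensets."""
    adj: dict = {n: set() for n in nodes}
    for u, v in edges:
        if u in adj and v in adj:
            adj[u].add(v)
            adj[v].add(u)
    seen = set()
    comps = []
    for n in nodes:
        if n in seen:
            continue
        stack = [n]
        comp = set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


def brute_rdf_histogram(config, pts_a, pts_b, edges, same):
    """Double-loop minimum-image pair histogram (ordered pairs)."""
    h = np.zeros(len(edges) - 1)
    for i, a in enumerate(pts_a):
        for j, b in enumerate(pts_b):
            if same and i == j:
                continue
            d = min_image_dist(a, b, config.box, config.periodic)
            k = np.searchsorted(edges, d, side="right") - 1
            if 0 <= k < len(h) and d < edges[-1]:
                h[k] += 1
    return h


def sampled_sphere_area(center, r_exp, occluder_centers, occluder_r_exp,
                        n_samples, seed):
    """Accessible area of one expanded sphere by dense random sampling."""
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_samples, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pts = center + r_exp * v
    buried = np.zeros(n_samples, bool)
    for c, r in zip(np.atleast_2d(occluder_centers), np.atleast_1d(occluder_r_exp)):
        buried |= ((pts - c) ** 2).sum(axis=1) < r**2
    return (1.0 - buried.mean()) * 4.0 * np.pi * r_exp**2


def grid_shell_volume(coords, radii, solute_radius, spacing=0.25):
    """Grid integration of the solute-center-excluded shell volume (Å³)."""
    coords = np.atleast_2d(coords)
    radii = np.atleast_1d(radii)
    expanded = radii + solute_radius
    lo = (coords - expanded[:, None]).min(axis=0)
    hi = (coords + expanded[:, None]).max(axis=0)
    axes = [np.arange(lo[k] + spacing / 2, hi[k], spacing) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    in_exp = np.zeros(len(pts), bool)
    in_bare = np.zeros(len(pts), bool)
    for c, r, re in zip(coords, radii, expanded):
        d2 = ((pts - c) ** 2).sum(axis=1)
        in_exp |= d2 < re**2
        in_bare |= d2 < r**2
    return float(np.sum(in_exp & ~in_bare)) * spacing**3
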