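"""Independent brute-force oracles for the descriptor engine.

These rebuild everything from scratch — adjacency lists straight from the
RDKit bond table, the closure edge appended by hand, deltas recounted by
walking neighbours — and never touch the package's graph machinery, so
agreement is a genuine cross-check.
"""

from __future__ import annotations

from collections import deque

from rdkit import Chem

_ZV = {"C": 4, "N": 5, "O": 6, "F": 7, "Si": 4, "P": 5, "S": 6, "Cl": 7, "Br": 7}
_Z = {"C": 6, "N": 7, "O": 8, "F": 9, "Si": 14, "P": 15, "S": 16, "Cl": 17, "Br": 35}
_SECOND_ROW = {"C", "N", "O", "F"}


def brute_force_graph(smiles: str):
    """(adjacency lists, edge list, element list, h list) of the heavy-atom
    graph with the closure edge, indices 0..n-1 in RDKit heavy-atom order."""
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 0]
    remap = {orig: k for k, orig in enumerate(heavy)}
    elements = [mol.GetAtomWithIdx(o).GetSymbol() for o in heavy]
    h_counts = [mol.GetAtomWithIdx(o).GetTotalNumHs() for o in heavy]

    attach = []
    for a in mol.GetAtoms():
        if a.GetAtomicNum() == 0:
            (nbr,) = a.GetNeighbors()
            attach.append(remap[nbr.GetIdx()])
    assert len(attach) == 2

    adj = [[] for _ in heavy]
    edges = []
    for b in mol.GetBonds():
        i, j = b.GetBeginAtom(), b.GetEndAtom()
        if i.GetAtomicNum() == 0 or j.GetAtomicNum() == 0:
            continue
        u, v = remap[i.GetIdx()], remap[j.GetIdx()]
        adj[u].append(v)
        adj[v].append(u)
        edges.append((u, v))
    u, v = attach
    adj[u].append(v)
    adj[v].append(u)
    edges.append((u, v))  # the closure edge, exactly once
    return adj, edges, elements, h_counts, attach


def brute_force_deltas(smiles: str):
    adj, _, elements, h_counts, _ = brute_force_graph(smiles)
    delta = [len(nbrs) for nbrs in adj]
    delta_v = []
    for el, h in zip(elements, h_counts):
        if el in _SECOND_ROW:
            delta_v.append(float(_ZV[el] - h))
        else:
            delta_v.append((_ZV[el] - h) / (_Z[el] - _ZV[el] - 1))
    return delta, delta_v


def brute_force_chi(smiles: str):
    """(chi0, chi0v, chi1, chi1v) by direct summation over the rebuilt graph."""
    adj, edges, _, _, _ = brute_force_graph(smiles)
    delta, delta_v = brute_force_deltas(smiles)
    chi0 = sum(d ** -0.5 for d in delta)
    chi0v = sum(d ** -0.5 for d in delta_v)
    chi1 = sum((delta[u] * delta[v]) ** -0.5 for u, v in edges)
    chi1v = sum((delta_v[u] * delta_v[v]) ** -0.5 for u, v in edges)
    return chi0, chi0v, chi1, chi1v


def bfs_backbone_distance(smiles: str) -> int:
    """Number of atoms on a shortest attachment-to-attachment path (BFS
    distance + 1), computed without the closure edge."""
    adj, edges, _, _, (src, dst) = brute_force_graph(smiles)
    # drop the closure edge (the last one appended)
    u, v = edges[-1]
    adj = [list(nbrs) for nbrs in adj]
    adj[u].remove(v)
    adj[v].remove(u)
    if src == dst:
        return 1
    dist = {src: 0}
    q = deque([src])
    while q:
        x = q.popleft()
        for y in adj[x]:
            if y not in dist:
                dist[y] = dist[x] + 1
                q.append(y)
    return dist[dst] + 1
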