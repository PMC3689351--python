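"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by direct enumeration, independently of
the implementation path it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_variable_sites(seqs: list) -> list:
    """1-based columns with >= 2 distinct non-N states, by direct scan."""
    out = []
    for j in range(len(seqs[0])):
        states = {s[j] for s in seqs if s[j] != "N"}
        if len(states) >= 2:
            out.append(j + 1)
    return out


def naive_collapse(seqs: list, policy: str) -> tuple:
    """(sorted group sizes, n excluded) by pairwise comparison.

    Identity is agreement at every variable column; under ``strict`` any
    sequence with N at a variable column is excluded; under ``resolve`` it
    joins the unique group matching all its non-N variable columns, else
    it is excluded.
    """
    var = [c - 1 for c in naive_variable_sites(seqs)]
    complete = [s for s in seqs if all(s[c] != "N" for c in var)]
    partial = [s for s in seqs if any(s[c] == "N" for c in var)]

    groups: list = []
    for s in complete:
        for g in groups:
            if all(g[0][c] == s[c] for c in var):
                g.append(s)
                break
        else:
            groups.append([s])

    excluded = 0
    for s in partial:
        if policy == "strict":
            excluded += 1
            continue
        known = [c for c in var if s[c] != "N"]
        matches = [g for g in groups if all(g[0][c] == s[c] for c in known)]
        if len(matches) == 1:
            matches[0].append(s)
        else:
            excluded += 1
    return sorted(len(g) for g in groups), excluded


def naive_fst(labels_a: list, labels_b: list) -> float:
    """F_ST by explicit enumeration of every individual pair."""

    def mean_within(labels):
        pairs = list(itertools.combinations(range(len(labels)), 2))
        return sum(labels[i] != labels[j] for i, j in pairs) / len(pairs)

    d_w_a = mean_within(labels_a)
    d_w_b = mean_within(labels_b)
    cross = [(i, j) for i in range(len(labels_a)) for j in range(len(labels_b))]
    d_b = sum(labels_a[i] != labels_b[j] for i, j in cross) / len(cross)
    if d_b == 0:
        return 0.0
    return (d_b - 0.5 * (d_w_a + d_w_b)) / d_b


def steiner_cost(seqs: list) -> int:
    """Exact Steiner minimal tree cost in the Hamming metric.

    Dreyfus-Wagner dynamic program over the lattice of all per-column
    observed states (exhaustive over every possible Steiner-point set).
    """
    cols = list(zip(*seqs))
    options = [sorted(set(c)) for c in cols]
    lattice = ["".join(p) for p in itertools.product(*options)] or [""]
    n = len(lattice)
    idx = {s: i for i, s in enumerate(lattice)}
    mat = np.array([np.frombuffer(s.encode(), dtype=np.uint8) for s in lattice])
    if mat.size == 0:
        mat = mat.reshape(n, 0)
    d = (mat[:, None, :] != mat[None, :, :]).sum(axis=2)
    terms = [idx[s] for s in seqs]
    if len(terms) <= 1:
        return 0
    t0, rest = terms[0], terms[1:]
    m = len(rest)
    INF = 10**9
    S = np.full((1 << m, n), INF, dtype=np.int64)
    for i, t in enumerate(rest):
        S[1 << i] = d[t]
    for mask in range(1, 1 << m):
        if mask & (mask - 1) == 0:
            continue
        best = np.full(n, INF, dtype=np.int64)
        sub = (mask - 1) & mask
        while sub:
            if sub < (mask ^ sub):
                np.minimum(best, S[sub] + S[mask ^ sub], out=best)
            sub = (sub - 1) & mask
        S[mask] = np.min(best[None, :] + d, axis=1)
    return int(S[(1 << m) - 1][t0])


def genealogy_instance(rng: np.random.Generator) -> list:
    """Random haplotype set grown along a genealogy (homoplasy allowed).

    Each new haplotype copies an existing one and flips 1-2 uniformly
    chosen sites; sites may be hit repeatedly (recurrent mutation).
    """
    nsites = int(rng.integers(2, 7))
    nhap = min(int(rng.integers(2, 6)), 2**nsites)
    seqs = ["A" * nsites]
    tries = 0
    while len(seqs) < nhap and tries < 100:
        tries += 1
        parent = list(seqs[int(rng.integers(len(seqs)))])
        for _ in range(int(rng.integers(1, 3))):
            j = int(rng.integers(nsites))
            parent[j] = "G" if parent[j] == "A" else "A"
        s = "".join(parent)
        if s not in seqs:
            seqs.append(s)
    return seqs
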