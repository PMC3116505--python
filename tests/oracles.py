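"""Independent brute-force oracles used to validate the algebraic paths.

These deliberately re-derive every quantity by naive enumeration (explicit
loops over triples, direct probability summation) and share no code with the
package's vectorized implementations.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np

from darffc.census import AUTOCONFIGS, MODE_PAIRS, TARGET_KINDS, CircuitCategory


def brute_force_census(matrix, modes, tf_gene_ids=None, edge_signs=None):
    """Count every category by explicit triple enumeration.

    Returns (counts dict keyed by CircuitCategory, excluded_unmoded).
    """
    M = np.asarray(matrix.entries, dtype=int)
    G, T = M.shape
    rows = [matrix.tf_row_of[s] for s in matrix.tf_symbols]
    auto = [bool(M[rows[j], j]) for j in range(T)]
    tf_genes = set(rows)
    if tf_gene_ids is not None:
        idx = {g: i for i, g in enumerate(matrix.gene_ids)}
        tf_genes |= {idx[g] for g in tf_gene_ids if g in idx}
    sign_letter = {1: "P", -1: "N"}
    tf_sign = [
        {"activator": 1, "repressor": -1}.get(
            modes.mode_of.get(matrix.tf_symbols[j], "unspecified"), 0
        )
        if modes is not None
        else 0
        for j in range(T)
    ]

    def edge_sign(z, j):
        if edge_signs is not None:
            return int(edge_signs[z, j]) if M[z, j] else 0
        return tf_sign[j] if M[z, j] else 0

    counts = Counter()
    excluded = 0
    for x in range(T):
        for y in range(T):
            if x == y or not M[rows[y], x]:
                continue
            ac = {
                (True, True): "double",
                (False, True): "intermediary_only",
                (True, False): "originating_only",
                (False, False): "none",
            }[(auto[x], auto[y])]
            counts[CircuitCategory("backbone_autoconfig", "any", ac)] += 1
            if tf_sign[x] and tf_sign[y]:
                mp = sign_letter[tf_sign[x]] + sign_letter[tf_sign[y]]
                counts[CircuitCategory("backbone_combined", mp, ac)] += 1
            for z in range(G):
                if z == rows[x] or z == rows[y]:
                    continue
                if not (M[z, x] and M[z, y]):
                    continue
                tk = "TF" if z in tf_genes else "effecter"
                counts[CircuitCategory("total", target_kind=tk)] += 1
                counts[CircuitCategory("total")] += 1
                counts[CircuitCategory("autoconfig", "any", ac, tk)] += 1
                s1, s2 = edge_sign(z, x), edge_sign(z, y)
                if s1 and s2:
                    mp = sign_letter[s1] + sign_letter[s2]
                    counts[CircuitCategory("coherence", mp, "any", tk)] += 1
                    counts[CircuitCategory("combined", mp, ac, tk)] += 1
                else:
                    excluded += 1
    counts[CircuitCategory("autoregulation")] = sum(auto)
    # fill zeros for the full canonical key set
    for tk in TARGET_KINDS:
        counts.setdefault(CircuitCategory("total", target_kind=tk), 0)
        for mp in MODE_PAIRS:
            counts.setdefault(CircuitCategory("coherence", mp, "any", tk), 0)
            for ac in AUTOCONFIGS:
                counts.setdefault(CircuitCategory("combined", mp, ac, tk), 0)
        for ac in AUTOCONFIGS:
            counts.setdefault(CircuitCategory("autoconfig", "any", ac, tk), 0)
    for ac in AUTOCONFIGS:
        counts.setdefault(CircuitCategory("backbone_autoconfig", "any", ac), 0)
        for mp in MODE_PAIRS:
            counts.setdefault(CircuitCategory("backbone_combined", mp, ac), 0)
    counts.setdefault(CircuitCategory("total"), 0)
    return dict(counts), excluded


def binom_upper_tail(f, D, r):
    """P(K >= f) by direct summation of binomial mass."""
    return sum(
        math.comb(D, k) * r**k * (1 - r) ** (D - k) for k in range(f, D + 1)
    )


def brute_force_triangles(edges):
    """All ordered (x, y, z) with (x,y), (x,z), (y,z) in the edge set."""
    nodes = sorted({n for e in edges for n in e})
    out = []
    for x in nodes:
        for y in nodes:
            for z in nodes:
                if len({x, y, z}) == 3 and (x, y) in edges and (x, z) in edges and (y, z) in edges:
                    out.append((x, y, z))
    return out


def degree_equivalent_matrices(M):
    """All binary matrices with the row/column sums of M (tiny inputs only)."""
    M = np.asarray(M, dtype=int)
    G, T = M.shape
    row_sums = M.sum(axis=1)
    col_sums = M.sum(axis=0)
    out = []
    total = M.sum()
    cells = G * T
    for bits in range(1 << cells):
        if bits.bit_count() != total:
            continue
        cand = np.array([(bits >> i) & 1 for i in range(cells)]).reshape(G, T)
        if (cand.sum(axis=1) == row_sums).all() and (cand.sum(axis=0) == col_sums).all():
            out.append(cand)
    return out
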