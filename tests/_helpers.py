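"""Shared test utilities: independent oracles kept deliberately naive."""

from __future__ import annotations

import numpy as np

from gliascan import phylo


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """A random binary tree with uniform(0.1, 2) branch lengths; returns
    (newick, ids).  Distances derived from it are exactly additive."""
    labels = [f"L{i}" for i in range(n_leaves)]

    def build(names):
        if len(names) == 1:
            return names[0]
        k = int(rng.integers(1, len(names)))
        left, right = build(names[:k]), build(names[k:])
        bl, br = rng.uniform(0.1, 2.0, size=2)
        return f"({left}:{bl:.6f},{right}:{br:.6f})"

    order = list(rng.permutation(labels))
    return build(order) + ";", labels


def tree_distance_matrix(newick: str, ids) -> np.ndarray:
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    return phylo.path_length_matrix(tree, ids)


def naive_substring_hits(protein: str, table) -> list[tuple[str, int]]:
    """O(n*m) all-substrings epitope scan: the brute-force oracle."""
    hits = []
    for name in table:
        pep = table[name]
        for off in range(len(protein) - len(pep) + 1):
            if protein[off : off + len(pep)] == pep:
                hits.append((name, off))
    return sorted(hits, key=lambda h: (h[1], h[0]))


def brute_force_windows(genome: str, query: str, min_identity: float):
    """Every equal-length window scored by hamming identity (valid for
    substitution-only fixtures); overlapping qualifying windows are merged
    to the best-identity interval."""
    g = np.frombuffer(genome.encode(), dtype=np.uint8)
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    L = len(q)
    if len(g) < L:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(g, L)
    ident = (windows == q).mean(axis=1)
    hits = [(int(i), float(ident[i])) for i in np.flatnonzero(ident >= min_identity)]
    merged = []
    for start, idy in hits:
        if merged and start < merged[-1][0] + L:
            if idy > merged[-1][1]:
                merged[-1] = (start, idy)
        else:
            merged.append((start, idy))
    return [(s, s + L) for s, _ in merged]


def exhaustive_codon_loglik(alignment, tree_lengths, kappa, weights, omegas, pi):
    """Site likelihood by explicit summation over the 61 internal-node
    states of a 3-taxon star tree (one internal node)."""
    from gliascan import _codon

    qs = [_codon.gy94_rate_matrix(kappa, w, pi) for w in omegas]
    rate = float(np.dot(weights, [_codon.expected_rate(q, pi) for q in qs]))
    props = [_codon.CodonPropagator(q / rate, pi) for q in qs]
    ids = list(alignment.ids)
    rows = dict(zip(alignment.ids, alignment.rows))
    n_codons = len(rows[ids[0]]) // 3
    states = {
        k: [_codon.CODON_INDEX[rows[k][3 * i : 3 * i + 3]] for i in range(n_codons)]
        for k in ids
    }
    total = 0.0
    for site in range(n_codons):
        site_l = 0.0
        for w, prop in zip(weights, props):
            pmats = {k: prop.prob_matrix(tree_lengths[k]) for k in ids}
            like = sum(
                pi[s] * np.prod([pmats[k][s, states[k][site]] for k in ids])
                for s in range(61)
            )
            site_l += w * like
        total += np.log(site_l)
    return total
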