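"""Codon-aware alignment, K2P(+Γ) distances, neighbor-joining and clade
assignment for gliadin gene copies.

The distance is Kimura's two-parameter model, separating the transition
proportion P from the transversion proportion Q:

    d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)

optionally with gamma-distributed rate variation across sites (shape α,
default 2.25):

    d = (α/2)[(1 − 2P − Q)^(−1/α) − 1] + (α/4)[(1 − 2Q)^(−1/α) − 1]

Trees are built with canonical neighbor joining (Q-criterion, ties broken by
the lowest index pair so runs are platform-deterministic) and supported by
codon-granular bootstrap resampling.  Clade assignment groups leaves into
maximal subtrees dominated by one locus label and flags copies that sit in a
clade of another locus — the tree-based evidence used to reassign unanchored
(chrUn) copies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from ._codon import STOP_CODONS, translate_codon
from .gene_discovery import _protein_aligner

logger = logging.getLogger(__name__)

DEFAULT_GAMMA_SHAPE = 2.25
DEFAULT_CEILING = 5.0
GAP_CODON = "---"


@dataclass(frozen=True)
class CodonAlignment:
    """Aligned codon sequences: equal-length rows over {A,C,G,T,-} whose
    length is a multiple of 3, with gaps in whole-codon triplets."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows have unequal lengths")
        if self.rows and len(self.rows[0]) % 3 != 0:
            raise ValueError("alignment length must be a multiple of 3")
        for sid, row in zip(self.ids, self.rows):
            if set(row) - set("ACGT-"):
                raise ValueError(f"{sid}: invalid characters in row")
            for i in range(0, len(row), 3):
                codon = row[i : i + 3]
                if "-" in codon and codon != GAP_CODON:
                    raise ValueError(
                        f"{sid}: gap not in whole-codon triplet at column {i}"
                    )

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def codon_columns(self) -> np.ndarray:
        """(n_seq, n_codons) array of codon strings."""
        return np.array(
            [[r[3 * i : 3 * i + 3] for i in range(self.n_codons)] for r in self.rows]
        )

    def subset_codons(self, codon_idx: Sequence[int]) -> "CodonAlignment":
        rows = tuple(
            "".join(r[3 * i : 3 * i + 3] for i in codon_idx) for r in self.rows
        )
        return CodonAlignment(self.ids, rows)

    def to_fasta(self, path) -> None:
        from .synthetic_data import write_fasta

        write_fasta(dict(zip(self.ids, self.rows)), path)

    @classmethod
    def from_fasta(cls, path) -> "CodonAlignment":
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        return cls(
            tuple(r.id for r in records),
            tuple(str(r.seq).upper() for r in records),
        )


# ---------------------------------------------------------------------------
# Protein-guided progressive (center-star) codon alignment
# ---------------------------------------------------------------------------

def _translate_for_alignment(cds: str, sid: str) -> str:
    if len(cds) % 3 != 0:
        raise ValueError(f"{sid}: CDS length {len(cds)} is not a multiple of 3")
    codons = [cds[3 * i : 3 * i + 3] for i in range(len(cds) // 3)]
    if any(c in STOP_CODONS for c in codons[:-1]):
        raise ValueError(f"{sid}: internal stop codon; clean the input first")
    return "".join(
        "*" if c in STOP_CODONS else translate_codon(c) for c in codons
    )


def _kmer_set(seq: str, k: int = 3) -> set[str]:
    return {seq[i : i + k] for i in range(max(len(seq) - k + 1, 1))}


def align_codons(cds_by_id: Mapping[str, str]) -> CodonAlignment:
    """Codon-aware multiple alignment via a protein-guided center-star:
    proteins are aligned pairwise to the most central sequence (highest
    total 3-mer similarity), merged once-a-gap-always-a-gap, and
    back-projected to codons."""
    ids = list(cds_by_id)
    if not ids:
        raise ValueError("no sequences to align")
    cds = {sid: cds_by_id[sid].upper() for sid in ids}
    proteins = {sid: _translate_for_alignment(cds[sid], sid) for sid in ids}
    if len(ids) == 1:
        return CodonAlignment((ids[0],), (cds[ids[0]],))

    kmers = {sid: _kmer_set(proteins[sid]) for sid in ids}

    def similarity(a, b):
        inter = len(kmers[a] & kmers[b])
        union = len(kmers[a] | kmers[b]) or 1
        return inter / union

    center = max(ids, key=lambda s: (sum(similarity(s, o) for o in ids), s))
    others = [s for s in ids if s != center]
    aligner = _protein_aligner()

    cprot = proteins[center]
    n = len(cprot)
    # per sequence: residue aligned to each center position, plus insertions
    aligned_to: dict[str, list[str]] = {}
    inserts: dict[str, dict[int, list[str]]] = {}
    for sid in others:
        alignment = aligner.align(cprot, proteins[sid])[0]
        row_c, row_s = str(alignment[0]), str(alignment[1])
        pos_map = ["-"] * n
        ins: dict[int, list[str]] = {}
        ci = 0
        for a, b in zip(row_c, row_s):
            if a == "-":
                ins.setdefault(ci, []).append(b)
            else:
                if b != "-":
                    pos_map[ci] = b
                ci += 1
        aligned_to[sid] = pos_map
        inserts[sid] = ins

    max_ins = [0] * (n + 1)
    for sid in others:
        for slot, chars in inserts[sid].items():
            max_ins[slot] = max(max_ins[slot], len(chars))

    def build_row(sid: str) -> str:
        if sid == center:
            parts = []
            for slot in range(n + 1):
                parts.append("-" * max_ins[slot])
                if slot < n:
                    parts.append(cprot[slot])
            return "".join(parts)
        parts = []
        ins = inserts[sid]
        pos_map = aligned_to[sid]
        for slot in range(n + 1):
            chars = ins.get(slot, [])
            parts.append("".join(chars) + "-" * (max_ins[slot] - len(chars)))
            if slot < n:
                parts.append(pos_map[slot])
        return "".join(parts)

    rows = []
    for sid in ids:
        prot_row = build_row(sid)
        codons = [cds[sid][3 * i : 3 * i + 3] for i in range(len(cds[sid]) // 3)]
        it = iter(codons)
        rows.append(
            "".join(GAP_CODON if ch == "-" else next(it) for ch in prot_row)
        )
    return CodonAlignment(tuple(ids), tuple(rows))


# ---------------------------------------------------------------------------
# K2P (+gamma) distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray  # substitutions/site
    alpha: float  # gamma shape; math.inf = plain K2P
    saturated: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self):
        m = self.matrix
        if m.shape != (len(self.ids),) * 2:
            raise ValueError("matrix shape does not match ids")
        if (np.diag(m) != 0).any():
            raise ValueError("diagonal must be zero")
        if (m < 0).any():
            raise ValueError("distances must be non-negative")
        if np.abs(m - m.T).max() > 1e-12:
            raise ValueError("matrix must be symmetric")

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for sid, row in zip(self.ids, self.matrix):
                fh.write(sid + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")


_PURINES = {"A", "G"}


def k2p_pair(p: float, q: float, alpha: float = math.inf,
             ceiling: float = DEFAULT_CEILING) -> tuple[float, bool]:
    """K2P distance for transition/transversion proportions (P, Q); returns
    (distance, saturated_flag).  Saturated pairs (log/power argument ≤ 0)
    get the ceiling distance."""
    w1, w2 = 1.0 - 2.0 * p - q, 1.0 - 2.0 * q
    if w1 <= 0 or w2 <= 0:
        return ceiling, True
    if math.isinf(alpha):
        d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    else:
        d = (alpha / 2.0) * (w1 ** (-1.0 / alpha) - 1.0) + (
            alpha / 4.0
        ) * (w2 ** (-1.0 / alpha) - 1.0)
    return max(d, 0.0), False


def k2p_gamma_distance(
    alignment: CodonAlignment,
    alpha: float = DEFAULT_GAMMA_SHAPE,
    deletion: str = "complete",
    ceiling: float = DEFAULT_CEILING,
) -> DistanceMatrix:
    """Pairwise K2P(+Γ) distances over the alignment.

    ``deletion='complete'`` (default) removes every codon column containing
    a gap in any row before computing proportions; ``'pairwise'`` uses, for
    each pair, the sites where both rows are ungapped.
    """
    if len(alignment.ids) < 2:
        raise ValueError("need at least 2 sequences")
    if deletion not in {"complete", "pairwise"}:
        raise ValueError("deletion must be 'complete' or 'pairwise'")
    arr = np.array([list(r) for r in alignment.rows])
    if deletion == "complete":
        gap_cols = (arr == "-").any(axis=0)
        # codon granularity: a gap anywhere in a codon kills the whole codon
        gap_codon = gap_cols.reshape(-1, 3).any(axis=1)
        keep = np.repeat(~gap_codon, 3)
        arr = arr[:, keep]

    n = len(alignment.ids)
    dist = np.zeros((n, n))
    saturated: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arr[i], arr[j]
            ok = (a != "-") & (b != "-")
            total = int(ok.sum())
            if total == 0:
                d, flag = ceiling, True
            else:
                diff = ok & (a != b)
                ts = 0
                for x, y in zip(a[diff], b[diff]):
                    ts += (x in _PURINES) == (y in _PURINES)
                p = ts / total
                q = (int(diff.sum()) - ts) / total
                d, flag = k2p_pair(p, q, alpha, ceiling)
            dist[i, j] = dist[j, i] = d
            if flag:
                saturated.add((alignment.ids[i], alignment.ids[j]))
                logger.warning(
                    "saturated pair (%s, %s): distance set to ceiling %.2f",
                    alignment.ids[i], alignment.ids[j], ceiling,
                )
    return DistanceMatrix(alignment.ids, dist, alpha, saturated)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Canonical neighbor joining (Saitou–Nei, Q-criterion join selection,
    standard branch-length updates).  Ties break on the lowest (row, column)
    index pair; negative branch-length estimates are clamped to 0."""
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = dm.matrix.astype(float).copy()
    labels = [_quote_label(sid) for sid in dm.ids]
    subtrees = list(labels)
    active = list(range(n))

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("negative NJ branch length %.4g clamped to 0", x)
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        qmat = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(qmat, np.inf)
        flat = int(np.argmin(qmat))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        li = clamp(0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2)))
        lj = clamp(dij - li)
        new_sub = f"({subtrees[ai]}:{li:.10g},{subtrees[aj]}:{lj:.10g})"
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (ai, aj):
                continue
            new_row[k] = 0.5 * (d[ai, k] + d[aj, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row[:-1]
        d[:-1, -1] = new_row[:-1]
        subtrees.append(new_sub)
        active = [k for k in active if k not in (ai, aj)] + [d.shape[0] - 1]

    a, b, c = active
    la = clamp(0.5 * (d[a, b] + d[a, c] - d[b, c]))
    lb = clamp(0.5 * (d[a, b] + d[b, c] - d[a, c]))
    lc = clamp(0.5 * (d[a, c] + d[b, c] - d[a, b]))
    newick = (
        f"({subtrees[a]}:{la:.10g},{subtrees[b]}:{lb:.10g},"
        f"{subtrees[c]}:{lc:.10g});"
    )
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    tree.is_rooted = False
    return tree


def _quote_label(label: str) -> str:
    if any(ch in label for ch in "(),:;[] \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def path_length_matrix(tree: dendropy.Tree, ids: Sequence[str]) -> np.ndarray:
    """Leaf-to-leaf patristic distances in the order of ``ids``."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(
                taxa[ids[i]], taxa[ids[j]]
            )
    return out


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits, each written as the leaf set on the side not
    containing the lexicographically smallest taxon."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref = leaves[0]
    n = len(leaves)
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = frozenset(leaves) - side
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return splits


def bootstrap_support(
    alignment: CodonAlignment,
    b_replicates: int = 1000,
    alpha: float = DEFAULT_GAMMA_SHAPE,
    seed: int = 0,
    deletion: str = "complete",
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """NJ tree of the full alignment with bootstrap supports (% of
    replicates containing each original bipartition).  Resampling is
    codon-granular; replicates whose distance matrix degenerates (all pairs
    saturated) are skipped and supports are normalized over the rest."""
    if b_replicates < 1:
        raise ValueError("need at least 1 bootstrap replicate")
    dm = k2p_gamma_distance(alignment, alpha, deletion)
    tree = nj_tree(dm)
    original = tree_bipartitions(tree)
    counts = {s: 0 for s in original}
    rng = np.random.default_rng(seed)
    n_codons = alignment.n_codons
    successful = 0
    for _ in range(b_replicates):
        idx = rng.integers(0, n_codons, size=n_codons)
        rep = alignment.subset_codons(list(idx))
        try:
            rep_dm = k2p_gamma_distance(rep, alpha, deletion)
            if len(rep_dm.saturated) == len(rep_dm.ids) * (len(rep_dm.ids) - 1) // 2:
                raise ValueError("all pairs saturated")
            rep_tree = nj_tree(rep_dm)
        except ValueError as exc:
            logger.warning("bootstrap replicate skipped: %s", exc)
            continue
        successful += 1
        rep_splits = tree_bipartitions(rep_tree)
        for s in original:
            if s in rep_splits:
                counts[s] += 1
    if successful == 0:
        raise ValueError("no successful bootstrap replicates")
    supports = {s: 100.0 * c / successful for s, c in counts.items()}

    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    ref = leaves[0]
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if ref in side:
            side = frozenset(leaves) - side
        if side in supports:
            node.label = f"{supports[side]:.0f}"
    return tree, supports


# ---------------------------------------------------------------------------
# Clade membership
# ---------------------------------------------------------------------------

UNANCHORED_LABEL = "chrUn"


def clade_membership(
    tree: dendropy.Tree,
    locus_by_leaf: Mapping[str, str],
) -> dict:
    """Group leaves into maximal subtrees dominated (>50%) by one locus
    label; flag leaves whose own label disagrees with their clade
    (the misplaced-copy evidence); chrUn leaves inherit the clade label.

    Returns dict with 'clade_by_leaf', 'outliers' and 'clades'.
    """
    leaf_labels = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        if name not in locus_by_leaf:
            raise ValueError(f"leaf {name!r} has no locus label")
        leaf_labels[name] = locus_by_leaf[name]

    clade_by_leaf: dict[str, str | None] = {}
    clades: list[tuple[str | None, tuple[str, ...]]] = []

    def informative(labels):
        return [l for l in labels if l != UNANCHORED_LABEL]

    def dominant(labels):
        info = informative(labels)
        if not info:
            return None, 0, 0
        counts: dict[str, int] = {}
        for l in info:
            counts[l] = counts.get(l, 0) + 1
        best = max(sorted(counts), key=lambda k: counts[k])
        return best, counts[best], len(info)

    def assign(node, label):
        names = tuple(l.taxon.label for l in node.leaf_iter())
        clades.append((label, names))
        for name in names:
            clade_by_leaf[name] = label

    def recurse(node, fallback):
        names = [l.taxon.label for l in node.leaf_iter()]
        labels = [leaf_labels[n] for n in names]
        best, cnt, total = dominant(labels)
        if total == 0:
            assign(node, fallback)
            return
        if 2 * cnt > total:
            assign(node, best)
            return
        for child in node.child_nodes():
            recurse(child, best)

    recurse(tree.seed_node, None)

    outliers = sorted(
        name
        for name, label in leaf_labels.items()
        if label != UNANCHORED_LABEL and clade_by_leaf.get(name) not in (None, label)
    )
    return {
        "clade_by_leaf": clade_by_leaf,
        "outliers": outliers,
        "clades": clades,
    }
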