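"""Shared codon-model machinery: genetic code tables, the GY94 rate matrix,
F3x4 codon frequencies, and the discretized-beta omega mixtures used by the
M7/M8 site models.

Everything here works on the 61 sense codons of the standard nuclear code,
indexed in the fixed lexicographic order of :data:`SENSE_CODONS`.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable
from scipy.stats import beta as beta_dist

NUCS = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

_standard = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_standard.stop_codons))
ALL_CODONS = tuple("".join(c) for c in itertools.product(NUCS, repeat=3))
SENSE_CODONS = tuple(c for c in ALL_CODONS if c not in STOP_CODONS)
N_SENSE = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA = {c: _standard.forward_table[c] for c in SENSE_CODONS}

# Purine<->purine or pyrimidine<->pyrimidine single-nucleotide changes.
_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in _TRANSITIONS


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon, '*' for a stop codon."""
    if codon in CODON_AA:
        return CODON_AA[codon]
    if codon in STOP_CODONS:
        return "*"
    raise ValueError(f"not a valid codon: {codon!r}")


def _single_diff(c1: str, c2: str):
    """Position of the single differing nucleotide, or None if 0 or >1 differ."""
    diffs = [k for k in range(3) if c1[k] != c2[k]]
    if len(diffs) == 1:
        return diffs[0]
    return None


def _build_change_tables():
    """Precompute, for every ordered sense-codon pair differing at one
    nucleotide: (i, j, is_transition, is_synonymous)."""
    rows, cols, ts, syn = [], [], [], []
    for i, c1 in enumerate(SENSE_CODONS):
        for j, c2 in enumerate(SENSE_CODONS):
            if i == j:
                continue
            k = _single_diff(c1, c2)
            if k is None:
                continue
            rows.append(i)
            cols.append(j)
            ts.append(is_transition(c1[k], c2[k]))
            syn.append(CODON_AA[c1] == CODON_AA[c2])
    return (
        np.asarray(rows, dtype=np.intp),
        np.asarray(cols, dtype=np.intp),
        np.asarray(ts, dtype=bool),
        np.asarray(syn, dtype=bool),
    )


_ROWS, _COLS, _IS_TS, _IS_SYN = _build_change_tables()


def uniform_codon_freqs() -> np.ndarray:
    return np.full(N_SENSE, 1.0 / N_SENSE)


def f3x4_frequencies(codon_counts: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from observed sense-codon counts.

    Position-specific nucleotide frequencies are taken from the codon counts;
    the codon frequency is their product, renormalized over sense codons.
    A small pseudocount keeps unseen nucleotides at nonzero frequency.
    """
    counts = np.asarray(codon_counts, dtype=float)
    if counts.shape != (N_SENSE,):
        raise ValueError(f"expected counts over {N_SENSE} sense codons")
    pos_freq = np.full((3, 4), 0.1)
    for idx, codon in enumerate(SENSE_CODONS):
        for k in range(3):
            pos_freq[k, NUC_INDEX[codon[k]]] += counts[idx]
    pos_freq /= pos_freq.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            pos_freq[0, NUC_INDEX[c[0]]]
            * pos_freq[1, NUC_INDEX[c[1]]]
            * pos_freq[2, NUC_INDEX[c[2]]]
            for c in SENSE_CODONS
        ]
    )
    return pi / pi.sum()


def gy94_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unnormalized GY94 generator.

    Rates for single-nucleotide codon changes i->j are
    ``pi_j * kappa^[transition] * omega^[nonsynonymous]``; multi-nucleotide
    changes are 0; the diagonal makes rows sum to zero.
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("kappa must be > 0 and omega >= 0")
    pi = np.asarray(pi, dtype=float)
    q = np.zeros((N_SENSE, N_SENSE))
    rates = pi[_COLS].copy()
    rates[_IS_TS] *= kappa
    rates[~_IS_SYN] *= omega
    q[_ROWS, _COLS] = rates
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def expected_rate(q: np.ndarray, pi: np.ndarray) -> float:
    """Expected substitutions per codon per unit time under generator q."""
    return float(-np.dot(pi, np.diag(q)))


class CodonPropagator:
    """Transition-probability matrices P(t) = expm(Q t) for a reversible
    generator, via symmetric eigendecomposition (done once per generator)."""

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        sqrt_pi = np.sqrt(np.asarray(pi, dtype=float))
        s = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
        s = 0.5 * (s + s.T)  # symmetrize away rounding noise
        self._evals, self._evecs = np.linalg.eigh(s)
        self._left = self._evecs / sqrt_pi[:, None]
        self._right = self._evecs * sqrt_pi[:, None]

    def prob_matrix(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError("branch length must be >= 0")
        p = (self._left * np.exp(self._evals * t)) @ self._right.T
        np.clip(p, 0.0, None, out=p)
        p /= p.sum(axis=1, keepdims=True)
        return p


def discretize_beta(p: float, q: float, k: int = 10) -> np.ndarray:
    """K equal-probability categories of Beta(p, q); each category is
    represented by the median of its probability slice (CODEML convention)."""
    if p <= 0 or q <= 0:
        raise ValueError("beta parameters must be positive")
    if k < 1:
        raise ValueError("need at least one category")
    quantiles = (np.arange(k) + 0.5) / k
    return beta_dist.ppf(quantiles, p, q)


def omega_mixture(model: str, p: float, q: float, p0: float = 1.0,
                  omega_s: float = 1.0, k: int = 10):
    """(weights, omegas) for the M7 or M8 site-class mixture.

    M7: omega ~ discretized Beta(p, q), K classes of weight 1/K.
    M8: weight p0 on the beta classes plus weight (1 - p0) on a point mass
    at omega_s >= 1.
    """
    betas = discretize_beta(p, q, k)
    if model == "M7":
        return np.full(k, 1.0 / k), betas
    if model == "M8":
        if not 0.0 <= p0 <= 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        if omega_s < 1.0:
            raise ValueError("omega_s must be >= 1")
        weights = np.append(np.full(k, p0 / k), 1.0 - p0)
        omegas = np.append(betas, omega_s)
        return weights, omegas
    raise ValueError(f"unknown site model {model!r}")
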