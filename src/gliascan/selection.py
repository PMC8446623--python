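"""Codon site-model analysis of diversifying selection (M7 vs M8).

The model is GY94: codons substitute one nucleotide at a time with rate
π_j · κ^[transition] · ω^[nonsynonymous], where ω = dN/dS measures selective
pressure per codon site.  Site-to-site variation in ω follows a mixture:

* **M7** — ω ~ Beta(p, q), discretized into K = 10 equal-probability
  categories represented by their medians (no site may have ω > 1);
* **M8** — with probability p0 the beta mixture, with probability 1 − p0 a
  positively selected class at ω_s ≥ 1.

Both models are fitted by maximizing the Felsenstein pruning likelihood over
a fixed input tree (branch lengths rescaled by one free multiplier), with
F3x4 codon frequencies estimated from the data.  Positive selection is
tested by a likelihood-ratio test of M8 against M7 (χ², 2 degrees of
freedom), and sites are localized with empirical-Bayes posteriors of
membership in the selected class; sites with posterior > 0.95 are flagged.

Alignment cleanup mirrors the conservative conventions of site-model
practice: sequences with premature stops, frameshifts or missing terminal
stops are dropped, the terminal stop is stripped, all-gap codon columns are
removed, and hard-to-align polyglutamine regions are masked.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import chi2

from ._codon import (
    CodonPropagator,
    CODON_INDEX,
    N_SENSE,
    STOP_CODONS,
    expected_rate,
    f3x4_frequencies,
    gy94_rate_matrix,
    omega_mixture,
    translate_codon,
)
from .phylo import CodonAlignment, GAP_CODON

logger = logging.getLogger(__name__)

N_CATEGORIES = 10
DEFAULT_STARTS = 5
POSTERIOR_THRESHOLD = 0.95


# ---------------------------------------------------------------------------
# Alignment cleanup
# ---------------------------------------------------------------------------

@dataclass
class MaskReport:
    dropped_rows: dict[str, str] = field(default_factory=dict)
    removed_columns: dict[int, str] = field(default_factory=dict)  # orig codon idx
    kept_columns: list[int] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"{len(self.dropped_rows)} rows dropped, "
            f"{len(self.removed_columns)} codon columns removed"
        )


def _row_codons(row: str) -> list[str]:
    return [row[3 * i : 3 * i + 3] for i in range(len(row) // 3)]


def prepare_selection_alignment(
    alignment: CodonAlignment,
    polyq_window: int = 8,
    polyq_fraction: float = 0.75,
) -> tuple[CodonAlignment, MaskReport]:
    """Drop unusable rows, strip terminal stops, remove all-gap codon
    columns and mask polyglutamine regions.

    A codon column is polyglutamine-masked when it lies inside a run of at
    least ``polyq_window`` consecutive columns whose non-gap residues are at
    least ``polyq_fraction`` Q or P.  Raises if fewer than 3 rows or 10
    codon columns survive.
    """
    report = MaskReport()
    kept_ids, kept_rows = [], []
    for sid, row in zip(alignment.ids, alignment.rows):
        codons = [c for c in _row_codons(row) if c != GAP_CODON]
        if not codons:
            report.dropped_rows[sid] = "empty sequence"
            continue
        if any(c in STOP_CODONS for c in codons[:-1]):
            report.dropped_rows[sid] = "premature stop"
            continue
        if codons[-1] not in STOP_CODONS:
            report.dropped_rows[sid] = "no terminal stop"
            continue
        # strip the terminal stop in place (replace with a codon gap)
        cells = _row_codons(row)
        last = max(i for i, c in enumerate(cells) if c != GAP_CODON)
        cells[last] = GAP_CODON
        kept_ids.append(sid)
        kept_rows.append(cells)

    if len(kept_ids) < 3:
        raise ValueError(
            f"only {len(kept_ids)} usable rows after cleanup; "
            "site models need at least 3"
        )

    n_codons = len(kept_rows[0])
    grid = np.array(kept_rows)  # (n_rows, n_codons) codon strings
    all_gap = (grid == GAP_CODON).all(axis=0)
    for idx in np.flatnonzero(all_gap):
        report.removed_columns[int(idx)] = "all gap"

    # polyglutamine mask over the non-all-gap columns
    qp_rich = np.zeros(n_codons, dtype=bool)
    for j in range(n_codons):
        if all_gap[j]:
            continue
        residues = [
            translate_codon(c) if c not in STOP_CODONS else "*"
            for c in grid[:, j]
            if c != GAP_CODON
        ]
        frac = sum(r in "QP" for r in residues) / len(residues)
        qp_rich[j] = frac >= polyq_fraction

    run_start = None
    consider = ~all_gap
    for j in range(n_codons + 1):
        rich = j < n_codons and qp_rich[j] and consider[j]
        if rich and run_start is None:
            run_start = j
        elif not rich and run_start is not None:
            if j - run_start >= polyq_window:
                for k in range(run_start, j):
                    report.removed_columns[k] = "polyglutamine"
            run_start = None

    keep = [
        j for j in range(n_codons)
        if j not in report.removed_columns
    ]
    report.kept_columns = keep
    if len(keep) < 10:
        raise ValueError(
            f"only {len(keep)} codon columns survive cleanup; "
            "site models need at least 10"
        )
    rows = tuple("".join(grid[i, j] for j in keep) for i in range(len(kept_ids)))
    return CodonAlignment(tuple(kept_ids), rows), report


# ---------------------------------------------------------------------------
# Pruning likelihood machinery
# ---------------------------------------------------------------------------

def _alignment_hash(alignment: CodonAlignment, tree_newick: str) -> str:
    h = hashlib.sha256()
    for sid, row in zip(alignment.ids, alignment.rows):
        h.update(sid.encode())
        h.update(row.encode())
    h.update(tree_newick.encode())
    return h.hexdigest()


class CodonLikelihood:
    """Felsenstein pruning likelihood of a codon alignment on a fixed tree
    under a GY94 ω-mixture, with site-pattern compression and per-node
    scaling."""

    def __init__(self, alignment: CodonAlignment, tree):
        import dendropy

        if not isinstance(tree, dendropy.Tree):
            tree = dendropy.Tree.get(
                data=tree, schema="newick", preserve_underscores=True
            )
        self.tree = tree
        leaf_names = [l.taxon.label for l in tree.leaf_node_iter()]
        missing = set(leaf_names) - set(alignment.ids)
        if missing:
            raise ValueError(f"tree leaves missing from alignment: {sorted(missing)}")
        extra = set(alignment.ids) - set(leaf_names)
        if extra:
            logger.warning(
                "alignment rows not on the tree are ignored: %s", sorted(extra)
            )
        row_by_id = dict(zip(alignment.ids, alignment.rows))

        # integer codon states per leaf; -1 encodes a gap/missing codon
        states = {}
        for name in leaf_names:
            row = row_by_id[name]
            codons = _row_codons(row)
            col = np.empty(len(codons), dtype=np.int64)
            for i, c in enumerate(codons):
                if c == GAP_CODON:
                    col[i] = -1
                elif c in STOP_CODONS:
                    raise ValueError(
                        f"{name}: stop codon in alignment; run "
                        "prepare_selection_alignment first"
                    )
                else:
                    col[i] = CODON_INDEX[c]
            states[name] = col

        mat = np.stack([states[n] for n in leaf_names])  # (n_leaf, n_codons)
        self.n_sites = mat.shape[1]
        patterns, inverse, counts = np.unique(
            mat, axis=1, return_inverse=True, return_counts=True
        )
        self.patterns = patterns  # (n_leaf, n_patterns)
        self.pattern_inverse = inverse.ravel()
        self.pattern_counts = counts.astype(float)
        self.leaf_names = leaf_names

        counts61 = np.zeros(N_SENSE)
        vals, cnts = np.unique(mat[mat >= 0], return_counts=True)
        counts61[vals] = cnts
        self.codon_freqs = f3x4_frequencies(counts61)

        # postorder traversal schedule
        self._postorder = list(self.tree.postorder_node_iter())
        self._leaf_index = {n: i for i, n in enumerate(leaf_names)}
        for node in self._postorder:
            if node.edge.length is None and node is not self.tree.seed_node:
                raise ValueError("tree must have branch lengths on every edge")

        self._propagator_cache: dict = {}

    # -- likelihood -----------------------------------------------------

    def _propagators(self, kappa: float, omegas: np.ndarray,
                     weights: np.ndarray):
        key = (round(kappa, 12), tuple(np.round(omegas, 12)),
               tuple(np.round(weights, 12)))
        cached = self._propagator_cache.get(key)
        if cached is not None:
            return cached
        pi = self.codon_freqs
        qs = [gy94_rate_matrix(kappa, w, pi) for w in omegas]
        mean_rate = float(np.dot(weights, [expected_rate(q, pi) for q in qs]))
        props = [CodonPropagator(q / mean_rate, pi) for q in qs]
        if len(self._propagator_cache) > 32:
            self._propagator_cache.clear()
        self._propagator_cache[key] = props
        return props

    def class_site_logliks(
        self,
        kappa: float,
        weights: np.ndarray,
        omegas: np.ndarray,
        scale: float,
    ) -> np.ndarray:
        """(n_classes, n_patterns) log-likelihoods per site pattern.

        All ω classes are propagated together as a batched dimension so the
        per-node work is a single stacked matrix product.
        """
        props = self._propagators(kappa, omegas, weights)
        npat = self.patterns.shape[1]
        ncls = len(omegas)
        log_scale = np.zeros((ncls, npat))
        partial_stack: dict = {}
        for node in self._postorder:
            if node.is_leaf():
                continue
            part = np.ones((ncls, npat, N_SENSE))
            for child in node.child_nodes():
                bl = max(float(child.edge.length) * scale, 0.0)
                pmats = np.stack([p.prob_matrix(bl) for p in props])
                if child.is_leaf():
                    # leaf partials are indicators: contribution is a gather
                    st = self.patterns[self._leaf_index[child.taxon.label]]
                    contrib = np.empty((ncls, npat, N_SENSE))
                    obs = st >= 0
                    contrib[:, obs, :] = pmats[:, :, st[obs]].transpose(0, 2, 1)
                    contrib[:, ~obs, :] = 1.0
                else:
                    contrib = partial_stack.pop(child) @ pmats.transpose(0, 2, 1)
                part *= contrib
            top = part.max(axis=2)
            top[top == 0.0] = 1.0
            part /= top[:, :, None]
            log_scale += np.log(top)
            partial_stack[node] = part
        root = partial_stack[self.tree.seed_node]
        site = root @ self.codon_freqs
        return np.log(np.clip(site, 1e-300, None)) + log_scale

    def log_likelihood(self, kappa, weights, omegas, scale) -> float:
        cls = self.class_site_logliks(kappa, weights, omegas, scale)
        site = logsumexp(cls, axis=0, b=weights[:, None])
        return float(np.dot(self.pattern_counts, site))

    def site_class_posteriors(self, kappa, weights, omegas, scale) -> np.ndarray:
        """(n_sites, n_classes) posterior class probabilities per site."""
        cls = self.class_site_logliks(kappa, weights, omegas, scale)
        with np.errstate(divide="ignore"):
            logw = np.where(weights > 0, np.log(weights), -np.inf)[:, None]
        joint = logw + cls
        joint[np.isneginf(logw).ravel()] = -np.inf
        post = np.exp(joint - logsumexp(joint, axis=0))
        return post.T[self.pattern_inverse]


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------

@dataclass
class SiteModelFit:
    model: str
    kappa: float
    p: float
    q: float
    p0: float
    omega_s: float
    tree_scale: float
    log_likelihood: float
    codon_freqs: np.ndarray
    class_weights: np.ndarray
    class_omegas: np.ndarray
    site_class_posterior: np.ndarray  # (n_sites, n_classes)
    converged: bool
    n_iterations: int
    n_starts: int
    at_boundary: list[str]
    data_hash: str
    n_sites: int
    likelihood: CodonLikelihood | None = field(default=None, repr=False)

    @property
    def site_positive_posterior(self) -> np.ndarray:
        """Per-site posterior of the positively selected class (zeros for
        M7, which has no such class)."""
        if self.model == "M8":
            return self.site_class_posterior[:, -1]
        return np.zeros(self.n_sites)


_BOUNDS = {
    "kappa": (0.1, 20.0),
    "p": (0.05, 50.0),
    "q": (0.05, 50.0),
    "scale": (1e-3, 50.0),
    "p0": (0.0, 1.0),
    "omega_s": (1.0, 25.0),
}


def _param_names(model: str) -> list[str]:
    base = ["kappa", "p", "q", "scale"]
    return base + (["p0", "omega_s"] if model == "M8" else [])


def fit_site_model(
    alignment: CodonAlignment,
    tree,
    model: str,
    starts: int = DEFAULT_STARTS,
    seed: int = 0,
    ncat: int = N_CATEGORIES,
    extra_starts: Sequence[dict] | None = None,
    maxiter: int = 500,
) -> SiteModelFit:
    """Maximum-likelihood fit of M7 or M8 by bounded quasi-Newton (L-BFGS-B)
    from ``starts`` seeded initial points (plus any ``extra_starts``); the
    best start is returned with convergence diagnostics."""
    if model not in {"M7", "M8"}:
        raise ValueError("model must be 'M7' or 'M8'")
    if starts < 1:
        raise ValueError("need at least one start")
    lik = CodonLikelihood(alignment, tree)
    newick = lik.tree.as_string(schema="newick")
    data_hash = _alignment_hash(alignment, newick)
    names = _param_names(model)
    bounds = [_BOUNDS[n] for n in names]

    def unpack(x):
        d = dict(zip(names, x))
        weights, omegas = omega_mixture(
            model, d["p"], d["q"], d.get("p0", 1.0), d.get("omega_s", 1.0), ncat
        )
        return d, weights, omegas

    def objective(x):
        d, weights, omegas = unpack(x)
        try:
            return -lik.log_likelihood(d["kappa"], weights, omegas, d["scale"])
        except (ValueError, FloatingPointError):
            return 1e12

    default = {"kappa": 2.0, "p": 0.8, "q": 2.0, "scale": 1.0,
               "p0": 0.9, "omega_s": 2.0}
    rng = np.random.default_rng(seed)
    inits = [np.array([default[n] for n in names])]
    for _ in range(starts - 1):
        cand = {
            "kappa": float(np.exp(rng.normal(np.log(2.0), 0.5))),
            "p": float(np.exp(rng.normal(0.0, 0.7))),
            "q": float(np.exp(rng.normal(0.7, 0.7))),
            "scale": float(np.exp(rng.normal(0.0, 0.5))),
            "p0": float(rng.uniform(0.5, 1.0)),
            "omega_s": float(1.0 + rng.exponential(2.0)),
        }
        inits.append(np.array([cand[n] for n in names]))
    for extra in extra_starts or []:
        merged = {**default, **extra}
        inits.append(np.array([merged[n] for n in names]))

    best = None
    n_ok = 0
    for x0 in inits:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter},
        )
        n_ok += bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if n_ok == 0:
        logger.warning("no start converged cleanly for %s; returning best", model)

    d, weights, omegas = unpack(best.x)
    posteriors = lik.site_class_posteriors(d["kappa"], weights, omegas, d["scale"])
    at_boundary = [
        n for n, v, (lo, hi) in zip(names, best.x, bounds)
        if np.isclose(v, lo, atol=1e-8) or np.isclose(v, hi, atol=1e-8)
    ]
    return SiteModelFit(
        model=model,
        kappa=d["kappa"],
        p=d["p"],
        q=d["q"],
        p0=d.get("p0", 1.0),
        omega_s=d.get("omega_s", 1.0),
        tree_scale=d["scale"],
        log_likelihood=-float(best.fun),
        codon_freqs=lik.codon_freqs,
        class_weights=weights,
        class_omegas=omegas,
        site_class_posterior=posteriors,
        converged=n_ok > 0,
        n_iterations=int(best.nit),
        n_starts=len(inits),
        at_boundary=at_boundary,
        data_hash=data_hash,
        n_sites=lik.n_sites,
        likelihood=lik,
    )


# ---------------------------------------------------------------------------
# LRT and site posteriors
# ---------------------------------------------------------------------------

@dataclass
class SelectionReport:
    lrt_statistic: float
    df: int
    p_value: float
    threshold: float = POSTERIOR_THRESHOLD
    site_posterior: np.ndarray | None = None
    significant_sites: list[int] = field(default_factory=list)  # 0-based
    notes: list[str] = field(default_factory=list)


LRT_DF = 2
_LRT_TOLERANCE = 1e-3


def lrt_m7_m8(fit7: SiteModelFit, fit8: SiteModelFit) -> SelectionReport:
    """Likelihood-ratio test of M8 (positive selection allowed) against M7;
    2Δℓ is clamped at 0 and referred to χ² with 2 degrees of freedom."""
    if fit7.model != "M7" or fit8.model != "M8":
        raise ValueError("expected an M7 fit and an M8 fit, in that order")
    if fit7.data_hash != fit8.data_hash:
        raise ValueError("fits were computed on different data or trees")
    stat = 2.0 * (fit8.log_likelihood - fit7.log_likelihood)
    notes = []
    if stat < -_LRT_TOLERANCE:
        notes.append(
            f"M8 log-likelihood below M7 by {-stat / 2:.4g}; "
            "check convergence"
        )
    if stat < 0:
        if not notes:
            notes.append("negative 2Δℓ within numerical tolerance; clamped to 0")
        stat = 0.0
    return SelectionReport(
        lrt_statistic=stat,
        df=LRT_DF,
        p_value=float(chi2.sf(stat, LRT_DF)) if stat > 0 else 1.0,
        notes=notes,
    )


def site_posteriors(
    fit8: SiteModelFit,
    threshold: float = POSTERIOR_THRESHOLD,
    method: str = "neb",
    grid_sizes: tuple[int, int] = (4, 4),
) -> SelectionReport:
    """Per-site posterior of the positively selected class.

    ``method='neb'`` (default) evaluates the posterior at the MLEs
    (naive empirical Bayes).  ``method='beb'`` averages the posterior over a
    coarse grid on (p0, ω_s) around the MLE — with (κ, p, q, scale) held at
    their MLEs — weighting grid points by the data likelihood.
    """
    if fit8.model != "M8":
        raise ValueError("site posteriors require an M8 fit")
    if not fit8.converged:
        raise ValueError("cannot compute site posteriors from a failed fit")
    if method == "neb":
        post = fit8.site_positive_posterior
    elif method == "beb":
        lik = fit8.likelihood
        if lik is None:
            raise ValueError("fit carries no likelihood engine for BEB")
        p0_grid = np.linspace(0.55, 1.0, grid_sizes[0])
        ws_grid = np.linspace(1.0, max(fit8.omega_s * 2.0, 4.0), grid_sizes[1])
        logls, posts = [], []
        for p0 in p0_grid:
            for ws in ws_grid:
                weights, omegas = omega_mixture(
                    "M8", fit8.p, fit8.q, p0, ws, len(fit8.class_omegas) - 1
                )
                logls.append(
                    lik.log_likelihood(fit8.kappa, weights, omegas,
                                       fit8.tree_scale)
                )
                posts.append(
                    lik.site_class_posteriors(
                        fit8.kappa, weights, omegas, fit8.tree_scale
                    )[:, -1]
                )
        logls = np.array(logls)
        w = np.exp(logls - logls.max())
        w /= w.sum()
        post = np.tensordot(w, np.array(posts), axes=1)
    else:
        raise ValueError("method must be 'neb' or 'beb'")
    significant = [int(i) for i in np.flatnonzero(post > threshold)]
    return SelectionReport(
        lrt_statistic=float("nan"),
        df=LRT_DF,
        p_value=float("nan"),
        threshold=threshold,
        site_posterior=post,
        significant_sites=significant,
    )
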