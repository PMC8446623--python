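"""Synthetic test-bed generator for the α-gliadin pipeline.

Real inputs to the pipeline are chromosome-scale wheat assemblies, long-read
depth tables and codon alignments of gliadin copies.  This module fabricates
all three with known ground truth:

* :func:`generate_assembly` plants tandem arrays of gliadin-like single-exon
  genes (with point mutations, pseudogenization and planted epitopes) on
  random background chromosomes, and returns a truth table of coordinates.
* :func:`simulate_codon_alignment` evolves codon sites over a tree under the
  GY94 model with an M7 or M8 site-class mixture of ω = dN/dS values.
* :func:`simulate_depth_table` emulates long-read gene coverage, with
  collapsed paralogs at ~2× and haplotype-specific copies at ~0.5× the
  genome-wide median.

All randomness flows through a mandatory integer seed; identical inputs give
byte-identical artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import _codon
from ._codon import (
    CodonPropagator,
    SENSE_CODONS,
    expected_rate,
    gy94_rate_matrix,
    omega_mixture,
    translate_codon,
    uniform_codon_freqs,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: One fixed codon per amino acid (first sense codon in lexicographic order)
#: used when reverse-translating planted epitope peptides.
PREFERRED_CODON = {}
for _c in SENSE_CODONS:
    PREFERRED_CODON.setdefault(translate_codon(_c), _c)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _default_template() -> str:
    """A gliadin-like template CDS (~200 codons): signal peptide, a Q/P-rich
    repetitive domain (free of the shipped epitope 9-mers so that planted
    epitope counts are exact), a polyglutamine run, two variable domains and
    a terminal stop."""
    protein = (
        "MKTFLILALLAIVATTA"                   # signal peptide
        + "QPFPQQPQQPFPQQPQQPFPQQPQQPFPQQPQQPFPQQPQQPFPQQPQ"  # repeat domain
        + "QQQQQQQQQQQQ"                       # polyglutamine
        + "VLQQHNIAQGSVQVLQESTYQLVQQLCCQELQQIPEQSQCQAIHNVVHAIILHQ"
        + "QQQQQQQQQ"                          # second polyQ
        + "SNAVQVSQQQAQQGVEGVSIVSGLHILLPLSQQEQVGEGSLVQGQGIIQPQQPAQL"
        + "EVIRSLVLQTLPTMCNVYIPPYCTIAPVGIFGTN"
    )
    return "".join(PREFERRED_CODON[a] for a in protein) + "TAA"


@dataclass(frozen=True)
class LocusSpec:
    """Tandem-array plan for one locus: anchors are sublocus start positions
    on the chromosome, ``copies[i]`` genes are planted head-to-tail from
    ``anchors[i]`` with ``spacing_bp`` of background between consecutive
    genes."""

    chromosome: str
    anchors_bp: tuple[int, ...]
    copies: tuple[int, ...]
    spacing_bp: int = 2_000

    def __post_init__(self):
        if len(self.anchors_bp) != len(self.copies):
            raise ValueError("anchors_bp and copies must have equal length")
        if any(c < 1 for c in self.copies):
            raise ValueError("each sublocus needs at least one copy")
        if self.spacing_bp < 0:
            raise ValueError("spacing_bp must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Full recipe for a synthetic accession.

    ``collapsed_genes`` and ``haplotype_specific_genes`` list 0-based gene
    indices (in planting order) whose read depth should look collapsed (~2×)
    or haplotype-specific (~0.5×); the assembly sequence itself is not
    duplicated — coverage is the only evidence, as in real assemblies.
    ``epitopes`` maps an epitope name to ``(peptide, copies_to_plant)``.
    """

    chromosomes: Mapping[str, int]
    loci: tuple[LocusSpec, ...]
    template_cds: str = field(default_factory=_default_template)
    substitution_rate: float = 0.02
    pseudogene_prob: float = 0.1
    collapsed_genes: tuple[int, ...] = ()
    haplotype_specific_genes: tuple[int, ...] = ()
    epitopes: Mapping[str, tuple[str, int]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        t = self.template_cds.upper()
        if len(t) % 3 != 0:
            raise ValueError("template CDS length must be a multiple of 3")
        if not t.startswith("ATG"):
            raise ValueError("template CDS must start with ATG")
        if set(t) - set("ACGT"):
            raise ValueError("template CDS must be over A/C/G/T")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must lie in [0, 1]")
        if not 0.0 <= self.pseudogene_prob <= 1.0:
            raise ValueError("pseudogene_prob must lie in [0, 1]")
        for spec in self.loci:
            if spec.chromosome not in self.chromosomes:
                raise ValueError(f"locus on unknown chromosome {spec.chromosome!r}")
            length = self.chromosomes[spec.chromosome]
            for a in spec.anchors_bp:
                if not 0 < a < length:
                    raise ValueError(
                        f"anchor {a} outside chromosome {spec.chromosome!r} "
                        f"(length {length})"
                    )
        for name, (peptide, count) in self.epitopes.items():
            if not peptide or set(peptide) - set(PREFERRED_CODON):
                raise ValueError(f"epitope {name!r} has an invalid peptide")
            if count < 0:
                raise ValueError(f"epitope {name!r} has negative copy count")


TRUTH_COLUMNS = [
    "gene_id", "chromosome", "start", "end", "strand", "intact_orf",
    "epitopes", "copy_status", "sublocus", "cds",
]


class GenerationError(ValueError):
    pass


def _subgenome_letter(chromosome: str) -> str:
    for ch in chromosome:
        if ch in "ABD":
            return ch
    return "Un"


def _sublocus_name(chromosome: str, index: int, n_subloci: int) -> str:
    base = f"Gli-{_subgenome_letter(chromosome)}2"
    return base if n_subloci == 1 else f"{base}-{index + 1}"


def _mutate(cds: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site independent substitutions at the given rate; the start codon
    is left untouched so the intact/pseudogene distinction stays under the
    explicit pseudogenization switch."""
    if rate <= 0:
        return cds
    arr = np.frombuffer(cds.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    hit[:3] = False
    idx = np.flatnonzero(hit)
    if idx.size:
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        shift = rng.integers(1, 4, size=idx.size)
        code = np.searchsorted(bases, arr[idx])
        arr[idx] = bases[(code + shift) % 4]
    return arr.tobytes().decode()


def _pseudogenize(cds: str, rng: np.random.Generator) -> str:
    """Apply exactly one lesion: lost start codon, internal stop, or a
    1–2 bp deletion (frameshift)."""
    mode = rng.integers(0, 3)
    if mode == 0:  # lost ATG
        return "C" + cds[1:]
    if mode == 1:  # internal premature stop
        n_codons = len(cds) // 3
        pos = int(rng.integers(1, n_codons - 1))
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
        return cds[: pos * 3] + stop + cds[pos * 3 + 3 :]
    size = int(rng.integers(1, 3))  # 1-2 bp deletion
    pos = int(rng.integers(3, len(cds) - 3 - size))
    return cds[:pos] + cds[pos + size :]


def _plant_epitope(cds: str, peptide: str, cursor_codon: int) -> tuple[str, int]:
    # trailing G separates the epitope from the Q/P-rich template so the
    # junction cannot create a spurious epitope occurrence
    codons = "".join(PREFERRED_CODON[a] for a in peptide + "G")
    start = cursor_codon * 3
    end = start + len(codons)
    if end > len(cds) - 3:
        raise GenerationError(
            f"epitope {peptide!r} does not fit in the template at codon "
            f"{cursor_codon}; use a longer template"
        )
    return cds[:start] + codons + cds[end:], cursor_codon + len(peptide) + 1


def _is_intact_orf(cds: str) -> bool:
    if len(cds) % 3 != 0 or not cds.startswith("ATG"):
        return False
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] not in _codon.STOP_CODONS:
        return False
    return not any(c in _codon.STOP_CODONS for c in codons[:-1])


def generate_assembly(config: SimConfig) -> tuple[dict[str, str], pd.DataFrame]:
    """Build the synthetic assembly and its ground-truth gene table.

    Returns ``(assembly, truth)`` where ``assembly`` maps chromosome name to
    sequence and ``truth`` has one row per planted gene (columns
    :data:`TRUTH_COLUMNS`; coordinates 0-based half-open on the forward
    strand; ``cds`` is in forward-coding orientation).
    """
    rng = np.random.default_rng(config.seed)
    template = config.template_cds.upper()

    # -- decide per-gene fates in planting order -------------------------
    plan = []  # (gene_index, chromosome, sublocus_name)
    for spec in config.loci:
        n_sub = len(spec.anchors_bp)
        for si in range(n_sub):
            name = _sublocus_name(spec.chromosome, si, n_sub)
            for _ in range(spec.copies[si]):
                plan.append((spec.chromosome, name, spec, si))
    n_genes = len(plan)
    pseudo = rng.random(n_genes) < config.pseudogene_prob
    strands = np.where(rng.random(n_genes) < 0.5, "+", "-")

    # -- mutate / pseudogenize each copy --------------------------------
    cds_list, epitope_lists = [], [[] for _ in range(n_genes)]
    for gi in range(n_genes):
        cds = _mutate(template, config.substitution_rate, rng)
        if pseudo[gi]:
            cds = _pseudogenize(cds, rng)
        cds_list.append(cds)

    # -- plant epitopes round-robin over non-pseudogenized copies --------
    recipients = [gi for gi in range(n_genes) if not pseudo[gi]]
    cursors = {gi: 22 for gi in recipients}  # first codon after the signal
    rr = 0
    for name, (peptide, count) in sorted(config.epitopes.items()):
        for _ in range(count):
            if not recipients:
                raise GenerationError("no intact copies available for epitopes")
            gi = recipients[rr % len(recipients)]
            rr += 1
            cds_list[gi], cursors[gi] = _plant_epitope(
                cds_list[gi], peptide, cursors[gi]
            )
            epitope_lists[gi].append(name)

    # -- lay out coordinates and check collisions ------------------------
    records = []
    cursor_by_anchor: dict[tuple[str, int], int] = {}
    for gi, (chrom, subname, spec, si) in enumerate(plan):
        key = (chrom, spec.anchors_bp[si])
        pos = cursor_by_anchor.get(key, spec.anchors_bp[si])
        start, end = pos, pos + len(cds_list[gi])
        cursor_by_anchor[key] = end + spec.spacing_bp
        if end > config.chromosomes[chrom]:
            raise GenerationError(
                f"gene {gi} extends past the end of {chrom} ({end} > "
                f"{config.chromosomes[chrom]})"
            )
        if gi in config.collapsed_genes:
            status = "collapsed"
        elif gi in config.haplotype_specific_genes:
            status = "haplotype_specific"
        else:
            status = "normal"
        records.append(
            {
                "gene_id": f"{chrom}.g{gi + 1:03d}",
                "chromosome": chrom,
                "start": start,
                "end": end,
                "strand": strands[gi],
                "intact_orf": _is_intact_orf(cds_list[gi]),
                "epitopes": ",".join(epitope_lists[gi]),
                "copy_status": status,
                "sublocus": subname,
                "cds": cds_list[gi],
            }
        )
    truth = pd.DataFrame.from_records(records, columns=TRUTH_COLUMNS)

    for chrom, grp in truth.groupby("chromosome"):
        grp = grp.sort_values("start")
        prev_end, prev_id = -1, None
        for _, row in grp.iterrows():
            if row.start < prev_end:
                raise GenerationError(
                    f"planted genes overlap on {chrom}: {prev_id} and "
                    f"{row.gene_id}"
                )
            prev_end, prev_id = row.end, row.gene_id

    # -- synthesize chromosomes ------------------------------------------
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    assembly: dict[str, str] = {}
    for chrom in config.chromosomes:
        length = config.chromosomes[chrom]
        arr = bases[rng.integers(0, 4, size=length)]
        for _, row in truth[truth.chromosome == chrom].iterrows():
            genomic = row.cds if row.strand == "+" else reverse_complement(row.cds)
            arr[row.start : row.end] = np.frombuffer(genomic.encode(), dtype=np.uint8)
        assembly[chrom] = arr.tobytes().decode()
    return assembly, truth


# ---------------------------------------------------------------------------
# Codon-alignment simulation under GY94 site models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteModelParams:
    """Parameters of an M7 or M8 ω-mixture over GY94.

    M7 draws site classes from a Beta(p, q) discretized into ``ncat``
    equal-probability categories (category medians); M8 additionally puts
    weight ``1 - p0`` on a positively selected class with ω = ``omega_s``.
    """

    model: str  # "M7" | "M8"
    p: float
    q: float
    p0: float = 1.0
    omega_s: float = 1.0
    kappa: float = 2.0
    ncat: int = 10

    def mixture(self):
        return omega_mixture(
            self.model, self.p, self.q, self.p0, self.omega_s, self.ncat
        )


def _parse_tree(tree) -> "dendropy.Tree":  # noqa: F821
    import dendropy

    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(
        data=tree, schema="newick", preserve_underscores=True
    )


def simulate_codon_alignment(
    tree,
    params: SiteModelParams,
    n_sites: int,
    seed: int,
    pi: np.ndarray | None = None,
) -> tuple[dict[str, str], list[str], np.ndarray]:
    """Evolve ``n_sites`` codon sites over ``tree`` under GY94.

    Each site draws an ω class from the model mixture; branch lengths are
    expected substitutions per codon under the mixture-average rate.  Only
    sense codons are emitted (stops are unreachable states).

    Returns ``(alignment, true_classes, omegas)`` where ``alignment`` maps
    leaf label to codon string and ``true_classes[i]`` is ``"positive"`` for
    sites drawn from the selected M8 class, else ``"beta"``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    t = _parse_tree(tree)
    leaves = t.leaf_nodes()
    if len(leaves) < 3:
        raise ValueError("tree must have at least 3 leaves")
    for edge in t.preorder_edge_iter():
        if edge.head_node is t.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree must have branch lengths on every edge")

    rng = np.random.default_rng(seed)
    pi = uniform_codon_freqs() if pi is None else np.asarray(pi, dtype=float)
    weights, omegas = params.mixture()
    classes = rng.choice(len(weights), size=n_sites, p=weights)
    is_positive = (params.model == "M8") & (classes == len(weights) - 1)
    site_omega = omegas[classes]

    # mixture-average rate normalization, shared with the fitting code
    qs = [gy94_rate_matrix(params.kappa, w, pi) for w in omegas]
    mean_rate = float(np.dot(weights, [expected_rate(q, pi) for q in qs]))
    propagators = [CodonPropagator(q / mean_rate, pi) for q in qs]

    def sample_children(parent_states, pmat):
        probs = pmat[parent_states]
        u = rng.random(parent_states.size)
        return np.minimum(
            (probs.cumsum(axis=1) < u[:, None]).sum(axis=1), _codon.N_SENSE - 1
        )

    states = {t.seed_node: rng.choice(_codon.N_SENSE, size=n_sites, p=pi)}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        bl = float(node.edge.length)
        parent = states[node.parent_node]
        child = np.empty(n_sites, dtype=np.intp)
        for ci in range(len(omegas)):
            mask = classes == ci
            if not mask.any():
                continue
            pmat = propagators[ci].prob_matrix(bl)
            child[mask] = sample_children(parent[mask], pmat)
        states[node] = child

    alignment = {
        (leaf.taxon.label if leaf.taxon else str(i)): "".join(
            SENSE_CODONS[s] for s in states[leaf]
        )
        for i, leaf in enumerate(leaves)
    }
    true_classes = ["positive" if f else "beta" for f in is_positive]
    return alignment, true_classes, site_omega


def balanced_tree(n_leaves: int = 8, branch_length: float = 0.3) -> str:
    """Newick for a balanced tree with uniform branch lengths, a convenient
    default topology for simulation studies."""
    labels = [f"t{i + 1}" for i in range(n_leaves)]

    def build(names):
        if len(names) == 1:
            return f"{names[0]}:{branch_length}"
        mid = len(names) // 2
        return f"({build(names[:mid])},{build(names[mid:])}):{branch_length}"

    inner = build(labels)
    return f"{inner};" if inner.startswith("(") else f"({inner});"


# ---------------------------------------------------------------------------
# Depth-table simulation
# ---------------------------------------------------------------------------

#: Median genome-wide gene coverage, in genome equivalents, used as the
#: default simulated sequencing depth.
DEFAULT_MEDIAN_COVERAGE = 32.23

_STATUS_MULTIPLIER = {"normal": 1.0, "collapsed": 2.0, "haplotype_specific": 0.5}


def simulate_depth_table(
    truth: pd.DataFrame,
    median_cov: float = DEFAULT_MEDIAN_COVERAGE,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene mean read depth: normal copies at the median, collapsed at
    2×, haplotype-specific at 0.5×, plus Gaussian noise truncated at 0."""
    if median_cov <= 0:
        raise ValueError("median_cov must be > 0")
    rng = np.random.default_rng(seed)
    mult = truth["copy_status"].map(_STATUS_MULTIPLIER)
    if mult.isna().any():
        bad = truth.loc[mult.isna(), "copy_status"].unique().tolist()
        raise ValueError(f"unknown copy status values: {bad}")
    depth = mult.to_numpy() * median_cov + rng.normal(0.0, noise_sd, len(truth))
    n_clipped = int((depth < 0).sum())
    if n_clipped:
        logger.warning("truncated %d negative depth draws at 0", n_clipped)
    depth = np.clip(depth, 0.0, None)
    return pd.DataFrame(
        {
            "gene_id": truth["gene_id"].to_numpy(),
            "mean_depth": depth,
            "true_status": truth["copy_status"].to_numpy(),
        }
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth_tsv(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def write_truth_bed(truth: pd.DataFrame, path) -> None:
    bed = truth[["chromosome", "start", "end", "gene_id"]].copy()
    bed["score"] = 0
    bed["strand"] = truth["strand"]
    bed.to_csv(path, sep="\t", index=False, header=False)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """A bread-wheat-like synthetic accession: a bipartite locus on a 6B-like
    chromosome (5 + 2 copies, anchors 43.5 and 63.0 Mb apart mirror the
    published bipartite locus geometry) and a compact single locus on a
    6D-like chromosome carrying planted epitopes."""
    kwargs = dict(
        chromosomes={"chr6B": 65_000_000, "chr6D": 30_000_000},
        loci=(
            LocusSpec("chr6B", anchors_bp=(43_500_000, 63_000_000), copies=(5, 2)),
            LocusSpec("chr6D", anchors_bp=(27_000_000,), copies=(4,)),
        ),
        substitution_rate=0.02,
        pseudogene_prob=0.2,
        collapsed_genes=(1,),
        haplotype_specific_genes=(4,),
        epitopes={
            "DQ2.5-glia-alpha1a": ("PFPQPQLPY", 2),
            "DQ2.5-glia-alpha2": ("PQPQLPYPQ", 2),
        },
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)
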