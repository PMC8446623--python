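"""Homology-based discovery of α-gliadin gene copies in an assembly.

The search is a deterministic seed-and-extend scheme: exact k-mer seeds from
each query CDS are located on both strands of every chromosome, co-linear
seeds are chained into candidate windows, and each window is resolved by a
global alignment of the query against the window (free end gaps on the
genomic side; match +1, mismatch −1, gap open −4, gap extend −1).  Hits are
kept if they reach a minimum identity and aligned length, and overlapping
hits on one strand are merged keeping the best score.  A hit is by
construction contiguous on the genome, which enforces the single-exon
structure of α-gliadin genes.

Candidates are never silently discarded on ORF defects: :func:`classify_orf`
sets flags (start codon, internal/terminal stops, frameshift) that drive the
downstream filters, and :func:`filter_divergent` separates copies whose
protein is too far from every query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner

from ._codon import STOP_CODONS, translate_codon
from .synthetic_data import reverse_complement

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_LEN = 300
DEFAULT_SEED_LEN = 16
DEFAULT_MAX_PDIST = 0.35


@dataclass(frozen=True)
class GeneCandidate:
    """One discovered gene copy. Coordinates are 0-based half-open on the
    forward strand; ``cds`` is in forward-coding orientation (reverse
    complemented for '-' strand hits)."""

    gene_id: str
    accession: str
    chromosome: str
    start: int
    end: int
    strand: str
    cds: str
    best_query: str
    identity: float
    score: float
    protein: str = ""
    starts_with_met: bool = False
    has_internal_stop: bool = False
    has_terminal_stop: bool = False
    frameshifted: bool = False
    divergent: bool = False

    def __post_init__(self):
        if self.end - self.start != len(self.cds):
            raise ValueError(
                f"{self.gene_id}: interval length != CDS length "
                f"({self.end - self.start} vs {len(self.cds)})"
            )
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"{self.gene_id}: identity outside [0, 1]")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


class QuerySet(dict):
    """Named query CDS sequences over A/C/G/T (e.g. the AS1–AS11 set)."""

    def __init__(self, sequences: Mapping[str, str]):
        if not sequences:
            raise ValueError("query set must be non-empty")
        clean = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - set("ACGT")
            if bad:
                raise ValueError(
                    f"query {name!r} contains non-ACGT characters: {sorted(bad)}"
                )
            clean[name] = seq
        super().__init__(clean)


def _dna_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    # free end gaps on the genomic window (unaligned window overhangs cost
    # nothing) so the query finds its own span within the window
    try:
        aligner.open_end_deletion_score = 0
        aligner.extend_end_deletion_score = 0
    except AttributeError:  # biopython < 1.88 naming
        aligner.query_end_open_gap_score = 0
        aligner.query_end_extend_gap_score = 0
    return aligner


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 4
    aligner.mismatch_score = -1
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    return aligner


_BASE_CODE = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(encoded: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-mer (Horner scheme, 2 bits per base)."""
    n = encoded.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        codes = codes * np.uint64(4) + encoded[j : j + n].astype(np.uint64)
    return codes


@dataclass
class _RawHit:
    chromosome: str
    start: int
    end: int
    strand: str
    query: str
    identity: float
    score: float
    cds: str = field(repr=False, default="")


def _alignment_stats(alignment, query_len: int):
    """(target_start, target_end, identity, columns) for one alignment,
    excluding the free genomic end gaps but charging query overhangs."""
    blocks_t, blocks_q = alignment.aligned
    t0, t1 = int(blocks_t[0][0]), int(blocks_t[-1][1])
    target = alignment.target
    query = alignment.query
    matches = 0
    cols = 0
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        if prev_t is not None:
            cols += max(ts - prev_t, qs - prev_q)
        sub_t, sub_q = target[ts:te], query[qs:qe]
        matches += sum(a == b for a, b in zip(sub_t, sub_q))
        cols += te - ts
        prev_t, prev_q = te, qe
    # query overhangs beyond the aligned region still count as columns
    cols += int(blocks_q[0][0]) + (query_len - int(blocks_q[-1][1]))
    identity = matches / cols if cols else 0.0
    return t0, t1, identity, cols


def _chain_seeds(gpos: np.ndarray, qpos: np.ndarray, query_len: int,
                 band: int = 32):
    """Greedy chaining of seed matches into clusters of co-linear seeds.
    Seeds are sorted by genomic position; a new cluster starts when the
    genomic gap exceeds the query length or the diagonal drifts by more than
    ``band``."""
    order = np.argsort(gpos, kind="stable")
    gpos, qpos = gpos[order], qpos[order]
    diag = gpos.astype(np.int64) - qpos.astype(np.int64)
    clusters = []
    current = None
    for g, d in zip(gpos, diag):
        if (
            current is None
            or g - current["last_g"] > query_len
            or abs(int(d) - current["diag"]) > band
        ):
            current = {"g_min": int(g), "g_max": int(g), "diag": int(d),
                       "last_g": int(g), "n": 1}
            clusters.append(current)
        else:
            current["g_max"] = int(g)
            current["last_g"] = int(g)
            current["n"] += 1
    return clusters


def find_candidates(
    assembly: Mapping[str, str],
    queries: QuerySet | Mapping[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_len: int = DEFAULT_MIN_LEN,
    seed_len: int = DEFAULT_SEED_LEN,
    accession: str = "accession",
    min_seeds: int = 2,
) -> list[GeneCandidate]:
    """Locate gliadin-like gene copies in ``assembly``.

    Returns candidates in coordinate order, with ORF flags already set via
    :func:`classify_orf`.  An empty assembly yields an empty list.
    """
    if not isinstance(queries, QuerySet):
        queries = QuerySet(queries)
    if seed_len < 8:
        raise ValueError("seed_len must be >= 8")
    if not 0.5 < min_identity <= 1.0:
        raise ValueError("min_identity must lie in (0.5, 1]")
    if seed_len > 31:
        raise ValueError("seed_len must be <= 31 (2-bit packing)")

    aligner = _dna_aligner()
    pad = 3 * seed_len
    hits: list[_RawHit] = []
    for chrom in sorted(assembly):
        seq = assembly[chrom].upper()
        if len(seq) < seed_len:
            continue
        genome_codes = _kmer_codes(_encode(seq), seed_len)
        for qname in sorted(queries):
            qseq = queries[qname]
            if len(qseq) < seed_len:
                logger.warning("query %s shorter than seed length; skipped", qname)
                continue
            for strand in "+-":
                eff = qseq if strand == "+" else reverse_complement(qseq)
                qcodes = _kmer_codes(_encode(eff), seed_len)
                code_to_qpos: dict[int, list[int]] = {}
                for qp, code in enumerate(qcodes):
                    code_to_qpos.setdefault(int(code), []).append(qp)
                present = np.isin(genome_codes, qcodes)
                gmatch = np.flatnonzero(present)
                if gmatch.size == 0:
                    continue
                g_list, q_list = [], []
                for g in gmatch:
                    for qp in code_to_qpos[int(genome_codes[g])]:
                        g_list.append(int(g))
                        q_list.append(qp)
                clusters = _chain_seeds(
                    np.asarray(g_list), np.asarray(q_list), len(eff)
                )
                windows = []
                for cl in clusters:
                    if cl["n"] < min_seeds:
                        continue
                    w0 = max(0, cl["diag"] - pad)
                    w1 = min(len(seq), cl["diag"] + len(eff) + pad)
                    windows.append((w0, w1))
                # merge overlapping windows to avoid duplicate alignments
                windows.sort()
                merged = []
                for w0, w1 in windows:
                    if merged and w0 <= merged[-1][1]:
                        merged[-1] = (merged[-1][0], max(merged[-1][1], w1))
                    else:
                        merged.append((w0, w1))
                for w0, w1 in merged:
                    window = seq[w0:w1]
                    alignment = aligner.align(window, eff)[0]
                    t0, t1, identity, _ = _alignment_stats(alignment, len(eff))
                    start, end = w0 + t0, w0 + t1
                    if identity < min_identity or end - start < min_len:
                        continue
                    genomic = seq[start:end]
                    cds = genomic if strand == "+" else reverse_complement(genomic)
                    hits.append(
                        _RawHit(chrom, start, end, strand, qname, identity,
                                float(alignment.score), cds)
                    )

    # merge overlapping hits on the same strand, keeping the best score
    hits.sort(key=lambda h: (h.chromosome, h.start, h.end))
    kept: list[_RawHit] = []
    for hit in hits:
        merged_in = False
        for prev in kept:
            if (
                prev.chromosome == hit.chromosome
                and prev.strand == hit.strand
                and hit.start < prev.end
                and prev.start < hit.end
            ):
                if hit.score > prev.score:
                    kept[kept.index(prev)] = hit
                merged_in = True
                break
        if merged_in:
            continue
        kept.append(hit)
    kept.sort(key=lambda h: (h.chromosome, h.start))

    candidates = []
    for i, hit in enumerate(kept):
        cand = GeneCandidate(
            gene_id=f"{accession}.{hit.chromosome}.c{i + 1:03d}",
            accession=accession,
            chromosome=hit.chromosome,
            start=hit.start,
            end=hit.end,
            strand=hit.strand,
            cds=hit.cds,
            best_query=hit.query,
            identity=hit.identity,
            score=hit.score,
        )
        candidates.append(classify_orf(cand))
    return candidates


def translate_cds(cds: str, strip_terminal_stop: bool = True) -> str:
    """Translate complete codons; internal stops render as '*'; a terminal
    stop is dropped by default."""
    n = len(cds) // 3
    codons = [cds[3 * i : 3 * i + 3] for i in range(n)]
    if strip_terminal_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return "".join(translate_codon(c) for c in codons)


def classify_orf(candidate: GeneCandidate) -> GeneCandidate:
    """Set ORF flags from the CDS and attach the translated protein.

    The protein covers all complete codons except a terminal stop; internal
    stops appear as '*'.  Candidates are never dropped here — the flags
    drive the downstream filters.
    """
    cds = candidate.cds.upper()
    if not cds:
        raise ValueError(f"{candidate.gene_id}: empty CDS")
    n = len(cds) // 3
    codons = [cds[3 * i : 3 * i + 3] for i in range(n)]
    frameshifted = len(cds) % 3 != 0
    terminal = bool(codons) and codons[-1] in STOP_CODONS
    internal = any(c in STOP_CODONS for c in codons[:-1])
    return replace(
        candidate,
        protein=translate_cds(cds),
        starts_with_met=cds.startswith("ATG"),
        has_internal_stop=internal,
        has_terminal_stop=terminal,
        frameshifted=frameshifted,
    )


def protein_p_distance(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """p-distance between two proteins after global alignment: mismatches
    over columns where both sequences have a residue."""
    if not a or not b:
        raise ValueError("cannot align an empty protein")
    aligner = aligner or _protein_aligner()
    alignment = aligner.align(a, b)[0]
    blocks_a, blocks_b = alignment.aligned
    matches = compared = 0
    for (s1, e1), (s2, e2) in zip(blocks_a, blocks_b):
        for x, y in zip(a[s1:e1], b[s2:e2]):
            compared += 1
            matches += x == y
    if compared == 0:
        return 1.0
    return 1.0 - matches / compared


def filter_divergent(
    candidates: Sequence[GeneCandidate],
    queries: QuerySet | Mapping[str, str],
    max_pdist: float = DEFAULT_MAX_PDIST,
) -> tuple[list[GeneCandidate], list[GeneCandidate]]:
    """Split candidates into (kept, discarded) by protein p-distance to the
    nearest query protein; order is preserved within each list."""
    if not isinstance(queries, QuerySet):
        queries = QuerySet(queries)
    qproteins = {name: translate_cds(seq) for name, seq in queries.items()}
    aligner = _protein_aligner()
    kept, discarded = [], []
    for cand in candidates:
        if not cand.protein:
            cand = classify_orf(cand)
        protein = cand.protein.replace("*", "")
        if not protein:
            logger.warning("%s: empty protein; discarded", cand.gene_id)
            discarded.append(replace(cand, divergent=True))
            continue
        dist = min(
            protein_p_distance(protein, qp, aligner) for qp in qproteins.values()
        )
        if dist > max_pdist:
            discarded.append(replace(cand, divergent=True))
        else:
            kept.append(cand)
    return kept, discarded


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def candidates_to_bed(candidates: Sequence[GeneCandidate], path) -> None:
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(
                f"{c.chromosome}\t{c.start}\t{c.end}\t{c.gene_id}"
                f"\t{int(round(c.score))}\t{c.strand}\n"
            )


def candidates_to_table(candidates: Sequence[GeneCandidate], path) -> None:
    import pandas as pd

    rows = [
        {
            "gene_id": c.gene_id,
            "accession": c.accession,
            "chromosome": c.chromosome,
            "start": c.start,
            "end": c.end,
            "strand": c.strand,
            "best_query": c.best_query,
            "identity": round(c.identity, 4),
            "score": c.score,
            "starts_with_met": c.starts_with_met,
            "has_internal_stop": c.has_internal_stop,
            "has_terminal_stop": c.has_terminal_stop,
            "frameshifted": c.frameshifted,
            "divergent": c.divergent,
        }
        for c in candidates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def proteins_to_fasta(candidates: Sequence[GeneCandidate], path) -> None:
    from .synthetic_data import write_fasta

    write_fasta({c.gene_id: c.protein for c in candidates if c.protein}, path)
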