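"""Celiac-disease epitope scanning and per-locus tabulation.

α-Gliadin proteins carry short immunogenic peptides (CD epitopes) such as
the DQ2.5-glia-α 9-mers, which in D-subgenome copies can overlap to form the
highly immunotoxic 33-mer fragment.  Scanning is exact substring matching,
overlap-aware: every occurrence of every table peptide is reported,
including overlapping and repeated ones.  Counts are then aggregated per
(accession, locus, epitope) with zero rows retained so that absences (e.g.
no DQ2.5-glia-α epitopes in the B subgenome) stay visible.

The epitope table is user-supplied (tab-separated: name, peptide, note);
the shipped default covers the four well-established DQ2.5-glia-α 9-mers
and the canonical 33-mer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

AA20 = set("ACDEFGHIKLMNPQRSTVWY")

#: The canonical 33-mer fragment (contains 6 overlapping repeat-domain
#: epitopes: 1× DQ2.5-glia-α1a, 2× α1b, 3× α2).
MER33 = "LQLQPFPQPQLPYPQPQLPYPQPQLPYPQPQPF"

#: The three repeat-domain 9-mers whose overlap constitutes the 33-mer.
REPEAT_DOMAIN_EPITOPES = {
    "DQ2.5-glia-alpha1a": "PFPQPQLPY",
    "DQ2.5-glia-alpha1b": "PYPQPQLPY",
    "DQ2.5-glia-alpha2": "PQPQLPYPQ",
}


@dataclass(frozen=True)
class EpitopeHit:
    gene_id: str
    epitope: str
    offset: int  # 0-based position in the protein


class EpitopeTable(dict):
    """Mapping of epitope name -> peptide, with a provenance note per entry."""

    def __init__(self, entries: Mapping[str, str] | Iterable[tuple[str, str]],
                 notes: Mapping[str, str] | None = None):
        entries = dict(entries)
        for name, peptide in entries.items():
            if not peptide:
                raise ValueError(f"epitope {name!r} has an empty peptide")
            bad = set(peptide) - AA20
            if bad:
                raise ValueError(
                    f"epitope {name!r} peptide contains invalid residues: "
                    f"{sorted(bad)}"
                )
        super().__init__(entries)
        self.notes = dict(notes or {})

    @classmethod
    def default(cls) -> "EpitopeTable":
        entries = dict(REPEAT_DOMAIN_EPITOPES)
        entries["DQ2.5-glia-alpha3"] = "FRPQQPYPQ"
        entries["33mer"] = MER33
        notes = {
            "DQ2.5-glia-alpha1a": "canonical DQ2.5 repeat-domain 9-mer",
            "DQ2.5-glia-alpha1b": "canonical DQ2.5 repeat-domain 9-mer",
            "DQ2.5-glia-alpha2": "canonical DQ2.5 repeat-domain 9-mer",
            "DQ2.5-glia-alpha3": "canonical DQ2.5 9-mer",
            "33mer": "immunotoxic 33-residue fragment with 6 overlapping epitopes",
        }
        return cls(entries, notes)

    @classmethod
    def from_tsv(cls, path) -> "EpitopeTable":
        df = pd.read_csv(path, sep="\t")
        required = {"name", "peptide"}
        if not required <= set(df.columns):
            raise ValueError(f"epitope table needs columns {sorted(required)}")
        if df["name"].duplicated().any():
            dupes = df.loc[df["name"].duplicated(), "name"].tolist()
            raise ValueError(f"duplicate epitope names: {dupes}")
        notes = (
            dict(zip(df["name"], df["note"])) if "note" in df.columns else {}
        )
        return cls(dict(zip(df["name"], df["peptide"])), notes)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "name": list(self),
                "peptide": [self[n] for n in self],
                "note": [self.notes.get(n, "") for n in self],
            }
        ).to_csv(path, sep="\t", index=False)


def _check_protein(protein: str, gene_id: str) -> None:
    bad = set(protein) - AA20
    if bad:
        raise ValueError(
            f"protein of {gene_id!r} contains invalid characters "
            f"{sorted(bad)}; proteins must be uppercase amino acids without "
            "stop symbols"
        )


def find_all(text: str, pattern: str) -> list[int]:
    """All (possibly overlapping) 0-based occurrences of pattern in text."""
    return [m.start() for m in re.finditer(f"(?={re.escape(pattern)})", text)]


def scan_epitopes(
    protein: str,
    table: EpitopeTable,
    gene_id: str = "",
) -> list[EpitopeHit]:
    """Every occurrence of every table peptide in the protein, overlapping
    and repeated occurrences included, ordered by (offset, name)."""
    _check_protein(protein, gene_id or "<protein>")
    hits = [
        EpitopeHit(gene_id, name, off)
        for name in table
        for off in find_all(protein, table[name])
    ]
    hits.sort(key=lambda h: (h.offset, h.epitope))
    return hits


@dataclass(frozen=True)
class Mer33Report:
    exact_count: int          # exact occurrences of the 33-mer peptide
    max_window_hits: int      # most repeat-domain epitope hits in a 33-aa window
    composite_detected: bool  # >= 6 overlapping repeat-domain hits in a window


def detect_33mer(protein: str, gene_id: str = "") -> Mer33Report:
    """Count exact 33-mer occurrences and check the composite criterion
    (≥6 overlapping repeat-domain epitope hits within a 33-residue window)."""
    _check_protein(protein, gene_id or "<protein>")
    exact = len(find_all(protein, MER33))
    offsets = sorted(
        off
        for pep in REPEAT_DOMAIN_EPITOPES.values()
        for off in find_all(protein, pep)
    )
    window = 33 - 9  # hit start offsets spanning at most one 33-mer window
    best = 0
    for i, start in enumerate(offsets):
        inside = sum(1 for o in offsets[i:] if o - start <= window)
        best = max(best, inside)
    return Mer33Report(exact, best, best >= 6)


def profile_counts(
    hits: Sequence[EpitopeHit],
    locus_by_gene: Mapping[str, str],
    accession_by_gene: Mapping[str, str],
    table: EpitopeTable,
) -> pd.DataFrame:
    """Count matrix indexed by (accession, locus, epitope), with all-zero
    rows retained over the full index so absences are visible."""
    unknown = sorted({h.gene_id for h in hits} - set(locus_by_gene))
    if unknown:
        raise ValueError(f"hits for genes without a locus assignment: {unknown}")
    accessions = sorted(set(accession_by_gene.values()))
    loci = sorted(set(locus_by_gene.values()))
    index = pd.MultiIndex.from_product(
        [accessions, loci, sorted(table)], names=["accession", "locus", "epitope"]
    )
    profile = pd.Series(0, index=index, name="count", dtype=int)
    for hit in hits:
        key = (
            accession_by_gene.get(hit.gene_id, accessions[0] if accessions else ""),
            locus_by_gene[hit.gene_id],
            hit.epitope,
        )
        profile.loc[key] += 1
    return profile.reset_index()


def genes_containing(
    hits: Sequence[EpitopeHit],
) -> pd.DataFrame:
    """Per-gene summary of distinct epitope names present (the
    presence/absence companion to the occurrence counts)."""
    by_gene: dict[str, set[str]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, set()).add(h.epitope)
    return pd.DataFrame(
        {
            "gene_id": sorted(by_gene),
            "distinct_epitopes": [len(by_gene[g]) for g in sorted(by_gene)],
            "epitopes": [",".join(sorted(by_gene[g])) for g in sorted(by_gene)],
        }
    )


def subgenome_marginals(profile: pd.DataFrame) -> pd.DataFrame:
    """Sum counts over loci by subgenome letter parsed from the locus name."""
    from .locus_map import subgenome_letter

    df = profile.copy()
    df["subgenome"] = [subgenome_letter(l) for l in df["locus"]]
    return (
        df.groupby(["accession", "subgenome", "epitope"], as_index=False)["count"]
        .sum()
    )


def profile_matrix(profile: pd.DataFrame) -> pd.DataFrame:
    """Pivot to the figure-shaped matrix: rows = epitope, columns =
    (accession, locus)."""
    return profile.pivot_table(
        index="epitope",
        columns=["accession", "locus"],
        values="count",
        aggfunc="sum",
        fill_value=0,
    )
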