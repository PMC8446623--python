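"""End-to-end orchestration: discover -> map loci -> epitopes -> phylo ->
selection -> coverage, driven by one config mapping and one global seed.

Every run directory gets a ``manifest.json`` recording per-stage status,
parameters, the seed, and SHA-256 hashes of all written artifacts, so a
rerun with the same config and seed reproduces identical manifests.  A
stage failure halts the run but keeps partial outputs next to a ``FAILED``
marker.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import coverage_qc, epitope_profile, gene_discovery, locus_map, phylo
from . import selection as selection_mod
from . import synthetic_data

logger = logging.getLogger(__name__)

STAGES = ["discover", "map_loci", "epitopes", "phylo", "selection", "coverage"]


def toy_config(seed: int = 0) -> dict:
    """A small synthetic accession exercising every stage quickly: the same
    locus structure as the full-scale default generator, compressed onto
    short chromosomes."""
    return {
        "accession": "synthA",
        "seed": seed,
        "simulate": {
            "chromosomes": {"chr6B": 120_000, "chr6D": 60_000},
            "loci": [
                {"chromosome": "chr6B", "anchors_bp": [20_000, 90_000],
                 "copies": [5, 2], "spacing_bp": 1_500},
                {"chromosome": "chr6D", "anchors_bp": [30_000],
                 "copies": [6], "spacing_bp": 1_500},
            ],
            "substitution_rate": 0.015,
            "pseudogene_prob": 0.1,
            "collapsed_genes": [1],
            "haplotype_specific_genes": [4],
            "epitopes": {
                "DQ2.5-glia-alpha1a": ["PFPQPQLPY", 2],
                "DQ2.5-glia-alpha2": ["PQPQLPYPQ", 2],
            },
        },
        "stages": {name: True for name in STAGES},
        "params": {
            "discover": {"min_identity": 0.9, "min_len": 300, "seed_len": 16},
            "map_loci": {"gap_mb": 0.005},  # scaled to the toy chromosomes
            "phylo": {"alpha": 2.25, "bootstrap": 50},
            "selection": {"starts": 1, "maxiter": 60},
            # noise kept below a third of the smallest classification margin
            # (0.1 x median between the 0.5x expectation and the 0.6x cutoff)
            "coverage": {"median": 32.23, "high": 1.5, "low": 0.6,
                         "noise_sd": 1.0},
        },
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _sim_config_from_mapping(sim: Mapping, seed: int) -> synthetic_data.SimConfig:
    loci = tuple(
        synthetic_data.LocusSpec(
            chromosome=l["chromosome"],
            anchors_bp=tuple(l["anchors_bp"]),
            copies=tuple(l["copies"]),
            spacing_bp=int(l.get("spacing_bp", 2_000)),
        )
        for l in sim["loci"]
    )
    return synthetic_data.SimConfig(
        chromosomes=dict(sim["chromosomes"]),
        loci=loci,
        template_cds=sim.get("template_cds", synthetic_data._default_template()),
        substitution_rate=float(sim.get("substitution_rate", 0.02)),
        pseudogene_prob=float(sim.get("pseudogene_prob", 0.1)),
        collapsed_genes=tuple(sim.get("collapsed_genes", ())),
        haplotype_specific_genes=tuple(sim.get("haplotype_specific_genes", ())),
        epitopes={k: (v[0], int(v[1])) for k, v in sim.get("epitopes", {}).items()},
        seed=seed,
    )


def load_config(source) -> dict:
    if isinstance(source, Mapping):
        return dict(source)
    with open(source) as fh:
        return yaml.safe_load(fh)


def _read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


def write_locus_table(rows: list[dict], path) -> pd.DataFrame:
    """Accession × locus report: positions as Mb ranges (1 decimal) and
    copy numbers in the 'total (intact ORF)' convention; unanchored loci
    print 'chrUn' in the position cell."""
    table_rows = {}
    loci_names = []
    for row in rows:
        acc = row["accession"]
        table_rows.setdefault(acc, {"accession": acc})
        name = row["locus"]
        if name not in loci_names:
            loci_names.append(name)
        pos = row["positions_mb"]
        if "Un" in str(row.get("chromosome", "")):
            pos = "chrUn"
        table_rows[acc][f"{name} positions"] = pos
        table_rows[acc][f"{name} copies (intact)"] = row["copy_number"]
    columns = ["accession"]
    for name in sorted(loci_names):
        columns += [f"{name} positions", f"{name} copies (intact)"]
    df = pd.DataFrame(
        [table_rows[acc] for acc in sorted(table_rows)], columns=columns
    )
    df.to_csv(path, sep="\t", index=False)
    return df


def write_epitope_matrix(profile: pd.DataFrame, path) -> pd.DataFrame:
    """Epitope × (accession, locus) count matrix with zero rows retained."""
    matrix = epitope_profile.profile_matrix(profile)
    matrix.to_csv(path, sep="\t")
    return matrix


def run_pipeline(config, out_dir) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    accession = cfg.get("accession", "accession")
    stages_on = {name: bool(cfg.get("stages", {}).get(name, True))
                 for name in STAGES}
    params = cfg.get("params", {})
    manifest = {
        "accession": accession,
        "seed": seed,
        "params": params,
        "stages": {},
        "inputs": {},
    }

    def record(stage: str, status: str, outputs: dict[str, Path] | None = None):
        manifest["stages"][stage] = {
            "status": status,
            "outputs": {
                name: _sha256(path) for name, path in (outputs or {}).items()
            },
        }

    def fail(stage: str, exc: Exception):
        record(stage, "failed")
        (out / "FAILED").write_text(f"{stage}: {exc}\n")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise

    # ---------------- inputs (synthetic or from paths) -----------------
    truth = None
    depth_df = None
    if "simulate" in cfg:
        sim_cfg = _sim_config_from_mapping(cfg["simulate"], seed)
        assembly, truth = synthetic_data.generate_assembly(sim_cfg)
        queries = {"ASQ1": sim_cfg.template_cds}
        noise = float(params.get("coverage", {}).get("noise_sd", 0.0))
        median = float(params.get("coverage", {}).get("median", 32.23))
        depth_df = synthetic_data.simulate_depth_table(
            truth, median_cov=median, noise_sd=noise, seed=seed + 1
        )
        synthetic_data.write_fasta(assembly, out / "assembly.fa")
        synthetic_data.write_fasta(queries, out / "queries.fa")
        synthetic_data.write_truth_tsv(truth, out / "truth.tsv")
        synthetic_data.write_truth_bed(truth, out / "truth.bed")
        depth_df.to_csv(out / "depth.tsv", sep="\t", index=False)
        manifest["inputs"] = {
            "assembly.fa": _sha256(out / "assembly.fa"),
            "queries.fa": _sha256(out / "queries.fa"),
            "depth.tsv": _sha256(out / "depth.tsv"),
        }
    else:
        paths = cfg.get("paths", {})
        assembly = _read_fasta(paths["assembly"])
        queries = _read_fasta(paths["queries"])
        if paths.get("depth_table"):
            depth_df = pd.read_csv(paths["depth_table"], sep="\t")
        manifest["inputs"] = {
            k: _sha256(Path(v)) for k, v in paths.items() if v and Path(v).exists()
        }

    table = (
        epitope_profile.EpitopeTable.from_tsv(cfg["paths"]["epitope_table"])
        if cfg.get("paths", {}).get("epitope_table")
        else epitope_profile.EpitopeTable.default()
    )

    # ---------------- discover -----------------------------------------
    candidates = []
    if stages_on["discover"]:
        try:
            p = params.get("discover", {})
            candidates = gene_discovery.find_candidates(
                assembly, queries,
                min_identity=float(p.get("min_identity", 0.9)),
                min_len=int(p.get("min_len", 300)),
                seed_len=int(p.get("seed_len", 16)),
                accession=accession,
            )
            gene_discovery.candidates_to_bed(candidates, out / "candidates.bed")
            gene_discovery.candidates_to_table(candidates, out / "candidates.tsv")
            gene_discovery.proteins_to_fasta(candidates, out / "proteins.fa")
            record("discover", "done", {
                "candidates.bed": out / "candidates.bed",
                "candidates.tsv": out / "candidates.tsv",
                "proteins.fa": out / "proteins.fa",
            })
        except Exception as exc:  # noqa: BLE001 - halt with marker
            fail("discover", exc)
    else:
        record("discover", "skipped")

    intact = [
        c for c in candidates
        if c.starts_with_met and not c.has_internal_stop and not c.frameshifted
    ]
    intact_by_gene = {c.gene_id: True for c in intact}

    # ---------------- map loci -----------------------------------------
    loci = []
    locus_by_gene: dict[str, str] = {}
    if stages_on["map_loci"]:
        try:
            gap = float(params.get("map_loci", {}).get("gap_mb", 5.0))
            rows = []
            for chrom in sorted({c.chromosome for c in candidates}):
                on_chrom = [c for c in candidates if c.chromosome == chrom]
                chrom_loci = locus_map.cluster_loci(on_chrom, gap_mb=gap)
                loci.extend(chrom_loci)
                for locus in chrom_loci:
                    for gid in locus.members:
                        locus_by_gene[gid] = locus.name
                rows.extend(
                    locus_map.locus_table_rows(accession, chrom_loci, intact_by_gene)
                )
            write_locus_table(rows, out / "locus_table.tsv")
            record("map_loci", "done", {"locus_table.tsv": out / "locus_table.tsv"})
        except Exception as exc:  # noqa: BLE001
            fail("map_loci", exc)
    else:
        record("map_loci", "skipped")

    # ---------------- epitopes ------------------------------------------
    if stages_on["epitopes"]:
        try:
            hits = []
            for cand in candidates:
                protein = cand.protein.replace("*", "")
                if protein:
                    hits.extend(
                        epitope_profile.scan_epitopes(protein, table, cand.gene_id)
                    )
            pd.DataFrame(
                [
                    {"gene_id": h.gene_id, "epitope": h.epitope, "offset": h.offset}
                    for h in hits
                ],
                columns=["gene_id", "epitope", "offset"],
            ).to_csv(out / "epitope_hits.tsv", sep="\t", index=False)
            profile = epitope_profile.profile_counts(
                hits,
                {c.gene_id: locus_by_gene.get(c.gene_id, "unassigned")
                 for c in candidates},
                {c.gene_id: accession for c in candidates},
                table,
            )
            profile.to_csv(out / "epitope_profile.tsv", sep="\t", index=False)
            write_epitope_matrix(profile, out / "epitope_matrix.tsv")
            record("epitopes", "done", {
                "epitope_hits.tsv": out / "epitope_hits.tsv",
                "epitope_profile.tsv": out / "epitope_profile.tsv",
                "epitope_matrix.tsv": out / "epitope_matrix.tsv",
            })
        except Exception as exc:  # noqa: BLE001
            fail("epitopes", exc)
    else:
        record("epitopes", "skipped")

    # ---------------- phylo ---------------------------------------------
    aln = None
    tree = None
    if stages_on["phylo"]:
        try:
            p = params.get("phylo", {})
            usable = {
                c.gene_id: c.cds for c in intact
                if len(c.cds) % 3 == 0 and not c.has_internal_stop
            }
            if len(usable) < 3:
                raise ValueError("fewer than 3 usable sequences for phylogeny")
            aln = phylo.align_codons(usable)
            aln.to_fasta(out / "codon_alignment.fa")
            tree, supports = phylo.bootstrap_support(
                aln,
                b_replicates=int(p.get("bootstrap", 100)),
                alpha=float(p.get("alpha", 2.25)),
                seed=seed + 2,
            )
            with open(out / "tree.nwk", "w") as fh:
                fh.write(tree.as_string(schema="newick"))
            membership = phylo.clade_membership(
                tree,
                {gid: locus_by_gene.get(gid, phylo.UNANCHORED_LABEL)
                 for gid in usable},
            )
            with open(out / "clades.json", "w") as fh:
                json.dump(
                    {
                        "clade_by_leaf": membership["clade_by_leaf"],
                        "outliers": membership["outliers"],
                    },
                    fh, indent=2, sort_keys=True,
                )
            record("phylo", "done", {
                "codon_alignment.fa": out / "codon_alignment.fa",
                "tree.nwk": out / "tree.nwk",
                "clades.json": out / "clades.json",
            })
        except Exception as exc:  # noqa: BLE001
            fail("phylo", exc)
    else:
        record("phylo", "skipped")

    # ---------------- selection ------------------------------------------
    if stages_on["selection"]:
        try:
            if aln is None or tree is None:
                raise ValueError("selection requires the phylo stage")
            p = params.get("selection", {})
            cleaned, mask = selection_mod.prepare_selection_alignment(aln)
            pd.DataFrame(
                [{"row": k, "reason": v} for k, v in mask.dropped_rows.items()]
                + [{"row": f"codon_column_{k}", "reason": v}
                   for k, v in sorted(mask.removed_columns.items())]
            ).to_csv(out / "mask_report.tsv", sep="\t", index=False)
            # NJ tree from the cleaned alignment as the fallback input tree
            keep_tree = phylo.nj_tree(
                phylo.k2p_gamma_distance(cleaned, deletion="pairwise")
            )
            starts = int(p.get("starts", 5))
            maxiter = int(p.get("maxiter", 500))
            fit7 = selection_mod.fit_site_model(
                cleaned, keep_tree, "M7", starts=starts, seed=seed + 3,
                maxiter=maxiter,
            )
            fit8 = selection_mod.fit_site_model(
                cleaned, keep_tree, "M8", starts=starts, seed=seed + 4,
                maxiter=maxiter,
                extra_starts=[{"kappa": fit7.kappa, "p": fit7.p, "q": fit7.q,
                               "scale": fit7.tree_scale, "p0": 1.0}],
            )
            lrt = selection_mod.lrt_m7_m8(fit7, fit8)
            sites = selection_mod.site_posteriors(fit8)
            result = {
                "M7": {"lnL": fit7.log_likelihood, "kappa": fit7.kappa,
                       "p": fit7.p, "q": fit7.q, "converged": fit7.converged},
                "M8": {"lnL": fit8.log_likelihood, "kappa": fit8.kappa,
                       "p": fit8.p, "q": fit8.q, "p0": fit8.p0,
                       "omega_s": fit8.omega_s, "converged": fit8.converged},
                "LRT": {"statistic": lrt.lrt_statistic, "df": lrt.df,
                        "p_value": lrt.p_value},
                "significant_sites": sites.significant_sites,
            }
            with open(out / "selection.json", "w") as fh:
                json.dump(result, fh, indent=2, sort_keys=True)
            pd.DataFrame(
                {
                    "site": np.arange(1, fit8.n_sites + 1),
                    "original_codon_column": [
                        mask.kept_columns[i] + 1 for i in range(fit8.n_sites)
                    ],
                    "posterior_positive": sites.site_posterior,
                }
            ).to_csv(out / "site_posteriors.tsv", sep="\t", index=False)
            record("selection", "done", {
                "mask_report.tsv": out / "mask_report.tsv",
                "selection.json": out / "selection.json",
                "site_posteriors.tsv": out / "site_posteriors.tsv",
            })
        except Exception as exc:  # noqa: BLE001
            fail("selection", exc)
    else:
        record("selection", "skipped")

    # ---------------- coverage ------------------------------------------
    if stages_on["coverage"]:
        try:
            p = params.get("coverage", {})
            if depth_df is None:
                raise ValueError("no depth table available")
            records = coverage_qc.summarize_gene_coverage(depth_df)
            classified, summary = coverage_qc.classify_copy_status(
                records,
                median_cov=float(p.get("median", 32.23)),
                high_ratio=float(p.get("high", 1.5)),
                low_ratio=float(p.get("low", 0.6)),
            )
            coverage_qc.records_to_table(classified, out / "coverage.tsv")
            with open(out / "coverage_summary.json", "w") as fh:
                json.dump(summary, fh, indent=2, sort_keys=True)
            record("coverage", "done", {
                "coverage.tsv": out / "coverage.tsv",
                "coverage_summary.json": out / "coverage_summary.json",
            })
        except Exception as exc:  # noqa: BLE001
            fail("coverage", exc)
    else:
        record("coverage", "skipped")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
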