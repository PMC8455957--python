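"""Stage orchestration: run each analysis step from a config, on disk.

Every stage reads its inputs from the configured output directory (or the
user's paths), writes TSV/FASTA/JSON artifacts, and records a stage
manifest with input hashes and parameters so identical inputs reproduce
identical outputs. Stage order for a full run:

    simulate -> identify -> properties -> duplicates -> synteny -> kaks
             -> tree -> expression -> promoters -> report
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import duplication, expression, family, kaks, phylogeny, profile_hmm, promoter
from .config import PipelineConfig
from .reference import load_reference_table
from .seqio import read_fasta, read_gene_models, write_fasta, write_gff3
from .simulate import (
    SyntheticGenome,
    TruthManifest,
    default_seed_alignment,
    generate_expression_matrix,
    generate_family_genome,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "identify", "properties", "duplicates", "synteny",
    "kaks", "tree", "expression", "promoters", "report",
)


class DataError(RuntimeError):
    """An input artifact is missing or inconsistent."""


def _outdir(cfg: PipelineConfig) -> Path:
    p = Path(cfg.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(cfg: PipelineConfig, name: str, producer: str) -> Path:
    p = _outdir(cfg) / name
    if not p.exists():
        raise DataError(
            f"missing input {p}; run the '{producer}' stage first"
        )
    return p


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_stage_manifest(cfg: PipelineConfig, stage: str, inputs: list[Path],
                          params: dict, outputs: list[Path]) -> None:
    man = {
        "stage": stage,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "outputs": {str(p): _sha256(p) for p in outputs},
        "parameters": params,
    }
    with open(_outdir(cfg) / f"manifest_{stage}.json", "w") as fh:
        json.dump(man, fh, indent=1, sort_keys=True)


def _seed_alignment(cfg: PipelineConfig) -> dict[str, str]:
    if cfg.seed_alignment_path:
        return read_fasta(cfg.seed_alignment_path)
    return default_seed_alignment(length=cfg.simulation.domain_length_aa)


def _calibrated_profile(cfg: PipelineConfig, rng) -> profile_hmm.ProfileModel:
    prof = profile_hmm.build_profile(_seed_alignment(cfg))
    return profile_hmm.calibrate(prof, rng, n_null=cfg.calibration_n)


def stage_simulate(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    sim = generate_family_genome(cfg.simulation, seed_alignment=_seed_alignment(cfg))
    write_fasta(sim.genome, out / "genome.fasta")
    write_gff3(sim.genes, out / "genes.gff3")
    write_fasta(sim.proteins, out / "proteins.fasta")
    write_fasta(sim.cds, out / "cds.fasta")
    sim.manifest.to_json(out / "truth.json")
    tpm = generate_expression_matrix(sim.manifest, cfg.simulation)
    tpm.to_csv(out / "expression_tpm.tsv", sep="\t", index_label="gene_id")
    outputs = [out / n for n in (
        "genome.fasta", "genes.gff3", "proteins.fasta", "cds.fasta",
        "truth.json", "expression_tpm.tsv",
    )]
    _write_stage_manifest(cfg, "simulate", [], {"seed": cfg.simulation.seed}, outputs)
    return {
        "n_genes": len(sim.genes),
        "n_family": len(sim.manifest.family_gene_ids),
        "n_tandem_pairs": len(sim.manifest.tandem_pairs),
        "n_segmental_pairs": len(sim.manifest.segmental_pairs),
    }


def stage_identify(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    prot_path = _require(cfg, "proteins.fasta", "simulate")
    gff_path = _require(cfg, "genes.gff3", "simulate")
    proteome = read_fasta(prot_path)
    gene_models = {g.gene_id: g for g in read_gene_models(gff_path)}
    rng = np.random.default_rng(cfg.seed)
    seed_profile = _calibrated_profile(cfg, rng)
    candidates = profile_hmm.two_pass_search(
        seed_profile, proteome, rng,
        e_first=cfg.e_value_first_pass, e_strict=cfg.e_value_strict,
        calibration_n=cfg.calibration_n,
    )
    members = family.confirm_and_filter(
        candidates, proteome, seed_profile, gene_models,
        mw_min_kda=cfg.mw_min_kda, mw_max_kda=cfg.mw_max_kda,
        confirm_e_value=cfg.e_value_first_pass,
        name_prefix=cfg.family_name_prefix,
    )
    df = pd.DataFrame(
        [
            {
                "assigned_name": m.assigned_name, "gene_id": m.gene_id,
                "chromosome": m.chromosome, "start_bp": m.start_bp,
                "aa_length": m.aa_length, "mw_kda": m.mw_kda, "pi": m.pi,
            }
            for m in members
        ],
        columns=["assigned_name", "gene_id", "chromosome", "start_bp",
                 "aa_length", "mw_kda", "pi"],
    )
    df.to_csv(out / "family_members.tsv", sep="\t", index=False)
    _write_stage_manifest(
        cfg, "identify", [prot_path, gff_path],
        {
            "e_value_first_pass": cfg.e_value_first_pass,
            "e_value_strict": cfg.e_value_strict,
            "mw_window_kda": [cfg.mw_min_kda, cfg.mw_max_kda],
            "excluded_by_mw": len(candidates) - len(members),
        },
        [out / "family_members.tsv"],
    )
    logger.info(
        "identify: %d candidates, %d members after confirmation and MW gate",
        len(candidates), len(members),
    )
    return {"n_candidates": len(candidates), "n_members": len(df)}


def _family_table(cfg: PipelineConfig) -> pd.DataFrame:
    return pd.read_csv(_require(cfg, "family_members.tsv", "identify"), sep="\t")


def stage_properties(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    fam = _family_table(cfg)
    proteome = read_fasta(_require(cfg, "proteins.fasta", "simulate"))
    cds = read_fasta(_require(cfg, "cds.fasta", "simulate"))
    from .properties import isoelectric_point, molecular_weight

    rows = []
    for rec in fam.itertuples(index=False):
        seq = proteome[rec.gene_id]
        rows.append(
            {
                "gene_id": rec.gene_id,
                "assigned_name": rec.assigned_name,
                "cds_bp": len(cds[rec.gene_id]),
                "aa_length": len(seq),
                "mw_kda": round(molecular_weight(seq), 2),
                "pi": round(isoelectric_point(seq), 2),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "assigned_name", "cds_bp", "aa_length", "mw_kda", "pi"],
    )
    df.to_csv(out / "protein_properties.tsv", sep="\t", index=False)
    _write_stage_manifest(cfg, "properties",
                          [out / "family_members.tsv"], {}, [out / "protein_properties.tsv"])
    return {"n_proteins": len(df)}


def stage_duplicates(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    genes = read_gene_models(_require(cfg, "genes.gff3", "simulate"))
    proteome = read_fasta(_require(cfg, "proteins.fasta", "simulate"))
    fam_ids = set(_family_table(cfg)["gene_id"])
    pairs, blocks, hits = duplication.find_duplicates(
        genes, proteome, e_value_max=cfg.blast_e_value,
        min_anchors=cfg.min_anchors, max_gap=cfg.max_rank_gap,
        cscore_min=cfg.cscore_min,
    )
    df = pd.DataFrame(
        [
            {
                "gene_a": p.gene_a, "gene_b": p.gene_b,
                "duplicate_class": p.duplicate_class,
                "block_id": p.block_id if p.block_id is not None else "",
                "family_pair": p.gene_a in fam_ids and p.gene_b in fam_ids,
            }
            for p in pairs
        ]
    )
    df.to_csv(out / "duplicate_pairs.tsv", sep="\t", index=False)
    bdf = pd.DataFrame(
        [
            {
                "block_id": b.block_id,
                "n_anchors": len(b.anchor_pairs),
                "anchors": ";".join(f"{a}|{b_}" for a, b_ in b.anchor_pairs),
            }
            for b in blocks
        ]
    )
    bdf.to_csv(out / "collinear_blocks.tsv", sep="\t", index=False)
    _write_stage_manifest(
        cfg, "duplicates",
        [out / "genes.gff3", out / "proteins.fasta"],
        {"blast_e_value": cfg.blast_e_value, "min_anchors": cfg.min_anchors,
         "max_rank_gap": cfg.max_rank_gap, "cscore_min": cfg.cscore_min},
        [out / "duplicate_pairs.tsv", out / "collinear_blocks.tsv"],
    )
    fam_pairs = df[df["family_pair"]]
    return {
        "n_hits": len(hits),
        "n_blocks": len(blocks),
        "tandem_family_pairs": int((fam_pairs["duplicate_class"] == "tandem").sum()),
        "segmental_family_pairs": int(
            (fam_pairs["duplicate_class"] == "wgd_segmental").sum()
        ),
    }


def stage_synteny(cfg: PipelineConfig, genome_b_gff: str | None = None,
                  genome_b_proteins: str | None = None) -> dict:
    """Cross-genome synteny with the cscore filter. Without a second genome
    the synthetic genome is compared against a relabeled copy of itself."""
    out = _outdir(cfg)
    genes_a = read_gene_models(_require(cfg, "genes.gff3", "simulate"))
    prot_a = read_fasta(_require(cfg, "proteins.fasta", "simulate"))
    if genome_b_gff and genome_b_proteins:
        genes_b = read_gene_models(genome_b_gff)
        prot_b = read_fasta(genome_b_proteins)
    else:
        genes_b = [
            type(g)(gene_id=f"B_{g.gene_id}", chrom=g.chrom, start=g.start,
                    end=g.end, strand=g.strand)
            for g in genes_a
        ]
        prot_b = {f"B_{k}": v for k, v in prot_a.items()}
    hits = duplication.all_vs_all(prot_a, e_value_max=cfg.blast_e_value, cross=prot_b)
    blocks = duplication.cross_species_synteny(
        genes_a, genes_b, hits, cscore_min=cfg.cscore_min,
        min_anchors=cfg.min_anchors, max_gap=cfg.max_rank_gap,
    )
    bdf = pd.DataFrame(
        [
            {"block_id": b.block_id, "n_anchors": len(b.anchor_pairs),
             "anchors": ";".join(f"{x}|{y}" for x, y in b.anchor_pairs)}
            for b in blocks
        ]
    )
    bdf.to_csv(out / "synteny_blocks.tsv", sep="\t", index=False)
    _write_stage_manifest(cfg, "synteny", [out / "genes.gff3"],
                          {"cscore_min": cfg.cscore_min}, [out / "synteny_blocks.tsv"])
    return {"n_blocks": len(blocks), "n_anchors": int(bdf["n_anchors"].sum() if len(bdf) else 0)}


def stage_kaks(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    dup = pd.read_csv(_require(cfg, "duplicate_pairs.tsv", "duplicates"), sep="\t")
    cds = read_fasta(_require(cfg, "cds.fasta", "simulate"))
    rows = []
    sel = dup[dup["family_pair"] & dup["duplicate_class"].isin(["tandem", "wgd_segmental"])]
    for rec in sel.itertuples(index=False):
        res = kaks.kaks_for_cds_pair(cds[rec.gene_a], cds[rec.gene_b])
        rows.append(
            {
                "gene_a": rec.gene_a, "gene_b": rec.gene_b,
                "duplicate_class": rec.duplicate_class,
                "ka": res.ka, "ks": res.ks,
                "ratio": res.ratio if res.ratio is not None else "",
                "selection_class": res.selection_class,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "duplicate_class", "ka", "ks", "ratio",
                 "selection_class"],
    )
    df.to_csv(out / "kaks.tsv", sep="\t", index=False)
    _write_stage_manifest(cfg, "kaks", [out / "duplicate_pairs.tsv"], {}, [out / "kaks.tsv"])
    return {"n_pairs": len(df)}


def stage_tree(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    fam = _family_table(cfg)
    proteome = read_fasta(_require(cfg, "proteins.fasta", "simulate"))
    rng = np.random.default_rng(cfg.seed)
    profile = _calibrated_profile(cfg, rng)
    # profile-anchored domain alignment: one match-state row per member
    alignment = {
        rec.assigned_name: profile_hmm.score_with_traceback(
            profile, proteome[rec.gene_id]
        )[3]
        for rec in fam.itertuples(index=False)
    }
    if len(alignment) < 3:
        raise DataError("tree stage needs at least 3 family members")
    tree = phylogeny.bootstrap_support(
        alignment, n_replicates=cfg.bootstrap_replicates, seed=cfg.seed
    )
    phylogeny.write_newick(tree, out / "family_tree.nwk")
    _write_stage_manifest(
        cfg, "tree", [out / "family_members.tsv", out / "proteins.fasta"],
        {"bootstrap_replicates": cfg.bootstrap_replicates}, [out / "family_tree.nwk"],
    )
    return {"n_taxa": len(alignment)}


def stage_expression(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    tpm = pd.read_csv(
        _require(cfg, "expression_tpm.tsv", "simulate"), sep="\t", index_col="gene_id"
    )
    z, constant = expression.zscore_by_gene(tpm)
    groups = expression.cluster_expression_groups(
        z, k=cfg.n_expression_groups, z_threshold=cfg.upregulation_z_threshold
    )
    z.to_csv(out / "expression_zscores.tsv", sep="\t", index_label="gene_id")
    gdf = pd.DataFrame(
        {
            "gene_id": z.index,
            "group": groups.labels.values,
            "hts_up": groups.hts_up.values,
            "constant": constant.values,
        }
    )
    gdf.to_csv(out / "expression_groups.tsv", sep="\t", index=False)
    _write_stage_manifest(
        cfg, "expression", [out / "expression_tpm.tsv"],
        {"k": cfg.n_expression_groups, "z_threshold": cfg.upregulation_z_threshold},
        [out / "expression_zscores.tsv", out / "expression_groups.tsv"],
    )
    sizes = gdf["group"].value_counts().to_dict()
    return {"group_sizes": sizes, "n_hts_up": int(gdf["hts_up"].sum())}


def stage_promoters(cfg: PipelineConfig) -> dict:
    out = _outdir(cfg)
    genome = read_fasta(_require(cfg, "genome.fasta", "simulate"))
    genes = read_gene_models(_require(cfg, "genes.gff3", "simulate"))
    fam = _family_table(cfg)
    fam_ids = list(fam["gene_id"])
    fam_genes = [g for g in genes if g.gene_id in set(fam_ids)]
    promoters = promoter.extract_promoters(genome, fam_genes, window=cfg.promoter_window)
    write_fasta({p.gene_id: p.sequence for p in promoters.values()},
                out / "promoters.fasta")
    catalog = promoter.load_motif_catalog()
    cis_rows, hse_rows = [], []
    for gid, prom in promoters.items():
        for h in promoter.scan_motifs(prom, catalog):
            cis_rows.append(
                {"gene_id": h.gene_id, "motif_name": h.motif_name,
                 "category": h.category, "subtype": h.subtype,
                 "offset": h.offset, "strand": h.strand}
            )
        for h in promoter.scan_hse(prom):
            hse_rows.append(
                {"gene_id": h.gene_id, "module": h.module, "offset": h.offset,
                 "strand": h.strand, "matched_sequence": h.matched_sequence}
            )
    cis_df = pd.DataFrame(
        cis_rows,
        columns=["gene_id", "motif_name", "category", "subtype", "offset", "strand"],
    )
    hse_df = pd.DataFrame(
        hse_rows,
        columns=["gene_id", "module", "offset", "strand", "matched_sequence"],
    )
    cis_df.to_csv(out / "cis_elements.tsv", sep="\t", index=False)
    hse_df.to_csv(out / "hse_hits.tsv", sep="\t", index=False)
    cis_hits = [
        promoter.CisElementHit(r["gene_id"], r["motif_name"], r["category"],
                               r["subtype"], r["offset"], r["strand"])
        for r in cis_rows
    ]
    summary = promoter.summarize_categories(cis_hits)
    summary.to_csv(out / "cis_element_summary.tsv", sep="\t", index=False)

    groups = pd.read_csv(_require(cfg, "expression_groups.tsv", "expression"), sep="\t")
    up_map = dict(zip(groups["gene_id"], groups["hts_up"]))
    hse_genes = set(hse_df["gene_id"]) if len(hse_df) else set()
    hse_presence = {gid: gid in hse_genes for gid in fam_ids}
    upregulated = {gid: bool(up_map.get(gid, False)) for gid in fam_ids}
    enr = promoter.hse_enrichment(hse_presence, upregulated)
    with open(out / "hse_enrichment.json", "w") as fh:
        json.dump(
            {"contingency": enr.contingency, "odds_ratio": enr.odds_ratio,
             "p_value": enr.p_value},
            fh, indent=1,
        )
    _write_stage_manifest(
        cfg, "promoters",
        [out / "genome.fasta", out / "genes.gff3", out / "expression_groups.tsv"],
        {"window": cfg.promoter_window},
        [out / "promoters.fasta", out / "cis_elements.tsv", out / "hse_hits.tsv",
         out / "cis_element_summary.tsv", out / "hse_enrichment.json"],
    )
    return {
        "n_cis_elements": len(cis_df),
        "n_hse_hits": len(hse_df),
        "enrichment_p": enr.p_value,
    }


REPORT_COLUMNS = [
    "Gene name", "Gene ID", "Chr", "Genomic locations", "CDS (bp)", "AA",
    "MW (kDa)", "pI",
]


def stage_report(cfg: PipelineConfig) -> dict:
    """Summary tables; the family table mirrors the reference column roster."""
    out = _outdir(cfg)
    fam = _family_table(cfg)
    props = pd.read_csv(_require(cfg, "protein_properties.tsv", "properties"), sep="\t")
    genes = {g.gene_id: g for g in read_gene_models(_require(cfg, "genes.gff3", "simulate"))}
    merged = fam.merge(props[["gene_id", "cds_bp"]], on="gene_id", how="left")
    rows = []
    for rec in merged.itertuples(index=False):
        g = genes[rec.gene_id]
        rows.append(
            {
                "Gene name": rec.assigned_name,
                "Gene ID": rec.gene_id,
                "Chr": rec.chromosome,
                "Genomic locations": f"{g.start}-{g.end}",
                "CDS (bp)": int(rec.cds_bp),
                "AA": rec.aa_length,
                "MW (kDa)": rec.mw_kda,
                "pI": rec.pi,
            }
        )
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    table.to_csv(out / "family_table.tsv", sep="\t", index=False)
    ref = load_reference_table()
    summary = {
        "n_members": len(table),
        "reference_n_members": int(len(ref)),
    }
    with open(out / "report_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    _write_stage_manifest(cfg, "report", [out / "family_members.tsv"], {},
                          [out / "family_table.tsv", out / "report_summary.json"])
    return summary


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "identify": stage_identify,
    "properties": stage_properties,
    "duplicates": stage_duplicates,
    "synteny": stage_synteny,
    "kaks": stage_kaks,
    "tree": stage_tree,
    "expression": stage_expression,
    "promoters": stage_promoters,
    "report": stage_report,
}


def run_stage(stage_name: str, cfg: PipelineConfig) -> dict:
    if stage_name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage_name!r}; stages are {STAGES}")
    logger.info("running stage %s", stage_name)
    return _STAGE_FUNCS[stage_name](cfg)


def run_all(cfg: PipelineConfig) -> dict:
    return {name: run_stage(name, cfg) for name in STAGES}
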