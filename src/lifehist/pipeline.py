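"""End-to-end orchestration of the trait-inference stages."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import ecology, qpcr as qpcr_mod, synthetic
from .config import PipelineConfig
from .drivers import lmm_group_effect
from .metagenome import (
    GrowthCalibration,
    average_genome_size,
    background_codon_usage,
    community_cub,
    gc_profile,
    genome_equivalents,
    predict_growth,
)
from .qpcr import StandardCurve
from .rrn import AsvTable, RrnReference, assign_rrn_copies, community_avg_rrn

log = logging.getLogger("lifehist")

STAGES = ("simulate", "rrn", "traits", "qpcr", "ecology", "drivers")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run simulate (optional) -> rrn -> traits -> qpcr -> ecology -> drivers.

    Writes per-stage tabular outputs under ``out_dir`` and a manifest
    JSON listing inputs, seeds, and per-output checksums. Any stage
    failure aborts with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "outputs": {}}
    state: dict = {}

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        for p in paths:
            manifest["outputs"][p.name] = _sha256(p)
        log.info("[%s] wrote %s", stage, ", ".join(p.name for p in paths))

    for stage in STAGES:
        try:
            paths = _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:  # propagate with stage context
            raise StageError(stage, exc) from exc
        record(stage, *paths)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_simulate(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    seed = config.seed
    if config.simulate:
        ref = synthetic.gen_reference(config.n_taxa, (1, 15), seed=seed)
        table, metadata, truth = synthetic.gen_communities(
            ref,
            config.n_sites,
            config.samples_per_site,
            effect=config.effect,
            site_sd=config.site_sd,
            depth=config.depth,
            seed=seed + 1,
        )
        reads, profiles, mg_truth = synthetic.gen_metagenome(
            [4_000_000.0] * 8, n_reads=40_000, seed=seed + 2
        )
        background = synthetic.random_background(seed + 3)
        calib = GrowthCalibration(config.calib_beta0, config.calib_beta1)
        genes, gene_truth = synthetic.gen_coding_genes(
            background, bias=1.0, n_ribosomal=50, n_background=200,
            calib=calib, seed=seed + 4,
        )
        curve = StandardCurve("all", slope=-3.3, intercept=38.0)
        gene_names = [f"gene{i:02d}" for i in range(6)]
        abundance = pd.DataFrame(
            np.random.default_rng(seed + 5).uniform(1e4, 1e6, (len(metadata), 7)),
            index=metadata.index,
            columns=["16S"] + gene_names,
        )
        wells, q_truth = synthetic.gen_qpcr(
            abundance, curve, frac_bad_eff=0.05, frac_neg_amp=0.02, seed=seed + 6
        )
        tree = synthetic.random_tree(list(table.counts.index), seed=seed + 7)
        state.update(
            table=table, metadata=metadata, reference=ref, reads=reads,
            profiles=profiles, genes=genes, background=background, calib=calib,
            wells=wells, curve=curve, tree=tree,
            truth={
                "communities": truth.to_jsonable(),
                "metagenome": mg_truth.to_jsonable(),
                "genes": gene_truth.to_jsonable(),
                "qpcr": q_truth.to_jsonable(),
            },
        )
        paths = []
        p = out / "counts.tsv"; table.counts.rename_axis("asv_id").to_csv(p, sep="\t"); paths.append(p)
        p = out / "taxonomy.tsv"; table.taxonomy.rename_axis("asv_id").to_csv(p, sep="\t"); paths.append(p)
        p = out / "reference.tsv"; ref.to_tsv(p); paths.append(p)
        p = out / "metadata.csv"; metadata.to_csv(p); paths.append(p)
        p = out / "qpcr_wells.csv"; wells.to_csv(p, index=False); paths.append(p)
        p = out / "tree.nwk"; p.write_text(tree); paths.append(p)
        p = out / "genes.fasta"
        with p.open("w") as fh:
            for g in genes.genes:
                fh.write(f">{g.gene_id} role={g.role}\n{''.join(g.codons)}\n")
        paths.append(p)
        p = out / "truth.json"
        p.write_text(json.dumps(state["truth"], indent=2, sort_keys=True))
        paths.append(p)
        return paths
    # load externally supplied inputs
    table = AsvTable.from_tsv(config.counts_tsv, config.taxonomy_tsv)
    state.update(
        table=table,
        metadata=pd.read_csv(config.metadata_csv, index_col=0),
        reference=RrnReference.from_tsv(config.reference_tsv),
        tree=Path(config.tree_newick).read_text() if config.tree_newick else None,
    )
    return []


def _stage_rrn(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    copies = assign_rrn_copies(
        state["table"], state["reference"], fallback_depth=config.rrn_fallback_rank
    )
    result = community_avg_rrn(state["table"], copies, min_matched=config.min_matched)
    state["rrn"] = result
    p = out / "community_rrn.csv"
    result.to_csv(p)
    return [p]


def _stage_traits(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    if "reads" not in state:
        return []
    gc_mean, gc_var = gc_profile(state["reads"], unit="percent")
    ge = genome_equivalents(state["profiles"])
    ags = average_genome_size(state["reads"].total_bp, ge)
    bg = background_codon_usage(state["genes"])
    cub = community_cub(state["genes"], bg)
    d, rate = predict_growth(cub, state["calib"])
    df = pd.DataFrame(
        [
            {
                "sample_id": "pooled",
                "gc_mean_percent": gc_mean,
                "gc_var_percent2": gc_var,
                "genome_equivalents": ge,
                "ags_bp": ags,
                "cub": cub,
                "min_gen_time_h": d,
                "max_growth_rate_per_h": rate,
            }
        ]
    ).set_index("sample_id")
    p = out / "genomic_traits.csv"
    df.to_csv(p)
    return [p]


def _stage_qpcr(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    if "wells" not in state:
        return []
    retained, excl = qpcr_mod.qc_filter(state["wells"])
    copies = qpcr_mod.absolute_from_ct(retained, state["curve"])
    rel = qpcr_mod.relative_abundance_matrix(
        copies.drop(columns=["16S"]), copies["16S"]
    )
    gene_map = pd.Series("other", index=rel.columns)
    sums = qpcr_mod.pathway_sums(rel, gene_map)
    p1 = out / "gene_relative_abundance.csv"; rel.to_csv(p1)
    p2 = out / "pathway_sums.csv"; sums.to_csv(p2)
    p3 = out / "qpcr_exclusions.json"
    p3.write_text(json.dumps(excl.groupby("rule").size().to_dict(), sort_keys=True))
    state["pathways"] = sums
    return [p1, p2, p3]


def _stage_ecology(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    table = state["table"]
    depth = min(config.rarefaction_depth, int(table.counts.sum(axis=0).min()))
    rare = ecology.rarefy(table, depth, seed=config.seed + 10)
    alpha = ecology.alpha_diversity(rare)
    if config.distance == "unifrac" and state.get("tree"):
        dist = ecology.weighted_unifrac(rare, state["tree"])
    else:
        dist = ecology.bray_curtis(rare)
    ord_ = ecology.nmds(
        dist, k=config.nmds_k, n_restarts=config.nmds_restarts, seed=config.seed + 11
    )
    genus = ecology.aggregate_by_genus(table)
    eco = state["metadata"]["ecosystem"]
    diff = ecology.nb_wald_test(genus, eco, reference="pristine")
    state["alpha"] = alpha
    state["ordination"] = ord_
    p1 = out / "alpha_diversity.csv"; alpha.to_csv(p1)
    p2 = out / "distance_matrix.tsv"; dist.to_frame().to_csv(p2, sep="\t")
    p3 = out / "ordination.csv"
    coords = ord_.coordinates.copy()
    coords["stress"] = ord_.stress
    coords.rename_axis("sample_id").to_csv(p3)
    p4 = out / "differential_genera.csv"; diff.to_csv(p4)
    return [p1, p2, p3, p4]


def _stage_drivers(config: PipelineConfig, out: Path, state: dict) -> list[Path]:
    meta = state["metadata"]
    rrn = state["rrn"]["avg_rrn"].reindex(meta.index)
    res = lmm_group_effect(rrn, meta["ecosystem"], meta["site_id"])
    df = pd.DataFrame(
        [
            {
                "trait": "avg_rrn",
                "estimate": res.fixed_effect_estimate,
                "se": res.se,
                "p": res.p,
                "site_variance": res.site_variance,
                "residual_variance": res.residual_variance,
                "method": res.method,
            }
        ]
    )
    p = out / "lmm_contrasts.csv"
    df.to_csv(p, index=False)
    return [p]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "rrn": _stage_rrn,
    "traits": _stage_traits,
    "qpcr": _stage_qpcr,
    "ecology": _stage_ecology,
    "drivers": _stage_drivers,
}
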