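"""End-to-end pipeline: read inputs, run every stage, write the bundle.

The run is driven by a configuration mapping (usually loaded from YAML)
naming the input files and stage parameters.  Outputs are tab-separated
tables — the type-by-species count matrix, the homolog pair table and
census, the lineage table and statistics, the cis-element summaries, the
FPKM / DEG / module tables — plus ``manifest.json`` recording inputs
(with content hashes), parameters, seed and package versions, so every
number in the bundle is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__, cis_elements, classify, core_io, expression, homology

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending record."""


def _require(config: Mapping[str, Any], key: str) -> Path:
    if key not in config:
        raise PipelineError(f"config: missing input {key!r}")
    p = Path(config[key])
    if not p.exists():
        raise PipelineError(f"config: input file not found: {p}")
    return p


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Run all configured stages; returns the summary bundle as a dict.

    Recognized config keys: ``domain_hits``, ``coils``, ``gff``, ``blast``,
    ``collinearity``, ``species_tree`` or ``species_chain``, ``elements``,
    ``counts``, ``lengths``, ``design``, plus parameter overrides
    (``gap_max``, ``cc_threshold``, ``evalue_max``, ``beta``,
    ``min_module_size``, ``cut_height``) and ``seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {}
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": int(config.get("seed", 0)),
        "inputs": {},
        "parameters": {
            k: config[k]
            for k in ("gap_max", "cc_threshold", "evalue_max", "beta",
                      "min_module_size", "cut_height")
            if k in config
        },
    }

    # --- classification stage -------------------------------------------
    type_of: dict[str, str] = {}
    genes_by_id: dict[str, core_io.GeneModel] = {}
    if "gff" in config:
        gff = _require(config, "gff")
        manifest["inputs"]["gff"] = _sha256(gff)
        gene_models = core_io.parse_gene_models(gff)
        genes_by_id = {g.gene_id: g for g in gene_models}
    if "domain_hits" in config:
        hits_path = _require(config, "domain_hits")
        manifest["inputs"]["domain_hits"] = _sha256(hits_path)
        try:
            hits = core_io.parse_domain_hits(
                hits_path, float(config.get("evalue_max", core_io.DEFAULT_EVALUE_MAX))
            )
            coils = []
            if "coils" in config:
                coils_path = _require(config, "coils")
                manifest["inputs"]["coils"] = _sha256(coils_path)
                coils = core_io.parse_coil_tracks(coils_path)
            species_of = {g: m.species for g, m in genes_by_id.items()}
            nbs, side = classify.classify_genes(
                hits, coils, species_of,
                gap_max=int(config.get("gap_max", classify.DEFAULT_GAP_MAX)),
                cc_threshold=float(config.get("cc_threshold", classify.DEFAULT_CC_THRESHOLD)),
            )
        except Exception as exc:
            raise PipelineError(f"classify stage: {exc}") from exc
        type_of = {a.gene_id: a.type_name for a in nbs + side}
        arch_df = pd.DataFrame(
            [(a.gene_id, a.species, a.type_name, a.subclass) for a in nbs],
            columns=["gene_id", "species", "type", "subclass"],
        )
        arch_df.to_csv(out / "architectures.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(a.gene_id, a.species, a.type_name) for a in side],
            columns=["gene_id", "species", "letters"],
        ).to_csv(out / "non_nbs_genes.tsv", sep="\t", index=False)
        table = classify.type_count_table(nbs)
        table.to_csv(out / "type_counts.tsv", sep="\t")
        bundle["type_counts"] = table
        if genes_by_id:
            focal = [a.gene_id for a in nbs if a.subclass == classify.NBS_LRR
                     and a.gene_id in genes_by_id]
            if len(focal) >= 3:
                exons = [genes_by_id[g].exon_count for g in focal]
                lengths = [genes_by_id[g].gene_length for g in focal]
                try:
                    r, p = classify.structure_correlation(exons, lengths)
                    bundle["structure_pearson"] = {"r": r, "p": p, "n": len(focal)}
                except ValueError:
                    logger.info("structure correlation degenerate; skipped")

    # --- homology stage --------------------------------------------------
    if "blast" in config:
        blast = _require(config, "blast")
        manifest["inputs"]["blast"] = _sha256(blast)
        coll = _require(config, "collinearity")
        manifest["inputs"]["collinearity"] = _sha256(coll)
        if "species_chain" in config:
            chain = list(config["species_chain"])
        else:
            tree = _require(config, "species_tree")
            manifest["inputs"]["species_tree"] = _sha256(tree)
            chain = core_io.species_chain_from_tree(tree)
        try:
            sim_hits = core_io.parse_similarity_hits(blast)
            blocks = core_io.parse_collinearity(coll)
            pairs = homology.build_pairs(sim_hits, genes_by_id, blocks, type_of)
            census = homology.pair_census(pairs)
            lineages = homology.assemble_lineages(
                pairs, chain, genes_by_id, type_of, blocks
            )
            stats = homology.lineage_stats(lineages)
        except Exception as exc:
            raise PipelineError(f"homology stage: {exc}") from exc
        pd.DataFrame(
            [(p.gene_a, p.gene_b, p.relation, p.evidence, p.same_type) for p in pairs],
            columns=["gene_a", "gene_b", "relation", "evidence", "same_type"],
        ).to_csv(out / "homolog_pairs.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                (
                    l.lineage_id,
                    ";".join(f"{sp}:{g}" for sp, g in l.members),
                    l.complete, l.type_conserved, l.chromosome_lineage,
                )
                for l in lineages
            ],
            columns=["lineage_id", "members", "complete", "type_conserved",
                     "chromosome_lineage"],
        ).to_csv(out / "lineages.tsv", sep="\t", index=False)
        bundle["census"] = census
        bundle["lineage_stats"] = stats
        with open(out / "homology_summary.json", "w") as fh:
            json.dump({"census": census, "lineage_stats": stats}, fh, indent=1)

    # --- cis-element stage ----------------------------------------------
    if "elements" in config:
        epath = _require(config, "elements")
        manifest["inputs"]["elements"] = _sha256(epath)
        try:
            elements = core_io.parse_cis_elements(epath)
            cmap = (
                cis_elements.load_category_map(config["category_map"])
                if "category_map" in config else None
            )
            cats = cis_elements.categorize_elements(elements, cmap)
            stress = cis_elements.subcategory_breakdown(
                elements, "stress-responsive", cmap
            )
        except Exception as exc:
            raise PipelineError(f"cis stage: {exc}") from exc
        cats.to_csv(out / "cis_categories.tsv", sep="\t")
        stress.to_csv(out / "cis_stress_functions.tsv", sep="\t")
        bundle["cis_categories"] = cats
        bundle["cis_stress_functions"] = stress

    # --- expression stage -----------------------------------------------
    if "counts" in config:
        counts_p = _require(config, "counts")
        lengths_p = _require(config, "lengths")
        design_p = _require(config, "design")
        for k, p in (("counts", counts_p), ("lengths", lengths_p),
                     ("design", design_p)):
            manifest["inputs"][k] = _sha256(p)
        try:
            counts = core_io.parse_counts(counts_p)
            lengths = core_io.parse_gene_lengths(lengths_p)
            design = core_io.parse_design(design_p)
            fpkm = expression.compute_fpkm(counts, lengths)
            degs = expression.call_degs(fpkm, design)
            log_fpkm = np.log2(fpkm + 1.0)
            adj = expression.soft_adjacency(
                log_fpkm, int(config.get("beta", expression.DEFAULT_BETA))
            )
            tom = expression.tom_similarity(adj.values)
            labels = expression.detect_modules(
                tom,
                int(config.get("min_module_size", expression.DEFAULT_MIN_MODULE_SIZE)),
                float(config.get("cut_height", expression.DEFAULT_CUT_HEIGHT)),
                genes=fpkm.index,
            )
            trait = (design == "treated").astype(float)
            modules = expression.module_table(log_fpkm, labels, trait)
        except Exception as exc:
            raise PipelineError(f"expression stage: {exc}") from exc
        fpkm.to_csv(out / "fpkm.tsv", sep="\t")
        deg_df = pd.DataFrame(
            [(d.gene_id, d.fold_change, d.p_raw, d.p_adj, d.status) for d in degs],
            columns=["gene_id", "fold_change", "p_raw", "p_adj", "status"],
        )
        deg_df.to_csv(out / "degs.tsv", sep="\t", index=False)
        labels.rename("module").to_frame().to_csv(out / "modules.tsv", sep="\t")
        modules.to_csv(out / "module_trait.tsv", sep="\t")
        bundle["deg_counts"] = deg_df["status"].value_counts().to_dict()
        bundle["modules"] = modules

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    bundle["manifest"] = manifest
    return bundle
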