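import warnings

import pytest

from nbsevolve import classify, homology, synthetic


@pytest.fixture(autouse=True)
def _quiet_warnings():
    """Generator fixtures legitimately trigger skip/fallback warnings."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture(scope="session")
def paper_shape_run():
    """Paper-shaped seven-species fixture, classified once per session."""
    genes, hits, coils, sim, blocks, truth = synthetic.generate_genomes(
        synthetic.preset_paper_shape(), seed=1
    )
    gene_map = {g.gene_id: g for g in genes}
    species_of = {g: m.species for g, m in gene_map.items()}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nbs, side = classify.classify_genes(hits, coils, species_of)
    return {
        "genes": gene_map,
        "truth": truth,
        "nbs": nbs,
        "side": side,
        "table": classify.type_count_table(nbs),
    }


@pytest.fixture(scope="session")
def lineage_run():
    """Planted 10 complete + 4 incomplete lineages (3 type-changed), assembled."""
    cfg = synthetic.preset_lineages()
    genes, hits, coils, sim, blocks, truth = synthetic.generate_genomes(cfg, seed=1)
    gene_map = {g.gene_id: g for g in genes}
    nbs, side = classify.classify_genes(
        hits, coils, {g: m.species for g, m in gene_map.items()}
    )
    type_of = {a.gene_id: a.type_name for a in nbs + side}
    pairs = homology.build_pairs(sim, gene_map, blocks, type_of)
    lineages = homology.assemble_lineages(
        pairs, list(cfg.species), gene_map, type_of, blocks
    )
    return {
        "config": cfg,
        "genes": gene_map,
        "truth": truth,
        "pairs": pairs,
        "lineages": lineages,
        "stats": homology.lineage_stats(lineages),
    }
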