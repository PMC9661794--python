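"""Synthetic multi-species fixtures with known ground truth.

Every pipeline stage is exercisable without downloads: this module plants
domain architectures, collinear ortholog blocks, within-species
duplications, cross-species orthologous lineages (with optional member
deletion and NB-ARC loss, the two degeneration modes), promoter
cis-elements and a two-condition expression experiment, then emits files
in exactly the dialects :mod:`nbsevolve.core_io` reads.

No nucleotide or amino-acid sequence is simulated — only coordinates,
hits and scores.  Each output file draws from its own pseudo-random
stream derived from the master seed, so adding an output never perturbs
existing fixtures, and a fixed seed yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import core_io
from .core_io import (
    CisElement,
    CoilTrack,
    CollinearBlock,
    DomainHit,
    GeneModel,
    SimilarityHit,
)
from .homology import HETERO_DUP, HOMO_DUP, ORTHOLOG

_LRR_ACCESSIONS = ("PF00560", "PF07723", "PF07725", "PF12799",
                   "PF13306", "PF08191", "PF13855")
_CLASS_ACCESSION = {"N": "PF00931", "T": "PF01582", "R": "PF05659"}

#: Table-shaped per-species architecture counts for the six-orchid +
#: outgroup study design (columns: type -> count).
PAPER_SHAPE_TYPE_COUNTS: dict[str, dict[str, int]] = {
    "Doff": {"CNL": 10, "CNLCN": 1, "NL": 9, "NLNL": 1, "NLNNL": 1,
             "CN": 24, "CNC": 1, "N": 27},
    "Dchr": {"CNL": 14, "CNLCN": 1, "NL": 9, "NNL": 1,
             "CN": 30, "N": 58, "NN": 2, "NNN": 1, "NNC": 1, "TNC": 1},
    "Dnob": {"CNL": 18, "NL": 14,
             "CN": 57, "CNCN": 3, "N": 75, "NN": 1, "TNC": 1},
    "Peq": {"CNL": 7, "CNNL": 1, "NL": 3,
            "CN": 18, "CNCN": 1, "N": 21, "NC": 6},
    "Vpl": {"CNL": 2, "NL": 2, "CN": 6, "N": 1, "TNC": 1},
    "Ash": {"CNL": 4, "NL": 3, "CN": 3, "N": 4, "TNC": 1},
    "Ath": {"CNL": 40, "NL": 18, "TNL": 48, "TNLC": 1, "TNLT": 4,
            "TNNL": 1, "NLT": 2,
            "CN": 40, "N": 22, "TN": 31, "TNN": 2, "RN": 1},
}

#: Type substitutions used when a lineage is planted as type-changed.
_TYPE_VARIANT = {"CNL": "NL", "NL": "CN", "CN": "N", "N": "CN", "TNC": "NC"}

_LINEAGE_BASE_TYPES = ("CNL", "NL", "CN", "N")


class ConfigError(ValueError):
    """Raised for infeasible generator configurations."""


# ---------------------------------------------------------------------------
# configs and truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeConfig:
    """Planted structure of a multi-species genome fixture."""

    species: tuple[str, ...] = ("Dchr", "Doff", "Dnob")
    n_chromosomes: int = 19
    #: per-species singleton genes: species -> {type_name: count}
    type_counts: Mapping[str, Mapping[str, int]] = field(default_factory=dict)
    n_lineages: int = 0
    n_incomplete: int = 0          # lineages losing one end-species member
    n_type_changed: int = 0        # lineages with one member of another type
    n_domain_loss: int = 0         # lineages with one member's NB-ARC hits deleted
    n_chromosome_lineages: int = 4
    n_homochromosomal_genes: int = 0
    n_heterochromosomal_genes: int = 0
    filler_pairs_per_block: int = 6

    def validate(self) -> None:
        if len(self.species) < 1:
            raise ConfigError("need at least one species")
        if self.n_lineages and len(self.species) < 2:
            raise ConfigError("lineages need at least two species")
        if self.n_incomplete + self.n_type_changed + self.n_domain_loss > 0 and \
                self.n_lineages == 0:
            raise ConfigError("planted lineage variants but n_lineages is 0")
        if self.n_incomplete > self.n_lineages:
            raise ConfigError("more incomplete lineages than lineages")
        if self.n_type_changed + self.n_domain_loss > self.n_lineages:
            raise ConfigError("more varied lineages than lineages")
        if self.n_lineages and self.n_chromosome_lineages > self.n_chromosomes:
            raise ConfigError("more chromosome lineages than chromosomes")
        if self.n_lineages and self.n_chromosome_lineages > self.n_lineages:
            raise ConfigError("more chromosome lineages than lineages")
        if self.n_incomplete and len(self.species) == 2:
            raise ConfigError("a two-species chain cannot lose a member")


@dataclass(frozen=True)
class ModuleBlockSpec:
    """One planted co-expression block."""

    size: int = 40
    driver: str = "latent"  # "latent" or "treatment"
    loading: float = 2.0    # log2-scale swing per unit of the driving factor


@dataclass(frozen=True)
class ExpressionConfig:
    """Planted structure of a two-condition count experiment.

    Defaults emulate a 3 + 3 replicate hormone-treatment design with
    shot-noise-dominated counts (clonal plantlets under controlled
    conditions): log-normal baseline means around 1,000 counts and a mild
    extra-Poisson dispersion of 0.005.
    """

    n_genes: int = 500
    n_treated: int = 3
    n_control: int = 3
    n_up: int = 20
    effect: float = 4.0
    dispersion: float = 0.005
    base_log_mean: float = math.log(1000.0)
    base_log_sd: float = 0.8
    gene_length_range: tuple[int, int] = (600, 6000)
    module_blocks: tuple[ModuleBlockSpec, ...] = ()

    def validate(self) -> None:
        if self.n_up > self.n_genes:
            raise ConfigError("more up-regulated genes than genes")
        if sum(b.size for b in self.module_blocks) + self.n_up > self.n_genes:
            raise ConfigError("planted blocks and up genes exceed gene count")
        if self.dispersion < 0 or self.effect <= 0:
            raise ConfigError("dispersion must be >= 0 and effect > 0")


@dataclass
class TruthSet:
    """Planted ground truth for one generated fixture."""

    seed: int
    architectures: dict[str, str] = field(default_factory=dict)
    relations: list[tuple[str, str, str]] = field(default_factory=list)
    lineages: list[dict] = field(default_factory=list)
    elements: dict[str, list[str]] = field(default_factory=dict)
    up_genes: list[str] = field(default_factory=list)
    module_blocks: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# genome-side generation
# ---------------------------------------------------------------------------


class _GeneFactory:
    """Places genes on chromosomes and realizes their domain architectures."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.cursor: dict[str, int] = {}
        self.genes: list[GeneModel] = []
        self.domain_hits: list[DomainHit] = []
        self.coil_tracks: list[CoilTrack] = []

    def add_gene(
        self,
        gene_id: str,
        species: str,
        chromosome: str,
        letters: str,
        drop_n_hits: bool = False,
    ) -> str:
        """Create a gene realizing ``letters``; returns its emitted letters.

        With ``drop_n_hits`` the NB-ARC hits are withheld from the output,
        emulating domain degeneration; the returned string is the letters
        actually recoverable from the files.
        """
        rng = self.rng
        exon_count = int(rng.integers(1, 13))
        length = int(max(600, round(1500 + 2000 * exon_count + rng.normal(0, 2300))))
        pos = self.cursor.get(chromosome, 0) + int(rng.integers(2000, 20000))
        self.cursor[chromosome] = pos + length
        self.genes.append(
            GeneModel(gene_id, species, chromosome, pos, pos + length - 1,
                      strand="+" if rng.random() < 0.5 else "-",
                      exon_count=exon_count)
        )
        if not letters:
            return ""

        emitted: list[str] = []
        runs_c: list[tuple[int, int]] = []
        cur = int(rng.integers(5, 60))
        for letter in letters:
            if letter == "C":
                width = int(rng.integers(16, 41))
                runs_c.append((cur + 1, cur + width))
                emitted.append("C")
                cur += width
            elif letter == "L":
                n_sub = int(rng.integers(2, 5))
                for si in range(n_sub):
                    width = int(rng.integers(20, 56))
                    self.domain_hits.append(
                        DomainHit(gene_id, "L", cur + 1, cur + width,
                                  10.0 ** -rng.uniform(15, 40),
                                  source=str(rng.choice(_LRR_ACCESSIONS)))
                    )
                    if si == 0:
                        emitted.append("L")
                    cur += width
                    if si < n_sub - 1:
                        cur += int(rng.integers(10, 121))
            else:
                width = {"N": (150, 301), "T": (80, 181), "R": (100, 171)}[letter]
                w = int(rng.integers(*width))
                if letter == "N" and drop_n_hits:
                    pass  # degeneration: the hit is withheld
                else:
                    self.domain_hits.append(
                        DomainHit(gene_id, letter, cur + 1, cur + w,
                                  10.0 ** -rng.uniform(15, 40),
                                  source=_CLASS_ACCESSION[letter])
                    )
                    emitted.append(letter)
                cur += w
            cur += int(rng.integers(160, 401))  # inter-domain spacing > gap_max

        protein_len = cur + int(rng.integers(20, 81))
        scores = rng.uniform(0.01, 0.45, protein_len)
        for s, e in runs_c:
            scores[s - 1:e] = rng.uniform(0.55, 0.98, e - s + 1)
        self.coil_tracks.append(
            CoilTrack(gene_id, tuple(np.round(scores, 3)))
        )
        return "".join(emitted)


def _ortholog_hit(rng, a: str, b: str) -> list[SimilarityHit]:
    ident = float(np.round(rng.uniform(70, 96), 2))
    alen = int(rng.integers(300, 900))
    ev = 10.0 ** -rng.uniform(30, 60)
    bits = float(np.round(rng.uniform(400, 900), 1))
    return [
        SimilarityHit(a, b, ident, alen, ev, bits),
        SimilarityHit(b, a, ident, alen, ev, bits),
    ]


def generate_genomes(config: GenomeConfig, seed: int):
    """Build a multi-species genome fixture.

    Returns ``(genes, domain_hits, coil_tracks, similarity_hits, blocks,
    truth)``.  Orthologous lineages are wired through collinear blocks with
    non-NBS filler anchors (so the chromosome correspondence is
    discoverable by majority vote); duplication pairs are similarity-only.
    """
    config.validate()
    truth = TruthSet(seed=seed)
    fac = _GeneFactory(_rng(seed, 0))
    sim_rng = _rng(seed, 2)
    similarity: list[SimilarityHit] = []
    blocks: list[CollinearBlock] = []
    species = list(config.species)

    def chrom(sp: str, idx: int) -> str:
        return f"{sp}.chr{idx + 1:02d}"

    # --- singleton genes realizing the per-species type table ------------
    for sp in species:
        for type_name, count in sorted(config.type_counts.get(sp, {}).items()):
            for i in range(count):
                gid = f"{sp}_{type_name}_{i:03d}"
                ci = int(fac.rng.integers(0, config.n_chromosomes))
                emitted = fac.add_gene(gid, sp, chrom(sp, ci), type_name)
                truth.architectures[gid] = emitted

    # --- orthologous lineages -------------------------------------------
    plan_rng = _rng(seed, 1)
    lineage_members: dict[int, list[tuple[str, str]]] = {}
    if config.n_lineages:
        variant_ids = plan_rng.permutation(config.n_lineages)
        type_changed = set(variant_ids[: config.n_type_changed].tolist())
        domain_loss = set(
            variant_ids[config.n_type_changed:
                        config.n_type_changed + config.n_domain_loss].tolist()
        )
        incomplete = set(
            plan_rng.permutation(config.n_lineages)[: config.n_incomplete].tolist()
        )
        for j in range(config.n_lineages):
            ci = j % config.n_chromosome_lineages
            base_type = str(plan_rng.choice(_LINEAGE_BASE_TYPES))
            member_species = list(species)
            if j in incomplete:
                # drop an end of the chain so the remainder stays connected
                if plan_rng.random() < 0.5:
                    member_species = member_species[1:]
                else:
                    member_species = member_species[:-1]
            changed_sp = (
                str(plan_rng.choice(member_species)) if j in type_changed else None
            )
            loss_sp = (
                str(plan_rng.choice(member_species)) if j in domain_loss else None
            )
            members: list[tuple[str, str]] = []
            emitted_types: list[str] = []
            for sp in member_species:
                gid = f"{sp}_lin{j:03d}"
                t = base_type
                if sp == changed_sp:
                    t = _TYPE_VARIANT[base_type]
                emitted = fac.add_gene(
                    gid, sp, chrom(sp, ci), t, drop_n_hits=(sp == loss_sp)
                )
                truth.architectures[gid] = emitted
                members.append((sp, gid))
                emitted_types.append(emitted)
            lineage_members[j] = members
            for (sa, ga), (sb, gb) in zip(members, members[1:]):
                similarity.extend(_ortholog_hit(sim_rng, ga, gb))
                truth.relations.append((*sorted((ga, gb)), ORTHOLOG))
            truth.lineages.append(
                {
                    "members": {sp: gid for sp, gid in members},
                    "complete": len(members) == len(species),
                    "type_conserved": len(set(emitted_types)) == 1,
                    "chromosome_lineage": ci,
                }
            )

        # self hits and non-reciprocal decoys, exercising best-hit filtering
        for sp in species:
            gid = f"{sp}_lin000"
            similarity.append(SimilarityHit(gid, gid, 100.0, 500, 0.0, 999.0))
        if config.n_lineages >= 2 and len(species) >= 2:
            a = f"{species[0]}_lin000"
            b = f"{species[1]}_lin001"
            similarity.append(SimilarityHit(a, b, 60.0, 200, 1e-12, 80.0))

        # collinear blocks with filler anchors per adjacent species pair
        block_rng = _rng(seed, 3)
        for i, (sa, sb) in enumerate(zip(species, species[1:])):
            for ci in range(config.n_chromosome_lineages):
                pairs: list[tuple[str, str]] = []
                for k in range(config.filler_pairs_per_block):
                    fa = f"{sa}_fill{i}_{ci}_{k}"
                    fb = f"{sb}_fill{i}_{ci}_{k}"
                    for sp, fg in ((sa, fa), (sb, fb)):
                        if all(g.gene_id != fg for g in fac.genes):
                            fac.add_gene(fg, sp, chrom(sp, ci), "")
                    pairs.append((fa, fb))
                for j, members in lineage_members.items():
                    if j % config.n_chromosome_lineages != ci:
                        continue
                    d = dict(members)
                    if sa in d and sb in d:
                        pairs.append((d[sa], d[sb]))
                blocks.append(
                    CollinearBlock(
                        f"b{i}_{ci}", sa, sb, tuple(pairs)
                    )
                )

    # --- within-species duplications ------------------------------------
    dup_rng = _rng(seed, 4)

    def plant_duplications(total_genes: int, relation: str, tag: str) -> None:
        if total_genes == 0:
            return
        if total_genes == 1:
            raise ConfigError(f"cannot plant a single {relation} gene")
        made = 0
        idx = 0
        while made < total_genes:
            sp = species[idx % len(species)]
            remaining = total_genes - made
            group = 3 if (remaining % 2 == 1) else 2
            ci = int(dup_rng.integers(0, config.n_chromosomes))
            gids = []
            for k in range(group):
                if relation == HOMO_DUP:
                    c = chrom(sp, ci)
                else:
                    cj = (ci + 1 + k) % config.n_chromosomes
                    c = chrom(sp, cj if k else ci)
                gid = f"{sp}_{tag}{idx:03d}_{k}"
                t = str(dup_rng.choice(_LINEAGE_BASE_TYPES))
                emitted = fac.add_gene(gid, sp, c, t)
                truth.architectures[gid] = emitted
                gids.append(gid)
            for ga, gb in zip(gids, gids[1:]):
                similarity.extend(_ortholog_hit(dup_rng, ga, gb))
                truth.relations.append((*sorted((ga, gb)), relation))
            made += group
            idx += 1

    plant_duplications(config.n_homochromosomal_genes, HOMO_DUP, "hd")
    plant_duplications(config.n_heterochromosomal_genes, HETERO_DUP, "xd")

    return fac.genes, fac.domain_hits, fac.coil_tracks, similarity, blocks, truth


# ---------------------------------------------------------------------------
# cis-element generation
# ---------------------------------------------------------------------------

#: element vocabulary used by the generator, drawn from the category map
_HORMONE_ELEMENTS = ("TCA-element", "ABRE", "CGTCA-motif", "TGACG-motif",
                     "GARE-motif", "TGA-element", "ERE", "P-box")
_STRESS_BY_FUNCTION = {
    "defense and stress responsiveness": "TC-rich repeats",
    "drought responsiveness": "MBS",
    "low temperature responsiveness": "LTR",
    "wound responsiveness": "WUN-motif",
}
_GROWTH_ELEMENTS = ("CAT-box", "O2-site", "circadian", "GCN4_motif")


def generate_cis_elements(
    gene_ids: Sequence[str],
    seed: int,
    n_hormone: int = 161,
    stress_counts: Mapping[str, int] | None = None,
    n_growth: int = 13,
    n_tca_genes: int = 7,
) -> tuple[list[CisElement], TruthSet]:
    """Plant promoter element occurrences over a gene set.

    Defaults plant the category composition of the study's promoter scan:
    161 hormone-related, 41 stress-responsive (14 defense/stress, 15
    drought, 10 low-temperature, 2 wound) and 13 growth-related
    occurrences, with the salicylic-acid responsive TCA-element confined
    to ``n_tca_genes`` genes.
    """
    if not gene_ids:
        raise ConfigError("no genes to attach elements to")
    if stress_counts is None:
        stress_counts = {"defense and stress responsiveness": 14,
                         "drought responsiveness": 15,
                         "low temperature responsiveness": 10,
                         "wound responsiveness": 2}
    rng = _rng(seed, 5)
    truth = TruthSet(seed=seed)
    elements: list[CisElement] = []
    tca_genes = [str(g) for g in
                 rng.choice(list(gene_ids), size=min(n_tca_genes, len(gene_ids)),
                            replace=False)]

    def plant(name: str, count: int, pool: Sequence[str]) -> None:
        for _ in range(count):
            gid = str(rng.choice(list(pool)))
            elements.append(
                CisElement(gid, name, int(rng.integers(1, 2001)),
                           "+" if rng.random() < 0.5 else "-")
            )
            truth.elements.setdefault(gid, []).append(name)

    n_tca = max(n_tca_genes, n_hormone // len(_HORMONE_ELEMENTS))
    plant("TCA-element", n_tca, tca_genes)
    remaining = n_hormone - n_tca
    others = [e for e in _HORMONE_ELEMENTS if e != "TCA-element"]
    for i, name in enumerate(others):
        share = remaining // len(others) + (1 if i < remaining % len(others) else 0)
        plant(name, share, gene_ids)
    for fn, count in sorted(stress_counts.items()):
        plant(_STRESS_BY_FUNCTION[fn], count, gene_ids)
    growth_each = n_growth // len(_GROWTH_ELEMENTS)
    for i, name in enumerate(_GROWTH_ELEMENTS):
        share = growth_each + (1 if i < n_growth % len(_GROWTH_ELEMENTS) else 0)
        plant(name, share, gene_ids)
    return elements, truth


# ---------------------------------------------------------------------------
# expression generation
# ---------------------------------------------------------------------------


def generate_expression(config: ExpressionConfig, seed: int):
    """Build a two-condition count experiment with planted effects.

    Returns ``(counts, gene_lengths, design, truth)`` as pandas objects.
    Counts are negative-binomial around log-normal baseline means; planted
    up-regulated genes get a multiplicative treatment effect; planted
    module blocks share a latent per-sample factor (or the treatment
    indicator itself) on the log scale.
    """
    config.validate()
    rng = _rng(seed, 6)
    truth = TruthSet(seed=seed)
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    samples = [f"T{i + 1}" for i in range(config.n_treated)] + \
              [f"C{i + 1}" for i in range(config.n_control)]
    treated_mask = np.array([s.startswith("T") for s in samples])

    base = rng.lognormal(config.base_log_mean, config.base_log_sd, config.n_genes)
    log2_mu = np.tile(np.log2(base)[:, None], (1, len(samples)))

    # planted module blocks occupy the head of the gene list; up-regulated
    # genes are drawn from the remainder so the two truths stay disjoint
    pos = 0
    for bi, spec in enumerate(config.module_blocks):
        members = genes[pos:pos + spec.size]
        truth.module_blocks[f"block{bi + 1}:{spec.driver}"] = members
        if spec.driver == "treatment":
            f = np.where(treated_mask, 0.5, -0.5)
        elif spec.driver == "latent":
            f = rng.normal(0.0, 1.0, len(samples))
        else:
            raise ConfigError(f"unknown block driver {spec.driver!r}")
        log2_mu[pos:pos + spec.size] += spec.loading * f[None, :]
        pos += spec.size

    up_idx = pos + rng.choice(config.n_genes - pos, config.n_up, replace=False)
    truth.up_genes = [genes[i] for i in sorted(up_idx)]
    log2_mu[np.ix_(up_idx, np.where(treated_mask)[0])] += np.log2(config.effect)

    mu = 2.0 ** log2_mu
    if config.dispersion > 0:
        nshape = 1.0 / config.dispersion
        counts = rng.negative_binomial(nshape, nshape / (nshape + mu))
    else:
        counts = rng.poisson(mu)

    lengths = rng.integers(*config.gene_length_range, config.n_genes)
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=samples)
    lengths_s = pd.Series(lengths, index=counts_df.index, name="length")
    design = pd.Series(
        ["treated" if t else "control" for t in treated_mask],
        index=pd.Index(samples, name="sample"), name="condition",
    )
    return counts_df, lengths_s, design, truth


# ---------------------------------------------------------------------------
# presets and file output
# ---------------------------------------------------------------------------


def preset_paper_shape() -> GenomeConfig:
    """Seven species with the study-shaped per-species type table."""
    return GenomeConfig(
        species=tuple(PAPER_SHAPE_TYPE_COUNTS),
        type_counts=PAPER_SHAPE_TYPE_COUNTS,
    )


def preset_lineages(
    n_complete: int = 10, n_incomplete: int = 4, n_type_changed: int = 3,
    n_chromosome_lineages: int = 4,
) -> GenomeConfig:
    """Three-species chain with planted complete/incomplete lineages."""
    return GenomeConfig(
        n_lineages=n_complete + n_incomplete,
        n_incomplete=n_incomplete,
        n_type_changed=n_type_changed,
        n_chromosome_lineages=n_chromosome_lineages,
    )


def preset_homology_census() -> GenomeConfig:
    """Two-member lineages and duplications sized like the study census:

    76 orthologous genes (38 two-member lineages), 94 homochromosomal and
    39 heterochromosomal duplication genes.
    """
    return GenomeConfig(
        n_lineages=38,
        n_incomplete=38,
        n_chromosome_lineages=13,
        n_homochromosomal_genes=94,
        n_heterochromosomal_genes=39,
    )


def preset_lineage_landscape() -> GenomeConfig:
    """Lineage landscape shaped like the study: 66 lineages on 13
    chromosome lineages, 40 incomplete, all but 4 type-changed."""
    return GenomeConfig(
        n_lineages=66,
        n_incomplete=40,
        n_type_changed=62,
        n_chromosome_lineages=13,
    )


def preset_deg_calibration() -> ExpressionConfig:
    """The 3 + 3 design with 20 planted 4x up-regulated genes."""
    return ExpressionConfig()


def preset_module_design() -> ExpressionConfig:
    """Two planted 40-gene blocks (one treatment-driven, one latent) in a
    10 + 10 design.

    Loadings give modest ~1.5-fold co-expression swings (so the blocks do
    not dominate per-sample library size) with within-block correlations
    near 0.9 at dispersion 0.02.
    """
    return ExpressionConfig(
        n_treated=10, n_control=10, n_up=0, dispersion=0.02,
        module_blocks=(
            ModuleBlockSpec(40, "treatment", 1.2),
            ModuleBlockSpec(40, "latent", 0.6),
        ),
    )


def write_genome_fixture(out_dir: str | Path, config: GenomeConfig, seed: int) -> dict[str, Path]:
    """Generate and write a genome fixture; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes, hits, coils, sim, blocks, truth = generate_genomes(config, seed)
    paths = {
        "gff": out / "genes.gff3",
        "domain_hits": out / "domain_hits.tsv",
        "coils": out / "coil_tracks.tsv",
        "blast": out / "similarity.tsv",
        "collinearity": out / "collinearity.txt",
        "tree": out / "species_tree.nwk",
        "truth": out / "truth.json",
    }
    core_io.write_gene_models(genes, paths["gff"])
    core_io.write_domain_hits(hits, paths["domain_hits"])
    core_io.write_coil_tracks(coils, paths["coils"])
    core_io.write_similarity_hits(sim, paths["blast"])
    core_io.write_collinearity(blocks, paths["collinearity"])
    chain = list(config.species)
    newick = "(" * (len(chain) - 1) + chain[0] if len(chain) > 1 else chain[0]
    for sp in chain[1:]:
        newick += f",{sp})"
    with open(paths["tree"], "w") as fh:
        fh.write(newick + ";\n")
    truth.to_json(paths["truth"])
    return paths


def write_expression_fixture(out_dir: str | Path, config: ExpressionConfig, seed: int) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts, lengths, design, truth = generate_expression(config, seed)
    paths = {
        "counts": out / "counts.tsv",
        "lengths": out / "gene_lengths.tsv",
        "design": out / "design.tsv",
        "truth": out / "expression_truth.json",
    }
    counts.to_csv(paths["counts"], sep="\t")
    lengths.to_frame().to_csv(paths["lengths"], sep="\t")
    design.to_frame().to_csv(paths["design"], sep="\t")
    truth.to_json(paths["truth"])
    return paths
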