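"""Homolog-pair typing and cross-species lineage assembly.

Similarity-linked gene pairs fall into three relation types:

* ``ortholog`` — different species, pair anchored inside a collinear block;
* ``homochromosomal_duplication`` — same species, same chromosome;
* ``heterochromosomal_duplication`` — same species, different chromosomes.

Cross-species pairs outside any collinear block carry no relation and are
logged.  Ortholog pairs between adjacent species of an ordered species
chain are stitched into orthologous lineages; a lineage is complete when
every species of the chain contributes a member, and type-conserved when
all members share one architecture type.  Loss of a member or of the
NB-ARC domain along a lineage is the degeneration signal this module
quantifies.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core_io import CollinearBlock, GeneModel, SimilarityHit

logger = logging.getLogger(__name__)

ORTHOLOG = "ortholog"
HOMO_DUP = "homochromosomal_duplication"
HETERO_DUP = "heterochromosomal_duplication"
RELATIONS = (ORTHOLOG, HOMO_DUP, HETERO_DUP)


@dataclass(frozen=True)
class HomologPair:
    """Two genes plus their relation type and supporting evidence."""

    gene_a: str
    gene_b: str
    relation: str
    evidence: str = ""
    same_type: bool | None = None

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.gene_a == self.gene_b:
            raise ValueError(f"self pair {self.gene_a}")


@dataclass(frozen=True)
class Lineage:
    """An ordered cross-species chain of orthologous genes."""

    lineage_id: str
    members: tuple[tuple[str, str], ...]  # (species, gene_id) in chain order
    complete: bool
    type_conserved: bool
    chromosome_lineage: str

    @property
    def member_genes(self) -> tuple[str, ...]:
        return tuple(g for _, g in self.members)


def classify_pair(a: GeneModel, b: GeneModel, in_block: bool) -> str | None:
    """Assign the relation type of one similarity-linked gene pair.

    Returns ``None`` for cross-species pairs lacking collinear-block
    support (no ortholog evidence; the pair is excluded).
    """
    if a.gene_id == b.gene_id:
        raise ValueError(f"self pair {a.gene_id}")
    if a.species != b.species:
        if in_block:
            return ORTHOLOG
        logger.info(
            "pair %s-%s: cross-species but outside collinear blocks; excluded",
            a.gene_id, b.gene_id,
        )
        return None
    if a.chromosome == b.chromosome:
        return HOMO_DUP
    return HETERO_DUP


def select_best_hits(
    hits: Sequence[SimilarityHit],
    species_of: Mapping[str, str] | None = None,
) -> list[SimilarityHit]:
    """Reduce raw similarity hits to homolog-candidate hits.

    Self hits are removed and, per directed query-subject pair, only the
    highest-bitscore hit is kept.  When ``species_of`` is supplied,
    cross-species hits are additionally restricted to reciprocal best hits
    (per species pair): gene A's best partner in species S must name A as
    its best partner back.
    """
    best: dict[tuple[str, str], SimilarityHit] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        key = (h.query_id, h.subject_id)
        if key not in best or h.bitscore > best[key].bitscore:
            best[key] = h
    kept = list(best.values())
    if species_of is None:
        return kept

    # best partner of each gene within each foreign species
    best_partner: dict[tuple[str, str], tuple[str, float]] = {}
    for h in kept:
        qs, ss = species_of[h.query_id], species_of[h.subject_id]
        if qs == ss:
            continue
        key = (h.query_id, ss)
        if key not in best_partner or h.bitscore > best_partner[key][1]:
            best_partner[key] = (h.subject_id, h.bitscore)

    out: list[SimilarityHit] = []
    for h in kept:
        qs, ss = species_of[h.query_id], species_of[h.subject_id]
        if qs == ss:
            out.append(h)
            continue
        fwd = best_partner.get((h.query_id, ss))
        rev = best_partner.get((h.subject_id, qs))
        if fwd and rev and fwd[0] == h.subject_id and rev[0] == h.query_id:
            out.append(h)
    return out


def _block_pair_index(blocks: Sequence[CollinearBlock]) -> dict[frozenset[str], str]:
    index: dict[frozenset[str], str] = {}
    for b in blocks:
        for ga, gb in b.gene_pairs:
            index.setdefault(frozenset((ga, gb)), b.block_id)
    return index


def build_pairs(
    hits: Sequence[SimilarityHit],
    genes: Mapping[str, GeneModel],
    blocks: Sequence[CollinearBlock] = (),
    type_of: Mapping[str, str] | None = None,
) -> list[HomologPair]:
    """Classify all similarity-supported gene pairs into relation types.

    ``hits`` should already be best-hit filtered; hits naming genes absent
    from ``genes`` are skipped with a log message.  ``type_of`` (gene ->
    architecture type name) fills the ``same_type`` flag when provided.
    """
    known = []
    for h in hits:
        if h.query_id in genes and h.subject_id in genes:
            known.append(h)
        else:
            logger.info("hit %s-%s: unknown gene; skipped", h.query_id, h.subject_id)
    species_of = {g: m.species for g, m in genes.items()}
    filtered = select_best_hits(known, species_of=species_of)
    in_block = _block_pair_index(blocks)

    pairs: dict[frozenset[str], HomologPair] = {}
    for h in filtered:
        key = frozenset((h.query_id, h.subject_id))
        if key in pairs:
            continue
        a, b = genes[h.query_id], genes[h.subject_id]
        block_id = in_block.get(key)
        rel = classify_pair(a, b, block_id is not None)
        if rel is None:
            continue
        same = None
        if type_of is not None:
            ta, tb = type_of.get(a.gene_id), type_of.get(b.gene_id)
            same = (ta == tb) if (ta is not None and tb is not None) else None
        ga, gb = sorted((a.gene_id, b.gene_id))
        pairs[key] = HomologPair(
            ga, gb, rel,
            evidence=block_id if block_id else f"similarity:{h.bitscore:g}",
            same_type=same,
        )
    return sorted(pairs.values(), key=lambda p: (p.gene_a, p.gene_b))


def pair_census(pairs: Iterable[HomologPair]) -> dict[str, int]:
    """Number of distinct genes participating in each relation type.

    A gene appearing in pairs of two different relations is counted once in
    each; within one relation it is counted once however many pairs name it.
    """
    members: dict[str, set[str]] = {r: set() for r in RELATIONS}
    for p in pairs:
        members[p.relation].update((p.gene_a, p.gene_b))
    return {r: len(members[r]) for r in RELATIONS}


def chromosome_correspondence(
    blocks: Sequence[CollinearBlock],
    genes: Mapping[str, GeneModel],
) -> dict[tuple[str, str], dict[str, str]]:
    """Majority-vote chromosome mapping between species from block anchors.

    For every ordered species pair observed in the blocks, each chromosome
    of the first species maps to the chromosome of the second species that
    pairs with it most often (ties broken by total paired-gene count, then
    lexicographically).
    """
    votes: dict[tuple[str, str], Counter] = defaultdict(Counter)
    totals: Counter = Counter()
    for b in blocks:
        for ga, gb in b.gene_pairs:
            if ga not in genes or gb not in genes:
                continue
            ma, mb = genes[ga], genes[gb]
            if ma.species == mb.species:
                continue
            votes[(ma.species, mb.species)][(ma.chromosome, mb.chromosome)] += 1
            votes[(mb.species, ma.species)][(mb.chromosome, ma.chromosome)] += 1
            totals[mb.chromosome] += 1
            totals[ma.chromosome] += 1

    out: dict[tuple[str, str], dict[str, str]] = {}
    for sp_pair, counter in votes.items():
        per_chrom: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
        for (ca, cb), n in counter.items():
            per_chrom[ca].append((n, totals[cb], cb))
        out[sp_pair] = {
            ca: min(opts, key=lambda t: (-t[0], -t[1], t[2]))[2]
            for ca, opts in per_chrom.items()
        }
    return out


def _root_chromosome(
    species: str,
    chrom: str,
    species_chain: Sequence[str],
    corr: Mapping[tuple[str, str], Mapping[str, str]],
) -> str:
    """Map a chromosome back to the first species' coordinates."""
    idx = species_chain.index(species)
    cur_sp, cur_chrom = species, chrom
    for i in range(idx, 0, -1):
        mapping = corr.get((cur_sp, species_chain[i - 1]))
        if mapping is None or cur_chrom not in mapping:
            return f"{species}:{chrom}"
        cur_chrom = mapping[cur_chrom]
        cur_sp = species_chain[i - 1]
    return cur_chrom


def assemble_lineages(
    pairs: Iterable[HomologPair],
    species_chain: Sequence[str],
    genes: Mapping[str, GeneModel],
    type_of: Mapping[str, str] | None = None,
    blocks: Sequence[CollinearBlock] = (),
) -> list[Lineage]:
    """Stitch adjacent-species ortholog pairs into orthologous lineages.

    Only ortholog pairs between neighbours in ``species_chain`` are used;
    connected chains become lineages of two or more members.  A chain
    holding two genes of the same species is a conflict and raises.  The
    chromosome lineage of each chain is its members' chromosomes mapped
    back to the first species through the block-derived chromosome
    correspondence.  Output order is deterministic and independent of the
    input pair order.
    """
    chain_index = {sp: i for i, sp in enumerate(species_chain)}
    adjacency: dict[str, set[str]] = defaultdict(set)
    used_pairs: list[HomologPair] = []
    for p in sorted(pairs, key=lambda p: (p.gene_a, p.gene_b)):
        if p.relation != ORTHOLOG:
            continue
        sa, sb = genes[p.gene_a].species, genes[p.gene_b].species
        if sa not in chain_index or sb not in chain_index:
            logger.info("pair %s-%s: species outside chain; skipped", p.gene_a, p.gene_b)
            continue
        if abs(chain_index[sa] - chain_index[sb]) != 1:
            logger.info("pair %s-%s: non-adjacent species; skipped", p.gene_a, p.gene_b)
            continue
        adjacency[p.gene_a].add(p.gene_b)
        adjacency[p.gene_b].add(p.gene_a)
        used_pairs.append(p)

    corr = chromosome_correspondence(blocks, genes)

    seen: set[str] = set()
    components: list[list[str]] = []
    for start in sorted(adjacency):
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            g = stack.pop()
            comp.append(g)
            for nb in sorted(adjacency[g]):
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        components.append(sorted(comp))

    lineages: list[Lineage] = []
    components.sort(key=lambda c: (min(chain_index[genes[g].species] for g in c), c[0]))
    for comp in components:
        by_species: dict[str, list[str]] = defaultdict(list)
        for g in comp:
            by_species[genes[g].species].append(g)
        dup = {sp: gs for sp, gs in by_species.items() if len(gs) > 1}
        if dup:
            raise ValueError(
                "conflicting lineage: multiple genes per species: "
                + "; ".join(f"{sp}: {', '.join(gs)}" for sp, gs in sorted(dup.items()))
            )
        members = tuple(
            (sp, by_species[sp][0]) for sp in species_chain if sp in by_species
        )
        complete = len(members) == len(species_chain)
        if type_of is not None:
            types = {type_of.get(g) for _, g in members}
            type_conserved = len(types) == 1 and None not in types
        else:
            type_conserved = True
        first_sp, first_gene = members[0]
        root = _root_chromosome(
            first_sp, genes[first_gene].chromosome, species_chain, corr
        )
        lineages.append(
            Lineage(
                lineage_id=f"L{len(lineages) + 1:04d}",
                members=members,
                complete=complete,
                type_conserved=type_conserved,
                chromosome_lineage=root,
            )
        )
    return lineages


def lineage_stats(lineages: Sequence[Lineage]) -> dict[str, int]:
    """Headline lineage counts: total, incomplete, type-changed, chromosome lineages."""
    return {
        "total": len(lineages),
        "incomplete": sum(not l.complete for l in lineages),
        "type_changed": sum(not l.type_conserved for l in lineages),
        "chromosome_lineages": len({l.chromosome_lineage for l in lineages}),
    }
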