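"""Readers, writers and the shared data model.

Every external format the pipeline touches is parsed here into small typed
records: domain-hit tables (HMMER-derived, tab separated), per-residue
coiled-coil score tracks, 12-column tabular protein similarity hits,
MCScanX-style collinearity text, GFF3 gene models, Newick species trees,
PlantCARE-style cis-element exports and count matrices with gene lengths.

Coordinates are 1-based inclusive throughout (the GFF3 convention); any
half-open arithmetic is hidden behind the record types.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DOMAIN_CLASSES = frozenset("NTCLR")

#: Pfam model accession -> single-letter domain class.
#: NB-ARC is PF00931; TIR is PF01582; RPW8 is PF05659; the LRR class is the
#: union of the seven Pfam LRR repeat families commonly used for NLR mining.
ACCESSION_TO_CLASS = {
    "PF00931": "N",
    "PF01582": "T",
    "PF05659": "R",
    "PF00560": "L",
    "PF07723": "L",
    "PF07725": "L",
    "PF12799": "L",
    "PF13306": "L",
    "PF08191": "L",
    "PF13855": "L",
}

#: Default significance cutoff applied to domain hits.  The similarity-search
#: stage of the pipeline uses E-value < 1e-10, and the same cutoff is applied
#: to HMM-derived hits unless the caller overrides it.
DEFAULT_EVALUE_MAX = 1e-10


class ParseError(ValueError):
    """Raised when an input file violates its expected dialect."""


# ---------------------------------------------------------------------------
# record types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DomainHit:
    """One significant domain match on a protein.

    ``domain_class`` is one of N (NB-ARC), T (TIR), C (coiled-coil),
    L (LRR), R (RPW8).  ``start``/``end`` are 1-based inclusive residue
    positions.
    """

    protein_id: str
    domain_class: str
    start: int
    end: int
    evalue: float = 0.0
    source: str = ""

    def __post_init__(self) -> None:
        if self.domain_class not in DOMAIN_CLASSES:
            raise ValueError(
                f"domain_class {self.domain_class!r} not in {sorted(DOMAIN_CLASSES)}"
            )
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with its exon count and genomic span."""

    gene_id: str
    species: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    exon_count: int = 1

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if self.exon_count < 1:
            raise ValueError(f"{self.gene_id}: exon_count must be >= 1")

    @property
    def gene_length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SimilarityHit:
    """One row of a 12-column tabular protein similarity report."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class CollinearBlock:
    """A collinear (syntenic) block: an ordered run of anchored gene pairs."""

    block_id: str
    species_a: str
    species_b: str
    gene_pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.gene_pairs:
            raise ValueError(f"block {self.block_id}: empty gene_pairs")


@dataclass(frozen=True)
class CoilTrack:
    """Per-residue coiled-coil propensity scores for one protein."""

    protein_id: str
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        for s in self.scores:
            if not (0.0 <= s <= 1.0):
                raise ValueError(
                    f"{self.protein_id}: coil score {s} outside [0, 1]"
                )

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class CisElement:
    """One promoter cis-element occurrence within 2 kb of the start codon."""

    gene_id: str
    element_name: str
    position: int
    strand: str = "+"
    function_label: str = ""
    category: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.position <= 2000):
            raise ValueError(
                f"{self.gene_id}/{self.element_name}: position {self.position} "
                "outside the 2,000 bp promoter window"
            )


# ---------------------------------------------------------------------------
# domain hits
# ---------------------------------------------------------------------------

_DOMAIN_COLUMNS = ["protein_id", "domain", "start", "end", "evalue"]


def parse_domain_hits(
    path: str | Path, evalue_max: float = DEFAULT_EVALUE_MAX
) -> list[DomainHit]:
    """Read a tab-separated domain-hit table.

    Columns: protein_id, domain class letter or Pfam accession, start, end,
    evalue.  Accessions are mapped to class letters through
    :data:`ACCESSION_TO_CLASS`; rows with an unmappable accession are skipped
    with a warning.  Hits with evalue > ``evalue_max`` are dropped.  Input
    order is preserved.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(
                    f"{path}: line {lineno}: expected >= 5 tab-separated "
                    f"fields, got {len(fields)}"
                )
            protein_id, domain, start_s, end_s, evalue_s = fields[:5]
            key = domain.split(".")[0]  # tolerate versioned accessions
            if key in DOMAIN_CLASSES:
                cls = key
            elif key in ACCESSION_TO_CLASS:
                cls = ACCESSION_TO_CLASS[key]
            else:
                warnings.warn(
                    f"{path}: line {lineno}: unknown domain model "
                    f"{domain!r}; row skipped"
                )
                continue
            try:
                start, end, evalue = int(start_s), int(end_s), float(evalue_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if evalue > evalue_max:
                continue
            try:
                hits.append(
                    DomainHit(protein_id, cls, start, end, evalue, source=domain)
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_domain_hits(hits: Iterable[DomainHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            src = h.source or h.domain_class
            fh.write(f"{h.protein_id}\t{src}\t{h.start}\t{h.end}\t{h.evalue!r}\n")


# ---------------------------------------------------------------------------
# similarity hits (12-column tabular)
# ---------------------------------------------------------------------------

_BLAST_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "evalue", "bitscore",
]


def parse_similarity_hits(path: str | Path) -> list[SimilarityHit]:
    """Read 12-column tabular similarity output (the classic ``-m 8`` dialect)."""
    try:
        df = pd.read_csv(path, sep="\t", names=_BLAST_COLUMNS, comment="#",
                         dtype={"query_id": str, "subject_id": str},
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return []
    return [
        SimilarityHit(
            r.query_id, r.subject_id, float(r.percent_identity),
            int(r.alignment_length), float(r.evalue), float(r.bitscore),
        )
        for r in df.itertuples(index=False)
    ]


def write_similarity_hits(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.2f}\t"
                f"{h.alignment_length}\t0\t0\t1\t{h.alignment_length}\t1\t"
                f"{h.alignment_length}\t{h.evalue!r}\t{h.bitscore:g}\n"
            )


# ---------------------------------------------------------------------------
# collinearity
# ---------------------------------------------------------------------------


def parse_collinearity(path: str | Path) -> list[CollinearBlock]:
    """Parse MCScanX-style collinearity text.

    Blocks open with ``## Alignment <id>: ... <chrA>&<chrB> ...`` headers and
    contain indexed gene-pair lines.  A pair line before any header is an
    error; a header with zero pairs is dropped with a warning.  The species
    fields of the block are taken from the chromosome tag when it carries a
    ``speciesChr&speciesChr`` pair, otherwise left empty for the caller to
    resolve against gene models.
    """
    blocks: list[CollinearBlock] = []
    cur_id: str | None = None
    cur_tag: tuple[str, str] = ("", "")
    cur_pairs: list[tuple[str, str]] = []

    def flush() -> None:
        nonlocal cur_id, cur_pairs
        if cur_id is None:
            return
        if not cur_pairs:
            warnings.warn(f"{path}: alignment {cur_id} has no gene pairs; dropped")
        else:
            blocks.append(
                CollinearBlock(cur_id, cur_tag[0], cur_tag[1], tuple(cur_pairs))
            )
        cur_id, cur_pairs = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("## Alignment"):
                flush()
                rest = line[len("## Alignment"):].strip()
                cur_id = rest.split(":")[0].strip()
                cur_tag = ("", "")
                for tok in rest.split():
                    if "&" in tok:
                        a, b = tok.split("&", 1)
                        cur_tag = (a, b)
                cur_pairs = []
            elif line.lstrip().startswith("#"):
                continue
            else:
                if cur_id is None:
                    raise ParseError(
                        f"{path}: line {lineno}: gene-pair line before any "
                        "'## Alignment' header"
                    )
                body = line.split(":", 1)[1] if ":" in line else line
                fields = body.split()
                if len(fields) < 2:
                    raise ParseError(
                        f"{path}: line {lineno}: expected two gene ids"
                    )
                cur_pairs.append((fields[0], fields[1]))
    flush()
    return blocks


def write_collinearity(blocks: Iterable[CollinearBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("############### Collinearity ###############\n")
        for b in blocks:
            tag = f" {b.species_a}&{b.species_b}" if b.species_a else ""
            fh.write(
                f"## Alignment {b.block_id}: score=0 e_value=0 "
                f"N={len(b.gene_pairs)}{tag} plus\n"
            )
            for i, (ga, gb) in enumerate(b.gene_pairs):
                fh.write(f"{b.block_id}-{i:3d}:\t{ga}\t{gb}\t0\n")


# ---------------------------------------------------------------------------
# gene models (GFF3)
# ---------------------------------------------------------------------------


def parse_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene and exon features from a GFF3 file.

    The species of a gene is taken from a ``species=`` attribute when
    present, otherwise from the source column.  ``exon_count`` is the number
    of exon features resolving (via Parent) to the gene; genes with no exon
    children are assigned exon_count 1 with a warning, matching the
    prevalence of intronless genes in this family.
    """
    import gffutils

    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    exon_counts: dict[str, int] = {}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents:
            warnings.warn(f"{path}: exon {exon.id} has no Parent; skipped")
            continue
        for parent in parents:
            exon_counts[parent] = exon_counts.get(parent, 0) + 1

    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        species = feat.attributes.get("species", [feat.source])[0]
        n_exons = exon_counts.get(gid, 0)
        if n_exons == 0:
            warnings.warn(
                f"{path}: gene {gid} has no exon features; exon_count set to 1"
            )
            n_exons = 1
        genes.append(
            GeneModel(
                gene_id=gid, species=species, chromosome=feat.seqid,
                start=feat.start, end=feat.end, strand=feat.strand or "+",
                exon_count=n_exons,
            )
        )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GFF3, one gene feature plus its exon features.

    Exons are emitted as an even partition of the span purely so the file
    round-trips; exon boundaries carry no meaning downstream (only the count
    does).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};species={g.species}"
            fh.write(
                f"{g.chromosome}\t{g.species}\tgene\t{g.start}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            bounds = np.linspace(g.start, g.end + 1, g.exon_count + 1).astype(int)
            for i in range(g.exon_count):
                es, ee = bounds[i], max(bounds[i], bounds[i + 1] - 1)
                fh.write(
                    f"{g.chromosome}\t{g.species}\texon\t{es}\t{ee}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.e{i + 1};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# coiled-coil tracks
# ---------------------------------------------------------------------------


def parse_coil_tracks(path: str | Path) -> list[CoilTrack]:
    """Read per-residue coil scores: ``protein_id<TAB>s1,s2,...`` per line."""
    tracks: list[CoilTrack] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                pid, scores_s = line.split("\t")
                scores = tuple(float(x) for x in scores_s.split(","))
                tracks.append(CoilTrack(pid, scores))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return tracks


def write_coil_tracks(tracks: Iterable[CoilTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tracks:
            fh.write(t.protein_id + "\t" + ",".join(f"{s:g}" for s in t.scores) + "\n")


# ---------------------------------------------------------------------------
# cis-elements
# ---------------------------------------------------------------------------


def parse_cis_elements(path: str | Path) -> list[CisElement]:
    """Read a PlantCARE-style export: gene, element, position, strand, function."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    required = {"gene_id", "element_name", "position"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for r in df.itertuples(index=False):
        out.append(
            CisElement(
                gene_id=r.gene_id,
                element_name=r.element_name,
                position=int(r.position),
                strand=getattr(r, "strand", "+") or "+",
                function_label=getattr(r, "function", "") or "",
            )
        )
    return out


def write_cis_elements(elements: Iterable[CisElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\telement_name\tposition\tstrand\tfunction\n")
        for e in elements:
            fh.write(
                f"{e.gene_id}\t{e.element_name}\t{e.position}\t{e.strand}\t"
                f"{e.function_label}\n"
            )


# ---------------------------------------------------------------------------
# species tree / expression tables
# ---------------------------------------------------------------------------


def species_chain_from_tree(path: str | Path) -> list[str]:
    """Leaf order of a Newick species tree, used as the lineage species chain."""
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(str(path), "newick")
    return [leaf.name for leaf in tree.get_terminals()]


def parse_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples count matrix (first column = gene id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative counts")
    return df


def parse_gene_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0].astype(float)
    if (s <= 0).any():
        raise ParseError(f"{path}: non-positive gene lengths")
    return s


def parse_design(path: str | Path) -> pd.Series:
    """Read a sample -> condition table (conditions: treated / control)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    s = df.iloc[:, 0].astype(str)
    bad = set(s) - {"treated", "control"}
    if bad:
        raise ParseError(f"{path}: unknown conditions {sorted(bad)}")
    return s
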