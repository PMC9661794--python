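"""Domain-architecture classification of NBS genes.

A gene's architecture is the ordered string of its domain-class letters
along the protein: N (NB-ARC), T (TIR), C (coiled-coil), L (LRR), R (RPW8).
The architecture string is the gene's type name (CNL, NL, CN, TNC, ...).
Genes carrying both an N and an L belong to the NBS-LRR subclass; genes
with an N but no L are the non-NBS-LRR subclass; genes without any N are
not NBS genes and are reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CoilTrack, DomainHit

logger = logging.getLogger(__name__)

#: Maximum residue gap between same-class hits merged into one letter.
#: Clustered LRR repeat hits sit well inside this; genuinely repeated
#: domains (NN, NNN architectures) are spaced further apart.
DEFAULT_GAP_MAX = 150

#: Coiled-coil segment calling defaults: per-residue score threshold and
#: minimal run length (about one heptad's worth of confident signal).
DEFAULT_CC_THRESHOLD = 0.5
DEFAULT_CC_MIN_LEN = 8

NBS_LRR = "NBS-LRR"
NON_NBS_LRR = "non-NBS-LRR"


@dataclass(frozen=True)
class Architecture:
    """The classified domain architecture of one gene."""

    gene_id: str
    letters: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.letters:
            raise ValueError(f"{self.gene_id}: empty architecture")

    @property
    def type_name(self) -> str:
        return self.letters

    @property
    def is_nbs(self) -> bool:
        return "N" in self.letters

    @property
    def subclass(self) -> str:
        return NBS_LRR if ("N" in self.letters and "L" in self.letters) else NON_NBS_LRR


def detect_cc(
    track: CoilTrack,
    threshold: float = DEFAULT_CC_THRESHOLD,
    min_len: int = DEFAULT_CC_MIN_LEN,
) -> list[DomainHit]:
    """Call coiled-coil segments from a per-residue score track.

    Maximal runs of at least ``min_len`` consecutive residues scoring
    >= ``threshold`` become C-class hits with the run's 1-based bounds.
    """
    scores = np.asarray(track.scores, dtype=float)
    above = scores >= threshold
    hits: list[DomainHit] = []
    start = None
    for i, flag in enumerate(np.append(above, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                hits.append(
                    DomainHit(track.protein_id, "C", start + 1, i, 0.0, "coil-track")
                )
            start = None
    return hits


def merge_hits(hits: Sequence[DomainHit], gap_max: int = DEFAULT_GAP_MAX) -> list[DomainHit]:
    """Collapse same-class hits into domain-level units and order them.

    Hits of the same class whose intervals overlap or lie within
    ``gap_max`` residues of each other are merged into a single unit
    spanning their union; different classes never merge.  The returned
    units are sorted by interval midpoint (ties: start, then class letter),
    so joining their class letters yields the architecture string.
    """
    if not hits:
        return []
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) > 1:
        raise ValueError(f"hits span multiple proteins: {sorted(protein_ids)}")

    merged: list[DomainHit] = []
    by_class: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_class.setdefault(h.domain_class, []).append(h)
    for cls, group in by_class.items():
        group = sorted(group, key=lambda h: (h.start, h.end))
        cur_start, cur_end, cur_ev = group[0].start, group[0].end, group[0].evalue
        for h in group[1:]:
            if h.start - cur_end - 1 <= gap_max:
                cur_end = max(cur_end, h.end)
                cur_ev = min(cur_ev, h.evalue)
            else:
                merged.append(DomainHit(h.protein_id, cls, cur_start, cur_end, cur_ev, "merged"))
                cur_start, cur_end, cur_ev = h.start, h.end, h.evalue
        merged.append(DomainHit(group[0].protein_id, cls, cur_start, cur_end, cur_ev, "merged"))

    merged.sort(key=lambda h: (h.midpoint, h.start, h.domain_class))
    return merged


def letters_of(merged: Sequence[DomainHit]) -> str:
    return "".join(h.domain_class for h in merged)


def classify_architecture(gene_id: str, letters: str | Sequence[str], species: str = "") -> Architecture:
    """Build an :class:`Architecture` from an ordered letter sequence.

    The type name is the letters verbatim; the subclass and NBS flags
    follow from the presence of N and L.  Empty input is an error: a gene
    with no recognized domains is not an NBS candidate and should have been
    filtered upstream.
    """
    s = letters if isinstance(letters, str) else "".join(letters)
    if not s:
        raise ValueError(f"{gene_id}: no domain letters; not an NBS candidate")
    return Architecture(gene_id=gene_id, letters=s, species=species)


def classify_genes(
    domain_hits: Sequence[DomainHit],
    coil_tracks: Sequence[CoilTrack] = (),
    species_of: Mapping[str, str] | None = None,
    gap_max: int = DEFAULT_GAP_MAX,
    cc_threshold: float = DEFAULT_CC_THRESHOLD,
    cc_min_len: int = DEFAULT_CC_MIN_LEN,
) -> tuple[list[Architecture], list[Architecture]]:
    """Classify every protein with at least one domain hit.

    Coiled-coil hits are called from the score tracks and pooled with the
    table hits before merging.  Returns ``(nbs, non_nbs)``: genes whose
    architecture contains an N, and the side table of genes that have
    recognizable domains but no NB-ARC.
    """
    pooled: dict[str, list[DomainHit]] = {}
    for h in domain_hits:
        pooled.setdefault(h.protein_id, []).append(h)
    for t in coil_tracks:
        cc = detect_cc(t, cc_threshold, cc_min_len)
        if cc:
            pooled.setdefault(t.protein_id, []).extend(cc)

    nbs: list[Architecture] = []
    side: list[Architecture] = []
    for pid in sorted(pooled):
        letters = letters_of(merge_hits(pooled[pid], gap_max))
        sp = species_of.get(pid, "") if species_of else ""
        arch = classify_architecture(pid, letters, sp)
        (nbs if arch.is_nbs else side).append(arch)
    return nbs, side


def type_count_table(architectures: Iterable[Architecture]) -> pd.DataFrame:
    """Type x species count matrix with subclass subtotals and totals.

    Rows: one per observed type name (NBS-LRR subclass types first, then
    non-NBS-LRR), plus ``Total (NBS-LRR)``, ``Total (non-NBS-LRR)`` and
    ``Total`` rows.  A final ``All species`` column holds row sums.
    """
    archs = [a for a in architectures if a.is_nbs]
    species = sorted({a.species for a in archs})
    if not archs:
        return pd.DataFrame(
            0,
            index=["Total (NBS-LRR)", "Total (non-NBS-LRR)", "Total"],
            columns=["All species"],
        )

    counts: dict[tuple[str, str], int] = {}
    for a in archs:
        counts[(a.type_name, a.species)] = counts.get((a.type_name, a.species), 0) + 1

    def subclass_types(sub: str) -> list[str]:
        names = {a.type_name for a in archs if a.subclass == sub}
        return sorted(names)

    rows = []
    index = []
    for sub in (NBS_LRR, NON_NBS_LRR):
        for t in subclass_types(sub):
            rows.append([counts.get((t, sp), 0) for sp in species])
            index.append(t)
        rows.append(
            [sum(counts.get((t, sp), 0) for t in subclass_types(sub)) for sp in species]
        )
        index.append(f"Total ({sub})")
    df = pd.DataFrame(rows, index=index, columns=species)
    df.loc["Total"] = (
        df.loc[f"Total ({NBS_LRR})"] + df.loc[f"Total ({NON_NBS_LRR})"]
    )
    df["All species"] = df.sum(axis=1)
    return df


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with its exact two-sided t-test p-value.

    Requires equal lengths of at least 3 and non-zero variance on both
    sides; degenerate input raises rather than returning NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def structure_correlation(exon_counts: Sequence[int], gene_lengths: Sequence[int]) -> tuple[float, float]:
    """Correlation between exon number and gene length across genes."""
    return pearson_r(exon_counts, gene_lengths)


def motif_order_conserved(motif_ids: Sequence[int], canonical: Sequence[int]) -> bool:
    """Is a gene's motif order consistent with the canonical arrangement?

    Motifs absent from ``canonical`` are ignored; the remaining sequence
    must be a subsequence of ``canonical`` (missing motifs are allowed,
    reordering is not).
    """
    canon = list(canonical)
    if len(set(canon)) != len(canon):
        raise ValueError("canonical order contains duplicate motifs")
    filtered = [m for m in motif_ids if m in set(canon)]
    it = iter(canon)
    return all(m in it for m in filtered)
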