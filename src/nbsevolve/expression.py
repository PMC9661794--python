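"""Expression-side statistics: FPKM, DEG calling and co-expression modules.

Differential expression is a desk-scale procedure: FPKM from raw counts,
Welch's unequal-variance t-test on log2(FPKM + 1), Benjamini-Hochberg
adjustment, and the field's conventional call rule — adjusted p < 0.05
with fold change strictly above 1.5 (or below 1/1.5 for down-regulation).

Co-expression modules follow the unsigned weighted-network recipe: soft
adjacency a_ij = |cor(x_i, x_j)|^beta, topological overlap (TOM),
average-linkage clustering of 1 - TOM with a static cut, size filtering at
``min_module_size`` (smaller clusters are left unassigned, "grey"), module
eigengenes as first principal components, and module-trait Pearson
correlation against a treatment indicator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .classify import pearson_r

logger = logging.getLogger(__name__)

DEFAULT_BETA = 6
DEFAULT_MIN_MODULE_SIZE = 30
#: Static cut height on the 1 - TOM dendrogram.  Within-module
#: dissimilarities sit well below 0.5 while unrelated genes sit above
#: ~0.97 even in small designs, where chance correlations fatten the null
#: TOM tail; 0.9 separates the two regimes with margin on both sides.
DEFAULT_CUT_HEIGHT = 0.9
FOLD_CHANGE_MIN = 1.5
P_ADJ_MAX = 0.05
#: pseudo-count added to mean FPKM before taking the ratio
FC_PSEUDOCOUNT = 0.01

#: module labels by decreasing size, the conventional color palette
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
)
GREY = "grey"


@dataclass(frozen=True)
class DEGRecord:
    """Per-gene differential-expression result."""

    gene_id: str
    fold_change: float
    p_raw: float
    p_adj: float
    status: str  # up / down / ns


def compute_fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series | Mapping[str, float],
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """FPKM = counts * 1e9 / (gene length in bp * library size).

    ``library_sizes`` defaults to the column sums of ``counts``.
    """
    lengths = pd.Series(gene_lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()
        raise ValueError(f"missing gene lengths for {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (library_sizes == 0).any():
        zero = library_sizes[library_sizes == 0].index.tolist()
        raise ValueError(f"zero library size for samples {zero}")
    return counts * 1e9 / np.outer(lengths.values, library_sizes.values)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    fpkm: pd.DataFrame,
    conditions: pd.Series | Mapping[str, str],
    fold_change_min: float = FOLD_CHANGE_MIN,
    p_adj_max: float = P_ADJ_MAX,
) -> list[DEGRecord]:
    """Two-condition DEG calling on an FPKM matrix.

    ``conditions`` maps sample -> {treated, control}; both groups need at
    least two replicates.  The test is Welch's t on log2(FPKM + 1); fold
    change is the ratio of mean treated to mean control FPKM with a small
    pseudo-count.  ``up`` requires fold change strictly > ``fold_change_min``
    and adjusted p < ``p_adj_max``; ``down`` mirrors it below the
    reciprocal threshold.
    """
    cond = pd.Series(conditions).reindex(fpkm.columns)
    if cond.isna().any():
        raise ValueError("conditions missing for some samples")
    treated = fpkm.columns[cond == "treated"]
    control = fpkm.columns[cond == "control"]
    if len(treated) < 2 or len(control) < 2:
        raise ValueError(
            f"need >= 2 replicates per condition, got {len(treated)} treated / "
            f"{len(control)} control"
        )

    log_t = np.log2(fpkm[treated].values + 1.0)
    log_c = np.log2(fpkm[control].values + 1.0)
    with np.errstate(invalid="ignore"):
        _, p_raw = stats.ttest_ind(log_t, log_c, axis=1, equal_var=False)
    p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)  # constant genes: no signal
    p_adj = bh_adjust(p_raw)

    fc = (fpkm[treated].mean(axis=1) + FC_PSEUDOCOUNT) / (
        fpkm[control].mean(axis=1) + FC_PSEUDOCOUNT
    )
    records = []
    for gene, f, pr, pa in zip(fpkm.index, fc, p_raw, p_adj):
        if pa < p_adj_max and f > fold_change_min:
            status = "up"
        elif pa < p_adj_max and f < 1.0 / fold_change_min:
            status = "down"
        else:
            status = "ns"
        records.append(DEGRecord(gene, float(f), float(pr), float(pa), status))
    return records


def soft_adjacency(fpkm: pd.DataFrame, beta: int = DEFAULT_BETA) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency |cor|^beta with zero diagonal."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    if fpkm.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = fpkm.values.astype(float)
    sd = x.std(axis=1)
    constant = fpkm.index[sd == 0].tolist()
    if constant:
        raise ValueError(f"constant expression rows: {constant[:10]}")
    r = np.corrcoef(x)
    a = np.abs(r) ** beta
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=fpkm.index, columns=fpkm.index)


def tom_similarity(adjacency: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Unsigned topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    TOM_ii = 1; the summation excludes u in {i, j} automatically because the
    diagonal of a valid adjacency is zero.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if np.abs(np.diag(a)).max(initial=0.0) > 1e-12:
        raise ValueError("adjacency diagonal must be zero")
    if a.min(initial=0.0) < 0 or a.max(initial=0.0) > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray,
    min_module_size: int = DEFAULT_MIN_MODULE_SIZE,
    cut_height: float = DEFAULT_CUT_HEIGHT,
    genes: Sequence[str] | None = None,
) -> pd.Series:
    """Cluster genes into co-expression modules from a TOM.

    Average-linkage hierarchical clustering on 1 - TOM is cut statically at
    ``cut_height``; clusters of at least ``min_module_size`` genes become
    modules labeled by decreasing size with the conventional color names,
    everything else is labeled grey.
    """
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if genes is None:
        genes = [f"g{i}" for i in range(n)]
    if n < 2:
        return pd.Series([GREY] * n, index=genes, dtype=object)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry for squareform
    z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_module_size]
    # decreasing size; ties by smallest member index for determinism
    order = sorted(
        big.index, key=lambda c: (-big[c], int(np.argmax(raw == c)))
    )
    label_of = {
        c: (MODULE_COLORS[i] if i < len(MODULE_COLORS) else f"module{i + 1}")
        for i, c in enumerate(order)
    }
    labels = [label_of.get(c, GREY) for c in raw]
    return pd.Series(labels, index=genes, dtype=object)


def module_eigengene(fpkm: pd.DataFrame, members: Sequence[str]) -> pd.Series:
    """First principal component of the standardized member expression.

    Returned as a unit-norm per-sample vector, sign-oriented so that its
    correlation with the members' mean standardized profile is positive.
    """
    members = list(members)
    if not members:
        raise ValueError("empty module")
    x = fpkm.loc[members].values.astype(float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - mean) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    v = vt[0]
    ref = z.mean(axis=0)
    if float(v @ (ref - ref.mean())) < 0:
        v = -v
    return pd.Series(v, index=fpkm.columns)


def module_trait_correlation(
    eigengene: pd.Series, trait: pd.Series | Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation of a module eigengene with a sample trait coding."""
    t = pd.Series(trait)
    if isinstance(trait, pd.Series):
        t = t.reindex(eigengene.index)
    return pearson_r(eigengene.values, np.asarray(t.values, dtype=float))


def module_table(
    fpkm: pd.DataFrame,
    labels: pd.Series,
    trait: pd.Series,
) -> pd.DataFrame:
    """Per-module summary: size, trait correlation r and p."""
    rows = []
    for label in sorted(labels.unique()):
        if label == GREY:
            continue
        members = labels.index[labels == label]
        eig = module_eigengene(fpkm, members)
        r, p = module_trait_correlation(eig, trait)
        rows.append({"module": label, "size": len(members), "trait_r": r, "trait_p": p})
    return pd.DataFrame(rows).set_index("module") if rows else pd.DataFrame(
        columns=["size", "trait_r", "trait_p"]
    )
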