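"""Promoter cis-element categorization.

Elements found in the 2,000 bp upstream of the translational start are
binned into three functional categories — hormone-related,
stress-responsive and plant growth — through a closed element-name
mapping.  The mapping ships as an editable TSV
(``data/cis_category_map.tsv``) seeded from the standard PlantCARE
vocabulary; unmapped element names fail loudly rather than defaulting.

Percentages are of the grand total of element occurrences (not of
element-gene incidences), rounded half-up to one decimal.
"""

from __future__ import annotations

import importlib.resources
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import CisElement

CATEGORIES = ("hormone-related", "stress-responsive", "plant growth")


def round_percent(part: float, total: float) -> float:
    """100 * part / total, rounded half-up to one decimal."""
    if total == 0:
        raise ValueError("total is zero")
    pct = Decimal(100 * part) / Decimal(total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def load_category_map(path: str | Path | None = None) -> pd.DataFrame:
    """Element-name -> (category, function_label) table.

    With no argument, the packaged default map is loaded.
    """
    if path is None:
        ref = importlib.resources.files("nbsevolve").joinpath(
            "data/cis_category_map.tsv"
        )
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"element_name", "category", "function_label"}
    if missing := required - set(df.columns):
        raise ValueError(f"category map missing columns {sorted(missing)}")
    bad = set(df["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories in map: {sorted(bad)}")
    return df.set_index("element_name")


def assign_categories(
    elements: Sequence[CisElement],
    category_map: pd.DataFrame | None = None,
) -> list[CisElement]:
    """Return elements with category and function labels filled from the map.

    Raises listing every unmapped element name.
    """
    cmap = load_category_map() if category_map is None else category_map
    unmapped = sorted(
        {e.element_name for e in elements if e.element_name not in cmap.index}
    )
    if unmapped:
        raise ValueError(f"unmapped cis-element names: {', '.join(unmapped)}")
    out = []
    for e in elements:
        row = cmap.loc[e.element_name]
        out.append(
            CisElement(
                gene_id=e.gene_id,
                element_name=e.element_name,
                position=e.position,
                strand=e.strand,
                function_label=e.function_label or str(row["function_label"]),
                category=str(row["category"]),
            )
        )
    return out


def categorize_elements(
    elements: Sequence[CisElement],
    category_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-category occurrence counts and percentages of the grand total.

    Output: one row per category (all three, even when empty) with columns
    ``count`` and ``percent``; counts sum to the number of occurrences.
    An empty input is an error (the denominator would be zero).
    """
    if not elements:
        raise ValueError("no cis-elements to categorize")
    assigned = assign_categories(elements, category_map)
    total = len(assigned)
    counts = {c: 0 for c in CATEGORIES}
    for e in assigned:
        counts[e.category] += 1
    return pd.DataFrame(
        {
            "count": [counts[c] for c in CATEGORIES],
            "percent": [round_percent(counts[c], total) for c in CATEGORIES],
        },
        index=pd.Index(CATEGORIES, name="category"),
    )


def genes_with_element(
    elements: Iterable[CisElement], element_name: str
) -> list[str]:
    """Sorted unique gene ids carrying at least one element of that name."""
    return sorted({e.gene_id for e in elements if e.element_name == element_name})


def subcategory_breakdown(
    elements: Sequence[CisElement],
    category: str,
    category_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-function counts within one category, as percentages of the grand total.

    The denominator is the total element count over all categories, so the
    rows of one category sum to that category's overall share.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    assigned = assign_categories(elements, category_map)
    total = len(assigned)
    counts: dict[str, int] = {}
    for e in assigned:
        if e.category == category:
            counts[e.function_label] = counts.get(e.function_label, 0) + 1
    labels = sorted(counts)
    return pd.DataFrame(
        {
            "count": [counts[l] for l in labels],
            "percent": [round_percent(counts[l], total) for l in labels],
        },
        index=pd.Index(labels, name="function"),
    )
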