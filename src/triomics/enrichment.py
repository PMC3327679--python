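"""Hypergeometric over-representation of annotation categories.

Up- and down-regulated feature lists are tested separately against
user-supplied category -> gene-set catalogs, with BH correction across
the categories tested within one direction.  Counts are always
restricted to the analysis universe (features that survived filtering
and map to a gene) before the tail probability is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr
from .io_tables import AnnotationCatalog

__all__ = ["EnrichmentRow", "hypergeom_p", "enrich", "enrichment_table"]


@dataclass(frozen=True)
class EnrichmentRow:
    category_id: str
    name: str
    overlap: int
    selected_n: int
    category_n: int
    universe_n: int
    p: float
    fdr: float
    direction: str


def hypergeom_p(overlap: int, selected_n: int, category_n: int, universe_n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    X counts category members in a draw of ``selected_n`` from a
    universe of ``universe_n`` containing ``category_n`` category
    members.
    """
    if not (0 <= overlap <= min(selected_n, category_n)):
        raise ValueError(
            f"overlap {overlap} outside [0, min(selected={selected_n}, "
            f"category={category_n})]"
        )
    if universe_n < max(selected_n, category_n):
        raise ValueError(
            f"universe {universe_n} smaller than selected {selected_n} or "
            f"category {category_n}"
        )
    if overlap == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap - 1, universe_n, category_n, selected_n))


def enrich(
    catalog: AnnotationCatalog,
    selected: set[str],
    universe: set[str],
    direction: str,
) -> list[EnrichmentRow]:
    """Test every catalog category with >= 1 universe member.

    Categories disjoint from the universe are not tested; categories
    with zero overlap are reported with p = 1 so the BH denominator does
    not depend on which selection happened to hit them.
    """
    offenders = selected - universe
    if offenders:
        raise ValueError(
            f"selected features outside the universe: {sorted(offenders)[:10]}"
        )
    rows: list[tuple[str, str, int, int, int]] = []
    universe_n = len(universe)
    selected_n = len(selected)
    for cid, (name, genes) in catalog.items():
        in_universe = genes & universe
        if not in_universe:
            continue
        overlap = len(in_universe & selected)
        rows.append((cid, name, overlap, len(in_universe), universe_n))
    if not rows:
        return []
    p = np.array(
        [hypergeom_p(ov, selected_n, cat_n, uni_n) for _, _, ov, cat_n, uni_n in rows]
    )
    fdr = bh_fdr(p)
    return [
        EnrichmentRow(cid, name, ov, selected_n, cat_n, uni_n, float(pi), float(qi), direction)
        for (cid, name, ov, cat_n, uni_n), pi, qi in zip(rows, p, fdr)
    ]


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Rows as a frame sorted by p (stable), ready to write to disk."""
    df = pd.DataFrame([r.__dict__ for r in rows])
    if df.empty:
        return pd.DataFrame(
            columns=[
                "category_id", "name", "overlap", "selected_n",
                "category_n", "universe_n", "p", "fdr", "direction",
            ]
        )
    return df.sort_values(["p", "category_id"], kind="stable").reset_index(drop=True)
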