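"""Matrisome category annotation and hypergeometric over-representation.

The matrisome divides ECM-related genes into a core matrisome
(collagens, ECM glycoproteins, proteoglycans) and matrisome-associated
classes (ECM regulators, secreted factors, ECM-affiliated). A small
representative category table ships with the package; full tables can be
supplied as TSV.

Over-representation analysis (ORA) asks whether a query gene set
overlaps a category more than expected under hypergeometric sampling
from the measured universe: ``p = P(X >= k)`` for
``X ~ Hypergeom(N, K, n)``.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .da import bh_adjust
from .io import GeneSet, read_matrisome_table


def packaged_matrisome_table() -> pd.DataFrame:
    """The small representative matrisome table bundled with the package."""
    with resources.as_file(
        resources.files("pcproteo").joinpath("data/matrisome_core.tsv")
    ) as p:
        return read_matrisome_table(p)


def annotate_matrisome(
    genes: list[str], table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Look up matrisome division/category per gene (case-insensitive).

    Unmatched genes are annotated non-matrisome / other.
    """
    if table is None:
        table = packaged_matrisome_table()
    lut = {
        str(g).upper(): (d, c)
        for g, d, c in zip(table["gene"], table["division"], table["category"])
    }
    rows = []
    for g in genes:
        d, c = lut.get(str(g).upper(), ("non-matrisome", "other"))
        rows.append({"gene": g, "division": d, "category": c})
    return pd.DataFrame(rows)


def ora_hypergeometric(
    query: set[str],
    universe: set[str],
    gene_sets: list[GeneSet],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in the query.

    Each gene set is intersected with the universe first. Per set:
    overlap ``k``, set size in universe ``K``, query size ``n``, universe
    size ``N``; upper-tail p-value ``P(X >= k)``; fold enrichment
    ``(k/n) / (K/N)``; BH adjustment across sets.
    """
    query = set(query)
    universe = set(universe)
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for gs in gene_sets:
        members = gs.members & universe
        K = len(members)
        k = len(members & query)
        if K == 0:
            p = 1.0
            fold = np.nan
        else:
            # P(X >= k) with X ~ Hypergeom(N, K, n)
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            fold = (k / n) / (K / N)
        rows.append(
            {
                "set_id": gs.set_id,
                "name": gs.name,
                "overlap": k,
                "set_size": K,
                "query_size": n,
                "universe_size": N,
                "p": min(1.0, max(0.0, p)),
                "fold_enrichment": fold,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["adj_p"] <= alpha
    return out
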