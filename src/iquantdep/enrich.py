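"""Hypergeometric over-representation analysis of DEP lists.

Two entry points mirror the two questions asked of a differential-protein
list in this kind of study:

* :func:`enrich_sets` — which functional gene sets (GO biological process /
  KEGG-style collections in GMT form) are over-represented among the DEPs of
  each class, stratified by regulation direction;
* :func:`cell_type_profile` — which neural cell type (neuron, astrocyte,
  oligodendrocyte) the DEPs point at, by testing overlap with cell-type
  marker gene sets.

Both use the upper-tail hypergeometric probability P(X >= k) with the
quantified-protein universe as background, report -log10(p) for bar
plotting, and apply the joint "p below cutoff AND at least ``min_overlap``
DEPs in the set" pass rule. No multiple-testing correction is applied to
the pass rule (a Benjamini-Hochberg column is emitted for information
only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

MARKER_SET_NAMES = ("neuron", "astrocyte", "oligodendrocyte")

DEP_CLASSES = ("1day", "2month", "2m_over_1d")

#: smallest p reported, so -log10(p) stays finite
_P_FLOOR = 1e-300


@dataclass
class GeneSetCollection:
    """Named gene sets over a gene-symbol namespace.

    Parameters
    ----------
    sets
        Mapping from set name to the member gene symbols.
    universe
        Gene symbols eligible for testing.  Every set is intersected with
        the universe before a test is run.
    """

    sets: dict[str, set[str]] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.sets = {name: set(members) for name, members in self.sets.items()}
        self.universe = set(self.universe)
        for name, members in self.sets.items():
            if len(members) < 1:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)

    def subset(self, names) -> "GeneSetCollection":
        """Collection restricted to ``names`` (same universe)."""
        missing = [n for n in names if n not in self.sets]
        if missing:
            raise KeyError(f"gene sets not in collection: {missing}")
        return GeneSetCollection(
            sets={n: set(self.sets[n]) for n in names},
            universe=set(self.universe),
        )

    def restricted_to(self, universe) -> "GeneSetCollection":
        """Collection with the universe replaced and sets intersected."""
        universe = set(universe)
        return GeneSetCollection(
            sets={
                n: members & universe
                for n, members in self.sets.items()
                if members & universe
            },
            universe=universe,
        )


def hypergeom_upper_tail(
    overlap: int, query_size: int, set_size: int, universe_size: int
) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    X counts the members of a random ``query_size``-subset of a
    ``universe_size`` universe that fall in a fixed set of ``set_size``
    elements.  The observed overlap is included in the tail (the standard
    over-representation convention), so ``overlap == 0`` gives exactly 1.
    """
    overlap, query_size, set_size, universe_size = (
        int(overlap),
        int(query_size),
        int(set_size),
        int(universe_size),
    )
    if universe_size < 0 or set_size < 0 or query_size < 0 or overlap < 0:
        raise ValueError("counts must be nonnegative")
    if set_size > universe_size or query_size > universe_size:
        raise ValueError(
            "set_size and query_size must not exceed universe_size "
            f"(got set={set_size}, query={query_size}, universe={universe_size})"
        )
    if overlap > min(set_size, query_size):
        raise ValueError(
            f"overlap {overlap} exceeds min(set_size={set_size}, "
            f"query_size={query_size})"
        )
    if overlap == 0:
        return 1.0
    # sf(k) = P(X > k), so P(X >= overlap) = sf(overlap - 1)
    p = float(hypergeom.sf(overlap - 1, universe_size, set_size, query_size))
    return float(min(1.0, max(p, _P_FLOOR)))


def _queries_from_deps(deps: pd.DataFrame) -> dict[tuple[str, str], set[str]]:
    """Split a DEP table into (class, direction) -> protein-id queries."""
    spec = {
        "1day": ("is_dep_1day", "direction_1day"),
        "2month": ("is_dep_2month", "direction_2month"),
        "2m_over_1d": ("is_dep_2m_over_1d", "direction_2month"),
    }
    queries: dict[tuple[str, str], set[str]] = {}
    for dep_class, (flag_col, dir_col) in spec.items():
        called = deps[deps[flag_col]]
        queries[(dep_class, "all")] = set(called["protein"])
        for direction in ("up", "down"):
            queries[(dep_class, direction)] = set(
                called.loc[called[dir_col] == direction, "protein"]
            )
    return queries


def _test_queries(
    queries: dict[tuple[str, str], set[str]],
    collection: GeneSetCollection,
    universe: set[str],
    p_cut: float,
    min_overlap: int,
) -> pd.DataFrame:
    rows = []
    for (dep_class, direction), query in queries.items():
        query = query & universe
        for set_name, members in collection.sets.items():
            members = members & universe
            if not members:
                continue
            overlap = len(query & members)
            p = hypergeom_upper_tail(overlap, len(query), len(members), len(universe))
            rows.append(
                {
                    "set_name": set_name,
                    "dep_class": dep_class,
                    "direction": direction,
                    "overlap_count": overlap,
                    "set_size": len(members),
                    "query_size": len(query),
                    "universe_size": len(universe),
                    "p_value": p,
                    "neg_log10_p": -np.log10(p),
                    "passes": bool(p < p_cut and overlap >= min_overlap),
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return out


def enrich_sets(
    deps: pd.DataFrame,
    collection: GeneSetCollection,
    p_cut: float = 0.1,
    min_overlap: int = 3,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each DEP class against a gene-set collection.

    For every DEP class (1 day, 2 months, 2 months / 1 day) crossed with
    regulation direction (up, down, all) and every set in ``collection``,
    computes the upper-tail hypergeometric p against the quantified-protein
    universe.  A result ``passes`` when p < ``p_cut`` and the overlap holds
    at least ``min_overlap`` DEPs.  Results are sorted by p ascending; a BH
    adjusted-p column is included for information only and plays no role in
    the pass rule.
    """
    if deps.empty:
        raise ValueError("DEP table is empty")
    universe = set(deps["protein"])
    if collection.universe:
        universe &= collection.universe
    if not universe:
        raise ValueError("empty universe: no overlap between DEP table and collection")
    unmapped = set(deps["protein"]) - universe
    if unmapped:
        import warnings

        warnings.warn(
            f"{len(unmapped)} quantified proteins are outside the collection "
            "universe and were dropped from the background"
        )
    return _test_queries(
        _queries_from_deps(deps), collection, universe, p_cut, min_overlap
    )


def cell_type_profile(
    deps: pd.DataFrame,
    markers: GeneSetCollection,
    p_cut: float = 0.05,
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Cell-type attribution of DEP classes via marker-set enrichment.

    Tests the three neural cell-type marker sets (neuron, astrocyte,
    oligodendrocyte) against the up- and down-regulated DEPs of each class:
    3 classes x 2 directions x 3 sets = 18 results, each with -log10(p) for
    bar plotting and a significance flag at ``p_cut`` (default .05, the
    conventional reference line on such bar charts).
    """
    missing = [n for n in MARKER_SET_NAMES if n not in markers]
    if missing:
        raise ValueError(f"marker collection is missing cell-type sets: {missing}")
    if deps.empty:
        raise ValueError("DEP table is empty")
    markers = markers.subset(MARKER_SET_NAMES)
    universe = set(deps["protein"])
    if markers.universe:
        universe &= markers.universe
    if not universe:
        raise ValueError("empty universe: no overlap between DEP table and markers")
    queries = {
        key: q for key, q in _queries_from_deps(deps).items() if key[1] != "all"
    }
    return _test_queries(queries, markers, universe, p_cut, min_overlap)
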