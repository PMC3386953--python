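"""Gene-set over-representation: hypergeometric overlap ("footprint") tests,
GMT-based enrichment with a minimum-set-size filter, Benjamini-Hochberg
adjustment, and a process-by-analysis cross-tabulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .errors import ConfigError
from .model_io import GeneSetCollection

logger = logging.getLogger(__name__)


def hypergeometric_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Summed in log space for numerical stability.  ``k = 0`` returns exactly
    1.0.
    """
    N, K, n, k = int(N), int(K), int(n), int(k)
    if N < 0 or K < 0 or n < 0 or k < 0:
        raise ConfigError("hypergeometric parameters must be non-negative")
    if K > N or n > N:
        raise ConfigError(f"need K <= N and n <= N, got N={N}, K={K}, n={n}")
    if k > min(K, n):
        raise ConfigError(f"k={k} exceeds min(K, n)={min(K, n)}")
    if k == 0:
        return 1.0
    upper = min(K, n)
    ks = np.arange(k, upper + 1)
    logp = stats.hypergeom.logpmf(ks, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept.

    q(i) = min_{j >= i} min(1, p(j) * m / j) over the ascending sort; ties
    are handled stably.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ConfigError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def bonferroni_adjust(pvalues: Iterable[float]) -> np.ndarray:
    p = np.asarray(list(pvalues), dtype=float)
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ConfigError("p-values must lie in [0, 1]")
    return np.minimum(p * p.size, 1.0)


@dataclass
class OverlapResult:
    """One hypergeometric overlap test between a query and a target set."""

    universe_size: int  # N
    target_size: int  # K, after restriction to the universe
    query_size: int  # n, after restriction to the universe
    overlap: int  # k
    p_value: float
    overlap_genes: list[str] = field(default_factory=list)
    dropped_query: list[str] = field(default_factory=list)
    dropped_target: list[str] = field(default_factory=list)

    @property
    def expected(self) -> float:
        return self.target_size * self.query_size / self.universe_size


def footprint_overlap_test(
    query_genes: Iterable[str],
    target_set: Iterable[str],
    universe_genes: Iterable[str],
) -> OverlapResult:
    """Overlap of a query gene list with a splicing factor's target set.

    Both lists are intersected with the universe before counting; members
    falling outside the universe are logged and reported in the result.
    """
    universe = set(universe_genes)
    if not universe:
        raise ConfigError("universe is empty")
    query_all = set(query_genes)
    target_all = set(target_set)
    query = query_all & universe
    target = target_all & universe
    dropped_q = sorted(query_all - universe)
    dropped_t = sorted(target_all - universe)
    if dropped_q:
        logger.info(
            "footprint: %d query gene(s) outside universe dropped", len(dropped_q)
        )
    if dropped_t:
        logger.info(
            "footprint: %d target gene(s) outside universe dropped", len(dropped_t)
        )
    if not query or not target:
        raise ConfigError(
            "query or target set empty after intersection with universe"
        )
    hits = sorted(query & target)
    p = hypergeometric_upper_tail(
        len(universe), len(target), len(query), len(hits)
    )
    return OverlapResult(
        universe_size=len(universe),
        target_size=len(target),
        query_size=len(query),
        overlap=len(hits),
        p_value=p,
        overlap_genes=hits,
        dropped_query=dropped_q,
        dropped_target=dropped_t,
    )


ENRICHMENT_COLUMNS = [
    "set_name",
    "set_size",
    "hits",
    "expected",
    "p_value",
    "p_adjusted",
    "hit_genes",
]


def annotation_enrichment(
    query_genes: Iterable[str],
    sets: GeneSetCollection,
    universe_genes: Iterable[str],
    min_genes: int = 10,
    method: str = "bh",
) -> pd.DataFrame:
    """One hypergeometric upper-tail test per gene set, multiplicity-adjusted.

    Sets are restricted to the universe first; only sets retaining at least
    ``min_genes`` members there are tested ("counted" at all).  Adjustment
    is across the surviving sets only.  Rows are sorted by adjusted p, then
    raw p, then name.
    """
    universe = set(universe_genes)
    if not universe:
        raise ConfigError("universe is empty")
    query = set(query_genes)
    outside = query - universe
    if outside:
        raise ConfigError(
            f"{len(outside)} query gene(s) outside the universe, "
            f"e.g. {sorted(outside)[:5]}"
        )
    if method not in ("bh", "bonferroni"):
        raise ConfigError(f"unknown adjustment method {method!r}")

    rows = []
    for gs in sets:
        members = set(gs.members) & universe
        if len(members) < min_genes:
            continue
        hits = sorted(members & query)
        p = hypergeometric_upper_tail(
            len(universe), len(members), len(query), len(hits)
        )
        rows.append(
            {
                "set_name": gs.name,
                "set_size": len(members),
                "hits": len(hits),
                "expected": len(members) * len(query) / len(universe),
                "p_value": p,
                "hit_genes": ",".join(hits),
            }
        )
    if not rows:
        logger.warning(
            "annotation_enrichment: no set has >= %d members in the "
            "universe; empty table", min_genes,
        )
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    table = pd.DataFrame(rows)
    adjust = bh_adjust if method == "bh" else bonferroni_adjust
    table["p_adjusted"] = adjust(table["p_value"].to_numpy())
    table = table.sort_values(
        ["p_adjusted", "p_value", "set_name"], kind="stable"
    ).reset_index(drop=True)
    return table[ENRICHMENT_COLUMNS]


def process_condition_matrix(
    enrichment_tables: Mapping[str, pd.DataFrame],
    alpha: float | None = None,
) -> pd.DataFrame:
    """Cross-tabulate adjusted p-values of processes across labelled analyses.

    Rows are the union of set names over all tables, columns the analysis
    labels; cells hold the adjusted p (NaN where the set did not survive
    that analysis).  ``unique_to`` names the single label a process appears
    under, or '' when it appears under several.  With ``alpha`` given,
    appearance additionally requires adjusted p < alpha.
    """
    if len(enrichment_tables) < 2:
        raise ConfigError("need >= 2 labelled enrichment tables")
    labels = list(enrichment_tables)
    all_names: list[str] = []
    for tbl in enrichment_tables.values():
        for name in tbl.get("set_name", []):
            if name not in all_names:
                all_names.append(name)
    out = pd.DataFrame(index=sorted(all_names), columns=labels, dtype=float)
    out.index.name = "set_name"
    for label, tbl in enrichment_tables.items():
        if len(tbl):
            out.loc[tbl["set_name"].to_numpy(), label] = tbl[
                "p_adjusted"
            ].to_numpy()
    appears = out.notna()
    if alpha is not None:
        appears &= out < alpha
    n_appear = appears.sum(axis=1)
    unique_to = []
    for name in out.index:
        if n_appear[name] == 1:
            unique_to.append(appears.columns[appears.loc[name]][0])
        else:
            unique_to.append("")
    out["unique_to"] = unique_to
    return out
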