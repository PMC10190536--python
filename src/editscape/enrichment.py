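"""Hypergeometric over-representation of DESs in regions and genes.

Region enrichment asks whether DESs concentrate in a transcribed region
(3'-UTR, intron, ...) beyond what the informative-site background
predicts; gene enrichment uses a changing background — each gene is
tested against its own number of informative editing sites, so long
genes with many sites are not called enriched merely for being long.

All tails are one-sided upper tails P(X >= k) including the observed k,
matching the over-representation question; depletion is not tested. No
multiple-testing correction is applied to the p < 0.05 call (a BH column
is emitted for transparency only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .io_formats import REGIONS


@dataclass
class EnrichmentResult:
    unit: str  # region name or gene id
    k: int  # DESs in the unit
    K: int  # informative sites in the unit
    n: int  # DESs drawn
    N: int  # informative-site population
    p: float  # upper-tail hypergeometric probability


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); P(X >= 0) = 1."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric parameters k={k} N={N} K={K} n={n}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _enrich_units(
    des_units: pd.Series, informative_units: pd.Series, units: Iterable[str]
) -> pd.DataFrame:
    N = len(informative_units)
    n = len(des_units)
    rows = []
    for unit in units:
        K = int((informative_units == unit).sum())
        k = int((des_units == unit).sum())
        p = hypergeom_upper_tail(k, N, K, n)
        rows.append((unit, k, K, n, N, p))
    out = pd.DataFrame(rows, columns=["unit", "k", "K", "n", "N", "p"]).set_index("unit")
    out["bh_q"] = stats.false_discovery_control(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["p"] < 0.05
    return out


def _lookup_regions(sites: Iterable[str], annotation: pd.DataFrame) -> pd.Series:
    sites = list(sites)
    missing = [s for s in sites if s not in annotation.index]
    if missing:
        raise ValueError(f"unannotated site: {missing[0]!r}")
    return annotation.loc[sites, "region"]


def region_enrichment(
    des_sites: Iterable[str],
    informative_sites: Iterable[str],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Per-region hypergeometric enrichment of DESs among informative sites.

    For each region: N = informative sites, K = informative sites in the
    region, n = DESs, k = DESs in the region, p = P(X >= k).
    """
    des_sites = list(des_sites)
    informative_sites = list(informative_sites)
    if not set(des_sites) <= set(informative_sites):
        raise ValueError("DES sites must be a subset of informative sites")
    des_regions = _lookup_regions(des_sites, annotation)
    info_regions = _lookup_regions(informative_sites, annotation)
    return _enrich_units(des_regions, info_regions, REGIONS)


def integrative_region_enrichment(
    des_by_condition: Mapping[str, Iterable[str]],
    informative_by_condition: Mapping[str, Iterable[str]],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Region enrichment pooling unique sites across all conditions."""
    des = sorted(set().union(*map(set, des_by_condition.values()))) if des_by_condition else []
    info = sorted(set().union(*map(set, informative_by_condition.values()))) if informative_by_condition else []
    return region_enrichment(des, info, annotation)


def gene_enrichment(
    des_sites: Iterable[str],
    informative_sites: Iterable[str],
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene DES over-representation with a gene-specific background.

    For gene g: N = informative sites in the condition, K = informative
    sites on g, n = DESs in the condition, k = DESs on g; p = P(X >= k).
    Genes with no informative sites are skipped; only gene-bearing sites
    enter K and k (the population N still counts every informative site).
    """
    des_sites = list(des_sites)
    informative_sites = list(informative_sites)
    if not set(des_sites) <= set(informative_sites):
        raise ValueError("DES sites must be a subset of informative sites")
    _lookup_regions(informative_sites, annotation)  # validates coverage
    des_genes = annotation.loc[des_sites, "gene_id"]
    info_genes = annotation.loc[informative_sites, "gene_id"]
    genes = sorted(g for g in info_genes.unique() if g)
    # background population is all informative sites, not only gene-bearing ones
    N = len(informative_sites)
    n = len(des_sites)
    rows = []
    for gene in genes:
        K = int((info_genes == gene).sum())
        k = int((des_genes == gene).sum())
        rows.append((gene, k, K, n, N, hypergeom_upper_tail(k, N, K, n)))
    out = pd.DataFrame(rows, columns=["unit", "k", "K", "n", "N", "p"]).set_index("unit")
    out["bh_q"] = stats.false_discovery_control(out["p"].to_numpy()) if len(out) else []
    out["significant"] = out["p"] < 0.05
    return out


def per_gene_summary(
    des_tables: Mapping[str, pd.DataFrame], annotation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per (gene, condition) DES pattern summary plus a cross-condition roll-up.

    Returns ``(per_condition, rollup)``. ``per_condition`` has one row per
    gene and condition with the DES count, the fraction of over-editing
    DESs and the fraction located in the 3'-UTR; ``rollup`` has one row
    per gene with the unique DES count and the number of conditions the
    gene appears in. Genes with no DESs appear in neither table.
    """
    rows = []
    per_gene_sites: dict[str, set] = {}
    per_gene_conditions: dict[str, set] = {}
    for cond, des in des_tables.items():
        if des.empty:
            continue
        sites = [s for s in des.index if s in annotation.index]
        genes = annotation.loc[sites, "gene_id"]
        for gene, site_ids in genes.groupby(genes.values):
            if not gene:
                continue
            ids = list(site_ids.index)
            sub = des.loc[ids]
            regions = annotation.loc[ids, "region"]
            rows.append(
                (
                    gene,
                    cond,
                    len(ids),
                    float((sub["direction"] == "over").mean()),
                    float((regions == "3'-UTR").mean()),
                )
            )
            per_gene_sites.setdefault(gene, set()).update(ids)
            per_gene_conditions.setdefault(gene, set()).add(cond)
    per_condition = pd.DataFrame(
        rows, columns=["gene_id", "condition", "n_des", "prop_over", "frac_3utr"]
    ).sort_values(["gene_id", "condition"]).reset_index(drop=True)
    rollup = pd.DataFrame(
        [
            (gene, len(per_gene_sites[gene]), len(per_gene_conditions[gene]))
            for gene in sorted(per_gene_sites)
        ],
        columns=["gene_id", "n_unique_des", "n_conditions"],
    )
    return per_condition, rollup
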