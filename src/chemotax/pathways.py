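"""Pathway co-localization of structurally similar compound clusters.

Given a user-supplied compound -> pathway mapping (e.g. exported KEGG
assignments), summarises how each structural cluster distributes over
pathways and computes the co-localization fraction: the share of mapped,
clustered compounds that sit in the same pathway as at least one other
mapped compound from the same cluster.  A high fraction means structural
similarity tracks biosynthetic proximity.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .dpcluso import MetaboliteCluster

logger = logging.getLogger(__name__)


def _pathways_by_compound(pmap: pd.DataFrame) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for cid, pid in pmap[["compound_id", "pathway_id"]].itertuples(index=False):
        out.setdefault(str(cid), set()).add(str(pid))
    return out


def cluster_pathway_table(
    clusters: Sequence[MetaboliteCluster], pmap: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster pathway counts.

    Returns one row per (cluster, pathway) with the number of cluster
    compounds mapped to that pathway; compounds absent from the mapping are
    tallied in the log as unmapped.  An empty mapping yields an empty table.
    """
    by_compound = _pathways_by_compound(pmap)
    rows = []
    n_unmapped = 0
    for c in clusters:
        counts: dict[str, int] = {}
        for cid in c.nodes:
            paths = by_compound.get(cid)
            if not paths:
                n_unmapped += 1
                continue
            for pid in paths:
                counts[pid] = counts.get(pid, 0) + 1
        for pid in sorted(counts):
            rows.append((c.cluster_id, pid, counts[pid]))
    logger.info(
        "cluster_pathway_table: %d (cluster, pathway) rows; %d cluster-compound "
        "memberships unmapped", len(rows), n_unmapped,
    )
    return pd.DataFrame(rows, columns=["cluster_id", "pathway_id", "n_compounds_mapped"])


def co_localization_fraction(
    clusters: Sequence[MetaboliteCluster],
    pmap: pd.DataFrame,
    denominator: str = "mapped",
) -> float | None:
    """Fraction of compounds co-localized with a same-cluster partner.

    A clustered, pathway-mapped compound counts as co-localized when at
    least one *other* mapped compound of one of its clusters shares a
    pathway with it.  ``denominator`` selects the reference population:
    ``"mapped"`` (default) divides by the number of mapped clustered
    compounds, ``"all"`` by all clustered compounds.  Returns ``None`` when
    the denominator is empty.
    """
    if denominator not in ("mapped", "all"):
        raise ValueError("denominator must be 'mapped' or 'all'")
    by_compound = _pathways_by_compound(pmap)
    clustered = sorted(set().union(*(c.nodes for c in clusters))) if clusters else []
    mapped = [cid for cid in clustered if by_compound.get(cid)]
    colocalized: set[str] = set()
    for c in clusters:
        members = [cid for cid in sorted(c.nodes) if by_compound.get(cid)]
        for cid in members:
            for other in members:
                if other != cid and by_compound[cid] & by_compound[other]:
                    colocalized.add(cid)
                    break
    denom = len(mapped) if denominator == "mapped" else len(clustered)
    if denom == 0:
        logger.warning("co_localization_fraction: empty denominator (%s)", denominator)
        return None
    frac = len(colocalized) / denom
    logger.info(
        "co_localization_fraction: %d/%d compounds co-localized (%s denominator)",
        len(colocalized), denom, denominator,
    )
    return frac


def cluster_colocalization_fraction(
    clusters: Sequence[MetaboliteCluster], pmap: pd.DataFrame
) -> float | None:
    """Cluster-denominated variant: fraction of clusters with >= 1 mapped
    compound in which some pathway holds >= 2 of the cluster's compounds."""
    by_compound = _pathways_by_compound(pmap)
    eligible = 0
    hit = 0
    for c in clusters:
        members = [cid for cid in c.nodes if by_compound.get(cid)]
        if not members:
            continue
        eligible += 1
        path_counts: dict[str, int] = {}
        for cid in members:
            for pid in by_compound[cid]:
                path_counts[pid] = path_counts.get(pid, 0) + 1
        if any(v >= 2 for v in path_counts.values()):
            hit += 1
    if eligible == 0:
        return None
    return hit / eligible
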