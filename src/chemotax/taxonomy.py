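"""Species classification from metabolite-group content.

Builds the binary species × metabolite-group matrix M (M_ik = 1 when species
i contains compounds from structural group k), computes Euclidean distances
d(i, j) = sqrt(sum_k (M_ik - M_jk)^2) — for binary rows, the square root of
the Hamming distance — and classifies species by agglomerative hierarchical
clustering.  Clades are top-level branches of the dendrogram (a 3-cut by
default); finer classifications come from a k-cut (k = 50 by convention).

Species are sorted by ID before clustering, so results are invariant to
input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .dpcluso import MetaboliteCluster
from .records import RelationTable

logger = logging.getLogger(__name__)


@dataclass
class SpeciesGroupMatrix:
    """Binary presence matrix of metabolite groups per species.

    Rows follow ``species_ids``, columns ``group_ids``; entries are 0/1.
    """

    species_ids: list[str]
    group_ids: list[str]
    M: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=np.int8)
        if self.M.shape != (len(self.species_ids), len(self.group_ids)):
            raise ValueError("matrix shape inconsistent with ID lists")
        if not np.isin(self.M, (0, 1)).all():
            raise ValueError("matrix entries must be binary")

    @property
    def shape(self) -> tuple[int, int]:
        return self.M.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=self.species_ids, columns=self.group_ids)


@dataclass
class ChemoTaxonomy:
    """Dendrogram over species with helpers for cutting and cophenetics.

    ``linkage_matrix`` is in scipy ``linkage`` format over species sorted by
    ID; merge heights are Euclidean distances between binary content rows.
    """

    species_ids: list[str]
    linkage_matrix: np.ndarray = field(repr=False)
    linkage: str = "average"

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Square matrix of dendrogram heights at which species pairs merge."""
        coph = squareform(hierarchy.cophenet(self.linkage_matrix))
        return pd.DataFrame(coph, index=self.species_ids, columns=self.species_ids)


def build_matrix(
    rel: RelationTable,
    clusters: Sequence[MetaboliteCluster],
    singletons: Iterable[str] = (),
    mode: str = "member",
    columns: str = "clusters+singletons",
) -> SpeciesGroupMatrix:
    """Assemble the species × metabolite-group binary matrix.

    Parameters
    ----------
    mode
        ``"member"`` (default): M_ik = 1 iff species i has >= 1 compound in
        group k.  ``"pair"``: the stricter reading requiring >= 2 compounds
        of the group in the species.
    columns
        ``"clusters+singletons"`` (default) gives one column per cluster plus
        one per unclustered network compound; ``"clusters"`` restricts to
        cluster columns.

    Species whose compounds fall in no column are dropped with a warning.
    """
    if mode not in ("member", "pair"):
        raise ValueError("mode must be 'member' or 'pair'")
    if columns not in ("clusters+singletons", "clusters"):
        raise ValueError("columns must be 'clusters+singletons' or 'clusters'")

    # compound -> column indices (overlapping clusters give multiple columns)
    col_ids: list[str] = [f"cluster_{c.cluster_id}" for c in clusters]
    compound_cols: dict[str, list[int]] = {}
    for j, c in enumerate(clusters):
        for cid in c.nodes:
            compound_cols.setdefault(cid, []).append(j)
    if columns == "clusters+singletons":
        for cid in sorted(singletons):
            compound_cols.setdefault(cid, []).append(len(col_ids))
            col_ids.append(f"singleton_{cid}")

    species = sorted(rel.compounds_by_species())
    by_species = rel.compounds_by_species()
    M = np.zeros((len(species), len(col_ids)), dtype=np.int8)
    min_hits = 1 if mode == "member" else 2
    for i, sp in enumerate(species):
        counts = np.zeros(len(col_ids), dtype=int)
        for cid in by_species[sp]:
            for j in compound_cols.get(cid, ()):
                counts[j] += 1
        M[i] = counts >= min_hits

    keep = M.any(axis=1)
    if not keep.all():
        dropped = [sp for sp, k in zip(species, keep) if not k]
        logger.warning(
            "build_matrix: dropping %d species with no group membership: %s",
            len(dropped), dropped[:10],
        )
    species = [sp for sp, k in zip(species, keep) if k]
    M = M[keep]
    if M.size == 0 or not species:
        raise ValueError("build_matrix: empty matrix after dropping uncovered species")
    logger.info("build_matrix: %d species x %d groups (mode=%s)", len(species), len(col_ids), mode)
    return SpeciesGroupMatrix(species, col_ids, M)


def euclidean_distance(mat: SpeciesGroupMatrix, i: int, j: int) -> float:
    """d(i, j) = sqrt(sum_k (M_ik - M_jk)^2) between two species rows."""
    diff = mat.M[i].astype(float) - mat.M[j].astype(float)
    return float(np.sqrt(np.sum(diff * diff)))


def distance_matrix(mat: SpeciesGroupMatrix) -> pd.DataFrame:
    """Full symmetric Euclidean distance matrix over species."""
    d = squareform(pdist(mat.M.astype(float), metric="euclidean"))
    return pd.DataFrame(d, index=mat.species_ids, columns=mat.species_ids)


def hierarchical_cluster(
    mat: SpeciesGroupMatrix, linkage: str = "average"
) -> ChemoTaxonomy:
    """Agglomerative clustering of species on Euclidean content distances.

    ``linkage`` is one of ``average`` (UPGMA, default), ``complete`` or
    ``ward``.  Species are put in canonical (sorted-ID) order first, which
    fixes the merge order and makes the result independent of input order.
    """
    if linkage not in ("average", "complete", "ward"):
        raise ValueError("linkage must be 'average', 'complete' or 'ward'")
    if len(mat.species_ids) < 2:
        raise ValueError("hierarchical_cluster needs at least 2 species")
    order = np.argsort(np.asarray(mat.species_ids, dtype=object))
    species = [mat.species_ids[i] for i in order]
    X = mat.M[order].astype(float)
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method=linkage)
    return ChemoTaxonomy(species_ids=species, linkage_matrix=Z, linkage=linkage)


def cut_tree(tax: ChemoTaxonomy, k: int = 50) -> dict[str, int]:
    """Cut the dendrogram into exactly k non-empty clusters.

    Labels are 1..k, assigned in first-seen order over the canonical species
    ordering, so equal trees yield equal labelings.
    """
    n = len(tax.species_ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    raw = hierarchy.cut_tree(tax.linkage_matrix, n_clusters=k).ravel()
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for sp, lab in zip(tax.species_ids, raw):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        out[sp] = relabel[lab]
    return out


def clade_report(
    tax: ChemoTaxonomy,
    annotation: Mapping[str, str] | None = None,
    n_clades: int = 3,
) -> pd.DataFrame:
    """Composition of each top-level clade (an ``n_clades``-cut).

    ``annotation`` maps species to plant group "M" (monocot), "D" (eudicot)
    or "MD"; unannotated species are counted as NA.  Columns: clade,
    n_species, n_monocot, n_eudicot, n_both, n_na; n_species sums to the
    total species count.
    """
    assign = cut_tree(tax, n_clades)
    annotation = annotation or {}
    rows = []
    for clade in sorted(set(assign.values())):
        members = [sp for sp, c in assign.items() if c == clade]
        labels = [annotation.get(sp, "NA") for sp in members]
        rows.append(
            {
                "clade": clade,
                "n_species": len(members),
                "n_monocot": labels.count("M"),
                "n_eudicot": labels.count("D"),
                "n_both": labels.count("MD"),
                "n_na": labels.count("NA"),
            }
        )
    return pd.DataFrame(rows)
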