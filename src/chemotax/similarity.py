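"""Structural similarity: fingerprints, Tanimoto coefficients and the
thresholded similarity network.

The similarity measure is the Tanimoto (Jaccard) coefficient
``|A ∩ B| / |A ∪ B|`` between two set-valued fingerprints.  Edges enter the
network when the coefficient is *strictly* greater than the cut-off
(default 0.85).  The comparison is performed on exact integer counts
(``|A ∩ B| * q > p * |A ∪ B|`` with the threshold as a rational ``p/q``) so
edge sets are bit-stable across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .records import CompoundRecord, RelationTable

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.85


@dataclass(frozen=True)
class Fingerprint:
    """A compound's descriptor set: integer feature IDs.

    Any deterministic set-valued fingerprint works (topological atom pairs
    computed from structures, or precomputed feature sets read from a table).
    """

    compound_id: str
    features: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", frozenset(self.features))


@dataclass(frozen=True)
class SimilarityEdge:
    """An undirected compound pair above the cut-off, stored with id_a < id_b."""

    id_a: str
    id_b: str
    tanimoto: float

    def __post_init__(self) -> None:
        if self.id_a >= self.id_b:
            raise ValueError("SimilarityEdge requires id_a < id_b")
        if not 0.0 <= self.tanimoto <= 1.0:
            raise ValueError("tanimoto must lie in [0, 1]")


@dataclass
class SimilarityNetwork:
    """Thresholded structural-similarity network.

    ``nodes`` keeps every compound, including isolated ones, so that single
    (degree-0) nodes remain countable after thresholding.
    """

    nodes: set[str]
    edges: list[SimilarityEdge]
    threshold: float

    def to_graph(self) -> nx.Graph:
        """Materialise as an undirected networkx graph with tanimoto weights."""
        g = nx.Graph(threshold=self.threshold)
        g.add_nodes_from(sorted(self.nodes))
        for e in self.edges:
            g.add_edge(e.id_a, e.id_b, tanimoto=e.tanimoto)
        return g

    @property
    def n_isolated(self) -> int:
        linked = {e.id_a for e in self.edges} | {e.id_b for e in self.edges}
        return len(self.nodes - linked)


def filter_species(rel: RelationTable, min_compounds: int = 2) -> RelationTable:
    """Drop species with fewer than ``min_compounds`` distinct compounds.

    Mirrors the pre-processing rule that plants with less than two different
    sulfur-containing compounds are removed before network construction.
    Compounds left unreferenced by the surviving species are logged; they are
    excluded downstream simply by no longer appearing in the table.
    """
    by_species = rel.compounds_by_species()
    keep = {sp for sp, comps in by_species.items() if len(comps) >= min_compounds}
    dropped = set(by_species) - keep
    out = rel.df[rel.df["species_id"].isin(keep)].reset_index(drop=True)
    if out.empty:
        raise ValueError(
            f"filter_species: no species with >= {min_compounds} compounds remain"
        )
    lost_compounds = set(rel.df["compound_id"]) - set(out["compound_id"])
    logger.info(
        "filter_species: kept %d/%d species (dropped %d); %d compounds now unreferenced",
        len(keep), len(by_species), len(dropped), len(lost_compounds),
    )
    if lost_compounds:
        logger.debug("unreferenced compounds: %s", sorted(lost_compounds))
    return RelationTable(out)


def fingerprint_from_structure(rec: CompoundRecord) -> Fingerprint:
    """Topological atom-pair fingerprint of a parsed structure.

    Enumerates pairs of atoms with their bond-path separation; the resulting
    feature-ID set is deterministic for a given connection table.  Molecules
    with fewer than two atoms have no atom pairs and are rejected.
    """
    if rec.mol is None:
        raise ValueError(f"{rec.compound_id}: no structure present")
    from rdkit.Chem import rdFingerprintGenerator

    gen = rdFingerprintGenerator.GetAtomPairGenerator()
    counts = gen.GetSparseCountFingerprint(rec.mol).GetNonzeroElements()
    if not counts:
        raise ValueError(
            f"{rec.compound_id}: structure yields an empty atom-pair fingerprint "
            "(fewer than two heavy atoms?)"
        )
    return Fingerprint(rec.compound_id, frozenset(counts))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A ∩ B| / |A ∪ B| between two fingerprints."""
    if not a.features or not b.features:
        raise ValueError("tanimoto is undefined for empty feature sets")
    inter = len(a.features & b.features)
    union = len(a.features) + len(b.features) - inter
    return inter / union


def build_network(
    fps: Sequence[Fingerprint], threshold: float = DEFAULT_THRESHOLD
) -> SimilarityNetwork:
    """Evaluate all compound pairs and keep edges with Tanimoto > threshold.

    The inequality is strict and evaluated on exact integers, so a pair whose
    coefficient equals the cut-off is excluded on every platform.  All input
    compounds become nodes; compounds without any qualifying partner remain
    as isolated nodes.
    """
    if len(fps) < 2:
        raise ValueError("build_network needs at least 2 fingerprints")
    ids = [fp.compound_id for fp in fps]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate compound_ids in fingerprint list")
    thr = Fraction(str(threshold))
    edges: list[SimilarityEdge] = []
    for fa, fb in combinations(sorted(fps, key=lambda f: f.compound_id), 2):
        inter = len(fa.features & fb.features)
        union = len(fa.features) + len(fb.features) - inter
        # inter/union > p/q  <=>  inter*q > p*union, all integers
        if inter * thr.denominator > thr.numerator * union:
            edges.append(SimilarityEdge(fa.compound_id, fb.compound_id, inter / union))
    net = SimilarityNetwork(nodes=set(ids), edges=edges, threshold=threshold)
    logger.info(
        "build_network: %d nodes, %d edges at Tanimoto > %s (%d isolated)",
        len(net.nodes), len(net.edges), threshold, net.n_isolated,
    )
    return net


def pair_table(fps: Sequence[Fingerprint], floor: float = 0.7) -> pd.DataFrame:
    """All compound pairs with Tanimoto strictly above a reporting floor.

    Columns: id_a, id_b, tanimoto (id_a < id_b, sorted).  The default floor
    of 0.7 mirrors the conventional reporting cut used alongside the 0.85
    network threshold.
    """
    rows = []
    thr = Fraction(str(floor))
    for fa, fb in combinations(sorted(fps, key=lambda f: f.compound_id), 2):
        inter = len(fa.features & fb.features)
        union = len(fa.features) + len(fb.features) - inter
        if inter * thr.denominator > thr.numerator * union:
            rows.append((fa.compound_id, fb.compound_id, inter / union))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "tanimoto"])


def degree_distribution(
    net: SimilarityNetwork,
) -> tuple[pd.DataFrame, float | None]:
    """Degree histogram plus a log--log least-squares power-law slope.

    Isolated nodes contribute degree 0 to the histogram.  The slope is fit by
    ordinary least squares of log10(count) on log10(degree) over degrees >= 1
    (the same simple fit network-analysis tools report); it is ``None`` when
    fewer than two distinct positive degrees exist.
    """
    g = net.to_graph()
    degs = [d for _, d in g.degree()]
    hist = pd.Series(degs).value_counts().sort_index()
    table = pd.DataFrame({"degree": hist.index, "count": hist.values})
    pos = table[table["degree"] >= 1]
    slope: float | None = None
    if len(pos) >= 2:
        x = np.log10(pos["degree"].to_numpy(float))
        y = np.log10(pos["count"].to_numpy(float))
        slope = float(np.polyfit(x, y, 1)[0])
    return table, slope


def fingerprints_from_records(
    records: Iterable[CompoundRecord], skip_errors: bool = True
) -> list[Fingerprint]:
    """Fingerprint every record with a structure; log and skip failures."""
    out: list[Fingerprint] = []
    for rec in records:
        try:
            out.append(fingerprint_from_structure(rec))
        except ValueError:
            if not skip_errors:
                raise
            logger.warning("skipping %s: fingerprint failed", rec.compound_id)
    return out
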