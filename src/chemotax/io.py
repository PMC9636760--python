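"""Readers and writers for every external representation the pipeline touches.

Structures come in as MOL directories or SDF (V2000); relations, annotations,
fingerprints and pathway maps as TSV/CSV tables (tab tried first, comma as
fallback); networks go out as Cytoscape-readable SIF and GraphML; trees as
Newick.  All readers log row accounting (rows in = kept + skipped).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .dpcluso import MetaboliteCluster
from .records import CompoundRecord, RelationTable
from .similarity import Fingerprint, SimilarityEdge, SimilarityNetwork
from .taxonomy import ChemoTaxonomy, SpeciesGroupMatrix

logger = logging.getLogger(__name__)


# --- tabular inputs --------------------------------------------------------

def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    """Read a delimited table, trying tab first then comma."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not set(required) <= set(df.columns):
        df = pd.read_csv(path, sep=",", dtype=str)
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {sorted(missing)}; "
            f"found {list(df.columns)}"
        )
    return df


def read_relations(path: str | Path) -> RelationTable:
    """Load species--compound relations; duplicates are collapsed and counted."""
    df = _read_table(path, ["species_id", "compound_id"])
    n_in = len(df)
    df = df[["species_id", "compound_id"]].dropna().drop_duplicates(ignore_index=True)
    logger.info("read_relations: %d rows in, %d kept (%d duplicates/blank)", n_in, len(df), n_in - len(df))
    if df.empty:
        logger.warning("read_relations: %s contains no data rows", path)
    return RelationTable(df)


def read_annotations(path: str | Path) -> dict[str, dict[str, str]]:
    """Compound annotations: compound_id -> {scc_class, plant_group}."""
    df = _read_table(path, ["compound_id"])
    out: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        out[str(row["compound_id"])] = {
            k: str(row[k]) for k in ("scc_class", "plant_group") if k in df.columns and pd.notna(row[k])
        }
    logger.info("read_annotations: %d compounds annotated", len(out))
    return out


def read_pathway_map(path: str | Path) -> pd.DataFrame:
    """Compound -> pathway mapping; duplicate (compound, pathway) pairs collapse."""
    df = _read_table(path, ["compound_id", "pathway_id"])
    n_in = len(df)
    df = df.drop_duplicates(subset=["compound_id", "pathway_id"], ignore_index=True)
    logger.info("read_pathway_map: %d rows in, %d kept", n_in, len(df))
    return df


def read_fingerprints(path: str | Path) -> list[Fingerprint]:
    """Precomputed fingerprints: columns compound_id, features
    (semicolon- or comma-separated integer feature IDs)."""
    df = _read_table(path, ["compound_id", "features"])
    fps = []
    for cid, feats in df[["compound_id", "features"]].itertuples(index=False):
        ids = {int(t) for t in str(feats).replace(",", ";").split(";") if t.strip()}
        fps.append(Fingerprint(str(cid), frozenset(ids)))
    logger.info("read_fingerprints: %d fingerprints", len(fps))
    return fps


def write_fingerprints(fps: Iterable[Fingerprint], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("compound_id\tfeatures\n")
        for fp in sorted(fps, key=lambda f: f.compound_id):
            fh.write(f"{fp.compound_id}\t{';'.join(map(str, sorted(fp.features)))}\n")
    return path


def write_relations(rel: RelationTable, path: str | Path) -> Path:
    path = Path(path)
    rel.df.sort_values(["species_id", "compound_id"]).to_csv(path, sep="\t", index=False)
    return path


# --- structures ------------------------------------------------------------

def read_structures(path: str | Path, format: str = "sdf") -> list[CompoundRecord]:
    """Parse molecules from an SDF file or a directory of .mol files.

    Unparseable entries are logged and skipped, never silently dropped.
    Raises if the path is missing or no molecule parses at all.
    """
    from rdkit import Chem, RDLogger

    RDLogger.DisableLog("rdApp.error")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format not in ("sdf", "mol_dir"):
        raise ValueError("format must be 'sdf' or 'mol_dir'")

    records: list[CompoundRecord] = []
    n_skipped = 0
    if format == "mol_dir":
        files = sorted(path.glob("*.mol")) + sorted(path.glob("*.MOL"))
        for f in files:
            mol = Chem.MolFromMolFile(str(f))
            if mol is None:
                n_skipped += 1
                logger.warning("read_structures: could not parse %s, skipped", f.name)
                continue
            records.append(CompoundRecord(compound_id=f.stem, mol=mol))
        n_in = len(files)
    else:
        supplier = Chem.SDMolSupplier(str(path))
        n_in = 0
        for i, mol in enumerate(supplier):
            n_in += 1
            if mol is None:
                n_skipped += 1
                logger.warning("read_structures: entry %d unparseable, skipped", i)
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol_{i + 1}"
            records.append(CompoundRecord(compound_id=name, mol=mol))
    logger.info("read_structures: %d entries in, %d parsed, %d skipped", n_in, len(records), n_skipped)
    if not records:
        raise ValueError(f"{path}: no parseable molecules")
    return records


# --- networks --------------------------------------------------------------

def write_network(
    net: SimilarityNetwork,
    path: str | Path,
    format: str = "graphml",
    plant_group: Mapping[str, str] | None = None,
) -> Path:
    """Write the similarity network for Cytoscape.

    SIF: one ``idA <tab> sim <tab> idB`` line per undirected edge.  GraphML:
    edge attribute ``tanimoto`` (6 decimal places) and node attribute
    ``plant_group`` when annotation is supplied.
    """
    path = Path(path)
    if format == "sif":
        with open(path, "w") as fh:
            for e in sorted(net.edges, key=lambda e: (e.id_a, e.id_b)):
                fh.write(f"{e.id_a}\tsim\t{e.id_b}\n")
    elif format == "graphml":
        g = nx.Graph()
        g.graph["threshold"] = float(net.threshold)
        for node in sorted(net.nodes):
            attrs = {}
            if plant_group and node in plant_group:
                attrs["plant_group"] = plant_group[node]
            g.add_node(node, **attrs)
        for e in sorted(net.edges, key=lambda e: (e.id_a, e.id_b)):
            g.add_edge(e.id_a, e.id_b, tanimoto=round(e.tanimoto, 6))
        nx.write_graphml(g, str(path))
    else:
        raise ValueError("format must be 'sif' or 'graphml'")
    logger.info("write_network: %d nodes, %d edges -> %s (%s)", len(net.nodes), len(net.edges), path, format)
    return path


def read_network(path: str | Path) -> SimilarityNetwork:
    """Read back a GraphML network written by :func:`write_network`."""
    g = nx.read_graphml(str(path))
    edges = [
        SimilarityEdge(*sorted((a, b)), tanimoto=float(d["tanimoto"]))
        for a, b, d in g.edges(data=True)
    ]
    return SimilarityNetwork(
        nodes=set(g.nodes), edges=edges, threshold=float(g.graph.get("threshold", 0.0))
    )


# --- clusters --------------------------------------------------------------

def write_clusters(
    clusters: Sequence[MetaboliteCluster], path: str | Path
) -> Path:
    """Membership TSV: cluster_id, compound_id — one row per membership, so
    compounds in overlapping clusters appear on multiple rows."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("cluster_id\tcompound_id\n")
        for c in clusters:
            for cid in sorted(c.nodes):
                fh.write(f"{c.cluster_id}\t{cid}\n")
    return path


def write_matrix(mat: SpeciesGroupMatrix, path: str | Path) -> Path:
    path = Path(path)
    mat.to_frame().rename_axis("species_id").to_csv(path, sep="\t")
    return path


# --- trees -----------------------------------------------------------------

def _sanitize(name: str) -> str:
    return name.replace(" ", "_").replace("\t", "_")


def write_newick(tax: ChemoTaxonomy, path: str | Path) -> Path:
    """Write the species dendrogram as single-rooted Newick.

    The tree is ultrametric: an internal node merging at height h sits at
    elevation h/2, so the path length between two leaves through their
    lowest common ancestor reproduces the cophenetic height exactly.
    """
    n = len(tax.species_ids)
    if n < 2:
        raise ValueError("write_newick needs at least 2 species")
    newick: dict[int, str] = {i: _sanitize(tax.species_ids[i]) for i in range(n)}
    elev: dict[int, float] = {i: 0.0 for i in range(n)}
    for idx, (a, b, h, _) in enumerate(tax.linkage_matrix):
        node = n + idx
        e = float(h) / 2.0
        left = f"{newick[int(a)]}:{e - elev[int(a)]:.10g}"
        right = f"{newick[int(b)]}:{e - elev[int(b)]:.10g}"
        newick[node] = f"({left},{right})"
        elev[node] = e
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(newick[n + len(tax.linkage_matrix) - 1] + ";\n")
    return path


def write_assignments(
    assignments: Mapping[str, int],
    clades: Mapping[str, int],
    path: str | Path,
) -> Path:
    """TSV of species_id, cluster, clade (k-cut and clade-cut labels)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("species_id\tcluster\tclade\n")
        for sp in sorted(assignments):
            fh.write(f"{sp}\t{assignments[sp]}\t{clades.get(sp, '')}\n")
    return path


def write_degree_table(table: pd.DataFrame, slope: float | None, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# power_law_slope\t{'' if slope is None else f'{slope:.6g}'}\n")
        table.to_csv(fh, sep="\t", index=False)
    return path
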