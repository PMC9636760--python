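"""End-to-end orchestration: similarity network -> overlapping clusters ->
species x group matrix -> hierarchical classification, with a machine-
readable run manifest.

Inputs are either real files (structures or precomputed fingerprints plus a
relation table) or a synthetic specification with planted ground truth.
Every stage's parameters and output row counts land in ``manifest.json`` so
a rerun can be checked for byte-level agreement of the counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import io as cio
from .dpcluso import ClusteringParams, dpcluso_cluster, overlap_graph
from .pathways import cluster_colocalization_fraction, co_localization_fraction, cluster_pathway_table
from .records import RelationTable
from .similarity import (
    Fingerprint,
    build_network,
    degree_distribution,
    filter_species,
    fingerprints_from_records,
    pair_table,
)
from .synthetic import SyntheticSpec, generate_dataset, write_ground_truth
from .taxonomy import build_matrix, clade_report, cut_tree, hierarchical_cluster

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters for one pipeline run.

    Exactly one input source must be set: ``synthetic`` for a generated
    dataset, or ``fingerprints_path``/``structures_path`` plus
    ``relations_path`` for real data.
    """

    outdir: str | Path = "chemotax_run"
    synthetic: SyntheticSpec | None = None
    structures_path: str | Path | None = None
    structures_format: str = "sdf"
    fingerprints_path: str | Path | None = None
    relations_path: str | Path | None = None
    annotations_path: str | Path | None = None
    pathway_map_path: str | Path | None = None
    # similarity stage
    threshold: float = 0.85
    report_floor: float = 0.7
    min_compounds: int = 2
    # clustering stage
    cp_in: float = 0.5
    d_in: float = 0.7
    min_cluster_size: int = 2
    overlap_mode: bool = True
    # taxonomy stage
    matrix_mode: str = "member"
    matrix_columns: str = "clusters+singletons"
    linkage: str = "average"
    k: int = 50
    n_clades: int = 3

    def validate(self) -> None:
        sources = [self.synthetic, self.fingerprints_path, self.structures_path]
        if sum(s is not None for s in sources) != 1:
            raise ValueError(
                "exactly one of synthetic / fingerprints_path / structures_path required"
            )
        if self.synthetic is None and self.relations_path is None:
            raise ValueError("relations_path required with real inputs")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        ClusteringParams(self.cp_in, self.d_in, self.min_cluster_size, self.overlap_mode)
        if self.matrix_mode not in ("member", "pair"):
            raise ValueError("matrix_mode must be 'member' or 'pair'")
        if self.linkage not in ("average", "complete", "ward"):
            raise ValueError("linkage must be 'average', 'complete' or 'ward'")
        if self.k < 1 or self.n_clades < 1:
            raise ValueError("k and n_clades must be >= 1")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> Path:
    """Execute every stage and return the run directory.

    Artifacts: pairs.tsv, network.sif, network.graphml, degree.tsv,
    clusters.tsv, singletons.txt, overlaps.tsv, matrix.tsv, tree.nwk,
    assignments.tsv, clade_report.tsv, pathway tables when a mapping is
    supplied, and manifest.json with parameters, input checksums and
    per-stage row counts.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    manifest: dict = {"parameters": {}, "inputs": {}, "counts": {}, "artifacts": [], "timings": {}}
    params = {k: v for k, v in asdict(config).items() if not k.endswith("_path") and k != "outdir"}
    if config.synthetic is not None:
        params["synthetic"] = asdict(config.synthetic)
    else:
        params.pop("synthetic", None)
    manifest["parameters"] = {k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()}

    def _stage(name: str):
        manifest["timings"][name] = round(time.perf_counter() - t0, 3)

    # --- inputs -----------------------------------------------------------
    annotation: dict[str, str] = {}
    truth = None
    if config.synthetic is not None:
        fps, rel, truth = generate_dataset(config.synthetic)
        paths = write_ground_truth(truth, outdir)
        manifest["artifacts"] += [p.name for p in paths.values()]
    else:
        if config.fingerprints_path is not None:
            fps = cio.read_fingerprints(config.fingerprints_path)
            manifest["inputs"]["fingerprints"] = _sha256(Path(config.fingerprints_path))
        else:
            recs = cio.read_structures(config.structures_path, config.structures_format)
            manifest["inputs"]["structures"] = _sha256(Path(config.structures_path))
            fps = fingerprints_from_records(recs)
        rel = cio.read_relations(config.relations_path)
        manifest["inputs"]["relations"] = _sha256(Path(config.relations_path))
    if config.annotations_path is not None:
        ann = cio.read_annotations(config.annotations_path)
        annotation = {cid: a["plant_group"] for cid, a in ann.items() if "plant_group" in a}
        manifest["inputs"]["annotations"] = _sha256(Path(config.annotations_path))
    manifest["counts"]["relations_in"] = len(rel)
    manifest["counts"]["fingerprints"] = len(fps)
    _stage("inputs")

    # --- similarity -------------------------------------------------------
    rel = filter_species(rel, config.min_compounds)
    manifest["counts"]["relations_filtered"] = len(rel)
    manifest["counts"]["species"] = len(rel.species_ids)
    kept_compounds = set(rel.compound_ids)
    fps = [fp for fp in fps if fp.compound_id in kept_compounds] or fps
    pairs = pair_table(fps, config.report_floor)
    pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False, float_format="%.6f")
    net = build_network(fps, config.threshold)
    cio.write_network(net, outdir / "network.sif", "sif")
    cio.write_network(net, outdir / "network.graphml", "graphml")
    deg, slope = degree_distribution(net)
    cio.write_degree_table(deg, slope, outdir / "degree.tsv")
    manifest["counts"]["pairs_above_floor"] = len(pairs)
    manifest["counts"]["network_nodes"] = len(net.nodes)
    manifest["counts"]["network_edges"] = len(net.edges)
    manifest["counts"]["network_isolated"] = net.n_isolated
    manifest["artifacts"] += ["pairs.tsv", "network.sif", "network.graphml", "degree.tsv"]
    _stage("similarity")

    # --- clustering -------------------------------------------------------
    cparams = ClusteringParams(config.cp_in, config.d_in, config.min_cluster_size, config.overlap_mode)
    clusters, singletons = dpcluso_cluster(net, cparams)
    cio.write_clusters(clusters, outdir / "clusters.tsv")
    (outdir / "singletons.txt").write_text("".join(f"{s}\n" for s in singletons))
    overlaps = overlap_graph(clusters)
    overlaps.to_csv(outdir / "overlaps.tsv", sep="\t", index=False)
    manifest["counts"]["clusters"] = len(clusters)
    manifest["counts"]["singletons"] = len(singletons)
    manifest["counts"]["overlapping_cluster_pairs"] = len(overlaps)
    manifest["artifacts"] += ["clusters.tsv", "singletons.txt", "overlaps.tsv"]
    _stage("clustering")

    # --- taxonomy ---------------------------------------------------------
    mat = build_matrix(rel, clusters, singletons, config.matrix_mode, config.matrix_columns)
    cio.write_matrix(mat, outdir / "matrix.tsv")
    tax = hierarchical_cluster(mat, config.linkage)
    k = min(config.k, len(tax.species_ids))
    assignments = cut_tree(tax, k)
    n_clades = min(config.n_clades, len(tax.species_ids))
    clades = cut_tree(tax, n_clades)
    cio.write_newick(tax, outdir / "tree.nwk")
    cio.write_assignments(assignments, clades, outdir / "assignments.tsv")
    species_group = {}
    if annotation:
        by_sp = rel.compounds_by_species()
        for sp, comps in by_sp.items():
            labels = {annotation.get(c) for c in comps} - {None}
            if labels == {"M"}:
                species_group[sp] = "M"
            elif labels and "M" not in labels:
                species_group[sp] = "D"
            elif labels:
                species_group[sp] = "MD"
    report = clade_report(tax, species_group, n_clades)
    report.to_csv(outdir / "clade_report.tsv", sep="\t", index=False)
    manifest["counts"]["matrix_species"] = mat.shape[0]
    manifest["counts"]["matrix_groups"] = mat.shape[1]
    manifest["counts"]["k_clusters"] = len(set(assignments.values()))
    manifest["counts"]["clades"] = len(set(clades.values()))
    manifest["artifacts"] += ["matrix.tsv", "tree.nwk", "assignments.tsv", "clade_report.tsv"]
    _stage("taxonomy")

    # --- pathways (optional) ---------------------------------------------
    if config.pathway_map_path is not None:
        pmap = cio.read_pathway_map(config.pathway_map_path)
        manifest["inputs"]["pathway_map"] = _sha256(Path(config.pathway_map_path))
        table = cluster_pathway_table(clusters, pmap)
        table.to_csv(outdir / "cluster_pathways.tsv", sep="\t", index=False)
        frac = co_localization_fraction(clusters, pmap)
        frac_cl = cluster_colocalization_fraction(clusters, pmap)
        manifest["counts"]["pathway_rows"] = len(table)
        manifest["counts"]["co_localization_fraction"] = frac
        manifest["counts"]["cluster_colocalization_fraction"] = frac_cl
        manifest["artifacts"] += ["cluster_pathways.tsv"]
        _stage("pathways")

    manifest["artifacts"] = sorted(set(manifest["artifacts"]))
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run_all: finished in %.2fs -> %s", time.perf_counter() - t0, outdir)
    return outdir
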