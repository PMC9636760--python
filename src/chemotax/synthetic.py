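"""Synthetic benchmark data with planted structure.

Emulates the statistical shape of a species--metabolite chemotaxonomy
dataset: structurally coherent compound groups (high within-group, low
between-group fingerprint similarity) and species whose metabolite content
follows clade-specific group profiles, plus off-profile noise.  Every
generated object carries ground truth, so downstream clustering and
classification can be scored exactly.

Fingerprint construction gives closed-form control of similarity.  Each
group g owns a base feature set B_g of size F: s features shared across all
groups plus F - s group-private features.  A member compound copies B_g and
swaps m features (removes m, adds m fresh compound-private ones), keeping
|fingerprint| = F.  Two same-group compounds then satisfy
Tanimoto >= (F - 2m) / (F + 2m), and two cross-group compounds
Tanimoto <= s / (2F - s); m and s are chosen from the requested within- and
between-group Jaccard targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import RelationTable
from .similarity import Fingerprint

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Defaults plant 4 compound groups of 10 compounds (64-feature
    fingerprints, within-group Jaccard target 0.90, between-group cap 0.30)
    and 2 clades of 20 species, each species drawing 6 metabolites from its
    clade's 2 profile groups with a 5% chance of one off-profile draw.
    """

    n_groups: int = 4
    compounds_per_group: int = 10
    fingerprint_size: int = 64
    within_group_jaccard: float = 0.90
    between_group_jaccard: float = 0.30
    n_clades: int = 2
    species_per_clade: int | tuple[int, ...] = 20
    groups_per_clade: int = 2
    metabolites_per_species: int = 6
    noise_rate: float = 0.05
    seed: int = 0
    allow_filter_victims: bool = False

    def __post_init__(self) -> None:
        counts = {
            "n_groups": self.n_groups,
            "compounds_per_group": self.compounds_per_group,
            "fingerprint_size": self.fingerprint_size,
            "n_clades": self.n_clades,
            "groups_per_clade": self.groups_per_clade,
            "metabolites_per_species": self.metabolites_per_species,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if not 0.0 < self.within_group_jaccard <= 1.0:
            raise ValueError("within_group_jaccard must lie in (0, 1]")
        if not 0.0 <= self.between_group_jaccard < self.within_group_jaccard:
            raise ValueError("need 0 <= between_group_jaccard < within_group_jaccard")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")
        if self.groups_per_clade > self.n_groups:
            raise ValueError("groups_per_clade cannot exceed n_groups")

    def species_counts(self) -> tuple[int, ...]:
        if isinstance(self.species_per_clade, int):
            return (self.species_per_clade,) * self.n_clades
        if len(self.species_per_clade) != self.n_clades:
            raise ValueError("species_per_clade tuple must have n_clades entries")
        return tuple(self.species_per_clade)


@dataclass
class GroundTruth:
    """Planted labels: compound -> group, species -> clade, clade -> profile."""

    compound_group: dict[str, int] = field(default_factory=dict)
    species_clade: dict[str, int] = field(default_factory=dict)
    clade_profile: dict[int, tuple[int, ...]] = field(default_factory=dict)

    def group_members(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for cid, g in self.compound_group.items():
            out.setdefault(g, set()).add(cid)
        return out


def _similarity_design(spec: SyntheticSpec) -> tuple[int, int]:
    """Choose (swap count m, shared feature count s) for the targets.

    m is the largest swap count with (F - 2m)/(F + 2m) >= within target;
    s the largest shared count with s/(2F - s) <= between cap.
    """
    F = spec.fingerprint_size
    t = spec.within_group_jaccard
    b = spec.between_group_jaccard
    m = math.floor(F * (1.0 - t) / (2.0 * (1.0 + t)))
    s = math.floor(2.0 * F * b / (1.0 + b))
    if F - 2 * m <= 0:
        raise ValueError(
            f"within_group_jaccard={t} infeasible at fingerprint_size={F}: "
            "swap count would empty the shared core"
        )
    if s >= F:
        raise ValueError(
            f"between_group_jaccard={b} infeasible at fingerprint_size={F}: "
            "shared pool would consume the whole fingerprint"
        )
    return m, s


def generate_fingerprints(
    spec: SyntheticSpec,
) -> tuple[list[Fingerprint], GroundTruth]:
    """Generate group-structured fingerprints and the compound->group truth.

    Deterministic under ``spec.seed``; compound IDs are ``G{g}C{i}``.
    """
    m, s = _similarity_design(spec)
    F = spec.fingerprint_size
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))

    shared = list(range(s))
    private_width = F - s
    next_fresh = s + spec.n_groups * private_width  # compound-private IDs start here

    truth = GroundTruth()
    fps: list[Fingerprint] = []
    for g in range(spec.n_groups):
        base = shared + list(
            range(s + g * private_width, s + (g + 1) * private_width)
        )
        for i in range(spec.compounds_per_group):
            cid = f"G{g + 1:02d}C{i + 1:03d}"
            feats = set(base)
            if m > 0:
                removed = rng.choice(len(base), size=m, replace=False)
                feats -= {base[r] for r in removed}
                feats |= set(range(next_fresh, next_fresh + m))
                next_fresh += m
            fps.append(Fingerprint(cid, frozenset(feats)))
            truth.compound_group[cid] = g + 1
    for c in range(spec.n_clades):
        start = (c * spec.groups_per_clade) % spec.n_groups
        truth.clade_profile[c + 1] = tuple(
            (start + j) % spec.n_groups + 1 for j in range(spec.groups_per_clade)
        )
    logger.info(
        "generate_fingerprints: %d compounds in %d groups (F=%d, swap m=%d, shared s=%d)",
        len(fps), spec.n_groups, F, m, s,
    )
    return fps, truth


def generate_relations(spec: SyntheticSpec, truth: GroundTruth) -> RelationTable:
    """Draw species--compound relations from the planted clade profiles.

    Each species in clade c samples ``metabolites_per_species`` distinct
    compounds from c's profile groups, plus one off-profile compound with
    probability ``noise_rate``.  Species IDs are ``SP{clade}_{index}``.
    With ``allow_filter_victims`` every tenth species is truncated to a
    single compound so the minimum-compound filter has something to remove.
    """
    if not truth.compound_group:
        raise ValueError("generate_relations: truth has no compounds (generate fingerprints first)")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    members = truth.group_members()
    all_compounds = sorted(truth.compound_group)

    pairs: list[tuple[str, str]] = []
    sp_index = 0
    for c, n_species in zip(range(1, spec.n_clades + 1), spec.species_counts()):
        profile = truth.clade_profile[c]
        pool = sorted(set().union(*(members[g] for g in profile)))
        if not pool:
            raise ValueError(f"clade {c}: profile groups are empty")
        off_pool = sorted(set(all_compounds) - set(pool))
        k = min(spec.metabolites_per_species, len(pool))
        for j in range(n_species):
            sp_index += 1
            sp = f"SP{c:02d}_{j + 1:03d}"
            chosen = list(rng.choice(pool, size=k, replace=False))
            if off_pool and rng.random() < spec.noise_rate:
                chosen.append(str(rng.choice(off_pool)))
            if spec.allow_filter_victims and sp_index % 10 == 0:
                chosen = chosen[:1]
            truth.species_clade[sp] = c
            pairs.extend((sp, str(cid)) for cid in chosen)
    rel = RelationTable.from_pairs(pairs)
    logger.info(
        "generate_relations: %d relations over %d species, %d clades",
        len(rel), len(truth.species_clade), spec.n_clades,
    )
    return rel


def generate_dataset(spec: SyntheticSpec) -> tuple[list[Fingerprint], RelationTable, GroundTruth]:
    """Fingerprints + relations + complete ground truth in one call."""
    fps, truth = generate_fingerprints(spec)
    rel = generate_relations(spec, truth)
    return fps, rel, truth


def off_profile_fraction(rel: RelationTable, truth: GroundTruth) -> float:
    """Fraction of relation rows whose compound lies outside the species'
    clade profile — the realised noise level."""
    off = 0
    for sp, cid in rel.df.itertuples(index=False):
        profile = truth.clade_profile[truth.species_clade[sp]]
        if truth.compound_group[cid] not in profile:
            off += 1
    return off / len(rel)


# --- optional structure emitter -------------------------------------------
# Tiny sulfur-substituted alkyl molecules for integration tests that walk
# the MOL/SDF parsing + structure-fingerprint path.  Not chemically diverse.

def synthetic_molecules(n: int) -> list[tuple[str, str]]:
    """n distinct (id, SMILES) thiol/sulfide chains, e.g. CCS, CCSC, CCCS."""
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    i = 0
    length = 1
    while len(out) < n:
        for tail in ("S", "SC", "SCC"):
            if len(out) >= n:
                break
            i += 1
            out.append((f"SYN{i:03d}", "C" * length + tail))
        length += 1
    return out


def write_sdf(path: str | Path, n: int = 6) -> Path:
    """Write n synthetic molecules as an uncompressed SDF (V2000)."""
    from rdkit import Chem

    path = Path(path)
    with Chem.SDWriter(str(path)) as w:
        for cid, smi in synthetic_molecules(n):
            mol = Chem.MolFromSmiles(smi)
            mol.SetProp("_Name", cid)
            w.write(mol)
    return path


def write_ground_truth(truth: GroundTruth, outdir: str | Path) -> dict[str, Path]:
    """Dump truth maps as TSVs (compound_id,group and species_id,clade)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cg = outdir / "truth_compound_group.tsv"
    sc = outdir / "truth_species_clade.tsv"
    with open(cg, "w") as fh:
        fh.write("compound_id\tgroup\n")
        for cid in sorted(truth.compound_group):
            fh.write(f"{cid}\t{truth.compound_group[cid]}\n")
    with open(sc, "w") as fh:
        fh.write("species_id\tclade\n")
        for sp in sorted(truth.species_clade):
            fh.write(f"{sp}\t{truth.species_clade[sp]}\n")
    return {"compound_group": cg, "species_clade": sc}
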