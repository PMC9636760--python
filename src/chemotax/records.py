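"""Core domain records shared across the pipeline.

Compound identifiers are opaque strings: KNApSAcK-style accessions
("C00001247"), synthetic IDs and anything else are treated alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

#: Allowed plant-group annotations: monocot, eudicot, or found in both.
PLANT_GROUPS = ("M", "D", "MD")


@dataclass
class CompoundRecord:
    """A compound with optional structure and annotation.

    Parameters
    ----------
    compound_id
        Non-empty opaque identifier, unique within a dataset.
    mol
        Optional RDKit molecule parsed from a MOL/SDF connection table.
    scc_class
        Optional compound-class label (e.g. "glucosinolate", "flavonoid").
    plant_group
        Optional ``"M"`` (monocot), ``"D"`` (eudicot) or ``"MD"`` (both).
    """

    compound_id: str
    mol: Any = None
    scc_class: str | None = None
    plant_group: str | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if self.plant_group is not None and self.plant_group not in PLANT_GROUPS:
            raise ValueError(
                f"plant_group must be one of {PLANT_GROUPS}, got {self.plant_group!r}"
            )


@dataclass(frozen=True)
class RelationTable:
    """Deduplicated species--metabolite binary relations.

    Wraps a two-column DataFrame (``species_id``, ``compound_id``) with no
    duplicate pairs.  Construct through :meth:`from_pairs` or
    :func:`chemotax.io.read_relations`.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        cols = list(self.df.columns)
        if cols[:2] != ["species_id", "compound_id"]:
            raise ValueError(
                f"RelationTable requires columns ['species_id', 'compound_id'], got {cols}"
            )
        if self.df.duplicated().any():
            raise ValueError("RelationTable rows must be unique (species_id, compound_id) pairs")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "RelationTable":
        df = pd.DataFrame(list(pairs), columns=["species_id", "compound_id"])
        n_in = len(df)
        df = df.drop_duplicates(ignore_index=True)
        if len(df) < n_in:
            logger.info("RelationTable: collapsed %d duplicate pairs", n_in - len(df))
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def species_ids(self) -> list[str]:
        return sorted(self.df["species_id"].unique())

    @property
    def compound_ids(self) -> list[str]:
        return sorted(self.df["compound_id"].unique())

    def compounds_by_species(self) -> dict[str, set[str]]:
        """Map each species to its set of distinct compounds."""
        out: dict[str, set[str]] = {}
        for sp, cid in self.df.itertuples(index=False):
            out.setdefault(sp, set()).add(cid)
        return out


def validate_annotation(annotation: Mapping[str, str]) -> None:
    """Check that every plant-group label is one of M / D / MD."""
    bad = {k: v for k, v in annotation.items() if v not in PLANT_GROUPS}
    if bad:
        raise ValueError(f"invalid plant_group labels: {bad}")
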