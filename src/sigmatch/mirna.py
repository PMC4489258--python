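"""miRNA-level queries translated into inverted mRNA query gene sets.

Nearly all experimentally verified miRNA–mRNA interactions are inhibitory,
so a list of up-regulated miRNAs implies a list of down-regulated target
genes and vice versa.  Input miRNA names are first normalized to canonical
miRBase-style identifiers through an alias dictionary; targets are then
looked up in an interaction table whose edges carry a support count (number
of source databases confirming the edge).  A gene implied both up and down
is dropped from both lists so the result is a valid query gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .matching import QueryGeneSet
from .signatures import DataError

logger = logging.getLogger(__name__)


class MirnaAliasDict:
    """Case-insensitive alias → canonical miRBase-style identifier map."""

    def __init__(self, aliases: Mapping[str, str] | None = None) -> None:
        self._map: dict[str, str] = {}
        for alias, canonical in (aliases or {}).items():
            self.add(alias, canonical)

    def add(self, alias: str, canonical: str) -> None:
        self._map[alias.strip().lower()] = canonical.strip()
        self._map.setdefault(canonical.strip().lower(), canonical.strip())

    def lookup(self, name: str) -> str | None:
        return self._map.get(name.strip().lower())

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_tsv(cls, path) -> "MirnaAliasDict":
        frame = pd.read_csv(
            path, sep="\t", header=None, names=["alias", "canonical"], dtype=str,
            comment="#",
        )
        d = cls()
        for alias, canonical in frame.itertuples(index=False):
            d.add(alias, canonical)
        return d


@dataclass
class InteractionTable:
    """miRNA → target-gene edges with per-edge source-database support."""

    edges: pd.DataFrame  # columns: mirna, gene, support

    def __post_init__(self) -> None:
        required = {"mirna", "gene", "support"}
        if not required.issubset(self.edges.columns):
            raise DataError(f"interaction table needs columns {sorted(required)}")
        self.edges = self.edges.copy()
        self.edges["gene"] = self.edges["gene"].astype(str).str.upper()
        self.edges["support"] = self.edges["support"].astype(int)
        if (self.edges["support"] < 1).any():
            raise DataError("interaction support counts must be >= 1")
        if self.edges.duplicated(["mirna", "gene"]).any():
            raise DataError("duplicate (mirna, gene) interaction edges")

    @classmethod
    def from_tsv(cls, path) -> "InteractionTable":
        frame = pd.read_csv(
            path, sep="\t", header=None, names=["mirna", "gene", "support"],
            dtype={"mirna": str, "gene": str}, comment="#",
        )
        return cls(frame)

    def targets_of(self, mirnas: Iterable[str], min_support: int = 1) -> set[str]:
        kept = self.edges[self.edges["support"] >= min_support]
        mask = kept["mirna"].isin(set(mirnas))
        return set(kept.loc[mask, "gene"])


def normalize_mirna_id(name: str, aliases: MirnaAliasDict) -> str | None:
    """Canonical identifier for a miRNA name, or None if unmapped."""
    if not name or not name.strip():
        raise DataError("empty miRNA name")
    return aliases.lookup(name)


@dataclass
class TranslationReport:
    """Bookkeeping from a miRNA→mRNA translation run."""

    unmapped: list[str] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)
    mapped_up: list[str] = field(default_factory=list)
    mapped_down: list[str] = field(default_factory=list)


def translate(
    up_mirnas: Sequence[str],
    down_mirnas: Sequence[str],
    table: InteractionTable,
    aliases: MirnaAliasDict | None = None,
    *,
    min_support: int = 1,
) -> tuple[QueryGeneSet, TranslationReport]:
    """Invert miRNA lists into an mRNA query via inhibitory target edges.

    Targets of up-regulated miRNAs become the down-gene list and vice versa.
    Unmapped miRNA names are reported, not silently dropped; genes implied in
    both directions are removed from both lists and reported as conflicts.
    """
    if not (list(up_mirnas) or list(down_mirnas)):
        raise DataError("no input miRNAs")
    aliases = aliases or MirnaAliasDict()
    report = TranslationReport()

    def _normalize(names: Sequence[str], dest: list[str]) -> list[str]:
        out = []
        for name in names:
            canonical = normalize_mirna_id(name, aliases)
            if canonical is None:
                # unknown to the alias dictionary: try the raw name against
                # the interaction table before declaring it unmapped
                if (table.edges["mirna"] == name.strip()).any():
                    canonical = name.strip()
                else:
                    report.unmapped.append(name)
                    continue
            out.append(canonical)
            dest.append(canonical)
        return out

    up_ids = _normalize(up_mirnas, report.mapped_up)
    down_ids = _normalize(down_mirnas, report.mapped_down)
    raw_down = table.targets_of(up_ids, min_support)
    raw_up = table.targets_of(down_ids, min_support)
    if not (raw_up or raw_down):
        raise DataError(
            f"no target genes left after mapping and min_support={min_support} "
            f"filtering ({len(report.unmapped)} unmapped miRNA name(s))"
        )
    both = raw_up & raw_down
    if both:
        logger.warning(
            "%d gene(s) implied both up and down, dropped: %s",
            len(both), sorted(both)[:5],
        )
        report.conflicts = sorted(both)
    query = QueryGeneSet(
        up=frozenset(raw_up - both), down=frozenset(raw_down - both)
    )
    return query, report
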