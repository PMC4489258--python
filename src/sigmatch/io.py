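"""On-disk formats: gene lists, GMT queries, RNK signatures, TSV tables,
and the signature store (a directory of RNK files plus a JSON manifest with
tag and citation sidecars).

All files are UTF-8 TSV (never comma), end with a newline, and floats are
written in their shortest round-trip representation, so identical inputs
and seeds reproduce byte-identical outputs.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .matching import RESULT_COLUMNS, QueryGeneSet
from .signatures import DataError, Publication, RankedSignature

MANIFEST_NAME = "manifest.json"
ANNOTATIONS_NAME = "annotations.tsv"


def _fmt(value) -> str:
    if isinstance(value, (float, np.floating)):
        if np.isnan(value):
            return "NA"
        return repr(float(value))
    if isinstance(value, (bool, np.bool_)):
        return "true" if value else "false"
    return str(value)


# ---------------------------------------------------------------------------
# gene lists and GMT queries

def read_gene_list(path) -> set[str]:
    """One symbol per line; '#' starts a comment; upper-cased, de-duplicated."""
    genes: set[str] = set()
    text = Path(path).read_text(encoding="utf-8")
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.add(line.upper())
    if not genes:
        raise DataError(f"{path}: no gene symbols found")
    return genes


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gene in sorted({g.upper() for g in genes}):
            fh.write(gene + "\n")


def read_gmt_query(path, name: str | None = None) -> QueryGeneSet:
    """Query from a GMT file holding `<name>_UP` and `<name>_DOWN` sets.

    Each GMT line is: set name, description, then the member genes, all
    tab-separated.  With ``name=None`` the file must contain exactly one
    _UP/_DOWN pair.
    """
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataError(f"{path}:{lineno}: GMT line needs >=3 fields")
        sets[fields[0]] = {g.upper() for g in fields[2:] if g.strip()}
    stems = {
        re.sub(r"_(UP|DOWN)$", "", s) for s in sets if re.search(r"_(UP|DOWN)$", s)
    }
    if name is None:
        if len(stems) != 1:
            raise DataError(
                f"{path}: expected one _UP/_DOWN pair, found stems {sorted(stems)}"
            )
        name = next(iter(stems))
    up = sets.get(f"{name}_UP", set())
    down = sets.get(f"{name}_DOWN", set())
    if not (up or down):
        raise DataError(f"{path}: no sets named {name}_UP / {name}_DOWN")
    return QueryGeneSet(up=frozenset(up), down=frozenset(down))


def write_gmt_query(query: QueryGeneSet, path, name: str = "query") -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for suffix, genes in (("UP", query.up), ("DOWN", query.down)):
            fh.write(
                "\t".join([f"{name}_{suffix}", "sigmatch query"] + sorted(genes))
                + "\n"
            )


# ---------------------------------------------------------------------------
# RNK ranked-list files

def read_rnk(path, *, resort: bool = False) -> list[tuple[str, float]]:
    """Read a gene TAB stat ranked list; reject unsorted files unless resort."""
    entries: list[tuple[str, float]] = []
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise DataError(f"{path}:{lineno}: expected 'gene<TAB>stat'")
        try:
            stat = float(fields[1])
        except ValueError:
            raise DataError(
                f"{path}:{lineno}: non-numeric statistic {fields[1]!r}"
            ) from None
        if not np.isfinite(stat):
            raise DataError(f"{path}:{lineno}: non-finite statistic {fields[1]!r}")
        entries.append((fields[0], stat))
    stats = [s for _, s in entries]
    if any(b > a for a, b in zip(stats, stats[1:])):
        if not resort:
            raise DataError(f"{path}: statistics not sorted descending")
        entries.sort(key=lambda e: (-e[1], e[0]))
    return entries


def write_rnk(signature: RankedSignature, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gene, stat in signature.entries:
            fh.write(f"{gene}\t{_fmt(stat)}\n")


# ---------------------------------------------------------------------------
# expression matrices, metadata, citations, annotations, stoplists

def read_expression_matrix(path) -> pd.DataFrame:
    """Genes x samples TSV: first column gene symbols, header = sample IDs."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.empty:
        raise DataError(f"{path}: empty expression matrix")
    return frame


def write_expression_matrix(matrix: pd.DataFrame, path) -> None:
    _write_table(matrix.reset_index(), path)


def read_sample_meta(path) -> pd.DataFrame:
    """Samples x variables TSV: first column sample IDs."""
    frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if frame.empty:
        raise DataError(f"{path}: empty sample metadata")
    return frame


def write_sample_meta(meta: pd.DataFrame, path) -> None:
    _write_table(meta.reset_index(), path)


def read_citations(path) -> list[Publication]:
    records = json.loads(Path(path).read_text(encoding="utf-8"))
    return [
        Publication(title=r["title"], authors=tuple(r["authors"])) for r in records
    ]


def write_citations(citations: Sequence[Publication], path) -> None:
    payload = [{"title": p.title, "authors": list(p.authors)} for p in citations]
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_annotations(path) -> dict[str, list[tuple[str, str]]]:
    """signature_id TAB category TAB term rows → per-signature term lists."""
    annotations: dict[str, list[tuple[str, str]]] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 3:
            raise DataError(
                f"{path}:{lineno}: expected 'signature_id<TAB>category<TAB>term'"
            )
        sig_id, category, term = fields
        annotations.setdefault(sig_id, []).append((term, category))
    return annotations


def write_annotations(
    annotations: Mapping[str, Sequence[tuple[str, str]]], path
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for sig_id in sorted(annotations):
            for term, category in annotations[sig_id]:
                fh.write(f"{sig_id}\t{category}\t{term}\n")


def read_stoplist(path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    ]


# ---------------------------------------------------------------------------
# generic result tables

def _write_table(frame: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(str(c) for c in frame.columns) + "\n")
        for row in frame.itertuples(index=False):
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_results(results: pd.DataFrame, path) -> None:
    """Ranked match-result table as TSV with fixed column order."""
    _write_table(results[RESULT_COLUMNS], path)


def read_results(path) -> pd.DataFrame:
    frame = pd.read_csv(
        path, sep="\t", na_values=["NA"], keep_default_na=False,
        dtype={"tags": str},
    )
    if "direction_known" in frame.columns:
        frame["direction_known"] = frame["direction_known"].map(
            {"true": True, "false": False}
        )
    if "tags" in frame.columns:
        frame["tags"] = frame["tags"].fillna("")
    return frame


# ---------------------------------------------------------------------------
# the signature store

@dataclass
class SignatureMeta:
    """Per-signature manifest record."""

    dataset_id: str
    stat_kind: str
    direction_known: bool
    tags: list[tuple[str, str]] = field(default_factory=list)


def _safe_name(signature_id: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", signature_id)


class SignatureStore:
    """In-memory collection of ranked signatures with tags and citations.

    On disk: one RNK file per signature, a JSON manifest mapping each
    signature to its RNK file, statistic kind, comparison-direction flag,
    source dataset, tag sidecar and citation sidecar; an annotations TSV;
    and one citation JSON per dataset.
    """

    def __init__(self) -> None:
        self._signatures: dict[str, RankedSignature] = {}
        self._meta: dict[str, SignatureMeta] = {}
        self._citations: dict[str, list[Publication]] = {}

    def __len__(self) -> int:
        return len(self._signatures)

    def signature_ids(self) -> list[str]:
        return list(self._signatures)

    def get(self, signature_id: str) -> RankedSignature:
        return self._signatures[signature_id]

    def meta(self, signature_id: str) -> SignatureMeta:
        return self._meta[signature_id]

    def citations_by_dataset(self) -> dict[str, list[Publication]]:
        return dict(self._citations)

    def annotations(self) -> dict[str, list[tuple[str, str]]]:
        return {s: list(m.tags) for s, m in self._meta.items() if m.tags}

    def add(
        self,
        signature: RankedSignature,
        dataset_id: str,
        *,
        tags: Sequence[tuple[str, str]] = (),
        citations: Sequence[Publication] | None = None,
    ) -> None:
        if signature.signature_id in self._signatures:
            raise DataError(f"duplicate signature id {signature.signature_id}")
        self._signatures[signature.signature_id] = signature
        self._meta[signature.signature_id] = SignatureMeta(
            dataset_id=dataset_id,
            stat_kind=signature.stat_kind,
            direction_known=signature.direction_known,
            tags=list(tags),
        )
        if citations is not None:
            self._citations[dataset_id] = list(citations)

    def set_tags(
        self, signature_id: str, tags: Sequence[tuple[str, str]]
    ) -> None:
        self._meta[signature_id].tags = list(tags)

    # -- persistence --------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "citations").mkdir(exist_ok=True)
        records = []
        used: set[str] = set()
        for sig_id in sorted(self._signatures):
            base = _safe_name(sig_id)
            fname = f"{base}.rnk"
            k = 1
            while fname in used:
                fname = f"{base}.{k}.rnk"
                k += 1
            used.add(fname)
            write_rnk(self._signatures[sig_id], directory / fname)
            meta = self._meta[sig_id]
            cit_file = (
                f"citations/{_safe_name(meta.dataset_id)}.json"
                if meta.dataset_id in self._citations
                else None
            )
            records.append({
                "signature_id": sig_id,
                "file": fname,
                "stat_kind": meta.stat_kind,
                "direction_known": meta.direction_known,
                "dataset_id": meta.dataset_id,
                "tags_file": ANNOTATIONS_NAME if meta.tags else None,
                "citations_file": cit_file,
            })
        for ds_id, pubs in sorted(self._citations.items()):
            write_citations(
                pubs, directory / "citations" / f"{_safe_name(ds_id)}.json"
            )
        write_annotations(self.annotations(), directory / ANNOTATIONS_NAME)
        (directory / MANIFEST_NAME).write_text(
            json.dumps({"signatures": records}, indent=2) + "\n",
            encoding="utf-8",
        )

    @classmethod
    def load(cls, directory) -> "SignatureStore":
        directory = Path(directory)
        manifest_path = directory / MANIFEST_NAME
        if not manifest_path.exists():
            raise DataError(f"{directory}: no {MANIFEST_NAME} — not a store")
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
        annotations: dict[str, list[tuple[str, str]]] = {}
        ann_path = directory / ANNOTATIONS_NAME
        if ann_path.exists():
            annotations = read_annotations(ann_path)
        store = cls()
        for record in manifest["signatures"]:
            entries = read_rnk(directory / record["file"])
            signature = RankedSignature(
                signature_id=record["signature_id"],
                genes=tuple(g for g, _ in entries),
                stats=np.array([s for _, s in entries]),
                stat_kind=record["stat_kind"],
                direction_known=record["direction_known"],
            )
            citations = None
            if record.get("citations_file"):
                ds_id = record["dataset_id"]
                if ds_id not in store._citations:
                    citations = read_citations(directory / record["citations_file"])
            store.add(
                signature,
                record["dataset_id"],
                tags=annotations.get(record["signature_id"], []),
                citations=citations,
            )
        return store
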