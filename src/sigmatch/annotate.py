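"""Drug/disease term aggregation and expert-author scoring over match results.

Signatures carry precomputed drug- and disease-related terms (sidecar
annotation files; term extraction itself is outside this package).  Given a
ranked result table, this module filters terms through a stoplist,
aggregates them into count tables, derives drug–disease co-occurrence edges,
and scores expert authors: an author gets one point per matched signature
whose source dataset cites at least one of their papers.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .signatures import DataError, Publication

CATEGORIES = ("drug", "disease")


def filter_terms(
    terms: Sequence[str], stoplist: Iterable[str]
) -> list[str]:
    """Remove stoplisted terms (case-insensitive exact match), keeping order."""
    stop = {t.strip().lower() for t in stoplist}
    return [t for t in terms if t.strip().lower() not in stop]


def filter_annotations(
    annotations: Mapping[str, Sequence[tuple[str, str]]],
    stoplist: Iterable[str],
) -> dict[str, list[tuple[str, str]]]:
    """Apply the stoplist to every signature's (term, category) list."""
    stop = {t.strip().lower() for t in stoplist}
    return {
        sig: [(t, c) for t, c in pairs if t.strip().lower() not in stop]
        for sig, pairs in annotations.items()
    }


def select_matched(
    results: pd.DataFrame, *, q_max: float = 0.05, top_n: int = 200
) -> pd.DataFrame:
    """Rows counted as 'matched' for aggregation: significant or top-ranked.

    The union of rows with q_value <= ``q_max`` and the ``top_n`` best-scoring
    rows (the table is already ranked), preserving the ranking order.
    """
    if results.empty:
        return results
    keep = (results["q_value"] <= q_max) | (results.index < top_n)
    return results[keep]


def aggregate_terms(
    results: pd.DataFrame,
    annotations: Mapping[str, Sequence[tuple[str, str]]],
    category: str,
    *,
    top_n_by_score: int = 30,
    min_count: int = 4,
) -> pd.DataFrame:
    """Count one category's terms over a ranked result table.

    Reported terms are the union of (a) terms tagging the ``top_n_by_score``
    best results and (b) terms appearing at least ``min_count`` times over
    all results; counts are always computed over all results.  Columns:
    term, count, best_score, best_rank (1-based rank of the best result
    carrying the term); sorted by count descending, term ascending.
    """
    if category not in CATEGORIES:
        raise DataError(f"category must be one of {CATEGORIES}, got {category!r}")
    columns = ["term", "count", "best_score", "best_rank"]
    if results.empty:
        return pd.DataFrame(columns=columns)
    counts: Counter[str] = Counter()
    best_score: dict[str, float] = {}
    best_rank: dict[str, int] = {}
    top_terms: set[str] = set()
    for rank, row in enumerate(results.itertuples(index=False), start=1):
        terms = [
            t for t, c in annotations.get(row.signature_id, ()) if c == category
        ]
        for term in terms:
            counts[term] += 1
            if term not in best_rank:
                best_rank[term] = rank
                best_score[term] = float(row.score)
            if rank <= top_n_by_score:
                top_terms.add(term)
    keep = top_terms | {t for t, n in counts.items() if n >= min_count}
    rows = [
        {
            "term": t,
            "count": counts[t],
            "best_score": best_score[t],
            "best_rank": best_rank[t],
        }
        for t in keep
    ]
    table = pd.DataFrame(rows, columns=columns)
    return table.sort_values(
        ["count", "term"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def drug_disease_edges(
    results: pd.DataFrame,
    annotations: Mapping[str, Sequence[tuple[str, str]]],
) -> pd.DataFrame:
    """Drug–disease pairs co-tagging the same matched signature.

    Edge weight is the number of matched signatures tagged with both terms.
    Columns: drug, disease, weight; sorted weight descending, then terms.
    """
    weights: Counter[tuple[str, str]] = Counter()
    if not results.empty:
        for row in results.itertuples(index=False):
            pairs = annotations.get(row.signature_id, ())
            drugs = sorted({t for t, c in pairs if c == "drug"})
            diseases = sorted({t for t, c in pairs if c == "disease"})
            for drug in drugs:
                for disease in diseases:
                    weights[(drug, disease)] += 1
    table = pd.DataFrame(
        [
            {"drug": d, "disease": s, "weight": w}
            for (d, s), w in weights.items()
        ],
        columns=["drug", "disease", "weight"],
    )
    return table.sort_values(
        ["weight", "drug", "disease"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)


def normalize_author(name: str) -> str:
    """Case-folded 'surname initials' form: 'Doe, Jane A.' -> 'doe ja'.

    Accepts 'Surname, Given ...' or 'Given ... Surname'; no attempt is made
    to disambiguate homonyms.
    """
    name = name.strip()
    if not name:
        raise DataError("empty author name")
    if "," in name:
        surname, _, given = name.partition(",")
    else:
        parts = name.split()
        surname, given = parts[-1], " ".join(parts[:-1])
    initials = "".join(w[0] for w in given.replace(".", " ").split() if w)
    surname = surname.strip().lower()
    return f"{surname} {initials.lower()}".strip()


def expert_scores(
    results: pd.DataFrame,
    citations_by_dataset: Mapping[str, Sequence[Publication]],
) -> pd.DataFrame:
    """Score authors by how many matched signatures cite their papers.

    Each matched signature contributes at most one point per author, even
    when its dataset cites several papers sharing that author; a score of N
    means the author was involved in the experiments behind N signatures
    similar to the query phenotype.  Columns: author, score; sorted score
    descending, author ascending.
    """
    scores: Counter[str] = Counter()
    if not results.empty:
        for row in results.itertuples(index=False):
            pubs = citations_by_dataset.get(row.dataset_id, ())
            authors = {
                normalize_author(a) for pub in pubs for a in pub.authors
            }
            for author in authors:
                scores[author] += 1
    table = pd.DataFrame(
        [{"author": a, "score": n} for a, n in scores.items()],
        columns=["author", "score"],
    )
    if not table.empty:
        table["score"] = table["score"].astype(int)
    return table.sort_values(
        ["score", "author"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
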