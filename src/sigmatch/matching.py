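"""Query scoring: weighted KS-like enrichment, permutation p-values, FDR.

A query phenotype is a pair of disjoint up-/down-regulated gene sets.  Each
ranked signature is scored by where the query genes concentrate: the up-set
should sit near the top and the down-set near the bottom of a concordant
signature.  The enrichment score of a set is the signed maximum deviation of
a hit/miss running sum walked down the signature — a hit at position i adds
w_i / N_R (w_i = |stat_i| when weighted, 1 otherwise; N_R the sum of hit
weights) and a miss subtracts 1 / (N - n_hits).  The combined score
c = (es_up - es_down) / 2 is nulled to 0 when both enrichment scores share a
strict sign (a discordant match, Connectivity-Map convention), then mapped
affinely onto [0, 100]: direct mode 50·(1 + c) rewards signatures mimicking
the query, inverse mode 50·(1 - c) rewards signatures opposing it — the
drug-repositioning direction.  Significance comes from a permutation test
over random same-size query surrogates, with Benjamini–Hochberg adjustment
across the signatures of a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .signatures import DataError, RankedSignature

if TYPE_CHECKING:  # pragma: no cover
    from .io import SignatureStore

logger = logging.getLogger(__name__)


class NoOverlapError(DataError):
    """The gene set shares no genes with the signature."""


@dataclass(frozen=True)
class QueryGeneSet:
    """The user phenotype: disjoint up- and down-regulated gene symbol sets."""

    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise DataError(
                f"up/down lists overlap: {sorted(self.up & self.down)[:5]}"
            )
        if not (self.up or self.down):
            raise DataError("query has no genes in either list")

    @classmethod
    def from_lists(
        cls, up: Iterable[str] = (), down: Iterable[str] = ()
    ) -> "QueryGeneSet":
        return cls(
            up=frozenset(g.upper() for g in up),
            down=frozenset(g.upper() for g in down),
        )

    def swapped(self) -> "QueryGeneSet":
        return QueryGeneSet(up=self.down, down=self.up)


def ks_enrichment(
    signature: RankedSignature,
    genes: Iterable[str],
    *,
    weighted: bool = True,
) -> float:
    """Weighted KS-like enrichment score of a gene set in a ranked signature.

    Returns the running-sum value at its maximum absolute deviation, in
    [-1, 1]: +1 when all hits sit at the very top, -1 at the very bottom.
    Raises :class:`NoOverlapError` with zero hits and :class:`DataError`
    when every signature gene is a hit (the miss denominator vanishes).
    If all hit statistics are zero in weighted mode, falls back to
    unweighted hits.
    """
    gene_set = {g.upper() for g in genes}
    hits = np.fromiter(
        (g in gene_set for g in signature.genes), dtype=bool, count=len(signature)
    )
    return _es_from_hits(signature.stats, hits, weighted=weighted)


def _es_from_hits(stats: np.ndarray, hits: np.ndarray, *, weighted: bool) -> float:
    n = len(stats)
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise NoOverlapError("gene set does not overlap the signature")
    if n_hits == n:
        raise DataError("gene set covers the whole signature: no misses to walk")
    # running sum as (cumulative hit weight)/N_R - (cumulative misses)/(N - n_hits):
    # algebraically the step walk, but exact (+/-1) when hits pack an extreme
    if weighted:
        w = np.abs(stats)
        hit_cum = np.cumsum(np.where(hits, w, 0.0))
        n_r = hit_cum[-1]
        if n_r == 0:
            return _es_from_hits(stats, hits, weighted=False)
    else:
        hit_cum = np.cumsum(hits.astype(float))
        n_r = float(n_hits)
    miss_cum = np.cumsum(~hits)
    running = hit_cum / n_r - miss_cum / float(n - n_hits)
    return float(running[_extreme_index(np.abs(running))])


def _extreme_index(abs_running: np.ndarray) -> int | np.ndarray:
    """Earliest position within 1e-12 of the maximum absolute deviation.

    The running sum can attain +a and -a exactly (unweighted mode walks
    rational steps), where raw argmax would let float noise pick the sign;
    a toleranced earliest-position rule makes the tie-break deterministic.
    """
    if abs_running.ndim == 1:
        return int(np.argmax(abs_running >= abs_running.max() - 1e-12))
    peaks = abs_running.max(axis=1, keepdims=True)
    return np.argmax(abs_running >= peaks - 1e-12, axis=1)


def combined_score(
    es_up: float | None,
    es_down: float | None,
    *,
    nulling: bool = True,
) -> float:
    """Merge up- and down-set enrichment scores into one statistic in [-1, 1].

    A missing score (that list had no overlap) counts as 0.  When both
    scores carry the same strict sign the query halves disagree about the
    signature's direction and the combined score is nulled to 0; pass
    ``nulling=False`` to keep the raw average ``(es_up - es_down) / 2``.
    """
    eu = 0.0 if es_up is None else float(es_up)
    ed = 0.0 if es_down is None else float(es_down)
    if nulling and eu * ed > 0:
        return 0.0
    return (eu - ed) / 2.0


def normalize_score(c: float, mode: str = "direct") -> float:
    """Affine map of the combined score onto the 0–100 similarity scale.

    Direct mode 50·(1 + c): 100 means the signature mimics the query.
    Inverse mode 50·(1 - c): 100 means it opposes the query (a candidate
    phenotype-reverting perturbation).
    """
    if not -1.0 - 1e-9 <= c <= 1.0 + 1e-9:
        raise ValueError(f"combined score {c} outside [-1, 1]")
    c = min(1.0, max(-1.0, c))
    if mode == "direct":
        return 50.0 * (1.0 + c)
    if mode == "inverse":
        return 50.0 * (1.0 - c)
    raise ValueError(f"mode must be 'direct' or 'inverse', got {mode!r}")


def _batch_es(
    stats: np.ndarray, positions: np.ndarray, *, weighted: bool
) -> np.ndarray:
    """Enrichment scores for B surrogate hit-position sets at once.

    ``positions`` is (B, k) with distinct column indices per row.  Returns a
    length-B array of signed max-deviation scores.
    """
    b, k = positions.shape
    n = len(stats)
    if k == 0:
        return np.zeros(b)
    rows = np.arange(b)[:, None]
    hit = np.zeros((b, n), dtype=bool)
    hit[rows, positions] = True
    if weighted:
        w = np.abs(stats)
        hit_cum = np.cumsum(np.where(hit, w[None, :], 0.0), axis=1)
        n_r = hit_cum[:, -1].copy()
        zero = n_r == 0
        if np.any(zero):  # degenerate all-zero weights: unweighted fallback
            hit_cum[zero] = np.cumsum(hit[zero].astype(float), axis=1)
            n_r[zero] = k
    else:
        hit_cum = np.cumsum(hit.astype(float), axis=1)
        n_r = np.full(b, float(k))
    miss_cum = np.cumsum(~hit, axis=1)
    running = hit_cum / n_r[:, None] - miss_cum / float(n - k)
    idx = _extreme_index(np.abs(running))
    return running[rows[:, 0], idx]


def _null_abs_combined(
    stats: np.ndarray,
    k_up: int,
    k_down: int,
    b: int,
    rng: np.random.Generator,
    *,
    weighted: bool,
    nulling: bool,
) -> np.ndarray:
    """|c| under B random disjoint query surrogates of matched sizes.

    The surrogate pair is drawn in canonical order (larger set first):
    |c| only depends on the unordered pair of sets, so the null — and hence
    the p-value — is invariant under swapping the query's up/down lists.
    """
    n = len(stats)
    k1, k2 = max(k_up, k_down), min(k_up, k_down)
    if k1 + k2 >= n:
        raise DataError(
            f"signature of {n} genes too small for disjoint surrogate sets "
            f"of sizes {k_up} and {k_down}"
        )
    order = np.argsort(rng.random((b, n)), axis=1)
    es1 = _batch_es(stats, order[:, :k1], weighted=weighted)
    es2 = _batch_es(stats, order[:, k1:k1 + k2], weighted=weighted)
    c = (es1 - es2) / 2.0
    if nulling:
        c = np.where(es1 * es2 > 0, 0.0, c)
    return np.abs(c)


def permutation_pvalue(
    signature: RankedSignature,
    query: QueryGeneSet,
    b: int = 1000,
    seed: int | np.random.Generator | None = None,
    *,
    weighted: bool = True,
    nulling: bool = True,
) -> float:
    """Permutation p-value of the query's combined score against a signature.

    Draws ``b`` random query surrogates — disjoint gene sets of the observed
    overlap sizes, sampled uniformly without replacement from the signature's
    gene universe — and reports the add-one-corrected fraction achieving
    ``|c|`` at least as extreme: ``p = (1 + #{|c_b| >= |c_obs|}) / (b + 1)``.
    """
    if b < 1:
        raise ValueError("permutation count must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sig_genes = set(signature.genes)
    k_up = len(query.up & sig_genes)
    k_down = len(query.down & sig_genes)
    if k_up + k_down == 0:
        raise NoOverlapError("query does not overlap the signature")
    es_up = ks_enrichment(signature, query.up, weighted=weighted) if k_up else None
    es_down = ks_enrichment(signature, query.down, weighted=weighted) if k_down else None
    c_obs = combined_score(es_up, es_down, nulling=nulling)
    null = _null_abs_combined(
        signature.stats, k_up, k_down, b, rng, weighted=weighted, nulling=nulling
    )
    return float((1 + int(np.sum(null >= abs(c_obs)))) / (b + 1))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


RESULT_COLUMNS = [
    "signature_id", "dataset_id", "es_up", "es_down", "combined", "score",
    "p_value", "q_value", "n_hits_up", "n_hits_down", "direction_known", "tags",
]


def query_database(
    store: "SignatureStore",
    query: QueryGeneSet,
    *,
    mode: str = "direct",
    weighted: bool = True,
    b: int = 1000,
    seed: int | None = None,
    min_overlap: int = 1,
    nulling: bool = True,
) -> pd.DataFrame:
    """Score a query against every signature in a store; ranked result table.

    Signatures with fewer than ``min_overlap`` total query hits are dropped.
    Rows are sorted by score descending, ties by p-value ascending then
    signature_id; q-values are Benjamini–Hochberg over all retained rows.
    Identical seed and inputs give a byte-identical table.
    """
    if len(store) == 0:
        raise DataError("signature store is empty")
    if mode not in ("direct", "inverse"):
        raise ValueError(f"mode must be 'direct' or 'inverse', got {mode!r}")
    sig_ids = sorted(store.signature_ids())
    seeds = np.random.SeedSequence(seed).spawn(len(sig_ids))
    rows = []
    for sig_id, child in zip(sig_ids, seeds):
        sig = store.get(sig_id)
        sig_genes = set(sig.genes)
        k_up = len(query.up & sig_genes)
        k_down = len(query.down & sig_genes)
        if k_up + k_down < max(min_overlap, 1):
            continue
        try:
            es_up = (
                ks_enrichment(sig, query.up, weighted=weighted) if k_up else None
            )
            es_down = (
                ks_enrichment(sig, query.down, weighted=weighted) if k_down else None
            )
            c = combined_score(es_up, es_down, nulling=nulling)
            rng = np.random.default_rng(child)
            null = _null_abs_combined(
                sig.stats, k_up, k_down, b, rng,
                weighted=weighted, nulling=nulling,
            )
        except DataError as exc:
            logger.warning("%s: skipped (%s)", sig_id, exc)
            continue
        p = float((1 + int(np.sum(null >= abs(c)))) / (b + 1))
        meta = store.meta(sig_id)
        rows.append({
            "signature_id": sig_id,
            "dataset_id": meta.dataset_id,
            "es_up": np.nan if es_up is None else es_up,
            "es_down": np.nan if es_down is None else es_down,
            "combined": c,
            "score": normalize_score(c, mode),
            "p_value": p,
            "q_value": np.nan,
            "n_hits_up": k_up,
            "n_hits_down": k_down,
            "direction_known": meta.direction_known,
            "tags": ";".join(f"{cat}:{term}" for term, cat in meta.tags),
        })
    if not rows:
        logger.warning("no signature overlaps the query")
        return pd.DataFrame(columns=RESULT_COLUMNS)
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    table = table.sort_values(
        ["score", "p_value", "signature_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return table
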