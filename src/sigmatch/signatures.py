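"""Ranked gene-expression signatures from class comparisons.

A signature is an ordered gene list from one two-class comparison of an
expression dataset, sorted by a differential-expression statistic with the
most up-regulated gene first.  Every pair of classes of every experimental
variable yields one comparison; the reference class is a recognized control
label, the earlier time point of a time series, or — when neither applies —
the lexicographically smaller label, in which case the direction of the
comparison is arbitrary and flagged as such.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Labels recognized as a reference/control class (case-insensitive search).
DEFAULT_CONTROL_PATTERNS: tuple[str, ...] = (
    "control",
    "untreated",
    "vehicle",
    "dmso",
    "wild.?type",
    "baseline",
    "normal",
    "none",
    "mock",
)

#: Variable names treated as time series when both class labels parse as times.
DEFAULT_TIME_PATTERNS: tuple[str, ...] = ("time", "hour", "day", "week", "age")

_TIME_LABEL_RE = re.compile(
    r"^\s*(\d+(?:\.\d+)?)\s*"
    r"(s|sec|seconds?|m|min|minutes?|h|hr|hours?|d|days?|w|wk|weeks?)?\s*$",
    re.IGNORECASE,
)

_TIME_UNIT_MINUTES = {
    "s": 1 / 60.0, "sec": 1 / 60.0, "second": 1 / 60.0, "seconds": 1 / 60.0,
    "m": 1.0, "min": 1.0, "minute": 1.0, "minutes": 1.0,
    "h": 60.0, "hr": 60.0, "hour": 60.0, "hours": 60.0,
    "d": 1440.0, "day": 1440.0, "days": 1440.0,
    "w": 10080.0, "wk": 10080.0, "week": 10080.0, "weeks": 10080.0,
}


class DataError(Exception):
    """Invalid or inconsistent input data."""


@dataclass(frozen=True)
class Publication:
    """One cited paper: title and its ordered author list."""

    title: str
    authors: tuple[str, ...]


@dataclass
class ExpressionDataset:
    """Genes x samples log-scale expression with per-sample class labels.

    ``matrix`` rows are gene symbols, columns sample identifiers;
    ``sample_meta`` rows are samples, columns experimental variables whose
    values are class labels.  ``citations`` holds the publications listed by
    the dataset's source record, used for expert scoring downstream.
    """

    dataset_id: str
    matrix: pd.DataFrame
    sample_meta: pd.DataFrame
    citations: list[Publication] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.matrix.shape[0] < 1 or self.matrix.shape[1] < 2:
            raise DataError(
                f"{self.dataset_id}: expression matrix needs >=1 gene and >=2 "
                f"samples, got {self.matrix.shape}"
            )
        self.matrix.index = self.matrix.index.astype(str).str.upper()
        if self.matrix.index.duplicated().any():
            dups = self.matrix.index[self.matrix.index.duplicated()].unique()
            raise DataError(
                f"{self.dataset_id}: duplicate gene symbols after "
                f"normalization: {list(dups)[:5]}"
            )
        missing = set(self.matrix.columns) - set(self.sample_meta.index)
        if missing:
            raise DataError(
                f"{self.dataset_id}: samples absent from metadata: "
                f"{sorted(missing)[:5]}"
            )


@dataclass(frozen=True)
class ComparisonSpec:
    """One two-class comparison: ``class_b`` (test) vs ``class_a`` (reference)."""

    variable: str
    class_a: str
    class_b: str
    direction_known: bool

    def __post_init__(self) -> None:
        if self.class_a == self.class_b:
            raise ValueError("comparison classes must differ")


@dataclass
class RankedSignature:
    """Ordered (gene, stat) list for one comparison, most up-regulated first."""

    signature_id: str
    genes: tuple[str, ...]
    stats: np.ndarray
    stat_kind: str  # "t" or "fold_change"
    direction_known: bool

    def __post_init__(self) -> None:
        self.stats = np.asarray(self.stats, dtype=float)
        if len(self.genes) != len(self.stats):
            raise ValueError("genes and stats length mismatch")
        if len(self.genes) < 2:
            raise DataError(f"{self.signature_id}: signature shorter than 2 genes")
        if len(set(self.genes)) != len(self.genes):
            raise DataError(f"{self.signature_id}: duplicate genes in signature")
        if np.any(np.diff(self.stats) > 0):
            raise DataError(f"{self.signature_id}: stats not sorted descending")
        if self.stat_kind not in ("t", "fold_change"):
            raise ValueError(f"unknown stat_kind {self.stat_kind!r}")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def entries(self) -> list[tuple[str, float]]:
        return list(zip(self.genes, (float(s) for s in self.stats)))

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


def _trigamma_inverse(x: float, iters: int = 50) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, fast)."""
    from scipy.special import polygamma

    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(iters):
        tri = float(polygamma(1, y))
        step = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += step
        if abs(step) < 1e-10 * y:
            break
    return y


def _moderate_variances(s2: np.ndarray, df: int) -> np.ndarray:
    """Empirical-Bayes posterior gene variances (scaled-inv-chi^2 prior).

    Fits the prior (d0, s0^2) by matching the moments of the log sample
    variances, then returns (d0*s0^2 + df*s2) / (d0 + df) — the shrinkage
    that tames the heavy tails of the t statistic at small replicate counts.
    Zero sample variances are excluded from the fit but still shrunk.
    """
    from scipy.special import polygamma

    pos = s2 > 0
    e = np.log(s2[pos]) - float(polygamma(0, df / 2)) + np.log(df / 2)
    evar = np.var(e, ddof=1) - float(polygamma(1, df / 2))
    if evar <= 0:  # sample variances more concentrated than chi^2: full shrink
        return np.full_like(s2, np.exp(np.mean(e)))
    d0 = 2.0 * _trigamma_inverse(evar)
    s02 = np.exp(np.mean(e) + float(polygamma(0, d0 / 2)) - np.log(d0 / 2))
    return (d0 * s02 + df * s2) / (d0 + df)


def compute_ranking_statistic(
    values_a: np.ndarray,
    values_b: np.ndarray,
    *,
    method: str = "moderated",
) -> tuple[np.ndarray, str]:
    """Per-gene ranking statistic of the test class ``b`` against reference ``a``.

    With >=2 replicates in both classes this is a two-sample t-statistic of
    (b - a); with fewer replicates the difference of class means (a log
    fold-change, since values are log scale).  Positive values mean
    up-regulated in ``b``.

    ``method`` picks the variance estimate: ``"moderated"`` (default)
    shrinks per-gene variances toward an empirical-Bayes prior fitted
    across genes — with 2–3 replicates the raw per-gene variance is so
    noisy that ordinary t ranks are dominated by lucky small variances;
    ``"pooled"`` is the ordinary pooled-variance t; ``"welch"`` drops the
    equal-variance assumption.  Moderation needs enough genes to fit the
    prior and falls back to pooled below 10 genes.

    Genes whose variance estimate is zero but whose means differ fall back
    to the mean difference (logged); genes constant and equal in both
    classes get statistic 0.  Accepts 1-D per-gene vectors or 2-D
    (genes x replicates) arrays; returns the statistic array and its kind,
    ``"t"`` or ``"fold_change"``.
    """
    if method not in ("moderated", "pooled", "welch"):
        raise ValueError(f"unknown ranking method {method!r}")
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    na, nb = a.shape[1], b.shape[1]
    if na == 0 or nb == 0:
        raise DataError("both classes need at least one sample")
    diff = b.mean(axis=1) - a.mean(axis=1)
    if na < 2 or nb < 2:
        return np.squeeze(diff), "fold_change"
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    if method == "welch":
        se = np.sqrt(va / na + vb / nb)
    else:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        if method == "moderated" and int(np.sum(sp2 > 0)) >= 10:
            sp2 = _moderate_variances(sp2, df)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    degenerate = se == 0
    if np.any(degenerate):
        n_fallback = int(np.sum(degenerate & (diff != 0)))
        if n_fallback:
            logger.warning(
                "%d gene(s) with zero variance and nonzero difference: "
                "mean-difference fallback (mixed statistic kinds)", n_fallback,
            )
        t = np.where(degenerate, diff, t)
    return np.squeeze(t), "t"


def _parse_time_label(label: str) -> float | None:
    m = _TIME_LABEL_RE.match(label)
    if m is None:
        return None
    value = float(m.group(1))
    unit = (m.group(2) or "").lower()
    return value * _TIME_UNIT_MINUTES.get(unit, 1.0)


def _matches_any(text: str, patterns: Sequence[str]) -> bool:
    return any(re.search(p, text, re.IGNORECASE) for p in patterns)


def enumerate_comparisons(
    sample_meta: pd.DataFrame,
    *,
    control_patterns: Sequence[str] = DEFAULT_CONTROL_PATTERNS,
    time_patterns: Sequence[str] = DEFAULT_TIME_PATTERNS,
    max_classes: int = 10,
) -> list[ComparisonSpec]:
    """Enumerate every unordered class pair within each experimental variable.

    The reference class of a pair is decided by, in order: a control-pattern
    match on exactly one label; time ordering when the variable looks like a
    time series and both labels parse as times; otherwise the
    lexicographically smaller label with ``direction_known=False``.
    Variables with fewer than 2 or more than ``max_classes`` classes are
    skipped (the latter with a warning).
    """
    specs: list[ComparisonSpec] = []
    for variable in sample_meta.columns:
        labels = sample_meta[variable].dropna().astype(str)
        classes = sorted(labels.unique())
        if len(classes) < 2:
            continue
        if len(classes) > max_classes:
            logger.warning(
                "variable %r has %d classes (> %d): skipped",
                variable, len(classes), max_classes,
            )
            continue
        is_time_var = _matches_any(str(variable), time_patterns)
        for i in range(len(classes)):
            for j in range(i + 1, len(classes)):
                x, y = classes[i], classes[j]
                ctl_x = _matches_any(x, control_patterns)
                ctl_y = _matches_any(y, control_patterns)
                if ctl_x != ctl_y:
                    ref, test = (x, y) if ctl_x else (y, x)
                    known = True
                else:
                    tx = _parse_time_label(x) if is_time_var else None
                    ty = _parse_time_label(y) if is_time_var else None
                    if tx is not None and ty is not None and tx != ty:
                        ref, test = (x, y) if tx < ty else (y, x)
                        known = True
                    else:
                        ref, test = x, y  # classes sorted, so x < y
                        known = False
                specs.append(ComparisonSpec(variable, ref, test, known))
    return specs


def collapse_duplicates(
    entries: Iterable[tuple[str, float]],
) -> list[tuple[str, float]]:
    """Collapse duplicate gene symbols (case-folded to upper) to one entry.

    Among duplicates the entry with the largest absolute statistic wins;
    ties break toward the larger (more up-regulated) statistic.  First-seen
    order of the surviving symbols is preserved.
    """
    best: dict[str, float] = {}
    order: list[str] = []
    for gene, stat in entries:
        g = gene.upper()
        s = float(stat)
        if g not in best:
            best[g] = s
            order.append(g)
        else:
            cur = best[g]
            if (abs(s), s) > (abs(cur), cur):
                best[g] = s
    return [(g, best[g]) for g in order]


def build_signatures(
    dataset: ExpressionDataset,
    *,
    control_patterns: Sequence[str] = DEFAULT_CONTROL_PATTERNS,
    time_patterns: Sequence[str] = DEFAULT_TIME_PATTERNS,
    max_classes: int = 10,
    method: str = "moderated",
) -> list[RankedSignature]:
    """Build one ranked signature per enumerated class comparison.

    Genes observed (non-missing) in only one class of a comparison are
    excluded with a warning; comparisons left with fewer than 2 genes are
    skipped.  Entries are sorted by statistic descending, ties broken by
    gene symbol for reproducibility.
    """
    meta = dataset.sample_meta.loc[list(dataset.matrix.columns)]
    specs = enumerate_comparisons(
        meta,
        control_patterns=control_patterns,
        time_patterns=time_patterns,
        max_classes=max_classes,
    )
    signatures: list[RankedSignature] = []
    for spec in specs:
        labels = meta[spec.variable].astype(str)
        cols_a = labels.index[labels == spec.class_a]
        cols_b = labels.index[labels == spec.class_b]
        sub_a = dataset.matrix[cols_a]
        sub_b = dataset.matrix[cols_b]
        # a gene must be observed in both classes to be comparable
        ok = sub_a.notna().any(axis=1) & sub_b.notna().any(axis=1)
        n_dropped = int((~ok).sum())
        if n_dropped:
            logger.warning(
                "%s %s: %d gene(s) measured in one class only, excluded",
                dataset.dataset_id, spec.variable, n_dropped,
            )
        sub_a, sub_b = sub_a[ok], sub_b[ok]
        if sub_a.shape[0] == 0:
            continue
        stats, kind = compute_ranking_statistic(
            sub_a.to_numpy(), sub_b.to_numpy(), method=method
        )
        entries = collapse_duplicates(zip(sub_a.index, np.atleast_1d(stats)))
        if len(entries) < 2:
            logger.warning(
                "%s %s %s_vs_%s: fewer than 2 genes, skipped",
                dataset.dataset_id, spec.variable, spec.class_b, spec.class_a,
            )
            continue
        genes = np.array([g for g, _ in entries])
        vals = np.array([s for _, s in entries])
        # stat descending, gene ascending on ties — lexsort keys in reverse order
        order = np.lexsort((genes, -vals))
        sig_id = (
            f"{dataset.dataset_id}:{spec.variable}:"
            f"{spec.class_b}_vs_{spec.class_a}"
        )
        signatures.append(
            RankedSignature(
                signature_id=sig_id,
                genes=tuple(genes[order]),
                stats=vals[order],
                stat_kind=kind,
                direction_known=spec.direction_known,
            )
        )
    return signatures
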