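"""Shared test helpers: independent brute-force oracles and tiny builders.

The oracles here deliberately re-derive results by naive enumeration so the
vectorized implementations are checked against an independent path.
"""

from __future__ import annotations

import numpy as np

from sigmatch.signatures import RankedSignature


def naive_running_sum_es(stats, hit_mask, weighted: bool) -> float:
    """O(N) pure-Python running-sum enrichment score.

    Walks the ranked list top to bottom: a hit adds w_i/N_R (w_i = |stat_i|
    weighted, 1 unweighted; N_R the sum of hit weights), a miss subtracts
    1/(N - n_hits); returns the running-sum value of maximum absolute
    deviation (earliest position within 1e-12 of the peak).
    """
    n = len(stats)
    n_hits = sum(bool(h) for h in hit_mask)
    assert 0 < n_hits < n
    if weighted:
        n_r = sum(abs(float(stats[i])) for i in range(n) if hit_mask[i])
        if n_r == 0:
            return naive_running_sum_es(stats, hit_mask, weighted=False)
    run = 0.0
    values = []
    for i in range(n):
        if hit_mask[i]:
            run += (abs(float(stats[i])) / n_r) if weighted else 1.0 / n_hits
        else:
            run -= 1.0 / (n - n_hits)
        values.append(run)
    peak = max(abs(v) for v in values)
    # earliest position within 1e-12 of the peak (same tie rule as the library)
    for v in values:
        if abs(v) >= peak - 1e-12:
            return v


def naive_bh(p_values) -> list[float]:
    """Hand Benjamini–Hochberg step-up with monotonicity enforcement."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    q = [0.0] * m
    running_min = 1.0
    for rank_from_end in range(m, 0, -1):
        i = order[rank_from_end - 1]
        running_min = min(running_min, p_values[i] * m / rank_from_end)
        q[i] = running_min
    return q


def random_signature(
    rng: np.random.Generator, n: int, sig_id: str = "SIG"
) -> RankedSignature:
    """Random ranked signature over genes g0..g{n-1}."""
    stats = np.sort(rng.normal(0.0, 2.0, size=n))[::-1]
    genes = tuple(rng.permutation([f"G{i:04d}" for i in range(n)]))
    return RankedSignature(
        signature_id=sig_id, genes=genes, stats=stats,
        stat_kind="t", direction_known=True,
    )
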