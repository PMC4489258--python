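"""Run configuration: every knob with a documented default, echoed to logs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

from .signatures import DEFAULT_CONTROL_PATTERNS, DEFAULT_TIME_PATTERNS


@dataclass
class RunConfig:
    """All tunable parameters of a signature-matching run.

    mode: 'direct' finds signatures mimicking the query, 'inverse' finds
        signatures opposing it (the drug-repositioning direction).
    weighted: weight running-sum hits by |stat| (unweighted hits otherwise).
    permutations: surrogate-query draws per signature for the p-value.
    min_overlap: minimum total query hits for a signature to be scored.
    nulling: zero the combined score when up- and down-set enrichment
        scores share a strict sign (discordant match).
    q_max / top_n_matched: a result row counts as 'matched' for term and
        expert aggregation when q_value <= q_max or it ranks in the top
        top_n_matched by score.
    top_n_by_score / min_count: term tables report terms tagging the best
        top_n_by_score rows plus terms seen at least min_count times.
    """

    mode: str = "direct"
    weighted: bool = True
    permutations: int = 1000
    seed: int | None = None
    min_overlap: int = 1
    nulling: bool = True
    stat_method: str = "moderated"
    max_classes: int = 10
    control_patterns: Sequence[str] = field(
        default_factory=lambda: list(DEFAULT_CONTROL_PATTERNS)
    )
    time_patterns: Sequence[str] = field(
        default_factory=lambda: list(DEFAULT_TIME_PATTERNS)
    )
    q_max: float = 0.05
    top_n_matched: int = 200
    top_n_by_score: int = 30
    min_count: int = 4
    min_support: int = 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def resolve_seed(self) -> int:
        """The configured seed, or one derived from the config hash."""
        if self.seed is not None:
            return int(self.seed)
        payload = json.dumps(
            {k: v for k, v in self.to_dict().items() if k != "seed"},
            sort_keys=True, default=str,
        )
        digest = hashlib.sha256(payload.encode()).digest()
        return int.from_bytes(digest[:4], "big") % (2**31)
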