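import numpy as np
import pytest

from sigmatch.matching import QueryGeneSet
from sigmatch.signatures import RankedSignature


@pytest.fixture
def toy_signature() -> RankedSignature:
    """Four-gene signature with symmetric statistics [2, 1, -1, -2]."""
    return RankedSignature(
        signature_id="toy:agent:treated_vs_control",
        genes=("A", "B", "C", "D"),
        stats=np.array([2.0, 1.0, -1.0, -2.0]),
        stat_kind="t",
        direction_known=True,
    )


@pytest.fixture
def small_query() -> QueryGeneSet:
    return QueryGeneSet.from_lists(
        up=[f"Q{i:03d}U" for i in range(10)],
        down=[f"Q{i:03d}D" for i in range(10)],
    )
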