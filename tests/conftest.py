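import numpy as np
import pytest

from ecgcascade.core import Segment
from ecgcascade.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def mini_cohort_config() -> CohortConfig:
    """Three short records: enough beats to segment, fast to generate."""
    return CohortConfig(n_subjects=3, duration_s=30.0, seed=42)


@pytest.fixture(scope="session")
def mini_cohort(mini_cohort_config):
    return generate_cohort(mini_cohort_config)


def make_segments(counts: dict[str, dict[int, int]], width: int = 8) -> list[Segment]:
    """Build dummy segments from a subject -> {label: count} table."""
    out = []
    for sid, labels in counts.items():
        for label, n in labels.items():
            for i in range(n):
                out.append(
                    Segment(subject_id=sid, record_id=sid, center_sample=1000 + i,
                            label=label, window=np.zeros(width))
                )
    return out
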