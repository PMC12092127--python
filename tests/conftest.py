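import numpy as np
import pytest

from abyssrange.alignment import Alignment
from abyssrange.records import OccurrenceRecord

BASES = "ACGT"


def random_alignment(n, L, seed, mask_fraction=0.0, localities=None):
    """Random alignment; optionally masks cells with gap/N/ambiguity codes."""
    rng = np.random.default_rng(seed)
    mat = rng.choice(list(BASES), size=(n, L))
    if mask_fraction > 0:
        mask = rng.random((n, L)) < mask_fraction
        fillers = rng.choice(list("-NRY"), size=(n, L))
        mat = np.where(mask, fillers, mat)
    ids = [f"s{i}" for i in range(n)]
    loc = None
    if localities:
        loc = {sid: localities[i % len(localities)] for i, sid in enumerate(ids)}
    return Alignment(ids=ids, matrix=mat.astype("U1"), locality=loc or {})


@pytest.fixture
def toy_alignment():
    return Alignment.from_sequences(
        [("a", "AAT"), ("b", "AAT"), ("c", "AAG"), ("d", "ACG")]
    )


@pytest.fixture
def toy_records():
    def rec(site, depth, basin="Pacific"):
        return OccurrenceRecord(
            site_id=site,
            feature_name="trench-A",
            basin=basin,
            latitude=-10.0,
            longitude=150.0,
            depth_m=depth,
            record_type="observation",
        )

    return [rec("siteA", 4000.0), rec("siteA", 5000.0), rec("siteB", 6000.0)]
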