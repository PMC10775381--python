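import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from surfhet.cohort import CohortTable
from surfhet.config import SchemaConfig


def build_cohort(rows, genomics=None, config=None):
    """Build a CohortTable from (pid, sid, bid, cid, site, {marker: h}) tuples."""
    config = config or SchemaConfig()
    recs = []
    for pid, sid, bid, cid, site, markers in rows:
        rec = {
            "patient_id": pid,
            "site_id": sid,
            "block_id": bid,
            "core_id": cid,
            "anatomic_site": site,
        }
        for m, h in markers.items():
            rec[config.hscore_column(m)] = float(h)
        recs.append(rec)
    g = None
    if genomics is not None:
        g = pd.DataFrame(genomics).set_index("patient_id")
    cohort = CohortTable(samples=pd.DataFrame(recs), config=config, genomics=g)
    cohort.validate()
    return cohort


def status_cohort(statuses_by_block, marker="TROP2", site="liver"):
    """Cohort whose binarized statuses per block are given directly.

    ``statuses_by_block``: {(pid, sid, bid): [True/False per core]}; True
    becomes H-score 150, False becomes 0.
    """
    rows = []
    for (pid, sid, bid), statuses in statuses_by_block.items():
        for i, s in enumerate(statuses):
            rows.append((pid, sid, bid, f"C{i + 1}", site, {marker: 150.0 if s else 0.0}))
    return build_cohort(rows)


@pytest.fixture
def tiny_cohort():
    return build_cohort(
        [
            ("P1", "S1", "B1", "C1", "liver", {"TROP2": 180, "PSMA": 40}),
            ("P1", "S1", "B1", "C2", "liver", {"TROP2": 10, "PSMA": 0}),
            ("P1", "S2", "B1", "C1", "lung", {"TROP2": 120, "PSMA": 25}),
            ("P2", "S1", "B1", "C1", "vertebral_bone", {"TROP2": 0, "PSMA": 0}),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
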