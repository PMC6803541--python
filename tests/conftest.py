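import numpy as np
import pandas as pd
import pytest

from oiassoc import reference
from oiassoc.cohort import PatientRecord


@pytest.fixture(scope="session")
def table1_counts() -> pd.DataFrame:
    """The published per-phenotype 2x2 counts in table-mode layout."""
    rows = [{"phenotype": phen, "gly_present": a, "gly_absent": b,
             "other_present": c, "other_absent": d}
            for phen, (a, b, c, d) in reference.PHENOTYPE_COUNTS.items()]
    return pd.DataFrame(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_record(pid="P1", effect="missense", hgvs_p="p.G100D", oi_type="unknown",
                sex="unknown", gene="COL1A1", phenotypes=None, **kw) -> PatientRecord:
    return PatientRecord(patient_id=pid, gene=gene, effect=effect, hgvs_p=hgvs_p,
                         oi_type=oi_type, sex=sex, phenotypes=phenotypes or {}, **kw)
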