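import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from drqpcr.design import default_design

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def paper_matrix():
    from drqpcr.qpcr_io import load_paper_call_matrix

    return load_paper_call_matrix()


@pytest.fixture()
def tiny_cq(design):
    """Minimal hand-written Cq table: one target gene + reference, one cell pair."""
    rows = []
    for treatment, cqs in (("water", [24.0, 25.0, 24.5]), ("dehydration", [22.0, 22.5, 21.5])):
        for rep, cq in enumerate(cqs, start=1):
            rows.append(("CaNAC16", "ILC482", "root", treatment, 2.0, rep, cq))
            rows.append(("IF4a", "ILC482", "root", treatment, 2.0, rep, 20.0))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "cultivar", "tissue", "treatment", "timepoint_h",
                 "bio_replicate", "cq"],
    )
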