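import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # makes tests/oracle.py importable

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def tiny_proteins():
    from phosforest.io import ProteinRecord

    return [
        ProteinRecord("p1", "MVKELRTA"),
        ProteinRecord("p2", "AAASAAAAYT"),
        ProteinRecord("p3", "SKRPAPVSTYSPE"),
    ]


@pytest.fixture()
def tiny_annotations(tiny_proteins):
    from phosforest.io import SiteAnnotation

    return [
        SiteAnnotation("p1", 7, "T", "negative"),
        SiteAnnotation("p2", 4, "S", "positive"),
        SiteAnnotation("p2", 9, "Y", "positive"),
        SiteAnnotation("p3", 1, "S", "positive"),
        SiteAnnotation("p3", 8, "S", "negative"),
        SiteAnnotation("p3", 10, "Y", "negative"),
    ]
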