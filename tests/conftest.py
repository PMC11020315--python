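import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def tooth_table_csv(tmp_path):
    """A small premaxilla transcription: 5 alveoli, replacement germs at
    positions 1, 3 and 5 (the early-juvenile right-premaxilla configuration:
    five teeth, three replacements)."""
    text = (
        "specimen_id,element,side,position,tooth_class,generation,total_length_mm,flags,growth_stage\n"
        "CUGW VH132,premaxilla,right,1,functional,0,5.0,,early_juvenile\n"
        "CUGW VH132,premaxilla,right,1,replacement,1,4.0,,early_juvenile\n"
        "CUGW VH132,premaxilla,right,2,functional,0,5.2,,early_juvenile\n"
        "CUGW VH132,premaxilla,right,3,functional,0,5.4,worn,early_juvenile\n"
        "CUGW VH132,premaxilla,right,3,replacement,1,2.7,,early_juvenile\n"
        "CUGW VH132,premaxilla,right,4,functional,0,5.1,,early_juvenile\n"
        "CUGW VH132,premaxilla,right,5,functional,0,4.8,,early_juvenile\n"
        "CUGW VH132,premaxilla,right,5,replacement,1,0.9,newly_erupted,early_juvenile\n"
    )
    path = tmp_path / "teeth.csv"
    path.write_text(text)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(0)
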