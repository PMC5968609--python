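import matplotlib
import pytest
from hypothesis import HealthCheck, settings

matplotlib.use("Agg")

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


from chipcyto import ChipGeometry, CycleKinetics, load_chip, simulate_cycles  # noqa: E402
from chipcyto.presets import STANDARD_PANEL, ms_like  # noqa: E402


@pytest.fixture(scope="session")
def ms_composition():
    return ms_like()


@pytest.fixture(scope="session")
def small_experiment(ms_composition):
    """3000-cell MS-like chip, standard panel, default kinetics."""
    exp = load_chip(3000, ms_composition, ChipGeometry(6, 6), seed=11)
    return simulate_cycles(exp, STANDARD_PANEL, CycleKinetics(), seed=11)
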