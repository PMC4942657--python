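import warnings

import pytest
from hypothesis import HealthCheck, settings

from qams import GeneratorConfig, datasets, default_registry
from qams.calibration import fit_calibration

settings.register_profile(
    "qams",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("qams")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def published_curves():
    """The published calibration curves (fixture coefficients)."""
    return datasets.calibration_curves()


@pytest.fixture(scope="session")
def stock():
    return datasets.stock_concentrations()


@pytest.fixture
def config():
    """Default synthetic system, fixed seed."""
    return GeneratorConfig(seed=1)


def fit_curves_from_series(levels, runs):
    """Fit per-compound curves from labelled standard runs (test helper)."""
    level_by_id = {lv.level_id: lv for lv in levels}
    points = {}
    for run in runs:
        conc = level_by_id[run.source].concentrations
        for p in run.peaks:
            if p.compound_id and p.compound_id in conc:
                points.setdefault(p.compound_id, []).append(
                    (conc[p.compound_id], p.area)
                )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # <6 levels is fine in tests
        return {cid: fit_calibration(pts, cid) for cid, pts in points.items()}
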