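import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import qscreen as q

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def series11():
    """The 11-point 1:3 dilution series topping at 46 uM."""
    return q.make_dilution_series(46e-6, 11, 3)


@pytest.fixture(scope="session")
def series8():
    """The 8-point 1:5 dilution series topping at 46 uM."""
    return q.make_dilution_series(46e-6, 8, 5)


@pytest.fixture(scope="session")
def archetype_screen(series11):
    """Noise-free screen with 50 compounds per archetype, plus the library."""
    mix = {a: 0.2 for a in q.simulate.ARCHETYPES}
    lib = q.generate_library(250, mix, seed=7)
    plates = q.simulate_viability_screen(
        lib, ["L1"], series11, noise_cv=0.0, baseline_plate_cv=0.0, seed=3
    )
    result = q.analyze_viability_screen(plates)
    return lib, result


@pytest.fixture(scope="session")
def recovery_screen(series11):
    """500 complete full-efficacy curves with 5% multiplicative noise."""
    lib = q.generate_library(500, {"complete_full": 1.0}, seed=11)
    plates = q.simulate_viability_screen(lib, ["L1"], series11, noise_cv=0.05, seed=12)
    result = q.analyze_viability_screen(plates)
    return lib, result


@pytest.fixture(scope="session")
def straddle_screen(series11):
    """500-compound screen with ground-truth actives straddling the cutoffs.

    Potencies are drawn log-uniform over 0.1-30 uM (either side of the 10 uM
    cutoff) and the partial-efficacy archetype straddles the 65% response
    cutoff; 5% multiplicative noise.  Returns (library, per-series fit
    bundles, consensus table).
    """
    mix = {
        "complete_full": 0.3,
        "complete_partial": 0.25,
        "incomplete": 0.15,
        "single_point": 0.1,
        "inactive": 0.2,
    }
    lib = q.generate_library(500, mix, ic50_range=(1e-7, 3e-5), seed=21)
    plates = q.simulate_viability_screen(lib, ["L1"], series11, noise_cv=0.05, seed=22)
    series = q.assemble_series(plates)
    bundles = []
    for s in series:
        fit = q.fit_hill(s)
        cls = q.classify_curve(fit, s)
        bundles.append((s, fit, cls))
    return lib, bundles


def make_series(concs, responses, compound_id="c1", cell_line="L1", rep=0,
                six_sd=True):
    """Shorthand for building a NormalizedSeries in tests."""
    return q.NormalizedSeries(
        compound_id=compound_id,
        cell_line=cell_line,
        replicate_index=rep,
        concentrations=np.asarray(concs, dtype=float),
        responses=np.asarray(responses, dtype=float),
        six_sd_crossed=six_sd,
    )


@pytest.fixture
def series_factory():
    return make_series
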