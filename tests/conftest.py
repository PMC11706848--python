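import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """One synthetic study (droplet plates + cohort) pushed through every
    pipeline stage; shared across tests that inspect stage outputs."""
    from trimeth.pipeline import call_stage, qc_stage, quantify_stage
    from trimeth.simulate import SimulationConfig, simulate_study

    cfg = SimulationConfig(seed=3, n_patients=16)
    study = simulate_study(cfg)
    measurements = quantify_stage(study.plates.droplets, study.plates.sample_sheet)
    qc_report = qc_stage(measurements, study.plates.sample_sheet)
    calls = call_stage(measurements, study.plates.sample_sheet, qc_report)
    return {
        "config": cfg,
        "study": study,
        "measurements": measurements,
        "qc_report": qc_report,
        "calls": calls,
    }


def km_product_limit_brute(times, events):
    """Hand product-limit estimator: loop over distinct event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    out_t, out_s = [], []
    s = 1.0
    for t in np.unique(times[events]):
        n_at_risk = int((times >= t).sum())
        d = int(((times == t) & events).sum())
        s *= 1.0 - d / n_at_risk
        out_t.append(float(t))
        out_s.append(s)
    return np.array(out_t), np.array(out_s)
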