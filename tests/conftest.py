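"""Shared fixtures: the desk-scale synthetic study used by the acceptance
tests.

The study emulates the clinical protocol at the generator's default
conditions (10 patients, 48^3 grids at 1.5 mm, prostate volumes
18.5-67.3 cc, three scans at 0.5-2.6-year intervals, noiseless for
self-consistency checks) and runs the fitting-forecasting scenario once
per session; individual tests assert different properties of the same run.
The solver time step for this study is 3 days (generation and calibration
share the discretization, so parameter recovery is well-posed).
"""

import json
from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

from fkgrowth.pipeline import ScenarioConfig, run_scenario
from fkgrowth.synthetic import CohortSpec, generate_cohort, write_cohort

STUDY_SEED = 0
STUDY_DT = 1.0  # days, as in the emulated protocol
STUDY_MARGIN_MM = "auto"


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """Noiseless 10-patient cohort + one fitting-forecasting run."""
    root = tmp_path_factory.mktemp("study")
    cohort_dir = root / "cohort"
    out_dir = root / "ff"
    spec = CohortSpec(n_patients=10, dt=STUDY_DT, noise_sigma=0.0,
                      seed=STUDY_SEED)
    cohort = generate_cohort(spec)
    write_cohort(cohort, cohort_dir)
    cfg = ScenarioConfig("fitting_forecasting", str(cohort_dir),
                         str(out_dir), margin_mm=STUDY_MARGIN_MM)
    summary = run_scenario(cfg)
    truth = {
        p.patient_id: {"d": p.true_params.d, "rho": p.true_params.rho}
        for p in cohort
    }
    return {
        "spec": spec,
        "cfg": cfg,
        "cohort_dir": cohort_dir,
        "out_dir": out_dir,
        "summary": summary,
        "truth": truth,
        "calibration": json.loads(
            (out_dir / "calibration.json").read_text()),
    }
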