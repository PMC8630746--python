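import numpy as np
import pytest

from crss.consensus import fit_stage_model
from crss.simulate import default_configs, generate_with_truth


@pytest.fixture(scope="session")
def mmin_run():
    """One fully fitted pipeline run on the mmin_like preset (n=400, seed 7).

    Shared by the consensus, rules, explainability and acceptance tests to
    avoid refitting; everything downstream treats it as read-only.
    """
    cfg = default_configs(n=400, seed=7)["mmin_like"]
    cohort, strata, flags = generate_with_truth(cfg)
    model, assignment, details = fit_stage_model(
        cohort, cfg.cutoffs, seed=7, return_details=True
    )
    return {
        "config": cfg,
        "cohort": cohort,
        "strata": strata,
        "flags": flags,
        "model": model,
        "assignment": assignment,
        "details": details,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
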