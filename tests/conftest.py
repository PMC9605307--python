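from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import edconjoint as ec

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=15,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def instrument():
    return ec.default_instrument()


@pytest.fixture(scope="session")
def small_book(instrument):
    """A three-respondent design, enough for structural checks."""
    return ec.generate_design(instrument, 3, seed=7)


@pytest.fixture(scope="session")
def profiles():
    return ec.reference_mindset_profiles()


def make_models_from_vectors(vectors, message_ids, constants=None):
    """RespondentModels with exactly the given coefficient vectors."""
    models = []
    for i, vec in enumerate(vectors):
        c = 50.0 if constants is None else constants[i]
        models.append(ec.RespondentModel(
            respondent_id=f"r{i + 1:03d}",
            constant=c,
            coefficients={m: float(b) for m, b in zip(message_ids, vec)},
            residual_se=0.0,
        ))
    return models


@pytest.fixture(scope="session")
def standard_panel(instrument, profiles):
    """The standard study-scale simulation: 38/38/36 respondents, sd=5.

    Shared across segmentation and reliability tests; seed fixed at 11.
    """
    book = ec.generate_design(instrument, 112, seed=11)
    cfg = ec.SimulationConfig(n_per_mindset=(38, 38, 36),
                              respondent_heterogeneity_sd=5.0, seed=11)
    table = ec.simulate_responses(book, profiles, cfg)
    models, total, data = ec.fit_panel(book, table)
    return {"book": book, "table": table, "models": models,
            "total": total, "data": data}
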