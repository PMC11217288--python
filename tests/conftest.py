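import logging

import numpy as np
import pytest

from eegcpm import cpm, synth

logging.getLogger("eegcpm.synth").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def behavior90():
    """A 90-subject behavior table, max-normalized (the internal-cohort size)."""
    return synth.normalize_behavior(synth.generate_behavior(90, seed=1000))


@pytest.fixture(scope="session")
def planted_cohort(behavior90):
    """90 subjects, 10 ROIs, 5+5 planted edges at the default effect size."""
    y = behavior90["c_total"].to_numpy()
    trait = synth.standardize_trait(y)
    planted = synth.PlantedEffect(tuple(range(5)), tuple(range(5, 10)),
                                  effect_size=0.2, noise_sd=0.02)
    connectomes = synth.generate_connectomes(90, 10, planted, trait, seed=0)
    return {"behavior": behavior90, "scores": y, "trait": trait,
            "planted": planted, "connectomes": connectomes,
            "X": cpm.features_matrix(connectomes)}


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
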