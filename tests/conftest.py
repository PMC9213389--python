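"""Shared fixtures: phantom cohorts and desk-scale trained ensembles.

The heavy session-scoped fixtures below are built once and shared by the
acceptance tests; every dataset is generated programmatically at test time.
"""
import numpy as np
import pandas as pd
import pytest

import polypcad as pc
from polypcad.cli import PROFILES
from polypcad.data_io import centre_crop

DESK = PROFILES["desk"]

#: cohort sizes for the scaled-down recovery experiment
N_TRAIN_PATIENTS = 30
N_TEST_PATIENTS = 15
COHORT_SEEDS = (301, 302)


def desk_params() -> pc.TrainingParams:
    return pc.TrainingParams(patience_epochs=DESK["patience_epochs"],
                             max_epochs=DESK["max_epochs"])


@pytest.fixture(scope="session")
def recovery_cohorts(tmp_path_factory):
    """Separability-1.0 train/test phantom cohorts (~120/60 segmentations)."""
    root = tmp_path_factory.mktemp("recovery")
    # single-stratum cohorts: polyp size is class-balanced nuisance variance
    # at this cohort scale, so the recovery experiment controls for it
    train = pc.generate_cohort(root / "train", n_patients=N_TRAIN_PATIENTS,
                               separability=1.0, size_mix=(0, 1, 0),
                               seed=COHORT_SEEDS[0])
    test = pc.generate_cohort(root / "test", n_patients=N_TEST_PATIENTS,
                              separability=1.0, size_mix=(0, 1, 0),
                              seed=COHORT_SEEDS[1])
    return {"train": train, "test": test, "root": root}


@pytest.fixture(scope="session")
def recovery_arrays(recovery_cohorts):
    out = {}
    for variant in ("noSEG",):
        Xtr, ytr, _ = pc.load_cohort(recovery_cohorts["train"], variant=variant)
        Xte, yte, rec = pc.load_cohort(recovery_cohorts["test"], variant=variant)
        out[variant] = {"Xtr": Xtr, "ytr": ytr, "Xte": Xte, "yte": yte,
                        "records": rec}
    _, _, _, masks = pc.load_cohort(recovery_cohorts["test"], variant="noSEG",
                                    with_masks=True)
    out["test_masks"] = masks
    return out


@pytest.fixture(scope="session")
def recovery_noseg(recovery_arrays):
    """Desk-profile 5-member noSEG ensemble trained on the recovery cohort."""
    d = recovery_arrays["noSEG"]
    return pc.train_ensemble(d["Xtr"], d["ytr"], variant="noSEG",
                             n_members=DESK["n_members"], base_seed=7,
                             params=desk_params())


@pytest.fixture(scope="session")
def test_inputs_50(recovery_arrays):
    """Centre-cropped 50^3 noSEG test inputs with aligned masks."""
    d = recovery_arrays["noSEG"]
    X50 = np.stack([centre_crop(x) for x in d["Xte"]])
    m50 = np.stack([centre_crop(m) for m in recovery_arrays["test_masks"]])
    return X50, m50, d["yte"]
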