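import numpy as np
import pandas as pd
import pytest

import deltaconn as dc


@pytest.fixture(scope="session")
def tiny_scheme():
    """4 ROIs: 2 cortical somatomotor, 1 cortical limbic, 1 subcortical."""
    return dc.make_parcellation(
        pd.DataFrame(
            {
                "roi_name": ["sm_a", "sm_b", "limbic_a", "stn"],
                "hemisphere": ["L", "R", "L", "bilateral"],
                "roi_class": ["cortical", "cortical", "cortical", "subcortical"],
                "network": ["somatomotor", "somatomotor", "limbic", "basal_ganglia"],
            }
        )
    )


@pytest.fixture(scope="session")
def sim_scheme():
    return dc.default_scheme(n_cortical=12, n_subcortical=3)


@pytest.fixture(scope="session")
def null_cohort(sim_scheme):
    cfg = dc.SimulationConfig(
        seed=11, n_subjects=120, scheme=sim_scheme
    )
    dataset, truth = dc.simulate_cohort(cfg)
    return dataset, truth


@pytest.fixture(scope="session")
def planted_cohort(sim_scheme):
    """One strong negative planted edge between the first subcortical ROI and cortex."""
    sub = int(sim_scheme.subcortical_ids[0])
    cfg = dc.SimulationConfig(
        seed=5,
        n_subjects=300,
        scheme=sim_scheme,
        planted_edges=((0, sub, -0.4),),
    )
    dataset, truth = dc.simulate_cohort(cfg)
    return dataset, truth


def make_cohort_from_edges(scheme, tp1, tp2, symptoms_tp2=None, symptoms_tp1=None,
                           sex=None, rng=None):
    """Assemble a CohortDataset directly from edge matrices (test helper)."""
    rng = rng or np.random.default_rng(0)
    n = tp1.shape[0]
    return dc.CohortDataset(
        subject_ids=[f"s{i}" for i in range(n)],
        scheme=scheme,
        rsfc_tp1=np.asarray(tp1, dtype=float),
        rsfc_tp2=np.asarray(tp2, dtype=float) if tp2 is not None else None,
        symptoms_tp1=(
            np.asarray(symptoms_tp1, dtype=float)
            if symptoms_tp1 is not None
            else rng.standard_normal(n)
        ),
        symptoms_tp2=(
            np.asarray(symptoms_tp2, dtype=float) if symptoms_tp2 is not None else None
        ),
        sex=(np.asarray(sex, dtype=int) if sex is not None else rng.binomial(1, 0.5, n)),
        sex_coding={"F": 0, "M": 1},
    )
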