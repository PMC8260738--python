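import numpy as np
import pandas as pd
import pytest

from sleepreact import behavior, crf, decode, pipeline, stats
from sleepreact.design import RewardMapping
from sleepreact.simulate import CohortConfig, simulate_cohort


def small_cohort_config(**overrides) -> CohortConfig:
    """Reduced-dimension generator settings for fast unit tests."""
    base = dict(
        n_rois=12,
        n_game_blocks=4,
        sleep_total_min=30.0,
        min_n3_min=5.0,
    )
    base.update(overrides)
    return CohortConfig(**base)


NULL_COHORT = small_cohort_config(
    react_amp=0.0, react_amp_subject_sd=0.0, delta_coupling=0.0, memory_coupling=0.0
)


def fast_null_run(seed: int, n_subjects: int = 8):
    """One reduced-size pipeline run with no injected reactivation and no
    memory coupling: everything downstream should behave as a null.

    Returns (p of the N3 Reward-vs-NoReward planned contrast, p of the
    reactivation-memory Spearman correlation, tidy stage-likelihood table).
    """
    cfg = pipeline.PipelineConfig(seed=seed, n_subjects_sleep=n_subjects, cohort=NULL_COHORT)
    cohort = simulate_cohort(n_subjects, cfg.cohort, seed=seed)
    model = pipeline.train_cohort_model(cohort, cfg)
    rows, betas, face, mazed = [], [], [], []
    for sub in cohort.subjects:
        lik = decode.decode_sleep(model, sub.sleep.roits)
        tab = decode.stage_mean_likelihood(
            lik, sub.sleep.hypnogram, RewardMapping(sub.won_game), sub.sleep.roits.tr
        )
        for stage in tab.means.index:
            if tab.n_scans[stage]:
                for state in tab.means.columns:
                    rows.append(
                        {"subject": sub.subject_id, "stage": stage, "state": state,
                         "value": tab.means.loc[stage, state]}
                    )
        n3 = sub.sleep.scan_stages() == "N3"
        betas.append(float(sub.sleep.roits.values[n3].mean()))
        face.append(behavior.face_memory_score(sub.record.face_truth, sub.record.face_placement))
        mazed.append(behavior.maze_memory_distance(sub.record.maze, sub.record.maze_final_node))
    long = pd.DataFrame(rows)
    _, _, p_contrast = stats.planned_comparison(
        long, factor="state", levels=("Reward", "NoReward"), at={"stage": "N3"}
    )
    fz, mz = behavior.zscore_memory(face, mazed)
    _, p_mem = behavior.reactivation_memory_correlation(betas, (fz + mz) / 2)
    return p_contrast, p_mem, long


def random_chain_instance(rng, T=None, S=None, N=3, scale=1.0, uniform=False):
    """A random CRFModel plus features for enumeration cross-checks."""
    T = T or int(rng.integers(2, 7))
    S = S or int(rng.integers(2, 4))
    lam = np.zeros((S, S)) if uniform else rng.normal(scale=scale, size=(S, S))
    mu = rng.normal(scale=scale, size=(S, N + 1))
    model = crf.CRFModel(
        states=[f"s{i}" for i in range(S)], lam=lam, mu=mu, transitions_uniform=uniform
    )
    feats = crf.FeatureMatrix(rng.normal(size=(T, N)), np.zeros(N), np.ones(N))
    return model, feats


@pytest.fixture(scope="session")
def tiny_game_cohort():
    """4-subject, 12-ROI game-only cohort reused across tests."""
    return simulate_cohort(4, small_cohort_config(include_sleep=False), seed=7)


@pytest.fixture(scope="session")
def tiny_sleep_cohort():
    """4-subject cohort with sleep sessions at default couplings."""
    return simulate_cohort(4, small_cohort_config(), seed=11)


@pytest.fixture(scope="session")
def tiny_trained(tiny_sleep_cohort):
    cfg = pipeline.PipelineConfig(seed=3)
    model = pipeline.train_cohort_model(tiny_sleep_cohort, cfg)
    return tiny_sleep_cohort, model
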