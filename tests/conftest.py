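import numpy as np
import pandas as pd
import pytest

from tck import simulate
from tck.containers import CohortDesign, ExpressionMatrix


@pytest.fixture(scope="session")
def small_config():
    return simulate.SimulationConfig(n_features=300, n_mirnas=20, seed=11)


@pytest.fixture(scope="session")
def small_signals(small_config):
    return simulate.activation_marker_signals(small_config) + simulate.spike_signals(
        small_config, n_up=10, n_down=10
    )


@pytest.fixture(scope="session")
def small_cohort(small_config, small_signals):
    """Raw cohort with activation markers and 20 early-window spikes."""
    return simulate.generate_cohort(small_config, small_signals)


@pytest.fixture(scope="session")
def small_log2(small_cohort):
    from tck import preprocess

    matrix, design, _ = small_cohort
    return preprocess.preprocess(matrix, design), design


def latent_log2_cohort(
    config: simulate.SimulationConfig,
    signals: list[simulate.SignalSpec],
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, CohortDesign]:
    """Log2-stage matrix straight from the latent model (no intensity layer).

    Useful for tests of the statistics layer that should not depend on
    background correction or normalization.
    """
    matrix, design, _ = simulate.generate_cohort(config, signals)
    n_feat, n_samp = matrix.shape
    latent = rng.normal(8.0, 1.0, size=(n_feat, 1)) + rng.normal(
        0.0, config.noise_sd, size=(n_feat, n_samp)
    )
    t_of = design.table["time_h"].to_numpy()
    is_pd = (design.table["group"] == "PD").to_numpy()
    ramp = 1.0 - np.exp(-t_of / config.activation_tau_h)
    for spec in signals:
        i = list(matrix.feature_ids).index(spec.feature_id)
        if spec.signal_class == "activation_shared":
            latent[i] += spec.effect_log2fc * ramp
        else:
            prof = simulate.latent_group_difference(spec, config)
            for j, t in enumerate(config.time_points_h):
                latent[i, (t_of == t) & is_pd] += prof[j]
    df = pd.DataFrame(latent, index=matrix.feature_ids, columns=matrix.sample_ids)
    return ExpressionMatrix(df, stage="log2"), design
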