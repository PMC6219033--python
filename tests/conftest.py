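import numpy as np
import pytest

from mtplong.model import ModelSpec, ParameterVector, RandomEffectsCov


@pytest.fixture
def toy_params():
    """Arbitrary but fixed mtp parameters for a 2-covariate model."""
    return ParameterVector(
        cont_coef=np.array([0.4, 0.3]),
        k=0.7,
        sigma=0.7,
        re_cov=RandomEffectsCov(0.6, 0.4, 0.2, correlated=True),
        alpha=np.array([0.2, -0.5]),
    )


@pytest.fixture
def five_subject_panel():
    """Deterministic 5-subject toy panel (mixed zeros and positives)."""
    rng = np.random.default_rng(2718)
    subj, y, Z, X = [], [], [], []
    y_vals = [
        [0.0, 1.3, 0.5],
        [0.8],
        [0.0, 0.0],
        [2.1, 0.0, 0.4, 1.1],
        [0.6, 0.9],
    ]
    for i, ys in enumerate(y_vals):
        for v in ys:
            subj.append(i)
            y.append(v)
            Z.append([1.0, rng.normal()])
            X.append([1.0, rng.normal()])
    from mtplong.model import PanelDataset

    return PanelDataset(subj, np.arange(len(y), dtype=float), y,
                        np.array(Z), np.array(X))


@pytest.fixture(scope="session")
def small_mtp_fit():
    """One mtp-gamma fit on a small simulated panel, shared across tests."""
    from mtplong.inference import FitOptions, fit_model
    from mtplong.simulate import default_study_config, simulate_panel

    cfg = default_study_config(zero_prop=0.3, n_subjects=120, n_visits=4, seed=11)
    data = simulate_panel(cfg, np.random.default_rng(11))
    fit = fit_model(data, cfg.spec, options=FitOptions(pre_fit=False))
    return cfg, data, fit
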