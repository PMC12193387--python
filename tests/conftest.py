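import numpy as np
import pytest

from fpturnover import QuantConfig, SimConfig, simulate_video_experiment
from fpturnover.pipeline import analyze_stacks


@pytest.fixture(scope="session")
def noiseless_experiment():
    """Small noise-free simulated experiment shared across tests."""
    cfg = SimConfig(
        n_days=5, n_vials=2, n_frames_per_day=4, noise_sd=0.0, seed=7
    )
    stacks, truth = simulate_video_experiment(cfg)
    return cfg, stacks, truth


@pytest.fixture
def full_frame_quant():
    """QuantConfig covering the default simulated frame, threshold above background."""
    def make(cfg: SimConfig, threshold: float | None = None) -> QuantConfig:
        h, w = cfg.frame_shape
        if threshold is None:
            threshold = cfg.background_level + 6 * max(cfg.noise_sd, 1.0)
        return QuantConfig(threshold=threshold, roi=(0, h, 0, w))
    return make


def pipeline_halflife(seed: int, true_half_life: float = 3.5,
                      noise_sd: float = 50.0) -> float:
    """Full pipeline estimate on one simulated experiment (study conditions:
    4 vials, 6 days, additive noise SD = 5% of fly peak intensity)."""
    cfg = SimConfig(seed=seed, true_half_life=true_half_life, noise_sd=noise_sd)
    stacks, _ = simulate_video_experiment(cfg)
    h, w = cfg.frame_shape
    qc = QuantConfig(threshold=300.0, roi=(0, h, 0, w))
    _, fit = analyze_stacks(stacks, qc)
    return fit.half_life
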