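from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from silacq.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def noise_free_config() -> SimConfig:
    return SimConfig(
        n_proteins=8,
        frac_up=0.25,
        frac_down=0.125,
        fold_log_sigma=0.0,
        sigma_bio=0.0,
        sigma_tech=0.0,
        ppm_sigma=0.0,
        rt_jitter=0.0,
        detect_prob=1.0,
        id_prob=1.0,
        wash_frac=0.0,
        missed_cleavage_frac=0.3,
        seed=11,
    )


@pytest.fixture(scope="session")
def noise_free_experiment(noise_free_config):
    return simulate(noise_free_config)


@pytest.fixture(scope="session")
def small_noisy_experiment():
    cfg = SimConfig(n_proteins=30, seq_length=(50, 90), seed=7)
    return simulate(cfg)


def random_features(rng: np.random.Generator, n: int, classes) -> pd.DataFrame:
    """A random single-run feature table with planted class-delta pairs."""
    masses = list(rng.uniform(600, 2500, size=n // 2))
    for k in range(n - len(masses)):
        base = masses[k % len(masses)]
        cls = classes[int(rng.integers(len(classes)))]
        jitter = rng.normal(0, 2e-6) * base  # ~2 ppm
        masses.append(base + cls.delta + jitter)
    masses = np.array(masses[:n])
    apex = rng.uniform(20, 30, n)
    span = rng.uniform(0.2, 1.0, n)
    return pd.DataFrame(
        {
            "feature_id": np.arange(n),
            "run_id": "r1",
            "charge": rng.choice([2, 2, 2, 3], n),
            "mass": masses,
            "rt_apex": apex,
            "rt_start": apex - span / 2,
            "rt_end": apex + span / 2,
            "area": rng.uniform(1e3, 1e6, n),
            "n_scans": 5,
        }
    )


def random_detections(rng: np.random.Generator, n_clusters: int) -> pd.DataFrame:
    """Per-scan rows forming noisy clusters plus stray singletons."""
    rows = []
    for c in range(n_clusters):
        run = f"r{rng.integers(2)}"
        charge = int(rng.choice([2, 3]))
        mass = rng.uniform(600, 2000)
        rt0 = rng.uniform(10, 60)
        for s in range(int(rng.integers(1, 7))):
            rows.append(
                {
                    "run_id": run,
                    "rt_min": rt0 + s * (2 / 60) * rng.choice([1, 1, 1, 2, 4]),
                    "mono_mass_da": mass * (1 + rng.normal(0, 1.5e-6)),
                    "charge": charge,
                    "area": rng.uniform(10, 1e5),
                }
            )
    df = pd.DataFrame(rows)
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
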