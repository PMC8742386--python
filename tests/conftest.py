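import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import snpenrich as se

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


def make_universe_frame(n, seed=0, chrom="chr1"):
    """Small fully-valid universe frame with distinct covariates."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "rsid": [f"rs{i + 1}" for i in range(n)],
        "chrom": chrom,
        "pos": np.sort(rng.choice(10 ** 6, size=n, replace=False)),
        "maf": rng.uniform(0.005, 0.5, size=n),
        "tss_distance": rng.integers(0, 500_000, size=n),
        "gc": rng.uniform(0.2, 0.7, size=n),
    })


@pytest.fixture(scope="session")
def sim_bundle():
    """Mid-size synthetic study: universe, tracks, ground truth, database."""
    cfg = se.SimConfig(seed=7, n_snps=5000, n_chroms=4,
                       chrom_length=2_000_000, n_samples=8)
    universe = se.simulate_universe(cfg)
    tracks, gt = se.simulate_tracks(universe, cfg)
    db = se.build_overlap_db(universe, tracks)
    universe = se.assign_decile_bins(universe)
    return {"cfg": cfg, "universe": universe, "tracks": tracks,
            "ground_truth": gt, "db": db}


@pytest.fixture()
def tiny_universe():
    return se.assign_decile_bins(se.SnpUniverse(make_universe_frame(200, seed=3)))
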