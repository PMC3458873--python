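"""Shared fixtures.

The expensive coalescent fixtures are session-scoped and shared between the
module tests and the acceptance tests: the calibrated island-model null
(5,000 replicates), the three-condition secondary-contact study (5
replicates x 300 loci per dispersal rate), and the Co-Co null-calibration
ensemble (100 replicates of 150 homogeneous Gaussian points).
"""

import numpy as np
import pytest

from clinescan.coco import CoCoOutlierDetector
from clinescan.fst_outlier import (
    IslandNullConfig,
    build_null_envelope,
    calibrate_migration,
    simulate_island_pairs,
)
from clinescan.simulate import (
    DemographyConfig,
    run_simulation_study,
    simulate_secondary_contact,
)
from clinescan.synth import GeneratorSpec, generate_dataset


@pytest.fixture(scope="session")
def island_null():
    """Calibrated island-model null: (config, migration rate, 5000 (He, FST) pairs)."""
    cfg = IslandNullConfig(n_replicates=5000, seed=101)
    m = calibrate_migration(cfg, pilot_replicates=1500, tol=0.01)
    pairs = simulate_island_pairs(cfg, m, 5000, seed=202)
    return cfg, m, pairs


@pytest.fixture(scope="session")
def null_envelope(island_null):
    _, _, pairs = island_null
    return build_null_envelope(pairs)


@pytest.fixture(scope="session")
def secondary_study():
    """Percent-clinal study: 4Nm in {0.4, 4, 40}, 5 replicates x 300 loci."""
    cfgs = [
        DemographyConfig(four_n_m=v, n_loci=300, seed=300 + i)
        for i, v in enumerate([0.4, 4.0, 40.0])
    ]
    return run_simulation_study(cfgs, n_replicates=5)


@pytest.fixture(scope="session")
def contact_dataset():
    """One secondary-contact dataset at 4Nm = 4 (300 loci, 40 copies/deme)."""
    return simulate_secondary_contact(DemographyConfig(four_n_m=4.0, n_loci=300, seed=777))


@pytest.fixture(scope="session")
def coco_null_fractions():
    """Outlier fraction at the 95% HDR over 100 replicates of 150 Gaussian points."""
    rng = np.random.default_rng(5)
    fracs = []
    for _ in range(100):
        pts = rng.normal(size=(150, 2))
        det = CoCoOutlierDetector(bandwidth_method="plugin", grid_size=128).fit(pts)
        fracs.append(float(det.predict(pts).mean()))
    return np.array(fracs)


@pytest.fixture(scope="session")
def recovery_fits():
    """Broken-stick fits of 200 strong synthetic stepped clines + truth."""
    from clinescan.cline import BrokenStickCline

    spec = GeneratorSpec(
        n_sites=20,
        n_loci=200,
        fraction_clinal=1.0,
        midpoint_range=(36.0, 44.0),
        delta_p_range=(0.4, 0.9),
        cline_shape="stepped",
        n_per_site=40,
        seed=21,
    )
    ds, truth = generate_dataset(spec)
    fits = []
    for lid in ds.locus_ids:
        x = ds.counts[lid][:, 0].astype(float)
        n = ds.sample_sizes(lid).astype(float)
        fits.append(BrokenStickCline().fit(ds.latitudes, x, n))
    return ds, truth, fits


@pytest.fixture()
def small_dataset():
    ds, truth = generate_dataset(GeneratorSpec(n_sites=20, n_loci=12, seed=3))
    return ds, truth
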