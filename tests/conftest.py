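"""Shared fixtures: small simulated cohorts and a score-level oracle.

The Gaussian score-level oracle simulates standardized true polygenic scores
directly from their family covariance structure (parents standard normal,
child = mid-parent + Mendelian deviation of variance 1/2), bypassing the
SNP machinery entirely.  It serves as an independent large-sample check on
the sibling-design estimates produced by the full genotype pipeline.
"""

import numpy as np
import pandas as pd
import pytest

import famfx as fx


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small all-features cohort: twins, adoptees, 300 families."""
    scen = fx.SimulationScenario(
        n_families=300, m_snps=120, seed=11, adoption_fraction=0.2,
        dz_fraction=0.3, mz_fraction=0.2, pgs_precision=1.0)
    cohort, weights = fx.simulate_cohort(scen)
    return cohort, weights


@pytest.fixture(scope="session")
def tiny_table(tiny_cohort):
    cohort, weights = tiny_cohort
    return fx.cohort_score_table(cohort, weights)


@pytest.fixture(scope="session")
def medium_cohort():
    """Mid-sized cohort for distributional checks (4,000 families)."""
    scen = fx.SimulationScenario(
        n_families=4_000, m_snps=250, seed=23, adoption_fraction=0.25,
        dz_fraction=0.2, mz_fraction=0.1, pgs_precision=1.0)
    cohort, weights = fx.simulate_cohort(scen)
    return cohort, weights


@pytest.fixture(scope="session")
def medium_table(medium_cohort):
    cohort, weights = medium_cohort
    return fx.cohort_score_table(cohort, weights)


def gaussian_sibling_oracle(beta_direct, beta_postnatal, n_families,
                            resid_sd=1.0, seed=0):
    """Large-sample sibling-design plims from a score-level simulation.

    Two-offspring families under random mating with true scores measured
    exactly; returns per-construct (population, within, indirect) slopes
    computed with the same standardization conventions as the design fitter
    (scores scaled on the sibling sample, outcome standardized).
    """
    rng = np.random.default_rng(seed)
    bd = np.asarray(beta_direct, dtype=float)
    bp = np.asarray(beta_postnatal, dtype=float)
    zf = rng.normal(size=(n_families, 2))
    zm = rng.normal(size=(n_families, 2))
    mid = 0.5 * (zf + zm)
    z1 = mid + rng.normal(scale=np.sqrt(0.5), size=(n_families, 2))
    z2 = mid + rng.normal(scale=np.sqrt(0.5), size=(n_families, 2))
    y1 = z1 @ bd + mid @ bp + rng.normal(scale=resid_sd, size=n_families)
    y2 = z2 @ bd + mid @ bp + rng.normal(scale=resid_sd, size=n_families)
    z = np.concatenate([z1, z2])
    y = np.concatenate([y1, y2])
    z = (z - z.mean(0)) / z.std(0)
    y = (y - y.mean()) / y.std()
    fam_mean = 0.5 * (z[: n_families] + z[n_families:])
    dev = z - np.concatenate([fam_mean, fam_mean])
    out = {}
    for c in range(2):
        pop = float(np.cov(y, z[:, c])[0, 1] / np.var(z[:, c]))
        within = float(np.cov(y, dev[:, c])[0, 1] / np.var(dev[:, c]))
        out[c] = {"population": pop, "within": within,
                  "indirect": pop - within}
    return out
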