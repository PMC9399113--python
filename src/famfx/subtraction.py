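"""Simplified per-SNP GWAS-by-subtraction path algebra.

Educational-attainment (EA) and cognitive-performance (CP) SNP effects are
modelled as loading on two independent latent factors: a cognitive factor
(Cog, shared between EA and CP) and a residual non-cognitive factor (NonCog,
the genetic variance of EA left after regressing out CP):

    beta_CP = lambda_cp_cog * b_cog
    beta_EA = lambda_ea_cog * b_cog + lambda_ea_noncog * b_noncog

Given identifiable loadings the per-SNP latent effects follow by an exact
triangular solve.  This is the deterministic core of the construct — enough
to generate internally consistent Cog/NonCog weight vectors for simulation —
not a full structural-equation treatment of GWAS sampling covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

# Default loadings: equal Cog paths into EA and CP and a NonCog path sized so
# the two latent factors contribute comparable EA variance.  These are
# configurable modelling choices, not estimates.
DEFAULT_LOADINGS = (1.0, 0.7, 0.7)


@dataclass(frozen=True)
class Loadings:
    """Path coefficients of the two-latent-factor model."""

    cp_cog: float = DEFAULT_LOADINGS[0]
    ea_cog: float = DEFAULT_LOADINGS[1]
    ea_noncog: float = DEFAULT_LOADINGS[2]

    def __post_init__(self):
        if self.cp_cog == 0 or self.ea_noncog == 0:
            raise ParameterError(
                "loadings cp_cog and ea_noncog must be nonzero for the "
                "model to be identifiable")


def solve_subtraction(beta_ea, beta_cp, loadings: Loadings = Loadings()):
    """Per-SNP latent Cog / NonCog effects from observed EA and CP effects.

    Exact triangular solve:
    b_cog = beta_cp / cp_cog;
    b_noncog = (beta_ea - ea_cog * b_cog) / ea_noncog.
    """
    beta_ea = np.asarray(beta_ea, dtype=float)
    beta_cp = np.asarray(beta_cp, dtype=float)
    if beta_ea.shape != beta_cp.shape:
        raise ParameterError("beta_ea and beta_cp must have equal shape")
    b_cog = beta_cp / loadings.cp_cog
    b_noncog = (beta_ea - loadings.ea_cog * b_cog) / loadings.ea_noncog
    return b_cog, b_noncog


def implied_sumstats(b_cog, b_noncog, loadings: Loadings = Loadings()):
    """Model-implied observed effects (the noiseless reconstruction)."""
    b_cog = np.asarray(b_cog, dtype=float)
    b_noncog = np.asarray(b_noncog, dtype=float)
    beta_cp = loadings.cp_cog * b_cog
    beta_ea = loadings.ea_cog * b_cog + loadings.ea_noncog * b_noncog
    return beta_ea, beta_cp


def simulate_sumstats(b_cog, b_noncog, loadings: Loadings = Loadings(),
                      se_scale: float = 0.0, seed=None):
    """Noisy observed EA / CP effects consistent with the path model.

    Observed effects are the model-implied values plus independent Gaussian
    noise with standard deviation ``se_scale``; ``se_scale=0`` reproduces the
    invariant identities exactly.
    """
    if se_scale < 0:
        raise ParameterError("se_scale must be >= 0")
    beta_ea, beta_cp = implied_sumstats(b_cog, b_noncog, loadings)
    if se_scale > 0:
        rng = np.random.default_rng(seed)
        beta_ea = beta_ea + rng.normal(scale=se_scale, size=beta_ea.shape)
        beta_cp = beta_cp + rng.normal(scale=se_scale, size=beta_cp.shape)
    return beta_ea, beta_cp


def solve_sumstats_frame(sumstats: pd.DataFrame,
                         loadings: Loadings = Loadings()) -> pd.DataFrame:
    """Solve a summary-statistics table into a weight-vector table.

    Expects columns snp_id, effect_allele, beta_ea, beta_cp; returns the
    standard weight format (snp_id, effect_allele, weight_cog,
    weight_noncog, provenance).
    """
    for col in ("snp_id", "effect_allele", "beta_ea", "beta_cp"):
        if col not in sumstats:
            raise ParameterError(f"sumstats missing column {col!r}")
    b_cog, b_noncog = solve_subtraction(sumstats["beta_ea"],
                                        sumstats["beta_cp"], loadings)
    return pd.DataFrame({
        "snp_id": sumstats["snp_id"],
        "effect_allele": sumstats["effect_allele"],
        "weight_cog": b_cog,
        "weight_noncog": b_noncog,
        "provenance": "subtraction",
    })
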