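"""Bootstrap uncertainty, contrast Z-tests, meta-analysis and PGS diagnostics.

The nonparametric bootstrap resamples whole families (keeping sibships and
trios intact) for the sibling and trio designs, and adoptee / non-adopted
strata separately for the adoption design; the same bootstrap samples feed
both regressions of the sibling design.  Confidence intervals are
bias-corrected normal-approximation intervals: centred at
2*theta_hat - mean(theta*) with a +/- z * SE(theta*) half-width (percentile
intervals are available as an option).

Meta-analysis pools estimates with a design-level random intercept on top of
residual heterogeneity, fitted by REML; with a single design (or
``random_intercept=False``) it collapses to a standard random-effects model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateInputError, ParameterError, StructuralError
from .scores import CONSTRUCTS

RATIO_GUARD = 1e-8


# ---------------------------------------------------------------------------
# Ratios and simple contrasts
# ---------------------------------------------------------------------------


def ratio(numerator: float, denominator: float) -> float:
    """Guarded ratio; raises when the denominator is numerically zero."""
    if abs(denominator) < RATIO_GUARD:
        raise DegenerateInputError("ratio denominator is (numerically) zero")
    return numerator / denominator


def percent_reduction(smaller: float, larger: float) -> float:
    """1 - smaller/larger, in percent (e.g. 0.02 vs 0.12 -> 83.3)."""
    return 100.0 * (1.0 - ratio(smaller, larger))


def ratio_stats(estimate_set) -> dict:
    """indirect/population and indirect/direct ratios per construct.

    Ratios with a denominator below tolerance are flagged unstable and
    reported as NaN (their CIs are suppressed downstream).
    """
    out = {}
    for c, quant in estimate_set.estimates.items():
        entry = {}
        for name, den_key in (("indirect_over_population", "population"),
                              ("indirect_over_direct", "direct")):
            num = quant.get("indirect", np.nan)
            den = quant.get(den_key, np.nan)
            if not np.isfinite(den) or abs(den) < RATIO_GUARD:
                entry[name] = np.nan
                entry[f"{name}_unstable"] = True
            else:
                entry[name] = num / den
                entry[f"{name}_unstable"] = False
        out[c] = entry
    return out


def z_difference(a: float, b: float, se_a: Optional[float] = None,
                 se_b: Optional[float] = None,
                 draws_a: Optional[np.ndarray] = None,
                 draws_b: Optional[np.ndarray] = None):
    """Two-sided Wald Z-test for the difference a - b.

    With paired bootstrap draws the SE is the standard deviation of the
    per-replicate differences; otherwise independent SEs are combined as
    sqrt(se_a^2 + se_b^2).
    """
    if draws_a is not None and draws_b is not None:
        draws_a = np.asarray(draws_a, dtype=float)
        draws_b = np.asarray(draws_b, dtype=float)
        if draws_a.shape != draws_b.shape:
            raise ParameterError("paired draws must have equal length")
        se = float(np.std(draws_a - draws_b, ddof=1))
    elif se_a is not None and se_b is not None:
        se = float(np.sqrt(se_a ** 2 + se_b ** 2))
    else:
        raise ParameterError("provide either paired draws or both SEs")
    if se == 0:
        if a == b:
            return 0.0, 1.0
        raise DegenerateInputError("zero SE for a nonzero difference")
    z = (a - b) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Bootstrap summary for the derived quantities of one design fit."""

    point: dict                  # (construct, quantity) -> estimate
    se: dict                     # (construct, quantity) -> bootstrap SE
    ci: dict                     # (construct, quantity) -> (lo, hi)
    draws: pd.DataFrame          # B x quantities replicate draws
    B: int
    n_failed: int
    seed: Optional[int]
    scheme: str
    level: float
    ci_method: str

    def summary(self) -> pd.DataFrame:
        rows = []
        for key, val in self.point.items():
            c, q = key
            lo, hi = self.ci.get(key, (np.nan, np.nan))
            rows.append({"construct": c, "quantity": q, "estimate": val,
                         "se": self.se.get(key, np.nan),
                         "ci_lower": lo, "ci_upper": hi})
        return pd.DataFrame(rows)


def _derived_quantities(est_set) -> dict:
    out = {}
    for c, quant in est_set.estimates.items():
        for q, v in quant.items():
            out[(c, q)] = v
    rs = ratio_stats(est_set)
    for c, entry in rs.items():
        for name in ("indirect_over_population", "indirect_over_direct"):
            out[(c, name)] = entry[name]
    return out


class _FamilyResampler:
    """Resample whole families with replacement, relabelling the draws so a
    family sampled twice counts as two distinct families downstream."""

    def __init__(self, table: pd.DataFrame):
        self.table = table.reset_index(drop=True)
        codes, _ = pd.factorize(self.table["family_id"], sort=False)
        order = np.argsort(codes, kind="stable")
        counts = np.bincount(codes)
        self.rows_by_fam = np.split(order, np.cumsum(counts)[:-1])
        self.sizes = counts

    def __call__(self, rng) -> pd.DataFrame:
        k = len(self.rows_by_fam)
        draw = rng.integers(0, k, size=k)
        idx = np.concatenate([self.rows_by_fam[d] for d in draw])
        out = self.table.take(idx)
        new_ids = np.repeat(np.arange(k), self.sizes[draw])
        out = out.reset_index(drop=True)
        out["family_id"] = new_ids
        out["rearing_family_id"] = new_ids
        return out


class _StrataResampler:
    """Resample adoptee and non-adopted offspring rows separately."""

    def __init__(self, table: pd.DataFrame):
        self.table = table.reset_index(drop=True)
        off = self.table["role"] == "offspring"
        self.ad = np.flatnonzero(off & self.table["adopted"])
        self.non = np.flatnonzero(off & ~self.table["adopted"])

    def __call__(self, rng) -> pd.DataFrame:
        rows = np.concatenate([
            self.ad[rng.integers(0, len(self.ad), size=len(self.ad))],
            self.non[rng.integers(0, len(self.non), size=len(self.non))]])
        out = self.table.take(rows).reset_index(drop=True)
        # duplicated persons must count as distinct sampling units downstream
        out["family_id"] = np.arange(len(out))
        out["rearing_family_id"] = out["family_id"]
        return out


def bootstrap_design(design_fn: Callable, table: pd.DataFrame,
                     B: int = 10_000, seed: Optional[int] = None,
                     scheme: str = "family", level: float = 0.95,
                     ci_method: str = "bias-corrected-normal",
                     max_fail_frac: float = 0.01,
                     **design_kwargs) -> BootstrapResult:
    """Ordinary nonparametric bootstrap of a design fitter.

    ``scheme='family'`` resamples families with replacement (sibling / trio
    designs; one draw feeds every regression inside the fitter), while
    ``scheme='two-strata'`` resamples adoptees and non-adopted rows
    separately (adoption design).  Replicates where the fitter fails are
    dropped and counted; more than ``max_fail_frac`` failures raise.
    """
    if B < 100:
        raise ParameterError("B must be >= 100")
    if scheme not in ("family", "two-strata"):
        raise ParameterError("scheme must be 'family' or 'two-strata'")
    if ci_method not in ("bias-corrected-normal", "percentile"):
        raise ParameterError("unknown ci_method")
    rng = np.random.default_rng(seed)
    point_set = design_fn(table, **design_kwargs)
    point = _derived_quantities(point_set)
    resample = (_FamilyResampler(table) if scheme == "family"
                else _StrataResampler(table))

    draws = []
    n_failed = 0
    for _ in range(B):
        boot = resample(rng)
        try:
            rep = design_fn(boot, **design_kwargs)
            draws.append(_derived_quantities(rep))
        except Exception:
            n_failed += 1
            if n_failed > max_fail_frac * B:
                raise StructuralError(
                    f"more than {100 * max_fail_frac:.0f}% of bootstrap "
                    "replicates failed")
    dmat = pd.DataFrame(draws)
    z = stats.norm.ppf(0.5 + level / 2)
    se, ci = {}, {}
    for key in point:
        x = dmat[key].to_numpy(dtype=float)
        finite = np.isfinite(x)
        if finite.sum() < 2 or not np.isfinite(point[key]):
            se[key] = np.nan
            ci[key] = (np.nan, np.nan)
            continue
        x = x[finite]
        s = float(np.std(x, ddof=1))
        se[key] = s
        if ci_method == "bias-corrected-normal":
            centre = 2 * point[key] - float(np.mean(x))
            ci[key] = (centre - z * s, centre + z * s)
        else:
            ci[key] = tuple(np.quantile(x, [0.5 - level / 2,
                                            0.5 + level / 2]))
    return BootstrapResult(point=point, se=se, ci=ci, draws=dmat, B=B,
                           n_failed=n_failed, seed=seed, scheme=scheme,
                           level=level, ci_method=ci_method)


# ---------------------------------------------------------------------------
# Meta-analysis
# ---------------------------------------------------------------------------


@dataclass
class MetaResult:
    pooled: float
    se: float
    ci: tuple
    tau2_within: float
    tau2_design: float
    k: int
    weights: np.ndarray
    method: str


def _reml_nll(theta, y, v, Z):
    """Negative restricted log-likelihood; theta = sqrt-scale components."""
    tau2_w = theta[0] ** 2
    tau2_d = theta[1] ** 2 if len(theta) > 1 else 0.0
    V = np.diag(v + tau2_w)
    if Z is not None:
        V = V + tau2_d * (Z @ Z.T)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return 1e12
    k = len(y)
    X = np.ones((k, 1))
    Vi_X = np.linalg.solve(V, X)
    Vi_y = np.linalg.solve(V, y)
    XtViX = (X.T @ Vi_X).item()
    mu = (X.T @ Vi_y).item() / XtViX
    r = y - mu
    Vi_r = np.linalg.solve(V, r)
    logdet = 2 * np.sum(np.log(np.diag(L)))
    return 0.5 * (logdet + np.log(XtViX) + float(r @ Vi_r))


def meta_analyze(estimates, ses=None, design=None,
                 random_intercept: bool = True,
                 level: float = 0.95) -> MetaResult:
    """Random-effects pooling with an optional design-level random intercept.

    Parameters may be given as arrays (``estimates``, ``ses``, ``design``
    labels) or as a DataFrame with columns ``beta``, ``se`` and optionally
    ``design``.  Variance components (residual heterogeneity tau2_within and
    between-design tau2_design) are estimated by REML; the pooled effect is
    the GLS mean under the fitted marginal covariance.
    """
    if isinstance(estimates, pd.DataFrame):
        df = estimates
        y = df["beta"].to_numpy(dtype=float)
        v = df["se"].to_numpy(dtype=float) ** 2
        labels = df["design"].to_numpy() if "design" in df else None
    else:
        y = np.asarray(estimates, dtype=float)
        if ses is None:
            raise ParameterError("ses required with array input")
        v = np.asarray(ses, dtype=float) ** 2
        labels = np.asarray(design) if design is not None else None
    k = len(y)
    if np.any(v <= 0):
        raise ParameterError("all SEs must be positive")
    if k == 1:
        warnings.warn("meta_analyze: single estimate, returned unchanged",
                      stacklevel=2)
        z = stats.norm.ppf(0.5 + level / 2)
        s = float(np.sqrt(v[0]))
        return MetaResult(pooled=float(y[0]), se=s,
                          ci=(y[0] - z * s, y[0] + z * s), tau2_within=0.0,
                          tau2_design=0.0, k=1, weights=np.array([1.0]),
                          method="passthrough")

    use_intercept = (random_intercept and labels is not None
                     and len(np.unique(labels)) > 1)
    Z = None
    if use_intercept:
        uniq = np.unique(labels)
        Z = (labels[:, None] == uniq[None, :]).astype(float)

    n_par = 2 if use_intercept else 1
    sd0 = max(float(np.std(y, ddof=1)), 1e-4)
    best = None
    for start in ([sd0 / 2] * n_par, [sd0] * n_par, [1e-3] * n_par):
        res = optimize.minimize(_reml_nll, x0=np.asarray(start),
                                args=(y, v, Z), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    tau2_w = float(best.x[0] ** 2)
    tau2_d = float(best.x[1] ** 2) if use_intercept else 0.0

    V = np.diag(v + tau2_w)
    if Z is not None:
        V = V + tau2_d * (Z @ Z.T)
    Vi_1 = np.linalg.solve(V, np.ones(k))
    denom = float(np.ones(k) @ Vi_1)
    pooled = float(Vi_1 @ y) / denom
    se = float(np.sqrt(1.0 / denom))
    zq = stats.norm.ppf(0.5 + level / 2)
    weights = Vi_1 / denom
    return MetaResult(pooled=pooled, se=se,
                      ci=(pooled - zq * se, pooled + zq * se),
                      tau2_within=tau2_w, tau2_design=tau2_d, k=k,
                      weights=weights,
                      method="reml-two-level" if use_intercept else "reml")


# ---------------------------------------------------------------------------
# PGS correlation diagnostics
# ---------------------------------------------------------------------------


def _fisher_ci(r, n, level=0.95):
    if n <= 3:
        return (np.nan, np.nan)
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def double_entry_icc(a, b):
    """Intraclass correlation by double entry: Pearson r of the stacked
    (a, b) and (b, a) orderings."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    x = np.concatenate([a, b])
    y = np.concatenate([b, a])
    return float(np.corrcoef(x, y)[0, 1])


def pgs_correlation_diagnostics(table: pd.DataFrame, min_pairs: int = 30
                                ) -> pd.DataFrame:
    """Sibling double-entry ICC and spousal Pearson r per construct.

    Sibling pairs are the first two non-adopted offspring of each
    multi-offspring family; couples are each family's father and mother.
    Under random mating with no population structure the sibling ICC is 0.5
    and the spousal correlation 0; elevations indicate assortative mating
    (or stratification).  CIs use the Fisher transform.
    """
    off = table.loc[(table["role"] == "offspring") & ~table["adopted"]]
    fams = off.groupby("family_id")
    pairs = {c: ([], []) for c in CONSTRUCTS}
    for _, g in fams:
        if len(g) < 2:
            continue
        for c in CONSTRUCTS:
            vals = g[f"pgs_{c}"].to_numpy()
            pairs[c][0].append(vals[0])
            pairs[c][1].append(vals[1])
    n_pairs = len(pairs[CONSTRUCTS[0]][0])

    fathers = table.loc[table["role"] == "father"].set_index("family_id")
    mothers = table.loc[table["role"] == "mother"].set_index("family_id")
    common = fathers.index.intersection(mothers.index)
    n_couples = len(common)
    if n_pairs < min_pairs or n_couples < min_pairs:
        raise StructuralError(
            f"need >= {min_pairs} sibling pairs and couples "
            f"(have {n_pairs} / {n_couples})")

    rows = []
    for c in CONSTRUCTS:
        icc = double_entry_icc(*[np.asarray(p) for p in pairs[c]])
        lo, hi = _fisher_ci(icc, 2 * n_pairs)
        rows.append({"construct": c, "statistic": "sibling_icc",
                     "value": icc, "n": n_pairs, "ci_lower": lo,
                     "ci_upper": hi})
        r = float(np.corrcoef(fathers.loc[common, f"pgs_{c}"],
                              mothers.loc[common, f"pgs_{c}"])[0, 1])
        lo, hi = _fisher_ci(r, n_couples)
        rows.append({"construct": c, "statistic": "spousal_r", "value": r,
                     "n": n_couples, "ci_lower": lo, "ci_upper": hi})
    return pd.DataFrame(rows)
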