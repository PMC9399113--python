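"""The three family-based polygenic score designs and sensitivity models.

Each fitter regresses a standardized educational-style outcome on Cog and
NonCog polygenic scores (always jointly) plus covariates, and reports the
population, direct and parental indirect genetic effects its design
identifies:

* sibling design — within-family (sibling-deviation) and between-family
  effects in one model, the population effect in a separate model on the
  same rows; indirect = population - within;
* adoption design — the population model fit separately in adoptees and
  non-adopted individuals; indirect = population(non-adopted) -
  direct(adoptees);
* trio design — transmitted and non-transmitted parental score composites in
  one model; indirect = beta_NT, direct = beta_T - beta_NT.

Sensitivity models: the quad model adds co-sibling scores to the trio
regression; the MZ/DZ contrast compares population effects between twin
types; the sibship-size moderation tests PGS x number-of-siblings
interactions with adoptees as a negative control.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (DegenerateInputError, ParameterError, SingularityError,
                     StructuralError)
from .scores import CONSTRUCTS, add_family_stats, standardize_for_design, _scale_cols

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------


@dataclass
class OLSFit:
    params: pd.Series
    se: pd.Series
    resid: np.ndarray
    nobs: int
    sigma2: float
    cov: pd.DataFrame

    def conf_int(self, level=0.95):
        z = stats.norm.ppf(0.5 + level / 2)
        lo = self.params - z * self.se
        hi = self.params + z * self.se
        return pd.DataFrame({"lower": lo, "upper": hi})


def fit_ols(y, X: pd.DataFrame, add_intercept: bool = True) -> OLSFit:
    """Ordinary least squares with named columns and a singularity guard.

    Raises :class:`SingularityError` naming the collinear columns when the
    design matrix is rank deficient.
    """
    y = np.asarray(y, dtype=float)
    if add_intercept:
        X = X.copy()
        X.insert(0, "intercept", 1.0)
    cols = list(X.columns)
    A = X.to_numpy(dtype=float)
    n, p = A.shape
    if n <= p:
        raise StructuralError(f"n={n} observations for p={p} parameters")
    if np.isnan(A).any() or np.isnan(y).any():
        raise StructuralError("NaN in regression inputs")
    # rank check via QR: small diagonal entries flag the collinear columns
    _, R, piv = _qr_pivoted(A)
    diag = np.abs(np.diag(R))
    tol = max(n, p) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    bad = diag <= tol
    if bad.any():
        names = [cols[piv[i]] for i in np.flatnonzero(bad)]
        raise SingularityError(
            f"rank-deficient design matrix; collinear columns: {names}",
            columns=names)
    beta, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sigma2 = float(resid @ resid) / (n - p)
    xtx_inv = np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    return OLSFit(params=pd.Series(beta, index=cols),
                  se=pd.Series(se, index=cols),
                  resid=resid, nobs=n, sigma2=sigma2,
                  cov=pd.DataFrame(xtx_inv * sigma2, index=cols,
                                   columns=cols))


def _qr_pivoted(A):
    from scipy.linalg import qr
    Q, R, piv = qr(A, mode="economic", pivoting=True)
    return Q, R, piv


def build_covariates(table: pd.DataFrame, pcs: Optional[pd.DataFrame] = None,
                     platform: Optional[str] = None) -> pd.DataFrame:
    """Standard covariate set: sex, age, sex x age, optional PCs, platform.

    Constant columns (e.g. a single genotyping platform) are dropped with a
    log line rather than raising.
    """
    cov = pd.DataFrame(index=table.index)
    cov["sex"] = table["sex"].astype(float)
    cov["age"] = table["age"].astype(float)
    cov["sex_x_age"] = cov["sex"] * cov["age"]
    if pcs is not None:
        for col in pcs.columns:
            cov[col] = pcs.loc[table.index, col].astype(float)
    if platform is not None and platform in table:
        dummies = pd.get_dummies(table[platform], prefix=platform,
                                 drop_first=True, dtype=float)
        cov = pd.concat([cov, dummies], axis=1)
    keep = [c for c in cov.columns if cov[c].nunique() > 1]
    dropped = sorted(set(cov.columns) - set(keep))
    if dropped:
        log.info("build_covariates: dropped constant columns %s", dropped)
    return cov[keep]


# ---------------------------------------------------------------------------
# Estimate container
# ---------------------------------------------------------------------------


@dataclass
class EstimateSet:
    """Fitted coefficients of one design, per construct.

    ``estimates[construct][quantity]`` and ``ses[construct][quantity]`` hold
    point estimates and (naive analytic) standard errors.  Derived
    identities are computed exactly from the fitted coefficients:
    sibling: indirect = population - within; trio: direct = beta_t -
    beta_nt; adoption: indirect = population - direct.
    """

    design: str
    estimates: dict
    ses: dict
    n_persons: int
    n_families: int
    intercept: float = float("nan")
    extra: dict = field(default_factory=dict)

    def get(self, construct: str, quantity: str) -> float:
        return self.estimates[construct][quantity]

    def se(self, construct: str, quantity: str) -> float:
        return self.ses[construct].get(quantity, float("nan"))

    def quantities(self):
        return {(c, q): v for c, d in self.estimates.items()
                for q, v in d.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.estimates:
            for q, v in self.estimates[c].items():
                rows.append({"design": self.design, "construct": c,
                             "quantity": q, "estimate": v,
                             "se": self.ses[c].get(q, np.nan)})
        return pd.DataFrame(rows)


def _pgs_terms(prefix=""):
    return [f"{prefix}{c}" for c in CONSTRUCTS]


def _std_outcome(tab, rows, outcome):
    y = tab.loc[rows, outcome].to_numpy(dtype=float)
    sd = y.std()
    if sd == 0 or not np.isfinite(sd):
        raise DegenerateInputError("constant outcome in analysis group")
    return (y - y.mean()) / sd


# ---------------------------------------------------------------------------
# Main designs
# ---------------------------------------------------------------------------


def sibling_design(table: pd.DataFrame, covariates=None,
                   outcome: str = "y") -> EstimateSet:
    """Within/between-family and population PGS effects among siblings.

    Uses non-adopted offspring in families with at least two genotyped
    siblings, keeping one member of each MZ pair (identical genotypes add no
    within-family information).  Scores are standardized on this sibling
    sample, the outcome within the same group.  Two regressions on identical
    rows: (1) within-family deviation + family mean, (2) population.  The
    covariate set is the same in both so the subtraction
    indirect = population - within is internally consistent.
    """
    tab = table.copy()
    off = (tab["role"] == "offspring") & (~tab["adopted"])
    mz_dup = off & (tab["zygosity"] == "MZ") & \
        tab.loc[off].groupby("family_id").cumcount().reindex(
            tab.index, fill_value=0).astype(bool) & \
        (tab["zygosity"] == "MZ")
    n_mz_dropped = int(mz_dup.sum())
    if n_mz_dropped:
        log.info("sibling_design: dropped %d MZ co-twins", n_mz_dropped)
    tab = tab.loc[~mz_dup]
    off = (tab["role"] == "offspring") & (~tab["adopted"])
    sizes = tab.loc[off].groupby("family_id")["person_id"].transform("size")
    keep = off.copy()
    keep.loc[off] = (sizes >= 2).to_numpy()
    n_single = int(off.sum() - keep.sum())
    if n_single:
        log.info("sibling_design: dropped %d singletons", n_single)
    if keep.sum() == 0:
        raise StructuralError("no families with >= 2 genotyped siblings")

    sub = tab.loc[keep].copy()
    sub = _scale_cols(sub, pd.Series(True, index=sub.index),
                      [f"pgs_{c}" for c in CONSTRUCTS])
    sub = add_family_stats(sub)
    y = _std_outcome(sub, pd.Series(True, index=sub.index), outcome)
    cov = covariates.loc[sub.index] if covariates is not None else \
        pd.DataFrame(index=sub.index)

    X1 = pd.DataFrame(index=sub.index)
    for c in CONSTRUCTS:
        X1[f"within_{c}"] = sub[f"pgs_dev_{c}"]
        X1[f"between_{c}"] = sub[f"pgs_fam_mean_{c}"]
    fit1 = fit_ols(y, pd.concat([X1, cov], axis=1))

    X2 = pd.DataFrame(index=sub.index)
    for c in CONSTRUCTS:
        X2[f"population_{c}"] = sub[f"pgs_{c}"]
    fit2 = fit_ols(y, pd.concat([X2, cov], axis=1))

    est, ses = {}, {}
    for c in CONSTRUCTS:
        within = fit1.params[f"within_{c}"]
        between = fit1.params[f"between_{c}"]
        pop = fit2.params[f"population_{c}"]
        est[c] = {"within": within, "between": between,
                  "population": pop, "direct": within,
                  "indirect": pop - within}
        ses[c] = {"within": fit1.se[f"within_{c}"],
                  "between": fit1.se[f"between_{c}"],
                  "population": fit2.se[f"population_{c}"],
                  "direct": fit1.se[f"within_{c}"],
                  "indirect": float(np.sqrt(fit1.se[f"within_{c}"] ** 2
                                            + fit2.se[f"population_{c}"] ** 2))}
    return EstimateSet(design="sibling", estimates=est, ses=ses,
                       n_persons=int(keep.sum()),
                       n_families=int(sub["family_id"].nunique()),
                       intercept=float(fit2.params["intercept"]),
                       extra={"n_mz_dropped": n_mz_dropped,
                              "n_singletons_dropped": n_single})


def adoption_design(table: pd.DataFrame, covariates=None,
                    outcome: str = "y", controls: str = "one_per_family",
                    seed=0) -> EstimateSet:
    """Population-model contrast between adoptees and non-adopted individuals.

    The population effect comes from the non-adopted group (by default one
    randomly chosen non-adopted offspring per family, mimicking an unrelated
    control sample; ``controls='all'`` uses every non-adopted offspring, e.g.
    when the caller has already drawn the control sample), the direct effect
    from the adoptees; scores and outcome are scaled within each group
    separately.  indirect = population - direct.
    """
    if controls not in ("one_per_family", "all"):
        raise ParameterError("controls must be 'one_per_family' or 'all'")
    tab = table.copy()
    off = tab["role"] == "offspring"
    ad = off & tab["adopted"]
    non = off & ~tab["adopted"]
    if controls == "one_per_family":
        rng = np.random.default_rng(seed)
        idx = tab.index[non].to_numpy()
        perm = rng.permutation(len(idx))
        fams = tab.loc[idx[perm], "family_id"].to_numpy()
        first = idx[perm][~pd.Series(fams).duplicated().to_numpy()]
        non = pd.Series(False, index=tab.index)
        non.loc[first] = True
    if ad.sum() == 0:
        raise StructuralError("no adoptees in table")
    if non.sum() == 0:
        raise StructuralError("no non-adopted controls in table")

    def _fit(rows):
        sub = tab.loc[rows].copy()
        sub = _scale_cols(sub, pd.Series(True, index=sub.index),
                          [f"pgs_{c}" for c in CONSTRUCTS])
        y = _std_outcome(sub, pd.Series(True, index=sub.index), outcome)
        cov = covariates.loc[sub.index] if covariates is not None else \
            pd.DataFrame(index=sub.index)
        X = pd.DataFrame({f"pgs_{c}": sub[f"pgs_{c}"] for c in CONSTRUCTS},
                         index=sub.index)
        p = X.shape[1] + cov.shape[1] + 1
        if len(sub) < 10 * p:
            warnings.warn(f"adoption_design: group n={len(sub)} < 10 x p={p}",
                          stacklevel=2)
        return fit_ols(y, pd.concat([X, cov], axis=1))

    fit_ad = _fit(ad)
    fit_non = _fit(non)
    est, ses = {}, {}
    for c in CONSTRUCTS:
        direct = fit_ad.params[f"pgs_{c}"]
        pop = fit_non.params[f"pgs_{c}"]
        est[c] = {"direct": direct, "population": pop,
                  "indirect": pop - direct}
        ses[c] = {"direct": fit_ad.se[f"pgs_{c}"],
                  "population": fit_non.se[f"pgs_{c}"],
                  "indirect": float(np.sqrt(fit_ad.se[f"pgs_{c}"] ** 2
                                            + fit_non.se[f"pgs_{c}"] ** 2))}
    return EstimateSet(design="adoption", estimates=est, ses=ses,
                       n_persons=int(ad.sum() + non.sum()),
                       n_families=int(tab.loc[ad | non,
                                              "family_id"].nunique()),
                       intercept=float(fit_non.params["intercept"]),
                       extra={"n_adoptees": int(ad.sum()),
                              "n_controls": int(non.sum())})


def trio_design(table: pd.DataFrame, covariates=None, outcome: str = "y",
                nt_convention: str = "average") -> EstimateSet:
    """Transmitted / non-transmitted parental score regression.

    One regression with the transmitted and non-transmitted composites of
    both constructs (plus covariates) among non-adopted offspring with both
    parental scores.  indirect = beta_NT; direct = beta_T - beta_NT; the
    population analogue is beta_T.
    """
    tab = table.copy()
    need = [f"pgs_{k}_{c}" for k in ("t_pat", "t_mat", "nt_pat", "nt_mat")
            for c in CONSTRUCTS]
    rows = (tab["role"] == "offspring") & (~tab["adopted"]) & \
        tab[need].notna().all(axis=1)
    n_dropped = int(((tab["role"] == "offspring") & ~tab["adopted"]).sum()
                    - rows.sum())
    if n_dropped:
        log.info("trio_design: dropped %d offspring with missing parents",
                 n_dropped)
    if rows.sum() == 0:
        raise StructuralError("no complete trios")
    sub = standardize_for_design(tab.loc[rows], "trio",
                                 trio_convention=nt_convention)
    y = _std_outcome(sub, pd.Series(True, index=sub.index), outcome)
    cov = covariates.loc[sub.index] if covariates is not None else \
        pd.DataFrame(index=sub.index)
    X = pd.DataFrame(index=sub.index)
    for c in CONSTRUCTS:
        X[f"t_{c}"] = sub[f"pgs_t_{c}"]
        X[f"nt_{c}"] = sub[f"pgs_nt_{c}"]
    fit = fit_ols(y, pd.concat([X, cov], axis=1))
    est, ses = {}, {}
    for c in CONSTRUCTS:
        bt = fit.params[f"t_{c}"]
        bnt = fit.params[f"nt_{c}"]
        var = fit.cov.loc[f"t_{c}", f"t_{c}"] + \
            fit.cov.loc[f"nt_{c}", f"nt_{c}"] - \
            2 * fit.cov.loc[f"t_{c}", f"nt_{c}"]
        est[c] = {"beta_t": bt, "beta_nt": bnt, "population": bt,
                  "indirect": bnt, "direct": bt - bnt}
        ses[c] = {"beta_t": fit.se[f"t_{c}"], "beta_nt": fit.se[f"nt_{c}"],
                  "population": fit.se[f"t_{c}"],
                  "indirect": fit.se[f"nt_{c}"],
                  "direct": float(np.sqrt(max(var, 0.0)))}
    return EstimateSet(design="trio", estimates=est, ses=ses,
                       n_persons=int(rows.sum()),
                       n_families=int(sub["family_id"].nunique()),
                       intercept=float(fit.params["intercept"]),
                       extra={"n_missing_parent_dropped": n_dropped})


# ---------------------------------------------------------------------------
# Sensitivity models
# ---------------------------------------------------------------------------


def sibling_effects_model(table: pd.DataFrame, covariates=None,
                          outcome: str = "y",
                          nt_convention: str = "average") -> EstimateSet:
    """Trio regression augmented with co-sibling scores ('quad' model).

    Requires DZ twin pairs (or two-offspring sibships) with both parents'
    transmitted / non-transmitted scores.  Each offspring of a pair enters
    as index child with the co-sibling's own score as an extra predictor.
    """
    tab = table.copy()
    off = (tab["role"] == "offspring") & (~tab["adopted"])
    sizes = tab.loc[off].groupby("family_id")["person_id"].transform("size")
    keep = off.copy()
    keep.loc[off] = (sizes >= 2).to_numpy()
    n_dropped = int(off.sum() - keep.sum())
    if n_dropped:
        log.info("sibling_effects_model: dropped %d offspring without "
                 "a co-sibling", n_dropped)
    if keep.sum() == 0:
        raise StructuralError("no multi-offspring families")
    sub = tab.loc[keep].copy()
    # co-sibling own score: mean of the other offspring in the family
    for c in CONSTRUCTS:
        grp = sub.groupby("family_id")[f"pgs_{c}"]
        tot = grp.transform("sum")
        cnt = grp.transform("size")
        sub[f"pgs_sib_{c}"] = (tot - sub[f"pgs_{c}"]) / (cnt - 1)
    sub = standardize_for_design(sub, "trio", trio_convention=nt_convention)
    sub = _scale_cols(sub, pd.Series(True, index=sub.index),
                      [f"pgs_sib_{c}" for c in CONSTRUCTS])
    y = _std_outcome(sub, pd.Series(True, index=sub.index), outcome)
    cov = covariates.loc[sub.index] if covariates is not None else \
        pd.DataFrame(index=sub.index)
    X = pd.DataFrame(index=sub.index)
    for c in CONSTRUCTS:
        X[f"t_{c}"] = sub[f"pgs_t_{c}"]
        X[f"nt_{c}"] = sub[f"pgs_nt_{c}"]
        X[f"sib_{c}"] = sub[f"pgs_sib_{c}"]
    fit = fit_ols(y, pd.concat([X, cov], axis=1))
    est, ses = {}, {}
    for c in CONSTRUCTS:
        est[c] = {"beta_t": fit.params[f"t_{c}"],
                  "beta_nt": fit.params[f"nt_{c}"],
                  "beta_sibling": fit.params[f"sib_{c}"]}
        ses[c] = {"beta_t": fit.se[f"t_{c}"], "beta_nt": fit.se[f"nt_{c}"],
                  "beta_sibling": fit.se[f"sib_{c}"]}
    return EstimateSet(design="quad", estimates=est, ses=ses,
                       n_persons=int(keep.sum()),
                       n_families=int(sub["family_id"].nunique()),
                       intercept=float(fit.params["intercept"]))


def mzdz_contrast(table: pd.DataFrame, covariates=None,
                  outcome: str = "y"):
    """Population PGS effects in MZ versus DZ twins, with a difference Z.

    One individual per twin pair enters each subset; the population model is
    fit per subset, and a pooled-SE Z statistic for beta_MZ - beta_DZ is
    returned per construct.  A positive sibling genetic effect predicts
    beta_MZ > beta_DZ because an MZ twin's score fully captures the co-twin's
    genotype.
    """
    tab = table.copy()

    def _subset(zyg):
        rows = (tab["role"] == "offspring") & (~tab["adopted"]) & \
            (tab["zygosity"] == zyg)
        sub = tab.loc[rows]
        first = ~sub["family_id"].duplicated()
        return sub.loc[first]

    results = {}
    for zyg in ("MZ", "DZ"):
        sub = _subset(zyg).copy()
        if len(sub) == 0:
            raise StructuralError(f"empty {zyg} subset")
        sub = _scale_cols(sub, pd.Series(True, index=sub.index),
                          [f"pgs_{c}" for c in CONSTRUCTS])
        y = _std_outcome(sub, pd.Series(True, index=sub.index), outcome)
        cov = covariates.loc[sub.index] if covariates is not None else \
            pd.DataFrame(index=sub.index)
        X = pd.DataFrame({f"pgs_{c}": sub[f"pgs_{c}"] for c in CONSTRUCTS},
                         index=sub.index)
        fit = fit_ols(y, pd.concat([X, cov], axis=1))
        est = {c: {"population": fit.params[f"pgs_{c}"]} for c in CONSTRUCTS}
        ses = {c: {"population": fit.se[f"pgs_{c}"]} for c in CONSTRUCTS}
        results[zyg] = EstimateSet(design=f"population-{zyg}", estimates=est,
                                   ses=ses, n_persons=len(sub),
                                   n_families=int(sub["family_id"].nunique()),
                                   intercept=float(fit.params["intercept"]))
    zstats = {}
    for c in CONSTRUCTS:
        d = results["MZ"].get(c, "population") - results["DZ"].get(
            c, "population")
        se = np.sqrt(results["MZ"].se(c, "population") ** 2
                     + results["DZ"].se(c, "population") ** 2)
        z = d / se
        zstats[c] = {"diff": d, "se": float(se), "z": float(z),
                     "p": float(2 * stats.norm.sf(abs(z)))}
    return results["MZ"], results["DZ"], zstats


@dataclass
class ModerationResult:
    group: str
    estimable: bool
    interactions: dict = field(default_factory=dict)
    ses: dict = field(default_factory=dict)
    n: int = 0
    reason: str = ""


def nsib_moderation(table: pd.DataFrame, covariates=None, outcome: str = "y",
                    group: str = "biological") -> ModerationResult:
    """PGS x sibship-size interaction, in biological or adopted sibships.

    A positive sibling genetic effect should make the own-PGS effect grow
    with the number of (genetically related) siblings; adoptees, unrelated
    to their rearing siblings, are the negative control.  A constant sibship
    size makes the interaction inestimable, which is flagged rather than
    raised.
    """
    if group not in ("biological", "adopted"):
        raise ParameterError("group must be 'biological' or 'adopted'")
    tab = table.copy()
    off = tab["role"] == "offspring"
    rows = off & (tab["adopted"] if group == "adopted" else ~tab["adopted"])
    if rows.sum() == 0:
        raise StructuralError(f"no rows in group {group!r}")
    sub = tab.loc[rows].copy()
    nsib = sub["n_sibship"].to_numpy(dtype=float) - 1.0
    if np.nanstd(nsib) == 0:
        return ModerationResult(group=group, estimable=False, n=len(sub),
                                reason="constant sibship size")
    sub = _scale_cols(sub, pd.Series(True, index=sub.index),
                      [f"pgs_{c}" for c in CONSTRUCTS])
    y = _std_outcome(sub, pd.Series(True, index=sub.index), outcome)
    cov = covariates.loc[sub.index] if covariates is not None else \
        pd.DataFrame(index=sub.index)
    X = pd.DataFrame(index=sub.index)
    for c in CONSTRUCTS:
        X[f"pgs_{c}"] = sub[f"pgs_{c}"]
    X["nsib"] = nsib
    for c in CONSTRUCTS:
        X[f"pgs_{c}_x_nsib"] = sub[f"pgs_{c}"].to_numpy() * nsib
    fit = fit_ols(y, pd.concat([X, cov], axis=1))
    inter = {c: float(fit.params[f"pgs_{c}_x_nsib"]) for c in CONSTRUCTS}
    ses = {c: float(fit.se[f"pgs_{c}_x_nsib"]) for c in CONSTRUCTS}
    return ModerationResult(group=group, estimable=True, interactions=inter,
                            ses=ses, n=len(sub))


def nsib_contrast(bio: ModerationResult, adopted: ModerationResult) -> dict:
    """Biological-minus-adoptee interaction contrast per construct."""
    if not (bio.estimable and adopted.estimable):
        raise DegenerateInputError("both groups must be estimable")
    out = {}
    for c in CONSTRUCTS:
        d = bio.interactions[c] - adopted.interactions[c]
        se = float(np.sqrt(bio.ses[c] ** 2 + adopted.ses[c] ** 2))
        out[c] = {"diff": d, "se": se, "z": d / se}
    return out
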