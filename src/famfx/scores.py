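"""Polygenic score computation and design-specific standardization.

Builds per-person scores from dosages and a weight table (own score,
transmitted / non-transmitted parental haplotype scores, family means and
within-family deviations), applies the scaling conventions each family
design expects, and computes ancestry principal components.

Raw-scale identities that hold exactly, per construct, for every cohort:

* ``pgs_t_pat + pgs_t_mat == own pgs`` for every offspring,
* ``pgs_t_pat + pgs_nt_pat == father's own pgs`` (same maternally),
* within-family deviations sum to zero inside each sibship.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
import pandas as pd

from .errors import (AlignmentError, DegenerateInputError, ParameterError,
                     StructuralError)
from .simkit import CONSTRUCTS, FamilyCohort

log = logging.getLogger(__name__)

DESIGNS = ("sibling", "adoption", "trio")


def align_weights(snps: pd.DataFrame, weights: pd.DataFrame):
    """Align a weight table to the counted allele of a SNP table.

    The weight's ``effect_allele`` defines which allele the weight counts.
    If it matches the SNP table's counted allele ``a1`` the weight is used as
    is; if it matches ``a2`` the weight is negated and a per-haplotype
    constant is accumulated so that scores are identical to counting the
    effect allele directly.  Unknown SNPs or alleles raise.

    Returns
    -------
    (w, hap_offset) : (ndarray (m, 2), ndarray (2,))
        Aligned per-a1-allele weights and the constant added per haplotype.
    """
    wtab = weights.set_index("snp_id")
    missing = [s for s in snps["snp_id"] if s not in wtab.index]
    if missing:
        raise AlignmentError(
            f"{len(missing)} SNPs missing from weight table "
            f"(first: {missing[0]})")
    wtab = wtab.loc[snps["snp_id"]]
    eff = wtab["effect_allele"].to_numpy()
    a1 = snps["a1"].to_numpy()
    a2 = snps["a2"].to_numpy()
    w = wtab[["weight_cog", "weight_noncog"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(w)):
        raise AlignmentError("non-finite weights")
    same = eff == a1
    flip = eff == a2
    bad = ~(same | flip)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise AlignmentError(
            f"effect allele {eff[i]!r} of {snps['snp_id'].iloc[i]} matches "
            f"neither allele ({a1[i]}/{a2[i]})")
    out = np.where(flip[:, None], -w, w)
    hap_offset = w[flip].sum(axis=0)
    return out, hap_offset


def compute_pgs(dosages, snps: pd.DataFrame, weights: pd.DataFrame,
                missing: str = "error") -> np.ndarray:
    """Weighted allele sum per person and construct.

    ``dosages`` is (n_persons, m_snps) counts of the SNP table's ``a1``
    allele.  Missing dosages (NaN) raise by default; with
    ``missing='mean'`` they are imputed with the per-SNP mean.
    """
    d = np.asarray(dosages, dtype=float)
    if d.ndim != 2 or d.shape[1] != len(snps):
        raise AlignmentError(
            f"dosage matrix has {d.shape[1] if d.ndim == 2 else '?'} columns, "
            f"SNP table has {len(snps)}")
    if np.isnan(d).any():
        if missing == "mean":
            mu = np.nanmean(d, axis=0)
            idx = np.where(np.isnan(d))
            d = d.copy()
            d[idx] = np.take(mu, idx[1])
        else:
            raise AlignmentError("missing dosages (set missing='mean' "
                                 "to impute)")
    w, hap_offset = align_weights(snps, weights)
    return d @ w + 2.0 * hap_offset


def haplotype_scores(cohort: FamilyCohort, weights: pd.DataFrame):
    """Transmitted and non-transmitted parental scores per offspring.

    For each offspring and parent, the transmitted score sums the aligned
    weights over the alleles the parent passed on, the non-transmitted score
    over the parent's other allele at each locus.  Per construct these
    satisfy exactly: T_pat + T_mat = offspring own score and
    T_parent + NT_parent = parent's own score.

    Returns dict with keys ``t_pat``, ``t_mat``, ``nt_pat``, ``nt_mat``,
    each (n_offspring, 2).
    """
    if cohort.trans_pat is None:
        raise StructuralError("cohort lacks transmission flags")
    w, hap_offset = align_weights(cohort.snps, weights)
    off = cohort.off_rows
    m = cohort.haps.shape[1]
    cols = np.arange(m)
    # transmitted alleles are the offspring's own haplotypes
    t_pat_allele = cohort.haps[off][:, :, 0]
    t_mat_allele = cohort.haps[off][:, :, 1]
    F = cohort.father_row_of_off
    M = cohort.mother_row_of_off
    nt_pat_allele = cohort.haps[F[:, None], cols[None, :],
                                1 - cohort.trans_pat]
    nt_mat_allele = cohort.haps[M[:, None], cols[None, :],
                                1 - cohort.trans_mat]
    return {
        "t_pat": t_pat_allele @ w + hap_offset,
        "t_mat": t_mat_allele @ w + hap_offset,
        "nt_pat": nt_pat_allele @ w + hap_offset,
        "nt_mat": nt_mat_allele @ w + hap_offset,
    }


def cohort_score_table(cohort: FamilyCohort,
                       weights: pd.DataFrame) -> pd.DataFrame:
    """Raw-scale score table for a simulated cohort (one row per person).

    Carries person metadata, the outcome, own scores for everyone and
    transmitted / non-transmitted parental scores for offspring.  All scores
    are raw weighted allele sums; design-specific scaling is applied later by
    :func:`standardize_for_design` or the design fitters.
    """
    d = cohort.dosages()
    own = compute_pgs(d, cohort.snps, weights)
    tab = cohort.persons.copy()
    tab["pgs_cog"] = own[:, 0]
    tab["pgs_noncog"] = own[:, 1]
    hs = haplotype_scores(cohort, weights)
    for key, arr in hs.items():
        for c, name in enumerate(CONSTRUCTS):
            col = f"pgs_{key}_{name}"
            tab[col] = np.nan
            tab.loc[cohort.off_rows, col] = arr[:, c]
    tab.attrs["scale"] = "raw"
    return tab


def add_family_stats(table: pd.DataFrame, group_col: str = "family_id",
                     offspring_only: bool = True) -> pd.DataFrame:
    """Add family-mean and within-family-deviation score columns.

    The family mean is taken over the (offspring) members present in the
    table; deviations therefore sum to zero within each sibship by
    construction.
    """
    tab = table.copy()
    rows = tab["role"] == "offspring" if offspring_only \
        else pd.Series(True, index=tab.index)
    for name in CONSTRUCTS:
        col = f"pgs_{name}"
        grp = tab.loc[rows].groupby(group_col)[col]
        fam_mean = grp.transform("mean")
        tab[f"pgs_fam_mean_{name}"] = np.nan
        tab.loc[rows, f"pgs_fam_mean_{name}"] = fam_mean.to_numpy()
        tab[f"pgs_dev_{name}"] = tab[col] - tab[f"pgs_fam_mean_{name}"]
    return tab


def _scale_cols(tab, rows, cols):
    for col in cols:
        x = tab.loc[rows, col].to_numpy(dtype=float)
        sd = np.nanstd(x)
        if sd == 0 or not np.isfinite(sd):
            raise DegenerateInputError(f"column {col} is constant in the "
                                       "scaling group")
        tab.loc[rows, col] = (x - np.nanmean(x)) / sd
    return tab


def build_trio_scores(table: pd.DataFrame, convention: str = "average"
                      ) -> pd.DataFrame:
    """Transmitted / non-transmitted composites for the trio design.

    The transmitted composite sums the paternal and maternal transmitted
    scores (equal to the offspring's own score on the raw scale).  The
    non-transmitted composite averages the two parental non-transmitted
    scores by default (``convention='average'``); ``'sum'`` adds them
    instead, which differs only by a factor that the subsequent
    standardization absorbs.  Both composites are scaled to mean 0, SD 1
    separately over the offspring rows with complete parental scores; rows
    with missing parental scores are excluded (with a log line).
    """
    if convention not in ("average", "sum"):
        raise ParameterError("convention must be 'average' or 'sum'")
    tab = table.copy()
    need = [f"pgs_{k}_{c}" for k in ("t_pat", "t_mat", "nt_pat", "nt_mat")
            for c in CONSTRUCTS]
    off = tab["role"] == "offspring"
    complete = off & tab[need].notna().all(axis=1)
    n_dropped = int(off.sum() - complete.sum())
    if n_dropped:
        log.info("build_trio_scores: excluded %d offspring with missing "
                 "parental scores", n_dropped)
    for c in CONSTRUCTS:
        t = tab[f"pgs_t_pat_{c}"] + tab[f"pgs_t_mat_{c}"]
        if convention == "average":
            nt = 0.5 * (tab[f"pgs_nt_pat_{c}"] + tab[f"pgs_nt_mat_{c}"])
        else:
            nt = tab[f"pgs_nt_pat_{c}"] + tab[f"pgs_nt_mat_{c}"]
        tab[f"pgs_t_{c}"] = np.where(complete, t, np.nan)
        tab[f"pgs_nt_{c}"] = np.where(complete, nt, np.nan)
    cols = [f"pgs_t_{c}" for c in CONSTRUCTS] + \
           [f"pgs_nt_{c}" for c in CONSTRUCTS]
    tab = _scale_cols(tab, complete, cols)
    tab.attrs["scale"] = "trio-convention"
    return tab


def standardize_for_design(table: pd.DataFrame, design: str,
                           trio_convention: str = "average") -> pd.DataFrame:
    """Apply a design's scaling convention to a raw score table.

    * ``sibling`` — scale own scores on the sibling sample (non-adopted
      offspring in families with >= 2 offspring), then form family means and
      within-family deviations;
    * ``adoption`` — scale own scores within the adoptee and the non-adopted
      offspring groups separately;
    * ``trio`` — build and scale transmitted / non-transmitted composites.
    """
    if design not in DESIGNS:
        raise ParameterError(f"unknown design {design!r}; "
                             f"expected one of {DESIGNS}")
    tab = table.copy()
    cols = [f"pgs_{c}" for c in CONSTRUCTS]
    if design == "sibling":
        off = (tab["role"] == "offspring") & (~tab["adopted"])
        sizes = tab.loc[off].groupby("family_id")["person_id"].transform("size")
        sib = off.copy()
        sib.loc[off] = (sizes >= 2).to_numpy()
        if sib.sum() == 0:
            raise StructuralError("no families with >= 2 siblings")
        tab = _scale_cols(tab, sib, cols)
        tab = add_family_stats(tab)
        tab.attrs["scale"] = "sibling-sample"
    elif design == "adoption":
        off = tab["role"] == "offspring"
        for grp, rows in (("adoptee-group", off & tab["adopted"]),
                          ("nonadopted-group", off & ~tab["adopted"])):
            if rows.sum() == 0:
                raise StructuralError(f"empty {grp}")
            tab = _scale_cols(tab, rows, cols)
        tab.attrs["scale"] = "adoptee/nonadopted-group"
    else:
        tab = build_trio_scores(tab, convention=trio_convention)
    return tab


def compute_pcs(dosages, K: int = 10, fit_rows=None):
    """Top-K principal components of a standardized dosage matrix.

    Columns are centred and scaled using the fitting subset (``fit_rows``,
    default: all rows); zero-variance SNPs in the fitting subset are dropped
    (logged).  Components are the left singular vectors of the standardized
    fitting matrix, hence orthonormal over the fitting rows, and all rows are
    projected onto them.

    Returns an (n, K) array of PC scores.
    """
    X = np.asarray(dosages, dtype=float)
    n, m = X.shape
    if fit_rows is None:
        fit_rows = np.arange(n)
    fit_rows = np.asarray(fit_rows)
    if K < 1:
        raise ParameterError("K must be >= 1")
    if len(fit_rows) < K + 1:
        raise ParameterError("need at least K + 1 fitting individuals")
    mu = X[fit_rows].mean(axis=0)
    sd = X[fit_rows].std(axis=0)
    keep = sd > 0
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("compute_pcs: dropped %d zero-variance SNPs", n_drop)
    if keep.sum() == 0:
        raise DegenerateInputError("all SNPs have zero variance")
    Z = (X[:, keep] - mu[keep]) / sd[keep]
    U, S, Vt = np.linalg.svd(Z[fit_rows], full_matrices=False)
    rank = int((S > S[0] * 1e-9).sum()) if len(S) else 0
    if K > rank:
        raise ParameterError(f"K={K} exceeds rank {rank} of the "
                             "standardized dosage matrix")
    proj = Z @ Vt[:K].T / S[:K]
    return proj


def cohort_pcs(cohort: FamilyCohort, K: int = 10) -> pd.DataFrame:
    """Ancestry PCs for a cohort, fit on one founder per family.

    Mimics cohort pipelines that fit the PCA on unrelated individuals (here:
    each family's father) and project every person onto the loadings.
    """
    n = cohort.n_families
    fit_rows = np.arange(n)  # fathers, one per family, mutually unrelated
    pcs = compute_pcs(cohort.dosages(), K=K, fit_rows=fit_rows)
    cols = {f"pc{i + 1}": pcs[:, i] for i in range(K)}
    return pd.DataFrame(cols, index=cohort.persons.index)
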