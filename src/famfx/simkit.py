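"""Synthetic two-generation family cohorts for family-based polygenic score designs.

The generator produces diploid, biallelic, unlinked SNP genotypes for founder
couples and their offspring, tracking per-locus transmission so that
transmitted / non-transmitted haplotype scores are exact.  On top of the
genetic layer it simulates the phenotype-generating components relevant to
family designs:

* direct genetic effects of the offspring's own (true) polygenic score,
* prenatal parental indirect effects (mid-parent score of the *biological*
  parents),
* postnatal parental indirect effects (mid-parent score of the *rearing*
  parents),
* sibling indirect effects (mean score of co-reared siblings),
* assortative mating (rank-coupled spouse matching to a target correlation),
* population stratification (Balding-Nichols allele-frequency divergence plus
  an ancestry-linked environmental shift).

Polygenic-score imprecision is modelled at the weight level: measured weights
are the true weights mixed with independent noise calibrated so that the
squared correlation between measured and true scores equals a user-chosen
precision.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError, StructuralError

CONSTRUCTS = ("cog", "noncog")
ALLELES = np.array(list("ACGT"))


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, Generator or None to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Scenario
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationScenario:
    """All generative parameters of a simulated family cohort.

    Effect-size conventions: ``beta_direct_*`` act per SD of the child's true
    score; ``beta_prenatal_*`` / ``beta_postnatal_*`` act per unit of the
    mid-parent (average of the two parents') standardized true score;
    ``beta_sibling_*`` act per SD of the mean co-reared sibling true score.
    ``pgs_precision`` is the squared correlation between the measured and the
    true polygenic score.
    """

    n_families: int = 20_000
    m_snps: int = 1_000
    maf_low: float = 0.05
    maf_high: float = 0.5
    n_subpops: int = 1
    fst: float = 0.0
    strat_env_shift: float = 0.0
    am_rho: float = 0.0
    mating_trait: str = "pgs"  # {"pgs", "phenotype"}
    beta_direct_cog: float = 0.15
    beta_direct_noncog: float = 0.15
    beta_prenatal_cog: float = 0.0
    beta_prenatal_noncog: float = 0.0
    beta_postnatal_cog: float = 0.2
    beta_postnatal_noncog: float = 0.2
    beta_sibling_cog: float = 0.0
    beta_sibling_noncog: float = 0.0
    pgs_precision: float = 1.0
    offspring_per_family: int = 2
    sibship_size_probs: Optional[tuple] = None  # probs over sizes 1..3
    dz_fraction: float = 0.0
    mz_fraction: float = 0.0
    adoption_fraction: float = 0.0
    resid_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_families < 2:
            raise ParameterError("n_families must be >= 2")
        if self.m_snps < 1:
            raise ParameterError("m_snps must be >= 1")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ParameterError("need 0 < maf_low <= maf_high <= 0.5")
        if self.n_subpops < 1:
            raise ParameterError("n_subpops must be >= 1")
        if self.fst < 0:
            raise ParameterError("fst must be >= 0")
        if not (0 <= self.am_rho < 1):
            raise ParameterError("am_rho must be in [0, 1)")
        if self.mating_trait not in ("pgs", "phenotype"):
            raise ParameterError("mating_trait must be 'pgs' or 'phenotype'")
        if not (0 < self.pgs_precision <= 1):
            raise ParameterError("pgs_precision must be in (0, 1]")
        if not (1 <= self.offspring_per_family <= 3):
            raise ParameterError("offspring_per_family must be in 1..3")
        if self.mz_fraction < 0 or self.dz_fraction < 0 or \
                self.mz_fraction + self.dz_fraction > 1:
            raise ParameterError("mz_fraction + dz_fraction must be in [0, 1]")
        if not (0 <= self.adoption_fraction < 1):
            raise ParameterError("adoption_fraction must be in [0, 1)")
        if self.sibship_size_probs is not None:
            p = np.asarray(self.sibship_size_probs, dtype=float)
            if p.shape != (3,) or (p < 0).any() or not np.isclose(p.sum(), 1):
                raise ParameterError(
                    "sibship_size_probs must be 3 probabilities summing to 1")
        if self.resid_sd < 0:
            raise ParameterError("resid_sd must be >= 0")

    @property
    def betas(self) -> dict:
        return {
            "direct": (self.beta_direct_cog, self.beta_direct_noncog),
            "prenatal": (self.beta_prenatal_cog, self.beta_prenatal_noncog),
            "postnatal": (self.beta_postnatal_cog, self.beta_postnatal_noncog),
            "sibling": (self.beta_sibling_cog, self.beta_sibling_noncog),
        }

    def replace(self, **kwargs) -> "SimulationScenario":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# Allele frequencies, SNP table, true weights
# ---------------------------------------------------------------------------


def draw_allele_freqs(m_snps, n_subpops, fst, maf_low, maf_high, seed=None):
    """Per-subpopulation allele frequencies under a Balding-Nichols model.

    Ancestral frequencies are uniform on [maf_low, maf_high]; each
    subpopulation draws its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F)
    around the ancestral p, so that E[(p_s - p)^2] = F p (1-p).
    With ``fst == 0`` all subpopulations share the ancestral frequencies.

    Returns
    -------
    (ancestral, subpop_freqs) : (ndarray (m,), ndarray (n_subpops, m))
    """
    if m_snps < 1 or n_subpops < 1:
        raise ParameterError("m_snps and n_subpops must be positive")
    if fst < 0:
        raise ParameterError("fst must be >= 0")
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ParameterError("need 0 < maf_low <= maf_high <= 0.5")
    rng = as_rng(seed)
    anc = rng.uniform(maf_low, maf_high, size=m_snps)
    if fst == 0:
        sub = np.tile(anc, (n_subpops, 1))
    else:
        if fst >= 1:
            raise ParameterError("fst must be < 1 for the Balding-Nichols draw")
        scale = (1.0 - fst) / fst
        sub = rng.beta(anc * scale, (1.0 - anc) * scale,
                       size=(n_subpops, m_snps))
        eps = 1e-6
        sub = np.clip(sub, eps, 1.0 - eps)
    return anc, sub


def make_snp_table(m_snps, seed=None) -> pd.DataFrame:
    """SNP ids and allele labels; ``a1`` is the counted (dosage) allele."""
    rng = as_rng(seed)
    i1 = rng.integers(0, 4, size=m_snps)
    i2 = (i1 + rng.integers(1, 4, size=m_snps)) % 4
    return pd.DataFrame({
        "snp_id": [f"snp{i:05d}" for i in range(m_snps)],
        "a1": ALLELES[i1],
        "a2": ALLELES[i2],
    })


def draw_true_weights(m_snps, seed=None) -> np.ndarray:
    """Independent standard-normal per-SNP weights for each construct."""
    rng = as_rng(seed)
    return rng.normal(size=(m_snps, 2))


def make_noisy_weights(true_weights, pgs_precision, freqs, seed=None):
    """Mix true weights with independent noise to a target score precision.

    The noise scale is chosen so that, in expectation over genotypes with
    allele frequencies ``freqs`` (ancestral, per SNP), the squared
    correlation between the noisy-weight score and the true score equals
    ``pgs_precision``.  Precision 1 returns the true weights unchanged.
    """
    w = np.asarray(true_weights, dtype=float)
    if w.ndim == 1:
        w = w[:, None]
    if not (0 < pgs_precision <= 1):
        raise ParameterError("pgs_precision must be in (0, 1]")
    if not np.any(w != 0):
        raise DegenerateInputError("all-zero true weights: precision target "
                                   "is undefined")
    if pgs_precision == 1:
        return w.copy()
    rng = as_rng(seed)
    p = np.asarray(freqs, dtype=float)
    if p.ndim > 1:
        p = p.mean(axis=0)
    v = 2.0 * p * (1.0 - p)  # per-SNP dosage variance
    noise = rng.normal(size=w.shape)
    out = np.empty_like(w)
    for c in range(w.shape[1]):
        s_true = float(np.sum(w[:, c] ** 2 * v))
        if s_true == 0:
            raise DegenerateInputError(
                f"construct {c}: all-zero true weights")
        # orthogonalize the noise against the true weights under the
        # genotype-variance inner product, then scale exactly: the noise
        # score is then uncorrelated with the true score in expectation and
        # contributes (1 - k)/k of its variance
        eta = noise[:, c]
        eta = eta - np.sum(eta * w[:, c] * v) / s_true * w[:, c]
        s_noise = float(np.sum(eta ** 2 * v))
        if s_noise == 0:
            raise DegenerateInputError("degenerate noise draw")
        b = np.sqrt((1.0 - pgs_precision) / pgs_precision
                    * s_true / s_noise)
        out[:, c] = w[:, c] + b * eta
    return out


def weights_frame(snps: pd.DataFrame, weights: np.ndarray,
                  provenance: str) -> pd.DataFrame:
    """Tabular weight vector (one row per SNP, both constructs)."""
    return pd.DataFrame({
        "snp_id": snps["snp_id"].to_numpy(),
        "effect_allele": snps["a1"].to_numpy(),
        "weight_cog": weights[:, 0],
        "weight_noncog": weights[:, 1],
        "provenance": provenance,
    })


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------


@dataclass
class FounderPool:
    """Unrelated founder generation: haplotypes, true scores, mating traits."""

    haps: np.ndarray            # (n_founders, m, 2) alleles in {0, 1}
    subpop: np.ndarray          # (n_founders,) int
    sex: np.ndarray             # (n_founders,) 0 = male, 1 = female
    score_raw: np.ndarray       # (n_founders, 2) raw weighted allele sums
    z: np.ndarray               # (n_founders, 2) standardized true scores
    phenotype: np.ndarray       # (n_founders,) founder-generation outcome
    ancestral_freqs: np.ndarray
    subpop_freqs: np.ndarray
    snps: pd.DataFrame
    weights_true: np.ndarray    # (m, 2)

    @property
    def n(self) -> int:
        return self.haps.shape[0]

    def dosages(self) -> np.ndarray:
        return self.haps.sum(axis=2)

    def mating_trait_values(self, mating_trait: str) -> np.ndarray:
        if mating_trait == "pgs":
            return self.z.sum(axis=1) / np.sqrt(2.0)
        if mating_trait == "phenotype":
            return self.phenotype
        raise ParameterError(f"unknown mating trait {mating_trait!r}")


def _standardize(x, axis=0, what="scores"):
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    if np.any(sd == 0):
        raise DegenerateInputError(f"cannot standardize constant {what}")
    return (x - mu) / sd


def simulate_founders(scenario: SimulationScenario, seed=None,
                      weights_true=None, snps=None,
                      freqs=None) -> FounderPool:
    """Draw 2 * n_families unrelated founders (equal numbers of each sex).

    Haplotype alleles are independent Bernoulli draws at the founder's
    subpopulation frequency.  Subpopulation labels are drawn uniformly per
    couple slot and shared between the male and female occupying the slot, so
    that every subpopulation contains equally many members of each sex.
    True scores are weighted allele sums standardized within the pool.
    """
    if seed is None:
        seed = scenario.seed
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    r_freq, r_geno, r_misc = [as_rng(s) for s in ss.spawn(3)]
    n = scenario.n_families
    m = scenario.m_snps
    if freqs is None:
        anc, sub = draw_allele_freqs(m, scenario.n_subpops, scenario.fst,
                                     scenario.maf_low, scenario.maf_high,
                                     r_freq)
    else:
        anc, sub = freqs
    if snps is None:
        snps = make_snp_table(m, r_freq)
    if weights_true is None:
        weights_true = draw_true_weights(m, r_freq)

    slot_subpop = r_misc.integers(0, scenario.n_subpops, size=n)
    subpop = np.concatenate([slot_subpop, slot_subpop])
    sex = np.repeat([0, 1], n).astype(np.int8)

    pf = sub[subpop]  # (2n, m)
    haps = (r_geno.random(size=(2 * n, m, 2)) < pf[:, :, None]).astype(np.int8)

    score_raw = haps.sum(axis=2) @ weights_true
    z = _standardize(score_raw, what="founder true scores")
    bd = np.array([scenario.beta_direct_cog, scenario.beta_direct_noncog])
    phenotype = z @ bd + r_misc.normal(scale=scenario.resid_sd, size=2 * n)

    return FounderPool(haps=haps, subpop=subpop, sex=sex,
                       score_raw=score_raw, z=z, phenotype=phenotype,
                       ancestral_freqs=anc, subpop_freqs=sub, snps=snps,
                       weights_true=weights_true)


# ---------------------------------------------------------------------------
# Spouse pairing
# ---------------------------------------------------------------------------


def pair_spouses(founders: FounderPool, am_rho, mating_trait="pgs",
                 seed=None) -> pd.DataFrame:
    """Match male and female founders within subpopulation.

    With ``am_rho == 0`` pairing is random.  Otherwise a Gaussian coupling is
    used: each couple slot draws a latent bivariate-normal pair with
    correlation ``am_rho``; males sorted by mating trait are matched to the
    rank order of the male latent, females to the female latent.  Because the
    mating trait is close to Gaussian, the realized spousal trait correlation
    approximates ``am_rho``.

    Returns a couples table with columns family_id, father_row, mother_row.
    """
    if not (0 <= am_rho < 1):
        raise ParameterError("am_rho must be in [0, 1)")
    rng = as_rng(seed)
    trait = founders.mating_trait_values(mating_trait)
    males = np.flatnonzero(founders.sex == 0)
    females = np.flatnonzero(founders.sex == 1)
    if len(males) != len(females):
        raise StructuralError(
            f"unbalanced sexes: {len(males)} males vs {len(females)} females")

    father = np.empty(len(males), dtype=np.int64)
    mother = np.empty(len(males), dtype=np.int64)
    pos = 0
    for s in np.unique(founders.subpop):
        ms = males[founders.subpop[males] == s]
        fs = females[founders.subpop[females] == s]
        if len(ms) != len(fs):
            raise StructuralError(
                f"unbalanced sexes within subpopulation {s}")
        k = len(ms)
        if am_rho == 0:
            father[pos:pos + k] = rng.permutation(ms)
            mother[pos:pos + k] = rng.permutation(fs)
        else:
            shared = rng.normal(size=k)
            um = np.sqrt(am_rho) * shared + np.sqrt(1 - am_rho) * rng.normal(size=k)
            uf = np.sqrt(am_rho) * shared + np.sqrt(1 - am_rho) * rng.normal(size=k)
            ms_sorted = ms[np.argsort(trait[ms], kind="stable")]
            fs_sorted = fs[np.argsort(trait[fs], kind="stable")]
            father[pos:pos + k] = ms_sorted[np.argsort(np.argsort(um))]
            mother[pos:pos + k] = fs_sorted[np.argsort(np.argsort(uf))]
        pos += k
    return pd.DataFrame({"family_id": np.arange(len(father)),
                         "father_row": father, "mother_row": mother})


# ---------------------------------------------------------------------------
# Cohort container
# ---------------------------------------------------------------------------


@dataclass
class FamilyCohort:
    """Two-generation cohort with phased haplotypes and transmission flags.

    ``haps[i, j]`` holds the two alleles of person ``i`` at SNP ``j``; for
    offspring, column 0 is the paternally and column 1 the maternally
    transmitted allele.  ``trans_pat[k, j]`` / ``trans_mat[k, j]`` record
    which of the parent's two haplotypes was transmitted to offspring ``k``,
    so the non-transmitted parental allele is recoverable exactly.
    """

    scenario: SimulationScenario
    persons: pd.DataFrame
    snps: pd.DataFrame
    ancestral_freqs: np.ndarray
    subpop_freqs: np.ndarray
    haps: np.ndarray                  # (N, m, 2)
    weights_true: np.ndarray          # (m, 2)
    z_true: np.ndarray                # (N, 2), standardized per generation
    off_rows: np.ndarray              # rows of offspring in person order
    father_row_of_off: np.ndarray     # biological father row per offspring
    mother_row_of_off: np.ndarray
    trans_pat: np.ndarray             # (n_off, m) transmitted hap index in {0,1}
    trans_mat: np.ndarray

    @property
    def n_families(self) -> int:
        return int(self.persons.loc[self.persons.role == "father"].shape[0])

    def dosages(self, rows=None) -> np.ndarray:
        h = self.haps if rows is None else self.haps[rows]
        return h.sum(axis=2)

    def parent_rows_of_family(self):
        """Map family_id -> (father_row, mother_row)."""
        n = self.n_families
        return np.arange(n), np.arange(n) + n

    def copy(self) -> "FamilyCohort":
        return FamilyCohort(
            scenario=self.scenario, persons=self.persons.copy(),
            snps=self.snps, ancestral_freqs=self.ancestral_freqs,
            subpop_freqs=self.subpop_freqs, haps=self.haps,
            weights_true=self.weights_true, z_true=self.z_true,
            off_rows=self.off_rows,
            father_row_of_off=self.father_row_of_off,
            mother_row_of_off=self.mother_row_of_off,
            trans_pat=self.trans_pat, trans_mat=self.trans_mat)


def plan_offspring(scenario: SimulationScenario, seed=None) -> pd.DataFrame:
    """Assign each family an offspring configuration.

    A family is an MZ-twin pair with probability ``mz_fraction``, a DZ-twin
    pair with probability ``dz_fraction``, otherwise a sibship of
    ``offspring_per_family`` singleton-born children (or a size drawn from
    ``sibship_size_probs`` when given).
    """
    rng = as_rng(seed)
    n = scenario.n_families
    u = rng.random(n)
    is_mz = u < scenario.mz_fraction
    is_dz = (~is_mz) & (u < scenario.mz_fraction + scenario.dz_fraction)
    if scenario.sibship_size_probs is not None:
        sizes = rng.choice([1, 2, 3], size=n,
                           p=np.asarray(scenario.sibship_size_probs))
    else:
        sizes = np.full(n, scenario.offspring_per_family)
    sizes = np.where(is_mz | is_dz, 2, sizes)
    fam = np.repeat(np.arange(n), sizes)
    birth_order = np.concatenate([np.arange(s) for s in sizes])
    zyg = np.where(np.repeat(is_mz, sizes), "MZ",
                   np.where(np.repeat(is_dz, sizes), "DZ", "none"))
    return pd.DataFrame({"family_id": fam, "birth_order": birth_order,
                         "zygosity": zyg})


def meiose(founders: FounderPool, couples: pd.DataFrame,
           plan: pd.DataFrame, seed=None,
           scenario: Optional[SimulationScenario] = None) -> FamilyCohort:
    """Create offspring by independent per-locus Mendelian transmission.

    Each offspring receives, per locus and per parent, one of the two
    parental alleles chosen by an independent fair coin; MZ co-twins
    duplicate a single meiosis.  Transmission flags are recorded for every
    offspring locus.
    """
    rng = as_rng(seed)
    if scenario is None:
        scenario = SimulationScenario(n_families=len(couples),
                                      m_snps=founders.haps.shape[1])
    n = len(couples)
    m = founders.haps.shape[1]
    fam = plan["family_id"].to_numpy()
    zyg = plan["zygosity"].to_numpy()
    birth = plan["birth_order"].to_numpy()
    n_off = len(plan)

    father_of_fam = couples["father_row"].to_numpy()
    mother_of_fam = couples["mother_row"].to_numpy()
    F = father_of_fam[fam]
    M = mother_of_fam[fam]

    c_pat = rng.integers(0, 2, size=(n_off, m), dtype=np.int8)
    c_mat = rng.integers(0, 2, size=(n_off, m), dtype=np.int8)
    # MZ second twin replays the first twin's meiosis
    mz_second = (zyg == "MZ") & (birth == 1)
    if mz_second.any():
        first = np.flatnonzero((zyg == "MZ") & (birth == 0))
        second = np.flatnonzero(mz_second)
        c_pat[second] = c_pat[first]
        c_mat[second] = c_mat[first]

    cols = np.arange(m)
    pat_allele = founders.haps[F[:, None], cols[None, :], c_pat]
    mat_allele = founders.haps[M[:, None], cols[None, :], c_mat]
    off_haps = np.stack([pat_allele, mat_allele], axis=2).astype(np.int8)

    # assemble cohort rows: fathers (by family), mothers, offspring
    haps = np.concatenate(
        [founders.haps[father_of_fam], founders.haps[mother_of_fam], off_haps])
    N = 2 * n + n_off
    off_rows = np.arange(2 * n, N)

    sex_off = (birth % 2).astype(np.int8)
    age = np.concatenate([rng.uniform(35, 55, size=2 * n),
                          rng.uniform(10, 18, size=n_off)])
    persons = pd.DataFrame({
        "person_id": np.arange(N),
        "family_id": np.concatenate([np.arange(n), np.arange(n), fam]),
        "rearing_family_id": np.concatenate([np.arange(n), np.arange(n), fam]),
        "role": np.array(["father"] * n + ["mother"] * n
                         + ["offspring"] * n_off),
        "zygosity": np.concatenate([np.full(2 * n, "none"), zyg]),
        "adopted": np.zeros(N, dtype=bool),
        "subpop": np.concatenate([founders.subpop[father_of_fam],
                                  founders.subpop[mother_of_fam],
                                  founders.subpop[father_of_fam][fam]]),
        "sex": np.concatenate([np.zeros(n, np.int8), np.ones(n, np.int8),
                               sex_off]),
        "age": age,
    })

    score_raw = haps.sum(axis=2) @ founders.weights_true
    z_true = np.empty_like(score_raw)
    z_true[: 2 * n] = _standardize(score_raw[: 2 * n],
                                   what="parental true scores")
    z_true[2 * n:] = _standardize(score_raw[2 * n:],
                                  what="offspring true scores")

    return FamilyCohort(
        scenario=scenario, persons=persons, snps=founders.snps,
        ancestral_freqs=founders.ancestral_freqs,
        subpop_freqs=founders.subpop_freqs, haps=haps,
        weights_true=founders.weights_true, z_true=z_true,
        off_rows=off_rows,
        father_row_of_off=fam,            # cohort row of father == family_id
        mother_row_of_off=fam + n,
        trans_pat=c_pat, trans_mat=c_mat)


def assign_adoption(cohort: FamilyCohort, adoption_fraction,
                    seed=None) -> FamilyCohort:
    """Re-assign a fraction of families' offspring to unrelated rearing families.

    One offspring from each selected family is reared by another selected
    family (a cyclic shift of a random ordering, so every rearing family
    receives exactly one adoptee and never its own child).  Biological links
    are retained, so prenatal effects still follow the biological parents.
    """
    if not (0 <= adoption_fraction < 1):
        raise ParameterError("adoption_fraction must be in [0, 1)")
    out = cohort.copy()
    if adoption_fraction == 0:
        return out
    rng = as_rng(seed)
    n = cohort.n_families
    n_adopt = int(round(adoption_fraction * n))
    if n_adopt < 2:
        if n_adopt <= 0:
            return out
        raise StructuralError(
            "adoption_fraction selects a single family; at least two are "
            "needed to cross-place adoptees")
    fams = rng.permutation(n)[:n_adopt]
    rearing = np.roll(fams, 1)  # cyclic shift: rearing family != own family

    persons = out.persons
    off = persons.index[persons.role == "offspring"]
    chosen_rows = []
    grouped = persons.loc[off].groupby("family_id").groups
    for f in fams:
        rows = np.asarray(grouped[f])
        chosen_rows.append(rng.choice(rows))
    chosen_rows = np.array(chosen_rows)
    persons.loc[chosen_rows, "rearing_family_id"] = rearing
    persons.loc[chosen_rows, "adopted"] = True
    return out


def simulate_outcome(cohort: FamilyCohort,
                     scenario: Optional[SimulationScenario] = None,
                     seed=None) -> FamilyCohort:
    """Generate offspring phenotypes from true-score components.

    y = sum over constructs of [ beta_direct * z_child
                                 + beta_prenatal * midparent(biological)
                                 + beta_postnatal * midparent(rearing)
                                 + beta_sibling * mean co-reared sibling z ]
        + strat_env_shift * subpop(own) + Normal(0, resid_sd^2)

    where z are standardized true scores and mid-parent is the average of the
    two parents' z.  The stratification shift follows the individual's own
    subpopulation (an ancestry-linked environment), wherever they are reared.
    Singletons receive no sibling term.
    """
    if scenario is None:
        scenario = cohort.scenario
    rng = as_rng(scenario.seed + 1 if seed is None else seed)
    persons = cohort.persons
    off_rows = cohort.off_rows
    n = cohort.n_families
    z = cohort.z_true

    z_child = z[off_rows]
    mid_bio = 0.5 * (z[cohort.father_row_of_off] + z[cohort.mother_row_of_off])

    rear = persons.loc[off_rows, "rearing_family_id"].to_numpy()
    if np.any(rear < 0) or np.any(rear >= n):
        raise StructuralError("offspring with missing rearing family")
    mid_rear = 0.5 * (z[rear] + z[rear + n])

    # mean co-reared-sibling z: group by rearing family
    n_off = len(off_rows)
    sums = np.zeros((n, 2))
    counts = np.zeros(n)
    np.add.at(sums, rear, z_child)
    np.add.at(counts, rear, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosib = (sums[rear] - z_child) / (counts[rear] - 1)[:, None]
    cosib[counts[rear] == 1] = 0.0

    b = scenario.betas
    y = np.zeros(n_off)
    for c in range(2):
        y += (b["direct"][c] * z_child[:, c]
              + b["prenatal"][c] * mid_bio[:, c]
              + b["postnatal"][c] * mid_rear[:, c]
              + b["sibling"][c] * cosib[:, c])
    y += scenario.strat_env_shift * persons.loc[off_rows, "subpop"].to_numpy()
    y += rng.normal(scale=scenario.resid_sd, size=n_off)

    out = cohort.copy()
    out.persons["y"] = np.nan
    out.persons.loc[off_rows, "y"] = y
    # record rearing sibship size (children co-reared in the family)
    counts_all = out.persons.loc[off_rows].groupby("rearing_family_id")[
        "person_id"].transform("size")
    out.persons["n_sibship"] = np.nan
    out.persons.loc[off_rows, "n_sibship"] = counts_all.to_numpy()
    return out


def simulate_cohort(scenario: SimulationScenario, seed=None):
    """End-to-end cohort generation.

    Runs founder simulation, spouse pairing, meiosis, adoptive reassignment,
    phenotype generation and measured-weight construction, all seeded from
    one master seed.

    Returns
    -------
    (cohort, weights) : (FamilyCohort, pd.DataFrame)
        ``weights`` is the measured weight table (noisy when
        ``pgs_precision < 1``) in the standard weight-vector format.
    """
    ss = np.random.SeedSequence(scenario.seed if seed is None else seed)
    s_found, s_pair, s_plan, s_mei, s_adopt, s_noise, s_out = ss.spawn(7)
    founders = simulate_founders(scenario, seed=s_found)
    couples = pair_spouses(founders, scenario.am_rho, scenario.mating_trait,
                           seed=as_rng(s_pair))
    plan = plan_offspring(scenario, seed=as_rng(s_plan))
    cohort = meiose(founders, couples, plan, seed=as_rng(s_mei),
                    scenario=scenario)
    cohort = assign_adoption(cohort, scenario.adoption_fraction,
                             seed=as_rng(s_adopt))
    cohort = simulate_outcome(cohort, scenario, seed=as_rng(s_out))
    w_meas = make_noisy_weights(cohort.weights_true, scenario.pgs_precision,
                                cohort.ancestral_freqs, seed=as_rng(s_noise))
    prov = "true" if scenario.pgs_precision == 1 else "noisy"
    weights = weights_frame(cohort.snps, w_meas, prov)
    return cohort, weights
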