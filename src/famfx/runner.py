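"""Config-driven experiment orchestration.

Runs scenario grids that mirror the bias-comparison simulation study: a set
of named generative scenarios (no-bias, prenatal, sibling-effect,
assortment, stratification, combined), each replicated with independent
seeds, with the three family designs fitted per replicate and summarised as
boxplot statistics (median, quartiles, 1.5 IQR whiskers).

Seeding is counter based: replicate (scenario s, index r) derives its seed
from SeedSequence([master_seed, s, r]), so any execution order yields
identical per-replicate results.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .designs import (adoption_design, build_covariates, sibling_design,
                      trio_design)
from .errors import ParameterError, StructuralError
from .scores import CONSTRUCTS, cohort_pcs, cohort_score_table
from .simkit import SimulationScenario, simulate_cohort

log = logging.getLogger(__name__)

MAIN_QUANTITIES = ("population", "direct", "indirect")

# Shared generative background of the bias-comparison grid: a direct effect
# and a postnatal parental indirect effect of both constructs, measured with
# an imprecise polygenic score (r^2 = 0.25 with the true score), two
# offspring per family with a twin admixture, and an oversampled adoptee
# group so the adoption contrast has usable precision.
_GRID_BASE = dict(
    m_snps=400, maf_low=0.05, maf_high=0.5,
    beta_direct_cog=0.15, beta_direct_noncog=0.15,
    beta_postnatal_cog=0.2, beta_postnatal_noncog=0.2,
    pgs_precision=0.25, offspring_per_family=2,
    dz_fraction=0.2, mz_fraction=0.1, adoption_fraction=0.3,
)

# Scenario-specific components / biases layered on the background.  The bias
# settings are deliberately strong so each bias channel is visible above
# Monte-Carlo noise in a moderately sized simulation.
SCENARIO_PRESETS = {
    "no_bias": {},
    "prenatal": {"beta_postnatal_cog": 0.0, "beta_postnatal_noncog": 0.0,
                 "beta_prenatal_cog": 0.2, "beta_prenatal_noncog": 0.2},
    "sibling_effect": {"beta_sibling_cog": 0.15, "beta_sibling_noncog": 0.15},
    "assortment": {"am_rho": 0.75},
    "stratification": {"n_subpops": 2, "fst": 0.1, "strat_env_shift": 1.0},
    "combined": {"beta_prenatal_cog": 0.2, "beta_prenatal_noncog": 0.2,
                 "beta_sibling_cog": 0.15, "beta_sibling_noncog": 0.15,
                 "am_rho": 0.75, "n_subpops": 2, "fst": 0.1,
                 "strat_env_shift": 1.0},
}


@dataclass
class ExperimentGrid:
    """A named set of simulation scenarios to replicate and fit."""

    scenarios: dict                       # name -> SimulationScenario
    replicates: int = 20
    designs: Sequence[str] = ("sibling", "adoption", "trio")
    master_seed: int = 0
    out_dir: Optional[str] = None
    pc_scenarios: frozenset = frozenset({"stratification", "combined"})
    n_pcs: int = 10

    def __post_init__(self):
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        if len(set(self.scenarios)) != len(self.scenarios):
            raise ParameterError("scenario names must be unique")


def make_grid(scale: str = "desk", scenario_names=None, replicates=None,
              n_families=None, master_seed: int = 0,
              out_dir=None) -> ExperimentGrid:
    """The standard bias-comparison grid.

    ``scale='full'`` uses 20,000 families x 100 replicates;
    ``scale='desk'`` is a 2,000-family x 20-replicate preset for quick runs
    (scale affects Monte-Carlo error only).  ``n_families`` / ``replicates``
    override the preset sizes.
    """
    if scale == "full":
        nf, reps = 20_000, 100
    elif scale == "desk":
        nf, reps = 2_000, 20
    else:
        raise ParameterError("scale must be 'desk' or 'full'")
    if n_families is not None:
        nf = n_families
    if replicates is not None:
        reps = replicates
    names = scenario_names or list(SCENARIO_PRESETS)
    scenarios = {}
    for name in names:
        if name not in SCENARIO_PRESETS:
            raise ParameterError(f"unknown scenario preset {name!r}")
        scenarios[name] = SimulationScenario(
            n_families=nf, **{**_GRID_BASE, **SCENARIO_PRESETS[name]})
    return ExperimentGrid(scenarios=scenarios, replicates=reps,
                          master_seed=master_seed, out_dir=out_dir)


def _replicate_seed(master: int, i_scen: int, rep: int) -> int:
    ss = np.random.SeedSequence([master, i_scen, rep])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def run_replicate(scenario: SimulationScenario, designs=("sibling",
                                                         "adoption", "trio"),
                  with_pcs: bool = False, n_pcs: int = 10) -> pd.DataFrame:
    """Simulate one cohort and fit the requested designs.

    Returns a long table (design, construct, quantity, value).  When
    ``with_pcs`` is true each design is additionally fit with ancestry PCs
    in the covariate set, labelled ``<design>+pcs``.
    """
    cohort, weights = simulate_cohort(scenario)
    table = cohort_score_table(cohort, weights)
    covars = build_covariates(table)
    variants = [("", covars)]
    if with_pcs:
        pcs = cohort_pcs(cohort, K=n_pcs)
        variants.append(("+pcs", build_covariates(table, pcs=pcs)))

    fitters = {"sibling": sibling_design, "adoption": adoption_design,
               "trio": trio_design}
    rows = []
    for suffix, cov in variants:
        for d in designs:
            est = fitters[d](table, covariates=cov)
            for c in CONSTRUCTS:
                for q in MAIN_QUANTITIES:
                    if q in est.estimates[c]:
                        rows.append({"design": d + suffix, "construct": c,
                                     "quantity": q,
                                     "value": est.get(c, q)})
    return pd.DataFrame(rows)


def run_grid(grid: ExperimentGrid) -> pd.DataFrame:
    """Run every scenario x replicate of a grid.

    Returns the replicate-level long table; when ``grid.out_dir`` is set,
    writes ``replicates.tsv``, ``summary.tsv`` and a provenance
    ``grid.json``.  A failing replicate is logged and skipped; a scenario
    in which every replicate fails raises.
    """
    frames = []
    for i_scen, (name, base) in enumerate(grid.scenarios.items()):
        n_ok = 0
        for rep in range(grid.replicates):
            seed = _replicate_seed(grid.master_seed, i_scen, rep)
            scen = base.replace(seed=seed)
            t0 = time.perf_counter()
            try:
                df = run_replicate(scen, designs=grid.designs,
                                   with_pcs=name in grid.pc_scenarios,
                                   n_pcs=grid.n_pcs)
            except Exception as exc:   # noqa: BLE001 - replicate isolation
                log.warning("replicate failed: scenario=%s rep=%d: %s",
                            name, rep, exc)
                continue
            df.insert(0, "scenario", name)
            df.insert(1, "replicate", rep)
            frames.append(df)
            n_ok += 1
            log.info("grid: scenario=%s rep=%d seed=%d n=%d runtime=%.2fs",
                     name, rep, seed, scen.n_families,
                     time.perf_counter() - t0)
        if n_ok == 0:
            raise StructuralError(f"all replicates failed in scenario {name!r}")
    result = pd.concat(frames, ignore_index=True)
    if grid.out_dir is not None:
        out = Path(grid.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_csv(out / "replicates.tsv", sep="\t", index=False)
        summarize_grid(result).to_csv(out / "summary.tsv", sep="\t",
                                      index=False)
        with open(out / "grid.json", "w") as fh:
            json.dump({"master_seed": grid.master_seed,
                       "replicates": grid.replicates,
                       "scenarios": sorted(grid.scenarios),
                       "designs": list(grid.designs)}, fh, indent=2)
    return result


def summarize_grid(replicates: pd.DataFrame) -> pd.DataFrame:
    """Boxplot statistics per scenario x design x construct x quantity.

    Emits median, quartiles and whisker bounds (the most extreme replicate
    values within 1.5 IQR of the quartiles), plus the replicate SD.
    """
    rows = []
    keys = ["scenario", "design", "construct", "quantity"]
    for vals, g in replicates.groupby(keys):
        x = g["value"].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = x[(x >= lo_fence) & (x <= hi_fence)]
        rows.append(dict(zip(keys, vals)) | {
            "n_reps": len(x), "median": med, "q1": q1, "q3": q3,
            "whisker_low": float(inside.min()) if len(inside) else np.nan,
            "whisker_high": float(inside.max()) if len(inside) else np.nan,
            "mean": float(x.mean()), "sd": float(x.std(ddof=1))
            if len(x) > 1 else np.nan,
        })
    return pd.DataFrame(rows)


def report(results_dir) -> str:
    """Markdown summary of a grid run; returns the report text.

    Re-derives the summary from ``replicates.tsv`` (so the written
    ``summary.tsv`` can be cross-checked) and writes ``report.md`` plus a
    boxplot-ready long TSV.
    """
    results_dir = Path(results_dir)
    rep_path = results_dir / "replicates.tsv"
    if not rep_path.exists():
        raise StructuralError(f"no replicates.tsv under {results_dir}")
    reps = pd.read_csv(rep_path, sep="\t")
    summary = summarize_grid(reps)
    lines = ["# Simulation grid summary", ""]
    for scen, g in summary.groupby("scenario"):
        lines.append(f"## scenario: {scen}")
        lines.append("")
        sub = g[g["quantity"] == "indirect"]
        lines.append("| design | construct | median indirect | Q1 | Q3 |")
        lines.append("|---|---|---|---|---|")
        for _, r in sub.iterrows():
            lines.append(f"| {r.design} | {r.construct} | {r['median']:.4f} "
                         f"| {r.q1:.4f} | {r.q3:.4f} |")
        lines.append("")
    text = "\n".join(lines)
    (results_dir / "report.md").write_text(text)
    summary.to_csv(results_dir / "summary.tsv", sep="\t", index=False)
    reps.to_csv(results_dir / "boxplot_long.tsv", sep="\t", index=False)
    return text


def plot_grid(replicates: pd.DataFrame, path, quantity: str = "indirect"):
    """Minimal boxplot of replicate estimates per scenario and design."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = replicates[replicates["quantity"] == quantity]
    scenarios = sub["scenario"].unique()
    designs = sub["design"].unique()
    fig, axes = plt.subplots(1, len(scenarios),
                             figsize=(3 * len(scenarios), 4), sharey=True)
    if len(scenarios) == 1:
        axes = [axes]
    for ax, scen in zip(axes, scenarios):
        data = [sub[(sub.scenario == scen) & (sub.design == d)]["value"]
                for d in designs]
        ax.boxplot(data, tick_labels=list(designs))
        ax.set_title(scen)
        ax.tick_params(axis="x", rotation=45)
    axes[0].set_ylabel(quantity)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
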