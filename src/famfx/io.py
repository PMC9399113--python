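"""Readers and writers for the package's tabular interchange formats.

All writers emit a provenance comment line (``# famfx ...``) that readers
skip; tables are plain TSV.  The dosage writer follows the PLINK ``.raw``
additive layout (FID IID PAT MAT SEX PHENOTYPE then one ``<snp>_<allele>``
count column per SNP).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError
from .simkit import FamilyCohort, SimulationScenario

PROVENANCE_PREFIX = "# famfx"


def _write_tsv(df: pd.DataFrame, path, provenance: str = ""):
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{PROVENANCE_PREFIX} {provenance}\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_person_table(cohort_or_df, path, provenance: str = "persons"):
    df = cohort_or_df.persons if isinstance(cohort_or_df, FamilyCohort) \
        else cohort_or_df
    _write_tsv(df, path, provenance)


def read_person_table(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_weights(weights: pd.DataFrame, path, provenance: str = "weights"):
    _write_tsv(weights, path, provenance)


def read_weights(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("snp_id", "effect_allele", "weight_cog", "weight_noncog"):
        if col not in df:
            raise ParameterError(f"weight table missing column {col!r}")
    return df


def write_score_table(table: pd.DataFrame, path,
                      provenance: Optional[str] = None):
    prov = provenance or f"scores scale={table.attrs.get('scale', 'raw')}"
    _write_tsv(table, path, prov)


def read_score_table(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_dosage_raw(cohort: FamilyCohort, path):
    """PLINK-.raw-style additive dosage TSV (one column per SNP)."""
    d = cohort.dosages()
    p = cohort.persons
    cols = {
        "FID": p["family_id"].to_numpy(),
        "IID": p["person_id"].to_numpy(),
        "PAT": 0, "MAT": 0,
        "SEX": p["sex"].to_numpy() + 1,
        "PHENOTYPE": p["y"].fillna(-9).to_numpy() if "y" in p else -9,
    }
    df = pd.DataFrame(cols)
    names = [f"{s}_{a}" for s, a in zip(cohort.snps["snp_id"],
                                        cohort.snps["a1"])]
    df = pd.concat([df, pd.DataFrame(d, columns=names)], axis=1)
    df.to_csv(path, sep="\t", index=False)


def read_dosage_raw(path):
    """Read a PLINK-.raw-style TSV -> (meta DataFrame, dosage array, snp table)."""
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    snp_cols = [c for c in df.columns if c not in meta_cols]
    snp_ids, alleles = zip(*(c.rsplit("_", 1) for c in snp_cols))
    snps = pd.DataFrame({"snp_id": snp_ids, "a1": alleles})
    return df[meta_cols], df[snp_cols].to_numpy(dtype=float), snps


def write_haplotypes(cohort: FamilyCohort, path, sidecar_path=None):
    """Haplotype TSV (two columns per SNP: paternal/maternal allele) plus a
    transmission-flag sidecar for offspring loci."""
    p = cohort.persons
    names = []
    for s in cohort.snps["snp_id"]:
        names += [f"{s}_pat", f"{s}_mat"]
    flat = cohort.haps.reshape(cohort.haps.shape[0], -1)
    df = pd.DataFrame({"person_id": p["person_id"].to_numpy()})
    df = pd.concat([df, pd.DataFrame(flat, columns=names)], axis=1)
    _write_tsv(df, path, "haplotypes")
    if sidecar_path is not None:
        side = pd.DataFrame(
            {"person_id": p["person_id"].to_numpy()[cohort.off_rows]})
        side = pd.concat([
            side,
            pd.DataFrame(cohort.trans_pat,
                         columns=[f"{s}_pat" for s in cohort.snps["snp_id"]]),
            pd.DataFrame(cohort.trans_mat,
                         columns=[f"{s}_mat" for s in cohort.snps["snp_id"]]),
        ], axis=1)
        _write_tsv(side, sidecar_path, "transmission-flags")


def write_scenario(scenario: SimulationScenario, path):
    data = dataclasses.asdict(scenario)
    if data.get("sibship_size_probs") is not None:
        data["sibship_size_probs"] = list(data["sibship_size_probs"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_scenario(path) -> SimulationScenario:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data.get("sibship_size_probs") is not None:
        data["sibship_size_probs"] = tuple(data["sibship_size_probs"])
    return SimulationScenario(**data)


def write_estimates_json(est_set, path, extra: Optional[dict] = None):
    """EstimateSet -> versioned JSON document."""
    doc = {
        "schema": "famfx.estimates/1",
        "design": est_set.design,
        "n_persons": est_set.n_persons,
        "n_families": est_set.n_families,
        "estimates": est_set.estimates,
        "ses": est_set.ses,
    }
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=float)


def write_sumstats(df: pd.DataFrame, path, provenance: str = "sumstats"):
    _write_tsv(df, path, provenance)


def read_sumstats(path) -> pd.DataFrame:
    return _read_tsv(path)
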