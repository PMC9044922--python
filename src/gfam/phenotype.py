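"""Root-depth phenotype analysis: heat damage index and class comparison.

The heat damage index (HDI) is defined here as the relative reduction of
mean root depth under heat versus control, in percent:
HDI = 100 * (mean control depth - mean heat depth) / mean control depth.
It is unitless, so rescaling all depths leaves it unchanged.  The
two-class comparison is a two-sided Welch t-test (unequal variances,
Satterthwaite degrees of freedom).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .qpcr_expression import CONTROL, HEAT, SUSCEPTIBLE, TOLERANT

logger = logging.getLogger("gfam")

PHENOTYPE_COLUMNS = ["genotype", "cls", "treatment", "replicate", "root_depth"]


@dataclass(frozen=True)
class PhenotypeRecord:
    genotype: str
    cls: str
    treatment: str
    replicate: int
    root_depth: float

    def __post_init__(self) -> None:
        if self.root_depth < 0:
            raise ValueError("root depth must be non-negative")
        if self.cls not in (TOLERANT, SUSCEPTIBLE):
            raise ValueError(f"unknown tolerance class {self.cls!r}")
        if self.treatment not in (CONTROL, HEAT):
            raise ValueError(f"unknown treatment {self.treatment!r}")


def records_to_frame(records: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=PHENOTYPE_COLUMNS)


def heat_damage_index(records: Sequence[PhenotypeRecord]) -> dict[str, object]:
    """HDI (%) per genotype and per tolerance class.

    Per genotype: relative reduction of mean root depth under heat.  Per
    class: the mean over member genotypes.  Every genotype needs at least
    one replicate per treatment and a non-zero mean control depth.
    """
    df = records_to_frame(records)
    per_genotype: dict[str, float] = {}
    cls_of: dict[str, str] = {}
    for genotype, grp in df.groupby("genotype"):
        control = grp.loc[grp["treatment"] == CONTROL, "root_depth"]
        heat = grp.loc[grp["treatment"] == HEAT, "root_depth"]
        if control.empty or heat.empty:
            raise ValueError(f"genotype {genotype!r} lacks control or heat replicates")
        if control.mean() == 0:
            raise ValueError(f"genotype {genotype!r} has zero mean control depth")
        per_genotype[genotype] = 100.0 * (control.mean() - heat.mean()) / control.mean()
        cls_of[genotype] = grp["cls"].iloc[0]
    per_class: dict[str, float] = {}
    for cls in (TOLERANT, SUSCEPTIBLE):
        members = [h for g, h in per_genotype.items() if cls_of[g] == cls]
        if members:
            per_class[cls] = float(np.mean(members))
    return {"per_genotype": per_genotype, "per_class": per_class}


def genotype_replicate_hdi(records: Sequence[PhenotypeRecord]) -> pd.DataFrame:
    """Per-replicate HDI values (each heat replicate vs its genotype's
    mean control depth), suitable for the class comparison test."""
    df = records_to_frame(records)
    rows = []
    for genotype, grp in df.groupby("genotype"):
        control_mean = grp.loc[grp["treatment"] == CONTROL, "root_depth"].mean()
        if not control_mean > 0:
            raise ValueError(f"genotype {genotype!r} has zero mean control depth")
        for _, row in grp[grp["treatment"] == HEAT].iterrows():
            rows.append(
                {
                    "genotype": genotype,
                    "cls": row["cls"],
                    "replicate": row["replicate"],
                    "hdi": 100.0 * (control_mean - row["root_depth"]) / control_mean,
                }
            )
    return pd.DataFrame(rows)


def compare_classes(hdi_values: pd.DataFrame) -> dict[str, float]:
    """Welch t-test between tolerant and susceptible per-replicate HDI.

    Returns the class-mean difference (susceptible minus tolerant), the
    Welch statistic, Satterthwaite df and the two-sided p-value.  Two
    identical zero-variance samples compare with p = 1.
    """
    tol = hdi_values.loc[hdi_values["cls"] == TOLERANT, "hdi"].to_numpy(float)
    sus = hdi_values.loc[hdi_values["cls"] == SUSCEPTIBLE, "hdi"].to_numpy(float)
    if len(tol) < 2 or len(sus) < 2:
        raise ValueError("need at least 2 HDI values per class")
    if tol.std(ddof=1) == 0 and sus.std(ddof=1) == 0 and tol.mean() == sus.mean():
        return {
            "difference": 0.0,
            "statistic": 0.0,
            "df": float(len(tol) + len(sus) - 2),
            "p_value": 1.0,
        }
    result = stats.ttest_ind(sus, tol, equal_var=False)
    return {
        "difference": float(sus.mean() - tol.mean()),
        "statistic": float(result.statistic),
        "df": float(result.df),
        "p_value": float(result.pvalue),
    }
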