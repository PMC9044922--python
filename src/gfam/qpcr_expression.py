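"""qPCR relative expression (2^-ddCt), fold change, and trait categorization.

The pipeline follows the comparative-Ct convention: per sample,
dCt = Ct_target - Ct_reference; per (gene, genotype), the treatment
replicate's ddCt is its dCt minus the mean control dCt (replicates are not
paired); the relative expression ratio is 2^-ddCt.

Two averaging scales coexist deliberately: the linear fold change FC is the
arithmetic mean of replicate ratios (then of genotype means within a
tolerance class), while Log2FC is the arithmetic mean of per-replicate
log2 ratios.  FC != 2^Log2FC in general (AM >= GM), and published
FC/Log2FC pairs from this design are only mutually consistent under this
reading.

Downstream calls are threshold rules on the class Log2FC pair:
|Log2FC| >= 1 flags significant up/down regulation; the sign pair places a
gene in one of four regulation-pattern groups (zero counts as up); and the
trait label weighs the evidence for heat tolerance (up in tolerant, down in
susceptible) against the evidence for susceptibility (the mirror image).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("gfam")

TOLERANT, SUSCEPTIBLE = "TOLERANT", "SUSCEPTIBLE"
CONTROL, HEAT = "CONTROL", "HEAT"

TRAIT_LABELS = (
    "highly heat-tolerant",
    "moderately highly heat-tolerant",
    "heat-tolerant",
    "highly heat-susceptible",
    "moderately highly heat-susceptible",
    "heat-susceptible",
    "neutral",
    "not-DE",
)

CT_COLUMNS = ["genotype", "cls", "treatment", "replicate", "gene", "ct"]


@dataclass(frozen=True)
class CtTable:
    """Validated Ct measurements plus the reference (housekeeping) gene.

    Technical repeats (duplicate rows for one (genotype, treatment,
    replicate, gene) cell) are averaged into a single Ct on construction.
    """

    data: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        df = self.data
        missing = set(CT_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        if not np.isfinite(df["ct"]).all():
            raise ValueError("all Ct values must be finite")
        bad_cls = set(df["cls"]) - {TOLERANT, SUSCEPTIBLE}
        if bad_cls:
            raise ValueError(f"unknown tolerance classes: {sorted(bad_cls)}")
        bad_tr = set(df["treatment"]) - {CONTROL, HEAT}
        if bad_tr:
            raise ValueError(f"unknown treatments: {sorted(bad_tr)}")
        collapsed = (
            df.groupby(["genotype", "cls", "treatment", "replicate", "gene"], sort=False)
            ["ct"].mean().reset_index()
        )
        object.__setattr__(self, "data", collapsed)
        samples = collapsed.groupby(["genotype", "treatment", "replicate"])
        for (genotype, treatment, replicate), grp in samples:
            if self.reference_gene not in set(grp["gene"]):
                raise ValueError(
                    f"reference gene {self.reference_gene!r} missing in sample "
                    f"({genotype}, {treatment}, {replicate})"
                )
        for genotype, grp in collapsed.groupby("genotype"):
            treatments = set(grp["treatment"])
            if treatments != {CONTROL, HEAT}:
                raise ValueError(
                    f"genotype {genotype!r} lacks a control or treatment replicate"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, reference_gene: str) -> "CtTable":
        df = pd.read_csv(path, sep="\t")
        return cls(data=df, reference_gene=reference_gene)

    @property
    def genes(self) -> list[str]:
        return [g for g in self.data["gene"].unique() if g != self.reference_gene]


@dataclass(frozen=True)
class ExpressionResult:
    gene: str
    fc_tolerant: float
    fc_susceptible: float
    log2fc_tolerant: float
    log2fc_susceptible: float
    sig_tolerant: str
    sig_susceptible: str
    group: int
    trait: str


def relative_expression(ct_table: CtTable) -> pd.DataFrame:
    """2^-ddCt ratio per (gene, genotype, heat replicate).

    Returns a DataFrame with columns gene, genotype, cls, replicate, ratio.
    """
    df = ct_table.data
    ref = df[df["gene"] == ct_table.reference_gene].set_index(
        ["genotype", "treatment", "replicate"]
    )["ct"]
    rows = []
    for (gene, genotype), grp in df[df["gene"] != ct_table.reference_gene].groupby(
        ["gene", "genotype"], sort=False
    ):
        cls = grp["cls"].iloc[0]
        dct = {}
        for _, row in grp.iterrows():
            key = (genotype, row["treatment"], row["replicate"])
            if key not in ref.index:
                raise ValueError(f"missing reference Ct for sample {key}")
            dct[(row["treatment"], row["replicate"])] = row["ct"] - ref.loc[key]
        control = [v for (tr, _), v in dct.items() if tr == CONTROL]
        if not control:
            raise ValueError(f"no control replicates for gene {gene}, genotype {genotype}")
        baseline = float(np.mean(control))
        for (tr, rep), v in dct.items():
            if tr != HEAT:
                continue
            ddct = v - baseline
            rows.append(
                {
                    "gene": gene,
                    "genotype": genotype,
                    "cls": cls,
                    "replicate": rep,
                    "ratio": 2.0 ** (-ddct),
                }
            )
    return pd.DataFrame(rows)


def class_fold_change(ratios: pd.DataFrame) -> pd.DataFrame:
    """Per-(gene, class) FC and Log2FC from replicate ratios.

    FC averages on the linear scale (replicates within genotype, then
    genotypes within class); Log2FC averages per-replicate log2 ratios
    across all (genotype, replicate) pairs of the class.
    """
    if (ratios["ratio"] <= 0).any():
        raise ValueError("expression ratios must be positive")
    rows = []
    for (gene, cls), grp in ratios.groupby(["gene", "cls"], sort=False):
        genotype_fc = grp.groupby("genotype")["ratio"].mean()
        rows.append(
            {
                "gene": gene,
                "cls": cls,
                "fc": float(genotype_fc.mean()),
                "log2fc": float(np.log2(grp["ratio"]).mean()),
            }
        )
    return pd.DataFrame(rows)


def significance(log2fc: float) -> str:
    """UP when Log2FC >= 1, DOWN when <= -1, else NS (boundaries inclusive)."""
    if not math.isfinite(log2fc):
        raise ValueError("Log2FC must be finite")
    if log2fc >= 1.0:
        return "UP"
    if log2fc <= -1.0:
        return "DOWN"
    return "NS"


def classify_group(log2fc_tol: float, log2fc_sus: float) -> int:
    """Regulation-pattern group from the sign pair (zero counts as up).

    1: up in tolerant, down in susceptible; 2: up in both;
    3: down in tolerant, up in susceptible; 4: down in both.
    """
    up_tol, up_sus = log2fc_tol >= 0, log2fc_sus >= 0
    if up_tol and not up_sus:
        return 1
    if up_tol and up_sus:
        return 2
    if not up_tol and up_sus:
        return 3
    return 4


def classify_trait(log2fc_tol: float, log2fc_sus: float) -> str:
    """Heat-response trait label from the class Log2FC pair.

    Tolerance evidence counts significant up-regulation in the tolerant
    class and significant down-regulation in the susceptible class;
    susceptibility evidence is the mirror.  Both kinds of evidence at once
    is 'neutral'; two pieces of one kind is 'highly'; one piece grades into
    'moderately highly' when the other class trends (non-significantly) the
    opposite way.
    """
    tol_up = log2fc_tol >= 1.0
    sus_down = log2fc_sus <= -1.0
    tol_down = log2fc_tol <= -1.0
    sus_up = log2fc_sus >= 1.0
    tol_ev = int(tol_up) + int(sus_down)
    sus_ev = int(tol_down) + int(sus_up)
    if tol_ev > 0 and sus_ev > 0:
        return "neutral"
    if tol_ev == 2:
        return "highly heat-tolerant"
    if tol_ev == 1:
        if tol_up:
            return "moderately highly heat-tolerant" if log2fc_sus < 0 else "heat-tolerant"
        return "heat-tolerant"
    if sus_ev == 2:
        return "highly heat-susceptible"
    if sus_ev == 1:
        if tol_down:
            return "moderately highly heat-susceptible" if log2fc_sus > 0 else "heat-susceptible"
        return "heat-susceptible"
    return "not-DE"


def result_from_log2fc(
    gene: str,
    log2fc_tol: float,
    log2fc_sus: float,
    fc_tol: float | None = None,
    fc_sus: float | None = None,
) -> ExpressionResult:
    """Assemble significance/group/trait for one gene from its Log2FC pair."""
    return ExpressionResult(
        gene=gene,
        fc_tolerant=float("nan") if fc_tol is None else fc_tol,
        fc_susceptible=float("nan") if fc_sus is None else fc_sus,
        log2fc_tolerant=log2fc_tol,
        log2fc_susceptible=log2fc_sus,
        sig_tolerant=significance(log2fc_tol),
        sig_susceptible=significance(log2fc_sus),
        group=classify_group(log2fc_tol, log2fc_sus),
        trait=classify_trait(log2fc_tol, log2fc_sus),
    )


def expression_results(ct_table: CtTable) -> list[ExpressionResult]:
    """Full pipeline from Ct measurements to per-gene trait calls."""
    fold = class_fold_change(relative_expression(ct_table))
    wide = fold.pivot(index="gene", columns="cls", values=["fc", "log2fc"])
    results = []
    for gene in ct_table.genes:
        if gene not in wide.index:
            continue
        results.append(
            result_from_log2fc(
                gene,
                float(wide.loc[gene, ("log2fc", TOLERANT)]),
                float(wide.loc[gene, ("log2fc", SUSCEPTIBLE)]),
                fc_tol=float(wide.loc[gene, ("fc", TOLERANT)]),
                fc_sus=float(wide.loc[gene, ("fc", SUSCEPTIBLE)]),
            )
        )
    logger.info("expression_results: %d genes analyzed", len(results))
    return results


def summarize_regulation(results: Sequence[ExpressionResult]) -> dict[str, object]:
    """Regulation summary: per-class up/down counts, DEG union, trait tallies."""
    if not results:
        raise ValueError("no expression results to summarize")
    up_tol = sum(1 for r in results if r.sig_tolerant == "UP")
    down_tol = sum(1 for r in results if r.sig_tolerant == "DOWN")
    up_sus = sum(1 for r in results if r.sig_susceptible == "UP")
    down_sus = sum(1 for r in results if r.sig_susceptible == "DOWN")
    union = sum(1 for r in results if "NS" != r.sig_tolerant or "NS" != r.sig_susceptible)
    traits = {label: 0 for label in TRAIT_LABELS}
    for r in results:
        traits[r.trait] += 1
    tolerant_category = sum(
        traits[t] for t in TRAIT_LABELS if t.endswith("heat-tolerant")
    )
    susceptible_category = sum(
        traits[t] for t in TRAIT_LABELS if t.endswith("heat-susceptible")
    )
    return {
        "up_tolerant": up_tol,
        "down_tolerant": down_tol,
        "total_tolerant": up_tol + down_tol,
        "up_susceptible": up_sus,
        "down_susceptible": down_sus,
        "total_susceptible": up_sus + down_sus,
        "deg_union": union,
        "per_trait": traits,
        "tolerant_category": tolerant_category,
        "susceptible_category": susceptible_category,
    }


def results_to_frame(results: Iterable[ExpressionResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
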