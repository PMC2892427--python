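"""Two-stage (LM -> LME) and three-stage (LM -> LME -> FBAT) orchestration.

Stage 1 screens every SNP with fast least squares at a liberal cut-off
(default 0.1); stage 2 confirms survivors with the kinship mixed model at a
genome-wide cut-off (default 1e-6); stage 3 validates stage-2 hits with FBAT,
whose robustness to population stratification they inherit.  The final
p-value is the FBAT p-value Bonferroni-corrected ONLY for the SNPs that
entered stage 3 (min(1, n_stage3 * p), capped at 1); SNPs that never reach
stage 3 are deemed not associated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import FbatLayout, fbat_test, fit_lm, fit_lme
from .genotypes import GenotypeMatrix
from .pedigree import KinshipMatrix, NuclearFamily

__all__ = [
    "StageConfig",
    "StagedResult",
    "run_two_stage",
    "run_three_stage",
    "select_top_snps",
]


@dataclass(frozen=True)
class StageConfig:
    """Stage cut-offs: alpha1 for the LM screen, alpha2 for genome-wide LME
    significance, alpha3_family for the familywise level of the Bonferroni-
    corrected FBAT stage."""

    alpha1: float = 0.1
    alpha2: float = 1e-6
    alpha3_family: float = 0.05

    def __post_init__(self):
        for name in ("alpha1", "alpha2", "alpha3_family"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class StagedResult:
    """Per-SNP stage progression plus the stage-3 multiplicity context.

    ``table`` columns: snp_id, stage_reached (1-3), lm_pvalue, lme_pvalue,
    fbat_pvalue, adjusted_pvalue, significant, note.  ``n_stage3`` counts
    every SNP that entered stage 3 (including ones FBAT could not test) and
    is the Bonferroni multiplier.
    """

    table: pd.DataFrame
    n_stage3: int
    config: StageConfig

    @property
    def significant_snps(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "snp_id"])


def bonferroni(pvalue: float, n_tests: int) -> float:
    """Familywise-adjusted p-value min(1, n * p)."""
    return min(1.0, n_tests * pvalue)


def _stage12(trait, genos: GenotypeMatrix, kinship: KinshipMatrix, cfg: StageConfig):
    rows = []
    for j, snp in enumerate(genos.snp_ids):
        x = genos.counts[:, j]
        lm = fit_lm(trait, x, snp_id=snp)
        row = {
            "snp_id": snp,
            "stage_reached": 1,
            "lm_pvalue": lm.pvalue,
            "lme_pvalue": None,
            "fbat_pvalue": None,
            "adjusted_pvalue": None,
            "significant": False,
            "note": lm.note,
        }
        if lm.pvalue is not None and lm.pvalue < cfg.alpha1:
            row["stage_reached"] = 2
            lme, _ = fit_lme(trait, x, kinship, snp_id=snp)
            row["lme_pvalue"] = lme.pvalue
            if not lme.converged:
                row["note"] = (row["note"] + "; " if row["note"] else "") + \
                    "LME did not converge"
            elif lme.note:
                row["note"] = lme.note
        rows.append(row)
    return rows


def run_two_stage(
    trait: np.ndarray,
    genos: GenotypeMatrix,
    kinship: KinshipMatrix,
    cfg: StageConfig = StageConfig(),
) -> StagedResult:
    """LM screen then LME; significance at ``alpha2`` on the LME p-value."""
    rows = _stage12(trait, genos, kinship, cfg)
    for row in rows:
        p = row["lme_pvalue"]
        row["significant"] = p is not None and p < cfg.alpha2
    return StagedResult(pd.DataFrame(rows), n_stage3=0, config=cfg)


def run_three_stage(
    trait: np.ndarray,
    genos: GenotypeMatrix,
    kinship: KinshipMatrix,
    families: list[NuclearFamily],
    cfg: StageConfig = StageConfig(),
) -> StagedResult:
    """Full three-stage pipeline with stage-3-restricted Bonferroni.

    A SNP is significant iff it reaches stage 3 and
    min(1, n_stage3 * fbat_p) <= alpha3_family.  SNPs FBAT cannot test
    (non-informative in the available nuclear families) still count toward
    n_stage3 — the conservative choice — but are reported not significant.
    """
    rows = _stage12(trait, genos, kinship, cfg)
    layout = FbatLayout(families) if families else None
    stage3 = [
        row for row in rows
        if row["lme_pvalue"] is not None and row["lme_pvalue"] < cfg.alpha2
    ]
    n3 = len(stage3)
    snp_col = {snp: j for j, snp in enumerate(genos.snp_ids)}
    for row in stage3:
        row["stage_reached"] = 3
        if layout is None:
            row["note"] = "no FBAT-usable nuclear families"
            continue
        fb = fbat_test(trait, genos.counts[:, snp_col[row["snp_id"]]], layout,
                       snp_id=row["snp_id"])
        row["fbat_pvalue"] = fb.pvalue
        if fb.pvalue is None:
            row["note"] = fb.note
            continue
        row["adjusted_pvalue"] = bonferroni(fb.pvalue, n3)
        row["significant"] = row["adjusted_pvalue"] <= cfg.alpha3_family
    return StagedResult(pd.DataFrame(rows), n_stage3=n3, config=cfg)


def select_top_snps(staged: StagedResult, loci: dict[str, str]) -> StagedResult:
    """Restrict stage 3 to the top SNP per locus and re-adjust.

    Keeps, per locus, the stage-3 SNP with the smallest LME p-value (ties
    broken by lowest snp_id); n_stage3 becomes the number of loci represented
    and the Bonferroni adjustment is recomputed.  ``loci`` maps snp_id ->
    locus label and must cover every stage-3 candidate.
    """
    tab = staged.table.copy()
    s3 = tab.index[tab["stage_reached"] == 3]
    missing = [tab.at[i, "snp_id"] for i in s3 if tab.at[i, "snp_id"] not in loci]
    if missing:
        raise ValueError(f"no locus assignment for stage-3 SNPs: {missing}")
    best: dict[str, int] = {}
    for i in s3:
        snp = tab.at[i, "snp_id"]
        locus = loci[snp]
        p = tab.at[i, "lme_pvalue"]
        if locus not in best:
            best[locus] = i
        else:
            bp = tab.at[best[locus], "lme_pvalue"]
            bsnp = tab.at[best[locus], "snp_id"]
            if (p, snp) < (bp, bsnp):
                best[locus] = i
    keep = set(best.values())
    n3 = len(best)
    for i in s3:
        if i not in keep:
            tab.at[i, "stage_reached"] = 2
            tab.at[i, "fbat_pvalue"] = None
            tab.at[i, "adjusted_pvalue"] = None
            tab.at[i, "significant"] = False
            continue
        p = tab.at[i, "fbat_pvalue"]
        if p is not None:
            adj = bonferroni(p, n3)
            tab.at[i, "adjusted_pvalue"] = adj
            tab.at[i, "significant"] = adj <= staged.config.alpha3_family
    return StagedResult(tab, n_stage3=n3, config=staged.config)
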