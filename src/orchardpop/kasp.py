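"""Allele-specific (KASP-style) marker panel for early-flowering selection.

Genotypes at a small marker panel are coded R (reference) / A (alternate):
dosage 0 -> R/R, 1 -> R/A, 2 -> A/A.  A sample is predicted early-flowering
when at least two of the three markers carry the alternate allele (R/A or
A/A); missing markers never count toward the quorum, so an all-missing
sample is conservatively predicted non-early (and flagged).  Accuracy is
evaluated against observed flowering dates with a day-of-year cutoff:
flowering on or before the cutoff day is the early phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix

#: Day-of-year of March 31 in a non-leap year.
MARCH_31 = 90

ALT_CODES = {"R/A", "A/A"}


@dataclass
class KaspCall:
    accession: str
    codes: tuple  # per-marker "R/R" | "R/A" | "A/A" | "missing"

    @property
    def all_missing(self) -> bool:
        return all(c == "missing" for c in self.codes)


def encode_calls(genotypes: GenotypeMatrix, marker_indices: Sequence[int]) -> list:
    """R/A encoding of the marker panel for every accession."""
    code_of = {0.0: "R/R", 1.0: "R/A", 2.0: "A/A"}
    calls = []
    for i, sample in enumerate(genotypes.samples):
        codes = []
        for j in marker_indices:
            d = genotypes.dosages[i, j]
            codes.append("missing" if np.isnan(d) else code_of[float(d)])
        calls.append(KaspCall(accession=sample, codes=tuple(codes)))
    return calls


def classify_early(call: KaspCall, quorum: int = 2) -> str:
    """Predict 'early' when >= ``quorum`` markers are R/A or A/A."""
    n_alt = sum(c in ALT_CODES for c in call.codes)
    return "early" if n_alt >= quorum else "non_early"


def _round1(x: float) -> float:
    return float(Decimal(x * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ClassifierReport:
    """Contingency of predicted class vs observed flowering phenotype.

    Accuracies are computed over records with a flowering date; percentages
    are rendered to 1 decimal (e.g. 87.5 means 87.5%).
    """

    n_pred_early: int
    early_correct: int
    early_wrong: int
    early_missing: int
    n_pred_non_early: int
    non_early_correct: int
    non_early_wrong: int
    non_early_missing: int

    @property
    def accuracy_early(self) -> float:
        return _round1(self.early_correct / (self.n_pred_early - self.early_missing))

    @property
    def accuracy_non_early(self) -> float:
        return _round1(
            self.non_early_correct / (self.n_pred_non_early - self.non_early_missing)
        )

    @property
    def accuracy_overall(self) -> float:
        correct = self.early_correct + self.non_early_correct
        scored = (self.n_pred_early - self.early_missing) + (
            self.n_pred_non_early - self.non_early_missing
        )
        return _round1(correct / scored)

    @property
    def prevalence(self) -> float:
        """Observed early-flowering share among records with dates."""
        obs_early = self.early_correct + self.non_early_wrong
        scored = (self.n_pred_early - self.early_missing) + (
            self.n_pred_non_early - self.non_early_missing
        )
        return _round1(obs_early / scored)

    @property
    def panel_size(self) -> int:
        return self.n_pred_early + self.n_pred_non_early


def evaluate(
    classifications: Sequence[str],
    flowering_days,
    cutoff: int = MARCH_31,
) -> ClassifierReport:
    """Contingency-based accuracy of the 2-of-3 rule.

    ``flowering_days`` holds day-of-year integers (NaN/None = missing
    record).  Observed early means flowering on or before ``cutoff``.
    """
    if len(classifications) == 0:
        raise ValueError("empty panel")
    ec = ew = em = nc = nw = nm = 0
    npe = nne = 0
    for pred, day in zip(classifications, flowering_days):
        missing = day is None or (isinstance(day, float) and np.isnan(day))
        obs_early = (not missing) and day <= cutoff
        if pred == "early":
            npe += 1
            if missing:
                em += 1
            elif obs_early:
                ec += 1
            else:
                ew += 1
        else:
            nne += 1
            if missing:
                nm += 1
            elif obs_early:
                nw += 1
            else:
                nc += 1
    return ClassifierReport(
        n_pred_early=npe, early_correct=ec, early_wrong=ew, early_missing=em,
        n_pred_non_early=nne, non_early_correct=nc, non_early_wrong=nw,
        non_early_missing=nm,
    )


def select_markers(
    genotypes: GenotypeMatrix,
    candidate_indices: Sequence[int],
    flowering_days,
    gwas_p: Optional[dict] = None,
    cutoff: int = MARCH_31,
    k: int = 3,
) -> list:
    """Heuristic marker selection: rank candidate SNPs by single-marker
    classification accuracy on the training panel, tie-break by call rate
    (descending), then GWAS p-value (ascending), then index.

    With fewer than ``k`` candidates, all are returned with a warning.
    """
    import logging

    days = np.asarray(flowering_days, dtype=float)
    scored = []
    for j in candidate_indices:
        col = genotypes.dosages[:, j]
        pred_early = col >= 1  # single-marker rule: any ALT copy
        valid = ~np.isnan(col) & ~np.isnan(days)
        if valid.sum() == 0:
            acc = 0.0
        else:
            obs_early = days <= cutoff
            acc = float(np.mean(pred_early[valid] == obs_early[valid]))
        call_rate = float(np.mean(~np.isnan(col)))
        p = gwas_p.get(j, 1.0) if gwas_p else 1.0
        scored.append((-acc, -call_rate, p, j))
    scored.sort()
    if len(scored) < k:
        logging.getLogger(__name__).warning(
            "only %d candidate markers available (requested %d)", len(scored), k
        )
    return [j for *_, j in scored[:k]]
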