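"""Predictive utility of the risk variant, with prevalence recalibration.

Two classifier rules are evaluated.  The genotype-only rule labels a subject
"high risk" when carrying at least one copy of the risk allele.  The
genotype-plus-local-ancestry rule additionally labels non-carriers "high
risk" when their windowed AFR dosage exceeds the EAS dosage (an exact tie is
low risk).  Because the second rule only widens the high-risk set, its
sensitivity can never decrease and its specificity can never increase
relative to the genotype-only rule.

Sample sensitivity and specificity are recalibrated to an externally assumed
population risk p via Bayes' rule:

    PPV(p) = sens * p / (sens * p + (1 - spec)(1 - p))
    NPV(p) = spec (1 - p) / (spec (1 - p) + (1 - sens) p)

The risk in the high-risk (low-risk) group is PPV (1 - NPV), and the
relative risk is p / PPV.  ``required_sensitivity`` inverts the residual
risk among test negatives to give the minimum sensitivity at which reduced
blood monitoring would be defensible.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort_io import CohortValidationError, PhenotypeClass

logger = logging.getLogger("clozanc")

DEFAULT_PREVALENCES = {"neutropenia": 0.038, "agranulocytosis": 0.009}


class ClassifierRule(enum.Enum):
    GENOTYPE_ONLY = "genotype_only"
    GENOTYPE_PLUS_LAE = "genotype_plus_lae"


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise CohortValidationError("confusion counts must be nonnegative")

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_cases

    @property
    def specificity(self) -> float:
        return self.tn / self.n_controls


@dataclass
class TestCharacteristics:
    """Confusion-derived rates plus prevalence-recalibrated predictive values."""

    sensitivity: float
    specificity: float
    prevalence: float
    ppv_adj: float
    npv_adj: float
    risk_high: float
    risk_low: float
    rr: float
    cm: Optional[ConfusionMatrix] = None


def classify(
    hard_call: Optional[float],
    afr_dosage: Optional[float] = None,
    eas_dosage: Optional[float] = None,
    rule: ClassifierRule = ClassifierRule.GENOTYPE_ONLY,
) -> str:
    """Risk label for one subject: ``"high_risk"`` or ``"low_risk"``.

    Carriers (hard call >= 1) are high risk under both rules; under the
    genotype-plus-LAE rule non-carriers are also high risk when their AFR
    window dosage strictly exceeds the EAS dosage (ties are low risk).
    """
    if hard_call is None or (isinstance(hard_call, float) and np.isnan(hard_call)):
        raise CohortValidationError("classify requires a non-missing hard call")
    if hard_call >= 1:
        return "high_risk"
    if rule is ClassifierRule.GENOTYPE_PLUS_LAE:
        if afr_dosage is None or eas_dosage is None or np.isnan(afr_dosage) or np.isnan(eas_dosage):
            raise CohortValidationError("genotype_plus_lae rule requires window dosages")
        if afr_dosage > eas_dosage:
            return "high_risk"
    return "low_risk"


def classify_subjects(
    hard_calls: pd.Series,
    windows: Optional[pd.DataFrame] = None,
    rule: ClassifierRule = ClassifierRule.GENOTYPE_ONLY,
) -> tuple[pd.Series, int]:
    """Vectorised risk labels; subjects missing required inputs are excluded.

    Returns ``(labels, n_excluded)``; excluded subjects are dropped from the
    labels and counted (with a log message), mirroring how subjects without
    a reliable hard call were left out of the published confusion counts.
    """
    calls = hard_calls.astype(float)
    usable = calls.notna()
    if rule is ClassifierRule.GENOTYPE_PLUS_LAE:
        if windows is None:
            raise CohortValidationError("genotype_plus_lae rule requires window dosages")
        afr = windows["dos_afr"].reindex(hard_calls.index)
        eas = windows["dos_eas"].reindex(hard_calls.index)
        usable &= afr.notna() & eas.notna()
        high = (calls >= 1) | ((calls == 0) & (afr > eas))
    else:
        high = calls >= 1
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("classify_subjects(%s): excluded %d subject(s)", rule.value, n_excluded)
    labels = high[usable].map({True: "high_risk", False: "low_risk"})
    labels.name = "risk_label"
    return labels, n_excluded


def confusion(
    predictions: pd.Series,
    phenotype_classes: pd.Series,
    case_definition: str = "neutropenia",
) -> ConfusionMatrix:
    """2x2 tally of high-risk labels against the phenotype classes.

    ``case_definition="neutropenia"`` counts every case (ANC <= 1500) as
    positive; ``"agranulocytosis"`` counts only ANC <= 500 cases and drops
    neutropenia-only subjects, keeping the same control set.
    """
    if case_definition not in ("neutropenia", "agranulocytosis"):
        raise CohortValidationError(f"unknown case definition {case_definition!r}")
    classes = phenotype_classes.reindex(predictions.index)
    if classes.isna().any():
        raise CohortValidationError("predictions and phenotype classes must share ids")
    if case_definition == "agranulocytosis":
        keep = classes != PhenotypeClass.NEUTROPENIA_ONLY
        predictions, classes = predictions[keep], classes[keep]
        positive = classes == PhenotypeClass.AGRANULOCYTOSIS
    else:
        positive = classes.map(lambda c: c.is_neutropenia)
    high = predictions == "high_risk"
    return ConfusionMatrix(
        tp=int((high & positive).sum()),
        fp=int((high & ~positive).sum()),
        fn=int((~high & positive).sum()),
        tn=int((~high & ~positive).sum()),
    )


def recalibrate(sens: float, spec: float, p: float) -> TestCharacteristics:
    """Predictive values at an assumed population risk ``p`` (Bayes' rule).

    Uses unrounded sensitivity/specificity.  When ``p`` equals the sample
    case fraction this reduces exactly to the raw sample PPV/NPV.
    """
    for name, value in (("sens", sens), ("spec", spec)):
        if not 0 <= value <= 1:
            raise CohortValidationError(f"{name} must lie in [0, 1], got {value}")
    if not 0 < p < 1:
        raise CohortValidationError(f"assumed risk must lie in (0, 1), got {p}")
    ppv = sens * p / (sens * p + (1 - spec) * (1 - p)) if sens * p + (1 - spec) * (1 - p) > 0 else float("nan")
    npv = spec * (1 - p) / (spec * (1 - p) + (1 - sens) * p)
    risk_high = ppv
    risk_low = 1 - npv
    return TestCharacteristics(
        sensitivity=float(sens),
        specificity=float(spec),
        prevalence=float(p),
        ppv_adj=float(ppv),
        npv_adj=float(npv),
        risk_high=float(risk_high),
        risk_low=float(risk_low),
        rr=float(p / risk_high) if risk_high > 0 else float("inf"),
    )


def required_sensitivity(acceptable_risk: float, p: float, spec: float = 1.0) -> float:
    """Minimum sensitivity bringing the risk among test-negatives down to target.

    Solves ``risk_low(s) = acceptable_risk`` for the sensitivity ``s``.  The
    default perfect-specificity convention gives the closed form
    ``s = 1 - acceptable_risk (1 - p) / (p (1 - acceptable_risk))``; passing
    the observed specificity generalises the inversion.  When the acceptable
    risk is not below the population risk the test is useless and 0 is
    returned with a warning.
    """
    if not 0 < p < 1:
        raise CohortValidationError(f"population risk must lie in (0, 1), got {p}")
    if not 0 < acceptable_risk < 1:
        raise CohortValidationError(f"acceptable risk must lie in (0, 1), got {acceptable_risk}")
    if not 0 < spec <= 1:
        raise CohortValidationError(f"specificity must lie in (0, 1], got {spec}")
    if acceptable_risk >= p:
        warnings.warn(
            "acceptable risk is not below the population risk; any test suffices (returning 0)",
            RuntimeWarning,
        )
        return 0.0
    return 1.0 - acceptable_risk * spec * (1 - p) / (p * (1 - acceptable_risk))


def characteristics_from_counts(
    cm: ConfusionMatrix, prevalence: float
) -> TestCharacteristics:
    """Full test characteristics from confusion counts at an assumed risk."""
    out = recalibrate(cm.sensitivity, cm.specificity, prevalence)
    out.cm = cm
    return out


def characteristics_table(
    phenotype_classes: pd.Series,
    hard_calls: pd.Series,
    windows: pd.DataFrame,
    *,
    prevalences: Optional[dict[str, float]] = None,
    rules: Sequence[ClassifierRule] = (ClassifierRule.GENOTYPE_ONLY, ClassifierRule.GENOTYPE_PLUS_LAE),
) -> pd.DataFrame:
    """Predictive-characteristics report, one row per (phenotype, rule).

    Every combination records the confusion counts, sensitivity,
    specificity and the prevalence-recalibrated metrics at the configured
    assumed risks (defaults: neutropenia 3.8%, agranulocytosis 0.9%).
    """
    prevalences = dict(DEFAULT_PREVALENCES if prevalences is None else prevalences)
    rows = []
    for rule in rules:
        labels, n_excluded = classify_subjects(hard_calls, windows, rule)
        classes = phenotype_classes.reindex(labels.index).dropna()
        labels = labels.reindex(classes.index)
        for phenotype, prevalence in prevalences.items():
            cm = confusion(labels, classes, case_definition=phenotype)
            tc = characteristics_from_counts(cm, prevalence)
            rows.append(
                {
                    "phenotype": phenotype,
                    "rule": rule.value,
                    "prevalence": prevalence,
                    "tp": cm.tp,
                    "fp": cm.fp,
                    "fn": cm.fn,
                    "tn": cm.tn,
                    "sensitivity": tc.sensitivity,
                    "specificity": tc.specificity,
                    "risk_high": tc.risk_high,
                    "risk_low": tc.risk_low,
                    "ppv": tc.ppv_adj,
                    "npv": tc.npv_adj,
                    "rr": tc.rr,
                    "n_excluded": n_excluded,
                }
            )
    return pd.DataFrame(rows)
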