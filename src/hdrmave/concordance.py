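"""Calibration of multiplexed calls: singleton assay, read-count tuning,
clinical sensitivity/specificity and OddsPath evidence strength.

The singleton HDR assay measures one variant at a time as a rescue
fraction relative to wild type; fixed cutoffs at 0.4 and 0.7 (log2 -1.32
and -0.51) give three classes.  Discordance between singleton and
multiplexed calls drives the read-count threshold: the threshold is
raised until enough discordant variants drop out of the multiplexed
dataset.

Against clinical truth sets, sensitivity is the fraction of
pathogenic/likely-pathogenic controls called loss of function and
specificity the fraction of benign/likely-benign controls called
functionally normal.  OddsPath converts the same confusion counts into
odds of pathogenicity for an abnormal (PS3) or normal (BS3) readout,
banded into ACMG evidence strengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classification import (
    FUNCTIONALLY_NORMAL,
    INTERMEDIATE_FUNCTION,
    LOSS_OF_FUNCTION,
    UNSCORED,
    FunctionalCall,
)
from .scoring import ScoreRecord

__all__ = [
    "SINGLETON_NONFUNCTIONAL_CUTOFF",
    "SINGLETON_NORMAL_CUTOFF",
    "PS3_BANDS",
    "BS3_BANDS",
    "SingletonResult",
    "ClinicalLabel",
    "ConcordanceReport",
    "singleton_classify",
    "tune_read_threshold",
    "sensitivity_specificity",
    "oddspath",
]

#: Singleton-assay rescue-fraction cutoffs (linear scale).
SINGLETON_NONFUNCTIONAL_CUTOFF = 0.4
SINGLETON_NORMAL_CUTOFF = 0.7

NONFUNCTIONAL = "nonfunctional"

BENIGN = "benign_likely_benign"
PATHOGENIC = "pathogenic_likely_pathogenic"
VUS = "vus"
CONFLICTING = "conflicting"

#: PS3 strength thresholds (odds of pathogenicity >= value), descending.
PS3_BANDS = (("very_strong", 350.0), ("strong", 18.7), ("moderate", 4.3), ("supporting", 2.1))
#: BS3 strength thresholds (odds of pathogenicity <= value), ascending.
BS3_BANDS = (("strong", 0.053), ("moderate", 0.23), ("supporting", 0.48))


@dataclass(frozen=True)
class SingletonResult:
    variant_label: str
    rescue_fraction: float
    log2_rescue: float  # rounded to 2 decimals for display; nan when rescue == 0
    call: str


@dataclass(frozen=True)
class ClinicalLabel:
    variant_label: str
    label: str
    review_status: str = ""

    def __post_init__(self) -> None:
        if self.label not in (BENIGN, PATHOGENIC, VUS, CONFLICTING):
            raise ValueError(f"unknown clinical label {self.label!r}")


@dataclass
class ConcordanceReport:
    confusion: pd.DataFrame  # label x call counts
    sensitivity: float | None
    specificity: float | None
    n_pathogenic_scored: int
    n_benign_scored: int
    vus_call_counts: dict[str, int] = field(default_factory=dict)
    oddspath_ps3: float | None = None
    oddspath_bs3: float | None = None
    ps3_strength: str | None = None
    bs3_strength: str | None = None


def singleton_classify(rescue_fraction: float) -> SingletonResult:
    """Classify a singleton-assay rescue fraction.

    < 0.4 is nonfunctional, [0.4, 0.7) intermediate, >= 0.7 functionally
    normal.  A rescue of exactly 0 is nonfunctional with an undefined
    (NaN) log2; negative input is a data error.
    """
    if rescue_fraction < 0:
        raise ValueError(f"rescue fraction must be >= 0, got {rescue_fraction}")
    log2 = float("nan") if rescue_fraction == 0 else round(math.log2(rescue_fraction), 2)
    if rescue_fraction < SINGLETON_NONFUNCTIONAL_CUTOFF:
        call = NONFUNCTIONAL
    elif rescue_fraction < SINGLETON_NORMAL_CUTOFF:
        call = INTERMEDIATE_FUNCTION
    else:
        call = FUNCTIONALLY_NORMAL
    return SingletonResult("", rescue_fraction, log2, call)


def _is_discordant(multiplexed_call: str, singleton_call: str) -> bool:
    """Hard discordance: LOF on one platform, functionally normal on the other."""
    return (
        multiplexed_call == LOSS_OF_FUNCTION and singleton_call == FUNCTIONALLY_NORMAL
    ) or (
        multiplexed_call == FUNCTIONALLY_NORMAL and singleton_call == NONFUNCTIONAL
    )


@dataclass
class ThresholdReport:
    threshold: int
    n_discordant_before: int
    n_discordant_eliminated: int
    removed_variants: list[str]
    retained_variants: list[str]


def tune_read_threshold(
    records: Mapping[str, ScoreRecord],
    multiplexed_calls: Mapping[str, str],
    singleton_calls: Mapping[str, str],
    target_eliminated: int,
) -> ThresholdReport:
    """Raise the input read-count threshold until discordance drops.

    Discordant variants are those called loss-of-function by one platform
    and functionally normal by the other.  Candidate thresholds are the
    observed min_input_count values; the smallest candidate whose
    application (keep variants with min_input_count >= threshold) removes
    at least ``target_eliminated`` discordant variants is returned.  If no
    candidate achieves the target, the error reports the maximum
    achievable elimination.
    """
    overlap = sorted(set(multiplexed_calls) & set(singleton_calls) & set(records))
    if not overlap:
        raise ValueError("no variants shared between multiplexed and singleton sets")
    discordant = {
        v for v in overlap if _is_discordant(multiplexed_calls[v], singleton_calls[v])
    }
    if target_eliminated > len(discordant):
        raise ValueError(
            f"target {target_eliminated} exceeds the {len(discordant)} discordant "
            "variants present"
        )

    candidates = sorted({records[v].min_input_count for v in records})
    best = None
    max_achievable = 0
    for t in candidates:
        removed = {v for v in discordant if records[v].min_input_count < t}
        max_achievable = max(max_achievable, len(removed))
        if len(removed) >= target_eliminated:
            best = (t, removed)
            break
    if best is None:
        raise ValueError(
            f"no candidate threshold eliminates {target_eliminated} discordant "
            f"variants (max achievable: {max_achievable})"
        )
    threshold, removed = best
    return ThresholdReport(
        threshold=int(threshold),
        n_discordant_before=len(discordant),
        n_discordant_eliminated=len(removed),
        removed_variants=sorted(removed),
        retained_variants=sorted(set(records) - {
            v for v in records if records[v].min_input_count < threshold
        }),
    )


def sensitivity_specificity(
    calls: Iterable[FunctionalCall], labels: Iterable[ClinicalLabel]
) -> ConcordanceReport:
    """Confusion of functional calls against clinical truth labels.

    Sensitivity: pathogenic/likely-pathogenic controls called loss of
    function, over pathogenic controls scored.  Specificity:
    benign/likely-benign controls called functionally normal, over benign
    controls scored.  Intermediate calls count as failures for both
    metrics; unscored variants leave the denominators; an empty control
    set yields None (undefined), never 0.  Records are deduplicated by
    variant label so duplicated rows cannot move the metrics.
    """
    call_by = {}
    for c in calls:
        call_by[c.variant_label] = c.call
    label_by = {}
    for l in labels:
        label_by[l.variant_label] = l.label

    call_order = [LOSS_OF_FUNCTION, INTERMEDIATE_FUNCTION, FUNCTIONALLY_NORMAL, UNSCORED]
    label_order = [BENIGN, PATHOGENIC, VUS, CONFLICTING]
    confusion = pd.DataFrame(0, index=label_order, columns=call_order, dtype=int)
    for v, lab in label_by.items():
        if v in call_by:
            confusion.loc[lab, call_by[v]] += 1

    def _metric(label: str, success_call: str) -> tuple[float | None, int]:
        scored = int(confusion.loc[label].sum() - confusion.loc[label, UNSCORED])
        if scored == 0:
            return None, 0
        return float(confusion.loc[label, success_call] / scored), scored

    sens, n_path = _metric(PATHOGENIC, LOSS_OF_FUNCTION)
    spec, n_ben = _metric(BENIGN, FUNCTIONALLY_NORMAL)
    vus_counts = {
        c: int(confusion.loc[VUS, c] + confusion.loc[CONFLICTING, c])
        for c in call_order
    }
    return ConcordanceReport(
        confusion=confusion,
        sensitivity=sens,
        specificity=spec,
        n_pathogenic_scored=n_path,
        n_benign_scored=n_ben,
        vus_call_counts=vus_counts,
    )


def _band_ps3(odds: float) -> str:
    for name, thr in PS3_BANDS:
        if odds >= thr:
            return name
    return "none"


def _band_bs3(odds: float) -> str:
    for name, thr in BS3_BANDS:
        if odds <= thr:
            return name
    return "none"


def oddspath(
    n_pathogenic_controls: int,
    n_benign_controls: int,
    n_pathogenic_abnormal: int,
    n_benign_abnormal: int,
    n_pathogenic_normal: int,
    n_benign_normal: int,
    ps3_bands: Sequence[tuple[str, float]] = PS3_BANDS,
    bs3_bands: Sequence[tuple[str, float]] = BS3_BANDS,
) -> tuple[float, float, str, str]:
    """Odds of pathogenicity for abnormal (PS3) and normal (BS3) readouts.

    With prior P1 = pathogenic controls / all controls and posterior P2 =
    proportion pathogenic among controls with the given readout,

        OddsPath = P2 (1 - P1) / ((1 - P2) P1).

    When concordance is perfect a confusion cell is empty and the odds
    would be unbounded; one hypothetical discordant control is then added
    to that readout set (a benign control to the abnormal set for PS3, a
    pathogenic control to the normal set for BS3), which is what keeps a
    perfectly concordant 11-pathogenic / 5-benign panel at moderate
    evidence (odds 5.0 and 1/11) rather than infinite.

    Returns (oddspath_ps3, oddspath_bs3, ps3_strength, bs3_strength).
    Controls with intermediate readouts are excluded upstream and do not
    enter these counts.
    """
    if n_pathogenic_controls + n_benign_controls == 0:
        raise ValueError("no controls supplied")
    if n_benign_controls == 0 or n_pathogenic_controls == 0:
        raise ValueError("need at least one control of each class")
    if n_pathogenic_abnormal + n_pathogenic_normal > n_pathogenic_controls:
        raise ValueError("pathogenic readout counts exceed pathogenic controls")
    if n_benign_abnormal + n_benign_normal > n_benign_controls:
        raise ValueError("benign readout counts exceed benign controls")

    p1 = n_pathogenic_controls / (n_pathogenic_controls + n_benign_controls)

    # PS3: pathogenic proportion among abnormal readouts
    pa, ba = n_pathogenic_abnormal, n_benign_abnormal
    if ba == 0:
        ba = 1  # hypothetical discordant benign control
    p2_ps3 = pa / (pa + ba)
    odds_ps3 = (p2_ps3 * (1 - p1)) / ((1 - p2_ps3) * p1)

    # BS3: pathogenic proportion among normal readouts
    pn, bn = n_pathogenic_normal, n_benign_normal
    if pn == 0:
        pn = 1  # hypothetical discordant pathogenic control
    p2_bs3 = pn / (pn + bn)
    if p2_bs3 == 1.0:
        raise ValueError("no benign controls with a normal readout: BS3 undefined")
    odds_bs3 = (p2_bs3 * (1 - p1)) / ((1 - p2_bs3) * p1)

    def band(odds: float, bands, cmp) -> str:
        for name, thr in bands:
            if cmp(odds, thr):
                return name
        return "none"

    ps3_strength = band(odds_ps3, ps3_bands, lambda o, t: o >= t)
    bs3_strength = band(odds_bs3, bs3_bands, lambda o, t: o <= t)
    return float(odds_ps3), float(odds_bs3), ps3_strength, bs3_strength


def read_clinical_labels(path) -> list[ClinicalLabel]:
    """Read a clinical-label TSV (variant_label, label[, stars, year])."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        status = " ".join(
            s for s in (getattr(row, "stars", ""), getattr(row, "year", "")) if s
        )
        out.append(ClinicalLabel(row.variant_label, row.label, status))
    return out


def read_singleton_results(path) -> list[SingletonResult]:
    """Read a singleton TSV (variant_label, replicate rescue columns or mean_rescue)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    rep_cols = [c for c in df.columns if c.startswith("rescue_rep")]
    out = []
    for row in df.itertuples(index=False):
        if rep_cols:
            rescue = float(np.mean([getattr(row, c) for c in rep_cols]))
        else:
            rescue = float(row.mean_rescue)
        res = singleton_classify(rescue)
        out.append(
            SingletonResult(row.variant_label, rescue, res.log2_rescue, res.call)
        )
    return out
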