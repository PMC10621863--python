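"""Score filtering, data-driven cutoffs and three-class functional calls.

Two cutoffs split the score axis into loss-of-function, intermediate and
functionally-normal classes:

* normal cutoff: the missense scores from the control-siRNA condition
  (endogenous BRCA1 present, so every variant behaves wild-type-like) are
  modelled as a normal distribution and the bottom first percentile,
  mean + sd * Phi^-1(0.01), separates functionally normal from
  intermediate.
* LOF cutoff: the hundredths place just above the highest-scoring
  nonsense variant in the knockdown condition, so by construction every
  nonsense variant classifies as loss of function.

Cutoffs are derived once on the pooled dataset (all sublibraries
combined).  Before cutoffs are applied, variants with replicate variance
strictly greater than the threshold (default 1) or with too few input
reads are removed and reported as unscored with their filter reasons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counts_io import _write_tsv
from .scoring import ScoreRecord
from .variants import annotate_variant, parse_label

__all__ = [
    "LOSS_OF_FUNCTION",
    "INTERMEDIATE_FUNCTION",
    "FUNCTIONALLY_NORMAL",
    "UNSCORED",
    "Cutoffs",
    "FunctionalCall",
    "apply_filters",
    "derive_normal_cutoff",
    "derive_lof_cutoff",
    "classify",
    "classify_records",
    "calls_to_frame",
    "write_calls",
]

LOSS_OF_FUNCTION = "loss_of_function"
INTERMEDIATE_FUNCTION = "intermediate"
FUNCTIONALLY_NORMAL = "functionally_normal"
UNSCORED = "unscored"

LOW_READ_COUNT = "low_read_count"
HIGH_VARIANCE = "high_variance"
TOO_FEW_REPLICATES = "too_few_replicates"

DEFAULT_MAX_VARIANCE = 1.0
DEFAULT_NORMAL_PERCENTILE = 0.01


class CutoffError(ValueError):
    """Degenerate input to cutoff derivation."""


@dataclass(frozen=True)
class Cutoffs:
    """The two class boundaries and a record of how they were derived."""

    normal_cutoff: float
    lof_cutoff: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lof_cutoff < self.normal_cutoff:
            raise CutoffError(
                f"lof_cutoff {self.lof_cutoff} must be < normal_cutoff "
                f"{self.normal_cutoff}"
            )


@dataclass(frozen=True)
class FunctionalCall:
    variant_label: str
    call: str
    filter_reasons: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if (self.call == UNSCORED) != bool(self.filter_reasons):
            raise ValueError("call is unscored iff filter_reasons nonempty")


def apply_filters(
    records: Iterable[ScoreRecord],
    min_input_count: int,
    max_variance: float = DEFAULT_MAX_VARIANCE,
) -> tuple[list[ScoreRecord], list[FunctionalCall]]:
    """Split records into those that pass QC and unscored stubs.

    A variant is removed when its replicate variance is strictly greater
    than ``max_variance`` (a variance of exactly the threshold is kept),
    when its minimum input-bin read count across replicates is below
    ``min_input_count``, or when fewer than two replicate scores exist.
    Filtering is idempotent: re-applying it to the survivors removes
    nothing.
    """
    if min_input_count < 0 or max_variance < 0:
        raise ValueError("filter thresholds must be nonnegative")
    passed: list[ScoreRecord] = []
    removed: list[FunctionalCall] = []
    for rec in records:
        reasons = set()
        if not rec.scored:
            reasons.add(TOO_FEW_REPLICATES)
        elif rec.replicate_variance is not None and rec.replicate_variance > max_variance:
            reasons.add(HIGH_VARIANCE)
        if rec.min_input_count < min_input_count:
            reasons.add(LOW_READ_COUNT)
        if reasons:
            removed.append(
                FunctionalCall(rec.variant_label, UNSCORED, frozenset(reasons))
            )
        else:
            passed.append(rec)
    return passed, removed


def derive_normal_cutoff(
    missense_control_scores: Sequence[float],
    percentile: float = DEFAULT_NORMAL_PERCENTILE,
) -> tuple[float, dict]:
    """Normal/intermediate boundary from a Gaussian fit of control scores.

    Fits mean and unbiased sd to the missense scores observed with
    endogenous BRCA1 intact and returns the ``percentile`` quantile of
    that fitted normal (bottom first percentile by default).  Returns
    (cutoff, provenance).
    """
    scores = np.asarray(missense_control_scores, dtype=float)
    scores = scores[~np.isnan(scores)]
    if scores.size < 2:
        raise CutoffError("need >= 2 missense control scores")
    if not 0 < percentile < 1:
        raise CutoffError("percentile must be in (0, 1)")
    mean = float(scores.mean())
    sd = float(scores.std(ddof=1))
    if sd == 0 or np.ptp(scores) == 0:
        raise CutoffError("zero variance in missense control scores: degenerate fit")
    cutoff = mean + sd * float(stats.norm.ppf(percentile))
    provenance = {
        "n_missense_control_scores": int(scores.size),
        "fit_mean": mean,
        "fit_sd": sd,
        "percentile": percentile,
    }
    if scores.size < 30:
        provenance["warning"] = "fewer than 30 scores; normal fit may be unstable"
    return cutoff, provenance


def derive_lof_cutoff(
    nonsense_experimental_scores: Sequence[float],
) -> tuple[float, dict]:
    """LOF/intermediate boundary anchored on the worst-behaving nonsense score.

    Returns the smallest multiple of 0.01 strictly greater than the
    highest nonsense score in the knockdown condition (so a maximum of
    -0.607 gives -0.60, and a maximum landing exactly on -0.60 gives
    -0.59).  Every nonsense variant in the same dataset then classifies as
    loss of function.
    """
    scores = np.asarray(nonsense_experimental_scores, dtype=float)
    scores = scores[~np.isnan(scores)]
    if scores.size == 0:
        raise CutoffError("no nonsense scores to anchor the LOF cutoff")
    top = float(scores.max())
    # hundredths ceiling, strict: round first to dodge float representation
    # artefacts (-0.60 * 100 is not exactly -60 in binary)
    cutoff = (math.floor(round(top * 100, 6)) + 1) / 100
    provenance = {"n_nonsense_scores": int(scores.size), "max_nonsense_score": top}
    return cutoff, provenance


def classify(score: float, cutoffs: Cutoffs) -> str:
    """Three-class call for a combined score.

    score < lof_cutoff -> loss_of_function; lof_cutoff <= score <
    normal_cutoff -> intermediate; score >= normal_cutoff ->
    functionally_normal.  Ties land in the more-functional class: the
    cutoffs are open lower bounds of the class above them.
    """
    if np.isnan(score):
        raise ValueError("cannot classify a NaN score")
    if score < cutoffs.lof_cutoff:
        return LOSS_OF_FUNCTION
    if score < cutoffs.normal_cutoff:
        return INTERMEDIATE_FUNCTION
    return FUNCTIONALLY_NORMAL


def classify_records(
    records: Iterable[ScoreRecord], cutoffs: Cutoffs
) -> list[FunctionalCall]:
    return [
        FunctionalCall(r.variant_label, classify(r.combined_score, cutoffs))
        for r in records
    ]


def calls_to_frame(
    calls: Iterable[FunctionalCall],
    records: Iterable[ScoreRecord] = (),
    wt_sequence: str | None = None,
    wt_offset: int = 1,
) -> pd.DataFrame:
    """Tabulate calls with scores, filter reasons and region annotations."""
    by_label = {r.variant_label: r for r in records}
    rows = []
    for c in sorted(calls, key=lambda c: c.variant_label):
        rec = by_label.get(c.variant_label)
        row: dict = {"variant_label": c.variant_label}
        try:
            v = parse_label(c.variant_label)
        except ValueError:
            v = None
        row["position"] = v.position if v else np.nan
        row["ref_aa"] = v.ref_aa if v else ""
        row["alt_aa"] = v.alt_aa if v else ""
        row["variant_class"] = (
            v.variant_class if v else (rec.variant_class if rec else "")
        )
        row["combined_score"] = (
            rec.combined_score if rec and rec.combined_score is not None else np.nan
        )
        row["replicate_variance"] = (
            rec.replicate_variance
            if rec and rec.replicate_variance is not None
            else np.nan
        )
        row["min_input_count"] = rec.min_input_count if rec else np.nan
        row["call"] = c.call
        row["filter_reasons"] = ";".join(sorted(c.filter_reasons))
        if v is not None and wt_sequence:
            ann = annotate_variant(v, wt_sequence, wt_offset)
            row["in_palb2_region"] = ann.in_palb2_region
            row["phospho_candidate"] = ann.phospho_candidate
            row["sublibrary"] = ann.sublibrary or ""
        rows.append(row)
    return pd.DataFrame(rows)


def write_calls(
    df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    _write_tsv(df, path, meta)
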