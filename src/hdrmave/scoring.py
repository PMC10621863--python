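"""Per-variant functional scores from GFP-positive vs input frequencies.

A variant's replicate score is the log2 ratio of its pseudocounted
frequency in the GFP-positive bin to its frequency in the input bin,
centred by the median of the same quantity over the synonymous
(wild-type-like) cohort:

    score(v) = log2(f_pos(v) / f_in(v)) - median_s[ log2(f_pos(s) / f_in(s)) ]

with f_bin(x) = (count_x + pc) / sum_variants(count + pc) and pseudocount
pc = 0.5 by default.  Replicates are combined by arithmetic mean; the
unbiased sample variance across replicates feeds the downstream variance
filter.  The GFP-negative bin is carried through the tables but takes no
part in scoring.

The synonymous *median* (not mean) makes the centring robust to the
occasional outlier synonymous variant; by construction the synonymous
cohort's median score is exactly zero in every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .counts_io import _write_tsv
from .variants import SYNONYMOUS

__all__ = [
    "ScoreRecord",
    "replicate_score",
    "replicate_scores",
    "combine_replicates",
    "score_condition",
    "write_scores",
    "read_scores",
]

DEFAULT_PSEUDOCOUNT = 0.5


class ScoringError(ValueError):
    """Raised when the scoring preconditions fail (e.g. no synonymous cohort)."""


@dataclass(frozen=True)
class ScoreRecord:
    """Per-variant scores for one condition across replicates."""

    variant_label: str
    variant_class: str
    condition: str
    replicate_scores: tuple[float, ...]
    combined_score: float | None  # None when < 2 replicate scores exist
    replicate_variance: float | None
    min_input_count: int

    @property
    def scored(self) -> bool:
        return self.combined_score is not None


def _slice(
    vcounts: pd.DataFrame, replicate: int, condition: str, bin_name: str
) -> pd.Series:
    sel = (
        (vcounts["replicate"] == replicate)
        & (vcounts["condition"] == condition)
        & (vcounts["bin"] == bin_name)
    )
    s = vcounts.loc[sel].set_index("variant_label")["count"]
    if s.index.has_duplicates:
        raise ScoringError("duplicate variant rows in count slice")
    return s


def replicate_scores(
    vcounts: pd.DataFrame,
    replicate: int,
    condition: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Centred log2 enrichment for every variant in one replicate/condition.

    Requires variant-level counts (columns variant_label, variant_class,
    replicate, condition, bin, count) and a nonempty synonymous cohort for
    the centring term.
    """
    if pseudocount <= 0:
        raise ScoringError("pseudocount must be positive")
    pos = _slice(vcounts, replicate, condition, "gfp_pos")
    inp = _slice(vcounts, replicate, condition, "input")
    pos, inp = pos.align(inp, fill_value=0)

    f_pos = (pos + pseudocount) / (pos + pseudocount).sum()
    f_in = (inp + pseudocount) / (inp + pseudocount).sum()
    raw = np.log2(f_pos / f_in)

    classes = (
        vcounts.drop_duplicates("variant_label")
        .set_index("variant_label")["variant_class"]
        .reindex(raw.index)
    )
    syn = raw[classes == SYNONYMOUS]
    if syn.empty:
        raise ScoringError(
            f"no synonymous variants to centre on (replicate {replicate}, {condition})"
        )
    return raw - float(syn.median())


def replicate_score(
    vcounts: pd.DataFrame,
    variant_label: str,
    replicate: int,
    condition: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Score of a single variant in one replicate/condition."""
    scores = replicate_scores(vcounts, replicate, condition, pseudocount)
    if variant_label not in scores.index:
        raise KeyError(variant_label)
    return float(scores.loc[variant_label])


def combine_replicates(scores: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and unbiased sample variance of replicate scores.

    Raises ScoringError with fewer than two replicates (such variants are
    emitted as unscored upstream).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size < 2:
        raise ScoringError("need >= 2 replicate scores to combine")
    return float(arr.mean()), float(arr.var(ddof=1))


def score_condition(
    vcounts: pd.DataFrame,
    condition: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    replicates: Iterable[int] | None = None,
) -> list[ScoreRecord]:
    """Score every variant in a condition across all replicates."""
    if replicates is None:
        replicates = sorted(
            vcounts.loc[vcounts["condition"] == condition, "replicate"].unique()
        )
    replicates = list(replicates)
    per_rep = {
        r: replicate_scores(vcounts, r, condition, pseudocount) for r in replicates
    }
    classes = (
        vcounts.drop_duplicates("variant_label")
        .set_index("variant_label")["variant_class"]
        .to_dict()
    )
    input_counts = {
        r: _slice(vcounts, r, condition, "input") for r in replicates
    }

    records = []
    labels = sorted(per_rep[replicates[0]].index) if replicates else []
    for label in labels:
        reps = tuple(float(per_rep[r].loc[label]) for r in replicates)
        min_in = int(min(input_counts[r].get(label, 0) for r in replicates))
        if len(reps) >= 2:
            combined, var = combine_replicates(reps)
        else:
            combined, var = None, None
        records.append(
            ScoreRecord(
                variant_label=label,
                variant_class=classes.get(label, "unknown"),
                condition=condition,
                replicate_scores=reps,
                combined_score=combined,
                replicate_variance=var,
                min_input_count=min_in,
            )
        )
    return records


def records_to_frame(records: Iterable[ScoreRecord]) -> pd.DataFrame:
    records = list(records)
    n_rep = max((len(r.replicate_scores) for r in records), default=0)
    rows = []
    for r in records:
        row = {
            "variant_label": r.variant_label,
            "variant_class": r.variant_class,
            "condition": r.condition,
        }
        for i in range(n_rep):
            row[f"score_rep{i + 1}"] = (
                r.replicate_scores[i] if i < len(r.replicate_scores) else np.nan
            )
        row["combined_score"] = np.nan if r.combined_score is None else r.combined_score
        row["replicate_variance"] = (
            np.nan if r.replicate_variance is None else r.replicate_variance
        )
        row["min_input_count"] = r.min_input_count
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(df: pd.DataFrame) -> list[ScoreRecord]:
    rep_cols = sorted(
        (c for c in df.columns if c.startswith("score_rep")),
        key=lambda c: int(c.removeprefix("score_rep")),
    )
    out = []
    for row in df.itertuples(index=False):
        reps = tuple(
            float(getattr(row, c)) for c in rep_cols if pd.notna(getattr(row, c))
        )
        combined = row.combined_score
        var = row.replicate_variance
        out.append(
            ScoreRecord(
                variant_label=row.variant_label,
                variant_class=row.variant_class,
                condition=row.condition,
                replicate_scores=reps,
                combined_score=None if pd.isna(combined) else float(combined),
                replicate_variance=None if pd.isna(var) else float(var),
                min_input_count=int(row.min_input_count),
            )
        )
    return out


def write_scores(
    records: Iterable[ScoreRecord], path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    _write_tsv(records_to_frame(records), path, meta)


def read_scores(path: str | Path) -> list[ScoreRecord]:
    return frame_to_records(pd.read_csv(path, sep="\t", comment="#"))
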