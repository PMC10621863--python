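"""End-to-end orchestration: counts -> scores -> cutoffs -> calls -> reports.

Stages are pure functions over their written inputs, so re-running a stage
from its artifacts reproduces its outputs byte for byte; all writers emit
deterministic, provenance-headed TSV/JSON (no timestamps).

A QC gate mirrors the wet-lab pre-sort check: when sorted-cell tallies are
available, the library's GFP-positive fraction under endogenous-BRCA1
knockdown must be lower than under control siRNA (a library containing
loss-of-function variants converts fewer cells); otherwise the run aborts.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import classification as cls
from . import concordance as conc
from . import counts_io, scoring, simulate
from .variants import AA1, STOP, parse_label

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "QCError",
    "run_pipeline",
    "export_sequence_function_map",
    "export_histograms",
    "labels_from_truth",
]


class PipelineError(ValueError):
    pass


class QCError(RuntimeError):
    """The pre-sort GFP QC gate failed."""


@dataclass
class PipelineConfig:
    """All tunable parameters of a run.

    When ``barcode_map``/``counts`` are unset the synthetic generator
    supplies them (using ``sim`` and ``seed``); file inputs always win
    over simulation.
    """

    outdir: str = "hdrmave_out"
    seed: int = 0

    # input files (optional; simulated when absent)
    barcode_map: str | None = None
    counts: str | None = None
    truth: str | None = None
    clinical_labels: str | None = None
    singleton: str | None = None
    cell_tallies: str | None = None

    # analysis parameters
    pseudocount: float = scoring.DEFAULT_PSEUDOCOUNT
    min_input_count: int = 10
    max_variance: float = cls.DEFAULT_MAX_VARIANCE
    normal_percentile: float = cls.DEFAULT_NORMAL_PERCENTILE
    experimental_condition: str = "siBRCA1_3UTR"
    control_condition: str = "control"

    sim: simulate.SimConfig = field(default_factory=simulate.SimConfig)

    @classmethod
    def from_yaml(cls_, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls_(**raw)
        if sim_raw:
            cfg.sim = simulate.SimConfig(**{**sim_raw, "seed": raw.get("seed", cfg.seed)})
        return cfg

    def validate(self) -> None:
        for name in ("barcode_map", "counts", "truth", "clinical_labels", "singleton", "cell_tallies"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError(f"configured {name} path does not exist: {p}")
        if self.pseudocount <= 0:
            raise PipelineError("pseudocount must be positive")
        if self.min_input_count < 0 or self.max_variance < 0:
            raise PipelineError("filter thresholds must be nonnegative")
        if not 0 < self.normal_percentile < 1:
            raise PipelineError("normal_percentile must be in (0, 1)")
        self.sim.validate()


def labels_from_truth(truth: simulate.SimTruth) -> list[conc.ClinicalLabel]:
    """Clinical-style labels from simulation ground truth.

    True-LOF variants play pathogenic/likely-pathogenic controls,
    true-functional variants benign/likely-benign, intermediates VUS.
    """
    mapping = {
        simulate.LOF: conc.PATHOGENIC,
        simulate.FUNCTIONAL: conc.BENIGN,
        simulate.INTERMEDIATE: conc.VUS,
    }
    return [
        conc.ClinicalLabel(label, mapping[tc], "synthetic truth")
        for label, tc in truth.true_class.items()
    ]


def qc_gate(cell_tallies: pd.DataFrame, experimental: str, control: str) -> dict:
    """Abort unless GFP+ fraction is lower under knockdown than control."""
    frac = (
        cell_tallies.assign(frac=lambda d: d["cells_gfp_pos"] / d["cells_total"])
        .groupby("condition")["frac"]
        .mean()
    )
    if experimental not in frac.index or control not in frac.index:
        raise QCError("cell tallies missing a required condition")
    if not frac[experimental] < frac[control]:
        raise QCError(
            f"GFP-positive fraction under {experimental} ({frac[experimental]:.4f}) "
            f"is not below {control} ({frac[control]:.4f}); library may lack "
            "loss-of-function variants or knockdown failed"
        )
    return {c: float(frac[c]) for c in frac.index}


def export_sequence_function_map(
    calls: Mapping[str, str], codon_range: tuple[int, int], wt_sequence: str
) -> pd.DataFrame:
    """Position x substitution matrix of functional calls.

    Rows are the 20 amino acids plus stop; columns are residue positions.
    Cell states: lof / intermediate / normal / wt / missing.  Exactly one
    wt cell per position (the wild-type residue); synonymous calls
    coincide with it and do not occupy extra cells.
    """
    lo, hi = codon_range
    if len(wt_sequence) != hi - lo + 1:
        raise PipelineError("wt_sequence length does not match codon range")
    rows = list(AA1) + [STOP]
    mat = pd.DataFrame(
        "missing", index=rows, columns=range(lo, hi + 1), dtype=object
    )
    state = {
        cls.LOSS_OF_FUNCTION: "lof",
        cls.INTERMEDIATE_FUNCTION: "intermediate",
        cls.FUNCTIONALLY_NORMAL: "normal",
    }
    for label, call in calls.items():
        v = parse_label(label)
        if not lo <= v.position <= hi or v.variant_class == "synonymous":
            continue
        if call in state:
            mat.loc[v.alt_aa, v.position] = state[call]
    for pos in range(lo, hi + 1):
        mat.loc[wt_sequence[pos - lo], pos] = "wt"
    return mat


def export_histograms(
    records: Iterable[scoring.ScoreRecord],
    labels: Iterable[conc.ClinicalLabel] = (),
    bin_width: float = 0.25,
) -> pd.DataFrame:
    """Fixed-width binned score counts per cohort (plot-ready, not an image).

    Cohorts are the variant classes (missense/nonsense/synonymous) per
    condition, plus one cohort per clinical label when labels are given.
    Bin edges are global multiples of ``bin_width`` and are recorded in
    the table, so cohort totals equal the sum of their bin counts.
    """
    records = [r for r in records if r.combined_score is not None]
    if not records:
        return pd.DataFrame(
            columns=["cohort", "condition", "bin_left", "bin_right", "count"]
        )
    scores = np.array([r.combined_score for r in records])
    lo = np.floor(scores.min() / bin_width) * bin_width
    hi = np.ceil(scores.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)

    label_by = {l.variant_label: l.label for l in labels}
    rows = []

    def add(cohort: str, condition: str, values: np.ndarray) -> None:
        counts, _ = np.histogram(values, bins=edges)
        for left, right, c in zip(edges[:-1], edges[1:], counts):
            rows.append(
                {
                    "cohort": cohort,
                    "condition": condition,
                    "bin_left": round(float(left), 6),
                    "bin_right": round(float(right), 6),
                    "count": int(c),
                }
            )

    df = pd.DataFrame(
        {
            "variant_label": [r.variant_label for r in records],
            "variant_class": [r.variant_class for r in records],
            "condition": [r.condition for r in records],
            "score": scores,
        }
    )
    for (vclass, condition), grp in df.groupby(["variant_class", "condition"], sort=True):
        add(vclass, condition, grp["score"].to_numpy())
    if label_by:
        df["clinical"] = df["variant_label"].map(label_by)
        for (lab, condition), grp in df.dropna(subset=["clinical"]).groupby(
            ["clinical", "condition"], sort=True
        ):
            add(lab, condition, grp["score"].to_numpy())
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    outdir: Path
    bmap: counts_io.BarcodeMap
    truth: simulate.SimTruth | None
    cutoffs: cls.Cutoffs
    records: dict[str, list[scoring.ScoreRecord]]  # condition -> records (filtered, experimental)
    calls: list[cls.FunctionalCall]
    control_calls: list[cls.FunctionalCall]
    report: conc.ConcordanceReport | None
    qc: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write all artifacts under config.outdir."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed}

    # --- inputs: load or simulate -------------------------------------
    truth: simulate.SimTruth | None = None
    tallies: pd.DataFrame | None = None
    if config.barcode_map is not None:
        bmap = counts_io.parse_barcode_map(config.barcode_map)
        if config.counts is None:
            raise PipelineError("a barcode map was given without counts")
        counts = counts_io.read_count_matrix(config.counts)
        meta["barcode_map_sha256"] = counts_io.file_sha256(config.barcode_map)
        meta["counts_sha256"] = counts_io.file_sha256(config.counts)
        if config.truth is not None:
            truth = simulate.read_truth(config.truth)
        if config.cell_tallies is not None:
            tallies = pd.read_csv(config.cell_tallies, sep="\t", comment="#")
    else:
        sim_cfg = (
            config.sim
            if config.sim.seed == config.seed
            else simulate.SimConfig(**{**asdict(config.sim), "seed": config.seed})
        )
        bmap, truth = simulate.generate_library(sim_cfg)
        sim_result = simulate.simulate_sort_counts(bmap, truth, sim_cfg)
        counts, tallies = sim_result.counts, sim_result.cell_tallies
        counts_io.write_barcode_map(bmap, outdir / "barcode_map.tsv", meta)
        counts_io.write_count_matrix(counts, outdir / "counts.tsv", meta)
        simulate.write_truth(truth, outdir / "truth.tsv", meta)
        counts_io._write_tsv(tallies, outdir / "cell_tallies.tsv", meta)

    # --- QC gate -------------------------------------------------------
    qc: dict = {}
    if tallies is not None:
        qc = qc_gate(tallies, config.experimental_condition, config.control_condition)

    # --- collapse and score ---------------------------------------------
    vcounts, drop_tally = counts_io.collapse_to_variants(counts, bmap)
    counts_io.write_count_matrix(
        vcounts, outdir / "variant_counts.tsv", {**meta, **drop_tally}
    )

    records: dict[str, list[scoring.ScoreRecord]] = {}
    for condition in (config.control_condition, config.experimental_condition):
        recs = scoring.score_condition(vcounts, condition, config.pseudocount)
        scoring.write_scores(recs, outdir / f"scores_{condition}.tsv", meta)
        records[condition] = recs

    # --- filters ---------------------------------------------------------
    passed_ctrl, _ = cls.apply_filters(
        records[config.control_condition], config.min_input_count, config.max_variance
    )
    passed_exp, removed_exp = cls.apply_filters(
        records[config.experimental_condition],
        config.min_input_count,
        config.max_variance,
    )

    # --- cutoffs (pooled dataset) ----------------------------------------
    missense_ctrl = [
        r.combined_score for r in passed_ctrl if r.variant_class == "missense"
    ]
    nonsense_exp = [
        r.combined_score for r in passed_exp if r.variant_class == "nonsense"
    ]
    normal_cutoff, prov_n = cls.derive_normal_cutoff(
        missense_ctrl, config.normal_percentile
    )
    lof_cutoff, prov_l = cls.derive_lof_cutoff(nonsense_exp)
    cutoffs = cls.Cutoffs(
        normal_cutoff=normal_cutoff,
        lof_cutoff=lof_cutoff,
        provenance={**prov_n, **prov_l, "seed": config.seed},
    )
    with open(outdir / "cutoffs.json", "w") as fh:
        json.dump(
            {
                "normal_cutoff": cutoffs.normal_cutoff,
                "lof_cutoff": cutoffs.lof_cutoff,
                "provenance": cutoffs.provenance,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")

    # --- classification ---------------------------------------------------
    calls = cls.classify_records(passed_exp, cutoffs) + removed_exp
    control_calls = cls.classify_records(passed_ctrl, cutoffs)
    wt = truth.wt_sequence if truth is not None else None
    calls_df = cls.calls_to_frame(
        calls,
        records[config.experimental_condition],
        wt_sequence=wt,
        wt_offset=bmap.window[0] if wt else 1,
    )
    cls.write_calls(calls_df, outdir / "calls.tsv", meta)

    # --- concordance -------------------------------------------------------
    labels: list[conc.ClinicalLabel] = []
    if config.clinical_labels is not None:
        labels = conc.read_clinical_labels(config.clinical_labels)
    elif truth is not None:
        labels = labels_from_truth(truth)
    report = None
    if labels:
        report = conc.sensitivity_specificity(calls, labels)
        n_path = int(report.confusion.loc[conc.PATHOGENIC].sum())
        n_ben = int(report.confusion.loc[conc.BENIGN].sum())
        n_unscored_p = int(report.confusion.loc[conc.PATHOGENIC, cls.UNSCORED])
        n_unscored_b = int(report.confusion.loc[conc.BENIGN, cls.UNSCORED])
        cm = report.confusion
        try:
            odds = conc.oddspath(
                n_pathogenic_controls=n_path - n_unscored_p,
                n_benign_controls=n_ben - n_unscored_b,
                n_pathogenic_abnormal=int(cm.loc[conc.PATHOGENIC, cls.LOSS_OF_FUNCTION]),
                n_benign_abnormal=int(cm.loc[conc.BENIGN, cls.LOSS_OF_FUNCTION]),
                n_pathogenic_normal=int(cm.loc[conc.PATHOGENIC, cls.FUNCTIONALLY_NORMAL]),
                n_benign_normal=int(cm.loc[conc.BENIGN, cls.FUNCTIONALLY_NORMAL]),
            )
            report.oddspath_ps3, report.oddspath_bs3 = odds[0], odds[1]
            report.ps3_strength, report.bs3_strength = odds[2], odds[3]
        except ValueError:
            pass  # too few controls for odds; sens/spec still reported
        _write_concordance(report, outdir)

    # --- figure-data exports ----------------------------------------------
    if wt:
        call_map = {c.variant_label: c.call for c in calls}
        sfm = export_sequence_function_map(call_map, bmap.window, wt)
        sfm.to_csv(outdir / "sequence_function_map.tsv", sep="\t")
    hist = export_histograms(
        [r for rs in records.values() for r in rs], labels
    )
    counts_io._write_tsv(hist, outdir / "histograms.tsv", meta)

    return PipelineResult(
        outdir=outdir,
        bmap=bmap,
        truth=truth,
        cutoffs=cutoffs,
        records={
            config.control_condition: passed_ctrl,
            config.experimental_condition: passed_exp,
        },
        calls=calls,
        control_calls=control_calls,
        report=report,
        qc=qc,
    )


def _write_concordance(report: conc.ConcordanceReport, outdir: Path) -> None:
    payload = {
        "confusion": {
            lab: {call: int(report.confusion.loc[lab, call]) for call in report.confusion.columns}
            for lab in report.confusion.index
        },
        "sensitivity": report.sensitivity,
        "specificity": report.specificity,
        "n_pathogenic_scored": report.n_pathogenic_scored,
        "n_benign_scored": report.n_benign_scored,
        "vus_call_counts": report.vus_call_counts,
        "oddspath_ps3": report.oddspath_ps3,
        "oddspath_bs3": report.oddspath_bs3,
        "ps3_strength": report.ps3_strength,
        "bs3_strength": report.bs3_strength,
    }
    with open(outdir / "concordance.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    lines = [
        "Concordance with clinical labels",
        "--------------------------------",
        f"sensitivity (P/LP called LOF): "
        + ("undefined" if report.sensitivity is None else f"{report.sensitivity:.1%}"),
        f"specificity (B/LB called normal): "
        + ("undefined" if report.specificity is None else f"{report.specificity:.1%}"),
        f"OddsPath PS3: "
        + ("n/a" if report.oddspath_ps3 is None else f"{report.oddspath_ps3:.3f} ({report.ps3_strength})"),
        f"OddsPath BS3: "
        + ("n/a" if report.oddspath_bs3 is None else f"{report.oddspath_bs3:.3f} ({report.bs3_strength})"),
    ]
    (outdir / "concordance.txt").write_text("\n".join(lines) + "\n")
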