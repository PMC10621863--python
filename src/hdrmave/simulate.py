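"""Synthetic sort-seq generator for the multiplexed HDR reporter assay.

Emulates the experiment end to end so every analysis stage is testable
without sequencing data: a mutagenized 297-codon region carrying missense,
nonsense and synonymous variants, several barcodes per variant, an
integration bottleneck, GFP conversion that depends on a variant's HDR
activity only when endogenous BRCA1 is silenced, FACS sorting into
GFP-positive/negative bins, and multinomial read sampling per bin.

Model per cell carrying variant v (rescue r_v in [0, 1], fraction of
wild-type HDR activity):

* ``control`` siRNA: endogenous BRCA1 repairs the break regardless of the
  integrated variant; P(GFP+) = p_gfp_max for every cell.
* ``siBRCA1_3UTR``: only the integrated variant can repair;
  P(GFP+) = p_bg + (p_gfp_max - p_bg) * r_v.
* ``siBRCA1_CDS``: both endogenous and integrated BRCA1 silenced;
  P(GFP+) = p_bg for every cell (assay-noise floor).

Randomness: one global seed; the library draws and the assay draws use
seed-sequence children [seed, 0] and [seed, 1] respectively, so the two
stages are independently reproducible.  Draw order within each stage is
fixed (documented in the function bodies).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .counts_io import BINS, CONDITIONS, BarcodeMap, BarcodeMapEntry, _write_tsv
from .variants import AA1, MUTAGENESIS_RANGE, STOP, ProteinVariant, synthetic_wt_sequence

__all__ = [
    "FUNCTIONAL",
    "INTERMEDIATE",
    "LOF",
    "SimConfig",
    "SimTruth",
    "SimResult",
    "generate_library",
    "simulate_sort_counts",
    "n_possible_variants",
    "write_truth",
    "read_truth",
    "emit_fastq",
]

FUNCTIONAL = "functional"
INTERMEDIATE = "intermediate"
LOF = "lof"

_DNA = np.array(list("ACGT"))


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for the synthetic assay.

    Defaults mirror the experiment's scale: a 297-codon mutagenized region
    (residues 1280-1576), a few hundred variants with ~3 barcodes each, an
    integration bottleneck of a few hundred thousand cells (colony and
    sorted-cell counts were in the 1.3e5-4e5 range), three replicates, and
    about 1e6 reads per sorted bin.
    """

    codon_range: tuple[int, int] = MUTAGENESIS_RANGE
    n_missense_per_codon: int = 1
    n_synonymous: int = 30
    n_nonsense: int = 40
    barcodes_per_variant: float = 3.0
    n_cells_integrated: int = 400_000
    p_gfp_max: float = 0.05
    p_gfp_background: float = 0.02
    sequencing_depth: int = 1_000_000
    n_replicates: int = 3
    seed: int = 0
    # true-class mixture among missense variants
    f_lof: float = 0.12
    f_intermediate: float = 0.08
    barcode_length: int = 16

    def validate(self) -> None:
        lo, hi = self.codon_range
        if hi < lo:
            raise SimConfigError(f"empty codon range {self.codon_range}")
        if not (0 <= self.p_gfp_background < self.p_gfp_max <= 1):
            raise SimConfigError(
                "require 0 <= p_gfp_background < p_gfp_max <= 1, got "
                f"{self.p_gfp_background}, {self.p_gfp_max}"
            )
        for name in (
            "n_synonymous",
            "n_nonsense",
            "n_missense_per_codon",
        ):
            if getattr(self, name) < 0:
                raise SimConfigError(f"{name} must be >= 0")
        for name in (
            "n_cells_integrated",
            "sequencing_depth",
            "n_replicates",
            "barcode_length",
        ):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        if self.barcodes_per_variant < 1:
            raise SimConfigError("barcodes_per_variant must be >= 1")
        if not (0 <= self.f_lof + self.f_intermediate <= 1):
            raise SimConfigError("class fractions must sum to <= 1")
        n_codons = hi - lo + 1
        if self.n_missense_per_codon > 19:
            raise SimConfigError("at most 19 distinct missense changes per codon")
        if self.n_nonsense > n_codons or self.n_synonymous > n_codons:
            raise SimConfigError("nonsense/synonymous counts exceed codon range")


@dataclass
class SimTruth:
    """Ground-truth functional class and rescue fraction per variant label.

    rescue is the variant's HDR activity as a fraction of wild type
    (functional ~1, intermediate 0.3-0.6, LOF ~0); every nonsense variant
    is LOF.  Synonymous variants have rescue exactly 1.
    """

    true_class: dict[str, str]
    rescue: dict[str, float]
    wt_sequence: str = ""

    def __post_init__(self) -> None:
        order = {LOF: 0, INTERMEDIATE: 1, FUNCTIONAL: 2}
        for label, cls in self.true_class.items():
            if cls not in order:
                raise ValueError(f"unknown true class {cls!r} for {label}")
            if label not in self.rescue:
                raise ValueError(f"no rescue value for {label}")


@dataclass
class SimResult:
    """Simulated read counts plus the per-bin sorted-cell tallies."""

    counts: pd.DataFrame  # long format: barcode, replicate, condition, bin, count
    cell_tallies: pd.DataFrame  # replicate, condition, cells_total, cells_gfp_pos


def n_possible_variants(codon_range: tuple[int, int]) -> int:
    """Number of possible single amino-acid variants in a codon range.

    20 substitutions per residue (19 missense + stop), matching the usual
    deep-mutational-scan accounting: a full 297-residue region gives 5940.
    """
    lo, hi = codon_range
    if hi < lo:
        raise SimConfigError(f"empty codon range {codon_range}")
    return (hi - lo + 1) * 20


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal(mean, sd) truncated to [0, 1] by resampling."""
    out = rng.normal(mean, sd, size)
    bad = (out < 0) | (out > 1)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < 0) | (out > 1)
    return out


def _draw_rescue(rng: np.random.Generator, cls: str) -> float:
    if cls == FUNCTIONAL:
        return float(_truncnorm(rng, 1.0, 0.05, 1)[0])
    if cls == INTERMEDIATE:
        return float(rng.uniform(0.3, 0.6))
    return float(_truncnorm(rng, 0.02, 0.02, 1)[0])


def generate_library(config: SimConfig) -> tuple[BarcodeMap, SimTruth]:
    """Draw a variant library, its barcode map and its ground truth.

    Draw order (fixed for reproducibility): wild-type sequence, missense
    alt residues per codon (ascending position), nonsense positions,
    synonymous positions, true classes for missense variants, rescue values
    (library order), barcode multiplicities, barcode sequences.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    lo, hi = config.codon_range
    wt = synthetic_wt_sequence(lo, hi, seed=config.seed)

    variants: list[ProteinVariant] = []
    for pos in range(lo, hi + 1):
        ref = wt[pos - lo]
        alts = [a for a in AA1 if a != ref]
        chosen = rng.choice(alts, size=config.n_missense_per_codon, replace=False)
        variants.extend(ProteinVariant(pos, ref, str(a)) for a in chosen)
    n_missense = len(variants)

    nonsense_pos = rng.choice(
        np.arange(lo, hi + 1), size=config.n_nonsense, replace=False
    )
    variants.extend(
        ProteinVariant(int(p), wt[int(p) - lo], STOP) for p in sorted(nonsense_pos)
    )
    syn_pos = rng.choice(np.arange(lo, hi + 1), size=config.n_synonymous, replace=False)
    variants.extend(
        ProteinVariant(int(p), wt[int(p) - lo], wt[int(p) - lo])
        for p in sorted(syn_pos)
    )

    # true classes: missense mixture; nonsense always LOF; synonymous WT-like
    classes: list[str] = list(
        rng.choice(
            [LOF, INTERMEDIATE, FUNCTIONAL],
            size=n_missense,
            p=[
                config.f_lof,
                config.f_intermediate,
                1.0 - config.f_lof - config.f_intermediate,
            ],
        )
    )
    classes += [LOF] * config.n_nonsense + [FUNCTIONAL] * config.n_synonymous

    true_class: dict[str, str] = {}
    rescue: dict[str, float] = {}
    for v, cls in zip(variants, classes):
        true_class[v.label] = cls
        rescue[v.label] = 1.0 if v.variant_class == "synonymous" else _draw_rescue(rng, cls)

    # barcodes: 1 + Poisson(mean - 1) per variant, unique random sequences
    n_bc = 1 + rng.poisson(config.barcodes_per_variant - 1.0, size=len(variants))
    seen: set[str] = set()
    entries: dict[str, BarcodeMapEntry] = {}
    for v, k in zip(variants, n_bc):
        for _ in range(int(k)):
            while True:
                bc = "".join(rng.choice(_DNA, size=config.barcode_length))
                if bc not in seen:
                    seen.add(bc)
                    break
            base_nt = 3 * (v.position - 1) + 1
            ref_b, alt_b = rng.choice(_DNA, size=2, replace=False)
            entries[bc] = BarcodeMapEntry(
                barcode=bc,
                aa_changes=(v,),
                nt_changes=(f"c.{base_nt + int(rng.integers(3))}{ref_b}>{alt_b}",),
            )

    bmap = BarcodeMap(entries=entries, window=(lo, hi))
    return bmap, SimTruth(true_class=true_class, rescue=rescue, wt_sequence=wt)


def _gfp_probability(condition: str, rescue: np.ndarray, config: SimConfig) -> np.ndarray:
    p_bg, p_max = config.p_gfp_background, config.p_gfp_max
    if condition == "control":
        return np.full_like(rescue, p_max)
    if condition == "siBRCA1_3UTR":
        return p_bg + (p_max - p_bg) * rescue
    if condition == "siBRCA1_CDS":
        return np.full_like(rescue, p_bg)
    raise ValueError(f"unknown condition {condition!r}")


def simulate_sort_counts(
    bmap: BarcodeMap, truth: SimTruth, config: SimConfig
) -> SimResult:
    """Simulate sorted-bin barcode read counts for every replicate/condition.

    Draw order: one integration-bottleneck multinomial over barcodes, then
    per replicate (1..n) and condition (control, siBRCA1_3UTR,
    siBRCA1_CDS): cell allocation multinomial, per-barcode GFP binomial,
    and read multinomials for input, gfp_pos, gfp_neg.  The input bin is
    drawn from the pre-sort pool.
    """
    config.validate()
    barcodes = list(bmap.entries)
    try:
        rescue = np.array(
            [truth.rescue[bmap.entries[b].variant_label] for b in barcodes]
        )
    except KeyError as e:
        raise KeyError(f"barcode map variant without truth entry: {e}") from e

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = len(barcodes)

    # integration bottleneck: the cell library is one multinomial draw
    bottleneck = rng.multinomial(config.n_cells_integrated, np.full(n, 1.0 / n))
    lib_props = bottleneck / bottleneck.sum()

    rows = []
    tallies = []
    for rep in range(1, config.n_replicates + 1):
        for condition in CONDITIONS:
            cells = rng.multinomial(config.n_cells_integrated, lib_props)
            p = _gfp_probability(condition, rescue, config)
            pos_cells = rng.binomial(cells, p)
            neg_cells = cells - pos_cells
            pools = {"input": cells, "gfp_pos": pos_cells, "gfp_neg": neg_cells}
            for bin_name in BINS:
                pool = pools[bin_name]
                total = pool.sum()
                if total == 0:
                    reads = np.zeros(n, dtype=np.int64)
                else:
                    reads = rng.multinomial(config.sequencing_depth, pool / total)
                rows.append(
                    pd.DataFrame(
                        {
                            "barcode": barcodes,
                            "replicate": rep,
                            "condition": condition,
                            "bin": bin_name,
                            "count": reads,
                        }
                    )
                )
            tallies.append(
                {
                    "replicate": rep,
                    "condition": condition,
                    "cells_total": int(cells.sum()),
                    "cells_gfp_pos": int(pos_cells.sum()),
                }
            )

    counts = pd.concat(rows, ignore_index=True)
    return SimResult(counts=counts, cell_tallies=pd.DataFrame(tallies))


def write_truth(truth: SimTruth, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    df = pd.DataFrame(
        {
            "variant_label": list(truth.true_class),
            "true_class": list(truth.true_class.values()),
            "rescue": [truth.rescue[k] for k in truth.true_class],
        }
    )
    all_meta = dict(meta or {})
    if truth.wt_sequence:
        all_meta["wt_sequence"] = truth.wt_sequence
    _write_tsv(df, path, all_meta)


def read_truth(path: str | Path) -> SimTruth:
    from .counts_io import _read_meta

    meta = _read_meta(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    return SimTruth(
        true_class=dict(zip(df["variant_label"], df["true_class"])),
        rescue=dict(zip(df["variant_label"], df["rescue"])),
        wt_sequence=meta.get("wt_sequence", ""),
    )


def emit_fastq(
    counts_slice: pd.DataFrame, path: str | Path, quality_char: str = "I"
) -> int:
    """Write one FASTQ read per counted barcode occurrence.

    Exercises the exact-match counting path; returns the number of reads
    written.  Reads are emitted in table order, so output is deterministic.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = 0
    with open(path, "w") as fh:
        for barcode, count in zip(counts_slice["barcode"], counts_slice["count"]):
            for _ in range(int(count)):
                n += 1
                fh.write(f"@read{n}\n{barcode}\n+\n{quality_char * len(barcode)}\n")
    return n
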