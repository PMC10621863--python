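"""Barcode-map and count-table I/O, barcode counting, variant collapse.

The assay quantifies variant abundance by sequencing short barcodes
integrated next to each BRCA1 cDNA; a long-read legend pairs each barcode
with the amino-acid change(s) its cDNA carries.  This module reads and
writes that legend and the per-bin count tables, counts exact-match
barcodes from FASTQ reads, and collapses barcode-level counts to
amino-acid-level variants (many barcodes encode the same substitution via
different nucleotide changes).

All tables are tab-delimited UTF-8 TSV with '.' decimals; writers prefix
provenance metadata lines with '#' so round-trips are bit-exact.
"""

from __future__ import annotations

import gzip
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

import pandas as pd

from .variants import (
    MUTAGENESIS_RANGE,
    SYNONYMOUS,
    ProteinVariant,
    parse_label,
)

__all__ = [
    "CONDITIONS",
    "BINS",
    "WT_LABEL",
    "BarcodeMapEntry",
    "BarcodeMap",
    "parse_barcode_map",
    "write_barcode_map",
    "count_barcodes",
    "read_count_matrix",
    "write_count_matrix",
    "complete_count_index",
    "collapse_to_variants",
]

CONDITIONS = ("control", "siBRCA1_3UTR", "siBRCA1_CDS")
BINS = ("input", "gfp_pos", "gfp_neg")

#: Label used for barcodes whose cDNA carries no in-window amino-acid change.
WT_LABEL = "WT"

COUNT_COLUMNS = ["barcode", "replicate", "condition", "bin", "count"]


class BarcodeMapError(ValueError):
    """Malformed or internally inconsistent barcode-map data."""


@dataclass(frozen=True)
class BarcodeMapEntry:
    """One legend row: a barcode and the change(s) its cDNA carries.

    ``aa_changes`` holds the in-window amino-acid changes after the
    outside-window cleanup; ``variant`` is the single effective variant
    (None for WT-like barcodes and for excluded multi-mutants).
    """

    barcode: str
    aa_changes: tuple[ProteinVariant, ...]
    nt_changes: tuple[str, ...] = ()
    excluded_multi: bool = False

    @property
    def variant_label(self) -> str:
        if self.excluded_multi:
            return "multi"
        if not self.aa_changes:
            return WT_LABEL
        return self.aa_changes[0].label

    @property
    def variant(self) -> ProteinVariant | None:
        if self.excluded_multi or not self.aa_changes:
            return None
        return self.aa_changes[0]

    @property
    def variant_class(self) -> str:
        # barcodes with a fully wild-type (or synonymous-only) cDNA join the
        # synonymous normalization cohort
        if self.excluded_multi:
            return "excluded"
        if not self.aa_changes:
            return SYNONYMOUS
        return self.aa_changes[0].variant_class


@dataclass
class BarcodeMap:
    """barcode -> variant legend with its mutagenesis window.

    The window is a required map-level attribute: changes outside it are
    treated as wild type (discarded), mirroring how barcodes paired with
    incidental changes outside the mutagenized region are handled.
    """

    entries: dict[str, BarcodeMapEntry]
    window: tuple[int, int] = MUTAGENESIS_RANGE

    def __post_init__(self) -> None:
        lengths = {len(b) for b in self.entries}
        if len(lengths) > 1:
            raise BarcodeMapError(f"barcodes of mixed lengths: {sorted(lengths)}")
        self.barcode_length = lengths.pop() if lengths else 0

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.entries

    def scoring_entries(self) -> dict[str, BarcodeMapEntry]:
        """Entries usable for scoring (multi-mutant barcodes excluded)."""
        return {b: e for b, e in self.entries.items() if not e.excluded_multi}

    def variant_classes(self) -> dict[str, str]:
        """variant_label -> variant_class over scoring entries."""
        out: dict[str, str] = {}
        for e in self.scoring_entries().values():
            out[e.variant_label] = e.variant_class
        return out


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_meta(path: str | Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with _open_text(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


def _provenance_lines(meta: Mapping[str, object] | None) -> list[str]:
    from . import __version__

    lines = [f"# hdrmave_version={__version__}"]
    for k, v in (meta or {}).items():
        lines.append(f"# {k}={v}")
    return lines


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        for line in _provenance_lines(meta):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def parse_barcode_map(path: str | Path, window: tuple[int, int] | None = None) -> BarcodeMap:
    """Read a barcode->variant legend TSV.

    Columns: ``barcode``, ``aa_changes`` (';'-joined p. labels, empty for a
    wild-type cDNA), ``nt_changes`` (';'-joined, free-form).  The
    mutagenesis window comes from a ``# window=lo-hi`` provenance line or
    the ``window`` argument (argument wins).

    Amino-acid changes outside the window are discarded (the cDNA is
    treated as WT there); entries left with two or more in-window changes
    are flagged ``excluded_multi`` and take no part in scoring.  A barcode
    occurring twice with conflicting in-window variants is a data error.
    """
    meta = _read_meta(path)
    if window is None:
        if "window" not in meta:
            raise BarcodeMapError(
                f"{path}: no mutagenesis window in header and none supplied"
            )
        lo, hi = meta["window"].split("-")
        window = (int(lo), int(hi))

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in ("barcode", "aa_changes"):
        if col not in df.columns:
            raise BarcodeMapError(f"{path}: missing required column {col!r}")

    lo, hi = window
    entries: dict[str, BarcodeMapEntry] = {}
    for row in df.itertuples(index=False):
        barcode = row.barcode
        labels = [s for s in row.aa_changes.split(";") if s]
        changes = tuple(parse_label(s) for s in labels)
        in_window = tuple(v for v in changes if lo <= v.position <= hi)
        nt = tuple(
            s for s in getattr(row, "nt_changes", "").split(";") if s
        )
        entry = BarcodeMapEntry(
            barcode=barcode,
            aa_changes=in_window,
            nt_changes=nt,
            excluded_multi=len(in_window) >= 2,
        )
        if barcode in entries:
            if entries[barcode].aa_changes != entry.aa_changes:
                raise BarcodeMapError(
                    f"duplicate barcode {barcode} with conflicting variants"
                )
            continue
        entries[barcode] = entry
    return BarcodeMap(entries=entries, window=window)


def write_barcode_map(
    bmap: BarcodeMap, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    """Write a BarcodeMap TSV (parse_barcode_map round-trips it losslessly)."""
    rows = []
    for e in bmap.entries.values():
        rows.append(
            {
                "barcode": e.barcode,
                "variant_label": e.variant_label,
                "variant_class": e.variant_class,
                "aa_changes": ";".join(v.label for v in e.aa_changes),
                "nt_changes": ";".join(e.nt_changes),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["barcode", "variant_label", "variant_class", "aa_changes", "nt_changes"],
    )
    all_meta = {"window": f"{bmap.window[0]}-{bmap.window[1]}"}
    all_meta.update(meta or {})
    _write_tsv(df, path, all_meta)


def count_barcodes(
    reads: str | Path | Iterable[str],
    bmap: BarcodeMap,
    replicate: int,
    condition: str,
    bin_name: str,
) -> tuple[pd.DataFrame, int]:
    """Tally exact-match barcode occurrences in a FASTQ stream.

    ``reads`` is a FASTQ path (gz-transparent) or an iterable of read
    sequences.  Only reads exactly equal to a known barcode count; anything
    else — including single-substitution neighbours — is tallied as
    unmatched (no fuzzy matching, no error correction).  Returns a complete
    count slice (every barcode present, zeros explicit) and the unmatched
    tally; matched + unmatched equals the number of reads.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if bin_name not in BINS:
        raise ValueError(f"unknown bin {bin_name!r}")

    if isinstance(reads, (str, Path)):
        from Bio import SeqIO

        with _open_text(reads) as fh:
            seqs = [str(rec.seq) for rec in SeqIO.parse(fh, "fastq")]
    else:
        seqs = list(reads)

    counts = dict.fromkeys(bmap.entries, 0)
    unmatched = 0
    for s in seqs:
        if s in counts:
            counts[s] += 1
        else:
            unmatched += 1

    df = pd.DataFrame(
        {
            "barcode": list(counts),
            "replicate": replicate,
            "condition": condition,
            "bin": bin_name,
            "count": list(counts.values()),
        }
    )
    return df, unmatched


def complete_count_index(
    df: pd.DataFrame,
    barcodes: Iterable[str],
    replicates: Iterable[int],
    conditions: Iterable[str] = CONDITIONS,
    bins: Iterable[str] = BINS,
) -> pd.DataFrame:
    """Reindex a long count table onto the full cartesian index, zero-filled."""
    idx = pd.MultiIndex.from_product(
        [list(barcodes), list(replicates), list(conditions), list(bins)],
        names=COUNT_COLUMNS[:4],
    )
    out = (
        df.set_index(COUNT_COLUMNS[:4])["count"]
        .reindex(idx, fill_value=0)
        .reset_index()
    )
    out["count"] = out["count"].astype("int64")
    return out


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Read a long-format count TSV (barcode/variant, replicate, condition, bin, count)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"count": "int64"})
    if (df["count"] < 0).any():
        raise ValueError(f"{path}: negative counts")
    return df


def write_count_matrix(
    df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    _write_tsv(df, path, meta)


def collapse_to_variants(
    counts: pd.DataFrame, bmap: BarcodeMap
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Sum barcode-level counts into amino-acid-level variant counts.

    Barcodes mapping to the same variant (different nucleotide changes,
    same substitution) are combined per (replicate, condition, bin).
    Unmapped barcodes and excluded multi-mutant barcodes are dropped; their
    read mass is returned in the tally so nothing disappears silently.
    Total mapped mass is conserved.
    """
    label_of = {b: e.variant_label for b, e in bmap.scoring_entries().items()}
    excluded = {b for b, e in bmap.entries.items() if e.excluded_multi}

    is_excluded = counts["barcode"].isin(excluded)
    is_mapped = counts["barcode"].isin(label_of.keys())
    tally = {
        "unmapped_reads": int(counts.loc[~is_mapped & ~is_excluded, "count"].sum()),
        "excluded_multi_reads": int(counts.loc[is_excluded, "count"].sum()),
    }

    mapped = counts[is_mapped].copy()
    mapped["variant_label"] = mapped["barcode"].map(label_of)
    grouped = (
        mapped.groupby(["variant_label", "replicate", "condition", "bin"], sort=True)[
            "count"
        ]
        .sum()
        .reset_index()
    )
    class_of = bmap.variant_classes()
    grouped.insert(1, "variant_class", grouped["variant_label"].map(class_of))
    return grouped, tally
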