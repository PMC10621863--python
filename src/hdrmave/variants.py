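"""Protein-variant identities, labels and region annotation.

Variants are single amino-acid substitutions in full-length BRCA1
coordinates, written in three-letter HGVS-like protein notation
(``p.Met1400Ser``).  The mutagenized region spans residues 1280-1576 and
is split into three sublibraries (CC1 1280-1375, CC2 1376-1471, CC3
1472-1576) covering the serine-cluster and coiled-coil (PALB2-binding)
domains.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "AA1",
    "STOP",
    "MUTAGENESIS_RANGE",
    "SUBLIBRARY_RANGES",
    "PALB2_REGION",
    "PHOSPHO_RESIDUES",
    "ProteinVariant",
    "parse_label",
    "annotate_variant",
    "synthetic_wt_sequence",
]

#: The 20 standard amino acids, one-letter codes.
AA1 = "ACDEFGHIKLMNPQRSTVWY"
STOP = "*"

#: Inclusive residue interval mutagenized in the assay.
MUTAGENESIS_RANGE = (1280, 1576)

#: Sublibrary residue intervals (inclusive).
SUBLIBRARY_RANGES = {
    "CC1": (1280, 1375),
    "CC2": (1376, 1471),
    "CC3": (1472, 1576),
}

#: Residues of the BRCA1 coiled-coil surface that contact PALB2 (inclusive).
PALB2_REGION = (1364, 1437)

#: Wild-type residues that can carry a phosphate group.
PHOSPHO_RESIDUES = frozenset("STY")

_THREE = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
    STOP: "Ter",
}
_ONE = {v: k for k, v in _THREE.items()}

_LABEL_RE = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")

MISSENSE = "missense"
NONSENSE = "nonsense"
SYNONYMOUS = "synonymous"


@dataclass(frozen=True, order=True)
class ProteinVariant:
    """A single amino-acid-level change.

    position is 1-based in full-length protein coordinates; alt_aa may be
    ``*`` (stop).  variant_class is derived: synonymous iff alt == ref,
    nonsense iff alt is stop, otherwise missense.
    """

    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.ref_aa not in AA1:
            raise ValueError(f"invalid reference amino acid {self.ref_aa!r}")
        if self.alt_aa not in AA1 and self.alt_aa != STOP:
            raise ValueError(f"invalid alternate amino acid {self.alt_aa!r}")
        if self.position < 1:
            raise ValueError(f"residue position must be >= 1, got {self.position}")

    @property
    def variant_class(self) -> str:
        if self.alt_aa == STOP:
            return NONSENSE
        if self.alt_aa == self.ref_aa:
            return SYNONYMOUS
        return MISSENSE

    @property
    def label(self) -> str:
        return f"p.{_THREE[self.ref_aa]}{self.position}{_THREE[self.alt_aa]}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_label(label: str) -> ProteinVariant:
    """Parse ``p.Met1400Ser`` three-letter notation into a ProteinVariant.

    Raises ValueError on malformed labels or unknown residue codes.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise ValueError(f"malformed variant label {label!r}")
    ref3, pos, alt3 = m.groups()
    if ref3 not in _ONE or alt3 not in _ONE:
        raise ValueError(f"unknown residue code in {label!r}")
    if _ONE[ref3] == STOP:
        raise ValueError(f"reference residue cannot be a stop: {label!r}")
    return ProteinVariant(int(pos), _ONE[ref3], _ONE[alt3])


def sublibrary_of(position: int) -> str | None:
    """Return the sublibrary (CC1/CC2/CC3) containing a residue, else None."""
    for name, (lo, hi) in SUBLIBRARY_RANGES.items():
        if lo <= position <= hi:
            return name
    return None


@dataclass(frozen=True)
class VariantAnnotation:
    in_palb2_region: bool
    phospho_candidate: bool
    sublibrary: str | None


def annotate_variant(
    variant: ProteinVariant, wt_sequence: str, offset: int = 1
) -> VariantAnnotation:
    """Annotate region membership and phospho-site status of a variant.

    Parameters
    ----------
    variant:
        The substitution to annotate.
    wt_sequence:
        Wild-type amino-acid string; ``wt_sequence[0]`` is residue ``offset``
        in protein coordinates.
    offset:
        Protein-coordinate position of the first character of wt_sequence.

    The phospho-candidate flag is set when the *wild-type* residue is
    serine, threonine or tyrosine (the serine-cluster domain is
    phosphorylated after DNA damage, so substitutions at such residues may
    remove a modification site).
    """
    idx = variant.position - offset
    if idx < 0 or idx >= len(wt_sequence):
        raise ValueError(
            f"position {variant.position} outside provided sequence "
            f"[{offset}, {offset + len(wt_sequence) - 1}]"
        )
    wt = wt_sequence[idx]
    if wt != variant.ref_aa:
        raise ValueError(
            f"reference mismatch at {variant.position}: variant says "
            f"{variant.ref_aa}, sequence says {wt}"
        )
    lo, hi = PALB2_REGION
    return VariantAnnotation(
        in_palb2_region=lo <= variant.position <= hi,
        phospho_candidate=wt in PHOSPHO_RESIDUES,
        sublibrary=sublibrary_of(variant.position),
    )


def synthetic_wt_sequence(start: int, end: int, seed: int = 0) -> str:
    """Seeded random amino-acid sequence for residues start..end inclusive.

    Synthetic stand-in for the real wild-type sequence of the mutagenized
    region, used by the simulator so that every downstream stage is testable
    without external sequence data.  Deterministic for a given (range, seed).
    """
    import numpy as np

    if end < start:
        raise ValueError("empty residue range")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AA1), size=end - start + 1))
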