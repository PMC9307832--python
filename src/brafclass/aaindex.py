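"""AAindex property scales and their condensation to two features.

Fifty-seven amino-acid property scales (24 "structural": helix, sheet,
turn and burial propensities; 33 "physicochemical": hydrophobicity,
polarity, charge, volume, size) are min-max normalized to [0, 1] over
the 20 standard residues.  For a mutation, the wild-type and mutant
residues each define a point in the 24- and 33-dimensional normalized
property spaces; the city-block (Manhattan) distance between the two
points condenses each category to a single number, so 57 raw scales
become 2 features: ``d_struct`` in [0, 24] and ``d_physchem`` in
[0, 33].

Scales are read from the standard AAindex1 flat-file format (H-line
accession, I-line value block).  Which accessions belong to which
category is a packaged manifest (``data/aaindex_manifest.tsv``),
overridable by the user.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import pandas as pd

from .datasets import AMINO_ACIDS

logger = logging.getLogger(__name__)

CATEGORIES = ("structural", "physicochemical")
EXPECTED_COUNTS = {"structural": 24, "physicochemical": 33}

# column order of the two I-line value rows in AAindex1 records
_I_ROW1 = "ARNDCQEGHILKMFPSTWYV"


class AAindexError(ValueError):
    pass


@dataclass(frozen=True)
class PropertyScale:
    accession: str
    category: str  # "structural" | "physicochemical"
    values: dict[str, float]
    normalized: dict[str, float] | None = None

    def __post_init__(self):
        missing = AMINO_ACIDS - set(self.values)
        if missing:
            raise AAindexError(
                f"{self.accession}: values missing for {sorted(missing)}")


def normalize_scale(raw: PropertyScale) -> PropertyScale:
    """Min-max normalize a scale to [0, 1] over the 20 standard residues.

    A constant scale maps to all zeros (with a warning) rather than
    dividing by zero.
    """
    vals = raw.values
    lo = min(vals.values())
    hi = max(vals.values())
    if hi == lo:
        logger.warning("%s: constant scale, normalized to all zeros", raw.accession)
        norm = {aa: 0.0 for aa in vals}
    else:
        norm = {aa: (v - lo) / (hi - lo) for aa, v in vals.items()}
    return replace(raw, normalized=norm)


def parse_aaindex1(path: str | Path,
                   categories: dict[str, str] | None = None) -> list[PropertyScale]:
    """Read AAindex1 flat-file records (H/I lines, ``//`` terminated).

    ``categories`` maps accession -> category; records without a mapping
    are skipped.  Returned scales are already normalized.
    """
    text = Path(path).read_text()
    scales: list[PropertyScale] = []
    for record in text.split("//"):
        lines = [ln for ln in record.splitlines() if ln.strip()]
        if not lines:
            continue
        accession = None
        values: dict[str, float] = {}
        for i, line in enumerate(lines):
            if line.startswith("H "):
                accession = line[2:].strip()
            elif line.startswith("I "):
                # two data rows follow the I header line
                rows = []
                for data_line in lines[i + 1:i + 3]:
                    rows.append(data_line.split())
                if len(rows) != 2 or len(rows[0]) != 10 or len(rows[1]) != 10:
                    raise AAindexError(
                        f"{accession}: malformed I-line value block")
                flat = rows[0] + rows[1]
                for aa, tok in zip(_I_ROW1, flat):
                    if tok in ("NA", "-"):
                        raise AAindexError(f"{accession}: missing value for {aa}")
                    values[aa] = float(tok)
                break
        if accession is None or not values:
            continue
        if categories is not None:
            if accession not in categories:
                continue
            category = categories[accession]
        else:
            category = "physicochemical"
        scales.append(normalize_scale(
            PropertyScale(accession=accession, category=category, values=values)))
    return scales


def load_manifest(path: str | Path | None = None) -> dict[str, str]:
    """Accession -> category mapping (packaged manifest by default)."""
    if path is None:
        path = str(resources.files("brafclass").joinpath("data/aaindex_manifest.tsv"))
    df = pd.read_csv(path, sep="\t")
    bad = set(df["category"]) - set(CATEGORIES)
    if bad:
        raise AAindexError(f"unknown categories in manifest: {sorted(bad)}")
    return dict(zip(df["accession"], df["category"]))


def validate_scale_set(scales: list[PropertyScale]) -> dict[str, int]:
    """Check the 24 + 33 category composition; returns counts."""
    counts = {c: sum(1 for s in scales if s.category == c) for c in CATEGORIES}
    if counts != EXPECTED_COUNTS:
        by_cat = {c: sorted(s.accession for s in scales if s.category == c)
                  for c in CATEGORIES}
        raise AAindexError(
            f"expected {EXPECTED_COUNTS} scales, got {counts}; "
            f"loaded accessions: {by_cat}")
    return counts


def city_block(wt_aa: str, mt_aa: str, scales: list[PropertyScale],
               category: str | None = None) -> float:
    """Manhattan distance between WT and mutant normalized property vectors."""
    if category is not None:
        scales = [s for s in scales if s.category == category]
    if not scales:
        raise AAindexError("empty scale list")
    total = 0.0
    for s in scales:
        norm = s.normalized
        if norm is None:
            raise AAindexError(f"{s.accession}: scale not normalized")
        total += abs(norm[wt_aa] - norm[mt_aa])
    return total


@dataclass(frozen=True)
class CondensedFeatures:
    d_struct: float
    d_physchem: float


def condense(wt_aa: str, mt_aa: str,
             scales: list[PropertyScale]) -> CondensedFeatures:
    """Condense the full scale set to the two city-block features."""
    validate_scale_set(scales)
    return CondensedFeatures(
        d_struct=city_block(wt_aa, mt_aa, scales, "structural"),
        d_physchem=city_block(wt_aa, mt_aa, scales, "physicochemical"),
    )
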