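"""Curated BRAF mutation tables and kinase-domain annotations.

The classifier operates on missense variants of the BRAF kinase domain
(residues 457-717) that have been assigned to functional class II
(RAS-independent dimeric activation) or class III (RAS-dependent,
impaired kinase activity).  Class I is the Val600 hotspot and is out of
scope.  This module loads and validates mutation tables and applies the
training-set filter: keep labelled class II/III records inside the
kinase domain, dropping the two outlier positions Glu549 and Glu586
whose behaviour is not explained by active-site geometry.

The packaged table ``braf_kinase_mutations_synthetic.tsv`` is a
synthetic stand-in for the curated literature set: a 52-row list of
plausible kinase-domain class II/III assignments reconstructed from
published hotspot positions, with the documented 26/24 class balance
after filtering.  Supply your own table for real analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class MutationParseError(ValueError):
    """A mutation-table row could not be parsed or validated."""


@dataclass(frozen=True)
class MutationRecord:
    """One missense variant in BRAF canonical (UniProt P15056) numbering."""

    position: int
    wt_aa: str
    mt_aa: str
    label: Optional[str] = None  # "II" | "III" | None

    def __post_init__(self):
        if self.position < 1:
            raise MutationParseError(f"position must be >= 1, got {self.position}")
        for which, aa in (("wild-type", self.wt_aa), ("mutant", self.mt_aa)):
            if aa not in AMINO_ACIDS:
                raise MutationParseError(
                    f"{which} amino acid {aa!r} at position {self.position} "
                    "is not a standard one-letter code"
                )
        if self.wt_aa == self.mt_aa:
            raise MutationParseError(
                f"wild-type and mutant residues are identical "
                f"({self.wt_aa}{self.position}{self.mt_aa})"
            )
        if self.label is not None and self.label not in ("II", "III"):
            raise MutationParseError(
                f"label must be 'II' or 'III', got {self.label!r}"
            )

    @property
    def name(self) -> str:
        """Protein-level shorthand, e.g. ``G469A``."""
        return f"{self.wt_aa}{self.position}{self.mt_aa}"


@dataclass(frozen=True)
class KinaseAnnotation:
    """Closed-interval region annotations of the BRAF kinase domain."""

    kinase_domain: tuple[int, int] = (457, 717)
    p_loop: tuple[int, int] = (458, 475)
    c_helix: tuple[int, int] = (491, 506)
    activation_loop: tuple[int, int] = (593, 633)
    dfg: tuple[int, int] = (594, 596)
    excluded_positions: frozenset[int] = frozenset({549, 586})

    def __post_init__(self):
        lo, hi = self.kinase_domain
        for name in ("p_loop", "c_helix", "activation_loop", "dfg"):
            a, b = getattr(self, name)
            if not (lo <= a <= b <= hi):
                raise ValueError(f"{name} [{a}, {b}] not inside kinase domain [{lo}, {hi}]")

    def in_domain(self, position: int) -> bool:
        lo, hi = self.kinase_domain
        return lo <= position <= hi


def packaged_mutation_table() -> Path:
    """Path to the packaged synthetic stand-in mutation table."""
    return Path(str(resources.files("brafclass").joinpath(
        "data/braf_kinase_mutations_synthetic.tsv")))


def load_mutations(path: str | Path) -> list[MutationRecord]:
    """Read a headered TSV with columns position/wt/mt[/label].

    Order is preserved.  Rows with a malformed amino-acid code or with
    wt == mt raise :class:`MutationParseError` naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"position", "wt", "mt"}
    missing = required - set(df.columns)
    if missing:
        raise MutationParseError(
            f"{path}: missing required column(s) {sorted(missing)}")
    records: list[MutationRecord] = []
    for i, row in df.iterrows():
        label = None
        if "label" in df.columns and pd.notna(row["label"]) and str(row["label"]).strip():
            label = str(row["label"]).strip()
        try:
            records.append(MutationRecord(
                position=int(row["position"]),
                wt_aa=str(row["wt"]).strip().upper(),
                mt_aa=str(row["mt"]).strip().upper(),
                label=label,
            ))
        except (MutationParseError, ValueError) as exc:
            raise MutationParseError(f"{path}, row {i + 2}: {exc}") from exc
    return records


def filter_training_set(
    records: list[MutationRecord],
    ann: KinaseAnnotation | None = None,
) -> list[MutationRecord]:
    """Apply the training-set curation filter.

    Keeps records that (i) carry a class II or III label, (ii) fall
    inside the kinase domain and (iii) are not at an excluded outlier
    position.  Val600 records (class I territory) are dropped with a
    logged notice.  Idempotent; an empty result warns rather than raises.
    """
    ann = ann or KinaseAnnotation()
    kept: list[MutationRecord] = []
    for rec in records:
        if rec.label not in ("II", "III"):
            continue
        if not ann.in_domain(rec.position):
            continue
        if rec.position in ann.excluded_positions:
            continue
        if rec.position == 600:
            logger.info("dropping Val600 record %s (class I territory)", rec.name)
            continue
        kept.append(rec)
    counts = class_counts(kept)
    if not kept:
        logger.warning("training-set filter produced an empty mutation list")
    else:
        logger.info("training set: %d mutations (%s)", len(kept),
                    ", ".join(f"class {k}: {v}" for k, v in sorted(counts.items())))
    return kept


def class_counts(records: list[MutationRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in records:
        if rec.label is not None:
            counts[rec.label] = counts.get(rec.label, 0) + 1
    return counts


def save_mutations(records: list[MutationRecord], path: str | Path) -> None:
    """Write records back to the headered TSV exchange format."""
    rows = [{"position": r.position, "wt": r.wt_aa, "mt": r.mt_aa,
             "label": r.label or ""} for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
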