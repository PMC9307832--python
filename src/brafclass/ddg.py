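"""Folding free-energy perturbation (ddG) providers.

The ddG feature is the predicted change in folding free energy upon
mutation, ddG = dG_mutant - dG_wild-type, in kcal/mol, as produced by
FoldX PositionScan.  FoldX is proprietary, so the pipeline is built
around a provider boundary with two implementations:

* :class:`DdgTable` — lookup from a precomputed TSV
  (structure_id / position / wt / mt / ddg); the default, and the only
  provider the test suite exercises with real data.
* :class:`FoldXRunner` — wraps an external FoldX 5 executable, invoking
  ``PositionScan`` and parsing the scanning-output report.  It also
  captures the two generated models: the side-chain-optimized wild-type
  reference and the mutant, both of which downstream distance features
  can consume.

A mutation without a ddG value is featurized with a NaN sentinel and
can only be scored by models whose feature subset excludes ddG (the
default best subset does).
"""

from __future__ import annotations

import logging
import math
import re
import shutil
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Protocol

import pandas as pd

from .datasets import MutationRecord, ONE_TO_THREE

logger = logging.getLogger(__name__)

MISSING = float("nan")


class DdgError(RuntimeError):
    pass


class DdgProvider(Protocol):
    def ddg(self, structure_id: str, mutation: MutationRecord) -> float: ...


@dataclass(frozen=True)
class DdgRecord:
    structure_id: str
    position: int
    wt_aa: str
    mt_aa: str
    ddg: float  # kcal/mol


class DdgTable:
    """Precomputed ddG lookup keyed by (structure, position, wt, mt)."""

    def __init__(self, records: list[DdgRecord]):
        self._table: dict[tuple[str, int, str, str], float] = {}
        for rec in records:
            if not math.isfinite(rec.ddg):
                raise DdgError(f"non-finite ddG for {rec}")
            key = (rec.structure_id, rec.position, rec.wt_aa, rec.mt_aa)
            if key in self._table and self._table[key] != rec.ddg:
                raise DdgError(
                    f"conflicting ddG values for {key}: "
                    f"{self._table[key]} vs {rec.ddg}")
            self._table[key] = rec.ddg

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DdgTable":
        df = pd.read_csv(path, sep="\t")
        required = {"structure_id", "position", "wt", "mt", "ddg"}
        missing = required - set(df.columns)
        if missing:
            raise DdgError(f"{path}: missing column(s) {sorted(missing)}")
        records = [DdgRecord(str(r.structure_id), int(r.position),
                             str(r.wt).upper(), str(r.mt).upper(), float(r.ddg))
                   for r in df.itertuples()]
        return cls(records)

    def ddg(self, structure_id: str, mutation: MutationRecord) -> float:
        if mutation.wt_aa == mutation.mt_aa:  # wt->wt is zero by definition
            return 0.0
        key = (structure_id, mutation.position, mutation.wt_aa, mutation.mt_aa)
        return self._table.get(key, MISSING)

    def __len__(self) -> int:
        return len(self._table)


class NullDdg:
    """Provider used when no ddG source is configured: always missing."""

    def ddg(self, structure_id: str, mutation: MutationRecord) -> float:
        if mutation.wt_aa == mutation.mt_aa:
            return 0.0
        return MISSING


@dataclass
class FoldXResult:
    ddg: float
    wt_model: Path
    mt_model: Path


class FoldXRunner:
    """Thin wrapper over a FoldX 5 binary's PositionScan command.

    Invocation contract (documented, mockable)::

        foldx --command=PositionScan --pdb=<file.pdb> --pdb-dir=<dir> \\
              --positions=<WT><chain><pos><MT> --output-dir=<workdir>

    The tool writes ``PS_<stem>_scanning_output.txt`` with one
    whitespace-separated ``<three-letter-mt><chain><pos> <ddg>`` line
    per scanned mutant, plus the rebuilt wild-type and mutant model
    PDB files in the output directory.
    """

    def __init__(self, executable: str | Path, chain: str = "A",
                 workdir: str | Path | None = None):
        self.executable = Path(executable)
        self.chain = chain
        self.workdir = Path(workdir) if workdir else None
        if shutil.which(str(self.executable)) is None and not self.executable.exists():
            raise DdgError(f"FoldX executable not found: {self.executable}")

    def position_scan(self, structure: str | Path,
                      mutation: MutationRecord) -> FoldXResult:
        structure = Path(structure)
        workdir = self.workdir or structure.parent
        workdir.mkdir(parents=True, exist_ok=True)
        cmd = [
            str(self.executable),
            "--command=PositionScan",
            f"--pdb={structure.name}",
            f"--pdb-dir={structure.parent}",
            f"--positions={mutation.wt_aa}{self.chain}{mutation.position}{mutation.mt_aa}",
            f"--output-dir={workdir}",
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise DdgError(
                f"FoldX PositionScan failed (exit {proc.returncode}):\n"
                f"{proc.stdout}\n{proc.stderr}")
        report = workdir / f"PS_{structure.stem}_scanning_output.txt"
        if not report.exists():
            raise DdgError(f"FoldX report not found: {report}\n{proc.stdout}")
        ddg = self._parse_report(report, mutation)
        wt_model = workdir / f"WT_{structure.stem}_{mutation.position}.pdb"
        mt_model = workdir / f"{ONE_TO_THREE[mutation.mt_aa]}{mutation.position}_{structure.stem}.pdb"
        for p in (wt_model, mt_model):
            if not p.exists():
                raise DdgError(f"FoldX model file not found: {p}")
        return FoldXResult(ddg=ddg, wt_model=wt_model, mt_model=mt_model)

    @staticmethod
    def _parse_report(report: Path, mutation: MutationRecord) -> float:
        target3 = ONE_TO_THREE[mutation.mt_aa]
        for line in report.read_text().splitlines():
            parts = line.split()
            if len(parts) < 2:
                continue
            ident = parts[0].upper()
            m = re.match(r"([A-Z]{3})([A-Z]?)(\d+)", ident)
            if not m:
                continue
            if m.group(1) == target3 and int(m.group(3)) == mutation.position:
                try:
                    return float(parts[-1])
                except ValueError as exc:
                    raise DdgError(f"unparsable ddG in line {line!r}") from exc
        raise DdgError(
            f"no ddG entry for {mutation.name} in {report}:\n"
            f"{report.read_text()}")

    def ddg(self, structure_id: str, mutation: MutationRecord) -> float:
        raise DdgError(
            "FoldXRunner needs a structure path; call position_scan() or "
            "wrap results in a DdgTable")
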