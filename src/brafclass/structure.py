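"""PDB parsing and key-atom selection for BRAF kinase structures.

Feature extraction needs kinase structures co-crystallized with the
catalytic Mg2+ ion and the non-hydrolyzable ATP analog ANP
(phosphoaminophosphonic acid-adenylate ester): the Mg2+ and the three
ANP phosphorus atoms (P-alpha, P-beta, P-gamma) are the reference
"key atoms" for ligand-proximity distance features.  Structures lacking
either het-group are ineligible and never reach featurization.

Parsing is delegated to gemmi; this module converts the first model
into a light-weight :class:`StructureModel` keeping only the selected
BRAF chain (the one containing the DFG aspartate, residue 594, and
covering most of the kinase domain), the het-groups and the
HELIX/SHEET secondary-structure spans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np

KINASE_DOMAIN = (457, 717)
DFG_ASP = 594
PHOSPHATE_NAMES = ("PA", "PB", "PG")


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: tuple[float, float, float]
    b_factor: float

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass
class StructureModel:
    """One chain of one PDB entry plus its MG/ANP het-groups."""

    id: str
    chain: str
    residues: dict[int, tuple[str, list[Atom]]]
    het_groups: dict[str, list[Atom]]
    ss_spans: list[tuple[str, int, int]]  # (kind in {helix, sheet}, start, end)

    @property
    def eligible(self) -> bool:
        """True when both MG and a complete ANP (PA/PB/PG) are present."""
        if "MG" not in self.het_groups or "ANP" not in self.het_groups:
            return False
        anp_names = {a.name for a in self.het_groups["ANP"]}
        return set(PHOSPHATE_NAMES) <= anp_names

    def residue(self, position: int) -> tuple[str, list[Atom]] | None:
        return self.residues.get(position)

    def heavy_atoms(self, position: int) -> list[Atom]:
        entry = self.residues.get(position)
        if entry is None:
            return []
        return [a for a in entry[1] if a.is_heavy]


@dataclass(frozen=True)
class KeyAtoms:
    mg: Atom
    p_alpha: Atom
    p_beta: Atom
    p_gamma: Atom

    def __post_init__(self):
        if self.mg.element.upper() != "MG":
            raise StructureError(f"mg atom has element {self.mg.element!r}")
        for p in (self.p_alpha, self.p_beta, self.p_gamma):
            if p.element.upper() != "P":
                raise StructureError(f"phosphate atom {p.name} has element {p.element!r}")

    def as_dict(self) -> dict[str, Atom]:
        return {"Mg": self.mg, "Pa": self.p_alpha, "Pb": self.p_beta,
                "Pg": self.p_gamma}


def _dedup_altloc(atoms: Iterable[gemmi.Atom]) -> list[gemmi.Atom]:
    # keep highest occupancy per atom name; ties by altloc identifier order
    best: dict[str, gemmi.Atom] = {}
    for at in atoms:
        prev = best.get(at.name)
        if prev is None:
            best[at.name] = at
        elif (at.occ, -ord(at.altloc or "z")) > (prev.occ, -ord(prev.altloc or "z")):
            best[at.name] = at
    return list(best.values())


def _convert_atom(at: gemmi.Atom) -> Atom:
    return Atom(
        name=at.name,
        element=at.element.name.upper(),
        coords=(at.pos.x, at.pos.y, at.pos.z),
        b_factor=max(float(at.b_iso), 0.0),
    )


def _select_chain(model: gemmi.Model) -> gemmi.Chain:
    """Pick the BRAF chain: contains residue 594, best kinase-domain coverage."""
    lo, hi = KINASE_DOMAIN
    best_chain, best_cov = None, -1
    for chain in model:
        nums = {r.seqid.num for r in chain if r.het_flag == "A"}
        if DFG_ASP not in nums:
            continue
        cov = sum(1 for n in nums if lo <= n <= hi)
        if cov > best_cov:
            best_chain, best_cov = chain, cov
    if best_chain is None:
        # fall back: chain with most polymer residues
        polymer = [(sum(1 for r in c if r.het_flag == "A"), c) for c in model]
        polymer = [(n, c) for n, c in polymer if n > 0]
        if not polymer:
            raise StructureError("no ATOM records in any chain")
        best_chain = max(polymer, key=lambda t: t[0])[1]
    return best_chain


def parse_pdb(path: str | Path) -> StructureModel:
    """Parse a PDB file into a :class:`StructureModel`.

    Uses the first MODEL of multi-model files.  Het-groups MG and ANP
    are collected from any chain (ligands often sit in their own chain
    or carry a separate residue number range).
    """
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise StructureError(f"{path}: no models")
    model = st[0]
    n_atom_records = sum(
        1 for ch in model for r in ch for _ in r if r.het_flag == "A")
    if n_atom_records == 0:
        raise StructureError(f"{path}: no ATOM records")

    chain = _select_chain(model)
    residues: dict[int, tuple[str, list[Atom]]] = {}
    for res in chain:
        if res.het_flag != "A":
            continue
        atoms = [_convert_atom(a) for a in _dedup_altloc(res)]
        residues[res.seqid.num] = (res.name, atoms)

    het_groups: dict[str, list[Atom]] = {}
    for ch in model:
        for res in ch:
            if res.het_flag == "H" and res.name in ("MG", "ANP"):
                atoms = [_convert_atom(a) for a in _dedup_altloc(res)]
                het_groups.setdefault(res.name, []).extend(atoms)

    ss_spans: list[tuple[str, int, int]] = []
    for h in st.helices:
        if h.start.chain_name == chain.name:
            ss_spans.append(("helix", h.start.res_id.seqid.num,
                             h.end.res_id.seqid.num))
    for sheet in st.sheets:
        for strand in sheet.strands:
            if strand.start.chain_name == chain.name:
                ss_spans.append(("sheet", strand.start.res_id.seqid.num,
                                 strand.end.res_id.seqid.num))

    stem = Path(path).stem
    return StructureModel(id=st.name or stem, chain=chain.name,
                          residues=residues, het_groups=het_groups,
                          ss_spans=ss_spans)


def select_eligible(models: list[StructureModel]) -> list[StructureModel]:
    """Keep structures with both MG and a PA/PB/PG-complete ANP."""
    kept = [m for m in models if m.eligible]
    if not kept:
        raise StructureError(
            "no eligible structure: featurization requires at least one "
            "model co-crystallized with Mg2+ and ANP (atoms PA, PB, PG)")
    return kept


def key_atoms(model: StructureModel) -> KeyAtoms:
    """Return the Mg2+ ion and the three ANP phosphorus atoms.

    If several Mg2+ ions are present the one nearest the ANP P-gamma
    atom is used.
    """
    if not model.eligible:
        raise StructureError(f"{model.id}: not eligible (needs MG and ANP)")
    anp = {a.name: a for a in model.het_groups["ANP"]}
    missing = [n for n in PHOSPHATE_NAMES if n not in anp]
    if missing:
        raise StructureError(f"{model.id}: ANP lacks phosphate atom(s) {missing}")
    pg = anp["PG"]
    mgs = model.het_groups["MG"]
    mg = min(mgs, key=lambda a: float(np.linalg.norm(a.xyz - pg.xyz)))
    return KeyAtoms(mg=mg, p_alpha=anp["PA"], p_beta=anp["PB"], p_gamma=anp["PG"])


def verify_wt_identity(model: StructureModel, position: int, wt_aa: str) -> bool:
    """Check that the structure's residue at ``position`` matches ``wt_aa``.

    Returns True on match, False when the position is unresolved;
    raises on a hard mismatch (numbering incongruent with canonical
    BRAF numbering).
    """
    from .datasets import ONE_TO_THREE

    entry = model.residue(position)
    if entry is None:
        return False
    resname = entry[0].upper()
    expected = ONE_TO_THREE.get(wt_aa)
    if resname != expected:
        raise StructureError(
            f"{model.id}: residue {position} is {resname}, expected {expected} "
            f"({wt_aa}); structure numbering is not canonical")
    return True


# --- serialization (round-trip support and fixture output) -----------------

_PDB_ATOM = ("{rec:<6s}{serial:>5d} {name:<4s}{alt:1s}{res:<3s} {chain:1s}"
             "{seq:>4d}{icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
             "          {el:>2s}\n")


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: element right-justified in 13-14 for 1-2 char elements
    if len(name) >= 4:
        return name[:4]
    if len(element) == 2:
        return f"{name:<4s}"[:4]
    return f" {name:<3s}"


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Serialize a StructureModel to PDB format (3-decimal coordinates)."""
    lines: list[str] = []
    helix_no = sheet_no = 0
    for kind, start, end in model.ss_spans:
        sname = model.residues.get(start, ("ALA",))[0]
        ename = model.residues.get(end, ("ALA",))[0]
        if kind == "helix":
            helix_no += 1
            lines.append(
                "HELIX  {n:>3d} {n:>3d} {sr:>3s} {c:1s} {ss:>4d}  {er:>3s} "
                "{c:1s} {es:>4d}  1{pad:30s}{ln:>6d}\n".format(
                    n=helix_no, sr=sname, c=model.chain, ss=start, er=ename,
                    es=end, pad="", ln=end - start + 1))
        else:
            sheet_no += 1
            lines.append(
                "SHEET  {n:>3d} {sid:>3s} 1 {sr:>3s} {c:1s}{ss:>4d}  "
                "{er:>3s} {c:1s}{es:>4d}  0\n".format(
                    n=1, sid=chr(ord("A") + sheet_no - 1), sr=sname,
                    c=model.chain, ss=start, er=ename, es=end))
    serial = 0
    for pos in sorted(model.residues):
        resname, atoms = model.residues[pos]
        for at in atoms:
            serial += 1
            lines.append(_PDB_ATOM.format(
                rec="ATOM", serial=serial, name=_format_atom_name(at.name, at.element),
                alt=" ", res=resname, chain=model.chain, seq=pos, icode=" ",
                x=at.coords[0], y=at.coords[1], z=at.coords[2], occ=1.0,
                b=at.b_factor, el=at.element))
    het_seq = 900
    for het_name in sorted(model.het_groups):
        het_seq += 1
        for at in model.het_groups[het_name]:
            serial += 1
            lines.append(_PDB_ATOM.format(
                rec="HETATM", serial=serial,
                name=_format_atom_name(at.name, at.element),
                alt=" ", res=het_name, chain=model.chain, seq=het_seq, icode=" ",
                x=at.coords[0], y=at.coords[1], z=at.coords[2], occ=1.0,
                b=at.b_factor, el=at.element))
    lines.append("END\n")
    Path(path).write_text("".join(lines))
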