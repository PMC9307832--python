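"""Per-mutation structural features computed from a kinase structure.

Four feature families are produced for a mutated position:

* side-chain solvent-accessible surface area (SASA), Shrake-Rupley
  rolling-probe with a 1.4 A water probe and CHARMM22 van der Waals
  radii.  Glycine has no heavy side-chain atoms; its two alpha
  hydrogens are counted as the side chain so that an exposed glycine
  does not score zero.  When the hydrogens are absent from the
  coordinate file they are rebuilt geometrically from N/CA/C.
* secondary-structure context: helix / sheet / coil from the HELIX and
  SHEET spans of the entry (closed intervals), encoded 2 / 1 / 0.
* normalized B-factor: z-score of the residue's mean heavy-atom
  temperature factor against the per-residue means of the whole chain,
  a crystallographic flexibility proxy.
* shortest heavy-atom Euclidean distance from the residue to each key
  atom (Mg2+ and the ANP P-alpha/P-beta/P-gamma), for both the
  wild-type and the mutant model, plus their absolute differences.

Positions unresolved in a structure yield NaN sentinels rather than
exceptions, so that aggregation across structures can skip them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .structure import Atom, KeyAtoms, StructureModel

logger = logging.getLogger(__name__)

PROBE_RADIUS = 1.4  # A, water probe
DEFAULT_SPHERE_POINTS = 960
MISSING = float("nan")

BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}
GLY_HA_NAMES = {"HA1", "HA2", "HA3"}

SS_ENCODING = {"coil": 0, "sheet": 1, "helix": 2}

KEY_LABELS = ("Mg", "Pa", "Pb", "Pg")


# --------------------------------------------------------------------------
# van der Waals radii

class RadiusTable:
    """Atom-name / element lookup of CHARMM22 Rmin/2 radii."""

    def __init__(self, by_name: dict[str, float], by_element: dict[str, float]):
        self.by_name = by_name
        self.by_element = by_element
        self._warned: set[str] = set()

    @classmethod
    def packaged(cls) -> "RadiusTable":
        path = resources.files("brafclass").joinpath("data/charmm22_radii.tsv")
        by_name: dict[str, float] = {}
        by_element: dict[str, float] = {}
        with path.open() as fh:
            next(fh)  # header
            for line in fh:
                kind, key, radius = line.split("\t")[:3]
                if kind == "name":
                    by_name[key] = float(radius)
                else:
                    by_element[key] = float(radius)
        return cls(by_name, by_element)

    @classmethod
    def from_charmm_files(cls, par_path: str | Path) -> "RadiusTable":
        """Read Rmin/2 values from a par_all22-dialect NONBONDED section.

        Atom-type radii are collapsed to element defaults (first letter
        of the type); the packaged name-specific rows are kept on top.
        """
        by_element: dict[str, list[float]] = {}
        in_nb = False
        for raw in Path(par_path).read_text().splitlines():
            line = raw.split("!")[0].strip()
            if not line:
                continue
            token = line.split()[0].upper()
            if token.startswith("NONB"):
                in_nb = True
                continue
            if token in ("HBOND", "NBFIX", "END", "BONDS", "ANGLES",
                         "DIHEDRALS", "IMPROPER", "CMAP"):
                in_nb = False
                continue
            if not in_nb:
                continue
            parts = line.split()
            if len(parts) < 4:
                continue
            try:
                rmin_half = float(parts[3])
            except ValueError:
                continue
            el = parts[0][:2].upper() if parts[0][:2].upper() in ("MG", "CL", "ZN", "FE", "NA") \
                else parts[0][0].upper()
            by_element.setdefault(el, []).append(rmin_half)
        packaged = cls.packaged()
        element_defaults = {el: float(np.median(v)) for el, v in by_element.items()}
        merged = dict(packaged.by_element)
        merged.update(element_defaults)
        return cls(dict(packaged.by_name), merged)

    def radius(self, atom: Atom) -> float:
        if atom.name in self.by_name:
            return self.by_name[atom.name]
        el = atom.element.upper()
        if el in self.by_element:
            return self.by_element[el]
        if el not in self._warned:
            self._warned.add(el)
            logger.warning("no van der Waals radius for element %r; using 1.8 A", el)
        return 1.8


# --------------------------------------------------------------------------
# Shrake-Rupley SASA

def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = PROBE_RADIUS,
    n_points: int = DEFAULT_SPHERE_POINTS,
    subset: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom accessible surface area by rolling-probe point sampling.

    ``subset`` optionally restricts which atoms are probed (all atoms
    still occlude).  Returns areas in A^2 for the probed atoms, in the
    order of ``subset`` (or all atoms).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    ext = radii + probe
    unit = sphere_points(n_points)
    if subset is None:
        subset = np.arange(len(coords))
    tree = cKDTree(coords)
    max_ext = float(ext.max()) if len(ext) else 0.0
    areas = np.empty(len(subset), dtype=float)
    for out_i, i in enumerate(subset):
        pts = coords[i] + ext[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext)
                     if j != i]
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (ext[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[out_i] = frac * 4.0 * math.pi * ext[i] ** 2
    return areas


def _gly_alpha_hydrogens(atoms: list[Atom]) -> list[Atom]:
    """Return glycine's HA atoms, rebuilding them from N/CA/C if absent.

    Standard tetrahedral geometry: the two hydrogens lie in the plane
    bisecting the N-CA-C angle, 1.09 A from CA.
    """
    present = [a for a in atoms if a.name in GLY_HA_NAMES]
    if present:
        return present
    lookup = {a.name: a for a in atoms}
    if not {"N", "CA", "C"} <= lookup.keys():
        return []
    n, ca, c = (lookup[k].xyz for k in ("N", "CA", "C"))
    u1 = (n - ca) / np.linalg.norm(n - ca)
    u2 = (c - ca) / np.linalg.norm(c - ca)
    bis = -(u1 + u2)
    bis /= np.linalg.norm(bis)
    perp = np.cross(u2, u1)
    perp /= np.linalg.norm(perp)
    half = math.radians(109.5 / 2.0)
    b = lookup["CA"].b_factor
    out = []
    for sign, name in ((1.0, "HA2"), (-1.0, "HA3")):
        direction = math.cos(half) * bis + sign * math.sin(half) * perp
        pos = ca + 1.09 * direction
        out.append(Atom(name=name, element="H", coords=tuple(pos), b_factor=b))
    return out


def _side_chain_atoms(resname: str, atoms: list[Atom]) -> list[Atom]:
    if resname.upper() == "GLY":
        return _gly_alpha_hydrogens(atoms)
    return [a for a in atoms if a.is_heavy and a.name not in BACKBONE_NAMES]


def sasa_side_chain(
    model: StructureModel,
    position: int,
    radii: RadiusTable | None = None,
    n_points: int = DEFAULT_SPHERE_POINTS,
) -> float:
    """Side-chain SASA (A^2) of the residue at ``position``.

    The occluding context is every heavy atom of the selected chain plus
    the het-groups; the probed set is the residue's side chain (glycine:
    its alpha hydrogens).  Unresolved position -> NaN sentinel.
    """
    entry = model.residue(position)
    if entry is None:
        return MISSING
    radii = radii or RadiusTable.packaged()
    resname, res_atoms = entry
    probe_atoms = _side_chain_atoms(resname, res_atoms)
    if not probe_atoms:
        logger.warning("%s: residue %d (%s) has no side-chain atoms",
                       model.id, position, resname)
        return MISSING

    context: list[Atom] = []
    for pos in model.residues:
        _, ats = model.residues[pos]
        context.extend(a for a in ats if a.is_heavy)
    for het_atoms in model.het_groups.values():
        context.extend(a for a in het_atoms if a.is_heavy)
    # glycine alpha hydrogens (from file or rebuilt) are not in the
    # heavy-atom context; append them so they carry radii and occlude
    extra = [a for a in probe_atoms if not a.is_heavy]
    allatoms = context + extra

    coords = np.array([a.xyz for a in allatoms])
    rads = np.array([radii.radius(a) for a in allatoms])
    probe_idx = []
    for pa in probe_atoms:
        for j, a in enumerate(allatoms):
            if a is pa or (a.name == pa.name and a.coords == pa.coords):
                probe_idx.append(j)
                break
    areas = shrake_rupley(coords, rads, n_points=n_points,
                          subset=np.asarray(probe_idx))
    return float(areas.sum())


# --------------------------------------------------------------------------
# distances, B-factor, secondary structure

def min_distance(model: StructureModel, position: int, key: Atom) -> float:
    """Shortest Euclidean distance (A) from the residue's heavy atoms to
    ``key``; NaN if the position is unresolved."""
    if model.residue(position) is None:
        return MISSING
    heavy = model.heavy_atoms(position)
    if not heavy:
        raise ValueError(
            f"{model.id}: residue {position} resolved but has no heavy atoms")
    return min(math.dist(a.coords, key.coords) for a in heavy)


def min_distance_atom(model: StructureModel, position: int, key: Atom) -> tuple[float, str]:
    """As :func:`min_distance` but also names the minimizing atom."""
    heavy = model.heavy_atoms(position)
    if not heavy:
        return MISSING, ""
    d = [math.dist(a.coords, key.coords) for a in heavy]
    i = int(np.argmin(d))
    return d[i], heavy[i].name


def normalized_b(model: StructureModel, position: int) -> float:
    """Z-score of the residue's mean heavy-atom B-factor over the chain.

    The reference distribution is the per-residue mean B-factor of every
    resolved residue of the selected chain (population standard
    deviation).  A flat B-factor column returns 0.
    """
    entry = model.residue(position)
    if entry is None:
        return MISSING
    means = {}
    for pos in model.residues:
        heavy = model.heavy_atoms(pos)
        if heavy:
            means[pos] = float(np.mean([a.b_factor for a in heavy]))
    if position not in means:
        return MISSING
    values = np.array(list(means.values()))
    mu, sigma = float(values.mean()), float(values.std())
    if sigma == 0.0:
        return 0.0
    return (means[position] - mu) / sigma


def ss_context(model: StructureModel, position: int) -> int:
    """Secondary-structure context: helix=2, sheet=1, coil=0.

    Spans are closed intervals; helix wins over sheet if spans overlap.
    """
    kinds = {kind for kind, start, end in model.ss_spans if start <= position <= end}
    if "helix" in kinds:
        return SS_ENCODING["helix"]
    if "sheet" in kinds:
        return SS_ENCODING["sheet"]
    return SS_ENCODING["coil"]


@dataclass
class DistanceFeatures:
    d_wt: dict[str, float]
    d_mt: dict[str, float]
    d_absdiff: dict[str, float]


def distance_features(
    wt_model: StructureModel,
    mt_model: StructureModel,
    position: int,
    keys: KeyAtoms,
) -> DistanceFeatures:
    """WT/mutant shortest distances to the four key atoms and their
    absolute differences (NaN propagates from unresolved positions)."""
    key_map = keys.as_dict()
    d_wt = {lbl: min_distance(wt_model, position, at) for lbl, at in key_map.items()}
    d_mt = {lbl: min_distance(mt_model, position, at) for lbl, at in key_map.items()}
    d_abs = {lbl: abs(d_wt[lbl] - d_mt[lbl]) for lbl in key_map}
    return DistanceFeatures(d_wt=d_wt, d_mt=d_mt, d_absdiff=d_abs)
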