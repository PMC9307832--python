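"""Synthetic test inputs: toy kinase structures and feature tables.

Everything the pipeline consumes can be generated here without network
access: small PDB files with a short peptide, an Mg2+ ion, an ANP-like
three-phosphate ligand, HELIX/SHEET records and a B-factor profile;
AAindex1 flat files carrying the packaged 57-accession manifest with
seeded synthetic values; ddG tables; and 18-column (or subset) feature
tables with two classes of tunable separability at the study's 50-row,
26/24 class balance.

The feature-table generator draws feature columns from standard
normals, forms logits through a known generating logistic model plus
Gaussian noise, and assigns class III to the rows with the largest
logits so that the requested class counts are exact while labels still
follow the generating model.  Separability is controlled by the ratio
of coefficient magnitude to noise scale; the defaults (|beta| ~ 1-1.5
per feature, unit noise) give strong but imperfect separation, the
regime a well-performing four-feature classifier occupies on a 50-row
curated set.  An optional ``margin`` widens the logit gap between the
classes for exactly-separable constructions.

All randomness flows from the spec seed through one named generator;
no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ONE_TO_THREE
from .features import DEFAULT_SUBSET
from .structure import Atom, StructureModel, write_pdb

DEFAULT_SEQUENCE = "GAVLKDEFST"


class FixtureError(ValueError):
    pass


@dataclass
class ToyStructureSpec:
    """Recipe for a small, valid, parseable kinase-like PDB file."""

    n_residues: int = 10
    sequence: str = DEFAULT_SEQUENCE
    start_position: int = 460
    helix_spans: list[tuple[int, int]] = field(default_factory=list)
    sheet_spans: list[tuple[int, int]] = field(default_factory=list)
    mg_position: tuple[float, float, float] = (0.0, 8.0, 0.0)
    anp_phosphate_positions: tuple[tuple[float, float, float], ...] = (
        (2.0, 10.0, 0.0), (4.0, 11.0, 0.0), (6.0, 12.0, 0.0))
    b_factor_profile: list[float] | None = None
    include_mg: bool = True
    include_anp: bool = True
    include_dfg_residue: bool = True  # add an ASP numbered 594 for chain selection
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.sequence) < self.n_residues:
            self.sequence = (self.sequence * (self.n_residues // len(self.sequence) + 1))
        self.sequence = self.sequence[: self.n_residues]


def _residue_atoms(aa: str, origin: np.ndarray, b: float,
                   rng: np.random.Generator, jitter: float) -> list[Atom]:
    """Minimal residue geometry: backbone N/CA/C/O plus CB (HA2/HA3 for Gly)."""
    def place(name: str, element: str, offset) -> Atom:
        pos = origin + np.asarray(offset, dtype=float)
        if jitter:
            pos = pos + rng.normal(0.0, jitter, 3)
        return Atom(name=name, element=element, coords=tuple(pos), b_factor=b)

    atoms = [
        place("N", "N", (-1.2, 0.6, 0.0)),
        place("CA", "C", (0.0, 0.0, 0.0)),
        place("C", "C", (1.3, 0.6, 0.0)),
        place("O", "O", (1.4, 1.8, 0.0)),
    ]
    if aa == "G":
        atoms.append(place("HA2", "H", (-0.4, -0.6, 0.85)))
        atoms.append(place("HA3", "H", (-0.4, -0.6, -0.85)))
    else:
        atoms.append(place("CB", "C", (-0.5, -1.0, 1.0)))
        if aa in "LIKRFYWEDQNMH":  # a second side-chain atom for bulkier residues
            atoms.append(place("CG", "C", (-0.3, -2.3, 1.4)))
    return atoms


def make_toy_model(spec: ToyStructureSpec) -> StructureModel:
    """Build the in-memory StructureModel described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    b_profile = spec.b_factor_profile
    if b_profile is None:
        b_profile = [20.0 + 2.0 * i for i in range(spec.n_residues)]
    if len(b_profile) < spec.n_residues:
        raise FixtureError("b_factor_profile shorter than n_residues")

    residues: dict[int, tuple[str, list[Atom]]] = {}
    for i, aa in enumerate(spec.sequence):
        pos = spec.start_position + i
        origin = np.array([3.8 * i, 0.0, 0.0])
        residues[pos] = (ONE_TO_THREE[aa],
                         _residue_atoms(aa, origin, b_profile[i], rng, spec.jitter))
    if spec.include_dfg_residue and 594 not in residues:
        origin = np.array([3.8 * spec.n_residues + 6.0, 0.0, 0.0])
        residues[594] = ("ASP",
                         _residue_atoms("D", origin, 25.0, rng, spec.jitter))

    het_groups: dict[str, list[Atom]] = {}
    if spec.include_mg:
        het_groups["MG"] = [Atom("MG", "MG", tuple(map(float, spec.mg_position)), 10.0)]
    if spec.include_anp:
        names = ("PA", "PB", "PG")
        het_groups["ANP"] = [
            Atom(n, "P", tuple(map(float, p)), 12.0)
            for n, p in zip(names, spec.anp_phosphate_positions)
        ] + [Atom("N3B", "N", (3.0, 10.5, 0.8), 12.0)]

    ss_spans = ([("helix", a, b) for a, b in spec.helix_spans]
                + [("sheet", a, b) for a, b in spec.sheet_spans])
    model = StructureModel(id=f"toy{spec.seed}", chain="A", residues=residues,
                           het_groups=het_groups, ss_spans=ss_spans)
    _check_clashes(model)
    return model


def _check_clashes(model: StructureModel, cutoff: float = 0.5) -> None:
    coords = []
    for _, atoms in model.residues.values():
        coords.extend(a.xyz for a in atoms)
    for atoms in model.het_groups.values():
        coords.extend(a.xyz for a in atoms)
    arr = np.asarray(coords)
    if len(arr) < 2:
        return
    from scipy.spatial.distance import pdist
    if pdist(arr).min() < cutoff:
        raise FixtureError(f"generated atoms closer than {cutoff} A")


def make_toy_pdb(spec: ToyStructureSpec, path: str | Path) -> Path:
    """Write the toy structure to a PDB file and return its path."""
    model = make_toy_model(spec)
    path = Path(path)
    write_pdb(model, path)
    return path


@dataclass
class SyntheticFeatureSpec:
    """Recipe for a labelled synthetic feature table."""

    n: int = 50
    class_balance: tuple[int, int] = (26, 24)  # (class II, class III)
    feature_names: tuple[str, ...] = DEFAULT_SUBSET
    true_coefficients: tuple[float, ...] = (1.5, -1.2, 1.0, 0.8)
    intercept: float = 0.0
    noise_scale: float = 1.0
    margin: float = 0.0  # minimum logit gap between the two classes
    seed: int = 0

    def __post_init__(self):
        if sum(self.class_balance) != self.n:
            raise FixtureError(
                f"class balance {self.class_balance} does not sum to n={self.n}")
        if min(self.class_balance) < 1:
            raise FixtureError("each class needs at least one row")
        if len(self.true_coefficients) != len(self.feature_names):
            raise FixtureError("one generating coefficient per feature required")


def make_feature_table(spec: SyntheticFeatureSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic feature table and class labels with exact class counts.

    Labels derive from the generating logistic model: class III goes to
    the rows with the highest noisy logits, so coefficient magnitude vs
    ``noise_scale`` tunes separability (zero coefficients give labels
    independent of the features; zero noise with large coefficients
    gives a linearly separable set).
    """
    rng = np.random.default_rng(spec.seed)
    X = rng.normal(0.0, 1.0, size=(spec.n, len(spec.feature_names)))
    beta = np.asarray(spec.true_coefficients, dtype=float)
    logits = spec.intercept + X @ beta + rng.normal(0.0, spec.noise_scale, spec.n)
    if np.allclose(beta, 0.0) and spec.noise_scale == 0.0:
        logits = rng.normal(0.0, 1.0, spec.n)  # degenerate: pure chance labels
    n_ii, n_iii = spec.class_balance
    order = np.argsort(logits, kind="stable")
    labels = np.empty(spec.n, dtype=object)
    labels[order[:n_ii]] = "II"
    labels[order[n_ii:]] = "III"
    if spec.margin > 0.0 and not np.allclose(beta, 0.0):
        # widen the logit gap between the classes by displacing class III
        # rows along the coefficient direction, keeping labels consistent
        # with the generating model
        iii = labels == "III"
        gap = logits[iii].min() - logits[~iii].max()
        if gap < spec.margin:
            shift = (spec.margin - gap) * beta / float(beta @ beta)
            X[iii] += shift
    table = pd.DataFrame(X, columns=list(spec.feature_names))
    return table, pd.Series(labels, name="label")


def make_aaindex_file(path: str | Path, accessions: dict[str, str] | None = None,
                      seed: int = 0) -> Path:
    """Write a synthetic AAindex1 flat file for the packaged manifest.

    Values are seeded uniform draws formatted in the standard H/I
    record layout.
    """
    from .aaindex import load_manifest, _I_ROW1

    accessions = accessions or load_manifest()
    rng = np.random.default_rng(abs(seed))
    lines: list[str] = []
    for acc in accessions:
        vals = rng.uniform(-3.0, 3.0, 20)
        lines.append(f"H {acc}")
        lines.append("D synthetic property values for testing")
        lines.append("I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V")
        row1 = "  ".join(f"{v:7.3f}" for v in vals[:10])
        row2 = "  ".join(f"{v:7.3f}" for v in vals[10:])
        lines.append(f"  {row1}")
        lines.append(f"  {row2}")
        lines.append("//")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def make_ddg_table(path: str | Path, mutations, structure_ids: list[str],
                   seed: int = 0) -> Path:
    """Seeded synthetic ddG TSV covering every (structure, mutation) pair."""
    rng = np.random.default_rng(seed)
    rows = []
    for sid in structure_ids:
        for m in mutations:
            rows.append({"structure_id": sid, "position": m.position,
                         "wt": m.wt_aa, "mt": m.mt_aa,
                         "ddg": round(float(rng.normal(1.0, 1.5)), 3)})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def make_fixture_dir(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a self-contained test-data directory.

    Contents: three toy PDB structures (one ineligible, lacking ANP), a
    synthetic AAindex file for the packaged manifest, a ddG table for
    the packaged mutation list, and a synthetic labelled feature table.
    """
    from .datasets import load_mutations, packaged_mutation_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    specs = {
        "toy_a.pdb": ToyStructureSpec(seed=seed, helix_spans=[(462, 465)]),
        "toy_b.pdb": ToyStructureSpec(seed=seed + 1, sheet_spans=[(461, 463)],
                                      jitter=0.05),
        "toy_noanp.pdb": ToyStructureSpec(seed=seed + 2, include_anp=False),
    }
    (out_dir / "structures").mkdir(exist_ok=True)
    for name, spec in specs.items():
        paths[name] = make_toy_pdb(spec, out_dir / "structures" / name)
    paths["aaindex.txt"] = make_aaindex_file(out_dir / "aaindex.txt", seed=seed)
    mutations = load_mutations(packaged_mutation_table())
    paths["ddg.tsv"] = make_ddg_table(out_dir / "ddg.tsv", mutations,
                                      ["toy0", "toy1"], seed=seed)
    table, labels = make_feature_table(SyntheticFeatureSpec(seed=seed))
    features = table.copy()
    features["label"] = labels
    feat_path = out_dir / "features.tsv"
    features.to_csv(feat_path, sep="\t", index=False)
    paths["features.tsv"] = feat_path
    return paths
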