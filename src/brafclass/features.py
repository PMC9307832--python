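"""Assembly of the 18-feature vector for each mutation.

Sixteen features come from the structures (ddG, side-chain SASA,
secondary-structure context, normalized B-factor, and the twelve
distance features: WT, mutant and absolute-difference shortest
heavy-atom distances to Mg2+, P-alpha, P-beta and P-gamma) and two are
the condensed AAindex city-block distances.  Structural features are
computed per structure and aggregated over every eligible structure in
which the position is resolved: arithmetic mean for continuous values,
majority vote for the secondary-structure code (ties fall back to
coil).  Absolute distance differences are taken per structure and then
averaged, so the aggregated |WT - MT| columns need not equal the
difference of the aggregated WT and MT columns.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aaindex import PropertyScale, condense
from .datasets import MutationRecord
from .ddg import DdgProvider, NullDdg
from .struct_features import (RadiusTable, distance_features, normalized_b,
                              sasa_side_chain, ss_context)
from .structure import StructureModel, key_atoms

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "ddg", "sasa", "struct", "norm_b",
    "wt_dMg", "mt_dMg", "absdiff_dMg",
    "wt_dPa", "mt_dPa", "absdiff_dPa",
    "wt_dPb", "mt_dPb", "absdiff_dPb",
    "wt_dPg", "mt_dPg", "absdiff_dPg",
    "d_struct", "d_physchem",
)

STRUCTURAL_FEATURE_NAMES = FEATURE_NAMES[:16]
CONDENSED_FEATURE_NAMES = FEATURE_NAMES[16:]

#: feature subsets evaluated in the model-selection workflow.  "best"
#: is the published four-feature model; the others are representative
#: combinations drawn from the pool of mainly-used features (ddG, SASA,
#: Mg distances, WT phosphate distances).
FEATURE_SUBSETS: dict[str, tuple[str, ...]] = {
    "best": ("sasa", "struct", "wt_dPa", "wt_dPg"),
    "model2": ("ddg", "sasa", "wt_dPa", "wt_dPg"),
    "model3": ("sasa", "struct", "wt_dMg", "wt_dPg"),
    "model4": ("ddg", "sasa", "wt_dMg", "mt_dMg", "wt_dPg"),
    "model5": ("sasa", "struct", "norm_b", "wt_dPa", "wt_dPg"),
    "all": FEATURE_NAMES,
}

DEFAULT_SUBSET = FEATURE_SUBSETS["best"]


class FeaturizationError(ValueError):
    pass


@dataclass(frozen=True)
class StructurePair:
    """A wild-type model and the matching (possibly identical) mutant model.

    When mutant models are unavailable (no FoldX run) the wild-type
    model stands in for both, which zeroes the absolute-difference
    distance features for that structure.
    """

    wt: StructureModel
    mt: StructureModel

    @classmethod
    def identity(cls, model: StructureModel) -> "StructurePair":
        return cls(wt=model, mt=model)


def _nanmean(values: list[float]) -> float:
    arr = np.asarray(values, dtype=float)
    good = arr[np.isfinite(arr)]
    return float(good.mean()) if good.size else float("nan")


def _majority_struct(codes: list[int]) -> int:
    if not codes:
        return 0
    counts = Counter(codes)
    top = counts.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return 0  # tie -> coil
    return top[0][0]


def featurize(
    mutation: MutationRecord,
    pairs: list[StructurePair],
    ddg_provider: DdgProvider | None = None,
    scales: list[PropertyScale] | None = None,
    radii: RadiusTable | None = None,
    sasa_points: int = 960,
) -> dict[str, float]:
    """Compute the named 18-feature vector for one mutation.

    Raises :class:`FeaturizationError` if the position is resolved in
    none of the supplied structures.
    """
    ddg_provider = ddg_provider or NullDdg()
    radii = radii or RadiusTable.packaged()

    per_struct: dict[str, list[float]] = {name: [] for name in FEATURE_NAMES}
    struct_codes: list[int] = []
    resolved_anywhere = False
    for pair in pairs:
        wt_model = pair.wt
        if wt_model.residue(mutation.position) is None:
            continue
        resolved_anywhere = True
        keys = key_atoms(wt_model)
        per_struct["ddg"].append(ddg_provider.ddg(wt_model.id, mutation))
        per_struct["sasa"].append(
            sasa_side_chain(wt_model, mutation.position, radii=radii,
                            n_points=sasa_points))
        struct_codes.append(ss_context(wt_model, mutation.position))
        per_struct["norm_b"].append(normalized_b(wt_model, mutation.position))
        dist = distance_features(wt_model, pair.mt, mutation.position, keys)
        for lbl in ("Mg", "Pa", "Pb", "Pg"):
            per_struct[f"wt_d{lbl}"].append(dist.d_wt[lbl])
            per_struct[f"mt_d{lbl}"].append(dist.d_mt[lbl])
            per_struct[f"absdiff_d{lbl}"].append(dist.d_absdiff[lbl])

    if not resolved_anywhere:
        tried = ", ".join(p.wt.id for p in pairs) or "none"
        raise FeaturizationError(
            f"position {mutation.position} resolved in no structure "
            f"(tried: {tried})")

    vector: dict[str, float] = {}
    for name in STRUCTURAL_FEATURE_NAMES:
        if name == "struct":
            vector[name] = float(_majority_struct(struct_codes))
        else:
            vector[name] = _nanmean(per_struct[name])

    if scales is not None:
        cond = condense(mutation.wt_aa, mutation.mt_aa, scales)
        vector["d_struct"] = cond.d_struct
        vector["d_physchem"] = cond.d_physchem
    else:
        vector["d_struct"] = float("nan")
        vector["d_physchem"] = float("nan")

    assert tuple(vector) == FEATURE_NAMES
    return vector


def featurize_table(
    mutations: list[MutationRecord],
    pairs_by_mutation: dict[str, list[StructurePair]] | list[StructurePair],
    ddg_provider: DdgProvider | None = None,
    scales: list[PropertyScale] | None = None,
    radii: RadiusTable | None = None,
    sasa_points: int = 960,
) -> pd.DataFrame:
    """Feature table for a mutation list: key columns then the 18 features.

    ``pairs_by_mutation`` may be a single structure-pair list shared by
    every mutation, or a dict keyed by mutation name (e.g. ``G469A``)
    for FoldX-built per-mutation models.
    """
    radii = radii or RadiusTable.packaged()
    rows = []
    for mut in mutations:
        if isinstance(pairs_by_mutation, dict):
            pairs = pairs_by_mutation.get(mut.name, [])
        else:
            pairs = pairs_by_mutation
        vec = featurize(mut, pairs, ddg_provider=ddg_provider, scales=scales,
                        radii=radii, sasa_points=sasa_points)
        row = {"position": mut.position, "wt": mut.wt_aa, "mt": mut.mt_aa,
               "label": mut.label or ""}
        row.update(vec)
        rows.append(row)
    return pd.DataFrame(rows)


def select_features(table: pd.DataFrame, subset: list[str] | tuple[str, ...]) -> pd.DataFrame:
    """Project the feature table onto a named feature subset."""
    unknown = [name for name in subset if name not in FEATURE_NAMES]
    if unknown:
        raise FeaturizationError(
            f"unknown feature name(s) {unknown}; valid names: "
            f"{list(FEATURE_NAMES)}")
    missing = [name for name in subset if name not in table.columns]
    if missing:
        raise FeaturizationError(f"feature(s) {missing} absent from table")
    return table.loc[:, list(subset)]


def resolve_subset(spec: str) -> tuple[str, ...]:
    """Resolve a subset argument: a named preset or a comma-separated list."""
    if spec in FEATURE_SUBSETS:
        return tuple(FEATURE_SUBSETS[spec])
    names = tuple(s.strip() for s in spec.split(",") if s.strip())
    unknown = [n for n in names if n not in FEATURE_NAMES]
    if unknown:
        raise FeaturizationError(
            f"unknown feature name(s) {unknown}; valid names: "
            f"{list(FEATURE_NAMES)} or presets {list(FEATURE_SUBSETS)}")
    return names
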