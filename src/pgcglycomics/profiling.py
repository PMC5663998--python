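"""Sample-level relative-abundance profiles and structural feature summaries.

Glycans are quantified by relative EIC peak integration: within each glycan
class (N or O) every sample's areas are normalized to 100%.  Structures are
grouped into the five canonical N-glycan types (high mannose, hybrid,
complex neutral, complex sialylated, paucimannose) and summarized per
sample by sialylation degree, antennarity, bisecting and LacdiNAc content
and alpha2,6 fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .fragments import find_core, _antennae, _antenna_is_complete
from .masses import Composition, GlycanTopology

GLYCAN_TYPES = (
    "high_mannose",
    "hybrid",
    "complex_neutral",
    "complex_sialylated",
    "paucimannose",
)

#: Structure-table columns consumed by :func:`summarize_features`.
STRUCTURE_COLUMNS = (
    "glycan_id",
    "composition",
    "glycan_type",
    "n_neu5ac",
    "antennae",
    "bisecting",
    "lacdinac",
)


@dataclass
class GlycanProfile:
    """Sample x glycan relative-abundance matrix (%) with metadata.

    ``abundances`` rows are samples, columns glycan ids; every row sums to
    100 within a glycan class.  ``metadata`` is indexed like the rows and
    carries at least ``diagnosis`` (OC/PC) and/or ``site``
    (ovary/omentum/peritoneum).
    """

    abundances: pd.DataFrame
    metadata: pd.DataFrame
    glycan_class: str = "N"

    def __post_init__(self) -> None:
        missing = self.abundances.index.difference(self.metadata.index)
        if len(missing):
            raise ValueError(f"metadata missing for samples: {list(missing)}")
        if (self.abundances.values < 0).any():
            raise ValueError("relative abundances must be non-negative")

    def group_labels(self, grouping: str) -> pd.Series:
        if grouping not in self.metadata.columns:
            raise ValueError(f"metadata column {grouping!r} not present")
        return self.metadata.loc[self.abundances.index, grouping]


def build_profile(
    areas: pd.DataFrame,
    metadata: pd.DataFrame,
    glycan_class: str = "N",
    merge_isomers: bool = True,
) -> GlycanProfile:
    """Normalize per-sample EIC areas (samples x glycans) to 100%.

    Isomer columns named ``"<glycan_id>@<isomer>"`` are summed into their
    parent glycan id when ``merge_isomers`` is set (isomer-level areas are
    kept by the caller for isomer metrics).  Samples whose total area is
    zero are rejected by name.
    """
    df = areas.astype(float).copy()
    if merge_isomers:
        parents = [c.split("@")[0] for c in df.columns]
        df = df.T.groupby(parents, sort=False).sum().T
    totals = df.sum(axis=1)
    zero = totals[totals <= 0].index.tolist()
    if zero:
        raise ValueError(f"samples with zero total area: {zero}")
    norm = df.div(totals, axis=0) * 100.0
    return GlycanProfile(abundances=norm, metadata=metadata, glycan_class=glycan_class)


def classify_glycan_type(
    comp: Composition, topo: Optional[GlycanTopology] = None
) -> str:
    """Assign one of the five N-glycan types to a composition.

    Rule precedence: paucimannose (HexNAc 2, no sialic acid, truncated
    mannoses: Hex <= 3, or Hex 4 when core-fucosylated), then high mannose
    (HexNAc 2, Hex 4-9, no fucose, no sialic acid), then hybrid (HexNAc 3
    with an unsubstituted mannose arm when a topology is available;
    compositional fallback HexNAc 3 and Hex >= 4), then complex, split into
    neutral vs sialylated by Neu5Ac count.
    """
    if comp.glycan_class != "N":
        raise ValueError("glycan-type classification applies to N-glycans only")
    if comp.hexnac == 2 and comp.neu5ac == 0:
        if comp.hex <= 3 or (comp.hex == 4 and comp.dhex > 0):
            return "paucimannose"
        if 4 <= comp.hex <= 9 and comp.dhex == 0:
            return "high_mannose"
    if comp.hexnac == 3:
        if topo is not None:
            core = find_core(topo)
            if core is not None:
                for arm in (core.arm3, core.arm6):
                    if arm is not None and not any(
                        c.identity == "GlcNAc" for c in arm.children
                    ):
                        return "hybrid"
            # topology present but no bare arm: fall through to complex
        elif comp.hex >= 4:
            return "hybrid"
    return "complex_sialylated" if comp.neu5ac > 0 else "complex_neutral"


def count_antennae(topo: GlycanTopology) -> int:
    """Count complete LacNAc/LacdiNAc antennae on the core alpha-Man arms.

    An antenna requires the full Gal-GlcNAc (or GalNAc-GlcNAc) disaccharide;
    the bisecting GlcNAc never counts, and sialylation or fucosylation of an
    antenna does not change the count.
    """
    core = find_core(topo)
    if core is None:
        return 0
    return sum(1 for a in _antennae(core) if _antenna_is_complete(a))


@dataclass
class FeatureSummary:
    """Per-sample structural feature percentages."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def summarize_features(
    profile: GlycanProfile,
    structures: pd.DataFrame,
    alpha26: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Sum relative abundances by structural feature membership.

    ``structures`` maps every glycan id of the profile to its type and motif
    flags (see STRUCTURE_COLUMNS).  A glycan may contribute to several
    features (e.g. bisecting and sialylated).  Sialylation-degree
    percentages (mono/di/tri) are expressed over sialylated species only.
    ``alpha26`` optionally supplies per-glycan alpha2,6 area fractions from
    the isomer assignment stage, yielding an abundance-weighted
    ``alpha26_fraction`` column.
    """
    st = structures.set_index("glycan_id") if "glycan_id" in structures.columns else structures
    unmapped = [g for g in profile.abundances.columns if g not in st.index]
    if unmapped:
        raise ValueError(f"glycan ids without structure mapping: {unmapped}")
    st = st.loc[profile.abundances.columns]
    ab = profile.abundances

    def total_for(mask: pd.Series) -> pd.Series:
        cols = mask[mask].index
        return ab[cols].sum(axis=1)

    out = pd.DataFrame(index=ab.index)
    for gtype in GLYCAN_TYPES:
        out[gtype] = total_for(st["glycan_type"] == gtype)
    sial = st["n_neu5ac"] > 0
    sial_total = total_for(sial)
    out["sialylated_total"] = sial_total
    for name, k in (("monosialylated", 1), ("disialylated", 2), ("trisialylated", 3)):
        num = total_for(st["n_neu5ac"] == k)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = np.where(sial_total > 0, 100.0 * num / sial_total, np.nan)
    for name, k in (("biantennary", 2), ("triantennary", 3), ("tetraantennary", 4)):
        out[name] = total_for(st["antennae"] == k)
    out["bisecting_total"] = total_for(st["bisecting"].astype(bool))
    out["lacdinac_total"] = total_for(st["lacdinac"].astype(bool))
    if alpha26 is not None:
        covered = [g for g in ab.columns if g in alpha26]
        weights = ab[covered]
        denom = weights.sum(axis=1)
        num = weights.mul(pd.Series(alpha26)[covered], axis=1).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out["alpha26_fraction"] = np.where(denom > 0, num / denom, np.nan)
    return out
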