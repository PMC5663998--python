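"""Synthetic cohorts, EIC traces and MS2 spectra for the glycomics pipeline.

The study's per-sample tissue measurements were not deposited, so every
pipeline stage is exercised on synthetic data carrying the statistical
structure the analysis assumes: two- or three-group cohorts of
compositional glycan profiles (percent of class total), isomer EIC peak
patterns with the alpha2,6-before-alpha2,3 PGC elution order, and MS2 peak
lists containing the predicted fragments of a known topology plus noise.

The default preset encodes the published cohort conditions: group sizes
14/14 (diagnosis) and 14/11/3 (sampling site); LacdiNAc-type N-glycans at
2.775 +/- 2.005 % of total N-glycans in ovarian cancer vs 0.1247 +/- 1.312 %
in peritoneal cancer, with the anchor sialyl-LacdiNAc species present in
93% of OC vs 22% of PC samples; total sialylation in the 66.3-68.5% band;
alpha2,6 shares of ~0.59 (hybrid) and ~0.65 (complex) on the isomeric
backbones.

Sampling model: the LacdiNAc block total is drawn as Bernoulli(presence) x
Gamma, moment-matched so its *unconditional* mean and SD equal the preset
values exactly; the remaining abundance is split over the background panel
by independent Gamma draws with a common scale, i.e. a Dirichlet split
whose expected shares equal the preset means exactly.  Glycans are treated
as independent apart from the compositional closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .chromatography import EICTrace
from .fragments import Spectrum, generate_fragments
from .masses import GlycanTopology, mz, neutral_mass, parse_composition
from .profiling import classify_glycan_type

# ---------------------------------------------------------------------------
# Panel definition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelGlycan:
    """One glycan mass of the synthetic panel.

    ``glycan_id`` is the printed (observed, low-resolution) [M-2H]2- label;
    the theoretical m/z is recomputed from the composition at run time.
    ``mean_pct`` maps group label -> mean relative abundance (%).
    """

    glycan_id: str
    composition: str
    mean_pct: dict[str, float]
    antennae: int = 2
    bisecting: bool = False
    lacdinac: bool = False
    hybrid_isomeric: bool = False  # member of the hybrid isomeric backbone set
    complex_isomeric: bool = False

    def n_neu5ac(self) -> int:
        return parse_composition(self.composition, glycan_class="N").neu5ac


def _g(gid, comp, oc, pc, per=None, om=None, **kw) -> PanelGlycan:
    means = {"OC": oc, "PC": pc, "ovary": oc, "omentum": om if om is not None else pc,
             "peritoneum": per if per is not None else pc}
    return PanelGlycan(glycan_id=gid, composition=comp, mean_pct=means, **kw)


#: N-glycan panel. Means sum to 100 per group (the constructor rescales the
#: background so the LacdiNAc block keeps its stated mean exactly).
N_GLYCAN_PANEL: tuple[PanelGlycan, ...] = (
    # high mannose (antennae 0)
    _g("617.3", "(Hex)5(HexNAc)2", 5.0, 5.0, antennae=0),
    _g("698.3", "(Hex)6(HexNAc)2", 3.5, 3.5, antennae=0),
    _g("779.3", "(Hex)7(HexNAc)2", 2.5, 2.5, antennae=0),
    _g("860.3", "(Hex)8(HexNAc)2", 1.7, 1.9, antennae=0),
    _g("941.4", "(Hex)9(HexNAc)2", 0.8, 0.8, antennae=0),
    # paucimannose
    _g("543.2", "(Hex)3(HexNAc)2", 1.5, 1.5, antennae=0),
    _g("616.3", "(Hex)3(HexNAc)2(dHex)1", 2.0, 2.0, antennae=0),
    # complex neutral
    _g("739.3", "(Hex)3(HexNAc)4(dHex)1", 2.5, 3.8, antennae=0),
    _g("820.3", "(Hex)5(HexNAc)4", 3.275, 2.525),
    _g("893.3", "(Hex)5(HexNAc)4(dHex)1", 6.0, 5.5),
    # bisecting-type (share the structure table with fragment evidence)
    _g("913.9b", "(Hex)4(HexNAc)5(dHex)1", 1.5, 1.6, antennae=1, bisecting=True),
    _g("921.9", "(Hex)5(HexNAc)5", 0.9, 0.35, bisecting=True),
    _g("994.9", "(Hex)5(HexNAc)5(dHex)1", 1.5, 2.6, bisecting=True),
    _g("986.5", "(Hex)4(HexNAc)5(Neu5Ac)1", 0.4, 0.35, antennae=1, bisecting=True),
    _g("1067.5", "(Hex)5(HexNAc)5(Neu5Ac)1", 0.45, 0.4, bisecting=True),
    _g("1140.4", "(Hex)5(HexNAc)5(dHex)1(Neu5Ac)1", 1.2, 1.1, bisecting=True),
    _g("1286.0", "(Hex)5(HexNAc)5(dHex)1(Neu5Ac)2", 0.9, 0.45, bisecting=True),
    # hybrid monosialylated isomeric backbones
    _g("783.3", "(Hex)4(HexNAc)3(Neu5Ac)1", 1.3, 1.3, antennae=1, hybrid_isomeric=True),
    _g("856.3", "(Hex)4(HexNAc)3(dHex)1(Neu5Ac)1", 2.2, 1.4, antennae=1, hybrid_isomeric=True),
    _g("864.3", "(Hex)5(HexNAc)3(Neu5Ac)1", 1.2, 1.2, antennae=1, hybrid_isomeric=True),
    _g("937.3", "(Hex)5(HexNAc)3(dHex)1(Neu5Ac)1", 3.2, 1.7, antennae=1, hybrid_isomeric=True),
    _g("945.3", "(Hex)6(HexNAc)3(Neu5Ac)1", 2.2, 2.2, antennae=1, hybrid_isomeric=True),
    # complex mono/disialylated
    _g("957.8", "(Hex)4(HexNAc)4(dHex)1(Neu5Ac)1", 2.0, 2.0, complex_isomeric=True),
    _g("965.9", "(Hex)5(HexNAc)4(Neu5Ac)1", 11.5, 11.5, complex_isomeric=True),
    _g("1038.9", "(Hex)5(HexNAc)4(dHex)1(Neu5Ac)1", 8.5, 10.5, complex_isomeric=True),
    _g("1111.4", "(Hex)5(HexNAc)4(Neu5Ac)2", 16.0, 17.2, complex_isomeric=True),
    _g("1184.5", "(Hex)5(HexNAc)4(dHex)1(Neu5Ac)2", 9.0, 9.5, complex_isomeric=True),
    # branched tri-/tetra-antennary
    _g("1148.5", "(Hex)6(HexNAc)5(Neu5Ac)1", 0.9, 1.5, per=2.1, antennae=3),
    _g("1221.5", "(Hex)6(HexNAc)5(dHex)1(Neu5Ac)1", 0.7, 0.8, antennae=3),
    _g("1294.0", "(Hex)6(HexNAc)5(Neu5Ac)2", 1.0, 1.8, per=2.5, antennae=3),
    _g("1440.0", "(Hex)6(HexNAc)5(Neu5Ac)3", 1.3, 0.9, antennae=3),
    _g("1550.1", "(Hex)7(HexNAc)6(dHex)1(Neu5Ac)2", 0.6, 0.6, antennae=4),
    # LacdiNAc block (block totals below override the absolute scale)
    _g("913.9l", "(Hex)4(HexNAc)5(dHex)1", 0.275, 0.275, antennae=2, lacdinac=True),
    _g("934.4", "(Hex)3(HexNAc)6(dHex)1", 0.3, 0.3, antennae=2, lacdinac=True),
    _g("1059.4", "(Hex)4(HexNAc)5(dHex)1(Neu5Ac)1", 0.6, 0.6, antennae=2, lacdinac=True),
    _g("1079.9", "(Hex)3(HexNAc)6(dHex)1(Neu5Ac)1", 0.4, 0.4, antennae=2, lacdinac=True),
    _g("1205.0", "(Hex)4(HexNAc)5(dHex)1(Neu5Ac)2", 1.2, 1.2, antennae=2, lacdinac=True),
)

#: LacdiNAc block totals and presence probabilities, and the alpha2,6 splits.
PRESET_PARAMETERS = {
    "lacdinac_mean": {"OC": 2.775, "PC": 0.1247, "ovary": 2.775,
                      "omentum": 0.35, "peritoneum": 0.1247},
    "lacdinac_sd": {"OC": 2.005, "PC": 1.312, "ovary": 2.005,
                    "omentum": 1.312, "peritoneum": 1.312},
    # presence of the anchor species m/z 1205.0 (defines block presence)
    "lacdinac_presence": {"OC": 0.93, "PC": 0.22, "ovary": 0.93,
                          "omentum": 0.30, "peritoneum": 0.22},
    # presence of the non-anchor LacdiNAc members given the block is present
    "member_presence": {"OC": 0.85, "PC": 0.30, "ovary": 0.85,
                        "omentum": 0.35, "peritoneum": 0.30},
    "alpha26_hybrid": 0.59,
    "alpha26_complex": 0.65,
    # Dirichlet concentration factor for the background split (alpha = c * mean%)
    "background_concentration": 2.0,
}

DIAGNOSIS_GROUPS = (("OC", 14), ("PC", 14))
SITE_GROUPS = (("ovary", 14), ("omentum", 11), ("peritoneum", 3))


@dataclass
class CohortDesign:
    """Everything :func:`generate_cohort` needs; the seed fixes the output."""

    groups: tuple[tuple[str, int], ...] = DIAGNOSIS_GROUPS
    panel: tuple[PanelGlycan, ...] = N_GLYCAN_PANEL
    parameters: dict = field(default_factory=lambda: dict(PRESET_PARAMETERS))
    grouping_column: str = "diagnosis"
    seed: int = 0

    def lacdinac_ids(self) -> list[str]:
        return [g.glycan_id for g in self.panel if g.lacdinac]

    def background(self) -> list[PanelGlycan]:
        return [g for g in self.panel if not g.lacdinac]


def diagnosis_design(seed: int = 0) -> CohortDesign:
    return CohortDesign(groups=DIAGNOSIS_GROUPS, grouping_column="diagnosis", seed=seed)


def site_design(seed: int = 0) -> CohortDesign:
    return CohortDesign(groups=SITE_GROUPS, grouping_column="site", seed=seed)


def structure_table(panel: Sequence[PanelGlycan] = N_GLYCAN_PANEL) -> pd.DataFrame:
    """Structure table (glycan_id -> composition, type, motif flags)."""
    rows = []
    for g in panel:
        comp = parse_composition(g.composition, glycan_class="N")
        rows.append(
            {
                "glycan_id": g.glycan_id,
                "composition": g.composition,
                "theoretical_mz2": round(mz(neutral_mass(comp), 2), 4),
                "glycan_type": classify_glycan_type(comp),
                "n_neu5ac": comp.neu5ac,
                "antennae": g.antennae,
                "bisecting": g.bisecting,
                "lacdinac": g.lacdinac,
            }
        )
    return pd.DataFrame(rows)


def _block_gamma_params(mean: float, sd: float, presence: float) -> tuple[float, float]:
    """Shape/scale of the conditional Gamma so the unconditional Bernoulli x
    Gamma mixture has exactly the requested mean and SD."""
    mc = mean / presence
    var_c = (sd**2 + mean**2) / presence - mc**2
    var_c = max(var_c, 1e-6)
    shape = mc**2 / var_c
    scale = var_c / mc
    return shape, scale


def generate_cohort(design: CohortDesign, seed: Optional[int] = None):
    """Draw a cohort of compositional profiles.

    Returns ``(areas, metadata)`` where ``areas`` rows sum to 100 (profiles
    are generated directly on the percent scale).  Per sample: the LacdiNAc
    block total is Bernoulli(presence) x Gamma (moment-matched); detected
    block members split it Dirichlet-wise (the anchor species 1205.0 is
    always present when the block is); the background panel splits the
    remaining 100 - L by a Dirichlet draw whose expected shares equal the
    preset means.
    """
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    pars = design.parameters
    ldn = [g for g in design.panel if g.lacdinac]
    bg = design.background()
    conc = pars["background_concentration"]

    rows = []
    meta_rows = []
    sample_idx = 0
    for group, n in design.groups:
        block_mean = pars["lacdinac_mean"][group]
        block_sd = pars["lacdinac_sd"][group]
        presence = pars["lacdinac_presence"][group]
        member_p = pars["member_presence"][group]
        shape, scale = _block_gamma_params(block_mean, block_sd, presence)
        ldn_weights = np.array([g.mean_pct[group] for g in ldn], dtype=float)
        ldn_weights = ldn_weights / ldn_weights.sum()
        bg_means = np.array([g.mean_pct[group] for g in bg], dtype=float)

        for _ in range(n):
            for _attempt in range(100):
                present = rng.random() < presence
                L = float(np.clip(rng.gamma(shape, scale), 0, 95.0)) if present else 0.0
                # split the block over detected members; anchor always detected
                member_mask = rng.random(len(ldn)) < member_p
                anchor = next(i for i, g in enumerate(ldn) if g.glycan_id == "1205.0")
                member_mask[anchor] = True
                ldn_part = np.zeros(len(ldn))
                if L > 0:
                    alpha = ldn_weights[member_mask] * 10.0
                    split = rng.gamma(np.maximum(alpha, 1e-3), 1.0)
                    if split.sum() <= 0:
                        continue
                    ldn_part[member_mask] = L * split / split.sum()
                # background Dirichlet split of the remainder
                bg_draw = rng.gamma(np.maximum(bg_means * conc, 1e-3), 1.0)
                if bg_draw.sum() <= 0:
                    continue
                bg_part = (100.0 - L) * bg_draw / bg_draw.sum()
                break
            else:
                raise RuntimeError("failed to draw a nonzero sample after 100 attempts")
            values = {}
            for g, v in zip(bg, bg_part):
                values[g.glycan_id] = v
            for g, v in zip(ldn, ldn_part):
                values[g.glycan_id] = v
            rows.append(values)
            meta_rows.append({design.grouping_column: group})
            sample_idx += 1

    index = [f"S{i+1:03d}" for i in range(sample_idx)]
    areas = pd.DataFrame(rows, index=index)[[g.glycan_id for g in design.panel]]
    metadata = pd.DataFrame(meta_rows, index=index)
    return areas, metadata


# ---------------------------------------------------------------------------
# EIC traces
# ---------------------------------------------------------------------------

def generate_eic(
    glycan_id: str,
    split: Sequence[float],
    rt_centers: Sequence[float],
    total_area: float = 1.0,
    width_min: float = 0.25,
    noise: float = 0.0,
    rt_range: tuple[float, float] = (30.0, 70.0),
    n_points: int = 1200,
    seed: int = 0,
) -> tuple[EICTrace, list[tuple[float, float]]]:
    """Sum-of-Gaussians EIC with optional white noise.

    ``split`` fractions must sum to 1; ``rt_centers`` are the isomer apexes
    in minutes, listed in elution order (the alpha2,6-first convention is
    the caller's responsibility and holds for the presets).  Returns the
    trace plus the ground-truth (rt, area) list.
    """
    split = np.asarray(split, dtype=float)
    if split.size and abs(split.sum() - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    if len(split) != len(rt_centers):
        raise ValueError("split and rt_centers must have the same length")
    rng = np.random.default_rng(seed)
    rt = np.linspace(rt_range[0], rt_range[1], n_points)
    y = np.zeros_like(rt)
    truth = []
    for frac, center in zip(split, rt_centers):
        area = total_area * frac
        y += area / (width_min * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((rt - center) / width_min) ** 2
        )
        truth.append((float(center), float(area)))
    if noise > 0:
        y = np.clip(y + rng.normal(0.0, noise, size=y.shape), 0.0, None)
    return EICTrace(glycan_id=glycan_id, rt=rt, intensity=y), truth


# ---------------------------------------------------------------------------
# MS2 spectra
# ---------------------------------------------------------------------------

def generate_spectrum(
    topology: GlycanTopology,
    precursor_charge: int = 2,
    jitter_sd: float = 0.0,
    decoy_rate: float = 0.0,
    seed: int = 0,
) -> Spectrum:
    """Theoretical fragment spectrum with m/z jitter and uniform decoys.

    Fragment m/z values are jittered N(0, jitter_sd^2); random intensities
    in (0.1, 1]; ``decoy_rate`` adds that fraction of extra uniform peaks
    over the fragment m/z range.
    """
    rng = np.random.default_rng(seed)
    ions = generate_fragments(topology)
    peaks = []
    for ion in ions:
        mz_obs = ion.theoretical_mz + (rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0)
        peaks.append((float(mz_obs), float(rng.uniform(0.1, 1.0))))
    n_decoys = int(round(decoy_rate * len(ions)))
    if n_decoys:
        lo = min(p[0] for p in peaks)
        hi = max(p[0] for p in peaks)
        for _ in range(n_decoys):
            peaks.append((float(rng.uniform(lo, hi)), float(rng.uniform(0.05, 0.5))))
    from .masses import topology_neutral_mass

    prec = mz(topology_neutral_mass(topology), precursor_charge)
    return Spectrum(
        precursor_mz=prec,
        precursor_charge=precursor_charge,
        peaks=peaks,
        title=f"synthetic {topology.name or ''}".strip(),
    )
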