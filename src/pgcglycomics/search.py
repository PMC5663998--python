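"""GlycoMod-style monosaccharide composition search.

Deconvoluted negative-mode precursor ions are assigned to candidate
monosaccharide compositions by exhaustive enumeration over a bounded integer
lattice of class counts, keeping candidates whose theoretical neutral mass
falls within the search tolerance (default +/- 0.5 Da, applied on the
neutral-mass scale) of the observed neutral mass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .masses import (
    Composition,
    InvalidCompositionError,
    REDUCTION,
    RESIDUE_MASSES,
    SULFATE,
    WATER,
    mz,
    neutral_from_mz,
)

#: Default per-class count bounds; wide enough to cover tetra-antennary
#: trisialylated species, the largest glycans reported on these tissues.
DEFAULT_BOUNDS: dict[str, tuple[int, int]] = {
    "Hex": (0, 12),
    "HexNAc": (0, 8),
    "dHex": (0, 4),
    "Neu5Ac": (0, 4),
    "sulfate": (0, 2),
}

#: Refuse unbounded searches above this neutral mass (Da).
UNBOUNDED_MASS_CAP = 6000.0


@dataclass(frozen=True)
class SearchQuery:
    observed_mz: float
    charge: int
    tolerance: float = 0.5
    glycan_class: str = "N"
    reduced: bool = True
    count_bounds: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.charge not in (1, 2, 3):
            raise ValueError("charge must be 1, 2 or 3")
        for cls, (lo, hi) in self.count_bounds.items():
            if lo < 0 or lo > hi:
                raise ValueError(f"invalid bounds for {cls}: ({lo}, {hi})")

    def bounds(self) -> dict[str, tuple[int, int]]:
        merged = dict(DEFAULT_BOUNDS)
        merged.update(self.count_bounds)
        return merged


@dataclass(frozen=True)
class CompositionCandidate:
    composition: Composition
    theoretical_mz: float
    delta: float  # observed neutral - theoretical neutral, Da


def enumerate_compositions(query: SearchQuery) -> list[CompositionCandidate]:
    """Enumerate all compositions matching the observed ion.

    Exhaustive over the bounded lattice; results sorted by |delta| ascending,
    ties broken by fewer total residues, then lexicographic class counts.
    N-class searches require the Man3GlcNAc2 core (Hex >= 3, HexNAc >= 2);
    O-class searches require HexNAc >= 1 (the reducing-end GalNAc-ol).
    """
    target = neutral_from_mz(query.observed_mz, query.charge)
    if not query.count_bounds and target > UNBOUNDED_MASS_CAP:
        raise ValueError(
            f"neutral mass {target:.1f} Da exceeds the {UNBOUNDED_MASS_CAP:.0f} Da "
            "cap for a search with default bounds; supply count_bounds"
        )
    bounds = query.bounds()
    tol = query.tolerance
    candidates: list[CompositionCandidate] = []

    hex_lo, hex_hi = bounds["Hex"]
    nac_lo, nac_hi = bounds["HexNAc"]
    dhx_lo, dhx_hi = bounds["dHex"]
    sia_lo, sia_hi = bounds["Neu5Ac"]
    sul_lo, sul_hi = bounds["sulfate"]
    if query.glycan_class == "N":
        hex_lo = max(hex_lo, 3)
        nac_lo = max(nac_lo, 2)
    else:
        nac_lo = max(nac_lo, 1)

    m_hex = RESIDUE_MASSES["Hex"]
    m_nac = RESIDUE_MASSES["HexNAc"]
    m_dhx = RESIDUE_MASSES["dHex"]
    m_sia = RESIDUE_MASSES["Neu5Ac"]

    # Nested loops with early mass pruning: each level bails out once the
    # partial sum already overshoots target + tol.
    base = WATER + (REDUCTION if query.reduced else 0.0)
    for n_hex in range(hex_lo, hex_hi + 1):
        m1 = base + n_hex * m_hex
        if m1 > target + tol:
            break
        for n_nac in range(nac_lo, nac_hi + 1):
            m2 = m1 + n_nac * m_nac
            if m2 > target + tol:
                break
            for n_dhx in range(dhx_lo, dhx_hi + 1):
                m3 = m2 + n_dhx * m_dhx
                if m3 > target + tol:
                    break
                for n_sia in range(sia_lo, sia_hi + 1):
                    m4 = m3 + n_sia * m_sia
                    if m4 > target + tol:
                        break
                    for n_sul in range(sul_lo, sul_hi + 1):
                        total = m4 + n_sul * SULFATE
                        if total > target + tol:
                            break
                        if abs(target - total) > tol:
                            continue
                        try:
                            comp = Composition(
                                hex=n_hex,
                                hexnac=n_nac,
                                dhex=n_dhx,
                                neu5ac=n_sia,
                                sulfate=n_sul,
                                reduced=query.reduced,
                                glycan_class=query.glycan_class,
                            )
                        except InvalidCompositionError:
                            continue
                        candidates.append(
                            CompositionCandidate(
                                composition=comp,
                                theoretical_mz=mz(total, query.charge),
                                delta=target - total,
                            )
                        )

    candidates.sort(
        key=lambda c: (
            abs(c.delta),
            c.composition.total_residues,
            tuple(c.composition.counts.values()),
            c.composition.sulfate,
        )
    )
    return candidates
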