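"""Packaged worked-example fixtures.

Two synthetic MS2 peak lists for the N-glycan mass m/z 913.9 [M-2H]2-,
whose two PGC-resolved compositional isomers carry different motifs: the
early-eluting bisecting-GlcNAc structure (diagnosed by the D-221 ion at
508.1) and the late-eluting LacdiNAc structure (diagnosed by the antenna B
ion 405.1 and F ion 465.1).  Peak values are transcribed at one-decimal
(printed) precision from the engine's theoretical ions; intensities are
nominal.
"""

from __future__ import annotations

from importlib import resources

from .fragments import Spectrum
from .masses import GlycanTopology, parse_topology

#: Bisected, core-fucosylated: (Gal)1(GlcNAc)3(Fuc)1 + core; the 6-arm
#: antenna is the bare GlcNAc, giving the agalactosylated D-221 at 508.17.
TOPOLOGY_913_BISECTING = (
    "GlcNAc(b1-2)Man(a1-6)[Gal(b1-4)GlcNAc(b1-2)Man(a1-3)][GlcNAc(b1-4)]"
    "Man(b1-4)GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc-ol"
)

#: LacdiNAc-type, core-fucosylated: (Gal)1(GalNAc)1(GlcNAc)2(Fuc)1 + core.
TOPOLOGY_913_LACDINAC = (
    "GalNAc(b1-4)GlcNAc(b1-2)Man(a1-6)[Gal(b1-4)GlcNAc(b1-2)Man(a1-3)]"
    "Man(b1-4)GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc-ol"
)

PRECURSOR_913 = (913.9, 2)

_FILES = {
    "bisecting": "ms2_913.9_isomer1_bisecting.txt",
    "lacdinac": "ms2_913.9_isomer2_lacdinac.txt",
}


def fig4_spectrum(which: str) -> Spectrum:
    """Load one of the packaged 913.9 isomer peak lists ('bisecting'/'lacdinac')."""
    if which not in _FILES:
        raise KeyError(f"unknown fixture {which!r}; choose from {sorted(_FILES)}")
    text = resources.files("pgcglycomics.data").joinpath(_FILES[which]).read_text()
    peaks = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        mz_str, inten_str = line.split()
        peaks.append((float(mz_str), float(inten_str)))
    mz_val, charge = PRECURSOR_913
    return Spectrum(precursor_mz=mz_val, precursor_charge=charge, peaks=peaks,
                    title=f"913.9 2- {which} isomer (synthetic fixture)")


def fig4_candidates() -> list[GlycanTopology]:
    """The two candidate topologies for the 913.9 precursor."""
    bis = parse_topology(TOPOLOGY_913_BISECTING)
    bis.name = "bisecting"
    ldn = parse_topology(TOPOLOGY_913_LACDINAC)
    ldn.name = "lacdinac"
    return [bis, ldn]
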