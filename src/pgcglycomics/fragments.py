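"""Negative-mode glycan fragment prediction and diagnostic-ion motif logic.

Collision-induced dissociation of deprotonated glycan alditols produces
Domon-Costello glycosidic cleavages (B/C from the non-reducing side, Y/Z
retaining the reducing end) plus two structure-diagnostic ion families that
carry the motif assignments in this pipeline:

* the **D ion** — a double glycosidic cleavage retaining the 6-arm antenna,
  the bisecting GlcNAc (when present) and the two branching core mannoses.
  Its satellite **D-221** (loss of HexNAc + H2O, 221.090 Da) appears only
  when a bisecting GlcNAc sits on the beta-mannose, making it diagnostic for
  bisected N-glycans (508.17 for the agalactosylated context, 670.22 for the
  galactosylated one).
* the **F ion** — a 1,3A cross-ring cleavage of the branching mannose,
  composed of a complete antenna plus a C2H3O2 stub (+59.013).  Together
  with the antenna B ion it distinguishes LacdiNAc (GalNAc-GlcNAc; B 405.15
  / F 465.17) from its isobaric bisected/LacNAc alternatives, and the
  sialylated antenna B ions 696.25 (Neu5Ac-GalNAc-GlcNAc) vs 655.22
  (Neu5Ac-Gal-GlcNAc) separate sialyl-LacdiNAc from sialyl-LacNAc.

Only singly deprotonated fragments are predicted by default (ion-trap MS2
of 1-/2- precursors shows singly charged diagnostics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .masses import (
    GlycanTopology,
    HEXNAC_PLUS_WATER,
    PROTON,
    REDUCTION,
    Residue,
    WATER,
    neutral_from_mz,
    topology_neutral_mass,
)

#: Mass of the O-CH=CH-O stub retained by the F ion (1,3A on the branching Man).
F_ION_TAG = 59.0133

ALL_KINDS = frozenset({"B", "C", "Y", "Z", "D", "D-221", "F"})
DEFAULT_MS2_TOLERANCE = 0.3  # Da, ion trap


@dataclass(frozen=True)
class FragmentIon:
    kind: str
    label: str  # residue content, e.g. "GalNAc-GlcNAc"
    theoretical_mz: float
    charge: int = 1


@dataclass
class Spectrum:
    """A deconvoluted MS2 peak list: precursor + (m/z, relative intensity)."""

    precursor_mz: float
    precursor_charge: int
    peaks: list[tuple[float, float]]
    title: str = ""

    def __post_init__(self) -> None:
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("peak intensities must be non-negative")
        self.peaks = sorted(self.peaks)

    @property
    def precursor_neutral_mass(self) -> float:
        return neutral_from_mz(self.precursor_mz, self.precursor_charge)


@dataclass
class PeakMatch:
    ion: FragmentIon
    peak_mz: float
    peak_intensity: float
    error: float  # observed - theoretical
    ambiguous: bool = False


@dataclass
class MotifReport:
    """Per-structure diagnostic outcome for one MS2 spectrum."""

    bisecting: bool = False
    lacdinac: bool = False
    sialyl_lacdinac: bool = False
    sialyl_lacnac: bool = False
    coverage_score: float = 0.0
    fragment_coverage: float = 0.0
    evidence: list[PeakMatch] = field(default_factory=list)


class CoreStructure:
    """Resolved N-glycan core context of a topology (None when absent)."""

    def __init__(
        self,
        beta_man: Residue,
        arm3: Optional[Residue],
        arm6: Optional[Residue],
        bisecting: Optional[Residue],
    ):
        self.beta_man = beta_man
        self.arm3 = arm3
        self.arm6 = arm6
        self.bisecting = bisecting


def find_core(t: GlycanTopology) -> Optional[CoreStructure]:
    """Locate the chitobiose + trimannosyl core of an N-glycan topology.

    Root GlcNAc -> GlcNAc -> beta-Man, whose Man children are the 3-arm /
    6-arm mannoses (by linkage position; first two Man children by order if
    positions are unknown) and whose GlcNAc child is the bisecting residue.
    """
    root = t.root
    if root.identity != "GlcNAc":
        return None
    inner = [c for c in root.children if c.identity == "GlcNAc"]
    if not inner:
        return None
    second = inner[0]
    mans = [c for c in second.children if c.identity == "Man"]
    if not mans:
        return None
    beta_man = mans[0]
    arm3 = arm6 = bisecting = None
    unplaced = []
    for child in beta_man.children:
        pos = child.parent_position
        if child.identity == "Man" and pos == "3":
            arm3 = child
        elif child.identity == "Man" and pos == "6":
            arm6 = child
        elif child.identity == "GlcNAc" and pos in ("4", None, "?"):
            bisecting = child
        elif child.identity == "Man":
            unplaced.append(child)
    for child in unplaced:
        if arm3 is None:
            arm3 = child
        elif arm6 is None:
            arm6 = child
    return CoreStructure(beta_man, arm3, arm6, bisecting)


def _antennae(core: CoreStructure) -> list[Residue]:
    """GlcNAc-rooted antenna subtrees on the core alpha-mannoses.

    The bisecting GlcNAc is not an antenna; an antenna is any GlcNAc child
    of an arm mannose together with its substituents.
    """
    out = []
    for arm in (core.arm3, core.arm6):
        if arm is None:
            continue
        out.extend(c for c in arm.children if c.identity == "GlcNAc")
    return out


def _antenna_is_complete(antenna: Residue) -> bool:
    """Complete antennae carry a Gal or GalNAc on the antenna GlcNAc."""
    return any(c.identity in ("Gal", "GalNAc") for c in antenna.children)


def generate_fragments(
    t: GlycanTopology, kinds: Optional[Sequence[str]] = None
) -> list[FragmentIon]:
    """Predict singly charged negative-mode fragment ions for a topology.

    Every glycosidic bond yields B/C (non-reducing fragment) and Y/Z
    (reducing fragment); D and D-221 are emitted only when the 6-arm /
    bisecting core context exists; one F ion per complete antenna.
    Deduplicated on (kind, mass).
    """
    wanted = ALL_KINDS if kinds is None else frozenset(kinds)
    unknown = wanted - ALL_KINDS
    if unknown:
        raise ValueError(f"unknown fragment kinds: {sorted(unknown)}")
    total = topology_neutral_mass(t)
    ions: list[FragmentIon] = []

    def label_of(node: Residue) -> str:
        return "-".join(n.identity for n in node.walk())

    for node in t.walk():
        if node is t.root:
            continue
        sub = node.subtree_residue_mass()
        lbl = label_of(node)
        b = sub - PROTON
        if "B" in wanted:
            ions.append(FragmentIon("B", lbl, b))
        if "C" in wanted:
            ions.append(FragmentIon("C", lbl, b + WATER))
        # Reducing-side fragment: everything except this subtree.
        y_neutral = total - sub - WATER  # residues of the Y side + water
        y = y_neutral + WATER - PROTON
        if "Y" in wanted:
            ions.append(FragmentIon("Y", f"M-{lbl}", y))
        if "Z" in wanted:
            ions.append(FragmentIon("Z", f"M-{lbl}", y - WATER))

    core = find_core(t)
    if core is not None and core.arm6 is not None:
        d_mass = core.arm6.subtree_residue_mass() + core.beta_man.residue_mass
        if core.bisecting is not None:
            d_mass += core.bisecting.subtree_residue_mass()
        d = d_mass - PROTON
        if "D" in wanted:
            ions.append(FragmentIon("D", "6-arm+2Man" + ("+bisect" if core.bisecting else ""), d))
        if "D-221" in wanted and core.bisecting is not None:
            ions.append(FragmentIon("D-221", "D minus HexNAc+H2O", d - HEXNAC_PLUS_WATER))
    if core is not None and "F" in wanted:
        for antenna in _antennae(core):
            if _antenna_is_complete(antenna):
                ions.append(
                    FragmentIon("F", label_of(antenna), antenna.subtree_residue_mass() + F_ION_TAG)
                )

    seen: set[tuple[str, float]] = set()
    unique: list[FragmentIon] = []
    for ion in sorted(ions, key=lambda f: (f.theoretical_mz, f.kind)):
        key = (ion.kind, round(ion.theoretical_mz, 6))
        if key not in seen:
            seen.add(key)
            unique.append(ion)
    return unique


def match_peaks(
    spectrum: Spectrum, ions: Sequence[FragmentIon], tol: float = DEFAULT_MS2_TOLERANCE
) -> list[PeakMatch]:
    """Match each theoretical ion to the nearest peak within ``tol`` Da.

    One peak may satisfy several isobaric ions; such matches are flagged
    ambiguous.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    matches: list[PeakMatch] = []
    for ion in ions:
        best_idx = None
        best_err = None
        for idx, (pmz, _) in enumerate(spectrum.peaks):
            err = pmz - ion.theoretical_mz
            if abs(err) <= tol and (best_err is None or abs(err) < abs(best_err)):
                best_idx, best_err = idx, err
        if best_idx is not None:
            pmz, pint = spectrum.peaks[best_idx]
            matches.append(PeakMatch(ion, pmz, pint, best_err))
    counts: dict[float, int] = {}
    for m in matches:
        counts[m.peak_mz] = counts.get(m.peak_mz, 0) + 1
    for m in matches:
        if counts[m.peak_mz] > 1:
            m.ambiguous = True
    return matches


def _diagnostic_ions(t: GlycanTopology) -> dict[str, list[FragmentIon]]:
    """Motif-bearing ions predicted for a topology, keyed by motif."""
    out: dict[str, list[FragmentIon]] = {
        "bisecting": [],
        "lacdinac": [],
        "sialyl_lacdinac": [],
        "sialyl_lacnac": [],
    }
    core = find_core(t)
    if core is None:
        return out
    for ion in generate_fragments(t, kinds=("D", "D-221")):
        if core.bisecting is not None:
            out["bisecting"].append(ion)
    for antenna in _antennae(core):
        names = [n.identity for n in antenna.walk()]
        sub = antenna.subtree_residue_mass()
        b = FragmentIon("B", "-".join(names), sub - PROTON)
        f = FragmentIon("F", "-".join(names), sub + F_ION_TAG)
        if names[0] == "GlcNAc" and "GalNAc" in names:
            if "Neu5Ac" in names:
                out["sialyl_lacdinac"].append(b)
            else:
                out["lacdinac"].extend([b, f])
        elif names[0] == "GlcNAc" and "Gal" in names and "Neu5Ac" in names:
            out["sialyl_lacnac"].append(b)
    return out


def motif_report(
    spectrum: Spectrum, t: GlycanTopology, tol: float = DEFAULT_MS2_TOLERANCE
) -> MotifReport:
    """Evaluate the diagnostic-ion rules for one candidate topology."""
    diag = _diagnostic_ions(t)
    report = MotifReport()
    predicted = 0
    matched = 0
    for motif, ions in diag.items():
        if not ions:
            continue
        hits = match_peaks(spectrum, ions, tol)
        predicted += len(ions)
        matched += len(hits)
        report.evidence.extend(hits)
        if motif == "lacdinac":
            # B 405.15 and/or F 465.17 suffices
            setattr(report, motif, len(hits) > 0)
        else:
            setattr(report, motif, len(hits) == len(ions) and len(ions) > 0)
    report.coverage_score = matched / predicted if predicted else 0.0
    all_ions = generate_fragments(t)
    all_hits = match_peaks(spectrum, all_ions, tol)
    report.fragment_coverage = len(all_hits) / len(all_ions) if all_ions else 0.0
    return report


def classify_motifs(
    spectrum: Spectrum,
    candidates: Sequence[GlycanTopology],
    tol: float = DEFAULT_MS2_TOLERANCE,
    precursor_tol: float = 0.5,
) -> list[tuple[GlycanTopology, MotifReport]]:
    """Rank candidate topologies for a spectrum by diagnostic-ion coverage.

    Candidates whose neutral mass is not within ``precursor_tol`` Da of the
    spectrum's precursor neutral mass are discarded; if none remain an error
    is raised.  Ranking: diagnostic coverage, then overall fragment coverage,
    then (stable, deterministic) input order.
    """
    viable: list[tuple[int, GlycanTopology]] = []
    target = spectrum.precursor_neutral_mass
    for i, cand in enumerate(candidates):
        if abs(topology_neutral_mass(cand) - target) <= precursor_tol:
            viable.append((i, cand))
    if not viable:
        raise ValueError(
            f"no candidate within {precursor_tol} Da of precursor neutral mass {target:.2f}"
        )
    scored = [(i, cand, motif_report(spectrum, cand, tol)) for i, cand in viable]
    scored.sort(key=lambda t3: (-t3[2].coverage_score, -t3[2].fragment_coverage, t3[0]))
    return [(cand, rep) for _, cand, rep in scored]
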