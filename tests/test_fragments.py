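"""Fragment prediction, diagnostic-ion anchors, and motif classification."""

import numpy as np
import pytest

from pgcglycomics.fixtures import (
    TOPOLOGY_913_BISECTING,
    TOPOLOGY_913_LACDINAC,
    fig4_candidates,
    fig4_spectrum,
)
from pgcglycomics.fragments import (
    Spectrum,
    classify_motifs,
    generate_fragments,
    match_peaks,
    motif_report,
)
from pgcglycomics.masses import WATER, parse_topology, topology_neutral_mass
from pgcglycomics.simulate import generate_spectrum

SIALYL_MIXED_1205 = (
    "Neu5Ac(a2-6)GalNAc(b1-4)GlcNAc(b1-2)Man(a1-6)"
    "[Neu5Ac(a2-3)Gal(b1-4)GlcNAc(b1-2)Man(a1-3)]"
    "Man(b1-4)GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc-ol"
)

GALACTO_BISECTED = (
    "Gal(b1-4)GlcNAc(b1-2)Man(a1-6)[Gal(b1-4)GlcNAc(b1-2)Man(a1-3)]"
    "[GlcNAc(b1-4)]Man(b1-4)GlcNAc(b1-4)GlcNAc-ol"
)


def ion_mz(topology_str, kind, label_contains=None):
    topo = parse_topology(topology_str)
    hits = [
        i for i in generate_fragments(topo)
        if i.kind == kind and (label_contains is None or label_contains in i.label)
    ]
    assert hits, f"no {kind} ion on {topology_str}"
    return [i.theoretical_mz for i in hits]


@pytest.mark.parametrize(
    "topology, kind, label, printed",
    [
        # LacdiNAc antenna B and F ions
        (TOPOLOGY_913_LACDINAC, "B", "GlcNAc-GalNAc", 405.1),
        (TOPOLOGY_913_LACDINAC, "F", "GlcNAc-GalNAc", 465.1),
        # agalactosylated bisected D-221
        (TOPOLOGY_913_BISECTING, "D-221", None, 508.1),
        # galactosylated bisected D-221
        (GALACTO_BISECTED, "D-221", None, 670.2),
        # sialylated antenna B ions: sialyl-LacdiNAc vs sialyl-LacNAc
        (SIALYL_MIXED_1205, "B", "GlcNAc-GalNAc-Neu5Ac", 696.2),
        (SIALYL_MIXED_1205, "B", "GlcNAc-Gal-Neu5Ac", 655.2),
    ],
)
def test_printed_diagnostic_ion_anchors(topology, kind, label, printed):
    values = ion_mz(topology, kind, label)
    assert min(abs(v - printed) for v in values) <= 0.1


def test_fragment_mass_conservation():
    """B-side neutral + Y-side neutral = precursor neutral + water for every
    single glycosidic cleavage."""
    from pgcglycomics.masses import PROTON

    topo = parse_topology(SIALYL_MIXED_1205)
    total = topology_neutral_mass(topo)
    ions = generate_fragments(topo, kinds=("B", "Y"))
    b_ions = {i.label: i.theoretical_mz for i in ions if i.kind == "B"}
    y_ions = {i.label[2:]: i.theoretical_mz for i in ions if i.kind == "Y"}
    checked = 0
    for label, b in b_ions.items():
        if label in y_ions:
            b_neutral = b + PROTON + WATER  # B fragment neutral incl. its water
            y_neutral = y_ions[label] + PROTON
            assert b_neutral + y_neutral == pytest.approx(total + WATER, abs=1e-6)
            checked += 1
    assert checked >= 5


def test_d221_requires_bisecting_context():
    plain = parse_topology(
        "Gal(b1-4)GlcNAc(b1-2)Man(a1-6)[Gal(b1-4)GlcNAc(b1-2)Man(a1-3)]"
        "Man(b1-4)GlcNAc(b1-4)GlcNAc-ol"
    )
    kinds = {i.kind for i in generate_fragments(plain)}
    assert "D" in kinds and "D-221" not in kinds


def test_match_peaks_empty_spectrum():
    topo = parse_topology(TOPOLOGY_913_LACDINAC)
    spec = Spectrum(precursor_mz=913.9, precursor_charge=2, peaks=[])
    assert match_peaks(spec, generate_fragments(topo)) == []


def test_match_peaks_exact_theoretical_list():
    topo = parse_topology(TOPOLOGY_913_LACDINAC)
    ions = generate_fragments(topo)
    spec = Spectrum(
        precursor_mz=913.9,
        precursor_charge=2,
        peaks=[(i.theoretical_mz, 1.0) for i in ions],
    )
    matches = match_peaks(spec, ions)
    assert len(matches) == len(ions)
    report = motif_report(spec, topo)
    assert report.fragment_coverage == pytest.approx(1.0)


def test_match_rate_under_jitter():
    """>= 95% of jittered (sigma 0.05) theoretical peaks match at tol 0.3."""
    topo = parse_topology(TOPOLOGY_913_LACDINAC)
    ions = generate_fragments(topo)
    rng = np.random.default_rng(11)
    matched = total = 0
    for _ in range(100):
        peaks = [(i.theoretical_mz + rng.normal(0, 0.05), 1.0) for i in ions]
        spec = Spectrum(precursor_mz=913.9, precursor_charge=2, peaks=peaks)
        matched += len(match_peaks(spec, ions, tol=0.3))
        total += len(ions)
    assert matched / total >= 0.95


def test_fig4_fixture_bisecting_ranked_first():
    """The early-eluting 913.9 isomer fixture (D-221 ion, no 405/465) is
    assigned the bisecting structure; LacdiNAc evidence absent."""
    ranked = classify_motifs(fig4_spectrum("bisecting"), fig4_candidates())
    top, report = ranked[0]
    assert top.name == "bisecting"
    assert report.bisecting and not report.lacdinac


def test_fig4_fixture_lacdinac_ranked_first():
    """The late-eluting isomer fixture (B 405.1 / F 465.1) is assigned the
    LacdiNAc structure; bisecting evidence absent."""
    ranked = classify_motifs(fig4_spectrum("lacdinac"), fig4_candidates())
    top, report = ranked[0]
    assert top.name == "lacdinac"
    assert report.lacdinac and not report.bisecting


def test_fixture_pair_yields_two_distinct_assignments():
    tops = [
        classify_motifs(fig4_spectrum(which), fig4_candidates())[0][0].name
        for which in ("bisecting", "lacdinac")
    ]
    assert sorted(tops) == ["bisecting", "lacdinac"]


def test_classify_motifs_deterministic():
    spec = fig4_spectrum("lacdinac")
    first = [t.name for t, _ in classify_motifs(spec, fig4_candidates())]
    second = [t.name for t, _ in classify_motifs(spec, fig4_candidates())]
    assert first == second


def test_classify_motifs_precursor_gate():
    far = Spectrum(precursor_mz=700.0, precursor_charge=2, peaks=[(405.15, 1.0)])
    with pytest.raises(ValueError):
        classify_motifs(far, fig4_candidates())


def test_recovery_simulation_with_decoys():
    """True topology is top-ranked in >= 90% of 200 noisy synthetic spectra
    (jitter sigma 0.05, 20% decoy peaks)."""
    candidates = fig4_candidates()
    wins = 0
    trials = 0
    for seed in range(100):
        for true_idx in (0, 1):
            spec = generate_spectrum(
                candidates[true_idx], jitter_sd=0.05, decoy_rate=0.2, seed=seed
            )
            ranked = classify_motifs(spec, candidates)
            wins += ranked[0][0].name == candidates[true_idx].name
            trials += 1
    assert trials == 200
    assert wins / trials >= 0.90
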