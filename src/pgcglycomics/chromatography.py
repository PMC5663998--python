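"""EIC peak integration and PGC sialyl-linkage isomer assignment.

Porous graphitized carbon separates glycan structural isomers that are
isobaric — in particular alpha2,3- vs alpha2,6-linked terminal sialic acids
on the same backbone.  On this column the alpha2,6-linked forms elute
earlier than their alpha2,3 counterparts (e.g. for the disialylated
biantennary backbone the elution order is a2,6/a2,6 < a2,6/a2,3 <
a2,3/a2,3), so within a single run an expected isomer set can be assigned
to integrated EIC peaks purely by elution order.  No quantitative
retention-time prediction is attempted, and retention times are only
compared within a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Labels containing this token count as alpha2,6-sialylated forms.
A26_TOKEN = "a26"


@dataclass
class EICTrace:
    """Extracted ion chromatogram for one glycan mass.

    Either a raw (rt, intensity) series or pre-integrated (rt apex, area)
    peaks.
    """

    glycan_id: str
    rt: Optional[np.ndarray] = None
    intensity: Optional[np.ndarray] = None
    peaks: Optional[list[tuple[float, float]]] = None  # (rt apex, area)

    def __post_init__(self) -> None:
        if self.rt is not None:
            self.rt = np.asarray(self.rt, dtype=float)
            self.intensity = np.asarray(self.intensity, dtype=float)
            if self.rt.shape != self.intensity.shape:
                raise ValueError("rt and intensity must have the same length")


@dataclass
class IsomerAssignment:
    """Elution-order labelling of isomer peaks with area fractions."""

    glycan_id: str
    labels: list[str] = field(default_factory=list)  # per assigned peak, rt order
    fractions: dict[str, float] = field(default_factory=dict)
    unassigned_area: float = 0.0
    low_confidence: bool = False

    @property
    def alpha26_fraction(self) -> float:
        """Area fraction of peaks whose label contains an alpha2,6 linkage."""
        return sum(frac for lbl, frac in self.fractions.items() if A26_TOKEN in lbl)


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.astype(float)
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(y)]
    return out


def integrate_peaks(
    trace: EICTrace,
    smoothing_window: int = 5,
    min_area: float = 0.0,
    valley_fraction: float = 0.10,
    min_height_fraction: float = 0.01,
) -> list[tuple[float, float]]:
    """Integrate an EIC into (rt apex, area) peaks.

    The signal is smoothed with a centered moving average; candidate apexes
    are local maxima above ``min_height_fraction`` of the trace maximum
    (baseline-noise ripples are not apexes); adjacent apexes are split only
    at local minima that drop below ``valley_fraction`` of the lower apex
    (otherwise they merge into one peak).  Areas are trapezoidal over the
    raw signal between delimiters; peaks below ``min_area`` are dropped.
    """
    if trace.peaks is not None:
        return [(rt, a) for rt, a in trace.peaks if a >= min_area]
    if trace.rt is None or len(trace.rt) < 3:
        raise ValueError("raw EIC integration needs at least 3 points")
    y = trace.intensity
    if np.all(y <= 0):
        return []
    s = _moving_average(y, smoothing_window)

    floor = min_height_fraction * s.max()
    apexes = [
        i
        for i in range(1, len(s) - 1)
        if s[i] > floor and s[i] >= s[i - 1] and s[i] > s[i + 1]
    ]
    if not apexes:
        return []

    # Merge apexes whose connecting valley stays above the split threshold.
    groups: list[list[int]] = [[apexes[0]]]
    for apex in apexes[1:]:
        prev = groups[-1][-1]
        valley = s[prev : apex + 1].min()
        if valley < valley_fraction * min(s[prev], s[apex]):
            groups.append([apex])
        else:
            groups[-1].append(apex)

    region_apexes = [max(g, key=lambda i: s[i]) for g in groups]
    # Delimiters: the minimum between adjacent region apexes; trace ends outside.
    bounds = [0]
    for left, right in zip(region_apexes[:-1], region_apexes[1:]):
        bounds.append(left + int(np.argmin(s[left : right + 1])))
    bounds.append(len(s) - 1)

    peaks: list[tuple[float, float]] = []
    for k, apex in enumerate(region_apexes):
        lo, hi = bounds[k], bounds[k + 1]
        area = float(np.trapezoid(y[lo : hi + 1], trace.rt[lo : hi + 1]))
        rt_apex = float(trace.rt[lo:hi + 1][np.argmax(y[lo : hi + 1])])
        if area >= min_area and area > 0:
            peaks.append((rt_apex, area))
    return peaks


def assign_sialyl_isomers(
    peaks: Sequence[tuple[float, float]],
    expected: Sequence[str],
    glycan_id: str = "",
) -> IsomerAssignment:
    """Label integrated peaks with an expected isomer set in elution order.

    ``expected`` lists isomer labels in their expected elution order, the
    alpha2,6-containing forms first (e.g. ``["a26a26", "a26a23", "a23a23"]``).
    Fewer observed peaks than labels: the leading labels are used and the
    assignment is flagged low-confidence (later labels absent).  Surplus
    peaks are pooled as unassigned.  Fractions are over assigned peaks and
    sum to 1.
    """
    if not expected:
        raise ValueError("expected isomer set must not be empty")
    ordered = sorted(peaks, key=lambda p: p[0])
    n_assign = min(len(ordered), len(expected))
    assigned = ordered[:n_assign]
    surplus = ordered[n_assign:]
    total = sum(a for _, a in assigned)
    fractions = {}
    labels = []
    for (rt, area), label in zip(assigned, expected):
        labels.append(label)
        fractions[label] = (area / total) if total > 0 else 0.0
    return IsomerAssignment(
        glycan_id=glycan_id,
        labels=labels,
        fractions=fractions,
        unassigned_area=sum(a for _, a in surplus),
        low_confidence=len(ordered) < len(expected),
    )


def percent_alpha26(
    assignments: dict[str, IsomerAssignment],
    weights: Optional[dict[str, float]] = None,
) -> Optional[float]:
    """Abundance-weighted alpha2,6-containing percentage over a glycan subset.

    ``weights`` are relative abundances of the glycans (profile percentages);
    uniform when omitted.  Returns None (reported as missing) when the total
    weight is zero or the subset empty.
    """
    if not assignments:
        raise ValueError("glycan subset must not be empty")
    if weights is None:
        weights = {gid: 1.0 for gid in assignments}
    num = 0.0
    den = 0.0
    for gid, assignment in assignments.items():
        w = weights.get(gid, 0.0)
        num += w * assignment.alpha26_fraction
        den += w
    if den <= 0:
        return None
    return 100.0 * num / den
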