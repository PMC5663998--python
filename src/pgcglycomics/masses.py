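"""Monosaccharide mass calculus for released glycan alditols.

Glycans released from membrane glycoproteins (PNGase F for N-glycans,
reductive beta-elimination for O-glycans) and reduced to alditols with
borohydride are detected in negative ionization mode as [M-H]1- and
[M-2H]2- ions on porous graphitized carbon (PGC) LC-MS.  This module
provides the residue-mass table, monosaccharide-class compositions, rooted
glycan topologies, and the neutral-mass / m/z arithmetic every other stage
builds on.

Mass-search units are *classes* (Hex, HexNAc, dHex, Neu5Ac): Gal vs Man and
GalNAc vs GlcNAc are mass-identical and can only be told apart by
fragmentation and PGC retention, so specific identities live exclusively in
:class:`GlycanTopology`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

# Monoisotopic residue masses (Da) of the dehydrated monosaccharide units.
RESIDUE_MASSES: dict[str, float] = {
    "Hex": 162.05282,
    "HexNAc": 203.07937,
    "dHex": 146.05791,
    "Neu5Ac": 291.09542,
}

#: Monoisotopic mass of the terminal water completing a free glycan.
WATER = 18.01056
#: Mass added on borohydride reduction of the reducing terminus (alditol, +2H).
REDUCTION = 2.01565
#: Monoisotopic mass of the sulfate modification (SO3).
SULFATE = 79.95682
#: Monoisotopic proton mass; the negative-mode charge carrier is a lost proton.
PROTON = 1.00728
#: HexNAc residue + water: the neutral loss behind the D-221 diagnostic ion.
HEXNAC_PLUS_WATER = 221.08993

#: Specific residue identity -> monosaccharide mass class.
IDENTITY_TO_CLASS: dict[str, str] = {
    "Man": "Hex",
    "Gal": "Hex",
    "Glc": "Hex",
    "GlcNAc": "HexNAc",
    "GalNAc": "HexNAc",
    "Fuc": "dHex",
    "Neu5Ac": "Neu5Ac",
}

CLASS_ORDER = ("Hex", "HexNAc", "dHex", "Neu5Ac")

#: Class counts of the N-glycan trimannosyl-chitobiose core, Man3GlcNAc2.
N_CORE_COUNTS = {"Hex": 3, "HexNAc": 2}


class InvalidCompositionError(ValueError):
    """Raised for negative counts or a violated glycan-class constraint."""


class CompositionParseError(ValueError):
    """Raised on malformed composition strings; carries the byte offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class Composition:
    """Counts of monosaccharide classes; the unit of mass search.

    ``glycan_class`` is "N" or "O".  N-glycan compositions are expected to
    contain the Man3GlcNAc2 core (Hex >= 3, HexNAc >= 2) unless
    ``fragment=True`` marks a sub-structural composition.
    """

    hex: int = 0
    hexnac: int = 0
    dhex: int = 0
    neu5ac: int = 0
    sulfate: int = 0
    reduced: bool = True
    glycan_class: str = "N"
    fragment: bool = False

    def __post_init__(self) -> None:
        counts = (self.hex, self.hexnac, self.dhex, self.neu5ac, self.sulfate)
        if any(c < 0 for c in counts):
            raise InvalidCompositionError(f"negative monosaccharide count in {counts}")
        if self.glycan_class not in ("N", "O"):
            raise InvalidCompositionError(f"glycan_class must be 'N' or 'O', got {self.glycan_class!r}")
        if (
            self.glycan_class == "N"
            and not self.fragment
            and self.total_residues > 0
            and (self.hex < 3 or self.hexnac < 2)
        ):
            raise InvalidCompositionError(
                "N-glycan composition must contain the Man3GlcNAc2 core "
                f"(Hex>=3, HexNAc>=2); got Hex{self.hex} HexNAc{self.hexnac}"
            )

    @property
    def counts(self) -> dict[str, int]:
        return {
            "Hex": self.hex,
            "HexNAc": self.hexnac,
            "dHex": self.dhex,
            "Neu5Ac": self.neu5ac,
        }

    @property
    def total_residues(self) -> int:
        return self.hex + self.hexnac + self.dhex + self.neu5ac

    def __str__(self) -> str:
        return composition_to_string(self)


def neutral_mass(comp: Composition) -> float:
    """Monoisotopic neutral mass (Da) of a composition.

    Sum of residue masses + terminal water, + 2H if the reducing end is an
    alditol, + one SO3 per sulfate.
    """
    mass = sum(RESIDUE_MASSES[cls] * n for cls, n in comp.counts.items())
    mass += WATER
    if comp.reduced:
        mass += REDUCTION
    mass += SULFATE * comp.sulfate
    return mass


def mz(mass: float, charge: int, mode: str = "negative") -> float:
    """m/z of a deprotonated ion: (M - z*proton) / z for z in {1, 2, 3}."""
    if mode != "negative":
        raise ValueError("only negative ionization mode is supported")
    if not isinstance(charge, int) or charge <= 0:
        raise ValueError(f"charge must be a positive integer, got {charge!r}")
    if charge > 3:
        raise ValueError("charge states above 3- are not modelled")
    return (mass - charge * PROTON) / charge


def neutral_from_mz(observed_mz: float, charge: int) -> float:
    """Invert :func:`mz`: neutral monoisotopic mass of an observed ion."""
    if charge <= 0:
        raise ValueError("charge must be positive")
    return observed_mz * charge + charge * PROTON


_TOKEN_RE = re.compile(r"\(([A-Za-z0-9]+)\)\s*(\d+)")

# Tokens accepted in composition strings, including specific identities
# (folded to classes) and the one-letter sulfate convention.
_COMPOSITION_TOKENS = {
    "Hex": ("Hex", 1),
    "HexNAc": ("HexNAc", 1),
    "dHex": ("dHex", 1),
    "Neu5Ac": ("Neu5Ac", 1),
    "NeuAc": ("Neu5Ac", 1),
    "Man": ("Hex", 1),
    "Gal": ("Hex", 1),
    "Glc": ("Hex", 1),
    "GlcNAc": ("HexNAc", 1),
    "GalNAc": ("HexNAc", 1),
    "Fuc": ("dHex", 1),
    "S": ("sulfate", 1),
    "Sulfate": ("sulfate", 1),
    "Sulphate": ("sulfate", 1),
}


def parse_composition(
    text: str,
    glycan_class: Optional[str] = None,
    reduced: bool = True,
) -> Composition:
    """Parse a "(Class)count..." composition string.

    Accepts the captions' dialect "(Hex)1(HexNAc)3(dHex)1 + (Man)3(GlcNAc)2"
    (the "+core" part folds into the totals) as well as plain forms with
    specific identities such as "(Neu5Ac)1(Gal)1(GalNAc)1".

    When ``glycan_class`` is not given it is inferred: a "+core" suffix or a
    class-count pattern compatible with the Man3GlcNAc2 core means "N",
    anything else "O".
    """
    counts = {"Hex": 0, "HexNAc": 0, "dHex": 0, "Neu5Ac": 0, "sulfate": 0}
    has_core_suffix = "+" in text
    pos = 0
    n_tokens = 0
    stripped = text
    for part in stripped.split("+"):
        base = stripped.index(part, pos)
        cursor = 0
        for m in _TOKEN_RE.finditer(part):
            gap = part[cursor : m.start()]
            if gap.strip():
                raise CompositionParseError(f"unparseable text {gap.strip()!r}", base + cursor)
            token, count = m.group(1), int(m.group(2))
            if token not in _COMPOSITION_TOKENS:
                raise CompositionParseError(f"unknown monosaccharide token {token!r}", base + m.start(1))
            cls, mult = _COMPOSITION_TOKENS[token]
            counts[cls] += count * mult
            n_tokens += 1
            cursor = m.end()
        if part[cursor:].strip():
            raise CompositionParseError(f"unparseable text {part[cursor:].strip()!r}", base + cursor)
        pos = base + len(part)
    if n_tokens == 0:
        raise CompositionParseError("no composition tokens found", 0)
    if glycan_class is None:
        if has_core_suffix or (counts["Hex"] >= 3 and counts["HexNAc"] >= 2):
            glycan_class = "N"
        else:
            glycan_class = "O"
    return Composition(
        hex=counts["Hex"],
        hexnac=counts["HexNAc"],
        dhex=counts["dHex"],
        neu5ac=counts["Neu5Ac"],
        sulfate=counts["sulfate"],
        reduced=reduced,
        glycan_class=glycan_class,
    )


def composition_to_string(comp: Composition) -> str:
    """Canonical "(Hex)h(HexNAc)n(dHex)d(Neu5Ac)s" serialization (round-trips)."""
    parts = []
    for cls in CLASS_ORDER:
        n = comp.counts[cls]
        if n:
            parts.append(f"({cls}){n}")
    if comp.sulfate:
        parts.append(f"(S){comp.sulfate}")
    return "".join(parts) if parts else "()0"


# ---------------------------------------------------------------------------
# Topologies
# ---------------------------------------------------------------------------

@dataclass
class Residue:
    """A node in a rooted glycan tree.

    ``linkage`` is the bond to the parent as written in condensed IUPAC,
    e.g. "b1-4" (anomeric config + child position - parent position); ``None``
    for the root.  Children order is not semantically meaningful except that
    serialization preserves it.
    """

    identity: str
    linkage: Optional[str] = None
    children: list["Residue"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.identity not in IDENTITY_TO_CLASS:
            raise ValueError(f"unknown residue identity {self.identity!r}")

    @property
    def mass_class(self) -> str:
        return IDENTITY_TO_CLASS[self.identity]

    @property
    def residue_mass(self) -> float:
        return RESIDUE_MASSES[self.mass_class]

    @property
    def parent_position(self) -> Optional[str]:
        """Acceptor position on the parent, e.g. '4' from 'b1-4'."""
        if self.linkage is None:
            return None
        return self.linkage.split("-")[-1] or None

    def walk(self) -> Iterator["Residue"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def subtree_residue_mass(self) -> float:
        return sum(node.residue_mass for node in self.walk())


@dataclass
class GlycanTopology:
    """Rooted tree of specific residues; the unit of fragment prediction.

    The root is the (former) reducing-end residue — an alditol when
    ``reduced`` is true.  N-glycan topologies contain the Man3GlcNAc2 core as
    a connected subtree rooted at the reducing-end GlcNAc.
    """

    root: Residue
    reduced: bool = True
    glycan_class: str = "N"
    name: Optional[str] = None

    def walk(self) -> Iterator[Residue]:
        return self.root.walk()

    def residue_count(self) -> int:
        return sum(1 for _ in self.walk())

    def __str__(self) -> str:
        return topology_to_string(self)


def topology_to_composition(t: GlycanTopology) -> Composition:
    """Project node identities to mass classes, preserving the reduced flag."""
    counts = {"Hex": 0, "HexNAc": 0, "dHex": 0, "Neu5Ac": 0}
    for node in t.walk():
        counts[node.mass_class] += 1
    return Composition(
        hex=counts["Hex"],
        hexnac=counts["HexNAc"],
        dhex=counts["dHex"],
        neu5ac=counts["Neu5Ac"],
        reduced=t.reduced,
        glycan_class=t.glycan_class,
        # Core constraint checked on topologies by the fragment engine; the
        # projection itself must stay total (partial antennae project too).
        fragment=(counts["Hex"] < 3 or counts["HexNAc"] < 2),
    )


_RESIDUE_TOKEN_RE = re.compile(r"(Neu5Ac|GlcNAc|GalNAc|Man|Gal|Glc|Fuc)(?:\(([ab?][12?]-[1-9?])\))?")


def parse_topology(notation: str) -> GlycanTopology:
    """Parse condensed-IUPAC linear notation into a rooted tree.

    Example: ``"Neu5Ac(a2-6)Gal(b1-4)GlcNAc(b1-2)Man(a1-6)[Neu5Ac(a2-3)
    Gal(b1-4)GlcNAc(b1-2)Man(a1-3)]Man(b1-4)GlcNAc(b1-4)GlcNAc-ol"``.
    Brackets attach branches to the residue that follows them; a trailing
    ``-ol`` marks the alditol (reduced) root.
    """
    text = notation.strip()
    reduced = text.endswith("-ol")
    if reduced:
        text = text[: -len("-ol")]
    # pending: per bracket level, subtrees awaiting their parent
    pending: list[Residue] = []
    stack: list[list[Residue]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            stack.append(pending)
            pending = []
            i += 1
        elif ch == "]":
            if not stack:
                raise ValueError(f"unbalanced ']' in {notation!r}")
            outer = stack.pop()
            pending = outer + pending
            i += 1
        else:
            m = _RESIDUE_TOKEN_RE.match(text, i)
            if not m:
                raise ValueError(f"cannot parse residue at offset {i} in {notation!r}")
            node = Residue(identity=m.group(1), linkage=m.group(2), children=pending)
            pending = [node]
            i = m.end()
    if stack:
        raise ValueError(f"unbalanced '[' in {notation!r}")
    if len(pending) != 1:
        raise ValueError(f"notation does not reduce to a single root: {notation!r}")
    root = pending[0]
    if root.linkage is not None:
        raise ValueError(f"root residue carries a linkage in {notation!r}")
    glycan_class = "N" if root.identity == "GlcNAc" else "O"
    return GlycanTopology(root=root, reduced=reduced, glycan_class=glycan_class)


def topology_to_string(t: GlycanTopology) -> str:
    def render(node: Residue) -> str:
        head = ""
        if node.children:
            first, *rest = node.children
            head = render(first) + "".join(f"[{render(c)}]" for c in rest)
        link = f"({node.linkage})" if node.linkage else ""
        return f"{head}{node.identity}{link}"

    return render(t.root) + ("-ol" if t.reduced else "")


def topology_neutral_mass(t: GlycanTopology) -> float:
    """Neutral mass via the class projection (additive over residues)."""
    return neutral_mass(topology_to_composition(t))
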