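"""Peptide sequence handling, cysteine-framework naming and isotope-aware masses.

Disulfide-rich venom peptides are usually described by two complementary
labels: the sequence positions of their half-cystines and the *framework* —
the pairing pattern written in cysteine ordinals (e.g. ``1-4,2-6,3-7,5-8``),
which is comparable across peptides of different length.  This module parses
one-letter sequences, derives frameworks from residue-numbered disulfide
pairs, and computes neutral monoisotopic/average masses with optional uniform
15N/13C enrichment and a C-terminal amide, from a per-residue elemental
composition table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "PeptideSequence",
    "IsotopeScheme",
    "DisulfideTopology",
    "parse_sequence",
    "cysteine_framework",
    "monoisotopic_mass",
    "average_mass",
    "CLTX_SEQUENCE",
    "CLTX_DISULFIDES",
]

#: Chlorotoxin (ClTx), the 36-residue scorpion toxin studied throughout.
CLTX_SEQUENCE = "MCMPCFTTDHQMARKCDDCCGGKGRGKCYGPQCLCR"

#: ClTx disulfide pairs in sequence numbering (framework 1-4,2-6,3-7,5-8).
CLTX_DISULFIDES = ((2, 19), (5, 28), (16, 33), (20, 35))

# Residue elemental composition (C, H, N, O, S) for the *residue*, i.e. the
# amino acid minus one water.  Standard compositions; a chain is the sum of
# its residues plus one water.
_RESIDUE_FORMULA: dict[str, tuple[int, int, int, int, int]] = {
    "G": (2, 3, 1, 1, 0),
    "A": (3, 5, 1, 1, 0),
    "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0),
    "V": (5, 9, 1, 1, 0),
    "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1),
    "L": (6, 11, 1, 1, 0),
    "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0),
    "D": (4, 5, 1, 3, 0),
    "Q": (5, 8, 2, 2, 0),
    "K": (6, 12, 2, 1, 0),
    "E": (5, 7, 1, 3, 0),
    "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0),
    "F": (9, 9, 1, 1, 0),
    "R": (6, 12, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0),
    "W": (11, 10, 2, 1, 0),
}

# Monoisotopic atomic masses (Da), CODATA/IUPAC values.
MONOISOTOPIC = {"C": 12.0, "H": 1.00783, "N": 14.00307, "O": 15.99491, "S": 31.97207}
# Standard average atomic weights (Da).
AVERAGE = {"C": 12.011, "H": 1.008, "N": 14.007, "O": 15.999, "S": 32.06}

#: Mass shifts for uniform isotope enrichment, per atom.
N15_SHIFT = 15.00011 - 14.00307
C13_SHIFT = 13.00335 - 12.0

#: Mass of a proton, for converting neutral masses to [M+H]+ values.
PROTON_MASS = 1.00728


@dataclass(frozen=True)
class PeptideSequence:
    """One-letter peptide sequence with derived cysteine positions."""

    residues: str
    cys_positions: tuple[int, ...] = field(init=False)

    def __post_init__(self) -> None:
        bad = [
            (i + 1, a)
            for i, a in enumerate(self.residues)
            if a not in _RESIDUE_FORMULA
        ]
        if not self.residues:
            raise ValueError("empty sequence")
        if bad:
            pos, letter = bad[0]
            raise ValueError(
                f"non-canonical residue {letter!r} at position {pos}"
            )
        object.__setattr__(
            self,
            "cys_positions",
            tuple(i + 1 for i, a in enumerate(self.residues) if a == "C"),
        )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class IsotopeScheme:
    """Uniform labelling flags plus the C-terminal chemistry.

    ``c_terminal_amide=False`` is the free-acid ("deamidated") form required
    for NRP1-b1 binding; recombinant material is a free acid by construction.
    """

    label_15N: bool = False
    label_13C: bool = False
    c_terminal_amide: bool = False


@dataclass(frozen=True)
class DisulfideTopology:
    """Disulfide pairs in residue numbering with the ordinal framework string."""

    pairs: tuple[tuple[int, int], ...]
    framework: str


def parse_sequence(text: str) -> PeptideSequence:
    """Parse a one-letter sequence (raw string or single-record FASTA).

    Case-insensitive; whitespace is ignored.  Raises ``ValueError`` naming the
    first offending position for non-canonical letters.
    """
    lines = [ln.strip() for ln in text.strip().splitlines() if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    seq = re.sub(r"\s+", "", "".join(lines)).upper()
    return PeptideSequence(seq)


def cysteine_framework(
    seq: PeptideSequence, pairs: "list[tuple[int, int]] | tuple[tuple[int, int], ...]"
) -> DisulfideTopology:
    """Convert residue-numbered disulfide pairs into an ordinal framework.

    Each cysteine's ordinal is its 1-based rank among the sequence's
    cysteines; the framework string lists ordinal pairs sorted by first
    ordinal (invariant to the order pairs are supplied in).
    """
    rank = {pos: i + 1 for i, pos in enumerate(seq.cys_positions)}
    seen: set[int] = set()
    ordinal_pairs = []
    norm_pairs = []
    for i, j in pairs:
        i, j = (i, j) if i < j else (j, i)
        for r in (i, j):
            if r not in rank:
                raise ValueError(f"residue {r} is not a cysteine of the sequence")
            if r in seen:
                raise ValueError(f"residue {r} appears in more than one pair")
            seen.add(r)
        norm_pairs.append((i, j))
        ordinal_pairs.append((rank[i], rank[j]))
    order = sorted(range(len(ordinal_pairs)), key=lambda k: ordinal_pairs[k])
    framework = ",".join(f"{ordinal_pairs[k][0]}-{ordinal_pairs[k][1]}" for k in order)
    return DisulfideTopology(
        pairs=tuple(norm_pairs[k] for k in order), framework=framework
    )


def elemental_composition(
    seq: PeptideSequence,
    scheme: IsotopeScheme = IsotopeScheme(),
    n_disulfides: int = 0,
) -> dict[str, int]:
    """Elemental composition (C/H/N/O/S counts) of the neutral peptide."""
    if 2 * n_disulfides > len(seq.cys_positions):
        raise ValueError(
            f"{n_disulfides} disulfides need {2 * n_disulfides} cysteines, "
            f"sequence has {len(seq.cys_positions)}"
        )
    c = h = n = o = s = 0
    for a in seq.residues:
        dc, dh, dn, do, ds = _RESIDUE_FORMULA[a]
        c, h, n, o, s = c + dc, h + dh, n + dn, o + do, s + ds
    h += 2
    o += 1  # terminal water
    h -= 2 * n_disulfides  # each S-S bond removes two hydrogens
    if scheme.c_terminal_amide:
        # -OH -> -NH2: elemental substitution, not a fixed mass offset
        o -= 1
        h += 1
        n += 1
    return {"C": c, "H": h, "N": n, "O": o, "S": s}


def _mass(seq, scheme, n_disulfides, table) -> float:
    comp = elemental_composition(seq, scheme, n_disulfides)
    m = sum(comp[el] * table[el] for el in comp)
    if scheme.label_15N:
        m += comp["N"] * N15_SHIFT
    if scheme.label_13C:
        m += comp["C"] * C13_SHIFT
    return m


def monoisotopic_mass(
    seq: PeptideSequence,
    scheme: IsotopeScheme = IsotopeScheme(),
    n_disulfides: int = 0,
) -> float:
    """Neutral monoisotopic mass in Da.

    Isotope labelling is modelled as 100% enrichment: the 15N (13C) shift is
    the number of nitrogen (carbon) atoms times the isotopic mass difference.
    """
    return _mass(seq, scheme, n_disulfides, MONOISOTOPIC)


def average_mass(
    seq: PeptideSequence,
    scheme: IsotopeScheme = IsotopeScheme(),
    n_disulfides: int = 0,
) -> float:
    """Neutral average mass in Da (standard atomic weights)."""
    return _mass(seq, scheme, n_disulfides, AVERAGE)


def mass_report(
    seq: PeptideSequence, scheme: IsotopeScheme = IsotopeScheme(), n_disulfides: int = 0
) -> dict[str, float]:
    """All four common conventions: neutral/[M+H]+ x monoisotopic/average.

    MALDI-quoted masses are often [M+H]+ and the averaging convention is not
    always stated, so callers get every combination rather than one guess.
    """
    mono = monoisotopic_mass(seq, scheme, n_disulfides)
    avg = average_mass(seq, scheme, n_disulfides)
    return {
        "monoisotopic_neutral": mono,
        "monoisotopic_mh": mono + PROTON_MASS,
        "average_neutral": avg,
        "average_mh": avg + PROTON_MASS,
    }
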