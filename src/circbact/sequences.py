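"""Amino-acid sequence carrier with explicit topology.

Circular bacteriocins are head-to-tail cyclized peptides: the backbone amide
bond between the last and first residues makes position ``n`` adjacent to
position 1.  Every peptide or protein in the toolkit travels as a
:class:`ResidueSequence` so that downstream mass and digestion code can
dispatch on topology instead of guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from .errors import AlphabetError, ModificationError, TopologyError

#: The 20 standard one-letter codes.  Ambiguity codes (B, J, O, U, X, Z) are
#: rejected: downstream mass targets are exact and cannot average residues.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


class Topology(str, Enum):
    LINEAR = "linear"
    CIRCULAR = "circular"


@dataclass(frozen=True)
class ResidueSequence:
    """An amino-acid sequence plus its backbone topology.

    Positions are 1-based.  For circular topology, position ``len(residues)``
    is covalently adjacent to position 1.

    Raises
    ------
    AlphabetError
        If any character is outside the 20-letter standard alphabet.
    TopologyError
        If a circular sequence is shorter than 2 residues.
    """

    residues: str
    topology: Topology = Topology.LINEAR

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlphabetError("empty residue sequence")
        for i, ch in enumerate(self.residues, start=1):
            if ch not in STANDARD_AA:
                raise AlphabetError(
                    f"invalid residue {ch!r} at position {i} "
                    "(only the 20 standard one-letter codes are accepted)"
                )
        # dataclass(frozen=True) stores via object.__setattr__; normalise enum
        if not isinstance(self.topology, Topology):
            object.__setattr__(self, "topology", Topology(self.topology))
        if self.topology is Topology.CIRCULAR and len(self.residues) < 2:
            raise TopologyError("circular topology requires length >= 2")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues

    @property
    def is_circular(self) -> bool:
        return self.topology is Topology.CIRCULAR

    def residue_at(self, position: int) -> str:
        """1-based access; circular sequences wrap in both directions."""
        n = len(self.residues)
        if self.is_circular:
            return self.residues[(position - 1) % n]
        if not 1 <= position <= n:
            raise IndexError(f"position {position} outside 1..{n}")
        return self.residues[position - 1]

    def as_linear(self) -> "ResidueSequence":
        return ResidueSequence(self.residues, Topology.LINEAR)

    def as_circular(self) -> "ResidueSequence":
        return ResidueSequence(self.residues, Topology.CIRCULAR)


@dataclass(frozen=True)
class Modification:
    """A localized mass shift, e.g. methionine oxidation (+15.994915 Da).

    ``position`` is 1-based on the carrier sequence; validation checks that
    the residue there matches ``target_residue``.
    """

    name: str
    target_residue: str
    position: int
    mass_shift_mono: float
    mass_shift_avg: float | None = None

    def mass_shift(self, scale: str = "monoisotopic") -> float:
        if scale == "monoisotopic" or self.mass_shift_avg is None:
            return self.mass_shift_mono
        return self.mass_shift_avg

    def validate_against(self, seq: ResidueSequence) -> None:
        if not 1 <= self.position <= len(seq):
            raise ModificationError(
                f"modification {self.name} at position {self.position} "
                f"outside sequence of length {len(seq)}"
            )
        actual = seq.residues[self.position - 1]
        if actual != self.target_residue:
            raise ModificationError(
                f"modification {self.name} targets {self.target_residue} "
                f"but position {self.position} is {actual}"
            )


def met_oxidation(position: int) -> Modification:
    """The standard +15.994915 Da variable modification on methionine."""
    return Modification(
        name="Oxidation",
        target_residue="M",
        position=position,
        mass_shift_mono=15.994915,
        mass_shift_avg=15.9994,
    )
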