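"""Exact mass arithmetic for linear and head-to-tail cyclized peptides.

Head-to-tail cyclization forms one extra backbone amide bond, so a circular
peptide weighs exactly one water less than its linear counterpart:

    M(circular) = sum(residue masses)            (the closure is a -H2O event)
    M(linear)   = sum(residue masses) + H2O

Charge handling follows the usual proteomics conventions:

    MH+        = M + m(proton)
    [M+zH]z+   = (M + z * m(proton)) / z

Residue masses come from the standard tables shipped with :mod:`pyteomics`;
the proton mass is 1.007276 Da (the physical proton, not atomic hydrogen),
which is required to reproduce 4-decimal MH+ values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from pyteomics import mass as _pmass

from .errors import TopologyError
from .sequences import Modification, ResidueSequence, STANDARD_AA, Topology

PROTON_MASS = 1.007276
WATER_MONO = 18.010565
WATER_AVG = 18.01528
MET_OXIDATION_MONO = 15.994915


def _standard_tables() -> tuple[dict[str, float], dict[str, float]]:
    mono = {aa: _pmass.std_aa_mass[aa] for aa in STANDARD_AA}
    avg = {
        aa: _pmass.calculate_mass(composition=_pmass.std_aa_comp[aa], average=True)
        for aa in STANDARD_AA
    }
    return mono, avg


@dataclass(frozen=True)
class MassConstants:
    """Residue and small-molecule masses used throughout the toolkit."""

    monoisotopic: Mapping[str, float]
    average: Mapping[str, float]
    water_mono: float = WATER_MONO
    water_avg: float = WATER_AVG
    proton: float = PROTON_MASS
    met_oxidation: float = MET_OXIDATION_MONO

    @classmethod
    def standard(cls) -> "MassConstants":
        mono, avg = _standard_tables()
        return cls(monoisotopic=mono, average=avg)

    def water(self, scale: str) -> float:
        return self.water_mono if scale == "monoisotopic" else self.water_avg

    def residue_mass(self, aa: str, scale: str) -> float:
        table = self.monoisotopic if scale == "monoisotopic" else self.average
        return table[aa]


_STANDARD = MassConstants.standard()


def peptide_mass(
    seq: ResidueSequence,
    mods: Iterable[Modification] = (),
    scale: str = "monoisotopic",
    constants: MassConstants = _STANDARD,
) -> float:
    """Neutral mass of a peptide, honouring topology.

    Linear peptides carry the terminal H and OH (one water); circular
    peptides do not, because the head-to-tail amide closure releases it.
    """
    if scale not in ("monoisotopic", "average"):
        raise ValueError(f"unknown mass scale {scale!r}")
    total = sum(constants.residue_mass(aa, scale) for aa in seq.residues)
    for mod in mods:
        mod.validate_against(seq)
        total += mod.mass_shift(scale)
    if seq.topology is Topology.LINEAR:
        total += constants.water(scale)
    return total


def mh_plus(
    seq: ResidueSequence,
    mods: Iterable[Modification] = (),
    constants: MassConstants = _STANDARD,
) -> float:
    """Singly-protonated monoisotopic mass of a *linear* peptide.

    Tryptic fragments are linear by construction; passing a circular
    sequence is a hard error rather than a silent -18 Da surprise.
    """
    if seq.is_circular:
        raise TopologyError("MH+ is defined for linear (tryptic) fragments only")
    return peptide_mass(seq, mods, "monoisotopic", constants) + constants.proton


def mz_for_charge(
    neutral_mass: float, charge: int, constants: MassConstants = _STANDARD
) -> float:
    """m/z of the [M+zH]z+ species for a neutral mass."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * constants.proton) / charge


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return 1e6 * (observed - theoretical) / theoretical
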