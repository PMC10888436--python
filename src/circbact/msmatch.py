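"""Match theoretical digests and intact masses against observed peaks.

Two independent lines of evidence decide whether a candidate peptide is
head-to-tail circular:

* **intact mass** — the cyclized molecule weighs one water less than its
  linear deduced mass.  Linear-mode MALDI-TOF measures average masses, so
  the intact check compares the singly-protonated *average* cyclic mass
  against the peak list with a Dalton-scale tolerance (default 1.5 Da).
* **junction-spanning fragments** — high-resolution LC-MS/MS of a tryptic
  digest can only contain a fragment crossing the last->first residue bond
  if that bond exists.  Fragment matching is monoisotopic with a ppm-scale
  tolerance (default 20 ppm).

The verdict is ``circular_supported`` only when both lines agree; an intact
mass matching the non-dehydrated linear species instead yields
``linear_only``; anything else is ``insufficient``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .digest import DigestPeptide
from .errors import ConfigurationError
from .masscalc import MassConstants, mz_for_charge, peptide_mass, ppm_error
from .mining import PrecursorModel
from .sequences import Modification, met_oxidation

_STD = MassConstants.standard()


@dataclass(frozen=True)
class PeakList:
    """Observed peaks, sorted ascending by m/z after load."""

    peaks: tuple[tuple[float, float], ...]
    kind: str  # "intact_maldi" | "fragment_lcmsms"

    def __post_init__(self) -> None:
        assert self.kind in ("intact_maldi", "fragment_lcmsms")
        for mz, inten in self.peaks:
            if mz <= 0:
                raise ValueError(f"nonpositive m/z {mz}")
            if inten < 0:
                raise ValueError(f"negative intensity {inten}")
        object.__setattr__(self, "peaks", tuple(sorted(self.peaks)))

    @property
    def mzs(self) -> list[float]:
        return [p[0] for p in self.peaks]


def load_peaklist(path: Path | str, kind: str) -> PeakList:
    """Read a peak list from two-column text (m/z [intensity], whitespace or
    comma separated; intensity defaults to 1.0) or minimal MGF."""
    text = Path(path).read_text()
    if "BEGIN IONS" in text:
        return _parse_mgf(text, kind)
    peaks: list[tuple[float, float]] = []
    for line in text.splitlines():
        line = line.strip().replace(",", " ")
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        mz = float(parts[0])
        inten = float(parts[1]) if len(parts) > 1 else 1.0
        peaks.append((mz, inten))
    return PeakList(tuple(peaks), kind)


def _parse_mgf(text: str, kind: str) -> PeakList:
    peaks: list[tuple[float, float]] = []
    inside = False
    for line in text.splitlines():
        line = line.strip()
        if line == "BEGIN IONS":
            inside = True
        elif line == "END IONS":
            inside = False
        elif inside and line and not line.startswith(("PEPMASS", "CHARGE", "TITLE", "RTINSECONDS")):
            parts = line.split()
            peaks.append((float(parts[0]), float(parts[1]) if len(parts) > 1 else 1.0))
    return PeakList(tuple(peaks), kind)


@dataclass(frozen=True)
class FragmentMatch:
    peptide: DigestPeptide
    mods: tuple[Modification, ...]
    charge: int
    theoretical_mz: float
    observed_mz: float
    error_ppm: float


@dataclass
class IntactCheck:
    """Outcome of the dehydration (cyclization) intact-mass test."""

    deduced_linear_avg: float
    expected_cyclic_mh: float
    expected_linear_mh: float
    matched_peak: float | None
    delta: float | None
    cyclic_pass: bool
    linear_pass: bool
    nominal_shift: float  # deduced linear minus expected cyclic neutral loss, ~18 Da


@dataclass
class CircularityEvidence:
    candidate: PrecursorModel | None
    intact_check: IntactCheck | None
    junction_matches: list[FragmentMatch]
    internal_matches: list[FragmentMatch]
    verdict: str  # "circular_supported" | "linear_only" | "insufficient"


def _mod_combinations(
    pep: DigestPeptide, max_ox_met: int
) -> Iterable[tuple[Modification, ...]]:
    yield ()
    if max_ox_met <= 0:
        return
    met_positions = [i + 1 for i, aa in enumerate(pep.sequence.residues) if aa == "M"]
    for k in range(1, max_ox_met + 1):
        for combo in itertools.combinations(met_positions, k):
            yield tuple(met_oxidation(p) for p in combo)


def match_fragments(
    theoretical: Sequence[DigestPeptide],
    peaks: PeakList,
    charges: Iterable[int] = (1, 2),
    tol_ppm: float = 20.0,
    max_ox_met: int = 1,
    constants: MassConstants = _STD,
) -> list[FragmentMatch]:
    """Every (peptide, modification combination, charge, peak) within the
    ppm tolerance, sorted by absolute error.  One observed peak may support
    several peptides; the ambiguity is preserved, never resolved silently.
    """
    if not theoretical:
        raise ConfigurationError("empty theoretical peptide set")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    assert peaks.kind == "fragment_lcmsms"
    matches: list[FragmentMatch] = []
    mzs = peaks.mzs
    for pep in theoretical:
        for mods in _mod_combinations(pep, max_ox_met):
            neutral = peptide_mass(pep.sequence, mods, "monoisotopic", constants)
            for z in charges:
                theo = mz_for_charge(neutral, z, constants)
                for obs in _neighbours(mzs, theo, theo * tol_ppm * 1e-6):
                    err = ppm_error(obs, theo)
                    if abs(err) <= tol_ppm:
                        matches.append(
                            FragmentMatch(pep, mods, z, theo, obs, err)
                        )
    matches.sort(key=lambda m: abs(m.error_ppm))
    return matches


def _neighbours(sorted_mzs: Sequence[float], center: float, radius: float) -> list[float]:
    import bisect

    lo = bisect.bisect_left(sorted_mzs, center - radius)
    hi = bisect.bisect_right(sorted_mzs, center + radius)
    return list(sorted_mzs[lo:hi])


def intact_cyclic_check_from_mass(
    deduced_linear_avg: float,
    peaks: PeakList | None,
    tol_da: float = 1.5,
    constants: MassConstants = _STD,
) -> IntactCheck:
    """Dehydration test from a deduced linear average mass.

    Expected observed species are singly-protonated:
    cyclic [M+H]+ = deduced - H2O(avg) + proton, and the competing linear
    hypothesis [M+H]+ = deduced + proton.  The nearest peak within tol_da
    of either hypothesis is recorded with its delta.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    cyclic_mh = deduced_linear_avg - constants.water_avg + constants.proton
    linear_mh = deduced_linear_avg + constants.proton
    matched = delta = None
    cyclic_pass = linear_pass = False
    if peaks is not None and peaks.peaks:
        assert peaks.kind == "intact_maldi"
        nearest_c = min(peaks.mzs, key=lambda mz: abs(mz - cyclic_mh))
        nearest_l = min(peaks.mzs, key=lambda mz: abs(mz - linear_mh))
        if abs(nearest_c - cyclic_mh) <= tol_da:
            cyclic_pass = True
            matched, delta = nearest_c, nearest_c - cyclic_mh
        if abs(nearest_l - linear_mh) <= tol_da:
            linear_pass = True
            if matched is None:
                matched, delta = nearest_l, nearest_l - linear_mh
    return IntactCheck(
        deduced_linear_avg=deduced_linear_avg,
        expected_cyclic_mh=cyclic_mh,
        expected_linear_mh=linear_mh,
        matched_peak=matched,
        delta=delta,
        cyclic_pass=cyclic_pass,
        linear_pass=linear_pass,
        nominal_shift=constants.water_mono,
    )


def intact_cyclic_check(
    model: PrecursorModel,
    peaks: PeakList | None,
    tol_da: float = 1.5,
    constants: MassConstants = _STD,
) -> IntactCheck:
    """Dehydration test for a precursor model: the deduced linear mass is
    the average mass of the (linearized) mature core."""
    deduced = peptide_mass(model.core.as_linear(), (), "average", constants)
    return intact_cyclic_check_from_mass(deduced, peaks, tol_da, constants)


def assemble_evidence(
    model: PrecursorModel | None,
    fragment_matches: Sequence[FragmentMatch],
    intact: IntactCheck | None,
) -> CircularityEvidence:
    """Combine the two evidence lines into one verdict.

    circular_supported: intact cyclic mass matched AND >= 1 junction-spanning
    fragment matched.  linear_only: intact matched the non-dehydrated linear
    hypothesis (and circular support is absent).  insufficient: otherwise.
    """
    junction = [m for m in fragment_matches if m.peptide.junction_spanning]
    internal = [m for m in fragment_matches if not m.peptide.junction_spanning]
    if intact is not None and intact.cyclic_pass and junction:
        verdict = "circular_supported"
    elif intact is not None and intact.linear_pass and not (intact.cyclic_pass and junction):
        verdict = "linear_only"
    else:
        verdict = "insufficient"
    return CircularityEvidence(
        candidate=model,
        intact_check=intact,
        junction_matches=junction,
        internal_matches=internal,
        verdict=verdict,
    )
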