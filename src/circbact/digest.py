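"""In-silico proteolysis of linear and head-to-tail circular peptides.

The point of digesting a *circular* peptide is the junction-spanning
fragment: a proteolytic product that covers the covalent bond between the
last and first residues of the mature cycle.  Detecting such a fragment in
an MS run is direct evidence that the peptide was circular, because no
linear form of the molecule can produce it.

Circular digestion is implemented by enumeration over the doubled sequence
(every fragment of length <= n that starts in the first copy), which covers
all rotations in one pass.  A brute-force all-rotations oracle lives in the
test suite and must agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

from .errors import TopologyError
from .sequences import ResidueSequence, Topology


@dataclass(frozen=True)
class ProteaseRule:
    """Cleave after any residue in ``cleave_after`` unless the next residue
    is in ``blocked_by_next`` (classic trypsin: after K/R, not before P)."""

    name: str
    cleave_after: frozenset[str]
    blocked_by_next: frozenset[str] = frozenset()


TRYPSIN = ProteaseRule("trypsin", frozenset("KR"), frozenset("P"))


@dataclass(frozen=True)
class DigestPeptide:
    """A proteolytic fragment located on its parent sequence.

    ``start`` is 1-based on the parent; a fragment of a circular parent
    wraps the n->1 adjacency iff ``start + length - 1 > parent_length``,
    in which case ``junction_spanning`` is True.
    """

    sequence: ResidueSequence
    start: int
    length: int
    missed_cleavages: int
    junction_spanning: bool
    parent_length: int
    specificity: str = "full"  # "full" | "semi"

    def __post_init__(self) -> None:
        assert 1 <= self.start <= self.parent_length
        assert len(self.sequence) == self.length


def cleavage_sites(seq: ResidueSequence, rule: ProteaseRule = TRYPSIN) -> list[int]:
    """1-based positions after which the protease cuts.

    For linear sequences the final position is eligible (cutting there is a
    no-op but marks the residue as a tryptic terminus).  For circular
    sequences position n is followed by position 1.
    """
    n = len(seq)
    sites: list[int] = []
    for p in range(1, n + 1):
        if seq.residues[p - 1] not in rule.cleave_after:
            continue
        if seq.is_circular:
            nxt = seq.residues[p % n]
        else:
            nxt = seq.residues[p] if p < n else None
        if nxt is not None and nxt in rule.blocked_by_next:
            continue
        sites.append(p)
    return sites


def digest_linear(
    seq: ResidueSequence,
    rule: ProteaseRule = TRYPSIN,
    max_missed: int = 0,
) -> list[DigestPeptide]:
    """All fully-specific fragments of a linear peptide with up to
    ``max_missed`` missed cleavages, ordered by (start, length)."""
    if seq.is_circular:
        raise TopologyError("digest_linear requires linear topology; use digest_circular")
    n = len(seq)
    internal = [p for p in cleavage_sites(seq, rule) if p < n]
    # fragment boundaries: 0, internal sites, n  (0-based half-open cuts)
    bounds = [0] + internal + [n]
    out: list[DigestPeptide] = []
    for i in range(len(bounds) - 1):
        for k in range(max_missed + 1):
            j = i + 1 + k
            if j >= len(bounds):
                break
            s, e = bounds[i], bounds[j]
            out.append(
                DigestPeptide(
                    sequence=ResidueSequence(seq.residues[s:e]),
                    start=s + 1,
                    length=e - s,
                    missed_cleavages=k,
                    junction_spanning=False,
                    parent_length=n,
                )
            )
    out.sort(key=lambda p: (p.start, p.length))
    return out


def digest_circular(
    core: ResidueSequence,
    rule: ProteaseRule = TRYPSIN,
    max_missed: int = 0,
) -> list[DigestPeptide]:
    """All fully-specific fragments of a head-to-tail circular peptide.

    With zero missed cleavages and >= 1 cleavage site the fragments
    partition the cycle, so there are exactly |sites| of them and exactly
    one wraps the junction.  A site-free cycle is trypsin-resistant and is
    returned whole as a single junction-spanning record.
    """
    if not core.is_circular:
        raise TopologyError("digest_circular requires circular topology; use digest_linear")
    n = len(core)
    sites = cleavage_sites(core, rule)
    if not sites:
        return [
            DigestPeptide(
                sequence=ResidueSequence(core.residues),
                start=1,
                length=n,
                missed_cleavages=0,
                junction_spanning=True,
                parent_length=n,
            )
        ]
    doubled = core.residues * 2
    m = len(sites)
    out: list[DigestPeptide] = []
    for i in range(m):
        start = sites[i] % n + 1  # first residue after the cut, wrapped into 1..n
        for k in range(max_missed + 1):
            if k + 1 > m:
                break  # would lap the full circle more than once
            end_site = sites[(i + 1 + k) % m]
            length = (end_site - start + 1) % n
            if length == 0:
                length = n
            frag = doubled[start - 1 : start - 1 + length]
            out.append(
                DigestPeptide(
                    sequence=ResidueSequence(frag),
                    start=start,
                    length=length,
                    missed_cleavages=k,
                    junction_spanning=start + length - 1 > n,
                    parent_length=n,
                )
            )
    out.sort(key=lambda p: (p.start, p.length))
    return out


def semi_specific_expand(
    peptides: Iterable[DigestPeptide], min_len: int = 6
) -> list[DigestPeptide]:
    """Prefixes and suffixes of fully-specific peptides (one ragged end).

    De-novo / open searches routinely report such semi-specific fragments;
    matching them requires enumerating them on our side.  The junction flag
    is recomputed from the truncated coordinates, never inherited: a suffix
    that starts past position n's wrap no longer covers the junction.
    """
    out: list[DigestPeptide] = []
    seen: set[tuple[str, int, int]] = set()
    for pep in peptides:
        n = pep.parent_length
        for length in range(min_len, pep.length):
            # prefix keeps the start
            pre = replace(
                pep,
                sequence=ResidueSequence(pep.sequence.residues[:length]),
                length=length,
                junction_spanning=pep.junction_spanning and pep.start + length - 1 > n,
                specificity="semi",
            )
            # suffix shifts the start forward (wrapping on circular parents)
            s = pep.start + (pep.length - length)
            s_norm = (s - 1) % n + 1
            suf = replace(
                pep,
                sequence=ResidueSequence(pep.sequence.residues[pep.length - length :]),
                start=s_norm,
                length=length,
                junction_spanning=pep.junction_spanning and s_norm + length - 1 > n,
                specificity="semi",
            )
            for cand in (pre, suf):
                key = (cand.sequence.residues, cand.start, cand.length)
                if key not in seen:
                    seen.add(key)
                    out.append(cand)
    out.sort(key=lambda p: (p.start, p.length))
    return out


def deduplicate_by_sequence(peptides: Iterable[DigestPeptide]) -> list[DigestPeptide]:
    """Reporting-layer helper: keep one record per distinct sequence,
    preferring fewer missed cleavages, then lower start."""
    best: dict[str, DigestPeptide] = {}
    for pep in peptides:
        key = pep.sequence.residues
        cur = best.get(key)
        if cur is None or (pep.missed_cleavages, pep.start) < (cur.missed_cleavages, cur.start):
            best[key] = pep
    return sorted(best.values(), key=lambda p: (p.start, p.length))
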