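"""Split-intein-mediated-ligation (SIML) construct design.

To express a head-to-tail circular peptide in a heterologous host, the
mature cycle is opened at a chosen residue (a circular permutation), the
resulting linear peptide is sandwiched between the C- and N-fragments of a
split intein (IntC - core - IntN), and a degradation tag is appended so
unspliced product is cleared.  Trans-splicing of the intein halves then
excises them and ligates the core's new termini back into the circle.

The module also builds plain T7 PCR templates (promoter + ATG + coding +
TAA + terminator with flanking primers) for cell-free expression of linear
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, DesignError
from .sequences import ResidueSequence, Topology

#: Constant regions of the cell-free expression primers; overridable.
T7_PROMOTER = "GCGAATTAATACGACTCACTATAGGG"
T7_TERMINATOR = "AACCCCTCTCTAAACGGAGGGGTTT"


# ---------------------------------------------------------------------------
# Circular permutation

def circular_permute(core: ResidueSequence, split_position: int) -> ResidueSequence:
    """Open the cycle so ``split_position`` becomes the new linear N-terminus.

    The last residue of the permuted peptide is the core residue at
    ``split_position - 1`` (wrapping), which is exactly the pair of residues
    the intein chemistry must re-ligate.
    """
    if not core.is_circular:
        raise ValueError("circular_permute requires a circular core")
    n = len(core)
    if not 1 <= split_position <= n:
        raise ValueError(f"split position {split_position} outside 1..{n}")
    s = core.residues
    return ResidueSequence(s[split_position - 1 :] + s[: split_position - 1], Topology.LINEAR)


# ---------------------------------------------------------------------------
# Intein configuration

@dataclass(frozen=True)
class InteinPair:
    """C- and N-terminal split-intein fragments (protein sequences).

    The part order in the construct is IntC - core - IntN (configurable);
    sequences are configuration inputs, loaded from YAML.
    """

    int_c: ResidueSequence
    int_n: ResidueSequence
    name: str = "intein"
    c_first: bool = True

    @classmethod
    def from_yaml(cls, path: Path | str) -> "InteinPair":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("int_c", "int_n"):
            if not data.get(key):
                raise ConfigurationError(
                    f"intein config {path} missing key {key!r} (protein sequence)"
                )
        return cls(
            int_c=ResidueSequence(data["int_c"]),
            int_n=ResidueSequence(data["int_n"]),
            name=data.get("name", "intein"),
            c_first=bool(data.get("c_first", True)),
        )

    @classmethod
    def bundled(cls) -> "InteinPair":
        """The placeholder pair shipped with the package (synthetic
        sequences; supply a curated YAML for real constructs)."""
        path = resources.files("circbact.data") / "inteins.yaml"
        with resources.as_file(path) as p:
            return cls.from_yaml(p)


@dataclass
class SplitDesign:
    core: ResidueSequence
    split_position: int
    permuted_core: ResidueSequence
    parts: list[tuple[str, str]]  # ordered (part name, protein sequence)
    protein: ResidueSequence
    dna: str | None = None


def build_siml_protein(
    core: ResidueSequence,
    split_position: int,
    inteins: InteinPair,
    tag: str | None = "AANDENYALAA",
) -> SplitDesign:
    """Assemble the SIML fusion protein for one split position.

    Default tag is the SsrA-style degradation signal; pass ``None`` to omit.
    """
    permuted = circular_permute(core, split_position)
    first, second = ("IntC", inteins.int_c), ("IntN", inteins.int_n)
    if not inteins.c_first:
        first, second = ("IntN", inteins.int_n), ("IntC", inteins.int_c)
    parts = [
        (first[0], first[1].residues),
        ("core", permuted.residues),
        (second[0], second[1].residues),
    ]
    if tag:
        parts.append(("tag", ResidueSequence(tag).residues))
    protein = ResidueSequence("".join(seq for _, seq in parts))
    return SplitDesign(
        core=core,
        split_position=split_position,
        permuted_core=permuted,
        parts=parts,
        protein=protein,
    )


# ---------------------------------------------------------------------------
# Codon usage and reverse translation

@dataclass(frozen=True)
class CodonUsageTable:
    """Relative synonymous codon frequencies per amino acid (+ ``*`` stops).

    Plain-text format, one entry per line: ``<aa> <codon> <fraction>``;
    fractions within each amino acid must sum to 1 (tolerance 1e-6).
    """

    codons: dict[str, tuple[tuple[str, float], ...]]
    organism: str = "unknown"

    def __post_init__(self) -> None:
        for aa, entries in self.codons.items():
            total = sum(f for _, f in entries)
            if abs(total - 1.0) > 1e-6:
                raise ConfigurationError(
                    f"codon frequencies for {aa!r} sum to {total}, expected 1"
                )

    @classmethod
    def from_text(cls, path: Path | str, organism: str = "unknown") -> "CodonUsageTable":
        table: dict[str, list[tuple[str, float]]] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            aa, codon, frac = line.split()
            table.setdefault(aa, []).append((codon.upper(), float(frac)))
        return cls({aa: tuple(v) for aa, v in table.items()}, organism)

    @classmethod
    def ecoli(cls) -> "CodonUsageTable":
        path = resources.files("circbact.data") / "ecoli_codon_usage.txt"
        with resources.as_file(path) as p:
            return cls.from_text(p, organism="E. coli K-12")

    def best_codon(self, aa: str) -> str:
        entries = self.codons.get(aa)
        if not entries:
            raise ConfigurationError(f"no codons for residue {aa!r} in usage table")
        return max(sorted(entries), key=lambda e: e[1])[0]


def reverse_translate(
    protein: ResidueSequence | str,
    table: CodonUsageTable | None = None,
    strategy: str = "max_frequency",
    seed: int | None = None,
) -> str:
    """Protein -> DNA using the codon-usage table.

    ``max_frequency`` is deterministic (most frequent codon, alphabetical
    tie-break); ``weighted`` samples codons by frequency and is reproducible
    for a given seed.  Round-trips exactly: translate(result) == protein.
    """
    table = table or CodonUsageTable.ecoli()
    seq = protein.residues if isinstance(protein, ResidueSequence) else protein
    if strategy == "max_frequency":
        return "".join(table.best_codon(aa) for aa in seq)
    if strategy == "weighted":
        rng = np.random.default_rng(seed)
        out = []
        for aa in seq:
            entries = table.codons.get(aa)
            if not entries:
                raise ConfigurationError(f"no codons for residue {aa!r} in usage table")
            codons = [c for c, _ in entries]
            probs = np.array([f for _, f in entries])
            out.append(codons[rng.choice(len(codons), p=probs / probs.sum())])
        return "".join(out)
    raise ValueError(f"unknown strategy {strategy!r}")


def translate_dna(dna: str) -> str:
    """Standard-code translation of an in-frame coding sequence."""
    return str(Seq(dna).translate())


# ---------------------------------------------------------------------------
# Expression cassette and T7 PCR template

def _check_frame(coding: str) -> None:
    if len(coding) % 3:
        raise DesignError(f"coding length {len(coding)} not divisible by 3")
    for i in range(0, len(coding) - 3 + 1, 3):
        if coding[i : i + 3] in ("TAA", "TAG", "TGA") and i < len(coding) - 3:
            raise DesignError(f"in-frame stop codon at codon {i // 3 + 1}")


def build_expression_cassette(
    coding_dna: str,
    promoter: str = T7_PROMOTER,
    terminator: str = T7_TERMINATOR,
    name: str = "siml_construct",
) -> SeqRecord:
    """Promoter + ATG + coding + TAA + terminator, as an annotated GenBank
    record (promoter / CDS / terminator features, 1-based inclusive)."""
    coding = coding_dna.upper()
    _check_frame(coding)
    if not coding.startswith("ATG"):
        coding = "ATG" + coding
    if coding[-3:] not in ("TAA", "TAG", "TGA"):
        coding = coding + "TAA"
    full = promoter + coding + terminator
    rec = SeqRecord(Seq(full), id=name, name=name[:16], description="SIML expression cassette")
    rec.annotations["molecule_type"] = "DNA"
    p = len(promoter)
    rec.features = [
        SeqFeature(FeatureLocation(0, p), type="regulatory",
                   qualifiers={"regulatory_class": ["promoter"], "note": ["T7 promoter"]}),
        SeqFeature(FeatureLocation(p, p + len(coding)), type="CDS",
                   qualifiers={"translation": [translate_dna(coding)[:-1]]}),
        SeqFeature(FeatureLocation(p + len(coding), len(full)), type="regulatory",
                   qualifiers={"regulatory_class": ["terminator"], "note": ["T7 terminator"]}),
    ]
    return rec


@dataclass
class LinearT7Template:
    target_protein: ResidueSequence
    forward_primer: str
    reverse_primer: str
    amplicon: str


def build_linear_t7_template(
    protein: ResidueSequence,
    table: CodonUsageTable | None = None,
    promoter: str = T7_PROMOTER,
    terminator: str = T7_TERMINATOR,
    primer_core_len: int = 24,
) -> LinearT7Template:
    """Linear PCR template for cell-free expression of a (linear) peptide.

    amplicon = promoter + ATG + coding + TAA + terminator;
    forward primer = promoter + first ``primer_core_len`` nt of the CDS;
    reverse primer = reverse-complement of (last ``primer_core_len`` coding
    nt + TAA + terminator).  Both primers are exact amplicon prefixes /
    reverse-complemented suffixes by construction.
    """
    if len(protein) * 3 < primer_core_len:
        raise ValueError(
            f"protein of {len(protein)} residues too short for "
            f"{primer_core_len}-nt primer cores"
        )
    coding = reverse_translate(protein, table)
    cds = "ATG" + coding + "TAA"
    amplicon = promoter + cds + terminator
    forward = promoter + cds[:primer_core_len]
    tail = coding[-primer_core_len:] + "TAA" + terminator
    reverse = str(Seq(tail).reverse_complement())
    return LinearT7Template(
        target_protein=protein,
        forward_primer=forward,
        reverse_primer=reverse,
        amplicon=amplicon,
    )
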