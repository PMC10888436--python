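"""Deterministic synthetic genomes, clusters and MS peak lists.

The generator produces the study conditions the rest of the toolkit is
validated against: a toy contig carrying a circular-bacteriocin cluster
(precursor ORF = leader + mature core, SpoIIM/DUF95-annotated gene, ABC
ATP-binding gene with Walker motifs, unannotated membrane gene), plus
simulated LC-MS/MS fragment peaks (doubly-protonated circular-digest
products with Gaussian ppm error and uniform decoys) and an intact MALDI
peak ([M+H]+ average mass of the cyclic or, in linear-truth mode, linear
species).  Every emitted peak is traceable to a peptide or marked decoy,
and regeneration with the same seed is byte-identical (numpy PCG64).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .designer import CodonUsageTable, reverse_translate
from .digest import TRYPSIN, digest_circular, digest_linear, semi_specific_expand
from .masscalc import MassConstants, mz_for_charge, peptide_mass
from .mining import ReferencePanel
from .sequences import ResidueSequence, Topology

_STD = MassConstants.standard()
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

CORE_N_TERM = "LVW"
CORE_C_TERM = "WYF"


@dataclass
class SynthParams:
    core_len: int = 65
    leader_len: int = 49
    context_roles: tuple[str, ...] = ("spoIIM_duf95", "abc_atp_binding", "membrane")
    mutation_rate: float = 0.25  # divergence of the core from its panel parent
    spacer_range: tuple[int, int] = (150, 400)
    circular_truth: bool = True

    def __post_init__(self) -> None:
        if self.core_len < 2:
            raise ValueError("core_len must be >= 2 (a cycle needs two residues)")
        if self.leader_len < 1:
            raise ValueError("leader_len must be >= 1 (includes the start Met)")


@dataclass
class NoiseParams:
    ppm_sigma: float = 5.0
    decoy_fraction: float = 0.3
    met_ox_prob: float = 0.0
    intact_sigma_da: float = 0.3
    decoy_min_ppm: float = 50.0  # decoys stay at least this far from true peaks

    def __post_init__(self) -> None:
        if self.ppm_sigma < 0 or self.intact_sigma_da < 0:
            raise ValueError("noise sigmas must be non-negative")
        if not 0 <= self.decoy_fraction < 1:
            raise ValueError("decoy_fraction must be in [0, 1)")


@dataclass
class SyntheticTruth:
    seed: int
    core: str
    leader: str
    circular_truth: bool
    genes: list[dict]  # role, id, start, end, strand
    panel_parent: str
    true_peptides: list[dict] = field(default_factory=list)
    peak_provenance: list[dict] = field(default_factory=list)
    noise: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)


# ---------------------------------------------------------------------------
# Protein construction helpers

def _random_protein(rng: np.random.Generator, n: int, alphabet: str = _AA20) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


def _mutate_core(rng: np.random.Generator, parent: str, target_len: int, rate: float) -> str:
    """Diverge a panel core: point mutations at ``rate`` plus middle
    indels to reach ``target_len``; the three terminal residues at each end
    are protected so the family's terminal rule survives."""
    core = list(parent)
    while len(core) > target_len:
        core.pop(len(core) // 2)
    while len(core) < target_len:
        core.insert(len(core) // 2, _AA20[rng.integers(0, 20)])
    for i in range(3, len(core) - 3):
        if rng.random() < rate:
            core[i] = _AA20[rng.integers(0, 20)]
    assert core[0] in CORE_N_TERM and core[-1] in CORE_C_TERM
    return "".join(core)


def _abc_protein(rng: np.random.Generator, n: int = 220) -> str:
    prot = list("M" + _random_protein(rng, n - 1, "ASTNQGDEHKLRPVI"))
    prot[40:49] = "GASGSGKST"  # Walker A
    prot[120:125] = "ILVFD"  # Walker B-like hydrophobic block + Asp
    return "".join(prot)


def _membrane_protein(rng: np.random.Generator, n: int = 140, n_tm: int = 2) -> str:
    # K-free polar background so no Walker A can arise by chance
    prot = list("M" + _random_protein(rng, n - 1, "STNQGPADE"))
    gap = (n - 20) // n_tm
    for t in range(n_tm):
        start = 5 + t * gap
        seg = _random_protein(rng, 21, "ILVFA")
        prot[start : start + 21] = seg
    return "".join(prot)


def _spoiim_protein(rng: np.random.Generator, n: int = 190) -> str:
    return _membrane_protein(rng, n, n_tm=4)


def _immunity_protein(rng: np.random.Generator, n: int = 60) -> str:
    return "M" + _random_protein(rng, n - 1, "STNQGADEKLIV")


_CONTEXT_BUILDERS = {
    "abc_atp_binding": (_abc_protein, ""),
    "membrane": (_membrane_protein, ""),
    "spoIIM_duf95": (_spoiim_protein, "SpoIIM/DUF95 family protein"),
    "immunity": (_immunity_protein, "putative immunity protein"),
}


# ---------------------------------------------------------------------------
# Cluster generation

def gen_cluster(
    seed: int,
    params: SynthParams | None = None,
    panel: ReferencePanel | None = None,
    contig: str = "synthetic1",
) -> tuple[SeqRecord, SyntheticTruth]:
    """One synthetic contig with a circular-bacteriocin cluster.

    The mature core is a mutated descendant of a bundled panel core (so the
    homology miner has something to anchor on, as it would for a real family
    member); the leader starts with Met and is otherwise random.  Returns
    the annotated GenBank record plus the complete ground truth.
    """
    params = params or SynthParams()
    panel = panel or ReferencePanel.bundled()
    rng = np.random.default_rng(seed)
    table = CodonUsageTable.ecoli()

    names = sorted(panel.circular)
    # prefer a parent close to the requested core length
    names.sort(key=lambda nm: abs(len(panel.circular[nm]) - params.core_len))
    parent = names[0]
    core = _mutate_core(rng, panel.circular[parent].residues, params.core_len, params.mutation_rate)
    leader = "M" + _random_protein(rng, params.leader_len - 1, "ASTNQGDEKLRIV")
    precursor = leader + core

    genes: list[tuple[str, str, str]] = [("precursor", precursor, "bacteriocin precursor")]
    for role in params.context_roles:
        builder, product = _CONTEXT_BUILDERS[role]
        genes.append((role, builder(rng), product))

    dna_parts: list[str] = []
    features: list[SeqFeature] = []
    truth_genes: list[dict] = []
    pos = 0
    for idx, (role, protein, product) in enumerate(genes):
        spacer = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(*params.spacer_range)))
        dna_parts.append(spacer)
        pos += len(spacer)
        cds = reverse_translate(protein, table) + "TAA"
        start, end = pos + 1, pos + len(cds)  # 1-based inclusive, stop included
        gene_id = f"syn{idx + 1:03d}"
        quals = {"locus_tag": [gene_id], "translation": [protein]}
        if product:
            quals["product"] = [product]
        features.append(
            SeqFeature(FeatureLocation(start - 1, end, strand=+1), type="CDS", qualifiers=quals)
        )
        truth_genes.append(
            {"role": role, "id": gene_id, "start": start, "end": end, "strand": "+"}
        )
        dna_parts.append(cds)
        pos += len(cds)
    tail = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(*params.spacer_range)))
    dna_parts.append(tail)

    rec = SeqRecord(Seq("".join(dna_parts)), id=contig, name=contig[:16],
                    description="synthetic circular-bacteriocin cluster")
    rec.annotations["molecule_type"] = "DNA"
    rec.features = features
    truth = SyntheticTruth(
        seed=seed,
        core=core,
        leader=leader,
        circular_truth=params.circular_truth,
        genes=truth_genes,
        panel_parent=parent,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# Peak-list generation

def gen_peaklists(
    truth: SyntheticTruth,
    seed: int,
    noise: NoiseParams | None = None,
    max_missed: int = 2,
    semi: bool = False,
    constants: MassConstants = _STD,
):
    """Simulated (fragment, intact) peak lists for a truth record.

    Fragment peaks are [M+2H]2+ of the tryptic digest of the core — the
    circular digest when the truth is circular, the linear digest otherwise
    — with Gaussian ppm error.  The intact peak is the singly-protonated
    average-mass species (cyclic: deduced - H2O).  Decoy peaks are uniform
    over the observed m/z range but kept >= decoy_min_ppm away from every
    true theoretical peak so they are decoys, not shifted duplicates.

    Imports are local to keep this module import-light:
    returns (fragment PeakList, intact PeakList).
    """
    from .msmatch import PeakList  # local import: msmatch imports mining

    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)
    core_circ = ResidueSequence(truth.core, Topology.CIRCULAR)
    if truth.circular_truth:
        peptides = digest_circular(core_circ, TRYPSIN, max_missed)
    else:
        peptides = digest_linear(core_circ.as_linear(), TRYPSIN, max_missed)
    if semi:
        peptides = peptides + semi_specific_expand(peptides)

    truth.true_peptides = [
        {"sequence": p.sequence.residues, "start": p.start, "length": p.length,
         "missed": p.missed_cleavages, "junction": p.junction_spanning,
         "specificity": p.specificity}
        for p in peptides
    ]

    frag_peaks: list[tuple[float, float]] = []
    provenance: list[dict] = []
    theo_mzs: list[float] = []
    for p in peptides:
        neutral = peptide_mass(p.sequence, (), "monoisotopic", constants)
        theo = mz_for_charge(neutral, 2, constants)
        theo_mzs.append(theo)
        obs = theo * (1.0 + rng.normal(0.0, noise.ppm_sigma) * 1e-6)
        inten = float(rng.uniform(0.2, 1.0))
        frag_peaks.append((obs, inten))
        provenance.append({"mz": obs, "peptide": p.sequence.residues,
                           "junction": p.junction_spanning, "decoy": False})

    n_true = len(frag_peaks)
    n_decoy = int(round(n_true * noise.decoy_fraction / (1.0 - noise.decoy_fraction)))
    lo, hi = min(theo_mzs) - 5.0, max(theo_mzs) + 5.0
    added = 0
    while added < n_decoy:
        mz = float(rng.uniform(lo, hi))
        if any(abs(mz - t) / t * 1e6 < noise.decoy_min_ppm for t in theo_mzs):
            continue
        frag_peaks.append((mz, float(rng.uniform(0.2, 1.0))))
        provenance.append({"mz": mz, "peptide": None, "junction": False, "decoy": True})
        added += 1

    deduced = peptide_mass(core_circ.as_linear(), (), "average", constants)
    if truth.circular_truth:
        intact_mh = deduced - constants.water_avg + constants.proton
    else:
        intact_mh = deduced + constants.proton
    intact_obs = intact_mh + rng.normal(0.0, noise.intact_sigma_da)
    intact_peaks = [(float(intact_obs), 1.0)]
    provenance.append({"mz": float(intact_obs), "peptide": "<intact>",
                       "junction": False, "decoy": False})

    truth.peak_provenance = provenance
    truth.noise = {"ppm_sigma": noise.ppm_sigma, "decoy_fraction": noise.decoy_fraction,
                   "intact_sigma_da": noise.intact_sigma_da, "seed": seed}
    return (
        PeakList(tuple(frag_peaks), "fragment_lcmsms"),
        PeakList(tuple(intact_peaks), "intact_maldi"),
    )


def write_fixture(seed: int, out_dir: Path | str,
                  params: SynthParams | None = None,
                  noise: NoiseParams | None = None) -> dict[str, Path]:
    """Generate and write genome.gbk + fragment/intact peak lists + truth
    JSON into ``out_dir``; returns the paths."""
    from Bio import SeqIO

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rec, truth = gen_cluster(seed, params)
    frags, intact = gen_peaklists(truth, seed + 1, noise)
    paths = {
        "genome": out / "genome.gbk",
        "fragments": out / "fragments.txt",
        "intact": out / "intact.txt",
        "truth": out / "truth.json",
    }
    SeqIO.write(rec, str(paths["genome"]), "genbank")
    paths["fragments"].write_text(
        "".join(f"{mz:.6f}\t{inten:.4f}\n" for mz, inten in frags.peaks))
    paths["intact"].write_text(
        "".join(f"{mz:.4f}\t{inten:.4f}\n" for mz, inten in intact.peaks))
    paths["truth"].write_text(truth.to_json())
    return paths
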