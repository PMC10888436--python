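"""Circular-bacteriocin gene-cluster mining.

Circular-bacteriocin biosynthetic loci share a recognisable architecture: a
short precursor ORF (leader peptide + mature core), an SpoIIM/DUF95-family
membrane protein, an ABC-transporter ATP-binding protein, one or more
membrane proteins and sometimes a small immunity protein.  The miner works
from that architecture:

1. collect protein-coding features (GenBank CDS, or six-frame ORF calling
   on raw FASTA),
2. classify context genes by annotation keywords first and sequence
   heuristics (Walker motifs, Kyte-Doolittle transmembrane segments) second,
3. anchor precursor candidates by local homology to a panel of known mature
   cores, then snap the leader/core boundary to the family's terminal-residue
   rule (core starts L/V/W, ends W/Y/F),
4. call a cluster around every precursor and score its completeness by the
   distinct context roles found nearby.

Coordinates are 1-based inclusive (GenBank dialect) throughout; the only
0-based arithmetic happens inside alignment internals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParamData import kd as KD_SCALE

from .errors import AlphabetError, ConfigurationError
from .sequences import ResidueSequence, STANDARD_AA, Topology

ROLES = (
    "precursor",
    "spoIIM_duf95",
    "abc_atp_binding",
    "membrane",
    "immunity",
    "bacteriocin_like_linear",
    "unknown",
)

CORE_N_TERM = frozenset("LVW")
CORE_C_TERM = frozenset("WYF")

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

WALKER_A = re.compile(r"[AG].{4}GK[ST]")
WALKER_B = re.compile(r"[ILVFM]{4}D")


@dataclass
class GeneFeature:
    """A protein-coding feature on a contig (1-based inclusive coords)."""

    id: str
    start: int
    end: int
    strand: str
    protein: ResidueSequence
    annotation_text: str = ""
    role: str = "unknown"
    contig: str = "contig1"

    def __post_init__(self) -> None:
        assert self.start <= self.end
        assert self.strand in "+-"


@dataclass
class PrecursorModel:
    """Leader + circular-core reading of a precursor protein."""

    precursor: ResidueSequence
    leader_len: int
    core: ResidueSequence
    source_feature: GeneFeature | None = None
    homology_support: tuple[str, float] | None = None
    low_confidence: bool = False

    def __post_init__(self) -> None:
        assert 0 <= self.leader_len < len(self.precursor)
        assert self.core.is_circular
        span = self.precursor.residues[self.leader_len : self.leader_len + len(self.core)]
        assert span == self.core.residues, "core must be a contiguous slice of the precursor"


@dataclass
class ClusterCall:
    """A genomic locus grouped around a bacteriocin candidate."""

    contig: str
    span: tuple[int, int]
    genes: list[GeneFeature]
    precursor_model: PrecursorModel | None
    completeness: int
    call_type: str = "circular"  # "circular" | "linear_like"

    def __post_init__(self) -> None:
        assert 0 <= self.completeness <= 3


@dataclass
class ReferencePanel:
    """Named mature cores used as homology anchors.

    ``circular`` entries are head-to-tail cyclized mature cores;
    ``linear`` entries are closticin-type linear bacteriocins used for the
    linear-candidate branch (reported without any cyclization claim).
    """

    circular: dict[str, ResidueSequence]
    linear: dict[str, ResidueSequence]

    @classmethod
    def bundled(cls) -> "ReferencePanel":
        """The panel shipped with the package (synthetic stand-in cores;
        see the FASTA header for provenance)."""
        path = resources.files("circbact.data") / "synthetic_panel.fasta"
        with resources.as_file(path) as p:
            return cls.from_fasta(p)

    @classmethod
    def from_fasta(cls, path: Path | str) -> "ReferencePanel":
        circular: dict[str, ResidueSequence] = {}
        linear: dict[str, ResidueSequence] = {}
        # fasta-pearson tolerates the ';' provenance comments in the bundled panel
        for rec in SeqIO.parse(str(path), "fasta-pearson"):
            kind = "circular"
            if "type=linear" in rec.description:
                kind = "linear"
            seq = ResidueSequence(str(rec.seq))
            (linear if kind == "linear" else circular)[rec.id] = seq
        if not circular:
            raise ConfigurationError(f"panel {path} contains no circular cores")
        return cls(circular=circular, linear=linear)


@dataclass
class MiningParams:
    min_identity: float = 30.0  # percent, local vs panel core
    min_coverage: float = 0.5  # fraction of panel core aligned
    strict_termini: bool = True
    precursor_min_len: int = 40
    precursor_max_len: int = 150
    snap_window: int = 3
    window_bp: int = 6000
    linear_min_identity: float = 40.0


# ---------------------------------------------------------------------------
# ORF calling

def _find_orfs_one_strand(dna: str, strand: str, total_len: int, min_len: int,
                          contig: str, counter: list[int]) -> list[GeneFeature]:
    feats: list[GeneFeature] = []
    n = len(dna)
    for frame in range(3):
        region_start = frame  # 0-based start of the current stop-to-stop region
        pos = frame
        while pos + 3 <= n:
            codon = dna[pos : pos + 3]
            if codon in STOP_CODONS:
                # maximal ORF: first start codon in the region, ending at this stop
                orf = _first_start_orf(dna, region_start, pos, min_len)
                if orf is not None:
                    s0, e0 = orf  # 0-based inclusive of stop codon
                    prot = _translate_orf(dna[s0 : e0 + 1])
                    if prot is not None and len(prot) >= min_len:
                        counter[0] += 1
                        if strand == "+":
                            start, end = s0 + 1, e0 + 1
                        else:
                            start, end = total_len - e0, total_len - s0
                        feats.append(
                            GeneFeature(
                                id=f"orf{counter[0]}",
                                start=start,
                                end=end,
                                strand=strand,
                                protein=ResidueSequence(prot),
                                contig=contig,
                            )
                        )
                region_start = pos + 3
            pos += 3
    return feats


def _first_start_orf(dna: str, region_start: int, stop_pos: int, min_len: int):
    pos = region_start
    while pos < stop_pos:
        if dna[pos : pos + 3] in START_CODONS:
            return pos, stop_pos + 2
        pos += 3
    return None


def _translate_orf(orf_dna: str) -> str | None:
    """Standard bacterial-code translation; the start codon reads as M.
    Any ambiguous (N-containing) codon rejects the ORF."""
    if "N" in orf_dna:
        return None
    prot = str(Seq(orf_dna[:-3]).translate(table=11))
    if "*" in prot:
        return None
    prot = "M" + prot[1:]
    if any(ch not in STANDARD_AA for ch in prot):
        return None
    return prot


def find_orfs(dna: str, min_len: int = 10, contig: str = "contig1") -> list[GeneFeature]:
    """All maximal ORFs (ATG/GTG/TTG start, standard stop) on both strands
    with protein length >= ``min_len``; coordinates 1-based inclusive on the
    input strand, spanning start codon through stop codon."""
    dna = dna.upper()
    bad = set(dna) - set("ACGTN")
    if bad:
        raise AlphabetError(f"non-nucleotide characters in input: {sorted(bad)}")
    counter = [0]
    feats = _find_orfs_one_strand(dna, "+", len(dna), min_len, contig, counter)
    rc = str(Seq(dna).reverse_complement())
    feats += _find_orfs_one_strand(rc, "-", len(dna), min_len, contig, counter)
    feats.sort(key=lambda f: (f.start, f.end))
    return feats


# ---------------------------------------------------------------------------
# Role classification

def hydropathy_segments(
    protein: str,
    window: int = 19,
    threshold: float = 1.6,
    min_seg: int = 17,
    merge_gap: int = 5,
) -> list[tuple[int, int]]:
    """Kyte-Doolittle transmembrane-like segments (1-based inclusive).

    A residue is hydrophobic-context if any length-``window`` window covering
    it has mean hydropathy above ``threshold``; maximal runs shorter than
    ``min_seg`` are dropped and runs separated by fewer than ``merge_gap``
    residues are merged first.
    """
    n = len(protein)
    if n < window:
        return []
    scores = [KD_SCALE.get(aa, 0.0) for aa in protein]
    marked = [False] * n
    acc = sum(scores[:window])
    for i in range(n - window + 1):
        if i:
            acc += scores[i + window - 1] - scores[i - 1]
        if acc / window > threshold:
            for j in range(i, i + window):
                marked[j] = True
    runs: list[list[int]] = []
    for i, m in enumerate(marked):
        if not m:
            continue
        if runs and i - runs[-1][1] < merge_gap:
            runs[-1][1] = i
        else:
            runs.append([i, i])
    return [(a + 1, b + 1) for a, b in runs if b - a + 1 >= min_seg]


def classify_gene_role(feature: GeneFeature) -> str:
    """Deterministic role cascade: curated annotation keywords first,
    sequence heuristics second, ``unknown`` otherwise.  Precursor status is
    assigned only by homology (``find_precursor_candidates``), never here."""
    text = feature.annotation_text.lower()
    if text:
        if "spoiim" in text or "duf95" in text or "sporulation protein m" in text:
            return "spoIIM_duf95"
        if "abc" in text or "atp-binding" in text:
            return "abc_atp_binding"
        if "immunity" in text:
            return "immunity"
    prot = feature.protein.residues
    n = len(prot)
    if WALKER_A.search(prot) and WALKER_B.search(prot):
        return "abc_atp_binding"
    tm = len(hydropathy_segments(prot))
    if not text and tm >= 4 and 150 <= n <= 400:
        return "spoIIM_duf95"  # low-confidence architecture-only call
    if tm >= 2 and 100 <= n <= 250:
        return "membrane"
    if n <= 150 and 1 <= tm <= 2:
        return "immunity"
    return "unknown"


# ---------------------------------------------------------------------------
# Alignment / identity

def _aligner(mode: str) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -10.0
    al.extend_gap_score = -1.0
    return al


def _alignment_stats(alignment) -> tuple[int, int, int, int, int]:
    """(identical, aligned_cols, total_cols, query_start, query_aligned_len)
    for one pairwise alignment; query is the first sequence."""
    identical = aligned = 0
    t_aligned = 0
    q_start = None
    q_end = 0
    blocks_q, blocks_t = alignment.aligned
    a, b = alignment.sequences
    for (qs, qe), (ts, te) in zip(blocks_q, blocks_t):
        if q_start is None:
            q_start = qs
        q_end = qe
        t_aligned += te - ts
        for i in range(qe - qs):
            aligned += 1
            if a[qs + i] == b[ts + i]:
                identical += 1
    total_cols = alignment.length
    return identical, aligned, int(total_cols), int(q_start or 0), t_aligned


def percent_identity(a: ResidueSequence, b: ResidueSequence, mode: str = "global") -> float:
    """Pairwise percent identity (BLOSUM62, gap open 10 / extend 1).

    Global (Needleman-Wunsch): identical columns over all alignment columns,
    gaps included.  Local (Smith-Waterman): identical columns over aligned
    residue pairs.  Reported to one decimal.
    """
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")
    al = _aligner(mode)
    best = al.align(a.residues, b.residues)[0]
    identical, aligned, total, _, _ = _alignment_stats(best)
    denom = total if mode == "global" else aligned
    if denom == 0:
        return 0.0
    return round(100.0 * identical / denom, 1)


# ---------------------------------------------------------------------------
# Precursor prediction

def _snap_terminus(prot: str, anchor: int, allowed: frozenset[str], window: int) -> int | None:
    """Closest position to ``anchor`` (1-based) within +-window whose residue
    is in ``allowed``; ties break toward the anchor itself, then leftward."""
    n = len(prot)
    for delta in range(window + 1):
        for pos in (anchor - delta, anchor + delta):
            if 1 <= pos <= n and prot[pos - 1] in allowed:
                return pos
    return None


def find_precursor_candidates(
    features: Sequence[GeneFeature],
    panel: ReferencePanel,
    params: MiningParams | None = None,
) -> list[PrecursorModel]:
    """Homology-anchored precursor models.

    For every protein in the precursor length range, align locally against
    each panel core; a hit at >= min_identity over >= min_coverage of the
    panel core fixes the tentative core start (leader = prefix).  The core
    boundary is then snapped to the terminal-residue rule: the N-terminus to
    an L/V/W within +-snap_window of the aligned start, the C-terminus must
    be W/Y/F at (or within snap_window of) the precursor's end — the
    trailing residues, if any, are kept outside the model, which is then
    flagged low-confidence.
    """
    params = params or MiningParams()
    if not panel.circular:
        raise ConfigurationError("reference panel has no circular cores")
    al = _aligner("local")
    out: list[PrecursorModel] = []
    for feat in features:
        prot = feat.protein.residues
        if not params.precursor_min_len <= len(prot) <= params.precursor_max_len:
            continue
        best = None  # (identity, name, query_start)
        for name, core in panel.circular.items():
            aln = al.align(prot, core.residues)
            if len(aln) == 0:
                continue
            top = aln[0]
            identical, aligned, _, q_start, t_aligned = _alignment_stats(top)
            if aligned == 0 or t_aligned / len(core) < params.min_coverage:
                continue
            ident = 100.0 * identical / aligned
            if ident < params.min_identity:
                continue
            if best is None or ident > best[0]:
                best = (ident, name, q_start + 1)
        if best is None:
            continue
        ident, name, aligned_start = best
        n_pos = _snap_terminus(prot, aligned_start, CORE_N_TERM, params.snap_window)
        c_ok = prot[-1] in CORE_C_TERM or _snap_terminus(
            prot, len(prot), CORE_C_TERM, params.snap_window
        ) is not None
        snapped = n_pos is not None and c_ok and prot[-1] in CORE_C_TERM
        if not snapped and params.strict_termini:
            continue
        start = n_pos if n_pos is not None else aligned_start
        if start >= len(prot):
            continue
        core_seq = ResidueSequence(prot[start - 1 :], Topology.CIRCULAR)
        out.append(
            PrecursorModel(
                precursor=feat.protein,
                leader_len=start - 1,
                core=core_seq,
                source_feature=feat,
                homology_support=(name, round(ident, 1)),
                low_confidence=not snapped,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Cluster calling

CONTEXT_ROLES = ("spoIIM_duf95", "abc_atp_binding", "membrane")


def call_clusters(
    features: Sequence[GeneFeature],
    panel: ReferencePanel | None = None,
    params: MiningParams | None = None,
) -> list[ClusterCall]:
    """Group features into bacteriocin cluster calls.

    One call per precursor candidate, spanning every feature within
    ``window_bp`` of the precursor gene; completeness counts the distinct
    context roles found (SpoIIM/DUF95, ABC ATP-binding, membrane; 0-3).
    Proteins matching a linear panel entry at >= linear_min_identity are
    emitted as ``linear_like`` calls carrying no cyclization model.
    """
    params = params or MiningParams()
    panel = panel or ReferencePanel.bundled()
    feats = sorted(features, key=lambda f: (f.contig, f.start))
    for f in feats:
        if f.role == "unknown":
            f.role = classify_gene_role(f)
    models = find_precursor_candidates(feats, panel, params)
    calls: list[ClusterCall] = []
    precursor_ids = set()
    for model in models:
        src = model.source_feature
        assert src is not None
        src.role = "precursor"
        precursor_ids.add(id(src))
        lo = src.start - params.window_bp
        hi = src.end + params.window_bp
        members = [f for f in feats if f.contig == src.contig and f.start <= hi and f.end >= lo]
        roles = {f.role for f in members}
        completeness = sum(1 for r in CONTEXT_ROLES if r in roles)
        calls.append(
            ClusterCall(
                contig=src.contig,
                span=(min(f.start for f in members), max(f.end for f in members)),
                genes=members,
                precursor_model=model,
                completeness=completeness,
                call_type="circular",
            )
        )
    if panel.linear:
        for f in feats:
            if id(f) in precursor_ids:
                continue
            if not 40 <= len(f.protein) <= 400:
                continue
            al = _aligner("local")
            for name, ref in panel.linear.items():
                top = al.align(f.protein.residues, ref.residues)[0]
                identical, aligned, _, _, t_aligned = _alignment_stats(top)
                if aligned == 0 or t_aligned / len(ref) < params.min_coverage:
                    continue
                ident = 100.0 * identical / aligned
                if ident >= params.linear_min_identity:
                    f.role = "bacteriocin_like_linear"
                    calls.append(
                        ClusterCall(
                            contig=f.contig,
                            span=(f.start, f.end),
                            genes=[f],
                            precursor_model=None,
                            completeness=0,
                            call_type="linear_like",
                        )
                    )
                    break
    calls.sort(key=lambda c: (c.contig, c.span[0]))
    return calls


# ---------------------------------------------------------------------------
# Genome input

def load_genome_features(path: Path | str, min_orf_len: int = 40) -> list[GeneFeature]:
    """Protein-coding features from a GenBank file (CDS features preferred)
    or a FASTA file (six-frame ORF calling)."""
    path = Path(path)
    fmt = "genbank" if path.suffix.lower() in (".gb", ".gbk", ".gbff", ".genbank") else "fasta"
    feats: list[GeneFeature] = []
    counter = 0
    for rec in SeqIO.parse(str(path), fmt):
        if fmt == "genbank":
            for f in rec.features:
                if f.type != "CDS":
                    continue
                quals = f.qualifiers
                prot = quals.get("translation", [None])[0]
                if prot is None or any(ch not in STANDARD_AA for ch in prot):
                    continue
                counter += 1
                note = " ".join(quals.get("product", []) + quals.get("note", []))
                feats.append(
                    GeneFeature(
                        id=quals.get("locus_tag", [f"cds{counter}"])[0],
                        start=int(f.location.start) + 1,
                        end=int(f.location.end),
                        strand="+" if f.location.strand != -1 else "-",
                        protein=ResidueSequence(prot),
                        annotation_text=note,
                        contig=rec.id,
                    )
                )
        else:
            feats.extend(find_orfs(str(rec.seq), min_len=min_orf_len, contig=rec.id))
    feats.sort(key=lambda f: (f.contig, f.start))
    return feats
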