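"""End-to-end orchestration: mine -> digest -> match -> evidence -> design.

A run takes one genome (GenBank or FASTA), optional fragment/intact peak
lists, and produces one JSON-serializable report: cluster calls, precursor
models, circularity verdicts, and (optionally) SIML construct designs.
Re-running an identical config on identical inputs yields an identical
report apart from the embedded timestamp.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .designer import InteinPair, build_siml_protein, circular_permute
from .digest import TRYPSIN, digest_circular, semi_specific_expand
from .mining import MiningParams, ReferencePanel, call_clusters, load_genome_features
from .msmatch import (
    CircularityEvidence,
    PeakList,
    assemble_evidence,
    intact_cyclic_check,
    load_peaklist,
    match_fragments,
)

log = logging.getLogger("circbact")


@dataclass
class RunConfig:
    genome: str
    fragment_peaks: str | None = None
    intact_peaks: str | None = None
    panel: str | None = None  # FASTA; defaults to the bundled panel
    tol_ppm: float = 20.0
    tol_da: float = 1.5
    max_missed: int = 2
    semi: bool = True
    semi_min_len: int = 6
    charges: tuple[int, ...] = (1, 2)
    min_identity: float = 30.0
    window_bp: int = 6000
    strict_termini: bool = True
    design: bool = False
    split_rule: str = "first_serine"  # or "1", "37", ... explicit position
    seed: int = 0
    out_dir: str = "circbact_out"

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "charges" in data:
            data["charges"] = tuple(data["charges"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["charges"] = list(self.charges)
        return d


def _split_position(rule: str, core: str) -> int:
    if rule.isdigit():
        return int(rule)
    if rule == "first_serine":
        idx = core.find("S", 1)
        return idx + 1 if idx >= 0 else max(1, len(core) // 2)
    raise ValueError(f"unknown split rule {rule!r}")


def _evidence_dict(ev: CircularityEvidence) -> dict:
    def match_dict(m):
        return {
            "peptide": m.peptide.sequence.residues,
            "start": m.peptide.start,
            "junction": m.peptide.junction_spanning,
            "specificity": m.peptide.specificity,
            "mods": [mod.name + str(mod.position) for mod in m.mods],
            "charge": m.charge,
            "theoretical_mz": round(m.theoretical_mz, 4),
            "observed_mz": round(m.observed_mz, 4),
            "error_ppm": round(m.error_ppm, 2),
        }

    out = {"verdict": ev.verdict,
           "junction_matches": [match_dict(m) for m in ev.junction_matches],
           "internal_matches": [match_dict(m) for m in ev.internal_matches]}
    if ev.intact_check is not None:
        ic = ev.intact_check
        out["intact"] = {
            "deduced_linear_avg": round(ic.deduced_linear_avg, 2),
            "expected_cyclic_mh": round(ic.expected_cyclic_mh, 2),
            "expected_linear_mh": round(ic.expected_linear_mh, 2),
            "matched_peak": None if ic.matched_peak is None else round(ic.matched_peak, 2),
            "delta": None if ic.delta is None else round(ic.delta, 3),
            "cyclic_pass": ic.cyclic_pass,
            "linear_pass": ic.linear_pass,
        }
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and return the consolidated report."""
    t0 = time.time()
    report: dict = {"config": config.to_dict(), "stages": {}, "clusters": []}

    panel = ReferencePanel.from_fasta(config.panel) if config.panel else ReferencePanel.bundled()
    params = MiningParams(
        min_identity=config.min_identity,
        window_bp=config.window_bp,
        strict_termini=config.strict_termini,
    )

    log.info("stage=mine genome=%s", config.genome)
    features = load_genome_features(config.genome)
    calls = call_clusters(features, panel, params)
    report["stages"]["mine"] = {"n_features": len(features), "n_calls": len(calls)}

    frag_peaks = intact_peaks = None
    if config.fragment_peaks:
        frag_peaks = load_peaklist(config.fragment_peaks, "fragment_lcmsms")
    if config.intact_peaks:
        intact_peaks = load_peaklist(config.intact_peaks, "intact_maldi")

    for call in calls:
        entry: dict = {
            "contig": call.contig,
            "span": list(call.span),
            "type": call.call_type,
            "completeness": call.completeness,
            "genes": [
                {"id": g.id, "start": g.start, "end": g.end, "strand": g.strand,
                 "role": g.role, "length_aa": len(g.protein)}
                for g in call.genes
            ],
        }
        model = call.precursor_model
        if model is not None:
            entry["precursor"] = {
                "length": len(model.precursor),
                "leader_len": model.leader_len,
                "core_len": len(model.core),
                "core": model.core.residues,
                "homology": list(model.homology_support or ()),
                "low_confidence": model.low_confidence,
            }
            peptides = digest_circular(model.core, TRYPSIN, config.max_missed)
            if config.semi:
                peptides = peptides + semi_specific_expand(peptides, config.semi_min_len)
            matches = []
            if frag_peaks is not None and frag_peaks.peaks:
                matches = match_fragments(
                    peptides, frag_peaks, config.charges, config.tol_ppm
                )
            intact = intact_cyclic_check(model, intact_peaks, config.tol_da)
            ev = assemble_evidence(model, matches, intact)
            entry["evidence"] = _evidence_dict(ev)
            if config.design:
                split = _split_position(config.split_rule, model.core.residues)
                design = build_siml_protein(model.core, split, InteinPair.bundled())
                entry["design"] = {
                    "split_position": split,
                    "permuted_core": design.permuted_core.residues,
                    "parts": [name for name, _ in design.parts],
                    "protein_length": len(design.protein),
                }
        report["clusters"].append(entry)

    report["stages"]["total_seconds"] = round(time.time() - t0, 3)
    return report


def write_report(report: dict, out_dir: Path | str) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=1))
    return path
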