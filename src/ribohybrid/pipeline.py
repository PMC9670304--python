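"""End-to-end orchestration: panel -> classify -> clones -> maternal -> export.

The pipeline is a pure function of (inputs, config, seed): every stage
writes TSV/FASTA artifacts plus a JSON manifest with thresholds and
checksums, and no sample is ever dropped silently — exclusions always land
in a log with a reason.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ribohybrid import __version__
from ribohybrid.clones import analyze_clones
from ribohybrid.hybrid import AdditivityCall, classify_direct, select_for_phylogeny
from ribohybrid.indels import concatenate_with_indels, export_nexus, simple_indel_code
from ribohybrid.maternal import (
    MaternalCall,
    assign_maternal,
    count_independent_origins,
    cross_marker_resolve,
)
from ribohybrid.panel import GenotypePanel, build_panel, collapse_identical, write_panel
from ribohybrid.seqio import Alignment, read_fasta, read_metadata, read_minor_fractions

__all__ = ["RunConfig", "HybridSummary", "run_pipeline", "summarize_combinations"]


@dataclass
class RunConfig:
    """File layout and thresholds for one pipeline run."""

    marker_fastas: dict[str, str]  # marker -> FASTA path
    metadata: str
    nuclear_marker: str = "ITS"
    plastid_markers: tuple[str, ...] = ("rpl20-rps12", "trnT-trnL")
    clones_fasta: str | None = None
    minor_fractions: str | None = None
    outdir: str = "ribohybrid_out"
    tolerance: int = 0
    min_minor_fraction: float = 0.30
    min_block: int = 2
    seed: int = 0

    def validate(self) -> None:
        for marker, path in self.marker_fastas.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"{marker} FASTA not found: {path}")
        if not Path(self.metadata).exists():
            raise FileNotFoundError(f"metadata not found: {self.metadata}")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if not 0 <= self.min_minor_fraction <= 1:
            raise ValueError("min_minor_fraction must be in [0, 1]")


@dataclass
class HybridSummary:
    """Genotype-combination and maternal-direction tabulation."""

    n_samples: int
    verdict_counts: dict[str, int]
    combinations: dict[str, dict[str, int]]  # hybrid type -> {"gtA x gtB": count}
    maternal_directions: dict[str, dict[str, int]]  # hybrid type -> {species: count}
    origins: dict[str, dict[str, object]]  # from count_independent_origins

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_samples": self.n_samples,
                "verdict_counts": self.verdict_counts,
                "combinations": self.combinations,
                "maternal_directions": self.maternal_directions,
                "origins": self.origins,
            },
            indent=2,
            sort_keys=True,
        )


def _hybrid_type(call: AdditivityCall, panel: GenotypePanel) -> str:
    labels = sorted(call.hypothesis)
    species = sorted({panel.species_of(g) for g in labels})
    if len(species) == 2:
        return f"{species[0]} x {species[1]}"
    return f"{species[0]} (intraspecific)"


def summarize_combinations(
    calls: list[AdditivityCall],
    maternal: dict[str, MaternalCall],
    panel: GenotypePanel,
) -> HybridSummary:
    """Tabulate verdicts, unordered genotype combinations, maternal directions.

    Independent origins are lower-bounded per hybrid type from the distinct
    (maternal species, maternal haplotype) tuples among its samples.
    """
    verdict_counts: dict[str, int] = {}
    combos: dict[str, dict[str, int]] = {}
    directions: dict[str, dict[str, int]] = {}
    origin_rows: list[dict[str, str]] = []

    for call in calls:
        verdict_counts[call.verdict] = verdict_counts.get(call.verdict, 0) + 1
        if call.verdict not in ("intraspecific_hybrid", "interspecific_hybrid"):
            continue
        htype = _hybrid_type(call, panel)
        combo = " x ".join(sorted(call.hypothesis))
        combos.setdefault(htype, {})
        combos[htype][combo] = combos[htype].get(combo, 0) + 1

        mcall = maternal.get(call.sample_id)
        if mcall is not None:
            mother = mcall.maternal or "?"
            directions.setdefault(htype, {})
            directions[htype][mother] = directions[htype].get(mother, 0) + 1
            origin_rows.append(
                {
                    "hybrid_type": htype,
                    "maternal": mcall.maternal or "",
                    "haplotype": mcall.matched_haplotype
                    or ";".join(mcall.derived_from)
                    or "",
                }
            )

    origins = (
        count_independent_origins(pd.DataFrame(origin_rows)) if origin_rows else {}
    )
    return HybridSummary(
        n_samples=len(calls),
        verdict_counts=verdict_counts,
        combinations=combos,
        maternal_directions=directions,
        origins=origins,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> HybridSummary:
    """Execute all stages and write artifacts under ``cfg.outdir``."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = read_metadata(cfg.metadata)

    minor = (
        read_minor_fractions(cfg.minor_fractions) if cfg.minor_fractions else {}
    )

    # --- stage: panel ------------------------------------------------------
    panels: dict[str, GenotypePanel] = {}
    alignments: dict[str, Alignment] = {}
    for marker, path in cfg.marker_fastas.items():
        mmeta = meta[meta["marker"] == marker]
        aln = read_fasta(path, marker=marker, metadata=mmeta)
        alignments[marker] = aln
        labelled = {
            str(r["sample_id"]): (str(r["species"]), str(r["genotype"]))
            for _, r in mmeta.iterrows()
            if str(r.get("genotype", "")) and str(r["species"]) != "unknown"
        }
        panels[marker] = build_panel(aln, labelled)
        write_panel(
            panels[marker],
            outdir / f"panel_{marker.replace('/', '_')}.fasta",
            outdir / f"panel_{marker.replace('/', '_')}.tsv",
        )
    nuc_panel = panels[cfg.nuclear_marker]
    nuc_aln = alignments[cfg.nuclear_marker]

    # --- stage: classify ---------------------------------------------------
    labelled_ids = {
        str(r["sample_id"])
        for _, r in meta.iterrows()
        if str(r.get("genotype", "")) and str(r["species"]) != "unknown"
    }
    calls: list[AdditivityCall] = []
    for seq in nuc_aln:
        if seq.role != "direct" or seq.id in labelled_ids:
            continue
        if seq.id in minor:
            fracs, majors = minor[seq.id]
            seq.minor_fraction, seq.major_base = fracs, majors
        calls.append(
            classify_direct(
                seq, nuc_panel,
                tolerance=cfg.tolerance,
                min_minor_fraction=cfg.min_minor_fraction,
            )
        )
    calls_df = pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "verdict": c.verdict,
                "hypothesis": c.hypothesis_label,
                "n_violated": len(c.violated_sites),
                "n_extra": len(c.extra_polymorphic_sites),
                "tied": ";".join(
                    t if isinstance(t, str) else " x ".join(sorted(t))
                    for t in c.tied_hypotheses
                ),
                "indel_sites": ";".join(
                    str(col + 1) for col in c.indel_polymorphic_sites
                ),
            }
            for c in calls
        ]
    )
    calls_df.to_csv(outdir / "calls.tsv", sep="\t", index=False)
    call_by_id = {c.sample_id: c for c in calls}

    # --- stage: clones -----------------------------------------------------
    clone_rows = []
    if cfg.clones_fasta and Path(cfg.clones_fasta).exists():
        clones_all = read_fasta(cfg.clones_fasta, marker=cfg.nuclear_marker)
        by_sample: dict[str, list] = {}
        for c in clones_all:
            sid = c.id.split("__c")[0]
            by_sample.setdefault(sid, []).append(c)
        for sid, cseqs in sorted(by_sample.items()):
            call = call_by_id.get(sid)
            if call is None or call.hypothesis is None or isinstance(call.hypothesis, str):
                continue
            ga, gb = sorted(call.hypothesis)
            report = analyze_clones(
                Alignment(cseqs, marker=cfg.nuclear_marker),
                nuc_aln[sid],
                nuc_panel.consensus(ga),
                nuc_panel.consensus(gb),
                min_block=cfg.min_block,
                panel=nuc_panel,
            )
            for cid, a in report.assignments.items():
                clone_rows.append(
                    {
                        "sample_id": sid,
                        "clone_id": cid,
                        "class": a.klass,
                        "distance_to_nearest": a.distance_to_nearest,
                        "n_corrections": len(report.corrections.get(cid, [])),
                        "breakpoints": ";".join(
                            f"{i + 1}-{j + 1}" for i, j in report.breakpoints.get(cid, [])
                        ),
                        "representative": any(
                            cid in reps for reps in report.representatives.values()
                        ),
                        "parents_recovered": report.parents_recovered,
                    }
                )
    pd.DataFrame(clone_rows).to_csv(outdir / "clone_reports.tsv", sep="\t", index=False)

    # --- stage: maternal ---------------------------------------------------
    maternal_calls: dict[str, MaternalCall] = {}
    maternal_rows = []
    for call in calls:
        if call.verdict != "interspecific_hybrid":
            continue
        parent_pair = tuple(sorted({nuc_panel.species_of(g) for g in call.hypothesis}))
        per_marker: list[MaternalCall] = []
        for marker in cfg.plastid_markers:
            if marker not in panels or call.sample_id not in alignments[marker]:
                continue
            try:
                per_marker.append(
                    assign_maternal(
                        alignments[marker][call.sample_id], panels[marker], parent_pair
                    )
                )
            except KeyError:
                continue
        if not per_marker:
            continue
        resolved = cross_marker_resolve(per_marker) if len(per_marker) > 1 else per_marker[0]
        maternal_calls[call.sample_id] = resolved
        maternal_rows.append(
            {
                "sample_id": call.sample_id,
                "call": resolved.call,
                "maternal": resolved.maternal or "",
                "candidates": ";".join(sorted(resolved.candidates)),
                "matched_haplotype": resolved.matched_haplotype or "",
                "distance": resolved.distance,
                "derived_from": ";".join(resolved.derived_from),
                "equivocal": resolved.asterisk,
            }
        )
    pd.DataFrame(maternal_rows).to_csv(outdir / "maternal.tsv", sep="\t", index=False)

    # --- stage: indel coding & export -------------------------------------
    tree_aln, exclusions = select_for_phylogeny(calls, nuc_aln)
    pd.DataFrame(exclusions, columns=["sample_id", "reason"]).to_csv(
        outdir / "exclusions.tsv", sep="\t", index=False
    )
    collapsed, dup_map = collapse_identical(tree_aln)
    pd.DataFrame(
        [
            {"representative": rep, "members": ";".join(ids)}
            for rep, ids in dup_map.items()
        ]
    ).to_csv(outdir / "identical_map.tsv", sep="\t", index=False)
    matrix = simple_indel_code(collapsed)
    coded = concatenate_with_indels(collapsed, matrix)
    partitions = [(cfg.nuclear_marker, 0, collapsed.length)]
    if matrix.n_characters:
        partitions.append(("indels", collapsed.length, coded.length))
    export_nexus(coded, outdir / "tree_matrix.nex", partitions)

    # --- stage: report -----------------------------------------------------
    summary = summarize_combinations(calls, maternal_calls, nuc_panel)
    (outdir / "summary.json").write_text(summary.to_json() + "\n")

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "tolerance": cfg.tolerance,
            "min_minor_fraction": cfg.min_minor_fraction,
            "min_block": cfg.min_block,
        },
        "inputs": {
            marker: _sha256(Path(path)) for marker, path in cfg.marker_fastas.items()
        },
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return summary
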