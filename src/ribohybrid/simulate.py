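"""Synthetic marker panels and sample collections with full ground truth.

The generator emulates the data structure the pipeline is built for: a
hexaploid aquatic-plant genus with geographically structured genotypes
(1-10 substitutions apart, occasional single gap runs), direct sequences
that are IUPAC-additive mixtures of two ribotypes, clone sets contaminated
by per-base polymerase errors and single-breakpoint chimeras, and plastid
haplotypes inherited from exactly one parent.

Substitutions are drawn without replacement over disjoint column sets per
lineage, so configured pairwise distances hold exactly by construction —
calibration targets such as "six substitutions between the two major
genotypes" are reproduced, not approximated.  Substituted columns are
confined to the first half of each marker and gap runs to the second half,
which keeps indels from erasing diagnostic sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ribohybrid.hybrid import expected_sequence
from ribohybrid.panel import GenotypePanel
from ribohybrid.seqio import AlignedSeq, Alignment, write_fasta

__all__ = [
    "SimConfig",
    "TruthRecord",
    "CloneTruth",
    "simulate_panel",
    "simulate_sample",
    "emit_collection",
    "stuckenia_like_topology",
]

BASES = np.array(list("ACGT"))

#: (label, parent label or None, substitutions from parent) per species.
GenotypeTopology = dict[str, list[tuple[str, str | None, int]]]


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults model the source system: a handful of species in two clades,
    2-3 genotypes per widespread species a few substitutions apart, clone
    sets of at least five with ~0.2% per-base polymerase error and 10%
    chimeras, and a sample collection dominated by pure samples with a
    substantial minority of intra- and interspecific hybrids.
    """

    seed: int = 0
    n_species: int = 4
    genotypes_per_species: tuple[int, ...] = (3, 2, 2, 1)
    seq_length: dict = field(
        default_factory=lambda: {"ITS": 600, "rpl20-rps12": 800, "trnT-trnL": 850}
    )
    nuclear_marker: str = "ITS"
    plastid_markers: tuple[str, ...] = ("rpl20-rps12", "trnT-trnL")
    interspecies_subst: int = 10
    intragenotype_subst: int = 4
    plastid_interspecies_subst: int = 6
    indel_prob: float = 0.3
    clone_error_rate: float = 0.002
    chimera_rate: float = 0.1
    min_clones: int = 5
    clone_cap: int = 20
    min_block: int = 2
    sample_mix: tuple[float, float, float] = (0.55, 0.15, 0.30)
    n_samples: int = 200
    genotype_topology: GenotypeTopology | None = None
    shared_plastid: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for p in (self.indel_prob, self.clone_error_rate, self.chimera_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.sample_mix) - 1.0) > 1e-9:
            raise ValueError("sample_mix must sum to 1")
        for marker, length in self.seq_length.items():
            if length < 50:
                raise ValueError(f"seq_length[{marker}] must be >= 50")

    def species_names(self) -> list[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]

    def topology(self) -> GenotypeTopology:
        """Genotype tree per species; default is a star from the first genotype."""
        if self.genotype_topology is not None:
            return self.genotype_topology
        topo: GenotypeTopology = {}
        for sp, n_gt in zip(self.species_names(), self.genotypes_per_species):
            entries: list[tuple[str, str | None, int]] = [(f"{sp}/g1", None, 0)]
            for k in range(2, n_gt + 1):
                entries.append((f"{sp}/g{k}", f"{sp}/g1", self.intragenotype_subst))
            topo[sp] = entries
        return topo


def stuckenia_like_topology() -> GenotypeTopology:
    """Genotype structure mirroring the published intraspecific variation.

    S. pectinata: two major genotypes six substitutions apart; genotype 1
    has variants 1a/1b one substitution apart; genotype 2 has subtypes
    2a-2e, each one substitution from 2a.  S. filiformis: two genotypes one
    substitution apart.  S. vaginata: genotypes 1 and 2a two substitutions
    apart, 2b derived from 2a by one more.  S. amblyphylla: one genotype.
    """
    return {
        "pectinata": [
            ("pectinata/1a", None, 0),
            ("pectinata/1b", "pectinata/1a", 1),
            ("pectinata/2a", "pectinata/1a", 6),
            ("pectinata/2b", "pectinata/2a", 1),
            ("pectinata/2c", "pectinata/2a", 1),
            ("pectinata/2d", "pectinata/2a", 1),
            ("pectinata/2e", "pectinata/2a", 1),
        ],
        "filiformis": [
            ("filiformis/1", None, 0),
            ("filiformis/2", "filiformis/1", 1),
        ],
        "vaginata": [
            ("vaginata/1", None, 0),
            ("vaginata/2a", "vaginata/1", 2),
            ("vaginata/2b", "vaginata/2a", 1),
        ],
        "amblyphylla": [("amblyphylla/1", None, 0)],
    }


@dataclass
class CloneTruth:
    clone_id: str
    source: str  # "A" | "B"
    error_positions: list[int]
    breakpoint: int | None  # column after which the template switches


@dataclass
class TruthRecord:
    sample_id: str
    true_class: str  # pure | intraspecific_hybrid | interspecific_hybrid
    true_genotypes: tuple[str, ...]
    true_maternal: str | None
    maternal_haplotype: str | None
    parental_haplotypes_differ: dict[str, bool] = field(default_factory=dict)
    clones: list[CloneTruth] = field(default_factory=list)


class ColumnPool:
    """Disjoint column allocator so lineage distances are exact."""

    def __init__(self, columns: np.ndarray, rng: np.random.Generator):
        self._cols = list(rng.permutation(columns))

    def take(self, n: int) -> list[int]:
        if n > len(self._cols):
            raise ValueError(
                "infeasible parameters: requested substitutions exceed available columns"
            )
        taken, self._cols = self._cols[:n], self._cols[n:]
        return taken


def _mutate(residues: str, cols: Iterable[int], rng: np.random.Generator) -> str:
    out = list(residues)
    for c in cols:
        choices = [b for b in "ACGT" if b != out[c]]
        out[c] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.integers(4, size=length)])


def _build_marker_panel(
    cfg: SimConfig,
    marker: str,
    topo: GenotypeTopology,
    species_subst: int,
    rng: np.random.Generator,
    with_indels: bool,
    per_species_single: bool = False,
) -> GenotypePanel:
    length = cfg.seq_length[marker]
    root = _random_seq(length, rng)
    sub_pool = ColumnPool(np.arange(length // 2), rng)
    species = list(topo)

    species_seq: dict[str, str] = {}
    for sp in species:
        species_seq[sp] = _mutate(root, sub_pool.take(species_subst // 2), rng)

    entries: dict[str, AlignedSeq] = {}
    species_index: dict[str, set[str]] = {sp: set() for sp in species}
    for sp in species:
        seqs: dict[str, str] = {}
        lineage = topo[sp]
        if per_species_single:
            lineage = lineage[:1]
        for label, parent, dist in lineage:
            base = species_seq[sp] if parent is None else seqs[parent]
            seq = _mutate(base, sub_pool.take(dist), rng)
            if with_indels and rng.random() < cfg.indel_prob:
                run_len = int(rng.integers(1, 7))
                start = int(rng.integers(length // 2, length - run_len))
                seq = seq[:start] + "-" * run_len + seq[start + run_len :]
            seqs[label] = seq
        for label, residues in seqs.items():
            entries[label] = AlignedSeq(
                id=label,
                residues=residues,
                species=sp,
                genotype=label,
                marker=marker,
                role="consensus",
            )
            species_index[sp].add(label)

    return GenotypePanel(
        marker=marker,
        entries=entries,
        species_index=species_index,
        alignment_length=length,
    )


def _plastid_panel(
    cfg: SimConfig, marker: str, topo: GenotypeTopology, rng: np.random.Generator
) -> GenotypePanel:
    """One main haplotype per species; a derived one where the species is variable.

    Optionally, species pairs in ``cfg.shared_plastid`` are forced to share
    their main haplotype, emulating closely related species whose plastids
    have not diverged (the equivocal-maternal-parent situation).
    """
    length = cfg.seq_length[marker]
    root = _random_seq(length, rng)
    pool = ColumnPool(np.arange(length // 2), rng)
    species = list(topo)

    entries: dict[str, AlignedSeq] = {}
    species_index: dict[str, set[str]] = {sp: set() for sp in species}
    shared_with: dict[str, str] = {}
    for a, b in cfg.shared_plastid:
        shared_with[b] = a

    main_hap: dict[str, str] = {}
    for sp in species:
        if sp in shared_with and shared_with[sp] in main_hap:
            residues = main_hap[shared_with[sp]]
        else:
            residues = _mutate(root, pool.take(cfg.plastid_interspecies_subst // 2), rng)
        main_hap[sp] = residues
        label = f"{sp}/h1"
        entries[label] = AlignedSeq(
            id=label, residues=residues, species=sp, genotype=label,
            marker=marker, role="consensus",
        )
        species_index[sp].add(label)
        if len(topo[sp]) >= 2:
            derived = _mutate(residues, pool.take(1), rng)
            dlabel = f"{sp}/h2"
            entries[dlabel] = AlignedSeq(
                id=dlabel, residues=derived, species=sp, genotype=dlabel,
                marker=marker, role="consensus",
            )
            species_index[sp].add(dlabel)

    return GenotypePanel(
        marker=marker,
        entries=entries,
        species_index=species_index,
        alignment_length=length,
    )


def simulate_panel(
    cfg: SimConfig,
) -> dict[str, GenotypePanel]:
    """Evolve nuclear and plastid panels on one species structure.

    Deterministic under ``cfg.seed``.  Nuclear genotype distances follow the
    configured topology exactly; plastid haplotypes evolve independently on
    the same species set.
    """
    rng = np.random.default_rng(cfg.seed)
    topo = cfg.topology()
    panels: dict[str, GenotypePanel] = {}
    panels[cfg.nuclear_marker] = _build_marker_panel(
        cfg, cfg.nuclear_marker, topo, cfg.interspecies_subst, rng, with_indels=True
    )
    for marker in cfg.plastid_markers:
        if marker not in cfg.seq_length:
            continue
        panels[marker] = _plastid_panel(cfg, marker, topo, rng)
    return panels


def _informative_cols(a: str, b: str) -> list[int]:
    return [
        c for c, (sa, sb) in enumerate(zip(a, b))
        if sa != sb and sa in "ACGT" and sb in "ACGT"
    ]


def _draw_clone(
    copy_a: str,
    copy_b: str,
    source: str,
    clone_id: str,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> CloneTruth | None:
    """Chimera decision + per-base polymerase errors for one clone.

    Chimeric clones switch template once, at a point chosen between
    informative sites so that at least ``min_block`` informative sites flank
    the breakpoint on each side (a switch outside the informative span is
    molecularly real but observationally identical to a parental clone).
    """
    templates = {"A": copy_a, "B": copy_b}
    length = len(copy_a)
    breakpoint = None
    info = _informative_cols(copy_a, copy_b)
    if rng.random() < cfg.chimera_rate and len(info) >= 2 * cfg.min_block:
        k = int(rng.integers(cfg.min_block, len(info) - cfg.min_block + 1))
        breakpoint = info[k - 1]  # switch right after this column
        other = "B" if source == "A" else "A"
        residues = templates[source][: breakpoint + 1] + templates[other][breakpoint + 1 :]
    else:
        residues = templates[source]

    out = list(residues)
    error_positions: list[int] = []
    n_err = rng.binomial(length, cfg.clone_error_rate)
    if n_err:
        for c in rng.choice(length, size=n_err, replace=False):
            c = int(c)
            if out[c] == "-":
                continue
            choices = [b for b in "ACGT" if b != out[c]]
            out[c] = choices[rng.integers(len(choices))]
            error_positions.append(c)
    return CloneTruth(
        clone_id=clone_id,
        source=source,
        error_positions=sorted(error_positions),
        breakpoint=breakpoint,
    ), "".join(out)


def simulate_sample(
    cfg: SimConfig,
    panels: dict[str, GenotypePanel],
    truth_class: str,
    rng: np.random.Generator,
    sample_id: str = "s1",
) -> tuple[AlignedSeq, Alignment | None, dict[str, AlignedSeq], TruthRecord]:
    """One sample: direct nuclear read, clone set (hybrids), plastid reads, truth.

    The direct sequence is the exact IUPAC superposition of the chosen
    ribotype(s).  Hybrid clone sets draw ``min_clones`` clones and keep
    drawing until both copy types are represented (cap ``clone_cap``),
    mirroring the adaptive sequencing rule.  Plastid sequences are copied
    from the designated maternal parent's haplotype.
    """
    nuc = panels[cfg.nuclear_marker]
    labels = nuc.labels
    by_species = {sp: sorted(nuc.species_index[sp]) for sp in nuc.species_index}
    multi_gt = [sp for sp, gts in by_species.items() if len(gts) >= 2]

    if truth_class == "pure":
        gt = labels[rng.integers(len(labels))]
        genotypes = (gt,)
        species_pair = (nuc.species_of(gt),)
    elif truth_class == "intraspecific_hybrid":
        if not multi_gt:
            raise ValueError("no species with >= 2 genotypes; cannot make intraspecific hybrid")
        sp = multi_gt[rng.integers(len(multi_gt))]
        pair = rng.choice(len(by_species[sp]), size=2, replace=False)
        genotypes = tuple(sorted(by_species[sp][i] for i in pair))
        species_pair = (sp,)
    elif truth_class == "interspecific_hybrid":
        sp_names = sorted(by_species)
        pair = rng.choice(len(sp_names), size=2, replace=False)
        spa, spb = sp_names[pair[0]], sp_names[pair[1]]
        ga = by_species[spa][rng.integers(len(by_species[spa]))]
        gb = by_species[spb][rng.integers(len(by_species[spb]))]
        genotypes = tuple(sorted((ga, gb)))
        species_pair = tuple(sorted((spa, spb)))
    else:
        raise ValueError(f"unknown truth class {truth_class!r}")

    hyp = genotypes[0] if len(genotypes) == 1 else frozenset(genotypes)
    exp = expected_sequence(nuc, hyp)
    direct = AlignedSeq(
        id=sample_id, residues=exp.residues, marker=cfg.nuclear_marker, role="direct"
    )

    # clone set (hybrids only)
    clones_aln: Alignment | None = None
    clone_truths: list[CloneTruth] = []
    if len(genotypes) == 2:
        copy_a = nuc.consensus(genotypes[0]).residues
        copy_b = nuc.consensus(genotypes[1]).residues
        clone_seqs: list[AlignedSeq] = []
        seen_sources: set[str] = set()
        k = 0
        while k < cfg.clone_cap:
            if k >= cfg.min_clones and {"A", "B"} <= seen_sources:
                break
            source = "A" if rng.random() < 0.5 else "B"
            cid = f"{sample_id}__c{k + 1}"
            truth, residues = _draw_clone(copy_a, copy_b, source, cid, cfg, rng)
            if truth.breakpoint is None:
                seen_sources.add(source)
            clone_truths.append(truth)
            clone_seqs.append(
                AlignedSeq(id=cid, residues=residues, marker=cfg.nuclear_marker, role="clone")
            )
            k += 1
        clones_aln = Alignment(clone_seqs, marker=cfg.nuclear_marker)

    # maternal parent and plastid reads
    if len(species_pair) == 1:
        maternal = species_pair[0]
    else:
        maternal = species_pair[rng.integers(2)]
    plastid_reads: dict[str, AlignedSeq] = {}
    maternal_hap: str | None = None
    haps_differ: dict[str, bool] = {}
    for marker in cfg.plastid_markers:
        if marker not in panels:
            continue
        pan = panels[marker]
        haps = pan.haplotypes_of_species(maternal)
        hap = haps[rng.integers(len(haps))]
        if maternal_hap is None:
            maternal_hap = hap
        plastid_reads[marker] = AlignedSeq(
            id=sample_id,
            residues=pan.consensus(hap).residues,
            marker=marker,
            role="direct",
        )
        if len(species_pair) == 2:
            other = species_pair[0] if species_pair[1] == maternal else species_pair[1]
            hybrid_res = pan.consensus(hap).residues
            haps_differ[marker] = all(
                pan.consensus(h).residues != hybrid_res
                for h in pan.haplotypes_of_species(other)
            )

    truth = TruthRecord(
        sample_id=sample_id,
        true_class=truth_class,
        true_genotypes=genotypes,
        true_maternal=maternal if len(species_pair) == 2 else species_pair[0],
        maternal_haplotype=maternal_hap,
        parental_haplotypes_differ=haps_differ,
        clones=clone_truths,
    )
    return direct, clones_aln, plastid_reads, truth


def simulate_collection(
    cfg: SimConfig,
) -> tuple[dict[str, GenotypePanel], list[tuple[AlignedSeq, Alignment | None, dict[str, AlignedSeq]]], list[TruthRecord]]:
    """Panels plus ``cfg.n_samples`` samples drawn from ``cfg.sample_mix``."""
    panels = simulate_panel(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    classes = ("pure", "intraspecific_hybrid", "interspecific_hybrid")
    samples = []
    truths: list[TruthRecord] = []
    for i in range(cfg.n_samples):
        cls = classes[rng.choice(3, p=cfg.sample_mix)]
        sid = f"q{i + 1:04d}"
        direct, clones, plastids, truth = simulate_sample(cfg, panels, cls, rng, sid)
        samples.append((direct, clones, plastids))
        truths.append(truth)
    return panels, samples, truths


def emit_collection(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a full synthetic collection to disk; deterministic under seed.

    Layout: per-marker FASTA (panel reference samples named ``ref_<label>``
    plus unknown queries), a clones FASTA for the nuclear marker, a
    metadata TSV, and truth TSVs for samples and clones.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panels, samples, truths = simulate_collection(cfg)

    meta_rows: list[dict[str, str]] = []
    files: dict[str, Path] = {}

    def ref_id(label: str) -> str:
        return "ref_" + label.replace("/", "_")

    # nuclear marker: references + directs
    nuc = panels[cfg.nuclear_marker]
    nuc_seqs = []
    for label in nuc.labels:
        c = nuc.consensus(label)
        nuc_seqs.append(
            AlignedSeq(id=ref_id(label), residues=c.residues, species=c.species,
                       genotype=label, marker=cfg.nuclear_marker, role="direct")
        )
        meta_rows.append(
            {"sample_id": ref_id(label), "species": c.species, "genotype": label,
             "marker": cfg.nuclear_marker, "role": "direct"}
        )
    clone_seqs: list[AlignedSeq] = []
    for (direct, clones, _), truth in zip(samples, truths):
        nuc_seqs.append(direct)
        meta_rows.append(
            {"sample_id": direct.id, "species": "unknown", "genotype": "",
             "marker": cfg.nuclear_marker, "role": "direct"}
        )
        if clones is not None:
            for c in clones:
                clone_seqs.append(c)
                meta_rows.append(
                    {"sample_id": c.id, "species": "unknown", "genotype": "",
                     "marker": cfg.nuclear_marker, "role": "clone"}
                )
    path = outdir / f"{cfg.nuclear_marker}.fasta"
    write_fasta(Alignment(nuc_seqs, marker=cfg.nuclear_marker), path)
    files[cfg.nuclear_marker] = path
    if clone_seqs:
        cpath = outdir / f"{cfg.nuclear_marker}_clones.fasta"
        write_fasta(Alignment(clone_seqs, marker=cfg.nuclear_marker), cpath)
        files["clones"] = cpath

    for marker in cfg.plastid_markers:
        if marker not in panels:
            continue
        pan = panels[marker]
        seqs = []
        for label in pan.labels:
            c = pan.consensus(label)
            seqs.append(
                AlignedSeq(id=ref_id(label), residues=c.residues, species=c.species,
                           genotype=label, marker=marker, role="direct")
            )
            meta_rows.append(
                {"sample_id": ref_id(label), "species": c.species, "genotype": label,
                 "marker": marker, "role": "direct"}
            )
        for (_, _, plastids), truth in zip(samples, truths):
            if marker in plastids:
                seqs.append(plastids[marker])
                meta_rows.append(
                    {"sample_id": truth.sample_id, "species": "unknown", "genotype": "",
                     "marker": marker, "role": "direct"}
                )
        mpath = outdir / f"{marker.replace('/', '_')}.fasta"
        write_fasta(Alignment(seqs, marker=marker), mpath)
        files[marker] = mpath

    meta_path = outdir / "metadata.tsv"
    pd.DataFrame(meta_rows).to_csv(meta_path, sep="\t", index=False)
    files["metadata"] = meta_path

    truth_rows = [
        {
            "sample_id": t.sample_id,
            "true_class": t.true_class,
            "genotype_a": t.true_genotypes[0],
            "genotype_b": t.true_genotypes[1] if len(t.true_genotypes) > 1 else "",
            "maternal_species": t.true_maternal or "",
            "maternal_haplotype": t.maternal_haplotype or "",
        }
        for t in truths
    ]
    tpath = outdir / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(tpath, sep="\t", index=False)
    files["truth"] = tpath

    clone_rows = [
        {
            "clone_id": c.clone_id,
            "sample_id": t.sample_id,
            "source": c.source,
            "error_positions": ";".join(str(p + 1) for p in c.error_positions),
            "breakpoint": "" if c.breakpoint is None else str(c.breakpoint + 1),
        }
        for t in truths
        for c in t.clones
    ]
    ctpath = outdir / "clone_truth.tsv"
    pd.DataFrame(clone_rows).to_csv(ctpath, sep="\t", index=False)
    files["clone_truth"] = ctpath
    return files
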