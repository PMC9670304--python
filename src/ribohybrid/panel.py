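"""Reference panels of species/genotype consensus sequences.

A GenotypePanel maps genotype labels (e.g. "pectinata/1a") to consensus
ribotypes or haplotypes and indexes them by species.  Hybrid classification
works entirely off the panel's diagnostic sites: alignment columns at which
two genotypes carry different unambiguous states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ribohybrid.seqio import (
    AlignedSeq,
    Alignment,
    iupac_merge,
    iupac_set,
    is_ambiguous,
    write_fasta,
)

__all__ = [
    "GenotypePanel",
    "DiagnosticSiteSet",
    "build_panel",
    "pairwise_substitutions",
    "diagnostic_sites",
    "collapse_identical",
    "write_panel",
    "read_panel",
]


@dataclass
class DiagnosticSiteSet:
    """Columns separating two genotypes.

    ``sites`` lists (0-based column, state_a, state_b) where both states are
    unambiguous and non-gap and differ; ``indel_sites`` lists columns where
    exactly one genotype has a gap.  The two lists are disjoint and sorted.
    """

    pair: tuple[str, str]
    sites: list[tuple[int, str, str]]
    indel_sites: list[int]


@dataclass
class GenotypePanel:
    """Per-marker map genotype label -> consensus, with a species index."""

    marker: str
    entries: dict[str, AlignedSeq]
    species_index: dict[str, set[str]]
    alignment_length: int
    aliases: dict[str, list[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._diag_columns: frozenset[int] | None = None

    @property
    def labels(self) -> list[str]:
        return sorted(self.entries)

    def species_of(self, label: str) -> str:
        for sp, labels in self.species_index.items():
            if label in labels:
                return sp
        raise KeyError(f"label {label!r} not in panel")

    def consensus(self, label: str) -> AlignedSeq:
        try:
            return self.entries[label]
        except KeyError:
            raise KeyError(f"label {label!r} not in panel") from None

    def haplotypes_of_species(self, species: str) -> list[str]:
        if species not in self.species_index:
            raise KeyError(f"species {species!r} not in panel")
        return sorted(self.species_index[species])

    def diagnostic_columns(self) -> frozenset[int]:
        """Union of substitution-diagnostic columns over all genotype pairs."""
        if self._diag_columns is None:
            cols: set[int] = set()
            labels = self.labels
            for i, g1 in enumerate(labels):
                for g2 in labels[i + 1 :]:
                    cols.update(c for c, _, _ in diagnostic_sites(self, g1, g2).sites)
            self._diag_columns = frozenset(cols)
        return self._diag_columns


def _residues(x: AlignedSeq | str) -> str:
    return x.residues if isinstance(x, AlignedSeq) else x


def pairwise_substitutions(a: AlignedSeq | str, b: AlignedSeq | str) -> int:
    """Number of columns where the two states share no base.

    Only columns where both sequences are non-gap count; ambiguity codes
    with overlapping base sets count as zero difference (a direct sequence
    showing R is compatible with both an A- and a G-genotype).  Indel
    differences are reported separately by :func:`diagnostic_sites`.
    """
    ra, rb = _residues(a), _residues(b)
    if len(ra) != len(rb):
        raise ValueError(f"length mismatch: {len(ra)} vs {len(rb)}")
    n = 0
    for sa, sb in zip(ra, rb):
        if sa == "-" or sb == "-":
            continue
        if not (iupac_set(sa) & iupac_set(sb)):
            n += 1
    return n


def indel_event_count(a: AlignedSeq | str, b: AlignedSeq | str) -> int:
    """Number of maximal runs of columns where exactly one sequence is gapped.

    A contiguous gap-presence difference is one mutational event, matching
    how spacer indels arise.
    """
    ra, rb = _residues(a), _residues(b)
    if len(ra) != len(rb):
        raise ValueError(f"length mismatch: {len(ra)} vs {len(rb)}")
    events = 0
    in_run = False
    for sa, sb in zip(ra, rb):
        diff = (sa == "-") != (sb == "-")
        if diff and not in_run:
            events += 1
        in_run = diff
    return events


def diagnostic_sites(panel: GenotypePanel, g1: str, g2: str) -> DiagnosticSiteSet:
    """Enumerate substitution- and indel-diagnostic columns for a pair.

    Columns where either consensus is N or an ambiguity code are excluded
    from ``sites`` (they cannot give a clean additive signal).
    """
    ca = panel.consensus(g1).residues
    cb = panel.consensus(g2).residues
    sites: list[tuple[int, str, str]] = []
    indels: list[int] = []
    for col, (sa, sb) in enumerate(zip(ca, cb)):
        ga, gb = sa == "-", sb == "-"
        if ga != gb:
            indels.append(col)
            continue
        if ga and gb:
            continue
        if sa == "N" or sb == "N" or is_ambiguous(sa) or is_ambiguous(sb):
            continue
        if sa != sb:
            sites.append((col, sa, sb))
    return DiagnosticSiteSet(pair=(g1, g2), sites=sites, indel_sites=indels)


def _consensus_column(states: list[str], col: int, warnings: list[str], label: str) -> str:
    """Majority call over unambiguous states; ties merge to an IUPAC code."""
    from collections import Counter

    unamb = [s for s in states if s in "ACGT"]
    gaps = [s for s in states if s == "-"]
    if not unamb:
        if gaps and len(gaps) >= len(states) / 2:
            return "-"
        return "N"
    counts = Counter(unamb)
    if len(counts) > 1:
        warnings.append(
            f"{label}: conflicting unambiguous states {dict(counts)} at column {col + 1}"
        )
    top = counts.most_common()
    best_count = top[0][1]
    tied = sorted(s for s, c in top if c == best_count)
    if len(tied) == 1:
        return tied[0]
    merged = tied[0]
    for s in tied[1:]:
        merged = iupac_merge(merged, s)
    warnings.append(f"{label}: tie {tied} at column {col + 1} stored as {merged}")
    return merged


def build_panel(
    aln: Alignment,
    labels: Mapping[str, tuple[str, str]] | pd.DataFrame,
) -> GenotypePanel:
    """Build a per-marker panel of genotype consensuses from labelled sequences.

    ``labels`` maps sample id -> (species, genotype label), or is a DataFrame
    with columns sample_id, species, genotype.  The consensus per genotype is
    the column-wise majority of unambiguous states; within-genotype conflicts
    are recorded as warnings.  Within a species, genotypes whose consensuses
    are identical over non-gap non-N columns are merged under the
    lexicographically first label, the others recorded as aliases.
    Cross-species identical consensuses (common for plastid haplotypes of
    closely related species) are retained and flagged, so downstream
    maternal assignment can yield an equivocal call.
    """
    if isinstance(labels, pd.DataFrame):
        labels = {
            str(r["sample_id"]): (str(r["species"]), str(r["genotype"]))
            for _, r in labels.iterrows()
        }
    if not labels:
        raise ValueError("empty label set")

    by_genotype: dict[str, list[AlignedSeq]] = {}
    species_of: dict[str, str] = {}
    for sid, (species, genotype) in labels.items():
        if sid not in aln:
            continue
        if genotype in species_of and species_of[genotype] != species:
            raise ValueError(
                f"genotype label {genotype!r} assigned to both "
                f"{species_of[genotype]!r} and {species!r}"
            )
        species_of[genotype] = species
        by_genotype.setdefault(genotype, []).append(aln[sid])
    if not by_genotype:
        raise ValueError("no labelled sequence found in alignment")

    warnings: list[str] = []
    consensuses: dict[str, str] = {}
    for genotype, members in by_genotype.items():
        residues = "".join(
            _consensus_column([m.residues[c] for m in members], c, warnings, genotype)
            for c in range(aln.length)
        )
        consensuses[genotype] = residues

    # merge identical consensuses within a species (compare where both informative)
    def same(a: str, b: str) -> bool:
        return all(
            sa == sb
            for sa, sb in zip(a, b)
            if sa not in "N-" and sb not in "N-"
        )

    aliases: dict[str, list[str]] = {}
    kept: dict[str, str] = {}
    for genotype in sorted(consensuses):
        merged_into = None
        for rep in kept:
            if species_of[rep] == species_of[genotype] and same(kept[rep], consensuses[genotype]):
                merged_into = rep
                break
        if merged_into is None:
            kept[genotype] = consensuses[genotype]
        else:
            aliases.setdefault(merged_into, []).append(genotype)
            warnings.append(
                f"genotype {genotype!r} identical to {merged_into!r}; merged as alias"
            )

    # flag (but keep) cross-species identity
    kept_labels = sorted(kept)
    for i, g1 in enumerate(kept_labels):
        for g2 in kept_labels[i + 1 :]:
            if species_of[g1] != species_of[g2] and same(kept[g1], kept[g2]):
                warnings.append(
                    f"consensuses of {g1!r} ({species_of[g1]}) and {g2!r} "
                    f"({species_of[g2]}) are identical (shared haplotype)"
                )

    entries = {
        g: AlignedSeq(
            id=g,
            residues=res,
            species=species_of[g],
            genotype=g,
            marker=aln.marker,
            role="consensus",
        )
        for g, res in kept.items()
    }
    species_index: dict[str, set[str]] = {}
    for g in entries:
        species_index.setdefault(species_of[g], set()).add(g)

    return GenotypePanel(
        marker=aln.marker,
        entries=entries,
        species_index=species_index,
        alignment_length=aln.length,
        aliases=aliases,
        warnings=warnings,
    )


def collapse_identical(aln: Alignment) -> tuple[Alignment, dict[str, list[str]]]:
    """Deduplicate identical residue strings, keeping first-seen representatives.

    Returns the collapsed alignment plus a map representative id -> all
    member ids (representative included), covering every input id.  This is
    the "exclude identical samples and map them afterwards" step used before
    handing a matrix to tree software.
    """
    reps: dict[str, str] = {}  # residues -> representative id
    mapping: dict[str, list[str]] = {}
    kept: list[AlignedSeq] = []
    for s in aln:
        if s.residues in reps:
            mapping[reps[s.residues]].append(s.id)
        else:
            reps[s.residues] = s.id
            mapping[s.id] = [s.id]
            kept.append(s)
    return Alignment(kept, marker=aln.marker), mapping


def write_panel(panel: GenotypePanel, fasta_path: str | Path, tsv_path: str | Path) -> None:
    """Serialize a panel as consensus FASTA + label/species/alias TSV."""
    aln = Alignment(list(panel.entries.values()), marker=panel.marker)
    write_fasta(aln, fasta_path)
    rows = []
    for label in panel.labels:
        rows.append(
            {
                "genotype": label,
                "species": panel.species_of(label),
                "aliases": ";".join(panel.aliases.get(label, [])),
            }
        )
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def read_panel(fasta_path: str | Path, tsv_path: str | Path, marker: str = "other") -> GenotypePanel:
    """Load a panel serialized by :func:`write_panel`."""
    from ribohybrid.seqio import read_fasta

    meta = pd.read_csv(tsv_path, sep="\t", dtype=str).fillna("")
    aln = read_fasta(fasta_path, marker=marker)
    entries: dict[str, AlignedSeq] = {}
    species_index: dict[str, set[str]] = {}
    aliases: dict[str, list[str]] = {}
    for _, row in meta.iterrows():
        label, species = row["genotype"], row["species"]
        seq = aln[label]
        entries[label] = AlignedSeq(
            id=label,
            residues=seq.residues,
            species=species,
            genotype=label,
            marker=marker,
            role="consensus",
        )
        species_index.setdefault(species, set()).add(label)
        if row.get("aliases"):
            aliases[label] = [a for a in row["aliases"].split(";") if a]
    return GenotypePanel(
        marker=marker,
        entries=entries,
        species_index=species_index,
        alignment_length=aln.length,
        aliases=aliases,
    )
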