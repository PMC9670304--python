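"""Maternal-parent assignment of hybrids from plastid haplotypes.

Plastid DNA is assumed maternally inherited, so a hybrid carries the
plastid haplotype of exactly one parent.  Given the two parent species
determined from nuclear additivity, the hybrid's plastid sequence is
compared to every haplotype of both species: an exact match to haplotypes
of one species assigns the mother; an exact match to a haplotype shared by
both species is explicitly equivocal (the asterisked cases); no exact
match yields a novel haplotype derived from its nearest neighbour(s).

Distances count substitutions plus one event per contiguous gap-run
difference — a spacer indel is a single mutation regardless of length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ribohybrid.panel import GenotypePanel, indel_event_count, pairwise_substitutions
from ribohybrid.seqio import AlignedSeq

__all__ = [
    "MaternalCall",
    "assign_maternal",
    "cross_marker_resolve",
    "count_independent_origins",
]


@dataclass
class MaternalCall:
    sample_id: str
    marker: str
    call: str  # assigned | equivocal | novel_haplotype | conflict
    maternal: str | None  # species label
    candidates: set[str]
    matched_haplotype: str | None
    distance: int
    derived_from: list[str] = field(default_factory=list)
    note: str = ""

    @property
    def asterisk(self) -> str:
        """Figure convention: '*' marks samples with equivocal maternal parent."""
        return "*" if self.call == "equivocal" else ""


def _distance(a: str, b: str, indels_as_events: bool) -> int:
    d = pairwise_substitutions(a, b)
    if indels_as_events:
        d += indel_event_count(a, b)
    return d


def assign_maternal(
    hybrid_seq: AlignedSeq,
    plastid_panel: GenotypePanel,
    parent_species: tuple[str, str] | None,
    indels_as_events: bool = True,
) -> MaternalCall:
    """Assign the maternal parent of one hybrid from a plastid marker.

    Candidates are restricted to the two nuclear-determined parents; pass
    ``parent_species=None`` for the open-panel mode that scans all species
    (the unknown-parent case), which reports novel haplotypes without
    species attribution rather than guessing.
    """
    if parent_species is not None:
        for sp in parent_species:
            if sp not in plastid_panel.species_index:
                raise KeyError(f"parent species {sp!r} absent from plastid panel")
        species_pool = set(parent_species)
    else:
        species_pool = set(plastid_panel.species_index)

    dists: dict[str, int] = {}
    for sp in sorted(species_pool):
        for hap in plastid_panel.haplotypes_of_species(sp):
            dists[hap] = _distance(
                hybrid_seq.residues,
                plastid_panel.consensus(hap).residues,
                indels_as_events,
            )
    if not dists:
        raise ValueError("no candidate haplotypes in panel")

    dmin = min(dists.values())
    nearest = sorted(h for h, d in dists.items() if d == dmin)
    nearest_species = {plastid_panel.species_of(h) for h in nearest}

    if dmin == 0:
        if parent_species is None:
            # open-panel: exact match still reported, but attribution only if unique
            pass
        if len(nearest_species) == 1:
            sp = next(iter(nearest_species))
            return MaternalCall(
                sample_id=hybrid_seq.id,
                marker=plastid_panel.marker,
                call="assigned",
                maternal=sp,
                candidates={sp},
                matched_haplotype=nearest[0],
                distance=0,
            )
        return MaternalCall(
            sample_id=hybrid_seq.id,
            marker=plastid_panel.marker,
            call="equivocal",
            maternal=None,
            candidates=nearest_species,
            matched_haplotype=nearest[0],
            distance=0,
            note="haplotype shared by candidate parents",
        )

    return MaternalCall(
        sample_id=hybrid_seq.id,
        marker=plastid_panel.marker,
        call="novel_haplotype",
        maternal=None,
        candidates=nearest_species,
        matched_haplotype=None,
        distance=dmin,
        derived_from=nearest,
        note="no exact haplotype match; nearest reported",
    )


def cross_marker_resolve(calls: Sequence[MaternalCall]) -> MaternalCall:
    """Combine maternal calls for one sample across plastid markers.

    Any assigned call wins (a second, conflicting assigned call produces an
    explicit conflict state, never a silent override).  Failing that, a
    novel haplotype derived from haplotypes of a single candidate species
    resolves by derivation.  Otherwise the result stays equivocal.
    """
    if not calls:
        raise ValueError("no calls to resolve")
    sample_ids = {c.sample_id for c in calls}
    if len(sample_ids) != 1:
        raise ValueError(f"calls span multiple samples: {sorted(sample_ids)}")
    sid = calls[0].sample_id

    assigned = [c for c in calls if c.call == "assigned"]
    if assigned:
        mothers = {c.maternal for c in assigned}
        if len(mothers) > 1:
            return MaternalCall(
                sample_id=sid,
                marker="combined",
                call="conflict",
                maternal=None,
                candidates=mothers,
                matched_haplotype=None,
                distance=-1,
                note="markers assign different maternal parents",
            )
        best = min(assigned, key=lambda c: c.distance)
        return MaternalCall(
            sample_id=sid,
            marker="combined",
            call="assigned",
            maternal=best.maternal,
            candidates={best.maternal},
            matched_haplotype=best.matched_haplotype,
            distance=best.distance,
            note=f"resolved by {best.marker}",
        )

    for c in calls:
        if c.call == "novel_haplotype" and len(c.candidates) == 1:
            sp = next(iter(c.candidates))
            return MaternalCall(
                sample_id=sid,
                marker="combined",
                call="assigned",
                maternal=sp,
                candidates={sp},
                matched_haplotype=None,
                distance=c.distance,
                derived_from=c.derived_from,
                note=f"assigned by derivation from {','.join(c.derived_from)} ({c.marker})",
            )

    cands: set[str] = set()
    for c in calls:
        cands |= c.candidates
    return MaternalCall(
        sample_id=sid,
        marker="combined",
        call="equivocal",
        maternal=None,
        candidates=cands,
        matched_haplotype=None,
        distance=min(c.distance for c in calls),
        note="unresolved across markers",
    )


def count_independent_origins(
    samples: pd.DataFrame,
) -> dict[str, dict[str, object]]:
    """Lower-bound the number of independent origins per hybrid type.

    ``samples`` needs columns hybrid_type (unordered "A x B" species pair),
    maternal (species or empty for equivocal), and haplotype (matched or
    nearest plastid haplotype label).  Two samples demonstrably arose from
    separate hybridization events when they differ in maternal species or
    in the maternal haplotype carried; the count of distinct
    (maternal, haplotype) tuples is therefore a lower bound on origins.
    ``reciprocal_cross`` is set when both parents occur as the mother.
    """
    out: dict[str, dict[str, object]] = {}
    for htype, grp in samples.groupby("hybrid_type"):
        tuples = {
            (str(r["maternal"]) or "?", str(r["haplotype"]))
            for _, r in grp.iterrows()
        }
        mothers = {str(r["maternal"]) for _, r in grp.iterrows() if str(r["maternal"])}
        parents = {p.strip() for p in str(htype).split(" x ")}
        out[str(htype)] = {
            "n_samples": int(len(grp)),
            "min_independent_origins": len(tuples),
            "reciprocal_cross": len(mothers & parents) >= 2,
            "maternal_species": sorted(mothers),
        }
    return out
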