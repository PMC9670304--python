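"""Analysis of cloned sequences from one (putatively hybrid) sample.

Cloning separates the copy classes that are superimposed in a direct read,
but introduces two artifact types: polymerase errors (unique substitutions
in single clones that do not correspond to polymorphisms in the direct
sequence) and PCR-mediated chimeras (template switching producing a clone
that is parent A up to a breakpoint and parent B after it).  This module
corrects the former, dismisses the latter, assigns each clean clone to a
parental copy class, and picks representative clones per parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ribohybrid.hybrid import peak_subtract
from ribohybrid.panel import GenotypePanel, pairwise_substitutions
from ribohybrid.seqio import AlignedSeq, Alignment, is_ambiguous, iupac_set

__all__ = [
    "CloneReport",
    "correct_polymerase_errors",
    "assign_clones",
    "detect_breakpoints",
    "choose_representatives",
    "infer_missing_parent",
    "analyze_clones",
    "cluster_clones_de_novo",
]


@dataclass
class CloneAssignment:
    clone_id: str
    klass: str  # parentA | parentB | recombinant | unassigned
    state_string: str  # over {A, B, N} at informative columns
    distance_to_nearest: int
    matched_genotype: str | None = None
    suspect_sites: list[int] = field(default_factory=list)


@dataclass
class CloneReport:
    """Full per-sample clone analysis result."""

    sample_id: str
    assignments: dict[str, CloneAssignment]
    breakpoints: dict[str, list[tuple[int, int]]]  # clone -> open intervals, 0-based cols
    corrections: dict[str, list[tuple[int, str, str]]]
    representatives: dict[str, list[str]]  # parentA/parentB -> clone ids (<=2 each)
    parents_recovered: bool
    inferred_parent: str | None = None  # residues of a subtraction-inferred copy
    warnings: list[str] = field(default_factory=list)


def correct_polymerase_errors(
    clones: Alignment, direct: AlignedSeq
) -> tuple[Alignment, dict[str, list[tuple[int, str, str]]]]:
    """Correct unique single-clone substitutions not seen in the direct read.

    A state in one clone is reset to the direct-sequence base when (i) it
    differs from every other clone at that column and (ii) the direct
    sequence is unambiguous there.  Truly polymorphic columns (direct shows
    an ambiguity) are never touched.  With fewer than two clones uniqueness
    cannot be established; the input is returned with a warning.
    """
    if clones.length != len(direct.residues):
        raise ValueError("clones and direct sequence must have equal length")
    corrections: dict[str, list[tuple[int, str, str]]] = {c.id: [] for c in clones}
    if len(clones) < 2:
        return clones, corrections

    new_residues = {c.id: list(c.residues) for c in clones}
    for col in range(clones.length):
        d = direct.residues[col]
        if d == "-" or d == "N" or is_ambiguous(d):
            continue
        states = [(c.id, c.residues[col]) for c in clones]
        for cid, sym in states:
            if sym == d:
                continue
            if any(other == sym for oid, other in states if oid != cid):
                continue  # shared deviant state: a real variant, keep
            new_residues[cid][col] = d
            corrections[cid].append((col, sym, d))
    fixed = Alignment(
        [
            AlignedSeq(
                id=c.id,
                residues="".join(new_residues[c.id]),
                species=c.species,
                genotype=c.genotype,
                marker=c.marker,
                role=c.role,
            )
            for c in clones
        ],
        marker=clones.marker,
    )
    return fixed, corrections


def informative_columns(parent_a: str, parent_b: str) -> list[int]:
    """Columns where the two parental copies differ with unambiguous states."""
    return [
        c
        for c, (sa, sb) in enumerate(zip(parent_a, parent_b))
        if sa != sb and sa in "ACGT" and sb in "ACGT"
    ]


def state_string(clone: str, parent_a: str, parent_b: str, cols: Sequence[int]) -> str:
    """Per informative column: A-state, B-state, or N (matches neither)."""
    out = []
    for c in cols:
        s = clone[c]
        if s == parent_a[c]:
            out.append("A")
        elif s == parent_b[c]:
            out.append("B")
        else:
            out.append("N")
    return "".join(out)


def detect_breakpoints(
    states: str, min_block: int = 2
) -> tuple[list[tuple[int, int]], list[int]]:
    """Segment an {A,B,N} state string into parental blocks.

    A clone is recombinant iff its string contains at least two maximal
    same-parent runs of length >= ``min_block`` with different parent
    identity.  Breakpoints are reported as open index intervals (i, j)
    between the last position of one solid run and the first of the next
    solid run of the other parent.  Positions in runs shorter than
    ``min_block`` are suspect sites (more parsimoniously polymerase errors
    than crossovers), not breakpoint evidence.

    Indices refer to positions within ``states`` (the informative-site
    coordinate system); N positions are ignored for run building.

    Semantics: find the smallest set of positions whose removal (always
    whole short runs — a solid run is never explained away) leaves every
    maximal same-parent block with length >= ``min_block``; ties go to the
    lexicographically smallest removed-position set.  Removed positions are
    the suspect sites; transitions between the remaining blocks are the
    breakpoints.  A lone discordant site inside a long block is thus one
    suspect site, not a double crossover.
    """
    positions = [i for i, s in enumerate(states) if s in "AB"]
    if not positions:
        return [], []
    # run-length encode over the N-filtered subsequence
    runs: list[tuple[str, list[int]]] = []
    for i in positions:
        if runs and runs[-1][0] == states[i]:
            runs[-1][1].append(i)
        else:
            runs.append((states[i], [i]))

    INF = float("inf")
    m = len(runs)
    cache: dict[tuple, float] = {}

    def cost(k: int, open_letter: str | None, open_len: int) -> float:
        """Min positions to delete among runs[k:] given the open block."""
        key = (k, open_letter, min(open_len, min_block))
        if key in cache:
            return cache[key]
        if k == m:
            out = 0.0 if open_letter is None or open_len >= min_block else INF
            cache[key] = out
            return out
        letter, idxs = runs[k]
        best = INF
        if len(idxs) < min_block:  # deleting solid runs is never considered
            best = len(idxs) + cost(k + 1, open_letter, open_len)
        if open_letter is None or open_letter == letter:
            best = min(best, cost(k + 1, letter, open_len + len(idxs)))
        elif open_len >= min_block:
            best = min(best, cost(k + 1, letter, len(idxs)))
        cache[key] = best
        return best

    total = cost(0, None, 0)
    # greedy left-to-right: deleting the earliest possible runs yields the
    # lexicographically smallest suspect set at the minimal total
    suspects: list[int] = []
    blocks: list[tuple[str, list[int]]] = []
    open_letter: str | None = None
    open_len = 0
    budget = total
    for k, (letter, idxs) in enumerate(runs):
        if (
            len(idxs) < min_block
            and len(idxs) + cost(k + 1, open_letter, open_len) == budget
        ):
            suspects.extend(idxs)
            budget -= len(idxs)
            continue
        if open_letter == letter:
            blocks[-1][1].extend(idxs)
            open_len += len(idxs)
        else:
            blocks.append((letter, list(idxs)))
            open_letter, open_len = letter, len(idxs)

    breakpoints = [
        (a[1][-1], b[1][0]) for a, b in zip(blocks, blocks[1:]) if a[0] != b[0]
    ]
    return breakpoints, sorted(suspects)


def is_recombinant(states: str, min_block: int = 2) -> bool:
    breakpoints, _ = detect_breakpoints(states, min_block=min_block)
    return len(breakpoints) >= 1


def assign_clones(
    clones: Alignment,
    parent_a: AlignedSeq | str,
    parent_b: AlignedSeq | str,
    min_block: int = 2,
    panel: GenotypePanel | None = None,
) -> tuple[dict[str, CloneAssignment], dict[str, list[tuple[int, int]]]]:
    """Assign each clone to parent A, parent B, recombinant, or unassigned.

    The decision uses only the informative columns (unambiguous differences
    between the parents).  All-A strings go to parentA, all-B to parentB;
    strings with solid blocks of both parents are recombinant; strings
    dominated by states matching neither parent are unassigned, with the
    substitution distance to the nearest parent (or panel genotype, when a
    panel is supplied) reported.
    """
    pa = parent_a.residues if isinstance(parent_a, AlignedSeq) else parent_a
    pb = parent_b.residues if isinstance(parent_b, AlignedSeq) else parent_b
    cols = informative_columns(pa, pb)
    if not cols:
        raise ValueError("parents share all unambiguous states: zero informative columns")

    assignments: dict[str, CloneAssignment] = {}
    all_breakpoints: dict[str, list[tuple[int, int]]] = {}
    refs: dict[str, str] = {"parentA": pa, "parentB": pb}
    if panel is not None:
        refs.update({g: panel.consensus(g).residues for g in panel.labels})

    for clone in clones:
        ss = state_string(clone.residues, pa, pb, cols)
        n_other = ss.count("N")
        breakpoints, suspects = detect_breakpoints(ss, min_block=min_block)
        # map breakpoint intervals from state-string indices to alignment columns
        bp_cols = [(cols[i], cols[j]) for i, j in breakpoints]

        dists = {name: pairwise_substitutions(clone.residues, ref) for name, ref in refs.items()}
        nearest = min(dists, key=lambda k: (dists[k], k))

        if n_other > len(cols) / 2:
            klass = "unassigned"
        elif breakpoints:
            klass = "recombinant"
        else:
            n_a, n_b = ss.count("A"), ss.count("B")
            if n_a and n_b:
                # mixed but no solid alternation: majority class, minority suspect
                klass = "parentA" if n_a >= n_b else "parentB"
            elif n_a:
                klass = "parentA"
            elif n_b:
                klass = "parentB"
            else:
                klass = "unassigned"

        matched = None
        if panel is not None and dists[nearest] == 0 and nearest not in ("parentA", "parentB"):
            matched = nearest
        assignments[clone.id] = CloneAssignment(
            clone_id=clone.id,
            klass=klass,
            state_string=ss,
            distance_to_nearest=dists[nearest],
            matched_genotype=matched,
            suspect_sites=[cols[i] for i in suspects],
        )
        if bp_cols:
            all_breakpoints[clone.id] = bp_cols
    return assignments, all_breakpoints


def choose_representatives(
    assignments: dict[str, CloneAssignment], clones: Alignment
) -> tuple[dict[str, list[str]], bool, list[str]]:
    """Pick at most two representative clones per parental copy class.

    If all members of a class are identical the first (by id) is taken; if
    the parent is polymorphic (two sequence variants among its clones), one
    clone per variant is chosen, capped at the two most frequent variants.
    Recombinant clones are never eligible.  Returns (representatives,
    parents_recovered, warnings).
    """
    reps: dict[str, list[str]] = {}
    warnings: list[str] = []
    for klass in ("parentA", "parentB"):
        members = sorted(
            (cid for cid, a in assignments.items() if a.klass == klass),
        )
        if not members:
            reps[klass] = []
            continue
        variants: dict[str, list[str]] = {}
        for cid in members:
            variants.setdefault(clones[cid].residues, []).append(cid)
        ordered = sorted(variants.values(), key=lambda ids: (-len(ids), ids[0]))
        if len(ordered) > 2:
            warnings.append(
                f"{klass}: {len(ordered)} sequence variants among clones; "
                "keeping the two most frequent"
            )
        reps[klass] = [ids[0] for ids in ordered[:2]]
    both = bool(reps["parentA"]) and bool(reps["parentB"])
    return reps, both, warnings


def infer_missing_parent(
    direct: AlignedSeq, recovered: AlignedSeq | str
) -> tuple[str, list[int]]:
    """Infer the unrecovered copy by peak subtraction from the direct read.

    Used when one parent is represented only by recombinant clones.  The
    result is tagged inferred by the caller; flagged columns remain
    ambiguous after subtraction.
    """
    return peak_subtract(direct, recovered)


def cluster_clones_de_novo(clones: Alignment, max_within: int = 1) -> tuple[str, str]:
    """Derive putative parental consensuses when no reference is available.

    Complete-linkage clustering at substitution distance <= ``max_within``;
    the two largest clusters' first members are taken as putative parents.
    """
    members = list(clones)
    clusters: list[list[AlignedSeq]] = []
    for seq in members:
        placed = False
        for cl in clusters:
            if all(pairwise_substitutions(seq.residues, m.residues) <= max_within for m in cl):
                cl.append(seq)
                placed = True
                break
        if not placed:
            clusters.append([seq])
    clusters.sort(key=lambda cl: (-len(cl), cl[0].id))
    if len(clusters) < 2:
        raise ValueError("de novo clustering found fewer than two copy classes")
    return clusters[0][0].residues, clusters[1][0].residues


def analyze_clones(
    clones: Alignment,
    direct: AlignedSeq,
    parent_a: AlignedSeq | str | None = None,
    parent_b: AlignedSeq | str | None = None,
    min_block: int = 2,
    panel: GenotypePanel | None = None,
) -> CloneReport:
    """Full clone workflow: correct errors, assign, dismiss chimeras, choose reps.

    Without parental references the two copy classes are derived de novo by
    clustering.  If one copy class ends up represented only by recombinant
    clones, the missing parent is inferred by peak subtraction from the
    direct sequence and the recovered parent.
    """
    warnings: list[str] = []
    if len(clones) < 2:
        warnings.append("fewer than 2 clones: polymerase-error correction skipped")
        corrected, corrections = clones, {c.id: [] for c in clones}
    else:
        corrected, corrections = correct_polymerase_errors(clones, direct)

    if parent_a is None or parent_b is None:
        pa, pb = cluster_clones_de_novo(corrected)
        warnings.append("parents derived de novo from clone clustering")
    else:
        pa = parent_a.residues if isinstance(parent_a, AlignedSeq) else parent_a
        pb = parent_b.residues if isinstance(parent_b, AlignedSeq) else parent_b

    assignments, breakpoints = assign_clones(
        corrected, pa, pb, min_block=min_block, panel=panel
    )
    reps, both, rep_warnings = choose_representatives(assignments, corrected)
    warnings.extend(rep_warnings)

    inferred = None
    if not both:
        missing = "parentA" if not reps["parentA"] else "parentB"
        present = "parentB" if missing == "parentA" else "parentA"
        if reps[present]:
            recovered = corrected[reps[present][0]].residues
            try:
                inferred, flagged = infer_missing_parent(direct, recovered)
                both = True
                warnings.append(
                    f"{missing} had no clean clone; inferred by peak subtraction"
                    + (f" ({len(flagged)} columns still ambiguous)" if flagged else "")
                )
            except ValueError as exc:
                warnings.append(f"{missing} unrecoverable: {exc}")

    return CloneReport(
        sample_id=direct.id,
        assignments=assignments,
        breakpoints=breakpoints,
        corrections={k: v for k, v in corrections.items()},
        representatives=reps,
        parents_recovered=both,
        inferred_parent=inferred,
        warnings=warnings,
    )
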