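"""Classification of direct sequences against a genotype panel.

A hybrid's direct (uncloned) sequence is the superposition of both parental
copies, so it shows the IUPAC union of the parental states at every column
where the parents differ ("character additivity").  classify_direct scores
every single-genotype and every unordered-pair hypothesis over the panel's
diagnostic columns and reports the best-supported verdict.

Matching is strict set equality at diagnostic sites: where the parents carry
A and T the query must show W; a plain A fails that site.  Hybrids maintain
the ribotypes of both parents, and partial peaks below detection are
handled by the integer ``tolerance``, not by relaxing the match.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Sequence

from ribohybrid.panel import GenotypePanel
from ribohybrid.seqio import (
    AlignedSeq,
    Alignment,
    is_ambiguous,
    iupac_merge,
    iupac_set,
    iupac_subtract,
)

__all__ = [
    "AdditivityCall",
    "ExpectedSequence",
    "expected_sequence",
    "classify_direct",
    "peak_subtract",
    "select_for_phylogeny",
    "PeakIncompatibilityError",
]

Hypothesis = str | frozenset


class PeakIncompatibilityError(ValueError):
    """The assumed parent's base is absent from the query's ambiguity set."""

    def __init__(self, columns: list[int]):
        self.columns = columns
        cols = ", ".join(str(c + 1) for c in columns)
        super().__init__(f"parent incompatible with query at column(s) {cols}")


@dataclass
class ExpectedSequence:
    """Predicted direct sequence under a hypothesis.

    For a pair hypothesis, ``residues`` holds the column-wise IUPAC merge of
    the two parental consensuses; columns where exactly one parent is gapped
    carry the non-gap parent's state and are listed in ``indel_additive``
    (gap-versus-base additivity is not expressible in IUPAC and is excluded
    from base matching).
    """

    hypothesis: Hypothesis
    residues: str
    indel_additive: list[int] = field(default_factory=list)


@dataclass
class AdditivityCall:
    """Classification verdict for one direct sequence."""

    sample_id: str
    verdict: str  # pure | intraspecific_hybrid | interspecific_hybrid | novel | ambiguous
    hypothesis: Hypothesis | None
    explained_sites: list[tuple[int, str, str]] = field(default_factory=list)
    violated_sites: list[tuple[int, str, str]] = field(default_factory=list)
    extra_polymorphic_sites: list[int] = field(default_factory=list)
    indel_polymorphic_sites: list[int] = field(default_factory=list)
    tied_hypotheses: list[Hypothesis] = field(default_factory=list)
    demoted_sites: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def hypothesis_label(self) -> str:
        if self.hypothesis is None:
            return "-"
        if isinstance(self.hypothesis, str):
            return self.hypothesis
        return " x ".join(sorted(self.hypothesis))


def expected_sequence(panel: GenotypePanel, hypothesis: Hypothesis) -> ExpectedSequence:
    """Predicted direct-read states under a pure or hybrid hypothesis."""
    cache = panel.__dict__.setdefault("_expected_cache", {})
    if hypothesis in cache:
        return cache[hypothesis]
    result = _expected_sequence(panel, hypothesis)
    cache[hypothesis] = result
    return result


def _expected_sequence(panel: GenotypePanel, hypothesis: Hypothesis) -> ExpectedSequence:
    if isinstance(hypothesis, str):
        return ExpectedSequence(hypothesis, panel.consensus(hypothesis).residues, [])
    labels = sorted(hypothesis)
    if len(labels) != 2:
        raise ValueError("pair hypothesis must contain exactly two labels")
    ra = panel.consensus(labels[0]).residues
    rb = panel.consensus(labels[1]).residues
    out: list[str] = []
    indel_additive: list[int] = []
    for col, (sa, sb) in enumerate(zip(ra, rb)):
        ga, gb = sa == "-", sb == "-"
        if ga and gb:
            out.append("-")
        elif ga != gb:
            indel_additive.append(col)
            out.append(sb if ga else sa)
        else:
            out.append(iupac_merge(sa, sb))
    return ExpectedSequence(frozenset(labels), "".join(out), indel_additive)


def _demote_weak_ambiguities(
    query: AlignedSeq, min_minor_fraction: float
) -> tuple[str, list[int], list[str]]:
    """Replace ambiguities whose minor peak is below threshold with the major base.

    Small secondary peaks (below about 30% of total signal for 5S-NTS in the
    source workflow) are background, not additivity.  Demotion needs the
    identity of the taller peak; sites without a recorded major base are
    left untouched with a warning.
    """
    if not query.minor_fraction:
        return query.residues, [], []
    residues = list(query.residues)
    demoted: list[int] = []
    warnings: list[str] = []
    majors = query.major_base or {}
    for pos, frac in query.minor_fraction.items():
        if frac >= min_minor_fraction:
            continue
        if not is_ambiguous(residues[pos]):
            continue
        major = majors.get(pos)
        if major is None:
            warnings.append(
                f"site {pos + 1}: minor fraction {frac:.2f} below threshold but "
                "major base unknown; ambiguity kept"
            )
            continue
        if major not in iupac_set(residues[pos]):
            warnings.append(
                f"site {pos + 1}: recorded major base {major!r} not in observed "
                f"state {residues[pos]!r}; ambiguity kept"
            )
            continue
        residues[pos] = major
        demoted.append(pos)
    return "".join(residues), sorted(demoted), warnings


def _score_hypothesis(
    residues: str,
    exp: ExpectedSequence,
    diag_cols: Iterable[int],
) -> tuple[list[tuple[int, str, str]], list[tuple[int, str, str]], list[int]]:
    """Explained/violated diagnostic sites and indel-polymorphic columns."""
    explained: list[tuple[int, str, str]] = []
    violated: list[tuple[int, str, str]] = []
    indel_poly: list[int] = []
    skip = set(exp.indel_additive)
    for col in sorted(diag_cols):
        if col in skip:
            continue
        q, e = residues[col], exp.residues[col]
        if q == "N" or e == "N":
            continue
        qg, eg = q == "-", e == "-"
        if qg or eg:
            if qg != eg:
                indel_poly.append(col)
            continue
        if iupac_set(q) == iupac_set(e):
            explained.append((col, q, e))
        else:
            violated.append((col, q, e))
    return explained, violated, indel_poly


def classify_direct(
    query: AlignedSeq,
    panel: GenotypePanel,
    tolerance: int = 0,
    min_minor_fraction: float = 0.30,
) -> AdditivityCall:
    """Classify one direct sequence as pure / hybrid / novel / ambiguous.

    Every single genotype and every unordered pair of distinct panel
    genotypes is scored by its number of violated diagnostic sites.  The
    best hypothesis must score within ``tolerance``, else the verdict is
    ``novel``.  A pure hypothesis is preferred over a pair at equal
    admissibility (parsimony); ties among pairs yield ``ambiguous`` with all
    tied pairs listed.  Ambiguities at non-diagnostic columns never
    penalize — they are reported as ``extra_polymorphic_sites`` (sequences
    "with further polymorphisms but otherwise identical to a genotype"
    remain pure).
    """
    if not panel.entries:
        raise ValueError("empty panel")
    if len(query.residues) != panel.alignment_length:
        raise ValueError(
            f"query length {len(query.residues)} != panel length {panel.alignment_length}"
        )

    residues, demoted, warnings = _demote_weak_ambiguities(query, min_minor_fraction)
    diag_cols = panel.diagnostic_columns()

    labels = panel.labels
    hypotheses: list[Hypothesis] = list(labels)
    hypotheses += [frozenset(p) for p in combinations(labels, 2)]

    scored: dict[Hypothesis, tuple] = {}
    for hyp in hypotheses:
        exp = expected_sequence(panel, hyp)
        explained, violated, indel_poly = _score_hypothesis(residues, exp, diag_cols)
        scored[hyp] = (len(violated), explained, violated, indel_poly)

    pure_best = min((scored[h][0] for h in labels), default=None)
    pair_hyps = [h for h in hypotheses if not isinstance(h, str)]
    pair_best = min((scored[h][0] for h in pair_hyps), default=None)

    extra_poly = sorted(
        col
        for col, sym in enumerate(residues)
        if col not in diag_cols and sym != "N" and is_ambiguous(sym)
    )

    def finish(verdict: str, hyp: Hypothesis | None, tied: list[Hypothesis]) -> AdditivityCall:
        if hyp is not None:
            _, explained, violated, indel_poly = scored[hyp]
        else:
            explained, violated, indel_poly = [], [], []
        return AdditivityCall(
            sample_id=query.id,
            verdict=verdict,
            hypothesis=hyp,
            explained_sites=explained,
            violated_sites=violated,
            extra_polymorphic_sites=extra_poly,
            indel_polymorphic_sites=indel_poly,
            tied_hypotheses=tied,
            demoted_sites=demoted,
            warnings=warnings,
        )

    if pure_best is not None and pure_best <= tolerance:
        best_pure = [h for h in labels if scored[h][0] == pure_best]
        if len(best_pure) == 1:
            return finish("pure", best_pure[0], [])
        return finish("ambiguous", None, best_pure)

    if pair_best is not None and pair_best <= tolerance:
        best_pairs = [h for h in pair_hyps if scored[h][0] == pair_best]
        if len(best_pairs) > 1:
            return finish("ambiguous", None, best_pairs)
        hyp = best_pairs[0]
        species = {panel.species_of(label) for label in hyp}
        verdict = "interspecific_hybrid" if len(species) == 2 else "intraspecific_hybrid"
        return finish(verdict, hyp, [])

    return finish("novel", None, [])


def peak_subtract(
    query: AlignedSeq | str, parent: AlignedSeq | str
) -> tuple[str, list[int]]:
    """Infer the second parental copy by removing the known parent's signal.

    Per column: an unambiguous query state is its own answer (the copies
    agree); at an ambiguous state the parent's bases are subtracted.
    Columns where the difference still holds more than one base are
    returned as flagged (still ambiguous).  Columns where the parent's base
    is absent from the query's set are collected and raised as a
    :class:`PeakIncompatibilityError`.
    """
    q = query.residues if isinstance(query, AlignedSeq) else query
    p = parent.residues if isinstance(parent, AlignedSeq) else parent
    if len(q) != len(p):
        raise ValueError(f"length mismatch: {len(q)} vs {len(p)}")

    out: list[str] = []
    flagged: list[int] = []
    bad: list[int] = []
    for col, (sq, sp) in enumerate(zip(q, p)):
        if sq == "-" or sp == "-":
            # indel columns pass through; gap additivity is a classification
            # concern, not a subtraction one
            out.append(sq)
            continue
        qset = iupac_set(sq)
        if len(qset) == 1:
            if not (iupac_set(sp) & qset):
                bad.append(col)
                out.append(sq)
            else:
                out.append(sq)
            continue
        if not iupac_set(sp) <= qset:
            bad.append(col)
            out.append(sq)
            continue
        res = iupac_subtract(sq, sp)
        if len(iupac_set(res)) > 1:
            flagged.append(col)
        out.append(res)
    if bad:
        raise PeakIncompatibilityError(bad)
    return "".join(out), flagged


def select_for_phylogeny(
    calls: Sequence[AdditivityCall],
    aln: Alignment,
    unique_genotype_ids: Iterable[str] = (),
) -> tuple[Alignment, list[tuple[str, str]]]:
    """Filter an alignment down to sequences suitable for tree construction.

    Direct sequences with a pure verdict are kept; hybrid, ambiguous, and
    novel directs are dropped.  Clone/allele sequences explicitly flagged in
    ``unique_genotype_ids`` (they carry a genotype absent from the panel)
    are kept regardless.  Returns the filtered alignment and an exclusion
    log of (id, reason) — nothing is dropped silently.
    """
    by_id = {c.sample_id: c for c in calls}
    unique = set(unique_genotype_ids)
    kept: list[str] = []
    log: list[tuple[str, str]] = []
    for seq in aln:
        if seq.id in unique:
            kept.append(seq.id)
            continue
        if seq.role != "direct":
            log.append((seq.id, f"role={seq.role}, not flagged unique-genotype"))
            continue
        call = by_id.get(seq.id)
        if call is None:
            log.append((seq.id, "no classification available"))
            continue
        if call.verdict == "pure":
            kept.append(seq.id)
        else:
            log.append((seq.id, f"verdict={call.verdict} ({call.hypothesis_label})"))
    return aln.subset(kept), log
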