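"""Additivity classification, peak subtraction, phylogeny selection."""

import itertools

import numpy as np
import pytest

from conftest import make_panel
from ribohybrid.hybrid import (
    PeakIncompatibilityError,
    classify_direct,
    expected_sequence,
    peak_subtract,
    select_for_phylogeny,
)
from ribohybrid.panel import diagnostic_sites
from ribohybrid.seqio import AlignedSeq, Alignment, iupac_merge


class TestExpectedSequence:
    def test_pair_merges_columnwise(self):
        p = make_panel({"a": ("X", "ACGT"), "b": ("X", "ACGA")})
        exp = expected_sequence(p, frozenset({"a", "b"}))
        assert exp.residues == "ACGW" and exp.indel_additive == []

    def test_single_label_is_identity(self):
        p = make_panel({"a": ("X", "ACGT")})
        assert expected_sequence(p, "a").residues == "ACGT"

    def test_one_sided_gap_marked_indel_additive(self):
        p = make_panel({"a": ("X", "AC-T"), "b": ("X", "ACGT")})
        exp = expected_sequence(p, frozenset({"a", "b"}))
        assert exp.indel_additive == [2]
        assert exp.residues[3] == "T"


class TestClassifyDirect:
    def test_constructed_additive_sequence_is_intraspecific_hybrid(self, two_species_panel):
        p = two_species_panel
        exp = expected_sequence(p, frozenset({"X/1", "X/2"}))
        call = classify_direct(AlignedSeq(id="q", residues=exp.residues), p)
        assert call.verdict == "intraspecific_hybrid"
        assert call.hypothesis == frozenset({"X/1", "X/2"})
        assert call.violated_sites == []

    def test_interspecific_pair_detected(self, two_species_panel):
        p = two_species_panel
        exp = expected_sequence(p, frozenset({"X/1", "Y/2"}))
        call = classify_direct(AlignedSeq(id="q", residues=exp.residues), p)
        assert call.verdict == "interspecific_hybrid"
        assert call.hypothesis == frozenset({"X/1", "Y/2"})

    def test_exact_consensus_is_pure(self, two_species_panel):
        p = two_species_panel
        call = classify_direct(AlignedSeq(id="q", residues=p.consensus("Y/1").residues), p)
        assert call.verdict == "pure" and call.hypothesis == "Y/1"

    def test_extra_polymorphism_outside_diagnostic_sites_stays_pure(self, two_species_panel):
        p = two_species_panel
        res = list(p.consensus("X/1").residues)
        assert 4 not in p.diagnostic_columns()
        res[4] = iupac_merge(res[4], "G" if res[4] != "G" else "T")
        call = classify_direct(AlignedSeq(id="q", residues="".join(res)), p)
        assert call.verdict == "pure" and call.hypothesis == "X/1"
        assert call.extra_polymorphic_sites == [4]

    def test_strict_equality_plain_base_fails_diagnostic_site(self, two_species_panel):
        # a pure X/1 read is NOT a hybrid even though its states are subsets
        # of the X/1 x X/2 merged expectation
        p = two_species_panel
        call = classify_direct(AlignedSeq(id="q", residues=p.consensus("X/1").residues), p)
        assert call.verdict == "pure"

    def test_unmatched_sequence_is_novel(self, two_species_panel):
        p = two_species_panel
        call = classify_direct(AlignedSeq(id="q", residues="GGGGGGGGGG"), p)
        assert call.verdict == "novel" and call.hypothesis is None

    def test_pectinata_like_intraspecific_variant_combination(self):
        """A sample merging the two variants of one genotype group resolves
        as an intraspecific hybrid of those variants."""
        p = make_panel(
            {
                "pect/1a": ("pectinata", "ACGTACGTAAGG"),
                "pect/1b": ("pectinata", "ACGTACGTAAGA"),
                "pect/2a": ("pectinata", "TTGAACGGCAGG"),
                "fili/1": ("filiformis", "ACGTTTTTAAGG"),
            }
        )
        exp = expected_sequence(p, frozenset({"pect/1a", "pect/1b"}))
        call = classify_direct(AlignedSeq(id="q", residues=exp.residues), p)
        assert call.verdict == "intraspecific_hybrid"
        assert call.hypothesis == frozenset({"pect/1a", "pect/1b"})

    def test_minor_fraction_below_threshold_demoted_to_major(self, two_species_panel):
        p = two_species_panel
        res = list(p.consensus("X/1").residues)
        col = sorted(p.diagnostic_columns())[0]
        true_base = res[col]
        res[col] = iupac_merge(true_base, "C" if true_base != "C" else "A")
        q = AlignedSeq(
            id="q", residues="".join(res),
            minor_fraction={col: 0.10}, major_base={col: true_base},
        )
        call = classify_direct(q, p, min_minor_fraction=0.30)
        assert call.verdict == "pure" and call.demoted_sites == [col]

    def test_minor_fraction_above_threshold_kept(self, two_species_panel):
        p = two_species_panel
        exp = expected_sequence(p, frozenset({"X/1", "X/2"}))
        cols = [c for c, _, _ in diagnostic_sites(p, "X/1", "X/2").sites]
        q = AlignedSeq(
            id="q", residues=exp.residues,
            minor_fraction={c: 0.45 for c in cols},
            major_base={c: p.consensus("X/1").residues[c] for c in cols},
        )
        call = classify_direct(q, p, min_minor_fraction=0.30)
        assert call.verdict == "intraspecific_hybrid"

    def test_length_mismatch_rejected(self, two_species_panel):
        with pytest.raises(ValueError, match="length"):
            classify_direct(AlignedSeq(id="q", residues="ACG"), two_species_panel)

    def test_invariant_under_label_permutation(self, two_species_panel):
        p = two_species_panel
        renamed = make_panel(
            {
                f"z{9 - i}": (p.species_of(g), p.consensus(g).residues)
                for i, g in enumerate(p.labels)
            }
        )
        exp = expected_sequence(p, frozenset({"X/1", "Y/1"}))
        c1 = classify_direct(AlignedSeq(id="q", residues=exp.residues), p)
        c2 = classify_direct(AlignedSeq(id="q", residues=exp.residues), renamed)
        assert c1.verdict == c2.verdict == "interspecific_hybrid"
        assert {p.consensus(g).residues for g in c1.hypothesis} == {
            renamed.consensus(g).residues for g in c2.hypothesis
        }


def random_panel(rng, n_genotypes, length=60, n_species=2, min_dist=2):
    """Random unambiguous panel with pairwise distance >= min_dist."""
    while True:
        seqs = {}
        base = "".join(rng.choice(list("ACGT"), size=length))
        for i in range(n_genotypes):
            res = list(base)
            cols = rng.choice(length, size=min_dist + int(rng.integers(0, 4)), replace=False)
            for c in cols:
                res[c] = rng.choice([b for b in "ACGT" if b != res[c]])
            seqs[f"g{i}"] = (f"sp{i % n_species}", "".join(res))
        p = make_panel(seqs)
        ok = all(
            len(diagnostic_sites(p, a, b).sites) >= 1
            for a, b in itertools.combinations(p.labels, 2)
        )
        if ok:
            return p


def test_exhaustive_pair_recovery_on_random_panels(rng):
    """Every merged pair of panel consensuses classifies back to exactly that
    unordered pair with zero violated sites (panels up to 8 genotypes)."""
    for n in (2, 3, 5, 8):
        p = random_panel(rng, n)
        for a, b in itertools.combinations(p.labels, 2):
            exp = expected_sequence(p, frozenset({a, b}))
            call = classify_direct(AlignedSeq(id="q", residues=exp.residues), p)
            assert call.hypothesis == frozenset({a, b}), (n, a, b, call.verdict)
            assert call.violated_sites == []


def test_single_sequencing_error_never_creates_hybrid_verdict(rng):
    """With tolerance 0 and >=2 diagnostic sites per pair, one simulated
    error in a pure read yields pure-with-extra-site or novel, never hybrid."""
    p = random_panel(rng, 4, length=80, min_dist=3)
    labels = p.labels
    length = p.alignment_length
    for _ in range(10_000):
        g = labels[rng.integers(len(labels))]
        res = list(p.consensus(g).residues)
        col = int(rng.integers(length))
        res[col] = rng.choice([b for b in "ACGT" if b != res[col]])
        call = classify_direct(AlignedSeq(id="q", residues="".join(res)), p)
        assert call.verdict in ("pure", "novel"), (g, col, call.verdict)


class TestPeakSubtract:
    @pytest.mark.parametrize(
        "query,parent,expected,flagged",
        [
            ("ACGWACGW", "ACGTACGT", "ACGAACGA", []),
            ("ACGT", "ACGT", "ACGT", []),
            ("AVGT", "ACGT", "ARGT", [1]),
        ],
    )
    def test_examples(self, query, parent, expected, flagged):
        result, still_ambiguous = peak_subtract(query, parent)
        assert result == expected and still_ambiguous == flagged

    def test_roundtrip_of_merge(self, two_species_panel):
        p = two_species_panel
        for a, b in itertools.combinations(p.labels, 2):
            exp = expected_sequence(p, frozenset({a, b}))
            ra = p.consensus(a).residues
            rb = p.consensus(b).residues
            inferred, _ = peak_subtract(exp.residues, ra)
            for col, (sa, sb) in enumerate(zip(ra, rb)):
                if sa in "ACGT" and sb in "ACGT":
                    assert inferred[col] == sb

    def test_incompatible_parent_lists_columns(self):
        with pytest.raises(PeakIncompatibilityError) as exc:
            peak_subtract("ACGW", "ACGC")
        assert exc.value.columns == [3]


class TestSelectForPhylogeny:
    def _aln_and_calls(self, two_species_panel):
        p = two_species_panel
        seqs, calls = [], []
        for i, g in enumerate(p.labels):
            s = AlignedSeq(id=f"pure{i}", residues=p.consensus(g).residues)
            seqs.append(s)
            calls.append(classify_direct(s, p))
        exp = expected_sequence(p, frozenset({"X/1", "X/2"}))
        for i in range(3):
            s = AlignedSeq(id=f"hyb{i}", residues=exp.residues)
            seqs.append(s)
            calls.append(classify_direct(s, p))
        return Alignment(seqs), calls, p

    def test_hybrids_dropped_with_log(self, two_species_panel):
        aln, calls, _ = self._aln_and_calls(two_species_panel)
        kept, log = select_for_phylogeny(calls, aln)
        assert len(kept) == 4 and len(log) == 3
        assert all("intraspecific" in reason for _, reason in log)

    def test_all_pure_identity(self, two_species_panel):
        aln, calls, _ = self._aln_and_calls(two_species_panel)
        pure_only = aln.subset([s.id for s in aln if s.id.startswith("pure")])
        kept, log = select_for_phylogeny(calls, pure_only)
        assert kept.ids == pure_only.ids and log == []

    def test_unique_genotype_clone_retained_direct_dropped(self, two_species_panel):
        aln, calls, p = self._aln_and_calls(two_species_panel)
        clone = AlignedSeq(id="hyb0_cloneA", residues=p.consensus("X/2").residues, role="clone")
        aln2 = Alignment(list(aln) + [clone])
        kept, log = select_for_phylogeny(calls, aln2, unique_genotype_ids={"hyb0_cloneA"})
        assert "hyb0_cloneA" in kept.ids and "hyb0" not in kept.ids
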