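# Methods

## The diagnostic model

Multicopy nuclear ribosomal markers (ITS, 5S-NTS) usually homogenize within
a species through concerted evolution, but hybrids — including the
hexaploid aquatic plants this package was designed around — retain the
ribotypes of both parents. The direct (uncloned) Sanger read of a hybrid is
then the superposition of the two copies: at each column where the parental
ribotypes differ, the electropherogram shows two peaks, called as the IUPAC
code for the union of the parental bases. Writing `set(x)` for the bases an
IUPAC symbol denotes, the predicted direct read of a hybrid between
genotypes *p* and *q* is, column-wise, the symbol encoding
`set(p_i) ∪ set(q_i)`. Classification inverts this model: a read is
compared, by strict set equality at diagnostic columns, to the prediction
of every single-genotype and every unordered-pair hypothesis over a
reference panel.

Key consequences of the model:

* **Strict equality, not containment.** At a column where the parents carry
  A and T the hybrid must show W; a plain A *fails* that site. Containment
  matching would let every pure genotype "explain" any pair that includes
  it. Partial peaks below detection are handled by the integer `tolerance`
  (number of violated diagnostic sites allowed; default 0), never by
  relaxing the match.
* **Parsimony preference.** A pure hypothesis within tolerance always beats
  a pair: a pure genotype trivially matches the merge of itself with
  itself, so pairs of identical members are excluded a priori and pairs are
  only accepted when no single genotype suffices.
* **Non-diagnostic ambiguities never penalize.** Intra-individual
  polymorphisms at columns that separate no pair of panel genotypes are
  reported (`extra_polymorphic_sites`) but do not change the verdict —
  sequences "with further polymorphisms but otherwise identical to a
  genotype" stay pure.
* **Gap additivity is not expressible in IUPAC.** Columns where one parent
  is gapped are excluded from base matching and reported as
  indel-polymorphic; the IUPAC algebra itself refuses gap operands.

Two-copy-class resolution is assumed throughout: even in high polyploids,
direct reads resolve at most two superimposed states per column, so
hypotheses are single genotypes or unordered pairs, never triples.

## Scoring scope

Hypotheses are scored over the union of diagnostic columns of the panel
(columns where at least two genotype consensuses carry different
unambiguous non-gap states). This gives pure and pair hypotheses a common,
pre-computable column set; columns where the query or the expectation is N
are skipped as missing data. Ties among equally good hypotheses yield an
explicit `ambiguous` verdict listing all tied hypotheses — with unambiguous
panel consensuses a merged pair read identifies its pair uniquely (two
unions `{p}∪{q}` and `{p}∪{r}` with `q ≠ r` can only be equal if all three
states coincide), so ties arise only from degenerate panels.

## Minor-signal demotion

Small secondary peaks (background noise, low-copy variants) are not
additivity. When per-site minor-signal fractions are supplied, ambiguities
whose minor peak is below `min_minor_fraction` (default 0.30, following the
practice of ignoring secondary 5S-NTS peaks below about 30% of total
signal) are demoted to the major base before classification. Demotion needs
to know which base is the major one; the fraction alone does not say. The
minor-fraction table therefore accepts an optional `major_base` column, and
sites below threshold without a recorded major base are left untouched with
a warning rather than guessed.

## Clone screening

Cloning separates the superimposed copies but introduces artifacts with
known signatures:

* **Polymerase errors** are unique substitutions in single clones that do
  not correspond to polymorphisms in the direct sequence. A clone state is
  corrected to the direct base exactly when no other clone shares it at
  that column and the direct read is unambiguous there. Columns where the
  direct read shows an ambiguity are never touched, so true polymorphism
  cannot be erased; fewer than two clones make uniqueness undecidable and
  correction is skipped with a warning.
* **PCR chimeras** switch template once, producing a clone that follows one
  parent up to a breakpoint and the other after it. Each clone is reduced
  to its state string over the informative columns (unambiguous differences
  between the parental copies) and segmented: the smallest set of positions
  (always whole runs shorter than `min_block`) is removed such that every
  remaining same-parent block has at least `min_block` informative sites,
  ties resolved toward the lexicographically smallest removal set. Removed
  positions are *suspect sites* (more parsimoniously polymerase errors than
  crossovers); transitions between the remaining blocks are breakpoints,
  and any breakpoint makes the clone a dismissed recombinant. `min_block`
  defaults to 2 — a single discordant informative site is an error, not a
  crossover — and is configurable.

Representatives are chosen per copy class: one clone if the class is
homogeneous, one per variant (max two, most frequent first) if the parent
is polymorphic; recombinants are never eligible. If one class contains only
recombinants, the missing copy is inferred by peak subtraction from the
direct read and the recovered parent, tagged inferred. A de novo mode
(complete-linkage clustering of clones at distance ≤ 1, two largest
clusters as putative parents) makes the module usable without references.

## Maternal assignment

Assuming maternal plastid inheritance, a hybrid carries exactly one
parent's haplotype. The hybrid's plastid sequence is compared to every
haplotype of its two nuclear-determined parent species (an open-panel mode
scans all species for the unknown-parent case, reporting novel haplotypes
without species attribution rather than guessing). Distance is substitution
count plus one event per contiguous gap-run difference — a spacer indel is
a single mutation whatever its length (configurable). The rule is
deterministic: distance 0 to one species assigns; distance 0 to a haplotype
shared by both species is `equivocal` (rendered as the asterisk convention
in figure-style output); minimum distance ≥ 1 is `novel_haplotype` with the
nearest haplotype(s) recorded as `derived_from`. Across markers, any
assigned call wins, two conflicting assigned calls surface as an explicit
`conflict` state, and a novel haplotype derivable from only one species
resolves the sample by derivation. Independent origins per hybrid type are
lower-bounded by the number of distinct (maternal species, haplotype)
tuples; a reciprocal cross is flagged when both parents occur as mothers.

## Indel coding

Simple indel coding: every distinct maximal internal gap run (same start
and end) is one character; per sequence the symbol is C (has exactly that
run), N (own run strictly contains it, or the range lies in the sequence's
missing data), else A. Leading and trailing gap runs are ragged Sanger ends
— missing data, not indel events: they produce no characters and code N for
ranges they cover. Partially overlapping gaps with different coordinates
are independent characters scoring A for each other (this is what makes the
method "simple"). Coded characters are appended to the residue matrix,
markers can be concatenated with N-fill for missing amplicons, and the
result exports as a NEXUS DATA block with charsets per partition; tree
search itself is deliberately out of scope and delegated to external
phylogenetics software.

## The synthetic generator

`simulate_panel` evolves a root sequence into species consensuses and
genotypes along a configurable topology, drawing substitution columns
without replacement from a shared pool, so configured pairwise distances
hold *exactly* — the calibration topology `stuckenia_like_topology()`
encodes the published intraspecific structure (two major genotypes six
substitutions apart in the most widespread species, with one-substitution
subtypes; one substitution and two substitutions in the other two variable
species). Substitutions are confined to the first half of each marker and
single gap runs (length 1–6, probability `indel_prob` = 0.3) to the second
half, so indels never erase diagnostic sites. Base changes are uniform over
the three alternatives (Jukes–Cantor-like); no rate heterogeneity is
modeled because classification uses site patterns, not branch lengths.

Defaults model the study conditions: four species, 2–3 genotypes for the
variable ones, four substitutions between genotypes (≥ 3 diagnostic sites
per pair), marker lengths of 600/800/850 columns, clone sets of at least
five drawn until both copy types are seen (cap 20), per-base polymerase
error 0.002, chimera rate 0.1, and a 200-sample collection mixed
0.55/0.15/0.30 pure/intraspecific/interspecific — hybrids constitute just
under half of samples, matching a collection enriched for suspected
hybrids. Plastid panels give each species one main haplotype (plus a
derived one for variable species); `shared_plastid` forces species pairs to
share their main haplotype to exercise the equivocal path.

Simulated chimeras place their breakpoint between informative sites with at
least `min_block` informative sites on each side. A template switch outside
the informative span is molecularly real but observationally identical to a
parental clone — no method could, even in principle, detect it from the
sequence — so the generator emulates the detectable events the screening
rule is meant to dismiss.

What the generator does **not** emulate: electropherogram noise and base
calling, alignment error (inputs are pre-aligned by construction),
within-copy-class ribotype polymorphism beyond the genotype structure,
concerted-evolution gradients, and coalescent population structure. Passing
recovery tests therefore demonstrates correctness of the inference rules
under the stated model, not robustness to misalignment or base-calling
artifacts.

## Numerical and design choices

* Coordinates are 0-based half-open internally; all reports and CLI output
  are 1-based inclusive.
* U and lowercase are normalized on ingest; any symbol outside the
  16-letter IUPAC+gap alphabet is a parse error naming record and column.
* Consensus building uses column-wise majority over unambiguous states;
  ties are stored as the IUPAC merge of the tied states and flagged, rather
  than forcing a call.
* Within a species, genotypes with identical consensuses (over mutually
  informative columns) merge under the lexicographically first label with
  an alias note. Across species, identical consensuses are *kept* and
  flagged: shared plastid haplotypes between close species are real and are
  precisely what makes maternal calls equivocal.
* Ambiguity overlap counts as zero distance in `pairwise_substitutions`
  (conservative: an R-carrying read is compatible with both an A- and a
  G-genotype), and indel differences are reported separately.
* The pipeline is a pure function of (inputs, config, seed); every stage
  writes artifacts plus a manifest of thresholds and SHA-256 checksums, and
  every excluded sequence appears in an exclusion log with a reason.

## Problem sizes

The test suite and the acceptance script run the discrete core exhaustively
(full 15×15 IUPAC table; all two-letter state strings to length 12 and
three-letter strings to length 8 against a brute-force segmentation oracle;
500 random gapped alignments against a brute-force coding oracle), the
default 200-sample collection for class and maternal recovery, 1,000
ten-clone sets for chimera recall/precision, and 10⁴ single-error trials
for the no-false-hybrid property. These sizes give exact checks where the
rule is discrete and two-digit-stable rates where it is statistical.

## Known limitations

* Hybrids between a panel genotype and an unsampled genotype classify as
  `novel`; the package reports nearest hypotheses but does not invent
  parents.
* Chimeras switching outside the informative span are undetectable in
  principle (see above).
* Peak subtraction cannot recover gap states: indel-polymorphic columns of
  an inferred copy remain flagged.
* Maternal assignment assumes strict maternal plastid inheritance and no
  plastid recombination; the assumption itself is not tested.
* Alignment construction is out of scope: all inputs must be pre-aligned,
  equal-length per marker.
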