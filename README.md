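# ribohybrid

Hybrid diagnosis for plant groups with multicopy nuclear markers.

In many plant genera — aquatic groups such as the pondweeds are a textbook
case — hybrids retain the ribosomal DNA copies of **both** parents. A direct
Sanger read of a hybrid's ITS or 5S-NTS amplicon is therefore a superposition
of the two parental ribotypes: at every alignment column where the parents
differ, the read shows the IUPAC ambiguity code for the union of their bases
(*character additivity*: parents A and T ⇒ the hybrid shows W). `ribohybrid`
turns that signal into a tested, reusable workflow:

* **Panel building** — per-marker consensus ribotypes/haplotypes for each
  species/genotype label, with diagnostic-site enumeration, within-genotype
  conflict warnings, and deduplication of identical sequences
  ("exclude and map afterwards").
* **Additivity classification** — every direct sequence is scored against
  all single-genotype and all unordered-pair hypotheses; verdicts are
  `pure`, `intraspecific_hybrid`, `interspecific_hybrid`, `novel`, or
  `ambiguous`, with per-site evidence. Matching at diagnostic sites is
  strict set equality (`W` required where parents are A/T); weak secondary
  peaks can be demoted by a configurable minor-signal threshold
  (default 0.30).
* **Peak subtraction** — given one known parental copy, the second copy is
  inferred by removing the parent's base from each ambiguous position.
* **Clone analysis** — polymerase errors (unique substitutions in single
  clones absent from the direct read) are corrected; PCR chimeras are
  detected by minimal segmentation of the informative-site state string and
  dismissed; one representative clone per parental copy class is chosen
  (two if a parent is polymorphic); a copy class represented only by
  recombinants is inferred by peak subtraction.
* **Maternal assignment** — plastid DNA is maternally inherited, so a
  hybrid's plastid haplotype identifies its mother among the two
  nuclear-determined parents. Shared haplotypes produce an explicit
  `equivocal` call; unmatched haplotypes are reported as novel with their
  nearest neighbour; calls are combined across plastid markers, and
  independent hybrid origins and reciprocal crosses are counted from
  distinct (maternal species, haplotype) combinations.
* **Indel coding and export** — each distinct alignment gap becomes one
  presence/absence character (simple coding, symbols A/C/N, strict
  containment ⇒ N), markers are concatenated with N-fill for failed
  amplifications, and matrices are exported as NEXUS for external tree
  software.
* **Synthetic data** — a generator that emulates the whole data structure
  (geographically structured genotypes a configurable number of
  substitutions apart, additive direct reads, noisy/chimeric clone sets,
  maternally inherited plastids) with exact-by-construction distances and
  full ground truth.

## Worked example

```python
from ribohybrid import assign_maternal, classify_direct, peak_subtract
from ribohybrid.hybrid import expected_sequence
from ribohybrid.seqio import AlignedSeq
from ribohybrid.simulate import SimConfig, simulate_panel, stuckenia_like_topology

cfg = SimConfig(seed=42, genotype_topology=stuckenia_like_topology())
panels = simulate_panel(cfg)
nuc = panels["ITS"]

# a direct read that superimposes one ribotype of each parent species
exp = expected_sequence(nuc, frozenset({"filiformis/1", "vaginata/2a"}))
query = AlignedSeq(id="sample_0042", residues=exp.residues, marker="ITS")

call = classify_direct(query, nuc)
print(f"{call.sample_id}: {call.verdict} ({call.hypothesis_label})")
print(f"explained diagnostic sites: {len(call.explained_sites)}, "
      f"violated: {len(call.violated_sites)}")

pl = panels["rpl20-rps12"]
hyb = AlignedSeq(id="sample_0042",
                 residues=pl.consensus("vaginata/h1").residues,
                 marker="rpl20-rps12")
m = assign_maternal(hyb, pl, ("filiformis", "vaginata"))
print(f"maternal parent: {m.maternal} (call={m.call}, "
      f"matched {m.matched_haplotype}, d={m.distance})")
```

prints

```
sample_0042: interspecific_hybrid (filiformis/1 x vaginata/2a)
explained diagnostic sites: 35, violated: 0
maternal parent: vaginata (call=assigned, matched vaginata/h1, d=0)
```

The read is recognized as an interspecific hybrid of exactly the two
ribotypes it was built from — all 35 columns separating any two panel
genotypes carry the predicted state, none contradicts it — and the plastid
sequence assigns *vaginata* as the mother (distance 0 to its haplotype,
≥1 substitution from every *filiformis* haplotype). `peak_subtract(query,
nuc.consensus("filiformis/1"))` reconstructs the *vaginata* copy at every
substitution column; columns where the parents differ by an indel are not
expressible in a single IUPAC read and stay flagged.

A `ribohybrid` console script exposes the same steps
(`simulate`, `panel`, `classify`, `clones`, `maternal`, `indelcode`, `run`);
`ribohybrid run --config run.yaml` executes the full pipeline and writes
TSV/FASTA/NEXUS artifacts plus a manifest with checksums.

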