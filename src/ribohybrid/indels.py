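"""Simple indel coding and export of analysis-ready matrices.

Alignment gaps carry phylogenetic signal but are ignored by standard DNA
substitution models, so each distinct gap (identical start and end across
sequences) is appended as one presence/absence character: C when the
sequence has exactly that gap, A when it does not, N when its own longer
gap strictly contains the range or the range falls in leading/trailing
missing data.  This is the "simple" coding method; partially overlapping
gaps with different coordinates are independent characters (each scores A
for the other).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from ribohybrid.seqio import AlignedSeq, Alignment

__all__ = [
    "IndelCharacterMatrix",
    "simple_indel_code",
    "concatenate_with_indels",
    "concatenate_markers",
    "export_nexus",
]


@dataclass
class IndelCharacterMatrix:
    """Coded indel characters for one alignment.

    ``gap_ranges`` are 0-based half-open column ranges sorted by
    (start, end); ``codes`` maps sequence id to a string over {A, C, N} of
    length ``len(gap_ranges)``; ``provenance`` records which sequences
    exhibit each range.
    """

    gap_ranges: list[tuple[int, int]]
    codes: dict[str, str]
    provenance: dict[tuple[int, int], list[str]] = field(default_factory=dict)

    @property
    def n_characters(self) -> int:
        return len(self.gap_ranges)


def _gap_runs(residues: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' as half-open (start, end) ranges."""
    runs = []
    start = None
    for i, sym in enumerate(residues):
        if sym == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(residues)))
    return runs


def _missing_mask(residues: str) -> list[bool]:
    """True at positions that are missing data: N anywhere, or terminal gap runs.

    Leading/trailing gap runs in Sanger reads are ragged ends, not indel
    events.
    """
    n = len(residues)
    mask = [sym == "N" for sym in residues]
    i = 0
    while i < n and residues[i] == "-":
        mask[i] = True
        i += 1
    j = n
    while j > 0 and residues[j - 1] == "-":
        mask[j - 1] = True
        j -= 1
    return mask


def simple_indel_code(aln: Alignment) -> IndelCharacterMatrix:
    """Code each distinct internal gap range as one A/C/N character.

    Per sequence and range r: C if the sequence has a gap run exactly
    spanning r; N if one of its gap runs strictly contains r or r lies
    wholly in the sequence's missing data; A otherwise.
    """
    internal_runs: dict[str, set[tuple[int, int]]] = {}
    all_runs: dict[str, list[tuple[int, int]]] = {}
    for seq in aln:
        runs = _gap_runs(seq.residues)
        all_runs[seq.id] = runs
        n = len(seq.residues)
        internal_runs[seq.id] = {
            (s, e) for s, e in runs if s > 0 and e < n
        }

    ranges = sorted({r for runs in internal_runs.values() for r in runs})
    provenance = {
        r: [seq.id for seq in aln if r in internal_runs[seq.id]] for r in ranges
    }

    codes: dict[str, str] = {}
    for seq in aln:
        mask = _missing_mask(seq.residues)
        symbols = []
        for r in ranges:
            s, e = r
            if r in internal_runs[seq.id]:
                symbols.append("C")
            elif any(
                rs <= s and e <= re and (rs, re) != r for rs, re in all_runs[seq.id]
            ) or all(mask[c] for c in range(s, e)):
                symbols.append("N")
            else:
                symbols.append("A")
        codes[seq.id] = "".join(symbols)

    return IndelCharacterMatrix(gap_ranges=ranges, codes=codes, provenance=provenance)


def concatenate_with_indels(aln: Alignment, m: IndelCharacterMatrix) -> Alignment:
    """Append each sequence's indel code string to its residues."""
    missing = set(aln.ids) ^ set(m.codes)
    if missing and m.gap_ranges:
        raise ValueError(f"sequence ids do not match indel matrix: {sorted(missing)}")
    seqs = [
        AlignedSeq(
            id=s.id,
            residues=s.residues + m.codes.get(s.id, ""),
            species=s.species,
            genotype=s.genotype,
            marker=s.marker,
            role=s.role,
        )
        for s in aln
    ]
    return Alignment(seqs, marker=aln.marker)


def concatenate_markers(
    alns: Sequence[Alignment], missing_fill: str = "N"
) -> tuple[Alignment, list[tuple[str, int, int]]]:
    """Join per-marker alignments by sample id, in the declared order.

    A sample absent from a marker receives a run of ``missing_fill`` of
    that marker's length (the way a failed amplification is represented in
    a combined matrix).  Returns the combined alignment and partition
    boundaries as (marker, start, end) half-open ranges.
    """
    if not alns:
        raise ValueError("empty marker list")
    order: list[str] = []
    seen = set()
    for aln in alns:
        for sid in aln.ids:
            if sid not in seen:
                seen.add(sid)
                order.append(sid)

    partitions: list[tuple[str, int, int]] = []
    offset = 0
    pieces: dict[str, list[str]] = {sid: [] for sid in order}
    for aln in alns:
        for sid in order:
            if sid in aln:
                pieces[sid].append(aln[sid].residues)
            else:
                pieces[sid].append(missing_fill * aln.length)
        partitions.append((aln.marker, offset, offset + aln.length))
        offset += aln.length

    template = {sid: next((a[sid] for a in alns if sid in a)) for sid in order}
    seqs = [
        AlignedSeq(
            id=sid,
            residues="".join(pieces[sid]),
            species=template[sid].species,
            genotype=template[sid].genotype,
            marker="other",
            role=template[sid].role,
        )
        for sid in order
    ]
    return Alignment(seqs, marker="other"), partitions


def _nexus_label(seq_id: str) -> str:
    if any(ch in seq_id for ch in " \t()[]{}/\\,;:=*'\"`<>"):
        return "'" + seq_id.replace("'", "''") + "'"
    return seq_id


def export_nexus(
    aln: Alignment,
    path: str | Path,
    partitions: Sequence[tuple[str, int, int]] | None = None,
) -> None:
    """Write a NEXUS DATA block (datatype=DNA, gap=-, missing=N).

    ``partitions`` are (name, start, end) half-open column ranges written
    as a SETS block with 1-based inclusive charsets, e.g. the residue part
    and the trailing coded-indel block of a concatenated matrix.
    """
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"    DIMENSIONS NTAX={len(aln)} NCHAR={aln.length};",
        "    FORMAT DATATYPE=DNA GAP=- MISSING=N;",
        "    MATRIX",
    ]
    width = max((len(_nexus_label(s.id)) for s in aln), default=0)
    for s in aln:
        lines.append(f"        {_nexus_label(s.id):<{width}}  {s.residues}")
    lines += ["    ;", "END;"]
    if partitions:
        lines.append("BEGIN SETS;")
        for name, start, end in partitions:
            safe = name.replace(" ", "_").replace("-", "_")
            lines.append(f"    CHARSET {safe} = {start + 1}-{end};")
        lines.append("END;")
    Path(path).write_text("\n".join(lines) + "\n")
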