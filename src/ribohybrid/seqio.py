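"""Sequence containers, FASTA/TSV I/O, and the IUPAC ambiguity algebra.

Every downstream operation — additivity detection, peak subtraction,
diagnostic-site enumeration — reduces to set algebra over the bases encoded
by IUPAC nucleotide symbols.  This module owns that algebra:

* ``iupac_set``      symbol -> set of bases ({} for the gap symbol)
* ``iupac_merge``    union (the additive state a hybrid shows)
* ``iupac_subtract`` set difference (peak subtraction)

Coordinates are 0-based half-open internally; report/CLI layers convert to
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "MARKERS",
    "ROLES",
    "AlignedSeq",
    "Alignment",
    "TrimResult",
    "AlignmentLengthError",
    "SequenceParseError",
    "iupac_set",
    "iupac_merge",
    "iupac_subtract",
    "is_ambiguous",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "read_minor_fractions",
    "trim_uninformative_ends",
]

MARKERS = ("ITS", "5S-NTS", "rpl20-rps12", "trnT-trnL", "other")
ROLES = ("direct", "clone", "consensus")

#: IUPAC nucleotide symbol -> bases it denotes.  "-" (gap) denotes no base;
#: N is full ambiguity.  U is normalized to T on ingest, lowercase is raised.
_CODE_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "-": frozenset(),
}

_BASES_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in _CODE_TO_BASES.items()}

VALID_SYMBOLS = frozenset(_CODE_TO_BASES)


class SequenceParseError(ValueError):
    """An input record contains a symbol outside the IUPAC+gap alphabet."""


class AlignmentLengthError(ValueError):
    """Sequences grouped into one alignment have unequal lengths."""


def iupac_set(code: str) -> frozenset[str]:
    """Return the set of bases denoted by an IUPAC symbol.

    The gap symbol ``-`` returns the empty set; ``N`` returns {A,C,G,T}.
    """
    try:
        return _CODE_TO_BASES[code]
    except KeyError:
        raise ValueError(f"unknown IUPAC symbol: {code!r}") from None


def iupac_merge(a: str, b: str) -> str:
    """Symbol whose base set is the union of the operands' base sets.

    This is the additive state a direct sequence shows where two parental
    copies differ.  Gap operands are refused: base-versus-gap additivity is
    not expressible in IUPAC and is handled by callers as an
    indel-polymorphic site.
    """
    if a == "-" or b == "-":
        raise ValueError("cannot merge a gap; handle indel additivity at the caller")
    return _BASES_TO_CODE[iupac_set(a) | iupac_set(b)]

def iupac_subtract(code: str, base_sym: str) -> str:
    """Peak subtraction: remove one parent's bases from an observed state.

    Returns the symbol for ``iupac_set(code) - iupac_set(base_sym)``.  If the
    difference is empty the two copies agree there and ``base_sym`` itself is
    returned.  Raises if ``base_sym`` is not contained in ``code``.
    """
    big, small = iupac_set(code), iupac_set(base_sym)
    if not small <= big:
        raise ValueError(
            f"cannot subtract {base_sym!r} from {code!r}: base set not contained"
        )
    diff = big - small
    return base_sym if not diff else _BASES_TO_CODE[diff]


def is_ambiguous(code: str) -> bool:
    """True for symbols denoting more than one base (includes N)."""
    return len(iupac_set(code)) > 1


def _normalize_residues(raw: str, record_id: str = "?") -> str:
    """Uppercase, map U->T, and validate against the 16-symbol alphabet."""
    out = raw.upper().replace("U", "T")
    for col, sym in enumerate(out):
        if sym not in VALID_SYMBOLS:
            raise SequenceParseError(
                f"record {record_id!r}: illegal symbol {sym!r} at column {col + 1}"
            )
    return out


@dataclass
class AlignedSeq:
    """One marker sequence over the IUPAC+gap alphabet with metadata.

    ``minor_fraction`` optionally records, per 0-based position holding an
    ambiguity, the fraction of total electropherogram signal contributed by
    the minor peak; ``major_base`` records the taller peak's base where
    known (needed to demote weak ambiguities before classification).
    """

    id: str
    residues: str
    species: str = "unknown"
    genotype: str | None = None
    marker: str = "other"
    role: str = "direct"
    minor_fraction: dict[int, float] | None = None
    major_base: dict[int, str] | None = None

    def __post_init__(self) -> None:
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}; expected one of {MARKERS}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TrimResult:
    """Trimmed alignment plus the mapping back to original coordinates."""

    alignment: "Alignment"
    offset: int  # original column = trimmed column + offset
    removed_leading: int
    removed_trailing: int


class Alignment:
    """Ordered collection of equal-length AlignedSeq sharing one marker."""

    def __init__(self, seqs: Iterable[AlignedSeq], marker: str | None = None):
        self.seqs: list[AlignedSeq] = list(seqs)
        if marker is None:
            marker = self.seqs[0].marker if self.seqs else "other"
        if marker not in MARKERS:
            raise ValueError(f"unknown marker {marker!r}")
        self.marker = marker
        lengths = {len(s.residues) for s in self.seqs}
        if len(lengths) > 1:
            raise AlignmentLengthError(
                f"unequal sequence lengths in alignment: {sorted(lengths)}"
            )
        ids = [s.id for s in self.seqs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids in alignment: {dupes}")
        self._by_id = {s.id: s for s in self.seqs}

    @property
    def length(self) -> int:
        return len(self.seqs[0].residues) if self.seqs else 0

    def __len__(self) -> int:
        return len(self.seqs)

    def __iter__(self) -> Iterator[AlignedSeq]:
        return iter(self.seqs)

    def __getitem__(self, seq_id: str) -> AlignedSeq:
        return self._by_id[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.seqs]

    def column(self, col: int) -> list[str]:
        return [s.residues[col] for s in self.seqs]

    def subset(self, keep_ids: Iterable[str]) -> "Alignment":
        keep = set(keep_ids)
        return Alignment([s for s in self.seqs if s.id in keep], marker=self.marker)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample metadata TSV (sample_id, species, genotype, marker, role)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "species"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata TSV missing columns: {sorted(missing)}")
    return df


def read_minor_fractions(
    path: str | Path,
) -> dict[str, tuple[dict[int, float], dict[int, str]]]:
    """Read the per-site minor-signal TSV.

    Columns: sample_id, position (1-based), fraction, optionally major_base.
    Returns per sample a pair (position->fraction, position->major base),
    positions converted to 0-based.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    out: dict[str, tuple[dict[int, float], dict[int, str]]] = {}
    has_major = "major_base" in df.columns
    for sid, grp in df.groupby("sample_id"):
        fracs = {int(p) - 1: float(f) for p, f in zip(grp["position"], grp["fraction"])}
        majors: dict[int, str] = {}
        if has_major:
            for p, m in zip(grp["position"], grp["major_base"]):
                if isinstance(m, str) and m.strip():
                    majors[int(p) - 1] = m.strip().upper()
        out[str(sid)] = (fracs, majors)
    return out


def read_fasta(
    path: str | Path,
    marker: str = "other",
    metadata: pd.DataFrame | Mapping[str, Mapping[str, str]] | None = None,
) -> Alignment:
    """Read a pre-aligned multi-FASTA into an Alignment.

    Residues are uppercased and U is mapped to T; any symbol outside the
    IUPAC+gap alphabet raises :class:`SequenceParseError` naming the record
    and 1-based column.  If ``metadata`` is given, species/genotype/role are
    attached per record id.
    """
    meta_by_id: dict[str, dict[str, str]] = {}
    if metadata is not None:
        if isinstance(metadata, pd.DataFrame):
            for _, row in metadata.iterrows():
                meta_by_id[str(row["sample_id"])] = {
                    k: str(row[k]) for k in metadata.columns if k != "sample_id"
                }
        else:
            meta_by_id = {k: dict(v) for k, v in metadata.items()}

    seqs: list[AlignedSeq] = []
    for record in SeqIO.parse(str(path), "fasta"):
        residues = _normalize_residues(str(record.seq), record.id)
        meta = meta_by_id.get(record.id, {})
        if metadata is not None and record.id not in meta_by_id:
            raise ValueError(f"FASTA id {record.id!r} absent from metadata table")
        seqs.append(
            AlignedSeq(
                id=record.id,
                residues=residues,
                species=meta.get("species") or "unknown",
                genotype=meta.get("genotype") or None,
                marker=marker,
                role=meta.get("role") or "direct",
            )
        )
    return Alignment(seqs, marker=marker)


def write_fasta(aln: Alignment, path: str | Path, width: int = 70) -> None:
    """Write an Alignment as FASTA; residues (gaps included) verbatim."""
    with open(path, "w") as fh:
        for s in aln:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def trim_uninformative_ends(aln: Alignment, max_missing_frac: float) -> TrimResult:
    """Drop leading/trailing columns dominated by missing data (N or gap).

    Terminal columns whose fraction of N/gap states exceeds
    ``max_missing_frac`` are removed; internal columns are never touched.
    Direct Sanger reads have ragged ends (N-padded or truncated); trimming
    them prevents spurious haplotype variation.
    """
    if not 0 <= max_missing_frac <= 1:
        raise ValueError("max_missing_frac must be in [0, 1]")
    n = len(aln)
    if n == 0 or aln.length == 0:
        return TrimResult(aln, 0, 0, 0)

    def missing_frac(col: int) -> float:
        return sum(1 for sym in aln.column(col) if sym in "N-") / n

    start = 0
    while start < aln.length and missing_frac(start) > max_missing_frac:
        start += 1
    end = aln.length
    while end > start and missing_frac(end - 1) > max_missing_frac:
        end -= 1

    trimmed = Alignment(
        [replace(s, residues=s.residues[start:end]) for s in aln],
        marker=aln.marker,
    )
    return TrimResult(trimmed, start, start, aln.length - end)
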