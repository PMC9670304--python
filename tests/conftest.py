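import numpy as np
import pytest

from ribohybrid.panel import GenotypePanel
from ribohybrid.seqio import AlignedSeq


def make_panel(genotypes: dict[str, tuple[str, str]], marker: str = "ITS") -> GenotypePanel:
    """Panel directly from {label: (species, residues)} without consensus building."""
    entries = {}
    species_index: dict[str, set[str]] = {}
    length = None
    for label, (species, residues) in genotypes.items():
        entries[label] = AlignedSeq(
            id=label, residues=residues, species=species, genotype=label,
            marker=marker, role="consensus",
        )
        species_index.setdefault(species, set()).add(label)
        length = len(residues)
    return GenotypePanel(
        marker=marker, entries=entries, species_index=species_index,
        alignment_length=length or 0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_species_panel():
    """Two species, two genotypes each, >=2 diagnostic sites per pair."""
    return make_panel(
        {
            "X/1": ("X", "ACGTACGTAC"),
            "X/2": ("X", "ACGTACTAAC"),   # differs from X/1 at cols 6,7
            "Y/1": ("Y", "TGGTACGTCC"),   # differs from X/1 at cols 0,1,8
            "Y/2": ("Y", "TGGTACGTGG"),   # differs from Y/1 at cols 8,9
        }
    )
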