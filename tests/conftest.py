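import pytest

from cehtools.model import (
    Haplotype,
    HaplotypeSource,
    Marker,
    MarkerKind,
    MarkerMap,
)


def make_map(positions, kinds=None, amplicons=None, subregions=None):
    n = len(positions)
    kinds = kinds or [MarkerKind.SNP] * n
    amplicons = amplicons or ["A1"] * n
    subregions = subregions or [None] * n
    return MarkerMap(
        [
            Marker(
                marker_id=f"m{i + 1}",
                position_bp=positions[i],
                kind=kinds[i],
                amplicon_id=amplicons[i],
                subregion_id=subregions[i],
            )
            for i in range(n)
        ]
    )


def hap(hid, alleles, group=None, source=HaplotypeSource.SYNTHETIC_TRUTH):
    return Haplotype(hid, list(alleles), source, group)


@pytest.fixture
def six_marker_map():
    return make_map([100, 200, 300, 400, 500, 600])


@pytest.fixture
def four_hap_group(six_marker_map):
    """Two faithful copies, one crossover at the 4th marker, one isolated
    mismatch at the 5th; dominant sequence ACGTAC."""
    h1 = hap("h1", "ACGTAC", group="G")
    h2 = hap("h2", "ACGTAC", group="G")
    h3 = hap("h3", "ACGATG", group="G")  # crossover from marker 4 on
    h4 = hap("h4", "ACGTGC", group="G")  # isolated mismatch at marker 5
    return [h1, h2, h3, h4]
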