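"""Reference genome descriptions: chromosome indexes and subgenome partitions.

The hexaploid *Camelina sativa* reference comprises 20 chromosomes
partitioned into three ancestral subgenomes (6 + 7 + 7).  The refined
partition used throughout this package assigns SG1 to the chromosome set
shared with the diploid *C. neglecta*, SG2 to the additional set shared
with the tetraploid *C. microcarpa*, and SG3 to the remainder (shared
with *C. hispida*).
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Dict, Iterable, Mapping

SG1 = "SG1"
SG2 = "SG2"
SG3 = "SG3"
UNPLACED = "UNPLACED"

SUBGENOMES = (SG1, SG2, SG3)

#: Refined chromosome -> subgenome assignment for the C. sativa reference.
CAMELINA_SUBGENOME_ASSIGNMENT: Dict[str, str] = {
    **{c: SG1 for c in ("Csa14", "Csa07", "Csa19", "Csa04", "Csa08", "Csa11")},
    **{c: SG2 for c in ("Csa03", "Csa16", "Csa01", "Csa06", "Csa13", "Csa10", "Csa18")},
    **{c: SG3 for c in ("Csa17", "Csa05", "Csa15", "Csa09", "Csa20", "Csa02", "Csa12")},
}

CAMELINA_CHROMOSOMES = tuple(f"Csa{i:02d}" for i in range(1, 21))


def scaled_reference_index(
    chrom_length: int = 2_000_000,
    fusion_chrom: str = "Csa11",
    fusion_length: int = 3_000_000,
) -> "OrderedDict[str, int]":
    """A scaled-down 20-chromosome index for simulation and testing.

    Chromosomes are uniform 2 Mb except one longer "fusion-like"
    chromosome (default Csa11, mirroring its status as the largest
    chromosome of the real karyotype), which exercises length
    normalization downstream.
    """
    idx: "OrderedDict[str, int]" = OrderedDict()
    for chrom in CAMELINA_CHROMOSOMES:
        idx[chrom] = fusion_length if chrom == fusion_chrom else chrom_length
    return idx


def subgenome_lengths(
    index: Mapping[str, int], assignment: Mapping[str, str]
) -> Dict[str, int]:
    """Total bp per subgenome label under ``assignment``."""
    out: Dict[str, int] = {}
    for chrom, length in index.items():
        label = assignment.get(chrom, UNPLACED)
        out[label] = out.get(label, 0) + length
    return out


def chromosomes_of(assignment: Mapping[str, str], label: str) -> list:
    return sorted(c for c, s in assignment.items() if s == label)


def validate_partition(assignment: Mapping[str, str], chromosomes: Iterable[str]) -> None:
    """Every reference chromosome must carry exactly one subgenome label."""
    missing = [c for c in chromosomes if c not in assignment]
    if missing:
        raise ValueError(f"chromosomes without subgenome assignment: {missing}")
    bad = {c: s for c, s in assignment.items() if s not in (*SUBGENOMES, UNPLACED)}
    if bad:
        raise ValueError(f"invalid subgenome labels: {bad}")
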