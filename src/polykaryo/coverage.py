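"""Karyotype classification and subgenome-map inference from binned depth.

An allopolyploid accession mapped against the hexaploid reference leaves a
characteristic footprint: a diploid relative of one subgenome covers only
that subgenome's chromosomes; a tetraploid covers two subgenomes at equal
dosage; a hexaploid with the reference karyotype covers all twenty
chromosomes evenly; and a cryptic hexaploid lacking the third subgenome
("Type 2") covers the first two subgenomes with roughly doubled relative
depth on the first, because reads from its extra cryptic subgenome
cross-map there.  A diploid relative of the third subgenome maps diffusely
but with a majority of reads attracted to SG3.

The chromosome-to-subgenome map itself is inferred from a ploidy ladder:
the diploid representative's present chromosomes define SG1, the
tetraploid adds SG2, and the remainder is SG3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .io_formats import BinnedCoverage
from .reference import SG1, SG2, SG3, SUBGENOMES, UNPLACED

DIPLOID_SG1 = "DIPLOID_SG1"
DIPLOID_SG3_AFFINE = "DIPLOID_SG3_AFFINE"
TETRAPLOID_SG1SG2 = "TETRAPLOID_SG1SG2"
HEXAPLOID_REFERENCE = "HEXAPLOID_REFERENCE"
HEXAPLOID_TYPE2 = "HEXAPLOID_TYPE2"
AMBIGUOUS = "AMBIGUOUS"

KARYOTYPE_CLASSES = (
    DIPLOID_SG1,
    DIPLOID_SG3_AFFINE,
    TETRAPLOID_SG1SG2,
    HEXAPLOID_REFERENCE,
    HEXAPLOID_TYPE2,
    AMBIGUOUS,
)


@dataclass
class SubgenomeMap:
    """Chromosome (or scaffold) -> subgenome label assignment."""

    assignment: Dict[str, str]
    provenance: str = "given"  # "given" | "inferred"
    warnings: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = {c: s for c, s in self.assignment.items()
               if s not in (*SUBGENOMES, UNPLACED)}
        if bad:
            raise ValueError(f"invalid subgenome labels: {bad}")

    def chromosomes(self, label: str) -> List[str]:
        return sorted(c for c, s in self.assignment.items() if s == label)

    def label_of(self, chrom: str) -> str:
        return self.assignment.get(chrom, UNPLACED)


@dataclass
class KaryotypeCall:
    accession_id: str
    karyotype: str
    presence: Dict[str, bool]
    chrom_depth: Dict[str, float]
    affinity: Dict[str, float]  # read fraction per SG (+ UNPLACED)
    sg_depth: Dict[str, float]  # median normalized depth per SG
    evidence: Dict[str, float]  # thresholds applied


@dataclass
class AnomalyReport:
    entries: pd.DataFrame  # chrom, observed, expected, score
    z_threshold: float


# ---------------------------------------------------------------------------


def normalize_coverage(cov: BinnedCoverage) -> pd.DataFrame:
    """Length-normalize bin counts and scale by the median non-zero depth.

    Returns the bin table with a unit-free ``depth`` column: per-bp depth
    divided by the median per-bp depth over bins with at least one read.
    Robust to entirely absent subgenomes (median over non-zero bins only),
    and invariant to global scaling of counts.
    """
    bins = cov.bins.copy()
    if cov.total_reads <= 0:
        raise ValueError(f"all-zero coverage for {cov.accession_id}")
    per_bp = bins["count"] / (bins["end"] - bins["start"])
    nonzero = per_bp[bins["count"] > 0]
    bins["depth"] = per_bp / float(np.median(nonzero))
    return bins


def chromosome_presence(
    norm: pd.DataFrame,
    depth_floor: float = 0.25,
    frac_present: float = 0.5,
) -> pd.DataFrame:
    """Call each chromosome present iff enough of its bins carry depth.

    A chromosome is present when the fraction of its bins with
    ``depth >= depth_floor`` exceeds ``frac_present``.
    """
    def _one(sub: pd.DataFrame) -> pd.Series:
        frac = float((sub["depth"] >= depth_floor).mean())
        return pd.Series(
            {"present": frac > frac_present, "mean_depth": float(sub["depth"].mean()),
             "frac_covered": frac}
        )

    out = norm.groupby("chrom", sort=False).apply(_one, include_groups=False)
    return out.reset_index()


def subgenome_affinity(
    norm: pd.DataFrame, sgmap: SubgenomeMap
) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Fraction of mapped reads and median depth per subgenome.

    Fractions over SG1/SG2/SG3 plus UNPLACED sum to 1; UNPLACED is
    reported separately alongside.
    """
    labels = norm["chrom"].map(sgmap.label_of)
    total = float(norm["count"].sum())
    fractions: Dict[str, float] = {}
    depths: Dict[str, float] = {}
    for sg in (*SUBGENOMES, UNPLACED):
        sub = norm[labels == sg]
        fractions[sg] = float(sub["count"].sum()) / total if total > 0 else 0.0
        if len(sub):
            # median over per-chromosome mean depths: robust to a single
            # aberrant chromosome yet continuous at low counts (a median
            # over raw bins sits on the count lattice and is unstable)
            chrom_means = sub.groupby("chrom", sort=False)["depth"].mean()
            depths[sg] = float(np.median(chrom_means))
        else:
            depths[sg] = float("nan")
    return fractions, depths


def _safe_ratio(a: float, b: float) -> float:
    if b <= 0:
        return float("inf") if a > 0 else 1.0
    return a / b


def classify_karyotype(
    accession_id: str,
    presence: pd.DataFrame,
    affinity: Tuple[Dict[str, float], Dict[str, float]],
    sgmap: SubgenomeMap,
    ratio_hi: float = 1.5,
    affinity_min: float = 0.5,
    depth_floor: float = 0.25,
    frac_present: float = 0.5,
) -> KaryotypeCall:
    """Apply the ordered decision rules to presence + affinity evidence.

    Rules (first match wins): diploid carrying SG1 only; tetraploid
    carrying SG1+SG2 at even dosage; "Type 2" hexaploid carrying SG1+SG2
    with elevated SG1 dosage; reference-like hexaploid covering all 20;
    SG3-affine diploid mapping diffusely with majority SG3 read share;
    otherwise AMBIGUOUS.
    """
    fractions, sg_depth = affinity
    chroms = {sg: set(sgmap.chromosomes(sg)) for sg in SUBGENOMES}
    placed = chroms[SG1] | chroms[SG2] | chroms[SG3]
    present = set(presence.loc[presence["present"], "chrom"]) & placed

    d1, d2, d3 = (sg_depth[sg] for sg in SUBGENOMES)
    n12 = len(chroms[SG1] | chroms[SG2])

    karyotype = AMBIGUOUS
    if present <= chroms[SG1] and len(present & chroms[SG1]) >= 5:
        karyotype = DIPLOID_SG1
    elif (
        len(present & (chroms[SG1] | chroms[SG2])) >= n12 - 1
        and len(present & chroms[SG3]) <= 1
    ):
        ratio = _safe_ratio(d1, d2)
        karyotype = TETRAPLOID_SG1SG2 if ratio < ratio_hi else HEXAPLOID_TYPE2
    elif len(present) == len(placed):
        depths = [d for d in (d1, d2, d3) if np.isfinite(d)]
        max_ratio = _safe_ratio(max(depths), min(depths))
        if max_ratio < ratio_hi:
            karyotype = HEXAPLOID_REFERENCE
        elif fractions[SG3] > affinity_min:
            karyotype = DIPLOID_SG3_AFFINE
    elif fractions[SG3] > affinity_min:
        karyotype = DIPLOID_SG3_AFFINE

    return KaryotypeCall(
        accession_id=accession_id,
        karyotype=karyotype,
        presence=dict(zip(presence["chrom"], presence["present"])),
        chrom_depth=dict(zip(presence["chrom"], presence["mean_depth"])),
        affinity=fractions,
        sg_depth=sg_depth,
        evidence={
            "ratio_hi": ratio_hi,
            "affinity_min": affinity_min,
            "depth_floor": depth_floor,
            "frac_present": frac_present,
        },
    )


def classify_accession(
    cov: BinnedCoverage, sgmap: SubgenomeMap, **params
) -> KaryotypeCall:
    """Convenience: normalize -> presence -> affinity -> classify."""
    thresholds = {
        k: params.pop(k)
        for k in ("depth_floor", "frac_present")
        if k in params
    }
    norm = normalize_coverage(cov)
    presence = chromosome_presence(norm, **thresholds)
    affinity = subgenome_affinity(norm, sgmap)
    return classify_karyotype(
        cov.accession_id, presence, affinity, sgmap, **thresholds, **params
    )


def infer_subgenome_map(
    diploid_present: Iterable[str],
    tetraploid_present: Iterable[str],
    reference_chromosomes: Iterable[str],
    tolerance: int = 1,
) -> SubgenomeMap:
    """Infer the 6/7/7 subgenome partition from a ploidy ladder.

    SG1 is the diploid representative's present set, SG2 the tetraploid's
    additional chromosomes, SG3 the remainder of the reference.  Up to
    ``tolerance`` diploid chromosomes absent from the tetraploid are
    tolerated and end up UNPLACED with a warning.
    """
    ref = list(reference_chromosomes)
    dip = set(diploid_present) & set(ref)
    tet = set(tetraploid_present) & set(ref)
    discordant = dip - tet
    if len(discordant) > tolerance:
        raise ValueError(
            "diploid presence set not contained in tetraploid presence set: "
            f"{sorted(discordant)}"
        )
    warnings: List[str] = []
    assignment: Dict[str, str] = {}
    sg1 = dip - discordant
    sg2 = tet - sg1
    for c in ref:
        if c in discordant:
            assignment[c] = UNPLACED
            warnings.append(f"{c}: present in diploid but not tetraploid; UNPLACED")
        elif c in sg1:
            assignment[c] = SG1
        elif c in sg2:
            assignment[c] = SG2
        else:
            assignment[c] = SG3
    if not sg2:
        warnings.append("tetraploid adds no chromosomes over diploid; SG2 empty")
    return SubgenomeMap(assignment=assignment, provenance="inferred", warnings=warnings)


def detect_anomalies(
    norm: pd.DataFrame,
    sgmap: SubgenomeMap,
    call: KaryotypeCall,
    z_threshold: float = 3.0,
) -> AnomalyReport:
    """Flag chromosomes/scaffolds whose depth departs from their subgenome.

    Expected depth for an entity is the median bin depth of its assigned
    subgenome; the deviation score is |observed - expected| / (scaled MAD
    of the subgenome's bin depths).  Only entries above ``z_threshold``
    are reported.
    """
    if call.karyotype == AMBIGUOUS:
        raise ValueError("cannot screen anomalies for an AMBIGUOUS call")
    labels = norm["chrom"].map(sgmap.label_of)
    rows = []
    for sg in SUBGENOMES:
        sub = norm[labels == sg]
        if sub.empty:
            continue
        depths = sub["depth"].to_numpy()
        expected = float(np.median(depths))
        mad = 1.4826 * float(np.median(np.abs(depths - expected)))
        if mad <= 0:
            mad = 1e-12
        for chrom, grp in sub.groupby("chrom", sort=False):
            observed = float(np.median(grp["depth"]))
            score = abs(observed - expected) / mad
            if np.isfinite(z_threshold) and score > z_threshold:
                rows.append(
                    {"chrom": chrom, "subgenome": sg, "observed": observed,
                     "expected": expected, "score": score}
                )
    entries = pd.DataFrame(rows, columns=["chrom", "subgenome", "observed",
                                          "expected", "score"])
    return AnomalyReport(entries=entries, z_threshold=z_threshold)


def calls_to_frame(calls: List[KaryotypeCall]) -> pd.DataFrame:
    """Flatten karyotype calls to a per-accession table for TSV output."""
    rows = []
    for c in calls:
        row = {"accession_id": c.accession_id, "karyotype": c.karyotype}
        row.update({f"frac_{sg}": c.affinity[sg] for sg in (*SUBGENOMES, UNPLACED)})
        row.update({f"depth_{sg}": c.sg_depth[sg] for sg in SUBGENOMES})
        row.update(c.evidence)
        rows.append(row)
    return pd.DataFrame(rows)
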