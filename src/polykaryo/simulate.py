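"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the pipeline's external inputs:

* binned GBS read-depth tables for accessions of each karyotype class
  (negative-binomial bin counts with dosage structure over subgenomes);
* multi-population biallelic genotype matrices under the F-model
  (Balding-Nichols), with admixture, missingness, indels and
  species-private minor alleles, plus matching sample/Q tables;
* dominance-skewed homoeolog-triplet TPM tables over 12 tissues.

Every generator takes an explicit seed; identical configuration and seed
give byte-identical output files.

F-model calibration
-------------------
For a pair of populations with Balding-Nichols parameter F, the expected
dosage-AMOVA differentiation is PhiPT = 2F / (1 + F): among-population
dosage variance is 4 F p(1-p), within-population (HWE) variance is
2 p(1-p)(1-F).  Inverting gives F = phi / (2 - phi), used to hit a
requested PhiPT target.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import coverage as cov_mod
from .io_formats import (
    MISSING,
    TISSUES,
    BinnedCoverage,
    GenotypeMatrix,
    QMatrix,
    SampleTable,
    TripletExpression,
)
from .reference import (
    CAMELINA_SUBGENOME_ASSIGNMENT,
    SG1,
    SG2,
    SG3,
    SUBGENOMES,
    scaled_reference_index,
)
from .coverage import (
    DIPLOID_SG1,
    DIPLOID_SG3_AFFINE,
    HEXAPLOID_REFERENCE,
    HEXAPLOID_TYPE2,
    TETRAPLOID_SG1SG2,
    SubgenomeMap,
)


def fst_for_target_phipt(phi: float) -> float:
    """Balding-Nichols F giving expected pairwise dosage-AMOVA PhiPT ``phi``."""
    if not 0 <= phi < 1:
        raise ValueError("target PhiPT must be in [0, 1)")
    return phi / (2.0 - phi)


# ---------------------------------------------------------------------------
# Coverage simulation
# ---------------------------------------------------------------------------


@dataclass
class CoverageSimConfig:
    """Study conditions for the read-depth generator.

    ``mean_count`` is the expected per-bin read count on a chromosome at
    unit dosage; ``dispersion`` is the negative-binomial alpha (variance
    = mu + alpha mu^2; 0 means Poisson); ``dropout`` is the per-bin
    probability of yielding no reads (GBS bins with no restriction
    fragment); ``type2_sg1_multiplier`` is the dosage excess on SG1 for
    cryptic "Type 2" hexaploids; ``sg3_affine_fraction`` is the read
    share attracted to SG3 for the SG3-affine diploid relative.
    """

    n_per_class: Mapping[str, int] = dc_field(
        default_factory=lambda: {c: 40 for c in (
            DIPLOID_SG1, DIPLOID_SG3_AFFINE, TETRAPLOID_SG1SG2,
            HEXAPLOID_REFERENCE, HEXAPLOID_TYPE2)}
    )
    mean_count: float = 20.0
    dispersion: float = 0.1
    dropout: float = 0.01
    type2_sg1_multiplier: float = 2.0
    sg3_affine_fraction: float = 0.57
    bin_size: int = 100_000
    reference_index: Optional[Mapping[str, int]] = None
    assignment: Optional[Mapping[str, str]] = None

    def resolve(self) -> Tuple[Mapping[str, int], Mapping[str, str]]:
        index = self.reference_index or scaled_reference_index()
        assignment = self.assignment or CAMELINA_SUBGENOME_ASSIGNMENT
        return index, assignment


def _class_dosage(karyotype: str, cfg: CoverageSimConfig) -> Dict[str, float]:
    if karyotype == DIPLOID_SG1:
        return {SG1: 1.0, SG2: 0.0, SG3: 0.0}
    if karyotype == TETRAPLOID_SG1SG2:
        return {SG1: 1.0, SG2: 1.0, SG3: 0.0}
    if karyotype == HEXAPLOID_TYPE2:
        return {SG1: cfg.type2_sg1_multiplier, SG2: 1.0, SG3: 0.0}
    if karyotype == HEXAPLOID_REFERENCE:
        return {SG1: 1.0, SG2: 1.0, SG3: 1.0}
    raise ValueError(f"no dosage profile for {karyotype}")


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    mu = np.maximum(mu, 0.0)
    if alpha <= 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + np.maximum(mu, 1e-12))
    out = rng.negative_binomial(size, p)
    out[mu <= 0] = 0
    return out


def simulate_coverage(
    cfg: CoverageSimConfig, seed: int
) -> Tuple[List[BinnedCoverage], Dict[str, str]]:
    """Generate per-accession binned coverage plus the true class labels."""
    rng = np.random.default_rng(seed)
    index, assignment = cfg.resolve()
    sgmap = SubgenomeMap(dict(assignment))
    from .io_formats import _bin_grid  # shared grid construction

    grid = _bin_grid(index, cfg.bin_size)
    bin_len = (grid["end"] - grid["start"]).to_numpy()
    labels = grid["chrom"].map(sgmap.label_of).to_numpy()
    mean_len = bin_len.mean()

    covs: List[BinnedCoverage] = []
    truth: Dict[str, str] = {}
    acc_no = 0
    for karyotype, n_acc in cfg.n_per_class.items():
        for _ in range(n_acc):
            acc_no += 1
            acc = f"SIM{acc_no:04d}"
            if karyotype == DIPLOID_SG3_AFFINE:
                # diffuse mapping: a fixed read share lands on SG3 bins,
                # the rest spreads over SG1+SG2, proportional to bin length
                mu = np.zeros(len(grid))
                sg3 = labels == SG3
                other = ~sg3
                total = cfg.mean_count * len(grid)
                mu[sg3] = (
                    total * cfg.sg3_affine_fraction
                    * bin_len[sg3] / bin_len[sg3].sum()
                )
                mu[other] = (
                    total * (1 - cfg.sg3_affine_fraction)
                    * bin_len[other] / bin_len[other].sum()
                )
            else:
                dosage = _class_dosage(karyotype, cfg)
                mu = np.array(
                    [dosage.get(l, 0.0) for l in labels]
                ) * cfg.mean_count * bin_len / mean_len
            counts = _nb_counts(rng, mu, cfg.dispersion)
            drop = rng.random(len(grid)) < cfg.dropout
            counts[drop] = 0
            bins = grid.copy()
            bins["count"] = counts
            covs.append(BinnedCoverage(accession_id=acc, bins=bins,
                                       bin_size=cfg.bin_size))
            truth[acc] = karyotype
    return covs, truth


# ---------------------------------------------------------------------------
# Genotype simulation
# ---------------------------------------------------------------------------


@dataclass
class GenotypeSimConfig:
    """F-model multi-population genotype generator settings.

    ``pop_fst`` gives each subpopulation's Balding-Nichols F relative to
    the shared ancestral pool; use :func:`fst_for_target_phipt` to aim a
    pairwise PhiPT.  ``n_admixed`` samples draw per-locus ancestries from
    a Dirichlet Q; ``private_minor_per_group`` appends loci whose
    alternate allele is homozygous in exactly one sample of one group and
    absent elsewhere (species-private minor alleles).
    """

    n_per_pop: Mapping[str, int] = dc_field(
        default_factory=lambda: {"CG1": 30, "CG2": 30, "CG3": 30}
    )
    pop_fst: Mapping[str, float] = dc_field(
        default_factory=lambda: {"CG1": 0.1, "CG2": 0.1, "CG3": 0.1}
    )
    n_loci: int = 2000
    ancestral_beta: Tuple[float, float] = (0.8, 0.8)
    maf_floor: float = 0.05
    missing_rate: float = 0.02
    indel_fraction: float = 0.0
    n_admixed: int = 0
    admix_alpha: float = 1.5
    private_minor_per_group: int = 0
    chrom_lengths: Optional[Mapping[str, int]] = None
    divergent_region: Optional[Tuple[str, int, int, float]] = None
    # (chrom, start_bp, end_bp, F) — extra divergence inside one window


@dataclass
class GenotypeTruth:
    pop_labels: Dict[str, str]  # sample -> population or ADMIXED
    q_true: pd.DataFrame
    private_minor: Dict[str, Set[int]]  # group -> locus row indices
    pop_fst: Dict[str, float]


def _draw_pop_freqs(
    rng: np.random.Generator, p_anc: np.ndarray, f: float
) -> np.ndarray:
    if f <= 0:
        return p_anc.copy()
    a = p_anc * (1 - f) / f
    b = (1 - p_anc) * (1 - f) / f
    return rng.beta(np.maximum(a, 1e-9), np.maximum(b, 1e-9))


def _distinct_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n sorted distinct 1-based positions on [1, length] without
    materializing the full range."""
    if n > length:
        raise ValueError("more loci than positions")
    out: np.ndarray = np.unique(rng.integers(1, length + 1, size=max(2 * n, 16)))
    while len(out) < n:
        more = rng.integers(1, length + 1, size=2 * n)
        out = np.unique(np.concatenate([out, more]))
    return np.sort(rng.choice(out, size=n, replace=False))


def simulate_genotypes(
    cfg: GenotypeSimConfig, seed: int
) -> Tuple[GenotypeMatrix, SampleTable, QMatrix, GenotypeTruth]:
    """Generate genotypes, metadata, a Q-matrix and the ground truth."""
    rng = np.random.default_rng(seed)
    pops = list(cfg.n_per_pop)
    k = len(pops)
    n_core = int(sum(cfg.n_per_pop.values()))
    n_samples = n_core + cfg.n_admixed
    n_background = cfg.n_loci
    n_private = cfg.private_minor_per_group * k
    n_total_loci = n_background + n_private

    # variant coordinates over a toy chromosome set
    chrom_lengths = cfg.chrom_lengths or {"Csa06": 20_000_000}
    chroms = list(chrom_lengths)
    chrom_choice = rng.integers(0, len(chroms), size=n_total_loci)
    pos = np.empty(n_total_loci, dtype=np.int64)
    for ci, chrom in enumerate(chroms):
        mask = chrom_choice == ci
        pos[mask] = _distinct_positions(rng, chrom_lengths[chrom], int(mask.sum()))
    order = np.lexsort((pos, chrom_choice))
    chrom_choice, pos = chrom_choice[order], pos[order]
    chrom_names = np.asarray(chroms)[chrom_choice]
    # background vs injected-private loci, after coordinate sorting
    is_private = np.zeros(n_total_loci, dtype=bool)
    if n_private:
        is_private[
            rng.choice(n_total_loci, size=n_private, replace=False)
        ] = True
    bg_idx = np.flatnonzero(~is_private)
    priv_idx = np.flatnonzero(is_private)

    p_anc = rng.beta(*cfg.ancestral_beta, size=n_background)
    p_anc = np.clip(p_anc, cfg.maf_floor, 1 - cfg.maf_floor)
    pop_p = np.zeros((k, n_background))
    for pi, pop in enumerate(pops):
        f = cfg.pop_fst[pop]
        pop_p[pi] = _draw_pop_freqs(rng, p_anc, f)
    if cfg.divergent_region is not None:
        chrom_r, start_r, end_r, f_r = cfg.divergent_region
        bg_pos = pos[bg_idx]
        bg_chrom = chrom_names[bg_idx]
        in_region = (bg_chrom == chrom_r) & (bg_pos > start_r) & (bg_pos <= end_r)
        for pi in range(k):
            pop_p[pi, in_region] = _draw_pop_freqs(
                rng, p_anc[in_region], f_r
            )

    calls = np.zeros((n_total_loci, n_samples), dtype=np.int8)
    sample_ids: List[str] = []
    pop_labels: Dict[str, str] = {}
    q_rows = np.zeros((n_samples, k))
    col = 0
    for pi, pop in enumerate(pops):
        for _ in range(cfg.n_per_pop[pop]):
            sid = f"ACC{col + 1:04d}"
            sample_ids.append(sid)
            pop_labels[sid] = pop
            calls[bg_idx, col] = rng.binomial(2, pop_p[pi])
            q = np.full(k, 0.0)
            q[pi] = 1.0
            q_rows[col] = q
            col += 1
    for _ in range(cfg.n_admixed):
        sid = f"ACC{col + 1:04d}"
        sample_ids.append(sid)
        pop_labels[sid] = "ADMIXED"
        q = rng.dirichlet(np.full(k, cfg.admix_alpha))
        q_rows[col] = q
        # per-locus, per-allele ancestry draws
        anc1 = rng.choice(k, size=n_background, p=q)
        anc2 = rng.choice(k, size=n_background, p=q)
        a1 = rng.random(n_background) < pop_p[anc1, np.arange(n_background)]
        a2 = rng.random(n_background) < pop_p[anc2, np.arange(n_background)]
        calls[bg_idx, col] = a1.astype(np.int8) + a2.astype(np.int8)
        col += 1

    # species-private minor alleles: one hom-alt carrier in one group
    private_truth: Dict[str, Set[int]] = {p: set() for p in pops}
    pop_cols = {
        p: [i for i, s in enumerate(sample_ids) if pop_labels[s] == p] for p in pops
    }
    for j, locus in enumerate(priv_idx):
        pop = pops[j % k]
        carrier = int(rng.choice(pop_cols[pop]))
        calls[locus, :] = 0
        calls[locus, carrier] = 2
        private_truth[pop].add(int(locus))

    # missingness (injected loci stay fully called so truth stays exact)
    if cfg.missing_rate > 0:
        miss = rng.random(calls.shape) < cfg.missing_rate
        miss[priv_idx, :] = False
        calls[miss] = MISSING

    bases = np.asarray(["A", "C", "G", "T"])
    ref = bases[rng.integers(0, 4, n_total_loci)]
    alt = np.array([bases[(np.flatnonzero(bases == r)[0] + 1) % 4] for r in ref])
    is_indel = np.zeros(n_total_loci, dtype=bool)
    if cfg.indel_fraction > 0:
        idl = rng.random(n_total_loci) < cfg.indel_fraction
        is_indel = idl
        alt = np.where(idl, np.char.add(alt, "T"), alt)

    variants = pd.DataFrame(
        {"chrom": chrom_names, "pos": pos, "ref": ref, "alt": alt,
         "is_indel": is_indel}
    )
    gm = GenotypeMatrix(variants=variants, calls=calls, sample_ids=sample_ids)
    samples = SampleTable(
        pd.DataFrame(
            {
                "accession_id": sample_ids,
                "species_label": [
                    "C. sativa" if pop_labels[s] != "CG3" else 'C. microcarpa Type 1'
                    for s in sample_ids
                ],
                "group_label": [pop_labels[s] for s in sample_ids],
                "habit": "unknown",
            }
        )
    )
    q = QMatrix(pd.DataFrame(q_rows, index=sample_ids, columns=pops))
    truth = GenotypeTruth(
        pop_labels=pop_labels,
        q_true=q.q.copy(),
        private_minor=private_truth,
        pop_fst=dict(cfg.pop_fst),
    )
    return gm, samples, q, truth


def simulate_q_matrix(
    n_assigned_per_pop: Mapping[str, int],
    n_admixed: int,
    seed: int,
    assigned_floor: float = 0.75,
    admixed_ceiling: float = 0.65,
) -> Tuple[QMatrix, pd.Series]:
    """Q-matrix with unambiguous truth labels for threshold classification.

    Assigned samples have a majority component >= ``assigned_floor``;
    admixed samples have max component <= ``admixed_ceiling``; both drawn
    by rejection so a 0.70 cutoff separates them with margin.
    """
    rng = np.random.default_rng(seed)
    pops = list(n_assigned_per_pop)
    k = len(pops)
    rows, idx, labels = [], [], []
    i = 0
    for pi, pop in enumerate(pops):
        for _ in range(n_assigned_per_pop[pop]):
            while True:
                q = rng.dirichlet(np.full(k, 0.3))
                if q.argmax() == pi and q.max() >= assigned_floor:
                    break
            rows.append(q)
            idx.append(f"Q{i + 1:04d}")
            labels.append(pop)
            i += 1
    for _ in range(n_admixed):
        while True:
            q = rng.dirichlet(np.full(k, 3.0))
            if q.max() <= admixed_ceiling:
                break
        rows.append(q)
        idx.append(f"Q{i + 1:04d}")
        labels.append("ADMIXED")
        i += 1
    q = QMatrix(pd.DataFrame(np.array(rows), index=idx, columns=pops))
    return q, pd.Series(labels, index=idx, name="truth")


# ---------------------------------------------------------------------------
# Triplet expression simulation
# ---------------------------------------------------------------------------


@dataclass
class TripletSimConfig:
    """Dominance-skewed homoeolog TPM generator settings.

    ``dominant_fraction`` maps subgenome label -> fraction of triplets
    whose homoeolog on that subgenome is shifted up by ``effect_log2``
    log2 units in every tissue; the remainder share means.  Replicate
    (block) effects and residual noise are Normal on the log2 scale.
    """

    n_triplets: int = 400
    n_replicates: int = 3
    tissues: Sequence[str] = TISSUES
    dominant_fraction: Mapping[str, float] = dc_field(
        default_factory=lambda: {"SG3": 0.25}
    )
    effect_log2: float = 2.0
    base_log2: float = 4.0
    noise_sd: float = 0.5
    replicate_sd: float = 0.25

    def __post_init__(self) -> None:
        total = sum(self.dominant_fraction.values())
        if total > 1:
            raise ValueError("dominant fractions exceed 1")
        if total > 0 and self.effect_log2 <= 0:
            raise ValueError(
                "triplets labeled dominant require a positive effect size"
            )


def simulate_triplets(
    cfg: TripletSimConfig, seed: int
) -> Tuple[TripletExpression, pd.Series]:
    """Generate a triplet TPM table and per-triplet dominance truth."""
    rng = np.random.default_rng(seed)
    sg_index = {"SG1": 0, "SG2": 1, "SG3": 2}
    labels = np.full(cfg.n_triplets, "NONE", dtype=object)
    cursor = 0
    for sg, frac in cfg.dominant_fraction.items():
        n = int(round(frac * cfg.n_triplets))
        labels[cursor:cursor + n] = sg
        cursor += n
    rng.shuffle(labels)

    n_t, n_r = cfg.n_triplets, cfg.n_replicates
    tids = np.array([f"TRP{t + 1:05d}" for t in range(n_t)])
    base = cfg.base_log2 + rng.normal(0, 1.0, size=n_t)
    effect = np.zeros((n_t, 3))
    for t in range(n_t):
        if labels[t] != "NONE":
            effect[t, sg_index[labels[t]]] = cfg.effect_log2

    frames = []
    for tissue in cfg.tissues:
        tissue_shift = rng.normal(0, 0.5, size=n_t)
        block = rng.normal(0, cfg.replicate_sd, size=(n_t, n_r))
        noise = rng.normal(0, cfg.noise_sd, size=(n_t, 3, n_r))
        log2tpm = (
            base[:, None, None]
            + tissue_shift[:, None, None]
            + effect[:, :, None]
            + block[:, None, :]
            + noise
        )
        tpm = np.power(2.0, log2tpm)  # (T, 3, R)
        frames.append(
            pd.DataFrame(
                {
                    "triplet_id": np.repeat(tids, n_r),
                    "gene_sg1": np.repeat(np.char.add(tids, ".SG1"), n_r),
                    "gene_sg2": np.repeat(np.char.add(tids, ".SG2"), n_r),
                    "gene_sg3": np.repeat(np.char.add(tids, ".SG3"), n_r),
                    "tissue": tissue,
                    "replicate": np.tile(np.arange(1, n_r + 1), n_t),
                    "tpm_sg1": tpm[:, 0, :].reshape(-1),
                    "tpm_sg2": tpm[:, 1, :].reshape(-1),
                    "tpm_sg3": tpm[:, 2, :].reshape(-1),
                }
            )
        )
    expr = TripletExpression(pd.concat(frames, ignore_index=True))
    truth = pd.Series(labels, index=[f"TRP{t + 1:05d}" for t in range(cfg.n_triplets)],
                      name="dominant_truth")
    return expr, truth
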