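"""Population-genetic statistics on biallelic genotype matrices.

Implements the diversity and differentiation toolkit applied to the
filtered SNP set: per-locus gene diversity (expected heterozygosity) and
polymorphic information content, Nei-1983 D_A genetic distance between
individuals, neighbor-joining trees, principal coordinates analysis,
distance-based AMOVA with the PhiPT differentiation estimator (the
GenAlEx-style F_ST analogue), a windowed PhiPT genome scan, a per-group
minor-allele catalog, and ancestry-threshold admixture classification.
"""

from __future__ import annotations

import logging
import warnings as _warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode

from .io_formats import MISSING, GenotypeMatrix, QMatrix

logger = logging.getLogger(__name__)

ADMIXED = "ADMIXED"


# ---------------------------------------------------------------------------
# Allele frequencies, He, PIC
# ---------------------------------------------------------------------------


def allele_frequencies(gm: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus allele frequencies from non-missing diploid calls."""
    calls = gm.calls
    called = calls != MISSING
    n_called = called.sum(axis=1)
    n_hom_ref = (calls == 0).sum(axis=1)
    n_het = (calls == 1).sum(axis=1)
    n_hom_alt = (calls == 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = (2.0 * n_hom_alt + n_het) / (2.0 * n_called)
        hom_ref_fraction = n_hom_ref / n_called
        hom_alt_fraction = n_hom_alt / n_called
    return pd.DataFrame(
        {
            "p_ref": 1.0 - p_alt,
            "p_alt": p_alt,
            "n_called": n_called,
            "missing_fraction": 1.0 - n_called / calls.shape[1],
            "hom_ref_fraction": hom_ref_fraction,
            "hom_alt_fraction": hom_alt_fraction,
        }
    )


def gene_diversity(freq: pd.DataFrame) -> pd.Series:
    """Nei's gene diversity He = 1 - sum_i p_i^2 per locus.

    Bounded by 0.5 for biallelic loci; undefined (NaN) where no calls.
    """
    he = 1.0 - freq["p_ref"] ** 2 - freq["p_alt"] ** 2
    he[freq["n_called"] == 0] = np.nan
    return he.rename("He")


def pic(freq: pd.DataFrame) -> pd.Series:
    """Botstein's polymorphic information content per locus.

    PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2; for a biallelic locus
    this is He - 2 p^2 q^2, hence PIC <= He with maximum 0.375 at p = 0.5.
    """
    p, q = freq["p_ref"], freq["p_alt"]
    out = 1.0 - p**2 - q**2 - 2.0 * p**2 * q**2
    out[freq["n_called"] == 0] = np.nan
    return out.rename("PIC")


def locus_stats(gm: GenotypeMatrix) -> pd.DataFrame:
    """Variant table annotated with He and PIC."""
    freq = allele_frequencies(gm)
    out = gm.variants.copy()
    out["He"] = gene_diversity(freq)
    out["PIC"] = pic(freq)
    return out


# ---------------------------------------------------------------------------
# Variant filtering
# ---------------------------------------------------------------------------


def filter_variants(
    gm: GenotypeMatrix,
    maf_min: float = 0.01,
    max_missing: float = 0.20,
    drop_indels: bool = True,
    log: Optional[List[str]] = None,
) -> GenotypeMatrix:
    """Filter loci by missingness, then minor allele frequency, then indels.

    MAF is strict (> ``maf_min``) and computed over all samples from
    non-missing calls; missingness is <= ``max_missing``.  Each predicate
    is locus-local, so the output is independent of locus order and the
    filter is idempotent.
    """
    def _log(msg: str) -> None:
        logger.info(msg)
        if log is not None:
            log.append(msg)

    freq = allele_frequencies(gm)
    _log(f"input: {gm.n_loci} loci")
    keep = freq["missing_fraction"].to_numpy() <= max_missing
    _log(f"after missingness <= {max_missing}: {int(keep.sum())} loci")
    maf = np.minimum(freq["p_ref"], freq["p_alt"]).to_numpy()
    keep &= np.nan_to_num(maf, nan=0.0) > maf_min
    _log(f"after MAF > {maf_min}: {int(keep.sum())} loci")
    if drop_indels:
        keep &= ~gm.variants["is_indel"].to_numpy()
        _log(f"after dropping indels: {int(keep.sum())} loci")
    if not keep.any():
        _warnings.warn("variant filter removed every locus", stacklevel=2)
    return gm.take_loci(keep)


# ---------------------------------------------------------------------------
# Nei-1983 D_A distance
# ---------------------------------------------------------------------------


def nei_da_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise Nei (1983) D_A distance between individuals.

    Each individual is a per-locus allele-frequency vector (0, 0.5, 1);
    D_A = 1 - (1/L) * sum_loci sum_alleles sqrt(x_i * y_i), averaging over
    loci called in both individuals of a pair.
    """
    n = gm.n_samples
    if n < 2:
        raise ValueError("need at least 2 samples")
    g = gm.calls.astype(float)
    g[gm.calls == MISSING] = np.nan
    x_alt = g / 2.0  # (L, n)
    x_ref = 1.0 - x_alt
    sqrt_alt = np.sqrt(x_alt)
    sqrt_ref = np.sqrt(x_ref)
    called = ~np.isnan(g)
    d = np.zeros((n, n))
    for i in range(n - 1):
        shared = called[:, i, None] & called[:, i + 1:]
        sim = (
            sqrt_ref[:, i, None] * sqrt_ref[:, i + 1:]
            + sqrt_alt[:, i, None] * sqrt_alt[:, i + 1:]
        )
        n_shared = shared.sum(axis=0)
        if (n_shared == 0).any():
            bad = [
                (gm.sample_ids[i], gm.sample_ids[i + 1 + j])
                for j in np.flatnonzero(n_shared == 0)
            ]
            raise ValueError(f"no shared called loci for pairs: {bad}")
        with np.errstate(invalid="ignore"):
            mean_sim = np.nansum(np.where(shared, sim, 0.0), axis=0) / n_shared
        d[i, i + 1:] = d[i + 1:, i] = 1.0 - mean_sim
    np.clip(d, 0.0, 1.0, out=d)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=gm.sample_ids)


def mismatch_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Simple allele-sharing mismatch dissimilarity (|g_i - g_j| / 2 mean)."""
    n = gm.n_samples
    g = gm.calls.astype(float)
    g[gm.calls == MISSING] = np.nan
    d = np.zeros((n, n))
    for i in range(n - 1):
        diff = np.abs(g[:, i, None] - g[:, i + 1:]) / 2.0
        d[i, i + 1:] = d[i + 1:, i] = np.nanmean(diff, axis=0)
    return DistanceMatrix(d, ids=gm.sample_ids)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with the Studier-Keppler criterion.

    Returns an unrooted tree (trifurcating root for n >= 3).  On additive
    matrices the tree's path lengths reproduce the input distances
    exactly.  Ties in the Q-criterion are broken by the lowest (row,
    column) index pair for reproducibility.
    """
    d = np.array(dist.data, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    nodes: List[TreeNode] = [TreeNode(name=str(i)) for i in dist.ids]
    n = len(nodes)
    if n < 2:
        return nodes[0]
    while n > 3:
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin -> lowest (row, col) among ties
        flat = int(np.argmin(q))
        i, j = divmod(flat, n)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        d[i, :] = dnew
        d[:, i] = dnew
        d[i, i] = 0.0
        nodes[i] = parent
        keep = [k for k in range(n) if k != j]
        d = d[np.ix_(keep, keep)]
        nodes.pop(j)
        n -= 1
    if n == 3:
        v0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
        v1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
        v2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
        for node, v in zip(nodes, (v0, v1, v2)):
            node.length = v
        return TreeNode(children=nodes)
    # n == 2
    nodes[0].length = nodes[1].length = d[0, 1] / 2.0
    return TreeNode(children=nodes)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes, ordered by eigenvalue
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # lambda_i / sum(positive lambda), retained axes


def pcoa(dist: DistanceMatrix) -> PCoAResult:
    """Classical (Gower) principal coordinates analysis.

    Double-centers the squared distance matrix and eigendecomposes it.
    Axes with positive eigenvalues are retained; negative eigenvalues are
    reported but excluded from the variance denominator.
    """
    d = np.asarray(dist.data, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(1.0, abs(evals[0]))
    positive = evals > tol
    coords = evecs[:, positive] * np.sqrt(evals[positive])
    frame = pd.DataFrame(
        coords,
        index=list(dist.ids),
        columns=[f"PCo{k + 1}" for k in range(int(positive.sum()))],
    )
    pos_sum = evals[positive].sum()
    return PCoAResult(
        coordinates=frame,
        eigenvalues=evals,
        proportion_explained=evals[positive] / pos_sum,
    )


# ---------------------------------------------------------------------------
# AMOVA / PhiPT
# ---------------------------------------------------------------------------


@dataclass
class FstResult:
    pop_a: str
    pop_b: str  # "overall" when more than a pair
    phipt: float  # clamped to [0, 1]
    phipt_raw: float
    sigma_among: float
    sigma_within: float
    df_among: int
    df_within: int
    p_value: Optional[float] = None
    n_permutations: int = 0


def genotype_squared_distances(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise squared Euclidean distance on genotype codes (0/1/2).

    Loci missing in either member of a pair are skipped and the sum is
    rescaled to the full locus count (L / L_shared).
    """
    g = gm.calls.astype(float)
    g[gm.calls == MISSING] = np.nan
    n = gm.n_samples
    L = gm.n_loci
    d2 = np.zeros((n, n))
    for i in range(n - 1):
        diff = g[:, i, None] - g[:, i + 1:]
        shared = ~np.isnan(diff)
        n_shared = shared.sum(axis=0)
        ss = np.nansum(diff**2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = np.where(n_shared > 0, ss * (L / n_shared), np.nan)
        d2[i, i + 1:] = d2[i + 1:, i] = scaled
    return d2


def phipt_from_distances(
    d2: np.ndarray,
    labels: Sequence[str],
    permutations: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> FstResult:
    """Distance-based AMOVA: PhiPT = sigma2_among / (sigma2_among + sigma2_within).

    Sums of squares follow the standard AMOVA identities on pairwise
    squared distances; the among component uses the unequal-sample-size
    coefficient n0.  Negative component estimates are retained raw and
    PhiPT is clamped to [0, 1].
    """
    labels = np.asarray(labels)
    pops = sorted(set(labels))
    sizes = {p: int((labels == p).sum()) for p in pops}
    small = [p for p, s in sizes.items() if s < 2]
    if small:
        raise ValueError(f"populations with fewer than 2 samples: {small}")
    n_tot = len(labels)
    k = len(pops)

    def _components(lab: np.ndarray) -> Tuple[float, float, float, float]:
        iu = np.triu_indices(n_tot, 1)
        ss_total = d2[iu].sum() / n_tot
        ss_within = 0.0
        for p in pops:
            idx = np.flatnonzero(lab == p)
            sub = d2[np.ix_(idx, idx)]
            ss_within += np.triu(sub, 1).sum() / len(idx)
        ss_among = ss_total - ss_within
        ms_among = ss_among / (k - 1)
        ms_within = ss_within / (n_tot - k)
        n0 = (n_tot - sum(s * s for s in sizes.values()) / n_tot) / (k - 1)
        sigma_within = ms_within
        sigma_among = (ms_among - ms_within) / n0
        denom = sigma_among + sigma_within
        phi = sigma_among / denom if denom > 0 else 0.0
        return phi, sigma_among, sigma_within, ss_among

    phi_raw, sig_a, sig_w, _ = _components(labels)
    p_value = None
    if permutations > 0:
        if rng is None:
            rng = np.random.default_rng()
        hits = 1  # include the observed arrangement
        for _ in range(permutations):
            perm = rng.permutation(labels)
            phi_p, *_ = _components(perm)
            if phi_p >= phi_raw - 1e-12:
                hits += 1
        p_value = hits / (permutations + 1)
    return FstResult(
        pop_a=pops[0] if k == 2 else "all",
        pop_b=pops[1] if k == 2 else "overall",
        phipt=float(np.clip(phi_raw, 0.0, 1.0)),
        phipt_raw=float(phi_raw),
        sigma_among=float(sig_a),
        sigma_within=float(sig_w),
        df_among=k - 1,
        df_within=n_tot - k,
        p_value=p_value,
        n_permutations=permutations,
    )


def amova_phipt(
    gm: GenotypeMatrix,
    pops: Mapping[str, str],
    permutations: int = 0,
    seed: Optional[int] = None,
) -> List[FstResult]:
    """Pairwise (and overall, when > 2 populations) PhiPT over samples.

    ``pops`` maps sample id to population label; samples absent from the
    mapping are excluded.
    """
    keep = [i for i, s in enumerate(gm.sample_ids) if s in pops]
    labels = np.asarray([pops[gm.sample_ids[i]] for i in keep])
    sub_ids = [gm.sample_ids[i] for i in keep]
    g = GenotypeMatrix(gm.variants.copy(), gm.calls[:, keep], sub_ids)
    d2 = genotype_squared_distances(g)
    pop_names = sorted(set(labels))
    rng = np.random.default_rng(seed)
    results: List[FstResult] = []
    for a, b in combinations(pop_names, 2):
        sel = np.isin(labels, (a, b))
        res = phipt_from_distances(
            d2[np.ix_(sel, sel)], labels[sel], permutations=permutations, rng=rng
        )
        results.append(res)
    if len(pop_names) > 2:
        results.append(
            phipt_from_distances(d2, labels, permutations=permutations, rng=rng)
        )
    return results


def fst_scan(
    gm: GenotypeMatrix,
    pops: Mapping[str, str],
    window_bp: int = 1_000_000,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Windowed PhiPT track along the genome.

    Windows with no variants are emitted with a missing PhiPT value.
    ``chrom_lengths`` controls the window grid extent; by default windows
    run to the last variant position per chromosome.
    """
    keep = [i for i, s in enumerate(gm.sample_ids) if s in pops]
    labels = [pops[gm.sample_ids[i]] for i in keep]
    rows = []
    for chrom, sub in gm.variants.groupby("chrom", sort=False):
        length = (
            chrom_lengths[chrom]
            if chrom_lengths is not None
            else int(sub["pos"].max())
        )
        pos = sub["pos"].to_numpy()
        loc_idx = sub.index.to_numpy()
        for start in range(0, length, window_bp):
            end = min(start + window_bp, length)
            in_win = (pos > start) & (pos <= end)
            if not in_win.any():
                rows.append({"chrom": chrom, "start": start, "end": end,
                             "n_loci": 0, "phipt": np.nan})
                continue
            wgm = GenotypeMatrix(
                sub.loc[loc_idx[in_win]].reset_index(drop=True),
                gm.calls[np.ix_(loc_idx[in_win], keep)],
                [gm.sample_ids[i] for i in keep],
            )
            d2 = genotype_squared_distances(wgm)
            res = phipt_from_distances(d2, labels)
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "n_loci": int(in_win.sum()), "phipt": res.phipt})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Minor-allele catalog
# ---------------------------------------------------------------------------


@dataclass
class MinorAlleleCatalog:
    """Per-group minor-allele locus sets and their 3-set Venn partition."""

    sets: Dict[str, Set[int]]  # group -> locus row indices
    venn: Dict[FrozenSet[str], int]  # exclusive region -> count
    hom_threshold: float
    mode: str

    @property
    def union_size(self) -> int:
        out: Set[int] = set()
        for s in self.sets.values():
            out |= s
        return len(out)


def minor_allele_catalog(
    gm: GenotypeMatrix,
    groups: Mapping[str, str],
    hom_threshold: float = 0.05,
    mode: str = "hom_fraction",
) -> MinorAlleleCatalog:
    """Catalog loci carrying a minor allele within each species group.

    Default criterion ("hom_fraction"): an allele is minor for a group
    iff the fraction of the group's non-missing genotypes homozygous for
    it is below ``hom_threshold`` and above zero.  The alternative
    "allele_freq" mode applies the same band to the allele frequency.
    A locus enters a group's set when either allele is minor there.
    """
    if mode not in ("hom_fraction", "allele_freq"):
        raise ValueError(f"unknown mode {mode!r}")
    group_names = sorted(set(groups.values()))
    sets: Dict[str, Set[int]] = {}
    for gname in group_names:
        idx = [i for i, s in enumerate(gm.sample_ids) if groups.get(s) == gname]
        if not idx:
            raise ValueError(f"group {gname!r} has no samples")
        sub = gm.calls[:, idx]
        called = sub != MISSING
        n_called = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            if mode == "hom_fraction":
                f_alt = (sub == 2).sum(axis=1) / n_called
                f_ref = (sub == 0).sum(axis=1) / n_called
            else:
                f_alt = ((sub == 2).sum(axis=1) * 2 + (sub == 1).sum(axis=1)) / (
                    2 * n_called
                )
                f_ref = 1.0 - f_alt
        minor = np.zeros(gm.n_loci, dtype=bool)
        for f in (f_alt, f_ref):
            f = np.nan_to_num(f, nan=0.0)
            minor |= (f > 0) & (f < hom_threshold)
        sets[gname] = set(np.flatnonzero(minor).tolist())

    venn: Dict[FrozenSet[str], int] = {}
    union: Set[int] = set()
    for s in sets.values():
        union |= s
    for locus in union:
        member = frozenset(g for g, s in sets.items() if locus in s)
        venn[member] = venn.get(member, 0) + 1
    return MinorAlleleCatalog(sets=sets, venn=venn, hom_threshold=hom_threshold,
                              mode=mode)


# ---------------------------------------------------------------------------
# Admixture classification
# ---------------------------------------------------------------------------


def classify_admixture(q: QMatrix, cutoff: float = 0.70) -> pd.Series:
    """Assign each sample to its majority ancestry, or ADMIXED.

    A sample joins population argmax_k Q_k iff max_k Q_k >= ``cutoff``.
    """
    vals = q.q.to_numpy(dtype=float)
    best = vals.argmax(axis=1)
    labels = [
        q.q.columns[b] if vals[i, b] >= cutoff else ADMIXED
        for i, b in enumerate(best)
    ]
    return pd.Series(labels, index=q.q.index, name="population")
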