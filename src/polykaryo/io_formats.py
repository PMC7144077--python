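"""Readers and writers for every external format the pipeline touches.

Conventions
-----------
* Coverage bins are 0-based half-open (BED convention); VCF positions are
  1-based.  Conversions live here and nowhere else.
* Missing genotype calls use the dedicated sentinel :data:`MISSING` (-1),
  never conflated with hom-ref (0).
* Multi-allelic VCF records are split into biallelic loci sharing a
  position by default; a "drop" policy is selectable.
* Terminal bins shorter than the declared bin size are retained; per-bin
  depths are length-normalized downstream before any comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from cyvcf2 import VCF

MISSING: int = -1

#: Tissue labels of the expression atlas (germinating seed, cotyledon,
#: young leaf, root, stem, senescing leaf, bud, flower, and four seed
#: development stages from early to late).
TISSUES = ("GS", "C", "YL", "R", "S", "SL", "BUD", "F", "ESD", "EMSD", "LMSD", "LSD")

HABITS = ("spring", "winter", "unknown")


class ParseError(ValueError):
    """Malformed input row; carries the offending line number."""


class ValidationError(ValueError):
    """Structurally parseable input violating a type invariant."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------


@dataclass
class BinnedCoverage:
    """Per-accession read counts in fixed genomic bins over the reference."""

    accession_id: str
    bins: pd.DataFrame  # columns: chrom, start, end, count
    bin_size: int = 100_000

    def counts_for(self, chrom: str) -> np.ndarray:
        return self.bins.loc[self.bins["chrom"] == chrom, "count"].to_numpy()

    @property
    def total_reads(self) -> int:
        return int(self.bins["count"].sum())


@dataclass
class GenotypeMatrix:
    """Biallelic loci x samples genotype calls.

    ``calls`` codes: 0 hom-ref, 1 het, 2 hom-alt, :data:`MISSING`.
    """

    variants: pd.DataFrame  # columns: chrom, pos, ref, alt, is_indel
    calls: np.ndarray  # int8, shape (n_loci, n_samples)
    sample_ids: List[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.variants), len(self.sample_ids)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.variants)} loci x {len(self.sample_ids)} samples"
            )
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValidationError("genotype codes must be in {0,1,2,MISSING}")
        # non-decreasing: split multi-allelics legitimately share a position
        for chrom, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if len(pos) > 1 and not (np.diff(pos) >= 0).all():
                raise ValidationError(f"positions not sorted on {chrom}")

    @property
    def n_loci(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def take_loci(self, sel) -> "GenotypeMatrix":
        """Subset loci by boolean mask or integer row positions."""
        sel = np.asarray(sel)
        idx = np.flatnonzero(sel) if sel.dtype == bool else sel
        return GenotypeMatrix(
            variants=self.variants.iloc[idx].reset_index(drop=True),
            calls=self.calls[idx],
            sample_ids=list(self.sample_ids),
        )


@dataclass
class SampleTable:
    """Per-sample metadata: species, analysis group, growth habit."""

    table: pd.DataFrame  # columns: accession_id, species_label, group_label, habit

    def __post_init__(self) -> None:
        ids = self.table["accession_id"]
        if ids.duplicated().any():
            dups = sorted(ids[ids.duplicated()].unique())
            raise ValidationError(f"duplicate accession ids: {dups}")
        bad = set(self.table["habit"]) - set(HABITS)
        if bad:
            raise ValidationError(f"unknown habit values: {sorted(bad)}")

    @property
    def accession_ids(self) -> List[str]:
        return list(self.table["accession_id"])

    def groups(self) -> Dict[str, str]:
        return dict(zip(self.table["accession_id"], self.table["group_label"]))

    def species(self) -> Dict[str, str]:
        return dict(zip(self.table["accession_id"], self.table["species_label"]))


@dataclass
class QMatrix:
    """Per-sample ancestry proportions over K source populations."""

    q: pd.DataFrame  # index: sample ids; columns: population labels

    def __post_init__(self) -> None:
        vals = self.q.to_numpy(dtype=float)
        if (vals < -1e-12).any() or (vals > 1 + 1e-12).any():
            raise ValidationError("Q entries must lie in [0, 1]")
        sums = vals.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-6
        if bad.any():
            offenders = list(self.q.index[bad])
            raise ValidationError(
                f"Q rows must sum to 1 (+-1e-6); offenders: {offenders}"
            )

    @property
    def k(self) -> int:
        return self.q.shape[1]


@dataclass
class TripletExpression:
    """Homoeolog-triplet TPM values per tissue and replicate (long layout)."""

    data: pd.DataFrame  # triplet_id, gene_sg1..3, tissue, replicate, tpm_sg1..3
    triplets: pd.DataFrame = field(init=False)  # triplet_id -> the 3 gene ids

    def __post_init__(self) -> None:
        d = self.data
        tpm = d[["tpm_sg1", "tpm_sg2", "tpm_sg3"]].to_numpy(dtype=float)
        if (tpm < 0).any() or not np.isfinite(tpm).all():
            raise ValidationError("TPM values must be finite and non-negative")
        genes = d.groupby("triplet_id")[["gene_sg1", "gene_sg2", "gene_sg3"]].nunique()
        if (genes.to_numpy() != 1).any():
            bad = genes.index[(genes != 1).any(axis=1)].tolist()
            raise ValidationError(f"inconsistent homoeolog gene ids for: {bad}")
        reps = d.groupby(["triplet_id", "tissue"])["replicate"].nunique()
        if (reps < 2).any():
            bad = reps.index[reps < 2].tolist()[:5]
            raise ValidationError(f"fewer than 2 replicates for: {bad}")
        self.triplets = (
            d[["triplet_id", "gene_sg1", "gene_sg2", "gene_sg3"]]
            .drop_duplicates("triplet_id")
            .reset_index(drop=True)
        )

    @property
    def tissues(self) -> List[str]:
        return sorted(self.data["tissue"].unique())

    def tissue_array(self, tissue: str) -> Tuple[List[str], np.ndarray]:
        """TPM values for one tissue as (triplet ids, array (T, 3, R))."""
        sub = self.data[self.data["tissue"] == tissue]
        if sub.empty:
            raise ValidationError(f"unknown tissue: {tissue!r}")
        sub = sub.sort_values(["triplet_id", "replicate"])
        ids = sub["triplet_id"].unique().tolist()
        n_rep = sub.groupby("triplet_id")["replicate"].size()
        if n_rep.nunique() != 1:
            raise ValidationError("unbalanced replicate counts within tissue")
        r = int(n_rep.iloc[0])
        arr = (
            sub[["tpm_sg1", "tpm_sg2", "tpm_sg3"]]
            .to_numpy(dtype=float)
            .reshape(len(ids), r, 3)
            .transpose(0, 2, 1)  # (T, 3 subgenomes, R replicates)
        )
        return ids, arr

    def subset(self, triplet_ids: Sequence[str]) -> "TripletExpression":
        keep = self.data["triplet_id"].isin(set(triplet_ids))
        return TripletExpression(self.data[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Coverage I/O
# ---------------------------------------------------------------------------


def _bin_grid(reference_index: Mapping[str, int], bin_size: int) -> pd.DataFrame:
    rows = []
    for chrom, length in reference_index.items():
        starts = np.arange(0, length, bin_size)
        ends = np.minimum(starts + bin_size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    grid = pd.concat(rows, ignore_index=True)
    grid["count"] = 0
    return grid


def read_coverage(
    path,
    reference_index: Mapping[str, int],
    accession_id: Optional[str] = None,
    bin_size: int = 100_000,
) -> BinnedCoverage:
    """Read a BED-like 4-column TSV (chrom, start, end, count) of binned depth.

    Chromosomes absent from the file are zero-filled over the full
    reference; rows must align to the ``bin_size`` grid (the terminal bin
    of a chromosome may be shorter).
    """
    grid = _bin_grid(reference_index, bin_size)
    key = {(c, s): i for i, (c, s) in enumerate(zip(grid["chrom"], grid["start"]))}
    counts = grid["count"].to_numpy().copy()

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:4] == ["chrom", "start", "end", "count"]:
                continue
            if len(parts) < 4:
                raise ParseError(f"line {lineno}: expected 4 columns, got {len(parts)}")
            chrom = parts[0]
            try:
                start, end, count = int(parts[1]), int(parts[2]), int(parts[3])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer field ({exc})") from None
            if chrom not in reference_index:
                raise ParseError(f"line {lineno}: unknown chromosome {chrom!r}")
            if not start < end:
                raise ParseError(f"line {lineno}: start must be < end")
            if count < 0:
                raise ParseError(f"line {lineno}: negative count")
            idx = key.get((chrom, start))
            expected_end = min(start + bin_size, reference_index[chrom])
            if idx is None or end != expected_end:
                raise ValidationError(
                    f"line {lineno}: bin [{start},{end}) off the {bin_size}-bp "
                    f"grid of {chrom}"
                )
            counts[idx] = count
    grid["count"] = counts
    acc = accession_id if accession_id is not None else str(path)
    return BinnedCoverage(accession_id=acc, bins=grid, bin_size=bin_size)


def write_coverage(cov: BinnedCoverage, path) -> None:
    cov.bins.to_csv(path, sep="\t", index=False, header=False,
                    columns=["chrom", "start", "end", "count"])


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------


def read_vcf(path, multiallelic: str = "split") -> Tuple[GenotypeMatrix, SampleTable]:
    """Read a VCF 4.x into a biallelic genotype matrix.

    Diploid GT fields map to {0, 1, 2, MISSING}.  ``multiallelic`` is
    "split" (each alt becomes its own locus; genotypes carrying a
    different alt are coded missing at that locus) or "drop".
    ``is_indel`` is true iff max(len(ref), len(alt)) > 1.
    """
    if multiallelic not in ("split", "drop"):
        raise ValueError(f"unknown multiallelic policy {multiallelic!r}")
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    rows = []
    call_rows: List[np.ndarray] = []
    for rec in vcf:
        gts = rec.genotypes  # [[a1, a2, phased], ...]
        for g, sample in zip(gts, samples):
            if len(g) != 3:  # ploidy + phased flag
                raise ValidationError(
                    f"non-diploid GT for sample {sample} at {rec.CHROM}:{rec.POS}"
                )
        alts = rec.ALT
        if not alts:
            continue
        if len(alts) > 1 and multiallelic == "drop":
            continue
        for k, alt in enumerate(alts, start=1):
            codes = np.full(len(samples), MISSING, dtype=np.int8)
            for j, g in enumerate(gts):
                a1, a2 = g[0], g[1]
                if a1 < 0 or a2 < 0:
                    continue
                if {a1, a2} <= {0, k}:
                    codes[j] = (a1 == k) + (a2 == k)
                # else: carries another alt -> missing at this split locus
            rows.append(
                {
                    "chrom": rec.CHROM,
                    "pos": rec.POS,
                    "ref": rec.REF,
                    "alt": alt,
                    "is_indel": max(len(rec.REF), len(alt)) > 1,
                }
            )
            call_rows.append(codes)
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "is_indel"])
    calls = (
        np.vstack(call_rows) if call_rows else np.empty((0, len(samples)), np.int8)
    )
    gm = GenotypeMatrix(variants=variants, calls=calls, sample_ids=samples)
    stub = SampleTable(
        pd.DataFrame(
            {
                "accession_id": samples,
                "species_label": "",
                "group_label": "",
                "habit": "unknown",
            }
        )
    )
    return gm, stub


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path, contigs: Optional[Mapping[str, int]] = None) -> None:
    """Write a minimal biallelic VCF 4.2 with GT-only genotypes."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contigs:
            for chrom, length in contigs.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in gm.variants["chrom"].unique():
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for i, row in enumerate(gm.variants.itertuples(index=False)):
            gts = "\t".join(_GT_STR[int(c)] for c in gm.calls[i])
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Tabular I/O: samples, Q-matrix, expression
# ---------------------------------------------------------------------------


def read_samples(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = ["accession_id", "species_label", "group_label", "habit"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"sample table missing columns: {missing}")
    df.loc[df["habit"] == "", "habit"] = "unknown"
    return SampleTable(df[required])


def write_samples(samples: SampleTable, path) -> None:
    samples.table.to_csv(path, sep="\t", index=False)


def read_q_matrix(path) -> QMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample":
        raise ParseError("Q-matrix TSV must start with a 'sample' column")
    df = df.set_index("sample")
    return QMatrix(df.astype(float))


def write_q_matrix(q: QMatrix, path) -> None:
    q.q.rename_axis("sample").reset_index().to_csv(path, sep="\t", index=False)


_EXPR_COLS = [
    "triplet_id", "gene_sg1", "gene_sg2", "gene_sg3",
    "tissue", "replicate", "tpm_sg1", "tpm_sg2", "tpm_sg3",
]


def read_expression(path) -> TripletExpression:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _EXPR_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"expression table missing columns: {missing}")
    df["replicate"] = df["replicate"].astype(int)
    return TripletExpression(df[_EXPR_COLS])


def write_expression(expr: TripletExpression, path) -> None:
    expr.data.to_csv(path, sep="\t", index=False, columns=_EXPR_COLS)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def _format_length(x: Optional[float]) -> str:
    if x is None:
        return ""
    return ":" + f"{float(x):.6g}"


def _newick_node(node) -> str:
    if node.is_tip():
        return f"{node.name}{_format_length(node.length)}"
    inner = ",".join(_newick_node(c) for c in node.children)
    name = node.name or ""
    return f"({inner}){name}{_format_length(node.length)}"


def write_newick(tree, path) -> None:
    """Serialize a scikit-bio ``TreeNode`` to Newick.

    Branch lengths are written with 6 significant digits.  A single-leaf
    tree is written as the bare label (``A;`` dialect).
    """
    names = [t.name for t in tree.tips()] or [tree.name]
    if len(names) != len(set(names)):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate leaf labels: {dups}")
    if tree.is_tip():
        text = f"{tree.name};"
    else:
        text = _newick_node(tree) + ";"
    with open(path, "w") as fh:
        fh.write(text + "\n")


def newick_string(tree) -> str:
    if tree.is_tip():
        return f"{tree.name};"
    return _newick_node(tree) + ";"
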