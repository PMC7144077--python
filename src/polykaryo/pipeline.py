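"""End-to-end orchestration of the analysis stages with provenance.

Chains karyotype classification, subgenome-map inference/validation,
variant filtering, diversity and differentiation statistics, the
minor-allele catalog, ordination/tree building, admixture
classification and (when expression data are supplied) the dominance
analysis.  A manifest with input hashes, the effective configuration
and record counts after each filter is written alongside the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__
from .coverage import (
    SubgenomeMap,
    calls_to_frame,
    classify_accession,
    infer_subgenome_map,
)
from .dominance import dominance_analysis
from .io_formats import (
    read_coverage,
    read_expression,
    read_q_matrix,
    read_samples,
    read_vcf,
    write_newick,
)
from .popgen import (
    amova_phipt,
    classify_admixture,
    filter_variants,
    fst_scan,
    locus_stats,
    minor_allele_catalog,
    nei_da_distance,
    nj_tree,
    pcoa,
)
from .reference import CAMELINA_SUBGENOME_ASSIGNMENT

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and stage parameters for a full pipeline run."""

    out_dir: str
    vcf: Optional[str] = None
    coverage_dir: Optional[str] = None
    samples: Optional[str] = None
    q_matrix: Optional[str] = None
    expression: Optional[str] = None
    reference_index: Optional[Dict[str, int]] = None
    subgenome_map: Optional[Dict[str, str]] = None
    infer_map: bool = False
    seed: int = 0
    # stage parameters (documented defaults)
    maf_min: float = 0.01
    max_missing: float = 0.20
    drop_indels: bool = True
    ratio_hi: float = 1.5
    affinity_min: float = 0.5
    depth_floor: float = 0.25
    frac_present: float = 0.5
    q_cutoff: float = 0.70
    hom_threshold: float = 0.05
    window_bp: int = 1_000_000
    permutations: int = 0
    alpha: float = 0.05
    min_tpm: float = 0.01

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> Dict:
    """Execute all applicable stages; returns the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "inputs": {},
        "stages": {},
    }
    for name in ("vcf", "coverage_dir", "samples", "q_matrix", "expression"):
        p = getattr(cfg, name)
        if p and Path(p).is_file():
            manifest["inputs"][name] = _sha256(Path(p))

    stage = "subgenome_map"
    try:
        sgmap = SubgenomeMap(dict(cfg.subgenome_map or CAMELINA_SUBGENOME_ASSIGNMENT))
        calls = []
        if cfg.coverage_dir:
            stage = "classify_ploidy"
            cov_paths = sorted(Path(cfg.coverage_dir).glob("*.tsv"))
            index = cfg.reference_index
            if index is None:
                raise ValueError("coverage analysis requires reference_index")
            for p in cov_paths:
                cov = read_coverage(p, index, accession_id=p.stem)
                calls.append(
                    classify_accession(
                        cov, sgmap,
                        ratio_hi=cfg.ratio_hi, affinity_min=cfg.affinity_min,
                        depth_floor=cfg.depth_floor, frac_present=cfg.frac_present,
                    )
                )
            frame = calls_to_frame(calls)
            frame.to_csv(out / "karyotype_calls.tsv", sep="\t", index=False)
            manifest["stages"]["classify_ploidy"] = {"n_accessions": len(calls)}
            if cfg.infer_map and calls:
                stage = "infer_subgenome_map"
                by_class = {c.karyotype: c for c in calls}
                dip = by_class.get("DIPLOID_SG1")
                tet = by_class.get("TETRAPLOID_SG1SG2")
                if dip and tet:
                    sgmap = infer_subgenome_map(
                        [c for c, p in dip.presence.items() if p],
                        [c for c, p in tet.presence.items() if p],
                        list(index),
                    )
                    pd.Series(sgmap.assignment).rename("subgenome").rename_axis(
                        "chrom"
                    ).reset_index().to_csv(
                        out / "subgenome_map.tsv", sep="\t", index=False
                    )
                    manifest["stages"]["infer_subgenome_map"] = {
                        "warnings": sgmap.warnings
                    }

        if cfg.vcf:
            stage = "filter_variants"
            gm, _ = read_vcf(cfg.vcf)
            log: List[str] = []
            filtered = filter_variants(
                gm, maf_min=cfg.maf_min, max_missing=cfg.max_missing,
                drop_indels=cfg.drop_indels, log=log,
            )
            manifest["stages"]["filter_variants"] = {
                "log": log, "n_in": gm.n_loci, "n_out": filtered.n_loci,
            }
            stage = "diversity"
            stats_frame = locus_stats(filtered)
            stats_frame.to_csv(out / "locus_stats.tsv", sep="\t", index=False)
            manifest["stages"]["diversity"] = {
                "mean_He": float(stats_frame["He"].mean()),
                "mean_PIC": float(stats_frame["PIC"].mean()),
            }
            groups = None
            if cfg.samples:
                samples = read_samples(cfg.samples)
                groups = {
                    a: g for a, g in samples.groups().items()
                    if g and a in filtered.sample_ids
                }
            if groups and len(set(groups.values())) >= 2:
                stage = "fst"
                results = amova_phipt(
                    filtered, groups, permutations=cfg.permutations, seed=cfg.seed
                )
                pd.DataFrame(
                    [dataclasses.asdict(r) for r in results]
                ).to_csv(out / "fst_pairwise.tsv", sep="\t", index=False)
                manifest["stages"]["fst"] = {
                    f"{r.pop_a}|{r.pop_b}": r.phipt for r in results
                }
                stage = "fst_scan"
                track = fst_scan(filtered, groups, window_bp=cfg.window_bp)
                track.to_csv(out / "fst_scan.tsv", sep="\t", index=False)
                manifest["stages"]["fst_scan"] = {"n_windows": len(track)}
                stage = "minor_alleles"
                species = {
                    a: s for a, s in samples.species().items()
                    if s and a in filtered.sample_ids
                }
                if len(set(species.values())) == 3:
                    catalog = minor_allele_catalog(
                        filtered, species, hom_threshold=cfg.hom_threshold
                    )
                    venn = {
                        "&".join(sorted(k)): v for k, v in catalog.venn.items()
                    }
                    manifest["stages"]["minor_alleles"] = {
                        "union": catalog.union_size, "venn": venn,
                    }
            stage = "ordination"
            dist = nei_da_distance(filtered)
            res = pcoa(dist)
            coords = res.coordinates.copy()
            coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
            tree = nj_tree(dist)
            write_newick(tree, out / "nj_tree.nwk")
            manifest["stages"]["ordination"] = {
                "axis1_pct": float(res.proportion_explained[0] * 100),
                "axis2_pct": float(res.proportion_explained[1] * 100)
                if len(res.proportion_explained) > 1 else None,
            }

        if cfg.q_matrix:
            stage = "classify_admixture"
            q = read_q_matrix(cfg.q_matrix)
            assign = classify_admixture(q, cutoff=cfg.q_cutoff)
            assign.rename_axis("sample").reset_index().to_csv(
                out / "admixture_assignments.tsv", sep="\t", index=False
            )
            manifest["stages"]["classify_admixture"] = {
                "n_assigned": int((assign != "ADMIXED").sum()),
                "n_admixed": int((assign == "ADMIXED").sum()),
            }

        if cfg.expression:
            stage = "dominance"
            expr = read_expression(cfg.expression)
            calls_frame, summaries = dominance_analysis(
                expr, alpha=cfg.alpha, min_tpm=cfg.min_tpm
            )
            calls_frame.to_csv(out / "dominance_calls.tsv", sep="\t", index=False)
            pd.DataFrame(
                [
                    {
                        "tissue": s.tissue, "n_tested": s.n_tested,
                        **{f"n_{sg}": s.counts[sg] for sg in s.counts},
                        "chi2": s.chi2, "p_value": s.p_value, **s.ratios,
                    }
                    for s in summaries
                ]
            ).to_csv(out / "dominance_summary.tsv", sep="\t", index=False)
            manifest["stages"]["dominance"] = {"n_tissues": len(summaries)}
        else:
            logger.info("no expression input; dominance stage skipped")
            manifest["stages"]["dominance"] = "skipped (no expression input)"
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
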