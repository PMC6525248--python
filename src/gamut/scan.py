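"""Gene-based genome scan: region assignment, per-gene tests, thresholds, plots.

Variants are assigned to flanked gene windows (default +/- 2 kb), filtered to
common variants (sample MAF > 5%), and each gene is tested with the requested
methods.  Study-wise significance is Bonferroni over the realized number of
tested units; suggestive thresholds are 1e-4 for gene-level tests and 1e-6
for single-SNP regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    all_snp_pvalues,
    cumulative_score,
    gamut_test,
    gene_minp,
    kmr_test,
)
from .io import VariantStore
from .kernels import CovariateMatrix, GenotypeMatrix, PhenotypeMatrix, WeightVector

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRegion",
    "ScanResult",
    "read_gene_regions",
    "assign_variants",
    "run_scan",
    "qq_manhattan_data",
    "SUGGESTIVE_GENE_P",
    "SUGGESTIVE_SNP_P",
]

SUGGESTIVE_GENE_P = 1e-4
SUGGESTIVE_SNP_P = 1e-6


@dataclass
class GeneRegion:
    """1-based closed gene interval with symmetric flank.

    A variant belongs to the gene when its position lies in
    [start - flank, end + flank], both ends included.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    flank: int = 2000

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.flank < 0:
            raise ValueError(f"{self.gene_id}: negative flank")

    @property
    def window(self) -> tuple[int, int]:
        return max(1, self.start - self.flank), self.end + self.flank


@dataclass
class ScanResult:
    """Per-gene (and optionally per-SNP) test records plus scan thresholds."""

    genes: pd.DataFrame
    snps: pd.DataFrame | None
    studywise_gene_p: float
    studywise_snp_p: float | None
    n_genes_tested: int
    n_genes_dropped: int
    suggestive_gene_p: float = SUGGESTIVE_GENE_P
    suggestive_snp_p: float = SUGGESTIVE_SNP_P


def read_gene_regions(
    path: str,
    flank: int = 2000,
    bed_semantics: bool = True,
) -> list[GeneRegion]:
    """4-column (chrom, start, end, gene_id) region file.

    ``bed_semantics=True`` (default) interprets start/end as 0-based
    half-open BED coordinates and converts to the 1-based closed convention
    used internally; set False if the file is already 1-based closed.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                     names=["chrom", "start", "end", "gene_id"],
                     dtype={"chrom": str, "gene_id": str})
    off = 1 if bed_semantics else 0
    return [
        GeneRegion(r.gene_id, r.chrom, int(r.start) + off, int(r.end), flank)
        for r in df.itertuples()
    ]


def assign_variants(
    regions: list[GeneRegion],
    store: VariantStore,
    maf_min: float = 0.05,
) -> dict[str, GenotypeMatrix]:
    """Per-gene genotype matrices of common variants in the flanked windows.

    Variants with sample MAF <= ``maf_min`` are excluded; a variant inside
    two overlapping windows appears in both genes.  Genes left with no
    qualifying variant are reported and omitted from the result.
    """
    out: dict[str, GenotypeMatrix] = {}
    n_empty = 0
    for region in regions:
        lo, hi = region.window
        dos, vids, pos = store.query(region.chrom, lo, hi)
        if dos.shape[1]:
            gm = GenotypeMatrix(dos, variant_ids=vids, positions=pos)
            keep = gm.maf > maf_min
            gm = GenotypeMatrix(gm.dosages[:, keep], variant_ids=gm.variant_ids[keep],
                                positions=gm.positions[keep]) if keep.any() else None
        else:
            gm = None
        if gm is None or gm.n_variants == 0:
            n_empty += 1
            logger.info("gene %s: no common variants in window, skipped", region.gene_id)
            continue
        out[region.gene_id] = gm
    if n_empty:
        logger.warning("%d gene(s) had no qualifying variants", n_empty)
    return out


def _weights_for(gm: GenotypeMatrix, scheme: str,
                 table: dict[str, float] | None) -> tuple[GenotypeMatrix, WeightVector] | None:
    if scheme == "none":
        return gm, WeightVector.flat(gm.n_variants)
    if scheme == "maf":
        return gm, WeightVector.from_maf(gm.maf)
    if scheme == "external":
        if table is None:
            raise ValueError("external weight scheme requires a weight table")
        w = np.array([abs(table.get(str(v), 0.0)) for v in gm.variant_ids])
        keep = w > 0
        if not keep.any():
            return None
        gm2 = GenotypeMatrix(gm.dosages[:, keep], variant_ids=gm.variant_ids[keep],
                             positions=gm.positions[keep])
        return gm2, WeightVector.external(w[keep])
    raise ValueError(f"unknown weight scheme: {scheme}")


def run_scan(
    gene_matrices: dict[str, GenotypeMatrix],
    gene_chrom: dict[str, str],
    phenotypes: PhenotypeMatrix,
    covariates: CovariateMatrix | None = None,
    methods: tuple[str, ...] = ("gamut_linear",),
    weight_scheme: str = "maf",
    weight_table: dict[str, float] | None = None,
    snp_regression_pass: bool = False,
) -> ScanResult:
    """Test every gene with every method and compute scan-wide thresholds.

    Gene-level methods: ``gamut_projection``, ``gamut_linear``, ``kmr``,
    ``linreg_minp``.  With ``snp_regression_pass`` a per-SNP regression table
    is also produced (each SNP once per gene window it falls in).  Genes with
    no variant carrying a positive weight under an external scheme are
    dropped and counted; per-gene failures are flagged and the scan
    continues.  The study-wise gene threshold is 0.05 divided by the number
    of genes actually tested.
    """
    score = cumulative_score(phenotypes)
    gene_rows: list[dict] = []
    snp_rows: list[dict] = []
    n_dropped = 0
    tested_genes: set[str] = set()
    for gene_id in sorted(gene_matrices):
        gm_raw = gene_matrices[gene_id]
        sel = _weights_for(gm_raw, weight_scheme, weight_table)
        if sel is None:
            n_dropped += 1
            logger.info("gene %s: no positively weighted variants, dropped", gene_id)
            continue
        gm, w = sel
        chrom = gene_chrom.get(gene_id, "NA")
        for method in methods:
            try:
                if method == "gamut_projection":
                    res = gamut_test(phenotypes, gm, w, covariates, mode="projection")
                elif method == "gamut_linear":
                    res = gamut_test(phenotypes, gm, w, covariates, mode="linear")
                elif method == "kmr":
                    res = kmr_test(score, gm, w, covariates)
                elif method == "linreg_minp":
                    pv = all_snp_pvalues(score, gm, covariates)
                    padj = gene_minp(pv, gm, covariates)
                    res = None
                    gene_rows.append({
                        "gene": gene_id, "chrom": chrom, "n_variants": gm.n_variants,
                        "method": method, "statistic": float(pv.min()), "p_value": padj,
                        "flags": "",
                    })
                else:
                    raise ValueError(f"unknown method: {method}")
            except Exception as exc:  # failures logged, scan continues
                logger.error("gene %s method %s failed: %s", gene_id, method, exc)
                gene_rows.append({
                    "gene": gene_id, "chrom": chrom, "n_variants": gm.n_variants,
                    "method": method, "statistic": np.nan, "p_value": np.nan,
                    "flags": f"error:{type(exc).__name__}",
                })
                continue
            if res is not None:
                flags = ";".join(
                    k for k, v in res.diagnostics.items()
                    if k in {"degenerate", "rank_deficient_phenotype"} and v
                )
                gene_rows.append({
                    "gene": gene_id, "chrom": chrom, "n_variants": res.n_variants,
                    "method": method, "statistic": res.statistic,
                    "p_value": res.p_value, "flags": flags,
                })
            tested_genes.add(gene_id)
        if snp_regression_pass:
            pv = all_snp_pvalues(score, gm, covariates)
            for j in range(gm.n_variants):
                snp_rows.append({
                    "gene": gene_id, "chrom": chrom,
                    "variant_id": str(gm.variant_ids[j]), "pos": int(gm.positions[j]),
                    "p_value": float(pv[j]),
                })
    genes = pd.DataFrame(gene_rows)
    snps = pd.DataFrame(snp_rows) if snp_regression_pass else None
    n_tested = len(tested_genes)
    snp_thresh = None
    if snps is not None and len(snps):
        snp_thresh = 0.05 / snps["variant_id"].nunique()
    return ScanResult(
        genes=genes,
        snps=snps,
        studywise_gene_p=0.05 / max(n_tested, 1),
        studywise_snp_p=snp_thresh,
        n_genes_tested=n_tested,
        n_genes_dropped=n_dropped,
    )


def _qq_frame(p: np.ndarray) -> pd.DataFrame:
    p = np.sort(np.asarray(p, dtype=float))
    n = p.size
    expected = (np.arange(1, n + 1) - 0.5) / n
    chisq = stats.chi2.isf(p, df=1)
    lam = float(np.median(chisq) / stats.chi2.ppf(0.5, df=1))
    df = pd.DataFrame({
        "expected_neglog10": -np.log10(expected),
        "observed_neglog10": -np.log10(np.clip(p, 1e-300, 1.0)),
    })
    df.attrs["genomic_inflation"] = lam
    return df


def qq_manhattan_data(result: ScanResult) -> dict[str, pd.DataFrame]:
    """Plot-ready QQ and Manhattan tables per method.

    QQ: expected vs observed -log10 p with the genomic-inflation factor
    (median observed 1-df chi-square over its null median) in
    ``frame.attrs``.  Manhattan: cumulative genome coordinate per gene,
    -log10 p, and threshold lines in ``frame.attrs``; chromosomes are laid
    end-to-end in sorted order, empty ones simply absent.
    """
    if result.genes is None or not len(result.genes):
        raise ValueError("empty scan result")
    out: dict[str, pd.DataFrame] = {}
    genes = result.genes.dropna(subset=["p_value"])
    for method, sub in genes.groupby("method"):
        out[f"qq_{method}"] = _qq_frame(sub["p_value"].to_numpy())
        sub = sub.sort_values(["chrom", "gene"]).reset_index(drop=True)
        man = pd.DataFrame({
            "gene": sub["gene"], "chrom": sub["chrom"],
            "coord": np.arange(len(sub)),
            "neglog10_p": -np.log10(np.clip(sub["p_value"].to_numpy(), 1e-300, 1.0)),
        })
        man.attrs["studywise_line"] = -np.log10(result.studywise_gene_p)
        man.attrs["suggestive_line"] = -np.log10(result.suggestive_gene_p)
        out[f"manhattan_{method}"] = man
    if result.snps is not None and len(result.snps):
        out["qq_snp"] = _qq_frame(result.snps["p_value"].to_numpy())
        s = result.snps.sort_values(["chrom", "pos"]).reset_index(drop=True)
        man = pd.DataFrame({
            "variant_id": s["variant_id"], "chrom": s["chrom"], "pos": s["pos"],
            "coord": np.arange(len(s)),
            "neglog10_p": -np.log10(np.clip(s["p_value"].to_numpy(), 1e-300, 1.0)),
        })
        if result.studywise_snp_p:
            man.attrs["studywise_line"] = -np.log10(result.studywise_snp_p)
        man.attrs["suggestive_line"] = -np.log10(result.suggestive_snp_p)
        out["manhattan_snp"] = man
    return out
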