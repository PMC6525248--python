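"""Readers and writers for the scan's external formats.

Phenotype/covariate tables are delimited text with a header and one subject
per row (``subject_id``, ``item_1..item_Q``, then covariates).  Variant
weights are two-column text.  Genotypes come from VCF (via cyvcf2) or PLINK
bed/bim/fam; the PLINK codec is implemented here directly (2-bit SNP-major
encoding) and round-trip tested against its own writer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "VariantStore",
    "read_phenotype_table",
    "read_weight_table",
    "load_genotypes",
    "write_plink",
]


@dataclass
class VariantStore:
    """In-memory genome-wide dosage store queryable by (chrom, interval).

    Holds one N x M dosage matrix (minor-allele counts, NaN for missing)
    plus variant coordinates.  Suits questionnaire-cohort scans where the
    genotype matrix fits in memory; positions are 1-based.
    """

    subject_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    variant_ids: np.ndarray
    dosages: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def query(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dosages, variant ids and positions inside [start, end] (1-based closed)."""
        m = (self.chrom == str(chrom)) & (self.pos >= start) & (self.pos <= end)
        return self.dosages[:, m], self.variant_ids[m], self.pos[m]

    def reorder(self, subject_ids: np.ndarray) -> "VariantStore":
        """Subset/reorder subjects to the given id sequence (inner order)."""
        index = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in index]
        if missing:
            raise KeyError(f"{len(missing)} subject(s) absent from genotype data, e.g. {missing[:3]}")
        rows = np.array([index[s] for s in subject_ids])
        return VariantStore(np.asarray(subject_ids), self.chrom, self.pos,
                            self.variant_ids, self.dosages[rows])


def read_phenotype_table(
    path: str | Path,
    item_prefix: str = "item_",
    sep: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a subject table into item-response and covariate frames.

    Returns ``(items, covariates)``, both indexed by ``subject_id``.  Columns
    beginning with ``item_prefix`` are questionnaire items; all remaining
    columns are treated as covariates.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: no 'subject_id' column")
    df = df.set_index("subject_id")
    item_cols = [c for c in df.columns if c.startswith(item_prefix)]
    if not item_cols:
        raise ValueError(f"{path}: no columns with prefix '{item_prefix}'")
    cov_cols = [c for c in df.columns if c not in item_cols]
    items = df[item_cols]
    if items.isna().any().any():
        raise ValueError(f"{path}: missing item responses are not supported")
    return items, df[cov_cols].astype(float)


def read_weight_table(path: str | Path, sep: str | None = None) -> dict[str, float]:
    """Two-column (variant_id, weight) text file -> mapping."""
    df = pd.read_csv(path, sep=sep, engine="python", header=None,
                     names=["variant_id", "weight"], comment="#")
    if df["weight"].dtype == object:  # header row present
        df = df.iloc[1:]
    return dict(zip(df["variant_id"].astype(str), df["weight"].astype(float)))


# ---------------------------------------------------------------------------
# VCF


def _load_vcf(path: str | Path) -> VariantStore:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = np.array(vcf.samples)
    chroms, poss, vids, rows = [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 3 hom-alt, 2 unknown
        dos = np.choose(rec.gt_types, [0.0, 1.0, np.nan, 2.0])
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        vids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        rows.append(dos)
    if n_skipped:
        logger.info("skipped %d multi-allelic record(s)", n_skipped)
    dosages = np.array(rows).T if rows else np.empty((subjects.size, 0))
    return VariantStore(subjects, np.array(chroms, dtype=object),
                        np.array(poss, dtype=int), np.array(vids, dtype=object), dosages)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major bed
# 2-bit genotype -> A1 (minor) dosage: 00 hom-A1, 01 missing, 10 het, 11 hom-A2
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def _load_plink(prefix: str | Path) -> VariantStore:
    prefix = str(prefix)
    if prefix.endswith(".bed"):
        prefix = prefix[:-4]
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str)
    bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None,
                      names=["chrom", "vid", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "vid": str})
    n, m = len(fam), len(bim)
    raw = np.fromfile(f"{prefix}.bed", dtype=np.uint8)
    if raw[:3].tobytes() != _PLINK_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK bed file")
    bpv = (n + 3) // 4  # bytes per variant
    body = raw[3:]
    if body.size != bpv * m:
        raise ValueError(f"{prefix}.bed: expected {bpv * m} data bytes, found {body.size}")
    blocks = body.reshape(m, bpv)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((m, bpv * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    dosages = _BED_DECODE[codes[:, :n]].T
    return VariantStore(
        fam["iid"].to_numpy(),
        bim["chrom"].to_numpy(dtype=object),
        bim["pos"].to_numpy(dtype=int),
        bim["vid"].to_numpy(dtype=object),
        dosages,
    )


def write_plink(store: VariantStore, prefix: str | Path) -> None:
    """Write a VariantStore as PLINK bed/bim/fam (missing dosages -> 01 code)."""
    prefix = str(prefix)
    n, m = store.n_subjects, store.n_variants
    pd.DataFrame({
        "fid": store.subject_ids, "iid": store.subject_ids,
        "pat": "0", "mat": "0", "sex": "0", "pheno": "-9",
    }).to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)
    pd.DataFrame({
        "chrom": store.chrom, "vid": store.variant_ids, "cm": 0,
        "pos": store.pos, "a1": "A", "a2": "B",
    }).to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    code_of = {2.0: 0b00, 1.0: 0b10, 0.0: 0b11}
    bpv = (n + 3) // 4
    out = np.zeros((m, bpv * 4), dtype=np.uint8)
    for j in range(m):
        col = store.dosages[:, j]
        codes = np.array([0b01 if np.isnan(x) else code_of[round(x)] for x in col],
                         dtype=np.uint8)
        out[j, :n] = codes
    packed = np.zeros((m, bpv), dtype=np.uint8)
    for k in range(4):
        packed |= out[:, k::4] << (2 * k)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_PLINK_MAGIC)
        fh.write(packed.tobytes())


def load_genotypes(path: str | Path, format: str | None = None) -> VariantStore:
    """Load a genome-wide variant store from VCF or PLINK bed/bim/fam.

    ``format`` is ``"vcf"`` or ``"plink_bed"``; inferred from the file
    extension when omitted.  Multi-allelic VCF records are skipped with a
    log message.
    """
    p = str(path)
    if format is None:
        if p.endswith((".vcf", ".vcf.gz", ".bcf")):
            format = "vcf"
        elif p.endswith((".bed", ".bim", ".fam")) or Path(p + ".bed").exists():
            format = "plink_bed"
        else:
            raise ValueError(f"cannot infer genotype format from {path}")
    if format == "vcf":
        return _load_vcf(path)
    if format == "plink_bed":
        return _load_plink(path)
    raise ValueError(f"unknown genotype format: {format}")
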