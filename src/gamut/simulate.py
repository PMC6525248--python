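"""Synthetic genotypes and BDI-like ordinal questionnaires for size/power studies.

The generator emulates the study design the tests were validated under:

* genotypes for a gene region are drawn by pairing haplotypes from a pool
  with realistic minor-allele-frequency spectra and autoregressive linkage
  disequilibrium (a synthetic stand-in for HapMap-derived gene structures:
  a STAT3-like region with 27 SNPs of which 14 are array-typed, and a
  LRFN5-like region with 127 SNPs of which 50 are typed);
* 21 correlated ordinal items (levels 0-3) arise from a Gaussian copula —
  a latent multivariate normal cut at per-item thresholds chosen to match
  right-skewed BDI-like marginal distributions;
* causal-variant effects shift the latent means of an affected subset of
  items (18/21, 12/21 or 6/21 in the power grid), so the association can be
  concentrated in a few symptoms rather than spread over the whole score;
* an optional continuous confounder shifts both the item latents and the
  haplotype sampling probabilities, inducing spurious marginal association.

Experiment drivers estimate empirical size (proportion of null p-values
below alpha) and power (proportion below alpha under a causal model) for
the distance-covariance test and its univariate comparators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    CumulativeScore,
    all_snp_pvalues,
    cumulative_score,
    gamut_test,
    gene_minp,
    kmr_test,
)
from .kernels import CovariateMatrix, GenotypeMatrix, PhenotypeMatrix, WeightVector

__all__ = [
    "HaplotypePool",
    "QuestionnaireModel",
    "EffectModel",
    "ExperimentConfig",
    "build_haplotype_pool",
    "stat3_like_pool",
    "lrfn5_like_pool",
    "draw_genotypes",
    "calibrate_margins",
    "default_bdi_model",
    "simulate_questionnaire",
    "run_size_experiment",
    "run_power_experiment",
    "DEFAULT_BETA",
]

#: default per-item latent effect of the causal dosage.  With 12 of 21 items
#: affected and the default BDI-like margins this puts a typical common
#: causal variant at roughly 0.5-1% of cumulative-score variance explained —
#: a modest overall effect that can nonetheless be concentrated in few items.
DEFAULT_BETA = 0.2

#: default confounder couplings: strong enough that ignoring the covariate
#: visibly inflates type-I error, mild enough that linear residualization of
#: the items restores nominal size.
DEFAULT_GAMMA_PHENO = 0.2
DEFAULT_GAMMA_GENO = 0.2


@dataclass
class HaplotypePool:
    """H x V binary haplotype matrix from which genotypes are drawn in pairs."""

    haplotypes: np.ndarray
    variant_ids: np.ndarray
    positions: np.ndarray
    target_maf: np.ndarray
    typed_mask: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        h = self.haplotypes.shape[0]
        if h < 100 or h % 2:
            raise ValueError("haplotype pool must hold an even number >= 100")

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]


@dataclass
class QuestionnaireModel:
    """Gaussian-copula model for Q correlated ordinal items.

    ``R`` is the Q x Q latent correlation matrix (positive definite, unit
    diagonal); ``cutpoints`` holds the Q x (L-1) nondecreasing standard-normal
    thresholds that carve each latent variable into L ordinal levels.
    """

    R: np.ndarray
    cutpoints: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.cutpoints = np.atleast_2d(np.asarray(self.cutpoints, dtype=float))
        q = self.R.shape[0]
        if self.R.shape != (q, q) or not np.allclose(self.R, self.R.T):
            raise ValueError("latent correlation matrix must be square symmetric")
        if not np.allclose(np.diag(self.R), 1.0):
            raise ValueError("latent correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(self.R).min() <= 0:
            raise ValueError(
                "latent correlation matrix is not positive definite; "
                "consider a nearest-PD repair before constructing the model"
            )
        if self.cutpoints.shape[0] != q:
            raise ValueError("one cutpoint row per item required")
        if np.any(np.diff(self.cutpoints, axis=1) < 0):
            raise ValueError("cutpoints must be nondecreasing per item")

    @property
    def n_items(self) -> int:
        return self.R.shape[0]


@dataclass
class EffectModel:
    """Causal architecture for power simulations.

    ``causal_index`` indexes the full variant panel (typed + untyped);
    ``affected_items`` lists the 0-based items whose latent means respond to
    the causal dosage with slopes ``betas``.  The optional confounder couples
    a standard-normal covariate U to all item latents (``gamma_pheno``) and to
    haplotype sampling (``gamma_geno``).
    """

    causal_index: int
    affected_items: np.ndarray
    betas: np.ndarray
    gamma_pheno: float = 0.0
    gamma_geno: float = 0.0

    def __post_init__(self) -> None:
        self.affected_items = np.asarray(self.affected_items, dtype=int)
        self.betas = np.broadcast_to(
            np.asarray(self.betas, dtype=float), self.affected_items.shape
        ).copy()
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("effect sizes must be finite")


@dataclass
class ExperimentConfig:
    """Replication settings for a size or power experiment."""

    N: int = 1000
    n_reps: int = 10_000
    alphas: tuple[float, ...] = (0.05, 0.01, 0.001)
    seed: int = 0
    methods: tuple[str, ...] = ("gamut_projection", "gamut_linear", "kmr", "linreg_minp")

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if any(not 0 < a < 1 for a in self.alphas):
            raise ValueError("alpha levels must lie in (0, 1)")


# ---------------------------------------------------------------------------
# genotypes


def build_haplotype_pool(
    V: int,
    maf_spec: np.ndarray,
    ld_decay: float,
    seed: int | np.random.Generator,
    n_haplotypes: int = 2000,
    positions: np.ndarray | None = None,
    typed_mask: np.ndarray | None = None,
    variant_ids: np.ndarray | None = None,
) -> HaplotypePool:
    """Binary haplotypes with AR(1)-correlated latent structure.

    Each haplotype is a thresholded draw of a latent Gaussian AR(1) process
    with lag-one correlation ``ld_decay``; thresholding at the standard-normal
    quantile of each variant's target MAF yields the requested frequency
    spectrum while adjacent variants inherit the latent correlation as
    linkage disequilibrium (``ld_decay`` = 0: independent variants;
    ``ld_decay`` -> 1: comonotone block).
    """
    if V < 2:
        raise ValueError("need at least two variants")
    if not 0.0 <= ld_decay < 1.0:
        raise ValueError("ld_decay must lie in [0, 1)")
    maf = np.broadcast_to(np.asarray(maf_spec, dtype=float), (V,)).copy()
    lo, hi = 1.0 / n_haplotypes, 0.5 - 1e-6
    if np.any((maf <= 0.0) | (maf >= 0.5)):
        warnings.warn("target MAFs at 0 or 0.5 clamped to feasible range", stacklevel=2)
        maf = np.clip(maf, lo, hi)
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_haplotypes, V))
    z = np.empty_like(eps)
    z[:, 0] = eps[:, 0]
    c = np.sqrt(1.0 - ld_decay**2)
    for j in range(1, V):
        z[:, j] = ld_decay * z[:, j - 1] + c * eps[:, j]
    haps = (z < stats.norm.ppf(maf)).astype(np.int8)
    if positions is None:
        positions = np.arange(1, V + 1) * 1000
    if typed_mask is None:
        typed_mask = np.ones(V, dtype=bool)
    if variant_ids is None:
        variant_ids = np.array([f"snp_{j + 1}" for j in range(V)])
    return HaplotypePool(haps, np.asarray(variant_ids), np.asarray(positions),
                         maf, np.asarray(typed_mask, dtype=bool))


def _default_pool(V: int, n_typed: int, ld_decay: float, seed: int,
                  span_bp: int) -> HaplotypePool:
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.05, 0.5, V)  # common-variant spectrum (MAF > 5%)
    typed = np.zeros(V, dtype=bool)
    typed[np.round(np.linspace(0, V - 1, n_typed)).astype(int)] = True
    positions = np.sort(rng.choice(np.arange(1, span_bp), V, replace=False))
    return build_haplotype_pool(
        V, maf, ld_decay, rng, n_haplotypes=2000,
        positions=positions, typed_mask=typed,
    )


def stat3_like_pool(seed: int = 2024, ld_decay: float = 0.9) -> HaplotypePool:
    """27-SNP gene region with 14 array-typed SNPs (STAT3-like structure)."""
    return _default_pool(27, 14, ld_decay, seed, span_bp=79_000)


def lrfn5_like_pool(seed: int = 2024, ld_decay: float = 0.9) -> HaplotypePool:
    """127-SNP gene region with 50 array-typed SNPs (LRFN5-like structure)."""
    return _default_pool(127, 50, ld_decay, seed, span_bp=323_000)


def draw_genotypes(
    pool: HaplotypePool,
    N: int,
    seed: int | np.random.Generator,
    confounder: np.ndarray | None = None,
    gamma_geno: float = 0.0,
) -> GenotypeMatrix:
    """Pair two haplotypes per subject, uniformly with replacement.

    With a confounder U, haplotype sampling weights follow a logistic model
    in the haplotype's standardized minor-allele count s_h:
    P(h | U) proportional to exp(gamma_geno * U * s_h), tilting allele
    frequencies with U and thereby correlating U with every dosage.
    """
    rng = np.random.default_rng(seed)
    haps = pool.haplotypes
    h = haps.shape[0]
    if confounder is None or gamma_geno == 0.0:
        idx = rng.integers(0, h, size=(N, 2))
    else:
        u = np.asarray(confounder, dtype=float).ravel()
        if u.size != N:
            raise ValueError("confounder length must equal N")
        s = haps.sum(axis=1).astype(float)
        s = (s - s.mean()) / max(s.std(), 1e-12)
        logits = gamma_geno * np.outer(u, s)  # N x H
        logits -= logits.max(axis=1, keepdims=True)
        w = np.exp(logits)
        cdf = np.cumsum(w, axis=1)
        cdf /= cdf[:, -1:]
        draws = rng.random((N, 2))
        idx = np.empty((N, 2), dtype=int)
        for k in range(2):
            idx[:, k] = (cdf < draws[:, [k]]).sum(axis=1)
    dosages = haps[idx[:, 0]].astype(float) + haps[idx[:, 1]].astype(float)
    return GenotypeMatrix(
        dosages,
        variant_ids=pool.variant_ids.copy(),
        positions=pool.positions.copy(),
        typed_mask=pool.typed_mask.copy(),
    )


# ---------------------------------------------------------------------------
# questionnaires


def calibrate_margins(item_freqs: np.ndarray) -> np.ndarray:
    """Standard-normal cutpoints reproducing given per-item level frequencies.

    ``item_freqs`` is Q x L, rows summing to 1.  Returns Q x (L-1) cutpoints
    at the normal quantiles of the cumulative frequencies; simulating from
    them recovers the input margins (round-trip property).  Zero-frequency
    levels yield duplicated cutpoints — the level is effectively merged with
    its neighbor — and trigger a warning.
    """
    f = np.atleast_2d(np.asarray(item_freqs, dtype=float))
    if np.any(f < 0):
        raise ValueError("frequencies must be nonnegative")
    if not np.allclose(f.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("each item's frequencies must sum to 1")
    if np.any(f == 0):
        warnings.warn(
            "zero-frequency level(s): merged with the neighboring level",
            stacklevel=2,
        )
    cum = np.cumsum(f, axis=1)[:, :-1]
    return stats.norm.ppf(np.clip(cum, 1e-12, 1 - 1e-12))


#: right-skewed BDI-like marginal distribution for a 0-3 item
BDI_LIKE_MARGINS = (0.55, 0.25, 0.12, 0.08)


def default_bdi_model(
    n_items: int = 21,
    margins: tuple[float, ...] = BDI_LIKE_MARGINS,
    base_corr: float = 0.2,
    block_corr: float = 0.45,
    n_blocks: int = 3,
) -> QuestionnaireModel:
    """Synthetic 21-item questionnaire model with BDI-like structure.

    All items share a right-skewed margin; the latent correlation is
    exchangeable at ``base_corr`` with ``n_blocks`` equal blocks (symptom
    clusters, e.g. affective/somatic/cognitive) raised to ``block_corr``.
    A synthetic stand-in for restricted questionnaire-derived estimates.
    """
    R = np.full((n_items, n_items), base_corr)
    block = n_items // n_blocks
    for b in range(n_blocks):
        lo = b * block
        hi = n_items if b == n_blocks - 1 else lo + block
        R[lo:hi, lo:hi] = block_corr
    np.fill_diagonal(R, 1.0)
    cuts = calibrate_margins(np.tile(margins, (n_items, 1)))
    return QuestionnaireModel(R, cuts)


def simulate_questionnaire(
    model: QuestionnaireModel,
    G: GenotypeMatrix | None,
    eff: EffectModel | None,
    N: int,
    seed: int | np.random.Generator,
    confounder: np.ndarray | None = None,
) -> tuple[PhenotypeMatrix, CovariateMatrix]:
    """Draw N subjects' ordinal item responses from the Gaussian copula.

    Latent Z ~ MVN(0, R); under an effect model the latents of affected items
    are shifted by beta times the (mean-centered) causal dosage, and under a
    confounder by gamma_pheno * U.  The ordinal response is the count of
    cutpoints below the latent value.  Returns the items plus a covariate
    matrix holding the confounder column (empty when no confounder is used).
    """
    rng = np.random.default_rng(seed)
    q = model.n_items
    L = np.linalg.cholesky(model.R)
    Z = rng.standard_normal((N, q)) @ L.T
    if eff is not None and eff.affected_items.size:
        if G is None:
            raise ValueError("an effect model requires genotypes")
        if not 0 <= eff.causal_index < G.n_variants:
            raise ValueError(f"causal index {eff.causal_index} outside 0..{G.n_variants - 1}")
        g = G.dosages[:, eff.causal_index]
        Z[:, eff.affected_items] += np.outer(g - g.mean(), eff.betas)
    if eff is not None and eff.gamma_pheno != 0.0:
        if confounder is None:
            raise ValueError("gamma_pheno set but no confounder values supplied")
        Z += eff.gamma_pheno * np.asarray(confounder, dtype=float)[:, None]
    y = np.zeros((N, q), dtype=np.int16)
    for j in range(q):
        y[:, j] = np.searchsorted(model.cutpoints[j], Z[:, j])
    n_levels = model.cutpoints.shape[1] + 1
    pheno = PhenotypeMatrix(y, n_levels=n_levels)
    if confounder is not None:
        cov = CovariateMatrix(np.asarray(confounder, dtype=float).reshape(-1, 1), labels=["U"])
    else:
        cov = CovariateMatrix.empty(N)
    return pheno, cov


# ---------------------------------------------------------------------------
# experiment drivers


def _run_methods(
    methods: tuple[str, ...],
    Y: PhenotypeMatrix,
    G: GenotypeMatrix,
    C: CovariateMatrix | None,
) -> dict[str, float]:
    """One replicate's p-value per requested method, MAF-weighted kernels."""
    Gt = G.typed()
    w = WeightVector.from_maf(Gt.maf)
    out: dict[str, float] = {}
    score: CumulativeScore | None = None
    for m in methods:
        if m == "gamut_projection":
            out[m] = gamut_test(Y, Gt, w, C, mode="projection").p_value
        elif m == "gamut_linear":
            out[m] = gamut_test(Y, Gt, w, C, mode="linear").p_value
        elif m == "kmr":
            score = score or cumulative_score(Y)
            out[m] = kmr_test(score, Gt, w, C).p_value
        elif m == "linreg_minp":
            score = score or cumulative_score(Y)
            pv = all_snp_pvalues(score, Gt, C)
            out[m] = gene_minp(pv, Gt, C, n_qmc=4096)
        else:
            raise ValueError(f"unknown method: {m}")
    return out


def run_size_experiment(
    cfg: ExperimentConfig,
    pool: HaplotypePool,
    model: QuestionnaireModel,
    gamma_pheno: float = 0.0,
    gamma_geno: float = 0.0,
    adjust_covariates: bool = True,
) -> pd.DataFrame:
    """Empirical type-I error under the null (no genetic effect on any item).

    Each replicate draws fresh genotypes and questionnaires, applies every
    configured method, and the rejection rate per method and alpha is the
    fraction of p-values below alpha (with its binomial standard error).
    Setting the gamma parameters switches on the confounding model;
    ``adjust_covariates=False`` then runs the tests without residualizing on
    the confounder, to expose the inflation that adjustment removes.

    Returns a tidy frame (method, alpha, rate, se, n_reps) with the raw
    p-values attached as ``frame.attrs["pvalues"]`` for QQ plotting.
    """
    root = np.random.SeedSequence(cfg.seed)
    confounded = gamma_pheno != 0.0 or gamma_geno != 0.0
    pvals: dict[str, np.ndarray] = {m: np.empty(cfg.n_reps) for m in cfg.methods}
    for rep, ss in enumerate(root.spawn(cfg.n_reps)):
        rng = np.random.default_rng(ss)
        u = rng.standard_normal(cfg.N) if confounded else None
        G = draw_genotypes(pool, cfg.N, rng, confounder=u, gamma_geno=gamma_geno)
        eff = EffectModel(0, np.array([], dtype=int), np.array([]),
                          gamma_pheno=gamma_pheno) if confounded else None
        Y, C = simulate_questionnaire(model, G, eff, cfg.N, rng, confounder=u)
        C_used = C if (confounded and adjust_covariates) else None
        for m, p in _run_methods(cfg.methods, Y, G, C_used).items():
            pvals[m][rep] = p
    rows = []
    for m in cfg.methods:
        for a in cfg.alphas:
            rate = float((pvals[m] < a).mean())
            se = float(np.sqrt(a * (1 - a) / cfg.n_reps))
            rows.append({"method": m, "alpha": a, "rate": rate, "se": se,
                         "n_reps": cfg.n_reps})
    out = pd.DataFrame(rows)
    out.attrs["pvalues"] = pvals
    return out


def run_power_experiment(
    cfg: ExperimentConfig,
    pool: HaplotypePool,
    model: QuestionnaireModel,
    causal_indices: np.ndarray | list[int],
    n_affected: int,
    beta: float = DEFAULT_BETA,
    alpha: float = 0.001,
) -> pd.DataFrame:
    """Power per causal SNP at significance level ``alpha``.

    Each listed variant of the full panel (typed or not) is treated as causal
    in turn; the first ``n_affected`` items respond to its dosage with slope
    ``beta`` on the latent scale.  Tests only ever see the typed variants, so
    an untyped causal SNP is detectable solely through linkage
    disequilibrium.  Genotypes are regenerated every replicate.
    """
    root = np.random.SeedSequence(cfg.seed)
    affected = np.arange(n_affected)
    rows = []
    for ci in causal_indices:
        hits = {m: 0 for m in cfg.methods}
        for ss in root.spawn(cfg.n_reps):
            rng = np.random.default_rng(ss)
            G = draw_genotypes(pool, cfg.N, rng)
            eff = EffectModel(int(ci), affected, beta) if n_affected else None
            Y, _ = simulate_questionnaire(model, G, eff, cfg.N, rng)
            for m, p in _run_methods(cfg.methods, Y, G, None).items():
                hits[m] += p < alpha
        for m in cfg.methods:
            power = hits[m] / cfg.n_reps
            rows.append({
                "method": m, "causal_snp": str(pool.variant_ids[ci]),
                "causal_typed": bool(pool.typed_mask[ci]),
                "n_affected": n_affected, "beta": beta, "alpha": alpha,
                "power": power,
                "se": float(np.sqrt(max(power * (1 - power), 1e-12) / cfg.n_reps)),
                "n_reps": cfg.n_reps,
            })
    return pd.DataFrame(rows)
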