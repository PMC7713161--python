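"""[AT] value as a genome phenotype: LD pruning, kinship, LMM association scan.

The scan fits y = mu + x*beta + g + e with g ~ N(0, sg2*K) and e ~ N(0, se2*I).
K is eigendecomposed once; the variance ratio delta = se2/sg2 is estimated by
REML under the null (intercept-only) model on a log-spaced grid with local
refinement, then reused for every marker (the single-spectral-decomposition
speed path of exact mixed-model association).  Each marker is tested by a Wald
t statistic in the rotated (whitened) model with exact t p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import ExpressionTable, GeneModelSet, GenotypeMatrix

log = logging.getLogger("polyat")


# ---------------------------------------------------------------------------
# Linkage disequilibrium


def ld_r2(geno: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of two dosage vectors over shared non-missing
    accessions; NaN when either has zero variance."""
    x = geno.dosage[:, i]
    y = geno.dosage[:, j]
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _r2_matrix(d: np.ndarray) -> np.ndarray:
    """Pairwise r^2 with per-site mean imputation of missing calls."""
    col_mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_mean[None, :], d)
    d = d - d.mean(axis=0)
    sd = d.std(axis=0)
    sd[sd == 0] = np.nan
    c = (d.T @ d) / len(d)
    r = c / np.outer(sd, sd)
    return r * r


def ld_prune(geno: GenotypeMatrix, window: int = 50, step: int = 50,
             r2_max: float = 0.3) -> np.ndarray:
    """PLINK-style greedy LD pruning; returns indices of retained sites.

    Within each ``window`` consecutive SNPs (per chromosome, position order)
    any pair with r^2 > r2_max loses its later-position member; the window
    slides by ``step``.  Passes repeat until a fixed point, so the output is
    idempotent under re-pruning.
    """
    sdf = geno.sites.df
    keep_global = np.ones(len(sdf), dtype=bool)
    changed = True
    while changed:
        changed = False
        for _, sub in sdf.groupby("chrom", sort=False):
            idx = sub.index.to_numpy()
            idx = idx[keep_global[idx]]
            start = 0
            while start < len(idx):
                widx = idx[start : start + window]
                alive = keep_global[widx].copy()
                if alive.sum() > 1:
                    r2 = _r2_matrix(geno.dosage[:, widx])
                    for a in range(len(widx)):
                        if not alive[a]:
                            continue
                        for b in range(a + 1, len(widx)):
                            if alive[b] and r2[a, b] > r2_max:
                                alive[b] = False
                                changed = True
                    keep_global[widx] = alive
                start += step
    return np.flatnonzero(keep_global)


# ---------------------------------------------------------------------------
# Kinship and PCA


def kinship(geno: GenotypeMatrix) -> np.ndarray:
    """Frequency-standardized marker cross-product (VanRaden-type) kinship.

    Missing dosages are mean-imputed per site; monomorphic sites are skipped.
    Symmetric PSD by construction.
    """
    if geno.n_accessions < 2:
        raise ValueError("need >= 2 accessions")
    d = geno.dosage
    p = np.nanmean(d, axis=0)
    ok = (p > 0) & (p < 1)
    d = np.where(np.isnan(d), p[None, :], d)[:, ok]
    p = p[ok]
    z = (d - p) / np.sqrt(p * (1 - p))
    return (z @ z.T) / z.shape[1]


def at_pc1_correlation(geno: GenotypeMatrix, at_values: pd.Series,
                       signed: bool = False) -> float:
    """|Pearson r| between per-accession [AT] values and PC1 of the dosage matrix.

    PC sign is arbitrary, so the absolute value is reported by default; with
    ``signed=True`` PC1 is oriented so its loading on the first accession's
    deviation is positive before correlating.
    """
    if geno.n_accessions < 3:
        raise ValueError("need >= 3 accessions")
    d = geno.dosage
    col_mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_mean[None, :], d)
    d = d - d.mean(axis=0)
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    if s[0] <= 0:
        raise ValueError("degenerate PCA: no variance in genotypes")
    pc1 = u[:, 0] * s[0]
    y = at_values.loc[geno.accessions].to_numpy(dtype=float)
    if np.std(y) == 0:
        raise ValueError("phenotype has zero variance")
    r = float(np.corrcoef(pc1, y)[0, 1])
    if signed:
        return r if pc1[0] >= 0 else -r
    return abs(r)


# ---------------------------------------------------------------------------
# LMM scan


@dataclass
class AssociationResult:
    """Per-marker scan results plus variance-component metadata."""

    df: pd.DataFrame  # chrom, pos, beta, se, t, p, neglog10p
    n: int
    m: int
    delta: float      # se2 / sg2 ratio at the null REML optimum
    sigma_g2: float
    sigma_e2: float


def _reml_neg_loglik(log_delta: float, s: np.ndarray, yr: np.ndarray,
                     xr: np.ndarray) -> float:
    """Negative restricted log-likelihood profiled over beta and sg2."""
    delta = np.exp(log_delta)
    w = 1.0 / (s + delta)
    n, p = xr.shape
    xtwx = xr.T @ (w[:, None] * xr)
    xtwy = xr.T @ (w * yr)
    beta = np.linalg.solve(xtwx, xtwy)
    resid = yr - xr @ beta
    rss = float(resid @ (w * resid))
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0 or rss <= 0:
        return np.inf
    ll = -0.5 * (
        (n - p) * np.log(2 * np.pi * rss / (n - p))
        + (n - p)
        + np.sum(np.log(s + delta))
        + logdet_xtwx
    )
    return -ll


def _fit_delta(s: np.ndarray, yr: np.ndarray, xr: np.ndarray,
               grid: int = 61) -> float:
    lg = np.linspace(-8.0, 8.0, grid)
    vals = np.array([_reml_neg_loglik(g, s, yr, xr) for g in lg])
    i = int(np.argmin(vals))
    lo = lg[max(i - 1, 0)]
    hi = lg[min(i + 1, grid - 1)]
    res = optimize.minimize_scalar(_reml_neg_loglik, bounds=(lo, hi), args=(s, yr, xr),
                                   method="bounded")
    return float(np.exp(res.x))


def lmm_scan(geno: GenotypeMatrix, phenotype: pd.Series, K: np.ndarray,
             min_eig: float = -1e-8) -> AssociationResult:
    """Single-marker LMM association scan of a quantitative genome phenotype."""
    y = phenotype.loc[geno.accessions].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype must be defined for every accession")
    n = len(y)
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise ValueError("kinship shape does not match accession count")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("kinship matrix must be symmetric")
    s, u = np.linalg.eigh(K)
    if s[0] < min_eig:
        log.warning("kinship not PSD (min eigenvalue %.3g); projecting to nearest PSD", s[0])
    s = np.clip(s, 0.0, None)

    yr = u.T @ y
    ones_r = u.T @ np.ones(n)
    delta = _fit_delta(s, yr, ones_r[:, None])
    w = 1.0 / (s + delta)

    d = geno.dosage
    col_mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), col_mean[None, :], d)
    xr = u.T @ d  # n x m rotated markers

    sy = float((w * ones_r * yr).sum())
    syy = float((w * yr * yr).sum())
    s11 = float((w * ones_r * ones_r).sum())
    sx = (w * ones_r) @ xr          # per-marker sum w*1*x
    sxx = (w[:, None] * xr * xr).sum(axis=0)
    sxy = (w * yr) @ xr

    denom = s11 * sxx - sx * sx
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (s11 * sxy - sx * sy) / denom
        mu = (sy - beta * sx) / s11
        rss = syy - mu * sy - beta * sxy
        dof = n - 2
        sigma2 = rss / dof
        var_beta = sigma2 * s11 / denom
        se = np.sqrt(var_beta)
        t = beta / se
    singular = (denom <= 1e-12 * np.maximum(s11 * sxx, 1e-300)) | ~np.isfinite(t)
    if singular.any():
        log.info("lmm_scan: %d singular/monomorphic markers skipped", int(singular.sum()))
    t = np.where(singular, np.nan, t)
    p = 2.0 * stats.t.sf(np.abs(t), dof)

    # variance components at the null optimum (for reporting)
    w0 = w
    b0 = float((w0 * ones_r * yr).sum() / (w0 * ones_r * ones_r).sum())
    resid0 = yr - ones_r * b0
    sg2 = float((w0 * resid0 * resid0).sum() / (n - 1))
    out = geno.sites.df[["chrom", "pos"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["t"] = t
    out["p"] = p
    with np.errstate(divide="ignore"):
        out["neglog10p"] = -np.log10(p)
    return AssociationResult(out, n, int((~singular).sum()), delta, sg2, sg2 * delta)


# ---------------------------------------------------------------------------
# Loci and candidate intervals


@dataclass
class Locus:
    chrom: str
    start: int
    end: int
    peak_idx: int
    peak_pos: int
    peak_neglog10p: float
    n_markers: int


def significant_loci(result: AssociationResult, threshold_neglogp: float = 6.0,
                     merge_dist: int = 5_000_000) -> list[Locus]:
    """Markers over the -log10 p threshold merged into loci within merge_dist."""
    df = result.df
    hits = df[df["neglog10p"] >= threshold_neglogp].sort_values(["chrom", "pos"])
    loci: list[Locus] = []
    for chrom, sub in hits.groupby("chrom", sort=False):
        block: list[int] = []
        last_pos = None
        for idx, row in sub.iterrows():
            if last_pos is not None and row.pos - last_pos > merge_dist:
                loci.append(_make_locus(df, chrom, block))
                block = []
            block.append(idx)
            last_pos = row.pos
        if block:
            loci.append(_make_locus(df, chrom, block))
    return loci


def _make_locus(df: pd.DataFrame, chrom: str, block: list[int]) -> Locus:
    sub = df.loc[block]
    peak = sub["neglog10p"].idxmax()
    return Locus(chrom, int(sub["pos"].min()), int(sub["pos"].max()), int(peak),
                 int(df.loc[peak, "pos"]), float(df.loc[peak, "neglog10p"]), len(block))


@dataclass
class CandidateInterval:
    chrom: str
    start: int
    end: int
    peak_idx: int
    peak_pos: int
    members: pd.DataFrame = field(repr=False)  # pos, r2
    genes: list[str] = field(default_factory=list)


def candidate_interval(result: AssociationResult, peak_idx: int,
                       geno: GenotypeMatrix, r2_min: float = 0.6,
                       gene_models: GeneModelSet | None = None) -> CandidateInterval:
    """LD-defined candidate interval around a peak marker (r^2 > r2_min)."""
    sdf = geno.sites.df
    chrom = sdf.loc[peak_idx, "chrom"]
    x = geno.dosage[:, peak_idx]
    ok = ~np.isnan(x)
    if np.nanstd(x) == 0:
        raise ValueError("peak marker is monomorphic")
    same = np.flatnonzero((sdf["chrom"] == chrom).to_numpy())
    r2 = np.array([ld_r2(geno, peak_idx, j) for j in same])
    member_mask = (r2 > r2_min) | (same == peak_idx)
    members = same[member_mask]
    pos = sdf.loc[members, "pos"].to_numpy()
    start, end = int(pos.min()), int(pos.max())
    genes = []
    if gene_models is not None:
        for g in gene_models.by_chrom().get(chrom, []):
            if g.end >= start and g.start <= end:
                genes.append(g.gene_id)
    mem_df = pd.DataFrame({"pos": pos, "r2": r2[member_mask]})
    return CandidateInterval(chrom, start, end, int(peak_idx),
                             int(sdf.loc[peak_idx, "pos"]), mem_df, genes)


def filter_expressed(genes: list[str], expression: ExpressionTable,
                     tissues: tuple[str, ...] = ("root", "shoot"),
                     tpm_min: float = 1.0) -> list[str]:
    """Genes with TPM strictly above tpm_min in ALL listed tissues.

    Genes absent from the table are treated as TPM 0 with a warning.
    """
    missing = [g for g in genes if g not in expression.df.index]
    if missing:
        log.warning("filter_expressed: %d genes missing from expression table (TPM=0)",
                    len(missing))
    out = []
    for g in genes:
        if all(expression.tpm(g, t) > tpm_min for t in tissues):
            out.append(g)
    return out
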