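"""Expression preprocessing: normalization, probe selection, stratification
correction, and ARD factor-analysis residuals ("REDUCED" data).

The processing chain is raw -> normalized (quantile within individual +
median across individuals, replicates collapsed) -> stratification-corrected
(per-probe residuals on genotype principal components, admixed populations)
-> reduced (residuals of a variational Bayesian factor analysis with
automatic-relevance-determination priors that switch off unneeded factors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from .containers import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def quantile_normalize_replicates(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize each individual's replicate hybridizations to a
    common distribution, then average them to one column per individual.

    Within one individual, rank k of every replicate is mapped to the mean
    of the k-th order statistics across that individual's replicates; a
    single replicate is left unchanged.
    """
    if raw.stage != "raw":
        raise ValueError(f"expected raw stage, got {raw.stage!r}")
    meta = raw.sample_meta
    if "individual" not in meta.columns:
        raise ValueError("sample_meta must carry an 'individual' column")
    out_cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for ind, grp in meta.groupby("individual", sort=False):
        cols = [c for c in raw.values.columns if c in set(grp.index)]
        if not cols:
            raise ValueError(f"individual {ind} has no replicate columns")
        block = raw.values[cols].to_numpy()
        if len(cols) > 1:
            order = np.argsort(block, axis=0, kind="stable")
            sorted_block = np.take_along_axis(block, order, axis=0)
            target = sorted_block.mean(axis=1)
            normed = np.empty_like(block)
            ranks = np.empty_like(order)
            np.put_along_axis(ranks, order, np.arange(block.shape[0])[:, None], axis=0)
            normed = target[ranks]
            out_cols[ind] = normed.mean(axis=1)
        else:
            out_cols[ind] = block[:, 0]
        first = grp.iloc[0]
        meta_rows.append(
            {"sample": ind, "individual": ind,
             "population": first["population"], "gender": first["gender"]}
        )
    values = pd.DataFrame(out_cols, index=raw.values.index)
    new_meta = pd.DataFrame(meta_rows).set_index("sample")
    return raw.advanced(values, "normalized", sample_meta=new_meta)


def median_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Shift each sample (additively, log2 scale) so its median equals the
    grand median of per-sample medians."""
    if expr.values.shape[1] < 2:
        raise ValueError("median normalization needs >= 2 samples")
    vals = expr.values.to_numpy()
    med = np.median(vals, axis=0)
    grand = np.median(med)
    shifted = vals + (grand - med)[None, :]
    values = pd.DataFrame(shifted, index=expr.values.index, columns=expr.values.columns)
    stage = "normalized" if expr.stage in ("raw", "normalized") else expr.stage
    return expr.advanced(values, stage)


def normalize(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Full normalization: quantile within individual, then median across
    all individuals of all populations."""
    return median_normalize(quantile_normalize_replicates(raw))


# ---------------------------------------------------------------------------
# Probe selection
# ---------------------------------------------------------------------------

def select_probes(annot: pd.DataFrame) -> pd.DataFrame:
    """Flag probes eligible for association mapping.

    Eligible = maps to exactly one gene AND autosomal AND has coordinates.
    Probes overlapping a common SNP are retained (flagged, not excluded) so
    their enrichment among significant hits can be tested downstream.
    """
    out = annot.copy()
    gene = out["gene_id"].astype(str)
    single_gene = ~gene.str.contains(";")
    autosomal = ~out["chrom"].astype(str).isin(["X", "Y", "chrX", "chrY"])
    has_coord = out["tss"].notna()
    n_nocoord = int((~has_coord).sum())
    if n_nocoord:
        logger.warning("%d probes lack TSS coordinates; marked ineligible", n_nocoord)
    out["eligible"] = single_gene & autosomal & has_coord
    if "snp_in_probe" not in out.columns:
        out["snp_in_probe"] = False
    return out


# ---------------------------------------------------------------------------
# Genotype PCA (stratification correction)
# ---------------------------------------------------------------------------

def genotype_pca(
    genotypes: GenotypeMatrix,
    n_axes: int = 10,
    min_maf: float = 0.05,
    max_missing: float = 0.20,
) -> pd.DataFrame:
    """Principal components of the standardized dosage matrix.

    SNPs are filtered to MAF > ``min_maf`` and missingness < ``max_missing``,
    missing dosages mean-imputed per SNP, columns standardized, and scores
    (centered at 0, ordered by variance explained) returned as a
    sample x axis table.
    """
    gm = genotypes.filter_snps(min_maf, max_missing)
    X = gm.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    X = X[:, keep] / sd[keep]
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = s.max() * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    k = min(n_axes, rank)
    if k < n_axes:
        logger.warning("requested %d axes but rank is %d; returning %d", n_axes, rank, k)
    scores = U[:, :k] * s[:k]
    return pd.DataFrame(
        scores, index=genotypes.samples, columns=[f"PC{i + 1}" for i in range(k)]
    )


def residualize_covariates(
    expr: ExpressionMatrix, covars: pd.DataFrame, stage: str = "strat_corrected"
) -> ExpressionMatrix:
    """Per-probe least-squares residuals of expression on covariates
    (+ intercept). Collinear covariates are handled by the pseudoinverse
    (redundant axes contribute nothing); residuals are orthogonal to every
    covariate column."""
    missing = set(expr.values.columns) - set(covars.index)
    if missing:
        raise ValueError(f"covariates missing for samples: {sorted(missing)[:5]}")
    C = covars.loc[expr.values.columns].to_numpy(dtype=float)
    X = np.column_stack([np.ones(C.shape[0]), C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        logger.info("collinear covariates detected; using pseudoinverse fit")
    Y = expr.values.to_numpy().T  # samples x probes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    values = pd.DataFrame(resid.T, index=expr.values.index, columns=expr.values.columns)
    return expr.advanced(values, stage)


# ---------------------------------------------------------------------------
# ARD variational factor analysis ("REDUCED" data)
# ---------------------------------------------------------------------------

@dataclass
class FactorModelConfig:
    """Settings for the Bayesian factor analysis.

    ``ard_prior`` is the Gamma(shape, rate) prior on per-factor loading
    precisions; when None, the shape defaults to the probe count of the fit
    (scaling the regularization with matrix size) with rate 0.022. The
    posterior rate is dominated by the data term, so this acts as a
    moderate per-factor shrinkage that switches unneeded factors off.
    """

    n_hidden: int = 32
    ard_prior: tuple[float, float] | None = None
    noise_prior: tuple[float, float] = (1e-3, 1e-3)
    max_iter: int = 1000
    tol: float = 1e-6


@dataclass
class FactorModel:
    """Fitted factor model and its residual ("REDUCED") expression."""

    config: FactorModelConfig
    loadings: pd.DataFrame  # probe x factor posterior means
    scores: pd.DataFrame  # factor x sample posterior means
    alpha: np.ndarray  # posterior mean ARD precisions per factor
    residuals: ExpressionMatrix
    n_effective: int
    converged: bool
    n_iter: int


def _gender_design(meta: pd.DataFrame, samples) -> np.ndarray | None:
    if "gender" not in meta.columns:
        return None
    g = meta.loc[samples, "gender"].astype(str)
    if g.nunique() < 2:
        return None
    return (g == sorted(g.unique())[0]).to_numpy(dtype=float)[:, None]


def fit_factor_residuals(
    expr: ExpressionMatrix,
    config: FactorModelConfig | None = None,
    known_covariates: pd.DataFrame | None = None,
    include_gender: bool = True,
) -> FactorModel:
    """Fit a variational Bayesian factor analysis with per-factor ARD
    priors and return residuals after removing known-covariate effects and
    the hidden-factor reconstruction.

    Intended to be run separately per population; the gender indicator is
    included as a known covariate by default, and additional known
    covariates (e.g. population indicators in a pooled run) can be passed.
    Convergence: relative improvement of the reconstruction objective
    < ``tol`` or ``max_iter`` iterations (non-convergence returns the best
    iterate with a log flag).
    """
    if config is None:
        config = FactorModelConfig()
    Y = expr.values.to_numpy().copy()  # probes x samples
    G, N = Y.shape

    # known covariates, removed by per-probe OLS (flat-prior Bayesian regression)
    design_parts = []
    gcol = _gender_design(expr.sample_meta, expr.values.columns) if include_gender else None
    if gcol is not None:
        design_parts.append(gcol)
    if known_covariates is not None:
        design_parts.append(known_covariates.loc[expr.values.columns].to_numpy(dtype=float))
    row_mean = Y.mean(axis=1, keepdims=True)
    Y = Y - row_mean
    if design_parts:
        X = np.column_stack([np.ones(N)] + design_parts)
        beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
        Y = Y - (X @ beta).T

    K = config.n_hidden
    if K == 0:
        values = pd.DataFrame(Y, index=expr.values.index, columns=expr.values.columns)
        return FactorModel(
            config=config,
            loadings=pd.DataFrame(np.zeros((G, 0)), index=expr.values.index),
            scores=pd.DataFrame(np.zeros((0, N)), columns=expr.values.columns),
            alpha=np.zeros(0),
            residuals=expr.advanced(values, "reduced"),
            n_effective=0, converged=True, n_iter=0,
        )

    a0, b0 = config.ard_prior if config.ard_prior is not None else (float(G), 0.022)
    c0, d0 = config.noise_prior

    # init from truncated SVD
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    k0 = min(K, len(s))
    M = np.zeros((G, K))
    M[:, :k0] = U[:, :k0] * (s[:k0] / np.sqrt(N))
    EZ = np.zeros((K, N))
    EZ[:k0, :] = Vt[:k0, :] * np.sqrt(N)
    Sigma_z = np.eye(K) / N
    alpha = np.ones(K)
    tau = 1.0 / np.maximum(Y.var(axis=1), 1e-8)
    Sg = np.broadcast_to(np.eye(K) * 1e-4, (G, K, K)).copy()

    obj_prev = np.inf
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        # q(Z)
        WtW = np.einsum("g,gij->ij", tau, Sg) + (M.T * tau) @ M
        Sigma_z = np.linalg.inv(np.eye(K) + WtW)
        EZ = Sigma_z @ (M.T * tau) @ Y
        Ezz = N * Sigma_z + EZ @ EZ.T  # K x K second moment sum

        # q(w_g): S_g = inv(diag(alpha) + tau_g * Ezz)
        # shared eigendecomposition of Ezz in the alpha metric
        A = np.diag(alpha)
        ZYt = EZ @ Y.T  # K x G
        for g in range(G):
            Sg[g] = np.linalg.inv(A + tau[g] * Ezz)
        M = np.einsum("gij,jg->gi", Sg, ZYt) * tau[:, None]

        # q(alpha)
        a_post = a0 + 0.5 * G
        w2 = (M ** 2).sum(axis=0) + np.einsum("gkk->k", Sg)
        b_post = b0 + 0.5 * w2
        alpha = a_post / b_post

        # q(tau)
        yy = (Y ** 2).sum(axis=1)
        cross = np.einsum("gk,kg->g", M, ZYt)
        Eww = Sg + np.einsum("gi,gj->gij", M, M)
        quad = np.einsum("gij,ji->g", Eww, Ezz)
        d_post = d0 + 0.5 * (yy - 2.0 * cross + quad)
        tau = (c0 + 0.5 * N) / np.maximum(d_post, 1e-12)

        obj = float(np.sum(yy - 2.0 * cross + quad))  # expected reconstruction error
        if obj_prev != np.inf:
            rel = abs(obj_prev - obj) / max(abs(obj_prev), 1e-12)
            if rel < config.tol:
                converged = True
                break
        obj_prev = obj

    if not converged:
        logger.warning("factor analysis did not converge in %d iterations", config.max_iter)

    resid = Y - M @ EZ
    total_var = Y.var()
    factor_var = (M ** 2).mean(axis=0) * (EZ ** 2).mean(axis=1)
    n_effective = int((factor_var > 1e-4 * max(total_var, 1e-12)).sum())

    values = pd.DataFrame(resid, index=expr.values.index, columns=expr.values.columns)
    return FactorModel(
        config=config,
        loadings=pd.DataFrame(M, index=expr.values.index,
                              columns=[f"factor{i}" for i in range(K)]),
        scores=pd.DataFrame(EZ, index=[f"factor{i}" for i in range(K)],
                            columns=expr.values.columns),
        alpha=alpha,
        residuals=expr.advanced(values, "reduced"),
        n_effective=n_effective,
        converged=converged,
        n_iter=it,
    )
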