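"""Spearman-rank cis association with permutation-calibrated per-gene
thresholds, expected-count and replication FDR estimators, and stepwise
conditional mapping of independent effects.

The nominal test is the Pearson correlation of mid-ranks with a two-sided
p-value from the t-approximation on n-2 degrees of freedom. Per-gene
significance thresholds are the empirical alpha-quantile (order statistic
floor(alpha * n_perms), 1-based) of minimum nominal p-values over all cis
SNPs under repeated permutation of the expression phenotype; an observed
minimum p is significant only when strictly below the threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .containers import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1_000_000
DEFAULT_MAF = 0.05
DEFAULT_MISS = 0.20
MIN_SAMPLES = 10

_TINY = np.finfo(float).tiny


# ---------------------------------------------------------------------------
# Nominal Spearman test
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    """Mid-ranks (average ranks for ties) of a 1-D array."""
    x = np.asarray(x)
    order = np.argsort(x, kind="stable")
    sx = x[order]
    starts = np.flatnonzero(np.r_[True, sx[1:] != sx[:-1]])
    ends = np.r_[starts[1:], len(x)]
    group_rank = (starts + 1 + ends) / 2.0  # mean of 1-based ranks in each tie group
    ranks = np.empty(len(x))
    ranks[order] = np.repeat(group_rank, ends - starts)
    return ranks


def _rank_standardize(x: np.ndarray) -> np.ndarray | None:
    """Mid-ranks, centered and scaled to unit norm (None if zero variance)."""
    r = _midranks(x)
    r = r - r.mean()
    norm = np.sqrt((r ** 2).sum())
    if norm == 0.0:
        return None
    return r / norm




def _p_from_rho(rho, n):
    """Two-sided p from the t-approximation with n-2 df; clamped into (0, 1]."""
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = rho ** 2 * (n - 2.0) / np.maximum(1.0 - rho ** 2, 1e-300)
        # survival of |t|: regularized incomplete beta, exact same form scipy uses
        p = special.betainc((n - 2.0) / 2.0, 0.5, (n - 2.0) / (n - 2.0 + t2))
    p = np.clip(p, _TINY, 1.0)
    return p


def spearman_assoc(
    dosage: np.ndarray, expr: np.ndarray, min_n: int = MIN_SAMPLES
) -> tuple[float, float, int]:
    """Spearman rank correlation between a dosage vector (NaN = missing,
    dropped pairwise) and an expression vector.

    Returns ``(rho, p_nominal, n_used)``; ``(nan, nan, n)`` when either
    vector has zero variance or fewer than ``min_n`` (default 10, the
    study's floor) paired observations remain.
    """
    dosage = np.asarray(dosage, dtype=float)
    expr = np.asarray(expr, dtype=float)
    mask = ~(np.isnan(dosage) | np.isnan(expr))
    n = int(mask.sum())
    if n < min_n:
        logger.debug("pair skipped: only %d paired observations", n)
        return (math.nan, math.nan, n)
    zx = _rank_standardize(dosage[mask])
    zy = _rank_standardize(expr[mask])
    if zx is None or zy is None:
        logger.debug("pair skipped: zero variance")
        return (math.nan, math.nan, n)
    rho = float(np.clip(zx @ zy, -1.0, 1.0))
    p = float(_p_from_rho(rho, n))
    return (rho, p, n)


# ---------------------------------------------------------------------------
# cis pair enumeration
# ---------------------------------------------------------------------------

def enumerate_cis_pairs(
    annot: pd.DataFrame,
    genotypes: GenotypeMatrix,
    window: int = DEFAULT_WINDOW,
    min_maf: float = DEFAULT_MAF,
    max_missing: float = DEFAULT_MISS,
) -> pd.DataFrame:
    """All SNP-probe pairs with |SNP - TSS| <= window on the same chromosome.

    Only eligible probes and SNPs passing the MAF/missingness filters are
    paired; distance is the signed genomic coordinate difference
    (SNP position - TSS), irrespective of strand. The window is a closed
    interval: a SNP exactly ``window`` bp away is included.
    """
    gm = genotypes.filter_snps(min_maf, max_missing)
    probes = annot[annot["eligible"]] if "eligible" in annot.columns else annot
    rows = []
    snps = gm.snps
    for chrom, chrom_snps in snps.groupby("chrom", sort=False):
        pos = chrom_snps["pos"].to_numpy()
        sub = probes[probes["chrom"].astype(str) == str(chrom)]
        for probe_id, prow in sub.iterrows():
            if pd.isna(prow["tss"]):
                logger.warning("probe %s has no TSS; skipped", probe_id)
                continue
            tss = int(prow["tss"])
            lo = np.searchsorted(pos, tss - window, side="left")
            hi = np.searchsorted(pos, tss + window, side="right")
            for j in range(lo, hi):
                rows.append(
                    (probe_id, prow["gene_id"], chrom_snps.index[j], str(chrom),
                     int(pos[j]), int(pos[j]) - tss)
                )
    return pd.DataFrame(
        rows, columns=["probe_id", "gene_id", "snp_id", "chrom", "pos", "distance"]
    )


# ---------------------------------------------------------------------------
# Permutation thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneThreshold:
    gene_id: str
    population: str
    alpha: float
    threshold_p: float
    n_perms: int


def _perm_min_p(
    dosage_block: np.ndarray,  # n x m (NaN = missing)
    expr: np.ndarray,  # n
    n_perms: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Minimum nominal p over the cis SNP block for each of n_perms
    permutations of the expression vector across individuals."""
    n, m = dosage_block.shape
    keys = rng.random((n_perms, n))
    idx = np.argsort(keys, axis=1)  # permutation index matrix

    complete = ~np.isnan(dosage_block).any(axis=0)
    min_p = np.full(n_perms, np.inf)

    if complete.any():
        Z = []
        for j in np.nonzero(complete)[0]:
            z = _rank_standardize(dosage_block[:, j])
            if z is not None:
                Z.append(z)
        if Z:
            Z = np.array(Z)  # m_c x n
            e = _rank_standardize(expr)
            if e is None:
                raise ValueError("expression vector has zero variance")
            Ep = e[idx]  # n_perms x n (permuted standardized ranks)
            rho = Z @ Ep.T  # m_c x n_perms
            max_abs = np.abs(rho).max(axis=0)
            min_p = np.minimum(min_p, _p_from_rho(max_abs, n))

    if (~complete).any():
        # Permuted expression restricted to a SNP's non-missing individuals
        # must be re-ranked (mid-ranks) within that subset. Permuting values
        # permutes their value-group codes, so within-subset mid-ranks
        # follow from per-permutation group counts (one bincount), with no
        # per-permutation sorting.
        _, codes = np.unique(expr, return_inverse=True)
        n_groups = int(codes.max()) + 1
        for j in np.nonzero(~complete)[0]:
            col = dosage_block[:, j]
            sub = ~np.isnan(col)
            n_sub = int(sub.sum())
            if n_sub < MIN_SAMPLES:
                continue
            z = _rank_standardize(col[sub])
            if z is None:
                continue
            Gsub = codes[idx[:, sub]]  # n_perms x n_sub group codes
            rows_flat = np.repeat(np.arange(n_perms), n_sub)
            width = n_groups + 1
            B = np.bincount(
                rows_flat * width + (Gsub.ravel() + 1), minlength=n_perms * width
            ).reshape(n_perms, width)
            cnt = np.take_along_axis(B, Gsub + 1, axis=1).astype(float)
            n_less = np.take_along_axis(np.cumsum(B, axis=1), Gsub, axis=1).astype(float)
            R = n_less + (cnt + 1.0) / 2.0  # within-subset mid-ranks
            # sum of mid-ranks is always n_sub(n_sub+1)/2; centering is
            # absorbed by zero-mean z, only the norm varies with ties
            mean = (n_sub + 1.0) / 2.0
            norms = np.sqrt((R ** 2).sum(axis=1) - n_sub * mean ** 2)
            ok = norms > 0
            rho = np.zeros(n_perms)
            rho[ok] = (R[ok] @ z) / norms[ok]
            min_p = np.minimum(min_p, _p_from_rho(np.abs(rho), n_sub))

    if not np.isfinite(min_p).all():
        min_p[~np.isfinite(min_p)] = 1.0
    return min_p


def permutation_threshold(
    min_p_values: np.ndarray, alpha: float, n_perms: int
) -> float:
    """The empirical alpha-quantile of permutation minimum p-values:
    the floor(alpha * n_perms)-th order statistic (1-based)."""
    if n_perms < 1.0 / alpha:
        raise ValueError(f"n_perms={n_perms} cannot resolve alpha={alpha}")
    k = int(math.floor(alpha * n_perms))
    return float(np.partition(np.asarray(min_p_values), k - 1)[k - 1])


# ---------------------------------------------------------------------------
# Per-population cis mapping
# ---------------------------------------------------------------------------

@dataclass
class CisMapResult:
    """Output of one population-level cis scan."""

    population: str
    associations: pd.DataFrame  # one row per tested SNP-probe pair
    thresholds: pd.DataFrame  # gene_id x alpha -> threshold_p
    best: pd.DataFrame  # per-gene most-significant pair + significance flags
    alphas: tuple[float, ...]
    n_genes_tested: int


def _best_row(sub: pd.DataFrame) -> pd.Series:
    """Most-significant SNP with deterministic tie-breaks: smallest p, then
    smallest |distance to TSS|, then lexicographic snp_id."""
    s = sub.assign(_absd=sub["distance"].abs())
    s = s.sort_values(["p_nominal", "_absd", "snp_id"], kind="stable")
    return s.iloc[0].drop("_absd")


def map_cis(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    annot: pd.DataFrame,
    alphas: tuple[float, ...] = (0.01, 0.001),
    n_perms: int = 10_000,
    window: int = DEFAULT_WINDOW,
    min_maf: float = DEFAULT_MAF,
    max_missing: float = DEFAULT_MISS,
    seed: int = 0,
    share_permutations: bool = False,
) -> CisMapResult:
    """Run the cis scan for one population.

    Expression columns must be per-individual and match ``genotypes.samples``
    (order is aligned here). Permutations are drawn per gene from one seeded
    stream by default; ``share_permutations`` reuses a single permutation
    matrix across genes (faster, preserves cross-gene correlation).
    """
    for a in alphas:
        if n_perms < 1.0 / a:
            raise ValueError(f"n_perms={n_perms} cannot resolve alpha={a}")
    common = [s for s in genotypes.samples if s in set(expr.values.columns)]
    if len(common) < MIN_SAMPLES:
        raise ValueError("fewer than 10 individuals shared between inputs")
    samp_idx = [genotypes.samples.index(s) for s in common]
    gm = genotypes.filter_snps(min_maf, max_missing)
    dosages = gm.dosages[samp_idx, :]
    evals = expr.values[common]

    pairs = enumerate_cis_pairs(annot, genotypes, window, min_maf, max_missing)
    pairs = pairs[pairs["probe_id"].isin(evals.index)]
    rng = np.random.default_rng(seed)

    assoc_rows = []
    thr_rows = []
    snp_pos = {s: i for i, s in enumerate(gm.snps.index)}
    for gene_id, gene_pairs in pairs.groupby("gene_id", sort=True):
        # a gene may be probed by several probes; permute each probe phenotype
        for probe_id, ppairs in gene_pairs.groupby("probe_id", sort=True):
            e = evals.loc[probe_id].to_numpy()
            cols = [snp_pos[s] for s in ppairs["snp_id"]]
            block = dosages[:, cols]
            obs = [spearman_assoc(block[:, j], e) for j in range(block.shape[1])]
            for (rho, p, n), (_, prow) in zip(obs, ppairs.iterrows()):
                assoc_rows.append(
                    (gene_id, probe_id, prow["snp_id"], prow["chrom"], prow["pos"],
                     prow["distance"], rho, p, n)
                )
            if np.nanstd(e) == 0:
                logger.warning("probe %s has zero expression variance; no thresholds", probe_id)
                continue
            # shared mode re-seeds per gene so every gene sees the same
            # permutation matrix (preserves cross-gene correlation)
            g_rng = np.random.default_rng(seed) if share_permutations else rng
            min_p = _perm_min_p(block, e, n_perms, g_rng)
            for a in alphas:
                thr_rows.append(
                    (gene_id, probe_id, a, permutation_threshold(min_p, a, n_perms), n_perms)
                )

    associations = pd.DataFrame(
        assoc_rows,
        columns=["gene_id", "probe_id", "snp_id", "chrom", "pos", "distance",
                 "rho", "p_nominal", "n_used"],
    )
    associations.insert(0, "population", genotypes.population)
    thresholds = pd.DataFrame(
        thr_rows, columns=["gene_id", "probe_id", "alpha", "threshold_p", "n_perms"]
    )

    best = call_significant_genes(associations, thresholds, alphas)
    n_genes = associations["gene_id"].nunique()
    return CisMapResult(
        population=genotypes.population,
        associations=associations,
        thresholds=thresholds,
        best=best,
        alphas=tuple(alphas),
        n_genes_tested=n_genes,
    )


def call_significant_genes(
    associations: pd.DataFrame,
    thresholds: pd.DataFrame,
    alphas: tuple[float, ...] = (0.01, 0.001),
) -> pd.DataFrame:
    """Per gene, the most-significant association and a significance flag
    per alpha (observed min p strictly below the permutation threshold)."""
    rows = []
    thr_idx = thresholds.set_index(["gene_id", "probe_id", "alpha"])["threshold_p"]
    valid = associations.dropna(subset=["p_nominal"])
    for (gene_id, probe_id), sub in valid.groupby(["gene_id", "probe_id"], sort=True):
        best = _best_row(sub)
        row = best.to_dict()
        for a in alphas:
            thr = thr_idx.get((gene_id, probe_id, a), np.nan)
            row[f"threshold_{a}"] = thr
            row[f"significant_{a}"] = bool(best["p_nominal"] < thr) if np.isfinite(thr) else False
        rows.append(row)
    if not rows:
        cols = list(associations.columns) + [
            c for a in alphas for c in (f"threshold_{a}", f"significant_{a}")
        ]
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows)


def significant_gene_sets(results: dict[str, CisMapResult], alpha: float) -> dict[str, set]:
    """Per-population sets of genes significant at ``alpha``."""
    out = {}
    for pop, res in results.items():
        flag = res.best[f"significant_{alpha}"]
        out[pop] = set(res.best.loc[flag, "gene_id"])
    return out


# ---------------------------------------------------------------------------
# FDR estimators
# ---------------------------------------------------------------------------

def fdr_expected(n_genes_tested: int, alpha: float, n_significant: int) -> float:
    """Expected-count FDR: (genes tested x per-gene threshold) / significant,
    capped at 1. NaN when nothing is significant."""
    if n_significant < 1:
        return math.nan
    return min(1.0, (n_genes_tested * alpha) / n_significant)


def fdr_replication(
    discovery_best: pd.DataFrame,
    other_associations: dict[str, pd.DataFrame],
    p_replication: float = 0.005,
) -> tuple[float, int, int, int]:
    """Replication-based FDR for one discovery population.

    ``discovery_best`` holds the per-gene most-significant pairs of the
    discovery population's significant genes (columns probe_id, snp_id,
    rho). A gene replicates when the same SNP-probe pair reaches nominal
    p < ``p_replication`` with the same rho sign in at least one other
    population. Returns (fdr, n_replicated, n_total, n_untested) where
    untested genes (best SNP absent everywhere else) count as
    non-replicated but are tallied separately.
    """
    n_total = len(discovery_best)
    if n_total == 0:
        return (math.nan, 0, 0, 0)
    lookups = {
        pop: df.set_index(["probe_id", "snp_id"])
        for pop, df in other_associations.items()
    }
    n_rep = 0
    n_untested = 0
    for _, row in discovery_best.iterrows():
        key = (row["probe_id"], row["snp_id"])
        tested = False
        replicated = False
        for pop, lut in lookups.items():
            if key not in lut.index:
                continue
            hit = lut.loc[key]
            if isinstance(hit, pd.DataFrame):
                hit = hit.iloc[0]
            if not np.isfinite(hit["p_nominal"]):
                continue
            tested = True
            if hit["p_nominal"] < p_replication and np.sign(hit["rho"]) == np.sign(row["rho"]):
                replicated = True
                break
        if not tested:
            n_untested += 1
        if replicated:
            n_rep += 1
    if n_untested:
        logger.info("%d discovery genes had their best SNP untyped in all other populations",
                    n_untested)
    return (1.0 - n_rep / n_total, n_rep, n_total, n_untested)


# ---------------------------------------------------------------------------
# Stepwise conditional mapping
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    gene_id: str
    population: str
    independent_snps: list[tuple[str, int, float]]  # (snp_id, step, p_at_step)


def stepwise_independent(
    gene_id: str,
    significant_snps: pd.DataFrame,  # columns snp_id, distance (initial significant set)
    expr: np.ndarray,
    genotypes: GenotypeMatrix,
    threshold_p: float,
    population: str | None = None,
) -> StepwiseResult:
    """Iteratively declare the most-significant SNP independent, regress its
    additive dosage effect out of expression, and re-test the remaining
    initially-significant SNPs against the original permutation threshold.

    Terminates when no remaining SNP passes (strictly below) the threshold;
    a SNP perfectly collinear with an already-declared one can never pass
    after residualization.
    """
    pop = population or genotypes.population
    remaining = significant_snps.copy()
    y = np.asarray(expr, dtype=float).copy()
    snp_pos = {s: i for i, s in enumerate(genotypes.snps.index)}
    independent: list[tuple[str, int, float]] = []
    step = 0
    while not remaining.empty:
        recs = []
        for _, row in remaining.iterrows():
            d = genotypes.dosages[:, snp_pos[row["snp_id"]]]
            rho, p, n = spearman_assoc(d, y)
            recs.append((row["snp_id"], abs(row["distance"]), rho, p))
        rec = pd.DataFrame(recs, columns=["snp_id", "absd", "rho", "p"]).dropna(subset=["p"])
        if rec.empty:
            break
        rec = rec.sort_values(["p", "absd", "snp_id"], kind="stable")
        top = rec.iloc[0]
        if not (top["p"] < threshold_p):
            break
        step += 1
        independent.append((str(top["snp_id"]), step, float(top["p"])))
        # regress out the additive effect of the chosen SNP (mean-imputed dosage)
        d = genotypes.dosages[:, snp_pos[top["snp_id"]]].copy()
        d = np.where(np.isnan(d), np.nanmean(d), d)
        X = np.column_stack([np.ones_like(d), d])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        y = y - X @ beta
        remaining = remaining[remaining["snp_id"] != top["snp_id"]]
    return StepwiseResult(gene_id=gene_id, population=pop, independent_snps=independent)


def stepwise_all(
    result: CisMapResult,
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    alpha: float = 0.01,
) -> list[StepwiseResult]:
    """Stepwise conditional mapping for every gene significant at ``alpha``
    with at least two significant cis SNPs."""
    out = []
    thr = result.thresholds[result.thresholds["alpha"] == alpha].set_index(
        ["gene_id", "probe_id"]
    )["threshold_p"]
    sig_best = result.best[result.best[f"significant_{alpha}"]]
    common = [s for s in genotypes.samples if s in set(expr.values.columns)]
    samp_idx = [genotypes.samples.index(s) for s in common]
    gm = GenotypeMatrix(
        population=genotypes.population,
        samples=common,
        snps=genotypes.snps,
        dosages=genotypes.dosages[samp_idx, :],
    )
    for _, row in sig_best.iterrows():
        gene_id, probe_id = row["gene_id"], row["probe_id"]
        t = thr.get((gene_id, probe_id), np.nan)
        sub = result.associations[
            (result.associations["gene_id"] == gene_id)
            & (result.associations["probe_id"] == probe_id)
            & (result.associations["p_nominal"] < t)
        ]
        if len(sub) < 2:
            continue
        y = expr.values.loc[probe_id, common].to_numpy()
        out.append(
            stepwise_independent(gene_id, sub[["snp_id", "distance"]], y, gm, float(t))
        )
    return out
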