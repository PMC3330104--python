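"""Population differentiation of expression (V_ST) and allele frequencies
(Hudson F_ST), and the Fisher-exact / Fisher-combined term-enrichment
procedures built on the top-differentiated probes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# V_ST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VstResult:
    probe_id: str | None
    pop_pair: tuple[str, str]
    v1: float
    v2: float
    n1: int
    n2: int
    v_s: float
    v_t: float
    vst: float


def vst(
    expr1: np.ndarray,
    expr2: np.ndarray,
    probe_id: str | None = None,
    pop_pair: tuple[str, str] = ("pop1", "pop2"),
) -> VstResult:
    """V_ST = (V_T - V_S) / V_T for one probe in two populations.

    V_S is the within-population variance weighted by sample size,
    (V1*n1 + V2*n2)/(n1+n2); V_T the variance over the pooled samples.
    Variances use the denominator-n (maximum-likelihood) convention so two
    identical populations give exactly 0; the result is clamped to [0, 1]
    and defined as 0 when V_T = 0.
    """
    x1 = np.asarray(expr1, dtype=float)
    x2 = np.asarray(expr2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each population needs >= 2 samples")
    v1 = float(np.var(x1))
    v2 = float(np.var(x2))
    v_s = (v1 * n1 + v2 * n2) / (n1 + n2)
    v_t = float(np.var(np.concatenate([x1, x2])))
    value = 0.0 if v_t == 0.0 else float(np.clip((v_t - v_s) / v_t, 0.0, 1.0))
    if value < 1e-12:  # identical populations must give exactly 0
        value = 0.0
    return VstResult(probe_id, tuple(pop_pair), v1, v2, n1, n2, v_s, v_t, value)


def vst_scan(
    expr: ExpressionMatrix, high_cutoff: float = 0.2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """V_ST for every probe and every pair of populations.

    Returns ``(table, summary)``: the full per-probe table and a per-pair
    summary (count of probes with V_ST > ``high_cutoff``, median, mean).
    Population pairs with fewer than 2 samples on either side are skipped
    with a warning.
    """
    meta = expr.sample_meta
    pops = sorted(meta["population"].unique())
    vals = expr.values
    cols_by_pop = {
        p: [c for c in vals.columns if meta.loc[c, "population"] == p] for p in pops
    }
    rows = []
    summary_rows = []
    for p1, p2 in itertools.combinations(pops, 2):
        c1, c2 = cols_by_pop[p1], cols_by_pop[p2]
        if len(c1) < 2 or len(c2) < 2:
            logger.warning("pair (%s, %s) skipped: fewer than 2 samples", p1, p2)
            continue
        X1 = vals[c1].to_numpy()
        X2 = vals[c2].to_numpy()
        n1, n2 = X1.shape[1], X2.shape[1]
        v1 = X1.var(axis=1)
        v2 = X2.var(axis=1)
        v_s = (v1 * n1 + v2 * n2) / (n1 + n2)
        pooled = np.concatenate([X1, X2], axis=1)
        v_t = pooled.var(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(v_t == 0.0, 0.0, np.clip((v_t - v_s) / np.maximum(v_t, 1e-300), 0, 1))
            v[v < 1e-12] = 0.0
        for probe, a, b, s, t, val in zip(vals.index, v1, v2, v_s, v_t, v):
            rows.append((probe, p1, p2, a, b, s, t, val))
        summary_rows.append(
            (p1, p2, int((v > high_cutoff).sum()), float(np.median(v)), float(np.mean(v)))
        )
    table = pd.DataFrame(
        rows, columns=["probe_id", "pop1", "pop2", "v1", "v2", "v_s", "v_t", "vst"]
    )
    summary = pd.DataFrame(
        summary_rows, columns=["pop1", "pop2", f"n_vst_gt_{high_cutoff}", "median", "mean"]
    )
    return table, summary


def top_vst_probes(table: pd.DataFrame, pop1: str, pop2: str, frac: float = 0.05) -> set[str]:
    """Top ``frac`` of probes ranked by V_ST for one population pair
    (ties broken by probe_id for determinism)."""
    sub = table[(table["pop1"] == pop1) & (table["pop2"] == pop2)]
    if sub.empty:
        sub = table[(table["pop1"] == pop2) & (table["pop2"] == pop1)]
    k = max(1, int(math.floor(frac * len(sub))))
    ordered = sub.sort_values(["vst", "probe_id"], ascending=[False, True], kind="stable")
    return set(ordered["probe_id"].head(k))


# ---------------------------------------------------------------------------
# Hudson F_ST
# ---------------------------------------------------------------------------

def fst_pairwise(
    p1: np.ndarray,
    p2: np.ndarray,
    n1: np.ndarray | int | None = None,
    n2: np.ndarray | int | None = None,
    window: int = 10_000,
) -> tuple[pd.Series, float]:
    """Hudson-style F_ST from per-SNP allele frequencies.

    With haploid sample sizes ``n1``/``n2`` the per-SNP numerator carries
    the finite-sample correction; without them the infinite-sample form
    (p1-p2)^2 / (p1(1-p2) + p2(1-p1)) is used. SNPs monomorphic in both
    populations are skipped. Estimates are ratio-of-averages per window of
    ``window`` consecutive SNPs, then averaged across windows. Returns
    (per-window values, genome average).
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2
    if n1 is not None:
        n1 = np.broadcast_to(np.asarray(n1, dtype=float), p1.shape)
        n2 = np.broadcast_to(np.asarray(n2, dtype=float), p2.shape)
        num = num - p1 * (1 - p1) / np.maximum(n1 - 1, 1) - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0  # drop SNPs monomorphic (same fixed allele) in both
    num, den = num[keep], den[keep]
    if len(num) == 0:
        return pd.Series(dtype=float), math.nan
    starts = np.arange(0, len(num), window)
    win_vals = []
    for s in starts:
        e = min(s + window, len(num))
        d = den[s:e].sum()
        win_vals.append(num[s:e].sum() / d if d > 0 else np.nan)
    win = pd.Series(win_vals, index=starts, name="fst")
    return win, float(np.nanmean(win.to_numpy()))


def fst_from_genotypes(
    gm1: GenotypeMatrix, gm2: GenotypeMatrix, window: int = 10_000
) -> tuple[pd.Series, float]:
    """Hudson F_ST between two populations, from genotype matrices sharing
    the same SNP set (frequencies and haploid counts from non-missing
    calls)."""
    if not gm1.snps.index.equals(gm2.snps.index):
        raise ValueError("genotype matrices must share the same SNPs")
    f1 = gm1.allele_freq().to_numpy()
    f2 = gm2.allele_freq().to_numpy()
    n1 = 2.0 * (~np.isnan(gm1.dosages)).sum(axis=0)
    n2 = 2.0 * (~np.isnan(gm2.dosages)).sum(axis=0)
    ok = (n1 >= 4) & (n2 >= 4) & ~np.isnan(f1) & ~np.isnan(f2)
    return fst_pairwise(f1[ok], f2[ok], n1[ok], n2[ok], window)


def fst_distance_matrix(
    genotypes: dict[str, GenotypeMatrix], window: int = 10_000
) -> pd.DataFrame:
    """Symmetric matrix of genome-average pairwise Hudson F_ST (negative
    averages floored at 0 so the matrix is a valid distance input)."""
    pops = sorted(genotypes)
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for p1, p2 in itertools.combinations(pops, 2):
        _, avg = fst_from_genotypes(genotypes[p1], genotypes[p2], window)
        avg = max(avg, 0.0)
        mat.loc[p1, p2] = mat.loc[p2, p1] = avg
    return mat


# ---------------------------------------------------------------------------
# Term enrichment
# ---------------------------------------------------------------------------

@dataclass
class TermEnrichment:
    term_id: str
    n_top_in_term: int
    n_top: int
    n_term: int
    n_universe: int
    p_one_sided: float


def term_enrichment(
    top_set: set[str],
    term_map: dict[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of each term in the top set.

    The 2x2 table is {in top set} x {annotated to term} over ``universe``;
    terms with no annotated genes in the universe are skipped.
    """
    top = top_set & universe
    rows = []
    for term_id in sorted(term_map):
        members = term_map[term_id] & universe
        if not members:
            logger.debug("term %s has no annotated genes in universe; skipped", term_id)
            continue
        a = len(top & members)
        b = len(top) - a
        c = len(members) - a
        d = len(universe) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((term_id, a, len(top), len(members), len(universe), float(p)))
    return pd.DataFrame(
        rows,
        columns=["term_id", "n_top_in_term", "n_top", "n_term", "n_universe", "p_one_sided"],
    )


def fisher_combine(p_values) -> float:
    """Fisher's combined probability: X = -2 sum(ln p) against chi-square
    with 2k degrees of freedom. Zero p-values are clamped to the smallest
    positive float with a warning."""
    ps = np.asarray(list(p_values), dtype=float)
    if len(ps) == 0:
        raise ValueError("need at least one p-value")
    if (ps <= 0).any():
        logger.warning("p-value of 0 clamped to smallest positive float")
        ps = np.maximum(ps, np.finfo(float).tiny)
    if (ps > 1).any():
        raise ValueError("p-values must be in (0, 1]")
    x = -2.0 * np.log(ps).sum()
    return float(stats.chi2.sf(x, 2 * len(ps)))


def _combine_over_pairs(
    enrichments: dict[tuple[str, str], pd.DataFrame], pairs: list[tuple[str, str]]
) -> pd.Series:
    """Per-term Fisher-combined p over the given population pairs."""
    frames = [
        enrichments[pr].set_index("term_id")["p_one_sided"] for pr in pairs
        if pr in enrichments
    ]
    if not frames:
        return pd.Series(dtype=float)
    wide = pd.concat(frames, axis=1)
    return wide.apply(lambda row: fisher_combine(row.dropna()), axis=1)


def _pairs_with(enrichments, pop, exclude=()):
    return [pr for pr in enrichments if pop in pr and not any(e in pr for e in exclude)]


def _pairs_without(enrichments, pop):
    return [pr for pr in enrichments if pop not in pr]


def population_specific_terms(
    enrichments: dict[tuple[str, str], pd.DataFrame],
    focal: str,
    significance: float = 0.05,
    top_n: int = 10,
) -> pd.DataFrame:
    """Terms differentiated specifically in the focal population.

    Per term, combine p-values over all pairs involving the focal
    population and, separately, over all pairs not involving it; terms
    whose non-focal combined p is also below ``significance`` are filtered
    out, and the top ``top_n`` by focal combined p are reported.
    """
    comb_focal = _combine_over_pairs(enrichments, _pairs_with(enrichments, focal))
    comb_other = _combine_over_pairs(enrichments, _pairs_without(enrichments, focal))
    df = pd.DataFrame({"combined_focal": comb_focal})
    df["combined_other"] = comb_other.reindex(df.index)
    surviving = df[~(df["combined_other"] < significance)].sort_values(
        ["combined_focal", "combined_other"]
    )
    if len(surviving) < top_n:
        logger.info("only %d terms survive the specificity filter for %s",
                    len(surviving), focal)
    return surviving.head(top_n).reset_index().rename(columns={"index": "term_id"})


def cross_population_informativeness(
    enrichments: dict[tuple[str, str], pd.DataFrame],
    pop_a: str,
    pop_b: str,
    significance: float = 0.05,
) -> dict:
    """Does differentiation in population A predict differentiation in B?

    Terms significant in A-vs-rest (pairs involving A, excluding B) are
    looked up in the B-vs-rest (excluding A) combined p-values; reported
    are the fraction of those terms below 0.05 in B and a one-sided
    rank-sum statistic against the remaining terms.
    """
    comb_a = _combine_over_pairs(enrichments, _pairs_with(enrichments, pop_a, exclude=(pop_b,)))
    comb_b = _combine_over_pairs(enrichments, _pairs_with(enrichments, pop_b, exclude=(pop_a,)))
    sig_terms = comb_a.index[comb_a < significance]
    if len(sig_terms) == 0:
        return {"n_significant_a": 0, "fraction_below_05": math.nan,
                "ranksum_p": math.nan}
    in_b = comb_b.reindex(sig_terms).dropna()
    rest = comb_b.drop(index=[t for t in sig_terms if t in comb_b.index])
    frac = float((in_b < 0.05).mean()) if len(in_b) else math.nan
    if len(in_b) and len(rest):
        _, rank_p = stats.mannwhitneyu(in_b, rest, alternative="less")
    else:
        rank_p = math.nan
    return {
        "n_significant_a": int(len(sig_terms)),
        "fraction_below_05": frac,
        "ranksum_p": float(rank_p),
    }
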