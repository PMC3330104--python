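"""Cross-population eQTL sharing: pairwise counts, allelic-direction
concordance, homozygote fold-change effect sizes, pi1 replication
enrichment, TSS-distance-by-sharing, multi-gene eQTL clusters, and the
F_ST-tree parsimony sharing analysis.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

logger = logging.getLogger(__name__)


def percent(k: int, n: int, ndigits: int = 0) -> float:
    """k/n as a percentage rounded to ``ndigits`` decimals (the rounding
    convention used in the study's reported sharing rates)."""
    if n == 0:
        return math.nan
    return round(100.0 * k / n, ndigits) if ndigits else float(round(100.0 * k / n))


# ---------------------------------------------------------------------------
# Sharing counts
# ---------------------------------------------------------------------------

@dataclass
class SharingSummary:
    pair_counts: pd.DataFrame  # pop x pop shared significant-gene counts
    histogram: pd.Series  # n_shared (1..K) -> gene count
    n_nonredundant: int
    n_shared_ge2: int
    n_shared_all: int
    pct_ge2: float
    pct_all: float


def sharing_matrix(significant_sets: dict[str, set[str]]) -> SharingSummary:
    """Pairwise shared-gene counts and the sharing-level histogram from
    per-population significant-gene sets."""
    pops = sorted(significant_sets)
    mat = pd.DataFrame(0, index=pops, columns=pops, dtype=int)
    for p1, p2 in itertools.combinations(pops, 2):
        n = len(significant_sets[p1] & significant_sets[p2])
        mat.loc[p1, p2] = mat.loc[p2, p1] = n
    for p in pops:
        mat.loc[p, p] = len(significant_sets[p])
    counts = Counter()
    for p in pops:
        for g in significant_sets[p]:
            counts[g] += 1
    hist = Counter(counts.values())
    histogram = pd.Series(
        {k: hist.get(k, 0) for k in range(1, len(pops) + 1)}, name="n_genes"
    )
    n_total = len(counts)
    n_ge2 = sum(v for k, v in hist.items() if k >= 2)
    n_all = hist.get(len(pops), 0)
    return SharingSummary(
        pair_counts=mat,
        histogram=histogram,
        n_nonredundant=n_total,
        n_shared_ge2=n_ge2,
        n_shared_all=n_all,
        pct_ge2=percent(n_ge2, n_total),
        pct_all=percent(n_all, n_total),
    )


def sharing_level(significant_sets: dict[str, set[str]]) -> pd.Series:
    """Per-gene count of populations in which the gene is significant."""
    counts = Counter()
    for genes in significant_sets.values():
        for g in genes:
            counts[g] += 1
    return pd.Series(counts, name="n_shared").sort_index()


# ---------------------------------------------------------------------------
# Allelic direction concordance
# ---------------------------------------------------------------------------

def harmonize_alleles(genotypes: dict[str, "GenotypeMatrix"]) -> dict:
    """Anchor every population's dosage to the alphabetically smaller
    allele string; SNPs whose allele pair differs across populations are
    dropped everywhere (with a log entry).

    Returns a new dict of GenotypeMatrix (inputs unmodified).
    """
    from .containers import GenotypeMatrix

    pops = list(genotypes)
    pairsets = {}
    dropped: set[str] = set()
    for pop in pops:
        snps = genotypes[pop].snps
        for snp_id, row in snps.iterrows():
            key = frozenset((str(row["ref"]), str(row["alt"])))
            if snp_id in pairsets and pairsets[snp_id] != key:
                dropped.add(snp_id)
            pairsets[snp_id] = key
    if dropped:
        logger.info("%d SNPs dropped: allele pairs differ across populations", len(dropped))
    out = {}
    for pop in pops:
        gm = genotypes[pop]
        keep = ~gm.snps.index.isin(dropped)
        snps = gm.snps.loc[keep].copy()
        dos = gm.dosages[:, keep].copy()
        # dosage counts the alphabetically smaller allele
        flip = snps["alt"].astype(str) > snps["ref"].astype(str)
        dos[:, flip.to_numpy()] = 2.0 - dos[:, flip.to_numpy()]
        new_ref = snps[["ref", "alt"]].min(axis=1)
        new_alt = snps[["ref", "alt"]].max(axis=1)
        snps["ref"], snps["alt"] = new_alt, new_ref  # dosage allele stored as alt
        out[pop] = GenotypeMatrix(
            population=pop, samples=list(gm.samples), snps=snps, dosages=dos
        )
    return out


def direction_concordance(
    best_1: pd.DataFrame, best_2: pd.DataFrame
) -> tuple[float, int]:
    """Proportion of SNP-probe pairs significant in both populations whose
    rho has the same sign (pairs with rho = 0 excluded). Inputs are the two
    populations' per-gene best tables restricted to significant rows, with
    columns probe_id, snp_id, rho; alleles must already be harmonized.

    Returns (concordance, n_shared_pairs); (nan, 0) with no shared pairs.
    """
    m = best_1.merge(best_2, on=["probe_id", "snp_id"], suffixes=("_1", "_2"))
    m = m[(m["rho_1"] != 0) & (m["rho_2"] != 0)]
    if m.empty:
        return (math.nan, 0)
    same = np.sign(m["rho_1"]) == np.sign(m["rho_2"])
    return (float(same.mean()), int(len(m)))


# ---------------------------------------------------------------------------
# Effect size
# ---------------------------------------------------------------------------

def homozygote_fold_change(
    expr: np.ndarray, dosage: np.ndarray, min_class: int = 2
) -> float:
    """Absolute log2 fold-change between homozygote class medians,
    |median(expr | dosage=2) - median(expr | dosage=0)|.

    NaN (with a debug log) when either homozygote class has fewer than
    ``min_class`` individuals."""
    expr = np.asarray(expr, dtype=float)
    dosage = np.asarray(dosage, dtype=float)
    hom0 = expr[dosage == 0]
    hom2 = expr[dosage == 2]
    if len(hom0) < min_class or len(hom2) < min_class:
        logger.debug("fold-change undefined: homozygote classes %d / %d",
                     len(hom0), len(hom2))
        return math.nan
    return float(abs(np.median(hom2) - np.median(hom0)))


def effect_size_vs_sharing(
    fold_changes: pd.Series, n_shared: pd.Series, min_genes: int = 30
) -> tuple[float, float]:
    """Pearson correlation (and p) of per-gene effect size with the number
    of populations sharing the eQTL. NaN when fewer than ``min_genes``
    genes have a defined fold-change or either variable is degenerate."""
    df = pd.DataFrame({"fc": fold_changes, "k": n_shared}).dropna()
    if len(df) < min_genes:
        logger.warning("effect-size-vs-sharing: only %d genes with fold-change", len(df))
        return (math.nan, math.nan)
    if df["fc"].std() == 0 or df["k"].std() == 0:
        return (math.nan, math.nan)
    r, p = stats.pearsonr(df["fc"], df["k"])
    return (float(r), float(p))


# ---------------------------------------------------------------------------
# pi1 replication enrichment
# ---------------------------------------------------------------------------

def pi1_estimate(p_values, lambda_: float = 0.5) -> float:
    """Storey-style estimate of the fraction of true positives among
    replication p-values: pi0 = #{p > lambda} / ((1 - lambda) m), clamped
    to [0, 1]; pi1 = 1 - pi0."""
    if not (0.0 < lambda_ < 1.0):
        raise ValueError("lambda must be in (0, 1)")
    ps = np.asarray(list(p_values), dtype=float)
    ps = ps[np.isfinite(ps)]
    m = len(ps)
    if m == 0:
        return math.nan
    if m < 50:
        logger.warning("pi1 estimated from only %d p-values; unstable", m)
    pi0 = (ps > lambda_).sum() / ((1.0 - lambda_) * m)
    return float(1.0 - min(max(pi0, 0.0), 1.0))


def replication_p_values(
    discovery_best: pd.DataFrame, other_associations: pd.DataFrame
) -> np.ndarray:
    """Nominal p-values of the discovery population's best SNP-probe pairs
    looked up in another population's association table."""
    lut = other_associations.set_index(["probe_id", "snp_id"])["p_nominal"]
    out = []
    for _, row in discovery_best.iterrows():
        key = (row["probe_id"], row["snp_id"])
        if key in lut.index:
            v = lut.loc[key]
            v = v.iloc[0] if isinstance(v, pd.Series) else v
            if np.isfinite(v):
                out.append(float(v))
    return np.array(out)


# ---------------------------------------------------------------------------
# TSS distance by sharing level
# ---------------------------------------------------------------------------

def tss_distance_by_sharing(
    best: pd.DataFrame, n_shared: pd.Series
) -> tuple[pd.DataFrame, float]:
    """|distance to TSS| distributions of best SNPs stratified by the
    number of populations sharing the gene's eQTL.

    ``best`` needs columns gene_id and distance (one row per significant
    gene per population). Returns (per-level quantile table, trend rho =
    Spearman correlation of the median |distance| with sharing level;
    NaN with fewer than 2 levels)."""
    df = best.copy()
    df["n_shared"] = df["gene_id"].map(n_shared)
    df = df.dropna(subset=["n_shared"])
    df["absd"] = df["distance"].abs()
    rows = []
    for level, sub in df.groupby("n_shared", sort=True):
        q = np.percentile(sub["absd"], [25, 50, 75])
        rows.append((int(level), len(sub), q[0], q[1], q[2]))
    table = pd.DataFrame(rows, columns=["n_shared", "n", "q25", "median", "q75"])
    if len(table) < 2 or table["median"].nunique() <= 1:
        return table, math.nan
    rho, _ = stats.spearmanr(table["n_shared"], table["median"])
    return table, float(rho)


# ---------------------------------------------------------------------------
# Multi-gene eQTL clusters
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    clusters: pd.DataFrame  # population, snp_id, n_genes, genes
    replicated_snps: set[str]  # cluster SNPs observed in >= 2 populations
    distance_ranksum_p: float  # cluster |distance| > single-gene |distance|


def multi_gene_clusters(best_per_pop: dict[str, pd.DataFrame]) -> ClusterResult:
    """Clusters of >= 2 genes whose most-significant eQTL SNP is identical,
    per population; clusters replicated in >= 2 populations; and a
    one-sided rank-sum comparison of cluster-SNP |TSS distance| against
    single-gene eQTL distances."""
    rows = []
    snp_pops: dict[str, set[str]] = {}
    cluster_d, single_d = [], []
    for pop, best in best_per_pop.items():
        for snp_id, sub in best.groupby("snp_id"):
            if len(sub) >= 2:
                rows.append((pop, snp_id, len(sub), ",".join(sorted(sub["gene_id"]))))
                snp_pops.setdefault(snp_id, set()).add(pop)
                cluster_d.extend(sub["distance"].abs().tolist())
            else:
                single_d.extend(sub["distance"].abs().tolist())
    clusters = pd.DataFrame(rows, columns=["population", "snp_id", "n_genes", "genes"])
    replicated = {s for s, ps in snp_pops.items() if len(ps) >= 2}
    if cluster_d and single_d:
        _, p = stats.mannwhitneyu(cluster_d, single_d, alternative="greater")
    else:
        p = math.nan
    return ClusterResult(clusters, replicated, float(p))


# ---------------------------------------------------------------------------
# Parsimony sharing on the F_ST tree
# ---------------------------------------------------------------------------

def build_population_tree(fst_matrix: pd.DataFrame) -> TreeNode:
    """Neighbour-joining tree from the pairwise F_ST distance matrix,
    midpoint-rooted so that "smallest covering clade" is well defined."""
    pops = list(fst_matrix.index)
    dm = DistanceMatrix(fst_matrix.to_numpy(), ids=pops)
    tree = nj(dm)
    tree = tree.root_at_midpoint()
    for i, node in enumerate(tree.traverse(include_self=True)):
        if not node.is_tip() and not node.name:
            node.name = f"node{i}"
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def build_gene_population_sets(
    discovery_sets: dict[str, set[str]],
    lenient_sets: dict[str, set[str]],
    seed: int = 0,
) -> dict[str, frozenset[str]]:
    """Per-gene population sets for the parsimony analysis: one discovery
    association per gene chosen at random (fixed seed), extended by every
    population where the gene passes the lenient (alpha 0.1) permutation
    threshold."""
    rng = np.random.default_rng(seed)
    gene_pops: dict[str, list[str]] = {}
    for pop in sorted(discovery_sets):
        for g in discovery_sets[pop]:
            gene_pops.setdefault(g, []).append(pop)
    out = {}
    for g in sorted(gene_pops):
        pops = sorted(gene_pops[g])
        chosen = pops[rng.integers(len(pops))]
        members = {chosen}
        for pop in sorted(lenient_sets):
            if g in lenient_sets[pop]:
                members.add(pop)
        out[g] = frozenset(members)
    return out


def _assign_node(tree: TreeNode, popset: frozenset[str], tip_cache: dict) -> str:
    """Smallest clade covering the population set (root when no clade
    does; a singleton maps to its leaf)."""
    pops = sorted(popset)
    if len(pops) == 1:
        return pops[0]
    lca = tree.lca([tip_cache[p] for p in pops])
    return lca.name


def parsimony_sharing(
    tree: TreeNode,
    gene_population_sets: dict[str, frozenset[str]],
    n_random: int = 100,
    seed: int = 0,
    mode: str = "labels",
    percentile: float = 95.0,
) -> pd.DataFrame:
    """Assign each gene's shared-population set to the smallest covering
    tree node and flag nodes with more assignments than expected under a
    randomization null.

    ``mode='labels'`` permutes the tree's leaf labels (equivalently,
    applies a random population bijection to every gene's set);
    ``mode='sets'`` redraws each gene's set at the same size uniformly over
    populations. A node is enriched when its observed count exceeds the
    given percentile of the ``n_random`` null counts.
    """
    if mode not in ("labels", "sets"):
        raise ValueError("mode must be 'labels' or 'sets'")
    rng = np.random.default_rng(seed)
    pops = sorted(t.name for t in tree.tips())
    tip_cache = {t.name: t for t in tree.tips()}
    node_names = [n.name for n in tree.traverse(include_self=True)]

    def count_assignments(sets_iter) -> Counter:
        c: Counter = Counter()
        for s in sets_iter:
            c[_assign_node(tree, s, tip_cache)] += 1
        return c

    observed = count_assignments(gene_population_sets.values())
    null_counts = {name: np.zeros(n_random) for name in node_names}
    sets = list(gene_population_sets.values())
    for r in range(n_random):
        if mode == "labels":
            perm = dict(zip(pops, rng.permutation(pops)))
            rand_sets = [frozenset(perm[p] for p in s) for s in sets]
        else:
            rand_sets = [
                frozenset(rng.choice(pops, size=len(s), replace=False).tolist())
                for s in sets
            ]
        c = count_assignments(rand_sets)
        for name in node_names:
            null_counts[name][r] = c.get(name, 0)

    rows = []
    for node in tree.traverse(include_self=True):
        name = node.name
        obs = observed.get(name, 0)
        null = null_counts[name]
        cutoff = float(np.percentile(null, percentile))
        rows.append(
            (name, ",".join(sorted(t.name for t in node.tips(include_self=True))),
             obs, cutoff, bool(obs > cutoff))
        )
    df = pd.DataFrame(
        rows, columns=["node", "tip_set", "observed", f"null_p{int(percentile)}", "enriched"]
    )
    total_assigned = sum(observed.values())
    if total_assigned != len(gene_population_sets):
        raise AssertionError("node assignment lost eQTLs")  # conservation invariant
    return df
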