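"""Synthetic multi-population genotype + expression generator with known truth.

Emulates an 8-population lymphoblastoid expression study: Balding-Nichols
allele-frequency drift around a shared ancestral pool (with continental
"pool" structure and per-individual admixture), Hardy-Weinberg genotype
draws with missing calls, and a log2 expression model with planted cis-eQTLs
whose effect sizes decay with distance to the transcription start site,
hidden global confounding factors, per-individual noise and two replicate
hybridizations per individual.

All randomness flows through one ``numpy.random.Generator`` seeded per run;
fixed seed gives byte-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population.

    ``divergence`` is the Balding-Nichols drift coefficient F in [0, 1)
    relative to its ancestral pool. Non-admixed populations name a single
    pool via ``ancestry``; admixed populations instead give
    ``admixture_props``, mixing weights over pools that must sum to 1.
    """

    name: str
    n_individuals: int
    divergence: float = 0.01
    ancestry: str | None = None
    admixture_props: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_individuals < 2:
            raise ValueError(f"{self.name}: n_individuals must be >= 2")
        if not (0.0 <= self.divergence < 1.0):
            raise ValueError(f"{self.name}: divergence must be in [0, 1)")
        if self.admixture_props is not None:
            total = sum(self.admixture_props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{self.name}: admixture_props sum to {total}, expected 1"
                )
        if self.ancestry is None and self.admixture_props is None:
            raise ValueError(f"{self.name}: needs ancestry or admixture_props")

    @property
    def dominant_pool(self) -> str:
        if self.ancestry is not None:
            return self.ancestry
        return max(self.admixture_props, key=self.admixture_props.get)


@dataclass(frozen=True)
class PlantedEqtl:
    """Ground truth for one planted cis-eQTL."""

    gene_id: str
    snp_id: str
    beta: float  # additive effect on log2 expression per dosage-allele copy
    shared_in: frozenset[str]  # populations in which the eQTL is present
    tss_distance: int  # signed bp, SNP position - TSS

    def __post_init__(self) -> None:
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")
        if not self.shared_in:
            raise ValueError("shared_in must be non-empty")


@dataclass
class SyntheticTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    planted_eqtls: list[PlantedEqtl]
    hidden_factor_loadings: pd.DataFrame  # factor x probe
    hidden_factor_scores: pd.DataFrame  # individual x factor
    snp_in_probe_ids: set[str]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [e.gene_id for e in self.planted_eqtls],
                "snp_id": [e.snp_id for e in self.planted_eqtls],
                "beta": [e.beta for e in self.planted_eqtls],
                "shared_in": [",".join(sorted(e.shared_in)) for e in self.planted_eqtls],
                "tss_distance": [e.tss_distance for e in self.planted_eqtls],
            }
        )


@dataclass(frozen=True)
class TruthConfig:
    """Planted-effect and confounder settings for expression simulation."""

    n_eqtls: int = 50
    beta_at_tss: float = 1.5  # |beta| for a SNP sitting on the TSS
    half_distance: float = 20_000.0  # |beta| halves every this many bp
    distance_scale: float = 50_000.0  # mean of |tss_distance| (exponential)
    max_distance: float = 1_000_000.0
    beta_min: float = 0.25  # floor on decayed |beta|
    absence_mode: str = "freq"  # "freq" (default) or "beta_zero"
    sharing_mode: str = "clade"  # "clade" or "random"
    high_freq: tuple[float, float] = (0.15, 0.5)  # causal freq where present
    low_freq: tuple[float, float] = (0.0, 0.04)  # causal freq where absent
    n_hidden_factors: int = 5
    factor_loading_sd: float = 0.5
    noise_sd: float = 0.25  # per-individual biological/technical noise
    replicate_sd: float = 0.10  # per-hybridization noise
    baseline_range: tuple[float, float] = (6.0, 12.0)
    snp_in_probe_beta: float = -0.4  # hybridization artifact per allele copy
    clone_correlation: float | None = None  # clone causal SNPs (proxy-SNP LD)

    def __post_init__(self) -> None:
        if self.absence_mode not in ("freq", "beta_zero"):
            raise ValueError("absence_mode must be 'freq' or 'beta_zero'")
        if self.sharing_mode not in ("clade", "random"):
            raise ValueError("sharing_mode must be 'clade' or 'random'")


def default_populations() -> list[PopulationSpec]:
    """The 8-population design at the study's sample sizes, with three
    continental pools (EUR, EAS, AFR) and four admixed populations."""
    return [
        PopulationSpec("CEU", 109, 0.005, ancestry="EUR"),
        PopulationSpec("CHB", 80, 0.005, ancestry="EAS"),
        PopulationSpec("GIH", 82, 0.005, admixture_props={"EUR": 0.65, "EAS": 0.35}),
        PopulationSpec("JPT", 82, 0.005, ancestry="EAS"),
        PopulationSpec("LWK", 82, 0.005, admixture_props={"AFR": 0.93, "EUR": 0.07}),
        PopulationSpec("MEX", 45, 0.005, admixture_props={"EUR": 0.55, "EAS": 0.35, "AFR": 0.10}),
        PopulationSpec("MKK", 138, 0.005, admixture_props={"AFR": 0.82, "EUR": 0.18}),
        PopulationSpec("YRI", 108, 0.005, ancestry="AFR"),
    ]


#: Default pool-level drift from the shared ancestral frequency.
DEFAULT_POOLS: dict[str, float] = {"EUR": 0.06, "EAS": 0.08, "AFR": 0.02}


@dataclass(frozen=True)
class StudyConfig:
    """Scale and structure of one simulated study."""

    pops: tuple[PopulationSpec, ...] = tuple(default_populations())
    pools: tuple[tuple[str, float], ...] = tuple(DEFAULT_POOLS.items())
    n_snps: int = 5_000
    n_probes: int = 300
    chrom_lengths: tuple[tuple[str, int], ...] = (("1", 30_000_000), ("2", 30_000_000))
    ancestral_maf_range: tuple[float, float] = (0.05, 0.95)
    missing_rate: float = 0.01
    frac_multi_gene: float = 0.02  # probes mapping to 2 genes (ineligible)
    frac_chrx: float = 0.03  # probes on chrX (ineligible)
    frac_snp_in_probe: float = 0.064  # flagged probes, artifact-prone
    admix_concentration: float = 10.0  # Dirichlet concentration of individual admixture
    truth: TruthConfig = field(default_factory=TruthConfig)


# ---------------------------------------------------------------------------
# Allele frequencies (Balding-Nichols with pool structure)
# ---------------------------------------------------------------------------

@dataclass
class AlleleFrequencies:
    """Per-SNP frequencies at each level of the drift hierarchy."""

    ancestral: pd.Series  # snp -> ancestral frequency
    pool: pd.DataFrame  # snp x pool
    population: pd.DataFrame  # snp x population (admixed = mixture mean)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, fst: float) -> np.ndarray:
    """Draw drifted frequencies Beta(p(1-F)/F, (1-p)(1-F)/F); F=0 -> copy."""
    if fst == 0.0:
        return p.copy()
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    return rng.beta(a, b)


def simulate_allele_freqs(
    n_snps: int,
    ancestral_maf_range: tuple[float, float],
    pops: list[PopulationSpec],
    seed: int,
    pools: dict[str, float] | None = None,
) -> AlleleFrequencies:
    """Simulate per-population allele frequencies under Balding-Nichols drift.

    Each continental pool drifts from a shared ancestral frequency (drawn
    uniformly in ``ancestral_maf_range``); each population then drifts from
    its pool with its own ``divergence``. Admixed populations get the
    mixture-mean frequency in the returned table (their individuals mix
    pools at genotype-simulation time).
    """
    lo, hi = ancestral_maf_range
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(f"ancestral_maf_range must be within (0,1), got {ancestral_maf_range}")
    if pools is None:
        pools = dict(DEFAULT_POOLS)
    for name, f in pools.items():
        if not (0.0 <= f < 1.0):
            raise ValueError(f"pool {name}: drift must be in [0, 1)")

    rng = np.random.default_rng(seed)
    snp_ids = pd.Index([f"snp{i:06d}" for i in range(n_snps)], name="snp_id")
    anc = rng.uniform(lo, hi, n_snps)

    pool_freqs = {}
    for name in sorted(pools):
        pool_freqs[name] = _balding_nichols(rng, anc, pools[name])
    pool_df = pd.DataFrame(pool_freqs, index=snp_ids)

    pop_freqs = {}
    for spec in pops:
        if spec.admixture_props is not None:
            f = np.zeros(n_snps)
            for pool_name, w in spec.admixture_props.items():
                f += w * pool_df[pool_name].to_numpy()
            pop_freqs[spec.name] = f
        else:
            base = pool_df[spec.ancestry].to_numpy()
            pop_freqs[spec.name] = _balding_nichols(rng, base, spec.divergence)
    pop_df = pd.DataFrame(pop_freqs, index=snp_ids)[[p.name for p in pops]]

    return AlleleFrequencies(
        ancestral=pd.Series(anc, index=snp_ids, name="ancestral"),
        pool=pool_df,
        population=pop_df,
    )


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _random_snp_map(
    snp_ids: pd.Index, chrom_lengths: dict[str, int], rng: np.random.Generator
) -> pd.DataFrame:
    """Assign SNPs to sorted 1-based positions spread over the toy genome."""
    chroms = list(chrom_lengths)
    total = sum(chrom_lengths.values())
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float) / total
    assign = rng.choice(len(chroms), size=len(snp_ids), p=weights)
    chrom_col = np.empty(len(snp_ids), dtype=object)
    pos_col = np.zeros(len(snp_ids), dtype=int)
    for ci, c in enumerate(chroms):
        mask = assign == ci
        n = int(mask.sum())
        pos = np.sort(rng.choice(chrom_lengths[c], size=n, replace=False)) + 1
        chrom_col[mask] = c
        pos_col[mask] = pos
    alleles = rng.choice(["A", "C", "G", "T"], size=(len(snp_ids), 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    df = pd.DataFrame(
        {"chrom": chrom_col, "pos": pos_col, "ref": alleles[:, 0], "alt": alleles[:, 1]},
        index=snp_ids,
    )
    # keep genome order: sort by chrom then position
    return df.sort_values(["chrom", "pos"], kind="stable")


def simulate_genotypes(
    freqs: AlleleFrequencies,
    pops: list[PopulationSpec],
    missing_rate: float,
    seed: int,
    snp_meta: pd.DataFrame | None = None,
    admix_concentration: float = 10.0,
) -> dict[str, GenotypeMatrix]:
    """Draw Hardy-Weinberg genotypes per population.

    Genotype counts per SNP are Binomial(2, freq). Admixed individuals draw
    each SNP's frequency from their own Dirichlet-distributed mixture of
    ancestral pools, which creates within-population admixture gradients
    that a genotype PCA can detect. Missing calls are masked at
    ``missing_rate`` uniformly at random.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    pop_f = freqs.population
    if ((pop_f.to_numpy() < 0) | (pop_f.to_numpy() > 1)).any():
        raise ValueError("frequencies must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if snp_meta is None:
        snp_meta = pd.DataFrame(
            {
                "chrom": "1",
                "pos": np.arange(1, len(pop_f.index) + 1),
                "ref": "A",
                "alt": "G",
            },
            index=pop_f.index,
        )
    order = snp_meta.index  # genome order
    out: dict[str, GenotypeMatrix] = {}
    for spec in pops:
        n = spec.n_individuals
        if spec.admixture_props is not None:
            pool_names = sorted(spec.admixture_props)
            props = np.array([spec.admixture_props[k] for k in pool_names])
            w = rng.dirichlet(admix_concentration * props, size=n)  # n x pools
            pool_mat = freqs.pool.loc[order, pool_names].to_numpy()  # m x pools
            f_ind = w @ pool_mat.T  # n x m, per-individual frequency
        else:
            f_ind = np.broadcast_to(
                pop_f.loc[order, spec.name].to_numpy(), (n, len(order))
            )
        dos = rng.binomial(2, f_ind).astype(float)
        if missing_rate > 0:
            miss = rng.random(dos.shape) < missing_rate
            dos[miss] = np.nan
        samples = [f"{spec.name}{i:04d}" for i in range(n)]
        out[spec.name] = GenotypeMatrix(
            population=spec.name,
            samples=samples,
            snps=snp_meta.loc[order].copy(),
            dosages=dos,
        )
    return out


# ---------------------------------------------------------------------------
# Probe annotation
# ---------------------------------------------------------------------------

def simulate_annotation(config: StudyConfig, seed: int) -> pd.DataFrame:
    """Generate a probe->gene annotation table.

    Most probes map to exactly one autosomal gene; configured fractions map
    to two genes (ineligible) or to chrX (ineligible), and a fraction is
    flagged as overlapping a common SNP (kept but flagged downstream).
    """
    rng = np.random.default_rng(seed)
    chrom_lengths = dict(config.chrom_lengths)
    chroms = list(chrom_lengths)
    n = config.n_probes
    probe_ids = [f"probe{i:05d}" for i in range(n)]
    gene_ids = [f"GENE{i:05d}" for i in range(n)]
    chrom = rng.choice(chroms, size=n)
    tss = np.array([rng.integers(1, chrom_lengths[c] + 1) for c in chrom])
    strand = rng.choice(["+", "-"], size=n)

    n_multi = int(round(config.frac_multi_gene * n))
    n_x = int(round(config.frac_chrx * n))
    special = rng.choice(n, size=n_multi + n_x, replace=False)
    multi_idx = set(special[:n_multi].tolist())
    x_idx = set(special[n_multi:].tolist())
    gene_col = []
    chrom_col = []
    for i in range(n):
        if i in multi_idx:
            gene_col.append(f"{gene_ids[i]};{gene_ids[(i + 1) % n]}")
        else:
            gene_col.append(gene_ids[i])
        chrom_col.append("X" if i in x_idx else chrom[i])
    snp_in_probe = rng.random(n) < config.frac_snp_in_probe
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_id": gene_col,
            "chrom": chrom_col,
            "tss": tss,
            "strand": strand,
            "snp_in_probe": snp_in_probe,
        }
    ).set_index("probe_id")


# ---------------------------------------------------------------------------
# Expression with planted truth
# ---------------------------------------------------------------------------

def _population_tree_sets(pops: list[PopulationSpec]) -> list[frozenset[str]]:
    """Candidate sharing sets respecting the pool structure: singletons,
    pool groups (by dominant ancestry), and the full set."""
    names = [p.name for p in pops]
    sets: list[frozenset[str]] = [frozenset([n]) for n in names]
    by_pool: dict[str, set[str]] = {}
    for p in pops:
        by_pool.setdefault(p.dominant_pool, set()).add(p.name)
    for members in by_pool.values():
        if len(members) >= 2:
            sets.append(frozenset(members))
    if len(names) >= 2:
        sets.append(frozenset(names))
    return sets


def _draw_sharing(
    rng: np.random.Generator, pops: list[PopulationSpec], mode: str
) -> frozenset[str]:
    names = [p.name for p in pops]
    if mode == "random":
        k = int(rng.integers(1, len(names) + 1))
        return frozenset(rng.choice(names, size=k, replace=False).tolist())
    sets = _population_tree_sets(pops)
    singles = [s for s in sets if len(s) == 1]
    groups = [s for s in sets if 1 < len(s) < len(names)]
    u = rng.random()
    if u < 0.45 or not groups:
        return singles[rng.integers(len(singles))]
    if u < 0.80:
        return groups[rng.integers(len(groups))]
    return frozenset(names)


def simulate_expression(
    genotypes: dict[str, GenotypeMatrix],
    annotation: pd.DataFrame,
    truth_config: TruthConfig,
    seed: int,
    pops: list[PopulationSpec] | None = None,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate raw log2 expression (two replicate hybridizations per
    individual) with planted cis-eQTLs, hidden factors and noise.

    Planted effects: for each planted gene a causal SNP is chosen near a
    distance drawn from a signed exponential around the TSS; |beta| decays
    exponentially with |distance| (half-distance configurable) and is
    floored at ``beta_min``. In the default ``"freq"`` absence mode the
    causal SNP's allele frequency is driven below 5% in populations outside
    ``shared_in`` (non-replication by frequency, the study's favored
    explanation); in ``"beta_zero"`` mode the effect itself is switched off
    there.

    Mutates ``genotypes`` in place when absence_mode == "freq" or when
    cloning proxy SNPs (the causal SNP's column is redrawn from the planted
    frequency).
    """
    tc = truth_config
    rng = np.random.default_rng(seed)
    pop_names = list(genotypes)
    if pops is None:
        specs = [
            PopulationSpec(name, genotypes[name].n_samples, 0.01, ancestry="POOL")
            for name in pop_names
        ]
    else:
        specs = [p for p in pops if p.name in genotypes]

    any_gm = genotypes[pop_names[0]]
    snp_meta = any_gm.snps
    # eligible planting targets: single-gene autosomal probes
    elig = annotation[
        (~annotation["gene_id"].str.contains(";"))
        & (~annotation["chrom"].isin(["X", "Y"]))
    ]
    if tc.n_eqtls > len(elig):
        raise ValueError(f"cannot plant {tc.n_eqtls} eQTLs in {len(elig)} eligible probes")
    planted_probes = rng.choice(elig.index.to_numpy(), size=tc.n_eqtls, replace=False)

    planted: list[PlantedEqtl] = []
    used_snps: set[str] = set()
    for probe in planted_probes:
        row = elig.loc[probe]
        chrom, tss = row["chrom"], int(row["tss"])
        cand = snp_meta[(snp_meta["chrom"] == chrom)]
        if cand.empty:
            raise RuntimeError(f"no SNPs on chromosome {chrom} for probe {probe}")
        target = tss + int(
            rng.choice([-1, 1]) * min(rng.exponential(tc.distance_scale), tc.max_distance)
        )
        free = cand[~cand.index.isin(used_snps)]
        order = (free["pos"] - target).abs().sort_values()
        snp_id = order.index[0]
        pos = int(free.loc[snp_id, "pos"])
        dist = pos - tss
        if abs(dist) > tc.max_distance:
            # fall back to the SNP nearest the TSS itself
            order2 = (free["pos"] - tss).abs().sort_values()
            snp_id = order2.index[0]
            pos = int(free.loc[snp_id, "pos"])
            dist = pos - tss
        used_snps.add(snp_id)
        mag = max(tc.beta_at_tss * 2.0 ** (-abs(dist) / tc.half_distance), tc.beta_min)
        beta = float(mag * rng.choice([-1.0, 1.0]))
        shared = _draw_sharing(rng, specs, tc.sharing_mode)
        planted.append(PlantedEqtl(str(row["gene_id"]), str(snp_id), beta, shared, int(dist)))

    # frequency-mode absence: redraw the causal SNP's genotype column
    if tc.absence_mode == "freq":
        for eq in planted:
            for name in pop_names:
                gm = genotypes[name]
                j = gm.snps.index.get_loc(eq.snp_id)
                if name in eq.shared_in:
                    f = rng.uniform(*tc.high_freq)
                else:
                    f = rng.uniform(*tc.low_freq)
                col = rng.binomial(2, f, size=gm.n_samples).astype(float)
                keep_missing = np.isnan(gm.dosages[:, j])
                col[keep_missing] = np.nan
                gm.dosages[:, j] = col

    # monomorphic guard where the effect must be detectable
    for eq in planted:
        for name in eq.shared_in:
            gm = genotypes[name]
            j = gm.snps.index.get_loc(eq.snp_id)
            col = gm.dosages[:, j]
            col = col[~np.isnan(col)]
            if len(col) == 0 or np.nanstd(col) == 0:
                raise RuntimeError(
                    f"planted SNP {eq.snp_id} is monomorphic in population {name}"
                )

    # optional proxy clone of every causal SNP (for stepwise collinearity tests)
    if tc.clone_correlation is not None:
        r = tc.clone_correlation
        for eq in planted:
            clone_id = f"{eq.snp_id}_clone"
            for name in pop_names:
                gm = genotypes[name]
                j = gm.snps.index.get_loc(eq.snp_id)
                col = gm.dosages[:, j].copy()
                if r < 1.0:
                    f = np.nanmean(col) / 2.0
                    redraw = rng.random(len(col)) > r
                    col[redraw] = rng.binomial(2, f, size=int(redraw.sum()))
                meta = gm.snps.loc[[eq.snp_id]].copy()
                meta.index = [clone_id]
                meta["pos"] = meta["pos"] + 1
                gm.snps = pd.concat([gm.snps, meta])
                gm.dosages = np.column_stack([gm.dosages, col])

    # ---- assemble expression -------------------------------------------
    probes = annotation.index
    n_probes = len(probes)
    individuals: list[str] = []
    pop_of_ind: list[str] = []
    for name in pop_names:
        individuals.extend(genotypes[name].samples)
        pop_of_ind.extend([name] * genotypes[name].n_samples)
    n_ind = len(individuals)

    baseline = rng.uniform(*tc.baseline_range, size=n_probes)
    expr = np.tile(baseline[:, None], (1, n_ind))

    # hidden global factors (sample-level confounders, e.g. batch/passage)
    k = tc.n_hidden_factors
    loadings = rng.normal(0.0, tc.factor_loading_sd, size=(k, n_probes))
    scores = rng.normal(0.0, 1.0, size=(n_ind, k))
    if k > 0:
        expr += (scores @ loadings).T

    probe_pos = {p: i for i, p in enumerate(probes)}
    gene_to_probe: dict[str, str] = {}
    for probe, row in annotation.iterrows():
        if ";" not in row["gene_id"]:
            gene_to_probe[row["gene_id"]] = probe

    col_offset = {}
    off = 0
    for name in pop_names:
        col_offset[name] = off
        off += genotypes[name].n_samples

    for eq in planted:
        gi = probe_pos[gene_to_probe[eq.gene_id]]
        for name in pop_names:
            if tc.absence_mode == "beta_zero" and name not in eq.shared_in:
                continue
            gm = genotypes[name]
            j = gm.snps.index.get_loc(eq.snp_id)
            dos = gm.dosages[:, j]
            dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
            sl = slice(col_offset[name], col_offset[name] + gm.n_samples)
            expr[gi, sl] += eq.beta * dos

    # SNP-in-probe hybridization artifact: a common SNP under the probe
    # shifts measured intensity additively per allele copy, everywhere.
    snp_in_probe_ids: set[str] = set()
    if "snp_in_probe" in annotation.columns and tc.snp_in_probe_beta != 0.0:
        flagged = annotation.index[annotation["snp_in_probe"].astype(bool)]
        for probe in flagged:
            row = annotation.loc[probe]
            cand = snp_meta[snp_meta["chrom"] == row["chrom"]]
            if cand.empty:
                continue
            snp_id = (cand["pos"] - int(row["tss"])).abs().idxmin()
            snp_in_probe_ids.add(probe)
            gi = probe_pos[probe]
            for name in pop_names:
                gm = genotypes[name]
                j = gm.snps.index.get_loc(snp_id)
                dos = gm.dosages[:, j]
                dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
                sl = slice(col_offset[name], col_offset[name] + gm.n_samples)
                expr[gi, sl] += tc.snp_in_probe_beta * dos

    expr += rng.normal(0.0, tc.noise_sd, size=expr.shape)

    # two replicate hybridizations per individual
    cols, meta_rows = [], []
    values = np.empty((n_probes, 2 * n_ind))
    genders = rng.choice(["F", "M"], size=n_ind)
    for i, ind in enumerate(individuals):
        for rep in (1, 2):
            noise = rng.normal(0.0, tc.replicate_sd, size=n_probes) if tc.replicate_sd > 0 else 0.0
            values[:, len(cols)] = expr[:, i] + noise
            cols.append(f"{ind}.r{rep}")
            meta_rows.append(
                {"sample": f"{ind}.r{rep}", "individual": ind, "replicate": rep,
                 "population": pop_of_ind[i], "gender": genders[i]}
            )
    vdf = pd.DataFrame(values, index=probes, columns=cols)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    raw = ExpressionMatrix(values=vdf, stage="raw", sample_meta=meta)

    truth = SyntheticTruth(
        planted_eqtls=planted,
        hidden_factor_loadings=pd.DataFrame(
            loadings, index=[f"factor{i}" for i in range(k)], columns=probes
        ),
        hidden_factor_scores=pd.DataFrame(
            scores, index=individuals, columns=[f"factor{i}" for i in range(k)]
        ),
        snp_in_probe_ids=snp_in_probe_ids,
    )
    return raw, truth


# ---------------------------------------------------------------------------
# Study orchestrator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    config: StudyConfig
    seed: int
    freqs: AlleleFrequencies
    genotypes: dict[str, GenotypeMatrix]
    annotation: pd.DataFrame
    expression: ExpressionMatrix  # raw, 2 replicates per individual
    truth: SyntheticTruth


def simulate_study(config: StudyConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate a complete synthetic study (genotypes, annotation, raw
    expression, ground truth) from one seed."""
    if config is None:
        config = StudyConfig()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    pops = list(config.pops)
    freqs = simulate_allele_freqs(
        config.n_snps, config.ancestral_maf_range, pops, seeds[0], pools=dict(config.pools)
    )
    meta_rng = np.random.default_rng(seeds[1])
    snp_meta = _random_snp_map(freqs.population.index, dict(config.chrom_lengths), meta_rng)
    genotypes = simulate_genotypes(
        freqs, pops, config.missing_rate, seeds[1], snp_meta=snp_meta,
        admix_concentration=config.admix_concentration,
    )
    annotation = simulate_annotation(config, seeds[2])
    expression, truth = simulate_expression(
        genotypes, annotation, config.truth, seeds[3], pops=pops
    )
    return SyntheticStudy(
        config=config, seed=seed, freqs=freqs, genotypes=genotypes,
        annotation=annotation, expression=expression, truth=truth,
    )
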