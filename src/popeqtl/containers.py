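"""Core in-memory containers shared across the pipeline.

Genotypes are held as diploid dosages (count of the dosage allele, 0/1/2)
with ``NaN`` marking missing calls; expression as a probe x sample matrix of
log2-scale values tagged with a processing stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Allowed expression processing stages, in pipeline order.
STAGES = ("raw", "normalized", "strat_corrected", "reduced")

#: Which stage transitions are legal (from -> allowed targets).
_STAGE_NEXT = {
    "raw": {"normalized"},
    "normalized": {"strat_corrected", "reduced"},
    "strat_corrected": {"reduced"},
    "reduced": set(),
}


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix for one population.

    Parameters
    ----------
    population : str
        Population label (e.g. ``"CEU"``).
    samples : list of str
        Individual identifiers, one per row of ``dosages``.
    snps : pandas.DataFrame
        SNP metadata indexed by snp_id with columns ``chrom`` (str),
        ``pos`` (1-based int), ``ref``, ``alt``.
    dosages : numpy.ndarray
        ``(n_samples, n_snps)`` float array; values in {0, 1, 2} or NaN
        for a missing call. Dosage counts copies of the dosage allele
        (by convention the alphabetically smaller allele after
        harmonization; the generator uses ``alt``).
    """

    population: str
    samples: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def allele_freq(self) -> pd.Series:
        """Dosage-allele frequency per SNP, over non-missing calls only."""
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return pd.Series(freq, index=self.snps.index, name="freq")

    def maf(self) -> pd.Series:
        """Minor allele frequency per SNP (non-missing calls only)."""
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f).rename("maf")

    def missing_rate(self) -> pd.Series:
        rate = np.mean(np.isnan(self.dosages), axis=0)
        return pd.Series(rate, index=self.snps.index, name="missing_rate")

    def filter_snps(self, min_maf: float = 0.05, max_missing: float = 0.20) -> "GenotypeMatrix":
        """Return a copy keeping SNPs with MAF > ``min_maf`` and
        missingness < ``max_missing`` (both strict, per the study design)."""
        keep = (self.maf().to_numpy() > min_maf) & (
            self.missing_rate().to_numpy() < max_missing
        )
        return GenotypeMatrix(
            population=self.population,
            samples=list(self.samples),
            snps=self.snps.loc[keep].copy(),
            dosages=self.dosages[:, keep].copy(),
        )

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        idx = self.snps.index.get_indexer(snp_ids)
        if (idx < 0).any():
            missing = [s for s, i in zip(snp_ids, idx) if i < 0]
            raise KeyError(f"unknown SNP ids: {missing[:5]}")
        return GenotypeMatrix(
            population=self.population,
            samples=list(self.samples),
            snps=self.snps.iloc[idx].copy(),
            dosages=self.dosages[:, idx].copy(),
        )


@dataclass
class ExpressionMatrix:
    """Probe x sample matrix of log2 expression at a named stage.

    ``values`` is a DataFrame (rows = probe ids, columns = sample ids; for
    raw data, sample ids are hybridization ids ``individual.rep``).
    ``sample_meta`` is indexed by the column names of ``values`` and carries
    at least ``individual``, ``population`` and ``gender``; raw-stage
    metadata also has ``replicate``.
    """

    values: pd.DataFrame
    stage: str
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")
        missing_meta = set(self.values.columns) - set(self.sample_meta.index)
        if missing_meta:
            raise ValueError(f"samples without metadata: {sorted(missing_meta)[:5]}")

    @property
    def probes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def advanced(self, values: pd.DataFrame, stage: str,
                 sample_meta: pd.DataFrame | None = None) -> "ExpressionMatrix":
        """Build the next-stage matrix, enforcing the documented stage order."""
        if stage != self.stage and stage not in _STAGE_NEXT[self.stage]:
            raise ValueError(f"illegal stage transition {self.stage!r} -> {stage!r}")
        meta = self.sample_meta if sample_meta is None else sample_meta
        return ExpressionMatrix(values=values, stage=stage, sample_meta=meta)

    def subset_population(self, population: str) -> "ExpressionMatrix":
        cols = self.sample_meta.index[self.sample_meta["population"] == population]
        cols = [c for c in self.values.columns if c in set(cols)]
        return ExpressionMatrix(
            values=self.values[cols].copy(),
            stage=self.stage,
            sample_meta=self.sample_meta.loc[cols].copy(),
        )
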