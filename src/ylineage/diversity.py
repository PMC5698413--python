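"""Y-STR summary statistics and their association with longitude.

Statistics follow the conventions of standard population-genetic
software: unbiased gene (haplotype) diversity D = n/(n-1) (1 - sum p_i^2)
with Nei's sampling variance, mean pairwise differences over all sample
pairs, per-locus unbiased heterozygosity, and per-locus allele-size
variance with the n-1 denominator.  The longitude association uses
Spearman rank correlation with an exact permutation P-value for small
panels (the usual case: a handful of populations), since the t
approximation is invalid there.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import STRHaplotypeTable


@dataclass
class DiversityResult:
    unit: str
    n: int
    gene_diversity: float
    gene_diversity_sd: float
    mean_pairwise_diff: float
    mean_locus_heterozygosity: float
    allele_size_variance: float
    longitude: float | None = None


def gene_diversity(haplotypes) -> tuple[float, float]:
    """Unbiased haplotype diversity and its sampling SD.

    D = n/(n-1) (1 - sum p_i^2) over distinct multi-locus haplotype
    frequencies; the SD comes from Nei's variance formula
    V = 2/(n(n-1)) [ 2(n-2)(sum p^3 - (sum p^2)^2) + sum p^2 - (sum p^2)^2 ].
    """
    haps = _as_tuples(haplotypes)
    n = len(haps)
    if n < 2:
        raise ValueError("gene diversity needs n >= 2")
    counts = pd.Series(haps).value_counts().to_numpy()
    p = counts / n
    s2 = float(np.sum(p ** 2))
    s3 = float(np.sum(p ** 3))
    d = n / (n - 1) * (1.0 - s2)
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2 ** 2) + s2 - s2 ** 2)
    return d, math.sqrt(max(var, 0.0))


def _as_tuples(haplotypes) -> list[tuple]:
    if isinstance(haplotypes, STRHaplotypeTable):
        return haplotypes.haplotype_tuples()
    arr = np.asarray(haplotypes)
    if arr.ndim == 1:
        return [(x,) for x in arr]
    return [tuple(row) for row in arr]


def _as_matrix(haplotypes) -> np.ndarray:
    if isinstance(haplotypes, STRHaplotypeTable):
        return haplotypes.matrix()
    arr = np.asarray(haplotypes, dtype=np.int64)
    return arr.reshape(len(arr), -1)


def mean_pairwise_differences(haplotypes, metric: str = "stepwise") -> float:
    """Mean distance over all n(n-1)/2 haplotype pairs.

    ``metric``: ``"stepwise"`` sums |repeat differences| over loci;
    ``"loci_differing"`` counts unequal loci.
    """
    m = _as_matrix(haplotypes)
    n = m.shape[0]
    if n < 2:
        raise ValueError("pairwise differences need n >= 2")
    diff = m[:, None, :] - m[None, :, :]
    if metric == "stepwise":
        d = np.abs(diff).sum(axis=2)
    elif metric == "loci_differing":
        d = (diff != 0).sum(axis=2)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    iu = np.triu_indices(n, k=1)
    return float(d[iu].mean())


def locus_heterozygosity(haplotypes, loci: list[str] | None = None
                         ) -> tuple[pd.Series, float]:
    """Unbiased per-locus gene diversity of allele frequencies, and its mean."""
    if isinstance(haplotypes, STRHaplotypeTable):
        loci = loci or haplotypes.loci
        m = haplotypes.matrix(loci)
    else:
        m = _as_matrix(haplotypes)
        loci = loci or [f"locus{j + 1}" for j in range(m.shape[1])]
    n = m.shape[0]
    if n < 2:
        raise ValueError("heterozygosity needs n >= 2")
    vals = {}
    for j, name in enumerate(loci):
        _, counts = np.unique(m[:, j], return_counts=True)
        p = counts / n
        vals[name] = n / (n - 1) * (1.0 - float(np.sum(p ** 2)))
    series = pd.Series(vals)
    return series, float(series.mean())


def allele_size_variance(haplotypes, loci: list[str] | None = None
                         ) -> tuple[pd.Series, float]:
    """Per-locus sample variance (n-1 denominator) of repeat counts, and mean."""
    if isinstance(haplotypes, STRHaplotypeTable):
        loci = loci or haplotypes.loci
        m = haplotypes.matrix(loci)
    else:
        m = _as_matrix(haplotypes)
        loci = loci or [f"locus{j + 1}" for j in range(m.shape[1])]
    if m.shape[0] < 2:
        raise ValueError("allele size variance needs n >= 2")
    series = pd.Series(np.var(m, axis=0, ddof=1), index=loci)
    return series, float(series.mean())


def diversity_by(table: STRHaplotypeTable, by: str = "population",
                 labels: pd.Series | None = None) -> pd.DataFrame:
    """Per-unit diversity summary (one row per population or haplogroup).

    ``labels`` overrides the grouping column, e.g. haplogroup
    assignments aligned with the table's samples.
    """
    if labels is None:
        if by != "population":
            raise ValueError("provide labels= when grouping by anything but population")
        labels = table.populations
    labels = pd.Series(np.asarray(labels), index=range(table.n_samples))
    rows = []
    for unit in pd.unique(labels):
        mask = (labels == unit).to_numpy()
        sub = table.subset(mask)
        if sub.n_samples < 2:
            warnings.warn(f"unit {unit!r} has fewer than 2 samples; skipped")
            continue
        d, sd = gene_diversity(sub)
        _, het = locus_heterozygosity(sub)
        _, var = allele_size_variance(sub)
        lon = None
        if sub.longitudes is not None:
            lon = float(sub.longitudes.mean())
        rows.append(DiversityResult(
            unit=str(unit), n=sub.n_samples, gene_diversity=d,
            gene_diversity_sd=sd,
            mean_pairwise_diff=mean_pairwise_differences(sub),
            mean_locus_heterozygosity=het, allele_size_variance=var,
            longitude=lon))
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("unit")


def spearman_longitude(stats_table: pd.DataFrame, field: str,
                       longitude: str = "longitude",
                       exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman correlation of a diversity statistic with longitude.

    Ties are handled by midranks.  For n <= ``exact_max_n`` the two-sided
    P-value is computed by full enumeration of the n! rank permutations;
    larger panels fall back to the large-sample approximation.
    """
    sub = stats_table[[longitude, field]].dropna()
    n = len(sub)
    if n < 4:
        raise ValueError("need at least 4 units with longitude")
    x = sub[longitude].to_numpy(dtype=float)
    y = sub[field].to_numpy(dtype=float)
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= exact_max_n:
        p = exact_spearman_pvalue(x, y)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def exact_spearman_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation P for Spearman's rho (full enumeration)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(_rank_corr(rx, ry))
    total = 0
    hits = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(_rank_corr(rx, np.asarray(perm))) >= obs - 1e-12:
            hits += 1
    return hits / total


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx ** 2).sum() * (ry ** 2).sum()))
    if denom == 0:
        return 0.0
    return float((rx * ry).sum() / denom)
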