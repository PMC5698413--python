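"""Hierarchical analysis of molecular variance (AMOVA) on STR haplotypes.

The classical Excoffier partition: total sums of squared deviations are
computed from a pairwise (squared) distance matrix, split into
among-group, among-population-within-group and within-population pieces,
and converted to variance components with the standard unequal-n
coefficients.  Phi statistics are the corresponding intraclass
correlations (Phi_ST, Phi_CT, Phi_SC) and P-values come from label
permutation, each component with its own permutation scheme.

The default distance is the count of differing loci (an Fst-style
haplotype distance); a squared stepwise distance is available for
R_ST-style sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import STRHaplotypeTable

METRICS = ("loci_differing", "stepwise_squared")


@dataclass
class AmovaDesign:
    """Sample-to-population mapping with an optional second grouping level.

    ``populations`` is either a ``{sample: population}`` mapping (used
    with an :class:`STRHaplotypeTable`) or a sequence of population
    labels aligned with the rows of a plain haplotype matrix.
    """

    populations: dict[str, str] | list[str]
    groups: dict[str, str] | None = None  # population -> group
    metric: str = "loci_differing"

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        values = (list(self.populations.values())
                  if isinstance(self.populations, dict) else list(self.populations))
        if len(set(values)) < 2:
            raise ValueError("AMOVA needs at least 2 populations")
        if self.groups is not None:
            missing = set(values) - set(self.groups)
            if missing:
                raise ValueError(f"populations without group assignment: {sorted(missing)}")


@dataclass
class AmovaResult:
    variance_components: dict[str, float]
    percent_variation: dict[str, float]
    phi_statistics: dict[str, float]
    ssd: dict[str, float]
    df: dict[str, int]
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp in self.variance_components:
            rows.append({
                "component": comp,
                "ssd": self.ssd.get(comp),
                "df": self.df.get(comp),
                "variance": self.variance_components[comp],
                "percent": self.percent_variation[comp],
            })
        frame = pd.DataFrame(rows)
        for name, val in self.phi_statistics.items():
            frame.attrs[name] = val
        return frame


def distance_matrix(haplotypes, metric: str = "loci_differing") -> np.ndarray:
    """Symmetric pairwise distance matrix between STR haplotypes."""
    if isinstance(haplotypes, STRHaplotypeTable):
        m = haplotypes.matrix()
    else:
        m = np.asarray(haplotypes, dtype=np.int64)
        m = m.reshape(len(m), -1)
    diff = m[:, None, :] - m[None, :, :]
    if metric == "loci_differing":
        return (diff != 0).sum(axis=2).astype(float)
    if metric == "stepwise_squared":
        return (diff ** 2).sum(axis=2).astype(float)
    raise ValueError(f"unknown metric {metric!r}")


def _prepare(haplotypes, design: AmovaDesign):
    d = distance_matrix(haplotypes, design.metric)
    if isinstance(design.populations, dict):
        if not isinstance(haplotypes, STRHaplotypeTable):
            raise ValueError("a {sample: population} mapping needs an STR table")
        pops = np.asarray([design.populations[s] for s in haplotypes.samples])
    else:
        pops = np.asarray(list(design.populations))
    if len(pops) != d.shape[0]:
        raise ValueError("population labels do not match the number of haplotypes")

    # populations of size 1 carry no within-population information
    sizes = pd.Series(pops).value_counts()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        warnings.warn(f"excluding populations with a single sample: {singletons}")
        keep = ~np.isin(pops, singletons)
        d = d[np.ix_(keep, keep)]
        pops = pops[keep]
        if len(set(pops)) < 2:
            raise ValueError("fewer than 2 populations remain after exclusions")
    return d, pops


def _components_from_labels(d: np.ndarray, pops: np.ndarray,
                            group_of: dict | None):
    """Variance components from a fixed distance matrix and labels."""
    n_tot = len(pops)
    pop_names = list(dict.fromkeys(pops))
    sizes = {p: int(np.sum(pops == p)) for p in pop_names}

    def ssd_of(mask: np.ndarray) -> float:
        # sum over unordered pairs of d, divided by subgroup size
        sub = d[np.ix_(mask, mask)]
        return float(sub.sum() / 2.0) / int(mask.sum())

    ssd_total = float(d.sum() / 2.0) / n_tot
    ssd_wp = sum(ssd_of(pops == p) for p in pop_names)

    if group_of is None:
        # one-level design
        df_ap, df_wp = len(pop_names) - 1, n_tot - len(pop_names)
        ssd_ap = ssd_total - ssd_wp
        sigma_w = ssd_wp / df_wp if df_wp else 0.0
        n_c = (n_tot - sum(s * s for s in sizes.values()) / n_tot) / df_ap
        sigma_a = (ssd_ap / df_ap - sigma_w) / n_c
        comps = {"among_populations": sigma_a, "within_populations": sigma_w}
        total = sigma_a + sigma_w
        phi = {"phi_st": sigma_a / total if total else 0.0}
        ssd = {"among_populations": ssd_ap, "within_populations": ssd_wp,
               "total": ssd_total}
        dfs = {"among_populations": df_ap, "within_populations": df_wp,
               "total": n_tot - 1}
        return comps, phi, ssd, dfs

    groups = np.asarray([group_of[p] for p in pops])
    group_names = list(dict.fromkeys(groups))
    g = len(group_names)
    p_count = len(pop_names)
    if g < 2:
        raise ValueError("two-level design needs >= 2 groups")
    ssd_wg = sum(ssd_of(groups == gn) for gn in group_names)
    ssd_ap = ssd_wg - ssd_wp          # among populations within groups
    ssd_ag = ssd_total - ssd_wg       # among groups
    df_ag, df_ap, df_wp = g - 1, p_count - g, n_tot - p_count

    group_sizes = {gn: int(np.sum(groups == gn)) for gn in group_names}
    pop_group = {p: group_of[p] for p in pop_names}
    sum_npg = sum(
        sum(sizes[p] ** 2 for p in pop_names if pop_group[p] == gn) / group_sizes[gn]
        for gn in group_names)
    n1 = (n_tot - sum_npg) / df_ap
    n2 = (sum_npg - sum(sizes[p] ** 2 for p in pop_names) / n_tot) / df_ag
    n3 = (n_tot - sum(group_sizes[gn] ** 2 for gn in group_names) / n_tot) / df_ag

    sigma_c = ssd_wp / df_wp if df_wp else 0.0
    sigma_b = (ssd_ap / df_ap - sigma_c) / n1
    sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sigma_b) / n3
    comps = {"among_groups": sigma_a,
             "among_populations_within_groups": sigma_b,
             "within_populations": sigma_c}
    total = sigma_a + sigma_b + sigma_c
    phi = {
        "phi_ct": sigma_a / total if total else 0.0,
        "phi_sc": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) else 0.0,
        "phi_st": (sigma_a + sigma_b) / total if total else 0.0,
    }
    ssd = {"among_groups": ssd_ag,
           "among_populations_within_groups": ssd_ap,
           "within_populations": ssd_wp, "total": ssd_total}
    dfs = {"among_groups": df_ag, "among_populations_within_groups": df_ap,
           "within_populations": df_wp, "total": n_tot - 1}
    return comps, phi, ssd, dfs


def amova(haplotypes, design: AmovaDesign) -> AmovaResult:
    """Partition molecular variance for a one- or two-level design.

    Negative variance components are reported as computed (the usual
    convention), and a two-level design whose populations all fall in one
    group collapses to the one-level analysis.
    """
    d, pops = _prepare(haplotypes, design)
    group_of = design.groups
    if group_of is not None and len(set(group_of[p] for p in set(pops))) < 2:
        group_of = None  # single group: collapse to one level
    comps, phi, ssd, dfs = _components_from_labels(d, pops, group_of)
    total = sum(comps.values())
    percent = {k: (100.0 * v / total if total else 0.0) for k, v in comps.items()}
    return AmovaResult(variance_components=comps, percent_variation=percent,
                       phi_statistics=phi, ssd=ssd, df=dfs)


def permutation_test(haplotypes, design: AmovaDesign, n_perm: int = 10_000,
                     seed: int | None = None) -> dict[str, float]:
    """Permutation P-values for the Phi statistics.

    Schemes: Phi_ST permutes samples among populations; Phi_CT permutes
    whole populations among groups; Phi_SC permutes samples among
    populations within their group.  p = (hits + 1) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    rng = np.random.default_rng(seed)
    d, pops = _prepare(haplotypes, design)
    group_of = design.groups
    if group_of is not None and len(set(group_of[p] for p in set(pops))) < 2:
        group_of = None

    obs_comps, obs_phi, _, _ = _components_from_labels(d, pops, group_of)
    hits = {k: 0 for k in obs_phi}

    pop_names = list(dict.fromkeys(pops))
    for _ in range(n_perm):
        # Phi_ST: samples shuffled among populations
        perm_pops = rng.permutation(pops)
        try:
            _, phi, _, _ = _components_from_labels(d, perm_pops, group_of)
            if phi["phi_st"] >= obs_phi["phi_st"] - 1e-12:
                hits["phi_st"] += 1
        except ValueError:
            pass
        if group_of is not None:
            # Phi_CT: populations shuffled among groups
            shuffled = rng.permutation([group_of[p] for p in pop_names])
            perm_groups = dict(zip(pop_names, shuffled))
            _, phi, _, _ = _components_from_labels(d, pops, perm_groups)
            if phi["phi_ct"] >= obs_phi["phi_ct"] - 1e-12:
                hits["phi_ct"] += 1
            # Phi_SC: samples shuffled among populations within groups
            perm_pops = pops.copy()
            groups_arr = np.asarray([group_of[p] for p in pops])
            for gn in set(groups_arr):
                idx = np.flatnonzero(groups_arr == gn)
                perm_pops[idx] = rng.permutation(pops[idx])
            _, phi, _, _ = _components_from_labels(d, perm_pops, group_of)
            if phi["phi_sc"] >= obs_phi["phi_sc"] - 1e-12:
                hits["phi_sc"] += 1
    return {k: (hits[k] + 1) / (n_perm + 1) for k in hits}


def amova_with_pvalues(haplotypes, design: AmovaDesign, n_perm: int = 10_000,
                       seed: int | None = None) -> AmovaResult:
    result = amova(haplotypes, design)
    result.p_values = permutation_test(haplotypes, design, n_perm=n_perm, seed=seed)
    result.n_permutations = n_perm
    return result
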