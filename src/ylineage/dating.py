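"""TMRCA estimation with the rho statistic.

rho is the mean number of mutations separating the sampled lineages from
their common ancestor; under rate constancy it is linearly related to
time, rho = mu * T.  On a tree with ``l_b`` mutations on branch ``b`` and
``n_b`` descendant tips out of ``n``,

    rho     = sum_b (n_b / n) * l_b            (equals the tip-wise mean)
    sigma^2 = sum_b (n_b / n)^2 * l_b          (Saillard et al. estimator)

SNP mode converts with T = rho / (snp_rate * callable_length); STR mode
with T = rho / str_rate (one mutation per haplotype per 858 years by
default).  Confidence intervals are T +/- z * sigma_T with z = 1.96 by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import STRHaplotypeTable
from .simulate import MutationRateSpec
from .tree import Node, Tree


@dataclass
class RhoEstimate:
    """A rho value with its standard error and (once converted) a TMRCA."""

    rho: float
    sigma_rho: float
    n_tips: int
    mode: str = "snp"  # or "str"
    tmrca: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    rate_spec: MutationRateSpec | None = None

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho cannot be negative")


def rho_snp(tree: Tree, focal_node: Node | str | None = None) -> RhoEstimate:
    """Compute rho and its standard error from per-edge mutation counts.

    ``focal_node`` (a node, node name, or None for the root) is the
    ancestor dated; edges strictly below it contribute ``(n_b/n) l_b``.
    """
    if focal_node is None:
        focal = tree.root
    elif isinstance(focal_node, str):
        focal = tree.find(focal_node)
    else:
        focal = focal_node

    sub = Tree(focal)
    tips = sub.leaves()
    n = len(tips)
    if n < 1:
        raise ValueError("focal node has no descendant tips")
    counts = sub.n_descendant_leaves()
    rho = 0.0
    var = 0.0
    for node in sub.preorder():
        if node is focal:
            continue
        w = counts[node] / n
        rho += w * node.mutations
        var += w * w * node.mutations
    return RhoEstimate(rho=rho, sigma_rho=float(np.sqrt(var)), n_tips=n, mode="snp")


def rho_tipwise(tree: Tree, focal_node: Node | str | None = None) -> float:
    """rho via the tip-wise definition (mean root-to-tip mutation count).

    Mathematically identical to :func:`rho_snp`; kept as an independent
    code path for cross-validation.
    """
    focal = tree.root if focal_node is None else (
        tree.find(focal_node) if isinstance(focal_node, str) else focal_node)

    totals = []

    def walk(node: Node, acc: int) -> None:
        if node is not focal:
            acc += node.mutations
        if node.is_leaf:
            totals.append(acc)
        for child in node.children:
            walk(child, acc)

    walk(focal, 0)
    return float(np.mean(totals))


def stepwise_distance(a: np.ndarray, b: np.ndarray) -> int:
    """Single-step metric: sum over loci of |repeat difference|."""
    return int(np.abs(np.asarray(a) - np.asarray(b)).sum())


def modal_haplotype(matrix: np.ndarray) -> np.ndarray:
    """Per-locus modal repeat vector (lowest repeat wins ties)."""
    out = np.empty(matrix.shape[1], dtype=np.int64)
    for j in range(matrix.shape[1]):
        vals, cnt = np.unique(matrix[:, j], return_counts=True)
        out[j] = vals[np.argmax(cnt)]  # np.unique sorts, so ties -> lowest
    return out


def rho_str(haplotypes: STRHaplotypeTable | np.ndarray,
            founder: np.ndarray | dict | str = "modal",
            loci: list[str] | None = None) -> RhoEstimate:
    """rho from STR haplotypes: mean stepwise distance to the founder.

    ``founder`` may be ``"modal"`` (per-locus modal vector, the usual
    choice for founder-age estimation), a repeat-count vector, or a
    ``{locus: repeats}`` mapping.  The standard error uses the star
    approximation sigma = sqrt(rho / n), which is exact when every sampled
    lineage descends independently from the founder.
    """
    if isinstance(haplotypes, STRHaplotypeTable):
        loci = loci or haplotypes.loci
        matrix = haplotypes.matrix(loci)
    else:
        matrix = np.asarray(haplotypes, dtype=np.int64)
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("rho_str needs at least 2 haplotypes")
    if isinstance(founder, str):
        if founder != "modal":
            raise ValueError("founder must be 'modal', a vector, or a mapping")
        fvec = modal_haplotype(matrix)
    elif isinstance(founder, dict):
        if loci is None:
            raise ValueError("locus names required for a founder mapping")
        fvec = np.asarray([founder[l] for l in loci], dtype=np.int64)
    else:
        fvec = np.asarray(founder, dtype=np.int64)
    if fvec.shape[0] != matrix.shape[1]:
        raise ValueError("founder length does not match locus count")
    dists = np.abs(matrix - fvec).sum(axis=1)
    rho = float(dists.mean())
    sigma = float(np.sqrt(rho / n))
    return RhoEstimate(rho=rho, sigma_rho=sigma, n_tips=n, mode="str")


def tmrca_from_rho(est: RhoEstimate, rates: MutationRateSpec,
                   mode: str | None = None,
                   ci_multiplier: float = 1.96) -> RhoEstimate:
    """Convert rho to years and attach a symmetric confidence interval."""
    mode = mode or est.mode
    if mode == "snp":
        mu = rates.snp_rate * rates.callable_length
    elif mode == "str":
        mu = rates.str_rate
    else:
        raise ValueError(f"unknown dating mode {mode!r}")
    if mu <= 0:
        raise ValueError("mutation rate must be positive for dating")
    t = est.rho / mu
    sigma_t = est.sigma_rho / mu
    return replace(est, mode=mode, tmrca=t,
                   ci_low=t - ci_multiplier * sigma_t,
                   ci_high=t + ci_multiplier * sigma_t,
                   rate_spec=rates)


def effective_rate_per_variable_site(rates: MutationRateSpec,
                                     n_variable_sites: int) -> float:
    """Rescale a per-callable-site rate onto a variable-sites-only alignment.

    When an alignment keeps only the variable sites, external clock-based
    dating must multiply the substitution rate by the callable length and
    divide by the number of variable sites.
    """
    if n_variable_sites <= 0:
        raise ValueError("n_variable_sites must be positive")
    return rates.snp_rate * rates.callable_length / n_variable_sites
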