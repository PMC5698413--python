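"""Coalescent-style simulator for Y-SNP and Y-STR panels with known TMRCA.

The generator produces, from a rooted genealogy with branch lengths in
years, (i) an infinite-sites SNP matrix over an L-bp callable region, with
per-branch Poisson mutation counts, and (ii) Y-STR haplotypes evolving by
symmetric single-step mutations at a per-haplotype-per-year rate.  Because
the genealogy's TMRCA is known exactly, every downstream estimator (rho
dating, perfect phylogeny, diversity, AMOVA, networks) can be checked
against truth.

Default rates follow the values commonly used for whole-Y dating: a "fast"
substitution rate of 1e-9/site/year, a "slow" rate of 6.17e-10/site/year,
a 4.88 Mb callable region of unique Y sequence, and an STR haplotype
mutation rate of one mutation per 858 years for the YFiler locus panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import STRHaplotypeTable, VariantMatrix
from .tree import Node, Tree

#: "fast" SNP substitution rate, substitutions/site/year.
FAST_SNP_RATE = 1e-9
#: "slow" SNP substitution rate, substitutions/site/year.
SLOW_SNP_RATE = 6.17e-10
#: callable unique Y-chromosome sequence, bp.
CALLABLE_LENGTH_BP = 4_880_000
#: Y-STR haplotype mutation rate: one mutation per haplotype per 858 years.
STR_RATE_PER_YEAR = 1.0 / 858.0
#: generation time in years used to convert effective sizes to a time scale.
GENERATION_TIME_YEARS = 30.0

#: YFiler single-copy loci used for network/dating work (13-locus panel).
DEFAULT_STR_LOCI = (
    "DYS19", "DYS389I", "DYS390", "DYS391", "DYS393", "DYS438", "DYS439",
    "DYS437", "DYS448", "DYS456", "DYS458", "YGATAH4", "DYS635",
)

#: A plausible modal founder haplotype for the default loci.
DEFAULT_FOUNDER = {
    "DYS19": 13, "DYS389I": 13, "DYS390": 24, "DYS391": 9, "DYS393": 13,
    "DYS438": 10, "DYS439": 11, "DYS437": 14, "DYS448": 19, "DYS456": 15,
    "DYS458": 18, "YGATAH4": 11, "DYS635": 21,
}

TOPOLOGIES = ("star", "coalescent_const", "coalescent_growth")


@dataclass(frozen=True)
class GenealogyModel:
    """Shape and depth of a single-population genealogy.

    ``tmrca`` is in years and is hit exactly: for the coalescent topologies
    the genealogy is conditioned on its root age by a linear rescaling of
    the simulated coalescent times.
    """

    n_samples: int
    tmrca: float
    topology: str = "star"
    growth_rate: float | None = None  # per year, growth model only
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("a genealogy needs at least 2 samples")
        if self.tmrca <= 0:
            raise ValueError("tmrca must be positive")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}; use one of {TOPOLOGIES}")
        if self.topology == "coalescent_growth" and not self.growth_rate:
            raise ValueError("coalescent_growth requires a positive growth_rate")


@dataclass(frozen=True)
class MutationRateSpec:
    """SNP and STR mutation rates plus the STR locus panel."""

    snp_rate: float = FAST_SNP_RATE
    callable_length: int = CALLABLE_LENGTH_BP
    str_rate: float = STR_RATE_PER_YEAR
    str_loci: tuple[str, ...] = DEFAULT_STR_LOCI
    per_locus_weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.snp_rate < 0 or self.str_rate < 0:
            raise ValueError("mutation rates must be non-negative")
        if self.callable_length <= 0:
            raise ValueError("callable_length must be positive")
        if self.per_locus_weights is not None:
            w = tuple(float(x) for x in self.per_locus_weights)
            if len(w) != len(self.str_loci):
                raise ValueError("per_locus_weights length != number of STR loci")
            if abs(sum(w) - 1.0) > 1e-12:
                raise ValueError("per_locus_weights must sum to 1")
            object.__setattr__(self, "per_locus_weights", w)

    @property
    def weights(self) -> np.ndarray:
        if self.per_locus_weights is None:
            k = len(self.str_loci)
            return np.full(k, 1.0 / k)
        return np.asarray(self.per_locus_weights)


@dataclass
class SimulatedPanel:
    """A multi-population panel plus the truth needed for validation."""

    genealogies: dict[str, Tree]
    variants: VariantMatrix
    strs: STRHaplotypeTable
    truth: dict


# ---------------------------------------------------------------------------
# genealogies
# ---------------------------------------------------------------------------

def coalescent_intervals(n: int, scale: float, rng: np.random.Generator,
                         growth_rate: float | None = None) -> np.ndarray:
    """Raw inter-coalescent waiting times for ``n`` lineages.

    ``scale`` is the coalescent time unit in years (effective size times
    generation time).  With ``n == 2`` the single waiting time is
    exponential with mean ``scale``.  Under exponential growth the
    waiting time for ``k`` lineages is drawn by inverting the cumulative
    coalescent intensity of a population shrinking backwards in time.
    """
    times = np.empty(n - 1)
    t = 0.0
    for i, k in enumerate(range(n, 1, -1)):
        pairs = k * (k - 1) / 2.0
        e = rng.exponential(1.0)
        if growth_rate:
            r = growth_rate
            # intensity up to w: pairs/(scale*r) * (exp(r*(t+w)) - exp(r*t))
            w = math.log(math.exp(r * t) + e * scale * r / pairs) / r - t
        else:
            w = e * scale / pairs
        times[i] = w
        t += w
    return times


def simulate_genealogy(model: GenealogyModel,
                       rng: np.random.Generator | None = None) -> Tree:
    """Simulate a rooted genealogy whose root-to-tip depth equals ``tmrca``.

    Star topology: ``n`` sibling tips, each on a branch of ``tmrca`` years.
    Coalescent topologies: a Kingman coalescent (optionally with
    exponential growth, which compresses coalescences near the root and
    yields star-like trees) simulated at an arbitrary time scale and then
    rescaled so the root age is exactly ``tmrca``.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    n = model.n_samples
    tips = [Node(f"t{i + 1}") for i in range(n)]

    if model.topology == "star":
        root = Node("root")
        for tip in tips:
            tip.length = float(model.tmrca)
            root.add_child(tip)
        return Tree(root)

    waits = coalescent_intervals(
        n, scale=model.tmrca, rng=rng,
        growth_rate=model.growth_rate if model.topology == "coalescent_growth" else None,
    )
    # random pairwise merging; node ages tracked to set branch lengths
    age = {id(tip): 0.0 for tip in tips}
    active = list(tips)
    t = 0.0
    for w in waits:
        t += w
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        b = active.pop(j)
        a = active.pop(i)
        parent = Node()
        for child in (a, b):
            child.length = t - age[id(child)]
            parent.add_child(child)
        age[id(parent)] = t
        active.append(parent)
    root = active[0]
    root.name = "root"
    tree = Tree(root)
    # condition on the root age: rescale the realised depth to tmrca
    depth = tree.height()
    tree.scale(model.tmrca / depth)
    return tree


# ---------------------------------------------------------------------------
# SNP mutations
# ---------------------------------------------------------------------------

def _branch_nodes(tree: Tree) -> list[Node]:
    """Every node except the root, i.e. one entry per branch."""
    return [n for n in tree.preorder() if n is not tree.root]


def _poisson_branch_counts(tree: Tree, per_year_rate: float,
                           rng: np.random.Generator) -> dict[int, int]:
    counts = {}
    for node in _branch_nodes(tree):
        counts[id(node)] = int(rng.poisson(per_year_rate * node.length))
    return counts


def _genotypes_from_counts(tree: Tree, counts: dict[int, int],
                           sample_order: list[str]) -> np.ndarray:
    """Derived-allele indicator matrix, one column per mutation, in branch
    preorder.  A mutation on a branch is carried by every descendant tip."""
    col_of = {s: i for i, s in enumerate(sample_order)}
    total = sum(counts.values())
    geno = np.zeros((len(sample_order), total), dtype=np.int8)
    j = 0
    # collect descendant tips per node once
    desc: dict[int, list[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            desc[id(node)] = [node.name]
        else:
            desc[id(node)] = [t for c in node.children for t in desc[id(c)]]
    for node in _branch_nodes(tree):
        k = counts[id(node)]
        if not k:
            continue
        rows = [col_of[t] for t in desc[id(node)]]
        geno[np.ix_(rows, range(j, j + k))] = 1
        j += k
    return geno


def drop_snp_mutations(tree: Tree, rates: MutationRateSpec,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None,
                       mean_depth: float = 30.0) -> VariantMatrix:
    """Drop infinite-sites SNP mutations on a genealogy.

    Per-branch counts are Poisson(snp_rate x callable_length x branch
    years); each mutation occupies a unique position in the callable
    region and its derived allele is carried by all descendant tips.  The
    realised count is recorded on each node's ``mutations`` attribute.
    Read depths are Poisson(``mean_depth``) per sample x site.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    per_year = rates.snp_rate * rates.callable_length
    counts = _poisson_branch_counts(tree, per_year, rng)
    for node in _branch_nodes(tree):
        node.mutations = counts[id(node)]
    samples = tree.leaf_names()
    geno = _genotypes_from_counts(tree, counts, samples)
    total = geno.shape[1]
    positions = np.sort(rng.choice(rates.callable_length, size=total, replace=False)) + 1
    # columns were laid out in branch preorder; reorder by position
    order = rng.permutation(total)
    geno = geno[:, order]
    depth = rng.poisson(mean_depth, size=geno.shape)
    return VariantMatrix(positions=positions, samples=samples,
                         genotypes=geno, depth=depth)


# ---------------------------------------------------------------------------
# STR evolution
# ---------------------------------------------------------------------------

def evolve_strs(tree: Tree, rates: MutationRateSpec,
                founder: dict[str, int] | None = None,
                seed: int | None = None,
                rng: np.random.Generator | None = None,
                population: str = "pop1",
                longitude: float | None = None) -> STRHaplotypeTable:
    """Evolve STR haplotypes down a genealogy by single-step mutation.

    Mutations arrive on each branch as Poisson(str_rate x branch years),
    are assigned to loci by ``per_locus_weights`` and step the repeat
    count by +1 or -1 with equal probability.  Counts cannot drop below
    1: a step that would do so reflects to +1.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if founder is None:
        founder = {l: DEFAULT_FOUNDER[l] for l in rates.str_loci}
    loci = list(rates.str_loci)
    if set(founder) != set(loci):
        raise ValueError("founder haplotype must cover exactly the configured loci")
    base = np.array([founder[l] for l in loci], dtype=np.int64)
    if np.any(base < 2):
        raise ValueError("founder repeat counts must be >= 2")
    weights = rates.weights

    rows: dict[str, np.ndarray] = {}

    def walk(node: Node, state: np.ndarray) -> None:
        if node.parent is not None:
            k = rng.poisson(rates.str_rate * node.length)
            if k:
                state = state.copy()
                locus_idx = rng.choice(len(loci), size=k, p=weights)
                steps = rng.choice((-1, 1), size=k)
                for li, st in zip(locus_idx, steps):
                    nxt = state[li] + st
                    state[li] = nxt if nxt >= 1 else state[li] + 1
        if node.is_leaf:
            rows[node.name] = state
        for child in node.children:
            walk(child, state)

    walk(tree.root, base)

    samples = tree.leaf_names()
    df = pd.DataFrame({"sample": samples, "population": population})
    if longitude is not None:
        df["longitude"] = float(longitude)
    mat = np.stack([rows[s] for s in samples])
    for j, locus in enumerate(loci):
        df[locus] = mat[:, j]
    return STRHaplotypeTable(df)


# ---------------------------------------------------------------------------
# multi-population panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """One population in a panel: genealogy model plus a sampling longitude."""

    name: str
    n_samples: int
    tmrca: float
    longitude: float = 0.0
    topology: str = "coalescent_const"
    growth_rate: float | None = None

    def model(self, seed: int | None = None) -> GenealogyModel:
        return GenealogyModel(n_samples=self.n_samples, tmrca=self.tmrca,
                              topology=self.topology,
                              growth_rate=self.growth_rate, seed=seed)


def _node_ids(tree: Tree) -> dict[int, str]:
    return {id(n): f"n{i}" for i, n in enumerate(tree.preorder())}


def generate_population_panel(populations: list[PopulationSpec],
                              rates: MutationRateSpec,
                              seed: int,
                              founder: dict[str, int] | None = None,
                              mean_depth: float = 30.0,
                              shared_genealogy: GenealogyModel | None = None,
                              ) -> SimulatedPanel:
    """Simulate a labelled multi-population SNP+STR panel.

    Each population gets its own genealogy (disjoint ancestries, so SNP
    sites are private to populations) unless ``shared_genealogy`` is
    given, in which case a single genealogy of the pooled sample size is
    simulated and tips are assigned to populations in blocks — under that
    sharing the population labels are exchangeable.
    """
    if not populations:
        raise ValueError("at least one population is required")
    names = [p.name for p in populations]
    if len(set(names)) != len(names):
        raise ValueError("duplicate population names in panel config")

    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    pop_seeds = ss.spawn(len(populations) + 2)

    genealogies: dict[str, Tree] = {}
    tip_pop: dict[str, str] = {}
    tip_long: dict[str, float] = {}

    if shared_genealogy is not None:
        total = sum(p.n_samples for p in populations)
        model = replace(shared_genealogy, n_samples=total)
        rng = np.random.default_rng(pop_seeds[0])
        tree = simulate_genealogy(model, rng=rng)
        # random tip-to-population assignment: labels must be exchangeable
        leaves = [tree.leaves()[k] for k in rng.permutation(total)]
        i = 0
        for p in populations:
            for k in range(p.n_samples):
                leaf = leaves[i]
                leaf.name = f"{p.name}_{k + 1}"
                tip_pop[leaf.name] = p.name
                tip_long[leaf.name] = p.longitude
                i += 1
        genealogies["__shared__"] = tree
        trees = [("__shared__", tree, np.random.default_rng(pop_seeds[1]))]
    else:
        trees = []
        for p, sub in zip(populations, pop_seeds):
            rng = np.random.default_rng(sub)
            tree = simulate_genealogy(p.model(), rng=rng)
            for k, leaf in enumerate(tree.leaves()):
                leaf.name = f"{p.name}_{k + 1}"
                tip_pop[leaf.name] = p.name
                tip_long[leaf.name] = p.longitude
            genealogies[p.name] = tree
            trees.append((p.name, tree, rng))

    # SNPs: per-tree branch counts, with one global unique-position pool
    per_year = rates.snp_rate * rates.callable_length
    all_counts: list[tuple[str, Tree, dict[int, int]]] = []
    total_mut = 0
    for name, tree, rng in trees:
        counts = _poisson_branch_counts(tree, per_year, rng)
        for node in _branch_nodes(tree):
            node.mutations = counts[id(node)]
        all_counts.append((name, tree, counts))
        total_mut += sum(counts.values())

    all_samples = [s for _, tree, _ in trees for s in tree.leaf_names()]
    geno = np.zeros((len(all_samples), total_mut), dtype=np.int8)
    offset_row = 0
    offset_col = 0
    for name, tree, counts in all_counts:
        block = _genotypes_from_counts(tree, counts, tree.leaf_names())
        n, m = block.shape
        geno[offset_row:offset_row + n, offset_col:offset_col + m] = block
        offset_row += n
        offset_col += m
    positions = np.sort(master.choice(rates.callable_length, size=total_mut,
                                      replace=False)) + 1
    order = master.permutation(total_mut)
    geno = geno[:, order]
    depth = master.poisson(mean_depth, size=geno.shape)
    variants = VariantMatrix(positions=positions, samples=all_samples,
                             genotypes=geno, depth=depth)

    # STRs: evolve per tree with its own stream
    str_rng = np.random.default_rng(pop_seeds[-1])
    frames = []
    for name, tree, _ in trees:
        table = evolve_strs(tree, rates, founder=founder, rng=str_rng)
        df = table.data
        df["population"] = [tip_pop[s] for s in df["sample"]]
        df["longitude"] = [tip_long[s] for s in df["sample"]]
        frames.append(df)
    strs = STRHaplotypeTable(pd.concat(frames, ignore_index=True))

    truth = {
        "seed": seed,
        "tmrca": ({"__shared__": shared_genealogy.tmrca} if shared_genealogy
                  else {p.name: p.tmrca for p in populations}),
        "branch_mutations": {
            name: {nid: counts[key] for key, nid in
                   ((id(n), _node_ids(tree)[id(n)]) for n in _branch_nodes(tree))}
            for name, tree, counts in all_counts
        },
        "founder": founder or {l: DEFAULT_FOUNDER[l] for l in rates.str_loci},
        "n_variants": int(total_mut),
    }
    return SimulatedPanel(genealogies=genealogies, variants=variants,
                          strs=strs, truth=truth)


def write_panel(panel: SimulatedPanel, outdir) -> dict[str, str]:
    """Write a panel to ``outdir`` as VCF + CSV + Newick + JSON truth."""
    import json
    from pathlib import Path

    from . import io as yio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    vcf = out / "variants.vcf"
    yio.write_vcf(panel.variants, vcf)
    paths["variants"] = str(vcf)
    strs = out / "strs.csv"
    yio.write_str_table(panel.strs, strs)
    paths["strs"] = str(strs)
    for name, tree in panel.genealogies.items():
        safe = name.strip("_") or "shared"
        p = out / f"genealogy_{safe}.nwk"
        p.write_text(tree.to_newick(mutations=True) + "\n")
        paths[f"genealogy_{name}"] = str(p)
    truth = out / "truth.json"
    truth.write_text(json.dumps(panel.truth, indent=2, sort_keys=True))
    paths["truth"] = str(truth)
    return paths
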