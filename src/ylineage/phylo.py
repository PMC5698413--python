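"""SNP trees, haplogroup assignment, and haplogroup frequency tables.

Y-chromosome SNPs are effectively homoplasy-free, so the sample tree is
built as a perfect phylogeny (every variant labels exactly one edge) with
an explicit conflict error when the data violate the four-gamete
condition, rather than by heuristic parsimony search.  Haplogroup
assignment walks a defining-SNP hierarchy: a sample is placed on the
deepest node whose whole defining path is derived, and a sample that is
derived at a node but not at any of its children's defining variants gets
the starred paragroup label (e.g. ``SM001*``).
"""

from __future__ import annotations

import importlib.resources
import warnings
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import DERIVED, HETEROZYGOUS, MISSING, VariantMatrix
from .tree import Node, Tree


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), as frequency tables print."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class FourGameteError(ValueError):
    """Raised when two sites cannot sit on a single mutation tree."""

    def __init__(self, site_a: str, site_b: str):
        self.sites = (site_a, site_b)
        super().__init__(
            f"four-gamete violation between sites {site_a} and {site_b}: "
            "their derived sets overlap without nesting"
        )


class HaplogroupInconsistencyError(ValueError):
    """A sample is derived below an edge whose defining variants are ancestral."""


# ---------------------------------------------------------------------------
# perfect phylogeny
# ---------------------------------------------------------------------------


def build_perfect_phylogeny(vm: VariantMatrix, missing: str = "error") -> Tree:
    """Build the unique perfect phylogeny of a binary variant matrix.

    Every group of identical site columns becomes one edge whose
    ``mutations`` count is the group size and whose ``variants`` list the
    site ids; edge descendant-tip counts and mutation counts feed the rho
    estimator directly.

    Parameters
    ----------
    missing
        ``"error"`` (default) refuses missing genotypes; ``"majority"``
        imputes each site's missing calls with the site's majority state
        (ties resolved to ancestral) and warns.
    """
    geno = vm.genotypes
    if np.any(geno == HETEROZYGOUS):
        raise ValueError("heterozygous calls present; run the filter cascade first")
    if np.any(geno == MISSING):
        if missing == "majority":
            geno = geno.copy()
            for j in range(geno.shape[1]):
                col = geno[:, j]
                miss = col == MISSING
                if miss.any():
                    derived = int((col == DERIVED).sum())
                    ancestral = int((col == 0).sum())
                    col[miss] = DERIVED if derived > ancestral else 0
            warnings.warn("missing genotypes imputed by per-site majority state")
        else:
            raise ValueError("missing genotypes present (use missing='majority')")

    carriers = geno == DERIVED  # (n_samples, n_sites) bool
    n = vm.n_samples

    # merge identical columns into clades
    groups: dict[bytes, list[int]] = {}
    for j in range(carriers.shape[1]):
        col = carriers[:, j]
        if not col.any():
            continue  # invariant column: no clade
        groups.setdefault(col.tobytes(), []).append(j)

    clades = []
    for key, cols in groups.items():
        members = np.frombuffer(key, dtype=bool)
        clades.append((members, [vm.ids[j] for j in cols]))
    clades.sort(key=lambda c: (-int(c[0].sum()), c[0].tobytes()), reverse=False)

    root = Node("root")
    nodes: list[Node] = []
    for i, (members, ids) in enumerate(clades):
        parent = root
        for j in range(i - 1, -1, -1):
            other = clades[j][0]
            if np.any(other & members):
                if not np.all(members <= other):
                    raise FourGameteError(clades[j][1][0], ids[0])
                parent = nodes[j]
                break
        # laminarity also requires checking every earlier overlapping clade
        for j in range(i):
            other = clades[j][0]
            if np.any(other & members) and not np.all(members <= other):
                raise FourGameteError(clades[j][1][0], ids[0])
        node = Node()
        node.variants = ids
        node.mutations = len(ids)
        parent.add_child(node)
        nodes.append(node)

    # attach tips at the smallest clade containing each sample
    for s_idx, sample in enumerate(vm.samples):
        best = None
        for i, (members, _) in enumerate(clades):
            if members[s_idx] and (best is None or
                                   clades[i][0].sum() < clades[best][0].sum()):
                best = i
        if best is not None and int(clades[best][0].sum()) == 1:
            nodes[best].name = sample  # singleton clade is the tip itself
        else:
            holder = root if best is None else nodes[best]
            holder.add_child(Node(sample))
    return Tree(root)


# ---------------------------------------------------------------------------
# haplogroup hierarchy
# ---------------------------------------------------------------------------


class HaplogroupTree:
    """Rooted hierarchy of haplogroups with defining variants per edge.

    The tree root is a virtual ancestor; its single child is the clade's
    top-level haplogroup (e.g. M183 defined by the M183 variant), so that
    samples ancestral at the top marker fall outside the clade
    (label ``Other``).
    """

    def __init__(self, tree: Tree):
        self.tree = tree
        children = tree.root.children
        if len(children) != 1:
            raise ValueError("haplogroup hierarchy must have a single top clade")

    @classmethod
    def from_edges(cls, rows: list[tuple[str, str | None, list[str]]]) -> "HaplogroupTree":
        nodes = {}
        for child, parent, variants in rows:
            if not variants:
                raise ValueError(f"haplogroup {child} has no defining variants")
            node = Node(child)
            node.variants = list(variants)
            node.mutations = len(variants)
            nodes[child] = (node, parent)
        root = Node("ROOT")
        for name, (node, parent) in nodes.items():
            if parent is None:
                root.add_child(node)
            else:
                if parent not in nodes:
                    raise ValueError(f"haplogroup {name} references unknown parent {parent}")
                nodes[parent][0].add_child(node)
        return cls(Tree(root))

    def edge_rows(self) -> list[tuple[str, str | None, list[str]]]:
        rows = []
        for node in self.tree.preorder():
            if node is self.tree.root:
                continue
            parent = node.parent.name if node.parent is not self.tree.root else None
            rows.append((node.name, parent, list(node.variants)))
        return rows

    def labels(self) -> list[str]:
        """Assignment labels in preorder: starred for internal nodes."""
        out = []
        for node in self.tree.preorder():
            if node is self.tree.root:
                continue
            out.append(f"{node.name}*" if node.children else node.name)
        return out

    def variant_names(self) -> list[str]:
        return [v for n in self.tree.preorder() if n is not self.tree.root
                for v in n.variants]


def default_haplogroup_tree() -> HaplogroupTree:
    """The E-M183 subclade hierarchy: M183 > SM001 > {Z5009, CTS12227,
    PF6794 > PF6789}."""
    return HaplogroupTree.from_edges([
        ("M183", None, ["M183"]),
        ("SM001", "M183", ["SM001"]),
        ("Z5009", "SM001", ["Z5009"]),
        ("CTS12227", "SM001", ["CTS12227"]),
        ("PF6794", "SM001", ["PF6794"]),
        ("PF6789", "PF6794", ["PF6789"]),
    ])


def _edge_state(calls: Mapping[str, int | None], node: Node) -> str:
    states = []
    for v in node.variants:
        s = calls.get(v)
        if s in (MISSING, None):
            continue
        states.append(int(s))
    if not states:
        return "missing"
    if all(s == DERIVED for s in states):
        return "derived"
    if all(s == 0 for s in states):
        return "ancestral"
    return "conflict"


def _any_derived_below(calls: Mapping[str, int | None], node: Node) -> str | None:
    for child in _descendants(node):
        for v in child.variants:
            if calls.get(v) == DERIVED:
                return v
    return None


def _descendants(node: Node):
    for child in node.children:
        yield child
        yield from _descendants(child)


def assign_haplogroup(calls: Mapping[str, int | None], tree: HaplogroupTree,
                      log: list | None = None) -> str:
    """Assign a sample to the deepest haplogroup its calls support.

    ``calls`` maps variant name to 0 (ancestral), 1 (derived) or
    missing (None / -1).  An edge with all defining variants missing
    blocks descent: assignment stays at the parent (conservative shallow
    placement, noted in ``log``).  A derived call below an ancestral edge
    raises :class:`HaplogroupInconsistencyError`.
    """
    node = tree.tree.root
    while True:
        derived_children = []
        for child in node.children:
            state = _edge_state(calls, child)
            if state == "conflict":
                raise HaplogroupInconsistencyError(
                    f"conflicting calls among defining variants of {child.name}: "
                    f"{ {v: calls.get(v) for v in child.variants} }")
            if state == "ancestral":
                below = _any_derived_below(calls, child)
                # the ancestral edge's own variants are excluded
                if below is not None and below not in child.variants:
                    raise HaplogroupInconsistencyError(
                        f"sample derived at {below} but ancestral at parent edge "
                        f"{child.name}")
            if state == "derived":
                derived_children.append(child)
            if state == "missing" and log is not None:
                log.append(f"descent into {child.name} blocked: defining variants missing")
        if len(derived_children) > 1:
            names = ", ".join(c.name for c in derived_children)
            raise HaplogroupInconsistencyError(
                f"sample derived on sibling branches: {names}")
        if not derived_children:
            if node is tree.tree.root:
                return "Other"
            return f"{node.name}*" if node.children else node.name
        node = derived_children[0]


def calls_from_matrix(vm: VariantMatrix, variant_of_site: Mapping[str, str]
                      ) -> dict[str, dict[str, int | None]]:
    """Per-sample call dicts for the named defining variants.

    ``variant_of_site`` maps a VariantMatrix site id to a haplogroup
    variant name (e.g. ``chrY:12345 -> SM001``)."""
    out: dict[str, dict[str, int | None]] = {s: {} for s in vm.samples}
    for j, sid in enumerate(vm.ids):
        if sid not in variant_of_site:
            continue
        name = variant_of_site[sid]
        for i, s in enumerate(vm.samples):
            g = int(vm.genotypes[i, j])
            out[s][name] = None if g == MISSING else g
    return out


# ---------------------------------------------------------------------------
# frequency tables
# ---------------------------------------------------------------------------


def frequency_table(assignments: Mapping[str, str],
                    populations: Mapping[str, str],
                    tree: HaplogroupTree | None = None) -> pd.DataFrame:
    """Population x haplogroup count table with %-within-clade summary.

    Columns follow the hierarchy preorder, then ``Other``, ``N`` and
    ``percent_em183`` = 100 x (N - Other)/N, printed to 2 decimals with
    round-half-up.
    """
    tree = tree or default_haplogroup_tree()
    labels = tree.labels()
    missing = {s for s in assignments if s not in populations}
    if missing:
        raise ValueError(f"samples without population label: {sorted(missing)[:5]}")
    counts: dict[str, dict[str, int]] = {}
    for sample, hap in assignments.items():
        pop = populations[sample]
        row = counts.setdefault(pop, {c: 0 for c in labels + ["Other"]})
        if hap not in row:
            raise ValueError(f"assignment {hap!r} not a label of the hierarchy")
        row[hap] += 1
    table = pd.DataFrame.from_dict(counts, orient="index")[labels + ["Other"]]
    table.index.name = "population"
    return add_frequency_summary(table)


def add_frequency_summary(counts: pd.DataFrame) -> pd.DataFrame:
    """Append N and percent_em183 to a raw count table."""
    table = counts.copy()
    table["N"] = table.sum(axis=1)
    in_clade = table["N"] - table["Other"]
    table["percent_em183"] = [
        round_half_up(100.0 * c / n) if n else 0.0
        for c, n in zip(in_clade, table["N"])
    ]
    return table


def percent_over_em183(table: pd.DataFrame, column: str) -> pd.Series:
    """Per-population share of a subclade among E-M183 chromosomes (%).

    Populations with no E-M183 carriers are flagged with a warning and
    reported as NaN rather than failing the whole table.
    """
    denom = table["N"] - table["Other"]
    out = {}
    for pop in table.index:
        d = denom.loc[pop]
        if d <= 0:
            warnings.warn(f"population {pop!r} has no E-M183 chromosomes; "
                          f"share of {column} undefined")
            out[pop] = float("nan")
        else:
            out[pop] = round_half_up(100.0 * table.loc[pop, column] / d)
    return pd.Series(out, name=f"{column}_over_em183_pct")


def percent_over_all(table: pd.DataFrame, column: str) -> pd.Series:
    """Per-population share of a subclade among all chromosomes (%)."""
    return pd.Series(
        {pop: round_half_up(100.0 * table.loc[pop, column] / table.loc[pop, "N"])
         for pop in table.index},
        name=f"{column}_over_all_pct")


def reference_counts() -> pd.DataFrame:
    """Published E-M183 subclade counts by population (validation panel)."""
    with importlib.resources.files("ylineage").joinpath(
            "data/em183_subclade_counts.csv").open() as fh:
        df = pd.read_csv(fh, index_col="population")
    return df
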