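"""Synthetic data generators: Yule trees, Brownian traits, binary trait tables.

Everything here exists so every statistic in the package can be exercised
with known ground truth and no external downloads.  The generators are
bit-reproducible given a seed.

* ``simulate_yule_tree`` — a pure-birth (Yule) tree: starting from the root
  split with two lineages, the waiting time while k lineages exist is
  Exp(k·birth_rate); after the n-th tip appears one further Exp(n·birth_rate)
  stretch is added before the present, so the expected root-to-tip depth is
  Σ_{k=2..n} 1/(k·birth_rate).  All tips end at the present: the tree is
  ultrametric, loosely emulating a dated bird supertree sample.
* ``simulate_bm_traits`` — Brownian motion along branches (root value 0,
  child = parent + Normal(0, σ²·branch length)); tip values have covariance
  σ²·C where C is the tree's phylogenetic VCV matrix.
* ``simulate_trait_table`` — binary bundles with a controllable
  specialization gradient: each species' number of 1-entries in a bundle of
  n traits is m = 1 + Binomial(n − 1, 1 − s), so s = 1 gives one-hot rows
  (corrected Gini exactly 1) and s = 0 gives all-ones rows (Gini 0), with a
  monotone gradient in between.  Rows are never all-zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .traits_io import TraitTable

__all__ = [
    "SynthConfig",
    "simulate_yule_tree",
    "simulate_bm_traits",
    "simulate_trait_table",
]


@dataclass
class SynthConfig:
    """Configuration for a synthetic species set.

    ``bundle_spec`` maps bundle name -> (n_traits, specialization target in
    [0, 1]).
    """

    n_species: int
    bundle_spec: dict[str, tuple[int, float]]
    tree_model: str = "yule"
    birth_rate: float = 1.0
    sigma2: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_species < 4:
            raise ValueError("need at least 4 species")
        for name, (k, s) in self.bundle_spec.items():
            if k < 2:
                raise ValueError(f"bundle {name!r}: need at least 2 traits")
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"bundle {name!r}: specialization must lie in [0,1]")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.tree_model != "yule":
            raise ValueError(f"unsupported tree model {self.tree_model!r}")


def _tip_labels(n: int) -> list[str]:
    return [f"t{i + 1}" for i in range(n)]


def simulate_yule_tree(
    n_tips: int, birth_rate: float = 1.0, seed: int | None = None
) -> dendropy.Tree:
    """Simulate a rooted ultrametric pure-birth tree with ``n_tips`` tips."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace(_tip_labels(n_tips))
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root = tree.seed_node
    a, b = dendropy.Node(), dendropy.Node()
    root.add_child(a)
    root.add_child(b)
    active = [a, b]
    pending = {id(a): 0.0, id(b): 0.0}
    k = 2
    while True:
        wait = rng.exponential(1.0 / (birth_rate * k))
        for node in active:
            pending[id(node)] += wait
        if k == n_tips:
            break
        split = active[rng.integers(0, k)]
        split.edge.length = pending.pop(id(split))
        c1, c2 = dendropy.Node(), dendropy.Node()
        split.add_child(c1)
        split.add_child(c2)
        active.remove(split)
        active += [c1, c2]
        pending[id(c1)] = pending[id(c2)] = 0.0
        k += 1
    order = rng.permutation(n_tips)
    for node, j in zip(active, order):
        node.edge.length = pending.pop(id(node))
        node.taxon = taxa[int(j)]
    return tree


def simulate_bm_traits(
    tree: dendropy.Tree, sigma2: float = 1.0, seed: int | None = None
) -> pd.Series:
    """Evolve a continuous trait by Brownian motion; returns tip values.

    The root value is 0; along each branch of length t an independent
    Normal(0, sigma2·t) increment is added.  The returned Series is indexed
    by tip label in the tree's leaf-iteration order (the order
    ``phylo.vcv_matrix`` uses).
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    rng = np.random.default_rng(seed)
    value = {id(tree.seed_node): 0.0}
    tips: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            t = node.edge.length
            if t is None or t < 0:
                raise ValueError("tree has missing or negative branch lengths")
            value[id(node)] = value[id(node.parent_node)] + rng.normal(
                0.0, np.sqrt(sigma2 * t)
            )
        if node.is_leaf():
            tips[node.taxon.label] = value[id(node)]
    labels = [l.taxon.label for l in tree.leaf_node_iter()]
    return pd.Series([tips[l] for l in labels], index=labels, name="trait")


def simulate_trait_table(cfg: SynthConfig) -> TraitTable:
    """Generate a binary trait table with per-bundle specialization targets."""
    rng = np.random.default_rng(cfg.seed)
    species = [f"sp{i + 1}" for i in range(cfg.n_species)]
    cols: dict[str, np.ndarray] = {}
    bundles: dict[str, list[str]] = {}
    for bundle, (k, s) in cfg.bundle_spec.items():
        names = [f"{bundle}_{j + 1}" for j in range(k)]
        bundles[bundle] = names
        mat = np.zeros((cfg.n_species, k), dtype=int)
        m = 1 + rng.binomial(k - 1, 1.0 - s, size=cfg.n_species)
        for i in range(cfg.n_species):
            ones = rng.choice(k, size=m[i], replace=False)
            mat[i, ones] = 1
        for j, name in enumerate(names):
            cols[name] = mat[:, j]
    values = pd.DataFrame(cols, index=pd.Index(species, name="species"))
    return TraitTable(values, bundles)
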