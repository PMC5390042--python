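"""Fritz-Purvis D statistic for phylogenetic signal of a binary trait.

The statistic asks whether a binary trait (e.g. "antimicrobially active")
is clumped on the phylogeny.  The observed quantity d_obs is the sum, over
internal nodes of a rooted bifurcating tree, of the absolute difference
between the two daughter values, where tips carry the trait (0/1) and each
internal node carries the mean of its two daughters (post-order recursion).
d_obs is located between two permutation nulls:

* a *random* null — tip states shuffled across the tips (no signal);
* a *Brownian-threshold* null — a continuous character evolved by Brownian
  motion along the branches (variance proportional to branch length) and
  thresholded at the quantile matching the observed prevalence (maximal
  clumping expected under gradual evolution).

D = (d_obs - mean d_brownian) / (mean d_random - mean d_brownian), so that
D ~ 1 for a phylogenetically random trait and D ~ 0 for Brownian-like
clumping.  ``p_random`` is the fraction of shuffled d values <= d_obs
(small => the trait is significantly more clumped than random, i.e. D
significantly below 1); ``p_brownian`` is the fraction of Brownian d values
>= d_obs.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

#: branch length substituted for zero-length edges created when resolving
#: polytomies, so the Brownian null has positive variance on every edge
POLYTOMY_EPSILON = 1e-8


def read_tree(path) -> dendropy.Tree:
    """Read a rooted Newick tree (quoted labels supported)."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True, rooting="force-rooted")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True)


def resolve_polytomies(tree: dendropy.Tree, seed: int) -> dendropy.Tree:
    """Split multifurcations into arbitrary bifurcations (deterministic per seed).

    New internal edges get length :data:`POLYTOMY_EPSILON` so Brownian
    simulation keeps positive variance.  A bifurcating tree passes through
    unchanged (a clone is returned either way).
    """
    out = tree.clone(depth=1)
    rng = _random.Random(seed)
    out.resolve_polytomies(rng=rng)
    for edge in out.preorder_edge_iter():
        if edge.head_node.parent_node is not None and not edge.length:
            edge.length = POLYTOMY_EPSILON
    return out


class _IndexedTree:
    """Array view of a rooted bifurcating tree for vectorised trait sweeps.

    Nodes are indexed 0..2n-2 with tips first (in a fixed label order), and
    internal nodes in post-order so a single forward loop implements the
    daughter-mean recursion.
    """

    def __init__(self, tree: dendropy.Tree):
        tips = [lf for lf in tree.leaf_node_iter()]
        for nd in tree.preorder_node_iter():
            if not nd.is_leaf() and len(nd.child_nodes()) != 2:
                raise ValueError(
                    "tree must be strictly bifurcating; resolve polytomies first"
                )
        labels = [t.taxon.label if t.taxon else t.label for t in tips]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")
        order = np.argsort(labels, kind="stable")
        tips = [tips[i] for i in order]
        self.tip_labels = [labels[i] for i in order]
        self.n_tips = len(tips)
        index = {}
        for i, t in enumerate(tips):
            index[id(t)] = i
        internals = [nd for nd in tree.postorder_node_iter() if not nd.is_leaf()]
        for j, nd in enumerate(internals):
            index[id(nd)] = self.n_tips + j
        self.n_nodes = self.n_tips + len(internals)
        # post-order internal schedule: (node, left child, right child)
        self.int_idx = np.array([index[id(nd)] for nd in internals], dtype=np.intp)
        self.left = np.array([index[id(nd.child_nodes()[0])] for nd in internals], dtype=np.intp)
        self.right = np.array([index[id(nd.child_nodes()[1])] for nd in internals], dtype=np.intp)
        # pre-order edge schedule for Brownian simulation
        pre = [nd for nd in tree.preorder_node_iter()]
        self.root_idx = index[id(pre[0])]
        self.pre_child = []
        self.pre_parent = []
        self.pre_blen = []
        for nd in pre[1:]:
            self.pre_child.append(index[id(nd)])
            self.pre_parent.append(index[id(nd.parent_node)])
            blen = nd.edge.length
            if blen is None or blen <= 0:
                raise ValueError("all branch lengths must be positive")
            self.pre_blen.append(float(blen))
        self.pre_child = np.array(self.pre_child, dtype=np.intp)
        self.pre_parent = np.array(self.pre_parent, dtype=np.intp)
        self.pre_blen = np.array(self.pre_blen, dtype=float)

    def sister_diff_sum(self, tip_values: np.ndarray) -> np.ndarray:
        """Sum of |left - right| over internal nodes, vectorised over rows.

        ``tip_values``: (m, n_tips) array in ``tip_labels`` order; returns (m,).
        """
        tip_values = np.atleast_2d(np.asarray(tip_values, dtype=float))
        m = tip_values.shape[0]
        vals = np.empty((m, self.n_nodes))
        vals[:, : self.n_tips] = tip_values
        d = np.zeros(m)
        for k, l, r in zip(self.int_idx, self.left, self.right):
            lv = vals[:, l]
            rv = vals[:, r]
            d += np.abs(lv - rv)
            vals[:, k] = 0.5 * (lv + rv)
        return d

    def simulate_brownian_tips(self, m: int, rng: np.random.Generator) -> np.ndarray:
        """m independent Brownian characters: tip values, variance = branch length."""
        vals = np.zeros((m, self.n_nodes))
        sq = np.sqrt(self.pre_blen)
        for child, parent, s in zip(self.pre_child, self.pre_parent, sq):
            vals[:, child] = vals[:, parent] + s * rng.standard_normal(m)
        return vals[:, : self.n_tips]


def threshold_at_prevalence(values: np.ndarray, k: int) -> np.ndarray:
    """Binarise each row at its own quantile so exactly k entries are 1 (the top k)."""
    values = np.atleast_2d(values)
    m, n = values.shape
    out = np.zeros((m, n), dtype=float)
    idx = np.argpartition(values, n - k, axis=1)[:, n - k:]
    np.put_along_axis(out, idx, 1.0, axis=1)
    return out


@dataclass
class DStatResult:
    """Fritz-Purvis D with its two permutation nulls.

    ``p_random`` small => trait significantly more clumped than a random
    shuffle (D significantly below 1).  ``D`` is NaN when the two null means
    coincide (degenerate tree).
    """

    d_obs: float
    D: float
    p_random: float
    p_brownian: float
    mean_d_random: float
    mean_d_brownian: float
    n_permutations: int
    seed: int | None

    @property
    def defined(self) -> bool:
        return not np.isnan(self.D)


def fritz_purvis_d(
    tree: dendropy.Tree,
    trait,
    n_perm: int = 1000,
    seed: int | None = None,
) -> DStatResult:
    """Estimate D for a binary trait on a rooted bifurcating tree.

    ``trait`` maps every tip label to 0/1 (dict or pandas Series).  Both
    states must be present; a monomorphic trait has no signal to test.
    The two nulls draw from independent substreams of ``seed``.
    """
    indexed = tree if isinstance(tree, _IndexedTree) else _IndexedTree(tree)
    trait = pd.Series(trait)
    missing = set(indexed.tip_labels) - set(trait.index)
    if missing:
        raise ValueError("trait missing for tips: " + ", ".join(sorted(missing)))
    states = trait.reindex(indexed.tip_labels).to_numpy(dtype=float)
    if not np.isin(states, [0.0, 1.0]).all():
        raise ValueError("trait must be binary (0/1)")
    k = int(states.sum())
    n = indexed.n_tips
    if k == 0 or k == n:
        raise ValueError("trait is monomorphic; D is undefined")

    d_obs = float(indexed.sister_diff_sum(states[None, :])[0])

    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    rng_shuffle, rng_brownian = (np.random.default_rng(s) for s in ss.spawn(2))

    shuffled = np.tile(states, (n_perm, 1))
    shuffled = rng_shuffle.permuted(shuffled, axis=1)
    d_rand = indexed.sister_diff_sum(shuffled)

    bm_tips = indexed.simulate_brownian_tips(n_perm, rng_brownian)
    d_brown = indexed.sister_diff_sum(threshold_at_prevalence(bm_tips, k))

    mean_r = float(d_rand.mean())
    mean_b = float(d_brown.mean())
    if mean_r == mean_b:
        D = float("nan")
    else:
        D = (d_obs - mean_b) / (mean_r - mean_b)
    return DStatResult(
        d_obs=d_obs,
        D=D,
        p_random=float(np.mean(d_rand <= d_obs)),
        p_brownian=float(np.mean(d_brown >= d_obs)),
        mean_d_random=mean_r,
        mean_d_brownian=mean_b,
        n_permutations=n_perm,
        seed=seed,
    )
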