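"""Fossil tree time-scaling and phylogenetic principal components analysis.

Time-scaling uses "basic" dating: each internal node is aged at the oldest
first-appearance datum (FAD) among its descendants, then parents are pushed
rootward (post-order, children first) until every branch reaches the
configured minimum length (default 1.0 Myr), which also guarantees an
invertible Brownian-motion covariance.

The pPCA follows the generalized-least-squares formulation: with C the
n x n Brownian tree covariance (shared root-to-MRCA path lengths),

    a = (1' C^-1 1)^-1 1' C^-1 X          (phylogenetic mean)
    R = (X - 1a)' C^-1 (X - 1a) / (n - 1) (evolutionary covariance)

``bm-correlation`` (the default) eigen-decomposes the correlation-
standardized R with scores on standardized deviations; ``bm-covariance``
uses R directly; ``uniform-bl`` first sets every branch length to 1;
``ordinary`` ignores the tree entirely (arithmetic mean, sample moments).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .errors import SingularMatrixError, ValidationError

MODES = ("bm-correlation", "bm-covariance", "uniform-bl", "ordinary")


def _newick_text(source) -> str:
    """Accept a newick string, a path to one, or a Path object."""
    if isinstance(source, Path):
        return source.read_text()
    s = str(source)
    if "(" in s or ";" in s:
        return s
    try:
        if Path(s).exists():
            return Path(s).read_text()
    except OSError:
        pass
    return s


# ----------------------------------------------------------------- time tree
@dataclass
class TimeTree:
    """A rooted, time-scaled tree (branch lengths in Myr) with node ages (Ma)."""

    tree: dendropy.Tree
    node_ages: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_newick(cls, source: str | Path) -> "TimeTree":
        tree = dendropy.Tree.get(data=_newick_text(source), schema="newick")
        tt = cls(tree=tree)
        tt._ages_from_lengths()
        return tt

    def _ages_from_lengths(self) -> None:
        """Derive relative node ages from branch lengths (root depth 0)."""
        depths = {}
        for node in self.tree.preorder_node_iter():
            d = 0.0 if node.parent_node is None else (
                depths[node.parent_node] + (node.edge.length or 0.0))
            depths[node] = d
        max_d = max(depths.values())
        self.node_ages = {n: max_d - d for n, d in depths.items()}

    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    def branch_lengths(self) -> dict[str, float]:
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                label = (node.taxon.label if node.taxon is not None
                         else f"node{id(node) % 10_000}")
                out[label] = node.edge.length
        return out

    def with_uniform_branch_lengths(self, length: float = 1.0) -> "TimeTree":
        clone = dendropy.Tree(self.tree)
        for edge in clone.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                edge.length = length
        tt = TimeTree(tree=clone)
        tt._ages_from_lengths()
        return tt


def time_scale_tree(topology, first_appearances: Mapping[str, float],
                    min_bl: float = 1.0) -> TimeTree:
    """Basic dating with a minimum branch length.

    ``topology`` is a dendropy Tree, a TimeTree, or a newick string/path;
    existing branch lengths are ignored. ``first_appearances`` maps every tip
    label to its FAD in Ma. Node age = max over children of (child age +
    min_bl), computed children-first so each parent is pushed rootward past
    its oldest descendant in a single pass.
    """
    if isinstance(topology, TimeTree):
        tree = dendropy.Tree(topology.tree)
    elif isinstance(topology, dendropy.Tree):
        tree = dendropy.Tree(topology)
    else:
        tree = dendropy.Tree.get(data=_newick_text(topology), schema="newick")

    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = sorted(t for t in tips if t not in first_appearances)
    if missing:
        raise ValidationError(f"missing first-appearance ages for tips: {missing}")
    for t in tips:
        age = first_appearances[t]
        if not (np.isfinite(age) and age > 0):
            raise ValidationError(f"first-appearance age for {t!r} must be positive finite")
    if min_bl < 0:
        raise ValidationError("min_bl must be >= 0")

    ages = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            ages[node] = float(first_appearances[node.taxon.label])
        else:
            ages[node] = max(ages[ch] + min_bl for ch in node.child_nodes())
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = ages[node.parent_node] - ages[node]
    return TimeTree(tree=tree, node_ages=ages)


def phylo_vcv(timetree: TimeTree) -> pd.DataFrame:
    """Brownian tree covariance: C[i,j] = root-to-MRCA(i,j) path length."""
    tree = timetree.tree
    depths = {}
    for node in tree.preorder_node_iter():
        depths[node] = (0.0 if node.parent_node is None
                        else depths[node.parent_node] + (node.edge.length or 0.0))
    leaves = list(tree.leaf_node_iter())
    labels = [l.taxon.label for l in leaves]
    n = len(leaves)
    C = np.zeros((n, n))
    for i, leaf in enumerate(leaves):
        C[i, i] = depths[leaf]
    # tips in different child subtrees of a node share exactly that node's depth
    tipsets = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = [labels.index(node.taxon.label)]
        else:
            groups = [tipsets[ch] for ch in node.child_nodes()]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for i in groups[gi]:
                        for j in groups[gj]:
                            C[i, j] = C[j, i] = depths[node]
            tipsets[node] = [i for g in groups for i in g]
    return pd.DataFrame(C, index=labels, columns=labels)


# ----------------------------------------------------------------------- pPCA
@dataclass
class PPCAResults:
    """Eigenstructure of an (evolutionary) covariance or correlation matrix.

    ``loadings`` columns are unit length with the deterministic sign
    convention that each column's largest-magnitude element is positive.
    """

    mode: str
    phylo_mean: pd.Series
    evo_covariance: pd.DataFrame
    evo_correlation: pd.DataFrame
    tree_covariance: pd.DataFrame | None
    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    scores: pd.DataFrame
    variance_proportions: np.ndarray

    @property
    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.variance_proportions)

    def variance_percent(self, k: int | None = None) -> float:
        """Cumulative percent variance of the first k components (all if None)."""
        k = len(self.variance_proportions) if k is None else k
        return float(100.0 * self.cumulative_variance[k - 1])

    def summary(self) -> str:
        lines = [
            "Phylogenetic principal components analysis",
            f"  mode: {self.mode}",
            f"  taxa: {len(self.scores)}   traits: {len(self.loadings)}",
            "",
            f"{'component':>10} {'eigenvalue':>12} {'%var':>8} {'cum%':>8}",
        ]
        for k, (lam, p, c) in enumerate(
            zip(self.eigenvalues, self.variance_proportions, self.cumulative_variance), 1
        ):
            lines.append(f"{'PC' + str(k):>10} {lam:>12.5g} {100 * p:>8.2f} {100 * c:>8.2f}")
        lines.append("")
        lines.append("Loadings:")
        with pd.option_context("display.width", 120, "display.float_format",
                               lambda v: f"{v: .3f}"):
            lines.append(self.loadings.to_string())
        return "\n".join(lines)

    def plot_morphospace(self, pcs: tuple[int, int] = (1, 2), ax=None,
                         labels: bool = True):
        """Scatter of taxa in a plane of the morphospace (1-based PC indices)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        i, j = pcs[0] - 1, pcs[1] - 1
        xs = self.scores.iloc[:, i]
        ys = self.scores.iloc[:, j]
        ax.scatter(xs, ys)
        if labels:
            for taxon, x, y in zip(self.scores.index, xs, ys):
                ax.annotate(taxon, (x, y), fontsize=7)
        ax.set_xlabel(f"PC{pcs[0]} ({100 * self.variance_proportions[i]:.0f}%)")
        ax.set_ylabel(f"PC{pcs[1]} ({100 * self.variance_proportions[j]:.0f}%)")
        ax.axhline(0, lw=0.5, color="0.6")
        ax.axvline(0, lw=0.5, color="0.6")
        return ax


class PhylogeneticPCA:
    """pPCA model object: trait table + time tree -> :class:`PPCAResults`.

    Parameters
    ----------
    X : DataFrame
        n taxa x p traits, no missing values, n >= 3, p >= 2. Row index
        must match the tree's tip labels (any order).
    tree : TimeTree, optional
        Required for the phylogenetic modes; ignored by ``ordinary``.
    mode : str
        One of ``bm-correlation`` (default), ``bm-covariance``,
        ``uniform-bl``, ``ordinary``.
    correlation : bool
        Whether ``uniform-bl`` / ``ordinary`` standardize to a correlation
        matrix (default True, mirroring the primary analysis).
    """

    def __init__(self, X: pd.DataFrame, tree: TimeTree | None = None,
                 mode: str = "bm-correlation", correlation: bool = True):
        X = pd.DataFrame(X).astype(float)
        if X.isna().any().any():
            raise ValidationError("trait table contains missing values")
        if X.shape[0] < 3 or X.shape[1] < 2:
            raise ValidationError("need >= 3 taxa and >= 2 traits")
        if mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}")
        if mode != "ordinary":
            if tree is None:
                raise ValidationError(f"mode {mode!r} requires a tree")
            tips = set(tree.taxa)
            rows = set(X.index)
            if tips != rows:
                raise ValidationError(
                    f"tips and trait rows differ: only-in-tree={sorted(tips - rows)}, "
                    f"only-in-table={sorted(rows - tips)}"
                )
        self.X = X
        self.tree = tree
        self.mode = mode
        self.correlation = correlation

    @classmethod
    def from_files(cls, traits_csv, tree_newick=None, ages_csv=None,
                   mode: str = "bm-correlation", min_bl: float = 1.0,
                   **kwargs) -> "PhylogeneticPCA":
        """Build from the on-disk dialects: traits CSV (taxon-indexed),
        newick topology, and optional FAD table (taxon, FAD_Ma[, LAD_Ma])."""
        X = pd.read_csv(traits_csv, index_col=0, comment="#")
        tree = None
        if tree_newick is not None:
            if ages_csv is not None:
                ages = pd.read_csv(ages_csv)
                fads = dict(zip(ages.iloc[:, 0], ages["FAD_Ma"]))
                tree = time_scale_tree(Path(str(tree_newick)).read_text(), fads, min_bl=min_bl)
            else:
                tree = TimeTree.from_newick(Path(str(tree_newick)))
        return cls(X, tree=tree, mode=mode, **kwargs)

    def fit(self) -> PPCAResults:
        X = self.X
        n, p = X.shape
        traits = list(X.columns)
        Xv = X.to_numpy()

        if self.mode == "ordinary":
            C_df = None
            a = Xv.mean(axis=0)
            Xc = Xv - a
            R = (Xc.T @ Xc) / (n - 1)
            use_corr = self.correlation
        else:
            tree = self.tree
            if self.mode == "uniform-bl":
                tree = tree.with_uniform_branch_lengths(1.0)
            C_df = phylo_vcv(tree).loc[X.index, X.index]
            C = C_df.to_numpy()
            try:
                cf = cho_factor(C)
            except np.linalg.LinAlgError as e:
                raise SingularMatrixError(f"tree covariance is singular: {e}")
            one = np.ones((n, 1))
            Ci1 = cho_solve(cf, one)
            denom = (one.T @ Ci1).item()
            if denom <= 0:
                raise SingularMatrixError("tree covariance is numerically singular")
            a = (Ci1.T @ Xv).ravel() / denom
            Xc = Xv - a
            R = (Xc.T @ cho_solve(cf, Xc)) / (n - 1)
            use_corr = (self.mode != "bm-covariance")

        sd = np.sqrt(np.diag(R))
        if np.any(sd <= 0):
            bad = [traits[i] for i in np.where(sd <= 0)[0]]
            raise ValidationError(f"traits with zero evolutionary variance: {bad}")
        Rstar = R / np.outer(sd, sd)

        target = Rstar if use_corr else R
        lam, V = np.linalg.eigh(target)
        order = np.argsort(lam, kind="stable")[::-1]
        lam = lam[order]
        V = V[:, order]
        lam = np.where((lam < 0) & (lam > -1e-12), 0.0, lam)
        # deterministic sign: largest-|.| element of each column positive
        for k in range(V.shape[1]):
            idx = int(np.argmax(np.abs(V[:, k])))
            if V[idx, k] < 0:
                V[:, k] = -V[:, k]

        dev = Xc / sd if use_corr else Xc
        S = dev @ V
        pcs = [f"PC{k + 1}" for k in range(p)]
        return PPCAResults(
            mode=self.mode,
            phylo_mean=pd.Series(a, index=traits, name="phylo_mean"),
            evo_covariance=pd.DataFrame(R, index=traits, columns=traits),
            evo_correlation=pd.DataFrame(Rstar, index=traits, columns=traits),
            tree_covariance=C_df,
            eigenvalues=lam,
            loadings=pd.DataFrame(V, index=traits, columns=pcs),
            scores=pd.DataFrame(S, index=X.index, columns=pcs),
            variance_proportions=lam / lam.sum(),
        )


def ppca(X: pd.DataFrame, tree: TimeTree | None = None,
         mode: str = "bm-correlation", **kwargs) -> PPCAResults:
    """Functional wrapper around :class:`PhylogeneticPCA`."""
    return PhylogeneticPCA(X, tree=tree, mode=mode, **kwargs).fit()
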