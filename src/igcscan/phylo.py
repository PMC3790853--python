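"""Tree inference and substitution-model fitting for paralog families.

The family topology is inferred by neighbor joining on F84 maximum-
likelihood distances, with bootstrap supports from column resampling.
Families whose tree contains a poorly supported node are reduced by
iteratively dropping a random leaf under the worst node; families that
fall below four members are rejected.  A GTR+Gamma(4)+I model is fitted on
the fixed topology by numerical likelihood maximisation (Felsenstein
pruning over compressed site patterns) and drives the no-exchange
simulation null.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .family_io import AlignedFamily, RejectionReport
from .substitution import SubstitutionModel

TOPOLOGY_LABELS = ("AB|CD", "AC|BD", "AD|BC")
#: index pairs grouped by each of the three quartet topologies, in the
#: order of TOPOLOGY_LABELS
TOPOLOGY_PAIRINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


@dataclass
class Tree:
    """Unrooted tree over family members: a scikit-bio ``TreeNode`` plus
    bootstrap supports keyed by canonical split."""

    node: TreeNode
    supports: dict[frozenset, float] = field(default_factory=dict)

    @property
    def leaf_names(self) -> list[str]:
        return [t.name for t in self.node.tips()]

    def copy(self) -> "Tree":
        return Tree(self.node.copy(), dict(self.supports))

    def splits(self) -> list[frozenset]:
        """Non-trivial splits, each as the canonical (lexicographically
        smaller) side of the bipartition."""
        all_names = frozenset(self.leaf_names)
        out = []
        for n in self.node.non_tips(include_self=False):
            clade = frozenset(t.name for t in n.tips())
            if 2 <= len(clade) <= len(all_names) - 2:
                out.append(canonical_split(clade, all_names))
        return out

    def clades(self) -> list[frozenset]:
        """Non-trivial internal clades as seen from the root placement."""
        all_names = frozenset(self.leaf_names)
        return [
            frozenset(t.name for t in n.tips())
            for n in self.node.non_tips(include_self=False)
            if 2 <= sum(1 for _ in n.tips()) <= len(all_names) - 2
        ]

    def to_newick(self) -> str:
        return str(self.node).strip()

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        return cls(TreeNode.read([text]))


def canonical_split(side: frozenset, all_names: frozenset) -> frozenset:
    other = all_names - side
    return side if tuple(sorted(side)) < tuple(sorted(other)) else other


# ---------------------------------------------------------------------------
# F84 distances


def f84_distance(a: np.ndarray, b: np.ndarray) -> float:
    """F84 maximum-likelihood distance between two gapless aligned
    sequences (integer-encoded).  Returns ``inf`` when the logarithms are
    undefined (saturation)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("sequences must be equal-length and non-empty")
    n = a.size
    diff = a != b
    purine = np.isin(a, (0, 2)) & np.isin(b, (0, 2))
    pyrim = np.isin(a, (1, 3)) & np.isin(b, (1, 3))
    p = float((diff & (purine | pyrim)).sum()) / n  # transitions
    q = float(diff.sum()) / n - p  # transversions

    counts = np.bincount(a, minlength=4) + np.bincount(b, minlength=4)
    pi = counts / counts.sum()
    pi_a, pi_c, pi_g, pi_t = pi
    pi_r, pi_y = pi_a + pi_g, pi_c + pi_t
    if pi_r == 0 or pi_y == 0:
        raise ValueError("degenerate base composition")
    big_a = pi_a * pi_g / pi_r + pi_c * pi_t / pi_y
    big_b = pi_a * pi_g + pi_c * pi_t
    big_c = pi_r * pi_y
    if big_a == 0 or big_c == 0:
        raise ValueError("degenerate base composition")
    x = 1.0 - p / (2 * big_a) - (big_a - big_b) * q / (2 * big_a * big_c)
    y = 1.0 - q / (2 * big_c)
    if x <= 0 or y <= 0:
        return float("inf")
    return float(-2 * big_a * np.log(x) + 2 * (big_a - big_b - big_c) * np.log(y))


def f84_distance_matrix(fam: AlignedFamily, cols: np.ndarray | None = None) -> np.ndarray:
    m = fam.matrix if cols is None else fam.matrix[:, cols]
    n = fam.n_members
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = f84_distance(m[i], m[j])
    return d


# ---------------------------------------------------------------------------
# neighbor joining with bootstrap supports


def _nj_from_matrix(d: np.ndarray, names: list[str]) -> TreeNode:
    dm = DistanceMatrix(d, ids=names)
    tree = nj(dm)
    # NJ can emit slightly negative branch lengths; clamp for downstream use
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def build_nj_tree(fam: AlignedFamily, n_boot: int = 100, seed: int | None = 0) -> Tree:
    """NJ topology on F84 distances with column-bootstrap supports.

    Supports are the fraction of ``n_boot`` column-resampled replicates in
    which each internal split of the primary tree reappears; pass
    ``n_boot=0`` to skip the bootstrap.  Deterministic given ``seed``.
    """
    if fam.n_members < 4:
        raise ValueError("need at least 4 members")
    d = f84_distance_matrix(fam)
    if not np.isfinite(d).all():
        i, j = np.argwhere(~np.isfinite(d))[0]
        raise ValueError(
            f"saturated F84 distance between {fam.names[i]} and {fam.names[j]}"
        )
    tree = Tree(_nj_from_matrix(d, fam.names))
    all_names = frozenset(fam.names)
    target = {s: 0 for s in tree.splits()}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        for _ in range(n_boot):
            cols = rng.integers(0, fam.length, size=fam.length)
            db = f84_distance_matrix(fam, cols)
            if not np.isfinite(db).all():
                continue
            bt = Tree(_nj_from_matrix(db, fam.names))
            for s in bt.splits():
                if s in target:
                    target[s] += 1
        tree.supports = {s: c / n_boot for s, c in target.items()}
    else:
        tree.supports = {s: float("nan") for s in target}
    return tree


def prune_low_support(
    fam: AlignedFamily,
    tree: Tree,
    threshold: float = 0.88,
    seed: int | None = 0,
    n_boot: int = 100,
):
    """Iteratively drop a random leaf under the worst-supported node until
    every support reaches ``threshold``; reject below four members.

    Returns ``(fam, tree)`` on success or a :class:`RejectionReport`.
    """
    rng = np.random.default_rng(seed)
    while True:
        if not tree.supports or min(tree.supports.values()) >= threshold:
            return fam, tree
        if fam.n_members <= 4:
            return RejectionReport(fam.family_id, "low support",
                                   "cannot prune below 4 members")
        worst_split = min(tree.supports, key=tree.supports.get)
        # leaves stemming from the worst node = members of the smaller side
        candidates = sorted(worst_split)
        victim = candidates[rng.integers(0, len(candidates))]
        keep = [i for i, n in enumerate(fam.names) if n != victim]
        fam = AlignedFamily(
            fam.family_id,
            [fam.members[i] for i in keep],
            fam.matrix[keep],
            fam.col_map[keep],
        )
        tree = build_nj_tree(fam, n_boot=n_boot, seed=int(rng.integers(2**31)))


# ---------------------------------------------------------------------------
# likelihood machinery (GTR+Gamma+I on a fixed topology)


def _compress_patterns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cols, counts = np.unique(matrix.T, axis=0, return_counts=True)
    return cols.T, counts.astype(float)


class _TreeLikelihood:
    """Felsenstein pruning over compressed site patterns on a fixed
    topology; rates mixed over the invariant class plus gamma classes."""

    def __init__(self, fam: AlignedFamily, tree: Tree):
        self.patterns, self.counts = _compress_patterns(fam.matrix)
        self.n_patterns = self.patterns.shape[1]
        root = tree.node.copy()
        # ensure binary-ish rooted traversal is fine; collect postorder
        self.postorder = list(root.postorder(include_self=True))
        self.root = root
        self.name_to_row = {n: i for i, n in enumerate(fam.names)}
        self.tip_partials = {}
        for node in self.postorder:
            if node.is_tip():
                row = self.patterns[self.name_to_row[node.name]]
                part = np.zeros((4, self.n_patterns))
                part[row, np.arange(self.n_patterns)] = 1.0
                self.tip_partials[id(node)] = part
        self.branches = [n for n in self.postorder if n is not self.root]
        self.n_branches = len(self.branches)

    def loglik(self, model: SubstitutionModel, branch_lengths: np.ndarray) -> float:
        blen = {id(n): branch_lengths[i] for i, n in enumerate(self.branches)}
        rates, weights = model.site_rates()
        pi = model.base_freqs
        site_lik = np.zeros(self.n_patterns)
        for r, w in zip(rates, weights):
            partials: dict[int, np.ndarray] = {}
            for node in self.postorder:
                if node.is_tip():
                    partials[id(node)] = self.tip_partials[id(node)]
                    continue
                part = np.ones((4, self.n_patterns))
                for child in node.children:
                    p = (
                        model.transition_matrix(blen[id(child)] * r)
                        if r > 0
                        else np.eye(4)
                    )
                    part *= p @ partials[id(child)]
                partials[id(node)] = part
            site_lik += w * (pi @ partials[id(self.root)])
        site_lik = np.clip(site_lik, 1e-300, None)
        return float(self.counts @ np.log(site_lik))


@dataclass
class GTRFitResults:
    """Fitted substitution model and optimisation diagnostics."""

    model: SubstitutionModel
    loglik: float
    branch_lengths: np.ndarray
    tree: Tree
    converged: bool
    n_evals: int

    def summary(self) -> str:
        ex = ", ".join(f"{v:.3f}" for v in self.model.exchangeabilities)
        pi = ", ".join(f"{v:.3f}" for v in self.model.base_freqs)
        return (
            "GTR+Gamma+I fit\n"
            f"  log-likelihood : {self.loglik:.2f}\n"
            f"  exchangeabilities (AC,AG,AT,CG,CT,GT): {ex}\n"
            f"  base frequencies (A,C,G,T): {pi}\n"
            f"  gamma shape    : {self.model.gamma_shape:.3f}\n"
            f"  p_invariant    : {self.model.p_inv:.3f}\n"
            f"  converged      : {self.converged}\n"
        )


def empirical_base_freqs(fam: AlignedFamily) -> np.ndarray:
    counts = np.bincount(fam.matrix.ravel(), minlength=4)
    return counts / counts.sum()


def fit_substitution_model(
    fam: AlignedFamily,
    tree: Tree,
    n_rate_classes: int = 4,
    maxiter: int = 200,
) -> GTRFitResults:
    """Fit GTR+Gamma+I by likelihood maximisation on the fixed topology.

    Base frequencies are fixed at their empirical values; exchangeabilities
    (GT normalised to 1), gamma shape, invariant fraction and branch
    lengths are optimised jointly with L-BFGS-B in log/logit space.
    """
    pi = empirical_base_freqs(fam)
    lik = _TreeLikelihood(fam, tree)
    nb = lik.n_branches
    init_blen = np.array(
        [max(b.length or 0.0, 1e-4) for b in lik.branches]
    )

    # theta = [log ex (5), log alpha, logit p_inv, log blen (nb)]
    theta0 = np.concatenate([np.zeros(5), [0.0], [-2.0], np.log(init_blen)])
    n_evals = [0]

    def unpack(theta):
        ex = np.concatenate([np.exp(theta[:5]), [1.0]])
        alpha = float(np.exp(theta[5]))
        p_inv = float(1.0 / (1.0 + np.exp(-theta[6]))) * 0.75
        blen = np.exp(theta[7:])
        model = SubstitutionModel(ex, pi, gamma_shape=alpha, p_inv=p_inv,
                                  n_rate_classes=n_rate_classes)
        return model, blen

    def negloglik(theta):
        n_evals[0] += 1
        model, blen = unpack(theta)
        return -lik.loglik(model, blen)

    bounds = (
        [(-4, 4)] * 5 + [(np.log(0.05), np.log(50.0))] + [(-12, 4)]
        + [(np.log(1e-7), np.log(5.0))] * nb
    )
    res = minimize(negloglik, theta0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": maxiter})
    if not np.isfinite(res.fun):
        raise RuntimeError(f"model fit failed to produce a finite likelihood: {res}")
    model, blen = unpack(res.x)
    fitted_tree = tree.copy()
    # write optimised branch lengths back in the postorder used by the fit
    fit_lik = _TreeLikelihood(fam, fitted_tree)
    for node, b in zip(fit_lik.branches, blen):
        node.length = float(b)
    fitted_tree.node = fit_lik.root
    return GTRFitResults(
        model=model,
        loglik=-float(res.fun),
        branch_lengths=blen,
        tree=fitted_tree,
        converged=bool(res.success),
        n_evals=n_evals[0],
    )


class GTRModel:
    """statsmodels-style front end: ``GTRModel(family, tree).fit()``."""

    def __init__(self, family: AlignedFamily, tree: Tree):
        self.family = family
        self.tree = tree

    def fit(self, **kwargs) -> GTRFitResults:
        return fit_substitution_model(self.family, self.tree, **kwargs)


# ---------------------------------------------------------------------------
# quartet topologies


def induced_quartet_topology(tree: Tree, leaves: tuple[str, str, str, str]) -> str:
    """The split of four leaves induced by the tree, as one of
    ``AB|CD``, ``AC|BD``, ``AD|BC`` relative to the given leaf order.

    Uses edge-count (topological) path lengths, so zero-length internal
    branches still resolve.
    """
    if len(set(leaves)) != 4:
        raise ValueError("need 4 distinct leaves")
    tips = {}
    for t in tree.node.tips():
        if t.name in leaves:
            tips[t.name] = t
    missing = set(leaves) - set(tips)
    if missing:
        raise ValueError(f"leaves not in tree: {sorted(missing)}")

    ancestors = {}
    for name, t in tips.items():
        chain = [t] + list(t.ancestors())
        ancestors[name] = {id(n): depth for depth, n in enumerate(chain)}

    def dist(x, y):
        ax, ay = ancestors[x], ancestors[y]
        best = None
        for node_id, dx in ax.items():
            if node_id in ay:
                tot = dx + ay[node_id]
                best = tot if best is None or tot < best else best
        return best

    a, b, c, d = leaves
    sums = [
        dist(a, b) + dist(c, d),
        dist(a, c) + dist(b, d),
        dist(a, d) + dist(b, c),
    ]
    order = np.argsort(sums)
    if sums[order[0]] == sums[order[1]]:
        raise ValueError("quartet is unresolved (multifurcation)")
    return TOPOLOGY_LABELS[order[0]]


def nni_concordance_check(fam: AlignedFamily, tree: Tree, fit: GTRFitResults) -> bool:
    """Lightweight ML concordance filter: the fitted topology should beat
    every nearest-neighbour-interchange rearrangement of each internal
    edge at the fitted model and branch lengths.  Returns True when the
    tree is concordant."""
    base = _TreeLikelihood(fam, fit.tree).loglik(
        fit.model, np.array([n.length or 0.0 for n in _TreeLikelihood(fam, fit.tree).branches])
    )
    for alt in _nni_neighbors(fit.tree):
        alt_lik = _TreeLikelihood(fam, alt)
        bl = np.array([n.length or 1e-4 for n in alt_lik.branches])
        if alt_lik.loglik(fit.model, bl) > base + 1e-6:
            return False
    return True


def _nni_neighbors(tree: Tree):
    """Yield the NNI rearrangements of each internal edge."""
    base = tree.node.copy()
    internal = [
        n for n in base.non_tips(include_self=False)
        if n.parent is not None and len(n.children) == 2
    ]
    for i, node in enumerate(internal):
        parent = node.parent
        siblings = [c for c in parent.children if c is not node]
        if not siblings:
            continue
        sib = siblings[0]
        for child_idx in (0, 1):
            t2 = tree.node.copy()
            internal2 = [
                n for n in t2.non_tips(include_self=False)
                if n.parent is not None and len(n.children) == 2
            ]
            node2 = internal2[i]
            parent2 = node2.parent
            sib2 = [c for c in parent2.children if c is not node2][0]
            child2 = node2.children[child_idx]
            # swap child2 and sib2
            node2.remove(child2)
            parent2.remove(sib2)
            node2.append(sib2)
            parent2.append(child2)
            yield Tree(t2)
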