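"""General time-reversible substitution model with gamma rate variation.

The model is GTR+Gamma(4)+I: six symmetric exchangeabilities, stationary
base frequencies, a discrete gamma distribution of site rates (category
means) and a proportion of invariant sites.  Branch lengths are expressed
in expected substitutions per site, so the rate matrix is normalised to
unit mean flux and the gamma rates are rescaled by 1/(1-p_inv) to keep the
overall mean site rate at 1.

Bases are encoded as integers 0..3 = A, C, G, T throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.stats import gamma as gamma_dist

ALPHABET = "ACGT"
A, C, G, T = 0, 1, 2, 3

#: order of the six GTR exchangeabilities
EXCHANGE_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode an A/C/G/T string as a uint8 array (case-insensitive)."""
    arr = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return arr


def decode(arr: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in arr)


def discrete_gamma_rates(alpha: float, n_classes: int = 4) -> np.ndarray:
    """Category-mean rates of a mean-1 gamma split into equiprobable classes.

    Uses the standard construction: class boundaries at quantiles i/k of
    Gamma(alpha, scale=1/alpha) and the conditional mean within each class,
    computed from the incomplete-gamma identity
    E[X; a<X<b] = F_{alpha+1}(b) - F_{alpha+1}(a) for scale 1/alpha.
    """
    if alpha <= 0:
        raise ValueError("gamma shape must be positive")
    k = n_classes
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), alpha, scale=1.0 / alpha)
    upper = gamma_dist.cdf(edges[1:], alpha + 1, scale=1.0 / alpha)
    lower = gamma_dist.cdf(edges[:-1], alpha + 1, scale=1.0 / alpha)
    rates = k * (upper - lower)
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """GTR+Gamma+I parameters.

    Parameters
    ----------
    exchangeabilities : array-like of 6 floats
        Symmetric rates in :data:`EXCHANGE_ORDER` (AC, AG, AT, CG, CT, GT).
        Scale is arbitrary; the rate matrix is renormalised.
    base_freqs : array-like of 4 floats
        Stationary frequencies pi(A, C, G, T); must sum to 1.
    gamma_shape : float
        Shape alpha of the gamma rate distribution.
    p_inv : float
        Proportion of invariant (rate-0) sites.
    n_rate_classes : int
        Number of discrete gamma categories.
    """

    exchangeabilities: np.ndarray
    base_freqs: np.ndarray
    gamma_shape: float = 1.0
    p_inv: float = 0.0
    n_rate_classes: int = 4
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.base_freqs = np.asarray(self.base_freqs, dtype=float)
        if self.exchangeabilities.shape != (6,) or (self.exchangeabilities < 0).any():
            raise ValueError("need 6 nonnegative exchangeabilities")
        if self.base_freqs.shape != (4,) or not np.isclose(self.base_freqs.sum(), 1.0):
            raise ValueError("base frequencies must be a 4-simplex point")
        if not 0 <= self.p_inv < 1:
            raise ValueError("p_inv must lie in [0, 1)")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")

    # -- rate matrix ------------------------------------------------------

    def rate_matrix(self) -> np.ndarray:
        """Normalised GTR rate matrix Q with -sum_i pi_i Q_ii = 1."""
        s = np.zeros((4, 4))
        pairs = ((A, C), (A, G), (A, T), (C, G), (C, T), (G, T))
        for rate, (i, j) in zip(self.exchangeabilities, pairs):
            s[i, j] = s[j, i] = rate
        q = s * self.base_freqs[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(self.base_freqs * np.diag(q)).sum()
        if mu <= 0:
            raise ValueError("degenerate rate matrix (no substitution flux)")
        return q / mu

    def _eigendecomposition(self):
        if self._eig is None:
            q = self.rate_matrix()
            pi = self.base_freqs
            d = np.sqrt(pi)
            sym = (q * d[:, None]) / d[None, :]
            w, v = linalg.eigh((sym + sym.T) / 2)
            right = v / d[:, None]
            left = v.T * d[None, :]
            # P(t) = right @ diag(exp(w t)) @ left, rows indexed by 'from'
            self._eig = (w, right, left)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows = ancestral state, columns = descendant."""
        if t < 0:
            raise ValueError("negative branch length")
        w, right, left = self._eigendecomposition()
        p = (right * np.exp(w * t)[None, :]) @ left
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)

    # -- rate classes -----------------------------------------------------

    def site_rates(self) -> tuple[np.ndarray, np.ndarray]:
        """(rates, weights) over the invariant class plus gamma classes.

        Gamma category rates are divided by (1 - p_inv) so the weighted
        mean rate is exactly 1.
        """
        g = discrete_gamma_rates(self.gamma_shape, self.n_rate_classes)
        if self.p_inv > 0:
            rates = np.concatenate([[0.0], g / (1.0 - self.p_inv)])
            w = np.concatenate(
                [[self.p_inv], np.full(self.n_rate_classes, (1 - self.p_inv) / self.n_rate_classes)]
            )
        else:
            rates = g
            w = np.full(self.n_rate_classes, 1.0 / self.n_rate_classes)
        return rates, w

    def expected_identity(self, t: float) -> float:
        """Expected fraction of identical sites between two sequences
        separated by total path length ``t`` (substitutions/site)."""
        rates, w = self.site_rates()
        pi = self.base_freqs
        ident = 0.0
        for r, wt in zip(rates, w):
            p = self.transition_matrix(t * r) if r > 0 else np.eye(4)
            ident += wt * float((pi * np.diag(p)).sum())
        return ident

    # -- convenience constructors ----------------------------------------

    @classmethod
    def jukes_cantor(cls, gamma_shape: float = 100.0, p_inv: float = 0.0) -> "SubstitutionModel":
        """Near-JC model (equal rates/frequencies; very large alpha makes
        the gamma effectively degenerate at rate 1)."""
        return cls(np.ones(6), np.full(4, 0.25), gamma_shape=gamma_shape, p_inv=p_inv)

    @classmethod
    def f84(cls, kappa: float, base_freqs) -> "SubstitutionModel":
        """F84 as a GTR special case: transversion exchangeability 1,
        transition exchangeabilities 1 + kappa/pi_group."""
        pi = np.asarray(base_freqs, dtype=float)
        pi_r = pi[A] + pi[G]
        pi_y = pi[C] + pi[T]
        ex = np.ones(6)
        ex[1] = 1.0 + kappa / pi_r  # AG
        ex[4] = 1.0 + kappa / pi_y  # CT
        return cls(ex, pi, gamma_shape=100.0, p_inv=0.0)


def evolve_along_tree(
    tree,
    model: SubstitutionModel,
    length: int,
    rng: np.random.Generator,
    site_rates: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Evolve a root sequence down a (rooted or basal-multifurcating)
    scikit-bio ``TreeNode`` and return leaf sequences.

    Each site is independently assigned the invariant class (probability
    p_inv) or one of the discrete gamma categories; conditional on its rate
    the site evolves by the GTR transition probabilities along every branch.
    The process is reversible, so the placement of the root is immaterial.

    ``site_rates`` overrides the per-site rate draw (used by callers that
    need the same rate layout across replicates).
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if site_rates is None:
        rates, weights = model.site_rates()
        cls_idx = rng.choice(len(rates), size=length, p=weights)
        site_rates = rates[cls_idx]
    root_seq = rng.choice(4, size=length, p=model.base_freqs)

    # group sites by rate value so each branch needs one P(t*r) per group
    uniq_rates, rate_group = np.unique(site_rates, return_inverse=True)

    leaves: dict[str, np.ndarray] = {}
    stack = [(tree, root_seq)]
    while stack:
        node, seq = stack.pop()
        for child in node.children:
            t = child.length or 0.0
            child_seq = seq.copy()
            if t > 0:
                for gi, r in enumerate(uniq_rates):
                    if r == 0:
                        continue
                    idx = np.flatnonzero(rate_group == gi)
                    if idx.size == 0:
                        continue
                    p = model.transition_matrix(t * r)
                    sub = seq[idx]
                    out = np.empty(idx.size, dtype=np.int64)
                    for b in range(4):
                        mask = sub == b
                        n = int(mask.sum())
                        if n:
                            out[mask] = rng.choice(4, size=n, p=p[b])
                    child_seq[idx] = out
            if child.is_tip():
                leaves[child.name] = child_seq
            else:
                stack.append((child, child_seq))
    return leaves
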