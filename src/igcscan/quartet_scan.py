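"""Quartet site classification and the family-level excess test.

Every four-sequence sub-alignment (quartet) of a paralog family is
classified site by site: parsimony-informative columns (two bases, each
twice) are Concordant when the pairing matches the quartet topology
induced by the family tree and Reticulate otherwise; columns with three
or more bases are Bimutational (obligate parallel mutation).  A family
with an excess of R sites relative to a no-exchange simulation null
carries a signal of interlocus recombination.  Clustering of R sites is
interrogated with a Wald-Wolfowitz runs test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.special import comb
from scipy.stats import norm

from .family_io import AlignedFamily
from .null_sim import SimulationSpec, simulate_alignment
from .phylo import Tree, induced_quartet_topology, TOPOLOGY_LABELS
from .substitution import SubstitutionModel

UNINFORMATIVE = -1
B_SITE = 3

_POPCOUNT = np.array([bin(i).count("1") for i in range(16)], dtype=np.int8)


def classify_quartet_columns(m: np.ndarray) -> np.ndarray:
    """Classify every column of a 4-row alignment block.

    Returns an int8 array: -1 uninformative, 0/1/2 the supported quartet
    topology (AB|CD, AC|BD, AD|BC) of an informative two-base column, 3 a
    bimutational (>=3 base) column.
    """
    if m.shape[0] != 4:
        raise ValueError("quartet block must have 4 rows")
    mask = (1 << m[0]) | (1 << m[1]) | (1 << m[2]) | (1 << m[3])
    distinct = _POPCOUNT[mask]
    eq01 = m[0] == m[1]
    eq23 = m[2] == m[3]
    eq02 = m[0] == m[2]
    eq13 = m[1] == m[3]
    eq03 = m[0] == m[3]
    eq12 = m[1] == m[2]
    out = np.full(m.shape[1], UNINFORMATIVE, dtype=np.int8)
    two = distinct == 2
    out[two & eq01 & eq23] = 0
    out[two & eq02 & eq13] = 1
    out[two & eq03 & eq12] = 2
    out[distinct >= 3] = B_SITE
    return out


def classify_quartet_site(column, dominant: int):
    """Classify a single 4-base column against the dominant topology.

    Returns ``("C", None)``, ``("R", alt_topology_index)``,
    ``("B", None)`` or ``("uninformative", None)``.
    """
    col = np.asarray(column, dtype=np.int64).reshape(4, 1)
    code = int(classify_quartet_columns(col)[0])
    if code == UNINFORMATIVE:
        return ("uninformative", None)
    if code == B_SITE:
        return ("B", None)
    if code == dominant:
        return ("C", None)
    return ("R", code)


@dataclass
class QuartetResult:
    """Site classification of one quartet against its induced topology."""

    leaves: tuple[str, str, str, str]
    rows: tuple[int, int, int, int]
    dominant: int
    cols: np.ndarray  # alignment columns of informative + B sites, increasing
    codes: np.ndarray  # topology index 0/1/2 or 3 for B, aligned with cols

    @property
    def dominant_label(self) -> str:
        return TOPOLOGY_LABELS[self.dominant]

    @property
    def n_C(self) -> int:
        return int((self.codes == self.dominant).sum())

    @property
    def n_B(self) -> int:
        return int((self.codes == B_SITE).sum())

    @property
    def n_R(self) -> int:
        return len(self.cols) - self.n_C - self.n_B

    @property
    def r_mask(self) -> np.ndarray:
        return (self.codes != self.dominant) & (self.codes != B_SITE)

    @property
    def r_columns(self) -> np.ndarray:
        return self.cols[self.r_mask]

    def cr_labels(self) -> tuple[np.ndarray, np.ndarray]:
        """(columns, labels) over C/R sites only, labels True for R."""
        keep = self.codes != B_SITE
        return self.cols[keep], self.r_mask[keep]


def _quartet_index_sets(n: int):
    return itertools.combinations(range(n), 4)


def scan_family(fam: AlignedFamily, tree: Tree) -> list[QuartetResult]:
    """Classify all C(N,4) quartets of a family against the family tree."""
    names = fam.names
    results = []
    for rows in _quartet_index_sets(fam.n_members):
        leaves = tuple(names[i] for i in rows)
        dominant = TOPOLOGY_LABELS.index(induced_quartet_topology(tree, leaves))
        codes = classify_quartet_columns(fam.matrix[list(rows)])
        keep = codes != UNINFORMATIVE
        cols = np.flatnonzero(keep)
        results.append(QuartetResult(leaves, rows, dominant, cols, codes[keep]))
    return results


def family_site_unions(results: list[QuartetResult], length: int):
    """Boolean masks over alignment columns: reticulate in >=1 quartet,
    bimutational in >=1 quartet, informative in >=1 quartet."""
    r_mask = np.zeros(length, dtype=bool)
    b_mask = np.zeros(length, dtype=bool)
    inf_mask = np.zeros(length, dtype=bool)
    for q in results:
        inf_mask[q.cols] = True
        r_mask[q.r_columns] = True
        b_mask[q.cols[q.codes == B_SITE]] = True
    return r_mask, b_mask, inf_mask


def _scan_matrix_unions(matrix: np.ndarray, quartets: list[QuartetResult]):
    """R/B union counts (plus per-quartet B counts) of an arbitrary
    alignment matrix scanned with the same quartets and dominant
    topologies as the observed family."""
    length = matrix.shape[1]
    r_mask = np.zeros(length, dtype=bool)
    b_mask = np.zeros(length, dtype=bool)
    per_quartet_b = np.empty(len(quartets), dtype=np.int64)
    for k, q in enumerate(quartets):
        codes = classify_quartet_columns(matrix[list(q.rows)])
        is_b = codes == B_SITE
        r_mask |= (codes >= 0) & ~is_b & (codes != q.dominant)
        b_mask |= is_b
        per_quartet_b[k] = int(is_b.sum())
    return int(r_mask.sum()), int(b_mask.sum()), per_quartet_b


@dataclass
class FamilyExcessTest:
    """Observed vs simulated reticulate-site excess for one family."""

    family_id: str
    observed_R: int
    observed_B: int
    boot_R: np.ndarray
    boot_B: np.ndarray
    sim_R: np.ndarray
    sim_B: np.ndarray
    p_value: float | None
    p_value_B: float | None
    skipped: str | None = None
    quartets: list[QuartetResult] = field(default_factory=list, repr=False)
    #: simulation-mean B count per quartet, aligned with ``quartets``
    expected_B_per_quartet: np.ndarray | None = None

    @property
    def ci_R(self) -> tuple[float, float]:
        return tuple(np.percentile(self.boot_R, [2.5, 97.5]))

    @property
    def ci_B(self) -> tuple[float, float]:
        return tuple(np.percentile(self.boot_B, [2.5, 97.5]))

    @property
    def expected_R(self) -> float:
        return float(np.mean(self.sim_R))

    @property
    def expected_B(self) -> float:
        return float(np.mean(self.sim_B))

    @property
    def excess_R(self) -> float:
        """Relative excess of observed over simulated R sites."""
        e = self.expected_R
        return float("nan") if e == 0 else self.observed_R / e - 1.0

    def summary(self) -> str:
        lines = [
            f"Family {self.family_id}: quartet excess test",
            f"  observed R sites : {self.observed_R}  (95% bootstrap CI "
            f"{self.ci_R[0]:.1f}-{self.ci_R[1]:.1f})",
            f"  expected R sites : {self.expected_R:.2f} (simulation null)",
            f"  observed B sites : {self.observed_B}  expected {self.expected_B:.2f}",
            f"  one-sided P (R excess): "
            + (f"{self.p_value:.2f}" if self.p_value is not None else "skipped"),
        ]
        if self.skipped:
            lines.append(f"  skipped: {self.skipped}")
        return "\n".join(lines)


def excess_test(
    fam: AlignedFamily,
    tree: Tree,
    model: SubstitutionModel,
    n_boot: int = 100,
    n_sim: int = 100,
    seed: int = 0,
    quartets: list[QuartetResult] | None = None,
) -> FamilyExcessTest:
    """Paired bootstrap-vs-simulation test for an excess of R sites.

    The observed family R count (columns reticulate in >=1 quartet) is
    bootstrapped by resampling alignment columns ``n_boot`` times;
    ``n_sim`` no-exchange replicates simulated along the tree are scanned
    identically.  After independent seeded shuffles the i-th bootstrap
    value is paired with the i-th simulated value and the one-sided
    P-value is the fraction of pairs in which the simulated count exceeds
    the bootstrap count.  The same machinery is applied to B sites (a
    conservativeness check: parallel mutation, not exchange, creates B
    sites).
    """
    rng = np.random.default_rng(seed)
    if quartets is None:
        quartets = scan_family(fam, tree)
    r_mask, b_mask, inf_mask = family_site_unions(quartets, fam.length)
    observed_R = int(r_mask.sum())
    observed_B = int(b_mask.sum())

    skipped = None
    if not inf_mask.any():
        skipped = "no informative sites"
    elif observed_R == 0:
        skipped = "no R sites"

    boot_R = np.empty(n_boot, dtype=np.int64)
    boot_B = np.empty(n_boot, dtype=np.int64)
    for i in range(n_boot):
        cols = rng.integers(0, fam.length, size=fam.length)
        boot_R[i] = int(r_mask[cols].sum())
        boot_B[i] = int(b_mask[cols].sum())

    spec = SimulationSpec(tree, model, fam.length, n_replicates=n_sim,
                          seed=int(rng.integers(2**31)))
    sim_R = np.empty(n_sim, dtype=np.int64)
    sim_B = np.empty(n_sim, dtype=np.int64)
    per_quartet_b_sum = np.zeros(len(quartets), dtype=np.int64)
    names = fam.names
    for i in range(n_sim):
        leaves = simulate_alignment(spec, i)
        matrix = np.vstack([leaves[n] for n in names])
        sim_R[i], sim_B[i], pqb = _scan_matrix_unions(matrix, quartets)
        per_quartet_b_sum += pqb

    if skipped is None:
        bo = boot_R[rng.permutation(n_boot)]
        si = sim_R[rng.permutation(n_sim)]
        n_pairs = min(n_boot, n_sim)
        p = float(np.mean(si[:n_pairs] > bo[:n_pairs]))
        bo_b = boot_B[rng.permutation(n_boot)]
        si_b = sim_B[rng.permutation(n_sim)]
        p_b = float(np.mean(si_b[:n_pairs] > bo_b[:n_pairs]))
    else:
        p = p_b = None

    return FamilyExcessTest(
        family_id=fam.family_id,
        observed_R=observed_R,
        observed_B=observed_B,
        boot_R=boot_R,
        boot_B=boot_B,
        sim_R=sim_R,
        sim_B=sim_B,
        p_value=p,
        p_value_B=p_b,
        skipped=skipped,
        quartets=quartets,
        expected_B_per_quartet=per_quartet_b_sum / n_sim,
    )


# ---------------------------------------------------------------------------
# runs test


@dataclass
class RunsTestResult:
    n1: int  # C labels
    n2: int  # R labels
    runs: int
    z: float
    p_one_sided: float
    method: str


def runs_count(labels: np.ndarray) -> int:
    labels = np.asarray(labels)
    return int(1 + (labels[1:] != labels[:-1]).sum()) if labels.size else 0


def runs_pvalue_exact(n1: int, n2: int, runs: int) -> float:
    """P(R <= runs) under random ordering of n1+n2 labels, by the standard
    combinatorial distribution of the number of runs."""
    total = comb(n1 + n2, n1, exact=True)
    acc = 0
    for r in range(2, runs + 1):
        if r % 2 == 0:
            m = r // 2
            ways = 2 * comb(n1 - 1, m - 1, exact=True) * comb(n2 - 1, m - 1, exact=True)
        else:
            m = (r - 1) // 2
            ways = comb(n1 - 1, m, exact=True) * comb(n2 - 1, m - 1, exact=True) + \
                comb(n1 - 1, m - 1, exact=True) * comb(n2 - 1, m, exact=True)
        acc += ways
    return acc / total


def runs_zstat(n1: int, n2: int, runs: int) -> float:
    n = n1 + n2
    mean = 1 + 2 * n1 * n2 / n
    var = 2 * n1 * n2 * (2 * n1 * n2 - n) / (n**2 * (n - 1))
    return (runs - mean) / np.sqrt(var) if var > 0 else 0.0


def runs_test(labels, method: str = "auto", exact_cutoff: int = 20) -> RunsTestResult:
    """Wald-Wolfowitz runs test for under-dispersion (clustering).

    ``labels``: ordered boolean array (True = R site) or a string over
    'C'/'R'.  One-sided P-value for *fewer* runs than expected; exact
    enumeration is used when n1+n2 <= ``exact_cutoff`` (or always with
    ``method='exact'``), otherwise the normal approximation.
    """
    if isinstance(labels, str):
        labels = np.array([c == "R" for c in labels])
    labels = np.asarray(labels, dtype=bool)
    n2 = int(labels.sum())
    n1 = int(labels.size - n2)
    if n1 == 0 or n2 == 0:
        raise ValueError("degenerate: runs test needs both label classes")
    r = runs_count(labels)
    z = runs_zstat(n1, n2, r)
    if method == "exact" or (method == "auto" and n1 + n2 <= exact_cutoff):
        p = runs_pvalue_exact(n1, n2, r)
        used = "exact"
    elif method in ("auto", "normal"):
        # continuity-corrected lower tail: P(R <= r) ~ Phi((r + 1/2 - E)/sd)
        n = n1 + n2
        mean = 1 + 2 * n1 * n2 / n
        var = 2 * n1 * n2 * (2 * n1 * n2 - n) / (n**2 * (n - 1))
        p = float(norm.cdf((r + 0.5 - mean) / np.sqrt(var))) if var > 0 else 1.0
        used = "normal"
    else:
        raise ValueError(f"unknown method {method!r}")
    return RunsTestResult(n1=n1, n2=n2, runs=r, z=z, p_one_sided=p, method=used)


def quartet_runs_test(q: QuartetResult, min_r: int = 5) -> RunsTestResult | None:
    """Runs test over a quartet's ordered C/R labels; only applied when the
    quartet has more than ``min_r`` R sites (too few R sites carry no
    clustering information)."""
    _, labels = q.cr_labels()
    n_r = int(labels.sum())
    if n_r <= min_r or n_r == labels.size:
        return None
    return runs_test(labels)


# ---------------------------------------------------------------------------
# R-run spacing


def r_runs(cols: np.ndarray, labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of consecutive R sites in the informative-site series,
    as (start_column, stop_column) pairs (inclusive alignment columns)."""
    runs = []
    start = None
    for i in range(labels.size):
        if labels[i]:
            if start is None:
                start = i
        else:
            if start is not None:
                runs.append((int(cols[start]), int(cols[i - 1])))
                start = None
    if start is not None:
        runs.append((int(cols[start]), int(cols[labels.size - 1])))
    return runs


def r_run_spacing(q: QuartetResult, min_len: int = 2, min_gap: int = 10) -> float | None:
    """Fraction of R-runs of >= ``min_len`` contiguous R sites whose
    nearest neighbouring R-run lies more than ``min_gap`` alignment bp
    away.  Returns None when no qualifying run exists.

    Multi-nucleotide mutation events are confined to ~10 bp, so R-runs
    separated by more than that are unlikely to be mutational artefacts.
    """
    cols, labels = q.cr_labels()
    runs = r_runs(cols, labels)
    sizes = []
    for start, stop in runs:
        i0 = np.searchsorted(cols, start)
        i1 = np.searchsorted(cols, stop)
        sizes.append(i1 - i0 + 1)
    qualifying = [k for k, s in enumerate(sizes) if s >= min_len]
    if not qualifying or len(runs) < 2:
        return None if not qualifying else 1.0
    ok = 0
    for k in qualifying:
        gaps = []
        if k > 0:
            gaps.append(runs[k][0] - runs[k - 1][1])
        if k < len(runs) - 1:
            gaps.append(runs[k + 1][0] - runs[k][1])
        if min(gaps) > min_gap:
            ok += 1
    return ok / len(qualifying)
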