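"""Perfect-identity fragment detection (Sawyer-statistic style).

For every sequence pair in a family, maximal runs of identity across the
family's polymorphic columns are candidate gene-conversion fragments; a
fragment is unusually long if, under random permutations of the
polymorphic-column order, a run of that many spanned polymorphic sites is
rarely attained.  Global P-values count permutations in which *any* pair
attains the observed score (alignment-wide multiplicity); pairwise
P-values are restricted to the fragment's own pair and Bonferroni
adjusted by the number of pairs.  Monomorphic columns never move the
statistic, which is the conditioning-on-variable-sites property of the
approach.

The permutations are realised by drawing one random rank assignment of
the polymorphic columns per replicate, shared by all pairs, so the joint
behaviour across pairs (they share sequences) is preserved.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .family_io import AlignedFamily


@dataclass
class PermutationConfig:
    n_perm: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100 for usable resolution")


@dataclass
class FragmentCall:
    """A maximal run of pairwise identity across polymorphic sites."""

    family_id: str
    pair: tuple[str, str]
    first_poly: int  # index into the polymorphic-column list
    last_poly: int
    start: int  # alignment column of the first spanned polymorphic site
    stop: int  # alignment column of the last spanned polymorphic site
    n_poly_spanned: int
    p_global: float | None = None
    p_pairwise: float | None = None
    genome_intervals: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return (self.p_global is not None and self.p_global < 0.05) or (
            self.p_pairwise is not None and self.p_pairwise < 0.05
        )


def polymorphic_columns(fam: AlignedFamily) -> np.ndarray:
    """Columns that vary across the family."""
    return np.flatnonzero((fam.matrix != fam.matrix[0]).any(axis=0))


def _match_runs(match: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first_index, last_index) pairs."""
    runs = []
    start = None
    for i, v in enumerate(match):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, match.size - 1))
    return runs


def score_pair_fragments(
    fam: AlignedFamily, pair: tuple[str, str], poly: np.ndarray | None = None
) -> list[FragmentCall]:
    """Candidate fragments for one sequence pair.

    Fragments are maximal runs over the ordered polymorphic-column list in
    which the pair is identical; the score is the number of polymorphic
    sites spanned.
    """
    if poly is None:
        poly = polymorphic_columns(fam)
    if poly.size < 2:
        return []
    i, j = fam.index_of(pair[0]), fam.index_of(pair[1])
    match = fam.matrix[i, poly] == fam.matrix[j, poly]
    return [
        FragmentCall(
            family_id=fam.family_id,
            pair=pair,
            first_poly=a,
            last_poly=b,
            start=int(poly[a]),
            stop=int(poly[b]),
            n_poly_spanned=b - a + 1,
        )
        for a, b in _match_runs(match)
    ]


# ---------------------------------------------------------------------------
# permutation null


def _pair_max_runs(ranks: np.ndarray, mismatch_idx: np.ndarray, n_sites: int) -> np.ndarray:
    """Per-permutation maximal identity-run length for one pair.

    ``ranks``: (n_perm, n_sites) random rank assignment per permutation.
    ``mismatch_idx``: polymorphic-site indices where the pair differs.
    """
    n_perm = ranks.shape[0]
    k = mismatch_idx.size
    if k == 0:
        return np.full(n_perm, n_sites, dtype=np.int64)
    r = np.sort(ranks[:, mismatch_idx], axis=1)
    lead = r[:, 0]
    trail = n_sites - 1 - r[:, -1]
    if k > 1:
        mid = np.max(np.diff(r, axis=1), axis=1) - 1
        return np.maximum(np.maximum(lead, trail), mid)
    return np.maximum(lead, trail)


class _PermutationNull:
    """Null distributions of the per-pair and alignment-wide maximal
    fragment score under shared random orderings of polymorphic columns."""

    def __init__(self, fam: AlignedFamily, cfg: PermutationConfig):
        self.fam = fam
        self.cfg = cfg
        self.poly = polymorphic_columns(fam)
        self.n_sites = int(self.poly.size)
        names = fam.names
        self.pairs = list(itertools.combinations(range(fam.n_members), 2))
        self.pair_names = [(names[i], names[j]) for i, j in self.pairs]
        rng = np.random.default_rng(cfg.seed)
        if self.n_sites < 2:
            self.pair_null = np.zeros((len(self.pairs), cfg.n_perm), dtype=np.int64)
            self.global_null = np.zeros(cfg.n_perm, dtype=np.int64)
            return
        sub = fam.matrix[:, self.poly]
        ranks = rng.permuted(
            np.tile(np.arange(self.n_sites), (cfg.n_perm, 1)), axis=1
        )
        per_pair = np.empty((len(self.pairs), cfg.n_perm), dtype=np.int64)
        for pi, (i, j) in enumerate(self.pairs):
            mis = np.flatnonzero(sub[i] != sub[j])
            per_pair[pi] = _pair_max_runs(ranks, mis, self.n_sites)
        self.global_null = np.sort(per_pair.max(axis=0))
        self.pair_null = np.sort(per_pair, axis=1)

    def p_global(self, score: int) -> float:
        n = self.cfg.n_perm
        return float(n - np.searchsorted(self.global_null, score)) / n

    def p_pairwise(self, pair: tuple[str, str], score: int) -> float:
        pi = self.pair_names.index(tuple(pair))
        n = self.cfg.n_perm
        raw = float(n - np.searchsorted(self.pair_null[pi], score)) / n
        return min(1.0, raw * len(self.pairs))

    def score_thresholds(self, alpha: float) -> tuple[int, np.ndarray]:
        """Smallest scores achieving global / per-pair significance."""
        n = self.cfg.n_perm
        k = int(np.ceil(alpha * n))
        glob = int(self.global_null[n - k]) + 1 if k >= 1 else self.n_sites + 1
        k_pair = int(np.ceil(alpha / max(len(self.pairs), 1) * n))
        if k_pair >= 1:
            pair = self.pair_null[:, n - k_pair].astype(np.int64) + 1
        else:
            pair = np.full(len(self.pairs), self.n_sites + 1, dtype=np.int64)
        return glob, pair


def permutation_test(
    fam: AlignedFamily,
    fragments: list[FragmentCall],
    cfg: PermutationConfig | None = None,
    null: _PermutationNull | None = None,
) -> list[FragmentCall]:
    """Attach permutation P-values to scored fragments.

    Ties count as at-least-as-extreme (conservative); P-value granularity
    is 1/n_perm.  Deterministic given ``cfg.seed``.
    """
    cfg = cfg or PermutationConfig()
    if null is None:
        null = _PermutationNull(fam, cfg)
    for f in fragments:
        f.p_global = null.p_global(f.n_poly_spanned)
        f.p_pairwise = null.p_pairwise(f.pair, f.n_poly_spanned)
    return fragments


def call_identity_tracks(
    fam: AlignedFamily, cfg: PermutationConfig | None = None
) -> list[FragmentCall]:
    """Significant identity tracks of a family (global OR pairwise
    P-value below ``cfg.alpha``), with genome coordinates attached.

    Only fragments that can reach significance are materialised, which
    keeps large scans cheap; the result is identical to scoring every
    fragment and filtering.
    """
    cfg = cfg or PermutationConfig()
    null = _PermutationNull(fam, cfg)
    if null.n_sites < 2:
        return []
    glob_thr, pair_thr = null.score_thresholds(cfg.alpha)
    poly = null.poly
    sub = fam.matrix[:, poly]
    out = []
    names = fam.names
    for pi, (i, j) in enumerate(null.pairs):
        thr = min(glob_thr, int(pair_thr[pi]))
        match = sub[i] == sub[j]
        for a, b in _match_runs(match):
            score = b - a + 1
            if score < thr:
                continue
            f = FragmentCall(
                family_id=fam.family_id,
                pair=(names[i], names[j]),
                first_poly=a,
                last_poly=b,
                start=int(poly[a]),
                stop=int(poly[b]),
                n_poly_spanned=score,
            )
            f.p_global = null.p_global(score)
            f.p_pairwise = null.p_pairwise(f.pair, score)
            if f.p_global < cfg.alpha or f.p_pairwise < cfg.alpha:
                _attach_genome_intervals(f, fam)
                out.append(f)
    return out


def _attach_genome_intervals(f: FragmentCall, fam: AlignedFamily) -> None:
    for name in f.pair:
        i = fam.index_of(name)
        g0 = int(fam.col_map[i, f.start])
        g1 = int(fam.col_map[i, f.stop])
        lo, hi = (g0, g1 + 1) if g0 <= g1 else (g1, g0 + 1)
        f.genome_intervals[name] = (fam.members[i].chrom, lo, hi)


# ---------------------------------------------------------------------------
# genomic deduplication


@dataclass
class UniqueTrack:
    """A disjoint genomic interval supported by one or more calls."""

    chrom: str
    start: int
    end: int
    supporting: list[FragmentCall] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def best_p(self) -> float:
        ps = [
            min(x for x in (f.p_global, f.p_pairwise) if x is not None)
            for f in self.supporting
            if f.p_global is not None or f.p_pairwise is not None
        ]
        return min(ps) if ps else float("nan")


def deduplicate_tracks(calls: list[FragmentCall]) -> tuple[list[UniqueTrack], list[FragmentCall]]:
    """Merge genomically overlapping calls into unique, disjoint tracks.

    Nested and redundant families report the same event at the same
    genomic coordinates; counting those repeatedly would double count
    overlapping features.  Both genome intervals of every call enter the
    sweep; intervals sharing >=1 bp merge.  Calls without genome
    coordinates are returned separately as an alignment-only stratum.
    """
    intervals = []  # (chrom, start, end, call)
    alignment_only = []
    for c in calls:
        if not c.genome_intervals:
            alignment_only.append(c)
            continue
        for chrom, start, end in c.genome_intervals.values():
            intervals.append((chrom, start, end, c))
    intervals.sort(key=lambda t: (t[0], t[1], t[2]))
    out: list[UniqueTrack] = []
    for chrom, start, end, call in intervals:
        if out and out[-1].chrom == chrom and start < out[-1].end:
            out[-1].end = max(out[-1].end, end)
            if call not in out[-1].supporting:
                out[-1].supporting.append(call)
        else:
            out.append(UniqueTrack(chrom, start, end, [call]))
    return out, alignment_only
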