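"""Ground-truth synthetic paralog families and toy genome layouts.

Every pipeline stage is exercised on data whose history is known exactly:
families evolved along a random duplication tree with *no* interlocus
exchange (the null), optionally perturbed by injected gene-conversion
tracks, non-allelic crossovers or multi-donor complex events (the truth
set records each one), and placed on a toy genome with pericentromeric/
subtelomeric zones, repeat and gene annotations and planted PRDM9 motifs.

The default generator profile mirrors the segmental-duplication dataset
the analysis is designed for: 4-12 paralogs of 10-40 kb aligned length at
88-99.9% mean pairwise identity, GTR+Gamma(4)+I substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .family_io import AlignedFamily, LocusRecord
from .phylo import Tree
from .substitution import SubstitutionModel, evolve_along_tree
from skbio import TreeNode

#: human-nuclear-like default model for synthetic families: transition-
#: biased exchangeabilities, mild GC<50% composition, moderate rate
#: heterogeneity and a substantial invariant fraction
DEFAULT_MODEL = SubstitutionModel(
    exchangeabilities=np.array([1.0, 4.0, 0.7, 1.1, 4.5, 1.0]),
    base_freqs=np.array([0.295, 0.205, 0.205, 0.295]),
    gamma_shape=1.0,
    p_inv=0.3,
)


@dataclass
class FamilyGenSpec:
    """Recipe for one synthetic family."""

    n_paralogs: int = 8
    length: int = 18_800
    target_identity: float = 0.958
    tree: str | None = None  # Newick; random birth tree when None
    model: SubstitutionModel = field(default_factory=lambda: DEFAULT_MODEL)
    cpg_boost: float = 0.0  # extra CpG transition intensity per unit branch
    seed: int = 0

    def __post_init__(self):
        if not 4 <= self.n_paralogs <= 16:
            raise ValueError("n_paralogs must lie in 4..16")
        if not 0.5 < self.target_identity < 1.0:
            raise ValueError("target identity must lie in (0.5, 1)")
        if self.length <= 0:
            raise ValueError("length must be positive")


@dataclass(frozen=True)
class TruthEvent:
    kind: str  # igc | crossover | complex
    donor: str
    acceptor: str
    start: int  # alignment bp, half-open interval [start, stop)
    stop: int
    generation: int = 0

    def __post_init__(self):
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor must differ")
        if self.stop <= self.start:
            raise ValueError("empty event interval")


@dataclass
class TruthSet:
    events: list[TruthEvent] = field(default_factory=list)

    def __len__(self):
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.events])


# ---------------------------------------------------------------------------
# tree generation and height calibration


def random_birth_tree(n_leaves: int, rng: np.random.Generator) -> TreeNode:
    """Random duplication history: pure-birth joins with exponential
    waiting times (unit rate), leaf names seq1..seqN."""
    nodes = [TreeNode(name=f"seq{i + 1}", length=0.0) for i in range(n_leaves)]
    heights = [0.0] * n_leaves
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(1.0 / k)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = TreeNode(length=0.0)
        for idx in (j, i):
            child = nodes.pop(idx)
            h = heights.pop(idx)
            child.length = t - h
            parent.append(child)
        nodes.append(parent)
        heights.append(t)
    return nodes[0]


def _mean_pairwise_path(tree: TreeNode) -> float:
    tips = list(tree.tips())
    depths = {}
    for tip in tips:
        d = 0.0
        node = tip
        chain = {}
        while node is not None:
            chain[id(node)] = d
            d += node.length or 0.0
            node = node.parent
        depths[tip.name] = chain
    total, n = 0.0, 0
    for a in range(len(tips)):
        for b in range(a + 1, len(tips)):
            ca, cb = depths[tips[a].name], depths[tips[b].name]
            best = min(ca[k] + cb[k] for k in ca if k in cb)
            total += best
            n += 1
    return total / n


def _scale_tree(tree: TreeNode, factor: float) -> None:
    for node in tree.traverse():
        if node.length is not None:
            node.length *= factor


def calibrate_tree_height(
    tree: TreeNode, model: SubstitutionModel, target_identity: float
) -> TreeNode:
    """Scale branch lengths so the expected mean pairwise identity under
    the model equals the target."""
    base = _mean_pairwise_path(tree)
    if base <= 0:
        raise ValueError("degenerate tree (zero height)")

    def gap(log_scale):
        return model.expected_identity(base * np.exp(log_scale)) - target_identity

    lo, hi = -12.0, 3.0
    if gap(lo) < 0:
        raise ValueError("identity target unattainable: tree too deep even at min scale")
    if gap(hi) > 0:
        raise ValueError("identity target unattainable: saturation floor above target")
    log_scale = brentq(gap, lo, hi, xtol=1e-10)
    out = tree.copy()
    _scale_tree(out, np.exp(log_scale))
    return out


# ---------------------------------------------------------------------------
# family generation


def _apply_cpg_hypermutation(
    parent: np.ndarray, child: np.ndarray, t: float, boost: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Extra C->T / G->A transitions at CpG dinucleotides of the parent,
    with probability 1 - exp(-boost * t) per strand symmetrically."""
    if boost <= 0 or t <= 0:
        return child
    p_extra = 1.0 - np.exp(-boost * t)
    cpg = (parent[:-1] == 1) & (parent[1:] == 2)
    c_pos = np.flatnonzero(cpg)
    g_pos = c_pos + 1
    hit_c = rng.random(c_pos.size) < p_extra
    hit_g = rng.random(g_pos.size) < p_extra
    out = child.copy()
    out[c_pos[hit_c]] = 3  # C -> T
    out[g_pos[hit_g]] = 0  # G -> A
    return out


def _evolve_with_cpg(tree: TreeNode, model: SubstitutionModel, length: int,
                     boost: float, rng: np.random.Generator) -> dict[str, np.ndarray]:
    rates, weights = model.site_rates()
    cls_idx = rng.choice(len(rates), size=length, p=weights)
    site_rates = rates[cls_idx]
    root_seq = rng.choice(4, size=length, p=model.base_freqs)
    leaves = {}
    stack = [(tree, root_seq)]
    while stack:
        node, seq = stack.pop()
        for child in node.children:
            t = child.length or 0.0
            child_seq = _evolve_branch(seq, t, model, site_rates, rng)
            child_seq = _apply_cpg_hypermutation(seq, child_seq, t, boost, rng)
            if child.is_tip():
                leaves[child.name] = child_seq
            else:
                stack.append((child, child_seq))
    return leaves


def _evolve_branch(seq: np.ndarray, t: float, model: SubstitutionModel,
                   site_rates: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    child = seq.copy()
    if t <= 0:
        return child
    for r in np.unique(site_rates):
        if r == 0:
            continue
        idx = np.flatnonzero(site_rates == r)
        p = model.transition_matrix(t * r)
        sub = seq[idx]
        out = np.empty(idx.size, dtype=np.int64)
        for b in range(4):
            mask = sub == b
            n = int(mask.sum())
            if n:
                out[mask] = rng.choice(4, size=n, p=p[b])
        child[idx] = out
    return child


def generate_null_family(
    spec: FamilyGenSpec, family_id: str = "synth"
) -> tuple[AlignedFamily, Tree, TruthSet]:
    """Evolve a family with no interlocus exchange.

    The tree (supplied or random birth) is height-calibrated so the
    realised mean identity falls within about a percentage point of the
    target; the truth set is empty by construction.  Fully deterministic
    under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.tree is not None:
        tree = TreeNode.read([spec.tree])
        for node in tree.traverse():
            if node.length is None:
                node.length = 0.0 if node.parent is None else 1.0
    else:
        tree = random_birth_tree(spec.n_paralogs, rng)
    tree = calibrate_tree_height(tree, spec.model, spec.target_identity)
    if spec.cpg_boost > 0:
        leaves = _evolve_with_cpg(tree, spec.model, spec.length, spec.cpg_boost, rng)
    else:
        leaves = evolve_along_tree(tree, spec.model, spec.length, rng)
    names = sorted(leaves, key=lambda s: (len(s), s))
    gap = 1000
    members = [
        LocusRecord(family_id, n, "chrT1", i * (spec.length + gap),
                    i * (spec.length + gap) + spec.length)
        for i, n in enumerate(names)
    ]
    matrix = np.vstack([leaves[n] for n in names])
    col_map = np.vstack([np.arange(m.start, m.end) for m in members])
    fam = AlignedFamily(family_id, members, matrix, col_map)
    return fam, Tree(tree), TruthSet()


# ---------------------------------------------------------------------------
# event injection


def inject_gene_conversion(
    fam: AlignedFamily, donor: str, acceptor: str, start: int, stop: int,
    truth: TruthSet | None = None,
) -> tuple[AlignedFamily, TruthEvent]:
    """Copy the donor's characters over the acceptor on alignment columns
    [start, stop); all other positions are untouched.  The event is
    recorded even when donor and acceptor were already identical there."""
    if not (0 <= start < stop <= fam.length):
        raise ValueError(f"interval [{start}, {stop}) outside alignment of length {fam.length}")
    di, ai = fam.index_of(donor), fam.index_of(acceptor)
    matrix = fam.matrix.copy()
    matrix[ai, start:stop] = matrix[di, start:stop]
    event = TruthEvent("igc", donor, acceptor, start, stop)
    if truth is not None:
        truth.events.append(event)
    out = AlignedFamily(fam.family_id, list(fam.members), matrix, fam.col_map.copy())
    return out, event


def inject_crossover(
    fam: AlignedFamily, pair: tuple[str, str], breakpoint: int,
    truth: TruthSet | None = None,
) -> tuple[AlignedFamily, TruthEvent]:
    """Swap the two sequences' suffixes from ``breakpoint`` to the end
    (a reciprocal non-allelic crossover); involution at fixed breakpoint."""
    if not (0 < breakpoint < fam.length):
        raise ValueError("breakpoint must be interior to the alignment")
    i, j = fam.index_of(pair[0]), fam.index_of(pair[1])
    matrix = fam.matrix.copy()
    matrix[i, breakpoint:], matrix[j, breakpoint:] = (
        fam.matrix[j, breakpoint:].copy(),
        fam.matrix[i, breakpoint:].copy(),
    )
    event = TruthEvent("crossover", pair[0], pair[1], breakpoint, fam.length)
    if truth is not None:
        truth.events.append(event)
    out = AlignedFamily(fam.family_id, list(fam.members), matrix, fam.col_map.copy())
    return out, event


def inject_complex_event(
    fam: AlignedFamily, donors: list[str], acceptor: str, start: int,
    segment: int, truth: TruthSet | None = None,
) -> tuple[AlignedFamily, list[TruthEvent]]:
    """Multi-donor patchwork (MMBIR-like): consecutive ``segment``-bp
    pieces from alternating donors pasted into the acceptor."""
    events = []
    out = fam
    pos = start
    for d in donors:
        stop = min(pos + segment, fam.length)
        if stop <= pos:
            break
        out, e = inject_gene_conversion(out, d, acceptor, pos, stop, truth)
        e = TruthEvent("complex", d, acceptor, pos, stop)
        events.append(e)
        pos = stop
    return out, events


# ---------------------------------------------------------------------------
# toy genome fixture


@dataclass
class GenomeFixture:
    chrom_lengths: dict[str, int]
    sequences: dict[str, str]
    placements: list[LocusRecord]
    zones: dict[str, pd.DataFrame]  # pericentromeric, subtelomeric
    annotations: dict[str, pd.DataFrame]  # repeat classes, gene, cds, pseudogene
    planted_motifs: list[tuple[str, int]]
    families: list[AlignedFamily] = field(default_factory=list)

    def write_beds(self, directory) -> None:
        import os

        for name, df in {**self.zones, **self.annotations}.items():
            df.to_csv(os.path.join(directory, f"{name}.bed"), sep="\t",
                      header=False, index=False)


def build_genome_fixture(
    families: list[AlignedFamily],
    n_chromosomes: int = 3,
    chrom_length: int = 400_000,
    zone_fraction: float = 0.1,
    n_genes: int = 20,
    n_repeats: int = 60,
    n_prdm9: int = 25,
    seed: int = 0,
) -> GenomeFixture:
    """Place family members on toy chromosomes and emit annotation BEDs.

    Pericentromeric and subtelomeric zones each cover about
    ``zone_fraction/2`` of every chromosome (centre and both ends); genes
    (with CDS subintervals), pseudogenes and repeat intervals are
    scattered uniformly; ``n_prdm9`` PRDM9 motifs are planted at recorded
    positions in otherwise-random chromosome sequence.
    """
    rng = np.random.default_rng(seed)
    chroms = {f"chr{i + 1}": chrom_length for i in range(n_chromosomes)}
    needed = sum((f.length + 2000) * f.n_members for f in families)
    if needed > n_chromosomes * chrom_length:
        raise ValueError("layout overflow: families do not fit on the toy genome")

    # member placement: round-robin across chromosomes, non-overlapping
    cursors = {c: 1000 for c in chroms}
    placements = []
    new_families = []
    order = list(chroms)
    k = 0
    for fam in families:
        new_members = []
        for m in fam.members:
            chrom = order[k % len(order)]
            k += 1
            start = cursors[chrom]
            end = start + fam.length
            if end > chroms[chrom]:
                raise ValueError("layout overflow on " + chrom)
            cursors[chrom] = end + 2000
            new_members.append(
                LocusRecord(fam.family_id, m.seq_name, chrom, start, end, m.strand)
            )
        col_map = np.vstack([np.arange(m.start, m.end) for m in new_members])
        new_families.append(
            AlignedFamily(fam.family_id, new_members, fam.matrix.copy(), col_map)
        )
        placements.extend(new_members)

    # zones: pericentromere at the centre, subtelomeres at both ends
    peri, subtel = [], []
    for chrom, L in chroms.items():
        half = int(L * zone_fraction / 2)
        mid = L // 2
        peri.append((chrom, mid - half // 2, mid + half // 2, "pericentromeric"))
        subtel.append((chrom, 0, half // 2, "subtelomeric"))
        subtel.append((chrom, L - half // 2, L, "subtelomeric"))
    zones = {
        "pericentromeric": pd.DataFrame(peri, columns=["chrom", "start", "end", "name"]),
        "subtelomeric": pd.DataFrame(subtel, columns=["chrom", "start", "end", "name"]),
    }

    def scatter(n, min_len, max_len, label):
        rows = []
        for _ in range(n):
            chrom = order[int(rng.integers(len(order)))]
            ln = int(rng.integers(min_len, max_len))
            s = int(rng.integers(0, chroms[chrom] - ln))
            rows.append((chrom, s, s + ln, label))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]
                            ).sort_values(["chrom", "start"]).reset_index(drop=True)

    genes = scatter(n_genes, 5000, 20000, "gene")
    cds_rows = []
    for _, g in genes.iterrows():
        span = g.end - g.start
        s = g.start + int(rng.integers(0, span // 2))
        cds_rows.append((g.chrom, s, min(g.end, s + span // 4 + 1), "cds"))
    annotations = {
        "gene": genes,
        "cds": pd.DataFrame(cds_rows, columns=["chrom", "start", "end", "name"]),
        "pseudogene": scatter(max(2, n_genes // 3), 2000, 10000, "pseudogene"),
        "SINE": scatter(n_repeats, 150, 400, "SINE"),
        "LINE": scatter(n_repeats // 2, 1000, 6000, "LINE"),
        "LTR": scatter(n_repeats // 3, 300, 3000, "LTR"),
    }

    # chromosome sequences with planted PRDM9 motifs
    from .genomic_context import PRDM9_MOTIF

    sequences = {}
    planted = []
    motif_template = PRDM9_MOTIF
    per_chrom = np.array_split(np.arange(n_prdm9), len(order))
    for chrom, idxs in zip(order, per_chrom):
        seq = rng.choice(list("ACGT"), size=chroms[chrom])
        for _ in idxs:
            pos = int(rng.integers(0, chroms[chrom] - len(motif_template)))
            inst = [
                ("ACGT"[rng.integers(4)] if ch == "N" else ch)
                for ch in motif_template
            ]
            seq[pos:pos + len(inst)] = inst
            planted.append((chrom, pos))
        sequences[chrom] = "".join(seq)

    return GenomeFixture(
        chrom_lengths=chroms,
        sequences=sequences,
        placements=placements,
        zones=zones,
        annotations=annotations,
        planted_motifs=planted,
        families=new_families,
    )


# ---------------------------------------------------------------------------
# forward evolution with conversion (equilibrium mode for rate estimation)


def evolve_with_igc(
    n_paralogs: int,
    length: int,
    mu: float,
    c: float,
    track_length: int,
    n_generations: int,
    seed: int = 0,
) -> AlignedFamily:
    """Forward-in-time paralog family under mutation-conversion balance.

    Each generation every paralog accrues Poisson(mu * length) random
    substitutions and is hit by conversion events pasting a
    ``track_length``-bp window from a uniformly chosen other paralog.
    ``c`` is on the estimator's scale: the per-site rate at which *either*
    member of a pair is overwritten from within the family, so each
    paralog individually initiates events at per-site rate c/2.  Starting
    from identical copies, a pair's per-site divergence relaxes to
    d = mu / lambda with lambda = (c/2)/(n-1) the one-directional
    pairwise rate, i.e. exactly d = 2 mu (n-1) / c, which the rate
    estimator inverts.
    """
    rng = np.random.default_rng(seed)
    seqs = np.tile(rng.choice(4, size=length), (n_paralogs, 1))
    ev_rate = (c / 2.0) * length / track_length
    for _ in range(n_generations):
        for i in range(n_paralogs):
            n_mut = rng.poisson(mu * length)
            if n_mut:
                pos = rng.integers(0, length, size=n_mut)
                seqs[i, pos] = (seqs[i, pos] + rng.integers(1, 4, size=n_mut)) % 4
            n_ev = rng.poisson(ev_rate)
            for _ in range(n_ev):
                donor = int(rng.integers(0, n_paralogs - 1))
                donor += donor >= i
                s = int(rng.integers(0, max(1, length - track_length)))
                seqs[i, s:s + track_length] = seqs[donor, s:s + track_length]
    members = [
        LocusRecord("igc-forward", f"seq{i + 1}", "chrT1", i * (length + 100),
                    i * (length + 100) + length)
        for i in range(n_paralogs)
    ]
    col_map = np.vstack([np.arange(m.start, m.end) for m in members])
    return AlignedFamily("igc-forward", members, seqs, col_map)
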