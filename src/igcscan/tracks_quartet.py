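"""Track and breakpoint estimation from classified quartet sites.

Runs of consecutive reticulate sites sharing one alternative topology are
conversion-track clusters; the most probable track boundaries are the
midpoints between the outermost R sites and the flanking C sites.  A
terminal run of at least five consecutive R sites reaching the first or
last informative site is a putative non-allelic crossover, localised to
the window between the flanking C site and the first R site of the run.
Alignments are also tiled into topology blocks (midpoint boundaries
between adjacent informative sites of differing supported topology) to
quantify the fraction of sites whose local tree disagrees with the
duplication history.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .family_io import AlignedFamily
from .phylo import TOPOLOGY_LABELS
from .quartet_scan import B_SITE, QuartetResult


@dataclass
class QuartetTrackCall:
    """A called exchange interval within one quartet."""

    family_id: str
    leaves: tuple[str, ...]
    start: float  # alignment bp
    stop: float
    n_R_support: int
    alt_topology: int
    kind: str  # conversion | crossover | complex
    genome_intervals: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    def __post_init__(self):
        if self.stop <= self.start:
            raise ValueError("track stop must exceed start")
        need = 5 if self.kind == "crossover" else 1
        if self.n_R_support < need:
            raise ValueError(f"{self.kind} call needs >= {need} supporting R sites")

    @property
    def length(self) -> float:
        return self.stop - self.start

    @property
    def alt_label(self) -> str:
        return TOPOLOGY_LABELS[self.alt_topology]


def select_informative_quartets(
    quartet_stats: list[tuple[QuartetResult, float]],
    max_expected_b: float = 5.0,
    min_observed_r: int = 5,
) -> list[QuartetResult]:
    """Quartets eligible for track estimation: simulation-expected B sites
    strictly below ``max_expected_b`` and observed R sites strictly above
    ``min_observed_r``.  With few B sites expected, observed R sites are
    unlikely to be parallel mutations, so clusters can be read as tracks.

    ``quartet_stats``: (quartet result, expected B count) pairs.
    """
    return [
        q
        for q, exp_b in quartet_stats
        if exp_b < max_expected_b and q.n_R > min_observed_r
    ]


def _r_cluster_spans(q: QuartetResult) -> list[tuple[int, int, int]]:
    """Maximal runs of consecutive R sites sharing one alternative
    topology, as (first_index, last_index, topology) over the ordered
    informative-site series with B sites removed."""
    cols, labels = q.cr_labels()
    codes = q.codes[q.codes != B_SITE]
    spans = []
    i = 0
    n = labels.size
    while i < n:
        if labels[i]:
            j = i
            while j + 1 < n and labels[j + 1] and codes[j + 1] == codes[i]:
                j += 1
            spans.append((i, j, int(codes[i])))
            i = j + 1
        else:
            i += 1
    return spans


def call_conversion_tracks(
    q: QuartetResult,
    family_id: str = "",
    alignment_length: int | None = None,
    min_crossover_run: int = 5,
) -> list[QuartetTrackCall]:
    """Call conversion tracks (and terminal crossover runs) by the
    midpoint rule.

    Each cluster of >=1 consecutive R sites supporting one alternative
    topology becomes a track from midpoint(flanking C, first R) to
    midpoint(last R, flanking C); clusters touching the informative-site
    range ends use the alignment boundary as flank.  Terminal clusters of
    >= ``min_crossover_run`` R sites are classified crossover (handled by
    :func:`call_crossover_breakpoints`); they are excluded here.
    """
    cols, labels = q.cr_labels()
    if not labels.any():
        return []
    L = alignment_length
    calls = []
    for i0, i1, topo in _r_cluster_spans(q):
        n_sites = i1 - i0 + 1
        terminal = i0 == 0 or i1 == labels.size - 1
        if terminal and n_sites >= min_crossover_run:
            continue  # crossover candidate, not a conversion track
        left_flank = cols[i0 - 1] if i0 > 0 else 0
        right_flank = cols[i1 + 1] if i1 < labels.size - 1 else (
            (L - 1) if L is not None else cols[-1]
        )
        start = (left_flank + cols[i0]) / 2
        stop = (cols[i1] + right_flank) / 2
        if stop <= start:
            continue  # degenerate single-site cluster at the boundary
        calls.append(
            QuartetTrackCall(
                family_id=family_id,
                leaves=q.leaves,
                start=start,
                stop=stop,
                n_R_support=n_sites,
                alt_topology=topo,
                kind="conversion",
            )
        )
    return calls


def call_crossover_breakpoints(
    q: QuartetResult,
    alignment_length: int,
    family_id: str = "",
    min_run: int = 5,
) -> list[QuartetTrackCall]:
    """Terminal runs of >= ``min_run`` consecutive R sites of one
    alternative topology reaching the first or last informative site are
    crossover candidates; the breakpoint window is the interval between
    the flanking C site and the first R site of the run."""
    cols, labels = q.cr_labels()
    if not labels.any():
        return []
    calls = []
    for i0, i1, topo in _r_cluster_spans(q):
        n_sites = i1 - i0 + 1
        if n_sites < min_run:
            continue
        if i0 == 0:  # run reaches the start of the informative range;
            # the breakpoint lies between the innermost R and the next C
            inner_flank = cols[i1 + 1] if i1 < labels.size - 1 else alignment_length - 1
            start, stop = float(cols[i1]), float(inner_flank)
        elif i1 == labels.size - 1:  # run reaches the end
            outer_flank = cols[i0 - 1]
            start, stop = float(outer_flank), float(cols[i0])
        else:
            continue
        calls.append(
            QuartetTrackCall(
                family_id=family_id,
                leaves=q.leaves,
                start=start,
                stop=stop,
                n_R_support=n_sites,
                alt_topology=topo,
                kind="crossover",
            )
        )
    return calls


# ---------------------------------------------------------------------------
# topology blocks


@dataclass
class TopologyBlockPartition:
    """Alignment tiled into maximal same-topology segments."""

    segments: list[tuple[float, float, int]]  # (start, stop, topology)
    dominant: int

    @property
    def fraction_discordant(self) -> float:
        total = sum(s[1] - s[0] for s in self.segments)
        disc = sum(s[1] - s[0] for s in self.segments if s[2] != self.dominant)
        return disc / total if total else 0.0

    def topology_at(self, pos: float) -> int:
        for start, stop, topo in self.segments:
            if start <= pos < stop:
                return topo
        raise ValueError(f"position {pos} outside alignment")


def partition_topology_blocks(
    q: QuartetResult, alignment_length: int
) -> TopologyBlockPartition:
    """Tile the alignment into topology blocks.

    C sites carry the dominant topology, R sites their alternative, B
    sites are transparent (they say nothing about topology).  Block
    boundaries are midpoints between adjacent informative sites of
    differing supported topology; the first and last blocks extend to the
    alignment ends.  Segment lengths sum exactly to the alignment length.
    """
    cols, labels = q.cr_labels()
    codes = q.codes[q.codes != B_SITE]
    L = float(alignment_length)
    if cols.size == 0:
        return TopologyBlockPartition([(0.0, L, q.dominant)], q.dominant)
    bounds = [0.0]
    topos = [int(codes[0])]
    for k in range(1, cols.size):
        if codes[k] != codes[k - 1]:
            bounds.append((cols[k - 1] + cols[k]) / 2)
            topos.append(int(codes[k]))
    bounds.append(L)
    segments = [
        (bounds[k], bounds[k + 1], topos[k]) for k in range(len(topos))
    ]
    return TopologyBlockPartition(segments, q.dominant)


def flag_complex_events(
    partition: TopologyBlockPartition,
    alignment_length: int,
    window: int = 2000,
    min_switches: int = 3,
    edge_margin: int = 1000,
) -> list[dict]:
    """Flag intervals with >= ``min_switches`` topology switches within
    ``window`` bp — the signature of complex repair (multi-template
    synthesis).  Flags near the alignment edges are annotated, since
    alignment quality often degrades there."""
    switches = [seg[0] for seg in partition.segments[1:]]
    flags = []
    i = 0
    n = len(switches)
    while i < n:
        j = i
        while j + 1 < n and switches[j + 1] - switches[i] <= window:
            j += 1
        if j - i + 1 >= min_switches:
            start, stop = switches[i], switches[j]
            flags.append(
                {
                    "start": start,
                    "stop": stop,
                    "n_switches": j - i + 1,
                    "edge_proximal": start < edge_margin
                    or stop > alignment_length - edge_margin,
                }
            )
            i = j + 1
        else:
            i += 1
    return flags


# ---------------------------------------------------------------------------
# genome-coordinate mapping


def map_call_to_genome(call: QuartetTrackCall, fam: AlignedFamily) -> QuartetTrackCall:
    """Attach genomic intervals (chrom, start, end half-open) for every
    member of the quartet, via the family's column maps."""
    lo = int(np.floor(call.start))
    hi = min(int(np.ceil(call.stop)), fam.length - 1)
    for name in call.leaves:
        i = fam.index_of(name)
        g0 = int(fam.col_map[i, lo])
        g1 = int(fam.col_map[i, hi])
        start, end = (g0, g1 + 1) if g0 <= g1 else (g1, g0 + 1)
        call.genome_intervals[name] = (fam.members[i].chrom, start, end)
    return call
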