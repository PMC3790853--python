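"""Genomic-context enrichment of unique conversion tracks.

Observed tracks are compared with length-matched random re-placements:
for each unique track of length l, an alignment is sampled with
probability proportional to its length L, a random sequence pair is
chosen, and a start is drawn uniformly on (1, L-l) (1-based); repeating
this for every track builds one simulated dataset, and the null
distribution of any context statistic comes from many such datasets.
P-values are quantile positions of the observed value in the simulated
distribution.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .family_io import AlignedFamily

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: the recombinogenic PRDM9 binding motif, n = any base
PRDM9_MOTIF = "CCNCCNTNNCCNC"


@dataclass
class RandomPlacement:
    """One length-matched re-placement of a track."""

    track_length: int
    family_id: str
    pair: tuple[str, str]
    start: int  # 1-based alignment bp

    def __post_init__(self):
        if self.start < 1:
            raise ValueError("placement start must be >= 1")


@dataclass
class PlacedEvent:
    """A (possibly simulated) conversion event as two genomic intervals."""

    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    identity: float = float("nan")

    @property
    def interchromosomal(self) -> bool:
        return self.chrom_a != self.chrom_b

    def intervals(self):
        yield (self.chrom_a, self.start_a, self.end_a)
        yield (self.chrom_b, self.start_b, self.end_b)


def place_random_tracks(
    track_lengths: list[int],
    families: list[AlignedFamily],
    n_datasets: int = 1000,
    seed: int = 0,
) -> list[list[RandomPlacement]]:
    """Length-matched random placements: ``n_datasets`` simulated
    datasets, each with one placement per input track length.

    Families are sampled with probability proportional to alignment
    length among those long enough to host the track; two member
    sequences are chosen at random; the start is uniform on 1..L-l.
    """
    rng = np.random.default_rng(seed)
    lengths = np.array([f.length for f in families], dtype=float)
    datasets = []
    for _ in range(n_datasets):
        ds = []
        for l in track_lengths:
            ok = np.flatnonzero(lengths > l)
            if ok.size == 0:
                raise ValueError(f"no alignment can host a track of length {l}")
            w = lengths[ok] / lengths[ok].sum()
            fi = int(ok[rng.choice(ok.size, p=w)])
            fam = families[fi]
            i, j = rng.choice(fam.n_members, size=2, replace=False)
            start = int(rng.integers(1, fam.length - l + 1))
            ds.append(
                RandomPlacement(l, fam.family_id, (fam.names[i], fam.names[j]), start)
            )
        datasets.append(ds)
    return datasets


def placement_to_event(p: RandomPlacement, fam: AlignedFamily) -> PlacedEvent:
    """Map an alignment-space placement to its two genomic intervals."""
    lo = p.start - 1  # to 0-based columns
    hi = lo + p.track_length - 1
    coords = []
    for name in p.pair:
        i = fam.index_of(name)
        g0, g1 = int(fam.col_map[i, lo]), int(fam.col_map[i, hi])
        a, b = (g0, g1 + 1) if g0 <= g1 else (g1, g0 + 1)
        coords.append((fam.members[i].chrom, a, b))
    ident = float(
        (fam.matrix[fam.index_of(p.pair[0])] == fam.matrix[fam.index_of(p.pair[1])]).mean()
    )
    (ca, sa, ea), (cb, sb, eb) = coords
    return PlacedEvent(ca, sa, ea, cb, sb, eb, identity=ident)


# ---------------------------------------------------------------------------
# BED annotations and overlap


def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader (chrom, start, end [, name, score, strand]);
    extra columns are dropped, missing names filled with '.', rows sorted
    by (chrom, start) when needed."""
    n = _n_cols(path)
    if n < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    names = ["chrom", "start", "end", "name", "score", "strand"][: min(n, 6)]
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=names, usecols=range(len(names)))
    if "name" not in df.columns:
        df["name"] = "."
    df = df[["chrom", "start", "end", "name"]]
    if not df[["chrom", "start"]].equals(
            df.sort_values(["chrom", "start"])[["chrom", "start"]].reset_index(drop=True)):
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return df


def _n_cols(path) -> int:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return len(line.rstrip("\n").split("\t"))
    return 0


class FeatureIndex:
    """Sorted per-chromosome interval sets with >=1 bp overlap queries
    (half-open, 0-based)."""

    def __init__(self, bed: pd.DataFrame):
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in bed.groupby("chrom"):
            starts = grp["start"].to_numpy(dtype=np.int64)
            ends = grp["end"].to_numpy(dtype=np.int64)
            order = np.argsort(starts)
            starts, ends = starts[order], ends[order]
            # running maximum of ends lets a single searchsorted answer
            # "does any interval starting before my end reach past my start"
            self._by_chrom[chrom] = (starts, np.maximum.accumulate(ends))

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self._by_chrom:
            return False
        starts, max_ends = self._by_chrom[chrom]
        k = int(np.searchsorted(starts, end, side="left"))
        return k > 0 and max_ends[k - 1] > start


def overlap_features(
    events: list[PlacedEvent], annotations: dict[str, pd.DataFrame]
) -> dict[str, float]:
    """Per-feature statistics over an event set (observed or simulated).

    ``annotations`` maps feature names to BED frames.  Returns, for each
    feature, the fraction of events with >=1 bp overlap on either side,
    plus the structural categories: inter-/intrachromosomal counts, mean
    pairwise identity, and mean intrachromosomal inter-track distance
    (between track midpoints on the same chromosome).
    """
    n = len(events)
    out: dict[str, float] = {}
    for name, bed in annotations.items():
        idx = FeatureIndex(bed)
        hits = sum(
            1 for e in events if any(idx.overlaps(*iv) for iv in e.intervals())
        )
        out[f"frac_overlap_{name}"] = hits / n if n else float("nan")
        if name in ("gene", "cds", "pseudogene"):
            both = sum(
                1
                for e in events
                if all(idx.overlaps(*iv) for iv in e.intervals())
            )
            out[f"n_{name}_{name}_events"] = both
    out["n_interchromosomal"] = sum(1 for e in events if e.interchromosomal)
    out["n_intrachromosomal"] = n - out["n_interchromosomal"]
    idents = [e.identity for e in events if np.isfinite(e.identity)]
    out["mean_pairwise_identity"] = float(np.mean(idents)) if idents else float("nan")
    mids: dict[str, list[float]] = {}
    for e in events:
        if not e.interchromosomal:
            mids.setdefault(e.chrom_a, []).append((e.start_a + e.end_a) / 2)
    dists = []
    for chrom, ms in mids.items():
        ms = sorted(ms)
        for a in range(len(ms)):
            for b in range(a + 1, len(ms)):
                dists.append(ms[b] - ms[a])
    out["mean_intrachrom_distance"] = float(np.mean(dists)) if dists else float("nan")
    return out


def count_prdm9(seq: str, motif: str = PRDM9_MOTIF) -> int:
    """Occurrences of the PRDM9 binding motif on both strands, overlapping
    matches allowed."""
    pat = re.compile("(?=(" + motif.upper().replace("N", "[ACGT]") + "))")
    fwd = len(pat.findall(seq.upper()))
    rev = len(pat.findall(seq.upper().translate(COMPLEMENT)[::-1]))
    return fwd + rev


# ---------------------------------------------------------------------------
# enrichment P-values


@dataclass
class EnrichmentResult:
    feature: str
    observed: float
    null_distribution: np.ndarray
    p_enriched: float
    p_depleted: float
    direction: str
    degenerate: bool = False

    @property
    def p_value(self) -> float:
        return self.p_enriched if self.direction == "enriched" else self.p_depleted

    @property
    def null_range(self) -> tuple[float, float]:
        return tuple(np.percentile(self.null_distribution, [2.5, 97.5]))


def enrichment_pvalue(
    observed: float, null_distribution, feature: str = ""
) -> EnrichmentResult:
    """Quantile-position P-value of an observed statistic in its simulated
    null, both tails, with the add-one correction (an observed value
    beyond all m simulated values reports 1/(m+1))."""
    null = np.asarray(null_distribution, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    m = null.size
    p_enr = (int((null >= observed).sum()) + 1) / (m + 1)
    p_dep = (int((null <= observed).sum()) + 1) / (m + 1)
    degenerate = bool(np.all(null == null[0]))
    direction = "enriched" if observed >= float(np.median(null)) else "depleted"
    return EnrichmentResult(
        feature=feature,
        observed=observed,
        null_distribution=null,
        p_enriched=float(p_enr),
        p_depleted=float(p_dep),
        direction=direction,
        degenerate=degenerate,
    )


def enrichment_table(
    observed_stats: dict[str, float],
    null_stats: list[dict[str, float]],
) -> pd.DataFrame:
    """Table-style report: observed value, central 95% null range and
    quantile P-value for every statistic computed by the same code path
    on observed and simulated event sets."""
    rows = []
    for feature, obs in observed_stats.items():
        null = [d[feature] for d in null_stats if np.isfinite(d.get(feature, np.nan))]
        if not null or not np.isfinite(obs):
            continue
        r = enrichment_pvalue(obs, null, feature)
        lo, hi = r.null_range
        rows.append(
            {
                "feature": feature,
                "observed": obs,
                "null_low": lo,
                "null_high": hi,
                "direction": r.direction,
                "p_value": r.p_value,
            }
        )
    return pd.DataFrame(rows)
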