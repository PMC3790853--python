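"""Ingest of duplication tables and aligned paralog families.

The entry formats mirror the UCSC segmental-duplication world: a
tab-separated table of family membership with genomic loci (0-based,
half-open, BED-style) and one aligned multi-FASTA per family ("-" gap
character).  Preprocessing applies the standard filters for quartet
analysis of large, high-identity duplications: terminal trimming, removal
of diverged members (<88% identity to every other member by default),
removal of gap-inflating members, deletion of every remaining gapped
column, and rejection of families that end up shorter than 10 kb or
smaller than four sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .substitution import encode, decode

GAP = "-"

IUPAC = set("ACGTRYSWKMBDHVN-")


@dataclass(frozen=True)
class LocusRecord:
    """Genomic locus of one family member (BED conventions)."""

    family_id: str
    seq_name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"{self.seq_name}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.seq_name}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PreprocessConfig:
    """Filter thresholds for family preprocessing."""

    min_identity: float = 0.88
    gap_inflation_factor: float = 0.25
    min_length: int = 10_000
    min_members: int = 4
    strip_cpg: bool = False
    #: leading/trailing columns are dropped until this many consecutive
    #: columns are gap-free in every sequence
    terminal_window: int = 20

    def __post_init__(self):
        if not 0 < self.min_identity < 1:
            raise ValueError("min_identity must lie in (0, 1)")
        if self.min_members < 4:
            raise ValueError("at least 4 members are required for quartets")


@dataclass
class AlignedFamily:
    """A gapless paralog alignment with genome-coordinate maps.

    ``matrix`` holds integer-encoded bases (rows = members, columns =
    alignment positions); ``col_map[i, j]`` is the original genomic
    position of column ``j`` in member ``i``.  After preprocessing every
    retained column maps to a genomic position in every member.
    """

    family_id: str
    members: list[LocusRecord]
    matrix: np.ndarray
    col_map: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D")
        if len(self.members) != self.matrix.shape[0]:
            raise ValueError("members/matrix row mismatch")
        if self.col_map.shape != self.matrix.shape:
            raise ValueError("col_map shape mismatch")

    @property
    def names(self) -> list[str]:
        return [m.seq_name for m in self.members]

    @property
    def n_members(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def mean_identity(self) -> float:
        """Mean pairwise identity over all member pairs."""
        n = self.n_members
        vals = [
            pairwise_identity(self.matrix[i], self.matrix[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
        return float(np.mean(vals))

    @property
    def mean_divergence(self) -> float:
        return 1.0 - self.mean_identity

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def sequence(self, name: str) -> str:
        return decode(self.matrix[self.index_of(name)])

    def subset_columns(self, cols: np.ndarray) -> "AlignedFamily":
        cols = np.asarray(cols)
        return AlignedFamily(
            self.family_id, list(self.members), self.matrix[:, cols], self.col_map[:, cols]
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for i, name in enumerate(self.names):
                fh.write(f">{name}\n{decode(self.matrix[i])}\n")


@dataclass
class RejectionReport:
    """Why a family was removed from the analysis."""

    family_id: str
    reason: str
    detail: str = ""


# ---------------------------------------------------------------------------
# duplication table


def load_family_table(path) -> dict[str, list[LocusRecord]]:
    """Read a tab-separated duplication table grouped by family.

    The header must name ``family``, ``name``, ``chrom``, ``start`` and
    ``end`` columns (``strand`` optional).  Families with fewer than four
    members are retained in the output but flagged via
    :func:`eligible_families`.
    """
    groups: dict[str, list[LocusRecord]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            idx = {k: header.index(k) for k in ("family", "name", "chrom", "start", "end")}
        except ValueError as exc:
            raise ValueError(f"{path}: missing required column: {exc}") from None
        strand_i = header.index("strand") if "strand" in header else None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < len(header):
                raise ValueError(f"{path}:{lineno}: malformed row ({len(parts)} fields)")
            try:
                rec = LocusRecord(
                    family_id=parts[idx["family"]],
                    seq_name=parts[idx["name"]],
                    chrom=parts[idx["chrom"]],
                    start=int(parts[idx["start"]]),
                    end=int(parts[idx["end"]]),
                    strand=parts[strand_i] if strand_i is not None else "+",
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            groups.setdefault(rec.family_id, []).append(rec)
    for fam, recs in groups.items():
        seen = set()
        for r in recs:
            key = (r.chrom, r.start, r.end)
            if key in seen:
                raise ValueError(f"{fam}: duplicate locus {key}")
            seen.add(key)
    return groups


def eligible_families(groups: dict[str, list[LocusRecord]], min_members: int = 4) -> dict[str, bool]:
    """Flag each family as eligible (>= min_members) or not; an unrooted
    quartet needs at least four sequences."""
    return {fam: len(recs) >= min_members for fam, recs in groups.items()}


# ---------------------------------------------------------------------------
# identity and preprocessing


def pairwise_identity(a, b) -> float:
    """Fraction of matching positions between two equal-length gapless
    aligned sequences (strings or encoded arrays)."""
    if isinstance(a, str):
        a = encode(a)
    if isinstance(b, str):
        b = encode(b)
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty sequences have no defined identity")
    return float((a == b).mean())


def read_family_fasta(path) -> dict[str, str]:
    """Aligned multi-FASTA -> ordered {name: gapped sequence}."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"{path}: no sequences")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(f"{path}: unaligned input (unequal lengths {sorted(lengths)})")
    return seqs


def _gapped_identity(a: str, b: str) -> float:
    """Identity over columns where neither sequence is gapped."""
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    keep = (x != ord(GAP)) & (y != ord(GAP))
    if not keep.any():
        return 0.0
    return float((x[keep] == y[keep]).mean())


def _terminal_trim(rows: np.ndarray, window: int) -> tuple[int, int]:
    """(lo, hi) column slice after removing ragged ends.

    Scans inward from each end for the first window of ``window``
    consecutive columns with no gap in any sequence.
    """
    gapfree = (rows != ord(GAP)).all(axis=0)
    if window <= 1:
        idx = np.flatnonzero(gapfree)
        return (int(idx[0]), int(idx[-1]) + 1) if idx.size else (0, 0)
    ok = np.convolve(gapfree.astype(int), np.ones(window, dtype=int), "valid") == window
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return 0, 0
    return int(idx[0]), int(idx[-1]) + window


def preprocess_alignment(
    raw: dict[str, str],
    members: list[LocusRecord],
    cfg: PreprocessConfig | None = None,
):
    """Apply the family filters and return an :class:`AlignedFamily`
    or a :class:`RejectionReport`.

    Steps, in order: (i) trim terminal ragged regions; (ii) drop sequences
    whose *maximum* identity to every other member is below
    ``cfg.min_identity`` (a member with no plausible conversion partner
    carries no signal); (iii) greedily drop the member whose removal most
    inflates the ungapped length while the relative gain exceeds
    ``cfg.gap_inflation_factor``; (iv) delete all remaining gapped columns;
    (v) reject if the result is shorter than ``cfg.min_length`` columns or
    has fewer than ``cfg.min_members`` sequences.
    """
    cfg = cfg or PreprocessConfig()
    fam_id = members[0].family_id if members else "?"
    by_name = {m.seq_name: m for m in members}
    names = [n for n in raw if n in by_name]
    if len(names) < len(raw):
        missing = sorted(set(raw) - set(by_name))
        raise ValueError(f"{fam_id}: sequences without locus metadata: {missing}")
    for n in names:
        bad = set(raw[n]) - IUPAC
        if bad:
            raise ValueError(f"{fam_id}/{n}: non-IUPAC characters {sorted(bad)}")

    rows = np.vstack(
        [np.frombuffer(raw[n].encode(), dtype=np.uint8) for n in names]
    )
    lo, hi = _terminal_trim(rows, cfg.terminal_window)
    if hi <= lo:
        return RejectionReport(fam_id, "min_length", "no gap-free core after trimming")
    rows = rows[:, lo:hi]

    # (ii) identity filter: keep sequences with >= min_identity to at least
    # one other member
    while len(names) > 1:
        dropped = False
        ident = np.zeros((len(names), len(names)))
        strs = ["".join(map(chr, r)) for r in rows]
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                ident[i, j] = ident[j, i] = _gapped_identity(strs[i], strs[j])
        max_ident = ident.max(axis=1)
        worst = int(np.argmin(max_ident))
        if max_ident[worst] < cfg.min_identity:
            rows = np.delete(rows, worst, axis=0)
            names.pop(worst)
            dropped = True
        if not dropped:
            break

    # (iii) gap-inflation filter, worst offender first
    def ungapped_len(r: np.ndarray) -> int:
        return int((r != ord(GAP)).all(axis=0).sum())

    while len(names) > 1:
        full = ungapped_len(rows)
        gains = np.array(
            [ungapped_len(np.delete(rows, i, axis=0)) for i in range(len(names))]
        )
        rel = np.where(gains > 0, (gains - full) / gains, 0.0)
        worst = int(np.argmax(rel))
        if rel[worst] > cfg.gap_inflation_factor:
            rows = np.delete(rows, worst, axis=0)
            names.pop(worst)
        else:
            break

    if len(names) < cfg.min_members:
        return RejectionReport(fam_id, "min_members", f"{len(names)} members survive")

    # (iv) build per-sequence genomic maps on the trimmed gapped alignment,
    # then delete every gapped column
    kept_members = [by_name[n] for n in names]
    gapped_cols = rows == ord(GAP)
    col_map = np.full(rows.shape, -1, dtype=np.int64)
    for i, m in enumerate(kept_members):
        # residue index within the *full* original sequence: count residues
        # trimmed off the left end too
        orig = raw[m.seq_name]
        left_residues = sum(1 for ch in orig[:lo] if ch != GAP)
        res_idx = np.cumsum(~gapped_cols[i]) - 1 + left_residues
        if m.strand == "+":
            col_map[i] = m.start + res_idx
        else:
            col_map[i] = m.end - 1 - res_idx
        col_map[i, gapped_cols[i]] = -1

    keep = ~gapped_cols.any(axis=0)
    rows = rows[:, keep]
    col_map = col_map[:, keep]
    if rows.shape[1] < cfg.min_length:
        return RejectionReport(
            fam_id, "min_length", f"{rows.shape[1]} ungapped columns < {cfg.min_length}"
        )

    matrix = np.vstack([encode("".join(map(chr, r))) for r in rows])
    fam = AlignedFamily(fam_id, kept_members, matrix, col_map)
    if cfg.strip_cpg:
        fam = strip_cpg(fam)
        if fam.length < cfg.min_length:
            return RejectionReport(fam_id, "min_length", "below min_length after CpG strip")
    return fam


def strip_cpg(fam: AlignedFamily) -> AlignedFamily:
    """Remove every column participating in a CpG dinucleotide.

    A column pair (j, j+1) is hypermutable if any member carries C at j
    followed by G at j+1 on the forward strand; both columns are removed
    for all members (strictest reading, unioned over members).
    """
    m = fam.matrix
    is_c = m[:, :-1] == 1
    is_g = m[:, 1:] == 2
    cg = (is_c & is_g).any(axis=0)
    drop = np.zeros(fam.length, dtype=bool)
    drop[:-1] |= cg
    drop[1:] |= cg
    return fam.subset_columns(np.flatnonzero(~drop))


def write_rejections(reports: list[RejectionReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("family\treason\tdetail\n")
        for r in reports:
            fh.write(f"{r.family_id}\t{r.reason}\t{r.detail}\n")
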