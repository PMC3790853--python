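import numpy as np
import pytest

from igcscan.phylo import build_nj_tree
from igcscan.quartet_scan import QuartetResult, scan_family
from igcscan.synthetic_data import (
    FamilyGenSpec,
    generate_null_family,
    inject_crossover,
    inject_gene_conversion,
)
from igcscan.tracks_quartet import (
    QuartetTrackCall,
    call_conversion_tracks,
    call_crossover_breakpoints,
    flag_complex_events,
    map_call_to_genome,
    partition_topology_blocks,
    select_informative_quartets,
)


def quartet(cols, codes, dominant=0):
    return QuartetResult(
        ("a", "b", "c", "d"), (0, 1, 2, 3), dominant,
        np.asarray(cols), np.asarray(codes, dtype=np.int8),
    )


# ---------------------------------------------------------------------------
# conversion tracks (midpoint rule)


def test_midpoint_rule_two_site_cluster():
    q = quartet([100, 200, 300, 400], [0, 1, 1, 0])
    (call,) = call_conversion_tracks(q, alignment_length=500)
    assert (call.start, call.stop) == (150.0, 350.0)
    assert call.length == 200.0
    assert call.n_R_support == 2
    assert call.kind == "conversion"


def test_midpoint_rule_isolated_r_site():
    q = quartet([200, 250, 320], [0, 1, 0])
    (call,) = call_conversion_tracks(q, alignment_length=400)
    assert (call.start, call.stop) == (225.0, 285.0)
    assert call.length == 60.0


def test_clusters_split_on_different_alternative_topologies():
    q = quartet([100, 200, 300, 400], [0, 1, 2, 0])
    calls = call_conversion_tracks(q, alignment_length=500)
    assert len(calls) == 2
    assert {c.alt_topology for c in calls} == {1, 2}


def test_boundary_cluster_uses_alignment_end_as_flank():
    q = quartet([100, 200], [1, 0])  # R run touching informative start
    (call,) = call_conversion_tracks(q, alignment_length=500)
    assert call.start == 50.0  # midpoint(0, 100)
    assert call.stop == 150.0


def test_tracks_within_quartet_never_overlap():
    rng = np.random.default_rng(5)
    for _ in range(25):
        n = int(rng.integers(6, 40))
        cols = np.sort(rng.choice(5000, size=n, replace=False))
        codes = rng.choice([0, 1, 2], size=n, p=[0.6, 0.25, 0.15])
        calls = call_conversion_tracks(quartet(cols, codes), alignment_length=5000)
        calls = sorted(calls, key=lambda c: c.start)
        for a, b in zip(calls, calls[1:]):
            assert a.stop <= b.start


# ---------------------------------------------------------------------------
# crossover breakpoints


def test_crossover_window_between_flanking_c_and_first_r():
    # terminal run of 6 R sites; flanking C at 5175, first R at 7532
    cols = [1000, 5175, 7532, 8000, 8500, 9000, 9500, 9900]
    codes = [0, 0, 1, 1, 1, 1, 1, 1]
    (call,) = call_crossover_breakpoints(quartet(cols, codes), 10_000)
    assert (call.start, call.stop) == (5175.0, 7532.0)
    assert call.kind == "crossover"
    assert call.n_R_support == 6


def test_terminal_run_of_four_r_sites_is_not_a_crossover():
    cols = [1000, 5175, 8000, 8500, 9000, 9500]
    codes = [0, 0, 1, 1, 1, 1]
    assert call_crossover_breakpoints(quartet(cols, codes), 10_000) == []


def test_crossover_candidates_excluded_from_conversion_tracks():
    cols = [1000, 5175, 8000, 8500, 9000, 9500, 9900]
    codes = [0, 0, 1, 1, 1, 1, 1]
    conv = call_conversion_tracks(quartet(cols, codes), alignment_length=10_000)
    assert conv == []


def test_crossover_calls_match_terminal_run_oracle():
    """Crossover calls correspond exactly to terminal runs of >=5
    same-topology consecutive R sites; their windows touch the run."""
    rng = np.random.default_rng(9)
    for _ in range(40):
        n = int(rng.integers(8, 30))
        cols = np.sort(rng.choice(5000, size=n, replace=False))
        codes = rng.choice([0, 1, 2], size=n, p=[0.45, 0.35, 0.2])
        q = quartet(cols, codes)
        calls = call_crossover_breakpoints(q, 5000)

        # oracle: re-scan the label series for terminal same-topology runs
        runs = []
        i = 0
        while i < n:
            if codes[i] != 0:
                j = i
                while j + 1 < n and codes[j + 1] == codes[i]:
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        expected = [
            (i, j) for i, j in runs
            if j - i + 1 >= 5 and (i == 0 or j == n - 1)
        ]
        assert len(calls) == len(expected)
        for call, (i, j) in zip(sorted(calls, key=lambda c: c.start),
                                sorted(expected)):
            assert call.n_R_support == j - i + 1


# ---------------------------------------------------------------------------
# eligibility


def test_select_informative_quartets_boundaries():
    q_ok = quartet(np.arange(12) * 10, [0, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0])
    assert q_ok.n_R == 6
    assert select_informative_quartets([(q_ok, 4.9)]) == [q_ok]
    assert select_informative_quartets([(q_ok, 5.0)]) == []  # strict <5
    q_few_r = quartet(np.arange(10) * 10, [0, 1, 1, 1, 1, 1, 0, 0, 0, 0])
    assert q_few_r.n_R == 5
    assert select_informative_quartets([(q_few_r, 1.0)]) == []  # needs >5


def test_select_matches_refilter_oracle():
    rng = np.random.default_rng(1)
    stats = []
    for _ in range(50):
        n = int(rng.integers(6, 25))
        cols = np.sort(rng.choice(3000, size=n, replace=False))
        codes = rng.choice([0, 1, 3], size=n, p=[0.5, 0.3, 0.2])
        stats.append((quartet(cols, codes), float(rng.uniform(0, 10))))
    got = select_informative_quartets(stats)
    oracle = [q for q, eb in stats if eb < 5.0 and q.n_R > 5]
    assert got == oracle


# ---------------------------------------------------------------------------
# topology blocks


def test_all_concordant_single_segment():
    q = quartet([100, 200, 300], [0, 0, 0])
    part = partition_topology_blocks(q, 1000)
    assert part.segments == [(0.0, 1000.0, 0)]
    assert part.fraction_discordant == 0.0


def test_half_alignment_discordant_by_bp():
    # informative sites at 249 (C) and 251 (R): switch midpoint at 250
    q = quartet([249, 251], [0, 1])
    part = partition_topology_blocks(q, 500)
    assert part.fraction_discordant == pytest.approx(0.5)


def test_blocks_tile_alignment_exactly():
    rng = np.random.default_rng(2)
    for _ in range(25):
        n = int(rng.integers(1, 50))
        L = int(rng.integers(200, 5000))
        cols = np.sort(rng.choice(L, size=min(n, L), replace=False))
        codes = rng.choice([0, 1, 2, 3], size=cols.size)
        if (codes == 3).all():
            codes[0] = 0
        q = quartet(cols, codes)
        part = partition_topology_blocks(q, L)
        total = sum(s[1] - s[0] for s in part.segments)
        assert total == pytest.approx(L)
        for a, b in zip(part.segments, part.segments[1:]):
            assert a[1] == b[0]
            assert a[2] != b[2]


def test_fraction_discordant_matches_per_bp_oracle():
    rng = np.random.default_rng(3)
    for _ in range(10):
        n = int(rng.integers(4, 30))
        L = 2000
        cols = np.sort(rng.choice(L, size=n, replace=False))
        codes = rng.choice([0, 1, 2], size=n)
        q = quartet(cols, codes)
        part = partition_topology_blocks(q, L)
        per_bp = np.array([part.topology_at(x + 0.5) for x in range(L)])
        assert part.fraction_discordant == pytest.approx((per_bp != 0).mean(), abs=2 / L)


# ---------------------------------------------------------------------------
# complex events


def test_complex_flag_for_clustered_switches():
    q = quartet([1000, 1400, 1800, 2200, 2600], [0, 1, 0, 1, 0])
    part = partition_topology_blocks(q, 10_000)
    flags = flag_complex_events(part, 10_000, window=2000)
    assert len(flags) == 1
    assert flags[0]["n_switches"] >= 3
    assert not flags[0]["edge_proximal"]


def test_no_flag_for_two_distant_switches():
    q = quartet([1000, 6000], [1, 0])
    part = partition_topology_blocks(q, 10_000)
    assert flag_complex_events(part, 10_000, window=2000) == []


# ---------------------------------------------------------------------------
# recovery of injected events


def test_injected_conversion_recovered_with_overlap():
    spec = FamilyGenSpec(n_paralogs=4, length=10_000, target_identity=0.95, seed=61)
    fam, tree, truth = generate_null_family(spec)
    nj = build_nj_tree(fam, n_boot=0)
    q0 = scan_family(fam, nj)[0]
    # pick non-sister pair relative to the quartet topology
    names = q0.leaves
    pairing = ((0, 1), (2, 3)) if q0.dominant == 0 else (
        ((0, 2), (1, 3)) if q0.dominant == 1 else ((0, 3), (1, 2)))
    donor, acceptor = names[pairing[0][0]], names[pairing[1][0]]
    fam2, ev = inject_gene_conversion(fam, donor, acceptor, 4000, 5000)
    q = scan_family(fam2, nj)[0]
    calls = call_conversion_tracks(q, alignment_length=fam2.length)
    hit = [c for c in calls if c.start < ev.stop and c.stop > ev.start]
    assert hit, "no called track overlaps the injected interval"
    best = max(hit, key=lambda c: c.n_R_support)
    assert abs(best.start - ev.start) < best.length
    assert abs(best.stop - ev.stop) < best.length


def test_injected_crossover_breakpoint_localised():
    """A suffix swap between non-sisters flips every downstream
    dominant-concordant site to R; at high identity the terminal run is
    uninterrupted and the breakpoint falls inside the called window."""
    spec = FamilyGenSpec(n_paralogs=4, length=10_000, target_identity=0.98, seed=60)
    fam, tree, truth = generate_null_family(spec)
    nj = build_nj_tree(fam, n_boot=0)
    q0 = scan_family(fam, nj)[0]
    names = q0.leaves
    pairing = ((0, 1), (2, 3)) if q0.dominant == 0 else (
        ((0, 2), (1, 3)) if q0.dominant == 1 else ((0, 3), (1, 2)))
    pair = (names[pairing[0][0]], names[pairing[1][0]])  # non-sisters
    bp = 8000
    fam2, ev = inject_crossover(fam, pair, bp)
    q = scan_family(fam2, nj)[0]
    calls = call_crossover_breakpoints(q, fam2.length)
    assert calls, "crossover not called"
    assert any(c.start <= bp <= c.stop for c in calls)


def test_map_call_to_genome_intervals():
    spec = FamilyGenSpec(n_paralogs=4, length=2000, target_identity=0.95, seed=63)
    fam, tree, _ = generate_null_family(spec)
    call = QuartetTrackCall("synth", tuple(fam.names), 100.4, 300.7, 3, 1, "conversion")
    call = map_call_to_genome(call, fam)
    for name, (chrom, s, e) in call.genome_intervals.items():
        i = fam.index_of(name)
        assert chrom == fam.members[i].chrom
        assert e - s == pytest.approx(202, abs=2)
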