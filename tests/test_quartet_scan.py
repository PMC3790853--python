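import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from igcscan.phylo import build_nj_tree
from igcscan.quartet_scan import (
    B_SITE,
    QuartetResult,
    classify_quartet_columns,
    classify_quartet_site,
    excess_test,
    family_site_unions,
    quartet_runs_test,
    r_run_spacing,
    runs_count,
    runs_pvalue_exact,
    runs_test,
    scan_family,
)
from igcscan.substitution import encode
from igcscan.synthetic_data import (
    FamilyGenSpec,
    generate_null_family,
    inject_gene_conversion,
)


# ---------------------------------------------------------------------------
# site classification


@pytest.mark.parametrize(
    "column,dominant,expected",
    [
        ("AAGG", 0, ("C", None)),  # pairing matches AB|CD
        ("AGAG", 0, ("R", 1)),  # supports AC|BD against dominant AB|CD
        ("AAGT", 0, ("B", None)),  # three bases: obligate double mutation
        ("AAGT", 2, ("B", None)),
        ("AAAA", 0, ("uninformative", None)),
        ("AAAG", 0, ("uninformative", None)),
        ("ACCA", 0, ("R", 2)),  # AD|BC pairing
        ("ACGT", 0, ("B", None)),
    ],
)
def test_classify_single_site(column, dominant, expected):
    assert classify_quartet_site(encode(column), dominant) == expected


def test_classify_columns_vectorised_matches_scalar():
    rng = np.random.default_rng(0)
    m = rng.choice(4, size=(4, 300))
    codes = classify_quartet_columns(m)
    for j in range(300):
        label, alt = classify_quartet_site(m[:, j], dominant=0)
        if label == "uninformative":
            assert codes[j] == -1
        elif label == "B":
            assert codes[j] == B_SITE
        elif label == "C":
            assert codes[j] == 0
        else:
            assert codes[j] == alt


# ---------------------------------------------------------------------------
# family scan


def test_scan_counts_quartets(null_family_small):
    fam, tree, _ = null_family_small
    results = scan_family(fam, tree)
    assert len(results) == math.comb(6, 4) == 15


def test_single_quartet_family_union_equals_quartet_r(null_family_quartet):
    fam, tree, _ = null_family_quartet
    results = scan_family(fam, tree)
    assert len(results) == 1
    r_mask, b_mask, inf_mask = family_site_unions(results, fam.length)
    assert int(r_mask.sum()) == results[0].n_R
    assert int(inf_mask.sum()) == len(results[0].cols)
    assert int(r_mask.sum()) <= int(inf_mask.sum())


def test_column_reticulate_in_several_quartets_counted_once(null_family_small):
    fam, tree, _ = null_family_small
    # force one column to be reticulate in many quartets: copy a base
    # between two non-sister members at one site
    results = scan_family(fam, tree)
    r_mask, _, _ = family_site_unions(results, fam.length)
    per_quartet = np.zeros(fam.length, dtype=int)
    for q in results:
        per_quartet[q.r_columns] += 1
    multi = per_quartet >= 3
    if multi.any():
        assert r_mask[multi].all()
        # union counts each column once regardless of quartet multiplicity
        assert int(r_mask.sum()) == int((per_quartet >= 1).sum())


# ---------------------------------------------------------------------------
# excess test


def test_excess_test_null_family_self_consistent(null_family_quartet, jc_model):
    """With observed data drawn from (nearly) the simulation model, the
    paired P-value is far from the rejection region."""
    fam, tree, _ = null_family_quartet
    spec = FamilyGenSpec(n_paralogs=4, length=8000, target_identity=0.95, seed=33)
    et = excess_test(fam, tree, spec.model, n_boot=100, n_sim=100, seed=5)
    assert et.p_value is not None
    assert 0.05 < et.p_value <= 1.0
    assert et.ci_R[0] <= et.observed_R <= et.ci_R[1]


def test_excess_test_detects_injected_igc(null_family_small):
    fam, tree, _ = null_family_small
    spec = FamilyGenSpec(n_paralogs=6, length=6000, target_identity=0.95, seed=20240)
    rng = np.random.default_rng(8)
    fam2 = fam
    for _ in range(10):
        donor, acceptor = rng.choice(fam.names, size=2, replace=False)
        s = int(rng.integers(0, fam.length - 600))
        fam2, _ = inject_gene_conversion(fam2, donor, acceptor, s, s + 600)
    et = excess_test(fam2, tree, spec.model, seed=5)
    assert et.p_value is not None and et.p_value <= 0.05


def test_excess_test_skips_without_r_sites(jc_model):
    from conftest import make_family
    from igcscan.phylo import Tree

    # identical sequences: no informative sites; tree supplied by hand
    fam = make_family({n: "ACGT" * 250 for n in ("a", "b", "c", "d")})
    tree = Tree.from_newick("((a:0.01,b:0.01):0.01,(c:0.01,d:0.01):0.01);")
    et = excess_test(fam, tree, jc_model, n_boot=20, n_sim=20, seed=0)
    assert et.skipped == "no informative sites"
    assert et.p_value is None


def test_igc_injection_cannot_create_b_sites(null_family_quartet):
    """Conversion copies an existing base, so in a quartet containing both
    donor and acceptor it can never produce a three-base column."""
    fam, tree, _ = null_family_quartet
    q0 = scan_family(fam, tree)[0]
    rng = np.random.default_rng(3)
    fam2 = fam
    for _ in range(5):
        donor, acceptor = rng.choice(fam.names, size=2, replace=False)
        s = int(rng.integers(0, fam.length - 500))
        fam2, _ = inject_gene_conversion(fam2, donor, acceptor, s, s + 500)
    q1 = scan_family(fam2, tree)[0]
    before = set(q0.cols[q0.codes == B_SITE])
    after = set(q1.cols[q1.codes == B_SITE])
    assert after <= before


# ---------------------------------------------------------------------------
# runs test


def brute_force_runs_p(n1, n2, observed_runs):
    labels = [False] * n1 + [True] * n2
    total = 0
    at_most = 0
    seen = set()
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        total += 1
        if runs_count(np.array(perm)) <= observed_runs:
            at_most += 1
    return at_most / total


def test_runs_exact_matches_exhaustive_enumeration():
    for n1, n2, r in [(4, 4, 2), (5, 3, 3), (4, 4, 5), (6, 2, 4)]:
        assert runs_pvalue_exact(n1, n2, r) == pytest.approx(
            brute_force_runs_p(n1, n2, r)
        )


def test_runs_test_clustered_vs_alternating():
    clustered = runs_test("CCCCRRRR")
    assert clustered.runs == 2
    assert clustered.method == "exact"
    assert clustered.p_one_sided == pytest.approx(brute_force_runs_p(4, 4, 2))
    assert clustered.p_one_sided < 0.05
    alternating = runs_test("CRCRCRCR")
    assert alternating.p_one_sided == pytest.approx(1.0)


def test_runs_test_degenerate_single_class():
    with pytest.raises(ValueError, match="degenerate"):
        runs_test("CCCC")


def test_runs_normal_approximation_tracks_exact_above_cutoff():
    """The normal tail is used beyond the exact cutoff; on moderate sizes
    the two agree to a few percent."""
    def arrangement(n1, n2, r):
        """A C/R sequence with exactly r runs."""
        k1, k2 = (r + 1) // 2, r // 2
        c = [n1 // k1] * k1
        c[0] += n1 - sum(c)
        rr = [n2 // k2] * k2 if k2 else []
        if k2:
            rr[0] += n2 - sum(rr)
        out = []
        for i in range(max(k1, k2)):
            if i < k1:
                out += [False] * c[i]
            if i < k2:
                out += [True] * rr[i]
        return np.array(out)

    diffs = []
    for n1, n2 in [(15, 15), (20, 12), (25, 25)]:
        for r in range(2, 2 * min(n1, n2)):
            pe = runs_pvalue_exact(n1, n2, r)
            res = runs_test(arrangement(n1, n2, r), method="normal")
            assert res.runs == r
            if 0.001 < pe < 0.999:
                diffs.append(abs(pe - res.p_one_sided))
    assert max(diffs) < 0.02


def test_quartet_runs_test_requires_more_than_five_r_sites():
    q = QuartetResult(
        ("a", "b", "c", "d"), (0, 1, 2, 3), 0,
        cols=np.arange(10) * 10,
        codes=np.array([0, 0, 1, 1, 1, 0, 0, 0, 1, 0], dtype=np.int8),
    )
    assert q.n_R == 4
    assert quartet_runs_test(q) is None  # only 4 R sites: not applied
    q2 = QuartetResult(
        ("a", "b", "c", "d"), (0, 1, 2, 3), 0,
        cols=np.arange(14) * 10,
        codes=np.array([0, 1, 1, 1, 0, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=np.int8),
    )
    res = quartet_runs_test(q2)
    assert res is not None and res.n2 == 6


# ---------------------------------------------------------------------------
# R-run spacing


def _quartet_from_labels(cols, labels):
    codes = np.where(np.array(labels), 1, 0).astype(np.int8)
    return QuartetResult(("a", "b", "c", "d"), (0, 1, 2, 3), 0,
                         np.asarray(cols), codes)


def test_r_run_spacing_far_apart_runs():
    q = _quartet_from_labels(
        [100, 101, 102, 200, 201], [True, True, False, True, True])
    # two runs of length >=2, separated by ~98 bp
    assert r_run_spacing(q) == 1.0


def test_r_run_spacing_close_runs():
    q = _quartet_from_labels(
        [100, 101, 104, 108, 109], [True, True, False, True, True])
    assert r_run_spacing(q) == 0.0


def test_r_run_spacing_no_qualifying_runs():
    q = _quartet_from_labels([10, 30, 50], [True, False, True])
    assert r_run_spacing(q) is None


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_r_run_spacing_matches_recount_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 40))
    cols = np.sort(rng.choice(2000, size=n, replace=False))
    labels = rng.random(n) < 0.4
    if not labels.any() or labels.all():
        return
    q = _quartet_from_labels(cols, labels)
    got = r_run_spacing(q)

    # independent linear re-scan
    runs = []
    i = 0
    while i < n:
        if labels[i]:
            j = i
            while j + 1 < n and labels[j + 1]:
                j += 1
            runs.append((cols[i], cols[j], j - i + 1))
            i = j + 1
        else:
            i += 1
    qual = [k for k, r in enumerate(runs) if r[2] >= 2]
    if not qual:
        assert got is None
        return
    if len(runs) == 1:
        assert got == 1.0
        return
    ok = 0
    for k in qual:
        gaps = []
        if k > 0:
            gaps.append(runs[k][0] - runs[k - 1][1])
        if k < len(runs) - 1:
            gaps.append(runs[k + 1][0] - runs[k][1])
        ok += min(gaps) > 10
    assert got == pytest.approx(ok / len(qual))
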