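"""Association statistics against brute-force oracles and hand-derived values."""
import itertools
import math

import numpy as np
import pytest
from scipy import stats

from metspread import (
    burden_summary,
    cooccurrence_matrix,
    origin_matrix,
    progression_matrix,
    relative_risk,
    rr_screen,
    site_frequency,
)
from metspread.patterns import FLAG_NULL

from conftest import make_cohort, make_record, random_small_cohort


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_rr(cohort, a, b):
    """Patient-by-patient enumeration of RR(a,b) = f(a&b)/(f(a)f(b))."""
    def member(rec, label):
        if label in cohort.vocab.secondary_sites:
            return rec.mets[cohort.vocab.secondary_index(label)] == 1
        return rec.primary_site == label

    n = len(cohort)
    fa = sum(member(r, a) for r in cohort.included) / n
    fb = sum(member(r, b) for r in cohort.included) / n
    fab = sum(member(r, a) and member(r, b) for r in cohort.included) / n
    if fa == 0 or fb == 0:
        return float("nan")
    return fab / (fa * fb)


def oracle_fisher_two_sided(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def prob(x):
        return (
            math.comb(col1, x)
            * math.comb(n - col1, row1 - x)
            / math.comb(n, row1)
        )

    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    p_obs = prob(a)
    return sum(p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs * (1 + 1e-9))


def oracle_bh(pvals):
    """Benjamini-Hochberg step-up adjusted q-values, by hand."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, pvals[idx] * m / rank)
        q[idx] = running
    return q


def oracle_kruskal_h(groups):
    """Tie-corrected Kruskal-Wallis H by direct rank computation."""
    flat = np.concatenate(groups)
    ranks = stats.rankdata(flat)
    n = len(flat)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12 / (n * (n + 1))
    _, counts = np.unique(flat, return_counts=True)
    tie = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / tie


# ---------------------------------------------------------------------------
# burden summary
# ---------------------------------------------------------------------------

def test_burden_identical_counts_gives_p_one():
    cohort = make_cohort(
        [make_record(id=str(i), primary=p, met_codes=("HEP", "PUL"))
         for i, p in enumerate(["lung"] * 3 + ["breast"] * 3)]
    )
    res = burden_summary(cohort)
    assert res.kruskal_h == 0.0 and res.kruskal_p == 1.0
    assert (res.per_primary["mean"] == 2.0).all()


def test_burden_two_group_example_matches_rank_oracle():
    """{1,1,1} vs {5,5,5} site counts: means 1 and 5; H matches enumeration."""
    recs = [make_record(id=f"a{i}", primary="lung", met_codes=("HEP",)) for i in range(3)]
    recs += [
        make_record(id=f"b{i}", primary="breast",
                    met_codes=("HEP", "PUL", "OSS", "LYM", "PLE"))
        for i in range(3)
    ]
    res = burden_summary(make_cohort(recs))
    means = res.per_primary["mean"]
    assert means["lung"] == 1.0 and means["breast"] == 5.0
    # oracle: H over the 20 assignments of {1,1,1,5,5,5} into two triples
    counts = np.array([1, 1, 1, 5, 5, 5])
    h_obs = oracle_kruskal_h([counts[:3], counts[3:]])
    assert res.kruskal_h == pytest.approx(h_obs, abs=1e-12)
    perm_h = [
        oracle_kruskal_h([counts[list(idx)],
                          counts[[i for i in range(6) if i not in idx]]])
        for idx in itertools.combinations(range(6), 3)
    ]
    p_exact = np.mean([h >= h_obs - 1e-12 for h in perm_h])
    assert p_exact == pytest.approx(2 / 20)
    assert 0 < res.kruskal_p < 0.1  # asymptotic p for H = 5.0


def test_burden_n_sums_to_cohort(reference_cohort):
    res = burden_summary(reference_cohort)
    assert res.per_primary["n"].sum() == len(reference_cohort)
    assert ((res.per_primary["mean"] >= 0) & (res.per_primary["mean"] <= 20)).all()
    assert (res.per_primary["sd"] >= 0).all()


def test_burden_drops_empty_primary_with_warning():
    cohort = make_cohort([make_record(id="a", primary="lung", met_codes=("HEP",)),
                          make_record(id="b", primary="lung", met_codes=("HEP", "PUL"))])
    with pytest.warns(UserWarning):
        res = burden_summary(cohort)
    assert list(res.per_primary.index) == ["lung"]


# ---------------------------------------------------------------------------
# frequency matrices
# ---------------------------------------------------------------------------

def test_site_frequency_direct_count():
    recs = [make_record(id=str(i), met_codes=("HEP",)) for i in range(6)]
    recs += [make_record(id=str(i + 6), met_codes=("PUL",)) for i in range(4)]
    frac, _ = site_frequency(make_cohort(recs))
    assert frac["HEP"] == 0.6 and frac["PUL"] == 0.4 and frac["OSS"] == 0.0


def test_site_frequency_all_bits_set():
    all_codes = tuple(c for c in make_cohort([]).vocab.secondary_sites)
    cohort = make_cohort([make_record(id=str(i), met_codes=all_codes) for i in range(5)])
    frac, p = site_frequency(cohort)
    assert (frac == 1.0).all() and p == pytest.approx(1.0)


def test_progression_matrix_examples():
    recs = [make_record(id=str(i), primary="breast", sex="female",
                        met_codes=("HEP",) if i < 3 else ("PUL",)) for i in range(4)]
    mat = progression_matrix(make_cohort(recs))
    assert mat.statistic.at["breast", "HEP"] == 0.75
    assert np.isnan(mat.statistic.at["lung", "HEP"])  # no lung patients: undefined


def test_single_primary_progression_row():
    recs = [make_record(id=str(i), primary="prostate", met_codes=("OSS",)) for i in range(7)]
    mat = progression_matrix(make_cohort(recs))
    row = mat.statistic.loc["prostate"]
    assert row["OSS"] == 1.0 and row.drop("OSS").eq(0).all()


def test_origin_matrix_example():
    recs = [make_record(id=f"l{i}", primary="lung", met_codes=("BRA",)) for i in range(2)]
    recs += [make_record(id=f"b{i}", primary="breast", sex="female", met_codes=("BRA",))
             for i in range(3)]
    mat = origin_matrix(make_cohort(recs))
    assert mat.statistic.at["BRA", "lung"] == pytest.approx(0.4)
    assert mat.statistic.at["BRA", "breast"] == pytest.approx(0.6)
    assert np.isnan(mat.statistic.loc["HEP"]).all()  # site never hit


def test_count_consistency_between_progression_and_origin(reference_cohort):
    """cell_prog(p,s)*n_p == cell_orig(s,p)*n_s == |patients with p and s|."""
    prog = progression_matrix(reference_cohort).statistic
    orig = origin_matrix(reference_cohort).statistic
    primaries = reference_cohort.primaries()
    mets = reference_cohort.met_matrix()
    v = reference_cohort.vocab
    for i, p in enumerate(v.primary_sites):
        n_p = int((primaries == p).sum())
        for j, s in enumerate(v.secondary_sites):
            n_s = int(mets[:, j].sum())
            joint = int(mets[primaries == p, j].sum())
            assert prog.at[p, s] * n_p == pytest.approx(joint, abs=1e-9)
            if n_s > 0:
                assert orig.at[s, p] * n_s == pytest.approx(joint, abs=1e-9)


def test_origin_rows_sum_to_one(reference_cohort):
    mat = origin_matrix(reference_cohort).statistic
    sums = mat.sum(axis=1, skipna=False).dropna()
    assert np.allclose(sums, 1.0)


# ---------------------------------------------------------------------------
# co-occurrence (Jaccard)
# ---------------------------------------------------------------------------

def test_cooccurrence_set_arithmetic():
    # A = {1,2,3} hit HEP; B = {3,4} hit PUL; overlap = {3}
    recs = [
        make_record(id="1", met_codes=("HEP",)),
        make_record(id="2", met_codes=("HEP",)),
        make_record(id="3", met_codes=("HEP", "PUL")),
        make_record(id="4", met_codes=("PUL",)),
    ]
    mat = cooccurrence_matrix(make_cohort(recs)).statistic
    assert mat.at["HEP", "PUL"] == pytest.approx(0.25)
    assert mat.at["PUL", "HEP"] == pytest.approx(0.25)
    assert mat.at["HEP", "HEP"] == 1.0
    assert np.isnan(mat.at["OSS", "OSS"])  # never hit: undefined


def test_cooccurrence_disjoint_and_identical():
    recs = [make_record(id="1", met_codes=("HEP",)), make_record(id="2", met_codes=("PUL",))]
    mat = cooccurrence_matrix(make_cohort(recs)).statistic
    assert mat.at["HEP", "PUL"] == 0.0
    recs = [make_record(id="1", met_codes=("HEP", "PUL"))]
    mat = cooccurrence_matrix(make_cohort(recs)).statistic
    assert mat.at["HEP", "PUL"] == 1.0


def test_cooccurrence_symmetric(reference_cohort):
    mat = cooccurrence_matrix(reference_cohort).statistic.to_numpy()
    assert np.allclose(mat, mat.T, equal_nan=True)


# ---------------------------------------------------------------------------
# relative risk
# ---------------------------------------------------------------------------

def test_rr_hand_derived_example():
    """n=10, |a|=4, |b|=5, |a&b|=3 -> RR = 0.3/(0.4*0.5) = 1.5."""
    recs = []
    for i in range(10):
        codes = []
        if i < 4:
            codes.append("HEP")   # a
        if i < 3 or i in (4, 5):
            codes.append("PUL")   # b: patients 0,1,2,4,5
        recs.append(make_record(id=str(i), met_codes=tuple(codes) or ("OTH",)))
    res = relative_risk(make_cohort(recs), "HEP", "PUL")
    assert res.rr == pytest.approx(1.5)
    assert res.counts.tolist() == [[3, 1], [2, 4]]


def test_rr_ubiquitous_site_is_one():
    recs = [make_record(id=str(i), primary="lung" if i < 4 else "breast",
                        met_codes=("HEP", "PUL") if i % 2 else ("HEP",)) for i in range(8)]
    res = relative_risk(make_cohort(recs), "lung", "HEP")
    assert res.rr == pytest.approx(1.0)


def test_rr_never_cooccurring_is_zero_and_undefined_margin_nan():
    recs = [make_record(id="1", met_codes=("HEP",)), make_record(id="2", met_codes=("PUL",))]
    cohort = make_cohort(recs)
    assert relative_risk(cohort, "HEP", "PUL").rr == 0.0
    res = relative_risk(cohort, "HEP", "OSS")
    assert np.isnan(res.rr) and res.p == 1.0


def test_rr_matches_enumeration_oracle_exhaustively():
    """RR equals patient-enumeration oracle for all pairs on small cohorts."""
    rng = np.random.default_rng(42)
    for trial in range(4):
        cohort = random_small_cohort(rng, n=int(rng.integers(5, 31)))
        labels = list(cohort.vocab.secondary_sites) + ["lung", "breast"]
        for a in labels:
            for b in cohort.vocab.secondary_sites:
                got = relative_risk(cohort, a, b).rr
                want = oracle_rr(cohort, a, b)
                if np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want, rel=1e-12)


def test_fisher_p_matches_hypergeometric_enumeration():
    """Fisher two-sided p agrees with full enumeration on tables with n <= 40."""
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(2, 41))
        a = int(rng.integers(0, n + 1))
        b = int(rng.integers(0, n - a + 1))
        c = int(rng.integers(0, n - a - b + 1))
        d = n - a - b - c
        table = [[a, b], [c, d]]
        _, p_impl = stats.fisher_exact(table, alternative="two-sided")
        assert p_impl == pytest.approx(oracle_fisher_two_sided(table), rel=1e-9, abs=1e-12)


def test_rr_fisher_on_derived_table():
    cohort = random_small_cohort(np.random.default_rng(3), n=25)
    res = relative_risk(cohort, "HEP", "PUL")
    assert res.p == pytest.approx(oracle_fisher_two_sided(res.counts.tolist()), rel=1e-9)


# ---------------------------------------------------------------------------
# RR screen
# ---------------------------------------------------------------------------

def test_bh_step_up_hand_example():
    q = oracle_bh(np.array([0.01, 0.02, 0.03, 0.04]))
    assert np.allclose(q, 0.04)
    from statsmodels.stats.multitest import multipletests

    _, q_sm, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
    assert np.allclose(q_sm, 0.04)


def test_bh_matches_statsmodels_random_vectors():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(5)
    for _ in range(20):
        p = rng.random(int(rng.integers(1, 40)))
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q_sm, oracle_bh(p))


def test_rr_screen_structure(reference_cohort):
    scr = rr_screen(reference_cohort, mode="primary_to_secondary")
    stat, p, q, flag = scr.statistic, scr.p, scr.q, scr.flag
    defined = np.isfinite(stat.to_numpy())
    assert (q.to_numpy()[defined] >= p.to_numpy()[defined] - 1e-12).all()
    sig = flag.to_numpy() != FLAG_NULL
    assert (q.to_numpy()[sig] < 0.05).all()
    enriched = flag.to_numpy() == "enriched"
    assert (stat.to_numpy()[enriched] > 1).all()


def test_rr_screen_secondary_pairs_symmetric(reference_cohort):
    scr = rr_screen(reference_cohort, mode="secondary_pairs")
    m = scr.statistic.to_numpy()
    assert np.allclose(m, m.T, equal_nan=True)
    assert np.isnan(np.diag(m)).all()
    q = scr.q.to_numpy()
    assert np.allclose(q, q.T, equal_nan=True)


def test_rr_screen_single_cell_null():
    # a vocabulary-complete cohort where only two sites vary
    recs = [make_record(id=str(i), met_codes=("HEP", "PUL")) for i in range(4)]
    scr = rr_screen(make_cohort(recs), mode="secondary_pairs")
    assert scr.p.at["HEP", "PUL"] == 1.0
    assert scr.q.at["HEP", "PUL"] == 1.0
    assert scr.flag.at["HEP", "PUL"] == FLAG_NULL


def test_mean_rr_near_one_under_independence():
    """Monte-Carlo null: mean pairwise RR is 1 within sampling error."""
    from metspread import apply_inclusion_filters, generate_registry
    from metspread.synthetic import make_eligible_cohort_config

    cfg = make_eligible_cohort_config(
        10_000, seed=31, coupling=np.eye(20), marginal_probs=np.full((16, 20), 0.35)
    )
    cohort = apply_inclusion_filters(generate_registry(cfg))
    scr = rr_screen(cohort, mode="secondary_pairs")
    iu = np.triu_indices(20, 1)
    assert np.nanmean(scr.statistic.to_numpy()[iu]) == pytest.approx(1.0, abs=0.02)
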