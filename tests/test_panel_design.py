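"""Marker-selection cascade: exact HWE test, LD pruning, F_ST, panel rules."""

import math
from fractions import Fraction

import numpy as np
import pytest

from snpmon.genotype_io import (
    CAT_HIGH_MAF,
    CAT_WOLF_JACKAL,
    MISSING,
    GenotypeTable,
    MarkerInfo,
)
from snpmon.panel_design import (
    SelectionConfig,
    compute_locus_stats,
    fst_locus,
    hwe_exact_test,
    ld_prune,
    ld_r2,
    minor_allele_frequency,
    select_panel,
)

from conftest import table_from_rows


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------


def hwe_enumeration_oracle(n_aa: int, n_ab: int, n_bb: int) -> Fraction:
    """Brute-force conditional HWE p-value with exact rational arithmetic."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab

    def weight(h: int) -> Fraction:
        haa = (n_a - h) // 2
        hbb = n - h - haa
        return Fraction(2**h * math.factorial(n),
                        math.factorial(haa) * math.factorial(h) * math.factorial(hbb))

    support = [h for h in range(0, min(n_a, 2 * n - n_a) + 1)
               if (n_a - h) % 2 == 0 and (n_a - h) >= 0 and (2 * n - n_a - h) >= 0]
    weights = {h: weight(h) for h in support}
    total = sum(weights.values())
    p_obs = weights[n_ab]
    return sum(w for w in weights.values() if w <= p_obs) / total


def test_hwe_hand_example_two_homozygote_classes():
    # counts (2,0,2): support {0,2,4} with probabilities 6/70, 48/70, 16/70
    assert hwe_exact_test(2, 0, 2) == pytest.approx(6 / 70, abs=1e-12)


def test_hwe_monomorphic_is_one():
    assert hwe_exact_test(7, 0, 0) == 1.0


def test_hwe_matches_enumeration_for_all_small_configurations():
    for n in range(1, 11):
        for n_aa in range(n + 1):
            for n_ab in range(n - n_aa + 1):
                n_bb = n - n_aa - n_ab
                expect = float(hwe_enumeration_oracle(n_aa, n_ab, n_bb))
                got = hwe_exact_test(n_aa, n_ab, n_bb)
                assert got == pytest.approx(expect, abs=1e-10), (n_aa, n_ab, n_bb)


def test_hwe_rejects_empty_input():
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------


def test_ld_r2_perfect_and_degenerate():
    assert ld_r2([0, 1, 2, 1], [0, 1, 2, 1]) == pytest.approx(1.0)
    assert math.isnan(ld_r2([0, 1, 2], [1, 1, 1]))


def test_ld_r2_ignores_missing_pairs():
    a = [0.0, 1.0, 2.0, np.nan, 2.0]
    b = [0.0, 1.0, 2.0, 2.0, np.nan]
    assert ld_r2(a, b) == pytest.approx(1.0)


def test_ld_r2_null_distribution(rng):
    """Independent markers show r^2 < 0.05 in at least 99% of replicates."""
    low = 0
    reps = 200
    for _ in range(reps):
        a = rng.binomial(2, 0.4, size=500).astype(float)
        b = rng.binomial(2, 0.4, size=500).astype(float)
        if ld_r2(a, b) < 0.05:
            low += 1
    assert low >= 0.99 * reps


def _duplicated_marker_table(rng, n=60):
    calls = []
    for _ in range(n):
        g = rng.integers(3)
        call = ["A/A", "A/G", "G/G"][g]
        hetmix = ["A/A", "A/G", "G/G"][rng.integers(3)]
        calls.append([call, call, hetmix])
    return table_from_rows([f"s{i}" for i in range(n)], ["m1", "m2", "m3"], calls)


def test_ld_prune_drops_exactly_one_of_a_duplicated_pair(rng):
    table = _duplicated_marker_table(rng)
    kept = ld_prune(table, ["m1", "m2", "m3"])
    assert "m3" in kept
    assert len(set(kept) & {"m1", "m2"}) == 1


def test_ld_prune_keeps_independent_markers_and_passes_audit(rng):
    n, m = 300, 30
    calls = [[["A/A", "A/G", "G/G"][rng.integers(3)] for _ in range(m)]
             for _ in range(n)]
    ids = [f"m{j}" for j in range(m)]
    table = table_from_rows([f"s{i}" for i in range(n)], ids, calls)
    cfg = SelectionConfig(ld_window=10, ld_step=2)
    kept = ld_prune(table, ids, cfg)
    assert len(kept) >= m - 2  # independent markers essentially all retained
    # audit: no retained pair within a window exceeds the threshold
    dos, _ = table.dosage_matrix(kept)
    for i in range(len(kept)):
        for j in range(i + 1, min(i + cfg.ld_window, len(kept))):
            r2 = ld_r2(dos[:, i], dos[:, j])
            assert math.isnan(r2) or r2 <= cfg.ld_r2_max


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------


def wc_theta_oracle(n1, p1, h1, n2, p2, h2):
    """Direct transcription of the two-population variance-components theta."""
    r = 2
    n_bar = (n1 + n2) / 2
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2
    return a / (a + b + c)


def _two_pop_table(rng, n1, n2, p1, p2):
    rows, labels = [], {}
    ids = []
    for k in range(n1):
        g = rng.binomial(1, p1) + rng.binomial(1, p1)
        rows.append([["A/A", "A/G", "G/G"][g]])
        ids.append(f"a{k}")
        labels[f"a{k}"] = "popA"
    for k in range(n2):
        g = rng.binomial(1, p2) + rng.binomial(1, p2)
        rows.append([["A/A", "A/G", "G/G"][g]])
        ids.append(f"b{k}")
        labels[f"b{k}"] = "popB"
    return table_from_rows(ids, ["m"], rows), labels


def test_fst_fixed_difference_is_one():
    table = table_from_rows(
        ["a1", "a2", "b1", "b2"], ["m"],
        [["A/A"], ["A/A"], ["G/G"], ["G/G"]],
    )
    labels = {"a1": "popA", "a2": "popA", "b1": "popB", "b2": "popB"}
    assert fst_locus(table, labels, "popA", "popB", "m") == pytest.approx(1.0)


def test_fst_near_zero_at_equal_frequencies(rng):
    table, labels = _two_pop_table(rng, 500, 500, 0.4, 0.4)
    theta = fst_locus(table, labels, "popA", "popB", "m")
    assert abs(theta) < 0.02


def test_fst_matches_direct_transcription(rng):
    """Implementation agrees with an independent formula transcription."""
    for _ in range(20):
        n1, n2 = int(rng.integers(5, 40)), int(rng.integers(5, 40))
        p1, p2 = rng.uniform(0.1, 0.9), rng.uniform(0.1, 0.9)
        table, labels = _two_pop_table(rng, n1, n2, p1, p2)
        col = table.marker_calls("m")
        obs = []
        for pop, size in (("popA", n1), ("popB", n2)):
            calls = [c for s, c in zip(table.sample_ids, col)
                     if labels[s] == pop and c != MISSING]
            dosage = [c.count("G") if c != "G/G" else 2 for c in calls]
            dosage = [2 if c == "G/G" else (1 if c == "A/G" else 0) for c in calls]
            het = [1 if c == "A/G" else 0 for c in calls]
            obs.append((len(calls), sum(dosage) / (2 * len(calls)),
                        sum(het) / len(calls)))
        theta = fst_locus(table, labels, "popA", "popB", "m")
        expect = wc_theta_oracle(*obs[0], *obs[1])
        if math.isnan(expect):
            assert math.isnan(theta)
        else:
            assert theta == pytest.approx(expect, abs=1e-12)


def test_fst_invariant_to_allele_label_swap(rng):
    table, labels = _two_pop_table(rng, 30, 30, 0.2, 0.7)
    swapped_calls = np.array(
        [[{"A/A": "G/G", "G/G": "A/A", "A/G": "A/G", MISSING: MISSING}[c]
          for c in row] for row in table.calls],
        dtype=object,
    )
    swapped = GenotypeTable(table.sample_ids, table.marker_ids, swapped_calls)
    t1 = fst_locus(table, labels, "popA", "popB", "m")
    t2 = fst_locus(swapped, labels, "popA", "popB", "m")
    assert t1 == pytest.approx(t2, abs=1e-12)


# ---------------------------------------------------------------------------
# Locus stats and panel selection
# ---------------------------------------------------------------------------


def test_locus_stats_hand_example():
    table = table_from_rows(["a", "b", "c"], ["m"], [["A/A"], ["A/G"], ["G/G"]])
    (st,) = compute_locus_stats(table)
    assert st.maf == pytest.approx(0.5)
    assert st.call_rate == 1.0
    assert st.counts[:3] == (1, 1, 1)


def test_locus_stats_all_missing_flagged():
    table = table_from_rows(["a", "b"], ["m"], [[MISSING], [MISSING]])
    (st,) = compute_locus_stats(table)
    assert st.call_rate == 0.0 and math.isnan(st.maf) and st.monomorphic


def test_maf_estimate_within_binomial_ci(rng):
    """36 simulated individuals at p=0.4: MAF inside the 99% binomial CI."""
    p = 0.4
    n = 36
    g = rng.binomial(1, p, (n, 2)).sum(axis=1)
    table = table_from_rows(
        [f"s{i}" for i in range(n)], ["m"],
        [[["A/A", "A/G", "G/G"][x]] for x in g],
    )
    maf = minor_allele_frequency(table.marker_calls("m"))
    se = math.sqrt(p * (1 - p) / (2 * n))
    assert abs(maf - p) < 2.58 * se + 1e-9


def _selection_fixture(rng):
    """60 samples x 12 markers: 5 fixed-difference, 5 good, 2 bad."""
    ids, rows, pops = [], [], {}
    markers = []
    for j in range(5):
        markers.append(MarkerInfo(f"diag{j}", "AUTOSOME", (j + 1) * 10**6,
                                  ("A", "G"), CAT_WOLF_JACKAL))
    for j in range(5):
        markers.append(MarkerInfo(f"good{j}", "AUTOSOME", (j + 6) * 10**6,
                                  ("A", "G"), CAT_HIGH_MAF))
    markers.append(MarkerInfo("lowmaf", "AUTOSOME", 11 * 10**6,
                              ("A", "G"), CAT_HIGH_MAF))
    markers.append(MarkerInfo("dead", "AUTOSOME", 12 * 10**6,
                              ("A", "G"), CAT_HIGH_MAF))
    for i in range(60):
        pop = "wolf" if i < 40 else "jackal"
        sid = f"s{i}"
        pops[sid] = pop
        row = []
        for j in range(5):  # fixed difference between wolf and jackal
            row.append("A/A" if pop == "wolf" else "G/G")
        for j in range(5):  # common variation, MAF ~ 0.5
            g = rng.binomial(1, 0.5) + rng.binomial(1, 0.5)
            row.append(["A/A", "A/G", "G/G"][g])
        g = rng.binomial(1, 0.03) + rng.binomial(1, 0.03)  # low MAF
        row.append(["A/A", "A/G", "G/G"][g])
        row.append(MISSING)  # dead marker
        ids.append(sid)
        rows.append(row)
    table = table_from_rows(ids, [m.marker_id for m in markers], rows)
    return table, markers, pops


def test_select_panel_recovers_planted_diagnostics(rng):
    table, markers, pops = _selection_fixture(rng)
    sel = select_panel(table, markers, SelectionConfig(),
                       population_labels=pops, rng=rng)
    assert sorted(sel.selected[CAT_WOLF_JACKAL]) == [f"diag{j}" for j in range(5)]
    assert set(sel.selected[CAT_HIGH_MAF]) == {f"good{j}" for j in range(5)}
    assert "Low MAF" in sel.rejected["lowmaf"]
    assert "No amplification" in sel.rejected["dead"]


def test_select_panel_counts_each_rejection_reason(rng):
    table, markers, pops = _selection_fixture(rng)
    flags = {"lowmaf": ["Readability"]}  # external wet-lab flag stacks up
    sel = select_panel(table, markers, SelectionConfig(),
                       population_labels=pops, external_flags=flags, rng=rng)
    att = sel.attrition.set_index("reason")
    assert att.loc["Readability", CAT_HIGH_MAF] == 1
    assert att.loc["No amplification", CAT_HIGH_MAF] == 1


def test_select_panel_empty_input():
    table = table_from_rows([], [], np.empty((0, 0)))
    sel = select_panel(table, [], SelectionConfig())
    assert all(len(v) == 0 for v in sel.selected.values())
    assert (sel.attrition.drop(columns="reason").to_numpy() == 0).all()


def test_select_panel_deterministic_under_seed(rng):
    table, markers, pops = _selection_fixture(rng)
    cfg = SelectionConfig(n_high_maf_subsample=3)
    s1 = select_panel(table, markers, cfg, population_labels=pops,
                      rng=np.random.default_rng(5))
    s2 = select_panel(table, markers, cfg, population_labels=pops,
                      rng=np.random.default_rng(5))
    assert s1.selected == s2.selected
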