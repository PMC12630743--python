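"""Replicate consensus, pass thresholds and reference error-rate accounting."""

import numpy as np
import pytest

from snpmon.genotype_io import MISSING, GenotypeTable, SampleRecord
from snpmon.replicate_qc import (
    QCConfig,
    amplification_success,
    check_negative_controls,
    duplicate_consensus,
    error_rate_vs_reference,
    overall_pass_pct,
    pass_filter,
)

from conftest import table_from_rows


def test_amplification_success_fraction():
    rows = [["A/A"] * 48 + [MISSING] * 48]
    table = table_from_rows(["s1"], [f"m{j}" for j in range(96)], rows)
    per_sample, per_marker = amplification_success(table)
    assert per_sample["s1"] == pytest.approx(0.5)
    assert per_marker.iloc[0] == 1.0 and per_marker.iloc[-1] == 0.0


def test_completely_failed_marker_has_zero_rate():
    table = table_from_rows(["a", "b"], ["ok", "dead"],
                            [["A/A", MISSING], ["A/G", MISSING]])
    _, per_marker = amplification_success(table)
    assert per_marker["dead"] == 0.0


@pytest.mark.parametrize("calls,expected_call,expected_mm", [
    (("A/A", "A/A"), "A/A", 0),
    (("A/A", "A/G"), MISSING, 1),
    (("A/A", MISSING), "A/A", 0),
    ((MISSING, MISSING), MISSING, 0),
])
def test_duplicate_consensus_rules(calls, expected_call, expected_mm):
    table = table_from_rows(["r1", "r2"], ["m"], [[calls[0]], [calls[1]]])
    samples = [SampleRecord("r1", "scat", "grp"), SampleRecord("r2", "scat", "grp")]
    consensus, mismatches = duplicate_consensus(table, samples)
    assert consensus.sample_ids == ["grp"]
    assert consensus.get("grp", "m") == expected_call
    assert mismatches["grp"] == expected_mm


def test_consensus_never_invents_and_is_order_invariant(rng):
    marker_ids = [f"m{j}" for j in range(20)]
    pool = ["A/A", "A/G", "G/G", MISSING]
    rows = [[pool[rng.integers(4)] for _ in marker_ids] for _ in range(3)]
    samples = [SampleRecord(f"r{i}", "scat", "g") for i in range(3)]
    t1 = table_from_rows(["r0", "r1", "r2"], marker_ids, rows)
    t2 = table_from_rows(["r2", "r0", "r1"], marker_ids,
                         [rows[2], rows[0], rows[1]])
    c1, m1 = duplicate_consensus(t1, samples)
    c2, m2 = duplicate_consensus(t2, samples)
    assert m1["g"] == m2["g"]
    for j, mid in enumerate(marker_ids):
        call = c1.get("g", mid)
        assert call == c2.get("g", mid)
        observed = {rows[i][j] for i in range(3)}
        assert call == MISSING or call in observed


def test_pass_filter_reproduces_overall_percentage():
    """Per-material pass counts 16/16, 166/188, 49/74, 2/4 give 83% overall."""
    assert overall_pass_pct([(16, 16), (166, 188), (49, 74), (2, 4)]) == 83


def test_pass_filter_by_material():
    samples = [
        SampleRecord("t1", "tissue"), SampleRecord("s1", "scat"),
        SampleRecord("s2", "scat"), SampleRecord("h1", "hair"),
    ]
    rates = {"t1": 0.99, "s1": 0.9, "s2": 0.5, "h1": 0.1}
    import pandas as pd
    passes, summary, overall = pass_filter(pd.Series(rates), samples, QCConfig())
    assert passes["t1"] and passes["s1"] and not passes["s2"] and not passes["h1"]
    by_mat = summary.set_index("material")
    assert by_mat.loc["tissue", "pct"] == 100
    assert by_mat.loc["scat", "n_pass"] == 1
    assert overall == 50


def test_all_empty_samples_fail():
    table = table_from_rows(["a", "b"], ["m1", "m2"],
                            [[MISSING, MISSING], [MISSING, MISSING]])
    per_sample, _ = amplification_success(table)
    samples = [SampleRecord("a", "scat"), SampleRecord("b", "scat")]
    _, _, overall = pass_filter(per_sample, samples, QCConfig())
    assert overall == 0


def test_negative_control_flagging():
    table = table_from_rows(["ntc", "s"], ["m1", "m2"],
                            [["A/A", MISSING], ["A/G", "G/G"]])
    samples = [SampleRecord("ntc", is_control="NEGATIVE"), SampleRecord("s")]
    assert check_negative_controls(table, samples) == ["ntc"]
    assert check_negative_controls(table, samples, QCConfig(ntc_max_calls=1)) == []


# ---------------------------------------------------------------------------
# Error rate vs reference
# ---------------------------------------------------------------------------


def _full_tables(rng, n_samples=15, n_markers=95):
    pool = ["A/A", "A/G", "G/G"]
    rows = [[pool[rng.integers(3)] for _ in range(n_markers)]
            for _ in range(n_samples)]
    ids = [f"s{i}" for i in range(n_samples)]
    mids = [f"m{j}" for j in range(n_markers)]
    return table_from_rows(ids, mids, rows), ids, mids, rows


def test_error_rate_comparison_count_and_identity(rng):
    """15 samples x 95 markers with a complete reference: 1425 comparisons."""
    panel, ids, mids, rows = _full_tables(rng)
    res = error_rate_vs_reference(panel, panel)
    assert res.n_comparisons == 1425
    assert res.n_mismatches == 0
    assert res.n_panel_missing == 0


def test_error_rate_planted_discordances(rng):
    panel, ids, mids, rows = _full_tables(rng, 5, 10)
    ref_rows = [list(r) for r in rows]
    rows2 = [list(r) for r in rows]
    rows2[0][0] = "A/G" if rows[0][0] != "A/G" else "A/A"  # het<->hom
    rows2[1][1] = {"A/A": "G/G", "G/G": "A/A", "A/G": "G/G"}[rows[1][1]]
    rows2[2][2] = MISSING  # dropout, not an error
    panel2 = table_from_rows(ids, mids, rows2)
    ref = table_from_rows(ids, mids, ref_rows)
    res = error_rate_vs_reference(panel2, ref)
    assert res.n_mismatches == 2
    assert res.n_panel_missing == 1
    assert res.n_comparisons == 5 * 10 - 1  # the missing locus is not compared
    assert res.per_marker_missing["m2"] == 1


def test_error_rate_requires_shared_markers():
    a = table_from_rows(["s"], ["m1"], [["A/A"]])
    b = table_from_rows(["s"], ["m2"], [["A/A"]])
    with pytest.raises(ValueError):
        error_rate_vs_reference(a, b)


def test_simulated_dropout_rate_recovered(rng):
    """Observed het->hom fraction matches the configured dropout rate."""
    from snpmon.synthetic_data import (
        ErrorModel, SamplePlan, SimConfig, corrupt_samples, make_markers,
    )
    d = 0.1
    cfg = SimConfig(
        error_models={"tissue": ErrorModel(0.0, d, 0.0)},
        seed=3,
    )
    markers = [m for m in make_markers(cfg) if m.chrom_class == "AUTOSOME"]
    n = 120  # 120 samples x 86 het loci = 10,320 het calls
    truth = table_from_rows(
        [f"i{k}" for k in range(n)],
        [m.marker_id for m in markers],
        [["A/G"] * len(markers) for _ in range(n)],
    )
    plan = [SamplePlan(f"i{k}", f"i{k}", "tissue", f"i{k}") for k in range(n)]
    obs, _, _ = corrupt_samples(truth, plan, markers, cfg, rng)
    hom = np.sum(obs.calls != "A/G")
    total = obs.calls.size
    se = np.sqrt(d * (1 - d) / total)
    assert abs(hom / total - d) < 3 * se
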