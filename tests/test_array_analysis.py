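"""Replicate aggregation, top-decile selection, enrichment z-test, log2 panels."""

import math

import numpy as np
import pytest

from chargescan import (
    PeptideIntensity,
    SpotRecord,
    aggregate,
    charge_binding_table,
    composition_ztest,
    enrichment_table,
    substitution_log2,
    top_fraction,
)


def spots_for(pid, values, excluded=()):
    return [
        SpotRecord(pid, i + 1, v, excluded=(i in excluded))
        for i, v in enumerate(values)
    ]


def test_aggregate_means_and_exclusions():
    spots = (
        spots_for("a", [10, 20, 30])
        + spots_for("b", [10, 20, 99], excluded={2})
        + spots_for("c", [1, 2, 3], excluded={0, 1, 2})
    )
    intens = {i.peptide_id: i for i in aggregate(spots)}
    assert "c" not in intens  # all replicates excluded -> dropped
    assert intens["a"].mean_raw == pytest.approx(20)
    assert intens["b"].mean_raw == pytest.approx(15) and intens["b"].n_replicates == 2
    assert intens["a"].normalized == pytest.approx(1.0)  # max-mean anchor
    assert intens["a"].decile == 10 and intens["b"].decile <= 9


def test_aggregate_rejects_bad_input():
    with pytest.raises(ValueError):
        aggregate([])
    with pytest.raises(ValueError):
        SpotRecord("a", 1, -5.0)


def test_normalization_idempotent():
    spots = spots_for("a", [10.0]) + spots_for("b", [40.0])
    once = {i.peptide_id: i.normalized for i in aggregate(spots)}
    again = {
        i.peptide_id: i.normalized
        for i in aggregate(
            [SpotRecord(pid, 1, v) for pid, v in once.items()]
        )
    }
    assert once == again


def _intens(values):
    top = max(values.values())
    return [
        PeptideIntensity(pid, 3, v, v / top, 1) for pid, v in values.items()
    ]


def test_top_fraction_counts_and_tie_inclusion():
    distinct = _intens({f"p{i}": float(i + 1) for i in range(100)})
    assert len(top_fraction(distinct, 0.10)) == 10
    # 9 distinct leaders, then a 3-way tie at the 10th-largest value
    values = {f"lead{i}": float(92 + i) for i in range(9)}
    values.update({"t1": 90.0, "t2": 90.0, "t3": 90.0})
    values.update({f"rest{i}": float(i + 1) for i in range(88)})
    top = top_fraction(_intens(values), 0.10)
    assert len(top) == 12
    two = _intens({"lo": 1.0, "hi": 2.0})
    assert [p.peptide_id for p in top_fraction(two, 0.5)] == ["hi"]


def test_top_fraction_small_input_warns_but_returns():
    single = _intens({"only": 5.0})
    assert len(top_fraction(single, 0.10)) == 1
    with pytest.raises(ValueError):
        top_fraction(single, 1.5)


def eq1_oracle(p_hat, p0, n):
    """Symbol-by-symbol z = (p_hat - p0)/sqrt(p0(1-p0)/n)."""
    return (p_hat - p0) / math.sqrt(p0 * (1 - p0) / n)


def test_ztest_examples_and_conventions():
    # top set with K proportion 0.2, background 0.1
    top = ["KA" * 5]                       # 10 residues, 5 K -> craft below
    top = ["KKAAAAAAAA"]                   # p_hat = 0.2
    bg = ["K" + "A" * 9] * 9               # 90 residues, 9 K -> p0 = 0.1
    r = composition_ztest(top, bg, "K", n_convention="combined")
    assert r.p_hat == pytest.approx(0.2) and r.p0 == pytest.approx(0.1)
    assert r.n == 100
    assert r.z == pytest.approx(eq1_oracle(0.2, 0.1, 100))
    assert r.z == pytest.approx(0.1 / math.sqrt(0.1 * 0.9 / 100))
    r_top = composition_ztest(top, bg, "K", n_convention="top_only")
    assert r_top.n == 10
    # identical composition -> z = 0
    r0 = composition_ztest(bg[:1], bg, "K")
    assert r0.z == pytest.approx(0.0)


def test_ztest_antisymmetric_around_fixed_background():
    bg = ["KAKAKAKAKA"] * 5  # p0 = 0.5
    up = composition_ztest(["KKKAKAKAKA"], bg, "K")
    down = composition_ztest(["AAKAKAKAKA"], bg, "K")
    assert up.z == pytest.approx(-down.z)


def test_ztest_matches_oracle_on_random_triples(rng):
    """Eq. 1 agrees with an independent symbol-by-symbol oracle, checked by
    reconstructing peptide sets whose proportions hit random (p_hat, p0)."""
    from chargescan.array_analysis import EnrichmentResult  # noqa: F401

    for _ in range(50):
        n_top, n_bg = int(rng.integers(20, 200)), int(rng.integers(50, 500))
        k_top = int(rng.integers(1, n_top))
        k_bg = int(rng.integers(1, n_bg))
        top = ["K" * k_top + "A" * (n_top - k_top)]
        bg = ["K" * k_bg + "A" * (n_bg - k_bg)]
        r = composition_ztest(top, bg, "K")
        expected = eq1_oracle(k_top / n_top, k_bg / n_bg, n_top + n_bg)
        assert r.z == pytest.approx(expected, abs=1e-12)


def test_ztest_rejects_zero_variance():
    with pytest.raises(ValueError):
        composition_ztest(["KA"], ["AA"], "K")
    with pytest.raises(ValueError):
        composition_ztest(["KA"], ["KK"], "K")


def test_enrichment_table_sorted_by_z():
    top = ["KRKRKRKRKR"]
    bg = ["KRDEAGSTVL"] * 10
    df = enrichment_table(top, bg)
    assert df.iloc[0]["unit"] == "basic"
    assert list(df["z"]) == sorted(df["z"], reverse=True)


def test_charge_binding_table_spearman():
    seqs = {"a": "KKKKKKKKKK", "b": "KKKKKAAAAA", "c": "AAAAAAAAAA"}
    intens = _intens({"a": 30.0, "b": 20.0, "c": 10.0})
    table, rho, p = charge_binding_table(intens, seqs)
    assert rho == pytest.approx(1.0)
    assert list(table["peptide_id"]) == ["a", "b", "c"]  # ranked by intensity
    # constant charge -> undefined, reported as None (never 0)
    _, rho_const, p_const = charge_binding_table(
        intens, {k: "AAAAAAAAAA" for k in seqs}
    )
    assert rho_const is None and p_const is None


def test_charge_binding_drops_missing_sequences():
    intens = _intens({"a": 3.0, "b": 2.0, "ghost": 1.0})
    table, _, _ = charge_binding_table(intens, {"a": "KKKK", "b": "AAAA"})
    assert set(table["peptide_id"]) == {"a", "b"}


def test_substitution_log2_reference_and_floor():
    panel = {(1, "L", "A"): 64.0, (1, "L", "G"): 128.0, (2, "P", "A"): 0.0,
             (2, "P", "G"): 16.0}
    entries = {(e.position, e.mutant): e for e in substitution_log2(panel, 64.0)}
    assert entries[(1, "A")].log2_ratio == pytest.approx(0.0)
    assert entries[(1, "G")].log2_ratio == pytest.approx(1.0)
    # zero floored at half the minimum positive value (8.0)
    zero = entries[(2, "A")].log2_ratio
    assert math.isfinite(zero) and zero == pytest.approx(math.log2(8.0 / 64.0))
    with pytest.raises(ValueError):
        substitution_log2(panel, 0.0)
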