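"""IWD statistic, shuffle nulls, Z-scores and batch surveys."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chargescan import (
    POSITIVE,
    ProteinSequence,
    ResiduePositions,
    batch_iwd,
    extract_positions,
    iwd,
    iwd_zscore,
    null_distribution,
    percentile_rank,
    resolve_class,
)
from chargescan.clustering import derive_seed


def brute_force_iwd(positions):
    """Independent double-loop oracle for the mean inverse pair distance."""
    pos = sorted(positions)
    pairs = list(itertools.combinations(pos, 2))
    return sum(1.0 / (b - a) for a, b in pairs) / len(pairs)


@pytest.mark.parametrize(
    "positions,expected",
    [({1, 2}, 1.0), ({1, 11}, 0.1), ({1, 2, 3}, (1 + 0.5 + 1) / 3)],
)
def test_iwd_examples(positions, expected):
    assert iwd(positions) == pytest.approx(expected)


@given(st.sets(st.integers(min_value=1, max_value=400), min_size=2, max_size=6))
def test_iwd_matches_brute_force_oracle(positions):
    assert iwd(positions) == pytest.approx(brute_force_iwd(positions), abs=1e-12)


@given(
    st.sets(st.integers(min_value=1, max_value=200), min_size=2, max_size=8),
    st.integers(min_value=-50, max_value=1000),
)
def test_iwd_translation_invariance(positions, shift):
    shifted = {p + shift for p in positions}
    assert iwd(positions) == pytest.approx(iwd(shifted), abs=1e-12)


@pytest.mark.parametrize(
    "before,after",
    [
        # one residue moved strictly closer to all the others
        ({1, 50, 60, 70}, {30, 50, 60, 70}),
        ({1, 100}, {50, 100}),
        ({5, 40, 41, 42, 43}, {20, 40, 41, 42, 43}),
    ],
)
def test_iwd_monotone_under_contraction(before, after):
    assert iwd(after) >= iwd(before)


def test_iwd_insufficient_residues():
    with pytest.raises(ValueError, match="insufficient residues"):
        iwd({5})


def test_extract_positions():
    seq = ProteinSequence("s", "KAKD")
    assert extract_positions(seq, POSITIVE).positions == (1, 3)
    assert extract_positions(ProteinSequence("s", "AAAA"), POSITIVE).positions == ()
    assert extract_positions(ProteinSequence("s", "RKRK"), POSITIVE).positions == (1, 2, 3, 4)


def test_residue_positions_must_increase():
    with pytest.raises(ValueError):
        ResiduePositions((3, 3))


def test_null_rejects_degenerate_classes():
    with pytest.raises(ValueError):
        null_distribution(ProteinSequence("s", "KKKK"), POSITIVE, 100, seed=0)
    with pytest.raises(ValueError):
        null_distribution(ProteinSequence("s", "KAAA"), POSITIVE, 100, seed=0)


def test_null_deterministic_under_seed(rng):
    letters = list("A" * 90 + "K" * 10)
    rng.shuffle(letters)
    seq = ProteinSequence("s", "".join(letters))
    a = null_distribution(seq, POSITIVE, n_shuffles=300, seed=11)
    b = null_distribution(seq, POSITIVE, n_shuffles=300, seed=11)
    assert a.mean == b.mean and a.sd == b.sd


def test_null_depends_only_on_composition_and_length(rng):
    letters = list("A" * 90 + "K" * 10)
    rng.shuffle(letters)
    seq = ProteinSequence("s", "".join(letters))
    perm = ProteinSequence("s", "".join(rng.permutation(letters)))
    a = null_distribution(seq, POSITIVE, n_shuffles=200, seed=3)
    b = null_distribution(perm, POSITIVE, n_shuffles=200, seed=3)
    assert a.mean == b.mean and a.sd == b.sd


def test_null_mean_matches_position_sampling_oracle(rng):
    """Full-sequence shuffling is equivalent to sampling class positions
    uniformly without replacement; the two null means must agree within
    Monte-Carlo error (3 standard errors)."""
    letters = list("A" * 90 + "K" * 10)
    rng.shuffle(letters)
    seq = ProteinSequence("s", "".join(letters))
    null = null_distribution(seq, POSITIVE, n_shuffles=2000, seed=5)
    draws = []
    for _ in range(2000):
        pos = np.sort(rng.choice(100, size=10, replace=False) + 1)
        diffs = pos[None, :] - pos[:, None]
        iu = np.triu_indices(10, k=1)
        draws.append(np.mean(1.0 / diffs[iu]))
    oracle_mean = np.mean(draws)
    se = np.std(draws, ddof=1) / np.sqrt(len(draws))
    combined_se = np.sqrt(se**2 + (null.sd / np.sqrt(2000)) ** 2)
    assert abs(null.mean - oracle_mean) < 3 * combined_se


def test_dense_run_is_significant_across_seeds():
    seq = ProteinSequence("s", "K" * 10 + "A" * 190)
    results = [
        iwd_zscore(seq, POSITIVE, n_shuffles=300, seed=s) for s in range(25)
    ]
    assert all(r.z > 1.96 and r.significant for r in results)


def test_batch_skips_degenerate_records_and_derives_stable_seeds():
    good = ProteinSequence("good", "KAKA" * 30)
    dup = ProteinSequence("dup", "KAKA" * 30)
    bad = ProteinSequence("bad", "A" * 50 + "K")
    results = batch_iwd([good, bad, dup], POSITIVE, n_shuffles=400, seed=9)
    assert [r.seq_id for r in results] == ["good", "dup"]
    assert results[0].iwd_obs == results[1].iwd_obs
    # same content, different ids: z agree within Monte-Carlo error
    assert results[0].z == pytest.approx(results[1].z, abs=0.6)
    # adding records never perturbs an existing record's seed
    assert results[0].seed == derive_seed(9, "good")
    assert derive_seed(9, "good") != derive_seed(9, "dup")


def test_batch_rejects_empty_input():
    with pytest.raises(ValueError):
        batch_iwd([], POSITIVE, 100, 0)


def test_percentile_rank_strict_comparison():
    def res(seq_id, z):
        return type("R", (), {"seq_id": seq_id, "z": z})()

    results = [res(f"r{i}", z) for i, z in enumerate([5.0, 2.0, 1.0])]
    assert percentile_rank("r0", results) == 0.0
    assert percentile_rank("r1", results) == pytest.approx(100 / 3)
    ties = [res(f"t{i}", 1.5) for i in range(4)]
    assert percentile_rank("t2", ties) == 0.0
    with pytest.raises(ValueError):
        percentile_rank("missing", results)


def test_resolve_class_custom():
    cls = resolve_class("custom:hy")
    assert cls.members == frozenset("HY")
    with pytest.raises(ValueError):
        resolve_class("nope")
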