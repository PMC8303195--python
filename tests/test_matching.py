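"""Distributed silo matching: padding, partial scores, pooling, rotation."""

from fractions import Fraction

import numpy as np
import pytest

from irisilo import (
    MatchRejectedError,
    PartialScore,
    PartialTemplate,
    RotationGrid,
    Silo,
    Template,
    aggregate_angle,
    build_padded_probe,
    distributed_match,
    divide_block,
    divide_r_dispersion,
    divide_z_dispersion,
    hamming_distance,
    modified_from_plain,
    partial_compare,
)
from conftest import random_template


def shifted(template, shift):
    """Whole-template circular column rotation used as oracle: position c of
    the rotated probe holds the probe bit at column (c + shift) mod q2."""
    return Template(
        np.roll(template.phase, -shift, axis=1),
        np.roll(template.mask, -shift, axis=1),
    )


class TestPaddedProbe:
    def test_no_rotation_means_no_padding(self, rng):
        t = random_template(rng)
        pos = [[0, 5], [3, 17]]
        padded = build_padded_probe(t, pos, RotationGrid((0,)))
        assert sorted(map(tuple, padded.positions.tolist())) == sorted(
            map(tuple, pos)
        )

    def test_single_position_padding_window(self, rng):
        t = random_template(rng)
        padded = build_padded_probe(t, [[0, 5]], RotationGrid.symmetric(2))
        assert set(map(tuple, padded.positions.tolist())) == {
            (0, 3), (0, 4), (0, 5), (0, 6), (0, 7)
        }

    def test_wrap_around_window(self, rng):
        t = random_template(rng)
        padded = build_padded_probe(t, [[0, 0]], RotationGrid.symmetric(1))
        assert set(map(tuple, padded.positions.tolist())) == {
            (0, 127), (0, 0), (0, 1)
        }

    def test_empty_position_set_rejected(self, rng):
        with pytest.raises(Exception):
            build_padded_probe(random_template(rng), [], RotationGrid((0,)))


class TestPartialCompare:
    def test_identity_probe(self, rng):
        t = random_template(rng)
        ref = PartialTemplate.from_template(t, [[r, c] for r in range(2) for c in range(4)])
        padded = build_padded_probe(t, ref.positions, RotationGrid((0,)))
        score = partial_compare(padded, ref, 0)
        assert score.mismatches == 0 and score.valid == len(ref)

    def test_hand_counted_disagreements(self):
        a = Template([[0, 1, 0, 1], [0, 0, 1, 1]])
        b = Template([[0, 1, 1, 1], [1, 0, 1, 1]])  # differs at (0,2) and (1,0)
        ref = PartialTemplate.from_template(
            b, [[r, c] for r in range(2) for c in range(4)]
        )
        padded = build_padded_probe(a, ref.positions, RotationGrid((0,)))
        score = partial_compare(padded, ref, 0)
        assert score.mismatches == 2 and score.valid == 8
        assert score.value == 0.25

    def test_fully_occluded_probe_is_undefined(self, rng):
        t = random_template(rng, (2, 4))
        blind = Template(t.phase, np.zeros_like(t.mask))
        ref = PartialTemplate.from_template(t, [[0, 0], [1, 3]])
        padded = build_padded_probe(blind, ref.positions, RotationGrid((0,)))
        score = partial_compare(padded, ref, 0)
        assert score.valid == 0 and not score.defined


class TestAggregation:
    def test_single_silo_degenerate(self):
        pooled = aggregate_angle([PartialScore(3, 10)])
        assert pooled.value == 0.3

    def test_uniform_weights_are_plain_mean(self):
        pooled = aggregate_angle([PartialScore(1, 10), PartialScore(3, 10)])
        assert pooled.value == pytest.approx(0.2)

    def test_all_undefined_raises(self):
        with pytest.raises(Exception):
            aggregate_angle([PartialScore(0, 0), PartialScore(0, 0)])

    def test_distributed_equals_monolithic_exactly(self, rng):
        """Pooled silo counts must equal the whole-template masked distance
        as exact rationals, for every scheme and shift (the central theorem
        of the protocol)."""
        grid = RotationGrid.symmetric(3)
        for i in range(60):
            probe = random_template(rng, (8, 32), mask_p=0.3)
            reference = random_template(rng, (8, 32), mask_p=0.3)
            scheme = i % 3
            if scheme == 0:
                partials = divide_block(reference, (2, 2))
            elif scheme == 1:
                partials = divide_r_dispersion(reference, 4, i)
            else:
                partials = divide_z_dispersion(reference, 4, i)
            shift = int(rng.integers(-3, 4))
            scores = [
                Silo(p).compare(build_padded_probe(probe, p.positions, grid), shift)
                for p in partials
            ]
            pooled = aggregate_angle(scores)
            whole = hamming_distance(shifted(probe, shift), reference)
            assert pooled.as_fraction == Fraction(whole.mismatches, whole.compared_bits)


class TestDistributedMatch:
    def test_self_match_is_zero_at_shift_zero(self, rng):
        t = random_template(rng)
        partials = divide_block(t, (1, 4))
        result = distributed_match(t, partials, RotationGrid.symmetric(4))
        assert result.score == 0.0 and result.best_shift == 0

    def test_zero_only_grid_equals_whole_template_distance(self, rng):
        probe = random_template(rng, mask_p=0.2)
        reference = random_template(rng, mask_p=0.2)
        partials = divide_r_dispersion(reference, 8, 0)
        result = distributed_match(probe, partials, RotationGrid((0,)))
        assert result.score == hamming_distance(probe, reference).value

    def test_rotated_probe_recovered_at_matching_shift(self, rng):
        reference = random_template(rng)
        probe = shifted(reference, -3)  # probe rotated; matching shift +3
        partials = divide_block(reference, (1, 4))
        result = distributed_match(probe, partials, RotationGrid.symmetric(4))
        assert result.score == 0.0 and result.best_shift == 3

    def test_mhd_metric_applies_bridge_to_pooled_counts(self, rng):
        probe = random_template(rng, mask_p=0.4)
        reference = random_template(rng, mask_p=0.4)
        partials = divide_block(reference, (2, 2))
        grid = RotationGrid((0,))
        plain = distributed_match(probe, reference_partials=partials, grid=grid)
        modified = distributed_match(probe, partials, grid, metric="mhd")
        whole = hamming_distance(probe, reference)
        assert modified.score == pytest.approx(
            modified_from_plain(plain.score, whole.compared_bits, whole.total_bits),
            abs=1e-12,
        )

    def test_score_is_minimum_over_angles(self, rng):
        probe = random_template(rng)
        reference = random_template(rng)
        partials = divide_block(reference, (1, 8))
        grid = RotationGrid.symmetric(5)
        result = distributed_match(probe, partials, grid)
        per_angle = [
            distributed_match(probe, partials, RotationGrid((s,))).score
            for s in grid.shifts
        ]
        assert result.score == min(per_angle)

    def test_ties_prefer_small_then_negative_shift(self, rng):
        # constant template: every shift scores 0; tie must resolve to 0
        t = Template(np.zeros((4, 8), dtype=np.uint8))
        partials = divide_block(t, (1, 2))
        result = distributed_match(t, partials, RotationGrid.symmetric(2))
        assert result.best_shift == 0
        result = distributed_match(t, partials, RotationGrid((2, -2)))
        assert result.best_shift == -2

    def test_blind_probe_rejected(self, rng):
        reference = random_template(rng, (4, 8))
        blind = Template(reference.phase, np.zeros(reference.shape, dtype=np.uint8))
        partials = divide_block(reference, (1, 2))
        with pytest.raises(MatchRejectedError):
            distributed_match(blind, partials, RotationGrid.symmetric(1))

    def test_silo_keeps_reference_bits_private(self, rng):
        silo = Silo(PartialTemplate.from_template(random_template(rng), [[0, 0]]))
        with pytest.raises(AttributeError):
            silo.reference
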