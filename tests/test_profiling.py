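"""Z-normalization, composite load scores and tertile block assignment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from storyload import (
    DegenerateFeatureError,
    FeatureVector,
    ValidationError,
    assign_blocks,
    composite_scores,
    profile_features,
    zscore_features,
)


def _vector(i, sc, wc, num, ius):
    return FeatureVector(
        stimulus_id=f"s{i}",
        sentence_count=sc,
        word_count=wc,
        avg_sentence_length=wc / sc,
        complex_ratio=num / sc,
        estimated_ius=ius,
    )


def _sort_and_slice_oracle(values, labels=("Low", "Medium", "High")):
    """Independent tertile oracle: sort, chunk into near-equal thirds."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    out = [None] * len(values)
    for label, chunk in zip(labels, np.array_split(order, len(labels))):
        for i in chunk:
            out[i] = label
    return out


class TestZScores:
    def test_population_sigma(self, table1_vectors):
        ztable, mu, sigma = zscore_features(table1_vectors)
        counts = np.array([v.sentence_count for v in table1_vectors], dtype=float)
        assert mu["sentence_count"] == pytest.approx(counts.mean())
        assert sigma["sentence_count"] == pytest.approx(counts.std(ddof=0))
        # Airport is first; its sentence-count z from the printed column
        assert ztable["z_sentence_count"].iloc[0] == pytest.approx(
            (14 - counts.mean()) / counts.std(ddof=0)
        )
        assert ztable["z_sentence_count"].iloc[0] == pytest.approx(0.3015, abs=5e-4)

    def test_each_column_standardized(self, table1_vectors):
        ztable, _, _ = zscore_features(table1_vectors)
        for col in ztable.columns:
            if not col.startswith("z_"):
                continue
            z = ztable[col].to_numpy()
            assert abs(z.mean()) < 1e-9
            assert abs(z.var() - 1) < 1e-9

    def test_constant_column_raises_naming_it(self):
        vecs = [_vector(i, 10, 100 + i, i % 3, 5 + i) for i in range(3)]
        with pytest.raises(DegenerateFeatureError, match="sentence_count"):
            zscore_features(vecs)

    def test_location_invariance_of_z(self):
        vecs = [_vector(i, 10 + i, 100 + 7 * i, i, 5 + 2 * i) for i in range(5)]
        shifted = [
            _vector(i, 10 + i, 100 + 7 * i, i, 5 + 2 * i + 100) for i in range(5)
        ]
        z1, _, _ = zscore_features(vecs)
        z2, _, _ = zscore_features(shifted)
        assert np.allclose(z1["z_estimated_ius"], z2["z_estimated_ius"])


class TestComposites:
    def test_mean_of_four_z_columns(self, table1_vectors):
        ztable, _, _ = zscore_features(table1_vectors)
        comp = composite_scores(ztable)
        manual = ztable[[c for c in ztable.columns if c.startswith("z_")]].sum(axis=1) / 4
        assert np.allclose(comp, manual)
        assert abs(comp.mean()) < 1e-9

    def test_missing_z_column_raises(self):
        with pytest.raises(ValidationError, match="z_estimated_ius"):
            composite_scores(pd.DataFrame({"z_sentence_count": [0.0, 1.0]}))

    def test_all_zero_rows_give_zero_composite(self):
        z = pd.DataFrame(
            {
                c: [0.0, 0.0]
                for c in (
                    "z_sentence_count",
                    "z_avg_sentence_length",
                    "z_complex_ratio",
                    "z_estimated_ius",
                )
            }
        )
        assert (composite_scores(z) == 0).all()

    def test_sample_sigma_would_miss_published_composites(self, table1_vectors):
        """The σ-convention check: only population σ reproduces 0.698."""
        cols = {
            "sentence_count": [v.sentence_count for v in table1_vectors],
            "avg_sentence_length": [v.avg_sentence_length for v in table1_vectors],
            "complex_ratio": [v.complex_ratio for v in table1_vectors],
            "estimated_ius": [v.estimated_ius for v in table1_vectors],
        }

        def composite_airport(ddof):
            total = 0.0
            for x in cols.values():
                x = np.asarray(x, dtype=float)
                total += (x[0] - x.mean()) / x.std(ddof=ddof)
            return total / 4

        assert abs(composite_airport(0) - 0.698) < 0.005
        assert abs(composite_airport(1) - 0.698) > 0.02


class TestBlocks:
    def test_three_values(self):
        assert assign_blocks([-1.0, 0.0, 1.0]) == ["Low", "Medium", "High"]

    def test_unsorted_input_keeps_positions(self):
        assert assign_blocks([1.0, -1.0, 0.0]) == ["High", "Low", "Medium"]

    @pytest.mark.parametrize("n", list(range(3, 31)))
    def test_agrees_with_sort_and_slice_oracle(self, n):
        rng = np.random.default_rng(n)
        values = rng.permutation(rng.uniform(-2, 2, size=n))  # distinct w.p. 1
        assert assign_blocks(values) == _sort_and_slice_oracle(values)

    def test_equal_sizes_when_divisible_by_three(self):
        rng = np.random.default_rng(0)
        blocks = assign_blocks(rng.normal(size=12))
        assert sorted(blocks.count(b) for b in ("Low", "Medium", "High")) == [4, 4, 4]

    def test_boundary_tie_warns_and_uses_input_order(self):
        with pytest.warns(UserWarning, match="tied"):
            blocks = assign_blocks([0.5, 0.5, 0.5, 1.0, 2.0, 3.0])
        assert blocks == ["Low", "Low", "Medium", "Medium", "High", "High"]

    def test_too_few_or_constant_raises(self):
        with pytest.raises(ValidationError):
            assign_blocks([1.0, 2.0])
        with pytest.raises(ValidationError, match="equal"):
            assign_blocks([1.0, 1.0, 1.0])


class TestProfileFeatures:
    def test_study_profile_matches_published_table(self, study_profile, fixtures):
        table = study_profile.table
        printed = fixtures.table1_features
        assert list(table["id"]) == list(printed["id"])
        assert np.max(np.abs(table["composite"] - printed["composite"])) < 0.005
        assert list(table["block"]) == list(printed["printed_block"])

    def test_permutation_invariance(self, table1_vectors):
        base = profile_features(table1_vectors).table.set_index("id")
        rng = np.random.default_rng(3)
        shuffled = [table1_vectors[i] for i in rng.permutation(len(table1_vectors))]
        perm = profile_features(shuffled).table.set_index("id")
        for sid in base.index:
            assert perm.loc[sid, "composite"] == pytest.approx(
                base.loc[sid, "composite"], abs=1e-12
            )
            assert perm.loc[sid, "block"] == base.loc[sid, "block"]

    def test_identical_stimuli_raise_degenerate(self):
        vecs = [_vector(i, 10, 100, 3, 8) for i in range(3)]
        with pytest.raises(DegenerateFeatureError):
            profile_features(vecs)

    def test_json_round_trip(self, study_profile, tmp_path):
        from storyload import ProfileTable

        path = tmp_path / "profile.json"
        study_profile.to_json(path)
        loaded = ProfileTable.from_json(path)
        assert np.allclose(loaded.table["composite"], study_profile.table["composite"])
        assert loaded.mu == study_profile.mu
        assert loaded.config is None or loaded.config == study_profile.config


@settings(max_examples=60, deadline=None)
@given(
    st.lists(
        st.integers(min_value=-50_000, max_value=50_000),
        min_size=2,
        max_size=20,
        unique=True,
    ).map(lambda xs: [x / 1000 for x in xs])
)
def test_zscore_identity_property(values):
    """Any non-constant column standardizes to mean 0, variance 1."""
    vecs = [
        _vector(i, 10 + i, int(1000 + 10 * i), i % 5, 5 + i) for i in range(len(values))
    ]
    # overwrite one feature with the hypothesis values via avg length column
    vecs = [
        FeatureVector(
            stimulus_id=v.stimulus_id,
            sentence_count=v.sentence_count,
            word_count=v.word_count,
            avg_sentence_length=float(x),
            complex_ratio=v.complex_ratio,
            estimated_ius=v.estimated_ius,
        )
        for v, x in zip(vecs, values)
    ]
    ztable, _, _ = zscore_features(vecs)
    z = ztable["z_avg_sentence_length"].to_numpy()
    assert abs(z.mean()) < 1e-9
    assert abs(z.var() - 1) < 1e-7
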