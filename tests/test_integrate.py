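"""Union feature spaces, zero-padded alignment, clinical encoding, and
cross-modality concatenation."""

import numpy as np
import pandas as pd
import pytest

from omisurv.integrate import (
    concat_modalities,
    encode_clinical,
    pad_and_align,
    union_features,
)
from omisurv.matrix import InvalidInputError

from conftest import make_matrix


class TestUnionFeatures:
    def test_basic_union(self):
        a = make_matrix([[1, 2]], feature_ids=["g1", "g2"])
        b = make_matrix([[3, 4]], feature_ids=["g2", "g3"])
        space = union_features([a, b])
        assert space.feature_ids == ["g1", "g2", "g3"]

    def test_identical_lists_returned_unchanged(self):
        # deliberately non-sorted shared ordering must be preserved
        ids = ["g9", "g1", "g5"]
        mats = [make_matrix([[1, 2, 3]], feature_ids=ids) for _ in range(3)]
        assert union_features(mats).feature_ids == ids

    def test_mixed_modalities_rejected(self):
        a = make_matrix([[1]], modality="protein")
        b = make_matrix([[1]], modality="mirna")
        with pytest.raises(InvalidInputError):
            union_features([a, b])

    def test_matches_brute_force_set_union(self, rng):
        pool = [f"g{i}" for i in range(40)]
        mats, id_sets = [], []
        for _ in range(5):
            ids = sorted(rng.choice(pool, size=12, replace=False))
            mats.append(make_matrix(rng.normal(size=(3, 12)), feature_ids=ids))
            id_sets.append(set(ids))
        space = union_features(mats)
        assert space.feature_ids == sorted(set().union(*id_sets))

    def test_source_cohorts_tracked(self):
        a = make_matrix([[1, 2]], feature_ids=["g1", "g2"])
        b = make_matrix([[3]], feature_ids=["g2"])
        space = union_features([a, b], cohort_names=["A", "B"])
        assert space.source_cohorts["g2"] == {"A", "B"}
        assert space.source_cohorts["g1"] == {"A"}


class TestPadAndAlign:
    def test_absent_feature_zero_filled_and_masked(self):
        m = make_matrix([[1.0, 2.0]], feature_ids=["g1", "g2"])
        space = union_features(
            [m, make_matrix([[5.0]], feature_ids=["g3"])]
        )
        out = pad_and_align(m, space)
        j = out.feature_ids.index("g3")
        assert out.values[0, j] == 0.0 and out.padding_mask[0, j]

    def test_identity_when_already_spanning(self):
        m = make_matrix([[1.0, 2.0]], feature_ids=["g1", "g2"])
        out = pad_and_align(m, union_features([m]))
        np.testing.assert_array_equal(out.values, m.values)
        assert not out.padding_mask.any()

    def test_orphan_feature_named_in_error(self):
        m = make_matrix([[1.0]], feature_ids=["gX"])
        space = union_features([make_matrix([[1.0]], feature_ids=["g1"])])
        with pytest.raises(InvalidInputError, match="gX"):
            pad_and_align(m, space)

    def test_round_trip_recovers_original(self, rng):
        ids = [f"g{i}" for i in range(6)]
        m = make_matrix(rng.normal(size=(4, 3)), feature_ids=ids[::2])
        wide = make_matrix(rng.normal(size=(2, 6)), feature_ids=ids)
        out = pad_and_align(m, union_features([m, wide]))
        keep = [out.feature_ids.index(f) for f in m.feature_ids]
        np.testing.assert_array_equal(out.values[:, keep], m.values)
        assert not out.padding_mask[:, keep].any()
        assert out.padding_mask.sum() == 4 * 3  # everything else padded


def clinical_table(n=8, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age": rng.uniform(40, 80, n),
            "gender": rng.choice(["male", "female"], n),
            "race": rng.choice(["white", "black"], n),
            "stage": rng.choice(["I", "II", "III"], n),
        },
        index=[f"s{i}" for i in range(n)],
    )


class TestEncodeClinical:
    def test_stage_columns_absent_when_excluded(self):
        block, enc = encode_clinical(clinical_table(), include_stage=False)
        assert not any(f.startswith("stage=") for f in block.feature_ids)
        assert enc.include_stage is False

    def test_age_standardized_on_fit_subset(self):
        table = clinical_table(10)
        fit_ids = [f"s{i}" for i in range(6)]
        block, _ = encode_clinical(table, fit_on=fit_ids)
        j = block.feature_ids.index("age")
        fit_rows = [block.sample_ids.index(s) for s in fit_ids]
        assert abs(block.values[fit_rows, j].mean()) < 1e-9
        assert abs(block.values[fit_rows, j].std() - 1.0) < 1e-9

    def test_unseen_category_transforms_to_zero_code(self):
        table = clinical_table(6)
        _, enc = encode_clinical(table)
        new = clinical_table(2, seed=9)
        new.loc[:, "race"] = "unknown-race"
        out = enc.transform(new)
        race_cols = [j for j, f in enumerate(out.feature_ids) if f.startswith("race=")]
        assert (out.values[:, race_cols] == 0).all()

    def test_missing_column_schema_error(self):
        with pytest.raises(InvalidInputError, match="stage"):
            encode_clinical(clinical_table().drop(columns="stage"))

    def test_one_hot_is_invertible(self):
        table = clinical_table(12)
        block, enc = encode_clinical(table)
        for var, cats in enc.categories.items():
            cols = [block.feature_ids.index(f"{var}={c}") for c in cats]
            onehot = block.values[:, cols]
            assert (onehot.sum(axis=1) == 1).all()
            decoded = [cats[k] for k in onehot.argmax(axis=1)]
            assert decoded == list(table[var])


class TestConcatModalities:
    def blocks(self, rng, widths=(3, 5, 2)):
        mods = ["gene_expression", "dna_methylation", "protein"]
        return [
            make_matrix(rng.normal(size=(4, w)), modality=mod)
            for mod, w in zip(mods, widths)
        ]

    def test_total_width_is_sum_of_block_widths(self, rng):
        im = concat_modalities(self.blocks(rng))
        assert im.width == 10
        assert im.block_offsets["dna_methylation"] == (3, 5)

    def test_block_order_canonical_regardless_of_input_order(self, rng):
        blocks = self.blocks(rng)
        a = concat_modalities(blocks)
        b = concat_modalities(blocks[::-1])
        np.testing.assert_array_equal(a.values, b.values)
        assert a.block_offsets == b.block_offsets

    def test_outer_join_zero_pads_missing_blocks(self, rng):
        expr = make_matrix(rng.normal(size=(2, 3)), modality="gene_expression")
        prot = make_matrix(rng.normal(size=(1, 2)), modality="protein")
        prot.sample_ids = ["s9"]  # only in the protein block
        im = concat_modalities([expr, prot])
        assert im.sample_ids == ["s0", "s1", "s9"]
        row = im.sample_ids.index("s9")
        sl = im.block_slice("gene_expression")
        assert (im.values[row, sl] == 0).all() and im.padding_mask[row, sl].all()

    def test_duplicate_modality_rejected(self, rng):
        b = self.blocks(rng)
        with pytest.raises(InvalidInputError):
            concat_modalities([b[0], b[0]])

    def test_masked_entries_are_exactly_zero_and_zeros_are_masked(self, rng):
        expr = make_matrix(rng.normal(size=(2, 3)), modality="gene_expression")
        prot = make_matrix(rng.normal(size=(1, 2)), modality="protein")
        prot.sample_ids = ["s9"]
        im = concat_modalities([expr, prot])
        assert (im.values[im.padding_mask] == 0).all()
        # no silent zeros: introduced zeros only where masked (generated
        # values are continuous, so exact zeros occur only by padding)
        assert ((im.values == 0) == im.padding_mask).all()

    def test_zero_blocks_equals_integrating_without_block(self, rng):
        blocks = self.blocks(rng)
        full = concat_modalities(blocks)
        ablated = full.zero_blocks(["protein"])
        without = concat_modalities(blocks[:2])
        sl = full.block_slice("protein")
        assert (ablated.values[:, sl] == 0).all()
        assert ablated.padding_mask[:, sl].all()
        np.testing.assert_array_equal(
            np.delete(ablated.values, np.r_[sl], axis=1), without.values
        )
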