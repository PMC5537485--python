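"""Z/P arithmetic, table normalization, harmonization and file round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import priorscan as ps
from priorscan.sumstats import SumStatError

from conftest import make_table


class TestZPArithmetic:
    @pytest.mark.parametrize("p,direction,expected", [
        (1.0, +1, 0.0),
        (0.05, -1, -1.959964),
        # a printed effect/se ratio of -6.3508 corresponds to P = 2.14e-10
        (2.14e-10, -1, -6.3509),
    ])
    def test_z_from_p(self, p, direction, expected):
        assert ps.z_from_p_and_direction(p, direction) == pytest.approx(
            expected, abs=1e-4)

    @pytest.mark.parametrize("z,expected,rel", [
        (0.0, 1.0, 1e-12),
        (-0.1575 / 0.0248, 2.14e-10, 5e-3),   # smoking-effect ratio
        (-0.0196 / 0.0068, 0.0039, 5e-2),     # schizophrenia-effect ratio
    ])
    def test_p_from_z(self, z, expected, rel):
        assert ps.p_from_z(z) == pytest.approx(expected, rel=rel)

    @pytest.mark.parametrize("z,n,expected", [
        (0.0, 10_000, 0.0),
        (2.0, 400, 0.1),
        (-6.3508, 250_000, -0.0127016),
    ])
    def test_standardized_effect(self, z, n, expected):
        assert ps.standardized_effect(z, n) == pytest.approx(expected, abs=1e-7)

    def test_invalid_inputs(self):
        with pytest.raises(SumStatError):
            ps.z_from_p_and_direction(0.0, 1)
        with pytest.raises(SumStatError):
            ps.z_from_p_and_direction(1.5, 1)
        with pytest.raises(SumStatError):
            ps.p_from_z(np.inf)
        with pytest.raises(SumStatError):
            ps.standardized_effect(1.0, 0)

    @given(p=st.floats(min_value=1e-300, max_value=1.0),
           sign=st.sampled_from([-1, 1]))
    @settings(deadline=None, max_examples=200)
    def test_p_z_round_trip(self, p, sign):
        z = ps.z_from_p_and_direction(p, sign)
        assert ps.p_from_z(z) == pytest.approx(p, rel=1e-9)
        assert z == 0 or np.sign(z) == sign

    @given(z=st.floats(-10, 10), n=st.integers(1, 10**7),
           k=st.sampled_from([4, 9, 16]))
    @settings(deadline=None, max_examples=100)
    def test_effect_scales_as_inverse_sqrt_n(self, z, n, k):
        assert ps.standardized_effect(z, k * n) == pytest.approx(
            ps.standardized_effect(z, n) / np.sqrt(k), rel=1e-12, abs=1e-300)


class TestTableConstruction:
    def test_z_derived_from_beta_se(self):
        tab = make_table([{"snp": "a"}])
        df = tab.df.drop(columns=["z", "p", "b"])
        df["beta"] = -0.1575
        df["se"] = 0.0248
        tab2 = ps.SumStatTable(df)
        assert tab2.df["z"].iloc[0] == pytest.approx(-6.35081, abs=1e-4)

    def test_z_derived_from_p_dir(self):
        df = pd.DataFrame([{"snp": "a", "chr": 1, "pos": 5, "a1": "A",
                            "a2": "G", "p": 1.0, "dir": "+", "n": 100}])
        tab = ps.SumStatTable(df)
        assert tab.df["z"].iloc[0] == 0.0

    def test_duplicate_id_is_hard_error(self):
        with pytest.raises(SumStatError, match="s0"):
            make_table([{"snp": "s0"}, {"snp": "s0", "pos": 999}])

    def test_no_statistic_column_is_error(self):
        df = pd.DataFrame([{"snp": "a", "chr": 1, "pos": 5,
                            "a1": "A", "a2": "G"}])
        with pytest.raises(SumStatError, match="statistic"):
            ps.SumStatTable(df)

    def test_sorted_by_position(self):
        tab = make_table([{"snp": "a", "chr": 2, "pos": 50, "z": 1.0},
                          {"snp": "b", "chr": 1, "pos": 99, "z": 2.0}])
        assert list(tab.df["snp"]) == ["b", "a"]


class TestHarmonize:
    def reference(self):
        return make_table([{"snp": "s0", "z": 0.0},
                           {"snp": "s1", "z": 0.0},
                           {"snp": "s2", "z": 0.0}])

    def test_matching_orientation_unchanged(self):
        study = make_table([{"snp": "s0", "z": 2.0}])
        out = ps.harmonize(study, self.reference())
        assert out.df["z"].iloc[0] == 2.0

    def test_swapped_alleles_flip_sign(self):
        study = make_table([{"snp": "s1", "pos": 200, "a1": "G", "a2": "A",
                             "z": 2.0}])
        out = ps.harmonize(study, self.reference())
        assert out.df["z"].iloc[0] == -2.0
        assert out.df["b"].iloc[0] < 0

    def test_ambiguous_dropped(self):
        study = make_table([{"snp": "s0", "a1": "A", "a2": "T", "z": 3.0}])
        out = ps.harmonize(study, self.reference())
        assert len(out) == 0

    def test_absent_and_irreconcilable_dropped(self):
        study = make_table([
            {"snp": "nope", "z": 1.0},
            {"snp": "s2", "pos": 300, "a1": "A", "a2": "C", "z": 1.0},
        ])
        ref = make_table([{"snp": "s2", "pos": 300, "a1": "A", "a2": "G"}])
        out = ps.harmonize(study, ref)
        assert len(out) == 0
        assert out.harmonize_counts["absent"] == 1
        assert out.harmonize_counts["irreconcilable"] == 1

    def test_idempotent(self):
        study = make_table([{"snp": "s0", "a1": "G", "a2": "A", "z": 1.5},
                            {"snp": "s1", "pos": 200, "z": -0.5}])
        ref = self.reference()
        once = ps.harmonize(study, ref)
        twice = ps.harmonize(once, ref)
        pd.testing.assert_frame_equal(once.df, twice.df)

    def test_swap_all_and_reharmonize_restores(self):
        study = make_table([{"snp": "s0", "z": 1.5},
                            {"snp": "s1", "pos": 200, "z": -0.5}])
        ref = self.reference()
        base = ps.harmonize(study, ref)
        swapped = base.df.copy()
        swapped[["a1", "a2"]] = swapped[["a2", "a1"]].to_numpy()
        swapped[["z", "b"]] *= -1
        restored = ps.harmonize(ps.SumStatTable(swapped), ref)
        pd.testing.assert_frame_equal(restored.df, base.df)


class TestIO:
    def test_round_trip(self, tmp_path, small_compendium):
        tables, outcome, _ = small_compendium
        path = tmp_path / "t.tsv"
        sub = ps.SumStatTable(tables[0].df.head(100).copy())
        ps.write_sumstats(sub, path)
        back = ps.read_sumstats(path)
        for col in ("z", "p", "b"):
            np.testing.assert_allclose(back.df[col], sub.df[col], rtol=1e-9)
        pd.testing.assert_frame_equal(
            back.df[["snp", "chr", "pos", "a1", "a2", "n"]],
            sub.df[["snp", "chr", "pos", "a1", "a2", "n"]])

    def test_column_map_and_beta_se_file(self, tmp_path):
        path = tmp_path / "s.tsv"
        path.write_text("rsid\tchr\tpos\ta1\ta2\tbeta\tse\n"
                        "rs1\t1\t100\tA\tG\t-0.1575\t0.0248\n")
        tab = ps.read_sumstats(path, column_map={"rsid": "snp"},
                               n_default=1000)
        assert tab.df["z"].iloc[0] == pytest.approx(-6.35081, abs=1e-4)
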