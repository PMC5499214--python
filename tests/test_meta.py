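"""Meta-analysis: worked examples against an independent erfc-based normal
oracle, invariances, filtering rules, and the table-level pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from enhancerenrich.meta import (
    CohortSnpStat,
    combine_cohorts,
    filter_and_flag,
    meta_analyse,
    meta_p_value,
    read_cohort_table,
    standard_error,
)

from _oracles import norm_isf, two_sided_p


def rec(beta, p, cohort="bulls", snp="s1"):
    return CohortSnpStat(snp, "1", 100, cohort, beta, p)


class TestStandardError:
    def test_two_sided_worked_example(self):
        # p = 0.04550026 is the two-sided tail of z = 2
        assert standard_error(0.4, 0.04550026) == pytest.approx(0.2, rel=1e-6)
        z = norm_isf(0.04550026 / 2)
        assert standard_error(0.4, 0.04550026) == pytest.approx(0.4 / z, rel=1e-9)

    def test_as_written_worked_example(self):
        assert standard_error(1.0, 0.05, "as-written") == pytest.approx(
            1 / 1.6448536, rel=1e-6
        )

    @pytest.mark.parametrize(
        "beta, p, mode",
        [
            (0.4, 1.0, "two-sided"),  # P = 1: removal rule
            (0.0, 0.5, "two-sided"),  # no effect: removal rule
            (0.4, 0.5, "as-written"),  # quantile of 0.5 is 0
        ],
    )
    def test_filterable_signalled_as_nan(self, beta, p, mode):
        assert np.isnan(standard_error(beta, p, mode))

    def test_vectorised_matches_scalar(self):
        beta = np.array([0.4, -1.2, 0.0])
        p = np.array([0.04550026, 0.3, 0.2])
        se = standard_error(beta, p)
        for b, pv, s in zip(beta, p, se):
            scalar = standard_error(float(b), float(pv))
            assert (np.isnan(s) and np.isnan(scalar)) or s == scalar

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            standard_error(0.4, 0.1, "sideways")


class TestCombineCohorts:
    def test_two_cohort_worked_example(self):
        """Bulls (b=0.4, p->z=2) + cows (b=0.2, p->z=1): both se = 0.2, so
        w = 5 each, weighted effects 2.0/1.0, combined effect 0.3 and
        dispersion sqrt(2/10)."""
        # input P values are 6-7 digit prints, so match to that precision
        r = combine_cohorts([rec(0.4, 0.04550026), rec(0.2, 0.317311, "cows")])
        assert r.w_by_cohort["bulls"] == pytest.approx(5.0, rel=1e-5)
        assert r.w_by_cohort["cows"] == pytest.approx(5.0, rel=1e-5)
        assert r.hat_beta_by_cohort["bulls"] == pytest.approx(2.0, rel=1e-5)
        assert r.hat_beta_by_cohort["cows"] == pytest.approx(1.0, rel=1e-5)
        assert r.tilde_beta == pytest.approx(0.3, rel=1e-5)
        assert r.tilde_v == pytest.approx(0.4472136, rel=1e-5)
        assert r.n_cohorts == 2
        p = meta_p_value(r.tilde_beta, r.tilde_v)
        assert p == pytest.approx(0.5023, abs=1e-4)
        assert p == pytest.approx(two_sided_p(0.3 / 0.4472136), rel=1e-6)

    def test_identical_cohorts_return_common_effect(self):
        r = combine_cohorts([rec(0.7, 0.01), rec(0.7, 0.01, "cows")])
        assert r.tilde_beta == pytest.approx(0.7, rel=1e-12)

    def test_cohort_order_invariance(self):
        a = combine_cohorts([rec(0.4, 0.045), rec(-0.2, 0.3, "cows")])
        b = combine_cohorts([rec(-0.2, 0.3, "cows"), rec(0.4, 0.045)])
        assert a.tilde_beta == b.tilde_beta and a.tilde_v == b.tilde_v

    def test_all_cohorts_invalid_drops_snp(self):
        assert combine_cohorts([rec(0.0, 0.5), rec(0.4, 1.0, "cows")]) is None

    def test_position_mismatch_rejected(self):
        recs = [rec(0.4, 0.1), CohortSnpStat("s1", "2", 999, "cows", 0.2, 0.1)]
        with pytest.raises(ValueError, match="disagree on position"):
            combine_cohorts(recs)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        beta=st.floats(0.01, 10),
        p1=st.floats(1e-6, 0.999),
        p2=st.floats(1e-6, 0.999),
        c=st.floats(0.1, 10),
    )
    def test_scale_invariance_of_p(self, beta, p1, p2, c):
        """Under inverse-variance (1/se^2) weights, scaling all effects by c
        scales the combined effect by c and leaves the combined P value
        unchanged. (Under the published 1/se weight the dispersion scales
        as sqrt(c), so the combined P is deliberately not scale-free.)"""
        base = combine_cohorts(
            [rec(beta, p1), rec(-beta / 2, p2, "cows")], weight_exponent=2
        )
        scaled = combine_cohorts(
            [rec(c * beta, p1), rec(-c * beta / 2, p2, "cows")], weight_exponent=2
        )
        assert scaled.tilde_beta == pytest.approx(c * base.tilde_beta, rel=1e-9)
        assert meta_p_value(scaled.tilde_beta, scaled.tilde_v) == pytest.approx(
            meta_p_value(base.tilde_beta, base.tilde_v), rel=1e-9
        )


class TestMetaPValue:
    def test_zero_effect_gives_p_one(self):
        assert meta_p_value(0.0, 1.0) == 1.0

    def test_oracle_values(self):
        assert meta_p_value(0.3, 0.4472136) == pytest.approx(0.5023, abs=1e-4)
        assert meta_p_value(2.0, 1.0) == pytest.approx(0.04550026, rel=1e-6)
        # monotone decreasing in |z|
        ps = [meta_p_value(z, 1.0) for z in (0.5, 1.0, 2.0, 4.0)]
        assert ps == sorted(ps, reverse=True)

    def test_nonpositive_dispersion_rejected(self):
        with pytest.raises(ValueError):
            meta_p_value(0.3, 0.0)


def test_single_cohort_round_trip_inverse_variance():
    """With inverse-variance (1/se^2) weights a one-cohort meta-analysis is
    the identity: the recomputed two-sided P matches the input P."""
    rng = np.random.default_rng(7)
    p_in = rng.uniform(1e-10, 0.999, size=500)
    beta = rng.normal(size=500)
    beta[beta == 0] = 0.1
    for b, p in zip(beta, p_in):
        r = combine_cohorts([rec(b, p)], weight_exponent=2)
        assert meta_p_value(r.tilde_beta, r.tilde_v) == pytest.approx(p, rel=1e-10)


class TestFilterAndFlag:
    def make_frame(self):
        return pd.DataFrame(
            {
                "snp_id": ["a", "b", "c", "d", "e"],
                "chrom": "1",
                "pos": range(1, 6),
                "tilde_beta": [0.5, 0.0, 0.5, 0.5, 0.5],
                "tilde_v": 1.0,
                "tilde_p": [1e-9, 0.5, 1.0, 1e-7, np.nan],
                "n_cohorts": 2,
            }
        )

    def test_removal_and_flagging(self):
        out, counts = filter_and_flag(self.make_frame(), threshold=1e-8)
        assert set(out["snp_id"]) == {"a", "d"}  # b: no effect; c: P=1; e: invalid
        assert counts == {
            "input_variants": 5,
            "removed_variants": 3,
            "variants_tested": 2,
            "significant_variants": 1,
        }
        flags = dict(zip(out["snp_id"], out["significant"]))
        assert flags == {"a": True, "d": False}  # 1e-9 passes 1e-8, 1e-7 does not

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            filter_and_flag(self.make_frame(), threshold=1.5)


class TestMetaAnalyse:
    def cohorts(self):
        bulls = pd.DataFrame(
            {
                "snp_id": ["s1", "s2", "s3"],
                "chrom": "1",
                "pos": [10, 20, 30],
                "beta": [0.4, 0.5, 0.3],
                "p": [0.04550026, 0.01, 0.2],
            }
        )
        cows = pd.DataFrame(
            {
                "snp_id": ["s1", "s2"],
                "chrom": "1",
                "pos": [10, 20],
                "beta": [0.2, 0.0],  # s2 invalid in cows -> variant removed
                "p": [0.317311, 0.3],
            }
        )
        return {"bulls": bulls, "cows": cows}

    def test_matches_per_snp_combination(self):
        out, counts = meta_analyse(self.cohorts())
        row = out.set_index("snp_id").loc["s1"]
        assert row["tilde_beta"] == pytest.approx(0.3, rel=1e-6)
        assert row["tilde_v"] == pytest.approx(0.4472136, rel=1e-6)
        assert row["tilde_p"] == pytest.approx(0.5023, abs=1e-4)
        # s2 removed (cows beta = 0); s3 kept with n = 1
        assert "s2" not in out["snp_id"].values
        assert out.set_index("snp_id").loc["s3", "n_cohorts"] == 1
        assert counts["removed_variants"] == 1

    def test_single_cohort_drop_mode(self):
        out, _ = meta_analyse(self.cohorts(), single_cohort="drop")
        assert set(out["snp_id"]) == {"s1"}

    def test_position_clash_rejected(self):
        cohorts = self.cohorts()
        cohorts["cows"].loc[0, "pos"] = 99
        with pytest.raises(ValueError, match="disagree"):
            meta_analyse(cohorts)

    def test_duplicate_snp_in_one_cohort_rejected(self):
        cohorts = self.cohorts()
        cohorts["bulls"] = pd.concat([cohorts["bulls"], cohorts["bulls"].iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            meta_analyse(cohorts)


def test_read_cohort_table_validates(tmp_path):
    path = tmp_path / "c.tsv"
    pd.DataFrame(
        {"snp_id": ["a"], "chrom": ["1"], "pos": [5], "beta": [0.1], "p": [0.5]}
    ).to_csv(path, sep="\t", index=False)
    df = read_cohort_table(path)
    assert list(df.columns[:5]) == ["snp_id", "chrom", "pos", "beta", "p"]
    bad = tmp_path / "bad.tsv"
    pd.DataFrame({"snp_id": ["a"], "chrom": ["1"], "pos": [5], "beta": [0.1], "p": [1.5]}).to_csv(
        bad, sep="\t", index=False
    )
    with pytest.raises(ValueError, match="outside"):
        read_cohort_table(bad)
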