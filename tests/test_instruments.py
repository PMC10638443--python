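import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tsmr
from tsmr.instruments import LdMatrix
from tsmr.summary_io import GwasAssociation, SummarySet


def _assoc(sid="rs1", chrom="1", pos=1000, p=1e-9, **kw):
    base = dict(
        snp_id=sid, effect_allele="A", other_allele="G", eaf=0.3,
        beta=0.1, se=0.02, pvalue=p, chrom=chrom, pos=pos,
    )
    base.update(kw)
    return GwasAssociation(**base)


def _set(records):
    return SummarySet.from_records("exp", "continuous", records)


class TestPvalueFilter:
    def test_genome_wide_threshold_keeps_all_fixture_snps(self, table2):
        exposure, _ = table2
        assert len(tsmr.filter_by_pvalue(exposure, 5e-8)) == 3

    def test_stricter_threshold_keeps_only_strongest(self, table2):
        exposure, _ = table2
        kept = tsmr.filter_by_pvalue(exposure, 1e-8)
        assert list(kept.records) == ["rs7626692"]

    def test_threshold_one_keeps_everything_in_order(self, table2):
        exposure, _ = table2
        kept = tsmr.filter_by_pvalue(exposure, 1.0)
        assert list(kept.records) == list(exposure.records)

    def test_invalid_threshold_rejected(self, table2):
        with pytest.raises(tsmr.ConfigurationError):
            tsmr.filter_by_pvalue(table2[0], 0.0)


class TestLdMatrix:
    def test_asymmetry_rejected(self):
        m = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(tsmr.ValidationError):
            LdMatrix(["a", "b"], m)

    def test_out_of_range_rejected(self):
        m = np.array([[1.0, 1.5], [1.5, 1.0]])
        with pytest.raises(tsmr.ValidationError):
            LdMatrix(["a", "b"], m)

    def test_long_format_reader(self, tmp_path):
        path = tmp_path / "ld.tsv"
        path.write_text("snp_a\tsnp_b\tr2\nrs1\trs2\t0.5\n")
        ld = tsmr.instruments.read_ld_long(path)
        assert ld.get("rs1", "rs2") == 0.5
        assert ld.get("rs1", "rs_missing") is None


def _brute_force_clump(records, ld, r2_threshold, window_kb):
    """Independent re-statement of the greedy rule by explicit enumeration."""
    remaining = sorted(records, key=lambda r: r.pvalue)
    accepted, removed = [], set()
    for rec in remaining:
        if rec.snp_id in removed:
            continue
        accepted.append(rec.snp_id)
        for other in remaining:
            if other.snp_id in removed or other.snp_id in [a for a in accepted]:
                continue
            same_chrom = rec.chrom == other.chrom and rec.chrom is not None
            in_window = (
                rec.pos is not None
                and other.pos is not None
                and abs(rec.pos - other.pos) <= window_kb * 1000
            )
            r2 = ld.get(rec.snp_id, other.snp_id) if ld is not None else None
            if same_chrom and in_window and r2 is not None and r2 > r2_threshold:
                removed.add(other.snp_id)
    return accepted


class TestLdClump:
    def test_different_chromosomes_never_clumped(self, table2):
        exposure, _ = table2
        ld = LdMatrix(list(exposure.records), np.full((3, 3), 1.0))
        np.fill_diagonal(ld.r2_values, 1.0)
        assert len(tsmr.ld_clump(exposure, ld)) == 3

    def test_correlated_pair_keeps_most_significant(self):
        sset = _set([
            _assoc("rs_a", pos=1000, p=1e-9),
            _assoc("rs_b", pos=6000, p=1e-8),
        ])
        ld = LdMatrix(["rs_a", "rs_b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        kept = tsmr.ld_clump(sset, ld, r2_threshold=0.001, window_kb=10_000)
        assert list(kept.records) == ["rs_a"]

    def test_pair_outside_window_both_kept(self):
        sset = _set([
            _assoc("rs_a", pos=1000, p=1e-9),
            _assoc("rs_b", pos=1000 + 20_000_000, p=1e-8),
        ])
        ld = LdMatrix(["rs_a", "rs_b"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        kept = tsmr.ld_clump(sset, ld, r2_threshold=0.001, window_kb=10_000)
        assert len(kept) == 2

    def test_snp_missing_from_ld_treated_independent(self):
        sset = _set([_assoc("rs_a", pos=1000), _assoc("rs_b", pos=2000, p=1e-8)])
        ld = LdMatrix.identity(["rs_a"])
        assert len(tsmr.ld_clump(sset, ld)) == 2

    def test_output_subset_and_min_pvalue_preserved(self):
        sset, ld = tsmr.generate_clump_instance([3, 2], within_r2=0.8, seed=3)
        kept = tsmr.ld_clump(sset, ld, r2_threshold=0.001, window_kb=10_000)
        assert set(kept.records) <= set(sset.records)
        assert min(r.pvalue for r in kept) == min(r.pvalue for r in sset)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        chroms = rng.choice(["1", "2"], n)
        positions = rng.integers(1, 30_000_000, n)
        pvals = 10.0 ** rng.uniform(-12, -4, n)
        records = [
            _assoc(f"rs{i}", chrom=chroms[i], pos=int(positions[i]), p=float(pvals[i]))
            for i in range(n)
        ]
        m = rng.uniform(0, 1, (n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 1.0)
        ld = LdMatrix([r.snp_id for r in records], m)
        kept = tsmr.ld_clump(_set(records), ld, r2_threshold=0.1, window_kb=10_000)
        expected = _brute_force_clump(records, ld, 0.1, 10_000)
        assert set(kept.records) == set(expected)


class TestVarianceExplained:
    @pytest.mark.parametrize(
        "se,expected_pct", [(0.0017, 6.993), (0.0019, 6.303)]
    )
    def test_matches_published_per_snp_values(self, se, expected_pct):
        rec = _assoc(se=se, beta=0.01, eaf=0.45)
        r2 = tsmr.variance_explained(rec, n=7824)
        assert 100 * r2 == pytest.approx(expected_pct, abs=5e-4)

    def test_sum_over_fixture_is_20_3_percent(self, table2):
        exposure, _ = table2
        total = sum(tsmr.variance_explained(rec, 7824) for rec in exposure)
        assert round(100 * total, 1) == 20.3

    @given(
        eaf=st.floats(0.01, 0.99),
        beta=st.floats(0.001, 10.0),
        se=st.floats(0.001, 1.0),
    )
    def test_printed_formula_depends_only_on_se_and_n(self, eaf, beta, se):
        # EAF and beta cancel algebraically in the formula as printed
        a = tsmr.variance_explained(_assoc(eaf=eaf, beta=beta, se=se), n=5000)
        b = tsmr.variance_explained(_assoc(eaf=0.5, beta=1.0, se=se), n=5000)
        assert a == pytest.approx(b, rel=1e-12)
        assert a == pytest.approx(1.0 / (1.0 + se * 5000), rel=1e-12)

    def test_standard_formula_differs_and_uses_se_squared(self):
        rec = _assoc(beta=0.1, se=0.02)
        std = tsmr.variance_explained(rec, n=1000, formula="standard")
        assert std == pytest.approx(0.1**2 / (0.1**2 + 1000 * 0.02**2), rel=1e-12)

    def test_small_se_limit_approaches_one(self):
        r2 = tsmr.variance_explained(_assoc(se=1e-12), n=10)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_zero_beta_or_degenerate_eaf_raise(self):
        with pytest.raises(tsmr.ValidationError):
            tsmr.variance_explained(_assoc(beta=0.0), n=100)
        with pytest.raises(tsmr.ValidationError):
            tsmr.variance_explained(_assoc(eaf=1.0), n=100)


class TestFStatistic:
    def test_half_variance_small_sample(self):
        assert tsmr.f_statistic(0.5, 103, 1) == pytest.approx(101.0)

    def test_fixture_strength_is_far_from_weak(self):
        assert tsmr.f_statistic(0.06993, 7824, 3) == pytest.approx(588.0, abs=0.5)

    def test_zero_r2_gives_zero(self):
        assert tsmr.f_statistic(0.0, 100, 1) == 0.0

    def test_monotone_in_r2_and_n(self):
        assert tsmr.f_statistic(0.2, 100, 1) > tsmr.f_statistic(0.1, 100, 1)
        assert tsmr.f_statistic(0.1, 200, 1) > tsmr.f_statistic(0.1, 100, 1)

    def test_insufficient_sample_raises(self):
        with pytest.raises(tsmr.ValidationError):
            tsmr.f_statistic(0.1, 2, 1)


class TestWeakInstrumentFilter:
    def test_fixture_strengths_all_retained(self, table2):
        exposure, _ = table2
        strengths = tsmr.instrument_strengths(exposure)
        assert sorted(s.f_stat for s in strengths) == pytest.approx(
            [526.0, 588.0, 588.0], abs=0.5
        )
        assert len(tsmr.weak_instrument_filter(strengths, 10.0)) == 3

    def test_weak_instruments_dropped(self):
        strengths = [
            tsmr.InstrumentStrength("a", 0.001, 5.0, 1000, 2),
            tsmr.InstrumentStrength("b", 0.01, 12.0, 1000, 2),
        ]
        assert tsmr.weak_instrument_filter(strengths, 10.0) == ["b"]

    def test_empty_input_empty_output(self):
        assert tsmr.weak_instrument_filter([], 10.0) == []


class TestMafCheck:
    def test_fixture_passes_at_one_percent(self, table2):
        exposure, _ = table2
        assert tsmr.maf_check(exposure, 0.01) == []

    def test_rare_allele_flagged_from_either_side(self):
        sset = _set([_assoc("rs_rare", eaf=0.995), _assoc("rs_common", eaf=0.5, pos=2000)])
        assert tsmr.maf_check(sset, 0.01) == ["rs_rare"]

    @pytest.mark.parametrize("maf_min", [0.01, 0.1, 0.49])
    def test_half_frequency_never_flagged(self, maf_min):
        sset = _set([_assoc(eaf=0.5)])
        assert tsmr.maf_check(sset, maf_min) == []


def _inst(sid="rs1", bx=0.1, sx=0.01, by=0.05, sy=0.02):
    return tsmr.HarmonizedInstrument(
        snp_id=sid, effect_allele="A", other_allele="G",
        beta_exp=bx, se_exp=sx, beta_out=by, se_out=sy, eaf_exp=0.3,
    )


class TestSteigerFilter:
    def test_fixture_has_no_reverse_causality(self, table2, nielsen_instruments):
        results = tsmr.steiger_filter(
            nielsen_instruments, n_exp=7824, n_out=1_030_836,
            outcome_type="binary", case_fraction=60_620 / 1_030_836,
        )
        assert len(results) == 3
        assert all(r.correct_direction for r in results)
        assert all(r.r2_exposure > r.r2_outcome for r in results)

    def test_equal_correlations_are_a_boundary(self):
        inst = _inst(bx=0.1, sx=0.02, by=0.1, sy=0.02)
        (res,) = tsmr.steiger_filter([inst], 1000, 1000, outcome_type="continuous")
        assert not res.correct_direction
        assert res.steiger_p == pytest.approx(1.0)

    def test_strong_exposure_weak_outcome_is_significant(self):
        inst = _inst(bx=0.1, sx=0.01, by=0.002, sy=0.02)  # t = 10 vs t = 0.1
        (res,) = tsmr.steiger_filter([inst], 1000, 1000, outcome_type="continuous")
        assert res.correct_direction
        assert res.steiger_p < 0.05

    def test_swapping_roles_negates_direction_keeps_pvalue(self):
        fwd = _inst(bx=0.1, sx=0.01, by=0.02, sy=0.02)
        rev = _inst(bx=0.02, sx=0.02, by=0.1, sy=0.01)
        (f,) = tsmr.steiger_filter([fwd], 500, 800, outcome_type="continuous")
        (r,) = tsmr.steiger_filter([rev], 800, 500, outcome_type="continuous")
        assert f.correct_direction != r.correct_direction
        assert f.steiger_p == pytest.approx(r.steiger_p, rel=1e-12)

    def test_binary_outcome_requires_case_fraction(self, nielsen_instruments):
        with pytest.raises(tsmr.ConfigurationError):
            tsmr.steiger_filter(nielsen_instruments, 7824, 1_030_836, "binary")

    def test_tiny_samples_rejected(self, nielsen_instruments):
        with pytest.raises(tsmr.ValidationError):
            tsmr.steiger_filter(nielsen_instruments, 2, 100, outcome_type="continuous")


class TestExclusionList:
    def test_round_trip_and_application(self, tmp_path, table2):
        exposure, _ = table2
        path = tmp_path / "exclude.txt"
        path.write_text("rs532545\n\nrs_not_present\n")
        excluded = tsmr.instruments.read_exclusion_list(path)
        kept = tsmr.instruments.apply_exclusion_list(exposure, excluded)
        assert list(kept.records) == ["rs2686796", "rs7626692"]
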