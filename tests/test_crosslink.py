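"""%XL quantitation, replicate statistics, condition comparison and the
outlier rule, checked against independent brute-force oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from epiconform.crosslink import (ConditionComparison, PairComparison,
                                  PairKey, XLMeasurement, compare_conditions,
                                  crosslink_percentage, flag_outliers,
                                  percentages_from_records, summarize_pair)
from epiconform.io import CrosslinkSpeciesRecord
from tests.conftest import make_species


def oracle_percentage(pair, records, condition, replicate):
    """Independent re-derivation of the %XL denominator membership:
    enumerate every record and decide inclusion from first principles."""
    num = 0.0
    denom = 0.0
    for r in records:
        if (r.protein_id != pair.protein_id or r.condition != condition
                or r.replicate != replicate):
            continue
        if r.species_type == "crosslink":
            touches = r.residue_i in (pair.residue_i, pair.residue_j) \
                or r.residue_j in (pair.residue_i, pair.residue_j)
            if touches:
                denom += r.peak_height
            if (r.residue_i, r.residue_j) == (pair.residue_i, pair.residue_j):
                num += r.peak_height
        else:
            if r.residue_i in (pair.residue_i, pair.residue_j):
                denom += r.peak_height
    return 100.0 * num / denom


def random_species_table(rng, n_pairs=4):
    """A replicate's worth of records with overlapping residue usage."""
    records = []
    residues = list(rng.choice(np.arange(5, 120), size=n_pairs + 3,
                               replace=False))
    pairs = []
    for _ in range(n_pairs):
        i, j = sorted(rng.choice(residues, size=2, replace=False))
        if i == j or any((p.residue_i, p.residue_j) == (i, j) for p in pairs):
            continue
        pairs.append(PairKey("P1", int(i), int(j)))
    for p in pairs:
        records.append(make_species(i=p.residue_i, j=p.residue_j,
                                    ph=float(rng.uniform(1, 1e3))))
    for r in residues:
        if rng.random() < 0.7:
            records.append(make_species(species="deadend", i=int(r),
                                        ph=float(rng.uniform(0, 1e3))))
    return records, pairs


class TestCrosslinkPercentage:
    def test_simple_arithmetic(self, simple_pair, simple_species_records):
        assert crosslink_percentage(simple_pair, simple_species_records,
                                    "PU", 1) == pytest.approx(50.0)

    def test_sole_species_is_100(self, simple_pair):
        records = [make_species(i=10, j=30, ph=42.0)]
        assert crosslink_percentage(simple_pair, records, "PU", 1) \
            == pytest.approx(100.0)

    def test_competing_crosslink_enters_denominator(self):
        pair = PairKey("P1", 10, 30)
        records = [
            make_species(i=10, j=30, ph=30.0),
            make_species(i=10, j=50, ph=10.0),   # shares residue 10
            make_species(species="deadend", i=10, ph=40.0),
            make_species(species="deadend", i=30, ph=20.0),
        ]
        assert crosslink_percentage(pair, records, "PU", 1) \
            == pytest.approx(30.0)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(300):
            records, pairs = random_species_table(rng)
            for pair in pairs:
                got = crosslink_percentage(pair, records, "PU", 1)
                want = oracle_percentage(pair, records, "PU", 1)
                assert got == pytest.approx(want, rel=1e-12)

    def test_unit_invariance(self, rng):
        records, pairs = random_species_table(rng)
        scaled = [CrosslinkSpeciesRecord(
            protein_id=r.protein_id, species_type=r.species_type,
            residue_i=r.residue_i, residue_j=r.residue_j,
            condition=r.condition, replicate=r.replicate,
            peak_height=r.peak_height * 7.3e4) for r in records]
        for pair in pairs:
            assert crosslink_percentage(pair, records, "PU", 1) \
                == pytest.approx(crosslink_percentage(pair, scaled, "PU", 1))

    def test_monotone_decreasing_in_deadend_height(self, simple_pair):
        previous = 101.0
        for de in [0.0, 10.0, 50.0, 500.0]:
            records = [make_species(i=10, j=30, ph=50.0),
                       make_species(species="deadend", i=10, ph=de)]
            pct = crosslink_percentage(simple_pair, records, "PU", 1)
            assert pct < previous
            previous = pct

    def test_bounded_in_0_100(self, rng):
        for _ in range(50):
            records, pairs = random_species_table(rng)
            for pair in pairs:
                assert 0.0 <= crosslink_percentage(pair, records, "PU", 1) \
                    <= 100.0

    def test_missing_pair_rejected(self, simple_pair):
        with pytest.raises(ValueError):
            crosslink_percentage(simple_pair,
                                 [make_species(species="deadend", i=10)],
                                 "PU", 1)

    def test_pair_only_denominator_option(self):
        pair = PairKey("P1", 10, 30)
        records = [
            make_species(i=10, j=30, ph=30.0),
            make_species(i=10, j=50, ph=10.0),
            make_species(species="deadend", i=10, ph=40.0),
            make_species(species="deadend", i=30, ph=20.0),
        ]
        assert crosslink_percentage(pair, records, "PU", 1,
                                    denominator="pair") \
            == pytest.approx(100.0 * 30 / 90)


class TestSummarize:
    def test_basic(self, simple_pair):
        ms = [XLMeasurement(simple_pair, "PU", r + 1, v)
              for r, v in enumerate([10.0, 20.0, 30.0])]
        assert summarize_pair(ms) == (20.0, 10.0, 3)

    def test_single_replicate_sd_absent(self, simple_pair):
        mean, sd, n = summarize_pair([XLMeasurement(simple_pair, "PU", 1, 7.0)])
        assert (mean, sd, n) == (7.0, None, 1)

    def test_matches_reference_statistics(self, rng, simple_pair):
        for _ in range(100):
            vals = rng.uniform(0, 100, size=int(rng.integers(2, 10)))
            ms = [XLMeasurement(simple_pair, "PU", r + 1, float(v))
                  for r, v in enumerate(vals)]
            mean, sd, n = summarize_pair(ms)
            assert mean == pytest.approx(np.mean(vals))
            assert sd == pytest.approx(np.std(vals, ddof=1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_pair([])


class TestCompareConditions:
    def _measurements(self, pair, a, b):
        ms = [XLMeasurement(pair, "PU", r + 1, v) for r, v in enumerate(a)]
        ms += [XLMeasurement(pair, "GA", r + 1, v) for r, v in enumerate(b)]
        return ms

    def test_identical_groups(self, simple_pair):
        ms = self._measurements(simple_pair, [10, 20, 30], [10, 20, 30])
        (cmp,) = compare_conditions(ms, "PU", "GA")
        assert cmp.delta == pytest.approx(0.0)
        assert cmp.t_stat == pytest.approx(0.0)
        assert cmp.p_value == pytest.approx(1.0)

    def test_closed_form_pooled_t(self, simple_pair):
        a, b = [10.0, 12.0, 14.0], [20.0, 22.0, 24.0]
        (cmp,) = compare_conditions(self._measurements(simple_pair, a, b),
                                    "PU", "GA")
        # closed-form pooled two-sample t with 4 df, computed by hand
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        t_expected = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (2 / 3))
        p_expected = 2 * stats.t.sf(abs(t_expected), df=4)
        assert cmp.t_stat == pytest.approx(t_expected)
        assert cmp.p_value == pytest.approx(p_expected)
        assert cmp.pooled_sd == pytest.approx(math.sqrt(sp2))

    def test_single_replicate_errors_when_test_required(self, simple_pair):
        ms = self._measurements(simple_pair, [10.0], [20.0, 22.0])
        with pytest.raises(ValueError):
            compare_conditions(ms, "PU", "GA", require_test=True)
        (cmp,) = compare_conditions(ms, "PU", "GA")
        assert cmp.p_value is None and cmp.t_stat is None

    def test_zero_variance_p_absent(self, simple_pair):
        ms = self._measurements(simple_pair, [10.0] * 3, [10.0] * 3)
        (cmp,) = compare_conditions(ms, "PU", "GA")
        assert cmp.p_value is None


class TestFlagOutliers:
    def _cmp(self, separation, delta_sds, p):
        pair = PairKey("P1", 10, 10 + separation)
        return PairComparison(pair=pair, condition_a="PU", condition_b="GA",
                              mean_a=50.0, mean_b=50.0 - delta_sds * 2.0,
                              n_a=3, n_b=3, delta=delta_sds * 2.0,
                              pooled_sd=2.0, t_stat=1.0, p_value=p)

    @pytest.mark.parametrize("sep,delta_sds,p,expected", [
        (5, 3.0, 0.001, False),    # short-range pairs are never outliers
        (20, 2.0, 0.01, True),
        (20, 1.0, 0.01, False),    # effect below 1.5 pooled SD
        (20, 2.0, 0.20, False),    # not significant
        (8, 1.5, 0.05, True),      # boundary values are inclusive
    ])
    def test_rule(self, sep, delta_sds, p, expected):
        (out,) = flag_outliers([self._cmp(sep, delta_sds, p)])
        assert out.outlier is expected

    def test_missing_test_fields_never_outlier(self):
        cmp = PairComparison(pair=PairKey("P1", 10, 40), condition_a="PU",
                             condition_b="GA", n_a=1, n_b=3)
        (out,) = flag_outliers([cmp])
        assert out.outlier is False
        assert not out.crit_effect and not out.crit_significant


class TestConditionComparison:
    def test_end_to_end_on_table(self):
        records = []
        for cond, base in (("PU", 60.0), ("GA", 20.0)):
            for rep in (1, 2, 3):
                wiggle = {1: -2.0, 2: 0.0, 3: 2.0}[rep]
                p = base + wiggle
                records.append(make_species(i=10, j=40, condition=cond,
                                            replicate=rep, ph=p))
                records.append(make_species(species="deadend", i=10,
                                            condition=cond, replicate=rep,
                                            ph=(100 - p) / 2))
                records.append(make_species(species="deadend", i=40,
                                            condition=cond, replicate=rep,
                                            ph=(100 - p) / 2))
        result = ConditionComparison(records, "PU", "GA")
        assert len(result.comparisons) == 1
        cmp = result.comparisons[0]
        assert cmp.mean_a == pytest.approx(60.0)
        assert cmp.mean_b == pytest.approx(20.0)
        assert cmp.outlier
        frame = result.to_frame()
        assert bool(frame.loc[0, "outlier"])
        assert "outliers: 1" in result.summary()
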