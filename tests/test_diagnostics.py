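"""Statistical-defect applicability domain and promoter extraction."""

import numpy as np
import pytest

import cwqsar as cq
from cwqsar.attributes import Attribute, AttributeDictionary, AttributeStats


def _dictionary(stats: dict, sizes=(100, 100, 100)) -> AttributeDictionary:
    entries = {
        Attribute.single(tok): AttributeStats(*counts, blocked=blocked)
        for tok, (counts, blocked) in stats.items()
    }
    set_sizes = {
        "active": sizes[0],
        "passive": sizes[1],
        "calibration": sizes[2],
        "validation": 0,
    }
    return AttributeDictionary(entries, threshold=1, set_sizes=set_sizes)


class TestStatisticalDefect:
    def test_identical_probabilities_give_zero(self):
        d = _dictionary({"C": ((50, 50, 50, 0), False)})
        assert cq.statistical_defect(Attribute.single("C"), d) == 0.0

    def test_worked_arithmetic(self):
        # P=0.6 (N=60), P'=0.5 (N'=50), P''=0.4 (N''=40)
        d = _dictionary({"C": ((60, 50, 40, 0), False)})
        expected = 0.1 / 110 + 0.2 / 100 + 0.1 / 90
        assert cq.statistical_defect(Attribute.single("C"), d) == pytest.approx(
            expected, abs=1e-15
        )

    def test_published_frequency_row_magnitude(self):
        # frequent attribute (191/200/182 of blocks ~210): published d_k
        # is 0.0002; direct evaluation must land in the same order of
        # magnitude
        d = _dictionary({"C": ((191, 200, 182, 0), False)}, sizes=(212, 210, 210))
        val = cq.statistical_defect(Attribute.single("C"), d)
        assert 1e-5 < val < 1e-3

    def test_absent_attribute_warns_zero(self):
        d = _dictionary({"C": ((0, 0, 0, 0), False)})
        with pytest.warns(UserWarning):
            assert cq.statistical_defect(Attribute.single("C"), d) == 0.0

    def test_unknown_attribute_rejected(self):
        d = _dictionary({"C": ((10, 10, 10, 0), False)})
        with pytest.raises(cq.InputError):
            cq.statistical_defect(Attribute.single("X"), d)


class TestCompoundDefect:
    def test_sums_per_occurrence(self):
        d = _dictionary(
            {
                "C": ((60, 50, 40, 0), False),
                "O": ((30, 35, 25, 0), False),
                "N": ((10, 10, 10, 0), False),
            }
        )
        defects = {
            a: cq.statistical_defect(a, d)
            for a in (
                Attribute.single("C"),
                Attribute.single("O"),
                Attribute.single("N"),
            )
        }
        # CCO: two C occurrences + one O (pairs are unknown -> contribute 0)
        expected = 2 * defects[Attribute.single("C")] + defects[Attribute.single("O")]
        assert cq.compound_defect("CCO", d) == pytest.approx(expected, abs=1e-15)

    def test_all_blocked_warns_zero(self):
        d = _dictionary({"C": ((1, 0, 0, 0), True)})
        with pytest.warns(UserWarning):
            assert cq.compound_defect("CC", d) == 0.0

    def test_uniform_distributions_give_zero(self):
        d = _dictionary(
            {"C": ((40, 40, 40, 0), False), "O": ((20, 20, 20, 0), False)}
        )
        assert cq.compound_defect("COC", d) == 0.0


class TestInDomain:
    def test_zero_defect_in_domain(self):
        assert cq.in_domain(0.0, 0.5)

    def test_boundary_is_strictly_excluded(self):
        assert not cq.in_domain(1.0, 0.5)  # D_j == 2*D_bar exactly
        assert cq.in_domain(1.0 - 1e-12, 0.5)

    def test_degenerate_zero_mean_defect_excludes_all(self):
        assert not cq.in_domain(0.0, 0.0)

    def test_domain_grows_with_mean_defect(self):
        d_js = [0.1, 0.5, 1.0, 2.0]
        counts = [
            sum(cq.in_domain(d, d_bar) for d in d_js)
            for d_bar in (0.0, 0.1, 0.5, 2.0)
        ]
        assert counts == sorted(counts)


class TestPromoters:
    def _weights(self, values: dict):
        return cq.CorrelationWeights(
            {Attribute.single(t): v for t, v in values.items()}
        )

    def _dict(self):
        return _dictionary(
            {
                "S": ((58, 70, 53, 0), False),
                "O": ((154, 145, 150, 0), False),
                "N": ((30, 30, 30, 0), False),
                "F": ((4, 30, 30, 0), False),
            },
            sizes=(210, 210, 210),
        )

    def _runs(self):
        return [
            self._weights({"S": 2.9994, "O": -0.6029, "N": 0.5, "F": 1.0}),
            self._weights({"S": 4.2808, "O": -0.9352, "N": -0.2, "F": 1.0}),
            self._weights({"S": 2.6871, "O": -0.4391, "N": 0.1, "F": 1.0}),
        ]

    def test_roles_and_filtering(self):
        table = cq.extract_promoters(self._runs(), self._dict(), min_frequency=10)
        roles = {r.attribute.tokens[0]: r.role for r in table.rows}
        # sign-stable positive -> increase; negative -> decrease
        assert roles == {"S": "increase", "O": "decrease"}
        # N is sign-unstable, F fails the active-set frequency cut

    def test_sorted_by_active_frequency(self):
        table = cq.extract_promoters(self._runs(), self._dict(), min_frequency=10)
        counts = [r.count_active for r in table.rows]
        assert counts == sorted(counts, reverse=True)

    def test_permutation_invariant_over_runs(self):
        runs = self._runs()
        t1 = cq.extract_promoters(runs, self._dict())
        t2 = cq.extract_promoters(runs[::-1], self._dict())
        assert [r.attribute for r in t1.rows] == [r.attribute for r in t2.rows]
        assert [r.role for r in t1.rows] == [r.role for r in t2.rows]

    def test_fewer_than_three_runs_rejected(self):
        with pytest.raises(cq.ConfigurationError):
            cq.extract_promoters(self._runs()[:2], self._dict())


class TestDefectReport:
    def test_pipeline_report_consistency(self, benchmark_tf1):
        report = benchmark_tf1.defect_report
        assert report.d_bar > 0
        # flags agree with the strict rule
        for cid, d_j in report.compound_defects.items():
            assert report.in_domain_flags[cid] == (d_j < report.threshold)
        # defects are non-negative
        assert all(v >= 0 for v in report.defects.values())
        # the advisory domain keeps most of the data
        frac = np.mean(list(report.in_domain_flags.values()))
        assert frac > 0.5
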