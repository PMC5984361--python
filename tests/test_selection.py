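"""SSB correction arithmetic, the neutrality test, FDR, and aggregation."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ssbdnds as s
from ssbdnds import errors
from ssbdnds.reference import SiteSpectrum


def _spec(na_by_class, ns_by_class):
    na = np.zeros(7); ns = np.zeros(7)
    for k, v in na_by_class.items():
        na[k] = v
    for k, v in ns_by_class.items():
        ns[k] = v
    return SiteSpectrum("SSB7", na, ns)


class TestCorrection:
    def test_expected_frequencies(self):
        spec = _spec({0: 200, 1: 80}, {0: 100, 1: 20})
        exp = s.expected_frequencies(spec)
        assert exp[0] == pytest.approx(0.75)
        assert exp[1] == pytest.approx(0.25)
        with pytest.raises(errors.EmptySpectrum):
            s.expected_frequencies(SiteSpectrum.zeros("SSB7"))

    def test_fold_change_two_class(self):
        expected = np.array([0.75, 0.25, 0, 0, 0, 0, 0])
        observed = np.array([50, 50, 0, 0, 0, 0, 0])
        w = s.fold_change_weights(observed, expected)
        assert w[0] == pytest.approx(2 / 3)
        assert w[1] == pytest.approx(2.0)
        assert (w[2:] == 0).all()

    def test_fold_change_identity_and_errors(self):
        expected = np.full(7, 1 / 7)
        observed = np.full(7, 10.0)
        assert s.fold_change_weights(observed, expected) == pytest.approx(
            np.ones(7))
        with pytest.raises(errors.NoMutations):
            s.fold_change_weights(np.zeros(7), expected)

    def test_corrected_sites_arithmetic(self):
        spec = _spec({0: 225, 1: 75}, {0: 75, 1: 25})
        w = np.array([2 / 3, 2, 0, 0, 0, 0, 0])
        na, ns = s.corrected_sites(spec, w)
        assert na == pytest.approx(300.0)
        assert ns == pytest.approx(100.0)
        # identity weights
        na, ns = s.corrected_sites(spec, np.ones(7))
        assert (na, ns) == (pytest.approx(300), pytest.approx(100))

    def test_reweighting_property(self):
        """Corrected class frequencies reproduce the observed mutation-class
        frequencies whenever every class is observed."""
        rng = np.random.default_rng(1)
        for _ in range(50):
            na = rng.uniform(10, 100, 7)
            ns = rng.uniform(5, 50, 7)
            spec = SiteSpectrum("SSB7", na, ns)
            observed = rng.integers(1, 200, 7).astype(float)
            w = s.fold_change_weights(observed, s.expected_frequencies(spec))
            corrected = w * (na + ns)
            np.testing.assert_allclose(corrected / corrected.sum(),
                                       observed / observed.sum(), rtol=1e-9)

    def test_system_mismatch(self):
        with pytest.raises(errors.SystemMismatch):
            s.corrected_sites(SiteSpectrum.zeros("SSB7"), np.ones(192))


class TestGeneDnds:
    def test_basic_values(self):
        dn, ds, dnds, ok = s.gene_dnds(2, 1, 100, 50)
        assert (dn, ds, dnds, ok) == (0.02, 0.02, pytest.approx(1.0), True)
        dn, ds, dnds, ok = s.gene_dnds(0, 5, 100, 50)
        assert dnds == 0.0 and ok

    def test_undefined_when_no_silent(self):
        dn, ds, dnds, ok = s.gene_dnds(4, 0, 100, 50)
        assert not ok and math.isnan(dnds)

    def test_degenerate_sites(self):
        with pytest.raises(errors.DegenerateSites):
            s.gene_dnds(1, 1, 0, 50)

    def test_monotone_in_n(self):
        vals = [s.gene_dnds(n, 5, 100, 50)[2] for n in range(0, 30)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestNeutralityTest:
    def test_symmetric_null_gives_p_one(self):
        assert s.neutrality_test(5, 5, 80, 80) == pytest.approx(1.0,
                                                                abs=1e-12)

    def test_matches_enumeration_oracle(self):
        """Two-sided exact binomial: sum point probabilities <= that of the
        observed outcome, enumerated independently."""
        cases = [(0, 10, 2.0, 1.0), (3, 7, 1.0, 1.0), (12, 2, 3.0, 1.0),
                 (1, 1, 1.0, 2.0), (20, 5, 2.5, 1.0)]
        for n, ss_, na, ns in cases:
            pi = na / (na + ns)
            total = n + ss_
            pmf = stats.binom.pmf(np.arange(total + 1), total, pi)
            expected = pmf[pmf <= pmf[n] * (1 + 1e-12)].sum()
            assert s.neutrality_test(n, ss_, na, ns) == pytest.approx(
                min(1.0, expected), rel=1e-9), (n, ss_, na, ns)

    def test_one_tail_closed_form(self):
        # with pi = 2/3 and 0 of 10 non-silent, the lower tail is (1/3)^10
        p = s.neutrality_test(0, 10, 2.0, 1.0)
        assert p >= (1 / 3) ** 10
        pmf = stats.binom.pmf(np.arange(11), 10, 2 / 3)
        assert p == pytest.approx(pmf[pmf <= pmf[0]].sum())

    def test_requires_mutations(self):
        with pytest.raises(errors.NoMutations):
            s.neutrality_test(0, 0, 10, 10)


class TestFdr:
    def test_bh_matches_brute_force(self):
        """Step-up BH oracle: q_i = min over j>=i of p_(j) * m / j."""
        rng = np.random.default_rng(2)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 40))
            order = np.argsort(p)
            m = p.size
            q_sorted = p[order] * m / np.arange(1, m + 1)
            q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1.0)
            np.testing.assert_allclose(s.bh_adjust(p), expected, rtol=1e-12)

    def test_classification_labels(self):
        res = pd.DataFrame({
            "gene": ["KRAS-like", "AP2S1-like", "flat"],
            "dnds": [25.681, 0.043, 1.2],
            "dnds_defined": [True, True, True],
            "p": [1e-12, 1e-3, 0.9],
        })
        out = s.fdr_classify(res, q_threshold=0.1)
        assert out.loc[0, "label"] == "positive"
        assert out.loc[1, "label"] == "negative"
        assert out.loc[2, "label"] == "neutral"

    def test_all_flat_p_all_neutral(self):
        res = pd.DataFrame({"gene": list("abc"), "dnds": [2.0, 0.5, 1.0],
                            "dnds_defined": [True] * 3, "p": [1.0] * 3})
        assert (s.fdr_classify(res)["label"] == "neutral").all()

    def test_undefined_dnds_can_only_be_positive(self):
        res = pd.DataFrame({"gene": ["x"], "dnds": [float("nan")],
                            "dnds_defined": [False], "p": [1e-9]})
        assert s.fdr_classify(res)["label"].tolist() == ["positive"]


class TestConfidenceInterval:
    def test_closed_form(self):
        lo, hi = s.dnds_confidence_interval(100, 100, 1000, 1000)
        z = stats.norm.ppf(0.975)
        assert lo == pytest.approx(math.exp(-z * math.sqrt(0.02)))
        assert hi == pytest.approx(math.exp(z * math.sqrt(0.02)))

    def test_width_shrinks_with_counts(self):
        widths = []
        for f in (1, 4, 16):
            lo, hi = s.dnds_confidence_interval(50 * f, 50 * f,
                                                500 * f, 500 * f)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_undefined_for_zero_counts(self):
        lo, hi = s.dnds_confidence_interval(0, 5, 100, 100)
        assert math.isnan(lo) and math.isnan(hi)


class TestGlobalAndPanCancer:
    def test_single_gene_cohort_equals_global(self, toy_tx, toy_spectra,
                                              neutral_cohort):
        one_tx = neutral_cohort["transcript"].iloc[0]
        sub = neutral_cohort[neutral_cohort["transcript"] == one_tx]
        single = s.Transcriptome([toy_tx[one_tx]])
        res = s.gene_selection_table(sub, single)
        glob = s.global_dnds(sub, single)
        assert len(res) == 1
        row = res.iloc[0]
        for key in ("n", "s", "na_corr", "ns_corr", "dnds"):
            assert row[key] == pytest.approx(glob[key])

    def test_duplication_invariance(self, toy_tx, neutral_cohort):
        g1 = s.global_dnds(neutral_cohort, toy_tx)
        doubled = pd.concat([neutral_cohort, neutral_cohort],
                            ignore_index=True)
        g2 = s.global_dnds(doubled, toy_tx)
        assert g2["dnds"] == pytest.approx(g1["dnds"], rel=1e-9)
        assert g2["n"] == 2 * g1["n"]

    def test_pan_cancer_weighted_sites(self):
        cohorts = [dict(m=1000, na_corr=100, ns_corr=40, n=30, s=10),
                   dict(m=3000, na_corr=200, ns_corr=60, n=80, s=25)]
        out = s.pan_cancer_combine(cohorts)
        assert out["na_corr"] == pytest.approx(0.25 * 100 + 0.75 * 200)
        assert out["ns_corr"] == pytest.approx(0.25 * 40 + 0.75 * 60)
        assert out["n"] == 110 and out["s"] == 35

    def test_pan_cancer_identities(self):
        c = dict(m=500, na_corr=120, ns_corr=40, n=12, s=4)
        single = s.pan_cancer_combine([c])
        assert single["dnds"] == pytest.approx(
            (12 / 120) / (4 / 40))
        trip = s.pan_cancer_combine([c, c, c])
        assert trip["na_corr"] == pytest.approx(c["na_corr"])
        assert trip["ns_corr"] == pytest.approx(c["ns_corr"])
        with pytest.raises(errors.NoMutations):
            s.pan_cancer_combine([])
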