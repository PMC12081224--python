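"""Dosage screen: normalization, bands, classification, incidence."""

import numpy as np
import pandas as pd
import pytest

from eparscan import simdata
from eparscan.dosage import (
    DosageScreen,
    ReferenceBands,
    build_reference_bands,
    classify_samples,
    incidence_summary,
    normalize_intensities,
    rate_percent,
    sex_balance_filter,
)


def _bands(haploid, diploid, deletion):
    return ReferenceBands(haploid, diploid, deletion, provenance={})


class TestNormalization:
    def test_hand_computed_example(self):
        intensities = pd.DataFrame(
            {"m1": [1.0, 1.0, 1.0, 0.4], "m2": [1.0, 1.0, 1.0, 0.6],
             "m3": [2.0, 2.0, 2.0, 1.4]},
            index=["f1", "f2", "f3", "s"],
        )
        values = normalize_intensities(
            intensities, ["f1", "f2", "f3"], ["m1", "m2", "m3"]
        )
        assert values["s"] == pytest.approx(-0.6)
        assert values["f1"] == pytest.approx(0.0)

    def test_translation_invariance_per_marker(self, noisy_cohort):
        cohort = noisy_cohort
        info = cohort.markers.loc[
            cohort.markers["region"] == "EPAR_INTERVAL", "marker_id"
        ].tolist()
        females = cohort.sex.index[cohort.sex == "F"]
        base = normalize_intensities(cohort.intensities, females, info)
        shifted = cohort.intensities.copy()
        shifted[info[0]] += 7.5  # all samples, females included
        after = normalize_intensities(shifted, females, info)
        pd.testing.assert_series_equal(base, after)

    def test_no_females_rejected(self):
        frame = pd.DataFrame({"m1": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="female"):
            normalize_intensities(frame, [], ["m1"])

    def test_undefined_female_median_marker_excluded_with_warning(self):
        frame = pd.DataFrame(
            {"m1": [1.0, 1.0, 0.0], "m2": [np.nan, np.nan, 5.0]},
            index=["f1", "f2", "s"],
        )
        with pytest.warns(UserWarning, match="undefined female median"):
            values = normalize_intensities(frame, ["f1", "f2"], ["m1", "m2"])
        assert values["s"] == pytest.approx(-1.0)


class TestBalanceFilter:
    @staticmethod
    def _toy(n_x=5, n_y=5):
        markers = pd.DataFrame({
            "marker_id": [f"x{i}" for i in range(n_x)]
            + [f"y{i}" for i in range(n_y)] + ["p0"],
            "chrom": ["chrX"] * n_x + ["chrY"] * n_y + ["chrX"],
            "pos": range(n_x + n_y + 1),
            "region": ["X_FLANK"] * n_x + ["Y_FLANK"] * n_y + ["PAR1"],
        })
        return markers

    def test_all_ratios_zero_pass(self):
        markers = self._toy()
        cols = markers["marker_id"].tolist()
        intensities = pd.DataFrame(
            [[1.0] * len(cols)] * 4, index=list("abcd"), columns=cols
        )
        sex = pd.Series(["M"] * 4, index=list("abcd"))
        assert sex_balance_filter(intensities, markers, sex).all()

    def test_extra_x_male_fails_at_threshold(self):
        """A doubled X-flank dosage exceeds the 0.35 log2-ratio threshold."""
        markers = self._toy()
        cols = markers["marker_id"].tolist()
        rows = [[100.0] * len(cols)] * 9
        extra = [200.0] * 5 + [100.0] * 6  # doubled X flank only
        intensities = pd.DataFrame(rows + [extra],
                                   index=[f"m{i}" for i in range(10)],
                                   columns=cols)
        sex = pd.Series(["M"] * 10, index=intensities.index)
        passes = sex_balance_filter(intensities, markers, sex,
                                    threshold=0.35, pseudocount=0.0)
        assert passes[:9].all() and not passes["m9"]

    def test_par_markers_excluded_from_filter(self):
        markers = self._toy()
        cols = markers["marker_id"].tolist()
        intensities = pd.DataFrame(
            [[1.0] * len(cols)] * 4, index=list("abcd"), columns=cols
        )
        intensities.loc["a", "p0"] = 1e6  # extreme but PAR-tagged
        sex = pd.Series(["M"] * 4, index=list("abcd"))
        assert sex_balance_filter(intensities, markers, sex).all()

    def test_no_flank_markers_rejected(self):
        markers = pd.DataFrame({
            "marker_id": ["p0"], "chrom": ["chrX"], "pos": [1],
            "region": ["PAR1"],
        })
        frame = pd.DataFrame({"p0": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="flank"):
            sex_balance_filter(frame, markers, pd.Series(["M"], index=["a"]))


class TestReferenceBands:
    def test_nearest_rank_band_on_41_values(self):
        """41 distinct male values 1..41 -> central 95% band [2, 40]."""
        males = pd.Series(np.arange(1.0, 42.0), index=[f"m{i}" for i in range(41)])
        females = pd.Series(100.0, index=[f"f{i}" for i in range(45)])
        values = pd.concat([males, females])
        sex = pd.Series(["M"] * 41 + ["F"] * 45, index=values.index)
        bands = build_reference_bands(values, sex)
        assert bands.haploid_band == (2.0, 40.0)
        assert bands.diploid_band == (100.0, 100.0)

    def test_constant_females_give_degenerate_diploid_band(self):
        values = pd.concat([
            pd.Series(-1.0, index=[f"m{i}" for i in range(50)]),
            pd.Series(0.0, index=[f"f{i}" for i in range(50)]),
        ])
        sex = pd.Series(["M"] * 50 + ["F"] * 50, index=values.index)
        bands = build_reference_bands(values, sex)
        assert bands.diploid_band == (0.0, 0.0)
        # deletion band must still be non-empty (zero-noise invariant)
        assert bands.deletion_band[0] < -2.0 < bands.deletion_band[1]

    def test_too_few_references_rejected(self):
        values = pd.concat([
            pd.Series(-1.0, index=[f"m{i}" for i in range(10)]),
            pd.Series(0.0, index=[f"f{i}" for i in range(50)]),
        ])
        sex = pd.Series(["M"] * 10 + ["F"] * 50, index=values.index)
        with pytest.raises(ValueError, match="at least 40"):
            build_reference_bands(values, sex)

    def test_band_ordering_violation_reported_with_endpoints(self):
        with pytest.raises(ValueError, match="not ordered"):
            _bands(haploid=(0.0, 1.0), diploid=(0.5, 2.0), deletion=(-2.0, 0.0))

    def test_gaussian_option(self):
        rng = np.random.default_rng(0)
        values = pd.concat([
            pd.Series(rng.normal(-1, 0.01, 200),
                      index=[f"m{i}" for i in range(200)]),
            pd.Series(rng.normal(0, 0.01, 200),
                      index=[f"f{i}" for i in range(200)]),
        ])
        sex = pd.Series(["M"] * 200 + ["F"] * 200, index=values.index)
        bands = build_reference_bands(values, sex, ci_method="gaussian")
        lo, hi = bands.haploid_band
        assert lo == pytest.approx(-1 - 1.96 * 0.01, abs=5e-3)
        assert hi == pytest.approx(-1 + 1.96 * 0.01, abs=5e-3)


class TestClassification:
    BANDS = _bands(haploid=(-1.1, -0.9), diploid=(-0.1, 0.1),
                   deletion=(-2.5, -1.1))

    @pytest.mark.parametrize("sex,value,expected", [
        ("M", -1.0, "REF"),
        ("M", 0.0, "EPAR"),
        ("M", -2.0, "DEL_HEMI"),
        ("M", -0.5, "UNCLASSIFIED"),
        ("F", 0.0, "REF"),
        ("F", -1.0, "HET_DEL"),
        ("F", -2.0, "HOM_DEL"),
        ("F", 3.0, "UNCLASSIFIED"),
    ])
    def test_band_semantics(self, sex, value, expected):
        calls = classify_samples(
            pd.Series([value], index=["s"]), self.BANDS,
            pd.Series([sex], index=["s"]),
        )
        assert calls.loc["s", "call"] == expected

    def test_balance_failure_overrides(self):
        calls = classify_samples(
            pd.Series([-1.0], index=["s"]), self.BANDS,
            pd.Series(["M"], index=["s"]),
            pd.Series([False], index=["s"]),
        )
        assert calls.loc["s", "call"] == "EXCLUDED_IMBALANCE"

    def test_partition_every_sample_called_once(self, noisy_cohort):
        cohort = noisy_cohort
        calls = DosageScreen().fit_predict(
            cohort.intensities, cohort.sex, cohort.markers
        )
        assert len(calls) == len(cohort.sex)
        assert calls["call"].isin([
            "REF", "EPAR", "DEL_HEMI", "HET_DEL", "HOM_DEL",
            "UNCLASSIFIED", "EXCLUDED_IMBALANCE",
        ]).all()

    def test_male_calls_monotone_in_value(self):
        """Increasing a male's value moves DEL_HEMI -> REF -> EPAR only."""
        order = {"DEL_HEMI": 0, "UNCLASSIFIED": None, "REF": 1, "EPAR": 2}
        values = pd.Series(np.linspace(-3, 1, 400),
                           index=[f"s{i}" for i in range(400)])
        sex = pd.Series("M", index=values.index)
        calls = classify_samples(values, self.BANDS, sex)["call"]
        ranks = [order[c] for c in calls if order[c] is not None]
        assert ranks == sorted(ranks)


class TestIncidence:
    def test_percentages_use_non_excluded_denominator(self):
        calls = pd.DataFrame({
            "sex": ["M"] * 6,
            "call": ["EPAR", "REF", "REF", "REF", "EXCLUDED_IMBALANCE",
                     "DEL_HEMI"],
        }, index=[f"s{i}" for i in range(6)])
        summary = incidence_summary(calls).set_index("call")
        assert summary.loc["EPAR", "denominator"] == 5
        assert summary.loc["EPAR", "percent"] == pytest.approx(20.0)

    def test_zero_carriers_zero_percent(self):
        calls = pd.DataFrame({"sex": ["F"], "call": ["REF"]}, index=["s"])
        summary = incidence_summary(calls).set_index("call")
        assert summary.loc["HET_DEL", "percent"] == 0.0

    def test_rate_percent_rounding_is_presentation_only(self):
        assert rate_percent(1, 3) == pytest.approx(100 / 3)
        assert rate_percent(1, 3, digits=2) == 33.33

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError):
            incidence_summary(pd.DataFrame(columns=["sex", "call"]))


class TestDosageScreenEstimator:
    def test_sklearn_param_interface(self):
        screen = DosageScreen(balance_threshold=0.5)
        params = screen.get_params()
        assert params["balance_threshold"] == 0.5
        screen.set_params(min_reference=41)
        assert screen.min_reference == 41

    def test_predict_before_fit_rejected(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            DosageScreen().predict()

    def test_high_signal_to_noise_has_no_cross_class_confusion(self):
        """At signal/noise >= 6 dosage classes never cross-contaminate.

        Central-95% bands leave ~5% of each class just outside its own
        band (UNCLASSIFIED), so per-class sensitivity is checked at 0.9
        and every definite call must match the truth exactly.
        """
        spec = simdata.CohortSpec(
            n_males=600, n_females=600, freq_epar=0.1, freq_xdel_allele=0.05,
            copy_signal=1.0, noise_sd=1 / 6, seed=17,
        )
        cohort = simdata.simulate_cohort(spec)
        calls = DosageScreen().fit_predict(
            cohort.intensities, cohort.sex, cohort.markers
        )
        merged = calls.join(cohort.truth[["label"]])
        for cls in ("EPAR", "DEL_HEMI", "HET_DEL"):
            truth_cls = merged[merged["label"] == cls]
            if len(truth_cls):
                assert (truth_cls["call"] == cls).mean() >= 0.9
        # definite calls are always the true class
        definite = merged[~merged["call"].isin(
            ["UNCLASSIFIED", "EXCLUDED_IMBALANCE"]
        )]
        assert (definite["call"] == definite["label"]).all()
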