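import numpy as np
import pandas as pd
import pytest

from radonvuln import (
    GeneratorConfig,
    annual_ratio_series,
    assign_strata,
    filter_deaths,
    generate_study,
    loess_smooth,
    median_smoking_split,
    misclassification_sensitivity,
    stratum_summary_table,
)
from radonvuln.trends import HIGHER, LOWER


def make_deaths(rows):
    return pd.DataFrame(
        rows, columns=["unit_id", "health_area_id", "year", "sex", "age", "cause_code"]
    )


class TestFilterDeaths:
    def test_lung_adult_kept_and_flagged(self):
        df = make_deaths([("u1", "h1", 2000, "male", 65, "C34")])
        kept, log = filter_deaths(df)
        assert len(kept) == 1 and kept["lung"].iloc[0]
        assert log["kept"] == 1

    def test_external_causes_dropped_including_v_codes(self):
        df = make_deaths(
            [
                ("u1", "h1", 2000, "male", 40, "V43"),  # transport accident
                ("u1", "h1", 2000, "male", 40, "T75"),
                ("u1", "h1", 2000, "male", 40, "Y10"),
                ("u1", "h1", 2000, "male", 40, "I21"),
            ]
        )
        kept, log = filter_deaths(df)
        assert len(kept) == 1 and not kept["lung"].iloc[0]
        assert log["external_cause"] == 3

    def test_counting_oracle_on_mixed_records(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(85):
            rows.append(("u1", "h1", 2000, "female", int(rng.integers(20, 90)), "J44"))
        for i in range(10):
            rows.append(("u1", "h1", 2000, "female", 50, "X42"))
        for i in range(5):
            rows.append(("u1", "h1", 2000, "female", 10, "I64"))
        kept, _ = filter_deaths(make_deaths(rows))
        assert len(kept) == 85

    def test_malformed_codes_dropped_and_logged(self):
        df = make_deaths(
            [("u1", "h1", 2000, "male", 50, ""), ("u1", "h1", 2000, "male", 50, "C34")]
        )
        kept, log = filter_deaths(df)
        assert len(kept) == 1
        assert log["malformed"] == 1


class TestMedianSmokingSplit:
    def test_three_areas_tie_goes_lower(self):
        s = pd.Series({"a": 0.1, "b": 0.2, "c": 0.3})
        out = median_smoking_split(s)
        assert list(out) == [LOWER, LOWER, HIGHER]

    def test_all_equal_is_all_lower(self):
        out = median_smoking_split(pd.Series({"a": 0.2, "b": 0.2, "c": 0.2}))
        assert (out == LOWER).all()

    def test_83_distinct_areas_give_41_higher(self):
        rng = np.random.default_rng(1)
        vals = rng.permutation(np.linspace(0.05, 0.35, 83))
        out = median_smoking_split(pd.Series(vals, index=[f"h{i}" for i in range(83)]))
        assert (out == HIGHER).sum() == 41

    def test_too_few_or_missing_rejected(self):
        with pytest.raises(ValueError):
            median_smoking_split(pd.Series({"a": 0.1}))
        with pytest.raises(ValueError):
            median_smoking_split(pd.Series({"a": 0.1, "b": np.nan}))


@pytest.fixture()
def toy_stratified():
    maps = pd.DataFrame(
        {
            "unit_id": ["u1", "u2", "u3"],
            "class_200": ["high", "low", "INELIGIBLE"],
            "class_600": ["low", "low", "INELIGIBLE"],
        }
    )
    deaths = make_deaths(
        [
            ("u1", "h1", 2000, "male", 60, "C34"),
            ("u1", "h1", 2000, "female", 70, "I21"),
            ("u2", "h2", 2001, "male", 80, "C34"),
            ("u3", "h1", 2000, "male", 55, "I21"),
        ]
    )
    kept, _ = filter_deaths(deaths)
    smoking = pd.Series({"h1": HIGHER, "h2": LOWER}, name="smoking_class")
    return assign_strata(kept, maps, smoking)


class TestAssignStrata:
    def test_nested_thresholds_can_disagree_per_death(self, toy_stratified):
        strat, _ = toy_stratified
        first = strat.iloc[0]
        assert first["class_200"] == "high" and first["class_600"] == "low"

    def test_ineligible_deaths_counted_in_exclusion_log(self, toy_stratified):
        _, exclusions = toy_stratified
        assert exclusions == {200.0: 1, 600.0: 1}

    def test_unmapped_unit_rejected(self):
        deaths = make_deaths([("zz", "h1", 2000, "male", 60, "C34")])
        kept, _ = filter_deaths(deaths)
        maps = pd.DataFrame({"unit_id": ["u1"], "class_200": ["high"]})
        with pytest.raises(ValueError):
            assign_strata(kept, maps, pd.Series({"h1": HIGHER}))

    def test_stratum_counts_match_hand_tally(self):
        rng = np.random.default_rng(3)
        units = [f"u{i}" for i in range(20)]
        classes = np.where(rng.random(20) < 0.4, "high", "low")
        maps = pd.DataFrame({"unit_id": units, "class_100": classes})
        rows = [
            (units[int(rng.integers(20))], "h1", 2000, "male", 60,
             "C34" if rng.random() < 0.1 else "I21")
            for _ in range(1000)
        ]
        kept, _ = filter_deaths(make_deaths(rows))
        strat, _ = assign_strata(kept, maps, pd.Series({"h1": LOWER}))
        lookup = dict(zip(units, classes))
        hand = sum(lookup[u] == "high" for u in kept["unit_id"])
        assert (strat["class_100"] == "high").sum() == hand
        # any stratification partitions the filtered deaths exactly
        assert (strat["class_100"] == "high").sum() + (
            strat["class_100"] == "low"
        ).sum() == len(kept)


class TestAnnualRatioSeries:
    def test_simple_ratios(self, toy_stratified):
        strat, _ = toy_stratified
        s = annual_ratio_series(strat, 200, "high")
        assert s.loc[s["year"] == 2000, "ratio"].iloc[0] == pytest.approx(0.5)

    def test_zero_lung_year_is_zero_and_empty_year_is_missing(self):
        maps = pd.DataFrame({"unit_id": ["u1"], "class_100": ["high"]})
        deaths = make_deaths(
            [("u1", "h1", 2000, "male", 60, "I21"), ("u1", "h1", 2002, "male", 61, "C34")]
        )
        kept, _ = filter_deaths(deaths)
        strat, _ = assign_strata(kept, maps, pd.Series({"h1": LOWER}))
        s = annual_ratio_series(strat, 100, "high", years=[2000, 2001, 2002])
        assert s["ratio"].tolist()[0] == 0.0
        assert np.isnan(s["ratio"].tolist()[1])
        assert s["ratio"].tolist()[2] == 1.0

    def test_generated_lung_fractions_recovered_in_series(self):
        """Pooled annual ratios recover the generating lung fractions
        (~0.10 high / 0.07 low) within 2 Monte-Carlo standard errors."""
        # odds scale: 0.07 base, OR such that the high stratum sits at 0.10
        orr = (0.10 / 0.90) / (0.07 / 0.93)
        cfg = GeneratorConfig(
            n_parent_areas=300, lung_base_rate=0.07, lung_effect_radon=orr,
            lung_effect_smoking=1.0, sex_effect=1.0, crude_death_rate=0.02,
            external_cause_fraction=0.0, under20_fraction=0.0, seed=23,
        )
        study = generate_study(cfg)
        kept, _ = filter_deaths(study.deaths)
        truth_map = pd.DataFrame(
            {
                "unit_id": study.truth["unit_id"],
                "class_200": np.where(study.truth["true_high"], "high", "low"),
            }
        )
        smoking = median_smoking_split(
            study.health_areas.set_index("health_area_id")["smoking_prevalence"]
        )
        strat, _ = assign_strata(kept, truth_map, smoking)
        for cls, target in (("high", 0.10), ("low", 0.07)):
            s = annual_ratio_series(strat, 200, cls)
            lung, nat = s["lung_deaths"].sum(), s["natural_deaths"].sum()
            se = np.sqrt(target * (1 - target) / nat)
            assert lung / nat == pytest.approx(target, abs=2 * se)


def oracle_loess(x, y, span, degree):
    """Brute-force LOESS: explicit tricube WLS at every fit point."""
    import math

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    q = max(degree + 1, min(n, math.ceil(span * n)))
    out = []
    for x0 in x:
        d = np.abs(x - x0)
        dmax = np.sort(d)[q - 1]
        if dmax == 0:
            out.append(y[d == 0].mean())
            continue
        w = np.where(d < dmax, (1 - (d / dmax) ** 3) ** 3, 0.0)
        if (w > 0).sum() < degree + 1:
            w = (d <= dmax).astype(float)
        W = np.diag(w)
        V = np.vander(x - x0, degree + 1, increasing=True)
        beta = np.linalg.pinv(V.T @ W @ V) @ V.T @ W @ y
        out.append(beta[0])
    return np.array(out)


class TestLoess:
    def test_reproduces_exact_line(self):
        x = np.arange(1998, 2014, dtype=float)
        y = 0.002 * (x - 2000) + 0.07
        for span in (0.3, 0.75, 1.0):
            fit = loess_smooth(x, y, span=span, degree=1)
            assert np.abs(fit - y).max() < 1e-9

    def test_constant_series_is_constant(self):
        x = np.arange(16, dtype=float)
        fit = loess_smooth(x, np.full(16, 0.08), span=0.75, degree=2)
        assert np.abs(fit - 0.08).max() < 1e-12

    def test_quadratic_with_full_span_matches_global_fit(self):
        x = np.arange(16, dtype=float)
        y = 0.001 * (x - 8) ** 2 - 0.01 * x + 0.2
        fit = loess_smooth(x, y, span=1.0, degree=2)
        assert np.abs(fit - y).max() < 1e-9  # exact model: WLS reproduces it

    def test_matches_bruteforce_oracle_on_random_series(self):
        rng = np.random.default_rng(8)
        for _ in range(60):
            n = int(rng.integers(8, 25))
            x = np.sort(rng.choice(np.arange(1990, 2030), n, replace=False)).astype(float)
            y = rng.normal(0.08, 0.02, n)
            span = float(rng.uniform(0.3, 1.0))
            degree = int(rng.integers(1, 3))
            fit = loess_smooth(x, y, span=span, degree=degree)
            ref = oracle_loess(x, y, span, degree)
            assert np.abs(fit - ref).max() < 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            loess_smooth([1, 2, 3], [1.0, 2.0, 1.5], degree=2)


class TestStratumSummaryTable:
    def _stratified(self):
        # counts engineered to print 22.9% / 26.2% (higher smoking) and
        # 3.2% / 3.7% (high radon at 500) of the natural / lung totals
        n_total, n_lung = 10_000, 1_000
        smoking = np.array([HIGHER] * 2290 + [LOWER] * (n_total - 2290))
        lung = np.zeros(n_total, dtype=bool)
        lung[:262] = True          # higher-smoking lung deaths
        lung[2290:2290 + 738] = True
        c500 = np.array(["low"] * n_total, dtype=object)
        c500[:37] = "high"         # 37 lung deaths in high-radon units
        c500[2290 + 738:2290 + 738 + 283] = "high"  # 320 high-radon natural total
        df = pd.DataFrame({"smoking_class": smoking, "lung": lung, "class_500": c500})
        assert int(lung.sum()) == n_lung
        return df

    def test_printed_percentage_ratios(self):
        table = stratum_summary_table(self._stratified(), [500])
        smoke = table[table["stratum"] == "higher_smoking"].iloc[0]
        assert smoke["pct_natural"] == 22.9 and smoke["pct_lung"] == 26.2
        assert smoke["ratio_of_percentages"] == pytest.approx(1.14)
        radon = table[table["stratum"] == "high_radon"].iloc[0]
        assert radon["pct_natural"] == 3.2 and radon["pct_lung"] == 3.7
        assert radon["ratio_of_percentages"] == pytest.approx(1.16)

    def test_unrounded_flag_uses_raw_counts(self):
        table = stratum_summary_table(self._stratified(), [500], from_rounded=False)
        radon = table[table["stratum"] == "high_radon"].iloc[0]
        assert radon["ratio_of_percentages"] == pytest.approx(
            round((37 / 1000) / (320 / 10000), 2)
        )

    def test_identical_percentages_give_unity(self):
        df = pd.DataFrame(
            {
                "smoking_class": [HIGHER, HIGHER, LOWER, LOWER],
                "lung": [True, False, True, False],
                "class_200": ["high", "high", "low", "low"],
            }
        )
        table = stratum_summary_table(df, [200])
        assert table[table["stratum"] == "higher_smoking"].iloc[0][
            "ratio_of_percentages"
        ] == pytest.approx(1.0)


class TestMisclassificationSensitivity:
    def test_identity_when_no_misclassification(self):
        rh, rl = misclassification_sensitivity(100, 900, 70, 930, 0.0, 0.0)
        assert rh == pytest.approx(0.1)
        assert rl == pytest.approx(0.07)

    def test_direct_count_arithmetic(self):
        rh, rl = misclassification_sensitivity(100, 900, 70, 930, 0.9, 0.95)
        assert rh == pytest.approx(10 / 55)
        assert rl == pytest.approx(160 / 1945)

    def test_totals_conserved_across_groups(self):
        lh, oh, ll, ol = 120, 880, 60, 940
        f_l, f_o = 0.4, 0.6
        rh, rl = misclassification_sensitivity(lh, oh, ll, ol, f_l, f_o)
        lh2, oh2 = lh * (1 - f_l), oh * (1 - f_o)
        ll2, ol2 = ll + lh * f_l, ol + oh * f_o
        assert lh2 + ll2 == pytest.approx(lh + ll)
        assert oh2 + ol2 == pytest.approx(oh + ol)
        assert rh == pytest.approx(lh2 / (lh2 + oh2))
        assert rl == pytest.approx(ll2 / (ll2 + ol2))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            misclassification_sensitivity(0, 0, 10, 10, 0.5, 0.5)
        with pytest.raises(ValueError):
            misclassification_sensitivity(1, 1, 1, 1, 1.5, 0.0)
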