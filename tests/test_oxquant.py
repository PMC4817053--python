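"""XIC extraction, AUC integration, ratios, fold changes, summaries."""

import numpy as np
import pandas as pd
import pytest

from proteox.chem import IonSpecies, apply_modification, parse_peptide
from proteox.oxquant import (
    XIC,
    auto_peak_window,
    default_targets,
    extract_xic,
    fold_change_vs_control,
    global_oxidation_ratio,
    integrate_auc,
    normalize_modbase,
    quantify_site,
    site_oxidation_ratio,
)
from proteox.spectra import Scan, SpectralDataset
from proteox.synth import OxidationPairConfig, simulate_lcms_oxidation


def _pair():
    pep = parse_peptide("VYEAGMK")
    return IonSpecies(apply_modification(pep, "ox", 6), "H", 2), IonSpecies(pep, "H", 2)


def _run(cfg_kwargs=None, odds=0.5, seed=0, group="g"):
    ox, nonox = _pair()
    cfg = OxidationPairConfig(
        nonox=nonox, ox=ox, replicates=1, run_length_min=4.0, nonox_center_min=2.0,
        ox_center_min=1.7, scan_interval_s=2.0, seed=seed, **(cfg_kwargs or {}),
    )
    runs, truth = simulate_lcms_oxidation(cfg, {group: odds})
    return cfg, runs[group][0], truth


class TestExtractXIC:
    def test_peak_at_configured_elution_center(self):
        cfg, run, _ = _run()
        xic = extract_xic(run, default_targets(cfg.nonox), 5.0)
        apex_time = xic.times[np.argmax(xic.intensities)]
        assert apex_time == pytest.approx(2.0, abs=0.1)

    def test_degenerate_tolerance_recovers_nothing(self):
        cfg, run, _ = _run()
        xic = extract_xic(run, default_targets(cfg.nonox), 1e-9)
        assert xic.intensities.max() <= 1e-6 * cfg.base_abundance

    def test_global_intensity_scaling(self):
        """Two runs differing only by a global scale give XICs in that ratio."""
        ox, nonox = _pair()
        xics = []
        for scale in (1.0, 3.0):
            cfg = OxidationPairConfig(
                nonox=nonox, ox=ox, replicates=1, run_length_min=4.0,
                nonox_center_min=2.0, ox_center_min=1.7, scan_interval_s=2.0,
                base_abundance=1e6 * scale, noise_floor=0.0, n_noise_peaks=0, seed=4,
            )
            runs, _ = simulate_lcms_oxidation(cfg, {"g": 0.2})
            xics.append(extract_xic(runs["g"][0], default_targets(nonox), 5.0))
        np.testing.assert_allclose(xics[1].intensities, 3.0 * xics[0].intensities, rtol=1e-9)

    def test_empty_run_gives_empty_xic(self):
        xic = extract_xic(SpectralDataset(()), [500.0], 5.0)
        assert len(xic.times) == 0
        assert integrate_auc(xic) == 0.0

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            extract_xic(SpectralDataset(()), [500.0], 0.0)


class TestIntegrateAUC:
    def test_rectangular_pulse(self):
        t = np.linspace(0, 10, 101)
        i = np.where((t >= 2) & (t <= 5), 1.0, 0.0)
        xic = XIC(t, i, (500.0,), 5.0)
        assert integrate_auc(xic, (2.0, 5.0)) == pytest.approx(3.0, rel=1e-6)

    def test_gaussian_closed_form(self):
        amp, sigma, center = 7.0, 0.3, 5.0
        t = np.linspace(0, 10, 2001)
        i = amp * np.exp(-0.5 * ((t - center) / sigma) ** 2)
        xic = XIC(t, i, (500.0,), 5.0)
        assert integrate_auc(xic) == pytest.approx(amp * sigma * np.sqrt(2 * np.pi), rel=0.01)

    def test_auto_window_brackets_apex(self):
        t = np.linspace(0, 10, 501)
        i = np.exp(-0.5 * ((t - 4.0) / 0.2) ** 2)
        w = auto_peak_window(XIC(t, i, (500.0,), 5.0))
        assert w[0] < 4.0 < w[1]

    def test_linearity_over_dilution_ladder(self):
        """AUC is proportional to injected abundance across 100x dilution."""
        ox, nonox = _pair()
        abundances = [1e4, 1e5, 1e6]
        aucs = []
        for a in abundances:
            cfg = OxidationPairConfig(
                nonox=nonox, ox=ox, replicates=1, run_length_min=4.0,
                nonox_center_min=2.0, ox_center_min=1.7, scan_interval_s=2.0,
                base_abundance=a, noise_floor=0.0, n_noise_peaks=0,
                intensity_cv=0.02, seed=8,
            )
            runs, _ = simulate_lcms_oxidation(cfg, {"g": 0.0})
            aucs.append(integrate_auc(extract_xic(runs["g"][0], default_targets(nonox), 5.0)))
        r = np.corrcoef(abundances, aucs)[0, 1]
        assert r**2 > 0.99

    def test_bad_window_rejected(self):
        xic = XIC(np.array([0.0, 1.0]), np.array([1.0, 1.0]), (500.0,), 5.0)
        with pytest.raises(ValueError):
            integrate_auc(xic, (2.0, 1.0))


class TestSiteRatio:
    def test_recovers_injected_odds(self):
        cfg, run, truth = _run(odds=0.5, seed=2)
        ratio = site_oxidation_ratio(run, cfg.ox, cfg.nonox)
        assert ratio == pytest.approx(truth.odds_injected.iloc[0], rel=0.05)

    def test_zero_oxidized_abundance(self):
        cfg, run, _ = _run(odds=0.0, seed=3)
        assert site_oxidation_ratio(run, cfg.ox, cfg.nonox) == pytest.approx(0.0, abs=0.01)

    def test_reciprocity_under_swap(self):
        cfg, run, _ = _run(odds=0.5, seed=4, cfg_kwargs={"noise_floor": 0.0, "n_noise_peaks": 0})
        r = site_oxidation_ratio(run, cfg.ox, cfg.nonox)
        r_inv = site_oxidation_ratio(run, cfg.nonox, cfg.ox)
        assert r * r_inv == pytest.approx(1.0, rel=1e-9)

    def test_zero_denominator_flags_nan(self):
        scan = Scan(0.0, np.array([100.0]), np.array([5.0]))
        scan2 = Scan(1.0, np.array([100.0]), np.array([5.0]))
        run = SpectralDataset((scan, scan2))
        cfg, _, _ = _run()
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(site_oxidation_ratio(run, cfg.ox, cfg.nonox))


class TestFoldChange:
    def test_identical_groups(self):
        g = [0.30, 0.35, 0.32]
        fold, p = fold_change_vs_control(g, g)
        assert fold == 1.0
        assert p == pytest.approx(1.0)

    def test_matches_textbook_t_formula(self):
        """Homoscedastic two-sample t on a hand-computed 3v3 example."""
        import math

        from scipy import stats as sstats

        a, b = [0.40, 0.45, 0.50], [0.10, 0.12, 0.14]
        fold, p = fold_change_vs_control(a, b)
        na, nb = 3, 3
        sa2 = sum((x - np.mean(a)) ** 2 for x in a) / (na - 1)
        sb2 = sum((x - np.mean(b)) ** 2 for x in b) / (nb - 1)
        sp = math.sqrt(((na - 1) * sa2 + (nb - 1) * sb2) / (na + nb - 2))
        t = (np.mean(a) - np.mean(b)) / (sp * math.sqrt(1 / na + 1 / nb))
        p_expected = 2 * sstats.t.sf(abs(t), na + nb - 2)
        assert p == pytest.approx(p_expected, abs=1e-10)
        assert fold == pytest.approx(np.mean(a) / np.mean(b), rel=1e-12)

    def test_degenerate_zero_variance(self):
        with pytest.warns(UserWarning, match="machine epsilon"):
            fold, p = fold_change_vs_control([0.4, 0.4], [0.2, 0.2])
        assert fold == pytest.approx(2.0)
        assert p == 0.0

    def test_nan_replicates_excluded(self):
        with pytest.warns(UserWarning, match="NaN"):
            fold, _ = fold_change_vs_control([0.4, np.nan, 0.4], [0.2, 0.2])
        assert fold == pytest.approx(2.0)

    def test_single_replicate_no_p(self):
        fold, p = fold_change_vs_control([0.4], [0.2])
        assert fold == pytest.approx(2.0)
        assert np.isnan(p)


class TestEndToEnd:
    def test_fold_recovery_against_generator(self):
        """Treated/control odds 0.41/0.01: recovered fold within 5% of truth."""
        ox, nonox = _pair()
        cfg = OxidationPairConfig(nonox=nonox, ox=ox, replicates=3, seed=17)
        runs, truth = simulate_lcms_oxidation(cfg, {"control": 0.01, "treated": 0.41})
        res = quantify_site(runs, ox, nonox, "control")
        tmeans = truth.groupby("group")["odds_injected"].mean()
        truth_fold = tmeans["treated"] / tmeans["control"]
        assert res.fold_changes["treated"] == pytest.approx(truth_fold, rel=0.05)
        assert res.p_values["treated"] < 0.05

    def test_unbiased_over_odds_grid(self):
        """Recovery is unbiased within Monte-Carlo error over an odds grid."""
        ox, nonox = _pair()
        for odds in (0.05, 0.2, 1.0):
            cfg = OxidationPairConfig(
                nonox=nonox, ox=ox, replicates=3, run_length_min=4.0,
                nonox_center_min=2.0, ox_center_min=1.7, scan_interval_s=2.0,
                seed=int(odds * 100),
            )
            runs, truth = simulate_lcms_oxidation(cfg, {"g": odds})
            res = quantify_site(runs, ox, nonox, "g")
            assert res.group_means["g"] == pytest.approx(
                truth.odds_injected.mean(), rel=0.06
            )


class TestSummaries:
    def test_global_ratio_arithmetic(self):
        table = pd.DataFrame(
            {"oxidized": [True, True, False, False], "intensity": [10.0, 30.0, 20.0, 20.0]}
        )
        assert global_oxidation_ratio(table) == pytest.approx(1.0)

    def test_global_ratio_scale_invariant(self):
        table = pd.DataFrame({"oxidized": [True, False], "intensity": [3.0, 6.0]})
        scaled = table.assign(intensity=table.intensity * 7.3)
        assert global_oxidation_ratio(table) == pytest.approx(global_oxidation_ratio(scaled))

    def test_global_ratio_no_nonoxidized(self):
        table = pd.DataFrame({"oxidized": [True], "intensity": [1.0]})
        with pytest.warns(UserWarning):
            assert np.isnan(global_oxidation_ratio(table))

    def test_normalize_modbase(self):
        out = normalize_modbase({"M95": 0.8, "M64": 0.2})
        assert out == {"M95": 1.0, "M64": pytest.approx(0.25)}
        assert normalize_modbase({"only": 0.3}) == {"only": 1.0}

    def test_normalize_modbase_order_invariant(self):
        a = normalize_modbase({"x": 0.1, "y": 0.4, "z": 0.2})
        b = normalize_modbase({"z": 0.2, "x": 0.1, "y": 0.4})
        assert a == b

    def test_normalize_modbase_all_zero(self):
        with pytest.warns(UserWarning):
            assert normalize_modbase({"a": 0.0, "b": 0.0}) == {"a": 0.0, "b": 0.0}
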