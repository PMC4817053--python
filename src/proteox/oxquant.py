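"""Site-specific oxidation quantitation from extracted ion chromatograms.

An XIC is reconstructed per run by summing, scan by scan, all centroid
intensities within a ppm tolerance (default 5 ppm) of the target m/z values
— by default the monoisotopic and A+1 peaks of the ion species.  Peak areas
(trapezoidal AUC over an auto-detected or explicit elution window) give the
oxidized:non-oxidized abundance ratio per replicate; group-mean ratios give
fold changes versus the control group, with a two-tailed homoscedastic
two-sample t-test across replicates.

Also provides the run-level summaries: the global oxidized/non-oxidized
intensity ratio over a peptide table, and per-site mod/base values
normalized to the largest site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem import IonSpecies, adduct_mz
from .spectra import SpectralDataset

__all__ = [
    "XIC",
    "XICQuantResult",
    "default_targets",
    "extract_xic",
    "integrate_auc",
    "auto_peak_window",
    "site_oxidation_ratio",
    "fold_change_vs_control",
    "quantify_site",
    "global_oxidation_ratio",
    "normalize_modbase",
]

DEFAULT_TOLERANCE_PPM = 5.0


@dataclass(frozen=True)
class XIC:
    """An extracted ion chromatogram: summed matched intensity per scan."""

    times: np.ndarray  # minutes
    intensities: np.ndarray
    targets: tuple[float, ...]
    tolerance_ppm: float

    def __post_init__(self):
        t = np.asarray(self.times, float)
        i = np.asarray(self.intensities, float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", i)
        if len(t) != len(i):
            raise ValueError("times and intensities differ in length")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(i < 0):
            raise ValueError("intensities must be >= 0")


def default_targets(species: IonSpecies, isotopes: Sequence[int] = (0, 1)) -> tuple[float, ...]:
    """Monoisotopic and A+1 m/z of the species (the default XIC targets)."""
    return tuple(
        adduct_mz(species.peptide, species.adduct, species.charge, iso) for iso in isotopes
    )


def extract_xic(
    run: SpectralDataset,
    targets: Sequence[float],
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
) -> XIC:
    """Sum centroid intensities within +-tolerance_ppm of any target, per scan."""
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be > 0")
    targets = tuple(float(t) for t in targets)
    times, totals = [], []
    for scan in run:
        total = 0.0
        for target in targets:
            half = target * tolerance_ppm * 1e-6
            lo = np.searchsorted(scan.mz, target - half, side="left")
            hi = np.searchsorted(scan.mz, target + half, side="right")
            total += float(scan.intensity[lo:hi].sum())
        times.append(scan.time_min)
        totals.append(total)
    return XIC(np.asarray(times), np.asarray(totals), targets, tolerance_ppm)


def auto_peak_window(xic: XIC, rel_threshold: float = 0.01) -> tuple[float, float]:
    """Elution window around the XIC apex: extend in both directions until
    intensity decays below `rel_threshold` of the apex."""
    inten = xic.intensities
    if len(inten) == 0 or inten.max() <= 0:
        return (float(xic.times[0]), float(xic.times[-1])) if len(inten) else (0.0, 0.0)
    apex = int(np.argmax(inten))
    cut = rel_threshold * inten[apex]
    lo = apex
    while lo > 0 and inten[lo - 1] >= cut:
        lo -= 1
    hi = apex
    while hi < len(inten) - 1 and inten[hi + 1] >= cut:
        hi += 1
    return float(xic.times[lo]), float(xic.times[hi])


def integrate_auc(xic: XIC, window: tuple[float, float] | None = None) -> float:
    """Trapezoidal area of the XIC over the window (auto-detected if None)."""
    if len(xic.times) == 0:
        return 0.0
    if window is None:
        window = auto_peak_window(xic)
    t0, t1 = window
    if t0 >= t1:
        raise ValueError("window must satisfy t0 < t1")
    mask = (xic.times >= t0) & (xic.times <= t1)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(xic.intensities[mask], xic.times[mask]))


def site_oxidation_ratio(
    run: SpectralDataset,
    oxidized: IonSpecies,
    nonoxidized: IonSpecies,
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
    window_ox: tuple[float, float] | None = None,
    window_nonox: tuple[float, float] | None = None,
) -> float:
    """AUC(oxidized)/AUC(non-oxidized) for one run, both isotope targets each.

    A zero non-oxidized AUC yields NaN with a warning (the replicate is
    excluded from group means downstream), never an exception.
    """
    auc_ox = integrate_auc(extract_xic(run, default_targets(oxidized), tolerance_ppm), window_ox)
    auc_nonox = integrate_auc(
        extract_xic(run, default_targets(nonoxidized), tolerance_ppm), window_nonox
    )
    if auc_nonox <= 0:
        warnings.warn("non-oxidized AUC is zero; ratio undefined for this replicate")
        return float("nan")
    return auc_ox / auc_nonox


def fold_change_vs_control(
    group_ratios: Sequence[float], control_ratios: Sequence[float]
) -> tuple[float, float]:
    """Fold change of group-mean ratio over control-mean ratio, with the
    two-tailed homoscedastic two-sample t-test p-value on per-replicate ratios.

    NaN replicates (undefined ratios) are excluded with a warning.  With
    fewer than 2 replicates in either group the p-value is NaN.  Two
    zero-variance groups with different means give p = 0 (flagged).
    """
    g = np.asarray(group_ratios, float)
    c = np.asarray(control_ratios, float)
    if np.isnan(g).any() or np.isnan(c).any():
        warnings.warn("excluding undefined (NaN) replicate ratios")
        g, c = g[~np.isnan(g)], c[~np.isnan(c)]
    if len(g) < 1 or len(c) < 1:
        raise ValueError("need at least one defined replicate per group")
    if c.mean() == 0:
        warnings.warn("control mean ratio is zero; fold change undefined")
        fold = float("nan")
    else:
        fold = float(g.mean() / c.mean())
    if len(g) < 2 or len(c) < 2:
        return fold, float("nan")
    if np.allclose(g.var(ddof=1), 0) and np.allclose(c.var(ddof=1), 0):
        if np.isclose(g.mean(), c.mean()):
            return fold, 1.0
        warnings.warn("both groups have zero variance with different means; p below machine epsilon")
        return fold, 0.0
    p = float(stats.ttest_ind(g, c, equal_var=True).pvalue)
    return fold, p


@dataclass(frozen=True)
class XICQuantResult:
    """Per-site quantitation: replicate AUCs/ratios, group means, fold, p."""

    site: str
    per_replicate: pd.DataFrame  # group, replicate, auc_ox, auc_nonox, ratio
    group_means: dict[str, float]
    control_group: str
    fold_changes: dict[str, float]  # group -> fold vs control
    p_values: dict[str, float]


def quantify_site(
    runs_by_group: Mapping[str, Sequence[SpectralDataset]],
    oxidized: IonSpecies,
    nonoxidized: IonSpecies,
    control_group: str,
    site: str = "",
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
) -> XICQuantResult:
    """Full per-site workflow over replicated treatment groups."""
    if control_group not in runs_by_group:
        raise KeyError(f"control group {control_group!r} not among {sorted(runs_by_group)}")
    rows = []
    ratios: dict[str, list[float]] = {}
    for group, runs in runs_by_group.items():
        ratios[group] = []
        for rep, run in enumerate(runs):
            xic_ox = extract_xic(run, default_targets(oxidized), tolerance_ppm)
            xic_nonox = extract_xic(run, default_targets(nonoxidized), tolerance_ppm)
            auc_ox = integrate_auc(xic_ox)
            auc_nonox = integrate_auc(xic_nonox)
            ratio = auc_ox / auc_nonox if auc_nonox > 0 else float("nan")
            rows.append(
                {"group": group, "replicate": rep, "auc_ox": auc_ox,
                 "auc_nonox": auc_nonox, "ratio": ratio}
            )
            ratios[group].append(ratio)
    means = {g: float(np.nanmean(r)) if len(r) else float("nan") for g, r in ratios.items()}
    folds, pvals = {}, {}
    for group in runs_by_group:
        if group == control_group:
            continue
        fold, p = fold_change_vs_control(ratios[group], ratios[control_group])
        folds[group] = fold
        pvals[group] = p
    return XICQuantResult(site, pd.DataFrame(rows), means, control_group, folds, pvals)


def global_oxidation_ratio(peptide_table: pd.DataFrame) -> float:
    """Sum of oxidized-peptide intensities over sum of non-oxidized ones.

    Expects columns ``oxidized`` (bool) and ``intensity``.
    """
    for col in ("oxidized", "intensity"):
        if col not in peptide_table:
            raise KeyError(f"peptide table lacks required column {col!r}")
    ox = peptide_table.loc[peptide_table.oxidized, "intensity"].sum()
    nonox = peptide_table.loc[~peptide_table.oxidized.astype(bool), "intensity"].sum()
    if nonox <= 0:
        warnings.warn("no non-oxidized intensity; global ratio undefined")
        return float("nan")
    return float(ox / nonox)


def normalize_modbase(values: Mapping[str, float]) -> dict[str, float]:
    """Divide every per-site mod/base value by the largest one (max -> 1.0)."""
    if not values:
        raise ValueError("empty mod/base map")
    if any(v < 0 for v in values.values()):
        raise ValueError("mod/base values must be >= 0")
    top = max(values.values())
    if top == 0:
        warnings.warn("all mod/base values are zero; returning zeros")
        return {k: 0.0 for k in values}
    return {k: v / top for k, v in values.items()}
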