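"""Synthetic-data generators with recorded ground truth.

Every input the analysis stages consume can be generated here with known
truth: LC-MS runs holding oxidized/non-oxidized peptide elution-peak pairs
at controlled abundance odds, direct-infusion time courses with first-order
dephosphorylation and H+/Na+/K+ adduct structure, per-residue Gaussian
conformational clouds with controlled mean displacement, and Beer-Lambert
absorbance progress curves driven by Michaelis-Menten kinetics with
substrate depletion.

All generators are seeded and bit-reproducible, and each returns a
ground-truth table sufficient to predict every downstream statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import IonSpecies, adduct_mz, apply_modification, parse_peptide
from .ensembles import ConformationalEnsemble
from .kinetics import path_length
from .spectra import Scan, SpectralDataset

__all__ = [
    "LCMSSpeciesSignal",
    "LCMSSimConfig",
    "simulate_lcms_run",
    "OxidationPairConfig",
    "simulate_lcms_oxidation",
    "InfusionSimConfig",
    "simulate_infusion_timecourse",
    "substrate_peak_table",
    "EnsembleSimConfig",
    "simulate_ensembles",
    "ProgressCurveSimConfig",
    "simulate_pnpp_progress",
    "SUBSTRATE",
    "PHOSPHO_SUBSTRATE",
]

# the phosphohistidine phosphatase substrate peptide and its phospho form
SUBSTRATE = parse_peptide("Suc-AHPF-pNA")
PHOSPHO_SUBSTRATE = apply_modification(SUBSTRATE, "phospho", 2)


# --- LC-MS runs -------------------------------------------------------------


@dataclass(frozen=True)
class LCMSSpeciesSignal:
    """One eluting ion species: abundance is the total ion count injected
    (the area of the noise-free monoisotopic elution profile)."""

    species: IonSpecies
    abundance: float
    elution_center_min: float
    elution_width_min: float  # Gaussian sigma

    def __post_init__(self):
        if self.elution_width_min <= 0:
            raise ValueError("elution width must be > 0")


@dataclass(frozen=True)
class LCMSSimConfig:
    species: tuple[LCMSSpeciesSignal, ...]
    ppm_error_sd: float = 1.5
    noise_floor: float = 50.0
    intensity_cv: float = 0.05
    scan_interval_s: float = 1.0
    run_length_min: float = 20.0
    a1_fraction: float = 0.4  # A+1 intensity relative to monoisotopic
    n_noise_peaks: int = 5
    mz_range: tuple[float, float] = (400.0, 900.0)
    seed: int = 0

    def __post_init__(self):
        if self.ppm_error_sd < 0:
            raise ValueError("ppm_error_sd must be >= 0")


def simulate_lcms_run(config: LCMSSimConfig, rng: np.random.Generator | None = None) -> SpectralDataset:
    """One centroided LC-MS run: Gaussian elution profiles at the species'
    monoisotopic and A+1 m/z, ppm-level mass jitter, CV-scaled intensity
    noise, and sparse background centroids above the noise floor."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times = np.arange(0.0, config.run_length_min * 60.0 + 1e-9, config.scan_interval_s) / 60.0
    scans = []
    for t in times:
        mzs: list[float] = []
        inten: list[float] = []
        for sig in config.species:
            sp = sig.species
            # Gaussian profile normalized so its time-integral (in minutes)
            # equals `abundance` for the monoisotopic trace
            amp = sig.abundance / (sig.elution_width_min * np.sqrt(2 * np.pi))
            profile = amp * np.exp(-0.5 * ((t - sig.elution_center_min) / sig.elution_width_min) ** 2)
            for iso, frac in ((0, 1.0), (1, config.a1_fraction)):
                base = profile * frac
                mz0 = adduct_mz(sp.peptide, sp.adduct, sp.charge, iso)
                mz = mz0 * (1.0 + rng.normal(0.0, config.ppm_error_sd) * 1e-6)
                i = base * (1.0 + rng.normal(0.0, config.intensity_cv))
                if i > config.noise_floor:
                    mzs.append(mz)
                    inten.append(i)
        for _ in range(config.n_noise_peaks):
            mzs.append(rng.uniform(*config.mz_range))
            inten.append(config.noise_floor * rng.exponential())
        order = np.argsort(mzs)
        scans.append(Scan(float(t), np.asarray(mzs)[order], np.asarray(inten)[order]))
    return SpectralDataset(tuple(scans))


@dataclass(frozen=True)
class OxidationPairConfig:
    """Replicated treated/control runs for one oxidized/non-oxidized peptide pair.

    The oxidized species' injected abundance is ``base_abundance`` times the
    group's oxidation odds; the oxidized form elutes slightly earlier, as
    sulfoxides do on reversed phase.
    """

    nonox: IonSpecies
    ox: IonSpecies
    base_abundance: float = 1.0e6
    nonox_center_min: float = 10.0
    ox_center_min: float = 9.7
    elution_width_min: float = 0.1
    replicates: int = 3
    replicate_odds_cv: float = 0.02  # biological spread of the true odds across replicates
    ppm_error_sd: float = 1.5
    noise_floor: float = 50.0
    intensity_cv: float = 0.05
    scan_interval_s: float = 1.0
    run_length_min: float = 20.0
    a1_fraction: float = 0.4
    n_noise_peaks: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def simulate_lcms_oxidation(
    config: OxidationPairConfig, ox_odds_by_group: Mapping[str, float]
) -> tuple[dict[str, list[SpectralDataset]], pd.DataFrame]:
    """Simulate replicated LC-MS runs per treatment group.

    ``ox_odds_by_group`` maps each group label to its oxidized:non-oxidized
    abundance odds.  Returns the runs plus a ground-truth table with the
    exact injected odds per replicate (jittered across replicates by
    ``replicate_odds_cv``) and an overlap warning flag raised when any
    oxidized/non-oxidized m/z targets sit closer than 3x the ppm error.
    """
    for g, odds in ox_odds_by_group.items():
        if odds < 0:
            raise ValueError(f"odds for group {g!r} must be >= 0")
    rng = np.random.default_rng(config.seed)
    targets = [
        adduct_mz(s.peptide, s.adduct, s.charge, iso)
        for s in (config.nonox, config.ox)
        for iso in (0, 1)
    ]
    min_sep_ppm = min(abs(a - b) / a * 1e6 for a in targets[:2] for b in targets[2:])
    overlap = bool(min_sep_ppm < 3.0 * config.ppm_error_sd)

    datasets: dict[str, list[SpectralDataset]] = {}
    rows = []
    for group, odds in ox_odds_by_group.items():
        runs = []
        for rep in range(config.replicates):
            realized = odds * (1.0 + rng.normal(0.0, config.replicate_odds_cv)) if odds > 0 else 0.0
            realized = max(realized, 0.0)
            run_cfg = LCMSSimConfig(
                species=(
                    LCMSSpeciesSignal(
                        config.nonox, config.base_abundance,
                        config.nonox_center_min, config.elution_width_min,
                    ),
                    LCMSSpeciesSignal(
                        config.ox, config.base_abundance * realized,
                        config.ox_center_min, config.elution_width_min,
                    ),
                ),
                ppm_error_sd=config.ppm_error_sd,
                noise_floor=config.noise_floor,
                intensity_cv=config.intensity_cv,
                scan_interval_s=config.scan_interval_s,
                run_length_min=config.run_length_min,
                a1_fraction=config.a1_fraction,
                n_noise_peaks=config.n_noise_peaks,
            )
            runs.append(simulate_lcms_run(run_cfg, rng))
            rows.append(
                {"group": group, "replicate": rep, "odds_injected": realized,
                 "overlap_warning": overlap}
            )
        datasets[group] = runs
    return datasets, pd.DataFrame(rows)


# --- direct-infusion time courses -------------------------------------------


@dataclass(frozen=True)
class InfusionSimConfig:
    """Direct-infusion time course of the substrate dephosphorylation assay.

    The phospho fraction decays as f(t) = f0 * exp(-k_dephos * t); the
    dephosphorylation is pseudo-first-order (substrate, 2.4 mM, vastly
    exceeds the 0.37 uM enzyme).  Each scan holds six peaks — the H+/Na+/K+
    adducts of the non-phosphorylated (m/z 691/713/729) and phosphorylated
    (771/793/809) substrate.  ``source_loss_fraction`` of each phosphopeptide
    intensity is transferred to its non-phospho counterpart in every scan
    (ESI-source phosphate loss).  Optional per-adduct rate multipliers model
    slower conversion of the Na/K adduct pools.
    """

    initial_phospho_fraction: float = 0.375
    k_dephos: float = 0.0  # per minute
    adduct_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"H": 0.6, "Na": 0.25, "K": 0.15}
    )
    source_loss_fraction: float = 0.0
    duration_min: float = 30.0
    scan_interval_s: float = 5.0
    noise_cv: float = 0.0
    total_intensity: float = 1.0e6
    adduct_rate_multipliers: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        for name, v in (
            ("initial_phospho_fraction", self.initial_phospho_fraction),
            ("source_loss_fraction", self.source_loss_fraction),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        total = sum(self.adduct_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"adduct fractions must sum to 1, got {total}")


def substrate_peak_table() -> pd.DataFrame:
    """The six assay peaks: phospho flag, adduct, exact and nominal m/z."""
    rows = []
    for phospho, pep in ((False, SUBSTRATE), (True, PHOSPHO_SUBSTRATE)):
        for adduct in ("H", "Na", "K"):
            mz = adduct_mz(pep, adduct, 1)
            rows.append({"phospho": phospho, "adduct": adduct, "mz": mz, "nominal": round(mz)})
    return pd.DataFrame(rows)


def simulate_infusion_timecourse(
    config: InfusionSimConfig,
) -> tuple[SpectralDataset, pd.DataFrame]:
    """Simulate the infusion assay; returns scans plus the true phospho
    fraction over time (overall and per adduct).  Total ion current is
    conserved in expectation: dephosphorylation converts phospho intensity
    into non-phospho intensity, never destroys it."""
    rng = np.random.default_rng(config.seed)
    peaks = substrate_peak_table()
    mult = dict(config.adduct_rate_multipliers or {})
    times = np.arange(0.0, config.duration_min * 60.0 + 1e-9, config.scan_interval_s) / 60.0
    f0, loss = config.initial_phospho_fraction, config.source_loss_fraction
    scans = []
    truth_rows = []
    for t in times:
        mzs, inten = [], []
        frac_by_adduct = {}
        for adduct, w in config.adduct_fractions.items():
            k_a = config.k_dephos * mult.get(adduct, 1.0)
            p = f0 * np.exp(-k_a * t)
            frac_by_adduct[adduct] = p
            pool = config.total_intensity * w
            phospho_i = pool * p * (1.0 - loss)
            non_i = pool * (1.0 - p + p * loss)
            for is_p, base in ((True, phospho_i), (False, non_i)):
                row = peaks[(peaks.phospho == is_p) & (peaks.adduct == adduct)].iloc[0]
                noisy = base * (1.0 + rng.normal(0.0, config.noise_cv)) if config.noise_cv > 0 else base
                mzs.append(row.mz)
                inten.append(max(noisy, 0.0))
        order = np.argsort(mzs)
        scans.append(Scan(float(t), np.asarray(mzs)[order], np.asarray(inten)[order]))
        overall = sum(config.adduct_fractions[a] * f for a, f in frac_by_adduct.items())
        truth_rows.append({"time_min": float(t), "phospho_fraction": overall,
                           **{f"fraction_{a}": f for a, f in frac_by_adduct.items()}})
    return SpectralDataset(tuple(scans)), pd.DataFrame(truth_rows)


# --- conformational ensembles ------------------------------------------------


@dataclass(frozen=True)
class EnsembleSimConfig:
    """Paired conformational ensembles as per-residue isotropic Gaussian clouds.

    Ensemble B's residue means are displaced from A's by ``mean_shift``
    (per-residue 3-vectors, Angstrom).  The reference coordinates default to
    a random self-avoiding-ish CA trace with 3.8 A steps.  Frames are
    independent draws; the dynamics itself is not simulated.
    """

    n_residues: int = 125
    n_frames: int = 3001
    reference: np.ndarray | None = None  # (n_residues, 3) Angstrom
    mean_shift: np.ndarray | None = None  # (n_residues, 3) Angstrom, default zero
    coord_sd: float | np.ndarray = 0.5  # Angstrom, scalar or per-residue
    frame_interval_ps: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if np.any(np.asarray(self.coord_sd) <= 0):
            raise ValueError("coordinate SDs must be > 0")


def _default_reference(n_residues: int, rng: np.random.Generator) -> np.ndarray:
    steps = rng.normal(size=(n_residues, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    return np.cumsum(3.8 * steps, axis=0)


def simulate_ensembles(
    config: EnsembleSimConfig,
) -> tuple[ConformationalEnsemble, ConformationalEnsemble, pd.DataFrame]:
    """Generate the ensemble pair plus ground-truth per-residue CoM separation."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n_residues, config.n_frames
    ref = (
        np.asarray(config.reference, float)
        if config.reference is not None
        else _default_reference(n, rng)
    )
    if ref.shape != (n, 3):
        raise ValueError(f"reference must have shape ({n}, 3)")
    shift = np.zeros((n, 3)) if config.mean_shift is None else np.asarray(config.mean_shift, float)
    if shift.shape != (n, 3):
        raise ValueError(f"mean_shift must have shape ({n}, 3)")
    sd = np.broadcast_to(np.asarray(config.coord_sd, float), (n,))[:, None]

    frames_a = ref[None] + rng.normal(size=(m, n, 3)) * sd[None]
    frames_b = (ref + shift)[None] + rng.normal(size=(m, n, 3)) * sd[None]
    residue_ids = np.arange(n)
    ens_a = ConformationalEnsemble(frames_a, residue_ids, ref, config.frame_interval_ps)
    ens_b = ConformationalEnsemble(frames_b, residue_ids, ref, config.frame_interval_ps)
    truth = pd.DataFrame(
        {"residue": np.arange(1, n + 1), "com_shift": np.linalg.norm(shift, axis=1)}
    )
    return ens_a, ens_b, truth


# --- colorimetric progress curves --------------------------------------------


@dataclass(frozen=True)
class ProgressCurveSimConfig:
    """pNPP progress curves under Michaelis-Menten kinetics with substrate
    depletion, read out as A405 through the Beer-Lambert contract of the
    kinetics module (path length from well geometry)."""

    Km_mM: float = 7.0
    Vmax_mM_min: float = 0.02
    E0_uM: float = 2.1
    substrate_series_mM: tuple[float, ...] = (0.8, 2.0, 5.0, 15.0, 40.0)
    duration_min: float = 120.0
    sample_interval_min: float = 3.0
    absorbance_noise_sd: float = 0.005
    epsilon_mM_cm: float = 17.8
    well_radius_mm: float = 4.0
    well_volume_ul: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if min(self.Km_mM, self.E0_uM) <= 0 or self.Vmax_mM_min < 0:
            raise ValueError("Km and E0 must be > 0 and Vmax >= 0")
        if not self.substrate_series_mM:
            raise ValueError("substrate_series_mM must be non-empty")


def _integrate_mm(s0: float, km: float, vmax: float, times: np.ndarray) -> np.ndarray:
    """Product concentration by RK4 on ds/dt = -Vmax*s/(Km+s)."""
    rate = lambda s: -vmax * s / (km + s)
    prod = np.empty_like(times)
    s = s0
    prod[0] = 0.0
    for i in range(1, len(times)):
        span = times[i] - times[i - 1]
        nsub = 50
        h = span / nsub
        for _ in range(nsub):
            k1 = rate(s)
            k2 = rate(max(s + 0.5 * h * k1, 0.0))
            k3 = rate(max(s + 0.5 * h * k2, 0.0))
            k4 = rate(max(s + h * k3, 0.0))
            s = max(s + h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0, 0.0)
        prod[i] = s0 - s
    return prod


def simulate_pnpp_progress(
    config: ProgressCurveSimConfig,
) -> tuple[pd.DataFrame, dict]:
    """Absorbance time series per substrate concentration + ground truth.

    Returns a long-form frame (substrate_mM, time_min, absorbance) and a
    truth dict with the generating Km, Vmax and the noise-free initial rates.
    """
    rng = np.random.default_rng(config.seed)
    path_cm = path_length(config.well_volume_ul, config.well_radius_mm)
    times = np.arange(0.0, config.duration_min + 1e-9, config.sample_interval_min)
    rows = []
    v0_truth = {}
    for s0 in config.substrate_series_mM:
        prod = _integrate_mm(s0, config.Km_mM, config.Vmax_mM_min, times)
        a405 = config.epsilon_mM_cm * path_cm * prod
        if config.absorbance_noise_sd > 0:
            a405 = a405 + rng.normal(0.0, config.absorbance_noise_sd, size=a405.shape)
        v0_truth[s0] = config.Vmax_mM_min * s0 / (config.Km_mM + s0)
        for t, a in zip(times, a405):
            rows.append({"substrate_mM": s0, "time_min": float(t), "absorbance": float(a)})
    truth = {
        "Km_mM": config.Km_mM,
        "Vmax_mM_min": config.Vmax_mM_min,
        "E0_uM": config.E0_uM,
        "path_cm": path_cm,
        "v0_mM_min": v0_truth,
    }
    return pd.DataFrame(rows), truth
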