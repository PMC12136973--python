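"""Synthetic diurnal multi-omics generator with ground truth.

Emulates the statistical structure of a synchronized algal diurnal
photoacclimation experiment so every downstream stage is testable without
the deposited datasets:

* a high fraction of 24-h-rhythmic transcripts with arbitrary phases
  (cosine mean structure on the log2 scale, negative-binomial counts);
* protein profiles lagging their cognate mRNA by 2-8 h with a compressed
  dynamic range, Gaussian log2 noise, left-censoring at a detection floor
  plus random dropout;
* planted light-responsive genes (constitutive and transient; HL-specific
  and shared-with-LL) as additive log2 condition effects against the ML
  control;
* pigment, thylakoid-morphometry, and chlorophyll-fluorescence tables with
  condition- and time-structured means (midday xanthophyll de-epoxidation
  in HL, looser/fewer thylakoid stacks in HL, HL Fv/Fm dip with late-day
  recovery, elevated maintained NPQ capacity in HL).

Every simulation is a pure function of its :class:`SimConfig` (seed
included); the same config yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io_model import (
    CONDITIONS,
    TIMEPOINT_LABELS,
    OmicsMatrix,
    build_design,
    normalize_label,
)

PERIOD_H = 24.0
_OMEGA = 2.0 * np.pi / PERIOD_H

RESPONSE_COLUMNS = tuple(
    f"resp_{cond}_{lab}" for cond in ("LL", "HL") for lab in TIMEPOINT_LABELS
)


@dataclass
class SimConfig:
    """Parameters of one simulated experiment.

    Defaults are the study conditions: 91% rhythmic genes, uniform phases,
    protein lags uniform on [2, 8] h, tight replicate agreement
    (negative-binomial dispersion 0.01), 10% responsive genes at a log2
    effect of 2 against the ML control.
    """

    seed: int
    n_genes: int = 2000
    frac_rhythmic: float = 0.91
    nb_dispersion: float = 0.01
    library_size: int = 5_000_000
    protein_noise_sd_log2: float = 0.25
    protein_loq: float = 16.0
    protein_missing_rate: float = 0.05
    effect_size_log2: float = 2.0
    frac_responsive: float = 0.10
    # secondary structure ------------------------------------------------
    mesor_log2_mean: float = 7.0
    mesor_log2_sd: float = 1.5
    amplitude_range: tuple = (0.5, 2.5)
    phase_mode: str = "uniform"  # or "bimodal" (dawn/dusk-weighted)
    protein_lag_range: tuple = (2.0, 8.0)
    protein_amp_scale_range: tuple = (0.3, 0.7)
    protein_mesor_offset: float = 3.0
    frac_constitutive: float = 0.5
    frac_shared: float = 0.5
    frac_down: float = 0.25
    frac_chloroplast: float = 0.05
    physio_noise_sd: float = 0.05

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for name in ("frac_rhythmic", "frac_responsive", "frac_constitutive",
                     "frac_shared", "frac_down", "frac_chloroplast"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.protein_missing_rate < 1.0:
            raise ValueError("protein_missing_rate must be in [0, 1)")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.protein_lag_range
        if not (2.0 <= lo <= hi <= 8.0):
            raise ValueError("protein_lag_range must lie within [2, 8]")
        if round(self.frac_responsive * self.n_genes) > self.n_genes:
            raise ValueError("more responsive genes than genes")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stream]))


def generate_truth(cfg: SimConfig) -> pd.DataFrame:
    """Per-gene ground truth table.

    ``round(frac_rhythmic * n_genes)`` genes are rhythmic with phases
    uniform on [0, 24) (or dawn/dusk-weighted bimodal), amplitudes uniform
    on ``amplitude_range`` and protein lags uniform on ``protein_lag_range``;
    non-rhythmic genes have amplitude exactly 0. ``round(frac_responsive *
    n_genes)`` genes carry planted response labels, split into
    shared-with-LL vs HL-specific and constitutive vs transient
    subpopulations. Deterministic under the config seed.
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    n = cfg.n_genes
    width = max(5, len(str(n)))
    feature_ids = [f"g{i:0{width}d}" for i in range(1, n + 1)]

    n_rhythmic = int(round(cfg.frac_rhythmic * n))
    is_rhythmic = np.zeros(n, dtype=bool)
    is_rhythmic[rng.choice(n, size=n_rhythmic, replace=False)] = True

    if cfg.phase_mode == "uniform":
        phase = rng.uniform(0.0, PERIOD_H, size=n)
    elif cfg.phase_mode == "bimodal":
        # dawn/dusk-weighted mixture of wrapped normals
        centers = rng.choice([1.0, 11.0], size=n)
        phase = np.mod(centers + rng.normal(0.0, 2.0, size=n), PERIOD_H)
    else:
        raise ValueError(f"unknown phase_mode {cfg.phase_mode!r}")

    amplitude = np.where(
        is_rhythmic, rng.uniform(*cfg.amplitude_range, size=n), 0.0
    )
    mesor = rng.normal(cfg.mesor_log2_mean, cfg.mesor_log2_sd, size=n)
    lag = rng.uniform(*cfg.protein_lag_range, size=n)
    amp_scale = rng.uniform(*cfg.protein_amp_scale_range, size=n)
    compartment = np.where(
        rng.random(n) < cfg.frac_chloroplast, "chloroplast", "nucleus"
    )

    truth = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "compartment": compartment,
            "is_rhythmic": is_rhythmic,
            "phase_hours": phase,
            "amplitude_log2": amplitude,
            "mesor_log2": mesor,
            "protein_lag_hours": lag,
            "protein_amp_scale": amp_scale,
            "response_mode": "none",
            "shared_with_LL": False,
        }
    )
    for col in RESPONSE_COLUMNS:
        truth[col] = "none"

    n_resp = int(round(cfg.frac_responsive * n))
    if n_resp:
        resp_idx = rng.choice(n, size=n_resp, replace=False)
        n_shared = int(round(cfg.frac_shared * n_resp))
        shared_mask = np.zeros(n_resp, dtype=bool)
        shared_mask[rng.choice(n_resp, size=n_shared, replace=False)] = True
        const_mask = rng.random(n_resp) < cfg.frac_constitutive
        direction = np.where(rng.random(n_resp) < cfg.frac_down, "down", "up")
        transient_tp = rng.choice(len(TIMEPOINT_LABELS), size=n_resp)

        truth.loc[resp_idx, "shared_with_LL"] = shared_mask
        truth.loc[resp_idx, "response_mode"] = np.where(
            const_mask, "constitutive", "transient"
        )
        for j, gi in enumerate(resp_idx):
            labels = (
                TIMEPOINT_LABELS
                if const_mask[j]
                else (TIMEPOINT_LABELS[transient_tp[j]],)
            )
            for lab in labels:
                truth.loc[gi, f"resp_HL_{lab}"] = direction[j]
                if shared_mask[j]:
                    truth.loc[gi, f"resp_LL_{lab}"] = direction[j]
    return truth


def _log2_mean_grid(truth: pd.DataFrame, design: pd.DataFrame,
                    cfg: SimConfig, protein: bool) -> np.ndarray:
    """Expected log2 abundance, gene x sample."""
    zt = design["zt_hours"].to_numpy(dtype=float)
    cond = design["condition"].to_numpy()
    lab = design["timepoint_label"].to_numpy()

    mesor = truth["mesor_log2"].to_numpy()[:, None]
    amp = truth["amplitude_log2"].to_numpy()[:, None]
    phase = truth["phase_hours"].to_numpy()[:, None]
    if protein:
        mesor = mesor + cfg.protein_mesor_offset
        amp = amp * truth["protein_amp_scale"].to_numpy()[:, None]
        phase = phase + truth["protein_lag_hours"].to_numpy()[:, None]

    mu = mesor + amp * np.cos(_OMEGA * (zt[None, :] - phase))

    effect = np.zeros_like(mu)
    for j in range(len(zt)):
        if cond[j] == "ML":
            continue
        col = f"resp_{cond[j]}_{lab[j]}"
        if col in truth.columns:
            labels = truth[col].to_numpy()
            effect[:, j] = np.where(
                labels == "up", cfg.effect_size_log2,
                np.where(labels == "down", -cfg.effect_size_log2, 0.0),
            )
    return mu + effect


def simulate_mrna(truth: pd.DataFrame, design: pd.DataFrame, cfg: SimConfig):
    """Simulate transcript counts and an FPKM-like normalized layer.

    Per-gene log2 mean = mesor + amplitude * cos(2*pi*(zt - phase)/24) plus
    the planted condition effect at labelled timepoints. Counts are
    negative-binomial with the configured dispersion (Poisson when 0);
    the FPKM-like layer rescales each sample to a common library of 1e6.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    mu = _log2_mean_grid(truth, design, cfg, protein=False)
    mean_lin = np.power(2.0, mu)
    # one global scale: mean library over samples hits cfg.library_size
    scale = cfg.library_size / mean_lin.sum(axis=0).mean()
    mean_counts = mean_lin * scale

    if cfg.nb_dispersion < 1e-12:
        counts = rng.poisson(mean_counts).astype(np.int64)
    else:
        r = 1.0 / cfg.nb_dispersion
        p = r / (r + mean_counts)
        counts = rng.negative_binomial(r, p).astype(np.int64)

    counts_df = pd.DataFrame(
        counts, index=truth["feature_id"].to_numpy(), columns=design["sample_id"]
    )
    libsize = counts_df.sum(axis=0).replace(0, 1)
    fpkm_df = counts_df / libsize.to_numpy()[None, :] * 1e6

    counts_m = OmicsMatrix("mrna", counts_df, design, unit="counts")
    fpkm_m = OmicsMatrix("mrna", fpkm_df, design, unit="FPKM-like")
    return counts_m, fpkm_m


def simulate_protein(truth: pd.DataFrame, design: pd.DataFrame,
                     cfg: SimConfig) -> OmicsMatrix:
    """Simulate reporter-intensity protein abundances.

    log2 intensity = protein mesor + amp_scale * amplitude *
    cos(2*pi*(zt - phase - lag)/24) + planted effects + Gaussian noise.
    Intensities below ``protein_loq`` are left-censored to missing, and a
    further ``protein_missing_rate`` fraction drops out at random.
    """
    cfg.validate()
    rng = _rng(cfg, 2)
    mu = _log2_mean_grid(truth, design, cfg, protein=True)
    log2_int = mu + rng.normal(0.0, cfg.protein_noise_sd_log2, size=mu.shape)
    intensity = np.power(2.0, log2_int)
    intensity[intensity < cfg.protein_loq] = np.nan
    dropout = rng.random(intensity.shape) < cfg.protein_missing_rate
    intensity[dropout] = np.nan

    df = pd.DataFrame(
        intensity, index=truth["feature_id"].to_numpy(), columns=design["sample_id"]
    )
    return OmicsMatrix("protein", df, design, unit="reporter-intensity")


def simulate_gaussian_abundance(truth: pd.DataFrame, design: pd.DataFrame,
                                cfg: SimConfig, noise_sd: float,
                                layer: str = "mrna") -> OmicsMatrix:
    """Analysis-scale (log2) abundances with plain Gaussian noise.

    A direct draw from the cosinor model itself; useful for calibration
    checks where count noise would confound the question being asked.
    """
    rng = _rng(cfg, 3)
    mu = _log2_mean_grid(truth, design, cfg, protein=(layer == "protein"))
    vals = mu + rng.normal(0.0, noise_sd, size=mu.shape)
    df = pd.DataFrame(
        vals, index=truth["feature_id"].to_numpy(), columns=design["sample_id"]
    )
    return OmicsMatrix(layer, df, design, unit="log2-abundance", raw=False)


# -- physiology tables --------------------------------------------------------

# configured state means over TIMEPOINT_LABELS order ("-2","+2","+6","+10","-10")
_PIGMENT_MEANS = {
    "Vio": {"LL": [28, 28, 28, 28, 28], "ML": [25, 25, 24, 25, 25],
            "HL": [20, 14, 12, 18, 20]},
    "Anthera": {"LL": [1, 1, 1, 1, 1], "ML": [2, 2.5, 2.5, 2, 2],
                "HL": [2, 5, 6, 3, 2]},
    "Zea": {"LL": [0.5, 0.5, 0.5, 0.5, 0.5], "ML": [1.5, 2, 2.5, 2, 1.5],
            "HL": [3, 10, 12, 5, 3]},
}
_SIZE_FACTOR = [0.95, 0.9, 1.05, 1.25, 1.0]  # cells grow over the day, divide at dusk
_PIGMENT_BASE = {
    "lutein": {"LL": 60, "ML": 55, "HL": 55},
    "alpha_car": {"LL": 8, "ML": 8, "HL": 7},
    "beta_car": {"LL": 12, "ML": 12, "HL": 11},
    "chl_a": {"LL": 180, "ML": 150, "HL": 110},
    "chl_b": {"LL": 70, "ML": 52, "HL": 32},
}
_THYLAKOID_LAYERS = {"LL": [7, 6, 5, 5, 6], "ML": [5, 5, 4, 4, 5],
                     "HL": [4, 3, 2, 3, 3]}
_THYLAKOID_SRD = {"LL": [15, 15, 16, 16, 15], "ML": [17, 17, 18, 18, 17],
                  "HL": [23, 20, 21, 22, 21]}
_FVFM = {"LL": [0.72, 0.70, 0.69, 0.70, 0.72], "ML": [0.71, 0.65, 0.63, 0.66, 0.70],
         "HL": [0.68, 0.45, 0.48, 0.60, 0.66]}
_NPQ_MAX = {"LL": [0.8, 0.8, 0.9, 0.9, 0.8], "ML": [1.5, 1.4, 1.5, 1.5, 1.5],
            "HL": [3.0, 2.8, 2.8, 2.9, 3.0]}
_PSI_PSII = {"LL": [0.45, 0.45, 0.45, 0.45, 0.45],
             "ML": [0.45, 0.55, 0.60, 0.60, 0.48],
             "HL": [0.50, 0.62, 0.55, 0.60, 0.50]}
ACTINIC_STEPS = (50, 200, 500, 1000, 1500)
_NPQ_RAMP = (0.15, 0.4, 0.7, 0.9, 1.0)


def _states(design: pd.DataFrame):
    seen = []
    for _, row in design.iterrows():
        key = (row["condition"], row["timepoint_label"], int(row["replicate"]))
        if key not in seen:
            seen.append(key)
    return seen


def _tp_index(label: str) -> int:
    return TIMEPOINT_LABELS.index(normalize_label(label))


def simulate_physio_tables(design: pd.DataFrame, cfg: SimConfig) -> dict:
    """Pigment, thylakoid-morphometry, fluorescence and 77 K spectra tables.

    Means encode the planted phenotypes: HL de-epoxidation highest early and
    midday and low at night; fewer thylakoid layers and higher stacking
    repeat distance in HL at every timepoint; an HL Fv/Fm dip at the start
    of the day recovering by the end; NPQ capacity highest in HL and
    maintained at night. With ``physio_noise_sd = 0`` every table equals its
    configured means exactly.
    """
    cfg.validate()
    rng = _rng(cfg, 4)
    sd = cfg.physio_noise_sd

    def noisy(mean, n=None):
        mean = np.asarray(mean, dtype=float)
        if sd == 0:
            return mean if n is None else np.broadcast_to(mean, (n,)).copy()
        shape = mean.shape if n is None else (n,)
        return mean * np.exp(rng.normal(0.0, sd, size=shape))

    pig_rows, fluor_rows = [], []
    for cond, lab, rep in _states(design):
        ti = _tp_index(lab)
        row = {"condition": cond, "timepoint_label": lab, "replicate": rep}
        for pig, by_cond in _PIGMENT_MEANS.items():
            row[pig] = float(noisy(by_cond[cond][ti]))
        for pig, base in _PIGMENT_BASE.items():
            row[pig] = float(noisy(base[cond] * _SIZE_FACTOR[ti]))
        pig_rows.append(row)

        fm = float(noisy(1.0))
        f0 = fm * (1.0 - float(noisy(_FVFM[cond][ti])))
        npq_max = float(noisy(_NPQ_MAX[cond][ti]))
        for actinic, ramp in zip(ACTINIC_STEPS, _NPQ_RAMP):
            fluor_rows.append(
                {"condition": cond, "timepoint_label": lab, "replicate": rep,
                 "actinic": actinic, "F0": f0, "Fm": fm,
                 "Fm_prime": fm / (1.0 + npq_max * ramp)}
            )

    thyl_rows = []
    n_regions = 40
    for cond, lab, rep in _states(design):
        ti = _tp_index(lab)
        layer_mean = _THYLAKOID_LAYERS[cond][ti]
        srd_mean = _THYLAKOID_SRD[cond][ti]
        if sd == 0:
            layers = np.full(n_regions, layer_mean, dtype=int)
        else:
            layers = np.clip(
                np.round(rng.normal(layer_mean, 3 * sd * layer_mean, n_regions)),
                1, None
            ).astype(int)
        heights = layers * noisy(np.full(n_regions, float(srd_mean)))
        for ri, (lay, h) in enumerate(zip(layers, heights), start=1):
            thyl_rows.append(
                {"condition": cond, "timepoint_label": lab, "replicate": rep,
                 "region_id": ri, "layers": int(lay), "height_nm": float(h)}
            )

    wavelengths = np.arange(650.0, 781.0, 2.0)
    spec_rows = []
    for cond, lab, rep in _states(design):
        ti = _tp_index(lab)
        ratio = float(noisy(_PSI_PSII[cond][ti]))
        spectrum = (
            np.exp(-0.5 * ((wavelengths - 684.0) / 8.0) ** 2)
            + ratio * np.exp(-0.5 * ((wavelengths - 711.0) / 8.0) ** 2)
            + 0.02
        )
        for wl, inten in zip(wavelengths, spectrum):
            spec_rows.append(
                {"condition": cond, "timepoint_label": lab, "replicate": rep,
                 "wavelength_nm": float(wl), "intensity": float(inten)}
            )

    return {
        "pigments": pd.DataFrame(pig_rows),
        "thylakoid": pd.DataFrame(thyl_rows),
        "fluorescence": pd.DataFrame(fluor_rows),
        "spectra": pd.DataFrame(spec_rows),
    }


def simulate_dataset(cfg: SimConfig, design: pd.DataFrame | None = None) -> dict:
    """Full synthetic experiment: truth, all molecular layers, physio tables."""
    if design is None:
        design = build_design()
    truth = generate_truth(cfg)
    counts, fpkm = simulate_mrna(truth, design, cfg)
    protein = simulate_protein(truth, design, cfg)
    physio = simulate_physio_tables(design, cfg)
    return {
        "config": asdict(cfg),
        "design": design,
        "truth": truth,
        "counts": counts,
        "fpkm": fpkm,
        "protein": protein,
        **physio,
    }
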