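"""Closed-form photophysiology and ultrastructure indices.

All indices are computed from measurement tables (pigment HPLC, thylakoid
TEM morphometry, PAM and 77 K chlorophyll fluorescence); no instrument or
image processing happens here.

* De-epoxidation state of the xanthophyll cycle:
  DES = (0.5*antheraxanthin + zeaxanthin) /
        (violaxanthin + antheraxanthin + zeaxanthin), in [0, 1].
* Stacking repeat distance SRD = stack height / number of membrane layers,
  defined only for stacked membranes (>= 2 layers).
* Maximum PSII photochemical efficiency Fv/Fm = (Fm - F0)/Fm.
* Non-photochemical quenching NPQ = (Fm - Fm')/Fm'.
* 77 K PSI/PSII fluorescence ratio: peak near 711 nm over peak near 684 nm
  after normalizing the spectrum to its PSII-window maximum.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("dielomics")

PSII_WINDOW_NM = (680.0, 690.0)
PSI_WINDOW_NM = (705.0, 720.0)


def de_epoxidation_state(vio, anthera, zea):
    """Xanthophyll de-epoxidation state (0.5*Anthera + Zea)/(Vio + Anthera + Zea).

    Inputs are pigment amounts (any common unit); the index is
    scale-invariant and bounded in [0, 1]. A zero xanthophyll pool leaves
    the index undefined (NaN, with a log entry for scalar input).
    """
    vio = np.asarray(vio, dtype=float)
    anthera = np.asarray(anthera, dtype=float)
    zea = np.asarray(zea, dtype=float)
    if np.nanmin(vio, initial=0) < 0 or np.nanmin(anthera, initial=0) < 0 \
            or np.nanmin(zea, initial=0) < 0:
        raise ValueError("pigment amounts must be nonnegative")
    pool = vio + anthera + zea
    with np.errstate(divide="ignore", invalid="ignore"):
        des = np.where(pool > 0, (0.5 * anthera + zea) / pool, np.nan)
    if des.ndim == 0:
        if pool == 0:
            logger.warning("zero xanthophyll pool; DES undefined")
        return float(des)
    return des


def srd(height_nm, layers):
    """Stacking repeat distance: stack height / membrane layers (nm per layer).

    Only defined for stacked membranes (layers >= 2); single membranes give
    NaN per the morphometry convention.
    """
    height_nm = np.asarray(height_nm, dtype=float)
    layers = np.asarray(layers)
    if np.nanmin(height_nm, initial=np.inf) <= 0:
        raise ValueError("height must be > 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(layers >= 2, height_nm / layers, np.nan)
    return float(out) if out.ndim == 0 else out


def fv_over_fm(f0, fm):
    """Maximum PSII photochemical efficiency (Fm - F0)/Fm, in [0, 1)."""
    f0 = np.asarray(f0, dtype=float)
    fm = np.asarray(fm, dtype=float)
    if np.any(f0 <= 0) or np.any(fm <= 0):
        raise ValueError("fluorescence values must be > 0")
    if np.any(f0 > fm):
        raise ValueError("F0 > Fm (instrument artifact)")
    out = (fm - f0) / fm
    return float(out) if out.ndim == 0 else out


def npq(fm, fm_prime):
    """Non-photochemical quenching (Fm - Fm')/Fm', >= 0.

    Fm' above Fm is physically inconsistent and rejected rather than
    silently clipped.
    """
    fm = np.asarray(fm, dtype=float)
    fm_prime = np.asarray(fm_prime, dtype=float)
    if np.any(fm_prime <= 0):
        raise ValueError("Fm' must be > 0")
    if np.any(fm_prime > fm):
        raise ValueError("Fm' exceeds Fm (flagged, not clipped)")
    out = (fm - fm_prime) / fm_prime
    return float(out) if out.ndim == 0 else out


def _window_peak(wavelength, intensity, window):
    lo, hi = window
    sel = (wavelength >= lo) & (wavelength <= hi)
    if not sel.any():
        # nearest wavelength fallback
        center = (lo + hi) / 2.0
        idx = int(np.argmin(np.abs(wavelength - center)))
        logger.warning("no wavelengths in window %s; using nearest %.1f nm",
                       window, wavelength[idx])
        return float(intensity[idx])
    return float(intensity[sel].max())


def psi_psii_ratio(wavelength, intensity,
                   psii_window=PSII_WINDOW_NM, psi_window=PSI_WINDOW_NM):
    """77 K PSI/PSII fluorescence emission ratio.

    The spectrum (650-780 nm) is normalized to its maximum in the PSII
    window (~684 nm); the ratio is the windowed maximum near 711 nm over
    the windowed maximum near 684 nm. Windowed maxima, rather than fixed
    wavelengths, tolerate small calibration shifts.
    """
    wavelength = np.asarray(wavelength, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if wavelength.min() > 650.0 or wavelength.max() < 780.0:
        raise ValueError("spectrum must cover 650-780 nm")
    psii_peak = _window_peak(wavelength, intensity, psii_window)
    if psii_peak <= 0:
        raise ValueError("nonpositive PSII peak; cannot normalize")
    norm = intensity / psii_peak
    return _window_peak(wavelength, norm, psi_window) / _window_peak(
        wavelength, norm, psii_window
    )


# -- tidy summaries -----------------------------------------------------------

_STATE = ["condition", "timepoint_label"]


def summarize_pigments(pigments: pd.DataFrame) -> pd.DataFrame:
    """Per-state mean/SD of pigments plus derived DES and Chl a/b."""
    df = pigments.copy()
    df["DES"] = de_epoxidation_state(df["Vio"], df["Anthera"], df["Zea"])
    if {"chl_a", "chl_b"} <= set(df.columns):
        df["chl_ab_ratio"] = df["chl_a"] / df["chl_b"]
    value_cols = [c for c in df.columns
                  if c not in _STATE + ["replicate"] and df[c].dtype != object]
    agg = df.groupby(_STATE, sort=False)[value_cols].agg(["mean", "std"])
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    return agg.reset_index()


def summarize_thylakoid(thylakoid: pd.DataFrame) -> pd.DataFrame:
    """Per-state mean/SD of membrane layers and SRD (stacked regions only)."""
    df = thylakoid.copy()
    df["srd_nm"] = srd(df["height_nm"], df["layers"])
    agg = df.groupby(_STATE, sort=False)[["layers", "srd_nm"]].agg(
        ["mean", "std", "count"]
    )
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    return agg.reset_index()


def summarize_fluorescence(fluor: pd.DataFrame) -> pd.DataFrame:
    """Per-state Fv/Fm and the NPQ induction curve over actinic steps."""
    df = fluor.copy()
    df["fv_fm"] = fv_over_fm(df["F0"], df["Fm"])
    df["npq"] = npq(df["Fm"], df["Fm_prime"])
    agg = (
        df.groupby(_STATE + ["actinic"], sort=False)[["fv_fm", "npq"]]
        .agg(["mean", "std"])
    )
    agg.columns = [f"{c}_{s}" for c, s in agg.columns]
    return agg.reset_index()


def summarize_spectra(spectra: pd.DataFrame) -> pd.DataFrame:
    """Per-state mean PSI/PSII 77 K emission ratio."""
    rows = []
    for (cond, lab, rep), grp in spectra.groupby(
        _STATE + ["replicate"], sort=False
    ):
        rows.append(
            {"condition": cond, "timepoint_label": lab, "replicate": rep,
             "psi_psii": psi_psii_ratio(grp["wavelength_nm"].to_numpy(),
                                        grp["intensity"].to_numpy())}
        )
    per_rep = pd.DataFrame(rows)
    agg = per_rep.groupby(_STATE, sort=False)["psi_psii"].agg(["mean", "std"])
    agg.columns = [f"psi_psii_{s}" for s in agg.columns]
    return agg.reset_index()


def summarize_physio(tables: dict, min_replicates: int = 2) -> dict:
    """Tidy per-state summaries for every supplied physiology table.

    ``tables`` may contain any of pigments / thylakoid / fluorescence /
    spectra (as produced by the generator or read from TSV). States with
    fewer than ``min_replicates`` replicates are reported but flagged in
    the log.
    """
    out = {}
    if "pigments" in tables:
        out["pigments"] = summarize_pigments(tables["pigments"])
    if "thylakoid" in tables:
        out["thylakoid"] = summarize_thylakoid(tables["thylakoid"])
    if "fluorescence" in tables:
        out["fluorescence"] = summarize_fluorescence(tables["fluorescence"])
    if "spectra" in tables:
        out["spectra"] = summarize_spectra(tables["spectra"])
    for name, summ in out.items():
        if "replicate" in summ.columns:
            continue
        counts = [c for c in summ.columns if c.endswith("_count")]
        for c in counts:
            if (summ[c] < min_replicates).any():
                logger.warning("%s: some states have < %d replicates",
                               name, min_replicates)
    return out
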