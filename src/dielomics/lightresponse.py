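"""Core light-response classification and mRNA/protein concordance.

A gene is *core HL-responsive* at a timepoint and layer when it is
significantly increased in the HL population while unchanged or decreased
in LL (core_up), or significantly decreased in HL while unchanged or
increased in LL (core_down) — both against the ML control. Changes shared
by HL and LL are attributed to productivity/synchrony differences and are
excluded. A *constitutive* response is a same-direction significant call at
all five sampled timepoints. mRNA/protein concordance counts a change at
both levels either simultaneously or with the protein change at the next
sampled timepoint exactly 4 h later (the 14 -> 22 ZT gap is 8 h and has no
4-h partner).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_model import TIMEPOINT_LABELS, normalize_label, zt_of_label
from .diffexp import CALL_UP, CALL_DOWN, CALL_UNCHANGED, CALL_NA

CORE_UP, CORE_DOWN, NOT_CORE = "core_up", "core_down", "not_core"

#: mRNA timepoint -> protein timepoint exactly 4 h later on the sampled grid.
LAG_4H_PAIRS = {"-2": "+2", "+2": "+6", "+6": "+10", "+10": "-10"}
assert all(
    np.mod(zt_of_label(b) - zt_of_label(a), 24.0) == 4.0
    for a, b in LAG_4H_PAIRS.items()
)


def classify_core(call_hl: str, call_ll: str, strict: bool = False) -> str:
    """Map an (HL call, LL call) pair to a core-response class.

    ``strict=False`` treats a not_evaluable input as unchanged (undetected
    in one arm does not veto the other arm); ``strict=True`` drops such
    pairs to not_core.
    """
    if CALL_NA in (call_hl, call_ll):
        if strict:
            return NOT_CORE
        call_hl = CALL_UNCHANGED if call_hl == CALL_NA else call_hl
        call_ll = CALL_UNCHANGED if call_ll == CALL_NA else call_ll
    if call_hl == CALL_UP and call_ll in (CALL_UNCHANGED, CALL_DOWN):
        return CORE_UP
    if call_hl == CALL_DOWN and call_ll in (CALL_UNCHANGED, CALL_UP):
        return CORE_DOWN
    return NOT_CORE


def classify_core_table(calls_hl: pd.DataFrame, calls_ll: pd.DataFrame,
                        strict: bool = False) -> pd.DataFrame:
    """Vectorized core classification of matching HL and LL call tables.

    Tables must describe the same features, layer and timepoint (against
    the ML control); mismatched keys are an error.
    """
    key = ["feature_id"]
    hl = calls_hl.set_index(key)
    ll = calls_ll.set_index(key)
    if not hl.index.equals(ll.index):
        raise ValueError("HL and LL call tables cover different features")
    for col in ("layer", "timepoint_label"):
        if col in hl.columns and col in ll.columns:
            if not (hl[col].to_numpy() == ll[col].to_numpy()).all():
                raise ValueError(f"HL/LL call tables disagree on {col}")
    out = pd.DataFrame(index=hl.index)
    out["call_HL"] = hl["call"]
    out["call_LL"] = ll["call"]
    out["core_call"] = [
        classify_core(a, b, strict=strict)
        for a, b in zip(out["call_HL"], out["call_LL"])
    ]
    out["had_not_evaluable"] = (out["call_HL"] == CALL_NA) | (
        out["call_LL"] == CALL_NA
    )
    for col in ("layer", "timepoint_label"):
        if col in hl.columns:
            out[col] = hl[col]
    return out.reset_index()


def core_union(core_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Gene-level union of core calls over timepoints and layers.

    Each input is a :func:`classify_core_table` result. Returns one row per
    gene with provenance: which (layer, timepoint, direction) combinations
    contributed.
    """
    events = []
    for tab in core_tables:
        hit = tab[tab["core_call"] != NOT_CORE]
        for _, row in hit.iterrows():
            events.append(
                {
                    "feature_id": row["feature_id"],
                    "layer": row.get("layer", ""),
                    "timepoint_label": row.get("timepoint_label", ""),
                    "core_call": row["core_call"],
                }
            )
    if not events:
        return pd.DataFrame(columns=["feature_id", "n_events", "provenance"])
    ev = pd.DataFrame(events)
    rows = []
    for fid, grp in ev.groupby("feature_id", sort=True):
        prov = ";".join(
            f"{r.layer}:{r.timepoint_label}:{r.core_call}"
            for r in grp.itertuples()
        )
        rows.append({"feature_id": fid, "n_events": len(grp), "provenance": prov})
    return pd.DataFrame(rows)


def constitutive_fraction(
    calls: pd.DataFrame,
    timepoint_labels=TIMEPOINT_LABELS,
    direction_specific: bool = True,
):
    """Fraction of responsive genes responding at all sampled timepoints.

    ``calls`` is a long table (feature_id, timepoint_label, call) for one
    layer and one test condition. The numerator requires a significant call
    at every timepoint — same-direction by default, either direction with
    ``direction_specific=False``; the denominator is every gene significant
    at >= 1 timepoint. Returns (fraction, constitutive gene list,
    responsive gene list).
    """
    labels = [normalize_label(t) for t in timepoint_labels]
    present = set(calls["timepoint_label"].map(normalize_label))
    missing = [t for t in labels if t not in present]
    if missing:
        raise ValueError(f"calls missing timepoint(s): {missing}")
    wide = (
        calls.assign(timepoint_label=calls["timepoint_label"].map(normalize_label))
        .pivot_table(index="feature_id", columns="timepoint_label",
                     values="call", aggfunc="first")
        .reindex(columns=labels)
    )
    sig = wide.isin([CALL_UP, CALL_DOWN])
    responsive = wide.index[sig.any(axis=1)]
    if direction_specific:
        all_up = (wide == CALL_UP).all(axis=1)
        all_down = (wide == CALL_DOWN).all(axis=1)
        constitutive = wide.index[all_up | all_down]
    else:
        constitutive = wide.index[sig.all(axis=1)]
    frac = len(constitutive) / len(responsive) if len(responsive) else np.nan
    return frac, list(constitutive), list(responsive)


_SIG = (CALL_UP, CALL_DOWN)


def concordance_with_lag(mrna_calls: pd.DataFrame,
                         protein_calls: pd.DataFrame):
    """Per-gene-per-timepoint mRNA/protein concordance with a 4-h lag rule.

    For each gene and mRNA timepoint: *simultaneous* if mRNA and protein
    show same-direction significant calls at the same timepoint; *lagged_4h*
    if the protein call instead appears, same direction, at the sampled
    timepoint exactly 4 h later; otherwise mrna_only / protein_only / none.
    The summary fraction is the share of all gene-level change events (a
    change at either level at a timepoint) explained at both levels under
    either rule.
    """
    def _wide(calls):
        return (
            calls.assign(
                timepoint_label=calls["timepoint_label"].map(normalize_label)
            )
            .pivot_table(index="feature_id", columns="timepoint_label",
                         values="call", aggfunc="first")
            .reindex(columns=list(TIMEPOINT_LABELS))
            .fillna(CALL_NA)
        )

    wm, wp = _wide(mrna_calls), _wide(protein_calls)
    genes = wm.index.union(wp.index)
    wm = wm.reindex(genes).fillna(CALL_NA)
    wp = wp.reindex(genes).fillna(CALL_NA)

    rows = []
    n_events = 0
    n_concordant_events = 0
    for fid in genes:
        for lab in TIMEPOINT_LABELS:
            cm = wm.at[fid, lab]
            cp = wp.at[fid, lab]
            lagged_lab = LAG_4H_PAIRS.get(lab)
            cp4 = wp.at[fid, lagged_lab] if lagged_lab else None
            msig, psig = cm in _SIG, cp in _SIG
            if msig and psig and cm == cp:
                cls = "simultaneous"
            elif msig and cp4 == cm:
                cls = "lagged_4h"
            elif msig:
                cls = "mrna_only"
            elif psig:
                cls = "protein_only"
            else:
                cls = "none"
            if cls != "none":
                rows.append({"feature_id": fid, "timepoint_label": lab,
                             "concordant": cls})
            if msig or psig:
                n_events += 1
                if cls in ("simultaneous", "lagged_4h"):
                    n_concordant_events += 1
    table = pd.DataFrame(rows, columns=["feature_id", "timepoint_label",
                                        "concordant"])
    summary = {
        "n_change_events": n_events,
        "n_concordant": n_concordant_events,
        "frac_concordant": (n_concordant_events / n_events) if n_events else np.nan,
    }
    return table, summary
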