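#!/usr/bin/env python
"""Photophysiology and ultrastructure indices per cellular state.

Computes the xanthophyll de-epoxidation state, Chl a/b ratio, thylakoid
stacking repeat distance, Fv/Fm, NPQ induction, and the 77 K PSI/PSII
fluorescence ratio from the measurement tables, and reports the planted
condition-and-time orderings.
"""

import argparse
import pathlib

import pandas as pd

from dielomics.physio import summarize_physio


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", default="results/data")
    ap.add_argument("--out-dir", default="results/physio")
    args = ap.parse_args()

    data = pathlib.Path(args.data_dir)
    out = pathlib.Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tables = {
        name: pd.read_csv(data / f"{name}.tsv", sep="\t",
                          dtype={"timepoint_label": str})
        for name in ("pigments", "thylakoid", "fluorescence", "spectra")
    }
    summaries = summarize_physio(tables)
    for name, summ in summaries.items():
        summ.to_csv(out / f"{name}_summary.tsv", sep="\t", index=False)

    pig = summaries["pigments"].set_index(["condition", "timepoint_label"])
    print("HL de-epoxidation state over the day:")
    for lab in ("-2", "+2", "+6", "+10", "-10"):
        print(f"  {lab:>4}: DES = {pig.loc[('HL', lab), 'DES_mean']:.2f}")
    print(f"Chl a/b at +6: HL {pig.loc[('HL', '+6'), 'chl_ab_ratio_mean']:.2f}"
          f" vs LL {pig.loc[('LL', '+6'), 'chl_ab_ratio_mean']:.2f}")

    thyl = summaries["thylakoid"].set_index(["condition", "timepoint_label"])
    print(f"thylakoid layers at +6: LL {thyl.loc[('LL', '+6'), 'layers_mean']:.1f}"
          f" vs HL {thyl.loc[('HL', '+6'), 'layers_mean']:.1f};"
          f" SRD {thyl.loc[('LL', '+6'), 'srd_nm_mean']:.0f} vs"
          f" {thyl.loc[('HL', '+6'), 'srd_nm_mean']:.0f} nm")

    fl = summaries["fluorescence"]
    fv = fl[fl["actinic"] == 50].set_index(["condition", "timepoint_label"])
    print(f"Fv/Fm: HL {fv.loc[('HL', '+2'), 'fv_fm_mean']:.2f} at +2 ->"
          f" {fv.loc[('HL', '+10'), 'fv_fm_mean']:.2f} at +10"
          f" (ML night: {fv.loc[('ML', '-2'), 'fv_fm_mean']:.2f})")
    top = fl[fl["actinic"] == 1500].set_index(["condition", "timepoint_label"])
    print(f"NPQ capacity at night (-2): HL {top.loc[('HL', '-2'), 'npq_mean']:.1f}"
          f" vs LL {top.loc[('LL', '-2'), 'npq_mean']:.1f}")

    spec = summaries["spectra"].set_index(["condition", "timepoint_label"])
    print(f"77 K PSI/PSII ratio, ML: {spec.loc[('ML', '-2'), 'psi_psii_mean']:.2f}"
          f" at -2 -> {spec.loc[('ML', '+6'), 'psi_psii_mean']:.2f} at +6")


if __name__ == "__main__":
    main()
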