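#!/usr/bin/env python
"""Differential abundance of LL and HL against the ML control, per timepoint.

Transcripts: NB Wald test on counts with the |log2FC| > 1 and BH p < 0.01
call contract. Proteins: replicate-mean log2 fold changes scored as
Z-score outliers (|Z| > 2) gated by the limit of quantitation. Writes one
long call table per layer plus the per-timepoint up/down count summary.
"""

import argparse
import pathlib

import pandas as pd

import dielomics as dl
from dielomics.io_model import load_design, load_matrix
from dielomics.diffexp import call_mrna_de, de_summary, nb_wald_test, \
    protein_de


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", default="results/data")
    ap.add_argument("--out-dir", default="results/diffexp")
    args = ap.parse_args()

    data = pathlib.Path(args.data_dir)
    out = pathlib.Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    design = load_design(data / "design.tsv")
    counts = load_matrix(data / "mrna_counts.tsv", "mrna", design,
                         unit="counts")
    protein = load_matrix(data / "protein_intensity.tsv", "protein", design,
                          unit="reporter-intensity")

    mrna_calls, prot_calls = [], []
    for test in ("LL", "HL"):
        for lab in dl.TIMEPOINT_LABELS:
            mrna_calls.append(
                call_mrna_de(nb_wald_test(counts, test_condition=test,
                                          timepoint_label=lab))
            )
            prot_calls.append(protein_de(protein, test, lab))
    mrna_long = pd.concat(mrna_calls, ignore_index=True)
    prot_long = pd.concat(prot_calls, ignore_index=True)
    mrna_long.to_csv(out / "mrna_calls.tsv", sep="\t", index=False)
    prot_long.to_csv(out / "protein_calls.tsv", sep="\t", index=False)

    for name, calls in (("mRNA", mrna_long), ("protein", prot_long)):
        summ = de_summary(calls)
        summ.to_csv(out / f"{name.lower()}_summary.tsv", sep="\t", index=False)
        print(f"{name} calls per (condition, timepoint):")
        for _, r in summ.iterrows():
            print(f"  {r['test_condition']:>3} {r['timepoint_label']:>4}:"
                  f" {r['n_up']} up, {r['n_down']} down")


if __name__ == "__main__":
    main()
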