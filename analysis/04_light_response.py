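#!/usr/bin/env python
"""Core light-response classification and mRNA/protein concordance.

Combines the per-timepoint LL and HL differential calls into core
HL-specific responses (changed in HL, unchanged or opposite in LL),
derives the gene-level core union with provenance, the constitutive
fraction of responses per layer, and the fraction of changes occurring at
both molecular levels simultaneously or after a 4-h lag. Where truth
labels are available the recovery of planted HL-specific genes is scored.
"""

import argparse
import pathlib

import pandas as pd

import dielomics as dl
from dielomics.lightresponse import (
    classify_core_table,
    concordance_with_lag,
    constitutive_fraction,
    core_union,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", default="results/data")
    ap.add_argument("--de-dir", default="results/diffexp")
    ap.add_argument("--out-dir", default="results/lightresponse")
    args = ap.parse_args()

    de = pathlib.Path(args.de_dir)
    out = pathlib.Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    mrna = pd.read_csv(de / "mrna_calls.tsv", sep="\t",
                       dtype={"timepoint_label": str})
    prot = pd.read_csv(de / "protein_calls.tsv", sep="\t",
                       dtype={"timepoint_label": str})

    core_tables = []
    for layer_name, calls in (("mrna", mrna), ("protein", prot)):
        for lab in dl.TIMEPOINT_LABELS:
            hl = calls[(calls["test_condition"] == "HL")
                       & (calls["timepoint_label"] == lab)]
            ll = calls[(calls["test_condition"] == "LL")
                       & (calls["timepoint_label"] == lab)]
            core_tables.append(classify_core_table(hl, ll))
    core_long = pd.concat(core_tables, ignore_index=True)
    core_long.to_csv(out / "core_calls.tsv", sep="\t", index=False)

    union = core_union(core_tables)
    union.to_csv(out / "core_gene_union.tsv", sep="\t", index=False)
    print(f"core HL-specific genes (union over layers/timepoints):"
          f" {len(union)}")

    truth_path = pathlib.Path(args.data_dir) / "truth.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        responsive = truth["response_mode"] != "none"
        specific = set(truth.loc[responsive & ~truth["shared_with_LL"],
                                 "feature_id"])
        shared = set(truth.loc[responsive & truth["shared_with_LL"],
                               "feature_id"])
        got = set(union["feature_id"])
        if specific:
            print(f"  recovery of planted HL-specific genes:"
                  f" {len(got & specific)}/{len(specific)}")
        if shared:
            print(f"  contamination from shared-response genes:"
                  f" {len(got & shared)}/{len(shared)}")

    for layer_name, calls in (("mRNA", mrna), ("protein", prot)):
        for test in ("LL", "HL"):
            sub = calls[calls["test_condition"] == test]
            frac, const, resp = constitutive_fraction(sub)
            print(f"{layer_name} {test}: {len(const)}/{len(resp)}"
                  f" responses constitutive ({frac:.0%})"
                  if resp else f"{layer_name} {test}: no responses")

    for test in ("LL", "HL"):
        m = mrna[mrna["test_condition"] == test]
        p = prot[prot["test_condition"] == test]
        table, summary = concordance_with_lag(m, p)
        table.to_csv(out / f"concordance_{test}.tsv", sep="\t", index=False)
        print(f"{test}: {summary['n_concordant']}/{summary['n_change_events']}"
              f" changes at both levels (simultaneous or 4-h lag)"
              f" = {summary['frac_concordant']:.1%}")


if __name__ == "__main__":
    main()
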