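"""Data model and I/O for diurnal multi-omics tables.

The study design is a full factorial of three diurnal light regimes
(LL ~50, ML ~200, HL ~1000 umol photons m-2 s-1), five timepoints sampled
around a 12 h light / 12 h dark cycle, and independent replicate cultures.
Timepoints are labelled relative to the dark-to-light transition ("+k" hours
into the light phase, "-k" hours before the next light phase) and mapped to
Zeitgeber Time (ZT, hours since lights-on).

Abundance tables (transcript FPKM-like values or raw counts, protein
reporter intensities, lipid peak intensities, pigments) are feature x sample
matrices in delimited text, validated against the sample design. Missing
protein/lipid entries are kept missing, never imputed to zero.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("dielomics")

CONDITIONS = ("LL", "ML", "HL")
#: Canonical label order as sampled chronologically over one experiment
#: (end of night, then through the light phase, then early night).
TIMEPOINT_LABELS = ("-2", "+2", "+6", "+10", "-10")
LAYERS = ("mrna", "protein", "lipid", "pigment")

#: Unicode minus / en-dash variants accepted in timepoint labels.
_MINUS_TRANSLATION = str.maketrans({"−": "-", "–": "-"})


def normalize_label(label: str) -> str:
    """Canonicalize a timepoint label (unicode minus -> ASCII hyphen)."""
    return str(label).strip().translate(_MINUS_TRANSLATION)


def zt_of_label(label: str) -> float:
    """Map a timepoint label to Zeitgeber Time in hours, in [0, 24).

    ZT0 is the dark-to-light transition of a 12:12 cycle, so "+k" is k hours
    after lights-on and "-k" is k hours before the *next* lights-on, i.e.
    24 - k. The five study labels order chronologically within one cycle as
    ZT 2, 6, 10, 14, 22.
    """
    lab = normalize_label(label)
    if lab not in TIMEPOINT_LABELS:
        raise ValueError(
            f"unknown timepoint label: {label!r} "
            f"(expected one of {list(TIMEPOINT_LABELS)})"
        )
    hours = float(lab[1:])
    return hours if lab[0] == "+" else 24.0 - hours


def build_design(
    conditions=CONDITIONS,
    timepoint_labels=TIMEPOINT_LABELS,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Build the full factorial sample sheet.

    Returns a DataFrame with columns ``sample_id, condition, timepoint_label,
    zt_hours, replicate``; row count equals
    ``len(conditions) * len(timepoint_labels) * n_replicates``. Row order is
    deterministic (condition-major, then timepoint, then replicate) so the
    pipeline is reproducible run to run.
    """
    conditions = [str(c) for c in conditions]
    timepoint_labels = [normalize_label(t) for t in timepoint_labels]
    if not conditions or not timepoint_labels:
        raise ValueError("conditions and timepoint_labels must be nonempty")
    if len(set(conditions)) != len(conditions):
        raise ValueError("duplicate condition labels")
    if len(set(timepoint_labels)) != len(timepoint_labels):
        raise ValueError("duplicate timepoint labels")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = [
        {
            "sample_id": f"{cond}_{label}_r{rep}",
            "condition": cond,
            "timepoint_label": label,
            "zt_hours": zt_of_label(label),
            "replicate": rep,
        }
        for cond in conditions
        for label in timepoint_labels
        for rep in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(rows)


def validate_design(design: pd.DataFrame) -> None:
    required = {"sample_id", "condition", "timepoint_label", "zt_hours", "replicate"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design is missing columns: {sorted(missing)}")
    if design["sample_id"].duplicated().any():
        dup = design.loc[design["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in design: {dup!r}")
    key = design[["condition", "timepoint_label", "replicate"]]
    if key.duplicated().any():
        raise ValueError("duplicate (condition, timepoint, replicate) triple in design")
    for lab, zt in zip(design["timepoint_label"], design["zt_hours"]):
        expect = zt_of_label(lab)
        # double-plotted designs carry zt in [24, 48); only the phase matters
        if abs(float(zt) % 24.0 - expect) > 1e-9:
            raise ValueError(
                f"zt_hours {zt} inconsistent with label {lab!r} (expected {expect})"
            )


@dataclass
class OmicsMatrix:
    """Feature x sample abundance table for one molecular layer.

    ``values`` is a DataFrame indexed by feature id with one column per
    sample id; every column must map to exactly one design row. ``raw`` marks
    matrices on the native nonnegative abundance scale (counts, FPKM,
    reporter intensity); log-transformed matrices set ``raw=False``.
    """

    layer: str
    values: pd.DataFrame
    design: pd.DataFrame
    unit: str = ""
    raw: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        validate_design(self.design)
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicated feature id: {dup!r}")
        known = set(self.design["sample_id"])
        unknown = [c for c in self.values.columns if c not in known]
        if unknown:
            raise ValueError(f"sample ids absent from design: {unknown}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated sample columns in matrix")
        if self.raw:
            vals = self.values.to_numpy(dtype=float)
            if np.nanmin(vals, initial=np.inf) < 0:
                raise ValueError(f"negative abundance in raw {self.layer} layer")

    # -- convenience accessors -------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    def column_design(self) -> pd.DataFrame:
        """Design rows aligned to the matrix columns, in column order."""
        d = self.design.set_index("sample_id").loc[list(self.values.columns)]
        return d.reset_index()

    def zt(self) -> np.ndarray:
        """ZT hours per matrix column."""
        return self.column_design()["zt_hours"].to_numpy(dtype=float)

    def subset(self, condition=None, timepoint_label=None) -> "OmicsMatrix":
        d = self.column_design()
        keep = pd.Series(True, index=d.index)
        if condition is not None:
            keep &= d["condition"] == condition
        if timepoint_label is not None:
            keep &= d["timepoint_label"] == normalize_label(timepoint_label)
        cols = d.loc[keep, "sample_id"].tolist()
        if not cols:
            raise ValueError(
                f"no samples for condition={condition!r}, timepoint={timepoint_label!r}"
            )
        return replace(self, values=self.values[cols])


def log2_transform(matrix: OmicsMatrix, pseudocount: float = 1.0) -> OmicsMatrix:
    """log2(x + pseudocount) on the analysis scale.

    The pseudocount is explicit because fold-change behaviour at low
    abundance depends on it; default 1 suits FPKM-like values.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    vals = np.log2(matrix.values + pseudocount)
    unit = f"log2({matrix.unit or 'abundance'}+{pseudocount:g})"
    return replace(matrix, values=vals, unit=unit, raw=False)


# -- file I/O -----------------------------------------------------------------


def load_matrix(
    path,
    layer: str,
    design: pd.DataFrame,
    unit: str = "",
    sep: str = "\t",
    raw: bool = True,
) -> OmicsMatrix:
    """Read a delimited feature x sample table and validate it.

    First column holds feature ids, header row holds sample ids (all of which
    must exist in the design). Empty cells become missing values (NaN), not
    zeros. Pass ``sep=','`` for CSV input.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    m = OmicsMatrix(layer=layer, values=df, design=design, unit=unit, raw=raw)
    logger.info("loaded %s matrix: %d features x %d samples from %s",
                layer, df.shape[0], df.shape[1], path)
    return m


def write_matrix(matrix: OmicsMatrix, path, sep: str = "\t") -> None:
    """Write a matrix as delimited text; missing entries become empty cells.

    Floats are written with shortest round-tripping repr so that
    load(write(m)) reproduces finite values bit-exactly.
    """
    df = matrix.values.copy()
    df.index.name = "feature_id"
    with open(path, "w") as fh:
        fh.write("feature_id" + sep + sep.join(map(str, df.columns)) + "\n")
        for fid, row in zip(df.index, df.to_numpy()):
            cells = ["" if (isinstance(v, float) and np.isnan(v)) else repr(float(v))
                     for v in row]
            fh.write(str(fid) + sep + sep.join(cells) + "\n")


def write_design(design: pd.DataFrame, path, sep: str = "\t") -> None:
    design.to_csv(path, sep=sep, index=False)


def load_design(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype={"timepoint_label": str})
    df["timepoint_label"] = df["timepoint_label"].map(normalize_label)
    if "zt_hours" not in df.columns:
        df["zt_hours"] = df["timepoint_label"].map(zt_of_label)
    validate_design(df)
    return df


def load_annotation(path, sep: str = "\t") -> pd.DataFrame:
    """Read feature annotation: feature_id, genome compartment, symbol, terms.

    ``terms`` is a semicolon-separated list of term ids; parsed to a python
    list per feature (empty list when absent).
    """
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    if df["feature_id"].duplicated().any():
        dup = df.loc[df["feature_id"].duplicated(), "feature_id"].iloc[0]
        raise ValueError(f"duplicated feature_id in annotation: {dup!r}")
    df["terms"] = [
        [t for t in str(x).split(";") if t] for x in df.get("terms", [""] * len(df))
    ]
    return df


def run_manifest(params: dict, inputs: dict | None = None) -> dict:
    """Machine-readable record of a pipeline stage: parameters + input hashes."""
    manifest = {"params": params, "inputs": {}}
    for name, path in (inputs or {}).items():
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 16), b""):
                h.update(chunk)
        manifest["inputs"][name] = {"path": str(path), "sha256": h.hexdigest()}
    return manifest


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
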