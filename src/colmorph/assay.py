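"""Plate-assay quantification: viability, melanin/TYR normalisation, qPCR.

Pure functions over tabular absorbance (OD) and threshold-cycle (Ct)
readings:

* cell survival (CCK-8 at 450 nm): 100 * (ODs - ODb) / (ODc - ODb), with
  s/b/c the sample, blank and untreated-control wells;
* melanin content (405 nm) as percent of the control-group mean OD — the
  same ratio-to-control normalisation serves relative tyrosinase (TYR)
  activity from DOPA-oxidation absorbance;
* relative gene expression by the Livak 2^(-ΔΔCt) method, target gene
  Ct normalised to a reference gene (beta-actin) within each condition and
  the treated condition referred to the control condition.  A treated
  target Ct *above* control (later amplification, less transcript) thus
  yields a fold change below 1.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AssayError

__all__ = ["cell_survival", "melanin_content", "relative_expression",
           "read_plate_csv", "read_qpcr_csv", "mean_sem"]


def cell_survival(od_sample, od_blank, od_control):
    """Percent cell survival from CCK-8 absorbances.

    100 * (OD_sample - OD_blank) / (OD_control - OD_blank).  Accepts scalars
    or arrays (broadcast); raises when control and blank coincide.
    """
    od_sample = np.asarray(od_sample, float)
    denom = np.asarray(od_control, float) - np.asarray(od_blank, float)
    if np.any(denom == 0):
        raise AssayError("control OD equals blank OD: viability undefined")
    out = 100.0 * (od_sample - np.asarray(od_blank, float)) / denom
    return float(out) if out.ndim == 0 else out


def melanin_content(od_sample, control_ods):
    """Percent of the control-group mean OD: 100 * OD_s / mean(OD_control).

    Also the normalisation used for relative TYR activity.
    """
    control = np.asarray(control_ods, float).ravel()
    if control.size == 0:
        raise AssayError("control group is empty")
    avg_c = control.mean()
    if avg_c == 0:
        raise AssayError("control mean OD is zero")
    out = 100.0 * np.asarray(od_sample, float) / avg_c
    return float(out) if out.ndim == 0 else out


def relative_expression(table: pd.DataFrame, target_gene: str = "target",
                        reference_gene: str = "reference",
                        treated: str = "treated",
                        control: str = "control") -> float:
    """Fold change by the Livak 2^(-ΔΔCt) method.

    ``table`` needs columns (condition, gene, ct); replicate Ct values are
    averaged per (condition, gene).  ΔCt = Ct_target - Ct_reference within
    each condition, ΔΔCt = ΔCt_treated - ΔCt_control, fold = 2^(-ΔΔCt).
    """
    required = {"condition", "gene", "ct"}
    if not required.issubset(table.columns):
        raise AssayError(f"qPCR table needs columns {sorted(required)}")
    cts = np.asarray(table["ct"], float)
    if not np.all(np.isfinite(cts)) or np.any(cts <= 0):
        raise AssayError("Ct values must be finite and positive")

    means = table.groupby(["condition", "gene"])["ct"].mean()

    def ct(cond: str, gene: str) -> float:
        try:
            return float(means.loc[(cond, gene)])
        except KeyError:
            raise AssayError(f"missing Ct for condition={cond!r}, gene={gene!r}")

    dct_treated = ct(treated, target_gene) - ct(treated, reference_gene)
    dct_control = ct(control, target_gene) - ct(control, reference_gene)
    ddct = dct_treated - dct_control
    return float(2.0 ** (-ddct))


def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean of replicate readings."""
    v = np.asarray(values, float).ravel()
    if v.size == 0:
        raise AssayError("no replicate values")
    sem = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
    return float(v.mean()), float(sem)


def read_plate_csv(path: str | Path) -> pd.DataFrame:
    """Read a plate table CSV with columns (well, group, od[, label])."""
    df = pd.read_csv(path)
    missing = {"well", "group", "od"} - set(df.columns)
    if missing:
        raise AssayError(f"plate CSV missing columns {sorted(missing)}")
    bad = set(df["group"]) - {"sample", "blank", "control"}
    if bad:
        raise AssayError(f"unknown plate groups {sorted(bad)}")
    if not np.all(np.isfinite(df["od"].astype(float))):
        raise AssayError("OD values must be finite")
    return df


def read_qpcr_csv(path: str | Path) -> pd.DataFrame:
    """Read a qPCR table CSV with columns (sample, condition, gene, ct)."""
    df = pd.read_csv(path)
    missing = {"sample", "condition", "gene", "ct"} - set(df.columns)
    if missing:
        raise AssayError(f"qPCR CSV missing columns {sorted(missing)}")
    return df
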