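"""Comparative-CT (delta-delta-CT) relative expression quantification.

Designed for the diel qPCR layout: transcript levels of target genes in
L/D-synchronized cultures, normalized to the *rnpB* internal standard and
referenced to the HL 06:00 calibrator sample.  Amplification efficiency is
assumed to be 2.0 (one doubling per cycle), the standard comparative-CT
assumption.  Technical duplicates are averaged on the CT scale before any
differencing; their mean absolute deviation is propagated to an RQ range by
interval arithmetic, matching the error-bar convention of diel expression
plots.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["ddct", "de_call", "load_primer_table", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("gene", "condition", "time_h", "replicate", "ct")

#: Comparative-CT differential-expression threshold on the log2 scale: genes
#: with |log2 FC| <= 1 are called not differentially expressed.
DE_THRESHOLD_LOG2 = 1.0


def load_primer_table() -> pd.DataFrame:
    """qPCR primer sets for the *P. marinus* PCC9511 diel expression panel.

    Metadata fixture used for input validation only (known locus tags and
    gene names); the sequences themselves are not used computationally.
    """
    with resources.files("dielcycle.data").joinpath(
        "qpcr_primers_pcc9511.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"CT table is missing column(s): {', '.join(missing)}")
    ct = records["ct"].to_numpy(dtype=float)
    if np.any(~np.isfinite(ct)) or np.any(ct <= 0) or np.any(ct >= 45):
        raise ValueError("CT values must lie in (0, 45)")
    return records


def _mean_mad_ct(records: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates on the CT scale; keep their spread."""
    g = records.groupby(["gene", "condition", "time_h"])["ct"]
    out = g.agg(ct_mean="mean", ct_mad=lambda x: np.mean(np.abs(x - x.mean())))
    return out.reset_index()


def de_call(log2_fc, threshold_log2: float = DE_THRESHOLD_LOG2):
    """Differential-expression call: ``|log2 FC| > threshold`` (strict)."""
    return np.abs(np.asarray(log2_fc)) > threshold_log2


def ddct(
    records: pd.DataFrame,
    target: str,
    reference_gene: str = "rnpB",
    calibrator=("HL", 6.0),
    threshold_log2: float = DE_THRESHOLD_LOG2,
    validate_genes: bool = False,
) -> pd.DataFrame:
    """Relative expression of ``target`` by the comparative-CT method.

    Per sample (condition, time): ``dCT = mean CT_target - mean CT_ref``;
    ``ddCT = dCT - dCT_calibrator``; ``RQ = 2^-ddCT``.  The calibrator's own
    RQ is exactly 1.

    Parameters
    ----------
    records : DataFrame
        Long-format CT table with columns ``gene, condition, time_h,
        replicate, ct``.
    target : str
        Gene to quantify.
    reference_gene : str
        Internal standard (default *rnpB*).
    calibrator : (condition, time_h)
        Reference sample all RQs are expressed against (default HL 06:00).
    validate_genes : bool
        Check gene names against the shipped primer panel.

    Returns
    -------
    DataFrame with columns ``gene, condition, time_h, d_ct, d_ct_mad,
    dd_ct, rq, rq_lo, rq_hi, log2_fc, de_call``.
    """
    records = _validate(records)
    if validate_genes:
        known = set(load_primer_table()["gene"])
        for g in (target, reference_gene):
            if g not in known:
                raise ValueError(f"unknown gene {g!r}: not in the qPCR primer panel")

    means = _mean_mad_ct(records)
    tgt = means[means["gene"] == target].set_index(["condition", "time_h"])
    ref = means[means["gene"] == reference_gene].set_index(["condition", "time_h"])
    if tgt.empty:
        raise ValueError(f"no CT measurements for target gene {target!r}")
    missing_ref = tgt.index.difference(ref.index)
    if len(missing_ref):
        raise ValueError(
            f"missing reference-gene ({reference_gene}) CT for sample(s): "
            f"{list(missing_ref)}"
        )

    d_ct = tgt["ct_mean"] - ref.loc[tgt.index, "ct_mean"]
    d_ct_mad = tgt["ct_mad"] + ref.loc[tgt.index, "ct_mad"]

    cal_key = (calibrator[0], float(calibrator[1]))
    if cal_key not in d_ct.index:
        raise ValueError(
            f"calibrator sample {cal_key} absent from the CT table for {target!r}"
        )
    dd_ct = d_ct - d_ct.loc[[cal_key]].iloc[0]
    u = d_ct_mad + d_ct_mad.loc[[cal_key]].iloc[0]

    out = pd.DataFrame(
        {
            "gene": target,
            "condition": [k[0] for k in d_ct.index],
            "time_h": [k[1] for k in d_ct.index],
            "d_ct": d_ct.to_numpy(),
            "d_ct_mad": d_ct_mad.to_numpy(),
            "dd_ct": dd_ct.to_numpy(),
        }
    )
    out["rq"] = 2.0 ** (-out["dd_ct"])
    out["rq_lo"] = 2.0 ** (-(out["dd_ct"] + u.to_numpy()))
    out["rq_hi"] = 2.0 ** (-(out["dd_ct"] - u.to_numpy()))
    out["log2_fc"] = -out["dd_ct"]
    out["de_call"] = de_call(out["log2_fc"], threshold_log2)
    return out.sort_values(["condition", "time_h"]).reset_index(drop=True)
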