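"""qPCR Ct preprocessing: detection filtering and global-centre normalization.

The raw input is a miRNA x sample matrix of threshold-cycle (Ct) values from
a TaqMan-array style assay; lower Ct means higher abundance (one cycle is
roughly a two-fold change).  Undetected reactions are missing values, never
an imputed Ct.  Relative expression is reported as negative centred Ct so
that larger values mean more abundant, which is how correlation signs are
interpreted downstream.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

DEFAULT_CT_CUTOFF = 35.0
DEFAULT_MIN_FRACTION = 0.25


def _validate_ct(ct: pd.DataFrame) -> None:
    if not isinstance(ct, pd.DataFrame):
        raise TypeError("Ct matrix must be a pandas DataFrame (miRNA x sample)")
    if ct.index.has_duplicates or ct.columns.has_duplicates:
        raise ValueError("duplicate miRNA or sample identifiers")
    vals = ct.to_numpy(dtype=float)
    detected = vals[~np.isnan(vals)]
    if detected.size and (np.any(detected <= 0) or np.any(detected > 45)):
        raise ValueError("detected Ct values must lie in (0, 45]")


def filter_informative(
    ct: pd.DataFrame,
    ct_cutoff: float = DEFAULT_CT_CUTOFF,
    min_fraction: float = DEFAULT_MIN_FRACTION,
) -> pd.DataFrame:
    """Keep miRNAs detected below ``ct_cutoff`` in at least ``min_fraction`` of samples.

    Detection is strict (``Ct < ct_cutoff``); the sample fraction is
    inclusive (``>= min_fraction``).  Row order is preserved.  The operation
    is idempotent.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    _validate_ct(ct)
    vals = ct.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        frac = np.mean(np.nan_to_num(vals, nan=np.inf) < ct_cutoff, axis=1)
    keep = frac >= min_fraction
    if not keep.any():
        warnings.warn("no miRNA passes the informative filter", stacklevel=2)
    return ct.loc[keep]


def normalize_global_centre(
    ct: pd.DataFrame, statistic: str = "mean"
) -> pd.DataFrame:
    """ΔCt-style between-sample normalization against a global per-sample centre.

    For each sample the centring statistic (mean or median) of its detected
    Ct values over the informative miRNAs is the normalization factor;
    relative expression is ``-(Ct - centre)`` so that one unit is about a
    two-fold change and larger means more abundant.  Undetected entries stay
    missing.
    """
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    _validate_ct(ct)
    n_detected = ct.notna().sum(axis=0)
    empty = n_detected[n_detected == 0]
    if len(empty):
        raise ValueError(
            f"samples with no detected miRNA: {list(empty.index)[:5]}"
        )
    centre = ct.mean(axis=0) if statistic == "mean" else ct.median(axis=0)
    expr = -(ct - centre)
    expr.attrs["scale_note"] = f"negative {statistic}-centred Ct"
    return expr


def replicate_concordance(a: pd.DataFrame, b: pd.DataFrame) -> pd.Series:
    """Per-sample Pearson r between two replicate expression matrices.

    Matrices must share feature and sample ids; r is computed on
    pairwise-complete features and requires at least 3 complete pairs.
    """
    if not (a.index.equals(b.index) and a.columns.equals(b.columns)):
        raise ValueError("replicate matrices must share feature and sample ids")
    out = {}
    for s in a.columns:
        x, y = a[s], b[s]
        ok = x.notna() & y.notna()
        if ok.sum() < 3:
            raise ValueError(f"sample {s}: fewer than 3 complete feature pairs")
        out[s] = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return pd.Series(out, name="pearson_r")
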