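"""Tabular summaries of replicate estimations and prediction errors.

Canonical outputs are CSV-ready DataFrames shaped like the boxplot data of
a simulation study: per-parameter bias/spread across replicate fits, and
per-group quantiles of relative prediction differences.  Plotting is left
to the caller; the summaries are pure functions of their inputs.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .model_core import Theta

__all__ = ["flatten_theta", "estimation_summary", "prediction_summary"]


def flatten_theta(theta: Theta, fixed_names: Optional[Sequence[str]] = None) -> Dict[str, float]:
    """One scalar per parameter: beta entries, sigma2, upper triangles of P, G."""
    out: Dict[str, float] = {}
    for j, b in enumerate(theta.beta):
        name = fixed_names[j] if fixed_names else f"beta_{j + 1}"
        out[name] = float(b)
    out["sigma2"] = theta.sigma2
    for label, mat in (("P", theta.P), ("G", theta.G)):
        n = mat.shape[0]
        for a in range(n):
            for b in range(a, n):
                out[f"{label}_{a + 1}{b + 1}"] = float(mat[a, b])
    return out


def estimation_summary(
    estimates: List[Theta],
    truth: Theta,
    fixed_names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Bias and spread of replicate estimates against the generating value.

    Relative bias is (mean - truth) / truth, NaN where the truth is zero.
    """
    if len(estimates) < 2:
        raise ValueError("need at least two replicate estimates")
    rows = [flatten_theta(est, fixed_names) for est in estimates]
    frame = pd.DataFrame(rows)
    true_flat = flatten_theta(truth, fixed_names)
    records = []
    for name in frame.columns:
        vals = frame[name].to_numpy()
        true_val = true_flat.get(name, np.nan)
        mean = float(vals.mean())
        rel_bias = (mean - true_val) / true_val if true_val else np.nan
        records.append(
            {
                "parameter": name,
                "truth": true_val,
                "mean": mean,
                "median": float(np.median(vals)),
                "sd": float(vals.std(ddof=1)),
                "relative_bias": rel_bias,
            }
        )
    return pd.DataFrame(records)


def prediction_summary(
    differences: pd.DataFrame,
    by: Sequence[str] = ("scenario", "kind", "index", "condition"),
    value: str = "relative_difference",
) -> pd.DataFrame:
    """Quantiles (5/25/50/75/95%) of relative differences per group."""
    if differences.empty:
        raise ValueError("no relative differences to summarize")
    by = [c for c in by if c in differences.columns]
    quantiles = (0.05, 0.25, 0.50, 0.75, 0.95)

    def agg(grp: pd.Series) -> pd.Series:
        clean = grp.dropna()
        stats = {f"q{int(100 * q)}": clean.quantile(q) for q in quantiles}
        stats["mean_abs"] = clean.abs().mean()
        stats["count"] = clean.size
        return pd.Series(stats)

    grouped = (
        differences.groupby(by, dropna=False)[value].apply(agg).unstack().reset_index()
    )
    return grouped
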