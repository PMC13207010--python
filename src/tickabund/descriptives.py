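"""Exploratory summaries of multistage count panels.

These are the standard first-look diagnostics for ecological count data:
per-stage mean, variance, variance-to-mean ratio (VMR), observed zero
proportion and the zero proportion a Poisson model with the same mean would
predict.  A VMR far above 1 together with an observed zero fraction far above
``exp(-mean)`` is the classic signature of overdispersion plus excess zeros
that motivates NB / ZINB modelling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .panel import STAGES

__all__ = ["expected_zero_poisson", "vmr", "describe_counts"]


def expected_zero_poisson(mean: float) -> float:
    """Zero probability of a Poisson with the given mean, ``exp(-mean)``."""
    if mean < 0:
        raise ValueError("mean must be non-negative")
    return float(np.exp(-mean))


def vmr(mean: float, variance: float) -> float:
    """Variance-to-mean ratio."""
    if mean <= 0:
        raise ValueError("mean must be positive for a VMR")
    return float(variance / mean)


def describe_counts(panel: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Stage-wise mean, variance, VMR, zero proportion, Poisson expected zero."""
    rows = {}
    for stage in STAGES:
        y = panel[stage].to_numpy(float)
        m = y.mean()
        v = y.var(ddof=ddof)
        rows[stage] = {
            "mean": m,
            "variance": v,
            "vmr": v / m if m > 0 else np.nan,
            "prop_zero": float((y == 0).mean()),
            "expected_zero_poisson": expected_zero_poisson(m),
        }
    return pd.DataFrame(rows).T
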