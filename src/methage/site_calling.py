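"""Binomial methylation-site calling against the bisulfite non-conversion null.

A truly unmethylated cytosine still reads methylated at the non-conversion
rate ``r`` (estimated from an unmethylated spike-in control).  Each covered
site is therefore tested with the exact binomial upper tail
``P(X >= n_meth | X ~ Binomial(depth, r))``; Benjamini-Hochberg q-values are
computed per sequence context (CG / CHG / CHH differ in base rate by orders
of magnitude), and a site is called methylated at q <= 0.05 with depth >= 5.

Methylation levels: ``ml_raw = n_meth / depth`` and the conversion-corrected
``ml_corrected = (ml_raw - r) / (1 - r)`` clipped to [0, 1], the linear form
whose expectation removes the additive non-conversion noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConversionStats",
    "binomial_site_pvalue",
    "call_sites",
    "corrected_ml",
    "estimate_nonconversion_rate",
]

DEFAULT_MIN_DEPTH = 5
DEFAULT_Q_MAX = 0.05


@dataclass(frozen=True)
class ConversionStats:
    """Spike-in-derived bisulfite non-conversion rate."""

    r: float
    n_meth_spike: int
    n_total_spike: int


def estimate_nonconversion_rate(spike: pd.DataFrame) -> ConversionStats:
    """Pooled methylated fraction of the (fully unmethylated) spike-in control.

    ``r = sum(n_meth) / sum(n_meth + n_unmeth)`` over all spike-in records.
    """
    n_meth = int(spike["n_meth"].sum())
    n_total = int(n_meth + spike["n_unmeth"].sum())
    if n_total == 0:
        raise ValueError("cannot estimate conversion rate: spike-in has zero total depth")
    return ConversionStats(r=n_meth / n_total, n_meth_spike=n_meth, n_total_spike=n_total)


def binomial_site_pvalue(n_meth, depth, r: float):
    """Exact upper-tail ``P(X >= n_meth)`` for ``X ~ Binomial(depth, r)``.

    Accepts scalars or arrays; monotone non-increasing in ``n_meth`` at
    fixed ``depth`` and ``r``.
    """
    n_meth = np.asarray(n_meth)
    depth = np.asarray(depth)
    if np.any(n_meth > depth) or np.any(n_meth < 0):
        raise ValueError("require 0 <= n_meth <= depth")
    if not 0 <= r <= 1:
        raise ValueError("require 0 <= r <= 1")
    # sf(k-1) = P(X >= k); exact for the discrete binomial
    p = stats.binom.sf(n_meth - 1, depth, r)
    return float(p) if p.ndim == 0 else p


def corrected_ml(n_meth, n_unmeth, r: float):
    """Conversion-corrected methylation level ``(ml - r) / (1 - r)``, clipped to [0, 1].

    Scalars or arrays; ``r = 0`` returns the raw level.  Zero depth is
    undefined and raises.
    """
    n_meth = np.asarray(n_meth, dtype=float)
    n_unmeth = np.asarray(n_unmeth, dtype=float)
    depth = n_meth + n_unmeth
    if np.any(depth <= 0):
        raise ValueError("no coverage: corrected_ml undefined at zero depth")
    if not 0 <= r < 1:
        raise ValueError("require 0 <= r < 1")
    ml = n_meth / depth
    out = np.clip((ml - r) / (1.0 - r), 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def call_sites(
    records: pd.DataFrame,
    conversion: ConversionStats,
    min_depth: int = DEFAULT_MIN_DEPTH,
    q_max: float = DEFAULT_Q_MAX,
) -> pd.DataFrame:
    """Test every covered cytosine and attach levels, p/q-values and calls.

    Returns the input columns plus ``depth``, ``ml_raw``, ``ml_corrected``,
    ``tested``, ``p_value``, ``q_value``, ``is_methylated``.  Sites below
    ``min_depth`` are excluded from testing (NaN p/q, never called) but keep
    their levels when covered, since profile statistics average levels over
    all covered sites.  BH runs separately within each context class.
    """
    out = records.copy()
    n = len(out)
    if n == 0:
        for col in ("depth", "ml_raw", "ml_corrected", "p_value", "q_value"):
            out[col] = pd.Series(dtype=float)
        out["tested"] = pd.Series(dtype=bool)
        out["is_methylated"] = pd.Series(dtype=bool)
        return out

    n_meth = out["n_meth"].to_numpy()
    depth = n_meth + out["n_unmeth"].to_numpy()
    out["depth"] = depth
    covered = depth > 0
    ml_raw = np.full(n, np.nan)
    ml_raw[covered] = n_meth[covered] / depth[covered]
    out["ml_raw"] = ml_raw
    ml_corr = np.full(n, np.nan)
    ml_corr[covered] = np.clip((ml_raw[covered] - conversion.r) / (1.0 - conversion.r), 0.0, 1.0)
    out["ml_corrected"] = ml_corr

    tested = depth >= min_depth
    out["tested"] = tested
    p = np.full(n, np.nan)
    p[tested] = stats.binom.sf(n_meth[tested] - 1, depth[tested], conversion.r)
    out["p_value"] = p

    q = np.full(n, np.nan)
    ctx = out["context"].to_numpy()
    for c in np.unique(ctx):
        sel = tested & (ctx == c)
        if sel.any():
            q[sel] = multipletests(p[sel], method="fdr_bh")[1]
    out["q_value"] = q
    out["is_methylated"] = tested & (q <= q_max)
    return out
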