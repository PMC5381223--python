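"""Sliding-window two-group differential methylation scan.

1000-bp windows slid in 100-bp steps; within each window the methylated /
unmethylated read counts of each pooled group are totalled and compared with
a two-sided Fisher's exact test (one pooled library per group leaves no
within-group replication, so the pooled-count 2x2 test is the natural
choice).  Windows pass when p < 0.05, mean depth per covered cytosine > 5 in
both groups, fold change of the mean corrected level > 2, and
Benjamini-Hochberg FDR < 0.05; runs of significant windows that overlap or
abut within one step are merged into DMRs, directed hyper/hypo for group 2
versus group 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import FunctionalElement

__all__ = [
    "DMR",
    "DmrConfig",
    "WINDOW_COLUMNS",
    "call_dmrs",
    "dmr_direction",
    "dmr_feature_distribution",
    "generate_windows",
    "scan_and_call",
    "scan_windows",
    "test_window",
]

_EPS = 1e-6


@dataclass(frozen=True)
class DmrConfig:
    """Scan geometry and the four significance filters."""

    window: int = 1000
    step: int = 100
    p_max: float = 0.05
    min_coverage: float = 5.0  # mean depth per covered cytosine, both groups
    min_fold_change: float = 2.0
    fdr_max: float = 0.05
    context: str = "CG"

    def __post_init__(self) -> None:
        if self.window <= 0 or self.step <= 0:
            raise ValueError("window and step must be positive")
        if self.step > self.window:
            raise ValueError("step > window would leave unscanned gaps")
        for name in ("p_max", "min_coverage", "min_fold_change", "fdr_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class DMR:
    """A merged run of significant windows."""

    chrom: str
    start: int
    end: int
    n_windows: int
    ml_g1: float
    ml_g2: float
    fold_change: float  # max over constituent windows
    p_value: float  # min over constituent windows
    fdr: float  # min over constituent windows
    direction: str = ""

    def __post_init__(self) -> None:
        if not self.direction:
            self.direction = dmr_direction(self)


def generate_windows(chrom_length: int, window: int = 1000, step: int = 100) -> np.ndarray:
    """Window spans ``[i*step, i*step + window)`` with ``start + window <= length``.

    A chromosome shorter than one window yields a single window covering it
    entirely.  Returns an (n, 2) int array.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if step > window:
        raise ValueError("step > window would leave unscanned gaps")
    if chrom_length <= 0:
        return np.empty((0, 2), dtype=np.int64)
    if chrom_length <= window:
        return np.array([[0, chrom_length]], dtype=np.int64)
    starts = np.arange(0, chrom_length - window + 1, step, dtype=np.int64)
    return np.column_stack([starts, starts + window])


def test_window(
    g1_counts: tuple[int, int], g2_counts: tuple[int, int], epsilon: float = _EPS
) -> tuple[float, float]:
    """Two-sided Fisher's exact p and directionless fold change for one window.

    ``g*_counts`` are the pooled (n_meth, n_unmeth) of each group; the fold
    change is the ratio of pooled methylation levels (pseudocount
    ``epsilon``), taken >= 1.  Raises when both groups have zero depth.
    """
    m1, u1 = g1_counts
    m2, u2 = g2_counts
    d1, d2 = m1 + u1, m2 + u2
    if d1 == 0 and d2 == 0:
        raise ValueError("window has zero depth in both groups")
    p = stats.fisher_exact([[m1, u1], [m2, u2]], alternative="two-sided")[1]
    ml1 = m1 / d1 if d1 else 0.0
    ml2 = m2 / d2 if d2 else 0.0
    ratio = (ml2 + epsilon) / (ml1 + epsilon)
    return float(p), float(max(ratio, 1.0 / ratio))


WINDOW_COLUMNS = [
    "chrom", "start", "end",
    "m1", "u1", "m2", "u2",
    "sites1", "sites2",
    "mean_depth1", "mean_depth2",
    "ml_g1", "ml_g2",
    "fold_change", "p_value",
]


def _window_sums(pos0: np.ndarray, values: np.ndarray, length: int, spans: np.ndarray) -> np.ndarray:
    acc = np.zeros(length + 1, dtype=float)
    np.add.at(acc, np.asarray(pos0, dtype=np.int64) + 1, values)
    cs = np.cumsum(acc)
    return cs[spans[:, 1]] - cs[spans[:, 0]]


def scan_windows(
    calls_g1: pd.DataFrame,
    calls_g2: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    config: DmrConfig = DmrConfig(),
) -> pd.DataFrame:
    """Test every window of every chromosome; one row per tested window.

    Only the configured context is scanned (CG by default; non-CpG signal
    would otherwise dilute it).  Windows with no covered cytosine in either
    group are skipped.  Output is independent of input row order.
    """
    rows = []
    g1 = calls_g1[(calls_g1["context"] == config.context) & (calls_g1["depth"] > 0)]
    g2 = calls_g2[(calls_g2["context"] == config.context) & (calls_g2["depth"] > 0)]
    for chrom in chrom_sizes:
        length = int(chrom_sizes[chrom])
        spans = generate_windows(length, config.window, config.step)
        if len(spans) == 0:
            continue
        per_group = []
        for g in (g1, g2):
            sub = g[g["chrom"] == chrom]
            pos0 = sub["pos"].to_numpy() - 1
            meth = _window_sums(pos0, sub["n_meth"].to_numpy(float), length, spans)
            unmeth = _window_sums(pos0, sub["n_unmeth"].to_numpy(float), length, spans)
            mlsum = _window_sums(pos0, sub["ml_corrected"].to_numpy(float), length, spans)
            nsites = _window_sums(pos0, np.ones(len(sub)), length, spans)
            per_group.append((meth, unmeth, mlsum, nsites))
        (m1, u1, s1, n1), (m2, u2, s2, n2) = per_group
        tested = (n1 > 0) & (n2 > 0)
        for i in np.flatnonzero(tested):
            ml1 = s1[i] / n1[i]
            ml2 = s2[i] / n2[i]
            ratio = (ml2 + _EPS) / (ml1 + _EPS)
            p = stats.fisher_exact(
                [[int(m1[i]), int(u1[i])], [int(m2[i]), int(u2[i])]]
            )[1]
            rows.append(
                (
                    chrom, int(spans[i, 0]), int(spans[i, 1]),
                    int(m1[i]), int(u1[i]), int(m2[i]), int(u2[i]),
                    int(n1[i]), int(n2[i]),
                    (m1[i] + u1[i]) / n1[i], (m2[i] + u2[i]) / n2[i],
                    ml1, ml2,
                    float(max(ratio, 1.0 / ratio)), float(p),
                )
            )
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def call_dmrs(windows: pd.DataFrame, config: DmrConfig = DmrConfig()) -> list[DMR]:
    """Apply the significance filters, then merge significant windows into DMRs.

    BH FDR is computed across *all* tested windows.  Significant windows on
    one chromosome merge when their spans overlap or lie within one step of
    each other; the DMR span is the union, its level the mean of its
    windows' levels, fold change the max, p and FDR the min.
    """
    if len(windows) == 0:
        return []
    windows = windows.copy()
    windows["fdr"] = multipletests(windows["p_value"].to_numpy(), method="fdr_bh")[1]
    sig = windows[
        (windows["p_value"] < config.p_max)
        & (windows["mean_depth1"] > config.min_coverage)
        & (windows["mean_depth2"] > config.min_coverage)
        & (windows["fold_change"] > config.min_fold_change)
        & (windows["fdr"] < config.fdr_max)
    ]
    dmrs: list[DMR] = []
    for chrom, sub in sig.groupby("chrom", observed=True):
        sub = sub.sort_values("start")
        run: list[pd.Series] = []
        run_end = -1
        for _, w in sub.iterrows():
            if run and w["start"] > run_end + config.step:
                dmrs.append(_merge_run(chrom, run))
                run = []
            run.append(w)
            run_end = max(run_end, int(w["end"]))
        if run:
            dmrs.append(_merge_run(chrom, run))
    dmrs.sort(key=lambda d: (d.chrom, d.start))
    return dmrs


def _merge_run(chrom: str, run: Sequence[pd.Series]) -> DMR:
    return DMR(
        chrom=chrom,
        start=int(min(w["start"] for w in run)),
        end=int(max(w["end"] for w in run)),
        n_windows=len(run),
        ml_g1=float(np.mean([w["ml_g1"] for w in run])),
        ml_g2=float(np.mean([w["ml_g2"] for w in run])),
        fold_change=float(max(w["fold_change"] for w in run)),
        p_value=float(min(w["p_value"] for w in run)),
        fdr=float(min(w["fdr"] for w in run)),
    )


def dmr_direction(dmr: DMR) -> str:
    """'hyper' when group 2 exceeds group 1, 'hypo' when below, else 'ambiguous'."""
    if dmr.ml_g2 > dmr.ml_g1:
        return "hyper"
    if dmr.ml_g2 < dmr.ml_g1:
        return "hypo"
    return "ambiguous"


def scan_and_call(
    calls_g1: pd.DataFrame,
    calls_g2: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    config: DmrConfig = DmrConfig(),
) -> list[DMR]:
    """Convenience wrapper: scan all windows, then filter and merge."""
    return call_dmrs(scan_windows(calls_g1, calls_g2, chrom_sizes, config), config)


def dmr_feature_distribution(
    dmrs: Sequence[DMR],
    elements: Sequence[FunctionalElement],
    classes: Sequence[str] = ("promoter", "utr5", "exon", "intron", "utr3", "intergenic"),
) -> pd.DataFrame:
    """Fraction of DMR-element assignments per class (multi-label).

    Each DMR counts once in *every* gene-element class it overlaps; a DMR
    overlapping no element counts as intergenic.  Fractions are taken over
    total assignments, so they sum to 1.
    """
    trees: dict[str, IntervalTree] = {}
    for e in elements:
        trees.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end, e.element)
    counts = {c: 0 for c in classes}
    for d in dmrs:
        tree = trees.get(d.chrom)
        hit = {iv.data for iv in tree.overlap(d.start, d.end)} if tree is not None else set()
        hit = {h for h in hit if h in counts}
        if not hit:
            hit = {"intergenic"}
        for h in hit:
            counts[h] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "element": list(classes),
            "count": [counts[c] for c in classes],
            "fraction": [counts[c] / total if total else np.nan for c in classes],
        }
    )
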