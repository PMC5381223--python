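"""Genome-wide descriptive methylation summaries.

Composition statistics (which contexts the methylcytosines fall in, what
fraction of each context is methylated) use the binomial *calls*; level
statistics (per chromosome, per functional element, metagene) average
``ml_corrected`` over all covered sites, called or not — levels and calls
answer different questions and are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import CONTEXTS, ElementLabeler, GeneModel

__all__ = [
    "ContextComposition",
    "chromosome_levels",
    "context_composition",
    "feature_levels",
    "metagene_profile",
    "neighbor_base_context",
    "track_levels",
]


@dataclass(frozen=True)
class ContextComposition:
    """Methylcytosine counts per context under two distinct normalisations.

    ``fraction_of_mc``: share of each context among methylcytosines
    (sums to 1).  ``methylation_rate``: fraction of covered sites of that
    context that are called methylated (mC_context / C_context).
    """

    n_methylated: dict[str, int]
    n_sites: dict[str, int]
    fraction_of_mc: dict[str, float]
    methylation_rate: dict[str, float]

    @property
    def total_methylated(self) -> int:
        return sum(self.n_methylated.values())


def context_composition(calls: pd.DataFrame) -> ContextComposition:
    """Composition of methylcytosines by context plus per-context call rates.

    Raises ``ValueError`` when no site is called methylated (fractions
    would be undefined).
    """
    covered = calls[calls["depth"] > 0]
    n_meth = {c: int(((covered["context"] == c) & covered["is_methylated"]).sum()) for c in CONTEXTS}
    n_sites = {c: int((covered["context"] == c).sum()) for c in CONTEXTS}
    total = sum(n_meth.values())
    if total == 0:
        raise ValueError("no methylated sites: composition fractions undefined")
    fraction = {c: n_meth[c] / total for c in CONTEXTS}
    rate = {c: (n_meth[c] / n_sites[c]) if n_sites[c] else np.nan for c in CONTEXTS}
    return ContextComposition(n_meth, n_sites, fraction, rate)


def chromosome_levels(calls: pd.DataFrame) -> pd.DataFrame:
    """Mean ``ml_corrected`` per chromosome x context over covered sites.

    Chromosomes with no covered sites simply do not appear (missing, not 0).
    """
    covered = calls[calls["depth"] > 0]
    out = (
        covered.groupby(["chrom", "context"], observed=True)["ml_corrected"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "level", "count": "n_sites"})
        .reset_index()
    )
    return out


def feature_levels(calls: pd.DataFrame, labeler: ElementLabeler) -> pd.DataFrame:
    """Mean level and site count per disjoint element class x context.

    Each covered site counts exactly once, under the highest-precedence
    element covering it (promoter > UTRs > exon > intron > CGI > repeat >
    intergenic); unannotated chromosomes are intergenic.
    """
    covered = calls[calls["depth"] > 0].copy()
    labels = np.empty(len(covered), dtype=object)
    for chrom, idx in covered.groupby("chrom", observed=True).indices.items():
        pos0 = covered["pos"].to_numpy()[idx] - 1
        labels[idx] = labeler.label_positions(chrom, pos0)
    covered["element"] = labels
    out = (
        covered.groupby(["element", "context"], observed=True)["ml_corrected"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "level", "count": "n_sites"})
        .reset_index()
    )
    return out


def track_levels(calls: pd.DataFrame, track) -> pd.DataFrame:
    """Mean level per context over *all* covered sites inside a named track
    (CGI or repeat), ignoring element precedence — the track plotted as its
    own class."""
    covered = calls[calls["depth"] > 0]
    mask = np.zeros(len(covered), dtype=bool)
    pos0_all = covered["pos"].to_numpy() - 1
    chrom_arr = covered["chrom"].to_numpy()
    for chrom, ivs in track.intervals.items():
        if len(ivs) == 0:
            continue
        on = chrom_arr == chrom
        if not on.any():
            continue
        pos0 = pos0_all[on]
        i = np.searchsorted(ivs[:, 0], pos0, side="right")
        inside = (i > 0) & (pos0 < ivs[np.maximum(i - 1, 0), 1])
        mask[np.flatnonzero(on)[inside]] = True
    sub = covered[mask]
    return (
        sub.groupby("context", observed=True)["ml_corrected"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "level", "count": "n_sites"})
        .reset_index()
        .assign(track=track.name)
    )


def metagene_profile(
    calls: pd.DataFrame,
    genes: Iterable[GeneModel],
    flank: int = 2000,
    flank_bins: int = 20,
    body_bins: int = 60,
) -> pd.DataFrame:
    """Mean methylation in bins over upstream flank / scaled gene body / downstream flank.

    Gene bodies are rescaled to ``body_bins`` relative bins; minus-strand
    genes are flipped so bin 0 is always the 5' end.  Genes shorter than
    ``body_bins`` bp are skipped.  Returns a tidy frame with ``bin``
    (0 .. flank_bins+body_bins+flank_bins-1), ``zone``, ``context``,
    ``level`` and ``n_sites``; bins with no sites are absent.
    """
    total_bins = 2 * flank_bins + body_bins
    covered = calls[calls["depth"] > 0]
    sums: dict[str, np.ndarray] = {c: np.zeros(total_bins) for c in CONTEXTS}
    counts: dict[str, np.ndarray] = {c: np.zeros(total_bins, dtype=np.int64) for c in CONTEXTS}
    by_chrom = {chrom: sub for chrom, sub in covered.groupby("chrom", observed=True)}

    for g in genes:
        body_len = g.tx_end - g.tx_start
        if body_len < body_bins:
            continue
        sub = by_chrom.get(g.chrom)
        if sub is None:
            continue
        pos0 = sub["pos"].to_numpy() - 1
        sel = (pos0 >= g.tx_start - flank) & (pos0 < g.tx_end + flank)
        if not sel.any():
            continue
        p = pos0[sel]
        if g.strand == "-":  # mirror so the 5' end comes first
            p = (g.tx_start + g.tx_end - 1) - p
        bins = np.empty(len(p), dtype=np.int64)
        up = p < g.tx_start
        body = (p >= g.tx_start) & (p < g.tx_end)
        down = p >= g.tx_end
        bins[up] = (p[up] - (g.tx_start - flank)) * flank_bins // flank
        bins[body] = flank_bins + (p[body] - g.tx_start) * body_bins // body_len
        bins[down] = flank_bins + body_bins + (p[down] - g.tx_end) * flank_bins // flank
        ml = sub["ml_corrected"].to_numpy()[sel]
        ctx = sub["context"].to_numpy()[sel]
        for c in CONTEXTS:
            m = ctx == c
            if m.any():
                np.add.at(sums[c], bins[m], ml[m])
                np.add.at(counts[c], bins[m], 1)

    rows = []
    zone = ["upstream"] * flank_bins + ["body"] * body_bins + ["downstream"] * flank_bins
    for c in CONTEXTS:
        for b in range(total_bins):
            if counts[c][b] > 0:
                rows.append((b, zone[b], c, sums[c][b] / counts[c][b], int(counts[c][b])))
    return pd.DataFrame(rows, columns=["bin", "zone", "context", "level", "n_sites"])


_COMP_TABLE = str.maketrans("ACGT", "TGCA")


def neighbor_base_context(
    calls: pd.DataFrame,
    sequences: Mapping[str, str],
    k: int = 4,
) -> pd.DataFrame:
    """Base frequencies at offsets -k..+k around called methylcytosines.

    The window is read 5'->3' on the site's own strand (minus-strand windows
    are reverse-complemented), so offset 0 is always C.  Sites within ``k``
    of a chromosome edge are skipped.  Returns a tidy frame:
    context, offset, base, count, frequency.
    """
    meth = calls[calls["is_methylated"]]
    counts: dict[tuple[str, int, str], int] = {}
    for chrom, sub in meth.groupby("chrom", observed=True):
        seq = sequences.get(chrom)
        if seq is None:
            continue
        L = len(seq)
        for pos, strand, ctx in zip(sub["pos"], sub["strand"], sub["context"]):
            c = pos - 1
            if c - k < 0 or c + k >= L:
                continue
            window = seq[c - k : c + k + 1]
            if strand == "-":
                window = window.translate(_COMP_TABLE)[::-1]
            for off, base in zip(range(-k, k + 1), window):
                key = (ctx, off, base)
                counts[key] = counts.get(key, 0) + 1
    rows = [(ctx, off, base, n) for (ctx, off, base), n in sorted(counts.items())]
    df = pd.DataFrame(rows, columns=["context", "offset", "base", "count"])
    if len(df):
        totals = df.groupby(["context", "offset"])["count"].transform("sum")
        df["frequency"] = df["count"] / totals
    else:
        df["frequency"] = pd.Series(dtype=float)
    return df
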