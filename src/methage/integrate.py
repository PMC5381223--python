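"""DMR-to-gene annotation and integration with expression and trait data.

A gene whose functional element (promoter, 5'UTR, exon, intron, 3'UTR)
overlaps a DMR is a differentially methylated gene (DMG).  DMGs are
intersected with differentially expressed genes (DEGs), stratified by
expression class, correlated with phenotypic traits, and filtered down to
promoter-hypermethylated / down-regulated candidate genes — the signature of
promoter methylation silencing a gene.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import FunctionalElement

__all__ = [
    "DMGRecord",
    "RelativeExpression",
    "expression_class_split",
    "load_example_dmg_deg_table",
    "map_dmrs_to_genes",
    "methylation_by_expression_class",
    "overlap_dmg_deg",
    "relative_expression",
    "select_candidates",
    "trait_correlation",
]

logger = logging.getLogger(__name__)

GENE_ELEMENT_ORDER = ("promoter", "utr5", "exon", "intron", "utr3")

# Published 18-row DMG x DEG table from a chicken breast-muscle ageing
# comparison (juvenile vs later laying-period hens); bundled as the package's
# worked example for the candidate-gene filter.
_EXAMPLE_DMG_DEG_TSV = """\
gene_id\tgene_name\tdmr_elements\tmethylation_stat\tregulation
ENSGALG00000015433\tABCA1\texon, utr5, promoter\tHyper\tDown
ENSGALG00000015960\tADAMTS2\tintron\tHyper\tDown
ENSGALG00000000621\tANKRD47\tpromoter\tHyper\tDown
ENSGALG00000005974\tCOL6A1\tpromoter\tHyper\tDown
ENSGALG00000003439\tCRY2\texon, intron\tHyper\tDown
ENSGALG00000006000\tEPHB2\tintron\tHypo\tDown
ENSGALG00000005204\tGSTT1L\tpromoter\tHyper\tDown
ENSGALG00000011762\tMALT1\tpromoter\tHyper\tDown
ENSGALG00000017130\tPLEKHM2\tintron\tHyper\tUp
ENSGALG00000001419\tPLXNA4\tintron\tHyper\tUp
ENSGALG00000002699\tRHOG\tintron\tHyper\tDown
ENSGALG00000008436\tRPIA\tpromoter\tHyper\tUp
ENSGALG00000004741\tSLC44A1\tintron\tHyper\tUp
ENSGALG00000014525\tSLC47A1\tintron\tHyper\tUp
ENSGALG00000015439\tUBA6\texon, utr5, promoter\tHyper\tUp
ENSGALG00000004583\tUBE4A\tintron\tHypo/hyper\tUp
ENSGALG00000005475\tUSP5\texon, intron\tHyper\tUp
ENSGALG00000002872\tVAV2\tintron\tHypo\tDown
"""


def load_example_dmg_deg_table() -> pd.DataFrame:
    """The bundled 18-gene DMG x DEG example table (joint-table schema)."""
    return pd.read_csv(io.StringIO(_EXAMPLE_DMG_DEG_TSV), sep="\t")


@dataclass
class DMGRecord:
    """One differentially methylated gene with its overlapping elements."""

    gene_id: str
    elements: tuple[str, ...]  # deduplicated, in GENE_ELEMENT_ORDER
    directions: tuple[str, ...] = ()  # per supporting DMR
    dmr_ids: tuple[int, ...] = ()  # indices into the input DMR list

    @property
    def methylation_stat(self) -> str:
        """Majority direction over supporting DMRs; a tie is 'Hypo/hyper'."""
        n_hyper = sum(d == "hyper" for d in self.directions)
        n_hypo = sum(d == "hypo" for d in self.directions)
        if n_hyper and n_hypo:
            if n_hyper == n_hypo:
                return "Hypo/hyper"
            return "Hyper" if n_hyper > n_hypo else "Hypo"
        return "Hyper" if n_hyper else "Hypo"


@dataclass(frozen=True)
class RelativeExpression:
    """2^-ddCt relative abundance for one condition versus the calibrator."""

    condition: str
    delta_ct: float
    delta_delta_ct: float
    fold: float


def map_dmrs_to_genes(dmrs: Sequence, elements: Sequence[FunctionalElement]) -> list[DMGRecord]:
    """One :class:`DMGRecord` per gene with any element <-> DMR overlap.

    Only gene elements (promoter/UTRs/exon/intron) count; CGI and repeat
    tracks do not define DMGs.  Elements are deduplicated and ordered
    promoter, utr5, exon, intron, utr3.
    """
    trees: dict[str, IntervalTree] = {}
    for e in elements:
        if e.element in GENE_ELEMENT_ORDER:
            trees.setdefault(e.chrom, IntervalTree()).addi(e.start, e.end, (e.gene_id, e.element))
    hits: dict[str, dict[str, object]] = {}
    for i, d in enumerate(dmrs):
        tree = trees.get(d.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(d.start, d.end):
            gene_id, element = iv.data
            rec = hits.setdefault(gene_id, {"elements": set(), "directions": [], "dmr_ids": []})
            rec["elements"].add(element)
            if i not in rec["dmr_ids"]:
                rec["dmr_ids"].append(i)
                rec["directions"].append(d.direction)
    out = []
    for gene_id in sorted(hits):
        rec = hits[gene_id]
        ordered = tuple(e for e in GENE_ELEMENT_ORDER if e in rec["elements"])
        out.append(
            DMGRecord(
                gene_id=gene_id,
                elements=ordered,
                directions=tuple(rec["directions"]),
                dmr_ids=tuple(rec["dmr_ids"]),
            )
        )
    return out


def overlap_dmg_deg(dmgs: Sequence[DMGRecord], expression: pd.DataFrame) -> pd.DataFrame:
    """Joint table of genes that are both differentially methylated and expressed.

    Columns: gene_id, dmr_elements (comma-joined), methylation_stat
    (Hyper/Hypo/'Hypo/hyper'), regulation (Up/Down).  DMGs whose gene id is
    absent from the expression table are logged and excluded.
    """
    expr = expression.set_index("gene_id")
    rows = []
    for dmg in dmgs:
        if dmg.gene_id not in expr.index:
            logger.warning("DMG %s absent from expression table; excluded", dmg.gene_id)
            continue
        e = expr.loc[dmg.gene_id]
        if not bool(e["is_de"]):
            continue
        rows.append(
            (dmg.gene_id, ", ".join(dmg.elements), dmg.methylation_stat, e["direction"])
        )
    return pd.DataFrame(rows, columns=["gene_id", "dmr_elements", "methylation_stat", "regulation"])


def select_candidates(
    joint_table: pd.DataFrame,
    require_promoter: bool = True,
    methylation: str | None = None,  # e.g. "Hyper"
    expression: str | None = None,  # e.g. "Down"
) -> pd.DataFrame:
    """Filter the joint DMG x DEG table down to candidate genes.

    ``require_promoter`` keeps genes with a promoter-overlapping DMR; the
    optional ``methylation`` / ``expression`` filters then select e.g. the
    promoter-hypermethylated, transcriptionally down-regulated signature.
    Adding filters never enlarges the set.
    """
    out = joint_table
    if require_promoter and len(out):
        has_promoter = out["dmr_elements"].str.split(r",\s*").apply(lambda els: "promoter" in els)
        out = out[has_promoter]
    if methylation is not None and len(out):
        out = out[out["methylation_stat"] == methylation]
    if expression is not None and len(out):
        out = out[out["regulation"] == expression]
    return out.reset_index(drop=True)


def expression_class_split(expression: pd.DataFrame, fpkm_columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Label each gene low/high expression per sample (median split).

    The cut is the median FPKM among genes with FPKM > 0 in that sample;
    ties at the median and zero-FPKM genes go to 'low'.  The split is
    rank-based, hence invariant under monotone rescaling.
    """
    if fpkm_columns is None:
        fpkm_columns = [c for c in expression.columns if c.startswith("fpkm")]
    out = pd.DataFrame({"gene_id": expression["gene_id"]})
    for col in fpkm_columns:
        fpkm = expression[col].to_numpy(float)
        positive = fpkm[fpkm > 0]
        if len(positive) == 0:
            logger.warning("%s: all FPKM are zero; every gene labelled low", col)
            out[col.replace("fpkm", "class")] = "low"
            continue
        cut = float(np.median(positive))
        out[col.replace("fpkm", "class")] = np.where(fpkm > cut, "high", "low")
    return out


def methylation_by_expression_class(
    calls: pd.DataFrame,
    elements: Sequence[FunctionalElement],
    classes: pd.DataFrame,
    class_column: str,
) -> pd.DataFrame:
    """Mean methylation per expression class x gene element x context.

    For each gene, the mean ``ml_corrected`` over covered sites in each of
    its five elements is computed (multi-label: overlapping elements each
    see the site), then averaged over the genes of each class.  Elements
    with no covered site are missing, not zero.
    """
    covered = calls[calls["depth"] > 0]
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in covered.groupby("chrom", observed=True):
        sub = sub.sort_values("pos")
        pos0 = sub["pos"].to_numpy() - 1
        by_chrom[chrom] = (pos0, sub["ml_corrected"].to_numpy(), sub["context"].to_numpy())

    label = classes.set_index("gene_id")[class_column]
    rows = []
    for e in elements:
        if e.element not in GENE_ELEMENT_ORDER or e.gene_id not in label.index:
            continue
        data = by_chrom.get(e.chrom)
        if data is None:
            continue
        pos0, ml, ctx = data
        lo, hi = np.searchsorted(pos0, [e.start, e.end])
        if hi > lo:
            for c in np.unique(ctx[lo:hi]):
                m = ctx[lo:hi] == c
                rows.append((e.gene_id, label[e.gene_id], e.element, c,
                             float(ml[lo:hi][m].mean()), int(m.sum())))
    per_gene = pd.DataFrame(
        rows, columns=["gene_id", "class", "element", "context", "level", "n_sites"]
    )
    if len(per_gene) == 0:
        return pd.DataFrame(columns=["class", "element", "context", "level", "n_genes"])
    # a gene's element may be split into several intervals: site-weighted mean first
    per_gene = (
        per_gene.assign(w=per_gene["level"] * per_gene["n_sites"])
        .groupby(["gene_id", "class", "element", "context"], observed=True)
        .agg(w=("w", "sum"), n_sites=("n_sites", "sum"))
        .reset_index()
    )
    per_gene["level"] = per_gene["w"] / per_gene["n_sites"]
    out = (
        per_gene.groupby(["class", "element", "context"], observed=True)["level"]
        .agg(["mean", "count"])
        .rename(columns={"mean": "level", "count": "n_genes"})
        .reset_index()
    )
    return out


def trait_correlation(sample_expression: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between each gene's per-sample expression and each trait.

    ``sample_expression`` is genes x samples; ``traits`` has a 'sample'
    column plus numeric trait columns.  Cells need >= 3 paired observations;
    zero variance in either vector leaves the cell NaN (flagged by
    ``defined``).  Returns a tidy frame: gene_id, trait, r, n, defined.
    """
    trait_cols = [c for c in traits.columns if c not in ("sample", "group")]
    tr = traits.set_index("sample")
    samples = [s for s in sample_expression.columns if s in tr.index]
    rows = []
    for gene_id, expr_row in sample_expression[samples].iterrows():
        x = expr_row.to_numpy(float)
        for trait in trait_cols:
            y = tr.loc[samples, trait].to_numpy(float)
            ok = ~(np.isnan(x) | np.isnan(y))
            n = int(ok.sum())
            if n < 3:
                raise ValueError(f"gene {gene_id} x {trait}: fewer than 3 paired observations")
            if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rows.append((gene_id, trait, np.nan, n, False))
            else:
                r = stats.pearsonr(x[ok], y[ok]).statistic
                rows.append((gene_id, trait, float(r), n, True))
    return pd.DataFrame(rows, columns=["gene_id", "trait", "r", "n", "defined"])


def relative_expression(
    ct_target: Mapping[str, float],
    ct_reference: Mapping[str, float],
    calibrator: str,
) -> list[RelativeExpression]:
    """Relative mRNA abundance by the 2^-ddCt method.

    ``dCt = Ct_target - Ct_reference`` per condition;
    ``ddCt = dCt_condition - dCt_calibrator``; ``fold = 2^-ddCt``.
    Every condition needs a reference Ct.
    """
    missing = set(ct_target) - set(ct_reference)
    if missing or calibrator not in ct_target:
        raise ValueError(f"missing reference Ct for conditions: {sorted(missing) or [calibrator]}")
    delta = {cond: ct_target[cond] - ct_reference[cond] for cond in ct_target}
    out = []
    for cond in ct_target:
        ddct = delta[cond] - delta[calibrator]
        out.append(RelativeExpression(cond, delta[cond], ddct, math.pow(2.0, -ddct)))
    return out
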