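"""Readers, writers and coordinate conventions for every external format the pipeline touches.

Conventions
-----------
* All internal coordinates are 0-based, half-open ``[start, end)``.
* The per-cytosine report (Bismark CX dialect) is 1-based; the conversion
  happens exactly once, inside :func:`read_cytosine_report` /
  :func:`write_cytosine_report`.
* BED-family files (gene models, CGI/repeat tracks, DMR output) are 0-based.

The canonical in-memory container for per-cytosine data is a
:class:`pandas.DataFrame` with the columns of
:data:`CYTOSINE_REPORT_COLUMNS`; :class:`CytosineRecord` is the
corresponding single-site record for small-scale work.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTEXTS",
    "CYTOSINE_REPORT_COLUMNS",
    "ELEMENT_PRECEDENCE",
    "CytosineRecord",
    "CytosineReportError",
    "ElementLabeler",
    "FunctionalElement",
    "GeneModel",
    "IntervalTrack",
    "context_from_trinucleotide",
    "derive_elements",
    "frame_from_records",
    "read_cytosine_report",
    "read_dmr_bed",
    "read_expression_table",
    "read_fasta",
    "read_gene_models",
    "read_interval_track",
    "read_trait_table",
    "records_from_frame",
    "write_calls_table",
    "write_cytosine_report",
    "write_dmr_bed",
    "write_gene_models",
    "write_interval_track",
]

CONTEXTS = ("CG", "CHG", "CHH")
STRANDS = ("+", "-")

#: Column order of the per-cytosine report (tab-separated, 1-based positions).
CYTOSINE_REPORT_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "n_meth",
    "n_unmeth",
    "context",
    "trinucleotide",
]

#: Single-label precedence when one class per site is required (highest first).
ELEMENT_PRECEDENCE = [
    "promoter",
    "utr5",
    "utr3",
    "exon",
    "intron",
    "cgi",
    "repeat",
    "intergenic",
]

PROMOTER_LENGTH = 2000  # bp upstream of the TSS, strand-aware


class CytosineReportError(ValueError):
    """Raised for malformed per-cytosine report rows; names the offending line."""


def context_from_trinucleotide(tri: str) -> str:
    """Classify a cytosine 3-mer into CG / CHG / CHH.

    The base immediately 3' of the cytosine decides CG; otherwise the base
    two positions 3' decides CHG vs CHH (H = A, C or T).
    """
    if len(tri) != 3 or tri[0] != "C":
        raise ValueError(f"not a cytosine trinucleotide: {tri!r}")
    if tri[1] == "G":
        return "CG"
    if tri[2] == "G":
        return "CHG"
    return "CHH"


@dataclass(frozen=True)
class CytosineRecord:
    """One strand-specific cytosine with methylated/unmethylated read counts."""

    chrom: str
    pos: int  # 1-based, as in the on-disk report
    strand: str
    n_meth: int
    n_unmeth: int
    context: str
    trinucleotide: str = ""

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("read counts must be non-negative")
        if self.trinucleotide and context_from_trinucleotide(self.trinucleotide) != self.context:
            raise ValueError(
                f"context {self.context} inconsistent with trinucleotide {self.trinucleotide}"
            )

    @property
    def depth(self) -> int:
        return self.n_meth + self.n_unmeth


def _validate_report_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        line = int(df.index[bad][0]) + 1
        raise CytosineReportError(
            f"{source}: unknown context token {df.loc[df.index[bad][0], 'context']!r} at line {line}"
        )
    bad = ~df["strand"].isin(STRANDS)
    if bad.any():
        line = int(df.index[bad][0]) + 1
        raise CytosineReportError(f"{source}: unknown strand at line {line}")
    if (df["n_meth"] < 0).any() or (df["n_unmeth"] < 0).any() or (df["pos"] < 1).any():
        raise CytosineReportError(f"{source}: negative count or non-positive position")
    return df


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Read a Bismark-style per-cytosine report (TSV, 7 columns, 1-based positions).

    Returns a DataFrame with :data:`CYTOSINE_REPORT_COLUMNS`; rows keep file
    order. Malformed rows raise :class:`CytosineReportError` naming the line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=CYTOSINE_REPORT_COLUMNS,
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
                "trinucleotide": str,
            },
            comment="#",
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=CYTOSINE_REPORT_COLUMNS)
    except ValueError as exc:
        raise CytosineReportError(f"{path}: {exc}") from exc
    if df.shape[1] != len(CYTOSINE_REPORT_COLUMNS):
        raise CytosineReportError(f"{path}: expected 7 columns, found {df.shape[1]}")
    for col in ("pos", "n_meth", "n_unmeth"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            line = int(df.index[bad][0]) + 1
            raise CytosineReportError(f"{path}: non-integer {col} at line {line}")
        df[col] = numeric.astype(np.int64)
    df["trinucleotide"] = df["trinucleotide"].fillna("")
    return _validate_report_frame(df, str(path))


def write_cytosine_report(records: pd.DataFrame | Iterable[CytosineRecord], path: str | Path) -> None:
    """Write records to the 7-column tab-separated report (1-based positions)."""
    df = records if isinstance(records, pd.DataFrame) else frame_from_records(records)
    df.loc[:, CYTOSINE_REPORT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def records_from_frame(df: pd.DataFrame) -> list[CytosineRecord]:
    return [
        CytosineRecord(
            chrom=row.chrom,
            pos=int(row.pos),
            strand=row.strand,
            n_meth=int(row.n_meth),
            n_unmeth=int(row.n_unmeth),
            context=row.context,
            trinucleotide=row.trinucleotide or "",
        )
        for row in df.itertuples(index=False)
    ]


def frame_from_records(records: Iterable[CytosineRecord]) -> pd.DataFrame:
    rows = [
        (r.chrom, r.pos, r.strand, r.n_meth, r.n_unmeth, r.context, r.trinucleotide)
        for r in records
    ]
    return pd.DataFrame(rows, columns=CYTOSINE_REPORT_COLUMNS)


# ---------------------------------------------------------------------------
# gene models and functional elements
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """One gene: transcript span, CDS span and exon structure (0-based half-open)."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if not self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end:
            raise ValueError(f"gene {self.gene_id}: CDS outside transcript span")
        prev_end = self.tx_start
        for a, b in self.exons:
            if a < prev_end or b <= a or b > self.tx_end:
                raise ValueError(f"gene {self.gene_id}: exons unsorted, overlapping or out of span")
            prev_end = b


@dataclass(frozen=True)
class FunctionalElement:
    """A labelled interval derived from one gene (promoter, UTR, exon, intron)."""

    gene_id: str
    element: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class IntervalTrack:
    """A named genome track (CGI or repeat) of merged, sorted intervals per chromosome."""

    name: str
    intervals: dict[str, np.ndarray] = field(default_factory=dict)  # (n, 2) int arrays

    @classmethod
    def from_tuples(cls, name: str, tuples: Iterable[tuple[str, int, int]]) -> "IntervalTrack":
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in tuples:
            per_chrom.setdefault(chrom, []).append((int(start), int(end)))
        merged: dict[str, np.ndarray] = {}
        for chrom, ivs in per_chrom.items():
            merged[chrom] = _merge_intervals(ivs)
        return cls(name=name, intervals=merged)

    def overlapping(self, chrom: str, start: int, end: int) -> bool:
        ivs = self.intervals.get(chrom)
        if ivs is None or len(ivs) == 0:
            return False
        i = np.searchsorted(ivs[:, 0], end)
        return bool(i > 0 and ivs[i - 1, 1] > start)


def _merge_intervals(ivs: Sequence[tuple[int, int]]) -> np.ndarray:
    ivs = sorted(ivs)
    out: list[list[int]] = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read BED12 gene models (chrom, start, end, name, score, strand, thickStart,
    thickEnd, rgb, blockCount, blockSizes, blockStarts)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns")
            chrom, start, end, name, _score, strand = parts[:6]
            thick_start, thick_end = int(parts[6]), int(parts[7])
            sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            offsets = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(sizes) != int(parts[9]) or len(offsets) != int(parts[9]):
                raise ValueError(f"{path}:{lineno}: block count mismatch")
            tx_start = int(start)
            exons = tuple((tx_start + o, tx_start + o + s) for o, s in zip(offsets, sizes))
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=int(end),
                    cds_start=thick_start,
                    cds_end=thick_end,
                    exons=exons,
                )
            )
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(b - a) for a, b in g.exons)
            offsets = ",".join(str(a - g.tx_start) for a, b in g.exons)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        g.chrom,
                        g.tx_start,
                        g.tx_end,
                        g.gene_id,
                        0,
                        g.strand,
                        g.cds_start,
                        g.cds_end,
                        "0,0,0",
                        len(g.exons),
                        sizes,
                        offsets,
                    )
                )
                + "\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA genome into a chrom -> uppercase sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_interval_track(path: str | Path, name: str) -> IntervalTrack:
    """Read a BED3 track; intervals are merged and sorted per chromosome."""
    tuples = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            tuples.append((chrom, int(start), int(end)))
    return IntervalTrack.from_tuples(name, tuples)


def write_interval_track(track: IntervalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track.intervals):
            for a, b in track.intervals[chrom]:
                fh.write(f"{chrom}\t{a}\t{b}\n")


def derive_elements(
    gene: GeneModel,
    chrom_size: int | None = None,
    promoter_length: int = PROMOTER_LENGTH,
) -> list[FunctionalElement]:
    """Decompose one gene into promoter / 5'UTR / exon / intron / 3'UTR intervals.

    The promoter is the ``promoter_length`` bp immediately upstream of the
    TSS (strand-aware), clipped at the chromosome boundary.  Exonic bases
    outside the CDS become 5'/3' UTR depending on strand; a gene without a
    CDS (``cds_start == cds_end``) has exon-labelled exons and no UTRs.
    """
    out: list[FunctionalElement] = []

    def add(element: str, a: int, b: int) -> None:
        if b > a:
            out.append(FunctionalElement(gene.gene_id, element, gene.chrom, a, b, gene.strand))

    if gene.strand == "+":
        add("promoter", max(0, gene.tx_start - promoter_length), gene.tx_start)
    else:
        p_end = gene.tx_end + promoter_length
        if chrom_size is not None:
            p_end = min(p_end, chrom_size)
        add("promoter", gene.tx_end, p_end)

    for (_, b), (c, _) in itertools.pairwise(gene.exons):
        add("intron", b, c)

    coding = gene.cds_end > gene.cds_start
    left_label = "utr5" if gene.strand == "+" else "utr3"
    right_label = "utr3" if gene.strand == "+" else "utr5"
    for a, b in gene.exons:
        if not coding:
            add("exon", a, b)
            continue
        add(left_label, a, min(b, gene.cds_start))
        add("exon", max(a, gene.cds_start), min(b, gene.cds_end))
        add(right_label, max(a, gene.cds_end), b)
    return out


def gene_elements(
    genes: Iterable[GeneModel],
    chrom_sizes: Mapping[str, int] | None = None,
    promoter_length: int = PROMOTER_LENGTH,
) -> list[FunctionalElement]:
    """Derived elements for every gene, in gene order."""
    out = []
    for g in genes:
        size = chrom_sizes.get(g.chrom) if chrom_sizes else None
        out.extend(derive_elements(g, chrom_size=size, promoter_length=promoter_length))
    return out


class ElementLabeler:
    """Assign each genome position a single functional-element label.

    Overlaps are resolved by :data:`ELEMENT_PRECEDENCE`
    (promoter > 5'UTR > 3'UTR > exon > intron > CGI > repeat > intergenic);
    positions outside every element — including whole unannotated
    chromosomes — are intergenic.  Implemented by painting one small integer
    per base in increasing precedence order, so lookup is O(1) per site.
    """

    #: painting order: lowest precedence first so higher labels overwrite
    _PAINT_ORDER = ["repeat", "cgi", "intron", "exon", "utr3", "utr5", "promoter"]
    LABELS = ["intergenic"] + _PAINT_ORDER  # code 0 == intergenic

    def __init__(
        self,
        genes: Iterable[GeneModel],
        chrom_sizes: Mapping[str, int],
        cgi: IntervalTrack | None = None,
        repeats: IntervalTrack | None = None,
        promoter_length: int = PROMOTER_LENGTH,
    ) -> None:
        self.chrom_sizes = dict(chrom_sizes)
        self._code = {label: i for i, label in enumerate(self.LABELS)}
        self._paint: dict[str, np.ndarray] = {
            chrom: np.zeros(size, dtype=np.int8) for chrom, size in self.chrom_sizes.items()
        }
        by_label: dict[str, list[tuple[str, int, int]]] = {k: [] for k in self._PAINT_ORDER}
        for track, label in ((repeats, "repeat"), (cgi, "cgi")):
            if track is not None:
                for chrom, ivs in track.intervals.items():
                    by_label[label].extend((chrom, int(a), int(b)) for a, b in ivs)
        self.elements = gene_elements(genes, chrom_sizes, promoter_length)
        for el in self.elements:
            by_label[el.element].append((el.chrom, el.start, el.end))
        for label in self._PAINT_ORDER:
            code = self._code[label]
            for chrom, a, b in by_label[label]:
                arr = self._paint.get(chrom)
                if arr is not None:
                    arr[max(0, a) : min(len(arr), b)] = code

    def label_codes(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Label codes (indices into :attr:`LABELS`) for 0-based positions."""
        arr = self._paint.get(chrom)
        if arr is None:
            return np.zeros(len(pos0), dtype=np.int8)
        return arr[np.asarray(pos0, dtype=np.int64)]

    def label_positions(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        return np.asarray(self.LABELS, dtype=object)[self.label_codes(chrom, pos0)]


# ---------------------------------------------------------------------------
# DMR, calls, expression and trait tables
# ---------------------------------------------------------------------------

_DMR_BED_HEADER = (
    "#chrom\tstart\tend\tname\tscore\tstrand\tml_g1\tml_g2\tfold_change\tp\tfdr\tdirection"
)


def write_dmr_bed(dmrs: Sequence, path: str | Path) -> None:
    """Write DMRs as BED6+ (0-based): score is -log10(FDR) capped at 1000."""
    with open(path, "w") as fh:
        fh.write(_DMR_BED_HEADER + "\n")
        for i, d in enumerate(dmrs):
            with np.errstate(divide="ignore"):
                score = min(1000.0, -np.log10(d.fdr)) if d.fdr > 0 else 1000.0
            fh.write(
                "\t".join(
                    [
                        d.chrom,
                        str(d.start),
                        str(d.end),
                        f"dmr_{i + 1}",
                        f"{score:.6f}",
                        ".",
                        f"{d.ml_g1:.6f}",
                        f"{d.ml_g2:.6f}",
                        f"{d.fold_change:.6f}",
                        f"{d.p_value:.6g}",
                        f"{d.fdr:.6g}",
                        d.direction,
                    ]
                )
                + "\n"
            )


def read_dmr_bed(path: str | Path) -> list:
    """Read the BED6+ DMR file back into :class:`methage.dmr.DMR` objects."""
    from .dmr import DMR  # local import avoids a module cycle

    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                DMR(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    n_windows=0,
                    ml_g1=float(f[6]),
                    ml_g2=float(f[7]),
                    fold_change=float(f[8]),
                    p_value=float(f[9]),
                    fdr=float(f[10]),
                    direction=f[11],
                )
            )
    return out


def write_calls_table(calls: pd.DataFrame, path: str | Path) -> None:
    calls.to_csv(path, sep="\t", index=False)


def read_calls_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "context": str})


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Expression TSV: gene_id, fpkm_g1, fpkm_g2, is_de, direction (Up/Down)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "direction": str})
    required = {"gene_id", "fpkm_g1", "fpkm_g2", "is_de", "direction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: expression table missing columns {sorted(missing)}")
    if (df[["fpkm_g1", "fpkm_g2"]] < 0).any().any():
        raise ValueError(f"{path}: negative FPKM")
    df["is_de"] = df["is_de"].astype(bool)
    return df


def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Trait TSV: sample, group, then one numeric column per trait."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "group": str})
    if "sample" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: trait table needs 'sample' and 'group' columns")
    return df
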