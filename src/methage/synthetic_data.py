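"""Two-group bisulfite-count simulator with known ground truth.

Emulates the pooled two-group design of a WGBS ageing comparison: one pooled
library per group, per-site read depth, bisulfite conversion failure
(an unmethylated spike-in control mirrors the lambda-DNA spike), planted
differentially methylated regions (DMRs) of known span and effect, and a
gene-expression table anticorrelated with promoter methylation.

The methylation landscape follows vertebrate biology: CpG sites are heavily
methylated genome-wide, promoters and CpG islands are hypomethylated, and
non-CpG (CHG/CHH) methylation is rare.  The background sequence is
CpG-depleted outside islands, as vertebrate genomes are.

Observed counts follow the binomial read-sampling model: given true
methylation level ``ml`` and non-conversion rate ``r``, a read scores
methylated with probability ``ml + (1 - ml) * r`` and
``n_meth ~ Binomial(depth, ml + (1 - ml) * r)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    CYTOSINE_REPORT_COLUMNS,
    GeneModel,
    IntervalTrack,
    derive_elements,
    write_cytosine_report,
    write_gene_models,
    write_interval_track,
)

__all__ = [
    "Genome",
    "PlantedDMR",
    "SimulatedDataset",
    "SimulationConfig",
    "TruthSet",
    "extract_cytosine_sites",
    "match_planted_dmrs",
    "simulate_cytosine_reports",
    "simulate_dataset",
    "simulate_expression",
    "simulate_genome",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = _BASES


@dataclass(frozen=True)
class PlantedDMR:
    """A region whose group-2 CpG methylation is shifted by ``delta_ml``."""

    chrom: str
    start: int
    end: int
    delta_ml: float
    direction: str  # "hyper" or "hypo" (group 2 vs group 1)

    def __post_init__(self) -> None:
        if self.direction not in ("hyper", "hypo"):
            raise ValueError(f"direction must be hyper/hypo, got {self.direction!r}")
        if not 0 <= self.delta_ml <= 1:
            raise ValueError("delta_ml must be in [0, 1]")


@dataclass
class SimulationConfig:
    """All knobs of the simulated study, reproducible from (config, seed).

    Defaults model the pooled two-group design: ~65% CpG methylation
    genome-wide, hypomethylated promoters/CGIs (15%), rare non-CpG
    methylation, mean read depth 30, non-conversion rate 0.005, three
    biological samples pooled per group for expression/traits.
    """

    seed: int = 0
    chrom_sizes: Mapping[str, int] = field(default_factory=lambda: {"chr1": 500_000})
    n_genes: int = 20
    gene_length: tuple[int, int] = (4_000, 9_000)
    exon_count: tuple[int, int] = (2, 5)
    intergenic_gap: tuple[int, int] = (2_500, 4_500)  # keeps neighbouring promoters disjoint
    gc_content: float = 0.42
    cpg_depletion: float = 0.75  # P(background CpG's G mutated away), vertebrate-style
    cgi_promoter_fraction: float = 0.7
    cgi_length: int = 1_000
    cgi_gc: float = 0.65
    n_extra_cgi: int = 2
    n_repeats: int = 10
    repeat_length: int = 500
    baseline_ml: Mapping[str, float] = field(
        default_factory=lambda: {"CG": 0.65, "CHG": 0.006, "CHH": 0.006}
    )
    hypomethylated_ml: float = 0.15  # mean CpG level inside promoters and CGIs
    hypomethylated_ml_sd: float = 0.06  # between-promoter spread of that level
    depth_mean: float = 30.0
    depth_dispersion: float | None = None  # None = Poisson; else neg. binomial size
    r_true: float = 0.005  # bisulfite non-conversion rate
    planted_dmrs: list[PlantedDMR] = field(default_factory=list)
    n_promoter_dmrs: int = 0
    dmr_delta_ml: float = 0.3
    dmr_direction: str = "hyper"
    spikein_length: int = 6_000
    # expression model: log2 FPKM = intercept - coupling * promoter_ml + noise
    expression_intercept: float = 5.0
    expression_coupling: float = 4.0
    gene_noise_sd: float = 0.5
    sample_noise_sd: float = 0.25
    n_samples_per_group: int = 3
    de_log2fc: float = 2.0  # extra group-2 knockdown for promoter-hyper genes
    n_random_de: int = 5
    trait_means: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "imf": (1.2, 2.6),  # intramuscular fat %, group1 vs group2
            "shear_force": (2.1, 3.4),  # kg/cm^2
            "drip_loss": (5.2, 3.1),  # %
        }
    )
    trait_cv: float = 0.08

    def __post_init__(self) -> None:
        for ctx, ml in self.baseline_ml.items():
            if not 0 <= ml <= 1:
                raise ValueError(f"baseline_ml[{ctx}] outside [0, 1]")
        if not 0 <= self.r_true <= 1:
            raise ValueError("r_true outside [0, 1]")
        if self.depth_mean < 0:
            raise ValueError("depth_mean must be >= 0")
        for d in self.planted_dmrs:
            size = self.chrom_sizes.get(d.chrom)
            if size is None or d.start < 0 or d.end > size:
                raise ValueError(f"planted DMR {d} outside chrom_sizes")


@dataclass
class Genome:
    """Simulated genome: sequences plus gene, CGI and repeat annotation."""

    sequences: dict[str, np.ndarray]  # uint8 ASCII per chromosome
    genes: list[GeneModel]
    cgi: IntervalTrack
    repeats: IntervalTrack

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def sequence_str(self, chrom: str) -> str:
        return self.sequences[chrom].tobytes().decode("ascii")

    def write_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom in self.sequences:
                fh.write(f">{chrom}\n")
                s = self.sequence_str(chrom)
                for i in range(0, len(s), width):
                    fh.write(s[i : i + width] + "\n")


@dataclass
class TruthSet:
    """Ground truth for evaluating every downstream stage."""

    planted_dmrs: pd.DataFrame  # chrom,start,end,delta_ml,direction,ml_g1,ml_g2
    promoter_ml: pd.DataFrame  # gene_id,ml_g1,ml_g2,planted_direction
    de_genes: pd.DataFrame  # gene_id,is_de,direction,from_planted_dmr
    r_true: float


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome: Genome
    report_g1: pd.DataFrame
    report_g2: pd.DataFrame
    spikein: pd.DataFrame
    expression: pd.DataFrame
    sample_expression: pd.DataFrame  # genes x samples FPKM
    traits: pd.DataFrame
    truth: TruthSet

    def write(self, outdir: str | Path) -> None:
        """Emit every table in the formats the io layer reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genome.write_fasta(outdir / "genome.fa")
        write_gene_models(self.genome.genes, outdir / "genes.bed")
        write_interval_track(self.genome.cgi, outdir / "cgi.bed")
        write_interval_track(self.genome.repeats, outdir / "repeats.bed")
        write_cytosine_report(self.report_g1, outdir / "group1.cx.tsv")
        write_cytosine_report(self.report_g2, outdir / "group2.cx.tsv")
        write_cytosine_report(self.spikein, outdir / "spikein.cx.tsv")
        self.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        self.sample_expression.to_csv(outdir / "sample_expression.tsv", sep="\t")
        self.traits.to_csv(outdir / "traits.tsv", sep="\t", index=False)
        self.truth.planted_dmrs.to_csv(outdir / "truth_dmrs.tsv", sep="\t", index=False)
        self.truth.de_genes.to_csv(outdir / "truth_de.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _segment_lengths(rng: np.random.Generator, total: int, k: int, min_seg: int) -> np.ndarray:
    """Partition ``total`` into k segments each >= min_seg."""
    slack = total - k * min_seg
    if slack < 0:
        raise ValueError("span too short for requested segments")
    w = rng.dirichlet(np.ones(k))
    extra = np.floor(w * slack).astype(int)
    extra[0] += slack - extra.sum()
    return min_seg + extra


def _make_gene(rng: np.random.Generator, gene_id: str, chrom: str, start: int, length: int,
               strand: str, n_exons: int) -> GeneModel:
    segs = _segment_lengths(rng, length, 2 * n_exons - 1, 100)
    bounds = start + np.concatenate([[0], np.cumsum(segs)])
    exons = tuple((int(bounds[i]), int(bounds[i + 1])) for i in range(0, 2 * n_exons - 1, 2))
    first_len = exons[0][1] - exons[0][0]
    last_len = exons[-1][1] - exons[-1][0]
    cds_start = exons[0][0] + int(rng.integers(10, max(11, first_len // 2)))
    cds_end = exons[-1][1] - int(rng.integers(10, max(11, last_len // 2)))
    return GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tx_start=start,
        tx_end=start + length,
        cds_start=cds_start,
        cds_end=cds_end,
        exons=exons,
    )


def simulate_genome(config: SimulationConfig, rng: np.random.Generator | None = None) -> Genome:
    """Random genome with CpG-depleted background, CG-dense CGIs, and
    non-overlapping multi-exon genes (each with its own 2-kb promoter space).

    Raises ``ValueError`` when the chromosomes cannot host ``n_genes``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sequences = {
        chrom: _random_sequence(rng, size, config.gc_content)
        for chrom, size in config.chrom_sizes.items()
    }

    # distribute genes across chromosomes proportionally to length
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    genes: list[GeneModel] = []
    cgi_tuples: list[tuple[str, int, int]] = []
    if config.n_genes > 0:
        share = np.floor(sizes / sizes.sum() * config.n_genes).astype(int)
        while share.sum() < config.n_genes:
            share[int(np.argmax(sizes / (share + 1)))] += 1
        gid = 0
        for chrom, n_here in zip(chroms, share):
            cursor = 2_500
            limit = config.chrom_sizes[chrom] - 2_500
            for _ in range(n_here):
                length = int(rng.integers(*config.gene_length))
                gap = int(rng.integers(*config.intergenic_gap))
                if cursor + 2_000 + length > limit:
                    raise ValueError(
                        f"chromosome {chrom} too small to host its share of {config.n_genes} genes"
                    )
                strand = "+" if rng.random() < 0.5 else "-"
                start = cursor + 2_000
                n_exons = int(rng.integers(config.exon_count[0], config.exon_count[1] + 1))
                genes.append(_make_gene(rng, f"gene_{gid:04d}", chrom, start, length, strand, n_exons))
                gid += 1
                cursor = start + length + gap

    # CGIs at a fraction of promoters (spanning the TSS) plus a few random ones
    for g in genes:
        if rng.random() < config.cgi_promoter_fraction:
            tss = g.tx_start if g.strand == "+" else g.tx_end
            half = config.cgi_length // 2
            a = max(0, tss - half)
            b = min(config.chrom_sizes[g.chrom], tss + half)
            cgi_tuples.append((g.chrom, a, b))
    for chrom in chroms:
        size = config.chrom_sizes[chrom]
        for _ in range(config.n_extra_cgi):
            if size > config.cgi_length:
                a = int(rng.integers(0, size - config.cgi_length))
                cgi_tuples.append((chrom, a, a + config.cgi_length))
    cgi = IntervalTrack.from_tuples("CGI", cgi_tuples)

    # rewrite CGI sequence with elevated GC (hence elevated CpG density)
    for chrom, ivs in cgi.intervals.items():
        for a, b in ivs:
            sequences[chrom][a:b] = _random_sequence(rng, b - a, config.cgi_gc)

    # vertebrate-style CpG depletion outside CGIs
    if config.cpg_depletion > 0:
        for chrom, seq in sequences.items():
            in_cgi = np.zeros(len(seq), dtype=bool)
            for a, b in cgi.intervals.get(chrom, []):
                in_cgi[a:b] = True
            cpg = np.flatnonzero((seq[:-1] == _C) & (seq[1:] == _G) & ~in_cgi[:-1])
            kill = cpg[rng.random(len(cpg)) < config.cpg_depletion]
            seq[kill + 1] = _A

    repeat_tuples = []
    for chrom in chroms:
        size = config.chrom_sizes[chrom]
        for _ in range(config.n_repeats):
            if size > config.repeat_length:
                a = int(rng.integers(0, size - config.repeat_length))
                repeat_tuples.append((chrom, a, a + config.repeat_length))
    repeats = IntervalTrack.from_tuples("repeat", repeat_tuples)
    return Genome(sequences=sequences, genes=genes, cgi=cgi, repeats=repeats)


# ---------------------------------------------------------------------------
# cytosine sites and counts
# ---------------------------------------------------------------------------

_COMP = np.zeros(256, dtype=np.uint8)
_COMP[_A], _COMP[_C], _COMP[_G], _COMP[_T] = _T, _G, _C, _A


def _chrom_sites(seq: np.ndarray, chrom: str) -> pd.DataFrame:
    """Strand-specific cytosines with context and trinucleotide (1-based pos).

    Sites within 2 bp of a chromosome edge are skipped (their context is
    undefined without flanking sequence).
    """
    frames = []
    # forward strand: C at i, neighbours i+1, i+2
    fwd = np.flatnonzero(seq[:-2] == _C)
    if len(fwd):
        n1, n2 = seq[fwd + 1], seq[fwd + 2]
        ctx = np.where(n1 == _G, "CG", np.where(n2 == _G, "CHG", "CHH"))
        tri = _triplets(seq[fwd], n1, n2)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": fwd + 1, "strand": "+", "context": ctx, "trinucleotide": tri}
            )
        )
    # reverse strand: G at i is a C on minus; 3' neighbours are comp(seq[i-1]), comp(seq[i-2])
    rev = np.flatnonzero(seq[2:] == _G) + 2
    if len(rev):
        n1, n2 = _COMP[seq[rev - 1]], _COMP[seq[rev - 2]]
        ctx = np.where(n1 == _G, "CG", np.where(n2 == _G, "CHG", "CHH"))
        tri = _triplets(np.full(len(rev), _C, dtype=np.uint8), n1, n2)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": rev + 1, "strand": "-", "context": ctx, "trinucleotide": tri}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context", "trinucleotide"])
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="stable", ignore_index=True)


def _triplets(c0: np.ndarray, c1: np.ndarray, c2: np.ndarray) -> np.ndarray:
    stacked = np.empty((len(c0), 3), dtype=np.uint8)
    stacked[:, 0], stacked[:, 1], stacked[:, 2] = c0, c1, c2
    flat = stacked.tobytes().decode("ascii")
    return np.array([flat[i : i + 3] for i in range(0, len(flat), 3)], dtype=object)


def extract_cytosine_sites(genome: Genome) -> pd.DataFrame:
    """All strand-specific cytosines of the genome, in chromosome order."""
    frames = [_chrom_sites(genome.sequences[c], c) for c in genome.sequences]
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "context", "trinucleotide"])
    return pd.concat(frames, ignore_index=True)


def _resolve_planted_dmrs(config: SimulationConfig, genome: Genome,
                          rng: np.random.Generator) -> list[PlantedDMR]:
    planted = list(config.planted_dmrs)
    if config.n_promoter_dmrs > 0:
        candidates = [g for g in genome.genes]
        if len(candidates) < config.n_promoter_dmrs:
            raise ValueError("not enough genes to host the requested promoter DMRs")
        picked = rng.choice(len(candidates), size=config.n_promoter_dmrs, replace=False)
        for i in sorted(picked):
            g = candidates[i]
            prom = [e for e in derive_elements(g, genome.chrom_sizes[g.chrom]) if e.element == "promoter"]
            if prom:
                planted.append(
                    PlantedDMR(g.chrom, prom[0].start, prom[0].end,
                               config.dmr_delta_ml, config.dmr_direction)
                )
    for d in planted:
        size = genome.chrom_sizes.get(d.chrom)
        if size is None or d.end > size:
            raise ValueError(f"planted DMR {d} outside the simulated genome")
    return planted


def _merge_low_regions(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for a, b in sorted(ivs):
        if out and a <= out[-1][1]:
            out[-1][1] = max(out[-1][1], b)
        else:
            out.append([a, b])
    return [(a, b) for a, b in out]


def _true_ml(config: SimulationConfig, genome: Genome, sites: pd.DataFrame,
             planted: list[PlantedDMR], rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-site true methylation levels for both groups."""
    ml = np.empty(len(sites), dtype=float)
    for ctx, level in config.baseline_ml.items():
        ml[np.asarray(sites["context"] == ctx)] = level

    # hypomethylated promoters and CGIs (CpG context only); each merged
    # region draws its own level, so promoter methylation varies between
    # genes the way real promoters do
    low_regions: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.sequences}
    for g in genome.genes:
        for e in derive_elements(g, genome.chrom_sizes[g.chrom]):
            if e.element == "promoter":
                low_regions[g.chrom].append((e.start, e.end))
    for chrom, ivs in genome.cgi.intervals.items():
        low_regions.setdefault(chrom, []).extend((int(a), int(b)) for a, b in ivs)
    is_cg = np.asarray(sites["context"] == "CG")
    pos0 = sites["pos"].to_numpy() - 1
    chrom_arr = sites["chrom"].to_numpy()
    for chrom in sorted(low_regions):
        merged = _merge_low_regions(low_regions[chrom])
        if not merged:
            continue
        on_chrom = chrom_arr == chrom
        level_map = np.full(len(genome.sequences[chrom]), -1.0)
        for a, b in merged:
            # keep levels low enough that a planted shift stays detectable
            level = float(
                np.clip(
                    rng.normal(config.hypomethylated_ml, config.hypomethylated_ml_sd),
                    0.02,
                    0.30,
                )
            )
            level_map[a:b] = level
        here = level_map[pos0.clip(0, len(level_map) - 1)]
        hit = on_chrom & is_cg & (here >= 0)
        ml[hit] = here[hit]

    ml_g1 = ml.copy()
    ml_g2 = ml.copy()
    for d in planted:
        in_span = (chrom_arr == d.chrom) & (pos0 >= d.start) & (pos0 < d.end) & is_cg
        if d.direction == "hyper":
            ml_g2[in_span] = np.clip(ml_g2[in_span] + d.delta_ml, 0.0, 1.0)
        else:
            ml_g2[in_span] = np.clip(ml_g2[in_span] - d.delta_ml, 0.0, 1.0)
    return ml_g1, ml_g2


def _draw_counts(rng: np.random.Generator, config: SimulationConfig,
                 ml: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(ml)
    if config.depth_mean == 0:
        depth = np.zeros(n, dtype=np.int64)
    elif config.depth_dispersion is None:
        depth = rng.poisson(config.depth_mean, size=n)
    else:
        k = config.depth_dispersion
        depth = rng.negative_binomial(k, k / (k + config.depth_mean), size=n)
    p_obs = ml + (1.0 - ml) * config.r_true
    n_meth = rng.binomial(depth, p_obs)
    return n_meth, depth - n_meth


def simulate_cytosine_reports(
    config: SimulationConfig,
    genome: Genome,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthSet]:
    """Per-cytosine count reports for both groups plus the spike-in control.

    Returns ``(report_g1, report_g2, spikein, truth)``; reports carry the
    seven columns of the on-disk dialect.  Spike-in sites are truly
    unmethylated, so their pooled methylated fraction estimates ``r_true``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sites = extract_cytosine_sites(genome)
    planted = _resolve_planted_dmrs(config, genome, rng)
    ml_g1, ml_g2 = _true_ml(config, genome, sites, planted, rng)

    reports = []
    for ml in (ml_g1, ml_g2):
        n_meth, n_unmeth = _draw_counts(rng, config, ml)
        rep = sites.copy()
        rep["n_meth"] = n_meth
        rep["n_unmeth"] = n_unmeth
        reports.append(rep[CYTOSINE_REPORT_COLUMNS])

    # spike-in: an unmethylated control sequence read through the same model
    spike_seq = _random_sequence(rng, config.spikein_length, 0.5)
    spike_sites = _chrom_sites(spike_seq, "lambda_spike")
    cfg_spike = replace(config, depth_mean=config.depth_mean, depth_dispersion=None)
    s_meth, s_unmeth = _draw_counts(rng, cfg_spike, np.zeros(len(spike_sites)))
    spike = spike_sites.copy()
    spike["n_meth"] = s_meth
    spike["n_unmeth"] = s_unmeth
    spike = spike[CYTOSINE_REPORT_COLUMNS]

    pos0 = sites["pos"].to_numpy() - 1
    chrom_arr = sites["chrom"].to_numpy()
    is_cg = np.asarray(sites["context"] == "CG")
    truth_rows = []
    for d in planted:
        in_span = (chrom_arr == d.chrom) & (pos0 >= d.start) & (pos0 < d.end) & is_cg
        truth_rows.append(
            (d.chrom, d.start, d.end, d.delta_ml, d.direction,
             float(ml_g1[in_span].mean()) if in_span.any() else np.nan,
             float(ml_g2[in_span].mean()) if in_span.any() else np.nan)
        )
    planted_df = pd.DataFrame(
        truth_rows,
        columns=["chrom", "start", "end", "delta_ml", "direction", "ml_g1", "ml_g2"],
    )

    prom_rows = []
    for g in genome.genes:
        prom = [e for e in derive_elements(g, genome.chrom_sizes[g.chrom]) if e.element == "promoter"]
        if not prom:
            prom_ml = (np.nan, np.nan)
            direction = ""
        else:
            e = prom[0]
            in_prom = (chrom_arr == g.chrom) & (pos0 >= e.start) & (pos0 < e.end) & is_cg
            prom_ml = (
                float(ml_g1[in_prom].mean()) if in_prom.any() else np.nan,
                float(ml_g2[in_prom].mean()) if in_prom.any() else np.nan,
            )
            direction = ""
            for d in planted:
                if d.chrom == g.chrom and d.start < e.end and d.end > e.start:
                    direction = d.direction
        prom_rows.append((g.gene_id, prom_ml[0], prom_ml[1], direction))
    promoter_ml = pd.DataFrame(prom_rows, columns=["gene_id", "ml_g1", "ml_g2", "planted_direction"])

    truth = TruthSet(
        planted_dmrs=planted_df,
        promoter_ml=promoter_ml,
        de_genes=pd.DataFrame(columns=["gene_id", "is_de", "direction", "from_planted_dmr"]),
        r_true=config.r_true,
    )
    return reports[0], reports[1], spike, truth


# ---------------------------------------------------------------------------
# expression and traits
# ---------------------------------------------------------------------------


def simulate_expression(
    config: SimulationConfig,
    genome: Genome,
    truth: TruthSet,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-gene FPKM with DE labels, per-sample expression, and sample traits.

    ``log2(FPKM) = intercept - coupling * promoter_ml + noise`` per group;
    genes whose promoter hosts a planted hyper-DMR receive an extra group-2
    knockdown (``de_log2fc``), hypo-DMR genes the mirror-image boost, and a
    few unrelated genes are made DE at random so set intersections are
    non-trivial downstream.  Updates ``truth.de_genes`` in place.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    pm = truth.promoter_ml.set_index("gene_id")
    gene_ids = list(pm.index)
    n = len(gene_ids)
    gene_noise = rng.normal(0.0, config.gene_noise_sd, size=n)
    log2_g1 = config.expression_intercept - config.expression_coupling * pm["ml_g1"].to_numpy() + gene_noise
    log2_g2 = config.expression_intercept - config.expression_coupling * pm["ml_g2"].to_numpy() + gene_noise

    from_planted = pm["planted_direction"].to_numpy()
    log2_g2 = log2_g2 - np.where(from_planted == "hyper", config.de_log2fc, 0.0)
    log2_g2 = log2_g2 + np.where(from_planted == "hypo", config.de_log2fc, 0.0)

    unplanted = np.flatnonzero(from_planted == "")
    n_rand = min(config.n_random_de, len(unplanted))
    rand_idx = rng.choice(unplanted, size=n_rand, replace=False) if n_rand else np.array([], dtype=int)
    rand_sign = rng.choice([-1.0, 1.0], size=n_rand)
    log2_g2[rand_idx] = log2_g2[rand_idx] + rand_sign * config.de_log2fc

    is_de = (from_planted != "") | np.isin(np.arange(n), rand_idx)
    fpkm_g1, fpkm_g2 = 2.0 ** log2_g1, 2.0 ** log2_g2
    direction = np.where(fpkm_g2 < fpkm_g1, "Down", "Up")
    expression = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "fpkm_g1": fpkm_g1,
            "fpkm_g2": fpkm_g2,
            "is_de": is_de,
            "direction": np.where(is_de, direction, ""),
        }
    )

    samples = [f"g1_s{i + 1}" for i in range(config.n_samples_per_group)] + [
        f"g2_s{i + 1}" for i in range(config.n_samples_per_group)
    ]
    sample_log2 = np.column_stack(
        [log2_g1 + rng.normal(0, config.sample_noise_sd, n) for _ in range(config.n_samples_per_group)]
        + [log2_g2 + rng.normal(0, config.sample_noise_sd, n) for _ in range(config.n_samples_per_group)]
    )
    sample_expression = pd.DataFrame(2.0 ** sample_log2, index=pd.Index(gene_ids, name="gene_id"),
                                     columns=samples)

    trait_rows = []
    for si, sample in enumerate(samples):
        group = "g1" if si < config.n_samples_per_group else "g2"
        row: dict[str, object] = {"sample": sample, "group": group}
        for trait, (m1, m2) in config.trait_means.items():
            m = m1 if group == "g1" else m2
            row[trait] = m + rng.normal(0, config.trait_cv * abs(m) if m else config.trait_cv)
        trait_rows.append(row)
    traits = pd.DataFrame(trait_rows)

    truth.de_genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "is_de": is_de,
            "direction": np.where(is_de, direction, ""),
            "from_planted_dmr": from_planted,
        }
    )
    return expression, sample_expression, traits


def match_planted_dmrs(
    dmrs: Iterable,
    planted: pd.DataFrame,
    min_reciprocal: float = 0.5,
) -> pd.DataFrame:
    """Match called DMRs against the planted truth by reciprocal overlap.

    A planted region is *recovered* when some call overlaps it by at least
    ``min_reciprocal`` of both spans; a call touching no planted span at all
    is a *false call*.  Returns one row per call with its best-matching
    planted index (-1 if none), the reciprocal overlap achieved, whether it
    is recovered-quality, and whether the direction agrees.
    """
    rows = []
    for d in dmrs:
        best = (-1, 0.0, False)
        overlaps_any = False
        for pi, p in planted.iterrows():
            if p["chrom"] != d.chrom:
                continue
            ov = min(d.end, p["end"]) - max(d.start, p["start"])
            if ov <= 0:
                continue
            overlaps_any = True
            rec = min(ov / (d.end - d.start), ov / (p["end"] - p["start"]))
            if rec > best[1]:
                best = (pi, rec, d.direction == p["direction"])
        rows.append(
            (d.chrom, d.start, d.end, d.direction, best[0], best[1],
             best[1] >= min_reciprocal, best[2], not overlaps_any)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "direction",
            "planted_index", "reciprocal_overlap",
            "recovered", "direction_correct", "false_call",
        ],
    )


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator: genome, count reports, spike-in, expression, traits."""
    rng = np.random.default_rng(config.seed)
    genome = simulate_genome(config, rng)
    report_g1, report_g2, spike, truth = simulate_cytosine_reports(config, genome, rng)
    expression, sample_expression, traits = simulate_expression(config, genome, truth, rng)
    return SimulatedDataset(
        config=config,
        genome=genome,
        report_g1=report_g1,
        report_g2=report_g2,
        spikein=spike,
        expression=expression,
        sample_expression=sample_expression,
        traits=traits,
        truth=truth,
    )
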