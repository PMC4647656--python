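"""Synthetic genomes, annotations, directional reads and covariate tables.

Generates data with the signal structure the downstream stages assume:
peaks whose planted RNA strand is purine-enriched, directional read pairs
with flags 163/147, peak enrichment inside promoters, expression-dependent
peak frequency downstream of the TSS, a methylation decrement inside peaks,
and window-level peak density driven by planted covariates.

The distributional choices here are stand-ins — the real data's generative
process is unknown — but every planted quantity is recorded in a truth table
so parameter recovery can be tested.  All outputs are byte-identical for a
fixed seed.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from rdipkit.genome_io import (
    FeatureSet,
    Genome,
    GenomicInterval,
    write_bed,
    write_bedgraph,
    write_fasta,
)

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_peaks_and_reads",
    "simulate_expression_and_tracks",
    "simulate_window_density",
    "write_sam",
    "run_simulation",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

REPEAT_FAMILIES: dict[str, list[str]] = {
    "L1": ["L1HS", "L1PA2"],
    "Alu": ["AluY", "AluSx"],
    "Satellite": ["(GAATG)n", "(CATTC)n", "ALR"],
}


@dataclasses.dataclass
class SimulationConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    # genes / annotation
    n_genes: int = 200
    gene_length_mean: float = 15_000.0
    gene_length_min: int = 2_000
    promoter_width: int = 2_000  # promoter = TSS +/- width/2
    cpg_island_width: int = 1_000
    cpg_island_promoter_fraction: float = 0.6
    n_random_cpg_islands: int = 30
    n_repeats: int = 300
    n_dnase_sites: int = 200
    dnase_width: int = 500
    n_histone_domains: int = 20
    histone_domain_width: int = 100_000
    # peaks / reads
    n_peaks: int = 500
    peak_length_mean: float = 500.0
    peak_length_min: int = 150
    reads_per_peak: int = 50
    read_length: int = 100
    fragment_length: int = 300
    p_strand: float = 0.95
    purine_delta: float = 0.15
    promoter_multiplier: float = 5.0
    # expression / tracks
    zero_inflation: float = 0.3
    expression_log_mean: float = 2.0
    expression_log_sd: float = 1.0
    expression_peak_boost: float = 3.0  # multiplier for genes with a TSS-proximal peak
    tss_proximal_bp: int = 1_500
    n_cpg_sites: int = 5_000
    methylation_mean: float = 0.75
    methylation_decrement: float = 0.10
    methylation_concentration: float = 30.0
    n_intergenic_transcribed: int = 40
    # window density regression
    window_width: int = 250_000
    n_covariates: int = 12
    covariate_effects: tuple[float, ...] = (3.0, 2.0, 1.0)
    covariate_correlation: float = 0.2
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if not 0.5 <= self.p_strand <= 1.0:
            raise ValueError("p_strand must be in [0.5, 1]")
        if not 0.0 <= self.purine_delta <= 0.5:
            raise ValueError("purine_delta must be in [0, 0.5]")
        if self.promoter_multiplier < 1.0:
            raise ValueError("promoter_multiplier must be >= 1")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must be in [0, 1)")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-specific generator derived from the global seed."""
        return np.random.default_rng([self.seed, stage])


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _nonoverlapping_placement(
    rng: np.random.Generator, chrom_len: int, lengths: Sequence[int]
) -> list[int]:
    """Non-overlapping starts for the given lengths via stick breaking."""
    total = int(sum(lengths))
    slack = chrom_len - total
    if slack < 0:
        raise ValueError("features overflow chromosome")
    gaps = np.sort(rng.integers(0, slack + 1, size=len(lengths)))
    starts = []
    consumed = 0
    for gap, length in zip(gaps, lengths):
        starts.append(int(gap) + consumed)
        consumed += int(length)
    return starts


def _split_counts(
    rng: np.random.Generator, total: int, weights: Sequence[float]
) -> np.ndarray:
    return rng.multinomial(total, np.asarray(weights) / np.sum(weights))


def simulate_genome(
    config: SimulationConfig,
) -> tuple[Genome, dict[str, FeatureSet]]:
    """Random genome sequence plus gene/promoter/CpG/repeat/DNase/domain tracks.

    Background base composition is uniform over A/C/G/T.  Genes are placed
    without overlap and carry strand; promoters are TSS +/- promoter_width/2.
    """
    rng = config.rng(stage=1)
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    sequences = {c: _random_sequence(rng, config.chrom_lengths[c]) for c in chroms}
    genome = Genome(dict(config.chrom_lengths), sequences)

    genes: list[GenomicInterval] = []
    per_chrom = _split_counts(rng, config.n_genes, lengths)
    for chrom, n_on_chrom in zip(chroms, per_chrom):
        if n_on_chrom == 0:
            continue
        glens = np.maximum(
            config.gene_length_min,
            rng.exponential(config.gene_length_mean, size=n_on_chrom),
        ).astype(int)
        # shrink toward the minimum length until the genes fit in 60% of
        # the chromosome; impossible only if even all-minimum overflows
        budget = int(0.6 * config.chrom_lengths[chrom])
        if n_on_chrom * config.gene_length_min > budget:
            raise ValueError(
                f"{n_on_chrom} genes of >= {config.gene_length_min} bp "
                f"overflow chromosome {chrom}"
            )
        while glens.sum() > budget:
            glens = np.maximum(config.gene_length_min, (glens * 0.9).astype(int))
        starts = _nonoverlapping_placement(rng, config.chrom_lengths[chrom], glens)
        for i, (start, glen) in enumerate(zip(starts, glens)):
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                GenomicInterval(
                    chrom, start, start + int(glen), strand, name=f"gene_{chrom}_{i}"
                )
            )
    genes.sort(key=lambda g: (g.chrom, g.start))
    genes = [
        dataclasses.replace(g, name=f"gene{i:04d}") for i, g in enumerate(genes)
    ]

    promoters: list[GenomicInterval] = []
    half = config.promoter_width // 2
    for gene in genes:
        tss = gene.start if gene.strand == "+" else gene.end
        start = max(0, tss - half)
        end = min(genome.lengths[gene.chrom], tss + half)
        promoters.append(GenomicInterval(gene.chrom, start, end, gene.strand, gene.name))

    cpg: list[GenomicInterval] = []
    half_cpg = config.cpg_island_width // 2
    for gene in genes:
        if rng.random() < config.cpg_island_promoter_fraction:
            tss = gene.start if gene.strand == "+" else gene.end
            start = max(0, tss - half_cpg)
            end = min(genome.lengths[gene.chrom], tss + half_cpg)
            cpg.append(GenomicInterval(gene.chrom, start, end))
    for _ in range(config.n_random_cpg_islands):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, config.chrom_lengths[chrom] - config.cpg_island_width))
        cpg.append(GenomicInterval(chrom, start, start + config.cpg_island_width))

    subfamilies = [
        (family, sub) for family, subs in REPEAT_FAMILIES.items() for sub in subs
    ]
    repeats: list[GenomicInterval] = []
    for _ in range(config.n_repeats):
        family, sub = subfamilies[int(rng.integers(len(subfamilies)))]
        rep_len = int(rng.integers(300, 6_000))
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, config.chrom_lengths[chrom] - rep_len))
        repeats.append(GenomicInterval(chrom, start, start + rep_len, name=sub))

    dnase: list[GenomicInterval] = []
    for _ in range(config.n_dnase_sites):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, config.chrom_lengths[chrom] - config.dnase_width))
        dnase.append(GenomicInterval(chrom, start, start + config.dnase_width))

    domains: list[GenomicInterval] = []
    for _ in range(config.n_histone_domains):
        chrom = chroms[int(rng.integers(len(chroms)))]
        width = min(config.histone_domain_width, config.chrom_lengths[chrom] - 1)
        start = int(rng.integers(0, config.chrom_lengths[chrom] - width))
        domains.append(GenomicInterval(chrom, start, start + width, name="H3K27me3"))

    features = {
        "gene": FeatureSet("gene", genes),
        "promoter": FeatureSet("promoter", promoters),
        "cpg_island": FeatureSet("cpg_island", cpg),
        "repeat": FeatureSet("repeat", repeats),
        "dnase": FeatureSet("dnase", dnase),
        "histone_domain": FeatureSet("histone_domain", domains),
    }
    return genome, features


# ---------------------------------------------------------------------------
# peaks + directional reads
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _skewed_sequence(
    rng: np.random.Generator, length: int, top_purine_prob: float
) -> str:
    """Sequence whose top strand is purine (G/A) with the given probability."""
    purine = rng.random(length) < top_purine_prob
    g_or_a = rng.random(length) < 0.5
    out = np.where(
        purine,
        np.where(g_or_a, b"G", b"A"),
        np.where(g_or_a, b"C", b"T"),
    )
    return out.astype("S1").tobytes().decode("ascii")


def simulate_peaks_and_reads(
    config: SimulationConfig,
    genome: Genome,
    features: dict[str, FeatureSet],
) -> tuple[list[GenomicInterval], list[str], pd.DataFrame]:
    """Plant peaks (promoter-enriched, purine-skewed) and emit read pairs.

    Peak placement probability is multiplied by ``promoter_multiplier``
    inside promoters (rejection sampling).  Each peak's genome sequence is
    rewritten so the planted RNA strand is purine with probability
    0.5 + purine_delta.  For each read pair the RNA-derived (second) read
    reports the planted strand with probability ``p_strand``: flag 163 when
    it maps to the top strand, 147 when to the bottom.  Returns
    (peak intervals, SAM text lines incl. header, truth table).

    The genome's sequences are modified in place (peak spans rewritten).
    """
    if genome.sequences is None:
        raise ValueError("genome must carry sequence")
    rng = config.rng(stage=2)
    chroms = genome.chromosomes
    lengths = np.array([genome.lengths[c] for c in chroms], dtype=float)

    from rdipkit.genome_io import _merged_by_chrom

    promoter_merged = _merged_by_chrom(features["promoter"].intervals)

    def in_promoter(chrom: str, start: int, end: int) -> bool:
        spans = promoter_merged.get(chrom)
        if spans is None:
            return False
        return bool(np.any((spans[:, 0] < end) & (spans[:, 1] > start)))

    peaks: list[GenomicInterval] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    m = config.promoter_multiplier
    while len(peaks) < config.n_peaks:
        plen = max(
            config.peak_length_min,
            int(rng.exponential(config.peak_length_mean)),
        )
        chrom = chroms[int(rng.choice(len(chroms), p=lengths / lengths.sum()))]
        if genome.lengths[chrom] <= plen:
            continue
        start = int(rng.integers(0, genome.lengths[chrom] - plen))
        end = start + plen
        accept_p = (m if in_promoter(chrom, start, end) else 1.0) / m
        if rng.random() >= accept_p:
            continue
        if any(s < end and start < e for s, e in occupied[chrom]):
            continue
        occupied[chrom].append((start, end))
        peaks.append(GenomicInterval(chrom, start, end, name=f"peak{len(peaks):04d}"))
    peaks.sort(key=lambda p: (p.chrom, p.start))
    peaks = [
        dataclasses.replace(p, name=f"peak{i:04d}") for i, p in enumerate(peaks)
    ]

    # rewrite peak sequence with the planted purine skew on the RNA strand
    planted_strand = np.where(rng.random(len(peaks)) < 0.5, "+", "-")
    mutable = {c: bytearray(genome.sequences[c], "ascii") for c in chroms}
    for peak, strand in zip(peaks, planted_strand):
        top_prob = (
            0.5 + config.purine_delta if strand == "+" else 0.5 - config.purine_delta
        )
        seq = _skewed_sequence(rng, len(peak), top_prob)
        mutable[peak.chrom][peak.start : peak.end] = seq.encode("ascii")
    genome.sequences = {c: mutable[c].decode("ascii") for c in chroms}

    sam_lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        *[f"@SQ\tSN:{c}\tLN:{genome.lengths[c]}" for c in chroms],
    ]
    truth_rows = []
    for peak, strand in zip(peaks, planted_strand):
        n_match = 0
        for j in range(config.reads_per_peak):
            frag_len = min(config.fragment_length, len(peak))
            read_len = min(config.read_length, frag_len)
            frag_start = peak.start + int(rng.integers(0, len(peak) - frag_len + 1))
            frag_end = frag_start + frag_len
            on_planted = rng.random() < config.p_strand
            rna_top = (strand == "+") == on_planted
            n_match += int(on_planted)
            qname = f"{peak.name}_r{j:03d}"
            seq_fwd_left = genome.sequences[peak.chrom][
                frag_start : frag_start + read_len
            ]
            seq_fwd_right = genome.sequences[peak.chrom][
                frag_end - read_len : frag_end
            ]
            qual = "I" * read_len
            if rna_top:
                # read2 forward at fragment left (163); read1 reverse at right (83)
                r2 = (
                    f"{qname}\t163\t{peak.chrom}\t{frag_start + 1}\t60\t{read_len}M"
                    f"\t=\t{frag_end - read_len + 1}\t{frag_len}\t{seq_fwd_left}\t{qual}"
                )
                r1 = (
                    f"{qname}\t83\t{peak.chrom}\t{frag_end - read_len + 1}\t60"
                    f"\t{read_len}M\t=\t{frag_start + 1}\t{-frag_len}"
                    f"\t{_revcomp(seq_fwd_right)}\t{qual}"
                )
            else:
                # read2 reverse at fragment right (147); read1 forward at left (99)
                r2 = (
                    f"{qname}\t147\t{peak.chrom}\t{frag_end - read_len + 1}\t60"
                    f"\t{read_len}M\t=\t{frag_start + 1}\t{-frag_len}"
                    f"\t{_revcomp(seq_fwd_right)}\t{qual}"
                )
                r1 = (
                    f"{qname}\t99\t{peak.chrom}\t{frag_start + 1}\t60\t{read_len}M"
                    f"\t=\t{frag_end - read_len + 1}\t{frag_len}\t{seq_fwd_left}\t{qual}"
                )
            sam_lines.extend([r1, r2])
        truth_rows.append(
            {
                "peak": peak.name,
                "chrom": peak.chrom,
                "start": peak.start,
                "end": peak.end,
                "planted_strand": strand,
                "planted_rna_purine": 0.5 + config.purine_delta,
                "n_reads": config.reads_per_peak,
                "n_reads_on_planted": n_match,
            }
        )
    return peaks, sam_lines, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# expression, methylation, transcription tracks
# ---------------------------------------------------------------------------


def simulate_expression_and_tracks(
    config: SimulationConfig,
    genes: Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval] = (),
) -> tuple[pd.DataFrame, list[tuple[str, int, int, float]], list[GenomicInterval]]:
    """Zero-inflated log-normal expression, methylation track, transcribed set.

    Genes with a peak in the first ``tss_proximal_bp`` downstream of their
    TSS get expression multiplied by ``expression_peak_boost``, planting the
    positive peak-frequency/expression-quantile association.  Methylation is
    Beta-distributed per CpG site with mean lowered by
    ``methylation_decrement`` inside peaks.  Transcribed intervals are the
    expressed genes plus ``n_intergenic_transcribed`` random loci.
    """
    rng = config.rng(stage=3)
    peak_list = list(peaks)

    def has_proximal_peak(gene: GenomicInterval) -> bool:
        if gene.strand == "+":
            region = GenomicInterval(
                gene.chrom, gene.start, gene.start + config.tss_proximal_bp
            )
        else:
            region = GenomicInterval(
                gene.chrom, max(0, gene.end - config.tss_proximal_bp), gene.end
            )
        return any(p.overlaps(region) for p in peak_list)

    rows = []
    for gene in genes:
        zero = rng.random() < config.zero_inflation
        value = 0.0
        if not zero:
            value = float(
                rng.lognormal(config.expression_log_mean, config.expression_log_sd)
            )
            if has_proximal_peak(gene):
                value *= config.expression_peak_boost
        rows.append({"gene": gene.name, "expression": value})
    expression = pd.DataFrame(rows)

    # methylation: per-CpG-site Beta values, planted decrement inside peaks
    from rdipkit.genome_io import _merged_by_chrom

    peak_merged = _merged_by_chrom(peak_list)
    chrom_names = sorted({g.chrom for g in genes} | {p.chrom for p in peak_list})
    meth: list[tuple[str, int, int, float]] = []
    kappa = config.methylation_concentration
    # put a fixed share of sites inside peaks so the contrast is estimable
    n_in_peaks = config.n_cpg_sites // 5 if peak_list else 0
    for _ in range(n_in_peaks):
        p = peak_list[int(rng.integers(len(peak_list)))]
        pos = int(rng.integers(p.start, p.end))
        mean = config.methylation_mean - config.methylation_decrement
        value = float(rng.beta(mean * kappa, (1 - mean) * kappa))
        meth.append((p.chrom, pos, pos + 1, value))
    chrom_max = {
        c: max(
            [g.end for g in genes if g.chrom == c]
            + [p.end for p in peak_list if p.chrom == c]
            + [1]
        )
        for c in chrom_names
    }
    for _ in range(config.n_cpg_sites - n_in_peaks):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        pos = int(rng.integers(0, chrom_max[chrom]))
        spans = peak_merged.get(chrom)
        inside = spans is not None and bool(
            np.any((spans[:, 0] <= pos) & (spans[:, 1] > pos))
        )
        mean = config.methylation_mean - (
            config.methylation_decrement if inside else 0.0
        )
        value = float(rng.beta(mean * kappa, (1 - mean) * kappa))
        meth.append((chrom, pos, pos + 1, value))
    meth.sort()

    transcribed = [
        GenomicInterval(g.chrom, g.start, g.end, g.strand, g.name)
        for g, row in zip(genes, rows)
        if row["expression"] > 0
    ]
    for i in range(config.n_intergenic_transcribed):
        chrom = chrom_names[int(rng.integers(len(chrom_names)))]
        start = int(rng.integers(0, max(1, chrom_max[chrom] - 2_000)))
        transcribed.append(
            GenomicInterval(chrom, start, start + 2_000, name=f"intergenic_tx{i}")
        )
    return expression, meth, transcribed


# ---------------------------------------------------------------------------
# window-level covariates + density response
# ---------------------------------------------------------------------------


def simulate_window_density(
    config: SimulationConfig,
    windows: Sequence[GenomicInterval] | int,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Correlated covariates and a linear-plus-noise peak-density response.

    Covariates are multivariate normal with exchangeable correlation
    ``covariate_correlation``; the response is ``X @ beta + noise`` with
    ``beta`` given by ``covariate_effects`` padded with zeros.  Returns
    (covariate table, response, truth with active covariates/coefficients).
    """
    rng = config.rng(stage=4)
    n = windows if isinstance(windows, int) else len(windows)
    p = config.n_covariates
    if p < 2:
        raise ValueError("need at least 2 covariates")
    if len(config.covariate_effects) > p:
        raise ValueError("more effects than covariates")
    rho = config.covariate_correlation
    if not -1.0 / (p - 1) < rho < 1.0:
        raise ValueError(f"correlation {rho} gives a singular covariance")
    cov = np.full((p, p), rho) + (1 - rho) * np.eye(p)
    X = rng.multivariate_normal(np.zeros(p), cov, size=n, method="cholesky")
    beta = np.zeros(p)
    beta[: len(config.covariate_effects)] = config.covariate_effects
    response = X @ beta + rng.normal(0.0, config.noise_sd, size=n)
    names = [f"cov{j:02d}" for j in range(p)]
    table = pd.DataFrame(X, columns=names)
    truth = {
        "coefficients": dict(zip(names, beta)),
        "active": [names[j] for j in range(p) if beta[j] != 0],
        "noise_sd": config.noise_sd,
    }
    return table, response, truth


# ---------------------------------------------------------------------------
# file emission
# ---------------------------------------------------------------------------


def write_sam(sam_lines: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("\n".join(sam_lines) + "\n")


def run_simulation(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run every generator stage and write all artefacts to ``outdir``.

    Emits FASTA, BED tracks, SAM read pairs, expression TSV, methylation
    bedGraph, transcribed BED, the window covariate table and response, and
    truth sidecars.  Returns a name -> path map.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, features = simulate_genome(config)
    peaks, sam_lines, peak_truth = simulate_peaks_and_reads(config, genome, features)
    expression, methylation, transcribed = simulate_expression_and_tracks(
        config, features["gene"].intervals, peaks
    )
    table, response, density_truth = simulate_window_density(
        config,
        sum(-(-length // config.window_width) for length in genome.lengths.values()),
    )

    paths: dict[str, Path] = {}

    def emit(name: str, filename: str) -> Path:
        paths[name] = outdir / filename
        return paths[name]

    write_fasta(genome, emit("genome", "genome.fa"))
    for label, fs in features.items():
        write_bed(fs.intervals, emit(label, f"{label}.bed"))
    write_bed(peaks, emit("peaks", "peaks.bed"))
    write_sam(sam_lines, emit("reads", "reads.sam"))
    peak_truth.to_csv(emit("peak_truth", "peak_truth.tsv"), sep="\t", index=False)
    expression.to_csv(emit("expression", "expression.tsv"), sep="\t", index=False)
    write_bedgraph(methylation, emit("methylation", "methylation.bedGraph"))
    write_bed(transcribed, emit("transcribed", "transcribed.bed"))
    density = table.copy()
    density["response"] = response
    density.to_csv(emit("window_density", "window_density.tsv"), sep="\t", index=False)
    pd.DataFrame(
        [
            {"covariate": name, "coefficient": coef}
            for name, coef in density_truth["coefficients"].items()
        ]
    ).to_csv(emit("density_truth", "density_truth.tsv"), sep="\t", index=False)
    return paths
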