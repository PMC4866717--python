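"""Synthetic SNP-array data with known copy-number truth.

The generator emulates a genotyping array of the kind used for cell
line screening: markers with exponentially distributed spacing (median
2 kb), U-shaped population allele frequencies tuned so that ~15% of
genotypes are heterozygous, Gaussian BAF/LRR noise (per-experiment
standard deviations drawn from 0.03-0.08 and 0.13-0.26 respectively)
and embedded CN1/CN3 aberrations whose lengths follow a two-piece
log-normal anchored at the 18 kb / 1.7 Mb / 4 Mb (1st percentile /
median / 99th percentile) length profile of real-array validation
aberrations.  Each experiment is one 40 Mb chromosome carrying 1-3
non-overlapping aberrations.

Whole-chromosome generators for aneuploidy and inter-individual
contamination support the BAF-distribution screening method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AA, GT_MISSING, RA, RR, MarkerTrack

__all__ = [
    "SimulationConfig",
    "TruthRegion",
    "simulate_positions",
    "simulate_genotypes",
    "inject_aberrations",
    "simulate_chromosome",
    "simulate_experiment_set",
    "simulate_whole_chromosome",
    "write_vcf",
    "write_truth",
    "read_truth",
]

_LN2 = np.log(2.0)
_Z99 = 2.3263478740408408  # two-sided 1%/99% normal quantile


@dataclass
class SimulationConfig:
    """Study conditions for the CNV simulation benchmark."""

    chrom: str = "1"
    chrom_length: int = 40_000_000
    n_markers: int | None = None          # overrides chrom_length when set
    median_spacing: float = 2_000.0       # bp between adjacent markers
    het_fraction: float = 0.15            # expected fraction of RA genotypes
    baf_sd: tuple[float, float] = (0.03, 0.08)   # per-experiment uniform range
    lrr_sd: tuple[float, float] = (0.13, 0.26)
    # aberration length percentiles: (1st, median, 99th) in bp
    length_quantiles: tuple[float, float, float] = (18_000.0, 1_700_000.0, 4_000_000.0)
    max_length: float = 10_000_000.0
    aberrant_cell_fraction: float = 1.0
    aberration_rate: float = 2.57         # Poisson rate before conditioning to 1..max
    max_aberrations: int = 3
    min_separation: int = 50_000          # bp between injected regions
    lrr_shift: tuple[float, float] = (-0.45, 0.3)   # CN1, CN3 LRR means

    def sd_pair(self, rng: np.random.Generator) -> tuple[float, float]:
        """Draw this experiment's (baf_sd, lrr_sd)."""
        b = rng.uniform(*self.baf_sd) if np.ndim(self.baf_sd) else float(self.baf_sd)
        l = rng.uniform(*self.lrr_sd) if np.ndim(self.lrr_sd) else float(self.lrr_sd)
        return b, l


@dataclass
class TruthRegion:
    """A simulated ground-truth aberration (1-based inclusive bp)."""

    chrom: str
    start: int
    end: int
    state: int                 # 1 (loss) or 3 (gain)
    n_markers: int = 0
    n_het_markers: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("truth region start must precede end")
        if self.n_het_markers > self.n_markers:
            raise ValueError("more het markers than markers")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _het_beta_param(het_fraction: float) -> float:
    """Beta(a, a) shape giving E[2q(1-q)] = het_fraction under HWE."""
    if not 0.0 < het_fraction < 0.5:
        raise ValueError("het_fraction must be in (0, 0.5)")
    return (1.0 / (1.0 - 2.0 * het_fraction) - 1.0) / 2.0


def simulate_positions(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Strictly increasing marker positions with exponential gaps.

    Gap median equals ``config.median_spacing``; generation stops after
    ``config.n_markers`` markers or once ``config.chrom_length`` is
    exceeded.
    """
    scale = config.median_spacing / _LN2
    if config.n_markers is not None:
        gaps = np.maximum(1, rng.exponential(scale, config.n_markers).astype(np.int64))
        return np.cumsum(gaps)
    # over-draw in chunks until the chromosome is covered
    est = int(config.chrom_length / scale * 1.2) + 100
    gaps = np.maximum(1, rng.exponential(scale, est).astype(np.int64))
    pos = np.cumsum(gaps)
    while pos[-1] < config.chrom_length:
        extra = np.maximum(1, rng.exponential(scale, est // 4 + 10).astype(np.int64))
        pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
    return pos[pos <= config.chrom_length]


def simulate_genotypes(positions: np.ndarray, het_fraction: float,
                       rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker genotypes and the allele frequencies they came from.

    Allele frequencies are drawn from a symmetric (U-shaped) Beta whose
    shape is solved so the expected Hardy-Weinberg heterozygosity
    equals ``het_fraction``; genotypes are then drawn per marker from
    the Hardy-Weinberg proportions of its frequency.
    """
    n = len(positions)
    a = _het_beta_param(het_fraction)
    q = rng.beta(a, a, n)
    p_rr = (1.0 - q) ** 2
    p_ra = 2.0 * q * (1.0 - q)
    u = rng.random(n)
    gt = np.where(u < p_rr, RR, np.where(u < p_rr + p_ra, RA, AA)).astype(np.int8)
    return gt, q


def _diploid_track(config: SimulationConfig, rng: np.random.Generator) -> MarkerTrack:
    """Noise-free diploid track: BAF at {0, 0.5, 1}, LRR 0."""
    pos = simulate_positions(config, rng)
    gt, q = simulate_genotypes(pos, config.het_fraction, rng)
    baf = gt.astype(float) / 2.0
    lrr = np.zeros(len(pos))
    return MarkerTrack(config.chrom, pos, baf, lrr, gt, q)


def draw_lengths(n: int, config: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Aberration lengths from a two-piece log-normal.

    The log-scale median is the printed median (1.7 Mb) and the lower
    and upper standard deviations are anchored so the 1st and 99th
    percentiles land on 18 kb and 4 Mb exactly -- a single log-normal
    cannot match the strongly asymmetric percentile profile.
    """
    q01, q50, q99 = config.length_quantiles
    mu = np.log(q50)
    s_lo = (mu - np.log(q01)) / _Z99
    s_hi = (np.log(q99) - mu) / _Z99
    z = rng.standard_normal(n)
    ln = mu + z * np.where(z < 0, s_lo, s_hi)
    return np.minimum(np.exp(ln), config.max_length).astype(np.int64)


def _draw_regions(config: SimulationConfig, rng: np.random.Generator,
                  n_aberrations: int | None = None) -> list[tuple[int, int, int]]:
    """(start, end, state) triples, non-overlapping with separation."""
    if n_aberrations is None:
        k = 0
        while not 1 <= k <= config.max_aberrations:
            k = rng.poisson(config.aberration_rate)
    else:
        k = n_aberrations
    L = config.chrom_length
    for _ in range(1000):
        lengths = draw_lengths(k, config, rng)
        if lengths.sum() + (k + 1) * config.min_separation >= L:
            continue
        starts = np.sort(rng.integers(1, L, k))
        ends = starts + lengths - 1
        ok = ends[-1] <= L and np.all(starts[1:] - ends[:-1] > config.min_separation)
        if ok:
            states = rng.choice([1, 3], k)
            return [(int(s), int(e), int(st)) for s, e, st in zip(starts, ends, states)]
    raise RuntimeError("could not place aberrations on the chromosome")


def inject_aberrations(track: MarkerTrack, regions: list[tuple[int, int, int]],
                       aberrant_cell_fraction: float, rng: np.random.Generator,
                       baf_sd: float = 0.0, lrr_sd: float = 0.0,
                       lrr_shift: tuple[float, float] = (-0.45, 0.3),
                       ) -> tuple[MarkerTrack, list[TruthRegion]]:
    """Overwrite signal means inside truth regions, then add noise.

    ``track`` is a noise-free diploid track.  Inside a loss (CN1)
    region a heterozygous marker loses one allele at random, moving its
    BAF towards 0 or 1 (exactly 0/1 when every cell is aberrant); in a
    gain (CN3) region one allele is duplicated, moving it to
    1/(2+f) or (1+f)/(2+f) for aberrant-cell fraction f.  Homozygous
    markers keep BAF 0/1.  LRR means shift to -0.45 (CN1) / +0.3 (CN3).
    Gaussian noise is then added genome-wide and BAF clipped to [0, 1].
    The recorded genotypes remain the underlying diploid genotypes.
    """
    regions = sorted(regions)
    for (s1, e1, _), (s2, _, _) in zip(regions, regions[1:]):
        if s2 <= e1:
            raise ValueError("aberration regions overlap")
    f = aberrant_cell_fraction
    if not 0.0 < f <= 1.0:
        raise ValueError("aberrant_cell_fraction must be in (0, 1]")
    baf = track.baf.copy()
    lrr = track.lrr.copy()
    het = track.genotypes == RA
    truths = []
    for start, end, state in regions:
        inside = (track.positions >= start) & (track.positions <= end)
        target = inside & het
        flip = rng.random(len(baf)) < 0.5  # which allele is lost/duplicated
        if state == 1:
            lo = (1.0 - f) / (2.0 - f)
            baf[target] = np.where(flip[target], lo, 1.0 - lo)
            lrr[inside] = lrr_shift[0]
        elif state == 3:
            lo = 1.0 / (2.0 + f)
            baf[target] = np.where(flip[target], lo, 1.0 - lo)
            lrr[inside] = lrr_shift[1]
        else:
            raise ValueError(f"unsupported aberration state {state}")
        truths.append(TruthRegion(track.chrom, start, end, state,
                                  int(inside.sum()), int(target.sum())))
    if baf_sd > 0:
        baf = np.clip(baf + rng.normal(0.0, baf_sd, len(baf)), 0.0, 1.0)
    if lrr_sd > 0:
        lrr = lrr + rng.normal(0.0, lrr_sd, len(lrr))
    out = MarkerTrack(track.chrom, track.positions, baf, lrr,
                      track.genotypes, track.alt_freq)
    return out, truths


def simulate_chromosome(config: SimulationConfig, rng: np.random.Generator,
                        n_aberrations: int | None = None,
                        ) -> tuple[MarkerTrack, list[TruthRegion]]:
    """One experiment: a chromosome with embedded CN1/CN3 aberrations."""
    base = _diploid_track(config, rng)
    regions = _draw_regions(config, rng, n_aberrations)
    baf_sd, lrr_sd = config.sd_pair(rng)
    return inject_aberrations(base, regions, config.aberrant_cell_fraction,
                              rng, baf_sd, lrr_sd, config.lrr_shift)


def simulate_experiment_set(n_experiments: int,
                            config: SimulationConfig | None = None,
                            seed: int = 0):
    """Yield ``n_experiments`` (track, truth-regions) pairs.

    Fully reproducible from ``seed``; experiments are generated lazily
    so arbitrarily many can be scored in constant memory.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    for _ in range(n_experiments):
        yield simulate_chromosome(config, rng)


def simulate_whole_chromosome(n_sites: int, kind: str, fraction: float,
                              rng: np.random.Generator,
                              baf_sd: float = 0.04, lrr_sd: float = 0.2,
                              het_fraction: float = 0.15,
                              median_spacing: float = 2_000.0,
                              chrom: str = "1") -> MarkerTrack:
    """Whole-chromosome track for aneuploidy/contamination screening.

    kind
        ``"diploid"`` -- normal CN2 chromosome;
        ``"trisomy"`` -- fraction ``f`` of cells carries a third copy,
        heterozygous BAF peaks at 1/(2+f) and (1+f)/(2+f);
        ``"contamination"`` -- fraction ``f`` of cells comes from a
        second individual with independent genotypes, BAF means
        ((1-f) a1 + f a2)/2 for allele doses a1, a2.
    """
    if kind not in ("diploid", "trisomy", "contamination"):
        raise ValueError(f"unknown kind {kind!r}")
    scale = median_spacing / _LN2
    pos = np.cumsum(np.maximum(1, rng.exponential(scale, n_sites).astype(np.int64)))
    gt, q = simulate_genotypes(pos, het_fraction, rng)
    baf = gt.astype(float) / 2.0
    lrr = np.zeros(n_sites)
    f = fraction
    if kind == "trisomy":
        if not 0.0 < f <= 1.0:
            raise ValueError("trisomy fraction must be in (0, 1]")
        het = gt == RA
        dup_b = rng.random(n_sites) < 0.5  # clonally duplicated allele
        baf[het] = np.where(dup_b[het], (1.0 + f) / (2.0 + f), 1.0 / (2.0 + f))
        lrr[:] = np.log2((2.0 + f) / 2.0) * 0.55  # array-attenuated intensity gain
    elif kind == "contamination":
        if not 0.0 < f < 1.0:
            raise ValueError("contamination fraction must be in (0, 1)")
        p_rr = (1.0 - q) ** 2
        p_ra = 2.0 * q * (1.0 - q)
        u = rng.random(n_sites)
        gt2 = np.where(u < p_rr, RR, np.where(u < p_rr + p_ra, RA, AA))
        baf = ((1.0 - f) * gt + f * gt2) / 2.0
    if baf_sd > 0:
        baf = np.clip(baf + rng.normal(0.0, baf_sd, n_sites), 0.0, 1.0)
    if lrr_sd > 0:
        lrr = lrr + rng.normal(0.0, lrr_sd, n_sites)
    return MarkerTrack(chrom, pos, baf, lrr, gt, q)


_GT_STR = {RR: "0/0", RA: "0/1", AA: "1/1", GT_MISSING: "./."}


def write_vcf(tracks: dict[str, MarkerTrack] | MarkerTrack, sample: str,
              path: str | Path, contig_length: int = 250_000_000) -> None:
    """Write tracks as a VCF with GT:BAF:LRR FORMAT fields and INFO/AF."""
    if isinstance(tracks, MarkerTrack):
        tracks = {tracks.chrom: tracks}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=cellcheck-simulate\n")
        for chrom in tracks:
            fh.write(f"##contig=<ID={chrom},length={contig_length}>\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alternate allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=BAF,Number=1,Type=Float,Description="B Allele Frequency">\n')
        fh.write('##FORMAT=<ID=LRR,Number=1,Type=Float,Description="Log R Ratio">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for chrom, tr in tracks.items():
            for i in range(len(tr)):
                baf = "." if np.isnan(tr.baf[i]) else f"{tr.baf[i]:.5f}"
                lrr = "." if np.isnan(tr.lrr[i]) else f"{tr.lrr[i]:.5f}"
                fh.write(f"{chrom}\t{tr.positions[i]}\t.\tA\tC\t.\t.\t"
                         f"AF={tr.alt_freq[i]:.5f}\tGT:BAF:LRR\t"
                         f"{_GT_STR[int(tr.genotypes[i])]}:{baf}:{lrr}\n")


def write_truth(truths: list[TruthRegion], path: str | Path) -> None:
    df = pd.DataFrame([(t.chrom, t.start, t.end, t.state, t.n_markers,
                        t.n_het_markers) for t in truths],
                      columns=["chrom", "start", "end", "state",
                               "n_markers", "n_het_markers"])
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> list[TruthRegion]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, comment="#")
    return [TruthRegion(str(r.chrom), int(r.start), int(r.end), int(r.state),
                        int(r.n_markers), int(r.n_het_markers))
            for r in df.itertuples(index=False)]
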