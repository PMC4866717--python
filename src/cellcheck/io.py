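"""Marker-level input/output for SNP-array BAF/LRR data.

The central container is :class:`MarkerTrack`, one per chromosome per
sample: parallel arrays of position, B-allele frequency (BAF), Log R
Ratio (LRR), genotype and population alternate-allele frequency.
Missing values are encoded as ``nan`` (BAF/LRR) and ``-1`` (genotype);
a marker with a called genotype but missing BAF is demoted to fully
missing, since a genotype without its underlying signal cannot be used
by either caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# genotype codes
RR, RA, AA, GT_MISSING = 0, 1, 2, -1

__all__ = [
    "MarkerTrack",
    "GenotypePriors",
    "CNVSegment",
    "genotype_priors",
    "hwe_priors",
    "read_markers",
    "smooth_lrr",
    "write_segments",
    "read_segments",
    "write_posteriors",
]


@dataclass
class MarkerTrack:
    """Ordered markers of one chromosome for one sample.

    Attributes
    ----------
    chrom : str
        Chromosome identifier.
    positions : ndarray of int64
        1-based bp coordinates, strictly increasing.
    baf : ndarray of float
        B-allele frequency in [0, 1], ``nan`` when missing.
    lrr : ndarray of float
        Log R Ratio (log2-scale intensity ratio), ``nan`` when missing.
    genotypes : ndarray of int8
        0 = RR, 1 = RA, 2 = AA, -1 = missing.
    alt_freq : ndarray of float
        Population alternate-allele frequency in [0, 1].
    """

    chrom: str
    positions: np.ndarray
    baf: np.ndarray
    lrr: np.ndarray
    genotypes: np.ndarray
    alt_freq: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.baf = np.asarray(self.baf, dtype=float)
        self.lrr = np.asarray(self.lrr, dtype=float)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.alt_freq = np.asarray(self.alt_freq, dtype=float)
        n = len(self.positions)
        for name in ("baf", "lrr", "genotypes", "alt_freq"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"length mismatch: {name} has "
                                 f"{len(getattr(self, name))} entries, expected {n}")
        if n > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError(f"positions not strictly increasing on {self.chrom}")
        ok = np.isnan(self.baf) | ((self.baf >= 0) & (self.baf <= 1))
        if not np.all(ok):
            raise ValueError("BAF values outside [0, 1]")
        # missing BAF and missing genotype co-occur (conservative)
        missing = np.isnan(self.baf) | (self.genotypes == GT_MISSING)
        self.baf[missing] = np.nan
        self.genotypes[missing] = GT_MISSING

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def is_missing(self) -> np.ndarray:
        """Markers with no usable call (missing genotype/BAF)."""
        return self.genotypes == GT_MISSING

    @property
    def is_het(self) -> np.ndarray:
        return self.genotypes == RA

    def drop_missing(self) -> "MarkerTrack":
        """Track restricted to markers with a usable call."""
        keep = ~self.is_missing
        return MarkerTrack(self.chrom, self.positions[keep], self.baf[keep],
                           self.lrr[keep], self.genotypes[keep], self.alt_freq[keep])

    def subset(self, mask: np.ndarray) -> "MarkerTrack":
        return MarkerTrack(self.chrom, self.positions[mask], self.baf[mask],
                           self.lrr[mask], self.genotypes[mask], self.alt_freq[mask])


@dataclass(frozen=True)
class GenotypePriors:
    """Prior genotype probabilities (f_RR, f_RA, f_AA), summing to 1."""

    f_rr: float
    f_ra: float
    f_aa: float

    def __post_init__(self) -> None:
        s = self.f_rr + self.f_ra + self.f_aa
        if min(self.f_rr, self.f_ra, self.f_aa) < 0 or abs(s - 1.0) > 1e-9:
            raise ValueError(f"invalid genotype priors {self}")


@dataclass
class CNVSegment:
    """A called copy-number segment (1-based inclusive coordinates).

    ``state`` is the copy-number state (0-3) of the (query) sample;
    ``control_state`` is set in paired calling.  ``quality`` is the mean
    posterior probability of the assigned state(s) over the segment's
    markers, as computed by the forward-backward algorithm.
    """

    chrom: str
    start: int
    end: int
    state: int
    quality: float = float("nan")
    n_markers: int = 0
    control_state: int | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def phred_quality(self) -> float:
        """Capped Phred transform -10*log10(1 - quality), cap 99."""
        if np.isnan(self.quality):
            return float("nan")
        if self.quality >= 1.0 - 1e-10:
            return 99.0
        return min(99.0, -10.0 * np.log10(1.0 - self.quality))


def genotype_priors(alt_freq: float) -> GenotypePriors:
    """Hardy-Weinberg genotype priors from the alternate-allele frequency."""
    if not 0.0 <= alt_freq <= 1.0:
        raise ValueError(f"allele frequency {alt_freq} outside [0, 1]")
    q = alt_freq
    return GenotypePriors((1 - q) ** 2, 2 * q * (1 - q), q * q)


def hwe_priors(alt_freq: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Hardy-Weinberg (f_RR, f_RA, f_AA) per marker."""
    q = np.asarray(alt_freq, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("allele frequency outside [0, 1]")
    return (1 - q) ** 2, 2 * q * (1 - q), q * q


def smooth_lrr(track: MarkerTrack, window: int) -> MarkerTrack:
    """Centered moving average of LRR over non-missing neighbours.

    BAF is untouched.  ``window`` is an odd marker count; ``window=1``
    is the identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window == 1:
        return replace(track)
    lrr = track.lrr
    finite = np.isfinite(lrr)
    vals = np.where(finite, lrr, 0.0)
    kernel = np.ones(window)
    num = np.convolve(vals, kernel, mode="same")
    den = np.convolve(finite.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        sm = num / den
    sm[~finite] = np.nan  # missing stays missing
    out = replace(track)
    out.lrr = sm
    return out


def read_markers(
    vcf_path: str | Path,
    sample: str,
    regions: list[str] | None = None,
    baf_tag: str = "BAF",
    lrr_tag: str = "LRR",
    af_tag: str | None = None,
) -> dict[str, MarkerTrack]:
    """Read per-sample BAF/LRR marker data from a VCF/BCF file.

    Only biallelic SNP records are used; others are skipped with a
    logged count.  Alternate-allele frequencies are taken from the INFO
    field ``af_tag`` if given, else computed from the cohort genotypes
    (when the file has more than one sample), else set globally from
    the sample's own genotype frequencies.

    A missing BAF FORMAT field is fatal; a missing LRR field degrades
    to LRR-less tracks (BAF-only calling) with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    if sample not in vcf.samples:
        raise ValueError(f"sample {sample!r} not found in {vcf_path}")
    sidx = vcf.samples.index(sample)
    n_samples = len(vcf.samples)

    def _has_format(tag: str) -> bool:
        try:
            vcf.get_header_type(tag)
            return True
        except KeyError:
            return False

    if not _has_format(baf_tag):
        raise ValueError(f"FORMAT/{baf_tag} not present in {vcf_path}")
    have_lrr = _has_format(lrr_tag)
    if not have_lrr:
        logger.warning("FORMAT/%s not present in %s; LRR set missing", lrr_tag, vcf_path)

    region_filter = _parse_regions(regions)

    data: dict[str, list] = {}
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        chrom, pos = rec.CHROM, rec.POS
        if region_filter is not None and not _in_regions(region_filter, chrom, pos):
            continue
        gt = int(rec.gt_types[sidx])
        gt = GT_MISSING if gt == 3 else gt
        arr = rec.format(baf_tag)
        baf = float(arr[sidx][0]) if arr is not None else np.nan
        if have_lrr:
            arr = rec.format(lrr_tag)
            lrr = float(arr[sidx][0]) if arr is not None else np.nan
        else:
            lrr = np.nan
        af = np.nan
        if af_tag is not None:
            v = rec.INFO.get(af_tag)
            if v is not None:
                af = float(v[0] if isinstance(v, tuple) else v)
        elif n_samples > 1:
            af = float(rec.aaf)
        data.setdefault(chrom, []).append((pos, baf, lrr, gt, af))
    if n_skipped:
        logger.info("skipped %d non-biallelic/non-SNP records", n_skipped)

    tracks: dict[str, MarkerTrack] = {}
    all_gts: list[np.ndarray] = []
    for chrom, rows in data.items():
        rows.sort(key=lambda r: r[0])
        pos, baf, lrr, gt, af = (np.array(x) for x in zip(*rows))
        tracks[chrom] = MarkerTrack(chrom, pos, baf, lrr, gt.astype(np.int8), af)
        all_gts.append(tracks[chrom].genotypes)
    if tracks and af_tag is None and n_samples == 1:
        # fall back to the sample's own genome-wide allele frequency
        gts = np.concatenate(all_gts)
        called = gts[gts != GT_MISSING]
        q = float(np.mean(called) / 2.0) if len(called) else 0.5
        for tr in tracks.values():
            tr.alt_freq[:] = q
    else:
        for tr in tracks.values():
            tr.alt_freq[np.isnan(tr.alt_freq)] = 0.5
    return tracks


def _parse_regions(regions: list[str] | None):
    if regions is None:
        return None
    parsed = []
    for r in regions:
        if ":" in r:
            chrom, rng = r.split(":", 1)
            lo, hi = rng.replace(",", "").split("-")
            parsed.append((chrom, int(lo), int(hi)))
        else:
            parsed.append((r, 1, np.iinfo(np.int64).max))
    return parsed


def _in_regions(parsed, chrom: str, pos: int) -> bool:
    return any(c == chrom and lo <= pos <= hi for c, lo, hi in parsed)


_SEGMENT_COLUMNS = ["chrom", "start", "end", "state", "control_state",
                    "quality", "n_markers"]


def write_segments(segments: list[CNVSegment], path: str | Path) -> None:
    """Write segments as a TSV, ordered by (chromosome, start).

    Overlapping segments on one chromosome are rejected.
    """
    segs = sorted(segments, key=lambda s: (s.chrom, s.start))
    prev: dict[str, int] = {}
    for s in segs:
        if s.chrom in prev and s.start <= prev[s.chrom]:
            raise ValueError(f"overlapping segments on {s.chrom} at {s.start}")
        prev[s.chrom] = s.end
    df = pd.DataFrame(
        [(s.chrom, s.start, s.end, s.state,
          "." if s.control_state is None else s.control_state,
          f"{s.quality:.6g}", s.n_markers) for s in segs],
        columns=_SEGMENT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> list[CNVSegment]:
    """Inverse of :func:`write_segments`."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"chrom": str, "control_state": str})
    out = []
    for row in df.itertuples(index=False):
        ctrl = None if row.control_state in (".", None) else int(row.control_state)
        out.append(CNVSegment(str(row.chrom), int(row.start), int(row.end),
                              int(row.state), float(row.quality),
                              int(row.n_markers), ctrl))
    return out


def write_posteriors(chrom: str, positions: np.ndarray, posteriors: np.ndarray,
                     path: str | Path) -> None:
    """Per-site most-likely state and its posterior, as TSV."""
    best = posteriors.argmax(axis=1)
    df = pd.DataFrame({
        "chrom": chrom,
        "pos": positions,
        "state": best,
        "posterior": np.round(posteriors[np.arange(len(best)), best], 6),
    })
    df.to_csv(path, sep="\t", index=False)
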