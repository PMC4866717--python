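"""Whole-chromosome aneuploidy and contamination screening.

Works purely on the per-chromosome distribution of BAF values.  A
normal diploid chromosome shows heterozygous BAF clustered at 0.5; a
trisomy carried by a fraction ``f`` of cells splits that cluster into
two peaks at 1/(2+f) and (1+f)/(2+f); contamination by a second
individual adds symmetric side peaks at (1-f)/2 and (1+f)/2 around a
retained central peak.  The method histograms the BAF values, smooths
and peak-normalizes the central region, then fits constrained
Gaussian-peak models for each candidate state by damped nonlinear
least squares and selects a state by goodness of fit.

Since a multi-peak model always fits at least as well as a nested
single-peak model, an aberrant state is only accepted when its mean
absolute deviation is below a fraction (default 30%) of the
single-peak deviation, and when the implied aberrant-cell fraction is
large enough (default 20%) for the side peaks to be cleanly separated.
Contamination is distinguished from trisomy at the sample level: it
shows the same split on (almost) all chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .io import MarkerTrack

__all__ = [
    "PolysomyConfig",
    "BAFDistribution",
    "PeakFit",
    "ChromosomeCall",
    "SampleCall",
    "build_distribution",
    "fit_state",
    "fraction_from_delta",
    "select_state",
    "call_chromosome",
    "call_sample",
]

STATE_CN2 = "CN2"
STATE_CN3 = "CN3"
STATE_CN4 = "CN4"      # contamination-type three-peak pattern
STATE_FAIL = "FAIL"


@dataclass
class PolysomyConfig:
    """Tuning knobs of the screening method.

    fit_gate
        An aberrant state is accepted only if its mean absolute
        deviation is below ``fit_gate`` times the CN2 deviation.
    min_fraction
        Minimum aberrant/contaminating cell fraction; below it the
        side peaks are too close to 0.5 to be trusted.
    cn4_gate
        The contamination model nests the two-peak model, so it is
        preferred over an otherwise acceptable CN3 fit only when its
        deviation is below ``cn4_gate`` times the CN3 deviation.
    peak_size
        Minimum fitted magnitude (in peak-normalized units) for the
        peaks that define an aberrant model; a model whose defining
        peak degenerates to less than this is not a real alternative
        to fewer peaks.
    cn2_abs_dev_cap
        Absolute deviation (in peak-normalized units) above which even
        the best fit is considered a failure to assign a state.
    """

    fit_gate: float = 0.30
    min_fraction: float = 0.20
    cn4_gate: float = 0.70
    peak_size: float = 0.10
    include_aa_peak: bool = False
    n_bins: int = 100
    smoothing_window: int = 5
    min_sites: int = 100
    cn2_abs_dev_cap: float = 0.30
    delta_starts: tuple[float, ...] = (0.05, 0.10, 0.17, 0.25)
    width_bounds: tuple[float, float] = (0.01, 0.15)
    free_widths: bool = False
    # sample-level contamination verdict
    contamination_min_autosomes: float = 0.5
    contamination_delta_spread: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.fit_gate < 1.0:
            raise ValueError("fit_gate must be in (0, 1)")
        if not 0.0 <= self.min_fraction < 0.5:
            raise ValueError("min_fraction must be in [0, 0.5)")


@dataclass
class BAFDistribution:
    """Binned, smoothed, peak-normalized BAF histogram of a chromosome."""

    bin_centers: np.ndarray
    density: np.ndarray            # scaled smoothed density (central max = 1)
    raw_density: np.ndarray
    smoothing_window: int
    peak_boundaries: np.ndarray    # bin indices of local minima
    fit_lo: int                    # first fitted bin
    fit_hi: int                    # last fitted bin (inclusive)
    n_sites: int
    scaled: bool = True

    @property
    def fit_slice(self) -> slice:
        return slice(self.fit_lo, self.fit_hi + 1)


@dataclass
class PeakFit:
    """A fitted constrained Gaussian-peak model for one candidate state."""

    cn_state: str
    delta: float                   # half-distance of side peaks from 0.5
    widths: np.ndarray
    magnitudes: np.ndarray
    abs_dev: float                 # mean |fit - data| over fitted bins
    converged: bool


@dataclass
class ChromosomeCall:
    chrom: str
    state: str                     # CN2 | CN3 | CN4 | FAIL
    fraction: float                # estimated aberrant/contaminating fraction
    fit_ratio: float               # abs_dev(best) / abs_dev(CN2)
    n_sites: int
    delta: float = 0.0


@dataclass
class SampleCall:
    """Per-chromosome calls plus the sample-level contamination verdict."""

    calls: list[ChromosomeCall]
    contaminated: bool
    contamination_fraction: float  # median 2*delta over affected chromosomes


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.copy()
    kernel = np.ones(window)
    return np.convolve(x, kernel, mode="same") / \
        np.convolve(np.ones_like(x), kernel, mode="same")


def _local_minima(x: np.ndarray) -> np.ndarray:
    if len(x) < 3:
        return np.empty(0, dtype=int)
    inner = np.flatnonzero((x[1:-1] <= x[:-2]) & (x[1:-1] <= x[2:])) + 1
    return inner


def build_distribution(bafs: np.ndarray, n_bins: int = 100,
                       smoothing_window: int = 5, min_sites: int = 100,
                       include_aa_peak: bool = False) -> BAFDistribution | None:
    """Histogram, smooth and peak-normalize a chromosome's BAF values.

    Returns ``None`` when fewer than ``min_sites`` usable values are
    available (the chromosome is then reported as FAIL).  The fitted
    (modelled) region runs from the first local minimum right of the
    RR peak to the last local minimum left of the AA peak (or through
    the AA peak when it is included), and the smoothed density is
    rescaled so the maximum of that region is 1.
    """
    bafs = np.asarray(bafs, dtype=float)
    bafs = bafs[np.isfinite(bafs)]
    if len(bafs) < min_sites:
        return None
    hist, edges = np.histogram(bafs, bins=n_bins, range=(0.0, 1.0), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = _moving_average(hist, smoothing_window)
    minima = _local_minima(smooth)

    rr_peak = int(np.argmax(np.where(centers < 0.25, smooth, -np.inf)))
    aa_peak = int(np.argmax(np.where(centers > 0.75, smooth, -np.inf)))
    right_of_rr = minima[minima > rr_peak]
    fit_lo = int(right_of_rr[0]) if len(right_of_rr) else rr_peak + 1
    if include_aa_peak:
        fit_hi = n_bins - 1
    else:
        left_of_aa = minima[(minima < aa_peak) & (minima >= fit_lo)]
        fit_hi = int(left_of_aa[-1]) if len(left_of_aa) else aa_peak - 1
    fit_hi = max(fit_hi, fit_lo + 3)  # keep a minimal fitting window

    peak = smooth[fit_lo:fit_hi + 1].max()
    scale = peak if peak > 0 else smooth.max()
    if scale <= 0:
        scale = 1.0
    return BAFDistribution(centers, smooth / scale, hist, smoothing_window,
                           minima, fit_lo, fit_hi, len(bafs))


def fraction_from_delta(cn_state: str, delta: float) -> float:
    """Aberrant/contaminating cell fraction implied by the peak split.

    Trisomy: side peaks at 1/(2+f) and (1+f)/(2+f), so
    delta = f/(2(2+f)) and f = 4*delta/(1 - 2*delta).  Contamination:
    side peaks at (1-f)/2 and (1+f)/2 from the host-heterozygous,
    contaminant-homozygous genotype mix, so f = 2*delta.
    """
    if not 0.0 <= delta < 0.5:
        raise ValueError("delta must be in [0, 0.5)")
    if cn_state == STATE_CN3:
        return min(1.0, 4.0 * delta / (1.0 - 2.0 * delta))
    if cn_state == STATE_CN4:
        # a contamination of fraction f is the mirror image of one of
        # fraction 1-f; report the minority genome
        return 2.0 * min(delta, 0.5 - delta)
    if cn_state == STATE_CN2:
        return 0.0
    raise ValueError(f"no fraction model for state {cn_state}")


def _model(x: np.ndarray, cn_state: str, params: np.ndarray,
           free_widths: bool, aa_mag: float | None) -> np.ndarray:
    """Constrained Gaussian-sum model evaluated at bin centers."""
    g = lambda c, w: np.exp(-((x - c) ** 2) / w**2)
    if cn_state == STATE_CN2:
        a, w = params[0], params[1]
        y = a * g(0.5, w)
    elif cn_state == STATE_CN3:
        a, delta = params[0], params[-1]
        w1, w2 = (params[1], params[2]) if free_widths else (params[1], params[1])
        y = a * g(0.5 - delta, w1) + a * g(0.5 + delta, w2)
    elif cn_state == STATE_CN4:
        # two-genome mixture at contaminating fraction f = 2*delta:
        # host-het peaks at 0.5 -/+ delta around the central peak, and
        # contaminant-het-over-host-homozygote peaks at delta / 1 - delta
        ac, a1, a2, ae1, ae2, delta = (params[0], params[1], params[2],
                                       params[3], params[4], params[-1])
        if free_widths:
            wc, w1, w2 = params[5], params[6], params[7]
        else:
            wc = w1 = w2 = params[5]
        y = ac * g(0.5, wc) + a1 * g(0.5 - delta, w1) + a2 * g(0.5 + delta, w2) \
            + ae1 * g(delta, w1) + ae2 * g(1.0 - delta, w2)
    else:
        raise ValueError(f"cannot fit state {cn_state}")
    if aa_mag is not None:
        w_aa = params[-1] if cn_state == STATE_CN2 else params[-2]
        y = y + aa_mag * g(1.0, w_aa)
    return y


def fit_state(dist: BAFDistribution, cn_state: str,
              config: PolysomyConfig | None = None) -> PeakFit:
    """Damped least-squares fit of one candidate state's peak model.

    The CN2 model is a single peak fixed at 0.5; CN3 two equal-height
    peaks at 0.5 +/- delta; CN4 a central peak plus two side peaks of
    independent heights.  Peaks share one width unless
    ``config.free_widths``.  Multi-peak models are restarted from
    several initial separations and the best solution (lowest mean
    absolute deviation, then smallest delta) is kept.
    """
    config = config or PolysomyConfig()
    x = dist.bin_centers[dist.fit_slice]
    y = dist.density[dist.fit_slice]
    wlo, whi = config.width_bounds
    free = config.free_widths
    include_aa = config.include_aa_peak

    def _fit_once(p0, lo, hi):
        aa = None
        if include_aa:
            p0 = np.append(p0, 1.0)
            lo, hi = np.append(lo, 0.0), np.append(hi, 5.0)

        def resid(p):
            if include_aa:
                return _model(x, cn_state, p[:-1], free, p[-1]) - y
            return _model(x, cn_state, p, free, None) - y

        try:
            res = least_squares(resid, p0, bounds=(lo, hi), method="trf")
        except Exception:
            return None
        return res

    nw = (3 if cn_state == STATE_CN4 else (2 if cn_state == STATE_CN3 else 1)) \
        if free else 1
    w0 = [0.05] * nw
    wlo_v, whi_v = [wlo] * nw, [whi] * nw
    if cn_state == STATE_CN2:
        starts = [(np.array([1.0] + w0), np.array([0.0] + wlo_v),
                   np.array([5.0] + whi_v))]
    elif cn_state == STATE_CN3:
        starts = [(np.array([1.0] + w0 + [d0]), np.array([0.0] + wlo_v + [0.005]),
                   np.array([5.0] + whi_v + [0.49])) for d0 in config.delta_starts]
    else:
        starts = [(np.array([1.0, 1.0, 1.0, 0.5, 0.5] + w0 + [d0]),
                   np.array([0.0] * 5 + wlo_v + [0.005]),
                   np.array([5.0] * 5 + whi_v + [0.49]))
                  for d0 in config.delta_starts]

    best: PeakFit | None = None
    for p0, lo, hi in starts:
        res = _fit_once(p0, lo, hi)
        if res is None:
            continue
        p = res.x[:-1] if include_aa else res.x
        delta = float(p[-1]) if cn_state in (STATE_CN3, STATE_CN4) else 0.0
        abs_dev = float(np.mean(np.abs(res.fun)))
        if cn_state == STATE_CN2:
            mags, widths = p[:1], p[1:2]
        elif cn_state == STATE_CN3:
            mags = np.array([p[0], p[0]])
            widths = p[1:-1] if free else p[1:2]
        else:
            mags = p[:5]
            widths = p[5:-1] if free else p[5:6]
        fit = PeakFit(cn_state, delta, np.asarray(widths), np.asarray(mags),
                      abs_dev, bool(res.success))
        if best is None or (fit.abs_dev, fit.delta) < (best.abs_dev, best.delta):
            best = fit
    if best is None:
        return PeakFit(cn_state, 0.0, np.array([np.nan]), np.array([np.nan]),
                       np.inf, False)
    return best


def select_state(fits: dict[str, PeakFit], config: PolysomyConfig,
                 chrom: str = "?", n_sites: int = 0) -> ChromosomeCall:
    """Pick the copy-number state from the per-state fits.

    The best aberrant fit is accepted only when its deviation beats
    ``fit_gate`` times the CN2 deviation *and* its implied cell
    fraction reaches ``min_fraction``; otherwise the chromosome is
    called CN2, or FAIL when even the single-peak fit is poor.
    """
    cn2 = fits[STATE_CN2]
    cn2_ok = cn2.converged and cn2.abs_dev <= config.cn2_abs_dev_cap
    candidates = {}
    for state in (STATE_CN3, STATE_CN4):
        fit = fits.get(state)
        if fit is None or not fit.converged or not np.isfinite(fit.abs_dev):
            continue
        frac = fraction_from_delta(state, fit.delta)
        # the peaks that define the aberrant pattern must exist: the
        # side pair for CN3, the central + side peaks for CN4
        defining = fit.magnitudes[:3] if state == STATE_CN4 else fit.magnitudes[:2]
        if np.min(defining) < config.peak_size:
            continue
        if fit.abs_dev < config.fit_gate * cn2.abs_dev and frac >= config.min_fraction:
            candidates[state] = (fit, frac)
    if STATE_CN3 in candidates and STATE_CN4 in candidates:
        # nested models: keep the extra central peak only when it
        # improves the fit substantially
        cn3, cn4 = candidates[STATE_CN3][0], candidates[STATE_CN4][0]
        state = STATE_CN4 if cn4.abs_dev < config.cn4_gate * cn3.abs_dev else STATE_CN3
    elif candidates:
        state = next(iter(candidates))
    else:
        state = None
    if state is not None:
        fit, frac = candidates[state]
        return ChromosomeCall(chrom, state, frac, fit.abs_dev / cn2.abs_dev,
                              n_sites, fit.delta)
    if cn2_ok:
        return ChromosomeCall(chrom, STATE_CN2, 0.0, 1.0, n_sites, 0.0)
    return ChromosomeCall(chrom, STATE_FAIL, 0.0, float("inf"), n_sites, 0.0)


def call_chromosome(bafs: np.ndarray, config: PolysomyConfig | None = None,
                    chrom: str = "?") -> tuple[ChromosomeCall, dict[str, PeakFit] | None]:
    """Full screen of one chromosome's BAF values."""
    config = config or PolysomyConfig()
    dist = build_distribution(bafs, config.n_bins, config.smoothing_window,
                              config.min_sites, config.include_aa_peak)
    n = int(np.isfinite(np.asarray(bafs, dtype=float)).sum())
    if dist is None:
        return ChromosomeCall(chrom, STATE_FAIL, 0.0, float("inf"), n), None
    fits = {s: fit_state(dist, s, config)
            for s in (STATE_CN2, STATE_CN3, STATE_CN4)}
    return select_state(fits, config, chrom, dist.n_sites), fits


def call_sample(tracks: dict[str, MarkerTrack],
                config: PolysomyConfig | None = None) -> SampleCall:
    """Screen every chromosome and issue the contamination verdict.

    A single aberrant chromosome among diploid ones is a trisomy; the
    same peak split appearing on most chromosomes with consistent
    separation is contamination, in which case the per-chromosome
    calls are re-labelled CN4 and the fraction re-estimated as
    2*delta.
    """
    config = config or PolysomyConfig()
    calls = []
    for chrom, track in tracks.items():
        call, _ = call_chromosome(track.baf, config, chrom)
        calls.append(call)
    aberrant = [c for c in calls if c.state in (STATE_CN3, STATE_CN4)]
    contaminated = False
    cont_frac = 0.0
    if calls and aberrant:
        share = len(aberrant) / len(calls)
        # mirrored contamination fits (delta vs 0.5-delta) describe the
        # same peak pattern; compare separations on the canonical side
        deltas = np.array([min(c.delta, 0.5 - c.delta) for c in aberrant])
        spread = float(deltas.max() - deltas.min())
        if share > config.contamination_min_autosomes and \
                spread < config.contamination_delta_spread:
            contaminated = True
            cont_frac = float(np.median(2.0 * deltas))
            for c in calls:
                if c.state == STATE_CN3:
                    c.state = STATE_CN4
                    c.fraction = 2.0 * min(c.delta, 0.5 - c.delta)
    return SampleCall(calls, contaminated, cont_frac)
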