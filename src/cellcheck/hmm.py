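"""Copy-number HMMs over BAF and LRR.

The single-sample model has four hidden states -- copy numbers 0
(complete loss), 1 (single-copy loss), 2 (normal diploid) and 3
(single-copy gain).  BAF emissions are mixtures of truncated Gaussian
peaks placed at the expected allelic ratios of each state, weighted by
Hardy-Weinberg genotype priors; LRR emissions are Gaussians around the
state-specific intensity shifts (-0.45, 0, +0.3).  The two signals are
combined with tunable weights ``b`` and ``l`` plus a uniform error
floor, so either can be down-weighted when unreliable.

Transitions are symmetric with a per-basepair switch probability ``p``;
the matrix is raised to the power of the inter-marker distance, so
sparse regions are penalized less per marker.  Decoding uses Viterbi
(most probable path) and forward-backward (per-site posteriors, used
for segment qualities and for re-estimating the heterozygous BAF shift
when only a fraction of cells carries a gain).

The paired model is the 16-state product of two single-sample models
with a shared-state prior ``sigma`` coupling the two chains, so copy
number variation present in both samples (inherited variation) is not
reported as a difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import sqrt, pi

import numpy as np
from scipy.special import erf

from .io import (
    RA,
    CNVSegment,
    GenotypePriors,
    MarkerTrack,
    hwe_priors,
)

__all__ = [
    "EmissionParams",
    "TransitionModel",
    "PairedCallResult",
    "gaussian_peak",
    "baf_emission",
    "lrr_emission",
    "site_emission",
    "pair_emission",
    "build_transitions",
    "pair_transitions",
    "viterbi",
    "forward_backward",
    "optimize_beta0",
    "call_cnv",
    "call_cnv_pair",
]

N_STATES = 4
CN2 = 2
_SQRT_PI = sqrt(pi)
# BAF probability of a missing call per state (paired calling only)
_NA_BAF = np.array([0.5, 0.5 / 3, 0.5 / 3, 0.5 / 3])
# Viterbi tie-break preference: CN2 first, then lower state index
_PREF4 = np.array([2, 0, 1, 3])


@dataclass
class EmissionParams:
    """Emission model parameters.

    d : BAF peak scale (the Gaussian exponent is (beta-beta0)^2/d^2),
        default 0.04.
    lam : LRR scale Lambda, default 0.2.
    mu : LRR means for states CN1, CN2, CN3, default (-0.45, 0, 0.3).
    b, l : BAF and LRR weights in [0, 1], defaults 1 and 0.2.  The low
        default LRR weight reflects the poor reproducibility of LRR on
        real arrays; simulated Gaussian LRR deserves ``l=1``.
    p_err : uniform probability of an erroneous reading, default 1e-4.
    beta0_het : expected BAF of the lower heterozygous peak under CN3;
        1/3 when every cell carries the gain, 1/(2+f) in general.
    """

    d: float = 0.04
    lam: float = 0.2
    mu: tuple[float, float, float] = (-0.45, 0.0, 0.3)
    b: float = 1.0
    l: float = 0.2
    p_err: float = 1e-4
    beta0_het: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.b <= 1.0 and 0.0 <= self.l <= 1.0):
            raise ValueError("weights b and l must be in [0, 1]")
        if self.d <= 0 or self.lam <= 0:
            raise ValueError("scales d and lam must be positive")
        if not 0.0 < self.beta0_het <= 0.5:
            raise ValueError("beta0_het must be in (0, 0.5]")


def _peak_norm(beta0, d: float):
    """Area of exp(-(beta-beta0)^2/d^2) truncated to [0, 1]."""
    beta0 = np.asarray(beta0, dtype=float)
    return d * _SQRT_PI * 0.5 * (erf((1.0 - beta0) / d) + erf(beta0 / d))


def gaussian_peak(beta, beta0, d: float):
    """Truncated Gaussian BAF peak, unit area over [0, 1].

    The normalizer accounts for truncation, so a boundary peak
    (beta0 = 0 or 1) is twice as tall as an interior one.
    """
    if d <= 0:
        raise ValueError("peak scale d must be positive")
    beta = np.asarray(beta, dtype=float)
    return np.exp(-((beta - beta0) ** 2) / d**2) / _peak_norm(beta0, d)


def _scaled_peak(beta, beta0, d: float):
    """gaussian_peak rescaled so an interior peak's mode is 1."""
    return gaussian_peak(beta, beta0, d) * d * _SQRT_PI


def baf_emission(beta, s: int, priors: GenotypePriors, params: EmissionParams):
    """P(beta | state), a unit-area density on [0, 1].

    State 0 has no allele to observe, so the density of any observed
    BAF value is 0.  State 3 places the heterozygous peaks at
    ``beta0_het`` and ``1 - beta0_het``.
    """
    b = np.asarray(beta, dtype=float)
    d = params.d
    G = lambda c: gaussian_peak(b, c, d)
    if s == 0:
        return np.zeros_like(b)
    if s == 1:
        return G(0.0) * (priors.f_rr + 0.5 * priors.f_ra) + \
            G(1.0) * (priors.f_aa + 0.5 * priors.f_ra)
    if s == 2:
        return G(0.0) * priors.f_rr + G(1.0) * priors.f_aa + G(0.5) * priors.f_ra
    if s == 3:
        b0 = params.beta0_het
        return G(0.0) * priors.f_rr + G(1.0) * priors.f_aa + \
            (G(b0) + G(1.0 - b0)) * 0.5 * priors.f_ra
    raise ValueError(f"invalid copy-number state {s}")


def lrr_emission(lambda_val, s: int, params: EmissionParams):
    """P(lambda | state), normalized so the maximum over lambda is 1."""
    if s not in (1, 2, 3):
        raise ValueError(f"no LRR model for state {s}")
    lam = np.asarray(lambda_val, dtype=float)
    mu = params.mu[s - 1]
    return np.exp(-((lam - mu) ** 2) / params.lam**2)


def site_emission(beta, lambda_val, s: int, priors: GenotypePriors,
                  params: EmissionParams) -> float:
    """Combined BAF+LRR emission for one site and one state.

    ``P_err + (1 - b(1 - P(beta|s))) * (1 - l(1 - P(lambda|s)))`` where
    the BAF density is rescaled by its interior-peak mode (d*sqrt(pi))
    so both factors are O(1).  ``beta``/``lambda`` may be NaN
    (missing): a missing BAF uses the missing-call probabilities (0.5
    for CN0, 0.5/3 otherwise, paired calling); a missing LRR sets the
    LRR weight to 0 for the site.
    """
    beta = float(beta)
    lambda_val = float(lambda_val)
    if np.isnan(beta):
        p_baf = _NA_BAF[s]
        l_eff = 0.0
    else:
        p_baf = 0.0 if s == 0 else \
            float(baf_emission(beta, s, priors, params)) * params.d * _SQRT_PI
        l_eff = 0.0 if np.isnan(lambda_val) else params.l
    p_lrr = 1.0 if (s == 0 or l_eff == 0.0) else float(lrr_emission(lambda_val, s, params))
    return params.p_err + (1.0 - params.b * (1.0 - p_baf)) * (1.0 - l_eff * (1.0 - p_lrr))


def pair_emission(beta1, lambda1, beta2, lambda2, s1: int, s2: int,
                  priors: GenotypePriors, params: EmissionParams) -> float:
    """Two-sample emission: product of the single-sample emissions."""
    return site_emission(beta1, lambda1, s1, priors, params) * \
        site_emission(beta2, lambda2, s2, priors, params)


def _emission_matrix(track: MarkerTrack, params: EmissionParams,
                     paired_na: bool = False) -> np.ndarray:
    """(n, 4) emission matrix for all markers of a track.

    With ``paired_na`` markers with a missing call get the
    missing-call BAF probabilities; otherwise the caller must have
    dropped them already.
    """
    beta = track.baf
    lam = track.lrr
    f_rr, f_ra, f_aa = hwe_priors(track.alt_freq)
    d = params.d
    b0 = params.beta0_het

    S = lambda c: _scaled_peak(beta, c, d)
    s_0, s_1, s_half = S(0.0), S(1.0), S(0.5)
    p_baf = np.empty((len(track), N_STATES))
    p_baf[:, 0] = 0.0
    p_baf[:, 1] = s_0 * (f_rr + 0.5 * f_ra) + s_1 * (f_aa + 0.5 * f_ra)
    p_baf[:, 2] = s_0 * f_rr + s_1 * f_aa + s_half * f_ra
    p_baf[:, 3] = s_0 * f_rr + s_1 * f_aa + (S(b0) + S(1.0 - b0)) * 0.5 * f_ra

    lam_ok = np.isfinite(lam)
    lam_safe = np.where(lam_ok, lam, 0.0)
    p_lrr = np.ones((len(track), N_STATES))
    for s in (1, 2, 3):
        p_lrr[:, s] = np.exp(-((lam_safe - params.mu[s - 1]) ** 2) / params.lam**2)

    missing = track.is_missing
    if paired_na:
        p_baf[missing] = _NA_BAF
    elif np.any(missing):
        raise ValueError("single-sample emissions require missing calls dropped")
    l_eff = np.where(lam_ok & ~missing, params.l, 0.0)[:, None]
    l_eff = np.broadcast_to(l_eff, (len(track), N_STATES)).copy()
    l_eff[:, 0] = 0.0  # no LRR model for CN0

    emis = params.p_err + (1.0 - params.b * (1.0 - p_baf)) * (1.0 - l_eff * (1.0 - p_lrr))
    return emis


class TransitionModel:
    """Distance-powered transition matrix with a cache of powers.

    The base matrix ``T`` is the per-basepair transition matrix.  The
    matrix for a gap of ``k`` bp is ``T**k``; powers up to
    ``cache_size`` (default 10,000) are pre-calculated, larger gaps are
    computed on demand by exponentiation-by-squaring and gaps beyond
    ``max_gap`` (default 10 Mb) use the ``max_gap`` power.
    """

    def __init__(self, matrix: np.ndarray, cache_size: int = 10_000,
                 max_gap: int = 10_000_000, p: float | None = None):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("transition matrix must be square")
        if not np.allclose(matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        self.matrix = matrix
        self.n_states = matrix.shape[0]
        self.cache_size = cache_size
        self.max_gap = max_gap
        self.p = p
        self._cache: np.ndarray | None = None
        self._log_cache: np.ndarray | None = None
        self._big: dict[int, np.ndarray] = {}

    @classmethod
    def from_p(cls, p: float = 1e-9, n_states: int = N_STATES, **kw) -> "TransitionModel":
        """Symmetric matrix: off-diagonal p, diagonal 1-(n-1)p."""
        if not 0.0 < p < 1.0 / (n_states - 1):
            raise ValueError(f"p must be in (0, 1/{n_states - 1})")
        t = np.full((n_states, n_states), p)
        np.fill_diagonal(t, 1.0 - (n_states - 1) * p)
        return cls(t, p=p, **kw)

    def _ensure_cache(self) -> None:
        if self._cache is not None:
            return
        S = self.n_states
        cache = np.empty((self.cache_size, S, S))
        cache[0] = self.matrix
        for k in range(1, self.cache_size):
            cache[k] = cache[k - 1] @ self.matrix
        self._cache = cache
        with np.errstate(divide="ignore"):  # sigma=1 forbids transitions
            self._log_cache = np.log(cache)

    def power(self, k: int) -> np.ndarray:
        """T**k (k >= 0), from the cache where possible."""
        k = int(k)
        if k < 0:
            raise ValueError("negative exponent")
        if k == 0:
            return np.eye(self.n_states)
        k = min(k, self.max_gap)
        if k <= self.cache_size:
            self._ensure_cache()
            return self._cache[k - 1]
        if k not in self._big:
            self._big[k] = np.linalg.matrix_power(self.matrix, k)
        return self._big[k]

    def matrices_for_gaps(self, gaps: np.ndarray, log: bool = False) -> np.ndarray:
        """(m, S, S) stack of T**gap (or its log) for each gap in bp."""
        gaps = np.clip(np.asarray(gaps, dtype=np.int64), 1, self.max_gap)
        self._ensure_cache()
        src = self._log_cache if log else self._cache
        out = np.empty((len(gaps), self.n_states, self.n_states))
        small = gaps <= self.cache_size
        out[small] = src[gaps[small] - 1]
        for k in np.unique(gaps[~small]):
            m = self.power(int(k))
            if log:
                with np.errstate(divide="ignore"):
                    m = np.log(m)
            out[gaps == k] = m
        return out

    def pair(self, sigma: float, **kw) -> "TransitionModel":
        """16-state paired model, see :func:`pair_transitions`."""
        return pair_transitions(self, sigma, **kw)


def build_transitions(p: float = 1e-9, n_states: int = N_STATES, **kw) -> TransitionModel:
    """Symmetric single-sample transition model with switch probability p."""
    return TransitionModel.from_p(p, n_states, **kw)


def pair_transitions(transitions: TransitionModel, sigma: float,
                     **kw) -> TransitionModel:
    """Coupled 16-state transition model for paired calling.

    For the pair transition (i, x) -> (j, y) of sample-1 state i -> j
    and sample-2 state x -> y::

        (1 - sigma) * T[i,j] * T[x,y] + sigma * T[i,j]   if j == y and i == x
        T[i,j] * T[x,y]                                  if j == y and i != x
        (1 - sigma) * T[i,j] * T[x,y]                    otherwise

    then each row is normalized to sum to 1.  At ``sigma=0`` this is
    the Kronecker product of independent chains; at ``sigma=1`` all
    transitions into discordant state pairs vanish.  Pair state (s1,
    s2) maps to index ``4*s1 + s2``.
    """
    if not 0.0 <= sigma <= 1.0:
        raise ValueError("sigma must be in [0, 1]")
    t = transitions.matrix
    S = transitions.n_states
    m = np.empty((S * S, S * S))
    for i in range(S):
        for x in range(S):
            for j in range(S):
                for y in range(S):
                    v = t[i, j] * t[x, y]
                    if j == y and i == x:
                        v = (1.0 - sigma) * v + sigma * t[i, j]
                    elif j != y:
                        v = (1.0 - sigma) * v
                    m[S * i + x, S * j + y] = v
    m /= m.sum(axis=1, keepdims=True)
    return TransitionModel(m, **kw)


def initial_priors(n_samples: int = 1, sigma: float = 0.0) -> np.ndarray:
    """Initial state distribution preferring CN2: P(2)=0.5, P(!=2)=0.5/3.

    For the paired chain the product prior is coupled by the
    shared-state parameter the same way the transitions are:
    ``(1-sigma) * P(s1)P(s2) + sigma * P(s1) [s1=s2]``, so ``sigma=1``
    forbids a discordant start just as it forbids discordant
    transitions.
    """
    init = np.full(N_STATES, 0.5 / 3)
    init[CN2] = 0.5
    if n_samples == 1:
        return init
    pair = (1.0 - sigma) * np.outer(init, init) + sigma * np.diag(init)
    return pair.ravel()


def _pair_pref() -> np.ndarray:
    """Pair-state tie-break: both-CN2 first, then fewer aberrant states."""
    keys = []
    for k in range(16):
        s1, s2 = divmod(k, 4)
        keys.append(((s1 != 2) + (s2 != 2), s1 != 2, s1, s2, k))
    return np.array([k[-1] for k in sorted(keys)])


_PREF16 = _pair_pref()


def _viterbi_path(log_emis: np.ndarray, log_trans: np.ndarray,
                  log_init: np.ndarray, pref: np.ndarray) -> np.ndarray:
    """Most probable path; ``pref`` orders states for deterministic ties."""
    n, S = log_emis.shape
    if n == 0:
        return np.empty(0, dtype=np.int64)
    idx = np.arange(S)
    ptr = np.zeros((n, S), dtype=np.int8)
    v = log_init + log_emis[0]
    for t in range(1, n):
        m = v[:, None] + log_trans[t - 1]
        mp = m[pref, :]
        am = np.argmax(mp, axis=0)  # first max wins -> preferred state
        ptr[t] = pref[am]
        v = mp[am, idx] + log_emis[t]
    path = np.empty(n, dtype=np.int64)
    path[-1] = pref[int(np.argmax(v[pref]))]
    for t in range(n - 1, 0, -1):
        path[t - 1] = ptr[t, path[t]]
    return path


def _forward_backward(emis: np.ndarray, trans: np.ndarray,
                      init: np.ndarray) -> tuple[np.ndarray, float]:
    """Scaled forward-backward.  Returns (posteriors, log-likelihood)."""
    n, S = emis.shape
    if n == 0:
        return np.empty((0, S)), 0.0
    alpha = np.empty((n, S))
    c = np.empty(n)
    a = init * emis[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, n):
        a = (alpha[t - 1] @ trans[t - 1]) * emis[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((n, S))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (trans[t] @ (beta[t + 1] * emis[t + 1])) / c[t + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post, float(np.log(c).sum())


def _prepare_single(track: MarkerTrack, params: EmissionParams,
                    transitions: TransitionModel):
    clean = track.drop_missing()
    emis = _emission_matrix(clean, params)
    gaps = np.diff(clean.positions)
    log_trans = transitions.matrices_for_gaps(gaps, log=True)
    return clean, emis, log_trans


def viterbi(tracks, params: EmissionParams | None = None,
            transitions: TransitionModel | None = None,
            sigma: float = 0.5) -> np.ndarray:
    """Most likely copy-number state path for one track (or a pair).

    For a single track, markers with missing calls are dropped first
    and the returned path aligns with ``track.drop_missing()``.  For a
    pair ``(track1, track2)`` the 16-state path over the site
    intersection is returned (pair index ``4*s1 + s2``).
    """
    params = params or EmissionParams()
    if isinstance(tracks, MarkerTrack):
        transitions = transitions or build_transitions()
        clean, emis, log_trans = _prepare_single(tracks, params, transitions)
        return _viterbi_path(np.log(emis), log_trans, np.log(initial_priors()), _PREF4)
    t1, t2 = tracks
    emis, log_trans, _, _ = _prepare_pair(t1, t2, params, transitions, sigma)
    with np.errstate(divide="ignore"):
        log_init = np.log(initial_priors(2, sigma))
    return _viterbi_path(np.log(emis), log_trans, log_init, _PREF16)


def forward_backward(tracks, params: EmissionParams | None = None,
                     transitions: TransitionModel | None = None,
                     sigma: float = 0.5) -> np.ndarray:
    """Per-site posterior state probabilities (rows sum to 1)."""
    params = params or EmissionParams()
    if isinstance(tracks, MarkerTrack):
        transitions = transitions or build_transitions()
        clean, emis, log_trans = _prepare_single(tracks, params, transitions)
        post, _ = _forward_backward(emis, np.exp(log_trans), initial_priors())
        return post
    t1, t2 = tracks
    emis, log_trans, _, _ = _prepare_pair(t1, t2, params, transitions, sigma)
    post, _ = _forward_backward(emis, np.exp(log_trans), initial_priors(2, sigma))
    return post


Z95 = 1.6448536269514722  # one-sided 95% normal quantile


def optimize_beta0(track: MarkerTrack, params: EmissionParams,
                   transitions: TransitionModel | None = None,
                   tol: float = 1e-4, max_iter: int = 20,
                   min_mass: float = 2.0) -> float:
    """Re-estimate the heterozygous CN3 BAF peak from the data.

    Iterates ``beta0' = sum_i (0.5 - |0.5 - beta_i|) P_i(s=3) /
    sum_i P_i(s=3)`` over heterozygous sites until convergence.  The
    update is rejected and iteration stops once ``0.5 - beta0'`` falls
    under ``z95 * sigma``, i.e. when the peak would sit so close to
    0.5 that less than 95% of normally distributed BAF values stay
    below 0.5 -- without that separation the shifted heterozygous
    peaks are not distinguishable from the diploid peak.  ``sigma`` is
    the CN3-weighted spread of the folded BAF values measured from the
    data (floored at the model scale ``d/sqrt(2)``), so the criterion
    adapts to the noise actually present.  When the total CN3
    posterior mass over heterozygous sites is below ``min_mass``
    effective sites there is no gain signal to estimate from and the
    current value is kept.
    """
    transitions = transitions or build_transitions()
    clean = track.drop_missing()
    het = clean.genotypes == RA
    if not het.any():
        return params.beta0_het
    b0 = params.beta0_het
    floor_sd = params.d / sqrt(2.0)
    gaps = np.diff(clean.positions)
    trans = transitions.matrices_for_gaps(gaps)
    init = initial_priors()
    shifted = 0.5 - np.abs(0.5 - clean.baf[het])
    for _ in range(max_iter):
        emis = _emission_matrix(clean, replace(params, beta0_het=b0))
        post, _ = _forward_backward(emis, trans, init)
        w = post[het, 3]
        ws = w.sum()
        if ws < min_mass:
            # fewer than ~min_mass effective CN3 sites: no gain signal
            # to estimate from, keep the current peak position
            return b0
        b0_new = float(np.sum(shifted * w) / ws)
        sigma = float(np.sqrt(np.sum(w * (shifted - b0_new) ** 2) / ws))
        if 0.5 - b0_new < Z95 * max(sigma, floor_sd):
            return b0  # separation guard: keep the last safe estimate
        if abs(b0_new - b0) < tol:
            return b0_new
        b0 = b0_new
    return b0


def _segments_from_path(clean: MarkerTrack, path: np.ndarray,
                        post: np.ndarray | None) -> list[CNVSegment]:
    if len(path) == 0:
        return []
    bounds = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [len(path)]))
    segs = []
    for lo, hi in zip(starts, ends):
        q = float(post[lo:hi, path[lo]].mean()) if post is not None else float("nan")
        segs.append(CNVSegment(clean.chrom, int(clean.positions[lo]),
                               int(clean.positions[hi - 1]), int(path[lo]),
                               q, int(hi - lo)))
    return segs


def call_cnv(track: MarkerTrack, params: EmissionParams | None = None,
             transitions: TransitionModel | None = None,
             optimize: bool = False, compute_quality: bool = True,
             return_posteriors: bool = False):
    """Single-sample CNV calling on one chromosome.

    Decodes the most likely copy-number path and merges same-state runs
    into segments; segment quality is the mean forward-backward
    posterior of the assigned state.  With ``optimize`` the CN3
    heterozygous peak position is first re-estimated from the data
    (supporting gains carried by a fraction of cells).
    """
    params = params or EmissionParams()
    transitions = transitions or build_transitions()
    clean = track.drop_missing()
    if len(clean) == 0:
        return ([], np.empty((0, N_STATES))) if return_posteriors else []
    if optimize:
        params = replace(params, beta0_het=optimize_beta0(clean, params, transitions))
    emis = _emission_matrix(clean, params)
    gaps = np.diff(clean.positions)
    log_trans = transitions.matrices_for_gaps(gaps, log=True)
    path = _viterbi_path(np.log(emis), log_trans, np.log(initial_priors()), _PREF4)
    post = None
    if compute_quality or return_posteriors:
        post, _ = _forward_backward(emis, np.exp(log_trans), initial_priors())
    segs = _segments_from_path(clean, path, post)
    return (segs, post) if return_posteriors else segs


@dataclass
class PairedCallResult:
    """Output of paired calling: per-sample segments and differences."""

    control_segments: list[CNVSegment]
    query_segments: list[CNVSegment]
    difference_segments: list[CNVSegment]
    positions: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    posteriors: np.ndarray | None = None


def _intersect_tracks(t1: MarkerTrack, t2: MarkerTrack):
    if t1.chrom != t2.chrom:
        raise ValueError("paired tracks must be on the same chromosome")
    common, i1, i2 = np.intersect1d(t1.positions, t2.positions, return_indices=True)
    return t1.subset(i1), t2.subset(i2)


def _prepare_pair(control: MarkerTrack, query: MarkerTrack,
                  params: EmissionParams,
                  transitions: TransitionModel | None, sigma: float,
                  query_params: EmissionParams | None = None):
    c, q = _intersect_tracks(control, query)
    base = transitions or build_transitions()
    pair_model = base if base.n_states == 16 else base.pair(sigma)
    e1 = _emission_matrix(c, params, paired_na=True)
    e2 = _emission_matrix(q, query_params or params, paired_na=True)
    emis = (e1[:, :, None] * e2[:, None, :]).reshape(len(c), 16)
    gaps = np.diff(c.positions)
    log_trans = pair_model.matrices_for_gaps(gaps, log=True)
    return emis, log_trans, c, q


def call_cnv_pair(control: MarkerTrack, query: MarkerTrack, sigma: float = 0.5,
                  params: EmissionParams | None = None,
                  transitions: TransitionModel | None = None,
                  optimize: bool = False,
                  compute_quality: bool = True) -> PairedCallResult:
    """Paired (control vs query) CNV calling on one chromosome.

    Decodes the 16-state product HMM over the intersection of marker
    positions; sites with a missing call in one sample use the
    missing-call emission for that sample.  Difference segments are
    maximal runs where the two decoded states disagree, the signature
    of variation novel to one of the samples.
    """
    params = params or EmissionParams()
    qparams = params
    if optimize:
        qclean = query.drop_missing()
        if len(qclean):
            base = transitions if (transitions and transitions.n_states == 4) \
                else build_transitions()
            qparams = replace(params, beta0_het=optimize_beta0(qclean, params, base))
    emis, log_trans, c, q = _prepare_pair(control, query, params, transitions,
                                          sigma, query_params=qparams)
    if len(c) == 0:
        return PairedCallResult([], [], [])
    init = initial_priors(2, sigma)
    with np.errstate(divide="ignore"):
        log_init = np.log(init)
    path = _viterbi_path(np.log(emis), log_trans, log_init, _PREF16)
    post = None
    if compute_quality:
        post, _ = _forward_backward(emis, np.exp(log_trans), init)
    s_ctrl, s_query = path // 4, path % 4

    def _marginal(post16, states, which):
        if post16 is None:
            return None
        m = post16.reshape(-1, 4, 4)
        return m.sum(axis=2) if which == 0 else m.sum(axis=1)

    ctrl_segs = _segments_from_path(c, s_ctrl, _marginal(post, s_ctrl, 0))
    query_segs = _segments_from_path(q, s_query, _marginal(post, s_query, 1))
    diff = []
    differs = s_ctrl != s_query
    if differs.any():
        # runs of constant (pair state, differing)
        change = np.flatnonzero(np.diff(path) != 0) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(path)]))
        for lo, hi in zip(starts, ends):
            if s_ctrl[lo] == s_query[lo]:
                continue
            qual = float(post[lo:hi, path[lo]].mean()) if post is not None else float("nan")
            diff.append(CNVSegment(c.chrom, int(c.positions[lo]),
                                   int(c.positions[hi - 1]), int(s_query[lo]),
                                   qual, int(hi - lo), control_state=int(s_ctrl[lo])))
    return PairedCallResult(ctrl_segs, query_segs, diff, c.positions, post)
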