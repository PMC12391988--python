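"""Single-particle track mobility statistics.

The headline statistic is the **maximum distance to the start point** of
each track — a robust discriminator between freely diffusing and
network-immobilized particles that needs no model fit.  The module also
computes per-track path length and the time-averaged mean squared
displacement (MSD; for free 2-D Brownian motion MSD(Δt) = 4·D·Δt), and
summarises a track population as a max-distance histogram with an optional
two-component Gaussian mixture on log-distances to separate mobile from
immobilized subpopulations.

The mixture is fitted by expectation–maximization with a deterministic,
seeded k-means++-style initialisation; the log-likelihood trace is
recorded (it is nondecreasing by construction of EM).  Distances are
modelled on the log scale because they are positive and right-skewed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "Track",
    "TrackStats",
    "MixtureFit",
    "PopulationSummary",
    "track_stats",
    "population_summary",
]


@dataclass
class Track:
    """Time-ordered 2-D positions of one tracked particle (μm)."""

    track_id: str
    frames: np.ndarray
    times_s: np.ndarray
    positions_um: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=int)
        t = np.asarray(self.times_s, dtype=float)
        xy = np.asarray(self.positions_um, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2 or not (f.shape[0] == t.shape[0] == xy.shape[0]):
            raise ValidationError("track arrays must align as (n,), (n,), (n, 2)")
        if t.size < 2:
            raise ValidationError("a track needs at least 2 points")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("track times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(xy))):
            raise ValidationError("non-finite track coordinates")
        self.frames = f
        self.times_s = t
        self.positions_um = xy


@dataclass
class TrackStats:
    """Per-track summary: extreme excursion, contour length, MSD curve."""

    track_id: str
    max_distance_to_start_um: float
    path_length_um: float
    msd_lags_s: np.ndarray
    msd_um2: np.ndarray


@dataclass
class MixtureFit:
    """Two-component (or single) Gaussian mixture on log max-distances.

    ``separated`` requires both that the component means differ by at least
    one pooled (within-component) standard deviation and that BIC prefers
    the two-component model over a single Gaussian — the latter guards
    against the well-known tendency of a 2-component EM fit to split a
    single homogeneous cloud into two overlapping pieces.
    """

    weights: np.ndarray
    means_log: np.ndarray
    sds_log: np.ndarray
    means_um: np.ndarray           # geometric means, back-transformed
    log_likelihood: float
    log_likelihood_trace: np.ndarray
    separated: bool
    n_iter: int
    bic_favors_split: bool = True
    responsibilities: np.ndarray = field(repr=False, default=None)


@dataclass
class PopulationSummary:
    """Histogram of max distances plus optional mixture decomposition."""

    n_tracks: int
    max_distances_um: np.ndarray
    bin_edges_um: np.ndarray
    counts: np.ndarray
    mixture: MixtureFit | None = None
    n_dropped_nonpositive: int = 0


def track_stats(track: Track) -> TrackStats:
    """Max distance to start, path length, and time-averaged MSD.

    The MSD uses all overlapping same-lag pairs (standard time average);
    lag times are reported as multiples of the median frame interval.
    """
    xy = track.positions_um
    disp = xy - xy[0]
    dist = np.hypot(disp[:, 0], disp[:, 1])
    steps = np.diff(xy, axis=0)
    path = float(np.sum(np.hypot(steps[:, 0], steps[:, 1])))

    n = xy.shape[0]
    dt = float(np.median(np.diff(track.times_s)))
    lags = np.arange(1, n)
    msd = np.empty(lags.size)
    for i, k in enumerate(lags):
        d = xy[k:] - xy[:-k]
        msd[i] = float(np.mean(d[:, 0] ** 2 + d[:, 1] ** 2))
    return TrackStats(
        track_id=track.track_id,
        max_distance_to_start_um=float(np.max(dist)),
        path_length_um=path,
        msd_lags_s=lags * dt,
        msd_um2=msd,
    )


# ---------------------------------------------------------------------------
# Mixture decomposition
# ---------------------------------------------------------------------------

_SIGMA2_FLOOR = 1e-12


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding on 1-D data with a seeded generator."""
    centers = [x[int(rng.integers(x.size))]]
    for _ in range(1, k):
        d2 = np.min([(x - c) ** 2 for c in centers], axis=0)
        total = d2.sum()
        if total <= 0:  # all points identical to a center
            centers.append(x[int(rng.integers(x.size))])
            continue
        centers.append(float(rng.choice(x, p=d2 / total)))
    return np.array(centers)


def _fit_gaussian_mixture_1d(
    x: np.ndarray,
    n_components: int,
    seed: int,
    max_iter: int = 500,
    tol: float = 1e-10,
) -> MixtureFit:
    rng = np.random.default_rng(seed)
    n = x.size
    if n_components == 1:
        mu = np.array([np.mean(x)])
        s2 = np.array([max(np.var(x), _SIGMA2_FLOOR)])
        ll = float(np.sum(_log_normal_pdf(x, mu[0], s2[0])))
        return MixtureFit(weights=np.array([1.0]), means_log=mu,
                          sds_log=np.sqrt(s2), means_um=np.exp(mu),
                          log_likelihood=ll, log_likelihood_trace=np.array([ll]),
                          separated=False, n_iter=0,
                          responsibilities=np.ones((n, 1)))

    mu = np.sort(_kmeanspp_init(x, n_components, rng))
    s2 = np.full(n_components, max(np.var(x), _SIGMA2_FLOOR))
    w = np.full(n_components, 1.0 / n_components)

    trace = []
    resp = None
    for it in range(max_iter):
        # E step
        log_pdf = np.stack([np.log(w[j]) + _log_normal_pdf(x, mu[j], s2[j])
                            for j in range(n_components)], axis=1)
        m = log_pdf.max(axis=1, keepdims=True)
        log_norm = m[:, 0] + np.log(np.exp(log_pdf - m).sum(axis=1))
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_pdf - log_norm[:, None])
        if it > 0 and abs(trace[-1] - trace[-2]) < tol * (1 + abs(trace[-2])):
            break
        # M step
        nk = resp.sum(axis=0)
        w = nk / n
        mu = (resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        s2 = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / np.maximum(nk, 1e-300)
        s2 = np.maximum(s2, _SIGMA2_FLOOR)

    order = np.argsort(mu)
    mu, s2, w = mu[order], s2[order], w[order]
    resp = resp[:, order]
    pooled_sd = float(np.sqrt(np.sum(w * s2)))

    # BIC comparison against the single-Gaussian fit (2 vs 5 free params)
    s2_one = max(float(np.var(x)), _SIGMA2_FLOOR)
    ll_one = float(np.sum(_log_normal_pdf(x, float(np.mean(x)), s2_one)))
    bic_two = -2.0 * trace[-1] + 5.0 * math.log(n)
    bic_one = -2.0 * ll_one + 2.0 * math.log(n)
    bic_favors_split = bool(bic_two < bic_one)

    separated = bool(abs(mu[-1] - mu[0]) >= pooled_sd) and bic_favors_split
    return MixtureFit(weights=w, means_log=mu, sds_log=np.sqrt(s2),
                      means_um=np.exp(mu), log_likelihood=trace[-1],
                      log_likelihood_trace=np.array(trace),
                      separated=separated, n_iter=len(trace),
                      bic_favors_split=bic_favors_split,
                      responsibilities=resp)


def _log_normal_pdf(x: np.ndarray, mu: float, s2: float) -> np.ndarray:
    return -0.5 * (np.log(2 * np.pi * s2) + (x - mu) ** 2 / s2)


def population_summary(
    stats: list[TrackStats],
    bin_width_um: float | None = None,
    n_components: int = 2,
    seed: int = 0,
) -> PopulationSummary:
    """Histogram of per-track max distances, with optional mixture split.

    ``bin_width_um`` defaults to a Freedman–Diaconis-style width.  With
    ``n_components == 2`` a Gaussian mixture on log-distances is fitted by
    EM (needs ≥ 10 tracks); components are reported in increasing order of
    mean, and ``separated`` is False when the component means differ by
    less than one pooled standard deviation.  Tracks with zero max distance
    cannot enter the log-scale mixture and are counted in
    ``n_dropped_nonpositive``.
    """
    if n_components not in (1, 2):
        raise ValidationError("n_components must be 1 or 2")
    if not stats:
        raise ValidationError("empty track list")
    d = np.array([s.max_distance_to_start_um for s in stats], dtype=float)

    if bin_width_um is None:
        q75, q25 = np.percentile(d, [75, 25])
        iqr = q75 - q25
        bin_width_um = 2 * iqr / max(d.size, 1) ** (1 / 3) if iqr > 0 else None
    if bin_width_um and bin_width_um > 0:
        upper = max(d.max(), bin_width_um)
        edges = np.arange(0.0, upper + bin_width_um, bin_width_um)
        if edges[-1] < upper:
            edges = np.append(edges, edges[-1] + bin_width_um)
    else:
        edges = np.linspace(0.0, max(d.max(), 1e-6), 11)
    counts, edges = np.histogram(d, bins=edges)

    mixture = None
    pos = d[d > 0]
    dropped = int(d.size - pos.size)
    if d.size >= 10 and pos.size >= max(10, 2 * n_components):
        mixture = _fit_gaussian_mixture_1d(np.log(pos), n_components, seed=seed)
    return PopulationSummary(n_tracks=d.size, max_distances_um=d,
                             bin_edges_um=edges, counts=counts,
                             mixture=mixture, n_dropped_nonpositive=dropped)
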