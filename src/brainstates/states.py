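"""Characterization of inferred brain states.

Temporal statistics (fractional occupancy, life times, interval times) are
computed on the hard Viterbi path; spectral characterization (state-wise
multitaper spectra, NNMF spectral modes, band-limited power topographies)
uses the soft state probabilities, weighting windowed spectral estimates by
the mean state probability within each window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.signal.windows import dpss

from .prep import ConcatenatedData
from .tdehmm import HMMModel, StateProbabilities, ViterbiPath

__all__ = [
    "StateStats",
    "StateSpectra",
    "SpectralModes",
    "Topography",
    "temporal_stats",
    "transition_summary",
    "state_spectra",
    "nnmf_modes",
    "power_map",
    "match_topographies",
]


@dataclass
class StateStats:
    """Temporal statistics of the state sequence.

    fractional_occupancy : (subjects, K), rows sum to 1.
    life_times[k] : durations (ms) of complete visits to state k; visits
        truncated by a subject boundary are excluded.
    interval_times[k] : gaps (ms) between consecutive complete visits within
        a subject; undefined (excluded) when a subject has fewer than two
        visits to the state.
    """

    fractional_occupancy: np.ndarray
    life_times: list[np.ndarray]
    interval_times: list[np.ndarray]
    fs: float

    @property
    def K(self) -> int:
        return self.fractional_occupancy.shape[1]

    def mean_life_times(self) -> np.ndarray:
        return np.array(
            [lt.mean() if lt.size else np.nan for lt in self.life_times]
        )

    def mean_interval_times(self) -> np.ndarray:
        return np.array(
            [it.mean() if it.size else np.nan for it in self.interval_times]
        )


@dataclass
class StateSpectra:
    """Per-state, per-parcel spectral estimates on a band-limited grid."""

    freqs: np.ndarray  # (F,) Hz, strictly increasing
    psd: np.ndarray  # (K, N, F), nonnegative
    coherence: np.ndarray | None = None  # (K, N, N, F) if computed

    @property
    def K(self) -> int:
        return self.psd.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.psd.shape[1]


@dataclass
class SpectralModes:
    """Nonnegative spectral factorization: psd ~ loadings . modes."""

    modes: np.ndarray  # (M, F) spectral profiles
    loadings: np.ndarray  # (K, N, M)
    error_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class Topography:
    """Per-parcel map of a state's band-limited power."""

    values: np.ndarray  # (N,)
    state: int
    band: tuple[float, float]
    subject: str = "group"


# ---------------------------------------------------------------------------
# temporal statistics


def _runs(labels: np.ndarray):
    """Run-length encode: yields (value, start, stop) half-open."""
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [labels.size]))
    for a, b in zip(starts, stops):
        yield int(labels[a]), int(a), int(b)


def temporal_stats(
    vp: ViterbiPath,
    boundaries: list[tuple[int, int]] | None = None,
    fs: float | None = None,
) -> StateStats:
    """Fractional occupancy, life times and interval times per state.

    Fractional occupancy is each state's label frequency per subject.  A
    visit is a maximal constant run of the path; runs touching a subject
    boundary are censored and excluded from life times, and only gaps between
    consecutive complete visits enter interval times.
    """
    if boundaries is None:
        boundaries = vp.boundaries or [(0, vp.labels.size)]
    if fs is None:
        fs = 250.0
    K = vp.K
    ms = 1000.0 / fs
    n_sub = len(boundaries)
    fo = np.zeros((n_sub, K))
    life: list[list[float]] = [[] for _ in range(K)]
    inter: list[list[float]] = [[] for _ in range(K)]
    for s, (a, b) in enumerate(boundaries):
        if b <= a:
            raise ValueError(f"empty segment for subject {s}")
        seg = vp.labels[a:b]
        counts = np.bincount(seg, minlength=K)
        fo[s] = counts / seg.size
        runs = list(_runs(seg))
        last_complete_stop = [None] * K
        for i, (k, ra, rb) in enumerate(runs):
            interior = i > 0 and i < len(runs) - 1
            if not interior:
                continue
            life[k].append((rb - ra) * ms)
            if last_complete_stop[k] is not None:
                inter[k].append((ra - last_complete_stop[k]) * ms)
            last_complete_stop[k] = rb
    return StateStats(
        fractional_occupancy=fo,
        life_times=[np.asarray(v) for v in life],
        interval_times=[np.asarray(v) for v in inter],
        fs=fs,
    )


def transition_summary(model: HMMModel):
    """Transition matrix, raw and with self-transitions removed.

    Returns ``(raw, renormalized, flagged_rows)``: the renormalized form
    divides each row's off-diagonal entries by their sum; rows whose
    off-diagonal mass is (numerically) zero are undefined, returned as NaN
    and listed in ``flagged_rows``.
    """
    raw = model.transition_matrix
    K = raw.shape[0]
    off = raw * (1.0 - np.eye(K))
    sums = off.sum(axis=1)
    flagged = np.flatnonzero(sums <= 1e-12)
    renorm = np.full_like(raw, np.nan)
    ok = sums > 1e-12
    renorm[ok] = off[ok] / sums[ok, None]
    np.fill_diagonal(renorm, 0.0)
    renorm[flagged] = np.nan
    return raw, renorm, flagged.tolist()


# ---------------------------------------------------------------------------
# spectral characterization


def _window_starts(a: int, b: int, win: int, step: int):
    return range(a, b - win + 1, step)


def state_spectra(
    x: ConcatenatedData,
    gamma: StateProbabilities,
    band: tuple[float, float] = (1.0, 30.0),
    window_s: float = 2.0,
    overlap: float = 0.5,
    time_bandwidth: float = 4.0,
    n_tapers: int = 7,
    compute_coherence: bool = False,
) -> StateSpectra:
    """State-wise multitaper (cross-)spectra.

    The concatenated data are cut into windows (default 2 s, 50% overlap)
    that never straddle subject boundaries.  Each window's multitaper
    spectrum ``S_w`` is averaged across states with weights equal to the mean
    state probability in the window:

        S_k(f) = sum_w gbar_{w,k} S_w(f) / sum_w gbar_{w,k}

    so a state's spectrum is estimated from the moments when it was likely
    active.  Estimates are restricted to ``band`` (default 1-30 Hz).
    """
    fs = x.fs
    win = int(round(window_s * fs))
    step = max(int(round(win * (1.0 - overlap))), 1)
    K = gamma.K
    N = x.n_parcels

    # map each original sample to its gamma row (or -1 where trimmed)
    T = x.data.shape[0]
    g_of_sample = np.full(T, -1, dtype=np.int64)
    if gamma.sample_indices is not None:
        g_of_sample[gamma.sample_indices] = np.arange(len(gamma))
    else:
        if len(gamma) != T:
            raise ValueError("gamma length does not match data and no alignment given")
        g_of_sample[:] = np.arange(T)

    tapers = dpss(win, time_bandwidth, n_tapers)  # (n_tapers, win)
    freqs_all = np.fft.rfftfreq(win, d=1.0 / fs)
    fsel = (freqs_all >= band[0]) & (freqs_all <= band[1])
    if not fsel.any():
        raise ValueError("band contains no frequency bins at this window length")
    freqs = freqs_all[fsel]
    F = freqs.size
    scale = 2.0 / fs  # one-sided psd with unit-energy tapers

    num = np.zeros((K, N, F))
    den = np.zeros(K)
    num_x = np.zeros((K, N, N, F), dtype=complex) if compute_coherence else None

    for a, b in x.boundaries:
        if b - a < win:
            raise ValueError("window longer than the shortest subject segment")
        for w0 in _window_starts(a, b, win, step):
            rows = g_of_sample[w0 : w0 + win]
            valid = rows >= 0
            if not valid.any():
                continue
            gbar = gamma.gamma[rows[valid]].mean(axis=0)  # (K,)
            seg = x.data[w0 : w0 + win]  # (win, N)
            seg = seg - seg.mean(axis=0)
            # (n_tapers, win, N) -> rfft over time
            tap = tapers[:, :, None] * seg[None, :, :]
            spec = np.fft.rfft(tap, axis=1)[:, fsel, :]  # (n_tapers, F, N)
            Sw = scale * np.mean(np.abs(spec) ** 2, axis=0)  # (F, N)
            num += gbar[:, None, None] * Sw.T[None]
            den += gbar
            if compute_coherence:
                cross = (scale / n_tapers) * np.einsum(
                    "afm,afn->mnf", spec, np.conj(spec)
                )
                num_x += gbar[:, None, None, None] * cross[None]

    if np.all(den <= 0):
        raise ValueError("no window received any probability mass")
    # a state with zero total mass has no spectrum: NaN, not an error
    psd = np.full_like(num, np.nan)
    ok = den > 0
    psd[ok] = num[ok] / den[ok, None, None]

    coh = None
    if compute_coherence:
        Sx = num_x / den[:, None, None, None]
        auto = np.sqrt(
            np.abs(np.einsum("knnf->knf", Sx))
        )
        coh = np.abs(Sx) / (auto[:, :, None, :] * auto[:, None, :, :] + 1e-300)
    return StateSpectra(freqs=freqs, psd=psd, coherence=coh)


def nnmf_modes(
    sp: StateSpectra,
    M: int = 3,
    seed: int = 0,
    restarts: int = 5,
    n_iter: int = 500,
) -> SpectralModes:
    """Nonnegative matrix factorization of the stacked state spectra.

    The ``(K*N, F)`` stack of all state/parcel spectra is factorized as
    ``W @ H`` with multiplicative (Frobenius) updates, whose reconstruction
    error is non-increasing.  The best of ``restarts`` seeded runs is kept.
    Modes are returned in descending peak-frequency order, so data-driven
    frequency bands (e.g. alpha-like before theta-like) come out ordered.
    """
    K, N, F = sp.psd.shape
    X = sp.psd.reshape(K * N, F)
    if M < 1 or M > min(X.shape):
        raise ValueError(f"mode count must be in 1..{min(X.shape)}")
    eps = 1e-12
    best = None
    for r in range(restarts):
        rng = np.random.default_rng(seed + r)
        W = rng.uniform(0.1, 1.0, size=(K * N, M)) * np.sqrt(X.mean() / M)
        H = rng.uniform(0.1, 1.0, size=(M, F)) * np.sqrt(X.mean() / M)
        errs = []
        for _ in range(n_iter):
            H *= (W.T @ X) / (W.T @ W @ H + eps)
            W *= (X @ H.T) / (W @ H @ H.T + eps)
            errs.append(np.linalg.norm(X - W @ H))
            if len(errs) > 1 and abs(errs[-2] - errs[-1]) < 1e-10 * max(errs[-1], 1.0):
                break
        if best is None or errs[-1] < best[0]:
            best = (errs[-1], W, H, np.asarray(errs))
    _, W, H, errs = best
    # fix scale indeterminacy: unit-max modes
    peak = H.max(axis=1)
    H = H / peak[:, None]
    W = W * peak[None, :]
    order = np.argsort(sp.freqs[np.argmax(H, axis=1)])[::-1]
    return SpectralModes(
        modes=H[order],
        loadings=W[:, order].reshape(K, N, M),
        error_trace=errs,
    )


def power_map(
    sp: StateSpectra,
    band: tuple[float, float] = (1.0, 30.0),
    subject: str = "group",
) -> list[Topography]:
    """Band-limited power per parcel and state: trapezoidal integral of the
    psd over ``band``."""
    sel = (sp.freqs >= band[0]) & (sp.freqs <= band[1])
    if sel.sum() < 2:
        raise ValueError(f"band {band} covers fewer than two frequency bins")
    f = sp.freqs[sel]
    return [
        Topography(
            values=np.trapezoid(sp.psd[k][:, sel], f, axis=1),
            state=k,
            band=(float(band[0]), float(band[1])),
            subject=subject,
        )
        for k in range(sp.K)
    ]


def match_topographies(A, B):
    """Match two sets of K state topographies by spatial correlation.

    Computes the full (non-symmetric) Pearson correlation matrix ``R`` with
    ``R[i, j] = corr(A_i, B_j)`` and the assignment of B-states to A-states
    maximizing total matched correlation (Hungarian algorithm).

    Returns ``(perm, R)`` where ``B[perm[i]]`` is the partner of ``A[i]``.
    """
    A = np.vstack([t.values if isinstance(t, Topography) else t for t in A])
    B = np.vstack([t.values if isinstance(t, Topography) else t for t in B])
    if A.shape != B.shape:
        raise ValueError(f"topography sets differ in shape: {A.shape} vs {B.shape}")
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    An = Ac / np.linalg.norm(Ac, axis=1, keepdims=True)
    Bn = Bc / np.linalg.norm(Bc, axis=1, keepdims=True)
    R = An @ Bn.T
    rows, cols = linear_sum_assignment(-R)
    perm = np.empty_like(cols)
    perm[rows] = cols
    return perm, R
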