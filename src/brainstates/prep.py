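"""Preparation of parcel time series for brain-state modelling.

Source-reconstructed electrophysiological data arrive as one time series per
cortical parcel.  Before a covariance-based hidden Markov model can be trained
on them they are band-limited and resampled, standardized per subject,
leakage-corrected by multivariate symmetric orthogonalization, and
concatenated across subjects into one long matrix with recorded subject
boundaries.

All operations here are deterministic; no randomness enters this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal


@dataclass
class ParcelTimeSeries:
    """A single subject's parcel-wise recording.

    Attributes
    ----------
    data
        Real matrix of shape ``(T, N)``: ``T`` time samples by ``N`` parcels.
    fs
        Sampling rate in Hz.
    subject_id
        Subject label.
    parcel_ids
        Length-``N`` parcel labels.  Auto-generated when omitted.
    """

    data: np.ndarray
    fs: float
    subject_id: str = "s00"
    parcel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (time x parcels) matrix")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_parcels < 1:
            raise ValueError("need at least one parcel")
        if not self.parcel_ids:
            self.parcel_ids = [f"p{i:03d}" for i in range(self.n_parcels)]
        if len(self.parcel_ids) != self.n_parcels:
            raise ValueError("parcel_ids length does not match data columns")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]


@dataclass
class ConcatenatedData:
    """Subject recordings stacked in time.

    ``boundaries`` holds ``(start, stop)`` row indices (half-open) for each
    subject; they partition the rows of ``data`` exactly.
    """

    data: np.ndarray
    boundaries: list[tuple[int, int]]
    fs: float
    subject_ids: list[str] = field(default_factory=list)
    parcel_ids: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.boundaries)

    @property
    def n_parcels(self) -> int:
        return self.data.shape[1]

    def segments(self):
        """Yield each subject's block as a view."""
        for start, stop in self.boundaries:
            yield self.data[start:stop]

    def split(self) -> list[np.ndarray]:
        return [self.data[a:b] for a, b in self.boundaries]


def bandpass_and_downsample(
    x: ParcelTimeSeries,
    band: tuple[float, float] = (1.0, 45.0),
    fs_out: float = 250.0,
    order: int = 5,
) -> ParcelTimeSeries:
    """Zero-phase band-pass filter, then polyphase resample to ``fs_out``.

    The filter is a forward-backward (zero-phase) Butterworth band-pass of the
    given order, applied before polyphase resampling with its own anti-alias
    filtering.  Pass-band gain is ~1; stop bands are strongly attenuated.

    Parameters
    ----------
    x
        Input recording.
    band
        ``(low, high)`` pass-band edges in Hz.  Must satisfy
        ``0 < low < high < fs_out / 2``.
    fs_out
        Output sampling rate in Hz.
    """
    low, high = float(band[0]), float(band[1])
    if not (0.0 < low < high):
        raise ValueError(f"invalid band {band}: need 0 < low < high")
    if high >= fs_out / 2:
        raise ValueError(
            f"band upper edge {high} Hz exceeds output Nyquist {fs_out / 2} Hz"
        )
    if high >= x.fs / 2:
        raise ValueError(f"band upper edge {high} Hz exceeds input Nyquist")

    # IIR designs at normalized edges below ~1e-3 or above ~0.99 Nyquist are
    # numerically meaningless; such a stage is a no-op and is skipped.
    nyq = x.fs / 2.0
    hp_needed = low / nyq >= 1e-3
    lp_needed = high / nyq <= 0.99
    if hp_needed and lp_needed:
        sos = signal.butter(order, [low, high], btype="bandpass", fs=x.fs, output="sos")
    elif hp_needed:
        sos = signal.butter(order, low, btype="highpass", fs=x.fs, output="sos")
    elif lp_needed:
        sos = signal.butter(order, high, btype="lowpass", fs=x.fs, output="sos")
    else:
        sos = None
    filtered = x.data if sos is None else signal.sosfiltfilt(sos, x.data, axis=0)

    if fs_out != x.fs:
        from fractions import Fraction

        frac = Fraction(fs_out / x.fs).limit_denominator(1000)
        filtered = signal.resample_poly(filtered, frac.numerator, frac.denominator, axis=0)

    return replace(x, data=np.ascontiguousarray(filtered), fs=float(fs_out))


def standardize(x: ParcelTimeSeries, ddof: int = 0) -> ParcelTimeSeries:
    """Z-score each parcel: column mean 0, standard deviation 1.

    Raises a ``ValueError`` naming the parcel if a column is (numerically)
    constant, since a zero-variance channel carries no state information and
    would blow up downstream covariance models.
    """
    mu = x.data.mean(axis=0)
    sd = x.data.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sd <= 1e-300)
    if bad.size:
        names = ", ".join(x.parcel_ids[i] for i in bad)
        raise ValueError(f"zero-variance parcel(s): {names}")
    return replace(x, data=(x.data - mu) / sd)


def symmetric_orthogonalize(
    x: ParcelTimeSeries,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> ParcelTimeSeries:
    """Multivariate symmetric (non-preferential) leakage correction.

    Finds the matrix closest in Frobenius norm to the input whose columns are
    mutually orthogonal, treating all parcels symmetrically while allowing a
    positive per-column scaling.  The algorithm alternates (a) the closest
    matrix with orthonormal columns via the polar decomposition of the
    column-scaled data and (b) the least-squares column scalings, until the
    relative Frobenius change of the reconstruction falls below ``tol``.

    Zero-lag correlations between output columns vanish to numerical
    precision, removing instantaneous signal leakage between parcels.
    """
    X = x.data
    T, N = X.shape
    if T <= N:
        raise ValueError("need more samples than parcels (T > N)")
    # work on mean-centred data so "orthogonal" matches zero correlation
    mu = X.mean(axis=0)
    Xc = X - mu

    rank = np.linalg.matrix_rank(Xc)
    if rank < N:
        raise ValueError(
            f"rank-deficient input (rank {rank} < {N} parcels); "
            "reduce dimensionality before orthogonalizing"
        )

    d = np.linalg.norm(Xc, axis=0)
    prev = None
    for _ in range(max_iter):
        U, _, Vt = np.linalg.svd(Xc * d, full_matrices=False)
        O = U @ Vt  # closest orthonormal-column matrix to Xc @ diag(d)
        d = np.einsum("tn,tn->n", Xc, O)  # least-squares column lengths
        Y = O * d
        err = np.linalg.norm(Xc - Y)
        if prev is not None and abs(prev - err) <= tol * max(err, 1.0):
            break
        prev = err
    return replace(x, data=Y + mu)


def concatenate(xs: list[ParcelTimeSeries]) -> ConcatenatedData:
    """Stack subject recordings in time, recording exact boundaries."""
    if not xs:
        raise ValueError("no subjects to concatenate")
    n = xs[0].n_parcels
    fs = xs[0].fs
    bad = [
        x.subject_id
        for x in xs
        if x.n_parcels != n or x.fs != fs or x.parcel_ids != xs[0].parcel_ids
    ]
    if bad:
        raise ValueError(f"inconsistent parcel count/order or fs for subjects: {bad}")
    boundaries = []
    start = 0
    for x in xs:
        boundaries.append((start, start + x.n_samples))
        start += x.n_samples
    data = np.vstack([x.data for x in xs])
    return ConcatenatedData(
        data=data,
        boundaries=boundaries,
        fs=fs,
        subject_ids=[x.subject_id for x in xs],
        parcel_ids=list(xs[0].parcel_ids),
    )


def prepare(
    xs: list[ParcelTimeSeries],
    band: tuple[float, float] = (1.0, 45.0),
    fs_out: float = 250.0,
    orthogonalize: bool = True,
) -> ConcatenatedData:
    """Full preparation pipeline: filter/resample, standardize per subject,
    optionally orthogonalize, and concatenate."""
    out = []
    for x in xs:
        y = bandpass_and_downsample(x, band=band, fs_out=fs_out)
        y = standardize(y)
        if orthogonalize:
            y = symmetric_orthogonalize(y)
            y = standardize(y)  # restore unit variance after rescaling
        out.append(y)
    return concatenate(out)
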