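"""Linking intracranial electrodes to inferred brain states.

Each depth electrode is reduced to its middle bipolar channel, whose
time-frequency power is correlated — frequency bin by frequency bin — with
each state's probability time course, yielding a per-electrode, per-state
"correlation spectrum" r(f) with pointwise p-values.  Electrodes are then
assigned to states in two independent ways: functionally (the state with the
highest significant peak correlation) and spatially (the state whose most
activated topography cluster lies closest to the electrode midpoint), and the
agreement between the two assignments is tested with a chi-square test of
independence on the cross-tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContactGeometry",
    "VoxelGrid",
    "TFRMatrix",
    "CorrelationSpectrum",
    "AssignmentTable",
    "AgreementResult",
    "middle_bipolar",
    "tfr_power",
    "correlation_spectrum",
    "fdr_mask",
    "functional_assign",
    "spatial_assign",
    "agreement_test",
    "broadcast_to_grid",
]


@dataclass
class ContactGeometry:
    """One depth electrode: ordered contact coordinates along the shaft."""

    electrode: str
    subject: str
    coords: np.ndarray  # (n_contacts, 3) x,y,z in mm, ordered along the shaft

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_contacts, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite contact coordinates")

    @property
    def n_contacts(self) -> int:
        return self.coords.shape[0]


@dataclass
class VoxelGrid:
    """Voxel grid in template space with per-voxel parcel membership.

    ``coords`` are voxel centers in mm on a regular lattice (default 8 mm
    spacing); ``parcel`` maps each voxel to a parcel index (-1 = outside any
    parcel).
    """

    coords: np.ndarray  # (V, 3) mm
    parcel: np.ndarray  # (V,) int
    spacing: float = 8.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.parcel = np.asarray(self.parcel, dtype=int)
        if self.coords.shape[0] != self.parcel.shape[0]:
            raise ValueError("coords and parcel membership differ in length")


@dataclass
class TFRMatrix:
    """Time-frequency power of one channel, aligned to the state time course."""

    power: np.ndarray  # (T', F) nonnegative
    freqs: np.ndarray  # (F,) Hz
    fs: float


@dataclass
class CorrelationSpectrum:
    """Frequency-resolved Pearson correlation of one state with one channel.

    ``valid`` marks bins where the correlation is defined; undefined bins
    (zero variance on either side) hold NaN and are excluded from the peak.
    ``peak`` is ``(r_max, f_at_max, p_at_max)`` or None if nothing is valid.
    """

    r: np.ndarray
    p: np.ndarray
    freqs: np.ndarray
    state: int
    electrode: str
    valid: np.ndarray = field(default=None)
    peak: tuple[float, float, float] | None = None


@dataclass
class ElectrodeAssignment:
    electrode: str
    subject: str
    functional_state: int | None
    spatial_state: int | None
    peak_r: float | None = None
    peak_f: float | None = None
    peak_p: float | None = None
    distances: np.ndarray | None = None  # per-state mean distance, mm
    tied_functional: bool = False
    tied_spatial: bool = False


@dataclass
class AssignmentTable:
    rows: list[ElectrodeAssignment]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class AgreementResult:
    crosstab: np.ndarray  # (K, K) counts, functional x spatial
    agreement_count: int
    total: int
    fraction: float
    chi2: float
    dof: int
    p_value: float
    n_unassigned: int = 0


# ---------------------------------------------------------------------------
# signal-level operations


_MIDDLE_PAIRS = {8: (4, 5), 16: (8, 9)}  # 1-based contact numbers


def middle_bipolar(rec: np.ndarray, geom: ContactGeometry):
    """Middle bipolar derivation of a depth electrode.

    Subtracts the two middle contacts (4-5 for 8-contact shafts, 8-9 for 16),
    suppressing far-field common signals, and returns the channel together
    with the midpoint of the two contacts' coordinates.
    """
    rec = np.asarray(rec, dtype=float)
    if rec.ndim != 2:
        raise ValueError("recording must be (T, n_contacts)")
    n = geom.n_contacts
    if rec.shape[1] != n:
        raise ValueError(
            f"recording has {rec.shape[1]} columns but geometry lists {n} contacts"
        )
    if n not in _MIDDLE_PAIRS:
        raise ValueError(f"unsupported electrode layout with {n} contacts (need 8 or 16)")
    a, b = _MIDDLE_PAIRS[n]
    channel = rec[:, a - 1] - rec[:, b - 1]
    midpoint = 0.5 * (geom.coords[a - 1] + geom.coords[b - 1])
    return channel, midpoint


def _morlet_kernel(f: float, fs: float, n_cycles: float) -> np.ndarray:
    """Complex Morlet wavelet, L2-normalized, at center frequency f."""
    sigma_t = n_cycles / (2.0 * np.pi * f)
    half = int(np.ceil(4.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    kern = np.exp(2j * np.pi * f * t) * np.exp(-(t**2) / (2.0 * sigma_t**2))
    return kern / np.sqrt(np.sum(np.abs(kern) ** 2))

def tfr_power(
    ch: np.ndarray,
    freqs: np.ndarray | None = None,
    fs: float = 250.0,
    fs_out: float | None = None,
    n_cycles: float = 5.0,
    sample_indices: np.ndarray | None = None,
) -> TFRMatrix:
    """Morlet-wavelet time-frequency power of a single channel.

    Convolves with complex Morlet wavelets (default 5 cycles) on a 1-45 Hz
    grid in 0.5 Hz steps and squares the magnitude.  If ``fs_out`` differs
    from ``fs`` the channel is polyphase-resampled first so the power time
    course shares the state time course's resolution.  ``sample_indices``
    (the embedding alignment) selects the rows matching gamma.
    """
    ch = np.asarray(ch, dtype=float)
    if freqs is None:
        freqs = np.arange(1.0, 45.0 + 1e-9, 0.5)
    freqs = np.asarray(freqs, dtype=float)
    if fs_out is not None and fs_out != fs:
        from fractions import Fraction

        frac = Fraction(fs_out / fs).limit_denominator(1000)
        ch = signal.resample_poly(ch, frac.numerator, frac.denominator)
        fs = fs_out
    if freqs.max() >= fs / 2:
        raise ValueError(
            f"frequency grid reaches {freqs.max()} Hz, at or above Nyquist {fs / 2} Hz"
        )
    power = np.empty((ch.size, freqs.size))
    for i, f in enumerate(freqs):
        kern = _morlet_kernel(f, fs, n_cycles)
        conv = signal.fftconvolve(ch.astype(complex), kern, mode="same")
        power[:, i] = np.abs(conv) ** 2
    if sample_indices is not None:
        power = power[sample_indices]
    return TFRMatrix(power=power, freqs=freqs, fs=fs)


def correlation_spectrum(
    gamma_k: np.ndarray,
    tfr: TFRMatrix,
    state: int = 0,
    electrode: str = "",
) -> CorrelationSpectrum:
    """Pearson correlation of one state's probability with band power per bin.

    For each frequency bin, computes Pearson r between the state probability
    time course and the power time course, with a two-sided p-value from the
    t distribution on T-2 degrees of freedom.  Bins with zero variance on
    either side are flagged invalid (NaN) and excluded from the peak.
    """
    g = np.asarray(gamma_k, dtype=float)
    X = tfr.power
    if g.ndim != 1 or X.shape[0] != g.size:
        raise ValueError("state probabilities and power differ in length")
    T = g.size
    if T < 3:
        raise ValueError("need at least 3 samples for a correlation p-value")
    gc = g - g.mean()
    gss = float(gc @ gc)
    Xc = X - X.mean(axis=0)
    xss = np.einsum("tf,tf->f", Xc, Xc)
    valid = (gss > 0) & (xss > 0)
    r = np.full(X.shape[1], np.nan)
    p = np.full(X.shape[1], np.nan)
    if gss > 0:
        ok = xss > 0
        r[ok] = (gc @ Xc[:, ok]) / np.sqrt(gss * xss[ok])
        r[ok] = np.clip(r[ok], -1.0, 1.0)
        with np.errstate(divide="ignore"):
            tstat = r[ok] * np.sqrt((T - 2) / np.maximum(1.0 - r[ok] ** 2, 1e-300))
        p[ok] = 2.0 * stats.t.sf(np.abs(tstat), T - 2)
        valid = np.zeros(X.shape[1], dtype=bool)
        valid[np.flatnonzero(ok)] = True
    else:
        valid = np.zeros(X.shape[1], dtype=bool)
    peak = None
    if valid.any():
        i = int(np.nanargmax(np.where(valid, r, -np.inf)))
        peak = (float(r[i]), float(tfr.freqs[i]), float(p[i]))
    return CorrelationSpectrum(
        r=r, p=p, freqs=tfr.freqs, state=state, electrode=electrode,
        valid=valid, peak=peak,
    )


def fdr_mask(p_values: np.ndarray, q: float = 0.05, r_values: np.ndarray | None = None):
    """Benjamini-Hochberg step-up over one pooled within-subject family.

    ``p_values`` is the flattened family of all (state, electrode, frequency)
    p-values of one subject.  Returns the boolean survival mask and, if
    ``r_values`` is given, the smallest surviving absolute correlation (the
    plotting threshold); NaN entries never survive.

    Uses the standard step-up rule: sort p, find the largest i with
    p_(i) <= i*q/m, reject all smaller.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value family")
    finite = np.isfinite(p)
    mask = np.zeros(p.size, dtype=bool)
    if finite.any():
        rej, _, _, _ = multipletests(p[finite], alpha=q, method="fdr_bh")[:4]
        mask[np.flatnonzero(finite)] = rej
    mask = mask.reshape(np.shape(p_values))
    if r_values is None:
        return mask
    r = np.asarray(r_values, dtype=float)
    surviving = np.abs(r[mask])
    r_min = float(surviving.min()) if surviving.size else np.nan
    return mask, r_min


# ---------------------------------------------------------------------------
# assignment


def functional_assign(spectra: list[CorrelationSpectrum], alpha: float = 0.05):
    """Assign an electrode to the state with the strongest significant peak.

    The candidate statistic per state is the peak correlation over frequency
    bins.  The electrode is assigned to the argmax state if that state's peak
    p-value is below ``alpha`` (uncorrected); otherwise to no state.  Exact
    ties in peak r break toward the lower state index and are flagged.

    Returns ``(state_or_None, peak_r, peak_f, peak_p, tied)``.
    """
    if not spectra:
        raise ValueError("no correlation spectra supplied")
    peaks = []
    for cs in sorted(spectra, key=lambda c: c.state):
        peaks.append((cs.state, cs.peak))
    valid = [(s, pk) for s, pk in peaks if pk is not None]
    if not valid:
        return None, None, None, None, False
    rs = np.array([pk[0] for _, pk in valid])
    best = int(np.argmax(rs))  # argmax returns first max -> lowest state index
    tied = bool(np.sum(rs == rs[best]) > 1)
    state, (r, f, p) = valid[best]
    if p < alpha:
        return state, r, f, p, tied
    return None, r, f, p, tied


def broadcast_to_grid(values: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Broadcast per-parcel topography values to grid voxels; voxels outside
    any parcel get NaN."""
    values = np.asarray(values, dtype=float)
    out = np.full(grid.parcel.size, np.nan)
    inside = grid.parcel >= 0
    out[inside] = values[grid.parcel[inside]]
    return out


def _largest_cluster(voxel_values: np.ndarray, grid: VoxelGrid, percentile: float):
    """Voxel coordinates of the biggest suprathreshold connected component
    (26-connectivity on the lattice); ties keep the component containing the
    global maximum."""
    vals = np.asarray(voxel_values, dtype=float)
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("empty topography: no cluster definable")
    thr = np.nanpercentile(vals, percentile)
    supra = finite & (vals >= thr)
    # embed voxels in a dense integer lattice for connected components
    ijk = np.round(grid.coords / grid.spacing).astype(int)
    ijk -= ijk.min(axis=0)
    shape = ijk.max(axis=0) + 1
    vol = np.zeros(shape, dtype=bool)
    vol[tuple(ijk[supra].T)] = True
    labels, n = ndimage.label(vol, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        raise ValueError("no suprathreshold voxels")
    sizes = ndimage.sum_labels(vol, labels, index=np.arange(1, n + 1))
    best_size = sizes.max()
    candidates = np.flatnonzero(sizes == best_size) + 1
    if candidates.size > 1:
        gmax = np.nanargmax(np.where(supra, vals, -np.inf))
        lab_of_max = labels[tuple(ijk[gmax])]
        lab = lab_of_max if lab_of_max in candidates else candidates[0]
    else:
        lab = candidates[0]
    member = labels[tuple(ijk.T)] == lab
    member &= supra
    return grid.coords[member]


def spatial_assign(
    midpoint: np.ndarray,
    voxel_topographies: np.ndarray,
    grid: VoxelGrid,
    percentile: float = 90.0,
    threshold_mode: str = "percentile",
):
    """Assign an electrode to the state whose activation cluster is nearest.

    Per state: threshold the voxel topography (default at its 90th
    percentile; ``threshold_mode='max'`` uses 90% of the maximum instead),
    keep the largest 26-connected component, and measure the mean Euclidean
    distance from the electrode midpoint to that component's voxel centers.
    The state with the smallest mean distance wins; ties break toward the
    lower index and are flagged.

    Returns ``(state, distances, tied)``.
    """
    midpoint = np.asarray(midpoint, dtype=float)
    K = voxel_topographies.shape[0]
    dists = np.empty(K)
    for k in range(K):
        vals = voxel_topographies[k]
        finite = np.isfinite(vals)
        if not finite.any() or np.nanmax(vals) == np.nanmin(vals):
            raise ValueError(
                f"state {k}: constant topography, no cluster definable"
            )
        if threshold_mode == "max":
            thr_vals = np.where(
                vals >= (percentile / 100.0) * np.nanmax(vals), vals, np.nan
            )
            # reuse percentile machinery with a 0th-percentile cut on masked values
            cluster = _largest_cluster(thr_vals, grid, 0.0)
        else:
            cluster = _largest_cluster(vals, grid, percentile)
        dists[k] = float(np.mean(np.linalg.norm(cluster - midpoint, axis=1)))
    best = int(np.argmin(dists))
    tied = bool(np.sum(dists == dists[best]) > 1)
    return best, dists, tied


def agreement_test(table: AssignmentTable, K: int | None = None) -> AgreementResult:
    """Chi-square test of independence between functional and spatial
    assignment over electrodes assigned by both criteria.

    Electrodes without a functional assignment are excluded from the
    cross-tabulation and counted in ``n_unassigned``.  The Pearson statistic
    is computed on the crosstab after dropping all-zero rows and columns;
    the agreement fraction is the diagonal mass of the full K x K table.
    """
    rows = [
        r for r in table
        if r.functional_state is not None and r.spatial_state is not None
    ]
    n_unassigned = len(table) - len(rows)
    if not rows:
        raise ValueError("no electrodes assigned by both criteria")
    if K is None:
        K = max(max(r.functional_state, r.spatial_state) for r in rows) + 1
    crosstab = np.zeros((K, K), dtype=int)
    for r in rows:
        crosstab[r.functional_state, r.spatial_state] += 1
    total = int(crosstab.sum())
    agree = int(np.trace(crosstab))

    nz = crosstab[crosstab.sum(axis=1) > 0][:, crosstab.sum(axis=0) > 0]
    if nz.shape[0] < 2 or nz.shape[1] < 2:
        raise ValueError(
            "degenerate margins (fewer than 2 categories per side); "
            "report descriptive agreement only"
        )
    chi2, p, dof, _ = stats.chi2_contingency(nz, correction=False)
    return AgreementResult(
        crosstab=crosstab,
        agreement_count=agree,
        total=total,
        fraction=agree / total,
        chi2=float(chi2),
        dof=int(dof),
        p_value=float(p),
        n_unassigned=n_unassigned,
    )
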