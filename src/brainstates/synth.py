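"""Synthetic data with known ground truth for the full pipeline.

Emulates the class of data the pipeline consumes: a K-state Markov chain
switching between brain states, parcel time series in which each state
expresses band-limited oscillations in its own set of parcels, intracranial
depth-electrode recordings whose band power is modulated by the occupancy of
a coupled state, contact coordinates placed near the coupled state's
activation cluster, and a voxel grid (8 mm spacing) carrying parcel
membership for topographies.

The default configuration is the desk-scale world used throughout the test
suite: K = 5 states at 250 Hz, 20 parcels, 3 subjects of 30,000 samples,
self-transition probability 0.95 (mean state lifetime 80 ms), unit-amplitude
oscillation bursts in white Gaussian noise, and one depth electrode per
state per subject with coupling gain 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .linkage import ContactGeometry, VoxelGrid
from .prep import ParcelTimeSeries

__all__ = [
    "OscSpec",
    "ElectrodeSpec",
    "GroundTruth",
    "StatePath",
    "IEEGRecording",
    "DEFAULT_CONFIG",
    "make_ground_truth",
    "simulate_state_path",
    "simulate_parcels",
    "simulate_ieeg",
    "simulate_dataset",
]


DEFAULT_CONFIG: dict = {
    "K": 5,
    "n_parcels": 20,
    "fs": 250.0,
    "n_subjects": 3,
    "n_samples": 30_000,
    "stickiness": 0.95,  # mean lifetime 20 samples = 80 ms at 250 Hz
    # center frequencies resolvable within the +/-28 ms lag window of the
    # default embedding; theta through beta
    "state_freqs": (7.0, 11.0, 15.0, 20.0, 26.0),
    # within a state, each parcel oscillates at its own nearby frequency:
    # coherent (phase-locked) parcels would be rotated into each other by
    # leakage correction in a subject-specific way
    "parcel_freq_offsets": (0.0, 1.25, -1.25),
    "parcels_per_state": 3,
    "amplitude": 2.0,  # burst variance 2.0 vs noise variance 0.25 in driven parcels
    "parcel_amp_taper": (1.0, 1.0, 1.0),  # uniform activation across a state's parcels
    "noise_sd": 0.5,
    "electrode_gain": 2.0,
    "electrode_noise_sd": 0.3,
    "band_halfwidth": 2.0,  # Hz around each state's center frequency
    "contact_spacing_mm": 3.5,  # 2 mm contact + 1.5 mm gap
    "grid_spacing_mm": 8.0,
    "envelope_taper_samples": 11,  # Hann taper, ~44 ms at 250 Hz; 0 = rectangular
    "parcel_blob_radius_voxels": 1,  # 3x3x3 voxel blob per parcel
}


@dataclass
class OscSpec:
    """One state-specific oscillation: which parcel, at which frequency."""

    parcel: int
    freq: float
    amplitude: float


@dataclass
class ElectrodeSpec:
    """One depth electrode's coupling to a state."""

    label: str
    subject: int
    state: int  # coupled state index
    band: tuple[float, float]  # coupled frequency band, Hz
    gain: float  # power modulation gain
    n_contacts: int  # 8 or 16
    parcel: int  # parcel whose activation cluster hosts the middle contacts


@dataclass
class StatePath:
    """Ground-truth hidden state sequence."""

    labels: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size < 1:
            raise ValueError("empty state path")


@dataclass
class IEEGRecording:
    """Stacked contact signals of one subject's electrodes.

    ``data`` is (T, total contacts); ``electrodes`` lists, per electrode, its
    spec, geometry and column slice into ``data``.
    """

    data: np.ndarray
    fs: float
    electrodes: list[tuple[ElectrodeSpec, ContactGeometry, slice]]

    def channel(self, i: int) -> np.ndarray:
        """The i-th electrode's contact block."""
        _, _, sl = self.electrodes[i]
        return self.data[:, sl]


@dataclass
class GroundTruth:
    """Fully specified generative world; every field is known exactly."""

    K: int
    fs: float
    n_parcels: int
    n_subjects: int
    n_samples: int
    transition_matrix: np.ndarray
    initial_probs: np.ndarray
    state_specs: list[list[OscSpec]]
    noise_sd: np.ndarray  # per-parcel
    electrode_specs: list[ElectrodeSpec]
    geometry: list[ContactGeometry]
    grid: VoxelGrid
    parcel_centers: np.ndarray  # (N, 3) mm
    electrode_noise_sd: float
    seed: int
    config: dict = field(default_factory=dict)

    def electrodes_of_subject(self, s: int):
        return [
            (spec, geom)
            for spec, geom in zip(self.electrode_specs, self.geometry)
            if spec.subject == s
        ]


def _validate_simplex(v: np.ndarray, name: str) -> None:
    if np.any(v < -1e-12):
        raise ValueError(f"{name} has negative entries")
    if abs(v.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} does not sum to 1 (got {v.sum()!r})")


def _parcel_layout(
    n_parcels: int, spacing: float, blob_radius: int, K: int, ppst: int
):
    """Parcel centers grouped by state, each with a cubic voxel blob.

    Brain states express spatially clustered networks, so the parcels a
    state drives sit together (40 mm apart) in a cluster whose origin is
    150 mm from other states' clusters; undriven parcels occupy further
    cluster slots.  Every parcel gets a (2r+1)^3 voxel blob at ``spacing``
    mm resolution.
    """
    centers = np.empty((n_parcels, 3))
    for p in range(n_parcels):
        cluster, member = divmod(p, ppst) if p < K * ppst else (
            K + (p - K * ppst) // ppst,
            (p - K * ppst) % ppst,
        )
        origin = np.array(
            [150.0 * (cluster % 3), 150.0 * (cluster // 3), 0.0]
        )
        centers[p] = origin + [40.0 * (member % 2), 40.0 * (member // 2), 0.0]
    offsets = np.arange(-blob_radius, blob_radius + 1) * spacing
    dx, dy, dz = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    blob = np.column_stack([dx.ravel(), dy.ravel(), dz.ravel()])
    coords = np.vstack([c + blob for c in centers])
    parcel = np.repeat(np.arange(n_parcels), blob.shape[0])
    return centers, VoxelGrid(coords=coords, parcel=parcel, spacing=spacing)


def make_ground_truth(config: dict | None = None, seed: int = 0) -> GroundTruth:
    """Build a fully populated generative world.

    ``config`` overrides entries of :data:`DEFAULT_CONFIG`; unknown keys are
    rejected.  Deterministic given ``(config, seed)``.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(cfg) - {"transition_matrix", "initial_probs"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    K = int(cfg["K"])
    N = int(cfg["n_parcels"])
    if K < 1:
        raise ValueError("K must be >= 1")
    if N < 1:
        raise ValueError("n_parcels must be >= 1")
    rng = np.random.default_rng(seed)

    if "transition_matrix" in cfg:
        A = np.asarray(cfg["transition_matrix"], dtype=float)
    elif K == 1:
        A = np.array([[1.0]])
    else:
        stick = float(cfg["stickiness"])
        if not 0.0 <= stick <= 1.0:
            raise ValueError("stickiness must be in [0, 1]")
        A = np.full((K, K), (1.0 - stick) / (K - 1))
        np.fill_diagonal(A, stick)
    for i, row in enumerate(A):
        _validate_simplex(row, f"transition_matrix row {i}")

    if "initial_probs" in cfg:
        pi = np.asarray(cfg["initial_probs"], dtype=float)
    else:
        pi = np.full(K, 1.0 / K)
    _validate_simplex(pi, "initial_probs")

    freqs = list(cfg["state_freqs"])
    while len(freqs) < K:  # extend deterministically if K exceeds the list
        freqs.append(freqs[-1] + 5.0)
    amp = float(cfg["amplitude"])
    if amp < 0:
        raise ValueError("amplitude must be >= 0")
    ppst = int(cfg["parcels_per_state"])
    taper = list(cfg["parcel_amp_taper"])
    while len(taper) < ppst:
        taper.append(taper[-1] * 0.8)
    offsets = list(cfg["parcel_freq_offsets"])
    while len(offsets) < ppst:
        offsets.append(offsets[-1] + 0.5)
    state_specs: list[list[OscSpec]] = []
    for k in range(K):
        state_specs.append(
            [
                OscSpec(
                    parcel=(k * ppst + j) % N,
                    freq=freqs[k] + offsets[j],
                    amplitude=amp * taper[j],
                )
                for j in range(ppst)
            ]
        )

    noise_sd = float(cfg["noise_sd"])
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    noise = np.full(N, noise_sd)

    centers, grid = _parcel_layout(
        N, float(cfg["grid_spacing_mm"]), int(cfg["parcel_blob_radius_voxels"]),
        K, ppst,
    )

    gain = float(cfg["electrode_gain"])
    if gain < 0:
        raise ValueError("electrode_gain must be >= 0")
    hw = float(cfg["band_halfwidth"])
    spacing = float(cfg["contact_spacing_mm"])
    specs: list[ElectrodeSpec] = []
    geoms: list[ContactGeometry] = []
    n_subjects = int(cfg["n_subjects"])
    for s in range(n_subjects):
        for k in range(K):
            n_contacts = 8 if (s + k) % 2 == 0 else 16
            if n_contacts not in (8, 16):
                raise ValueError("contact count must be 8 or 16")
            target = state_specs[k][0].parcel
            spec = ElectrodeSpec(
                label=f"s{s:02d}e{k:02d}",
                subject=s,
                state=k,
                band=(max(freqs[k] - hw, 0.5), freqs[k] + hw),
                gain=gain,
                n_contacts=n_contacts,
                parcel=target,
            )
            # shaft along z through the parcel center; the midpoint of the
            # middle bipolar pair lands exactly on the center, well inside
            # the 3x3x3-voxel activation blob
            mid = (n_contacts - 1) / 2.0  # 3.5 for 8 contacts, 7.5 for 16
            z = (np.arange(n_contacts) - mid) * spacing
            coords = np.column_stack(
                [
                    np.full(n_contacts, centers[target, 0]),
                    np.full(n_contacts, centers[target, 1]),
                    centers[target, 2] + z,
                ]
            )
            specs.append(spec)
            geoms.append(
                ContactGeometry(electrode=spec.label, subject=f"s{s:02d}", coords=coords)
            )
            if spec.state >= K:
                raise ValueError("coupled state out of range")

    return GroundTruth(
        K=K,
        fs=float(cfg["fs"]),
        n_parcels=N,
        n_subjects=n_subjects,
        n_samples=int(cfg["n_samples"]),
        transition_matrix=A,
        initial_probs=pi,
        state_specs=state_specs,
        noise_sd=noise,
        electrode_specs=specs,
        geometry=geoms,
        grid=grid,
        parcel_centers=centers,
        electrode_noise_sd=float(cfg["electrode_noise_sd"]),
        seed=int(seed),
        config=cfg,
    )


def simulate_state_path(gt: GroundTruth, T: int, seed: int = 0) -> StatePath:
    """Sample a length-T state sequence from the ground-truth Markov chain."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(gt.transition_matrix, axis=1)
    u = rng.random(T)
    labels = np.empty(T, dtype=np.int64)
    labels[0] = int(np.searchsorted(np.cumsum(gt.initial_probs), u[0], side="right"))
    for t in range(1, T):
        labels[t] = int(np.searchsorted(cum[labels[t - 1]], u[t], side="right"))
    labels = np.minimum(labels, gt.K - 1)  # guard against u == 1.0 edge
    return StatePath(labels=labels, fs=gt.fs)


def _state_envelope(labels: np.ndarray, k: int, taper: int) -> np.ndarray:
    """Occupancy indicator of state k, smoothed by a short Hann taper.

    Real oscillatory bursts wax and wane over tens of milliseconds rather
    than switching instantaneously; a rectangular gate would also inject an
    artificial "transition regime" that a lag-embedded model latches onto.
    """
    ind = (labels == k).astype(float)
    if taper and taper > 1:
        from scipy.signal import fftconvolve
        from scipy.signal.windows import hann

        kern = hann(taper)
        kern /= kern.sum()
        ind = np.clip(fftconvolve(ind, kern, mode="same"), 0.0, 1.0)
    return ind


def simulate_parcels(
    gt: GroundTruth, path: StatePath, seed: int = 0, subject_id: str = "s00"
) -> ParcelTimeSeries:
    """Parcel time series: state-gated oscillatory bursts plus white noise.

    Each parcel's signal is the sum, over the oscillation descriptors of
    whichever state is active, of ``amplitude * env_k(t) * sin(2 pi f t +
    phi)`` where ``env_k`` is the state's smoothed occupancy indicator —
    phase is a function of absolute time, hence continuous across a state's
    visits — plus independent white Gaussian noise of the parcel's noise
    scale.
    """
    if path.fs != gt.fs:
        raise ValueError("state path sampling rate does not match the world's")
    rng = np.random.default_rng(seed)
    T = path.labels.size
    t = np.arange(T) / gt.fs
    taper = int(gt.config.get("envelope_taper_samples", 0))
    x = rng.standard_normal((T, gt.n_parcels)) * gt.noise_sd
    for k, specs in enumerate(gt.state_specs):
        env = _state_envelope(path.labels, k, taper)
        for spec in specs:
            phi = rng.uniform(0.0, 2.0 * np.pi)
            if not env.any():
                continue
            x[:, spec.parcel] += spec.amplitude * env * np.sin(
                2.0 * np.pi * spec.freq * t + phi
            )
    return ParcelTimeSeries(data=x, fs=gt.fs, subject_id=subject_id)


def simulate_ieeg(
    gt: GroundTruth, path: StatePath, seed: int = 0, subject: int = 0
) -> IEEGRecording:
    """Depth-electrode recordings for one subject.

    Each electrode carries a narrow-band oscillation at its coupled band's
    center whose instantaneous amplitude is ``1 + gain * env(t)`` with
    ``env`` the coupled state's smoothed occupancy indicator,
    spread across contacts with a Gaussian profile peaked at the first middle
    contact (so the middle bipolar derivation retains it), plus independent
    contact noise.  Contact coordinates come from the ground truth, with the
    middle pair inside the coupled state's activation cluster.
    """
    pairs = gt.electrodes_of_subject(subject)
    if not pairs:
        raise ValueError(f"no electrodes defined for subject {subject}")
    rng = np.random.default_rng(seed)
    T = path.labels.size
    t = np.arange(T) / gt.fs
    blocks = []
    electrodes = []
    col = 0
    taper = int(gt.config.get("envelope_taper_samples", 0))
    for spec, geom in pairs:
        f0 = 0.5 * (spec.band[0] + spec.band[1])
        phi = rng.uniform(0.0, 2.0 * np.pi)
        envelope = 1.0 + spec.gain * _state_envelope(path.labels, spec.state, taper)
        osc = envelope * np.sin(2.0 * np.pi * f0 * t + phi)
        peak = spec.n_contacts // 2 - 1  # 0-based first middle contact
        w = np.exp(-0.5 * (np.arange(spec.n_contacts) - peak) ** 2)
        block = osc[:, None] * w[None, :]
        block += rng.standard_normal(block.shape) * gt.electrode_noise_sd
        blocks.append(block)
        electrodes.append((spec, geom, slice(col, col + spec.n_contacts)))
        col += spec.n_contacts
    return IEEGRecording(data=np.hstack(blocks), fs=gt.fs, electrodes=electrodes)


@dataclass
class SyntheticSubject:
    path: StatePath
    parcels: ParcelTimeSeries
    ieeg: IEEGRecording


def simulate_dataset(gt: GroundTruth, seed: int = 0) -> list[SyntheticSubject]:
    """All subjects' paths, parcel series and iEEG, deterministically seeded."""
    subjects = []
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(gt.n_subjects)
    for s, child in enumerate(children):
        s_path, s_parc, s_ieeg = (
            int(x) % (2**31) for x in child.generate_state(3)
        )
        path = simulate_state_path(gt, gt.n_samples, seed=s_path)
        parcels = simulate_parcels(gt, path, seed=s_parc, subject_id=f"s{s:02d}")
        ieeg = simulate_ieeg(gt, path, seed=s_ieeg, subject=s)
        subjects.append(SyntheticSubject(path=path, parcels=parcels, ieeg=ieeg))
    return subjects
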