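"""End-to-end convenience drivers tying the modules together.

These functions run the full analysis on in-memory objects: prepare parcel
data, fit the embedded HMM, characterize states, and link intracranial
electrodes to states.  They exist so that scripts and tests exercise one
code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import linkage as lk
from . import prep, states, tdehmm
from .synth import GroundTruth, SyntheticSubject

__all__ = ["HMMRun", "fit_pipeline", "link_electrodes", "align_states"]


@dataclass
class HMMRun:
    """Everything produced by one training run on prepared data."""

    data: prep.ConcatenatedData
    reduced: np.ndarray
    basis: tdehmm.PCABasis
    cfg: tdehmm.EmbeddingConfig
    boundaries: list[tuple[int, int]]
    sample_indices: np.ndarray
    result: tdehmm.FitResult
    viterbi: tdehmm.ViterbiPath


def fit_pipeline(
    subjects: list[prep.ParcelTimeSeries],
    K: int = 5,
    band: tuple[float, float] = (1.0, 45.0),
    fs_out: float = 250.0,
    orthogonalize: bool = True,
    lags: np.ndarray | None = None,
    pca_dim: int | None = None,
    seed: int = 0,
    **fit_opts,
) -> HMMRun:
    """Prepare, embed, reduce and fit in one call."""
    data = prep.prepare(subjects, band=band, fs_out=fs_out, orthogonalize=orthogonalize)
    cfg = tdehmm.EmbeddingConfig(
        lags=lags if lags is not None else np.arange(-7, 8), fs=fs_out
    )
    y, basis, sidx, bounds = tdehmm.embed_and_reduce(data, cfg, P=pca_dim)
    res = tdehmm.fit(
        y, K=K, boundaries=bounds, seed=seed, fs=fs_out,
        sample_indices=sidx, **fit_opts,
    )
    vp = tdehmm.viterbi(res.model, y, bounds, sample_indices=sidx)
    return HMMRun(
        data=data, reduced=y, basis=basis, cfg=cfg, boundaries=bounds,
        sample_indices=sidx, result=res, viterbi=vp,
    )


def align_states(labels: np.ndarray, truth: np.ndarray, K: int):
    """Optimal label permutation between a decoded and a reference sequence.

    Returns ``(accuracy, perm)`` where ``perm[j]`` is the model state
    matched to reference state ``j`` by the Hungarian assignment on the
    joint-frequency matrix.
    """
    C = np.zeros((K, K))
    for k in range(K):
        mk = labels == k
        for j in range(K):
            C[k, j] = np.mean(mk & (truth == j))
    rows, cols = linear_sum_assignment(-C)
    perm = np.empty(K, dtype=int)
    for k, j in zip(rows, cols):
        perm[j] = k
    return float(C[rows, cols].sum()), perm


def link_electrodes(
    run: HMMRun,
    subjects: list[SyntheticSubject],
    grid: lk.VoxelGrid,
    band: tuple[float, float] = (1.0, 30.0),
    tfr_freqs: np.ndarray | None = None,
    alpha: float = 0.05,
    percentile: float = 90.0,
) -> tuple[lk.AssignmentTable, dict]:
    """Correlate each electrode with every state and assign it both ways.

    For every subject: per-subject state spectra give the subject-specific
    band-power topographies used for spatial assignment; each electrode's
    middle bipolar channel is wavelet-decomposed, correlated with each
    state's probability time course (within the subject's aligned rows), and
    functionally assigned to its best significant state.

    Returns the assignment table plus a dict of per-electrode correlation
    spectra keyed by electrode label.
    """
    gamma = run.result.gamma
    rows: list[lk.ElectrodeAssignment] = []
    spectra_out: dict[str, list[lk.CorrelationSpectrum]] = {}
    K = gamma.K

    for s, subj in enumerate(subjects):
        a, b = run.boundaries[s]
        orig_a, orig_b = run.data.boundaries[s]
        sub_gamma = tdehmm.StateProbabilities(
            gamma=gamma.gamma[a:b], fs=gamma.fs,
            sample_indices=gamma.sample_indices[a:b] - orig_a,
        )
        sub_cat = prep.ConcatenatedData(
            data=run.data.data[orig_a:orig_b],
            boundaries=[(0, orig_b - orig_a)],
            fs=run.data.fs,
        )
        sp = states.state_spectra(sub_cat, sub_gamma, band=band)
        topos = states.power_map(sp, band=band, subject=f"s{s:02d}")
        vox = np.vstack([lk.broadcast_to_grid(t.values, grid) for t in topos])

        for spec, geom, sl in subj.ieeg.electrodes:
            ch, midpoint = lk.middle_bipolar(subj.ieeg.data[:, sl], geom)
            tfr = lk.tfr_power(
                ch, freqs=tfr_freqs, fs=subj.ieeg.fs,
                sample_indices=sub_gamma.sample_indices,
            )
            cs = [
                lk.correlation_spectrum(
                    sub_gamma.gamma[:, k], tfr, state=k, electrode=spec.label
                )
                for k in range(K)
            ]
            spectra_out[spec.label] = cs
            f_state, r, f, p, f_tied = lk.functional_assign(cs, alpha=alpha)
            s_state, dists, s_tied = lk.spatial_assign(
                midpoint, vox, grid, percentile=percentile
            )
            rows.append(
                lk.ElectrodeAssignment(
                    electrode=spec.label, subject=f"s{s:02d}",
                    functional_state=f_state, spatial_state=s_state,
                    peak_r=r, peak_f=f, peak_p=p, distances=dists,
                    tied_functional=f_tied, tied_spatial=s_tied,
                )
            )
    return lk.AssignmentTable(rows=rows), spectra_out
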