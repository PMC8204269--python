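"""Time-delay embedded hidden Markov model (TDE-HMM).

A K-state HMM whose observation vector at time t is the window of the signal
across a set of time lags.  Each state's emission is a zero-mean
full-covariance Gaussian over a PCA reduction of the embedded space, so a
state is characterized by a multivariate autocovariance signature — spectral
as well as spatial structure — rather than instantaneous amplitude alone.

Inference is variational Bayes EM with conjugate priors: Dirichlet rows on
the transition matrix and initial distribution, and Wishart posteriors on the
state precisions (equivalently inverse-Wishart on covariances).  The E-step
runs forward-backward under expected log parameters; the M-step applies
closed-form conjugate updates.  The variational free energy (negative
evidence lower bound) is non-increasing across full-batch cycles and is used
to select among random restarts.  A trained observation model can be frozen
and applied to new data (`apply_model`) to obtain state probability time
courses on a different dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import digamma, gammaln, multigammaln

from ._kernels import forward_backward, viterbi_path
from .prep import ConcatenatedData

__all__ = [
    "EmbeddingConfig",
    "PCABasis",
    "HMMPriors",
    "HMMModel",
    "StateProbabilities",
    "ViterbiPath",
    "FreeEnergy",
    "FitResult",
    "embed",
    "pca_reduce",
    "embed_and_reduce",
    "fit",
    "free_energy",
    "viterbi",
    "apply_model",
]


# ---------------------------------------------------------------------------
# embedding and PCA


@dataclass
class EmbeddingConfig:
    """Time-delay embedding window.

    ``lags`` are sample offsets; the default +/-7 at 250 Hz spans 30 ms in
    each direction (15 lags total), so embedded covariance captures
    autocorrelation structure up to ~60 ms.
    """

    lags: np.ndarray = field(default_factory=lambda: np.arange(-7, 8))
    fs: float = 250.0

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        if self.lags.size < 1:
            raise ValueError("need at least one lag")
        if np.unique(self.lags).size != self.lags.size:
            raise ValueError("lags must be distinct")
        self.lags = np.sort(self.lags)

    @property
    def n_lags(self) -> int:
        return int(self.lags.size)

    @property
    def span(self) -> int:
        return int(self.lags.max() - self.lags.min())


@dataclass
class PCABasis:
    """Orthonormal principal directions of the embedded data.

    ``components`` has shape ``(L*N, P)``; projection of new data must reuse
    the stored ``mean``.  ``explained_variance`` are the top-P eigenvalues of
    the pooled empirical covariance, non-increasing.
    """

    components: np.ndarray
    mean: np.ndarray
    explained_variance: np.ndarray

    @property
    def p(self) -> int:
        return self.components.shape[1]

    def project(self, e: np.ndarray) -> np.ndarray:
        return (e - self.mean) @ self.components


def _embed_segment(x: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Embed one contiguous segment; rows needing out-of-range samples are
    dropped.  Column order is parcel-major: (n, l) -> n * L + rank(l)."""
    T, N = x.shape
    lo, hi = int(lags.min()), int(lags.max())
    span = hi - lo
    if T <= span:
        raise ValueError("segment shorter than the lag window")
    Tp = T - span
    L = lags.size
    out = np.empty((Tp, N * L))
    # row t of the output corresponds to original sample t - lo  (lag 0)
    for j, l in enumerate(lags):
        shift = l - lo  # in 0..span
        out[:, j::L] = x[shift : shift + Tp, :]
    return out


def embed(x: ConcatenatedData, cfg: EmbeddingConfig):
    """Time-delay embed concatenated data, per subject segment.

    Column ``(n, l)`` of the output at row t equals ``x[t + l, n]``.  Rows
    that would need samples outside a subject's segment are dropped — there
    is no wraparound across subject boundaries.

    Returns
    -------
    e : (T', L*N) embedded matrix
    sample_indices : (T',) index into the original concatenated rows of each
        embedded row's lag-0 sample
    boundaries : per-subject (start, stop) row ranges of ``e``
    """
    lo = int(cfg.lags.min())
    span = cfg.span
    blocks, idx, bounds = [], [], []
    pos = 0
    for s, (a, b) in enumerate(x.boundaries):
        if b - a <= span:
            sid = x.subject_ids[s] if x.subject_ids else str(s)
            raise ValueError(
                f"subject {sid!r} segment of {b - a} samples is too short for "
                f"a lag window spanning {span} samples"
            )
        e = _embed_segment(x.data[a:b], cfg.lags)
        blocks.append(e)
        idx.append(np.arange(a - lo, a - lo + e.shape[0]))
        bounds.append((pos, pos + e.shape[0]))
        pos += e.shape[0]
    return np.vstack(blocks), np.concatenate(idx), bounds


def pca_reduce(e: np.ndarray, P: int):
    """Project embedded data onto its top-P principal directions.

    The basis is computed on the pooled matrix (all subjects together) from
    the eigendecomposition of the empirical covariance; it is stored so the
    identical projection can be reused on new data.
    """
    T, D = e.shape
    if not 1 <= P <= D:
        raise ValueError(f"P must be in 1..{D}, got {P}")
    if T < P:
        raise ValueError("fewer rows than requested components")
    mean = e.mean(axis=0)
    ec = e - mean
    C = (ec.T @ ec) / (T - 1)
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1][:P]
    evals = evals[order]
    if evals[-1] <= max(1e-12 * max(evals[0], 1.0), 0.0) and P > 1:
        rank = int(np.sum(evals > 1e-12 * max(evals[0], 1.0)))
        if rank < P:
            raise ValueError(f"P={P} exceeds numerical rank {rank} of the data")
    basis = PCABasis(
        components=evecs[:, order],
        mean=mean,
        explained_variance=np.maximum(evals, 0.0),
    )
    return basis.project(e), basis


def embed_and_reduce(x: ConcatenatedData, cfg: EmbeddingConfig, P: int | None = None):
    """Convenience pipeline: embed, then PCA-reduce to ``P`` dimensions
    (default 4*N, the standard reduction from L*N = 15*N)."""
    if P is None:
        P = 4 * x.n_parcels
    e, sample_indices, boundaries = embed(x, cfg)
    y, basis = pca_reduce(e, P)
    return y, basis, sample_indices, boundaries


# ---------------------------------------------------------------------------
# model containers


@dataclass
class HMMPriors:
    """Conjugate prior hyperparameters.

    ``trans_alpha0``: Dirichlet pseudo-counts per transition row (symmetric
    count 1 plus a small diagonal stickiness).  ``init_alpha0``: Dirichlet
    counts for the initial distribution.  ``prec_scale_inv`` / ``prec_dof``:
    Wishart prior W(V0, n0) on each state precision, parameterized by
    V0^{-1} (= the prior inverse-Wishart scale on the covariance) and n0.
    """

    trans_alpha0: np.ndarray
    init_alpha0: np.ndarray
    prec_scale_inv: np.ndarray
    prec_dof: float

    @classmethod
    def default(cls, K: int, y: np.ndarray, stickiness: float = 5.0) -> "HMMPriors":
        P = y.shape[1]
        S0 = (y.T @ y) / y.shape[0]  # empirical second moment (zero-mean model)
        S0 = S0 + 1e-10 * np.trace(S0) / P * np.eye(P)
        n0 = P + 2.0
        # prior mean of the covariance equals S0:  E[Sigma] = V0inv/(n0-P-1)
        return cls(
            trans_alpha0=np.ones((K, K)) + stickiness * np.eye(K),
            init_alpha0=np.ones(K),
            prec_scale_inv=S0 * (n0 - P - 1.0),
            prec_dof=n0,
        )


@dataclass
class HMMModel:
    """Posterior of a fitted (or constructed) TDE-HMM.

    The observation model of state k is a zero-mean Gaussian whose precision
    has Wishart posterior W(V_k, n_k), stored via ``prec_scale_inv[k]`` =
    V_k^{-1} and ``prec_dof[k]`` = n_k.  Posterior-mean point estimates are
    exposed as properties.
    """

    K: int
    trans_alpha: np.ndarray  # (K, K) Dirichlet posterior counts per row
    init_alpha: np.ndarray  # (K,) Dirichlet posterior counts
    prec_scale_inv: np.ndarray  # (K, P, P) V_k^{-1}, symmetric positive definite
    prec_dof: np.ndarray  # (K,)
    priors: HMMPriors | None = None

    def __post_init__(self) -> None:
        self.trans_alpha = np.asarray(self.trans_alpha, dtype=float)
        self.init_alpha = np.asarray(self.init_alpha, dtype=float)
        self.prec_scale_inv = np.asarray(self.prec_scale_inv, dtype=float)
        self.prec_dof = np.atleast_1d(np.asarray(self.prec_dof, dtype=float))
        if self.prec_dof.size == 1:
            self.prec_dof = np.repeat(self.prec_dof, self.K)
        for k in range(self.K):
            ev = np.linalg.eigvalsh(self.prec_scale_inv[k])
            if ev.min() <= 0:
                raise ValueError(f"state {k} covariance scale is not positive definite")

    @property
    def P(self) -> int:
        return self.prec_scale_inv.shape[1]

    @property
    def transition_matrix(self) -> np.ndarray:
        return self.trans_alpha / self.trans_alpha.sum(axis=1, keepdims=True)

    @property
    def initial_probs(self) -> np.ndarray:
        return self.init_alpha / self.init_alpha.sum()

    @property
    def state_covariances(self) -> np.ndarray:
        """Posterior-mean covariance of each state (inverse-Wishart mean)."""
        denom = self.prec_dof - self.P - 1.0
        denom = np.maximum(denom, 1.0)
        return self.prec_scale_inv / denom[:, None, None]

    @classmethod
    def from_point_estimates(
        cls,
        covariances: np.ndarray,
        transition_matrix: np.ndarray,
        initial_probs: np.ndarray,
        concentration: float = 1e12,
    ) -> "HMMModel":
        """Build a model whose posteriors are sharply concentrated at given
        point parameters (useful for decoding with known parameters)."""
        covariances = np.asarray(covariances, dtype=float)
        K, P, _ = covariances.shape
        n = concentration
        return cls(
            K=K,
            trans_alpha=np.asarray(transition_matrix, dtype=float) * concentration,
            init_alpha=np.asarray(initial_probs, dtype=float) * concentration,
            prec_scale_inv=covariances * (n - P - 1.0),
            prec_dof=np.full(K, n),
            priors=None,
        )

    def permuted(self, perm: np.ndarray) -> "HMMModel":
        """Return the model with state indices relabelled by ``perm`` (state
        ``perm[k]`` of the original becomes state ``k``)."""
        perm = np.asarray(perm)
        return HMMModel(
            K=self.K,
            trans_alpha=self.trans_alpha[np.ix_(perm, perm)],
            init_alpha=self.init_alpha[perm],
            prec_scale_inv=self.prec_scale_inv[perm],
            prec_dof=self.prec_dof[perm],
            priors=self.priors,
        )


@dataclass
class StateProbabilities:
    """State probability time course gamma: rows sum to one.

    ``sample_indices`` maps each embedded row back to its lag-0 sample in the
    original concatenated data; ``boundaries`` are per-subject row ranges of
    ``gamma``.
    """

    gamma: np.ndarray
    fs: float
    sample_indices: np.ndarray | None = None
    boundaries: list[tuple[int, int]] | None = None

    @property
    def K(self) -> int:
        return self.gamma.shape[1]

    def __len__(self) -> int:
        return self.gamma.shape[0]


@dataclass
class ViterbiPath:
    """Hard state assignment: the single most probable state sequence."""

    labels: np.ndarray
    K: int
    sample_indices: np.ndarray | None = None
    boundaries: list[tuple[int, int]] | None = None

    @property
    def binary(self) -> np.ndarray:
        out = np.zeros((self.labels.size, self.K))
        out[np.arange(self.labels.size), self.labels] = 1.0
        return out


@dataclass
class FreeEnergy:
    """Variational free energy and its additive components.

    ``total = -expected_loglik - entropy + kl_transition + kl_initial +
    kl_emission``; lower is better.
    """

    total: float
    expected_loglik: float
    entropy: float
    kl_transition: float
    kl_initial: float
    kl_emission: float

    def components_sum(self) -> float:
        return (
            -self.expected_loglik
            - self.entropy
            + self.kl_transition
            + self.kl_initial
            + self.kl_emission
        )


@dataclass
class FitResult:
    model: HMMModel
    gamma: StateProbabilities
    free_energy_trace: np.ndarray
    n_restarts: int
    chosen_restart: int
    restart_free_energies: np.ndarray
    converged: bool


# ---------------------------------------------------------------------------
# variational expectations


def _dirichlet_elog(alpha: np.ndarray) -> np.ndarray:
    """E[log p] under Dirichlet(alpha), rows if 2-D."""
    if alpha.ndim == 1:
        return digamma(alpha) - digamma(alpha.sum())
    return digamma(alpha) - digamma(alpha.sum(axis=1, keepdims=True))


def _chol_logdet(L: np.ndarray) -> float:
    return 2.0 * float(np.sum(np.log(np.diag(L))))


def _expected_loglik_matrix(model: HMMModel, y: np.ndarray) -> np.ndarray:
    """E_q[log N(y_t | 0, Sigma_k)] for all t, k.

    With q(Lambda_k) = Wishart(V_k, n_k):
      E[log|Lambda|] = sum_i psi((n+1-i)/2) + P log 2 + log|V|
      E[y' Lambda y] = n * y' V y = n * ||L^{-1} y||^2  with V^{-1} = L L'.
    """
    T, P = y.shape
    out = np.empty((T, model.K))
    const = -0.5 * P * np.log(2.0 * np.pi)
    for k in range(model.K):
        n = model.prec_dof[k]
        Vinv = model.prec_scale_inv[k]
        L = np.linalg.cholesky(Vinv)
        logdet_V = -_chol_logdet(L)
        elogdet = (
            np.sum(digamma(0.5 * (n - np.arange(P))))
            + P * np.log(2.0)
            + logdet_V
        )
        z = solve_triangular(L, y.T, lower=True)
        quad = n * np.einsum("ij,ij->j", z, z)
        out[:, k] = const + 0.5 * elogdet - 0.5 * quad
    return out


def _point_loglik_matrix(model: HMMModel, y: np.ndarray) -> np.ndarray:
    """log N(y_t | 0, Sigma_k) at the posterior-mean covariances."""
    T, P = y.shape
    out = np.empty((T, model.K))
    const = -0.5 * P * np.log(2.0 * np.pi)
    covs = model.state_covariances
    for k in range(model.K):
        L = np.linalg.cholesky(covs[k])
        z = solve_triangular(L, y.T, lower=True)
        quad = np.einsum("ij,ij->j", z, z)
        out[:, k] = const - 0.5 * _chol_logdet(L) - 0.5 * quad
    return out


def _kl_dirichlet(alpha: np.ndarray, alpha0: np.ndarray) -> float:
    """KL(Dir(alpha) || Dir(alpha0)) summed over rows."""
    a = np.atleast_2d(alpha)
    a0 = np.atleast_2d(alpha0)
    asum = a.sum(axis=1)
    kl = (
        gammaln(asum)
        - gammaln(a).sum(axis=1)
        - gammaln(a0.sum(axis=1))
        + gammaln(a0).sum(axis=1)
        + np.sum((a - a0) * (digamma(a) - digamma(asum)[:, None]), axis=1)
    )
    return float(kl.sum())


def _kl_wishart(Vinv1: np.ndarray, n1: float, Vinv0: np.ndarray, n0: float) -> float:
    """KL( W(V1, n1) || W(V0, n0) ), scales passed as inverses."""
    P = Vinv1.shape[0]
    L1 = np.linalg.cholesky(Vinv1)
    L0 = np.linalg.cholesky(Vinv0)
    logdet_V1 = -_chol_logdet(L1)
    logdet_V0 = -_chol_logdet(L0)
    # tr(V0^{-1} V1) = tr(Vinv0 @ V1)
    V1 = np.linalg.inv(Vinv1)
    tr = float(np.trace(Vinv0 @ V1))
    psi_p = float(np.sum(digamma(0.5 * (n1 - np.arange(P)))))  # psi_P(n1/2)
    return (
        -0.5 * n0 * (logdet_V1 - logdet_V0)
        + 0.5 * n1 * (tr - P)
        + multigammaln(0.5 * n0, P)
        - multigammaln(0.5 * n1, P)
        + 0.5 * (n1 - n0) * psi_p
    )


def _estep(model: HMMModel, y: np.ndarray, boundaries, point_estimate: bool = False):
    """Forward-backward over all segments.

    Returns gamma (T, K), summed xi (K, K), per-segment first-row gamma sum
    (K,), and the accumulated log normalizer.
    """
    if point_estimate:
        loglik = _point_loglik_matrix(model, y)
        logA = np.log(np.maximum(model.transition_matrix, 1e-300))
        logpi = np.log(np.maximum(model.initial_probs, 1e-300))
    else:
        loglik = _expected_loglik_matrix(model, y)
        logA = _dirichlet_elog(model.trans_alpha)
        logpi = _dirichlet_elog(model.init_alpha)
    K = model.K
    gamma = np.empty((y.shape[0], K))
    xi = np.zeros((K, K))
    g0 = np.zeros(K)
    logz = 0.0
    ell = 0.0  # sum_t gamma . loglik  (expected emission term)
    for a, b in boundaries:
        g, x, lz = forward_backward(
            np.ascontiguousarray(loglik[a:b]), logA, logpi
        )
        gamma[a:b] = g
        xi += x
        g0 += g[0]
        logz += lz
        ell += float(np.sum(g * loglik[a:b]))
    trans_term = float(np.sum(xi * logA)) + float(np.sum(g0 * logpi))
    return gamma, xi, g0, logz, ell + trans_term


def _mstep(priors: HMMPriors, y: np.ndarray, gamma: np.ndarray, xi: np.ndarray, g0: np.ndarray) -> HMMModel:
    K = gamma.shape[1]
    P = y.shape[1]
    prec_scale_inv = np.empty((K, P, P))
    dof = np.empty(K)
    for k in range(K):
        w = gamma[:, k]
        Sk = (y * w[:, None]).T @ y
        Vinv = priors.prec_scale_inv + Sk
        # regularize if numerically indefinite
        ev_min = np.linalg.eigvalsh(Vinv).min()
        if ev_min < 1e-10:
            Vinv = Vinv + (1e-8 * np.trace(Vinv) / P) * np.eye(P)
        prec_scale_inv[k] = 0.5 * (Vinv + Vinv.T)
        dof[k] = priors.prec_dof + w.sum()
    return HMMModel(
        K=K,
        trans_alpha=priors.trans_alpha0 + xi,
        init_alpha=priors.init_alpha0 + g0,
        prec_scale_inv=prec_scale_inv,
        prec_dof=dof,
        priors=priors,
    )


def free_energy(
    model: HMMModel,
    y: np.ndarray,
    boundaries: list[tuple[int, int]] | None = None,
    point_estimate: bool = False,
) -> FreeEnergy:
    """Variational free energy of ``model`` on data ``y``.

    Runs one E-step (forward-backward) and assembles
    ``F = KL(transitions) + KL(initial) + KL(emissions) - log Z~`` where
    ``log Z~`` is the forward-pass normalizer under expected log parameters.
    The decomposition reported is ``F = -E[log p] - H[q(Z)] + KL terms`` with
    ``H[q(Z)] = log Z~ - E[log p]``.

    With ``point_estimate=True`` parameters are treated as fixed at their
    posterior means and all KL terms are zero, so ``total`` equals
    ``-log p(y | theta_hat)`` from the forward algorithm.
    """
    if boundaries is None:
        boundaries = [(0, y.shape[0])]
    _, _, _, logz, ell = _estep(model, y, boundaries, point_estimate=point_estimate)
    if point_estimate or model.priors is None:
        kl_t = kl_i = kl_e = 0.0
    else:
        pr = model.priors
        kl_t = _kl_dirichlet(model.trans_alpha, pr.trans_alpha0)
        kl_i = _kl_dirichlet(model.init_alpha, pr.init_alpha0)
        kl_e = sum(
            _kl_wishart(
                model.prec_scale_inv[k],
                float(model.prec_dof[k]),
                pr.prec_scale_inv,
                pr.prec_dof,
            )
            for k in range(model.K)
        )
    entropy = logz - ell
    total = -ell - entropy + kl_t + kl_i + kl_e
    return FreeEnergy(
        total=float(total),
        expected_loglik=float(ell),
        entropy=float(entropy),
        kl_transition=float(kl_t),
        kl_initial=float(kl_i),
        kl_emission=float(kl_e),
    )


# ---------------------------------------------------------------------------
# fitting


def _kl_terms(model: HMMModel) -> float:
    pr = model.priors
    kl = _kl_dirichlet(model.trans_alpha, pr.trans_alpha0)
    kl += _kl_dirichlet(model.init_alpha, pr.init_alpha0)
    for k in range(model.K):
        kl += _kl_wishart(
            model.prec_scale_inv[k],
            float(model.prec_dof[k]),
            pr.prec_scale_inv,
            pr.prec_dof,
        )
    return kl


def _init_responsibilities(
    rng, y: np.ndarray, K: int, boundaries, method: str = "kmeans",
    chunk_mean: int = 50, window: int = 25,
):
    """Random initial responsibilities.

    ``method='kmeans'`` (default): k-means on windowed log-power features —
    each non-overlapping window of ``window`` samples is summarized by the
    log mean square of every reduced dimension, clustered into K groups, and
    the cluster is soft-assigned (0.9) to the window's samples.  Because the
    states differ in (auto)covariance, local power signatures separate them
    and the start lands near the basin of the good optimum; restarts differ
    through the k-means seeding.

    ``method='chunks'``: each segment is cut into random contiguous chunks
    (geometric length, mean ``chunk_mean``) assigned to random states —
    temporally coherent noise, used as a fully uninformed fallback.
    """
    T = y.shape[0]
    soft_off = 0.1 / max(K - 1, 1)
    gamma = np.full((T, K), soft_off)
    if K == 1:
        gamma[:] = 1.0
    elif method == "kmeans":
        from scipy.cluster.vq import kmeans2

        feats, spans = [], []
        for a, b in boundaries:
            n = max((b - a) // window, 1)
            w = min(window, b - a)
            blk = (y[a : a + n * w] ** 2).reshape(n, w, -1).mean(axis=1)
            feats.append(np.log(blk + 1e-12))
            spans.append((a, n, w, b))
        F = np.vstack(feats)
        if F.shape[0] < 2 * K:  # too few windows to cluster meaningfully
            return _init_responsibilities(
                rng, y, K, boundaries, method="chunks", chunk_mean=chunk_mean
            )
        _, labels = kmeans2(
            F, K, minit="++", seed=rng.integers(2**31 - 1)
        )
        pos = 0
        for a, n, w, b in spans:
            for i in range(n):
                lo = a + i * w
                hi = b if i == n - 1 else lo + w
                gamma[lo:hi, labels[pos + i]] = 0.9
            pos += n
    elif method == "chunks":
        for a, b in boundaries:
            pos = a
            while pos < b:
                ln = 1 + rng.geometric(1.0 / chunk_mean)
                k = rng.integers(K)
                gamma[pos : min(pos + ln, b), k] = 0.9
                pos += ln
    else:
        raise ValueError(f"unknown init method {method!r}")
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = np.zeros((K, K))
    g0 = np.zeros(K)
    for a, b in boundaries:
        g = gamma[a:b]
        xi += g[:-1].T @ g[1:]
        g0 += g[0]
    return gamma, xi, g0


def _run_vb(
    priors, y, boundaries, gamma, xi, g0, max_cycles, tolerance, trace=None
):
    """VB coordinate ascent from given responsibilities.  Returns the final
    model, gamma and the free-energy trace (one entry per completed cycle,
    evaluated after the E-step)."""
    trace = [] if trace is None else trace
    model = None
    converged = False
    for _ in range(max_cycles):
        model = _mstep(priors, y, gamma, xi, g0)
        gamma, xi, g0, logz, _ = _estep(model, y, boundaries)
        f = _kl_terms(model) - logz
        trace.append(f)
        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if abs(prev - cur) <= tolerance * abs(cur):
                converged = True
                break
    return model, gamma, xi, g0, trace, converged


def fit(
    y: np.ndarray,
    K: int,
    boundaries: list[tuple[int, int]] | None = None,
    *,
    restarts: int = 10,
    max_cycles: int = 500,
    tolerance: float = 1e-6,
    init_cycles: int | None = None,
    init: str = "kmeans",
    batch_segments: int | None = None,
    stickiness: float = 5.0,
    seed: int = 0,
    fs: float = 250.0,
    sample_indices: np.ndarray | None = None,
) -> FitResult:
    """Fit a K-state TDE-HMM to reduced embedded data by variational Bayes.

    Parameters
    ----------
    y
        ``(T', P)`` matrix of PCA-reduced embedded observations.
    K
        Number of states.
    boundaries
        Per-subject ``(start, stop)`` row ranges; forward-backward never
        crosses them.  Defaults to one segment.
    restarts
        Independently seeded initializations; the fit with the lowest final
        free energy is returned.
    max_cycles, tolerance
        Stop a run after ``max_cycles`` VB cycles or when the relative change
        in free energy falls below ``tolerance``.
    init_cycles
        If given, run every restart for only this many cycles first, then
        continue the best one to ``max_cycles`` (cheap restart screening).
    init
        Initialization method per restart: ``'kmeans'`` (windowed
        log-power k-means, default) or ``'chunks'`` (random contiguous
        chunk assignment).
    batch_segments
        If given, use stochastic inference: each iteration updates on a
        random batch of this many contiguous segments with a decaying
        forgetting rate.  Free energy is then not monotone; full-batch is the
        default.
    stickiness
        Extra diagonal Dirichlet pseudo-count on transition rows.
    seed
        Base seed; restart r uses ``seed + r``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in input")
    T = y.shape[0]
    if boundaries is None:
        boundaries = [(0, T)]
    priors = HMMPriors.default(K, y, stickiness=stickiness)

    if batch_segments is not None:
        return _fit_stochastic(
            priors, y, boundaries, K, restarts, max_cycles, tolerance,
            batch_segments, seed, fs, sample_indices,
        )

    runs = []
    for r in range(restarts):
        rng = np.random.default_rng(seed + r)
        gamma, xi, g0 = _init_responsibilities(rng, y, K, boundaries, method=init)
        n_first = init_cycles if init_cycles is not None else max_cycles
        state = _run_vb(priors, y, boundaries, gamma, xi, g0, n_first, tolerance)
        runs.append(state)

    finals = np.array([s[4][-1] for s in runs])
    best = int(np.argmin(finals))
    model, gamma, xi, g0, trace, converged = runs[best]
    if init_cycles is not None and not converged and max_cycles > init_cycles:
        model, gamma, xi, g0, trace, converged = _run_vb(
            priors, y, boundaries, gamma, xi, g0,
            max_cycles - init_cycles, tolerance, trace=trace,
        )
        finals[best] = trace[-1]

    sp = StateProbabilities(
        gamma=gamma, fs=fs, sample_indices=sample_indices, boundaries=boundaries
    )
    return FitResult(
        model=model,
        gamma=sp,
        free_energy_trace=np.asarray(trace),
        n_restarts=restarts,
        chosen_restart=best,
        restart_free_energies=finals,
        converged=converged,
    )


def _fit_stochastic(
    priors, y, boundaries, K, restarts, max_iters, tolerance,
    batch_segments, seed, fs, sample_indices,
):
    """Stochastic VB: interpolate sufficient statistics from random segment
    batches with forgetting rate ``0.7 * iter^(-0.7)``; not monotone."""
    T = y.shape[0]
    n_seg = len(boundaries)
    scale = n_seg / min(batch_segments, n_seg)
    best_run = None
    for r in range(restarts):
        rng = np.random.default_rng(seed + r)
        gamma, xi, g0 = _init_responsibilities(rng, y, K, boundaries)
        # running full-data statistic estimates
        stat_xi, stat_g0 = xi.copy(), g0.copy()
        stat_S = np.stack(
            [(y * gamma[:, k][:, None]).T @ y for k in range(K)]
        )
        stat_N = gamma.sum(axis=0)
        model = None
        trace = []
        for it in range(1, max_iters + 1):
            model = HMMModel(
                K=K,
                trans_alpha=priors.trans_alpha0 + stat_xi,
                init_alpha=priors.init_alpha0 + stat_g0,
                prec_scale_inv=priors.prec_scale_inv[None] + stat_S,
                prec_dof=priors.prec_dof + stat_N,
                priors=priors,
            )
            pick = rng.choice(n_seg, size=min(batch_segments, n_seg), replace=False)
            batch = [boundaries[i] for i in pick]
            rho = 0.7 * it ** (-0.7)
            b_xi = np.zeros((K, K))
            b_g0 = np.zeros(K)
            b_S = np.zeros_like(stat_S)
            b_N = np.zeros(K)
            logz = 0.0
            for a, b in batch:
                g, x, lz = forward_backward(
                    np.ascontiguousarray(_expected_loglik_matrix(model, y[a:b])),
                    _dirichlet_elog(model.trans_alpha),
                    _dirichlet_elog(model.init_alpha),
                )
                b_xi += x
                b_g0 += g[0]
                b_N += g.sum(axis=0)
                for k in range(K):
                    b_S[k] += (y[a:b] * g[:, k][:, None]).T @ y[a:b]
                logz += lz
            stat_xi = (1 - rho) * stat_xi + rho * scale * b_xi
            stat_g0 = (1 - rho) * stat_g0 + rho * (n_seg / len(batch)) * b_g0
            stat_S = (1 - rho) * stat_S + rho * scale * b_S
            stat_N = (1 - rho) * stat_N + rho * scale * b_N
            trace.append(_kl_terms(model) - scale * logz)
        # final full E-step for reporting
        gamma, xi, g0, logz, _ = _estep(model, y, boundaries)
        f_final = _kl_terms(model) - logz
        if best_run is None or f_final < best_run[0]:
            best_run = (f_final, r, model, gamma, trace)
    f_final, r, model, gamma, trace = best_run
    sp = StateProbabilities(
        gamma=gamma, fs=fs, sample_indices=sample_indices, boundaries=boundaries
    )
    return FitResult(
        model=model,
        gamma=sp,
        free_energy_trace=np.asarray(trace),
        n_restarts=restarts,
        chosen_restart=r,
        restart_free_energies=np.array([f_final]),
        converged=False,
    )


# ---------------------------------------------------------------------------
# decoding and transfer


def viterbi(
    model: HMMModel,
    y: np.ndarray,
    boundaries: list[tuple[int, int]] | None = None,
    sample_indices: np.ndarray | None = None,
) -> ViterbiPath:
    """Most probable hard state sequence under posterior-mean parameters.

    Log-domain dynamic programming per subject segment; ties break toward the
    lower state index.
    """
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite values in input")
    if boundaries is None:
        boundaries = [(0, y.shape[0])]
    loglik = _point_loglik_matrix(model, y)
    logA = np.log(np.maximum(model.transition_matrix, 1e-300))
    logpi = np.log(np.maximum(model.initial_probs, 1e-300))
    labels = np.empty(y.shape[0], dtype=np.int64)
    for a, b in boundaries:
        lab, _ = viterbi_path(np.ascontiguousarray(loglik[a:b]), logA, logpi)
        labels[a:b] = lab
    return ViterbiPath(
        labels=labels, K=model.K, sample_indices=sample_indices, boundaries=boundaries
    )


def apply_model(
    model: HMMModel,
    basis: PCABasis,
    cfg: EmbeddingConfig,
    x_new: ConcatenatedData,
    return_viterbi: bool = False,
):
    """Apply a trained observation model to new data with parameters frozen.

    The new recording is embedded with the training lag set, projected onto
    the *training* PCA basis, and decoded by forward-backward with all model
    parameters fixed — no re-estimation.  This is how a model trained on one
    cohort is transferred to another.
    """
    expected_dim = basis.components.shape[0]
    n_expected = expected_dim // cfg.n_lags
    if x_new.n_parcels != n_expected:
        raise ValueError(
            f"dimension mismatch: model was trained on {n_expected} parcels, "
            f"got {x_new.n_parcels}"
        )
    e, sample_indices, boundaries = embed(x_new, cfg)
    y = basis.project(e)
    gamma, _, _, _, _ = _estep(model, y, boundaries)
    sp = StateProbabilities(
        gamma=gamma, fs=x_new.fs, sample_indices=sample_indices, boundaries=boundaries
    )
    if return_viterbi:
        vp = viterbi(model, y, boundaries, sample_indices=sample_indices)
        return sp, vp
    return sp
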