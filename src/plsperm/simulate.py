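"""Synthetic two-block data with a controllable latent effect.

Two regimes are provided:

* ``null`` — both blocks are iid standard-normal draws with no cross-block
  structure; the population first canonical correlation is 0.
* ``latent`` — observations are drawn from a joint multivariate normal whose
  correlation matrix encodes exactly one latent effect between the blocks,
  parameterised by its first canonical correlation ``r``.

In the latent regime, the cross-block structure is built in whitened space:
a random unit-vector pair (a, b) defines the effect direction and

    C_XY = C_XX^{1/2} · a · r · b^T · C_YY^{1/2},

so the population's first canonical correlation is exactly r and no other
pair is constrained.  By default the within-block correlation matrices are
the identity, which keeps the embedded canonical correlation analytically
exact; an optional power-law eigenvalue-decay mode provides correlated
within-block structure (canonical correlations are invariant to the
per-variable rescaling used to return to unit diagonals, so the embedded r
is preserved there too).

Additive Gaussian noise of a chosen standard deviation can degrade a
sampled dataset after generation, attenuating all pairwise correlations by
a factor 1/(1 + sd_noise^2) on unit-variance data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .data import TwoBlockDataset

__all__ = [
    "SimulationSpec",
    "JointCorrelationModel",
    "generate_null_dataset",
    "build_joint_correlation",
    "population_canonical_correlations",
    "sample_dataset",
    "add_noise",
    "generate_dataset",
]

_PD_RETRIES = 10


@dataclass
class SimulationSpec:
    """Parameters of one simulated dataset.

    Defaults mirror the simulation design this package reproduces: 90 X
    features, 10 Y features, a single latent effect of canonical
    correlation 0.3, and no added noise.
    """

    n: int = 1000
    p: int = 90
    q: int = 10
    regime: str = "latent"
    r: float = 0.3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in ("null", "latent"):
            raise ValueError("regime must be 'null' or 'latent'")
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.p < 1 or self.q < 1:
            raise ValueError("p and q must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.regime == "latent" and not (0.0 < self.r < 1.0):
            raise ValueError("r must lie in (0, 1) for the latent regime")


@dataclass
class JointCorrelationModel:
    """Population correlation structure with one embedded latent effect.

    The assembled (p+q) x (p+q) joint matrix [[C_XX, C_XY], [C_XY^T, C_YY]]
    is symmetric positive definite with unit diagonal, and its first
    canonical correlation equals ``r``.
    """

    C_XX: np.ndarray
    C_YY: np.ndarray
    C_XY: np.ndarray
    r: float
    m: int = 1
    within_structure: str = "identity"
    _cholesky: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def p(self) -> int:
        return self.C_XX.shape[0]

    @property
    def q(self) -> int:
        return self.C_YY.shape[0]

    def joint(self) -> np.ndarray:
        return np.block([[self.C_XX, self.C_XY], [self.C_XY.T, self.C_YY]])

    def cholesky(self) -> np.ndarray:
        if self._cholesky is None:
            self._cholesky = np.linalg.cholesky(self.joint())
        return self._cholesky


def _random_unit_vector(dim: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(dim)
    return v / np.linalg.norm(v)


def _powerlaw_correlation(dim: int, rng: np.random.Generator, decay: float) -> np.ndarray:
    """Correlation matrix with power-law eigenvalue decay and random axes."""
    lam = np.arange(1, dim + 1, dtype=float) ** (-decay)
    lam *= dim / lam.sum()
    Q, _ = np.linalg.qr(rng.standard_normal((dim, dim)))
    S = (Q * lam) @ Q.T
    d = np.sqrt(np.diag(S))
    return S / np.outer(d, d)


def build_joint_correlation(
    p: int,
    q: int,
    r: float,
    seed: int = 0,
    within_structure: str = "identity",
    decay: float = 1.0,
) -> JointCorrelationModel:
    """Construct the population correlation model for one latent effect.

    Parameters
    ----------
    p, q : int
        Feature counts of the two blocks.
    r : float in (0, 1)
        Target first canonical correlation of the effect.
    within_structure : {"identity", "powerlaw"}
        Within-block correlation structure.  Identity keeps the embedding
        analytically exact and is the default; the power-law mode draws
        random principal axes with eigenvalues decaying as i^-decay.

    The assembled joint matrix is verified positive definite; on failure a
    fresh draw is attempted up to a retry cap.
    """
    if not (0.0 < r < 1.0):
        raise ValueError("r must lie in (0, 1)")
    if within_structure not in ("identity", "powerlaw"):
        raise ValueError("within_structure must be 'identity' or 'powerlaw'")
    rng = np.random.default_rng(seed)
    for _ in range(_PD_RETRIES):
        if within_structure == "identity":
            C_XX = np.eye(p)
            C_YY = np.eye(q)
            sqrt_x = np.eye(p)
            sqrt_y = np.eye(q)
        else:
            C_XX = _powerlaw_correlation(p, rng, decay)
            C_YY = _powerlaw_correlation(q, rng, decay)
            sqrt_x = scipy.linalg.sqrtm(C_XX).real
            sqrt_y = scipy.linalg.sqrtm(C_YY).real
        a = _random_unit_vector(p, rng)
        b = _random_unit_vector(q, rng)
        C_XY = sqrt_x @ np.outer(a, b) @ sqrt_y * r
        joint = np.block([[C_XX, C_XY], [C_XY.T, C_YY]])
        if within_structure == "powerlaw":
            # return to unit diagonal; canonical correlations are invariant
            # to this per-variable rescaling
            d = np.sqrt(np.diag(joint))
            joint = joint / np.outer(d, d)
            C_XX = joint[:p, :p]
            C_YY = joint[p:, p:]
            C_XY = joint[:p, p:]
        try:
            chol = np.linalg.cholesky(joint)
        except np.linalg.LinAlgError:
            continue
        return JointCorrelationModel(
            C_XX=C_XX,
            C_YY=C_YY,
            C_XY=C_XY,
            r=float(r),
            m=1,
            within_structure=within_structure,
            _cholesky=chol,
        )
    raise RuntimeError(
        "failed to build a positive definite joint correlation matrix "
        f"after {_PD_RETRIES} attempts"
    )


def population_canonical_correlations(model: JointCorrelationModel) -> np.ndarray:
    """Canonical correlations of the population model, largest first.

    Solved as the generalized eigenproblem
    ``C_XY C_YY^{-1} C_YX a = rho^2 C_XX a`` — an independent route that
    does not reuse the construction's whitened factorisation.
    """
    C_YX = model.C_XY.T
    M = model.C_XY @ np.linalg.solve(model.C_YY, C_YX)
    eigvals = scipy.linalg.eigh(M, model.C_XX, eigvals_only=True)
    rho2 = np.clip(eigvals, 0.0, 1.0)
    return np.sqrt(np.sort(rho2)[::-1][: min(model.p, model.q)])


def _feature_names(p: int, q: int) -> tuple[list[str], list[str]]:
    return [f"x{j}" for j in range(p)], [f"y{j}" for j in range(q)]


def generate_null_dataset(spec: SimulationSpec) -> TwoBlockDataset:
    """iid standard-normal blocks with no cross-block structure."""
    if spec.regime != "null":
        raise ValueError("generate_null_dataset requires regime='null'")
    rng = np.random.default_rng(spec.seed)
    nx, ny = _feature_names(spec.p, spec.q)
    X = rng.standard_normal((spec.n, spec.p))
    Y = rng.standard_normal((spec.n, spec.q))
    return TwoBlockDataset(X, Y, nx, ny)


def sample_dataset(model: JointCorrelationModel, n: int, seed: int = 0) -> TwoBlockDataset:
    """Draw n observations from the model's joint multivariate normal."""
    if n < 3:
        raise ValueError("n must be >= 3")
    rng = np.random.default_rng(seed)
    L = model.cholesky()
    Z = rng.standard_normal((n, model.p + model.q)) @ L.T
    nx, ny = _feature_names(model.p, model.q)
    return TwoBlockDataset(Z[:, : model.p], Z[:, model.p :], nx, ny)


def add_noise(data: TwoBlockDataset, noise_sd: float, seed: int = 0) -> TwoBlockDataset:
    """Add iid Gaussian noise of the given standard deviation to both blocks.

    ``noise_sd = 0`` returns the input values bit-identically.  Noise is
    added to the raw (pre-z-scoring) data; standardisation happens inside
    the PLS itself.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd == 0:
        return TwoBlockDataset(
            data.X.copy(), data.Y.copy(), data.feature_names_x, data.feature_names_y
        )
    rng = np.random.default_rng(seed)
    X = data.X + rng.normal(0.0, noise_sd, data.X.shape)
    Y = data.Y + rng.normal(0.0, noise_sd, data.Y.shape)
    return TwoBlockDataset(X, Y, data.feature_names_x, data.feature_names_y)


def generate_dataset(spec: SimulationSpec) -> TwoBlockDataset:
    """One-call generation following a :class:`SimulationSpec`.

    Null regime: iid normal blocks.  Latent regime: build the joint
    correlation model, sample n observations, then add noise if requested.
    Sub-seeds for the model, the sampling and the noise are derived
    deterministically from ``spec.seed``.
    """
    ss = np.random.SeedSequence(spec.seed)
    s_model, s_sample, s_noise = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    if spec.regime == "null":
        data = generate_null_dataset(
            SimulationSpec(
                n=spec.n, p=spec.p, q=spec.q, regime="null", noise_sd=0.0, seed=s_sample
            )
        )
    else:
        model = build_joint_correlation(spec.p, spec.q, spec.r, seed=s_model)
        data = sample_dataset(model, spec.n, seed=s_sample)
    if spec.noise_sd > 0:
        data = add_noise(data, spec.noise_sd, seed=s_noise)
    return data
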