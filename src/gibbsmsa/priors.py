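"""Dirichlet-mixture emission priors, posterior emission estimates and
Bayesian integral log-odds (BILD) column scores.

All scores are in nats.  Counts may be fractional (sequence-weighted);
Dirichlet-multinomial (Polya) marginals are evaluated through log-Gamma.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.special import gammaln, logsumexp

from .seqio import NRES


@dataclass(frozen=True)
class DirichletMixture:
    """Mixture of Dirichlet densities over amino-acid frequency vectors."""

    rho: np.ndarray  # (L,) mixture coefficients, sum 1
    alpha: np.ndarray  # (L, 20) positive concentration vectors
    name: str = ""

    def __post_init__(self) -> None:
        rho = np.asarray(self.rho, dtype=float)
        alpha = np.asarray(self.alpha, dtype=float)
        object.__setattr__(self, "rho", rho)
        object.__setattr__(self, "alpha", alpha)
        if rho.ndim != 1 or alpha.shape != (len(rho), NRES):
            raise ValueError("mixture shape mismatch")
        if np.any(rho <= 0) or abs(rho.sum() - 1.0) > 1e-9:
            raise ValueError("mixture coefficients must be positive and sum to 1")
        if np.any(alpha <= 0):
            raise ValueError("Dirichlet parameters must be strictly positive")

    @property
    def n_components(self) -> int:
        return len(self.rho)

    def component_means(self) -> np.ndarray:
        return self.alpha / self.alpha.sum(axis=1, keepdims=True)

    def mean(self) -> np.ndarray:
        """rho-weighted mean of the component means."""
        return self.rho @ self.component_means()


@dataclass(frozen=True)
class Background:
    """Background residue distribution theta0 and its Dirichlet parameter."""

    theta0: np.ndarray
    alpha: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.theta0, dtype=float)
        a = np.asarray(self.alpha, dtype=float)
        object.__setattr__(self, "theta0", t)
        object.__setattr__(self, "alpha", a)
        if t.shape != (NRES,) or a.shape != (NRES,):
            raise ValueError("background vectors must have length 20")
        if np.any(t <= 0) or abs(t.sum() - 1.0) > 1e-12:
            raise ValueError("theta0 must be strictly positive and sum to 1")
        if np.any(a <= 0):
            raise ValueError("background Dirichlet parameters must be positive")

    @property
    def log_theta0(self) -> np.ndarray:
        return np.log(self.theta0)


def background_from_mixture(dm: DirichletMixture, concentration: float = 20.0) -> Background:
    theta0 = dm.mean()
    theta0 = theta0 / theta0.sum()
    return Background(theta0=theta0, alpha=concentration * theta0)


def uniform_mixture() -> DirichletMixture:
    return DirichletMixture(rho=np.ones(1), alpha=np.ones((1, NRES)), name="uniform")


def log_polya(counts: np.ndarray, alpha: np.ndarray) -> float:
    """Log Dirichlet-multinomial marginal of an *ordered* residue sample.

    ln Gamma(|a|) - ln Gamma(|a|+n) + sum_i [ln Gamma(a_i+c_i) - ln Gamma(a_i)]
    with n = |counts|; no multinomial coefficient, matching a product of
    sequential predictive probabilities.  Valid for fractional counts.
    """
    counts = np.asarray(counts, dtype=float)
    a0 = alpha.sum()
    return float(
        gammaln(a0)
        - gammaln(a0 + counts.sum())
        + np.sum(gammaln(alpha + counts) - gammaln(alpha))
    )


def _component_logmarg(counts: np.ndarray, dm: DirichletMixture) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    a0 = dm.alpha.sum(axis=1)
    return (
        gammaln(a0)
        - gammaln(a0 + counts.sum())
        + np.sum(gammaln(dm.alpha + counts[None, :]) - gammaln(dm.alpha), axis=1)
    )


def _batch_component_logmarg(counts: np.ndarray, dm: DirichletMixture) -> np.ndarray:
    """(w, L) per-column per-component log Polya marginals."""
    counts = np.asarray(counts, dtype=float)
    a0 = dm.alpha.sum(axis=1)  # (L,)
    base = gammaln(dm.alpha).sum(axis=1)  # (L,)
    lg = gammaln(dm.alpha[None, :, :] + counts[:, None, :]).sum(axis=2)  # (w, L)
    return gammaln(a0)[None, :] - gammaln(a0[None, :] + counts.sum(axis=1)[:, None]) + lg - base[None, :]


def batch_mixture_log_marginal(counts: np.ndarray, dm: DirichletMixture) -> np.ndarray:
    """(w,) mixture log marginals for a stack of count vectors."""
    lw = np.log(dm.rho)[None, :] + _batch_component_logmarg(counts, dm)
    return logsumexp(lw, axis=1)


def batch_bild_scores(counts: np.ndarray, dm: DirichletMixture, bg: Background) -> np.ndarray:
    """(w,) BILD scores; zero-count columns score exactly 0."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        return np.zeros(0)
    out = batch_mixture_log_marginal(counts, dm) - counts @ bg.log_theta0
    out[counts.sum(axis=1) == 0] = 0.0
    return out


def batch_posterior_mean_emissions(counts: np.ndarray, dm: DirichletMixture) -> np.ndarray:
    """(w, 20) posterior-mean residue distributions, one per count row."""
    counts = np.asarray(counts, dtype=float)
    lw = np.log(dm.rho)[None, :] + _batch_component_logmarg(counts, dm)
    lw -= logsumexp(lw, axis=1, keepdims=True)
    resp = np.exp(lw)  # (w, L)
    post = counts[:, None, :] + dm.alpha[None, :, :]
    post /= post.sum(axis=2, keepdims=True)
    theta = np.einsum("wl,wla->wa", resp, post)
    return theta / theta.sum(axis=1, keepdims=True)


def batch_sample_emission_vectors(
    counts: np.ndarray, dm: DirichletMixture, rng: np.random.Generator
) -> np.ndarray:
    """(w, 20) posterior draws, one per count row."""
    counts = np.asarray(counts, dtype=float)
    lw = np.log(dm.rho)[None, :] + _batch_component_logmarg(counts, dm)
    lw -= logsumexp(lw, axis=1, keepdims=True)
    resp = np.exp(lw)
    w = counts.shape[0]
    # inverse-CDF component choice, vectorized over columns
    u = rng.random(w)
    comp = (resp.cumsum(axis=1) < u[:, None]).sum(axis=1)
    comp = np.minimum(comp, dm.n_components - 1)
    out = np.empty_like(counts)
    for j in range(w):
        theta = rng.dirichlet(counts[j] + dm.alpha[comp[j]])
        theta = np.maximum(theta, 1e-300)
        out[j] = theta / theta.sum()
    return out


def mixture_log_marginal(counts: np.ndarray, dm: DirichletMixture) -> float:
    """ln sum_l rho_l * Polya(counts; alpha_l)."""
    return float(logsumexp(np.log(dm.rho) + _component_logmarg(counts, dm)))


def component_responsibilities(counts: np.ndarray, dm: DirichletMixture) -> np.ndarray:
    lw = np.log(dm.rho) + _component_logmarg(counts, dm)
    lw -= logsumexp(lw)
    return np.exp(lw)


def posterior_mean_emissions(counts: np.ndarray, dm: DirichletMixture) -> np.ndarray:
    """Posterior-mean residue distribution given weighted counts.

    Mixture posterior mean: sum_l rho'_l (counts+alpha_l)/|counts+alpha_l|
    where rho'_l are the marginal-likelihood responsibilities.
    """
    counts = np.asarray(counts, dtype=float)
    resp = component_responsibilities(counts, dm)
    post = counts[None, :] + dm.alpha
    post /= post.sum(axis=1, keepdims=True)
    theta = resp @ post
    return theta / theta.sum()


def sample_emission_vector(
    counts: np.ndarray, dm: DirichletMixture, rng: np.random.Generator
) -> np.ndarray:
    """Draw a residue distribution from the mixture posterior."""
    counts = np.asarray(counts, dtype=float)
    resp = component_responsibilities(counts, dm)
    l = rng.choice(dm.n_components, p=resp)
    theta = rng.dirichlet(counts + dm.alpha[l])
    # guard against numerically zero simplex coordinates
    theta = np.maximum(theta, 1e-300)
    return theta / theta.sum()


def bild_score(counts: np.ndarray, dm: DirichletMixture, bg: Background) -> float:
    """BILD column score: prior-predictive log-odds of a column vs background.

    ln[ sum_l rho_l Polya(counts; alpha_l) / prod_a theta0_a^counts_a ].
    Zero counts give exactly 0.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.sum() == 0:
        return 0.0
    return mixture_log_marginal(counts, dm) - float(counts @ bg.log_theta0)


# ---------------------------------------------------------------------------
# Mixture file I/O


def read_dirichlet_mixture(path: str | Path) -> DirichletMixture:
    """Read a mixture text file.

    Format: '#' comments; first data line the component count L; then L lines
    of 21 numbers ``rho alpha_1 .. alpha_20`` with residues in alphabetical
    one-letter order ACDEFGHIKLMNPQRSTVWY.
    """
    path = Path(path)
    lines = [
        ln.strip()
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: empty mixture file")
    try:
        L = int(lines[0])
    except ValueError as exc:
        raise ValueError(f"{path}: first data line must be the component count") from exc
    if len(lines) != L + 1:
        raise ValueError(f"{path}: expected {L} component lines, got {len(lines) - 1}")
    rho = np.empty(L)
    alpha = np.empty((L, NRES))
    for i, ln in enumerate(lines[1:]):
        vals = [float(x) for x in ln.split()]
        if len(vals) != NRES + 1:
            raise ValueError(f"{path}: component {i + 1} needs 21 numbers")
        rho[i], alpha[i] = vals[0], vals[1:]
    if abs(rho.sum() - 1.0) > 1e-3:
        raise ValueError(f"{path}: mixture coefficients sum to {rho.sum():.4f}")
    rho = rho / rho.sum()  # absorb file rounding
    return DirichletMixture(rho=rho, alpha=alpha, name=path.name)


def load_default_mixture(phase: int) -> DirichletMixture:
    """Packaged default mixture: compact (phase 1) or large (phase 2)."""
    fname = "dm20.txt" if phase == 1 else "dm58.txt"
    ref = resources.files("gibbsmsa.data").joinpath(fname)
    with resources.as_file(ref) as p:
        return read_dirichlet_mixture(p)
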