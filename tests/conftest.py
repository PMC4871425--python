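import numpy as np
import pytest

from gibbsmsa.model import TransitionPriors
from gibbsmsa.phase2 import MsaState
from gibbsmsa.priors import (
    Background,
    DirichletMixture,
    background_from_mixture,
    load_default_mixture,
    uniform_mixture,
)
from gibbsmsa.seqio import GappedMSA, SequenceRecord, SequenceSet
from gibbsmsa.weights import WeightState


@pytest.fixture(scope="session")
def dm20() -> DirichletMixture:
    return load_default_mixture(1)


@pytest.fixture(scope="session")
def dm58() -> DirichletMixture:
    return load_default_mixture(2)


@pytest.fixture(scope="session")
def bg(dm58) -> Background:
    return background_from_mixture(dm58)


@pytest.fixture(scope="session")
def uniform_bg() -> Background:
    t = np.ones(20) / 20
    return Background(theta0=t, alpha=t * 20)


@pytest.fixture(scope="session")
def flat_dm() -> DirichletMixture:
    return uniform_mixture()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def lumped_chisquare_pvalue(counts: np.ndarray, prob: np.ndarray) -> float:
    """Chi-square GOF p-value with low-expectation categories lumped."""
    from scipy.stats import chisquare

    trials = counts.sum()
    keep = prob * trials >= 5
    obs = list(counts[keep])
    exp = list(prob[keep] * trials)
    rest_p = prob[~keep].sum()
    if rest_p * trials > 0.5:
        obs.append(counts[~keep].sum())
        exp.append(rest_p * trials)
    elif np.any(~keep):
        # fold negligible tail into the largest category
        i = int(np.argmax(exp))
        obs[i] += counts[~keep].sum()
        exp[i] += rest_p * trials
    if len(obs) < 2:
        return 1.0
    exp = np.array(exp) * (sum(obs) / sum(exp))
    return float(chisquare(obs, exp).pvalue)


def m_from_msa(msa: GappedMSA) -> np.ndarray:
    """Match matrix (residue index or -1 per column) from a GappedMSA."""
    m = np.full((len(msa), msa.n_match), -1, dtype=np.int64)
    for i in range(len(msa)):
        m[i] = msa.match_columns(i)
    return m


def make_trap_instance(
    seed: int,
    dm: DirichletMixture,
    bg: Background,
    n_free: int = 8,
    cluster_size: int = 14,
    w: int = 16,
    flank: int = 8,
    offset: int = 3,
):
    """A tight-cluster trap: all sequences share a strongly conserved
    gapless domain; one cluster of identical sequences is planted into the
    alignment mis-offset by ``offset`` columns.  Weights are frozen uniform
    so the correlated cluster genuinely dominates its own leave-one-out
    model (Henikoff weighting would otherwise defuse the trap at this tiny
    scale).  Returns (state, truth match matrix, cluster member indices)."""
    rng = np.random.default_rng(seed)
    theta0 = bg.theta0
    consensus = rng.choice(20, size=w, p=theta0)

    def domain_seq():
        out = consensus.copy()
        noise = rng.random(w) < 0.15
        out[noise] = rng.choice(20, size=int(noise.sum()), p=theta0)
        return out

    def full_seq(core):
        fl = rng.choice(20, size=flank, p=theta0)
        fr = rng.choice(20, size=flank, p=theta0)
        return np.concatenate([fl, core, fr]).astype(np.int8)

    residues = [full_seq(domain_seq()) for _ in range(n_free)]
    residues.extend([full_seq(domain_seq())] * cluster_size)  # exact copies
    recs = []
    m = np.zeros((n_free + cluster_size, w), dtype=np.int64)
    for k, full in enumerate(residues):
        recs.append(SequenceRecord(f"t{k}", "", full.copy()))
        m[k] = np.arange(w) + flank
    seqs = SequenceSet(recs)
    truth_m = m.copy()
    cluster = list(range(n_free, n_free + cluster_size))
    m[cluster] += offset
    state = make_state(seqs, m, dm, bg)
    return state, truth_m, cluster


def make_state(
    seqs: SequenceSet,
    m: np.ndarray,
    dm: DirichletMixture,
    bg: Background,
    weights: np.ndarray | None = None,
    frozen: bool = True,
) -> MsaState:
    if weights is None:
        weights = np.full(len(seqs), 100, dtype=np.int64)
    ws = WeightState(raw=weights / 100.0, integer=np.asarray(weights), frozen=frozen)
    return MsaState(seqs, m, TransitionPriors(), dm, bg, ws)
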