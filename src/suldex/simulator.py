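"""Forward simulation of ligand-binding sequencing experiments.

Given true dissociation constants and a free TF concentration, binding
probabilities and bound-fraction frequencies follow exactly from the
isotherm; sequencing is simulated as multinomial draws at a fixed total read
budget in each fraction.  Named presets reproduce the geometry of the three
published control designs (43- and 46-oligo pools with equal pre-bound
frequencies; a 436-oligo Hamming-ball pool with GSM-mixture frequencies)
with generated energy landscapes standing in for the external Kd sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .binding_core import OligoSet, bound_freqs, fraction_bound
from .gem import NUCLEOTIDES, EnergyModel, additive_energy, encode_sequences
from .gsm import GSMModel, gsm_predicted_counts

__all__ = [
    "SimulationConfig",
    "SimulatedExperiment",
    "enumerate_neighborhood",
    "generate_landscape",
    "prebound_mixture",
    "simulate_experiment",
    "solve_mass_balance",
    "poisson_relative_std_pct",
    "n_randomized_oligos",
    "pooled_synthesis_count",
    "max_targetable_oligos",
    "leu3_like_preset",
    "arca_like_preset",
    "zif268_like_preset",
    "PRESETS",
    "DESIGN_GRIDS",
]


# ---------------------------------------------------------------------------
# experimental-design arithmetic


def poisson_relative_std_pct(expectation: float) -> float:
    """Relative std (std / expectation) of a Poisson count, in percent."""
    if expectation <= 0:
        raise ValueError("expectation must be positive")
    return 100.0 * np.sqrt(expectation) / expectation


def n_randomized_oligos(n_sites: int, n_letters: int = 4) -> int:
    """Distinct species from fully randomizing n_sites positions."""
    return n_letters**n_sites


def pooled_synthesis_count(n_pools: int, n_sites_per_pool: int, n_letters: int = 4) -> int:
    """Total species across pools that each fully randomize a site subset."""
    return n_pools * n_randomized_oligos(n_sites_per_pool, n_letters)


def max_targetable_oligos(total_reads: float, mean_depth: float) -> int:
    """How many distinct oligos a read budget covers at a mean depth."""
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    return int(total_reads // mean_depth)


# ---------------------------------------------------------------------------
# pool construction


def enumerate_neighborhood(consensus: str, max_mismatches: int) -> list[str]:
    """All sequences within a Hamming ball, deduplicated, deterministic order."""
    if not set(consensus) <= set(NUCLEOTIDES):
        raise ValueError(f"invalid alphabet in consensus {consensus!r}")
    if max_mismatches > len(consensus):
        raise ValueError("max_mismatches exceeds the sequence length")
    result = []
    seen = set()
    for r in range(max_mismatches + 1):
        for positions in itertools.combinations(range(len(consensus)), r):
            alternatives = [
                [nt for nt in NUCLEOTIDES if nt != consensus[pos]] for pos in positions
            ]
            for subst in itertools.product(*alternatives):
                seq = list(consensus)
                for pos, nt in zip(positions, subst):
                    seq[pos] = nt
                seq = "".join(seq)
                if seq not in seen:
                    seen.add(seq)
                    result.append(seq)
    return result


def generate_landscape(
    sequences,
    consensus: str,
    term_sampler,
    epsilon_std: float,
    kd_opt: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Kd map from an additive energy landscape plus lognormal noise.

    Kd_i = Kd_opt · exp(additive relative energy + ε_i) with
    ε ~ N(0, epsilon_std²).  ``term_sampler(rng)`` yields one non-negative
    energy term per (position, non-consensus nucleotide).  The consensus
    attains the minimum additive energy by construction.

    Returns ``(kd_map, energy_model)``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    length = len(consensus)
    codes = encode_sequences([consensus])[0]
    terms = np.zeros((length, 4))
    for pos in range(length):
        for nt in range(4):
            if nt != codes[pos]:
                value = float(term_sampler(rng))
                if value < 0:
                    raise ValueError("term_sampler must yield non-negative terms")
                terms[pos, nt] = value
    model = EnergyModel(optimal_sequence=consensus, e0=0.0, terms=terms, sigma=max(epsilon_std, 1e-6))
    e_rel = additive_energy(encode_sequences(list(sequences)), model)
    eps = rng.normal(0.0, epsilon_std, size=len(e_rel)) if epsilon_std > 0 else 0.0
    kds = kd_opt * np.exp(e_rel + eps)
    return dict(zip(sequences, kds)), model


def prebound_mixture(observed_freqs: np.ndarray, gsm_freqs: np.ndarray, w_obs: float):
    """Convex combination of observed and GSM-predicted frequencies.

    Returns w_obs·observed + (1−w_obs)·gsm, renormalized to the simplex.
    """
    if not 0.0 <= w_obs <= 1.0:
        raise ValueError("w_obs must be in [0, 1]")
    observed = np.asarray(observed_freqs, dtype=float)
    gsm = np.asarray(gsm_freqs, dtype=float)
    if observed.shape != gsm.shape:
        raise ValueError("frequency vectors must cover the same sequence set")
    mix = w_obs * observed / observed.sum() + (1.0 - w_obs) * gsm / gsm.sum()
    if np.any(mix <= 0):
        raise ValueError("mixture frequency is zero for some sequence")
    return mix / mix.sum()


# ---------------------------------------------------------------------------
# experiment simulation


@dataclass
class SimulationConfig:
    """Inputs of one simulated experiment."""

    sequences: list[str]
    kds: dict[str, float]
    tf_free: float
    mean_depth_pre: float
    mean_depth_bound: float
    reference_sequences: list[str] = field(default_factory=list)
    prebound_freqs: np.ndarray | None = None  # None -> equal frequencies
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_depth_pre <= 0 or self.mean_depth_bound <= 0:
            raise ValueError("mean depths must be positive")
        if self.tf_free <= 0:
            raise ValueError("tf_free must be positive")
        missing = [s for s in self.reference_sequences if s not in self.kds]
        if missing:
            raise ValueError(f"reference sequences not in the oligo set: {missing}")


@dataclass
class SimulatedExperiment:
    """Counts plus the exact ground truth they were drawn from."""

    oligo_set: OligoSet
    true_kds: np.ndarray
    true_theta: np.ndarray
    true_B: np.ndarray
    true_P: np.ndarray
    config: SimulationConfig
    replicate: int = 0

    @property
    def true_kd_map(self) -> dict[str, float]:
        return dict(zip(self.oligo_set.sequences, self.true_kds))


def simulate_experiment(config: SimulationConfig, replicate: int = 0) -> SimulatedExperiment:
    """Equilibrate and sequence one in-silico experiment.

    Ground truth (θ, B) is exact; counts are multinomial draws whose totals
    are K x mean depth (rounded) in each fraction.  Different replicate
    indices with the same base seed yield independent count draws over
    identical ground truth.
    """
    seqs = config.sequences
    k = len(seqs)
    kds = np.array([config.kds[s] for s in seqs], dtype=float)
    p = (
        np.full(k, 1.0 / k)
        if config.prebound_freqs is None
        else np.asarray(config.prebound_freqs, dtype=float) / np.sum(config.prebound_freqs)
    )
    theta = fraction_bound(config.tf_free, kds)
    b = bound_freqs(p, theta)
    rng = np.random.default_rng((config.seed, replicate))
    n_pre = int(round(k * config.mean_depth_pre))
    n_bound = int(round(k * config.mean_depth_bound))
    pre_counts = rng.multinomial(n_pre, p)
    bound_counts = rng.multinomial(n_bound, b)
    oligo_set = OligoSet(
        sequences=list(seqs),
        pre_counts=pre_counts,
        bound_counts=bound_counts,
        reference_kds={s: config.kds[s] for s in config.reference_sequences},
    )
    return SimulatedExperiment(
        oligo_set=oligo_set,
        true_kds=kds,
        true_theta=theta,
        true_B=b,
        true_P=p,
        config=config,
        replicate=replicate,
    )


def solve_mass_balance(
    tf_total: float, kds: np.ndarray, ligand_concs: np.ndarray, tol: float = 1e-12
) -> float:
    """Optional mode: realized free TF from total TF and ligand content.

    Solves t + Σ_i L_i · t / (t + Kd_i) = tf_total by bisection (the left
    side is strictly increasing in t).
    """
    kds = np.asarray(kds, dtype=float)
    ligand = np.asarray(ligand_concs, dtype=float)

    def excess(t: float) -> float:
        return t + float(np.sum(ligand * t / (t + kds))) - tf_total

    lo, hi = 0.0, tf_total
    while hi - lo > tol * max(1.0, tf_total):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# named presets mirroring the published control designs


def _subset_neighborhood(consensus: str, n_oligos: int, rng: np.random.Generator) -> list[str]:
    """Consensus plus a reproducible sample of nearby variants."""
    pool = enumerate_neighborhood(consensus, 2)
    if n_oligos > len(pool):
        raise ValueError("requested more oligos than the neighborhood holds")
    singles = enumerate_neighborhood(consensus, 1)
    chosen = list(singles[: min(len(singles), n_oligos)])
    remaining = [s for s in pool if s not in set(chosen)]
    extra = n_oligos - len(chosen)
    if extra > 0:
        chosen += list(rng.choice(remaining, size=extra, replace=False))
    return chosen[:n_oligos]


def _landscape_preset(
    consensus: str,
    n_oligos: int,
    tf_free: float,
    mean_depth: float,
    seed: int,
    epsilon_std: float,
    term_scale: float,
    kd_opt: float,
    ref_boost: float = 10.0,
) -> SimulationConfig:
    rng = np.random.default_rng(seed)
    sequences = _subset_neighborhood(consensus, n_oligos, rng)
    term_sampler = lambda r: r.gamma(2.0, term_scale / 2.0)
    kds, _ = generate_landscape(
        sequences, consensus, term_sampler, epsilon_std, kd_opt=kd_opt, rng=rng
    )
    # references: the consensus (strong anchor, well covered in the bound
    # fraction) plus a mid-range binder whose partial occupancy carries the
    # information about the free TF concentration
    ordered = sorted(kds, key=kds.get)
    references = [consensus, ordered[3 * len(ordered) // 4]]
    # represent the references at high pre-bound frequency (variance
    # reduction for the tf/scale calibration); others stay equal-frequency
    weights = np.array([ref_boost if s in references else 1.0 for s in sequences])
    return SimulationConfig(
        sequences=sequences,
        kds=kds,
        tf_free=tf_free,
        mean_depth_pre=mean_depth,
        mean_depth_bound=mean_depth,
        reference_sequences=references,
        prebound_freqs=weights / weights.sum(),
        seed=seed,
    )


def leu3_like_preset(
    tf_free: float = 10.0, mean_depth: float = 10.0, seed: int = 0, epsilon_std: float = 0.4
) -> SimulationConfig:
    """43 oligos around a 10-mer consensus, equal pre-bound frequencies.

    tf_free grid of interest: {1, 10, 50} nM; mean depths 1-100.
    """
    return _landscape_preset(
        consensus="CCGGTACCGG",
        n_oligos=43,
        tf_free=tf_free,
        mean_depth=mean_depth,
        seed=seed,
        epsilon_std=epsilon_std,
        term_scale=1.3,
        kd_opt=10.0,
    )


def arca_like_preset(
    tf_free: float = 100.0, mean_depth: float = 20.0, seed: int = 0, epsilon_std: float = 0.1
) -> SimulationConfig:
    """46 oligos around a 15-mer consensus, nearly additive landscape.

    tf_free grid of interest: {1, 100, 1000} nM; depths {20, 100, 200, 1000}.
    """
    return _landscape_preset(
        consensus="GTTACCATTATGTTA",
        n_oligos=46,
        tf_free=tf_free,
        mean_depth=mean_depth,
        seed=seed,
        epsilon_std=epsilon_std,
        term_scale=1.4,
        kd_opt=20.0,
    )


def zif268_like_preset(
    tf_free: float = 1.0,
    mean_depth_pre: float = 1000.0,
    mean_depth_bound: float = 1000.0,
    seed: int = 0,
    epsilon_std: float = 0.3,
    gsm_model: GSMModel | None = None,
    w_obs: float = 0.8,
) -> SimulationConfig:
    """All 436 oligos within two mismatches of a 10-mer consensus.

    tf_free grid of interest: {0.1, 1, 10, 100} nM.  Pre-bound frequencies
    are skewed: 0.8 x a random draw standing in for observed frequencies
    plus 0.2 x GSM predictions when a GSM is supplied.
    """
    consensus = "GCGTGGGCGT"
    sequences = enumerate_neighborhood(consensus, 2)
    rng = np.random.default_rng(seed)
    term_sampler = lambda r: r.gamma(2.0, 0.5)
    kds, _ = generate_landscape(
        sequences, consensus, term_sampler, epsilon_std, kd_opt=0.15, rng=rng
    )
    observed = rng.dirichlet(np.full(len(sequences), 5.0))
    if gsm_model is not None:
        gsm_freqs = gsm_predicted_counts(sequences, gsm_model, strict=False)
        freqs = prebound_mixture(observed, gsm_freqs, w_obs)
    else:
        freqs = observed
    ordered = sorted(kds, key=kds.get)
    references = [consensus, ordered[1], ordered[2]]
    return SimulationConfig(
        sequences=sequences,
        kds=kds,
        tf_free=tf_free,
        mean_depth_pre=mean_depth_pre,
        mean_depth_bound=mean_depth_bound,
        reference_sequences=list(dict.fromkeys(references)),
        prebound_freqs=freqs,
        seed=seed,
    )


PRESETS = {
    "leu3_like": leu3_like_preset,
    "arca_like": arca_like_preset,
    "zif268_like": zif268_like_preset,
}

# the published design sweeps, as (tf_free grid, mean-depth grid) in nM / reads
DESIGN_GRIDS = {
    "leu3_like": {"tf_free": (1.0, 10.0, 50.0), "mean_depth": (1.0, 10.0, 100.0)},
    "arca_like": {"tf_free": (1.0, 100.0, 1000.0), "mean_depth": (20.0, 100.0, 200.0, 1000.0)},
    "zif268_like": {"tf_free": (0.1, 1.0, 10.0, 100.0), "mean_depth": (20.0, 100.0, 200.0, 1000.0)},
}
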