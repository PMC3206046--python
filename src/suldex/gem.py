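"""Generative Energy Model: additive position-specific binding energies.

A sequence's binding energy is the optimal-sequence offset plus one
non-negative term per position at which it differs from the optimal
nucleotide.  A per-sequence Gaussian residual of scale sigma absorbs
non-additivity, mediating between energy-model predictions and pure
count-based estimates.  An indicator matrix delta toggles individual terms
in and out of the model (reversible-jump moves live in :mod:`suldex.mcmc`);
hooks for interactive (higher-order) terms exist but the sampler constrains
them to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bbm import BBMData, bbm_log_likelihood
from .binding_core import BindingState

__all__ = [
    "NUCLEOTIDES",
    "encode_sequence",
    "encode_sequences",
    "EnergyModel",
    "GEMState",
    "additive_energy",
    "residuals",
    "gem_log_likelihood",
    "inclusion_probability",
]

NUCLEOTIDES = "ACGT"
_CODE = {nt: i for i, nt in enumerate(NUCLEOTIDES)}

LOG_2PI = float(np.log(2.0 * np.pi))


def encode_sequence(sequence: str) -> np.ndarray:
    """Integer codes (A,C,G,T -> 0..3) for one sequence."""
    try:
        return np.array([_CODE[ch] for ch in sequence], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in {sequence!r}") from None


def encode_sequences(sequences) -> np.ndarray:
    """K x L integer code matrix for a list of equal-length sequences."""
    return np.vstack([encode_sequence(s) for s in sequences])


@dataclass
class EnergyModel:
    """Additive energy terms anchored at zero on the optimal nucleotide.

    Attributes
    ----------
    optimal_sequence
        The consensus / optimal sequence; its per-position entries in
        ``terms`` are structurally zero.
    e0
        Energy offset of the optimal sequence (RT units); maps to Kd_opt.
    terms
        L x 4 matrix of non-negative position-specific energies.
    indicators
        L x 4 binary inclusion matrix delta; an excluded term is zero.
    sigma
        Scale of the per-sequence Gaussian residual, > 0.
    testable_mask
        L x 4 booleans marking (position, nucleotide) combinations that occur
        in the data; untested cells carry no information.
    """

    optimal_sequence: str
    e0: float = 0.0
    terms: np.ndarray | None = None
    indicators: np.ndarray | None = None
    sigma: float = 0.3
    testable_mask: np.ndarray | None = None
    interaction_terms: dict = field(default_factory=dict)  # scaffold hook, kept zero

    def __post_init__(self) -> None:
        self.opt_codes = encode_sequence(self.optimal_sequence)
        length = len(self.optimal_sequence)
        if self.terms is None:
            self.terms = np.zeros((length, 4))
        self.terms = np.asarray(self.terms, dtype=float)
        if self.terms.shape != (length, 4):
            raise ValueError(f"terms must be {length} x 4")
        if self.indicators is None:
            self.indicators = (self.terms > 0).astype(int)
        self.indicators = np.asarray(self.indicators, dtype=int)
        if self.testable_mask is None:
            self.testable_mask = np.ones((length, 4), dtype=bool)
        self.testable_mask = np.asarray(self.testable_mask, dtype=bool)
        self.validate()

    def validate(self) -> None:
        if np.any(self.terms < 0):
            raise ValueError("energy terms must be non-negative")
        pos = np.arange(len(self.opt_codes))
        if np.any(self.terms[pos, self.opt_codes] != 0):
            raise ValueError("optimal-nucleotide entries must be zero")
        if np.any(self.terms[self.indicators == 0] != 0):
            raise ValueError("excluded terms must be zero")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if any(v != 0 for v in self.interaction_terms.values()):
            raise ValueError("interactive energy terms are constrained to zero")

    @property
    def length(self) -> int:
        return len(self.optimal_sequence)

    def anchor_mask(self) -> np.ndarray:
        """L x 4 booleans: True at the optimal nucleotide of each position."""
        mask = np.zeros((self.length, 4), dtype=bool)
        mask[np.arange(self.length), self.opt_codes] = True
        return mask

    def toggleable_mask(self) -> np.ndarray:
        """Cells eligible for reversible-jump moves: testable, non-anchor."""
        return self.testable_mask & ~self.anchor_mask()


@dataclass
class GEMState:
    """A binding state paired with an energy model and its Kd_opt anchor."""

    binding_state: BindingState
    energy_model: EnergyModel
    kd_opt: float = 1.0

    def residual_vector(self, sequences) -> np.ndarray:
        return residuals(self.binding_state, self.energy_model, sequences, self.kd_opt)


def additive_energy(sequence, model: EnergyModel):
    """e0 + sum of the position-specific terms selected by the sequence.

    ``sequence`` may be a string or an encoded int array; a K x L code matrix
    yields a vector of energies.
    """
    if isinstance(sequence, str):
        codes = encode_sequence(sequence)
    else:
        codes = np.asarray(sequence)
    if codes.ndim == 1:
        if len(codes) != model.length:
            raise ValueError("sequence length does not match the model")
        return model.e0 + float(model.terms[np.arange(model.length), codes].sum())
    if codes.shape[1] != model.length:
        raise ValueError("sequence length does not match the model")
    return model.e0 + model.terms[np.arange(model.length), codes].sum(axis=1)


def residuals(binding_state: BindingState, model: EnergyModel, sequences, kd_opt: float):
    """Per-sequence ε = ln(Kd_i / Kd_opt) − (additive energy − e0).

    Zero everywhere when the Kds sit exactly on the additive model.
    Reference sequences contribute residuals like any other (their Kds are
    data-like constants).
    """
    codes = sequences if isinstance(sequences, np.ndarray) else encode_sequences(sequences)
    observed = np.log(binding_state.kds / kd_opt)
    predicted = additive_energy(codes, model) - model.e0
    return observed - predicted


def gem_log_likelihood(state: GEMState, data: BBMData, codes: np.ndarray | None = None) -> float:
    """BBM log-likelihood plus the Gaussian residual penalty.

    Returns ``-inf`` for sigma <= 0 (a rejected state).
    """
    model = state.energy_model
    if model.sigma <= 0:
        return -np.inf
    base = bbm_log_likelihood(state.binding_state, data)
    if not np.isfinite(base):
        return base
    if codes is None:
        codes = encode_sequences(data.oligo_set.sequences)
    eps = residuals(state.binding_state, model, codes, state.kd_opt)
    k = len(eps)
    penalty = -0.5 * k * LOG_2PI - k * np.log(model.sigma) - float(
        np.sum(eps**2)
    ) / (2.0 * model.sigma**2)
    return base + penalty


def inclusion_probability(delta_samples, testable_mask=None):
    """Posterior inclusion probability per (position, nucleotide) term.

    Parameters
    ----------
    delta_samples
        Array of shape (n_samples, L, 4) of 0/1 indicator draws.
    testable_mask
        Optional L x 4 booleans; untested cells are returned as NaN
        (no information) rather than 0.
    """
    delta_samples = np.asarray(delta_samples)
    if delta_samples.ndim != 3 or delta_samples.shape[0] < 1:
        raise ValueError("need at least one post-burn-in sample of shape (n, L, 4)")
    prob = delta_samples.mean(axis=0).astype(float)
    if testable_mask is not None:
        prob = np.where(np.asarray(testable_mask, dtype=bool), prob, np.nan)
    return prob
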