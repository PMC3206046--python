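"""Generative Sequence Model: order-m Markov prediction of pool counts.

Ligand pools are rarely synthesized at their nominal frequencies.  The GSM
predicts the count of any full-length oligo from the count-weighted
frequency of its first m-mer and the conditional probabilities of each
subsequent nucleotide given the preceding m-mer context.  By default
transition counts are pooled across positions (position-homogeneous chain);
a position-conditioned variant is available.

The GSM is used for simulation-input generation and optional frequency
smoothing; it never silently replaces observed counts in a likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GSMModel",
    "fit_gsm",
    "default_order",
    "gsm_predicted_count",
    "gsm_predicted_counts",
    "gsm_rmse",
    "write_gsm",
    "read_gsm",
]

_NTS = "ACGT"
_NT_INDEX = {nt: i for i, nt in enumerate(_NTS)}


class MissingContextError(KeyError):
    """Raised when a sequence traverses a context absent from the model."""


@dataclass
class GSMModel:
    """Start-frequency and transition tables of an order-m Markov chain.

    ``transitions`` maps an m-mer context to a 4-vector of next-nucleotide
    probabilities (A, C, G, T); with ``position_specific`` fits the keys are
    ``(position, context)`` tuples instead.
    """

    order: int
    start_freqs: dict[str, float]
    transitions: dict
    n_total: float
    position_specific: bool = False
    fallback: "GSMModel | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        total = sum(self.start_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("start frequencies must sum to 1")
        for ctx, vec in self.transitions.items():
            if abs(float(np.sum(vec)) - 1.0) > 1e-9:
                raise ValueError(f"transition vector for context {ctx!r} must sum to 1")


def fit_gsm(
    counts: dict[str, float],
    m: int,
    position_specific: bool = False,
    with_fallback: bool = False,
) -> GSMModel:
    """Fit an order-m GSM from count-weighted polynucleotide frequencies.

    Parameters
    ----------
    counts
        Map from uniform-length sequence to its (positive) count.
    m
        Polynucleotide (context) length; must satisfy 1 <= m < L.
    position_specific
        Condition transition frequencies on position instead of pooling.
    with_fallback
        Recursively fit orders m-1, ..., 1 for missing-context backoff.
    """
    if not counts:
        raise ValueError("empty input")
    lengths = {len(s) for s in counts}
    if len(lengths) != 1:
        raise ValueError("sequences must have uniform length")
    length = lengths.pop()
    if not 1 <= m < length:
        raise ValueError(f"order m must satisfy 1 <= m < L = {length}")
    n_total = float(sum(counts.values()))
    if n_total <= 0:
        raise ValueError("total count must be positive")

    start: dict[str, float] = {}
    trans_counts: dict = {}
    for seq, c in counts.items():
        if c < 0:
            raise ValueError("counts must be non-negative")
        start[seq[:m]] = start.get(seq[:m], 0.0) + c
        for k in range(m, length):
            ctx = seq[k - m : k]
            key = (k, ctx) if position_specific else ctx
            vec = trans_counts.setdefault(key, np.zeros(4))
            vec[_NT_INDEX[seq[k]]] += c
    start_freqs = {kmer: c / n_total for kmer, c in start.items()}
    transitions = {key: vec / vec.sum() for key, vec in trans_counts.items()}
    fallback = None
    if with_fallback and m > 1:
        fallback = fit_gsm(counts, m - 1, position_specific=position_specific, with_fallback=True)
    return GSMModel(
        order=m,
        start_freqs=start_freqs,
        transitions=transitions,
        n_total=n_total,
        position_specific=position_specific,
        fallback=fallback,
    )


def default_order(counts: dict[str, float], min_counts_per_context: float = 100.0) -> int:
    """Largest m with at most n_total / min_counts_per_context distinct (m+1)-mers.

    Operationalizes "the longest polynucleotide that can be accurately
    measured": each possible (m+1)-mer should be observable ~100 times on
    average.
    """
    length = len(next(iter(counts)))
    n_total = float(sum(counts.values()))
    m = 1
    while m + 1 < length and 4 ** (m + 2) <= n_total / min_counts_per_context:
        m += 1
    return m


def _transition_prob(model: GSMModel, position: int, context: str, nt: str, strict: bool):
    key = (position, context) if model.position_specific else context
    vec = model.transitions.get(key)
    if vec is not None:
        return float(vec[_NT_INDEX[nt]])
    if strict or model.fallback is None:
        raise MissingContextError(
            f"context {context!r} at position {position} not present in the "
            f"order-{model.order} model"
        )
    return _transition_prob(model.fallback, position, context[1:], nt, strict)


def gsm_predicted_count(sequence: str, model: GSMModel, strict: bool = True) -> float:
    """Predicted count: n_total x start(first m-mer) x product of transitions."""
    m = model.order
    if len(sequence) <= m:
        raise ValueError("sequence must be longer than the model order")
    prob = model.start_freqs.get(sequence[:m])
    if prob is None:
        if strict or model.fallback is None:
            raise MissingContextError(f"start {sequence[:m]!r} not present in the model")
        # Back off the start term: order m-1 start times its transition into
        # position m-1.
        return gsm_predicted_count(sequence, model.fallback, strict=strict)
    for k in range(m, len(sequence)):
        prob *= _transition_prob(model, k, sequence[k - m : k], sequence[k], strict)
    return model.n_total * prob


def gsm_predicted_counts(sequences, model: GSMModel, strict: bool = True) -> np.ndarray:
    return np.array([gsm_predicted_count(s, model, strict=strict) for s in sequences])


def gsm_rmse(model: GSMModel, observed: dict[str, float], strict: bool = True) -> float:
    """RMSE of relative prediction errors, as a percentage.

    Scores sqrt(mean(((predicted - observed) / observed)^2)) x 100 over the
    given sequences; every observed count must be positive (the metric is
    only meaningful for accurately countable oligos).
    """
    if any(c <= 0 for c in observed.values()):
        raise ValueError("observed counts must be positive for all scored sequences")
    seqs = list(observed)
    predicted = gsm_predicted_counts(seqs, model, strict=strict)
    obs = np.array([observed[s] for s in seqs], dtype=float)
    rel = (predicted - obs) / obs
    return float(np.sqrt(np.mean(rel**2)) * 100.0)


def write_gsm(model: GSMModel, transitions_path, start_path) -> None:
    """Serialize as two TSV tables: (context, A, C, G, T) and (kmer, freq)."""
    rows = []
    for key, vec in sorted(model.transitions.items(), key=lambda kv: str(kv[0])):
        if model.position_specific:
            pos, ctx = key
        else:
            pos, ctx = -1, key
        rows.append({"position": pos, "context": ctx, **{nt: vec[i] for i, nt in enumerate(_NTS)}})
    pd.DataFrame(rows).to_csv(transitions_path, sep="\t", index=False)
    start = pd.DataFrame(
        sorted(model.start_freqs.items()), columns=["kmer", "frequency"]
    )
    start.insert(0, "n_total", model.n_total)
    start.to_csv(start_path, sep="\t", index=False)


def read_gsm(transitions_path, start_path) -> GSMModel:
    trans_df = pd.read_csv(transitions_path, sep="\t", dtype={"context": str})
    start_df = pd.read_csv(start_path, sep="\t", dtype={"kmer": str})
    position_specific = bool((trans_df["position"] >= 0).any())
    transitions = {}
    for _, row in trans_df.iterrows():
        vec = np.array([row[nt] for nt in _NTS], dtype=float)
        key = (int(row["position"]), row["context"]) if position_specific else row["context"]
        transitions[key] = vec
    start_freqs = dict(zip(start_df["kmer"], start_df["frequency"].astype(float)))
    order = len(next(iter(start_freqs)))
    return GSMModel(
        order=order,
        start_freqs=start_freqs,
        transitions=transitions,
        n_total=float(start_df["n_total"].iloc[0]),
        position_specific=position_specific,
    )
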