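"""Equilibrium binding mathematics.

Relates dissociation constants (Kd, nM), free transcription-factor
concentration (nM), per-sequence binding probabilities and the pre-bound /
bound frequency vectors of a ligand pool, together with the map between Kd
and dimensionless (RT-unit) binding energies.

All concentrations are in nM throughout the package; energies are natural-log
ratios of Kds and therefore dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OligoSet",
    "BindingState",
    "fraction_bound",
    "bound_freqs",
    "calibrate_from_references",
    "kd_from_freqs",
    "kd_to_energy",
    "energy_to_kd",
]

_ALPHABET = frozenset("ACGT")


def _validate_sequences(sequences: list[str]) -> int:
    if not sequences:
        raise ValueError("empty sequence set")
    length = len(sequences[0])
    seen = set()
    for seq in sequences:
        if len(seq) != length:
            raise ValueError(
                f"ragged sequence lengths: expected {length}, got {len(seq)} for {seq!r}"
            )
        if not _ALPHABET.issuperset(seq):
            raise ValueError(f"invalid characters in sequence {seq!r}")
        if seq in seen:
            raise ValueError(f"duplicate sequence {seq!r}")
        seen.add(seq)
    return length


@dataclass
class OligoSet:
    """A pool of fixed-length ds-oligos with paired sequencing counts.

    Parameters
    ----------
    sequences
        Fixed-length DNA strings over {A, C, G, T}; unique.
    pre_counts
        Non-negative integer counts in the pre-bound fraction, one per
        sequence.
    bound_counts
        Non-negative integer counts in the bound fraction, one per sequence.
    reference_kds
        Known dissociation constants (nM) for a subset of the sequences.
    """

    sequences: list[str]
    pre_counts: np.ndarray
    bound_counts: np.ndarray
    reference_kds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.length = _validate_sequences(self.sequences)
        self.pre_counts = np.asarray(self.pre_counts)
        self.bound_counts = np.asarray(self.bound_counts)
        k = len(self.sequences)
        for name, vec in (("pre_counts", self.pre_counts), ("bound_counts", self.bound_counts)):
            if vec.shape != (k,):
                raise ValueError(f"{name} must have one entry per sequence")
            if np.any(vec < 0):
                raise ValueError(f"{name} must be non-negative")
        members = set(self.sequences)
        for seq, kd in self.reference_kds.items():
            if seq not in members:
                raise ValueError(f"reference sequence {seq!r} not in the oligo set")
            if kd <= 0:
                raise ValueError(f"reference Kd for {seq!r} must be positive, got {kd}")
        self._index = {s: i for i, s in enumerate(self.sequences)}

    @property
    def n_oligos(self) -> int:
        return len(self.sequences)

    def index_of(self, sequence: str) -> int:
        return self._index[sequence]

    @property
    def reference_indices(self) -> np.ndarray:
        return np.array([self._index[s] for s in self.reference_kds], dtype=int)


@dataclass
class BindingState:
    """Free parameters of the binding model plus derived quantities.

    Free parameters are the pre-bound frequency simplex ``prebound_freqs``,
    the per-sequence dissociation constants ``kds`` (reference entries fixed
    at their known values) and the free TF concentration ``tf_free``.  The
    binding probabilities ``theta`` and bound frequencies ``bound_freqs`` are
    derived.
    """

    prebound_freqs: np.ndarray
    kds: np.ndarray
    tf_free: float
    tf_total: float | None = None
    ref_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.prebound_freqs = np.asarray(self.prebound_freqs, dtype=float)
        self.kds = np.asarray(self.kds, dtype=float)
        if self.ref_mask is None:
            self.ref_mask = np.zeros(len(self.kds), dtype=bool)
        self.validate()

    def validate(self) -> None:
        p = self.prebound_freqs
        if np.any(p <= 0):
            raise ValueError("pre-bound frequencies must be strictly positive")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("pre-bound frequencies must sum to 1")
        if np.any(self.kds <= 0):
            raise ValueError("dissociation constants must be positive")
        if self.tf_free <= 0:
            raise ValueError("tf_free must be positive")
        if self.tf_total is not None and not self.tf_free < self.tf_total:
            raise ValueError("tf_free must be below tf_total")

    @property
    def theta(self) -> np.ndarray:
        return fraction_bound(self.tf_free, self.kds)

    @property
    def bound_freqs(self) -> np.ndarray:
        return bound_freqs(self.prebound_freqs, self.theta)


def fraction_bound(tf_free, kd):
    """Binding probability θ = [TF] / ([TF] + Kd) of the hyperbolic isotherm.

    Accepts scalars or arrays; both arguments must be strictly positive.
    """
    tf_free = np.asarray(tf_free, dtype=float)
    kd = np.asarray(kd, dtype=float)
    if np.any(tf_free <= 0):
        raise ValueError("tf_free must be positive")
    if np.any(kd <= 0):
        raise ValueError("kd must be positive")
    theta = tf_free / (tf_free + kd)
    return float(theta) if theta.ndim == 0 else theta


def bound_freqs(P, theta):
    """Bound-fraction frequencies B_i = P_i θ_i / Σ_j P_j θ_j."""
    P = np.asarray(P, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if P.shape != theta.shape:
        raise ValueError("P and theta must have equal lengths")
    w = P * theta
    z = w.sum()
    if z <= 0:
        raise ValueError("all-zero numerator: no sequence has binding weight")
    return w / z


def calibrate_from_references(P, B, refs):
    """Solve for (tf_free, enrichment_scale) from reference enrichments.

    Each reference with known Kd supplies one instance of the relation
    θ_i = s · (B_i / P_i) with θ_i = t / (t + Kd_i), where s is the common
    proportionality constant (the bound-weight normalizer) and t the free TF
    concentration.  Writing r_i = B_i / P_i this is linear in (s, s/t):

        1 / r_i = s + (s / t) · Kd_i

    so two references with distinct Kds determine the system exactly and more
    references give a least-squares solution.

    Parameters
    ----------
    P, B
        Full frequency vectors (reference entries must be strictly positive).
    refs
        Sequence of ``(index, kd)`` pairs into P and B.

    Returns
    -------
    (tf_free, enrichment_scale, residual)
        ``residual`` is the root-mean-square misfit of ``1/r_i`` (zero for an
        exactly determined or consistent system).
    """
    P = np.asarray(P, dtype=float)
    B = np.asarray(B, dtype=float)
    refs = list(refs)
    if len(refs) < 2:
        raise ValueError("at least 2 references are required for calibration")
    idx = np.array([i for i, _ in refs], dtype=int)
    kds = np.array([kd for _, kd in refs], dtype=float)
    if np.any(P[idx] <= 0) or np.any(B[idx] <= 0):
        raise ValueError("reference entries of P and B must be strictly positive")
    r = B[idx] / P[idx]
    if np.ptp(kds) == 0 or np.ptp(r) == 0:
        raise np.linalg.LinAlgError(
            "degenerate reference system: identical Kds or identical enrichments"
        )
    design = np.column_stack([np.ones_like(kds), kds])
    y = 1.0 / r
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    s, s_over_t = coef
    if s <= 0 or s_over_t <= 0:
        raise np.linalg.LinAlgError(
            "calibration produced non-positive scale; references are inconsistent"
        )
    tf_free = s / s_over_t
    residual = float(np.sqrt(np.mean((design @ coef - y) ** 2)))
    return float(tf_free), float(s), residual


def kd_from_freqs(p_i, b_i, tf_free, enrichment_scale):
    """Invert the frequency transformation to a dissociation constant.

    θ_i = enrichment_scale · (b_i / p_i) must land strictly inside (0, 1);
    otherwise the frequencies are inconsistent with the calibration and an
    error is raised rather than silently clamping.
    """
    p_i = np.asarray(p_i, dtype=float)
    b_i = np.asarray(b_i, dtype=float)
    if np.any(p_i <= 0) or np.any(b_i <= 0):
        raise ValueError("frequencies must be strictly positive")
    if tf_free <= 0:
        raise ValueError("tf_free must be positive")
    theta = enrichment_scale * b_i / p_i
    if np.any(theta >= 1.0):
        raise ValueError(
            "implied binding probability >= 1; frequencies are inconsistent "
            "with the calibration"
        )
    kd = tf_free * (1.0 - theta) / theta
    return float(kd) if kd.ndim == 0 else kd


def kd_to_energy(kd, kd_opt):
    """Dimensionless binding energy ln(Kd / Kd_opt) relative to the optimum."""
    kd = np.asarray(kd, dtype=float)
    if np.any(kd <= 0) or kd_opt <= 0:
        raise ValueError("dissociation constants must be positive")
    e = np.log(kd / kd_opt)
    return float(e) if e.ndim == 0 else e


def energy_to_kd(energy, kd_opt):
    """Inverse of :func:`kd_to_energy`: Kd = Kd_opt · exp(energy)."""
    if kd_opt <= 0:
        raise ValueError("kd_opt must be positive")
    kd = kd_opt * np.exp(np.asarray(energy, dtype=float))
    return float(kd) if kd.ndim == 0 else kd
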