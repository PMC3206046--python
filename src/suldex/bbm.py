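"""Basic Binding Model: multinomial count likelihood over both fractions.

The observed pre-bound and bound counts are modelled as multinomial draws
from the parametric frequency vectors P and B, where B is derived from
{P, Kd, tf_free} through the binding isotherm.  Multinomial normalization
constants are dropped throughout (they are constant in the parameters), so
log-likelihood values are comparable only as differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .binding_core import (
    BindingState,
    OligoSet,
    bound_freqs,
    calibrate_from_references,
    fraction_bound,
    kd_to_energy,
)

__all__ = ["BBMData", "bbm_log_likelihood", "initialize_state", "derived_parameters"]


@dataclass
class BBMData:
    """An oligo set together with the total counts of each fraction."""

    oligo_set: OligoSet
    n_pre: int | None = None
    n_bound: int | None = None

    def __post_init__(self) -> None:
        c_total = int(self.oligo_set.pre_counts.sum())
        d_total = int(self.oligo_set.bound_counts.sum())
        if self.n_pre is None:
            self.n_pre = c_total
        elif self.n_pre != c_total:
            raise ValueError(f"n_pre {self.n_pre} != sum of pre_counts {c_total}")
        if self.n_bound is None:
            self.n_bound = d_total
        elif self.n_bound != d_total:
            raise ValueError(f"n_bound {self.n_bound} != sum of bound_counts {d_total}")


def bbm_log_likelihood(state: BindingState, data: BBMData) -> float:
    """Constant-free multinomial log-likelihood Σ C_i ln P_i + Σ D_i ln B_i.

    Returns ``-inf`` (a rejected state, not an exception) whenever a
    parametric frequency is non-positive where a count is non-zero, and for
    states violating the tf_total bound.
    """
    c = data.oligo_set.pre_counts
    d = data.oligo_set.bound_counts
    p = state.prebound_freqs
    if state.tf_total is not None and state.tf_free >= state.tf_total:
        return -np.inf
    if np.any(p <= 0):
        return -np.inf
    b = state.bound_freqs
    if np.any(b <= 0):
        return -np.inf
    return float(np.dot(c, np.log(p)) + np.dot(d, np.log(b)))


def initialize_state(
    data: BBMData,
    pseudocount: float = 0.5,
    tf_free: float | None = None,
    tf_total: float | None = None,
) -> BindingState:
    """Build a valid starting state from pseudocount-smoothed frequencies.

    P is initialized to (C_i + pc) / (N_C + K·pc); tf_free and the enrichment
    scale come from reference calibration on the smoothed frequencies (or
    from the supplied fixed value), and the non-reference Kds from inverting
    the frequency transformation.  Implied binding probabilities are clamped
    into (0, 1) here — initialization only — so that noisy data always yield
    a valid state.
    """
    oligos = data.oligo_set
    k = oligos.n_oligos
    refs = oligos.reference_kds
    if len(refs) < 2 and tf_free is None:
        raise ValueError(
            "identifiability requires at least 2 reference sequences, or 1 "
            "reference plus a fixed tf_free"
        )
    if len(refs) < 1:
        raise ValueError("at least one reference sequence is required")

    c = oligos.pre_counts
    d = oligos.bound_counts
    p = (c + pseudocount) / (data.n_pre + k * pseudocount)
    b_hat = (d + pseudocount) / (data.n_bound + k * pseudocount)

    ref_items = [(oligos.index_of(s), kd) for s, kd in refs.items()]
    if tf_free is None:
        try:
            tf_free, scale, _ = calibrate_from_references(p, b_hat, ref_items)
        except np.linalg.LinAlgError:
            # Noisy references can defeat the linear solve; fall back to a
            # mid-scale guess anchored on the strongest reference.
            tf_free = min(kd for _, kd in ref_items)
            i0, kd0 = ref_items[0]
            scale = fraction_bound(tf_free, kd0) * p[i0] / b_hat[i0]
    else:
        i0, kd0 = ref_items[0]
        scale = fraction_bound(tf_free, kd0) * p[i0] / b_hat[i0]
    if tf_total is not None and tf_free >= tf_total:
        tf_free = 0.5 * tf_total

    theta = np.clip(scale * b_hat / p, 1e-9, 1.0 - 1e-9)
    kds = tf_free * (1.0 - theta) / theta
    ref_mask = np.zeros(k, dtype=bool)
    for i, kd in ref_items:
        kds[i] = kd
        ref_mask[i] = True
    return BindingState(
        prebound_freqs=p, kds=kds, tf_free=tf_free, tf_total=tf_total, ref_mask=ref_mask
    )


def derived_parameters(state: BindingState):
    """Derived (θ, B, energies) with energies anchored at the minimum Kd."""
    theta = fraction_bound(state.tf_free, state.kds)
    b = bound_freqs(state.prebound_freqs, theta)
    kd_opt = float(state.kds.min())
    energies = kd_to_energy(state.kds, kd_opt)
    return theta, b, energies
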