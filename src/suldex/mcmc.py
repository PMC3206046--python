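"""Metropolis-Hastings engine with proposal tuning and reversible jumps.

Flat priors and symmetric proposals are used throughout, so the acceptance
ratio is the likelihood ratio except where an explicit Hastings/measure
correction is required (simplex renormalization moves, log-scale proposals
for sigma under its flat linear-scale prior).  Dissociation constants and
the free TF concentration are sampled on the log scale with flat priors on
that scale; energy terms are sampled on the natural scale, reflected at
zero, with a uniform prior on [0, w_E] that doubles as the reversible-jump
birth distribution so that model-occupancy ratios estimate Bayes factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bbm import BBMData, initialize_state
from .binding_core import BindingState
from .gem import LOG_2PI, EnergyModel, GEMState, encode_sequences

__all__ = [
    "MCMCConfig",
    "ChainResult",
    "ProposalBlock",
    "mh_step",
    "frequency_move",
    "joint_frequency_move",
    "tune_width",
    "tune_proposals",
    "convergence_ratio",
    "rj_step",
    "BBMSampler",
    "GEMSampler",
    "fit_bbm",
    "fit_gem",
]


# ---------------------------------------------------------------------------
# configuration & results


@dataclass
class MCMCConfig:
    """Chain-length, tuning and reversible-jump settings."""

    n_generations: int = 100_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    n_chains: int = 2
    proposal_widths: dict = field(default_factory=dict)
    target_acceptance_1d: float = 0.45
    target_acceptance_multi: float = 0.234
    tune_interval: int = 200
    rj_birth_width: float = 3.0  # w_E, RT units; spans the largest plausible terms
    rj_refine_steps: int = 10  # N_r fixed-dimension refinement steps per jump
    rj_moves_per_generation: int = 0  # 0 -> one per toggleable term block sweep
    # Flat prior support on log Kd / log tf_free, in nM.  None -> derived
    # from the reference Kds as [min_ref / window, max_ref * window]: with
    # fully unbounded flat log-scale priors the posterior is improper along
    # the ridge where tf_free and all free Kds grow together (reference
    # binding saturates), so bounds anchored to the measurable window are
    # part of the model, not a numerical convenience.
    kd_bounds: tuple | None = None
    tf_bounds: tuple | None = None
    prior_window: float = 1e3
    sigma_bounds: tuple = (1e-4, 1e3)

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_generations:
            raise ValueError("burn_in must be smaller than n_generations")
        if self.thin < 1 or self.rj_refine_steps < 1:
            raise ValueError("thin and rj_refine_steps must be >= 1")
        for w in self.proposal_widths.values():
            if w <= 0:
                raise ValueError("proposal widths must be positive")


@dataclass
class ChainResult:
    """Posterior draws plus per-block acceptance and convergence statistics."""

    samples: dict
    acceptance_rates: dict
    log_lik_trace: np.ndarray
    config: MCMCConfig
    convergence: dict = field(default_factory=dict)
    chains: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.log_lik_samples)

    @property
    def log_lik_samples(self) -> np.ndarray:
        return self.samples["log_lik"]


# ---------------------------------------------------------------------------
# generic Metropolis-Hastings machinery


@dataclass
class ProposalBlock:
    """A named scalar proposal on an unconstrained scale.

    Modes: ``linear`` (additive Gaussian), ``log`` (symmetric in log space,
    flat prior on the log scale), ``log_jacobian`` (log-space proposal with a
    flat prior on the *linear* scale, contributing the +ln(v'/v) correction),
    ``reflect`` (additive Gaussian reflected at zero).
    """

    key: str
    width: float
    mode: str = "linear"
    lower: float = -np.inf
    upper: float = np.inf

    def propose(self, value: float, rng) -> tuple[float, float]:
        z = rng.normal(0.0, self.width)
        if self.mode == "linear":
            return value + z, 0.0
        if self.mode == "log":
            return value * math.exp(z), 0.0
        if self.mode == "log_jacobian":
            new = value * math.exp(z)
            return new, math.log(new / value)
        if self.mode == "reflect":
            return abs(value + z), 0.0
        raise ValueError(f"unknown proposal mode {self.mode!r}")

    def in_bounds(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def mh_step(state: dict, log_lik_fn, proposal_block: ProposalBlock, rng) -> tuple[dict, bool]:
    """One Metropolis-Hastings update of a single scalar block.

    Accepts with probability min(1, exp(Δ log-lik + Δ log-Hastings)); a
    rejected proposal returns the input state object unchanged (bit-exact).
    A NaN log-likelihood is a hard failure with a state dump.
    """
    current_ll = log_lik_fn(state)
    if math.isnan(current_ll):
        raise RuntimeError(f"NaN log-likelihood at state {state!r}")
    value = state[proposal_block.key]
    new_value, log_hastings = proposal_block.propose(value, rng)
    if not proposal_block.in_bounds(new_value):
        return state, False
    proposal = dict(state)
    proposal[proposal_block.key] = new_value
    new_ll = log_lik_fn(proposal)
    if math.isnan(new_ll):
        raise RuntimeError(f"NaN log-likelihood at proposed state {proposal!r}")
    if math.log(rng.uniform()) < new_ll - current_ll + log_hastings:
        return proposal, True
    return state, False


def frequency_move(P, index: int, width: float, rng):
    """Perturb one log-frequency of a simplex vector and renormalize.

    Returns the proposed simplex vector and the exact log correction needed
    for detailed balance with respect to densities on the uniform simplex
    measure.  The move multiplies the selected component's odds by a
    log-normal factor; the combined proposal-asymmetry and fiber-measure
    correction is Σ ln P'_j − Σ ln P_j (so a flat simplex density is
    sampled by accepting with probability min(1, exp(correction))).
    """
    P = np.asarray(P, dtype=float)
    z = rng.normal(0.0, width)
    raw = P.copy()
    raw[index] = P[index] * math.exp(z)
    new = raw / raw.sum()
    log_hastings = float(np.log(new).sum() - np.log(P).sum())
    return new, log_hastings


def joint_frequency_move(P, width: float, rng):
    """Perturb all log-frequencies simultaneously and renormalize.

    Symmetric in log-ratio coordinates; the correction for the uniform
    simplex measure is again Σ ln P'_j − Σ ln P_j.
    """
    P = np.asarray(P, dtype=float)
    z = rng.normal(0.0, width, size=P.shape)
    raw = P * np.exp(z)
    new = raw / raw.sum()
    log_hastings = float(np.log(new).sum() - np.log(P).sum())
    return new, log_hastings


def tune_width(width: float, acceptance: float, target: float) -> float:
    """Multiplicative width adaptation toward a target acceptance rate."""
    factor = math.exp(2.0 * (acceptance - target))
    return width * min(3.0, max(1.0 / 3.0, factor))


def tune_proposals(trace: dict, targets: dict, widths: dict) -> dict:
    """Adapt every block's width from its recorded acceptance indicators.

    ``trace`` maps block name to a sequence of 0/1 acceptance outcomes (or a
    scalar rate); ``targets`` maps block name to its target acceptance.
    """
    new_widths = dict(widths)
    for name, outcomes in trace.items():
        rate = float(np.mean(outcomes))
        new_widths[name] = tune_width(widths[name], rate, targets[name])
    return new_widths


def convergence_ratio(chains) -> np.ndarray | float:
    """Gelman-Rubin-style potential scale reduction from >= 2 chains.

    ``chains`` is a list of equal-length 1-D (or (n, p)) sample arrays.
    Returns sqrt(Var+ / W), approximately 1 at convergence.
    """
    arrays = [np.asarray(c, dtype=float) for c in chains]
    if len(arrays) < 2:
        raise ValueError("convergence assessment requires at least 2 chains")
    if len({a.shape for a in arrays}) != 1:
        raise ValueError("chains must have equal lengths")
    stacked = np.stack(arrays)  # (m, n) or (m, n, p)
    n = stacked.shape[1]
    within = stacked.var(axis=1, ddof=1).mean(axis=0)
    between_over_n = stacked.mean(axis=1).var(axis=0, ddof=1)
    var_plus = (n - 1) / n * within + between_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / within)
    rhat = np.where((within == 0) & (between_over_n == 0), 1.0, rhat)
    return float(rhat) if rhat.ndim == 0 else rhat


# ---------------------------------------------------------------------------
# BBM sampler

_LN = math.log


class BBMSampler:
    """Fast in-place sampler for the basic binding model.

    Free parameters: non-reference log-Kds (one scalar block each), the free
    TF concentration (log scale, unless fixed) and the pre-bound frequency
    simplex (one joint block, unless fixed).
    """

    def __init__(
        self,
        data: BBMData,
        config: MCMCConfig,
        tf_free: float | None = None,
        tf_total: float | None = None,
        fix_freqs: bool = False,
        fix_tf: bool = False,
        fix_kds: bool = False,
        initial_state: BindingState | None = None,
    ):
        self.data = data
        self.config = config
        self.oligos = data.oligo_set
        self.C = data.oligo_set.pre_counts.astype(float)
        self.D = data.oligo_set.bound_counts.astype(float)
        self.ND = float(self.D.sum())
        self.K = self.oligos.n_oligos
        self.fix_freqs = fix_freqs
        self.fix_tf = fix_tf or tf_free is not None
        self.fix_kds = fix_kds
        if initial_state is None:
            initial_state = initialize_state(data, tf_free=tf_free, tf_total=tf_total)
        self.initial_state = initial_state
        self.tf_total = initial_state.tf_total
        self.ref_mask = initial_state.ref_mask
        self.free_kd_idx = (
            np.array([], dtype=int) if fix_kds else np.where(~self.ref_mask)[0]
        )
        ref_kds = list(self.oligos.reference_kds.values())
        window = config.prior_window
        if config.kd_bounds is None and ref_kds:
            kd_bounds = (min(ref_kds) / window, max(ref_kds) * window)
        elif config.kd_bounds is None:
            kd_bounds = (1e-4, 1e7)
        else:
            kd_bounds = config.kd_bounds
        tf_bounds = kd_bounds if config.tf_bounds is None else config.tf_bounds
        self.kd_bounds = kd_bounds
        self.log_kd_lo, self.log_kd_hi = (math.log(b) for b in kd_bounds)
        self.log_tf_lo, self.log_tf_hi = (math.log(b) for b in tf_bounds)
        if self.tf_total is not None:
            self.log_tf_hi = min(self.log_tf_hi, math.log(self.tf_total))

    # -- state & cache ------------------------------------------------------

    def _reset(self, rng: np.random.Generator) -> None:
        st = self.initial_state
        self.P = st.prebound_freqs.copy()
        self.kd = st.kds.copy()
        # keep the free starting Kds inside the prior support
        self.kd[self.free_kd_idx] = np.clip(
            self.kd[self.free_kd_idx], self.kd_bounds[0], self.kd_bounds[1]
        )
        self.tf = float(
            np.clip(st.tf_free, math.exp(self.log_tf_lo) * 1.001, math.exp(self.log_tf_hi) / 1.001)
        )
        self._refresh_cache()
        widths = self.config.proposal_widths
        self.widths = {
            "tf_free": widths.get("tf_free", 0.3),
            "freqs": widths.get("freqs", 0.3),
            "scale": widths.get("scale", 0.3),
        }
        self.kd_widths = np.full(self.K, widths.get("kd", 0.5))
        self._acc: dict[str, list] = {}
        self._proposals: dict[str, int] = {}
        self._accepts: dict[str, int] = {}

    def _refresh_cache(self) -> None:
        self.lnP = np.log(self.P)
        self.theta = self.tf / (self.tf + self.kd)
        self.ln_theta = np.log(self.theta)
        self.Z = float(np.dot(self.P, self.theta))
        self.A = float(np.dot(self.C + self.D, self.lnP))
        self.Bd = float(np.dot(self.D, self.ln_theta))
        self.ll = self._assemble_ll()

    def _assemble_ll(self) -> float:
        return self.A + self.Bd - self.ND * _LN(self.Z)

    # -- bookkeeping --------------------------------------------------------

    def _record_acc(self, name: str, accepted: bool) -> None:
        self._acc.setdefault(name, []).append(1 if accepted else 0)
        self._proposals[name] = self._proposals.get(name, 0) + 1
        if accepted:
            self._accepts[name] = self._accepts.get(name, 0) + 1

    def _tune(self) -> None:
        t1 = self.config.target_acceptance_1d
        tm = self.config.target_acceptance_multi
        for name, outcomes in self._acc.items():
            if not outcomes:
                continue
            rate = float(np.mean(outcomes))
            if name == "kd":
                self.kd_widths[self.free_kd_idx] = np.clip(
                    self.kd_widths[self.free_kd_idx]
                    * min(3.0, max(1 / 3.0, math.exp(2.0 * (rate - t1)))),
                    1e-4,
                    20.0,
                )
            elif name in self.widths:
                target = tm if name == "freqs" else t1
                self.widths[name] = min(
                    50.0, max(1e-4, tune_width(self.widths[name], rate, target))
                )
        self._acc = {name: [] for name in self._acc}

    # -- moves --------------------------------------------------------------

    def _move_kd(self, i: int, rng) -> None:
        log_kd = _LN(self.kd[i])
        log_kd_new = log_kd + rng.normal(0.0, self.kd_widths[i])
        if not self.log_kd_lo <= log_kd_new <= self.log_kd_hi:
            self._record_acc("kd", False)
            return
        kd_new = math.exp(log_kd_new)
        theta_new = self.tf / (self.tf + kd_new)
        z_new = self.Z + self.P[i] * (theta_new - self.theta[i])
        bd_new = self.Bd + self.D[i] * (_LN(theta_new) - self.ln_theta[i])
        delta = (bd_new - self.Bd) - self.ND * (_LN(z_new) - _LN(self.Z))
        delta += self._kd_move_extra(i, kd_new)
        if _LN(rng.uniform()) < delta:
            self.kd[i] = kd_new
            self.theta[i] = theta_new
            self.ln_theta[i] = _LN(theta_new)
            self.Z = z_new
            self.Bd = bd_new
            self.ll = self._assemble_ll() + self._extra_ll()
            self._apply_kd_extra(i)
            self._record_acc("kd", True)
        else:
            self._record_acc("kd", False)

    def _kd_move_extra(self, i: int, kd_new: float) -> float:
        return 0.0  # GEM adds the residual-penalty delta

    def _apply_kd_extra(self, i: int) -> None:
        pass

    def _extra_ll(self) -> float:
        return 0.0

    def _move_tf(self, rng) -> None:
        log_tf_new = _LN(self.tf) + rng.normal(0.0, self.widths["tf_free"])
        if not self.log_tf_lo <= log_tf_new < self.log_tf_hi:
            self._record_acc("tf_free", False)
            return
        tf_new = math.exp(log_tf_new)
        theta_new = tf_new / (tf_new + self.kd)
        ln_theta_new = np.log(theta_new)
        z_new = float(np.dot(self.P, theta_new))
        bd_new = float(np.dot(self.D, ln_theta_new))
        delta = (bd_new - self.Bd) - self.ND * (_LN(z_new) - _LN(self.Z))
        if _LN(rng.uniform()) < delta:
            self.tf = tf_new
            self.theta = theta_new
            self.ln_theta = ln_theta_new
            self.Z = z_new
            self.Bd = bd_new
            self.ll = self._assemble_ll() + self._extra_ll()
            self._record_acc("tf_free", True)
        else:
            self._record_acc("tf_free", False)

    def _move_scale(self, rng) -> None:
        # Joint rescaling of tf_free and all non-reference Kds by a common
        # factor: theta is invariant for non-references, so this traverses
        # the tf/Kd scale ridge at O(n_refs) cost.  Symmetric in log space.
        z = rng.normal(0.0, self.widths["scale"])
        log_tf_new = _LN(self.tf) + z
        if not self.log_tf_lo <= log_tf_new < self.log_tf_hi:
            self._record_acc("scale", False)
            return
        factor = math.exp(z)
        kd_free_new = self.kd[self.free_kd_idx] * factor
        if kd_free_new.size and not (
            self.kd_bounds[0] <= kd_free_new.min()
            and kd_free_new.max() <= self.kd_bounds[1]
        ):
            self._record_acc("scale", False)
            return
        tf_new = math.exp(log_tf_new)
        ref_idx = np.where(self.ref_mask)[0]
        theta_ref_new = tf_new / (tf_new + self.kd[ref_idx])
        ln_theta_ref_new = np.log(theta_ref_new)
        z_new = self.Z + float(
            np.dot(self.P[ref_idx], theta_ref_new - self.theta[ref_idx])
        )
        bd_new = self.Bd + float(
            np.dot(self.D[ref_idx], ln_theta_ref_new - self.ln_theta[ref_idx])
        )
        delta = (bd_new - self.Bd) - self.ND * (_LN(z_new) - _LN(self.Z))
        delta += self._scale_move_extra(factor)
        if _LN(rng.uniform()) < delta:
            self.tf = tf_new
            self.kd[self.free_kd_idx] = kd_free_new
            self.theta[ref_idx] = theta_ref_new
            self.ln_theta[ref_idx] = ln_theta_ref_new
            self.Z = z_new
            self.Bd = bd_new
            self._apply_scale_extra(factor)
            self.ll = self._assemble_ll() + self._extra_ll()
            self._record_acc("scale", True)
        else:
            self._record_acc("scale", False)

    def _scale_move_extra(self, factor: float) -> float:
        return 0.0

    def _apply_scale_extra(self, factor: float) -> None:
        pass

    def _move_freqs(self, rng) -> None:
        new_p, log_hastings = joint_frequency_move(self.P, self.widths["freqs"], rng)
        ln_new = np.log(new_p)
        a_new = float(np.dot(self.C + self.D, ln_new))
        z_new = float(np.dot(new_p, self.theta))
        delta = (a_new - self.A) - self.ND * (_LN(z_new) - _LN(self.Z))
        if _LN(rng.uniform()) < delta + log_hastings:
            self.P = new_p
            self.lnP = ln_new
            self.A = a_new
            self.Z = z_new
            self.ll = self._assemble_ll() + self._extra_ll()
            self._record_acc("freqs", True)
        else:
            self._record_acc("freqs", False)

    def _extra_moves(self, rng) -> None:
        pass

    # -- main loop ----------------------------------------------------------

    def _generation(self, rng) -> None:
        for i in self.free_kd_idx:
            self._move_kd(int(i), rng)
        if not self.fix_tf:
            self._move_tf(rng)
            if self.free_kd_idx.size:
                self._move_scale(rng)
        if not self.fix_freqs:
            self._move_freqs(rng)
        self._extra_moves(rng)

    def _snapshot(self) -> dict:
        return {"kd": self.kd.copy(), "tf_free": self.tf, "P": self.P.copy()}

    def run(self, seed: int | None = None) -> ChainResult:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        self._reset(rng)
        ll_trace = np.empty(cfg.n_generations)
        records: list[dict] = []
        for gen in range(cfg.n_generations):
            self._generation(rng)
            if gen < cfg.burn_in:
                if (gen + 1) % cfg.tune_interval == 0:
                    self._tune()
                if gen + 1 == cfg.burn_in:
                    # freeze adaptation so the post-burn-in kernel is fixed
                    self._acc = {}
                    self._proposals = {}
                    self._accepts = {}
            elif (gen - cfg.burn_in) % cfg.thin == 0:
                records.append(self._snapshot())
            if (gen + 1) % 2000 == 0:
                self._refresh_cache()  # guard against float drift
            ll_trace[gen] = self.ll
        samples = {
            key: np.stack([r[key] for r in records]) for key in records[0]
        }
        samples["log_lik"] = ll_trace[cfg.burn_in :][:: cfg.thin][: len(records)]
        acceptance = {
            name: self._accepts.get(name, 0) / max(1, n)
            for name, n in self._proposals.items()
        }
        return ChainResult(
            samples=samples,
            acceptance_rates=acceptance,
            log_lik_trace=ll_trace,
            config=cfg,
        )


# ---------------------------------------------------------------------------
# GEM sampler with reversible jumps


class GEMSampler(BBMSampler):
    """Sampler for the generative energy model.

    Adds the Gaussian residual penalty, scalar blocks for sigma and (when the
    optimal sequence is not a reference) log Kd_opt, per-term reflected
    Gaussian moves, and reversible-jump birth/death moves over the indicator
    matrix with fixed-dimension proposal-reallocation refinement.
    """

    def __init__(
        self,
        data: BBMData,
        config: MCMCConfig,
        optimal_sequence: str | None = None,
        initial_model: EnergyModel | None = None,
        fix_sigma: bool = False,
        **kwargs,
    ):
        super().__init__(data, config, **kwargs)
        self.codes = encode_sequences(self.oligos.sequences)
        self.L = self.codes.shape[1]
        if optimal_sequence is None:
            optimal_sequence = self.oligos.sequences[int(np.argmin(self.initial_state.kds))]
        self.optimal_sequence = optimal_sequence
        testable = np.zeros((self.L, 4), dtype=bool)
        for pos in range(self.L):
            testable[pos, np.unique(self.codes[:, pos])] = True
        self.testable = testable
        if initial_model is None:
            initial_model = EnergyModel(
                optimal_sequence=optimal_sequence, sigma=0.3, testable_mask=testable
            )
        self.initial_model = initial_model
        self.fix_sigma = fix_sigma
        self.kd_opt_is_ref = optimal_sequence in self.oligos.reference_kds
        # flat index (pos * 4 + nt) per sequence position, for fast energy sums
        self.flat_idx = np.arange(self.L) * 4 + self.codes
        self.cell_members = {}
        for pos in range(self.L):
            for nt in range(4):
                members = np.where(self.codes[:, pos] == nt)[0]
                if members.size:
                    self.cell_members[(pos, nt)] = members
        anchor = initial_model.anchor_mask()
        self.toggleable = [
            (pos, nt)
            for pos in range(self.L)
            for nt in range(4)
            if testable[pos, nt] and not anchor[pos, nt]
        ]

    # -- state & cache ------------------------------------------------------

    def _reset(self, rng) -> None:
        super()._reset(rng)
        model = self.initial_model
        self.terms = model.terms.copy()
        self.delta = model.indicators.copy()
        self.sigma = float(model.sigma)
        if self.kd_opt_is_ref:
            self.kd_opt = float(self.oligos.reference_kds[self.optimal_sequence])
        else:
            self.kd_opt = float(self.kd.min())
        widths = self.config.proposal_widths
        self.widths["sigma"] = widths.get("sigma", 0.3)
        self.widths["terms"] = widths.get("terms", 0.3)
        self.widths["kd_opt"] = widths.get("kd_opt", 0.3)
        self._refresh_gauss()
        self.ll = self._assemble_ll() + self._extra_ll()

    def _refresh_gauss(self) -> None:
        e_rel = self.terms.ravel()[self.flat_idx].sum(axis=1)
        self.eps = np.log(self.kd / self.kd_opt) - e_rel
        self.sse = float(np.sum(self.eps**2))

    def _refresh_cache(self) -> None:
        super()._refresh_cache()
        if hasattr(self, "terms"):
            self._refresh_gauss()
            self.ll = self._assemble_ll() + self._extra_ll()

    def _extra_ll(self) -> float:
        return (
            -0.5 * self.K * LOG_2PI
            - self.K * _LN(self.sigma)
            - self.sse / (2.0 * self.sigma**2)
        )

    # -- GEM-specific deltas for inherited moves ----------------------------

    def _kd_move_extra(self, i: int, kd_new: float) -> float:
        eps_new = self.eps[i] + _LN(kd_new) - _LN(self.kd[i])
        self._pending_eps = eps_new
        return -(eps_new**2 - self.eps[i] ** 2) / (2.0 * self.sigma**2)

    def _apply_kd_extra(self, i: int) -> None:
        self.sse += self._pending_eps**2 - self.eps[i] ** 2
        self.eps[i] = self._pending_eps
        self.ll = self._assemble_ll() + self._extra_ll()

    def _scale_move_extra(self, factor: float) -> float:
        # Rescaling free Kds shifts their residuals by ln(factor); when
        # Kd_opt is free it rescales too, shifting reference residuals by
        # -ln(factor) instead and leaving free-Kd residuals unchanged.
        z = _LN(factor)
        eps_new = self.eps.copy()
        if self.kd_opt_is_ref:
            eps_new[~self.ref_mask] += z
        else:
            eps_new[self.ref_mask] -= z
        sse_new = float(np.sum(eps_new**2))
        self._pending_scale = (eps_new, sse_new)
        return -(sse_new - self.sse) / (2.0 * self.sigma**2)

    def _apply_scale_extra(self, factor: float) -> None:
        self.eps, self.sse = self._pending_scale
        if not self.kd_opt_is_ref:
            self.kd_opt *= factor

    # -- GEM moves ----------------------------------------------------------

    def _move_sigma(self, rng) -> None:
        # flat prior on sigma itself, proposed on the log scale -> Jacobian
        log_s_new = _LN(self.sigma) + rng.normal(0.0, self.widths["sigma"])
        sigma_new = math.exp(log_s_new)
        lo, hi = self.config.sigma_bounds
        if not lo <= sigma_new <= hi:
            self._record_acc("sigma", False)
            return
        delta = (
            -self.K * (log_s_new - _LN(self.sigma))
            - self.sse * (1.0 / (2 * sigma_new**2) - 1.0 / (2 * self.sigma**2))
            + (log_s_new - _LN(self.sigma))  # Hastings term for the log proposal
        )
        if _LN(rng.uniform()) < delta:
            self.sigma = sigma_new
            self.ll = self._assemble_ll() + self._extra_ll()
            self._record_acc("sigma", True)
        else:
            self._record_acc("sigma", False)

    def _move_kd_opt(self, rng) -> None:
        log_new = _LN(self.kd_opt) + rng.normal(0.0, self.widths["kd_opt"])
        if not self.log_kd_lo <= log_new <= self.log_kd_hi:
            self._record_acc("kd_opt", False)
            return
        shift = log_new - _LN(self.kd_opt)
        eps_new = self.eps - shift
        sse_new = float(np.sum(eps_new**2))
        delta = -(sse_new - self.sse) / (2.0 * self.sigma**2)
        if _LN(rng.uniform()) < delta:
            self.kd_opt = math.exp(log_new)
            self.eps = eps_new
            self.sse = sse_new
            self.ll = self._assemble_ll() + self._extra_ll()
            self._record_acc("kd_opt", True)
        else:
            self._record_acc("kd_opt", False)

    def _term_delta(self, pos: int, nt: int, new_value: float) -> tuple[float, np.ndarray, float]:
        members = self.cell_members[(pos, nt)]
        change = new_value - self.terms[pos, nt]
        eps_new = self.eps[members] - change
        sse_new = self.sse + float(np.sum(eps_new**2) - np.sum(self.eps[members] ** 2))
        delta = -(sse_new - self.sse) / (2.0 * self.sigma**2)
        return delta, eps_new, sse_new

    def _set_term(self, pos: int, nt: int, value: float, eps_new, sse_new) -> None:
        self.terms[pos, nt] = value
        self.eps[self.cell_members[(pos, nt)]] = eps_new
        self.sse = sse_new
        self.ll = self._assemble_ll() + self._extra_ll()

    def _move_term(self, pos: int, nt: int, rng, record: bool = True) -> bool:
        value = self.terms[pos, nt]
        new_value = abs(value + rng.normal(0.0, self.widths["terms"]))
        if new_value > self.config.rj_birth_width:  # uniform prior support
            if record:
                self._record_acc("terms", False)
            return False
        delta, eps_new, sse_new = self._term_delta(pos, nt, new_value)
        if _LN(rng.uniform()) < delta:
            self._set_term(pos, nt, new_value, eps_new, sse_new)
            if record:
                self._record_acc("terms", True)
            return True
        if record:
            self._record_acc("terms", False)
        return False

    def _extra_moves(self, rng) -> None:
        if not self.fix_sigma:
            self._move_sigma(rng)
        if not self.kd_opt_is_ref:
            self._move_kd_opt(rng)
        for pos, nt in self.toggleable:
            if self.delta[pos, nt]:
                self._move_term(pos, nt, rng)
        n_rj = self.config.rj_moves_per_generation or max(1, len(self.toggleable) // 2)
        for _ in range(n_rj):
            rj_step(self, rng)

    def _snapshot(self) -> dict:
        snap = super()._snapshot()
        snap.update(
            sigma=self.sigma,
            kd_opt=self.kd_opt,
            terms=self.terms.copy(),
            delta=self.delta.copy(),
        )
        return snap

    # -- views --------------------------------------------------------------

    def current_energy_model(self) -> EnergyModel:
        return EnergyModel(
            optimal_sequence=self.optimal_sequence,
            e0=_LN(self.kd_opt),
            terms=self.terms.copy(),
            indicators=self.delta.copy(),
            sigma=self.sigma,
            testable_mask=self.testable,
        )

    def current_gem_state(self) -> GEMState:
        binding = BindingState(
            prebound_freqs=self.P.copy(),
            kds=self.kd.copy(),
            tf_free=self.tf,
            tf_total=self.tf_total,
            ref_mask=self.ref_mask,
        )
        return GEMState(
            binding_state=binding, energy_model=self.current_energy_model(), kd_opt=self.kd_opt
        )


def rj_step(sampler: GEMSampler, rng) -> bool:
    """One reversible-jump birth/death move over the indicator matrix.

    A uniformly chosen toggleable term is born (value drawn from
    U(0, w_E), accepted on the likelihood ratio at the drawn value, then
    refined with N_r fixed-dimension MH steps) or killed (first refined with
    N_r steps, then collapsed to zero on the likelihood ratio at the refined
    value).  With the term prior equal to the birth distribution this leaves
    the posterior invariant and the occupancy ratio between adjacent models
    estimates their Bayes factor.  Untestable terms are never proposed.
    Returns True when the dimension change is accepted.
    """
    if not sampler.toggleable:
        raise ValueError("no toggleable energy term exists")
    pos, nt = sampler.toggleable[rng.integers(len(sampler.toggleable))]
    n_refine = sampler.config.rj_refine_steps
    if sampler.delta[pos, nt] == 0:
        # birth
        value = rng.uniform(0.0, sampler.config.rj_birth_width)
        delta_ll, eps_new, sse_new = sampler._term_delta(pos, nt, value)
        if _LN(rng.uniform()) < delta_ll:
            sampler.delta[pos, nt] = 1
            sampler._set_term(pos, nt, value, eps_new, sse_new)
            for _ in range(n_refine):
                sampler._move_term(pos, nt, rng, record=False)
            sampler._record_acc("rj", True)
            return True
        sampler._record_acc("rj", False)
        return False
    # death: proposal reallocation first, decision at the refined value
    for _ in range(n_refine):
        sampler._move_term(pos, nt, rng, record=False)
    delta_ll, eps_new, sse_new = sampler._term_delta(pos, nt, 0.0)
    if _LN(rng.uniform()) < delta_ll:
        sampler._set_term(pos, nt, 0.0, eps_new, sse_new)
        sampler.delta[pos, nt] = 0
        sampler._record_acc("rj", True)
        return True
    sampler._record_acc("rj", False)
    return False


# ---------------------------------------------------------------------------
# drivers


def _run_chains(make_sampler, config: MCMCConfig) -> ChainResult:
    results = []
    for chain in range(config.n_chains):
        sampler = make_sampler()
        results.append(sampler.run(seed=config.seed + 1000 * chain))
    primary = results[0]
    primary.chains = results
    if len(results) >= 2:
        convergence = {}
        for key in ("tf_free", "sigma", "kd_opt"):
            if key in primary.samples:
                convergence[key] = convergence_ratio([r.samples[key] for r in results])
        if "kd" in primary.samples:
            convergence["log_kd"] = convergence_ratio(
                [np.log(r.samples["kd"]) for r in results]
            )
        primary.convergence = convergence
    return primary


def fit_bbm(data: BBMData, config: MCMCConfig, **kwargs) -> ChainResult:
    """Run the BBM sampler (config.n_chains chains; first chain reported)."""
    return _run_chains(lambda: BBMSampler(data, config, **kwargs), config)


def fit_gem(data: BBMData, config: MCMCConfig, **kwargs) -> ChainResult:
    """Run the GEM sampler (config.n_chains chains; first chain reported)."""
    return _run_chains(lambda: GEMSampler(data, config, **kwargs), config)
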