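"""Accuracy metrics and posterior summaries.

Point estimates are posterior means; the headline accuracy metric is the
RMSE of log10 dissociation constants against truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AccuracyReport",
    "log_kd_rmse",
    "signed_log_errors",
    "categorize_kd",
    "cv_compare",
    "energy_table",
    "accuracy_report",
]

NUCLEOTIDES = "ACGT"


@dataclass
class AccuracyReport:
    rmse_log_kd: float
    per_oligo_errors: dict[str, float]
    kd_category: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence": list(self.per_oligo_errors),
                "signed_log10_error": list(self.per_oligo_errors.values()),
                "kd_category": [self.kd_category[s] for s in self.per_oligo_errors],
            }
        )


def _common_keys(estimated, truth, exclude=()):
    keys = [k for k in truth if k in estimated and k not in exclude]
    if not keys:
        raise ValueError("no overlapping sequences between estimates and truth")
    return keys


def signed_log_errors(estimated: dict, truth: dict, exclude_refs=()) -> dict[str, float]:
    """Per-oligo log10(estimate) − log10(truth)."""
    keys = _common_keys(estimated, truth, exclude_refs)
    errors = {}
    for k in keys:
        if estimated[k] <= 0 or truth[k] <= 0:
            raise ValueError(f"non-positive Kd for {k!r}")
        errors[k] = float(np.log10(estimated[k]) - np.log10(truth[k]))
    return errors


def log_kd_rmse(estimated: dict, truth: dict, exclude_refs=()) -> float:
    """sqrt(mean((log10 estimate − log10 truth)²)) over shared oligos."""
    errors = np.array(list(signed_log_errors(estimated, truth, exclude_refs).values()))
    return float(np.sqrt(np.mean(errors**2)))


def categorize_kd(kd: float, kd_distribution, medium_factor: float = 3.0) -> str:
    """Place one Kd relative to a target-Kd distribution.

    ``low``: below the minimum target Kd (stronger than the strongest
    target); ``medium``: within ``medium_factor`` x the minimum; ``high``:
    the rest of the distribution's range and above.
    """
    targets = np.asarray(list(kd_distribution), dtype=float)
    if targets.size == 0:
        raise ValueError("empty target distribution")
    lowest = float(targets.min())
    if kd < lowest:
        return "low"
    if kd <= medium_factor * lowest:
        return "medium"
    return "high"


def cv_compare(bbm_samples: np.ndarray, gem_samples: np.ndarray):
    """Per-oligo posterior coefficients of variation under the two models.

    Inputs are (n_draws, K) arrays of Kd samples over a matched oligo set;
    returns a (cv_bbm, cv_gem) pair of length-K arrays for paired scatter
    comparison.
    """
    results = []
    for name, samples in (("bbm", bbm_samples), ("gem", gem_samples)):
        samples = np.asarray(samples, dtype=float)
        if samples.ndim != 2 or samples.shape[0] < 100:
            raise ValueError(f"{name} needs >= 100 posterior draws, shape (n, K)")
        mean = samples.mean(axis=0)
        if np.any(mean <= 0):
            raise ValueError("zero or negative posterior mean Kd")
        results.append(samples.std(axis=0, ddof=1) / mean)
    cv_bbm, cv_gem = results
    if cv_bbm.shape != cv_gem.shape:
        raise ValueError("mismatched oligo sets")
    return cv_bbm, cv_gem


def energy_table(
    term_samples: np.ndarray,
    optimal_sequence: str,
    testable_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Posterior summary of position-specific energy terms.

    One row per position; per nucleotide a mean and std column (terms count
    as zero in draws that exclude them), a ``*`` marker on the optimal
    nucleotide's entry and a dash for untested variants.
    """
    term_samples = np.asarray(term_samples, dtype=float)
    n, length, _ = term_samples.shape
    mean = term_samples.mean(axis=0)
    std = term_samples.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    if testable_mask is None:
        testable_mask = np.ones((length, 4), dtype=bool)
    rows = []
    for pos in range(length):
        row: dict = {"position": pos + 1}
        optimal_nt = optimal_sequence[pos]
        min_nt = None
        tested = [
            nt for i, nt in enumerate(NUCLEOTIDES) if testable_mask[pos, i]
        ]
        if tested:
            min_nt = min(tested, key=lambda nt: mean[pos, NUCLEOTIDES.index(nt)])
        for i, nt in enumerate(NUCLEOTIDES):
            if not testable_mask[pos, i]:
                row[f"{nt}_mean"] = "-"
                row[f"{nt}_std"] = "-"
                continue
            marker = "*" if nt == optimal_nt else ""
            row[f"{nt}_mean"] = f"{mean[pos, i]:.2f}{marker}"
            row[f"{nt}_std"] = f"{std[pos, i]:.2f}"
        row["lowest"] = min_nt if min_nt is not None else "-"
        rows.append(row)
    return pd.DataFrame(rows)


def accuracy_report(
    estimated: dict, truth: dict, reference_sequences=(), medium_factor: float = 3.0
) -> AccuracyReport:
    """Bundle RMSE, per-oligo errors and Kd categories into one report."""
    errors = signed_log_errors(estimated, truth, reference_sequences)
    rmse = float(np.sqrt(np.mean(np.array(list(errors.values())) ** 2)))
    targets = [truth[s] for s in truth]
    categories = {s: categorize_kd(truth[s], targets, medium_factor) for s in errors}
    return AccuracyReport(rmse_log_kd=rmse, per_oligo_errors=errors, kd_category=categories)
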