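"""Binned-likelihood model comparison.

Observed changes in heading are scored against each model's simulated
probability mass functions, condition by condition; models are then ranked
by total log likelihood, with AIC and BIC reported as ratios relative to
the maximally likely model (best log-likelihood ratio 0, best AIC/BIC
ratio 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import MODEL_N_PARAMS
from .simulate import PopulationPMF, bin_index

__all__ = [
    "EvaluationResult",
    "data_log_likelihood",
    "compare_models",
    "evaluate_models",
    "results_to_frame",
]


@dataclass(frozen=True)
class EvaluationResult:
    """One row of the cross-model comparison table."""

    model: str
    n_params: int
    log_likelihood: float
    log_likelihood_ratio: float
    aic: float
    aic_ratio: float
    bic: float
    bic_ratio: float
    n_data: int

    def to_dict(self) -> dict:
        return asdict(self)


def data_log_likelihood(
    data: Mapping[str, Sequence[float] | np.ndarray],
    pmfs: Mapping[str, PopulationPMF],
) -> float:
    """Total log likelihood (nats) of per-condition changes under the PMFs.

    ``data`` maps condition labels to wrapped change-in-heading angles in
    radians; each datum contributes the log of the mass of the bin it falls
    in, and conditions are summed (conditional independence).
    """
    total = 0.0
    for label, changes in data.items():
        if label not in pmfs:
            raise KeyError(f"no PMF for condition {label!r}")
        pmf = pmfs[label]
        changes = np.atleast_1d(np.asarray(changes, dtype=float))
        if changes.size == 0:
            continue
        width = float(pmf.bin_edges_deg[1] - pmf.bin_edges_deg[0])
        mass = pmf.mass[bin_index(changes, width)]
        if np.any(mass <= 0.0):
            raise ValueError(
                f"datum fell in a zero-mass bin for condition {label!r}; "
                "build PMFs with a pseudocount floor"
            )
        total += float(np.sum(np.log(mass)))
    return total


def compare_models(
    log_likelihoods: Mapping[str, float],
    n_data: int | Mapping[str, int],
    n_params: Mapping[str, int] | None = None,
) -> list[EvaluationResult]:
    """Rank models by log likelihood and attach LR, AIC and BIC ratios.

    LR(M) = lnP(M) - lnP(best); AIC = 2k - 2 lnP; BIC = k ln(n) - 2 lnP.
    Ratios are raw AIC(M)/AIC(best) and BIC(M)/BIC(best) where "best" is the
    maximally likely model, so the top row reads 0 / 1 / 1.

    ``n_data`` may be given per model, in which case the counts must agree
    (all models must have been evaluated on identical data).
    """
    if len(log_likelihoods) < 2:
        raise ValueError("need at least 2 models to compare")
    if isinstance(n_data, Mapping):
        counts = set(n_data.values())
        if len(counts) != 1:
            raise ValueError(
                f"inconsistent evaluation: models scored on different n: {dict(n_data)}"
            )
        n_data = counts.pop()
    if n_data < 1:
        raise ValueError("n_data must be >= 1")
    k_of = n_params or MODEL_N_PARAMS
    best_lnp = max(log_likelihoods.values())
    best_model = max(log_likelihoods, key=log_likelihoods.__getitem__)
    aic_best = 2.0 * k_of[best_model] - 2.0 * best_lnp
    bic_best = k_of[best_model] * math.log(n_data) - 2.0 * best_lnp
    rows = []
    for model, lnp in sorted(
        log_likelihoods.items(), key=lambda kv: kv[1], reverse=True
    ):
        k = k_of[model]
        aic = 2.0 * k - 2.0 * lnp
        bic = k * math.log(n_data) - 2.0 * lnp
        rows.append(
            EvaluationResult(
                model=model,
                n_params=k,
                log_likelihood=lnp,
                log_likelihood_ratio=lnp - best_lnp,
                aic=aic,
                aic_ratio=aic / aic_best,
                bic=bic,
                bic_ratio=bic / bic_best,
                n_data=n_data,
            )
        )
    return rows


def evaluate_models(
    data: Mapping[str, np.ndarray],
    pmfs: Mapping[tuple[str, str], PopulationPMF],
    models: Sequence[str],
    n_params: Mapping[str, int] | None = None,
) -> list[EvaluationResult]:
    """Score every model's PMF set against the same data and rank them.

    ``pmfs`` is keyed by (model, condition label) as produced by
    :func:`cueint.simulate.run_condition_grid`. All models must be scored on
    exactly the same data points.
    """
    n_data = int(sum(np.atleast_1d(np.asarray(v)).size for v in data.values()))
    lnps = {}
    for model in models:
        model_pmfs = {
            label: pmf for (m, label), pmf in pmfs.items() if m == model
        }
        lnps[model] = data_log_likelihood(data, model_pmfs)
    return compare_models(lnps, n_data=n_data, n_params=n_params)


def results_to_frame(results: Sequence[EvaluationResult]) -> pd.DataFrame:
    """Comparison table with the familiar column layout."""
    return pd.DataFrame(
        {
            "Model": [r.model for r in results],
            "Parameters": [r.n_params for r in results],
            "Log likelihood": [r.log_likelihood for r in results],
            "Log likelihood ratio": [r.log_likelihood_ratio for r in results],
            "AIC ratio": [r.aic_ratio for r in results],
            "BIC ratio": [r.bic_ratio for r in results],
            "n": [r.n_data for r in results],
        }
    )
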