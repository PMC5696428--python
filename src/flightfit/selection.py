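"""Information-criterion ranking and BIC-approximate model probabilities.

For model ``M_i`` with maximized log-likelihood ``l_i``, ``k_i`` free
parameters and ``n`` recorded flights: ``AIC = 2k - 2l``,
``BIC = k ln n - 2l``.  Approximate posterior model probabilities use the
numerically stable delta-BIC form

    p(M_i) = exp(-dBIC_i / 2) / sum_r exp(-dBIC_r / 2),
    dBIC_i = BIC_i - BIC_min,

which is invariant to adding a constant to every BIC and cannot overflow for
the huge BIC gaps that coarse loggers produce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import FitResult

__all__ = [
    "information_criteria",
    "model_probabilities",
    "rank_models",
    "ModelComparison",
]


def information_criteria(fit: FitResult) -> dict[str, float]:
    """AIC and BIC of a converged fit; n is the number of recorded flights."""
    if not fit.converged:
        raise ValueError(f"fit of {fit.family} did not converge; criteria undefined")
    aic = 2.0 * fit.k - 2.0 * fit.loglik
    bic = fit.k * np.log(fit.n) - 2.0 * fit.loglik
    return {"AIC": aic, "BIC": bic}


def model_probabilities(bics) -> np.ndarray:
    """BIC-approximate model probabilities from a vector of BIC values.

    Non-finite BICs (failed fits) receive probability zero with a warning.
    """
    bics = np.asarray(bics, dtype=float)
    if bics.size < 2:
        raise ValueError("need at least two models to compare")
    finite = np.isfinite(bics)
    if not finite.any():
        raise ValueError("no finite BIC values")
    if not finite.all():
        warnings.warn("non-finite BIC assigned model probability 0", stacklevel=2)
    delta = np.where(finite, bics - bics[finite].min(), np.inf)
    w = np.exp(-0.5 * delta)
    return w / w.sum()


@dataclass
class ModelComparison:
    """Per-family ranking of fits to a single record."""

    table: pd.DataFrame  # columns: family, method, loglik, k, n, AIC, BIC, dBIC, prob
    best_family: str

    @property
    def bic_min(self) -> float:
        return float(self.table["BIC"].min())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def rank_models(fits: list[FitResult]) -> ModelComparison:
    """Rank >= 2 converged fits of the same record by BIC (ascending).

    Ties are broken by fewer parameters, then family name, so the ranking is
    deterministic and invariant to input order.
    """
    conv = [f for f in fits if f.converged and np.isfinite(f.loglik)]
    if len(conv) < 2:
        raise ValueError("need at least two converged fits to rank")
    if len({(f.n, f.interval_s) for f in conv}) != 1:
        raise ValueError("fits were made on mismatched records (different n or tau)")
    rows = []
    for f in conv:
        ic = information_criteria(f)
        rows.append({
            "family": f.family, "method": f.method, "loglik": f.loglik,
            "k": f.k, "n": f.n, **ic,
        })
    df = pd.DataFrame(rows)
    df["dBIC"] = df["BIC"] - df["BIC"].min()
    df["prob"] = model_probabilities(df["BIC"].to_numpy())
    df = df.sort_values(["BIC", "k", "family"], kind="mergesort").reset_index(drop=True)
    return ModelComparison(df, best_family=str(df.loc[0, "family"]))
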