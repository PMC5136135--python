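"""AIC/AICc model selection and Akaike weights over a candidate set."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["aic", "aicc", "akaike_weights", "selection_table", "N_EFF_CELLS"]

# Effective sample size used for the small-sample AIC correction: the
# number of histogram cells (46 bins x 6 months) that the likelihood is
# evaluated over.  Alternative conventions (e.g. total fish counted,
# n = 2137) can be passed explicitly to ``aicc``/``selection_table``.
N_EFF_CELLS = 276


def aic(neg_log_lik: float, K_params: int) -> float:
    """Akaike information criterion, 2K + 2*(-ln L)."""
    if K_params < 1:
        raise ValueError("K_params must be >= 1")
    return 2.0 * K_params + 2.0 * neg_log_lik


def aicc(neg_log_lik: float, K_params: int, n_eff: float = N_EFF_CELLS) -> float:
    """Small-sample corrected AIC: AIC + 2K(K+1)/(n_eff - K - 1)."""
    if n_eff <= K_params + 1:
        raise ValueError(
            f"n_eff must exceed K_params + 1 ({K_params + 1}), got {n_eff}"
        )
    return aic(neg_log_lik, K_params) + 2.0 * K_params * (K_params + 1) / (
        n_eff - K_params - 1
    )


def akaike_weights(delta_aicc) -> np.ndarray:
    """Relative model support w_i = exp(-d_i/2) / sum_j exp(-d_j/2)."""
    d = np.asarray(delta_aicc, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("deltas must be finite")
    e = np.exp(-(d - d.min()) / 2.0)
    return e / e.sum()


def selection_table(
    models: dict[str, tuple[float, int]], n_eff: float = N_EFF_CELLS
) -> pd.DataFrame:
    """Build the model-comparison table from {name: (-lnL, K)} pairs.

    Columns mirror the usual reporting order: -ln(L), K, AIC, AICc,
    delta AICc and Akaike weight, sorted by AICc.
    """
    rows = []
    for name, (nll, K) in models.items():
        rows.append(
            {
                "model": name,
                "neg_log_lik": nll,
                "K": K,
                "AIC": aic(nll, K),
                "AICc": aicc(nll, K, n_eff),
            }
        )
    df = pd.DataFrame(rows).sort_values("AICc", ignore_index=True)
    df["delta_AICc"] = df["AICc"] - df["AICc"].min()
    df["weight"] = akaike_weights(df["delta_AICc"].to_numpy())
    return df
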