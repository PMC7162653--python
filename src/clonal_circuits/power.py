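"""Lineage-pooling power analysis for lateral connectivity.

A labeled clone of S neurons pools N radial-glial (RGC) lineages.  If only a
shared RGC raises connectivity (by fold change FC over the unrelated rate),
the clone-pooled rates are diluted mixtures:

  vertical:  P_rv = P_uv (N-1)/N + FC P_uv / N
  lateral:   P_rl = [P_ul (S/L) (N-1)/N + P_ul FC (S/(NL) - 1)] / (S/L - 1)

The lateral formula excludes the cell itself from its own same-layer,
same-lineage pool of S/(NL) cells.  Inverting the vertical equation gives
the FC implied by observed vertical rates; pushing that FC through the
lateral equation predicts the lateral effect, whose detectability is scored
with Cohen's h and the two-proportion normal-approximation power for
unequal group sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .config import PowerConfig


class PowerDomainError(ValueError):
    """Raised for inputs outside the pooling equations' domain."""


def predicted_lateral_cp(
    p_ul: float, S: float, L: float, N: int, FC: float
) -> float:
    """Clone-pooled lateral connection probability under fold change FC.

    Requires S/L > 1 (at least one other same-layer clone member).  Values
    exceeding 1 are clipped with a warning so that coarse FC grids stay
    total.
    """
    if S / L <= 1:
        raise PowerDomainError("need S/L > 1 for the lateral pooling equation")
    if N < 1:
        raise PowerDomainError("N must be >= 1")
    p = (p_ul * (S / L) * (N - 1) / N + p_ul * FC * (S / (N * L) - 1)) / (S / L - 1)
    if p > 1.0:
        warnings.warn(
            f"predicted lateral probability {p:.3f} > 1; clipping", stacklevel=2
        )
        return 1.0
    return max(p, 0.0)


@dataclass(frozen=True)
class FoldChangeEstimate:
    fc: float
    single_rgc_vertical_p: float  # FC * P_uv, the implied one-lineage rate


def infer_fc_from_vertical(p_rv: float, p_uv: float, N: int) -> FoldChangeEstimate:
    """Fold change implied by observed vertical rates under N pooled lineages.

    Solves P_rv = P_uv (N-1)/N + FC P_uv / N for FC; also reports the implied
    vertical connection probability between cells of a single RGC lineage.
    """
    if p_uv <= 0:
        raise PowerDomainError("p_uv must be positive to infer a fold change")
    if N < 1:
        raise PowerDomainError("N must be >= 1")
    fc = N * p_rv / p_uv - (N - 1)
    return FoldChangeEstimate(fc=fc, single_rgc_vertical_p=fc * p_uv)


def cohens_h(p1: float, p2: float) -> float:
    """Arcsine effect size 2 asin(sqrt(p1)) - 2 asin(sqrt(p2)), in radians."""
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise PowerDomainError("proportions must lie in [0, 1]")
    return float(2 * np.arcsin(np.sqrt(p1)) - 2 * np.arcsin(np.sqrt(p2)))


def two_proportion_power(
    h: float,
    n1: int,
    n2: int,
    alpha: float = 0.05,
    alternative: str = "two-sided",
) -> float:
    """Power of the two-proportion arcsine test with unequal group sizes.

    Uses the harmonic-mean effective size n~ = n1 n2 / (n1 + n2); two-sided
    power sums both rejection tails.
    """
    if n1 < 2 or n2 < 2:
        raise PowerDomainError("group sizes must be >= 2")
    n_eff = n1 * n2 / (n1 + n2)
    shift = abs(h) * np.sqrt(n_eff)
    if alternative == "two-sided":
        z = norm.ppf(1 - alpha / 2)
        return float(norm.cdf(shift - z) + norm.cdf(-shift - z))
    if alternative == "one-sided":
        z = norm.ppf(1 - alpha)
        return float(norm.cdf(shift - z))
    raise ValueError(f"unknown alternative {alternative!r}")


def two_proportion_sample_size(
    h: float, alpha: float = 0.05, power: float = 0.9
) -> float:
    """Per-group n for the balanced two-sided arcsine test (generic helper)."""
    if h == 0:
        raise PowerDomainError("cannot size a study for a null effect")
    z_a = norm.ppf(1 - alpha / 2)
    z_b = norm.ppf(power)
    return float(((z_a + z_b) / abs(h)) ** 2)


def power_for_config(config: PowerConfig) -> dict:
    """One pass of the pooled-lateral power pipeline at the configured N.

    Infers FC from the vertical rates unless ``config.FC`` is set, predicts
    the pooled lateral rate, and returns FC, P_rl, Cohen's h and power.
    """
    if config.FC is None:
        est = infer_fc_from_vertical(config.p_rv, config.p_uv, config.N)
        fc = est.fc
    else:
        fc = config.FC
    p_rl = predicted_lateral_cp(config.p_ul, config.S, config.L, config.N, fc)
    h = cohens_h(config.p_ul, p_rl)
    pw = two_proportion_power(h, config.n1, config.n2, config.alpha)
    return {"N": config.N, "FC": fc, "p_rl": p_rl, "h": h, "power": pw}


def _trace_row(config: PowerConfig, n: int, fc: float | None = None) -> dict:
    """One (N, FC) evaluation without re-validating the config invariant.

    Grids legitimately span N where the same-lineage pool S/(NL) drops below
    one cell; there the pool term turns negative and the predicted rate is
    clipped at 0 rather than rejected.
    """
    if fc is None:
        fc = infer_fc_from_vertical(config.p_rv, config.p_uv, n).fc
    p_rl = predicted_lateral_cp(config.p_ul, config.S, config.L, n, fc)
    h = cohens_h(config.p_ul, p_rl)
    pw = two_proportion_power(h, config.n1, config.n2, config.alpha)
    return {"N": int(n), "FC": float(fc), "p_rl": p_rl, "h": h, "power": pw}


def inferred_fc_trace(
    config: PowerConfig, n_values: range | list = range(1, 21)
) -> pd.DataFrame:
    """The vertical-data trace: for each N, the implied FC and lateral power."""
    return pd.DataFrame([_trace_row(config, int(n)) for n in n_values])


def power_grid(
    config: PowerConfig | None = None,
    n_values: range | list = range(1, 21),
    fc_values: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full (N, FC) grid of predicted lateral rates, effect sizes and power.

    Defaults: N in 1..20 (integer steps) and FC in 0..30 at step 0.1.
    """
    config = config or PowerConfig()
    if fc_values is None:
        fc_values = np.round(np.arange(0.0, 30.0 + 1e-9, 0.1), 10)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clipping warnings on extreme FC
        for n in n_values:
            for fc in fc_values:
                rows.append(_trace_row(config, int(n), float(fc)))
    return pd.DataFrame(rows)
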