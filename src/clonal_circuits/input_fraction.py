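"""Binomial cortical-cylinder model of input from clonally related cells.

A postsynaptic cell in layer j receives input from a cylinder of cortex
around it.  The number of inputs from layer i and lineage relation
l in {related, unrelated} is modeled Binomial(n_i * q_l, p_il), with n_i
the excitatory cells of layer i in the cylinder, q_r the fraction of
cylinder cells belonging to the clone, q_u = 1 - q_r, and p_il the measured
connection probability.  The expected fraction of related input then has
the closed form

    e = p_r q_r / (p_r q_r + p_u (1 - q_r))

(the pool sizes n_i cancel).  The standard error of e is propagated from
the binomial standard errors of p_r and p_u by a first-order Taylor
expansion, treating the two rates as independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import CylinderModel


class ModelDomainError(ValueError):
    """Raised for inputs outside the model's domain (e.g. p_r = p_u = 0)."""


@dataclass(frozen=True)
class FractionEstimate:
    """Related-input fraction e with its propagated standard error."""

    e: float
    se: float
    p_r: float
    p_u: float
    m_r: int
    m_u: int
    q_r: float

    @property
    def percent(self) -> float:
        return round_half_away(100 * self.e, 1)

    @property
    def percent_se(self) -> float:
        return round_half_away(100 * self.se, 1)


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of the printed percentages)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor)


def cylinder_counts(model: CylinderModel) -> pd.DataFrame:
    """Per-layer excitatory counts of the cylinder and the related fraction.

    Returns a frame indexed by layer with columns ``n_cells`` (= fraction_i x
    N_total), ``n_related`` and ``n_unrelated`` (pool splits by q_r); the
    totals are available as ``.attrs["n_total"]`` and ``.attrs["q_r"]``.
    """
    n_total = model.total_excitatory
    q_r = model.q_related
    layers = list(model.layer_fractions)
    n_cells = np.array([model.layer_fractions[l] for l in layers]) * n_total
    out = pd.DataFrame(
        {
            "n_cells": n_cells,
            "n_related": n_cells * q_r,
            "n_unrelated": n_cells * (1 - q_r),
        },
        index=pd.Index(layers, name="layer"),
    )
    out.attrs["n_total"] = n_total
    out.attrs["q_r"] = q_r
    return out


def related_input_fraction(p_r: float, p_u: float, q_r: float) -> float:
    """Expected fraction of inputs that come from clonally related cells."""
    if not 0.0 <= q_r <= 1.0:
        raise ModelDomainError(f"q_r must lie in [0, 1], got {q_r}")
    if p_r < 0 or p_u < 0:
        raise ModelDomainError("connection probabilities must be nonnegative")
    denom = p_r * q_r + p_u * (1.0 - q_r)
    if denom == 0.0:
        if p_r == p_u == 0.0:
            raise ModelDomainError("e undefined when p_r = p_u = 0")
        return 0.0 if q_r == 0.0 else 1.0
    return p_r * q_r / denom


def input_fraction_se(
    p_r: float, p_u: float, m_r: int, m_u: int, q_r: float
) -> float:
    """First-order (delta-method) standard error of the input fraction.

    m_r and m_u are the numbers of tested connections behind p_r and p_u;
    the two rates are treated as independent binomial estimates.
    """
    if m_r < 1 or m_u < 1:
        raise ModelDomainError("m_r and m_u must be >= 1")
    denom = p_u * (1.0 - q_r) + p_r * q_r
    if denom == 0.0:
        raise ModelDomainError("SE undefined when p_r = p_u = 0")
    var = (
        q_r**2
        * (1.0 - q_r) ** 2
        * (p_u**2 * p_r * (1.0 - p_r) / m_r + p_r**2 * p_u * (1.0 - p_u) / m_u)
        / denom**4
    )
    return float(np.sqrt(var))


def input_fraction_from_counts(
    k_r: int, m_r: int, k_u: int, m_u: int, model: CylinderModel | None = None
) -> FractionEstimate:
    """Estimate e +/- SE from raw connected/tested counts for both lineages."""
    model = model or CylinderModel()
    p_r, p_u = k_r / m_r, k_u / m_u
    q = model.q_related
    return FractionEstimate(
        e=related_input_fraction(p_r, p_u, q),
        se=input_fraction_se(p_r, p_u, m_r, m_u, q),
        p_r=p_r,
        p_u=p_u,
        m_r=m_r,
        m_u=m_u,
        q_r=q,
    )


def input_fraction_table(
    counts: pd.DataFrame, model: CylinderModel | None = None
) -> pd.DataFrame:
    """Apply the model to a frame with columns k_r, m_r, k_u, m_u.

    Returns the input columns plus e, se and their one-decimal percent forms.
    """
    model = model or CylinderModel()
    out = counts.copy()
    ests: list[FractionEstimate | None] = []
    for r in counts.itertuples():
        try:
            ests.append(input_fraction_from_counts(r.k_r, r.m_r, r.k_u, r.m_u, model))
        except ModelDomainError:  # no connections in either group
            ests.append(None)
    out["e"] = [est.e if est else np.nan for est in ests]
    out["se"] = [est.se if est else np.nan for est in ests]
    out["e_percent"] = [est.percent if est else np.nan for est in ests]
    out["se_percent"] = [est.percent_se if est else np.nan for est in ests]
    return out


def expected_inputs(
    model: CylinderModel, probs: pd.DataFrame | dict
) -> pd.DataFrame:
    """Expected counts of related/unrelated presynaptic partners per layer.

    ``probs`` maps input layer -> (p_related, p_unrelated), either a dict or
    a frame with columns p_r/p_u indexed by layer.  Each pool is binomial, so
    mean = pool * p and variance = pool * p * (1 - p).
    """
    if isinstance(probs, dict):
        probs = pd.DataFrame(probs, index=["p_r", "p_u"]).T
    pools = cylinder_counts(model)
    rows = []
    for layer, row in probs.iterrows():
        if layer not in pools.index:
            raise ModelDomainError(f"no cylinder pool for layer {layer!r}")
        n_r = pools.loc[layer, "n_related"]
        n_u = pools.loc[layer, "n_unrelated"]
        p_r, p_u = float(row["p_r"]), float(row["p_u"])
        rows.append(
            {
                "layer": layer,
                "mean_related": n_r * p_r,
                "var_related": n_r * p_r * (1 - p_r),
                "mean_unrelated": n_u * p_u,
                "var_unrelated": n_u * p_u * (1 - p_u),
            }
        )
    out = pd.DataFrame(rows).set_index("layer")
    out["e"] = out["mean_related"] / (out["mean_related"] + out["mean_unrelated"])
    return out
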