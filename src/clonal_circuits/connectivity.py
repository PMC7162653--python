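"""Connection-probability estimation and lineage comparisons for pair tables.

A pair table holds one row per tested directed connection with pre/post
layer, lineage relation, distances, rostrocaudal position and the binary
outcome.  This module provides the exact binomial (Clopper-Pearson)
estimate, Fisher and chi-squared comparisons, the distance-matched
bootstrap control, Laplace-smoothed log-ratio heatmaps, the binomial
connectivity GLM with pairwise interactions, and rostrocaudal
stratification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

PAIR_COLUMNS = [
    "pre_layer",
    "post_layer",
    "relation",
    "connected",
    "bidirectional_tested",
    "tangential_um",
    "vertical_um",
    "euclidean_um",
    "rostrocaudal",
    "clone_id",
]


class EmptySelectionError(ValueError):
    """A filter left no tested pairs; a 0/0 rate is never reported."""


def connection_class(pre_layer: str, post_layer: str) -> str:
    """"vertical" for across-layer pairs, "lateral" for within-layer."""
    return "lateral" if pre_layer == post_layer else "vertical"


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval via beta quantiles.

    Lower bound is 0 at k=0 and upper bound 1 at k=n, by convention.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    lo = 0.0 if k == 0 else float(st.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(st.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass(frozen=True)
class CPEstimate:
    """Connection probability k/n with its 95% Clopper-Pearson interval."""

    k: int
    n: int
    p_hat: float
    ci_low: float
    ci_high: float

    @classmethod
    def from_counts(cls, k: int, n: int, alpha: float = 0.05) -> "CPEstimate":
        if n < 1:
            raise EmptySelectionError("no tested pairs in selection")
        lo, hi = clopper_pearson(k, n, alpha)
        return cls(k=int(k), n=int(n), p_hat=k / n, ci_low=lo, ci_high=hi)


def select_pairs(
    pairs: pd.DataFrame,
    relation: str | list[str] | None = None,
    conn_class: str | None = None,
    pre_layer: str | None = None,
    post_layer: str | None = None,
    bidirectional_only: bool = False,
) -> pd.DataFrame:
    """Subset a pair table by relation, connection class and layers."""
    mask = np.ones(len(pairs), dtype=bool)
    if relation is not None:
        rel = [relation] if isinstance(relation, str) else list(relation)
        mask &= pairs["relation"].isin(rel).to_numpy()
    if conn_class is not None:
        cls = np.where(
            pairs["pre_layer"].to_numpy() == pairs["post_layer"].to_numpy(),
            "lateral",
            "vertical",
        )
        mask &= cls == conn_class
    if pre_layer is not None:
        mask &= pairs["pre_layer"].to_numpy() == pre_layer
    if post_layer is not None:
        mask &= pairs["post_layer"].to_numpy() == post_layer
    if bidirectional_only:
        mask &= pairs["bidirectional_tested"].to_numpy().astype(bool)
    return pairs.loc[mask]


def connection_probability(pairs: pd.DataFrame, **filters) -> CPEstimate:
    """Connections divided by connections tested within the filtered subset."""
    sub = select_pairs(pairs, **filters)
    if len(sub) == 0:
        raise EmptySelectionError(f"no pairs match filter {filters!r}")
    return CPEstimate.from_counts(int(sub["connected"].sum()), len(sub))


def bidirectional_probability(pairs: pd.DataFrame, **filters) -> CPEstimate:
    """Fraction of both-directions-tested pairs connected in both directions.

    Requires a ``pair_id`` column linking the two directed tests of one
    physical pair; only pairs with both directions present are counted.
    """
    sub = select_pairs(pairs, **filters)
    sub = sub[sub["bidirectional_tested"].astype(bool)]
    if "pair_id" not in sub.columns:
        raise EmptySelectionError("bidirectional statistics need a pair_id column")
    per_pair = sub.groupby("pair_id")["connected"].agg(["sum", "size"])
    both_tested = per_pair[per_pair["size"] == 2]
    if len(both_tested) == 0:
        raise EmptySelectionError("no pairs with both directions tested")
    return CPEstimate.from_counts(int((both_tested["sum"] == 2).sum()), len(both_tested))


def fisher_exact(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p comparing k1/n1 with k2/n2.

    Uses the minimum-likelihood convention (sums tables whose point
    probability does not exceed the observed one).  Degenerate tables with
    an all-zero margin return p = 1 with a warning.
    """
    if min(k1, n1 - k1, k2, n2 - k2) < 0:
        raise ValueError("counts must satisfy 0 <= k <= n in both groups")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    if k1 + k2 == 0 or (n1 - k1) + (n2 - k2) == 0 or n1 == 0 or n2 == 0:
        warnings.warn("degenerate 2x2 margin; Fisher p set to 1", stacklevel=2)
        return 1.0
    return float(st.fisher_exact(table, alternative="two-sided")[1])


def chi_squared_test(
    contingency: np.ndarray | pd.DataFrame, bonferroni_m: int = 1
) -> tuple[float, float]:
    """Pearson chi-squared test on a contingency table of counts.

    Returns (statistic, p), with p multiplied by ``bonferroni_m`` and capped
    at 1 for post-hoc corrections.  No continuity correction.
    """
    arr = np.asarray(contingency, dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero row or column margin")
    stat, p, _, _ = st.chi2_contingency(arr, correction=False)
    return float(stat), float(min(p * bonferroni_m, 1.0))


@dataclass
class MatchedBootstrapResult:
    related_cp: np.ndarray  # per-iteration related connection probability
    matched_cp: np.ndarray  # per-iteration matched-control probability
    mean_difference: float
    p_value: float
    n_related_used: int
    n_related_dropped: int


def distance_matched_bootstrap(
    pairs: pd.DataFrame,
    tol_um: float = 20.0,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
) -> MatchedBootstrapResult:
    """Compare related pairs with distance-matched control pairs.

    Controls are pairs with at least one unlabeled cell (relations
    "unrelated" and "control_any_unlabeled"); a control matches a related
    pair when it shares both layers and both its tangential and vertical
    distances are within ``tol_um`` (inclusive).  Related pairs without any
    match are dropped.  Each of the B iterations resamples related pairs
    with replacement and draws one matched control per selected pair; the
    two-tailed p-value inverts the bootstrap interval of the difference
    (the mean difference is subtracted, and p is the fraction of shifted
    differences at least as large in magnitude as the mean difference).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    related = pairs[pairs["relation"] == "related"].reset_index(drop=True)
    controls = pairs[
        pairs["relation"].isin(["unrelated", "control_any_unlabeled"])
    ].reset_index(drop=True)
    if len(related) == 0 or len(controls) == 0:
        raise EmptySelectionError("need both related pairs and control pairs")

    ctl_pre = controls["pre_layer"].to_numpy()
    ctl_post = controls["post_layer"].to_numpy()
    ctl_tan = controls["tangential_um"].to_numpy(float)
    ctl_ver = controls["vertical_um"].to_numpy(float)
    match_lists: list[np.ndarray] = []
    keep: list[int] = []
    for i, row in enumerate(related.itertuples()):
        ok = (
            (ctl_pre == row.pre_layer)
            & (ctl_post == row.post_layer)
            & (np.abs(ctl_tan - row.tangential_um) <= tol_um)
            & (np.abs(ctl_ver - row.vertical_um) <= tol_um)
        )
        idx = np.flatnonzero(ok)
        if idx.size:
            match_lists.append(idx)
            keep.append(i)
    if not keep:
        raise EmptySelectionError("no related pair has a distance-matched control")

    rel_conn = related["connected"].to_numpy(bool)[keep]
    ctl_conn = controls["connected"].to_numpy(bool)
    n_rel = len(keep)

    rel_cp = np.empty(B)
    mat_cp = np.empty(B)
    for b in range(B):
        draw = rng.integers(0, n_rel, size=n_rel)
        rel_cp[b] = rel_conn[draw].mean()
        chosen = [match_lists[j][rng.integers(0, len(match_lists[j]))] for j in draw]
        mat_cp[b] = ctl_conn[np.asarray(chosen)].mean()

    diffs = rel_cp - mat_cp
    mean_diff = float(diffs.mean())
    shifted = diffs - mean_diff
    p = float(np.mean(np.abs(shifted) >= abs(mean_diff)))
    return MatchedBootstrapResult(
        related_cp=rel_cp,
        matched_cp=mat_cp,
        mean_difference=mean_diff,
        p_value=p,
        n_related_used=n_rel,
        n_related_dropped=len(related) - n_rel,
    )


def smoothed_log_ratio(A: int, B: int, C: int, D: int) -> float:
    """log2 of the Laplace-smoothed rate ratio [(A+1)/(B+1)] / [(C+1)/(D+1)]."""
    return float(np.log2(((A + 1) / (B + 1)) / ((C + 1) / (D + 1))))


def log_ratio_heatmap(
    pairs: pd.DataFrame,
    B_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Smoothed log2 related/unrelated rate ratios per connection type.

    For each (pre, post) layer combination with A/B related and C/D
    unrelated connected/tested counts, reports the smoothed log-ratio and a
    95% bootstrap coverage interval: per replicate, A ~ Binomial(B, (A+1)/(B+1))
    and C ~ Binomial(D, (C+1)/(D+1)) are redrawn and the smoothed log-ratio
    recomputed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    combos = (
        pairs.groupby(["pre_layer", "post_layer", "relation"])["connected"]
        .agg(["sum", "size"])
        .reset_index()
    )
    rows = []
    for (pre, post), grp in combos.groupby(["pre_layer", "post_layer"]):
        by_rel = grp.set_index("relation")
        if not {"related", "unrelated"}.issubset(by_rel.index):
            continue
        A, Bn = int(by_rel.loc["related", "sum"]), int(by_rel.loc["related", "size"])
        C, Dn = int(by_rel.loc["unrelated", "sum"]), int(
            by_rel.loc["unrelated", "size"]
        )
        point = smoothed_log_ratio(A, Bn, C, Dn)
        a_boot = rng.binomial(Bn, (A + 1) / (Bn + 1), size=B_reps)
        c_boot = rng.binomial(Dn, (C + 1) / (Dn + 1), size=B_reps)
        lr_boot = np.log2(((a_boot + 1) / (Bn + 1)) / ((c_boot + 1) / (Dn + 1)))
        lo, hi = np.percentile(lr_boot, [2.5, 97.5])
        rows.append(
            {
                "pre_layer": pre,
                "post_layer": post,
                "A": A,
                "B": Bn,
                "C": C,
                "D": Dn,
                "log2_ratio": point,
                "ci_low": float(lo),
                "ci_high": float(hi),
                "significant": not (lo <= 0.0 <= hi),
            }
        )
    return pd.DataFrame(rows)


GLM_TERMS = ["const", "L", "C", "D", "R", "L:C", "L:D", "L:R", "C:D", "C:R", "D:R"]


class GLMFitError(RuntimeError):
    """Non-convergence or separation in the connectivity GLM."""


def glm_design(pairs: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Design matrix (constant, L, C, D, R and pairwise interactions) and y.

    L = 1 for related pairs, C = 1 for vertical pairs, D = Euclidean distance
    in microns, R = rostrocaudal position 1..5.
    """
    L = (pairs["relation"] == "related").astype(float).to_numpy()
    C = (pairs["pre_layer"] != pairs["post_layer"]).astype(float).to_numpy()
    D = pairs["euclidean_um"].to_numpy(float)
    R = pairs["rostrocaudal"].to_numpy(float)
    X = pd.DataFrame(
        {
            "const": 1.0,
            "L": L,
            "C": C,
            "D": D,
            "R": R,
            "L:C": L * C,
            "L:D": L * D,
            "L:R": L * R,
            "C:D": C * D,
            "C:R": C * R,
            "D:R": D * R,
        }
    )
    y = pairs["connected"].to_numpy(float)
    return X, y


def connectivity_glm(pairs: pd.DataFrame) -> pd.DataFrame:
    """Binomial (logit) GLM of the connection outcome per tested directed pair.

    Returns one row per term with the estimate, Wald SE, t statistic and
    two-sided p; residual degrees of freedom are n_pairs - 11.  Separation
    or non-convergence raises :class:`GLMFitError` with diagnostics rather
    than returning a silent result.
    """
    X, y = glm_design(pairs)
    model = sm.GLM(y, X, family=sm.families.Binomial())
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        res = model.fit(maxiter=100)
    if not res.converged:
        raise GLMFitError("IRLS did not converge")
    if np.any(np.abs(res.params) > 1e3) or np.any(~np.isfinite(res.bse)):
        raise GLMFitError(
            "apparent separation: runaway coefficients "
            f"{dict(res.params[np.abs(res.params) > 1e3])}"
        )
    perfect = [w for w in caught if "PerfectSeparation" in str(w.category)]
    if perfect:
        raise GLMFitError("perfect separation detected by the fitter")
    out = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    out.attrs["df_resid"] = int(res.df_resid)
    out.attrs["llf"] = float(res.llf)
    return out


def stratify_by_rostrocaudal(
    pairs: pd.DataFrame, split_rule=None
) -> pd.DataFrame:
    """Re-run the related-vs-unrelated comparison within rostrocaudal strata.

    ``split_rule`` maps a rostrocaudal position (1..5) to a stratum label;
    the default splits at the median position into "rostral"/"caudal".
    Returns one row per (stratum, connection class) with both CP estimates
    and the Fisher p; strata missing either lineage group are skipped with a
    warning.
    """
    if split_rule is None:
        median = float(pairs["rostrocaudal"].median())

        def split_rule(r):  # noqa: F811 - default rule
            return "rostral" if r <= median else "caudal"

    strata = pairs["rostrocaudal"].map(split_rule)
    rows = []
    for (stratum, cls), grp in pairs.groupby(
        [strata, np.where(pairs["pre_layer"] == pairs["post_layer"], "lateral", "vertical")]
    ):
        try:
            rel = connection_probability(grp, relation="related")
            unrel = connection_probability(grp, relation="unrelated")
        except EmptySelectionError:
            warnings.warn(
                f"stratum {stratum!r}/{cls} lacks a lineage group; skipped",
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "stratum": stratum,
                "connection_class": cls,
                "k_related": rel.k,
                "n_related": rel.n,
                "p_related": rel.p_hat,
                "k_unrelated": unrel.k,
                "n_unrelated": unrel.n,
                "p_unrelated": unrel.p_hat,
                "fisher_p": fisher_exact(rel.k, rel.n, unrel.k, unrel.n),
            }
        )
    return pd.DataFrame(rows)
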