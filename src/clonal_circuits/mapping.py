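"""Patch-seq QC, normalization and reference-atlas mapping.

Covers the single-cell side of the analysis: MAD-based cell QC, mean-count
gene filtering, size-factor normalization, dropout-curve variable-gene
selection, projection of query cells onto a precomputed reference
embedding via correlation kNN with gene-bootstrap precision, nearest-
centroid cluster assignment, same-cluster pair statistics, and a
cross-validated region-prediction classifier with a permutation null.

Matrix convention: counts are cells x genes throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .config import VariableGeneParams
from .connectivity import chi_squared_test, clopper_pearson


class QCError(ValueError):
    pass


def qc_filter_cells(
    counts: np.ndarray, metadata: pd.DataFrame | None = None, n_mads: float = 3.0
):
    """Drop cells > ``n_mads`` median absolute deviations below the median.

    The rule is applied to both library size (total counts) and the number
    of genes detected; a cell failing either is removed.  The MAD carries
    the usual normal-consistency scaling (1.4826), matching the R outlier
    helpers this emulates.  Returns (filtered counts, filtered metadata,
    boolean keep mask).
    """
    counts = np.asarray(counts)
    if counts.shape[0] < 4:
        raise QCError("need at least 4 cells for a meaningful MAD filter")
    lib = counts.sum(axis=1)
    detected = (counts > 0).sum(axis=1)
    keep = np.ones(counts.shape[0], dtype=bool)
    for metric in (lib, detected):
        med = np.median(metric)
        mad = median_abs_deviation(metric, scale="normal")
        keep &= metric >= med - n_mads * mad
    if not keep.any():
        raise QCError("QC removed every cell")
    meta = metadata.loc[keep].reset_index(drop=True) if metadata is not None else None
    return counts[keep], meta, keep


def filter_genes(counts: np.ndarray, min_mean: float = 1.0) -> np.ndarray:
    """Boolean mask of genes with mean count per cell >= ``min_mean``.

    Genes with strictly less than one read per cell on average are dropped;
    a mean of exactly ``min_mean`` is retained.
    """
    return np.asarray(counts).mean(axis=0) >= min_mean


def normalize_counts(counts: np.ndarray, size_factors: np.ndarray | None = None):
    """Size-factor normalization and log2(x+1) transform.

    Default size factors are library size over the geometric mean library
    size; precomputed factors (e.g. from a pooling method) can be supplied
    instead.  Returns (size_factors, lognorm) with lognorm cells x genes.
    """
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=1)
    if np.any(lib <= 0):
        raise QCError("zero-library cell present; run QC first")
    if size_factors is None:
        size_factors = lib / np.exp(np.mean(np.log(lib)))
    lognorm = np.log2(counts / np.asarray(size_factors)[:, None] + 1.0)
    return np.asarray(size_factors), lognorm


def dropout_curve_stats(
    counts: np.ndarray, params: VariableGeneParams
) -> pd.DataFrame:
    """Per-gene (mu, tau) statistics for the dropout-curve selector.

    Genes with counts at or above the threshold in fewer than ``min_cells``
    cells are excluded outright (``eligible`` False).  mu is the mean log2
    count over counts strictly above the threshold; tau the fraction
    strictly below it — counts exactly at the threshold enter neither
    statistic, though they do count toward eligibility.
    """
    counts = np.asarray(counts)
    t = params.count_threshold
    eligible = (counts >= t).sum(axis=0) >= params.min_cells
    mu = np.array(
        [
            np.log2(col[col > t]).mean() if (col > t).any() else np.nan
            for col in counts.T
        ]
    )
    tau = (counts < t).mean(axis=0)
    return pd.DataFrame({"mu": mu, "tau": tau, "eligible": eligible})


def select_variable_genes(
    counts: np.ndarray, params: VariableGeneParams | None = None
) -> np.ndarray:
    """Select ~``n_target`` variable genes by a dropout-curve binary search.

    Finds the offset b such that ``n_target`` eligible genes satisfy
    tau > exp(slope * mu + b) + margin; b is binary-searched (selection
    count is non-increasing in b) until the count hits the target or the
    bracket is below 1e-9, returning the closest achievable set.  Returns
    the boolean gene mask.
    """
    params = params or VariableGeneParams()
    stats = dropout_curve_stats(counts, params)
    ok = stats["eligible"].to_numpy() & np.isfinite(stats["mu"].to_numpy())
    mu = stats["mu"].to_numpy()[ok]
    tau = stats["tau"].to_numpy()[ok]
    idx = np.flatnonzero(ok)

    if idx.size < params.n_target:
        warnings.warn(
            f"only {idx.size} candidate genes for target {params.n_target}; "
            "returning all candidates",
            stacklevel=2,
        )
        mask = np.zeros(len(stats), dtype=bool)
        mask[idx] = True
        return mask

    def n_selected(b: float) -> np.ndarray:
        return tau > np.exp(params.slope * mu + b) + params.margin

    lo, hi = -60.0, 60.0  # selects (almost) all / none
    best = None
    while hi - lo > 1e-9:
        mid = (lo + hi) / 2
        sel = n_selected(mid)
        count = int(sel.sum())
        if best is None or abs(count - params.n_target) < abs(
            int(best[1].sum()) - params.n_target
        ):
            best = (mid, sel)
        if count == params.n_target:
            best = (mid, sel)
            break
        if count > params.n_target:
            lo = mid
        else:
            hi = mid
    mask = np.zeros(len(stats), dtype=bool)
    mask[idx[best[1]]] = True
    return mask


def _pearson_rows(query: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation matrix (queries x references).

    Zero-variance rows yield NaN correlations (flagged by callers).
    """
    q = query - query.mean(axis=1, keepdims=True)
    r = ref - ref.mean(axis=1, keepdims=True)
    qn = np.linalg.norm(q, axis=1)
    rn = np.linalg.norm(r, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (q @ r.T) / np.outer(qn, rn)
    return corr


def map_cells_knn(
    query_log: np.ndarray,
    ref_log: np.ndarray,
    ref_embedding: np.ndarray,
    k: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Project query cells onto the reference embedding by correlation kNN.

    Per query cell, Pearson correlation against every reference cell over
    the shared genes (both matrices log2(x+1)); the cell is placed at the
    coordinate-wise median embedding position of its k best-correlated
    references.  Returns (positions, valid mask); zero-variance queries are
    flagged invalid with NaN positions.
    """
    if query_log.shape[1] == 0:
        raise ValueError("shared gene set is empty")
    corr = _pearson_rows(query_log, ref_log)
    valid = ~np.isnan(corr).all(axis=1)
    positions = np.full((query_log.shape[0], 2), np.nan)
    for i in np.flatnonzero(valid):
        order = np.argsort(-corr[i])[:k]
        positions[i] = np.median(ref_embedding[order], axis=0)
    if not valid.all():
        warnings.warn(
            f"{(~valid).sum()} query cells had zero variance over shared genes "
            "and were skipped",
            stacklevel=2,
        )
    return positions, valid


def mapping_precision_bootstrap(
    query_log: np.ndarray,
    ref_log: np.ndarray,
    ref_embedding: np.ndarray,
    B: int = 100,
    percentile: float = 80.0,
    k: int = 10,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Gene-bootstrap mapping precision per query cell.

    B times, resample the shared genes with replacement (same size), re-map,
    and record the Euclidean displacement from the original position; the
    precision is the ``percentile``-th percentile of those displacements
    (smaller = more precise).  Dot-size classes follow the convention:
    precision <= 5 "large", 5 < precision <= 10 "intermediate", > 10 "small".
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base, valid = map_cells_knn(query_log, ref_log, ref_embedding, k=k)
    n_genes = query_log.shape[1]
    disp = np.full((B, query_log.shape[0]), np.nan)
    for b in range(B):
        g = rng.integers(0, n_genes, size=n_genes)
        pos, v = map_cells_knn(query_log[:, g], ref_log[:, g], ref_embedding, k=k)
        disp[b] = np.linalg.norm(pos - base, axis=1)
    precision = np.nanpercentile(disp, percentile, axis=0)
    size_class = np.where(
        precision > 10, "small", np.where(precision > 5, "intermediate", "large")
    )
    return pd.DataFrame(
        {
            "x": base[:, 0],
            "y": base[:, 1],
            "precision": precision,
            "size_class": size_class,
            "valid": valid,
        }
    )


def assign_to_clusters(
    query_log: np.ndarray,
    centroids: np.ndarray,
    cluster_names: list[str],
    class_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Nearest-centroid cluster assignment by Pearson correlation.

    ``centroids`` is clusters x genes of mean log2(x+1) profiles over the
    same shared genes as ``query_log``.  Ties go to the lowest cluster
    index (logged).  A cluster -> broad-class map adds a class column.
    """
    corr = _pearson_rows(query_log, centroids)
    best = np.nanargmax(corr, axis=1)
    ties = (corr == corr[np.arange(len(best)), best][:, None]).sum(axis=1) > 1
    if ties.any():
        warnings.warn(f"{ties.sum()} assignment ties broken to lowest index", stacklevel=2)
    labels = [cluster_names[j] for j in best]
    out = pd.DataFrame(
        {
            "cluster": labels,
            "correlation": corr[np.arange(len(best)), best],
        }
    )
    if class_map:
        out["broad_class"] = [class_map.get(lab, "unknown") for lab in labels]
    return out


@dataclass(frozen=True)
class SameTypeStats:
    fractions: pd.DataFrame  # per group: k, n, fraction, ci_low, ci_high
    chi2: float
    p: float


def same_type_pair_probability(
    labels: pd.Series,
    pairs: pd.DataFrame,
    condition_on_layer: bool = False,
    layers: pd.Series | None = None,
    deduplicate: bool = False,
) -> SameTypeStats:
    """Fraction of cell pairs whose two members map to the same type.

    ``labels`` maps cell id -> assigned cluster (or broad class); ``pairs``
    needs columns cell_a, cell_b, group.  With ``condition_on_layer`` only
    pairs whose two cells share a layer (from ``layers``) are kept.  Groups
    are compared with a chi-squared test on the same/different table.
    """
    df = pairs.copy()
    if deduplicate:
        key = df[["cell_a", "cell_b"]].apply(lambda r: tuple(sorted(r)), axis=1)
        df = df.loc[~key.duplicated()]
    if condition_on_layer:
        if layers is None:
            raise ValueError("layer conditioning requires a layers series")
        df = df[layers.loc[df["cell_a"]].to_numpy() == layers.loc[df["cell_b"]].to_numpy()]
    same = labels.loc[df["cell_a"]].to_numpy() == labels.loc[df["cell_b"]].to_numpy()
    rows = []
    for group, mask in df.groupby("group").groups.items():
        s = same[df.index.get_indexer(mask)]
        if len(s) == 0:
            raise ValueError(f"group {group!r} has no pairs")
        k, n = int(s.sum()), len(s)
        lo, hi = clopper_pearson(k, n)
        rows.append(
            {"group": group, "k": k, "n": n, "fraction": k / n, "ci_low": lo, "ci_high": hi}
        )
    frac = pd.DataFrame(rows).set_index("group")
    if len(frac) >= 2:
        table = np.column_stack([frac["k"], frac["n"] - frac["k"]])
        try:
            chi2, p = chi_squared_test(table)
        except ValueError:  # all pairs same (or all different) in every group
            warnings.warn("degenerate same/different margin; p set to 1", stacklevel=2)
            chi2, p = 0.0, 1.0
    else:
        chi2, p = np.nan, np.nan
    return SameTypeStats(fractions=frac, chi2=chi2, p=p)


def _cv_best_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    folds: int,
    Cs: np.ndarray,
    penalty: str,
    rng: np.random.Generator,
) -> float:
    """Best mean CV accuracy over the regularization path."""
    skf = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=int(rng.integers(2**31))
    )
    splits = list(skf.split(X, y))
    accs = np.zeros(len(Cs))
    for ci, C in enumerate(Cs):
        correct = 0
        for train, test in splits:
            if penalty == "l1":
                clf = LogisticRegression(
                    C=float(C), solver="saga", l1_ratio=1.0, max_iter=500
                )
            else:
                clf = LogisticRegression(C=float(C), max_iter=500)
            clf.fit(X[train], y[train])
            correct += (clf.predict(X[test]) == y[test]).sum()
        accs[ci] = correct / len(y)
    return float(accs.max())


def region_prediction_cv(
    lognorm: np.ndarray,
    regions: np.ndarray | pd.Series,
    folds: int = 20,
    permutations: int = 1000,
    seed: int | np.random.Generator = 0,
    penalty: str = "l2",
    Cs: np.ndarray | None = None,
) -> dict:
    """Penalized multinomial classifier of cortical region, permutation-tested.

    Cross-validated accuracy is the best mean accuracy over the
    regularization grid; the null distribution re-runs the same procedure
    on region labels shuffled without replacement.  The one-tailed p-value
    uses the add-one convention (1 + #null >= observed) / (1 + permutations),
    which is valid at any number of permutations.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = np.asarray(regions)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two regions to fit a classifier")
    folds = min(folds, int(counts.min()))
    if folds < 2:
        raise ValueError("too few cells per region for cross-validation")
    X = np.asarray(lognorm)
    if Cs is None:
        Cs = np.logspace(-2, 2, 5)
    observed = _cv_best_accuracy(X, y, folds, Cs, penalty, rng)
    null = np.array(
        [
            _cv_best_accuracy(X, rng.permutation(y), folds, Cs, penalty, rng)
            for _ in range(permutations)
        ]
    )
    p = (1 + int((null >= observed).sum())) / (1 + permutations)
    return {"accuracy": observed, "null": null, "p": p, "folds": folds}
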