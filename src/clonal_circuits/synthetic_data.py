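"""Synthetic clones, pair-test tables and expression matrices.

Emulates the data the analyses consume: labeled clones of configurable size
pooled from N radial-glial lineages inside a cortical cylinder of unlabeled
background cells, Bernoulli pair tests at configurable per-type connection
probabilities, and cluster-structured negative-binomial count matrices with
a fixed 2-D reference embedding.  Every generator takes a seed (or an
existing Generator); one global seed is expanded into independent
substreams so modules can be exercised separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    LAYER_DEPTH_UM,
    ConfigurationError,
    ExpressionConfig,
    SimConfig,
    spawn_rngs,
)

CELL_COLUMNS = [
    "cell_id",
    "site_id",
    "clone_id",
    "lineage_id",
    "layer",
    "x_um",
    "y_um",
    "depth_um",
    "tdtomato",
    "rostrocaudal",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _disc_positions(n: int, radius_um: float, rng: np.random.Generator):
    """Uniform positions in the cylinder's tangential disc."""
    r = radius_um * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return r * np.cos(theta), r * np.sin(theta)


def simulate_clone_population(
    config: SimConfig, seed: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Labeled clones plus unlabeled background cells, one cylinder per clone.

    Each of ``n_clones`` recording sites holds one labeled clone of
    ``clone_size`` cells split multinomially over ``n_lineages`` lineages,
    plus tdTomato-negative background cells filling the cylinder to the
    configured density (override with ``background_per_site``).  Layers are
    multinomial on ``layer_fractions``; positions are uniform in the disc
    and uniform in the layer's depth band; each site draws a rostrocaudal
    position 1..5.
    """
    rng = _rng(config.seed if seed is None else seed)
    radius_um = config.cylinder_radius_mm * 1000.0
    layers = list(config.layer_fractions)
    fracs = np.array([config.layer_fractions[l] for l in layers])
    if config.background_per_site is None:
        n_bg = max(int(round(config.cells_per_cylinder)) - config.clone_size, 0)
    else:
        n_bg = int(config.background_per_site)
        if n_bg < 0:
            raise ConfigurationError("background_per_site must be >= 0")

    frames = []
    next_id = 0
    for site in range(config.n_clones):
        rc = int(rng.integers(1, 6))
        n_cells = config.clone_size + n_bg
        layer_idx = rng.choice(len(layers), size=n_cells, p=fracs)
        x, y = _disc_positions(n_cells, radius_um, rng)
        lo = np.array([LAYER_DEPTH_UM[layers[i]][0] for i in layer_idx])
        hi = np.array([LAYER_DEPTH_UM[layers[i]][1] for i in layer_idx])
        depth = rng.uniform(lo, hi)
        labeled = np.zeros(n_cells, dtype=bool)
        labeled[: config.clone_size] = True
        lineage = np.full(n_cells, -1, dtype=int)
        lineage[: config.clone_size] = rng.integers(
            0, config.n_lineages, size=config.clone_size
        )
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": np.arange(next_id, next_id + n_cells),
                    "site_id": site,
                    "clone_id": np.where(labeled, site, -1),
                    "lineage_id": lineage,
                    "layer": [layers[i] for i in layer_idx],
                    "x_um": x,
                    "y_um": y,
                    "depth_um": depth,
                    "tdtomato": labeled,
                    "rostrocaudal": rc,
                }
            )
        )
        next_id += n_cells
    return pd.concat(frames, ignore_index=True)


def _pair_distances(cells: pd.DataFrame, pre: np.ndarray, post: np.ndarray):
    x = cells["x_um"].to_numpy()
    y = cells["y_um"].to_numpy()
    d = cells["depth_um"].to_numpy()
    tang = np.hypot(x[pre] - x[post], y[pre] - y[post])
    vert = np.abs(d[pre] - d[post])
    return tang, vert, np.hypot(tang, vert)


def simulate_pair_tests(
    cells: pd.DataFrame,
    config: SimConfig,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Bernoulli pair tests at the configured per-type probabilities.

    For every (relation, pre layer, post layer) key of ``config.conn_probs``
    draws ``n_pairs_per_type`` directed pairs within a random site: related
    pairs take two distinct labeled cells of one clone, unrelated pairs one
    labeled and one unlabeled cell (orientation randomized), and
    control_any_unlabeled pairs one unlabeled cell with any partner.  Each
    pair connects Bernoulli at its configured probability; distances follow
    from positions.
    """
    rng = _rng(seed)
    cells = cells.reset_index(drop=True)
    idx_by = {}
    for site, grp in cells.groupby("site_id"):
        for layer, sub in grp.groupby("layer"):
            lab = sub.index[sub["tdtomato"]].to_numpy()
            unlab = sub.index[~sub["tdtomato"]].to_numpy()
            idx_by[(site, layer)] = (lab, unlab)
    sites = cells["site_id"].unique()
    rc_by_site = cells.groupby("site_id")["rostrocaudal"].first()

    rows = []
    for (relation, pre_layer, post_layer), p in sorted(config.conn_probs.items()):
        n_pairs = config.n_pairs_per_type
        made = 0
        attempts = 0
        while made < n_pairs:
            attempts += 1
            if attempts > 50 * n_pairs + 100:
                raise ConfigurationError(
                    f"cannot sample pairs for {(relation, pre_layer, post_layer)}; "
                    "population too small for this relation/layer combination"
                )
            site = sites[rng.integers(len(sites))]
            pre_lab, pre_unlab = idx_by.get((site, pre_layer), ((), ()))
            post_lab, post_unlab = idx_by.get((site, post_layer), ((), ()))
            if relation == "related":
                if len(pre_lab) == 0 or len(post_lab) == 0:
                    continue
                a = pre_lab[rng.integers(len(pre_lab))]
                b = post_lab[rng.integers(len(post_lab))]
                if a == b:
                    continue
            elif relation == "unrelated":
                swap = rng.random() < 0.5
                pool_a = pre_lab if not swap else pre_unlab
                pool_b = post_unlab if not swap else post_lab
                if len(pool_a) == 0 or len(pool_b) == 0:
                    continue
                a = pool_a[rng.integers(len(pool_a))]
                b = pool_b[rng.integers(len(pool_b))]
            elif relation == "control_any_unlabeled":
                pool_a = pre_unlab
                pool_b = np.concatenate([post_lab, post_unlab])
                if len(pool_a) == 0 or len(pool_b) == 0:
                    continue
                a = pool_a[rng.integers(len(pool_a))]
                b = pool_b[rng.integers(len(pool_b))]
                if a == b:
                    continue
            else:
                raise ConfigurationError(f"unknown relation {relation!r}")
            rows.append((relation, pre_layer, post_layer, int(site), int(a), int(b)))
            made += 1

    frame = pd.DataFrame(
        rows, columns=["relation", "pre_layer", "post_layer", "site", "pre", "post"]
    )
    frame["pair_id"] = np.arange(len(frame))

    # a physical pair flagged as tested in both directions contributes two
    # independent directed Bernoulli draws; the reverse direction is only
    # testable when its probability is configured
    bidir = rng.random(len(frame)) < config.bidirectional_fraction
    rev_ok = np.array(
        [
            (r.relation, r.post_layer, r.pre_layer) in config.conn_probs
            for r in frame.itertuples()
        ]
    )
    bidir &= rev_ok
    frame["bidirectional_tested"] = bidir
    reverse = frame.loc[bidir].rename(
        columns={"pre_layer": "post_layer", "post_layer": "pre_layer", "pre": "post", "post": "pre"}
    )
    frame = pd.concat([frame, reverse], ignore_index=True)

    tang, vert, eucl = _pair_distances(
        cells, frame["pre"].to_numpy(), frame["post"].to_numpy()
    )
    p_vec = np.array(
        [
            config.conn_probs[(r.relation, r.pre_layer, r.post_layer)]
            for r in frame.itertuples()
        ]
    )
    out = pd.DataFrame(
        {
            "pre_layer": frame["pre_layer"],
            "post_layer": frame["post_layer"],
            "relation": frame["relation"],
            "connected": rng.random(len(frame)) < p_vec,
            "bidirectional_tested": frame["bidirectional_tested"].to_numpy(),
            "tangential_um": tang,
            "vertical_um": vert,
            "euclidean_um": eucl,
            "rostrocaudal": rc_by_site.loc[frame["site"]].to_numpy(),
            "clone_id": frame["site"].to_numpy(),
            "pair_id": frame["pair_id"].to_numpy(),
        }
    )
    return out


@dataclass
class ExpressionBundle:
    """Query-cell counts with metadata and (optionally) normalized values.

    ``counts`` is cells x genes; ``cells`` carries per-cell metadata aligned
    row-for-row (layer, region, label, clone, true cluster).
    """

    counts: np.ndarray
    genes: list[str]
    cells: pd.DataFrame
    lognorm: np.ndarray | None = None
    size_factors: np.ndarray | None = None

    def to_anndata(self):
        import anndata

        ad = anndata.AnnData(
            X=self.counts.astype(float),
            obs=self.cells.copy(),
            var=pd.DataFrame(index=self.genes),
        )
        if self.lognorm is not None:
            ad.layers["lognorm"] = self.lognorm
        return ad


@dataclass
class ReferenceAtlas:
    """Reference count matrix with cluster labels and a fixed 2-D embedding."""

    counts: np.ndarray
    genes: list[str]
    clusters: np.ndarray  # cluster label per reference cell
    embedding: np.ndarray  # n_cells x 2, precomputed coordinates
    class_map: dict[str, str] = field(default_factory=dict)

    def log_counts(self) -> np.ndarray:
        return np.log2(self.counts + 1.0)

    def centroids(self) -> tuple[np.ndarray, list[str]]:
        """Mean log2(x+1) profile per cluster (clusters x genes)."""
        logc = self.log_counts()
        labels = sorted(pd.unique(self.clusters))
        mat = np.vstack([logc[self.clusters == lab].mean(axis=0) for lab in labels])
        return mat, [str(lab) for lab in labels]


def _nb_counts(
    mean: np.ndarray, cfg: ExpressionConfig, rng: np.random.Generator
) -> np.ndarray:
    if cfg.poisson:
        return rng.poisson(mean)
    theta = cfg.dispersion
    return rng.negative_binomial(theta, theta / (theta + np.maximum(mean, 1e-12)))


def simulate_expression(
    cells: pd.DataFrame,
    config: SimConfig,
    seed: int | np.random.Generator = 0,
) -> tuple[ExpressionBundle, ReferenceAtlas]:
    """Cluster-structured counts for labeled cells plus a reference atlas.

    Clusters get disjoint marker genes over a shared lognormal baseline;
    query cells are the labeled cells, each assigned a true cluster by
    cycling over layers so that cluster structure correlates with anatomy.
    Reference cells are drawn from the same cluster means; the embedding
    places cluster centroids on a circle with Gaussian jitter.  Region
    identity (rostral: positions 1-2, caudal: 3-5) modulates
    ``n_region_markers`` genes in the query cells by ``region_fold``.
    """
    cfg = config.expression
    rng = _rng(seed)
    genes = [f"gene{g:04d}" for g in range(cfg.n_genes)]

    base = cfg.base_mean * rng.lognormal(0.0, 0.5, size=cfg.n_genes)
    means = np.tile(base, (cfg.n_clusters, 1))
    for c in range(cfg.n_clusters):
        start = c * cfg.n_markers_per_cluster
        means[c, start : start + cfg.n_markers_per_cluster] *= cfg.marker_fold

    query = cells[cells["tdtomato"]].reset_index(drop=True)
    if len(query) == 0:
        raise ConfigurationError("no labeled cells to profile")
    layer_order = {lay: i for i, lay in enumerate(pd.unique(query["layer"]))}
    true_cluster = np.array(
        [layer_order[lay] % cfg.n_clusters for lay in query["layer"]]
    )

    lib_q = rng.uniform(*cfg.library_size_range, size=len(query))
    mean_q = means[true_cluster] * lib_q[:, None]
    if cfg.n_region_markers > 0:
        region_genes = rng.choice(cfg.n_genes, size=cfg.n_region_markers, replace=False)
        caudal = (query["rostrocaudal"].to_numpy() >= 3).astype(float)
        mean_q[:, region_genes] *= cfg.region_fold ** caudal[:, None]
    counts_q = _nb_counts(mean_q, cfg, rng)

    meta = pd.DataFrame(
        {
            "cell_id": query["cell_id"].to_numpy(),
            "clone_id": query["clone_id"].to_numpy(),
            "layer": query["layer"].to_numpy(),
            "region": np.where(query["rostrocaudal"] >= 3, "caudal", "rostral"),
            "label": "related",
            "true_cluster": [f"cl{c}" for c in true_cluster],
        }
    )
    bundle = ExpressionBundle(counts=counts_q, genes=genes, cells=meta)

    n_ref = cfg.n_ref_cells_per_cluster * cfg.n_clusters
    ref_cluster = np.repeat(np.arange(cfg.n_clusters), cfg.n_ref_cells_per_cluster)
    lib_r = rng.uniform(*cfg.library_size_range, size=n_ref)
    counts_r = _nb_counts(means[ref_cluster] * lib_r[:, None], cfg, rng)
    angles = 2 * np.pi * np.arange(cfg.n_clusters) / cfg.n_clusters
    centers = cfg.embedding_scale * np.column_stack([np.cos(angles), np.sin(angles)])
    embedding = centers[ref_cluster] + rng.normal(
        0.0, cfg.embedding_jitter, size=(n_ref, 2)
    )
    atlas = ReferenceAtlas(
        counts=counts_r,
        genes=genes,
        clusters=np.array([f"cl{c}" for c in ref_cluster]),
        embedding=embedding,
        class_map={f"cl{c}": f"class{c % 2}" for c in range(cfg.n_clusters)},
    )
    return bundle, atlas


def simulate_study(config: SimConfig):
    """Run all three generators from one global seed via substreams."""
    rng_pop, rng_pairs, rng_expr = spawn_rngs(config.seed, 3)
    cells = simulate_clone_population(config, rng_pop)
    pairs = simulate_pair_tests(cells, config, rng_pairs)
    bundle, atlas = simulate_expression(cells, config, rng_expr)
    return cells, pairs, bundle, atlas
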