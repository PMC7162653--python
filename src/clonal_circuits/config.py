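"""Configuration dataclasses shared across the simulation and analysis modules.

Units: all distances stored in data tables are micrometres; the cortical
cylinder geometry (:class:`CylinderModel`, ``SimConfig.cylinder_radius_mm``)
is specified in millimetres, matching how cortical densities are usually
quoted (neurons per mm^2).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

LAYERS = ("L2/3", "L4", "L5", "L6")

#: depth band of each layer below the pia, in micrometres (approximate mouse
#: somatosensory values; only used to place simulated cells)
LAYER_DEPTH_UM: dict[str, tuple[float, float]] = {
    "L2/3": (100.0, 400.0),
    "L4": (400.0, 550.0),
    "L5": (550.0, 800.0),
    "L6": (800.0, 1100.0),
}

RELATIONS = ("related", "unrelated", "control_any_unlabeled")

DEFAULT_LAYER_FRACTIONS: dict[str, float] = {
    "L2/3": 0.35,
    "L4": 0.15,
    "L5": 0.25,
    "L6": 0.25,
}


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


def _check_fractions(fractions: Mapping[str, float]) -> None:
    total = float(sum(fractions.values()))
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"layer fractions must sum to 1, got {total!r}")
    for layer, f in fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ConfigurationError(f"fraction for {layer} outside [0, 1]: {f}")
        if layer not in LAYERS:
            raise ConfigurationError(f"unknown layer token {layer!r}")


@dataclass
class ExpressionConfig:
    """Parameters of the clustered negative-binomial expression generator.

    Counts for a cell in cluster ``c`` are drawn NB(mean = library-size factor
    x cluster mean, dispersion ``dispersion``); ``poisson=True`` takes the
    infinite-dispersion (Poisson) limit.  Each cluster gets
    ``n_markers_per_cluster`` private marker genes whose mean is multiplied by
    ``marker_fold``.  Region identity ("rostral"/"caudal", derived from the
    clone's rostrocaudal position) modulates ``n_region_markers`` genes by
    ``region_fold``.
    """

    n_genes: int = 300
    n_clusters: int = 4
    n_markers_per_cluster: int = 20
    base_mean: float = 2.0
    marker_fold: float = 10.0
    dispersion: float = 2.0
    poisson: bool = False
    library_size_range: tuple[float, float] = (0.5, 2.0)
    n_ref_cells_per_cluster: int = 80
    embedding_scale: float = 20.0
    embedding_jitter: float = 1.0
    n_region_markers: int = 0
    region_fold: float = 2.0

    def __post_init__(self) -> None:
        if self.dispersion <= 0 and not self.poisson:
            raise ConfigurationError("dispersion must be > 0 (or set poisson=True)")
        if self.n_clusters < 2:
            raise ConfigurationError("need >= 2 clusters with distinct means")
        if self.n_genes < self.n_clusters * self.n_markers_per_cluster:
            raise ConfigurationError("n_genes too small for the requested markers")
        lo, hi = self.library_size_range
        if not 0 < lo <= hi:
            raise ConfigurationError("library_size_range must satisfy 0 < lo <= hi")


def default_conn_probs() -> dict[tuple[str, str, str], float]:
    """Connection probabilities by (relation, pre layer, post layer).

    Defaults are the empirical rates of the paired-recording dataset shipped
    in :mod:`clonal_circuits.datasets` (related and unrelated, for every
    tested layer combination); the ``control_any_unlabeled`` relation reuses
    the unrelated rates.
    """
    from .datasets import connection_counts

    table = connection_counts()
    probs: dict[tuple[str, str, str], float] = {}
    for row in table.itertuples():
        p = row.k / row.n
        probs[(row.relation, row.pre_layer, row.post_layer)] = p
        if row.relation == "unrelated":
            probs[("control_any_unlabeled", row.pre_layer, row.post_layer)] = p
    return probs


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic clone/pair generator.

    ``clone_size`` (S) and ``n_lineages`` (N) default to the median clone of
    60 neurons pooled from 2 radial-glial lineages; ``layer_fractions`` are
    the canonical excitatory composition of the cortical cylinder.
    """

    clone_size: int = 60
    n_lineages: int = 2
    n_clones: int = 10
    layer_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LAYER_FRACTIONS)
    )
    conn_probs: dict[tuple[str, str, str], float] = field(
        default_factory=default_conn_probs
    )
    n_pairs_per_type: int = 100
    cylinder_radius_mm: float = 0.087
    neurons_per_mm2: float = 100_000.0
    excitatory_fraction: float = 0.8
    background_per_site: int | None = None  # None = fill cylinder to density
    bidirectional_fraction: float = 0.45
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clone_size < self.n_lineages or self.n_lineages < 1:
            raise ConfigurationError(
                "need clone_size >= n_lineages >= 1, got "
                f"{self.clone_size} / {self.n_lineages}"
            )
        if self.n_clones < 1:
            raise ConfigurationError("n_clones must be >= 1")
        if self.n_pairs_per_type < 0:
            raise ConfigurationError("n_pairs_per_type must be >= 0")
        _check_fractions(self.layer_fractions)
        for key, p in self.conn_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"connection probability {key} outside [0,1]")
        if self.cylinder_radius_mm <= 0:
            raise ConfigurationError("cylinder radius must be positive")

    @property
    def cells_per_cylinder(self) -> float:
        """Total excitatory cells in one cylinder at the configured density."""
        r = self.cylinder_radius_mm
        return float(np.pi * r * r * self.neurons_per_mm2 * self.excitatory_fraction)


@dataclass
class PowerConfig:
    """Inputs of the lineage-pooling power analysis.

    Defaults are the observed rates: unrelated lateral 51/626, unrelated
    vertical 19/711, related (clone-pooled) vertical 28/464; clone size S=60
    spread over L=4 layers; lateral comparison sample sizes 626 and 248.
    """

    p_ul: float = 51 / 626
    p_uv: float = 19 / 711
    p_rv: float = 28 / 464
    S: float = 60.0
    L: float = 4.0
    N: int = 2
    FC: float | None = None
    n1: int = 626
    n2: int = 248
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("p_ul", "p_uv", "p_rv"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} outside [0, 1]: {v}")
        if self.S / (self.N * self.L) < 1:
            raise ConfigurationError(
                "S/(N*L) must be >= 1 so the same-lineage pool is nonnegative"
            )
        if self.n1 < 2 or self.n2 < 2:
            raise ConfigurationError("group sizes must be >= 2")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")


@dataclass
class CylinderModel:
    """Composition of the cortical cylinder feeding the input-fraction model.

    A 1 mm^2 slab of cortex holds ~100,000 neurons, 80% excitatory; a cell is
    assumed to receive input only from within tangential radius ``radius_mm``
    (0.087 mm, half the 99% quantile of recorded pairwise distances).  With
    those defaults the cylinder holds pi r^2 x 80,000 ~ 1902 excitatory
    neurons; ``total_override=1908`` reproduces published round-offs exactly
    (the printed radius is itself rounded).  ``clone_size`` k sets the related
    fraction q_r = k / N_total.
    """

    neurons_per_mm2: float = 100_000.0
    excitatory_fraction: float = 0.8
    radius_mm: float = 0.087
    layer_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LAYER_FRACTIONS)
    )
    clone_size: float = 60.0
    total_override: float | None = None

    def __post_init__(self) -> None:
        _check_fractions(self.layer_fractions)
        if self.total_excitatory <= 0:
            raise ConfigurationError("cylinder must contain a positive cell count")
        if not 0.0 < self.q_related < 1.0:
            raise ConfigurationError("q_r = clone_size / N_total must lie in (0, 1)")

    @property
    def total_excitatory(self) -> float:
        if self.total_override is not None:
            return float(self.total_override)
        r = self.radius_mm
        return float(np.pi * r * r * self.neurons_per_mm2 * self.excitatory_fraction)

    @property
    def q_related(self) -> float:
        return self.clone_size / self.total_excitatory


@dataclass
class VariableGeneParams:
    """Dropout-curve variable-gene selection parameters.

    A gene needs counts above ``count_threshold`` in at least ``min_cells``
    cells to be considered; mu is its mean log2 count over counts strictly
    above the threshold and tau the fraction strictly below; the selector
    binary-searches the offset b so that ``n_target`` genes satisfy
    tau > exp(slope * mu + b) + margin.
    """

    count_threshold: float = 32.0
    min_cells: int = 10
    slope: float = -1.5
    margin: float = 0.02
    n_target: int = 3000

    def __post_init__(self) -> None:
        if self.count_threshold <= 0:
            raise ConfigurationError("count_threshold must be positive")
        if self.n_target < 1:
            raise ConfigurationError("n_target must be >= 1")


def normalize_layer(token: str) -> str:
    """Map a layer alias ("L23", "l2/3", "2/3") to the canonical token."""
    t = str(token).strip().upper().lstrip("L")
    aliases = {"2/3": "L2/3", "23": "L2/3", "4": "L4", "5": "L5", "6": "L6"}
    if t in aliases:
        return aliases[t]
    raise ConfigurationError(f"unrecognized layer token {token!r}")


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Expand one global seed into independent per-operation substreams."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def as_dict(cfg) -> dict:
    """Dataclass -> JSON-serializable dict (tuple keys flattened to strings)."""
    d = dataclasses.asdict(cfg)

    def fix(value):
        if isinstance(value, dict):
            return {
                ("|".join(k) if isinstance(k, tuple) else k): fix(v)
                for k, v in value.items()
            }
        if isinstance(value, tuple):
            return list(value)
        return value

    return fix(d)
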