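"""Synthetic structural connectomes and damage maps.

The simulations run on a sparse, symmetric structural network of cortical
regions with 3-D coordinates (coordinates set the axonal conduction delays
between regions). Published atlas-based structural matrices are not shipped;
instead a distance-biased random graph with mirrored hemispheres emulates the
gross organisation of such networks: short-range connections are more probable
than long-range ones, and the two hemispheres are geometric mirror images.

Damage maps describe where and how strongly pathology strikes: a boolean edge
mask of white-matter predilection sites (biased toward long, periventricular-
like tracts), a per-region cortical atrophy map of maximal fractional
reductions, and a single scalar for thalamic volume loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "Connectome",
    "DamageMaps",
    "generate_connectome",
    "generate_damage_maps",
    "delay_matrix",
    "read_connectome",
    "write_connectome",
    "read_damage_maps",
    "write_damage_maps",
]


@dataclass
class Connectome:
    """A weighted, undirected structural brain network.

    Attributes
    ----------
    n_regions:
        Number of regions (nodes).
    adjacency:
        Symmetric non-negative ``(n, n)`` matrix with zero diagonal.
    coordinates:
        ``(n, 3)`` region centroids in mm; the first axis separates the
        hemispheres (negative x = left, positive x = right).
    labels:
        Region name per node.
    hemisphere:
        ``"left"`` or ``"right"`` per node.
    """

    n_regions: int
    adjacency: np.ndarray
    coordinates: np.ndarray
    labels: list[str] = field(default_factory=list)
    hemisphere: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not self.labels:
            self.labels = [f"R{i:03d}" for i in range(self.n_regions)]
        if not self.hemisphere:
            self.hemisphere = [
                "left" if x < 0 else "right" for x in self.coordinates[:, 0]
            ]

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        n = self.n_regions
        A = self.adjacency
        if A.shape != (n, n):
            raise ValueError(f"adjacency shape {A.shape} != ({n}, {n})")
        bad = np.argwhere(~np.isclose(A, A.T))
        if bad.size:
            raise ValueError(f"adjacency not symmetric at entries {bad[:5].tolist()}")
        neg = np.argwhere(A < 0)
        if neg.size:
            raise ValueError(f"negative adjacency entries at {neg[:5].tolist()}")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if self.coordinates.shape != (n, 3):
            raise ValueError("coordinates must be (n, 3)")
        n_comp, _ = connected_components(A > 0, directed=False)
        if n_comp != 1:
            raise ValueError(f"structural graph is disconnected ({n_comp} components)")

    @property
    def distances(self) -> np.ndarray:
        """Euclidean inter-region distances in mm, ``(n, n)``."""
        return squareform(pdist(self.coordinates))

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    def edge_list(self) -> np.ndarray:
        """Upper-triangle ``(m, 2)`` index pairs of existing edges."""
        return np.argwhere(np.triu(self.adjacency, 1) > 0)

    def copy(self) -> "Connectome":
        return Connectome(
            self.n_regions,
            self.adjacency.copy(),
            self.coordinates.copy(),
            list(self.labels),
            list(self.hemisphere),
        )


@dataclass
class DamageMaps:
    """Spatial maps of where structural damage is applied.

    ``wm_mask`` marks predilection-site edges (symmetric boolean matrix);
    ``cortical_map`` gives each region's maximal fractional loss of
    intracortical connection density; ``thalamic_max_fraction`` is the global
    maximal fractional loss of intrathalamic density (default 0.11, i.e. the
    relative thalamic volume loss 1 - 18.50/20.78 reported for longstanding
    disease).
    """

    wm_mask: np.ndarray
    cortical_map: np.ndarray
    wm_max_fraction: float = 0.14
    thalamic_max_fraction: float = 0.11

    def validate(self, connectome: Connectome | None = None) -> None:
        mask = np.asarray(self.wm_mask, dtype=bool)
        if not np.array_equal(mask, mask.T):
            raise ValueError("wm_mask must be symmetric")
        for name, f in (
            ("wm_max_fraction", self.wm_max_fraction),
            ("thalamic_max_fraction", self.thalamic_max_fraction),
        ):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name}={f} outside [0, 1]")
        cm = np.asarray(self.cortical_map, dtype=float)
        if np.any((cm < 0) | (cm > 1)):
            raise ValueError("cortical_map entries must lie in [0, 1]")
        if connectome is not None and np.any(mask & (connectome.adjacency == 0)):
            raise ValueError("wm_mask marks edges absent from the adjacency")


def generate_connectome(
    n_regions: int = 78,
    edge_density: float = 0.15,
    seed: int = 0,
    hemisphere_half_width: float = 70.0,
    jitter_sigma: float = 0.35,
) -> Connectome:
    """Generate a connected, distance-biased random connectome.

    Regions are placed uniformly inside two mirrored boxes of half-width
    ``hemisphere_half_width`` mm (one per hemisphere); edges are then taken
    in order of jittered Euclidean distance under a per-node degree cap, so
    that near regions are preferentially connected and the degree
    distribution stays narrow — mimicking the short-range-dominated, fairly
    degree-homogeneous organisation of atlas-based cortical structural
    networks. A Euclidean minimum spanning tree is always included,
    guaranteeing connectivity. Adjacency is binary 0/1.

    ``jitter_sigma`` sets the multiplicative log-normal jitter applied to
    distances before ranking; larger values make the topology more random.
    Deterministic for a fixed ``seed``.
    """
    if n_regions < 4:
        raise ValueError("n_regions must be >= 4")
    if not 0.0 < edge_density <= 1.0:
        raise ValueError("edge_density must lie in (0, 1]")
    n_pairs = n_regions * (n_regions - 1) // 2
    m_target = int(round(edge_density * n_pairs))
    if m_target < n_regions - 1:
        raise ValueError(
            f"edge_density={edge_density} yields {m_target} edges; a connected "
            f"graph on {n_regions} nodes needs at least {n_regions - 1}"
        )

    rng = np.random.default_rng(seed)
    n_left = (n_regions + 1) // 2
    # left hemisphere: x in [-w, -5]; right is the mirror image
    w = hemisphere_half_width
    left = np.column_stack(
        [
            rng.uniform(-w, -5.0, n_left),
            rng.uniform(-90.0, 60.0, n_left),
            rng.uniform(-40.0, 70.0, n_left),
        ]
    )
    right = left[: n_regions - n_left] * np.array([-1.0, 1.0, 1.0])
    coords = np.vstack([left, right])

    dist = squareform(pdist(coords))
    # spanning backbone over Euclidean distance keeps the graph connected
    mst = minimum_spanning_tree(dist).toarray()
    A = ((mst + mst.T) > 0).astype(float)

    iu = np.triu_indices(n_regions, 1)
    jitter = rng.lognormal(0.0, jitter_sigma, iu[0].size)
    order = np.argsort(dist[iu] * jitter)
    degree_cap = int(np.ceil(2.0 * m_target / n_regions)) + 1
    degree = A.sum(axis=1)
    m_current = int(A[iu].sum())
    for relax in (0, n_regions):  # second pass lifts the cap if short
        for k in order:
            if m_current >= m_target:
                break
            i, j = int(iu[0][k]), int(iu[1][k])
            if A[i, j] == 0 and degree[i] < degree_cap + relax \
                    and degree[j] < degree_cap + relax:
                A[i, j] = A[j, i] = 1.0
                degree[i] += 1
                degree[j] += 1
                m_current += 1

    labels = [f"L{i:02d}" for i in range(n_left)] + [
        f"R{i:02d}" for i in range(n_regions - n_left)
    ]
    hemi = ["left"] * n_left + ["right"] * (n_regions - n_left)
    c = Connectome(n_regions, A, coords, labels, hemi)
    c.validate()
    return c


def generate_damage_maps(
    connectome: Connectome,
    wm_site_fraction: float = 0.3,
    seed: int = 0,
    cortical_range: tuple[float, float] = (0.02, 0.15),
    wm_max_fraction: float = 0.14,
    thalamic_max_fraction: float = 0.11,
) -> DamageMaps:
    """Draw damage maps on an existing connectome.

    ``wm_site_fraction`` of the existing edges are marked as predilection
    sites, sampled with probability proportional to their Euclidean length
    (long, periventricular-like tracts are preferentially hit). The cortical
    atrophy map is drawn uniformly in ``cortical_range`` — fractional
    thickness losses consistent with those reported for longstanding disease.
    """
    if not 0.0 < wm_site_fraction <= 1.0:
        raise ValueError("wm_site_fraction must lie in (0, 1]")
    lo, hi = cortical_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("cortical_range must be ordered and within [0, 1]")

    rng = np.random.default_rng(seed)
    edges = connectome.edge_list()
    m = len(edges)
    k = max(1, int(round(wm_site_fraction * m)))
    lengths = connectome.distances[edges[:, 0], edges[:, 1]]
    if k >= m:
        chosen = np.arange(m)
    else:
        p = lengths / lengths.sum()
        chosen = rng.choice(m, size=k, replace=False, p=p)
    mask = np.zeros_like(connectome.adjacency, dtype=bool)
    rows, cols = edges[chosen, 0], edges[chosen, 1]
    mask[rows, cols] = True
    mask[cols, rows] = True

    cortical = rng.uniform(lo, hi, connectome.n_regions)
    maps = DamageMaps(
        wm_mask=mask,
        cortical_map=cortical,
        wm_max_fraction=wm_max_fraction,
        thalamic_max_fraction=thalamic_max_fraction,
    )
    maps.validate(connectome)
    return maps


def delay_matrix(connectome: Connectome, velocity: float = 10.0) -> np.ndarray:
    """Axonal conduction delays in seconds, ``tau[j, n] = d_jn / velocity``.

    ``velocity`` is the conduction velocity in m/s (coordinates are in mm).
    Entries are zero on the diagonal and for unconnected pairs, which carry
    no signal.
    """
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    if not np.all(np.isfinite(connectome.coordinates)):
        raise ValueError("non-finite coordinates")
    tau = connectome.distances / 1000.0 / velocity
    tau[connectome.adjacency == 0] = 0.0
    np.fill_diagonal(tau, 0.0)
    return tau


# -- plain-text I/O --------------------------------------------------------

def write_connectome(connectome: Connectome, directory: str | Path) -> None:
    """Persist as header-free adjacency TSV plus a regions table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / "adjacency.tsv", connectome.adjacency,
               delimiter="\t", fmt="%.17g")
    df = pd.DataFrame(
        {
            "label": connectome.labels,
            "hemisphere": connectome.hemisphere,
            "x_mm": connectome.coordinates[:, 0],
            "y_mm": connectome.coordinates[:, 1],
            "z_mm": connectome.coordinates[:, 2],
        }
    )
    df.to_csv(directory / "regions.tsv", sep="\t", index=False,
              float_format="%.17g")


def read_connectome(directory: str | Path) -> Connectome:
    """Load a connectome written by :func:`write_connectome`, validating it."""
    directory = Path(directory)
    A = np.loadtxt(directory / "adjacency.tsv", delimiter="\t", ndmin=2)
    df = pd.read_csv(directory / "regions.tsv", sep="\t",
                     float_precision="round_trip")
    coords = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        bad = df.index[~np.isfinite(coords).all(axis=1)].tolist()
        raise ValueError(f"non-finite coordinates for regions {bad}")
    c = Connectome(
        n_regions=A.shape[0],
        adjacency=A,
        coordinates=coords,
        labels=df["label"].astype(str).tolist(),
        hemisphere=df["hemisphere"].astype(str).tolist(),
    )
    c.validate()
    return c


def write_damage_maps(maps: DamageMaps, directory: str | Path,
                      labels: list[str] | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pairs = np.argwhere(np.triu(maps.wm_mask, 1))
    pd.DataFrame(pairs, columns=["i", "j"]).to_csv(
        directory / "wm_mask.tsv", sep="\t", index=False)
    n = len(maps.cortical_map)
    if labels is None:
        labels = [f"R{i:03d}" for i in range(n)]
    pd.DataFrame({"label": labels, "max_fraction": maps.cortical_map}).to_csv(
        directory / "cortical_map.tsv", sep="\t", index=False,
        float_format="%.17g")
    (directory / "damage_scalars.json").write_text(json.dumps({
        "wm_max_fraction": maps.wm_max_fraction,
        "thalamic_max_fraction": maps.thalamic_max_fraction,
        "n_regions": n,
    }, indent=2))


def read_damage_maps(directory: str | Path) -> DamageMaps:
    directory = Path(directory)
    scalars = json.loads((directory / "damage_scalars.json").read_text())
    n = scalars["n_regions"]
    pairs = pd.read_csv(directory / "wm_mask.tsv", sep="\t").to_numpy(int)
    mask = np.zeros((n, n), dtype=bool)
    if pairs.size:
        mask[pairs[:, 0], pairs[:, 1]] = True
        mask[pairs[:, 1], pairs[:, 0]] = True
    cortical = pd.read_csv(directory / "cortical_map.tsv", sep="\t",
                           float_precision="round_trip")[
        "max_fraction"].to_numpy(float)
    maps = DamageMaps(
        wm_mask=mask,
        cortical_map=cortical,
        wm_max_fraction=scalars["wm_max_fraction"],
        thalamic_max_fraction=scalars["thalamic_max_fraction"],
    )
    maps.validate()
    return maps
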