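"""Self-organizing-map classification of daily pressure patterns (Method A).

A 4x4 Kohonen lattice is trained on flattened daily sea-level-pressure
rasters so that each node's codebook vector is a canonical winter synoptic
pattern (e.g. a deep low east of the site). Observation days are assigned to
their best-matching unit (BMU, minimum Euclidean distance) and each node
carries an empirical sighting probability ``n_sighted / n_days``; a forecast
pressure snapshot is classified to its BMU and inherits that probability.

Training is the deterministic batch algorithm: the codebook is initialized
on the plane of the first two principal components of the inputs, then per
epoch every input is assigned to its BMU and every codebook vector is
recomputed as the Gaussian-neighborhood-weighted mean of the inputs, with
the neighborhood radius shrinking linearly from ``max(rows, cols)/2`` to
0.5. Batch updates plus PCA initialization make retraining reproducible,
which a forecast product needs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import xarray as xr

from .errors import FormatError, TrainingError
from .metfields import GridField, flatten_pattern

DEFAULT_ROWS = 4
DEFAULT_COLS = 4
DEFAULT_ITERATIONS = 100
QE_TOL = 1e-6


@dataclass
class SomModel:
    """Trained SOM: codebook vectors on a rows x cols lattice.

    ``node_frequency[k]`` is the fraction of training days whose BMU is node
    k (the climatological frequency of that weather pattern). Nodes are
    numbered row-major 1..rows*cols, reported as #001..#016.
    """

    grid_rows: int
    grid_cols: int
    codebook: np.ndarray        # (n_nodes, n_features)
    node_frequency: np.ndarray  # (n_nodes,)
    n_inputs: int
    iterations_run: int
    seed: int | None
    quantization_error: float
    latitudes: np.ndarray | None = None
    longitudes: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.grid_rows * self.grid_cols

    def node_label(self, node_id: int) -> str:
        return f"#{node_id + 1:03d}"

    def lattice_position(self, node_id: int) -> tuple[int, int]:
        return divmod(node_id, self.grid_cols)


def _lattice_coords(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(float)


def _pca_init(x: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Spread the initial codebook over the first two principal directions.

    Component signs are disambiguated by making each PC's largest-magnitude
    loading positive, so initialization is deterministic.
    """
    mean = x.mean(axis=0)
    xc = x - mean
    # SVD of the centered data; right singular vectors are the PCs
    _, s, vt = np.linalg.svd(xc, full_matrices=False)
    n = x.shape[0]
    pcs, sds = [], []
    for i in range(min(2, vt.shape[0])):
        v = vt[i]
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            v = -v
        pcs.append(v)
        sds.append(s[i] / np.sqrt(max(n - 1, 1)))
    while len(pcs) < 2:  # degenerate rank-deficient input
        pcs.append(np.zeros(x.shape[1]))
        sds.append(0.0)
    a = np.linspace(-2.0, 2.0, rows) * sds[0] if rows > 1 else np.zeros(1)
    b = np.linspace(-2.0, 2.0, cols) * sds[1] if cols > 1 else np.zeros(1)
    code = np.empty((rows * cols, x.shape[1]))
    for r in range(rows):
        for c in range(cols):
            code[r * cols + c] = mean + a[r] * pcs[0] + b[c] * pcs[1]
    return code


def _bmus(codebook: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """BMU index and distance per input row (ties -> lowest node id)."""
    # ||x-w||^2 = ||x||^2 - 2 x.w + ||w||^2 ; argmin is tie-stable (first min)
    d2 = (
        np.einsum("ij,ij->i", x, x)[:, None]
        - 2.0 * x @ codebook.T
        + np.einsum("ij,ij->i", codebook, codebook)[None, :]
    )
    np.maximum(d2, 0.0, out=d2)
    bmu = np.argmin(d2, axis=1)
    return bmu, np.sqrt(d2[np.arange(len(x)), bmu])


def train_som(
    patterns,
    rows: int = DEFAULT_ROWS,
    cols: int = DEFAULT_COLS,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = 0,
    latitudes=None,
    longitudes=None,
) -> SomModel:
    """Batch-train a SOM on flattened pressure-pattern vectors.

    Stops after ``iterations`` epochs or when the mean quantization error
    changes by less than 1e-6 between epochs.
    """
    x = np.asarray(patterns, dtype=float)
    if x.ndim != 2:
        raise FormatError("patterns must be a 2-D array (n_days, n_features)")
    if len({row.size for row in x}) > 1:
        raise FormatError("pattern vectors differ in length")
    n_nodes = rows * cols
    if x.shape[0] < n_nodes:
        raise TrainingError(
            f"need at least {n_nodes} patterns, got {x.shape[0]}"
        )

    codebook = _pca_init(x, rows, cols)
    lattice = _lattice_coords(rows, cols)
    lat2 = ((lattice[:, None, :] - lattice[None, :, :]) ** 2).sum(-1)

    r0 = max(rows, cols) / 2.0
    r1 = 0.5
    prev_qe = np.inf
    epochs_run = 0
    for epoch in range(iterations):
        frac = epoch / max(iterations - 1, 1)
        radius = r0 + (r1 - r0) * frac
        bmu, dist = _bmus(codebook, x)
        qe = float(dist.mean())
        h = np.exp(-lat2 / (2.0 * radius * radius))  # (nodes, nodes)
        w = h[bmu]                                   # (n, nodes) input weights
        denom = w.sum(axis=0)
        num = w.T @ x
        nonzero = denom > 1e-300
        codebook[nonzero] = num[nonzero] / denom[nonzero, None]
        epochs_run = epoch + 1
        if abs(prev_qe - qe) < QE_TOL:
            break
        prev_qe = qe

    bmu, dist = _bmus(codebook, x)
    freq = np.bincount(bmu, minlength=n_nodes) / x.shape[0]
    return SomModel(
        grid_rows=rows,
        grid_cols=cols,
        codebook=codebook,
        node_frequency=freq,
        n_inputs=x.shape[0],
        iterations_run=epochs_run,
        seed=seed,
        quantization_error=float(dist.mean()),
        latitudes=None if latitudes is None else np.asarray(latitudes, float),
        longitudes=None if longitudes is None else np.asarray(longitudes, float),
    )


def assign_node(model: SomModel, pattern) -> tuple[int, float]:
    """BMU of one pattern: (node_id, Euclidean distance); ties go to the
    lowest node id."""
    p = np.asarray(pattern, dtype=float).reshape(1, -1)
    if p.shape[1] != model.codebook.shape[1]:
        raise FormatError(
            f"pattern length {p.shape[1]} != codebook length "
            f"{model.codebook.shape[1]}"
        )
    bmu, dist = _bmus(model.codebook, p)
    return int(bmu[0]), float(dist[0])


@dataclass
class NodeProbabilityTable:
    """Per-node sighting counts and empirical probabilities.

    A node that received no observation days has ``probability`` NaN and is
    flagged missing: 0/0 is no evidence of absence, and a forecast landing
    there reports "missing" rather than 0%.
    """

    n_days: np.ndarray     # (n_nodes,) int
    n_sighted: np.ndarray  # (n_nodes,) int

    @property
    def probability(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.n_days > 0, self.n_sighted / np.maximum(self.n_days, 1), np.nan
            )

    @property
    def missing(self) -> np.ndarray:
        return self.n_days == 0

    def as_dict(self) -> dict:
        return {
            "n_days": self.n_days.tolist(),
            "n_sighted": self.n_sighted.tolist(),
            "probability": [
                None if m else float(p)
                for p, m in zip(self.probability, self.missing)
            ],
        }


def node_probabilities(model: SomModel, observation_days) -> NodeProbabilityTable:
    """Tally sighted/total observation days per BMU.

    ``observation_days`` is an iterable of (pattern_vector, sighted: bool);
    days should already be effort-filtered by the caller.
    """
    n_days = np.zeros(model.n_nodes, dtype=int)
    n_sighted = np.zeros(model.n_nodes, dtype=int)
    for pattern, sighted in observation_days:
        node, _ = assign_node(model, pattern)
        n_days[node] += 1
        if sighted:
            n_sighted[node] += 1
    if (n_sighted > n_days).any():
        raise AssertionError("n_sighted exceeded n_days")  # unreachable
    return NodeProbabilityTable(n_days=n_days, n_sighted=n_sighted)


def forecast_method_a(
    model: SomModel, table: NodeProbabilityTable, snapshot: GridField
) -> tuple[float | None, int, float]:
    """Classify a forecast pressure snapshot and return its node's sighting
    probability.

    Returns (probability or None, node_id, bmu_distance); probability is
    None (missing) when the BMU node had no observation days.
    """
    if model.latitudes is not None:
        if (
            snapshot.nlat != len(model.latitudes)
            or snapshot.nlon != len(model.longitudes)
            or not np.allclose(snapshot.latitudes, model.latitudes)
            or not np.allclose(snapshot.longitudes, model.longitudes)
        ):
            raise FormatError("snapshot grid does not match the training grid")
    vec = flatten_pattern(snapshot)
    node, dist = assign_node(model, vec)
    if table.missing[node]:
        return None, node, dist
    return float(table.probability[node]), node, dist


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_som(model: SomModel, path) -> None:
    """Persist as NetCDF: codebook as (node, lat, lon) when the training grid
    is known, else as (node, feature)."""
    if model.latitudes is not None:
        nlat, nlon = len(model.latitudes), len(model.longitudes)
        da = xr.DataArray(
            model.codebook.reshape(model.n_nodes, nlat, nlon),
            coords={
                "node": np.arange(model.n_nodes),
                "lat": model.latitudes,
                "lon": model.longitudes,
            },
            dims=("node", "lat", "lon"),
            name="codebook",
        )
    else:
        da = xr.DataArray(
            model.codebook,
            coords={"node": np.arange(model.n_nodes)},
            dims=("node", "feature"),
            name="codebook",
        )
    ds = da.to_dataset()
    ds["node_frequency"] = ("node", model.node_frequency)
    ds.attrs.update(
        grid_rows=model.grid_rows,
        grid_cols=model.grid_cols,
        n_inputs=model.n_inputs,
        iterations_run=model.iterations_run,
        seed=-1 if model.seed is None else model.seed,
        quantization_error=model.quantization_error,
    )
    ds.to_netcdf(path, engine="scipy")


def load_som(path) -> SomModel:
    with xr.open_dataset(path, engine="scipy") as ds:
        code = np.asarray(ds["codebook"].values, dtype=float)
        lats = lons = None
        if code.ndim == 3:
            lats = np.asarray(ds["lat"].values, dtype=float)
            lons = np.asarray(ds["lon"].values, dtype=float)
            code = code.reshape(code.shape[0], -1)
        seed = int(ds.attrs["seed"])
        return SomModel(
            grid_rows=int(ds.attrs["grid_rows"]),
            grid_cols=int(ds.attrs["grid_cols"]),
            codebook=code,
            node_frequency=np.asarray(ds["node_frequency"].values, dtype=float),
            n_inputs=int(ds.attrs["n_inputs"]),
            iterations_run=int(ds.attrs["iterations_run"]),
            seed=None if seed == -1 else seed,
            quantization_error=float(ds.attrs["quantization_error"]),
            latitudes=lats,
            longitudes=lons,
        )


def save_node_table(table: NodeProbabilityTable, path) -> None:
    with open(path, "w") as fh:
        json.dump(table.as_dict(), fh, indent=2)


def load_node_table(path) -> NodeProbabilityTable:
    with open(path) as fh:
        d = json.load(fh)
    return NodeProbabilityTable(
        n_days=np.asarray(d["n_days"], dtype=int),
        n_sighted=np.asarray(d["n_sighted"], dtype=int),
    )
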