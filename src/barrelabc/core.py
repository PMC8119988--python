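"""Connectome data model, validation, binarization and Matrix Market I/O.

A connectome is a signed directed graph over a population of excitatory and
inhibitory neurons.  The adjacency convention throughout the package is
``A[post, pre]``: entry ``(i, j)`` is nonzero iff presynaptic neuron ``j``
connects to postsynaptic neuron ``i``.  The sign of every entry in column
``j`` equals the sign of neuron ``j``'s type (+1 excitatory, -1 inhibitory).
Excitatory neurons occupy indices ``0 .. n_e-1``, inhibitory neurons
``n_e .. n-1``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "BarrelConfig",
    "Connectome",
    "ReconstructionBudget",
    "validate",
    "binarize",
    "write_connectome",
    "read_connectome",
]


@dataclass(frozen=True)
class BarrelConfig:
    """Circuit constraints of a layer-4 barrel module.

    Defaults follow the experimentally established constraints: 1800
    excitatory and 200 inhibitory neurons, excitatory connection probability
    p_e = p_ee = p_ei = 0.2, inhibitory connection probability
    p_i = p_ii = p_ie = 0.6, excitatory-excitatory reciprocity in
    [0.15, 0.35], and a cubic volume of side 300 um.
    """

    n_e: int = 1800
    n_i: int = 200
    p_e: float = 0.2
    p_i: float = 0.6
    r_ee_range: tuple[float, float] = (0.15, 0.35)
    p_ee_range: tuple[float, float] = (0.15, 0.25)
    barrel_side: float = 300.0

    def __post_init__(self) -> None:
        if self.n_e < 0 or self.n_i < 0:
            raise ValueError("population sizes must be non-negative")
        if not (0.0 <= self.p_e <= 1.0 and 0.0 <= self.p_i <= 1.0):
            raise ValueError("connection probabilities must lie in [0, 1]")
        lo, hi = self.r_ee_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("r_ee_range must be a sub-interval of [0, 1]")

    @property
    def n(self) -> int:
        return self.n_e + self.n_i

    @property
    def r_i(self) -> float:
        """Inhibitory fraction of the population."""
        return self.n_i / self.n

    def scaled(self, n: int) -> "BarrelConfig":
        """Return a configuration with the same composition at total size n."""
        n_i = int(round(n * self.r_i))
        return BarrelConfig(
            n_e=n - n_i,
            n_i=n_i,
            p_e=self.p_e,
            p_i=self.p_i,
            r_ee_range=self.r_ee_range,
            p_ee_range=self.p_ee_range,
            barrel_side=self.barrel_side,
        )


@dataclass(frozen=True)
class ReconstructionBudget:
    """Inputs of the annotation time / synapse count estimate.

    path_density: km of neurite path per mm^3 of tissue.
    volume_mm3:   reconstructed tissue volume in mm^3.
    speed_mm_h:   annotation speed in mm of path per work hour.
    synapses_per_connection: mean number of synapses per connected pair.
    measured_fraction: fraction of neurons reconstructed (f_m).
    """

    path_density: float = 10.0
    volume_mm3: float = 0.3**3
    speed_mm_h: float = 1.5
    synapses_per_connection: float = 3.36
    measured_fraction: float = 1.0

    def __post_init__(self) -> None:
        for name in ("path_density", "volume_mm3", "speed_mm_h",
                     "synapses_per_connection", "measured_fraction"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.measured_fraction > 1:
            raise ValueError("measured_fraction must be <= 1")


class Connectome:
    """Signed directed connectome with neuron type labels.

    Parameters
    ----------
    adjacency : scipy sparse or dense array, shape (n, n)
        Signed adjacency with convention ``A[post, pre]``.
    types : array-like of {+1, -1}, length n
        +1 for excitatory, -1 for inhibitory neurons.
    positions : ndarray (n, 3), optional
        Soma positions in micrometres.
    binary : bool
        Whether all weights are in {0, +1, -1}.
    provenance : dict, optional
        Generator name, parameters and seed used to create the graph.
    """

    def __init__(self, adjacency, types, positions=None, binary=False,
                 provenance=None):
        adjacency = sp.csr_matrix(adjacency)
        types = np.asarray(types, dtype=np.int8)
        if adjacency.shape[0] != adjacency.shape[1]:
            raise ValueError("adjacency must be square")
        if adjacency.shape[0] != types.shape[0]:
            raise ValueError(
                f"adjacency is {adjacency.shape[0]}x{adjacency.shape[0]} but "
                f"{types.shape[0]} neuron types were given")
        if positions is not None:
            positions = np.asarray(positions, dtype=float)
            if positions.shape != (types.shape[0], 3):
                raise ValueError("positions must have shape (n, 3)")
        self.adjacency = adjacency
        self.types = types
        self.positions = positions
        self.binary = bool(binary)
        self.provenance = dict(provenance or {})

    # -- basic structure ---------------------------------------------------
    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def exc_mask(self) -> np.ndarray:
        return self.types > 0

    @property
    def inh_mask(self) -> np.ndarray:
        return self.types < 0

    @property
    def n_e(self) -> int:
        return int(self.exc_mask.sum())

    @property
    def n_i(self) -> int:
        return int(self.inh_mask.sum())

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz)

    def copy(self) -> "Connectome":
        return Connectome(self.adjacency.copy(), self.types.copy(),
                          None if self.positions is None else self.positions.copy(),
                          self.binary, dict(self.provenance))

    def support(self) -> sp.csr_matrix:
        """Unsigned {0,1} adjacency (int8 CSR)."""
        out = self.adjacency.copy()
        out.data = np.ones_like(out.data, dtype=np.int8)
        return out.astype(np.int8)

    def __repr__(self) -> str:  # pragma: no cover
        model = self.provenance.get("model", "?")
        return (f"<Connectome n={self.n} (e={self.n_e}, i={self.n_i}) "
                f"edges={self.n_edges} model={model}>")


def binarize(connectome: Connectome) -> Connectome:
    """Map every weight to +-1 preserving its sign; idempotent."""
    adj = connectome.adjacency.copy()
    adj.data = np.sign(adj.data).astype(np.int8)
    adj.eliminate_zeros()
    return Connectome(adj, connectome.types, connectome.positions,
                      binary=True, provenance=connectome.provenance)


def validate(connectome: Connectome, barrel_side: float | None = None) -> list[dict]:
    """Check connectome invariants; return one record per violation.

    Checks: no self-connections; every nonzero column entry carries the sign
    of the presynaptic neuron's type; positions (when present) lie inside the
    barrel cube.
    """
    violations: list[dict] = []
    adj = sp.coo_matrix(connectome.adjacency)
    self_loops = np.flatnonzero(adj.row == adj.col)
    for k in self_loops:
        violations.append({"kind": "self-connection", "neuron": int(adj.row[k])})
    pre_sign = connectome.types[adj.col]
    mismatch = np.flatnonzero(np.sign(adj.data) != pre_sign)
    for k in mismatch:
        violations.append({
            "kind": "sign mismatch",
            "pre": int(adj.col[k]),
            "post": int(adj.row[k]),
            "weight": float(adj.data[k]),
        })
    if connectome.positions is not None:
        side = barrel_side if barrel_side is not None else float(
            connectome.provenance.get("barrel_side", np.inf))
        bad = np.flatnonzero(
            (connectome.positions < 0).any(axis=1)
            | (connectome.positions > side).any(axis=1))
        for k in bad:
            violations.append({"kind": "out-of-range position", "neuron": int(k)})
    return violations


# -- I/O -------------------------------------------------------------------

def write_connectome(connectome: Connectome, path) -> None:
    """Write adjacency as Matrix Market plus a JSON metadata sidecar.

    ``path`` is a prefix: ``<path>.mtx`` and ``<path>.json`` are written.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mmwrite(str(path.with_suffix(".mtx")), connectome.adjacency.tocoo())
    meta = {
        "n": connectome.n,
        "types": ["e" if t > 0 else "i" for t in connectome.types],
        "positions": None if connectome.positions is None
        else connectome.positions.tolist(),
        "binary": connectome.binary,
        "model": connectome.provenance.get("model"),
        "params": connectome.provenance.get("params"),
        "seed": connectome.provenance.get("seed"),
    }
    extra = {k: v for k, v in connectome.provenance.items()
             if k not in ("model", "params", "seed")}
    if extra:
        meta["provenance_extra"] = extra
    with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh)


def read_connectome(path) -> Connectome:
    """Read a connectome written by :func:`write_connectome`."""
    path = Path(path)
    mtx_path = path.with_suffix(".mtx")
    json_path = path.with_suffix(".json")
    if not json_path.exists():
        raise FileNotFoundError(f"missing metadata sidecar {json_path}")
    with open(json_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    adj = sp.csr_matrix(mmread(str(mtx_path)))
    types = np.array([1 if t == "e" else -1 for t in meta["types"]],
                     dtype=np.int8)
    if adj.shape[0] != len(types):
        raise ValueError(
            f"matrix has {adj.shape[0]} rows but sidecar lists "
            f"{len(types)} neuron types")
    positions = meta.get("positions")
    if positions is not None:
        positions = np.asarray(positions, dtype=float)
    provenance = {"model": meta.get("model"), "params": meta.get("params"),
                  "seed": meta.get("seed")}
    provenance.update(meta.get("provenance_extra", {}))
    provenance = {k: v for k, v in provenance.items() if v is not None}
    if adj.nnz and np.issubdtype(adj.dtype, np.floating):
        # Matrix Market round-trips integers through "real"; restore int8
        # weights for binary graphs.
        if meta.get("binary"):
            adj = adj.astype(np.int8)
    return Connectome(adj, types, positions, binary=bool(meta.get("binary")),
                      provenance=provenance)
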