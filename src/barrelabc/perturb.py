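"""Simulated connectome measurement corruption.

Reconstruction errors are modelled on the connection graph only: random
rewiring (remove a fraction xi of edges, reinsert the same number at random
empty slots), biased removal-only (split errors) or insertion-only (merge
errors), uniform neuron subsampling (fractional reconstruction of f_m of the
neurons, hence ~f_m^2 of the connections), and restriction to a dense
subvolume with additional loss of connections established outside the imaged
volume.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .core import Connectome

__all__ = ["rewire_noise", "biased_noise", "subsample_neurons",
           "restrict_subvolume", "MeasurementParams"]

from dataclasses import dataclass


@dataclass(frozen=True)
class MeasurementParams:
    """Measurement protocol: noise fraction xi, noise mode, measured neuron
    fraction f_m, optional dense subvolume side (um) and within-subvolume
    connection retention probability p_keep."""

    xi: float = 0.0
    mode: str = "rewire"
    f_m: float = 1.0
    subvolume_side: float | None = None
    p_keep: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.xi <= 1.0:
            raise ValueError("xi must lie in [0, 1]")
        if not 0.0 < self.f_m <= 1.0:
            raise ValueError("f_m must lie in (0, 1]")
        if not 0.0 < self.p_keep <= 1.0:
            raise ValueError("p_keep must lie in (0, 1]")
        if self.mode not in ("rewire", "remove_only", "add_only"):
            raise ValueError(f"unknown noise mode {self.mode!r}")


def _require_binary(connectome: Connectome) -> None:
    if not connectome.binary:
        raise ValueError("noise models operate on binarized connectomes")


def _edge_keys(coo: sp.coo_matrix, n: int) -> np.ndarray:
    return coo.row.astype(np.int64) * n + coo.col.astype(np.int64)


def _sample_empty_slots(occupied: set, n: int, k: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Draw k distinct empty off-diagonal slots by rejection sampling."""
    n_slots = n * (n - 1)
    if n_slots - len(occupied) < k:
        raise ValueError("not enough empty slots to reinsert edges")
    chosen: list[int] = []
    taken = set(occupied)
    while len(chosen) < k:
        batch = max(64, 2 * (k - len(chosen)))
        rows = rng.integers(0, n, size=batch)
        cols = rng.integers(0, n, size=batch)
        for r, c in zip(rows, cols):
            if r == c:
                continue
            key = int(r) * n + int(c)
            if key in taken:
                continue
            taken.add(key)
            chosen.append(key)
            if len(chosen) == k:
                break
    return np.asarray(chosen, dtype=np.int64)


def _rebuild(connectome: Connectome, rows, cols) -> Connectome:
    n = connectome.n
    signs = connectome.types[cols]  # sign follows the new presynaptic type
    adj = sp.csr_matrix((signs.astype(np.int8), (rows, cols)), shape=(n, n))
    out = Connectome(adj, connectome.types, connectome.positions, binary=True,
                     provenance=dict(connectome.provenance))
    return out


def rewire_noise(connectome: Connectome, xi: float, seed) -> Connectome:
    """Remove a uniformly chosen fraction xi of edges and reinsert the same
    number at uniformly chosen empty off-diagonal slots; reinserted edges
    take the sign of their new presynaptic neuron.  Edge count is conserved
    exactly."""
    _require_binary(connectome)
    if not 0.0 <= xi <= 1.0:
        raise ValueError("xi must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    if xi == 0.0 or connectome.n_edges == 0:
        return connectome.copy()
    n = connectome.n
    coo = sp.coo_matrix(connectome.adjacency)
    E = coo.nnz
    k = int(round(xi * E))
    keep = np.ones(E, dtype=bool)
    keep[rng.choice(E, size=k, replace=False)] = False
    kept_keys = _edge_keys(coo, n)[keep]
    new_keys = _sample_empty_slots(set(kept_keys.tolist()), n, k, rng)
    keys = np.concatenate([kept_keys, new_keys])
    rows, cols = keys // n, keys % n
    out = _rebuild(connectome, rows, cols)
    out.provenance["noise"] = {"mode": "rewire", "xi": xi}
    return out


def biased_noise(connectome: Connectome, xi: float, mode: str,
                 seed) -> Connectome:
    """Remove-only (split-error emulation) or add-only (merge-error
    emulation) noise of strength xi relative to the original edge count."""
    _require_binary(connectome)
    if mode not in ("remove_only", "add_only"):
        raise ValueError("mode must be 'remove_only' or 'add_only'")
    if not 0.0 <= xi:
        raise ValueError("xi must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    n = connectome.n
    coo = sp.coo_matrix(connectome.adjacency)
    E = coo.nnz
    k = int(round(xi * E))
    keys = _edge_keys(coo, n)
    if mode == "remove_only":
        if xi > 1.0:
            raise ValueError("cannot remove more edges than exist")
        keep = np.ones(E, dtype=bool)
        keep[rng.choice(E, size=k, replace=False)] = False
        keys = keys[keep]
    else:
        new_keys = _sample_empty_slots(set(keys.tolist()), n, k, rng)
        keys = np.concatenate([keys, new_keys])
    out = _rebuild(connectome, keys // n, keys % n)
    out.provenance["noise"] = {"mode": mode, "xi": xi}
    return out


def _induced_subgraph(connectome: Connectome, idx: np.ndarray) -> Connectome:
    idx = np.sort(idx)
    adj = connectome.adjacency[np.ix_(idx, idx)]
    types = connectome.types[idx]
    pos = None if connectome.positions is None else connectome.positions[idx]
    return Connectome(adj, types, pos, binary=connectome.binary,
                      provenance=dict(connectome.provenance))


def subsample_neurons(connectome: Connectome, f_m: float, seed) -> Connectome:
    """Uniformly draw round(f_m * n) neurons and return the induced
    subgraph (fractional connectome measurement)."""
    if not 0.0 < f_m <= 1.0:
        raise ValueError("f_m must lie in (0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    if f_m == 1.0:
        return connectome.copy()
    n = connectome.n
    k = int(round(f_m * n))
    idx = rng.choice(n, size=k, replace=False)
    out = _induced_subgraph(connectome, idx)
    if out.n_e == 0 or out.n_i == 0:
        raise ValueError("subsampling removed an entire neuron population")
    out.provenance["f_m"] = f_m
    return out


def restrict_subvolume(connectome: Connectome, subvolume_side: float,
                       p_keep: float, seed, *,
                       barrel_side: float | None = None) -> Connectome:
    """Keep only neurons whose soma lies in a centred cube of the given side,
    then retain each surviving connection independently with probability
    p_keep (connections of in-volume neurons may run outside the imaged
    volume and be lost).

    Connectomes without stored soma positions are assigned uniform positions
    first, so the operation is defined for every model.
    """
    if not 0.0 < p_keep <= 1.0:
        raise ValueError("p_keep must lie in (0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    L = barrel_side if barrel_side is not None else float(
        connectome.provenance.get("barrel_side", 300.0))
    conn = connectome
    if conn.positions is None:
        conn = conn.copy()
        conn.positions = rng.uniform(0.0, L, size=(conn.n, 3))
    lo, hi = (L - subvolume_side) / 2.0, (L + subvolume_side) / 2.0
    inside = np.flatnonzero(((conn.positions >= lo)
                             & (conn.positions <= hi)).all(axis=1))
    out = _induced_subgraph(conn, inside)
    if out.n_e == 0 or out.n_i == 0:
        raise ValueError("subvolume contains an empty neuron population")
    if p_keep < 1.0 and out.n_edges:
        coo = sp.coo_matrix(out.adjacency)
        keep = rng.random(coo.nnz) < p_keep
        adj = sp.csr_matrix((coo.data[keep], (coo.row[keep], coo.col[keep])),
                            shape=out.adjacency.shape)
        out = Connectome(adj, out.types, out.positions, binary=out.binary,
                         provenance=dict(out.provenance))
    out.provenance["subvolume"] = {"side": subvolume_side, "p_keep": p_keep}
    return out
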