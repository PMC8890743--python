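"""Random and structured (replay) connectome construction.

The circuit has five directed projections: E->E, E->I, I->E, I->I and
CA3->E.  In the unstructured networks every ordered pair is connected
independently with the projection's probability (no self-connections within
a population, no multi-edges).  The structured replay networks partition
both CA1 populations into K+1 groups and apply two masks to the random
graph: group E_k makes no synapses onto I-group k+1, and I-group k projects
*only* onto E-group k.  A pulse of spikes in E_k therefore silences every
I group except I_{k+1}; the resulting gap in inhibition disinhibits E_{k+1},
which fires on the next ripple cycle — alternating E-pulse and I-gap coding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "Projection",
    "Connectome",
    "build_random_connectome",
    "build_replay_connectome",
]

_BLOCK_ROWS = 2000  # presynaptic rows sampled per Bernoulli block


class Projection:
    """Directed adjacency of one projection, CSR over presynaptic neurons."""

    def __init__(self, n_pre: int, n_post: int, indptr: np.ndarray, indices: np.ndarray):
        self.n_pre = int(n_pre)
        self.n_post = int(n_post)
        self.indptr = np.asarray(indptr, dtype=np.int64)
        self.indices = np.asarray(indices, dtype=np.int32)

    @property
    def n_edges(self) -> int:
        return int(self.indices.size)

    def targets_of(self, pre_ids) -> np.ndarray:
        """Concatenated postsynaptic targets of the given presynaptic neurons."""
        pre_ids = np.atleast_1d(pre_ids)
        if pre_ids.size == 0:
            return np.empty(0, dtype=np.int32)
        chunks = [self.indices[self.indptr[i]:self.indptr[i + 1]] for i in pre_ids]
        return np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int32)

    def out_degrees(self) -> np.ndarray:
        return np.diff(self.indptr)

    def in_degrees(self) -> np.ndarray:
        return np.bincount(self.indices, minlength=self.n_post)

    def edge_list(self) -> np.ndarray:
        """(n_edges, 2) array of (pre, post) pairs."""
        pre = np.repeat(np.arange(self.n_pre), self.out_degrees())
        return np.column_stack([pre, self.indices])


def _sample_bernoulli_projection(
    n_pre: int,
    n_post: int,
    p: float,
    rng: np.random.Generator,
    exclude_self: bool = False,
    post_mask_for_pre=None,
) -> Projection:
    """Sample each ordered (pre, post) pair independently with probability p.

    ``post_mask_for_pre(pre_block_start, block)``, if given, may zero out
    forbidden entries of the boolean block (rows = pre within block,
    columns = post) before edges are read off.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"connection probability must be in [0, 1], got {p}")
    indptr = np.zeros(n_pre + 1, dtype=np.int64)
    parts: list[np.ndarray] = []
    for start in range(0, n_pre, _BLOCK_ROWS):
        stop = min(start + _BLOCK_ROWS, n_pre)
        block = rng.random((stop - start, n_post)) < p
        if exclude_self:
            rows = np.arange(start, stop)
            block[np.arange(stop - start), rows] = False
        if post_mask_for_pre is not None:
            post_mask_for_pre(start, block)
        rows, cols = np.nonzero(block)
        counts = np.bincount(rows, minlength=stop - start)
        indptr[start + 1:stop + 1] = counts
        parts.append(cols.astype(np.int32))
    np.cumsum(indptr, out=indptr)
    indices = np.concatenate(parts) if parts else np.empty(0, dtype=np.int32)
    return Projection(n_pre, n_post, indptr, indices)


@dataclass
class Connectome:
    """All projections of one network realization plus replay group labels."""

    projections: dict  # name -> Projection; names: EE, EI, IE, II, CA3E
    n_e: int
    n_i: int
    n_ca3: int
    probabilities: dict
    seed: Optional[int] = None
    e_groups: Optional[np.ndarray] = None  # per-E-neuron group index, or None
    i_groups: Optional[np.ndarray] = None

    @property
    def structured(self) -> bool:
        return self.e_groups is not None

    def __getitem__(self, name: str) -> Projection:
        return self.projections[name]

    # -- text export / import ------------------------------------------------
    def save(self, directory) -> None:
        """Write per-projection edge lists (TSV) and a JSON header."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        header = {
            "n_e": self.n_e, "n_i": self.n_i, "n_ca3": self.n_ca3,
            "probabilities": self.probabilities, "seed": self.seed,
            "structured": self.structured,
        }
        (directory / "connectome.json").write_text(json.dumps(header, indent=1))
        for name, proj in self.projections.items():
            np.savetxt(directory / f"edges_{name}.tsv", proj.edge_list(),
                       fmt="%d", delimiter="\t", header="pre\tpost")
        if self.structured:
            np.savetxt(directory / "groups_E.tsv", self.e_groups, fmt="%d")
            np.savetxt(directory / "groups_I.tsv", self.i_groups, fmt="%d")

    @classmethod
    def load(cls, directory) -> "Connectome":
        directory = Path(directory)
        header = json.loads((directory / "connectome.json").read_text())
        sizes = {"EE": (header["n_e"], header["n_e"]),
                 "EI": (header["n_e"], header["n_i"]),
                 "IE": (header["n_i"], header["n_e"]),
                 "II": (header["n_i"], header["n_i"]),
                 "CA3E": (header["n_ca3"], header["n_e"])}
        projections = {}
        for name, (n_pre, n_post) in sizes.items():
            path = directory / f"edges_{name}.tsv"
            if not path.exists():
                continue
            edges = np.loadtxt(path, dtype=np.int64, ndmin=2)
            if edges.size == 0:
                edges = np.empty((0, 2), dtype=np.int64)
            order = np.lexsort((edges[:, 1], edges[:, 0]))
            edges = edges[order]
            indptr = np.zeros(n_pre + 1, dtype=np.int64)
            np.add.at(indptr, edges[:, 0] + 1, 1)
            np.cumsum(indptr, out=indptr)
            projections[name] = Projection(n_pre, n_post, indptr,
                                           edges[:, 1].astype(np.int32))
        e_groups = i_groups = None
        if header.get("structured"):
            e_groups = np.loadtxt(directory / "groups_E.tsv", dtype=np.int64)
            i_groups = np.loadtxt(directory / "groups_I.tsv", dtype=np.int64)
        return cls(projections=projections, n_e=header["n_e"], n_i=header["n_i"],
                   n_ca3=header["n_ca3"], probabilities=header["probabilities"],
                   seed=header["seed"], e_groups=e_groups, i_groups=i_groups)


def build_random_connectome(
    n_e: int,
    n_i: int,
    n_ca3: int = 0,
    p_ee: float = 0.0164,
    p_ei: float = 0.1,
    p_ie: float = 0.1,
    p_ii: float = 0.2,
    p_ca3e: float = 130.0 / 15000.0,
    seed: int | np.random.SeedSequence = 0,
) -> Connectome:
    """Uniformly random connectome; every pair connected independently."""
    rng = np.random.default_rng(seed)
    projections = {
        "EE": _sample_bernoulli_projection(n_e, n_e, p_ee, rng, exclude_self=True),
        "EI": _sample_bernoulli_projection(n_e, n_i, p_ei, rng),
        "IE": _sample_bernoulli_projection(n_i, n_e, p_ie, rng),
        "II": _sample_bernoulli_projection(n_i, n_i, p_ii, rng, exclude_self=True),
    }
    if n_ca3 > 0:
        projections["CA3E"] = _sample_bernoulli_projection(n_ca3, n_e, p_ca3e, rng)
    probs = {"p_EE": p_ee, "p_EI": p_ei, "p_IE": p_ie, "p_II": p_ii, "p_CA3E": p_ca3e}
    return Connectome(projections=projections, n_e=n_e, n_i=n_i, n_ca3=n_ca3,
                      probabilities=probs,
                      seed=seed if isinstance(seed, int) else None)


def _partition_groups(n: int, k_plus_1: int) -> np.ndarray:
    """Contiguous, near-equal partition of ``n`` neurons into k_plus_1 groups."""
    return np.minimum((np.arange(n) * k_plus_1) // n, k_plus_1 - 1)


def build_replay_connectome(
    n_e: int,
    n_i: int,
    k: int = 9,
    n_ca3: int = 0,
    p_ee: float = 0.0164,
    p_ei: float = 0.1,
    p_ie: float = 0.1,
    p_ii: float = 0.2,
    p_ca3e: float = 130.0 / 15000.0,
    seed: int | np.random.SeedSequence = 0,
    e_groups: Optional[np.ndarray] = None,
    i_groups: Optional[np.ndarray] = None,
) -> Connectome:
    """Structured connectome for sequence replay (K+1 E groups, K+1 I groups).

    Masks relative to the random network: E-group k has no edges onto
    I-group k+1 (for k < K), and I-group k projects only onto E-group k.
    Within the allowed blocks, edges are drawn with the same base
    probabilities as the random network.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    kp1 = k + 1
    e_groups = _partition_groups(n_e, kp1) if e_groups is None else np.asarray(e_groups)
    i_groups = _partition_groups(n_i, kp1) if i_groups is None else np.asarray(i_groups)
    if e_groups.size != n_e or i_groups.size != n_i:
        raise ValueError("group label arrays must match the population sizes")
    if e_groups.max() >= kp1 or i_groups.max() >= kp1:
        raise ValueError("group labels must lie in 0..K")

    rng = np.random.default_rng(seed)

    def mask_ei(start: int, block: np.ndarray) -> None:
        # E_k makes no synapses onto I_{k+1}
        pre_groups = e_groups[start:start + block.shape[0]]
        forbidden = pre_groups + 1  # group K has no successor: values == kp1 match nothing
        block &= i_groups[None, :] != forbidden[:, None]

    def mask_ie(start: int, block: np.ndarray) -> None:
        # I_k projects only onto E_k
        pre_groups = i_groups[start:start + block.shape[0]]
        block &= e_groups[None, :] == pre_groups[:, None]

    projections = {
        "EE": _sample_bernoulli_projection(n_e, n_e, p_ee, rng, exclude_self=True),
        "EI": _sample_bernoulli_projection(n_e, n_i, p_ei, rng, post_mask_for_pre=mask_ei),
        "IE": _sample_bernoulli_projection(n_i, n_e, p_ie, rng, post_mask_for_pre=mask_ie),
        "II": _sample_bernoulli_projection(n_i, n_i, p_ii, rng, exclude_self=True),
    }
    if n_ca3 > 0:
        projections["CA3E"] = _sample_bernoulli_projection(n_ca3, n_e, p_ca3e, rng)
    probs = {"p_EE": p_ee, "p_EI": p_ei, "p_IE": p_ie, "p_II": p_ii, "p_CA3E": p_ca3e}
    return Connectome(projections=projections, n_e=n_e, n_i=n_i, n_ca3=n_ca3,
                      probabilities=probs, seed=seed if isinstance(seed, int) else None,
                      e_groups=e_groups, i_groups=i_groups)
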