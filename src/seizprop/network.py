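"""Sparse random two-population network plus an external Poisson population.

The model network holds ``N_total`` neurons split into an excitatory
regular-spiking population (RS, 80%) and an inhibitory fast-spiking
population (FS, 20%), each pair of neurons connected independently with a
fixed probability (Erdős–Rényi, default 5%).  A third, external population
(EXT, same size as RS) delivers Poisson spike trains through the same
connection rule.  The inhibitory out-probabilities p_ie (FS→RS) and
p_ii (FS→FS) are individually adjustable for connectivity screens.

Each of the six directed blocks (RS/FS/EXT → RS/FS) is drawn from its own
random substream spawned from ``connectivity_seed``, so changing, say,
p_ie redraws only the FS→RS block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Iterator

import numpy as np
import scipy.sparse as sp

__all__ = [
    "PopulationSpec",
    "Connectivity",
    "NetworkConfig",
    "Network",
    "build_connectivity",
    "build_network",
    "in_degrees",
]

POPULATIONS = ("RS", "FS", "EXT")
#: (source, target) keys of the six connectivity blocks, in build order.
BLOCKS = (
    ("RS", "RS"), ("RS", "FS"),
    ("FS", "RS"), ("FS", "FS"),
    ("EXT", "RS"), ("EXT", "FS"),
)


@dataclass(frozen=True)
class PopulationSpec:
    name: str                    # one of RS, FS, EXT
    size: int
    model_kind: str              # adex | cadex | hh | poisson
    cell_class: str = ""         # preset key ("RS"/"FS"); empty for poisson

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("population size must be positive")
        if self.name not in POPULATIONS:
            raise ValueError(f"unknown population name {self.name!r}")


@dataclass
class Connectivity:
    """One directed block of boolean connections, stored sparse (CSR).

    ``adjacency[i, j]`` is True when source neuron i projects to target
    neuron j.  Regenerating with the same seed reproduces the block
    bit-exactly.
    """

    source: str
    target: str
    p: float
    adjacency: sp.csr_matrix
    seed: int

    @property
    def n_source(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_target(self) -> int:
        return self.adjacency.shape[1]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz)

    def in_degrees(self) -> np.ndarray:
        """Afferent edge count per target neuron (column sums)."""
        return np.asarray(self.adjacency.sum(axis=0)).ravel().astype(np.int64)


@dataclass(frozen=True)
class NetworkConfig:
    """Structural and synaptic configuration of the default network."""

    N_total: int = 10_000
    frac_inhibitory: float = 0.2
    p_default: float = 0.05
    p_ie: float = 0.05           # FS -> RS connection probability
    p_ii: float = 0.05           # FS -> FS connection probability
    Q_E: float = 1.5             # excitatory quantal conductance (nS)
    Q_I: float = 5.0             # inhibitory quantal conductance (nS)
    E_E: float = 0.0             # excitatory synaptic reversal (mV)
    E_I: float = -80.0           # inhibitory synaptic reversal (mV)
    tau_syn: float = 5.0         # synaptic decay time constant (ms)
    model_kind: str = "adex"
    connectivity_seed: int = 0
    drive_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_default, self.p_ie, self.p_ii):
            if not 0.0 < p <= 1.0:
                raise ValueError("connection probabilities must lie in (0, 1]")
        if not (self.Q_E > 0 and self.Q_I > 0 and self.tau_syn > 0):
            raise ValueError("Q_E, Q_I and tau_syn must be positive")
        n_inh = self.N_total * self.frac_inhibitory
        if abs(n_inh - round(n_inh)) > 1e-9:
            raise ValueError(
                f"N_total={self.N_total} with frac_inhibitory="
                f"{self.frac_inhibitory} gives a fractional population size"
            )

    @property
    def n_inhibitory(self) -> int:
        return round(self.N_total * self.frac_inhibitory)

    @property
    def n_excitatory(self) -> int:
        return self.N_total - self.n_inhibitory

    def block_p(self, source: str, target: str) -> float:
        if source == "FS":
            return self.p_ie if target == "RS" else self.p_ii
        return self.p_default

    def to_dict(self) -> dict:
        return asdict(self)

    def desk_scaled(self, factor: int) -> "NetworkConfig":
        """Shrink the network by `factor` while preserving mean in-degrees.

        N_total is divided by the factor and every connection probability
        multiplied by it, so each neuron keeps the same expected number of
        afferents (and hence the same mean synaptic conductances) at a
        smaller, faster network size.
        """
        if self.N_total % factor:
            raise ValueError("factor must divide N_total")
        return replace(
            self,
            N_total=self.N_total // factor,
            p_default=min(1.0, self.p_default * factor),
            p_ie=min(1.0, self.p_ie * factor),
            p_ii=min(1.0, self.p_ii * factor),
        )


def build_connectivity(
    n_source: int,
    n_target: int,
    p: float,
    seed: int | np.random.SeedSequence,
    *,
    source: str = "",
    target: str = "",
    exclude_self: bool = False,
) -> Connectivity:
    """Draw a Bernoulli(p) random block of directed connections.

    Each ordered (source, target) pair is connected independently with
    probability p.  With ``exclude_self`` the diagonal is forced empty
    (used within a population, where autapses are disallowed).
    Deterministic given the seed.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"connection probability {p} outside [0, 1]")
    if n_source <= 0 or n_target <= 0:
        raise ValueError("population sizes must be positive")
    seed_int = seed if isinstance(seed, (int, np.integer)) else seed.entropy
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    # Chunked Bernoulli draws keep peak memory at ~chunk * n_target floats.
    chunk = max(1, min(n_source, 4_000_000 // max(n_target, 1) + 1))
    for start in range(0, n_source, chunk):
        stop = min(start + chunk, n_source)
        mask = rng.random((stop - start, n_target)) < p
        if exclude_self:
            d = np.arange(start, stop)
            keep = d < n_target
            mask[np.arange(stop - start)[keep], d[keep]] = False
        r, c = np.nonzero(mask)
        rows.append((r + start).astype(np.int32))
        cols.append(c.astype(np.int32))
    row = np.concatenate(rows) if rows else np.empty(0, np.int32)
    col = np.concatenate(cols) if cols else np.empty(0, np.int32)
    adj = sp.csr_matrix(
        (np.ones(row.size, dtype=np.int8), (row, col)),
        shape=(n_source, n_target),
    )
    return Connectivity(source=source, target=target, p=p, adjacency=adj,
                        seed=int(seed_int) if np.ndim(seed_int) == 0 else 0)


@dataclass
class Network:
    """Populations plus the six connectivity blocks RS/FS/EXT -> RS/FS."""

    config: NetworkConfig
    populations: dict[str, PopulationSpec]
    blocks: dict[tuple[str, str], Connectivity]

    @property
    def n_rs(self) -> int:
        return self.populations["RS"].size

    @property
    def n_fs(self) -> int:
        return self.populations["FS"].size

    @property
    def n_ext(self) -> int:
        return self.populations["EXT"].size

    @property
    def n_net(self) -> int:
        """Number of simulated (non-external) neurons."""
        return self.n_rs + self.n_fs

    def block(self, source: str, target: str) -> Connectivity:
        return self.blocks[(source, target)]

    def afferent_matrix(self, source: str) -> sp.csr_matrix:
        """Horizontal stack of `source`'s projections onto [RS | FS].

        Rows index source neurons, columns index network neurons in global
        order (RS first, then FS).
        """
        return sp.hstack(
            [self.blocks[(source, "RS")].adjacency,
             self.blocks[(source, "FS")].adjacency],
            format="csr",
        )

    def inhibitory_in_degrees(self, population: str) -> np.ndarray:
        return in_degrees(self, "FS", population)


def build_network(cfg: NetworkConfig) -> Network:
    """Assemble populations and all six random connectivity blocks.

    Every block draws from an independent substream spawned from
    ``cfg.connectivity_seed`` in a fixed order, so varying p_ie or p_ii
    redraws only the corresponding inhibitory block.
    """
    n_fs = cfg.n_inhibitory
    n_rs = cfg.n_excitatory
    pops = {
        "RS": PopulationSpec("RS", n_rs, cfg.model_kind, "RS"),
        "FS": PopulationSpec("FS", n_fs, cfg.model_kind, "FS"),
        "EXT": PopulationSpec("EXT", n_rs, "poisson"),
    }
    sizes = {"RS": n_rs, "FS": n_fs, "EXT": n_rs}
    substreams = np.random.SeedSequence(cfg.connectivity_seed).spawn(len(BLOCKS))
    blocks: dict[tuple[str, str], Connectivity] = {}
    for (src, tgt), ss in zip(BLOCKS, substreams):
        blocks[(src, tgt)] = build_connectivity(
            sizes[src], sizes[tgt], cfg.block_p(src, tgt), ss,
            source=src, target=tgt, exclude_self=(src == tgt),
        )
        blocks[(src, tgt)].seed = cfg.connectivity_seed
    return Network(config=cfg, populations=pops, blocks=blocks)


def in_degrees(net: Network, source_population: str, target_population: str) -> np.ndarray:
    """Afferent edge count from one population, per neuron of another."""
    return net.block(source_population, target_population).in_degrees()
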