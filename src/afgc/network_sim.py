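"""Coupled stochastic circadian oscillator networks.

Each cell is a three-state negative-feedback clock: PER mRNA (``M``) is
transcribed under Hill-type repression by nuclear PER protein (``PN``),
translated into cytoplasmic protein (``PC``), and the protein shuttles
between cytoplasm and nucleus.  Cells influence one another through the
transcription rate

    vs_i = vs_base + L + alpha * (Mbar_i - M_i)

where ``Mbar_i`` is the mean mRNA concentration over the in-neighbours of
cell ``i`` on a directed graph.  The ODE system is converted to a discrete
stochastic reaction network by scaling concentrations with a system volume
``omega`` (molecules per concentration unit); small ``omega`` gives noisy
single-cell traces, large ``omega`` recovers the deterministic limit.

Six reaction channels per cell:

=====  ===================  =========================================
 #     transition           propensity
=====  ===================  =========================================
 0     M -> M+1             omega * vs_i * K1^n / (K1^n + (PN/omega)^n)
 1     M -> M-1             omega * vm * (M/omega) / (Km + M/omega)
 2     PC -> PC+1           ks * M
 3     PC -> PC-1           omega * vd * (PC/omega) / (Kd + PC/omega)
 4     PC -> PC-1, PN+1     k1 * PC
 5     PN -> PN-1, PC+1     k2 * PN
=====  ===================  =========================================

``vs_i`` is recomputed from the current counts at every step and clamped at
zero (strong coupling can drive it negative).  Cells with no in-neighbours
run uncoupled with ``vs = vs_base + L``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

SPECIES = ("M", "PC", "PN")

__all__ = [
    "SPECIES",
    "SimulationParams",
    "DirectedNetwork",
    "Trajectory",
    "make_topology",
    "simulate",
    "integrate_deterministic",
    "add_measurement_noise",
]


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationParams:
    """Kinetic constants and simulation controls.

    Rates are per hour, concentration-scale constants in the same units as
    the deterministic model.  The kinetic defaults are a minimal-PER
    parameter set adjusted (slower nucleocytoplasmic exchange, tighter
    protein-degradation saturation) so that the three-state reduction has a
    sustained limit cycle with a ~23.5 h period; see docs/methods.md.
    """

    vs_base: float = 0.83      # basal transcription rate (conc/h)
    L: float = 0.0             # light input offset (conc/h); 0 = darkness
    alpha: float = 100.0       # coupling strength (1/h)
    vm: float = 0.65           # max mRNA degradation rate (conc/h)
    Km: float = 0.5            # mRNA degradation Michaelis constant (conc)
    ks: float = 0.38           # translation rate (1/h)
    vd: float = 0.95           # max protein degradation rate (conc/h)
    Kd: float = 0.1            # protein degradation Michaelis constant
    k1: float = 0.3            # cytoplasm -> nucleus transport (1/h)
    k2: float = 0.65           # nucleus -> cytoplasm transport (1/h)
    K1: float = 1.0            # repression threshold (conc)
    n: int = 4                 # Hill coefficient
    omega: float = 50.0        # system volume (molecules per conc unit)
    t_end: float = 120.0       # simulated duration (h)
    sample_interval: float = 1.0   # sampling interval (minutes)
    seed: int = 0
    method: str = "exact"      # "exact" (direct SSA) or "tau-leap"
    tau_leap_dt: float = 0.001  # tau-leap step (h)
    init_jitter_h: float = 0.0  # SD of per-cell phase jitter on the cycle (h)

    def __post_init__(self) -> None:
        for name in ("vs_base", "vm", "Km", "ks", "vd", "Kd", "k1", "k2", "K1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError("n must be an integer >= 1")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")
        if self.method not in ("exact", "tau-leap"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.tau_leap_dt <= 0:
            raise ValueError("tau_leap_dt must be > 0")

    def with_(self, **kw) -> "SimulationParams":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# directed networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DirectedNetwork:
    """Directed influence graph: edge (source, target) means the source
    cell's mRNA enters the target's coupling average."""

    n_cells: int
    edges: tuple
    scores: Mapping | None = None   # optional per-edge score

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            s, t = e
            if s == t:
                raise ValueError(f"self-edge {e} not allowed")
            if not (0 <= s < self.n_cells and 0 <= t < self.n_cells):
                raise ValueError(f"edge {e} outside [0, {self.n_cells})")
            if e in seen:
                raise ValueError(f"duplicate edge {e}")
            seen.add(e)
        object.__setattr__(self, "edges", tuple(sorted((int(s), int(t)) for s, t in self.edges)))

    @property
    def edge_set(self) -> frozenset:
        return frozenset(self.edges)

    def in_neighbors_csr(self) -> tuple:
        """In-neighbour lists in CSR form (indices, pointers)."""
        inn: list = [[] for _ in range(self.n_cells)]
        for s, t in self.edges:
            inn[t].append(s)
        ptr = [0]
        idx: list = []
        for lst in inn:
            idx.extend(sorted(lst))
            ptr.append(len(idx))
        return np.asarray(idx, dtype=np.int64), np.asarray(ptr, dtype=np.int64)

    # -- serialization ------------------------------------------------------

    def write_edgelist(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["source", "target"])
            for s, t in self.edges:
                w.writerow([s, t])

    @classmethod
    def read_edgelist(cls, path, n_cells: int | None = None) -> "DirectedNetwork":
        edges = []
        with open(path, newline="") as fh:
            rd = csv.reader(fh)
            header = next(rd)
            if [h.strip() for h in header[:2]] != ["source", "target"]:
                # header optional: treat first row as data if numeric
                try:
                    edges.append((int(header[0]), int(header[1])))
                except ValueError:
                    pass
            for row in rd:
                if not row or not row[0].strip():
                    continue
                edges.append((int(row[0]), int(row[1])))
        if n_cells is None:
            n_cells = 1 + max((max(s, t) for s, t in edges), default=-1)
        return cls(n_cells=n_cells, edges=tuple(edges))

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_cells))
        g.add_edges_from(self.edges)
        return g

    def write_graphml(self, path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def read_graphml(cls, path) -> "DirectedNetwork":
        import networkx as nx

        g = nx.read_graphml(path)
        nodes = sorted(g.nodes(), key=lambda v: int(v))
        relabel = {v: i for i, v in enumerate(nodes)}
        edges = tuple((relabel[u], relabel[v]) for u, v in g.edges())
        return cls(n_cells=len(nodes), edges=edges)


def _dual_chain10() -> tuple:
    """Two 5-cell feed-forward chains with rung edges in both directions
    between same-position cells (exact published wiring unavailable)."""
    edges = []
    for k in range(5):
        if k > 0:
            edges.append((k - 1, k))
            edges.append((5 + k - 1, 5 + k))
        edges.append((k, 5 + k))
        edges.append((5 + k, k))
    return tuple(edges)


def _mini_scn20(rng: np.random.Generator) -> tuple:
    """Two all-to-all bidirectional 10-cell groups plus four random
    one-way edges from group 0 into group 1."""
    edges = []
    for g in (range(10), range(10, 20)):
        for a in g:
            for b in g:
                if a != b:
                    edges.append((a, b))
    sources = rng.choice(10, size=4, replace=False)
    targets = rng.choice(np.arange(10, 20), size=4, replace=False)
    edges.extend((int(s), int(t)) for s, t in zip(sources, targets))
    return tuple(edges)


def make_topology(
    kind: str,
    n_cells: int | None = None,
    seed: int | None = None,
    kind_params: Mapping | None = None,
) -> DirectedNetwork:
    """Build a named directed topology.

    ``chain3``, ``bypass4``, ``dual_chain10`` and ``mini_scn20`` have fixed
    cell counts (3, 4, 10, 20).  ``barabasi_albert`` (default 100 cells,
    out-degree 1) and ``watts_strogatz`` (default 100 cells, ring degree 2,
    rewiring beta = 0.1) are random and reproducible given ``seed``.
    ``custom`` takes an explicit edge list in ``kind_params['edges']``.
    """
    kind_params = dict(kind_params or {})
    fixed = {"chain3": 3, "bypass4": 4, "dual_chain10": 10, "mini_scn20": 20}
    if kind in fixed:
        expected = fixed[kind]
        if n_cells is not None and n_cells != expected:
            raise ValueError(f"{kind} has {expected} cells, got n_cells={n_cells}")
        n_cells = expected
    if kind == "chain3":
        return DirectedNetwork(3, ((0, 1), (1, 2)))
    if kind == "bypass4":
        return DirectedNetwork(4, ((0, 1), (0, 2), (1, 2), (2, 3)))
    if kind == "dual_chain10":
        return DirectedNetwork(10, _dual_chain10())
    if kind == "mini_scn20":
        rng = np.random.default_rng(seed)
        return DirectedNetwork(20, _mini_scn20(rng))
    if kind == "barabasi_albert":
        import networkx as nx

        n_cells = 100 if n_cells is None else n_cells
        m = int(kind_params.get("m", 1))
        g = nx.barabasi_albert_graph(n_cells, m, seed=seed)
        # orient each attachment edge from the newcomer to the node it
        # attached to, giving average out-degree m
        edges = tuple((max(u, v), min(u, v)) for u, v in g.edges())
        return DirectedNetwork(n_cells, edges)
    if kind == "watts_strogatz":
        import networkx as nx

        n_cells = 100 if n_cells is None else n_cells
        k = int(kind_params.get("k", 2))
        beta = float(kind_params.get("beta", 0.1))
        g = nx.watts_strogatz_graph(n_cells, k, beta, seed=seed)
        rng = np.random.default_rng(seed)
        edges = []
        for u, v in g.edges():
            if rng.random() < 0.5:
                edges.append((u, v))
            else:
                edges.append((v, u))
        return DirectedNetwork(n_cells, tuple(edges))
    if kind == "custom":
        if n_cells is None:
            raise ValueError("custom topology requires n_cells")
        return DirectedNetwork(n_cells, tuple(tuple(e) for e in kind_params.get("edges", ())))
    raise ValueError(f"unknown topology kind {kind!r}")


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Sampled counts on a uniform grid: ``counts[t, cell, species]`` with
    species ordered (M, PC, PN).  Counts are integers for noise-free
    simulator output and reals after measurement noise."""

    times: np.ndarray
    counts: np.ndarray
    params: SimulationParams
    network: DirectedNetwork

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_interval(self) -> float:
        """Sampling interval in minutes."""
        return self.params.sample_interval

    def species_matrix(self, species: str = "M") -> np.ndarray:
        """(n_samples, n_cells) matrix for one species."""
        return self.counts[:, :, SPECIES.index(species)]

    # -- serialization ------------------------------------------------------

    def write_csv(self, path, layout: str = "long", species: str = "M") -> None:
        if layout == "long":
            with open(path, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["time_h", "cell", "species", "count"])
                for it, t in enumerate(self.times):
                    for c in range(self.n_cells):
                        for sp_i, sp in enumerate(SPECIES):
                            w.writerow([f"{t:.6f}", c, sp, repr(float(self.counts[it, c, sp_i]))])
        elif layout == "wide":
            mat = self.species_matrix(species)
            with open(path, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["time_h"] + [f"cell{c}" for c in range(self.n_cells)])
                for it, t in enumerate(self.times):
                    w.writerow([f"{t:.6f}"] + [repr(float(x)) for x in mat[it]])
        else:
            raise ValueError(f"unknown layout {layout!r}")

    @classmethod
    def read_csv(cls, path, params: SimulationParams | None = None,
                 network: DirectedNetwork | None = None) -> "Trajectory":
        """Read a long-layout trajectory CSV."""
        import pandas as pd

        df = pd.read_csv(path)
        required = {"time_h", "cell", "species", "count"}
        if not required.issubset(df.columns):
            raise ValueError(f"trajectory CSV needs columns {sorted(required)}")
        times = np.sort(df["time_h"].unique())
        cells = np.sort(df["cell"].unique())
        counts = np.zeros((len(times), len(cells), 3))
        t_pos = {t: i for i, t in enumerate(times)}
        c_pos = {c: i for i, c in enumerate(cells)}
        for row in df.itertuples(index=False):
            counts[t_pos[row.time_h], c_pos[row.cell], SPECIES.index(row.species)] = row.count
        if params is None:
            dt_min = float(np.median(np.diff(times))) * 60.0
            params = SimulationParams(sample_interval=dt_min, t_end=max(float(times[-1]), dt_min / 60))
        if network is None:
            network = DirectedNetwork(len(cells), ())
        return cls(times=times, counts=counts, params=params, network=network)


# ---------------------------------------------------------------------------
# deterministic limit and initial conditions
# ---------------------------------------------------------------------------

def _ode_rhs(params: SimulationParams, adj_idx: np.ndarray, adj_ptr: np.ndarray,
             n_cells: int):
    vs0 = params.vs_base + params.L
    K1n = params.K1 ** params.n

    def rhs(t, y):
        y = y.reshape(n_cells, 3)
        M, PC, PN = y[:, 0], y[:, 1], y[:, 2]
        vs = np.full(n_cells, vs0)
        for i in range(n_cells):
            lo, hi = adj_ptr[i], adj_ptr[i + 1]
            if hi > lo:
                vs[i] = vs0 + params.alpha * (M[adj_idx[lo:hi]].mean() - M[i])
        vs = np.maximum(vs, 0.0)
        dM = vs * K1n / (K1n + PN ** params.n) - params.vm * M / (params.Km + M)
        dPC = params.ks * M - params.vd * PC / (params.Kd + PC) - params.k1 * PC + params.k2 * PN
        dPN = params.k1 * PC - params.k2 * PN
        return np.column_stack([dM, dPC, dPN]).ravel()

    return rhs


def integrate_deterministic(network: DirectedNetwork, params: SimulationParams,
                            y0: np.ndarray | None = None) -> Trajectory:
    """Integrate the coupled ODE system and sample it on the same grid as
    the stochastic simulator (concentration units, not counts)."""
    n_cells = network.n_cells
    adj_idx, adj_ptr = network.in_neighbors_csr()
    if y0 is None:
        y0 = np.tile(_limit_cycle_point(params), n_cells)
    dt = params.sample_interval / 60.0
    times = np.arange(0.0, params.t_end + dt / 2, dt)
    sol = solve_ivp(_ode_rhs(params, adj_idx, adj_ptr, n_cells), (0.0, times[-1]), y0,
                    t_eval=times, method="LSODA", rtol=1e-8, atol=1e-10)
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    counts = sol.y.T.reshape(len(times), n_cells, 3)
    return Trajectory(times=times, counts=counts, params=params, network=network)


def _limit_cycle_point(params: SimulationParams) -> np.ndarray:
    """Single-cell state at a trough of M on the deterministic limit cycle,
    found after a 200 h burn-in.  Returns concentrations (M, PC, PN)."""
    p = params
    K1n = p.K1 ** p.n
    vs0 = p.vs_base + p.L

    def rhs(t, y):
        M, PC, PN = y
        return [
            vs0 * K1n / (K1n + PN ** p.n) - p.vm * M / (p.Km + M),
            p.ks * M - p.vd * PC / (p.Kd + PC) - p.k1 * PC + p.k2 * PN,
            p.k1 * PC - p.k2 * PN,
        ]

    sol = solve_ivp(rhs, (0.0, 300.0), [0.5, 0.3, 1.2], dense_output=True,
                    method="LSODA", rtol=1e-9, atol=1e-11)
    t = np.arange(200.0, 300.0, 1.0 / 60.0)
    M = sol.sol(t)[0]
    # interior troughs of M = start of the rising phase
    interior = (M[1:-1] < M[:-2]) & (M[1:-1] <= M[2:])
    amp = M.max() - M.min()
    idx = np.flatnonzero(interior & (M[1:-1] < M.min() + 0.05 * max(amp, 1e-12))) + 1
    i = idx[0] if len(idx) else int(np.argmin(M))
    return np.asarray(sol.sol(t[i]))


def _phase_states(params: SimulationParams, offsets_h: np.ndarray) -> np.ndarray:
    """Limit-cycle states at the given phase offsets (h) past the M trough."""
    y0 = _limit_cycle_point(params)
    if np.all(offsets_h == 0):
        return np.tile(y0, (len(offsets_h), 1))
    p = params
    K1n = p.K1 ** p.n
    vs0 = p.vs_base + p.L

    def rhs(t, y):
        M, PC, PN = y
        return [
            vs0 * K1n / (K1n + PN ** p.n) - p.vm * M / (p.Km + M),
            p.ks * M - p.vd * PC / (p.Kd + PC) - p.k1 * PC + p.k2 * PN,
            p.k1 * PC - p.k2 * PN,
        ]

    tmax = float(offsets_h.max()) + 1e-6
    sol = solve_ivp(rhs, (0.0, tmax), y0, dense_output=True, method="LSODA",
                    rtol=1e-9, atol=1e-11)
    return np.column_stack([sol.sol(o) for o in offsets_h]).T


# ---------------------------------------------------------------------------
# stochastic kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _propensities(M, PC, PN, adj_idx, adj_ptr, a, vs_base, L, alpha,
                  vm, Km, ks, vd, Kd, k1, k2, K1n, n, omega):
    n_cells = M.shape[0]
    for i in range(n_cells):
        lo, hi = adj_ptr[i], adj_ptr[i + 1]
        if hi > lo:
            mbar = 0.0
            for jj in range(lo, hi):
                mbar += M[adj_idx[jj]]
            mbar /= hi - lo
            vs = vs_base + L + alpha * (mbar - M[i]) / omega
        else:
            vs = vs_base + L
        if vs < 0.0:
            vs = 0.0
        pn_c = PN[i] / omega
        m_c = M[i] / omega
        pc_c = PC[i] / omega
        a[6 * i + 0] = omega * vs * K1n / (K1n + pn_c ** n)
        a[6 * i + 1] = omega * vm * m_c / (Km + m_c)
        a[6 * i + 2] = ks * M[i]
        a[6 * i + 3] = omega * vd * pc_c / (Kd + pc_c)
        a[6 * i + 4] = k1 * PC[i]
        a[6 * i + 5] = k2 * PN[i]


@njit(cache=True)
def _ssa_direct(adj_idx, adj_ptr, M, PC, PN, t_end, dt_samp, vs_base, L, alpha,
                vm, Km, ks, vd, Kd, k1, k2, K1, n, omega, seed):
    np.random.seed(seed)
    n_cells = M.shape[0]
    n_samp = int(round(t_end / dt_samp)) + 1
    out = np.zeros((n_samp, n_cells, 3), dtype=np.int64)
    a = np.zeros(6 * n_cells)
    K1n = K1 ** n
    t = 0.0
    isamp = 0
    while isamp < n_samp:
        _propensities(M, PC, PN, adj_idx, adj_ptr, a, vs_base, L, alpha,
                      vm, Km, ks, vd, Kd, k1, k2, K1n, n, omega)
        a0 = 0.0
        for k in range(6 * n_cells):
            a0 += a[k]
        if not np.isfinite(a0) or a0 > 1e12:
            raise RuntimeError("propensity overflow in SSA")
        if a0 <= 0.0:
            # absorbing state: emit remaining samples unchanged
            while isamp < n_samp:
                for i in range(n_cells):
                    out[isamp, i, 0] = int(M[i])
                    out[isamp, i, 1] = int(PC[i])
                    out[isamp, i, 2] = int(PN[i])
                isamp += 1
            break
        t_next = t - math.log(np.random.random()) / a0
        while isamp < n_samp and isamp * dt_samp <= t_next:
            for i in range(n_cells):
                out[isamp, i, 0] = int(M[i])
                out[isamp, i, 1] = int(PC[i])
                out[isamp, i, 2] = int(PN[i])
            isamp += 1
        t = t_next
        r = np.random.random() * a0
        acc = 0.0
        k = 0
        for k in range(6 * n_cells):
            acc += a[k]
            if acc >= r:
                break
        i = k // 6
        ch = k % 6
        if ch == 0:
            M[i] += 1
        elif ch == 1:
            M[i] -= 1
        elif ch == 2:
            PC[i] += 1
        elif ch == 3:
            PC[i] -= 1
        elif ch == 4:
            PC[i] -= 1
            PN[i] += 1
        else:
            PN[i] -= 1
            PC[i] += 1
    return out


@njit(cache=True)
def _tau_leap(adj_idx, adj_ptr, M, PC, PN, t_end, dt_samp, vs_base, L, alpha,
              vm, Km, ks, vd, Kd, k1, k2, K1, n, omega, seed, dt_leap):
    np.random.seed(seed)
    n_cells = M.shape[0]
    n_samp = int(round(t_end / dt_samp)) + 1
    out = np.zeros((n_samp, n_cells, 3), dtype=np.int64)
    a = np.zeros(6 * n_cells)
    K1n = K1 ** n
    t = 0.0
    isamp = 0
    newM = np.zeros(n_cells)
    newPC = np.zeros(n_cells)
    newPN = np.zeros(n_cells)
    while isamp < n_samp:
        while isamp < n_samp and isamp * dt_samp <= t + 1e-12:
            for i in range(n_cells):
                out[isamp, i, 0] = int(M[i])
                out[isamp, i, 1] = int(PC[i])
                out[isamp, i, 2] = int(PN[i])
            isamp += 1
        if isamp >= n_samp:
            break
        _propensities(M, PC, PN, adj_idx, adj_ptr, a, vs_base, L, alpha,
                      vm, Km, ks, vd, Kd, k1, k2, K1n, n, omega)
        a0 = a.sum()
        if not np.isfinite(a0) or a0 > 1e12:
            raise RuntimeError("propensity overflow in tau-leap")
        # retry with halved steps until no count would go negative
        dt = dt_leap
        for _attempt in range(40):
            ok = True
            for i in range(n_cells):
                nb = np.random.poisson(a[6 * i + 0] * dt)
                nd = np.random.poisson(a[6 * i + 1] * dt)
                ntr = np.random.poisson(a[6 * i + 2] * dt)
                npd = np.random.poisson(a[6 * i + 3] * dt)
                nin = np.random.poisson(a[6 * i + 4] * dt)
                nout = np.random.poisson(a[6 * i + 5] * dt)
                newM[i] = M[i] + nb - nd
                newPC[i] = PC[i] + ntr - npd - nin + nout
                newPN[i] = PN[i] + nin - nout
                if newM[i] < 0 or newPC[i] < 0 or newPN[i] < 0:
                    ok = False
                    break
            if ok:
                break
            dt *= 0.5
        if not ok:
            raise RuntimeError("tau-leap could not find a non-negative step")
        for i in range(n_cells):
            M[i] = newM[i]
            PC[i] = newPC[i]
            PN[i] = newPN[i]
        t += dt
    return out


def simulate(network: DirectedNetwork, params: SimulationParams) -> Trajectory:
    """Run the coupled discrete stochastic model and sample counts every
    ``params.sample_interval`` minutes.

    All cells start from the same point on the deterministic single-cell
    limit cycle (the trough of M, i.e. the start of the rising phase),
    scaled by ``omega`` and rounded; ``init_jitter_h > 0`` adds per-cell
    phase jitter along the cycle.  Output is bit-reproducible for a fixed
    seed and method.
    """
    n_cells = network.n_cells
    adj_idx, adj_ptr = network.in_neighbors_csr()
    rng = np.random.default_rng(params.seed)
    if params.init_jitter_h > 0:
        offsets = np.abs(rng.normal(0.0, params.init_jitter_h, n_cells))
        states = _phase_states(params, offsets)
    else:
        states = np.tile(_limit_cycle_point(params), (n_cells, 1))
    y0 = np.rint(states * params.omega).astype(np.float64)
    M, PC, PN = y0[:, 0].copy(), y0[:, 1].copy(), y0[:, 2].copy()
    dt_samp = params.sample_interval / 60.0
    args = (adj_idx, adj_ptr, M, PC, PN, params.t_end, dt_samp,
            params.vs_base, params.L, params.alpha, params.vm, params.Km,
            params.ks, params.vd, params.Kd, params.k1, params.k2,
            params.K1, float(params.n), params.omega, params.seed % (2 ** 31))
    if params.method == "exact":
        counts = _ssa_direct(*args)
    else:
        counts = _tau_leap(*args, params.tau_leap_dt)
    n_samp = counts.shape[0]
    times = np.arange(n_samp) * dt_samp
    return Trajectory(times=times, counts=counts.astype(np.float64),
                      params=params, network=network)


# ---------------------------------------------------------------------------
# measurement noise
# ---------------------------------------------------------------------------

def add_measurement_noise(traj: Trajectory, noise_fraction: float,
                          seed: int = 0) -> Trajectory:
    """Add i.i.d. Gaussian measurement noise.

    For each species, the noise SD equals ``noise_fraction`` times the
    largest per-cell sample SD of that species' series, so a fraction of
    1.0 corresponds to a signal-to-noise ratio of one for the most variable
    cell.  Output counts are reals (no rounding); a fraction of 0 returns
    the trajectory unchanged.
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    if noise_fraction == 0:
        return Trajectory(times=traj.times.copy(), counts=traj.counts.copy(),
                          params=traj.params, network=traj.network)
    rng = np.random.default_rng(seed)
    counts = traj.counts.astype(np.float64).copy()
    for sp_i in range(counts.shape[2]):
        sd_ref = counts[:, :, sp_i].std(axis=0, ddof=1).max()
        counts[:, :, sp_i] += rng.normal(0.0, noise_fraction * sd_ref,
                                         counts[:, :, sp_i].shape)
    return Trajectory(times=traj.times.copy(), counts=counts,
                      params=traj.params, network=traj.network)
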