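"""Spiking-population node dynamics.

Every node of a ground-truth network is a small cortical column of Izhikevich
neurons (quadratic membrane dynamics with a discontinuous reset), densely and
randomly coupled within the column and driven by independent noisy thalamic
input.  Directed network edges act like fibre bundles: the low-pass-filtered
population firing rate of the source column is injected, after a conduction
delay, as an extra current into the excitatory pool of the target column.

The readout is the population firing rate of each column on a fixed time
grid (:class:`NeuralActivity`), which the haemodynamic stage converts into
BOLD volumes.  A linear VAR surrogate generator with the same readout shape
is provided for fast benchmarking (:func:`simulate_var_surrogate_activity`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numba import njit

from .graphs import DirectedNetwork

__all__ = [
    "ColumnParams",
    "NetworkSimParams",
    "NeuralActivity",
    "izhikevich_step",
    "simulate_network_activity",
    "simulate_var_surrogate_activity",
    "DESK_COLUMN",
    "FULL_COLUMN",
    "SimulationError",
]


class SimulationError(RuntimeError):
    """Numerical failure (divergence / non-finite state) during simulation."""


@dataclass(frozen=True)
class ColumnParams:
    """Composition and coupling of one cortical column.

    The two cell classes follow the canonical Izhikevich network recipe:
    regular-spiking excitatory cells ``(a, b, c, d) = (0.02, 0.2, -65, 8)``
    and fast-spiking inhibitory cells ``(0.1, 0.2, -65, 2)``, with the usual
    quadratic heterogeneity across cells.  Intra-column weights are dense and
    random (excitatory positive, inhibitory negative), normalized so the
    expected total synaptic input is independent of column size, and scaled
    by ``intra_gain``.  ``noise_sd`` scales the independent Gaussian thalamic
    drive (excitatory cells receive 5x, inhibitory 2x its value per step).
    """

    n_neurons: int = 100
    excitatory_fraction: float = 0.8
    izh_a: tuple[float, float] = (0.02, 0.1)  # (excitatory, inhibitory)
    izh_b: tuple[float, float] = (0.2, 0.2)
    izh_c: tuple[float, float] = (-65.0, -65.0)
    izh_d: tuple[float, float] = (8.0, 2.0)
    intra_gain: float = 1.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if not 0.0 <= self.excitatory_fraction <= 1.0:
            raise ValueError("excitatory_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class NetworkSimParams:
    """Network-level simulation settings (units: seconds).

    ``inter_gain`` scales the current injected along ground-truth edges;
    ``conduction_delay`` is the effective latency of the fibre bundle between
    columns (a compound, polysynaptic pathway, hence well above a single
    axonal delay); ``tau_syn`` the low-pass time constant applied to the
    presynaptic population rate; ``sat_rate`` (Hz) the soft (tanh) saturation
    scale of the summed presynaptic rate, which keeps columns with many
    in-edges stable.
    """

    inter_gain: float = 0.5
    conduction_delay: float = 0.35
    dt: float = 0.001
    duration: float = 885.0
    tau_syn: float = 0.10
    dt_bin: float = 0.010
    sat_rate: float = 60.0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0 or self.dt_bin <= 0:
            raise ValueError("dt, duration, dt_bin must be positive")
        if self.conduction_delay < 0:
            raise ValueError("conduction_delay must be >= 0")
        if self.sat_rate <= 0:
            raise ValueError("sat_rate must be positive")


#: Desk-scale preset: 50-neuron columns, cheap enough for repeated benchmarks.
DESK_COLUMN = ColumnParams(n_neurons=50)
#: Full-scale preset: 100-neuron columns.
FULL_COLUMN = ColumnParams(n_neurons=100)


@dataclass
class NeuralActivity:
    """Population firing rate per node on a regular time grid.

    ``rates[k, t]`` is the mean rate (Hz, spikes per neuron per second) of
    node ``k`` in time bin ``t`` of width ``dt_bin`` seconds.
    """

    rates: np.ndarray  # (n_nodes, n_bins)
    dt_bin: float
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    @property
    def duration(self) -> float:
        return self.n_bins * self.dt_bin

    def save(self, path: str | Path) -> None:
        """Compressed rate matrix plus a JSON sidecar with grid metadata."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), rates=self.rates)
        sidecar = {"dt_bin": self.dt_bin, "seed": self.seed, "meta": self.meta}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "NeuralActivity":
        path = Path(path)
        rates = np.load(path.with_suffix(".npz"))["rates"]
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(rates=rates, dt_bin=sidecar["dt_bin"], seed=sidecar["seed"],
                   meta=sidecar.get("meta", {}))


# ---------------------------------------------------------------------------
# single-step update (reference implementation, also used by unit tests)
# ---------------------------------------------------------------------------


def izhikevich_step(
    v: np.ndarray,
    u: np.ndarray,
    input_current: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    dt_ms: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One update of the Izhikevich model ``dv/dt = 0.04 v^2 + 5 v + 140 - u + I``.

    Neurons at or above the 30 mV threshold on entry are flagged as spiking
    and reset (``v <- c``, ``u <- u + d``) without further integration this
    step; all others follow the quadratic update (two half-steps for ``v``,
    then ``du/dt = a (b v - u)``).  Returns ``(v', u', spiked)``.
    """
    v = np.asarray(v, dtype=float)
    u = np.asarray(u, dtype=float)
    if not (np.all(np.isfinite(v)) and np.all(np.isfinite(u))):
        raise SimulationError("non-finite membrane state")
    spiked = v >= 30.0
    v_new = v.copy()
    u_new = u.copy()
    v_new[spiked] = np.asarray(c, dtype=float)[spiked] if np.ndim(c) else c
    u_new[spiked] = u[spiked] + (np.asarray(d, dtype=float)[spiked] if np.ndim(d) else d)
    live = ~spiked
    vv = v[live]
    for _ in range(2):  # two half-steps for the stiff quadratic part
        vv = vv + 0.5 * dt_ms * (0.04 * vv * vv + 5.0 * vv + 140.0 - u[live]
                                 + np.asarray(input_current, dtype=float)[live])
    v_new[live] = vv
    aa = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    u_new[live] = u[live] + dt_ms * (aa[live] if aa.ndim else aa) * (
        (bb[live] if bb.ndim else bb) * vv - u[live])
    return v_new, u_new, spiked


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _run_chunk(noise, t0, n_nodes, n_per, exc_count,
               a, b, c, d, noise_amp, w,
               in_src, in_ptr, inter_gain, sat_rate, delay_steps, lp_coef,
               dt_ms, bin_steps,
               v, u, s, sbuf, rates_out):  # pragma: no cover - jitted
    """Advance all columns over one chunk of pre-drawn noise, in place.

    ``noise`` is ``(steps, n_total)`` standard normal; ``sbuf`` the ring
    buffer of delayed low-pass population rates; ``t0`` the absolute step
    index of the first chunk row.
    """
    n_steps = noise.shape[0]
    n_total = n_nodes * n_per
    n_buf = sbuf.shape[0]
    i_syn = np.zeros(n_total)
    fired = np.zeros(n_total, dtype=np.bool_)
    rate_norm = 1.0 / (n_per * dt_ms * 0.001)
    for ti in range(n_steps):
        t = t0 + ti
        # spikes at entry (threshold crossed during the previous update)
        i_syn[:] = 0.0
        count = np.zeros(n_nodes)
        for node in range(n_nodes):
            base = node * n_per
            for k in range(n_per):
                idx = base + k
                if v[idx] >= 30.0:
                    fired[idx] = True
                    v[idx] = c[idx]
                    u[idx] += d[idx]
                    count[node] += 1.0
                    rates_out[node, t // bin_steps] += 1.0
                    for post in range(n_per):
                        i_syn[base + post] += w[node, post, k]
                else:
                    fired[idx] = False
        # low-pass population rate (Hz) and its delayed copy
        head = t % n_buf
        for node in range(n_nodes):
            s[node] += lp_coef * (count[node] * rate_norm - s[node])
            sbuf[head, node] = s[node]
        # inter-node drive into excitatory pools (saturating synaptic transfer)
        if t >= delay_steps:
            tail = (t - delay_steps) % n_buf
            for node in range(n_nodes):
                drive = 0.0
                for p in range(in_ptr[node], in_ptr[node + 1]):
                    drive += sbuf[tail, in_src[p]]
                if drive != 0.0:
                    drive = inter_gain * sat_rate * np.tanh(drive / sat_rate)
                    base = node * n_per
                    for k in range(exc_count):
                        i_syn[base + k] += drive
        # integrate
        for idx in range(n_total):
            if fired[idx]:
                continue  # reset this step; no further integration
            cur = i_syn[idx] + noise_amp[idx] * noise[ti, idx]
            uu = u[idx]
            vv = v[idx]
            vv += 0.5 * dt_ms * (0.04 * vv * vv + 5.0 * vv + 140.0 - uu + cur)
            vv += 0.5 * dt_ms * (0.04 * vv * vv + 5.0 * vv + 140.0 - uu + cur)
            if vv > 30.0:
                vv = 30.0  # peak clamp; reset happens on the next step
            elif vv < -150.0:
                vv = -150.0
            v[idx] = vv
            u[idx] = uu + dt_ms * a[idx] * (b[idx] * vv - uu)
    return 0


def _build_neurons(network: DirectedNetwork, col: ColumnParams,
                   rng: np.random.Generator):
    """Per-neuron parameter arrays and intra-column weights for all columns."""
    n_nodes = network.n_nodes
    n_per = col.n_neurons
    exc_count = int(round(col.excitatory_fraction * n_per))
    n_total = n_nodes * n_per
    a = np.empty(n_total)
    b = np.empty(n_total)
    c = np.empty(n_total)
    d = np.empty(n_total)
    noise_amp = np.empty(n_total)
    w = np.zeros((n_nodes, n_per, n_per))
    # normalize weights so expected total input matches a 100-neuron column
    wscale = col.intra_gain * (100.0 / max(n_per, 1))
    ae, ai = col.izh_a
    be, bi = col.izh_b
    ce, ci = col.izh_c
    de, di = col.izh_d
    for node in range(n_nodes):
        base = node * n_per
        r = rng.random(n_per)
        for k in range(n_per):
            idx = base + k
            if k < exc_count:  # regular-spiking excitatory, r^2 heterogeneity
                a[idx] = ae
                b[idx] = be
                c[idx] = ce + 15.0 * r[k] ** 2
                d[idx] = de - 6.0 * r[k] ** 2
                noise_amp[idx] = 5.0 * col.noise_sd
            else:  # fast-spiking inhibitory, linear heterogeneity
                a[idx] = 0.02 + (ai - 0.02) * r[k]
                b[idx] = bi + 0.05 * (1.0 - r[k])
                c[idx] = ci
                d[idx] = di
                noise_amp[idx] = 2.0 * col.noise_sd
        wmat = rng.random((n_per, n_per))
        wmat[:, :exc_count] *= 0.5 * wscale
        wmat[:, exc_count:] *= -1.0 * wscale
        np.fill_diagonal(wmat, 0.0)
        w[node] = wmat
    return a, b, c, d, noise_amp, w, exc_count


def _in_edge_csr(network: DirectedNetwork) -> tuple[np.ndarray, np.ndarray]:
    """CSR arrays of source nodes per target node."""
    n = network.n_nodes
    per_target: list[list[int]] = [[] for _ in range(n)]
    for i, j in network.sorted_edges():
        per_target[j].append(i)
    ptr = np.zeros(n + 1, dtype=np.int64)
    src: list[int] = []
    for node in range(n):
        ptr[node + 1] = ptr[node] + len(per_target[node])
        src.extend(per_target[node])
    return np.asarray(src, dtype=np.int64), ptr


def simulate_network_activity(
    network: DirectedNetwork,
    col: ColumnParams = DESK_COLUMN,
    sim: NetworkSimParams = NetworkSimParams(),
    rng: np.random.Generator | None = None,
) -> NeuralActivity:
    """Simulate coupled Izhikevich columns and return binned population rates.

    Each directed edge ``j -> i`` injects the delayed, low-pass-filtered
    population rate of column ``j`` (scaled by ``sim.inter_gain``) as a
    current into the excitatory cells of column ``i``.  Reproducible under a
    fixed seed: the kernel RNG seed is drawn from ``rng``.
    """
    if rng is None:
        rng = np.random.default_rng()
    dt_ms = sim.dt * 1000.0
    bin_steps = max(1, int(round(sim.dt_bin / sim.dt)))
    n_steps = int(round(sim.duration / sim.dt))
    n_bins = n_steps // bin_steps
    n_steps = n_bins * bin_steps  # whole bins only
    delay_steps = int(round(sim.conduction_delay / sim.dt))
    lp_coef = min(1.0, sim.dt / sim.tau_syn)
    a, b, c, d, noise_amp, w, exc_count = _build_neurons(network, col, rng)
    in_src, in_ptr = _in_edge_csr(network)
    n_total = network.n_nodes * col.n_neurons
    rates = np.zeros((network.n_nodes, n_bins))
    v = np.full(n_total, -65.0)
    u = b * v
    sbuf = np.zeros((delay_steps + 1, network.n_nodes))
    s = np.zeros(network.n_nodes)
    chunk = 20000
    for t0 in range(0, n_steps, chunk):
        steps = min(chunk, n_steps - t0)
        noise = rng.standard_normal((steps, n_total), dtype=np.float32)
        _run_chunk(noise, t0, network.n_nodes, col.n_neurons, exc_count,
                   a, b, c, d, noise_amp, w, in_src, in_ptr,
                   float(sim.inter_gain), float(sim.sat_rate),
                   delay_steps, lp_coef,
                   dt_ms, bin_steps, v, u, s, sbuf, rates)
        if not np.all(np.isfinite(v)):
            raise SimulationError(
                f"membrane divergence at step {t0 + steps} "
                f"(inter_gain={sim.inter_gain}, intra_gain={col.intra_gain})")
    rates /= col.n_neurons * sim.dt_bin  # spikes -> Hz per neuron
    mean_rate = float(rates.mean())
    if mean_rate > 500.0:
        raise SimulationError(
            f"mean rate {mean_rate:.0f} Hz diverged; reduce intra_gain or "
            f"inter_gain")
    return NeuralActivity(rates=rates, dt_bin=sim.dt_bin, seed=None,
                          meta={"generator": "izhikevich",
                                "column": asdict(col), "sim": asdict(sim),
                                "n_edges": network.n_edges})


# ---------------------------------------------------------------------------
# linear surrogate generator
# ---------------------------------------------------------------------------


def simulate_var_surrogate_activity(
    network: DirectedNetwork,
    sim: NetworkSimParams = NetworkSimParams(),
    coupling: float = 0.25,
    self_coef: float = 0.6,
    rng: np.random.Generator | None = None,
) -> NeuralActivity:
    """Linear VAR(1) surrogate of the node rate dynamics.

    Node activity follows ``r_t = Phi r_{t-1} + eta_t`` on the ``dt_bin``
    grid, with ``Phi = self_coef * I + coupling * A^T / max(1, indegree)``
    (edges ``j -> i`` feed node ``i``), rescaled if needed to keep the
    spectral radius below 0.95.  Output is shifted and scaled into a
    nonnegative pseudo-rate so it can be fed to the same haemodynamic stage
    as the spiking generator.
    """
    if rng is None:
        rng = np.random.default_rng()
    n = network.n_nodes
    n_bins = int(round(sim.duration / sim.dt_bin))
    adj = network.adjacency().astype(float)
    indeg = np.maximum(adj.sum(axis=0), 1.0)
    phi = self_coef * np.eye(n) + coupling * (adj.T / indeg[:, None])
    rad = float(np.max(np.abs(np.linalg.eigvals(phi))))
    if rad >= 0.95:
        phi *= 0.95 / rad
    x = np.zeros((n, n_bins))
    state = np.zeros(n)
    noise = rng.standard_normal((n_bins, n))
    for t in range(n_bins):
        state = phi @ state + noise[t]
        x[:, t] = state
    # map to a nonnegative pseudo-rate around 10 Hz
    rates = 10.0 + 2.0 * x
    np.maximum(rates, 0.0, out=rates)
    return NeuralActivity(rates=rates, dt_bin=sim.dt_bin,
                          seed=None,
                          meta={"generator": "var_surrogate",
                                "coupling": coupling, "self_coef": self_coef,
                                "n_edges": network.n_edges})
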