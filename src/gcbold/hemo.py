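"""Balloon-model haemodynamics: node firing rates -> BOLD volumes.

Each node's population rate drives a four-state neurovascular system —
vasodilatory signal ``s``, normalized blood inflow ``f``, venous volume ``v``
and deoxyhaemoglobin content ``q``:

.. math::

    \\dot s &= z(t) - \\kappa s - \\gamma (f - 1) \\\\
    \\dot f &= s \\\\
    \\tau \\dot v &= f - v^{1/\\alpha} \\\\
    \\tau \\dot q &= f \\, E(f)/E_0 - v^{1/\\alpha} q / v

with oxygen extraction ``E(f) = 1 - (1 - E0)^(1/f)`` and readout

.. math::

    \\mathrm{BOLD} = V_0 (k_1 (1 - q) + k_2 (1 - q/v) + k_3 (1 - v)).

The system is integrated with a fixed-step 4th-order Runge–Kutta scheme on
the neural bin grid and decimated at the scanner TR after a discarded
burn-in, which models the aggressive down-sampling a scanner applies to the
underlying neural dynamics.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from numba import njit

from .graphs import DirectedNetwork
from .neural import (
    ColumnParams,
    DESK_COLUMN,
    NetworkSimParams,
    NeuralActivity,
    simulate_network_activity,
    simulate_var_surrogate_activity,
)

__all__ = ["HemoParams", "BoldTimeseries", "simulate_bold", "generate_dataset"]


@dataclass(frozen=True)
class HemoParams:
    """Balloon-model constants (standard published parameterization).

    ``kappa`` [1/s] signal decay, ``gamma`` [1/s] flow-dependent elimination,
    ``tau`` [s] haemodynamic transit time, ``alpha`` Grubb's vessel stiffness
    exponent, ``E0`` resting oxygen extraction fraction, ``V0`` resting blood
    volume fraction.  ``drive_gain`` scales the normalized firing rate into
    the vasodilatory drive ``z``; with ``center=True`` (default) the drive is
    the rate's relative fluctuation around its time mean, so the node rests
    at the haemodynamic fixed point.  ``rate_norm`` overrides the per-node
    normalizing rate (defaults to the node's time mean).  ``noise_snr``, if
    set, adds white measurement noise at that signal-to-noise ratio.
    """

    kappa: float = 0.65
    gamma: float = 0.41
    tau: float = 0.98
    alpha: float = 0.32
    E0: float = 0.34
    V0: float = 0.02
    drive_gain: float = 0.4
    center: bool = True
    rate_norm: float | None = None
    burn_in: float = 20.0
    noise_snr: float | None = None

    def __post_init__(self) -> None:
        if min(self.kappa, self.gamma, self.tau, self.V0, self.drive_gain) <= 0:
            raise ValueError("rate constants and gains must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.E0 < 1:
            raise ValueError("E0 must be in (0, 1)")

    @property
    def k1(self) -> float:
        return 7.0 * self.E0

    @property
    def k2(self) -> float:
        return 2.0

    @property
    def k3(self) -> float:
        return 2.0 * self.E0 - 0.2


@dataclass
class BoldTimeseries:
    """Node x volume BOLD matrix sampled at repetition time ``tr``."""

    data: np.ndarray  # (n_nodes, n_volumes)
    tr: float
    labels: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")
        if not self.labels:
            self.labels = [str(i) for i in range(self.data.shape[0])]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]

    def as_observations(self) -> np.ndarray:
        """(n_volumes, n_nodes) array, the orientation the estimator expects."""
        return self.data.T

    def to_tsv(self, path: str | Path) -> None:
        """Rows = volumes, columns = nodes, header of node ids; JSON sidecar."""
        path = Path(path)
        header = "\t".join(self.labels)
        body = "\n".join(
            "\t".join(f"{x:.10g}" for x in row) for row in self.data.T
        )
        path.write_text(header + "\n" + body + "\n")
        sidecar = {"tr": self.tr, "meta": self.meta}
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, tr: float | None = None) -> "BoldTimeseries":
        path = Path(path)
        sidecar_path = path.with_suffix(path.suffix + ".json")
        meta: dict = {}
        if tr is None:
            if not sidecar_path.exists():
                raise ValueError("tr not given and no sidecar found")
            sidecar = json.loads(sidecar_path.read_text())
            tr = float(sidecar["tr"])
            meta = sidecar.get("meta", {})
        lines = path.read_text().strip().splitlines()
        labels = lines[0].split("\t")
        data = np.array([[float(x) for x in ln.split("\t")] for ln in lines[1:]])
        return cls(data=data.T, tr=tr, labels=labels, meta=meta)


@njit(cache=True)
def _balloon_rk4(z, h, kappa, gamma, tau, alpha, e0):  # pragma: no cover - jitted
    """Integrate the Balloon system for all nodes over the drive array ``z``.

    ``z`` is (n_nodes, n_bins), piecewise constant on bins of width ``h``.
    Returns states (s, f, v, q) per node per bin, valued at the bin's
    *start* (so column ``t`` is the state at time ``t * h`` exactly).
    """
    n_nodes, n_bins = z.shape
    out = np.empty((4, n_nodes, n_bins))
    ialpha = 1.0 / alpha
    for node in range(n_nodes):
        s = 0.0
        f = 1.0
        vv = 1.0
        q = 1.0
        for t in range(n_bins):
            out[0, node, t] = s
            out[1, node, t] = f
            out[2, node, t] = vv
            out[3, node, t] = q
            zz = z[node, t]
            # classic RK4 with the drive held constant over the bin
            ef = 1.0 - (1.0 - e0) ** (1.0 / f)
            ds1 = zz - kappa * s - gamma * (f - 1.0)
            df1 = s
            dv1 = (f - vv ** ialpha) / tau
            dq1 = (f * ef / e0 - vv ** ialpha * q / vv) / tau
            s2 = s + 0.5 * h * ds1
            f2 = f + 0.5 * h * df1
            v2 = vv + 0.5 * h * dv1
            q2 = q + 0.5 * h * dq1
            ef = 1.0 - (1.0 - e0) ** (1.0 / f2)
            ds2 = zz - kappa * s2 - gamma * (f2 - 1.0)
            df2 = s2
            dv2 = (f2 - v2 ** ialpha) / tau
            dq2 = (f2 * ef / e0 - v2 ** ialpha * q2 / v2) / tau
            s3 = s + 0.5 * h * ds2
            f3 = f + 0.5 * h * df2
            v3 = vv + 0.5 * h * dv2
            q3 = q + 0.5 * h * dq2
            ef = 1.0 - (1.0 - e0) ** (1.0 / f3)
            ds3 = zz - kappa * s3 - gamma * (f3 - 1.0)
            df3 = s3
            dv3 = (f3 - v3 ** ialpha) / tau
            dq3 = (f3 * ef / e0 - v3 ** ialpha * q3 / v3) / tau
            s4 = s + h * ds3
            f4 = f + h * df3
            v4 = vv + h * dv3
            q4 = q + h * dq3
            ef = 1.0 - (1.0 - e0) ** (1.0 / f4)
            ds4 = zz - kappa * s4 - gamma * (f4 - 1.0)
            df4 = s4
            dv4 = (f4 - v4 ** ialpha) / tau
            dq4 = (f4 * ef / e0 - v4 ** ialpha * q4 / v4) / tau
            s += h / 6.0 * (ds1 + 2.0 * ds2 + 2.0 * ds3 + ds4)
            f += h / 6.0 * (df1 + 2.0 * df2 + 2.0 * df3 + df4)
            vv += h / 6.0 * (dv1 + 2.0 * dv2 + 2.0 * dv3 + dv4)
            q += h / 6.0 * (dq1 + 2.0 * dq2 + 2.0 * dq3 + dq4)
            if f < 1e-3:
                f = 1e-3
            if vv < 1e-3:
                vv = 1e-3
            if q < 1e-6:
                q = 1e-6
    return out


def drive_from_activity(activity: NeuralActivity, params: HemoParams) -> np.ndarray:
    """Vasodilatory drive ``z`` per node per bin from normalized firing rate."""
    rates = np.asarray(activity.rates, dtype=float)
    if params.rate_norm is not None:
        ref = np.full(rates.shape[0], float(params.rate_norm))
    else:
        ref = rates.mean(axis=1)
    safe = np.where(ref > 0, ref, 1.0)
    z = params.drive_gain * rates / safe[:, None]
    if params.center:
        z -= params.drive_gain * np.where(ref > 0, 1.0, 0.0)[:, None]
    z[ref == 0] = 0.0
    return z


def simulate_bold(
    activity: NeuralActivity,
    params: HemoParams = HemoParams(),
    tr: float = 0.72,
    n_volumes: int = 1200,
    rng: np.random.Generator | None = None,
) -> BoldTimeseries:
    """Integrate the Balloon system and sample BOLD every ``tr`` seconds.

    The first ``params.burn_in`` seconds are discarded; volume ``n`` is read
    at time ``burn_in + n * tr``.  Requires
    ``activity.duration >= burn_in + n_volumes * tr``.
    """
    needed = params.burn_in + n_volumes * tr
    if activity.duration < needed - 1e-9:
        raise ValueError(
            f"activity covers {activity.duration:.1f}s < "
            f"{needed:.1f}s (burn-in + n_volumes * tr)")
    z = drive_from_activity(activity, params)
    h = activity.dt_bin
    states = _balloon_rk4(z, h, params.kappa, params.gamma, params.tau,
                          params.alpha, params.E0)
    if not np.all(np.isfinite(states)):
        raise FloatingPointError("Balloon integration diverged")
    v_state = states[2]
    q_state = states[3]
    bold_fine = params.V0 * (
        params.k1 * (1.0 - q_state)
        + params.k2 * (1.0 - q_state / v_state)
        + params.k3 * (1.0 - v_state)
    )
    idx = np.round((params.burn_in + tr * np.arange(n_volumes)) / h).astype(int)
    idx = np.minimum(idx, bold_fine.shape[1] - 1)
    data = bold_fine[:, idx]
    if params.noise_snr is not None:
        if rng is None:
            rng = np.random.default_rng()
        sd = data.std(axis=1, keepdims=True) / params.noise_snr
        data = data + sd * rng.standard_normal(data.shape)
    return BoldTimeseries(data=data, tr=tr,
                          meta={"hemo": {k: v for k, v in asdict(params).items()},
                                "n_volumes": n_volumes,
                                "activity": activity.meta})


def generate_dataset(
    network: DirectedNetwork,
    col: ColumnParams = DESK_COLUMN,
    sim: NetworkSimParams | None = None,
    hemo: HemoParams = HemoParams(),
    tr: float = 0.72,
    n_volumes: int = 1200,
    rng: np.random.Generator | None = None,
    generator: str = "izhikevich",
) -> BoldTimeseries:
    """End-to-end synthetic dataset: network -> spiking columns -> BOLD.

    ``generator`` selects the neural stage: ``"izhikevich"`` (spiking
    columns) or ``"var"`` (linear surrogate).  Fully reproducible for a given
    ``rng`` state.
    """
    if rng is None:
        rng = np.random.default_rng()
    duration = hemo.burn_in + n_volumes * tr + 1.0
    if sim is None:
        sim = NetworkSimParams(duration=duration)
    elif sim.duration < hemo.burn_in + n_volumes * tr:
        raise ValueError("sim.duration too short for requested volumes")
    if generator == "izhikevich":
        activity = simulate_network_activity(network, col, sim, rng)
    elif generator == "var":
        activity = simulate_var_surrogate_activity(network, sim, rng=rng)
    else:
        raise ValueError(f"unknown generator {generator!r}")
    bold = simulate_bold(activity, hemo, tr=tr, n_volumes=n_volumes, rng=rng)
    graph_hash = hashlib.sha1(
        repr(network.sorted_edges()).encode()).hexdigest()[:12]
    bold.meta["graph_sha1"] = graph_hash
    bold.meta["generator"] = generator
    return bold
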