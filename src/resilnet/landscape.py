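"""Stability landscapes of Ising symptom networks.

The Boltzmann distribution of a K-node network is computed by exact
enumeration of all 2^K states and projected onto the number of active
symptoms n, giving the marginal P(n) and the generalized potential
U(n) = -ln P(n) (in nats). Valleys of U are attractor states in the
ball-in-cup sense; the *stability difference*

    S = min_{n in unhealthy} U(n) - min_{n in healthy} U(n)

contrasts the depth of the healthy region (at most ``healthy_max`` = 2
active symptoms by default, i.e. unhealthy = 3+ symptoms in line with the
60% MHI-5 cutoff) with the unhealthy region. Positive S means the healthy
state is the more stable attractor; any shared barrier between the two
regional minima cancels in the difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _fast
from .ising import IsingNetwork

#: exact enumeration is the contract; beyond this many nodes, refuse
MAX_EXACT_NODES = 20


@dataclass
class StabilityLandscape:
    K: int
    P: np.ndarray            # P(n), n = 0..K
    U: np.ndarray            # -ln P(n)
    minima: tuple[int, ...]  # local minima of U (plateau -> smallest n)
    healthy_max: int = 2

    @property
    def healthy_region(self) -> range:
        return range(0, self.healthy_max + 1)

    @property
    def unhealthy_region(self) -> range:
        return range(self.healthy_max + 1, self.K + 1)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "n": np.arange(self.K + 1),
            "P": self.P,
            "U": self.U,
            "is_minimum": [int(n in self.minima) for n in range(self.K + 1)],
        })


def hamiltonian(x, net: IsingNetwork) -> float:
    """H(x) = -sum_i tau_i x_i - sum_{i<j} W_ij x_i x_j on the 0/1 domain."""
    x = np.asarray(x, dtype=float)
    if x.shape != (net.K,):
        raise ValueError(f"state must have length {net.K}")
    if not np.isin(x, (0, 1)).all():
        raise ValueError("state entries must be 0/1")
    pair = 0.5 * x @ net.W @ x  # W symmetric, zero diagonal -> each pair once
    return float(-(net.tau @ x) - pair)


def state_distribution(net: IsingNetwork) -> np.ndarray:
    """Boltzmann probabilities P(x) over all 2^K states, exactly.

    State index s encodes x via its bits (bit i = x_i). Raises for
    K > 20 rather than silently approximating.
    """
    if net.K > MAX_EXACT_NODES:
        raise ValueError(f"exact enumeration limited to K <= {MAX_EXACT_NODES}")
    lw = _fast.state_log_weights(net.tau, net.W)
    lw = lw - lw.max()
    p = np.exp(lw)
    return p / p.sum()


def _local_minima(U: np.ndarray) -> tuple[int, ...]:
    """Local minima with plateaus collapsed to their smallest n."""
    minima = []
    i = 0
    m = len(U)
    while i < m:
        j = i
        while j + 1 < m and U[j + 1] == U[i]:
            j += 1
        left_ok = i == 0 or U[i - 1] > U[i]
        right_ok = j == m - 1 or U[j + 1] > U[i]
        if left_ok and right_ok:
            minima.append(i)
        i = j + 1
    return tuple(minima)


def activation_landscape(net: IsingNetwork, healthy_max: int = 2) -> StabilityLandscape:
    """Project the exact state distribution onto the activation count."""
    if not 0 <= healthy_max < net.K:
        raise ValueError("healthy_max must lie in [0, K)")
    Pn = _fast.activation_probabilities(net.tau, net.W)
    if np.any(Pn <= 0.0):
        raise ValueError("P(n) underflowed to zero; parameters too extreme "
                         "for a finite landscape")
    U = -np.log(Pn)
    return StabilityLandscape(K=net.K, P=Pn, U=U,
                              minima=_local_minima(U), healthy_max=healthy_max)


def stability_difference(land: StabilityLandscape) -> float:
    """Depth of the healthy regional minimum relative to the unhealthy one.

    S = min over the unhealthy region of U minus min over the healthy
    region of U; positive values mean the healthy state is more stable.
    """
    h = min(land.U[n] for n in land.healthy_region)
    u = min(land.U[n] for n in land.unhealthy_region)
    return float(u - h)


def has_second_attractor(land: StabilityLandscape) -> bool:
    """True iff a local minimum of U exists in the unhealthy region (in
    addition to one in the healthy region)."""
    healthy = any(n in land.minima for n in land.healthy_region)
    unhealthy = any(n in land.minima for n in land.unhealthy_region)
    return bool(healthy and unhealthy)


def write_landscape_csv(land: StabilityLandscape, path, header_lines=()) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        land.to_frame().to_csv(fh, index=False)


def landscape_summary(land: StabilityLandscape) -> dict:
    """JSON-ready summary: S, minima and the region split."""
    return {
        "stability_difference": stability_difference(land),
        "minima": list(land.minima),
        "healthy_region": [0, land.healthy_max],
        "unhealthy_region": [land.healthy_max + 1, land.K],
        "has_second_attractor": has_second_attractor(land),
    }
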