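"""Markov-model potential-of-mean-force estimation from 1-D reaction
coordinates, in the unbiased-trajectory limit of the dynamic histogram
analysis method (DHAM).

The coordinate series is discretized onto a uniform grid, lag-``lag``
transition counts are pooled across series, the maximum-likelihood
row-stochastic transition matrix is restricted to its largest strongly
connected component, and the free energy per bin is

    F_i = -k_B T ln(pi_i),   pi = leading left eigenvector of T,

min-shifted so the lowest occupied bin is 0.  Bins outside the connected
component are flagged, not interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

#: Boltzmann constant, kcal/(mol*K).
KB_KCAL = 0.0019872


@dataclass
class BinnedSeries:
    """Bin-label series plus its grid and a report of dropped points."""

    labels: np.ndarray
    edges: np.ndarray
    n_dropped: int = 0

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def bin_series(
    x: np.ndarray,
    n_bins: int,
    range_: tuple[float, float],
    clip: str = "error",
) -> BinnedSeries:
    """Uniform binning with the half-open convention (an interior edge
    belongs to the bin on its right; the last bin is closed).

    ``clip`` controls out-of-range points: ``"error"`` raises, ``"drop"``
    excludes them (counted in ``n_dropped``), ``"clamp"`` assigns them to
    the edge bins.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = range_
    if not hi > lo:
        raise ValueError("range must be increasing")
    out_of_range = (x < lo) | (x > hi)
    n_dropped = 0
    if out_of_range.any():
        if clip == "error":
            raise ValueError(
                f"{out_of_range.sum()} points outside [{lo}, {hi}]; "
                "pass clip='drop' or clip='clamp'"
            )
        if clip == "drop":
            n_dropped = int(out_of_range.sum())
            x = x[~out_of_range]
        elif clip == "clamp":
            x = np.clip(x, lo, hi)
        else:
            raise ValueError(f"unknown clip policy {clip!r}")
    width = (hi - lo) / n_bins
    labels = np.floor((x - lo) / width).astype(int)
    labels = np.minimum(labels, n_bins - 1)  # x == hi joins the last bin
    edges = lo + width * np.arange(n_bins + 1)
    return BinnedSeries(labels=labels, edges=edges, n_dropped=n_dropped)


def transition_counts(labels: np.ndarray, n_states: int, lag: int = 1) -> np.ndarray:
    """C[i, j] = #{t : label(t) = i and label(t + lag) = j}."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) < lag + 1:
        raise ValueError(f"need at least lag+1={lag + 1} labels")
    C = np.zeros((n_states, n_states), dtype=float)
    np.add.at(C, (labels[:-lag], labels[lag:]), 1.0)
    return C


def transition_matrix(labels: np.ndarray, lag: int = 1) -> np.ndarray:
    """Maximum-likelihood row-stochastic matrix over the visited states.

    States with no outgoing transitions are excluded from the state set,
    so a constant label series yields the valid 1x1 matrix [[1]].
    """
    labels = np.asarray(labels, dtype=int)
    states = np.unique(labels)
    remap = {s: i for i, s in enumerate(states)}
    relabeled = np.array([remap[s] for s in labels])
    C = transition_counts(relabeled, len(states), lag)
    rowsum = C.sum(axis=1)
    keep = rowsum > 0
    C = C[np.ix_(keep, keep)]
    return C / C.sum(axis=1, keepdims=True)


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Leading left eigenvector of a row-stochastic matrix, normalized to
    a probability vector."""
    w, v = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class PMFProfile:
    """Free-energy profile over a uniform bin grid."""

    bin_centers: np.ndarray
    free_energy: np.ndarray           # kcal/mol; NaN on unoccupied bins
    occupied: np.ndarray              # mask of bins inside the Markov model
    temperature: float                # K
    lag: int                          # frames
    source: str = ""
    n_samples: int = 0
    n_bins: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_bins = len(self.bin_centers)

    @property
    def kT(self) -> float:
        return KB_KCAL * self.temperature

    def value_at(self, x: float) -> float:
        """PMF of the occupied bin whose center is nearest ``x``."""
        occ = np.flatnonzero(self.occupied)
        i = occ[int(np.argmin(np.abs(self.bin_centers[occ] - x)))]
        return float(self.free_energy[i])

    def to_frame(self, segment: str = "full") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "pmf": self.free_energy,
                "occupied": self.occupied,
                "segment": segment,
            }
        )


def pmf_from_series(
    series: list[np.ndarray] | np.ndarray,
    n_bins: int = 30,
    lag: int = 1,
    temperature: float = 310.0,
    burn_in: float = 0.10,
    range_: tuple[float, float] | None = None,
    source: str = "",
) -> PMFProfile:
    """DHAM-style PMF from one or more unbiased coordinate series.

    Transition counts are pooled across series (counts never bridge two
    series), the transition matrix is restricted to its largest strongly
    connected component, and F = -k_B T ln(pi) is min-shifted to zero.
    """
    if isinstance(series, np.ndarray) and series.ndim == 1:
        series = [series]
    trimmed = []
    for x in series:
        x = np.asarray(x, dtype=float)
        start = int(np.floor(burn_in * len(x)))
        if start >= len(x):
            raise ValueError("burn-in removes an entire series")
        trimmed.append(x[start:])
    pooled = np.concatenate(trimmed)
    if range_ is None:
        range_ = (float(pooled.min()), float(pooled.max()))
    C = np.zeros((n_bins, n_bins))
    n_samples = 0
    for x in trimmed:
        if len(x) < lag + 1:
            raise ValueError("a series is shorter than lag+1 after burn-in")
        b = bin_series(x, n_bins, range_, clip="clamp")
        C += transition_counts(b.labels, n_bins, lag)
        n_samples += len(x)
    edges = np.linspace(range_[0], range_[1], n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    G = nx.DiGraph()
    G.add_nodes_from(np.flatnonzero(C.sum(axis=1) + C.sum(axis=0) > 0))
    src, dst = np.nonzero(C)
    G.add_edges_from(zip(src.tolist(), dst.tolist()))
    if G.number_of_nodes() == 0:
        raise ValueError("no transitions observed")
    components = sorted(
        nx.strongly_connected_components(G),
        key=lambda c: C[np.ix_(sorted(c), sorted(c))].sum(),
        reverse=True,
    )
    scc = sorted(components[0])
    total_in_scc = C[np.ix_(scc, scc)].sum()
    if len(scc) < 2 and n_bins > 1 and total_in_scc < 0.5 * C.sum():
        raise ValueError(
            "transition graph has no dominant strongly connected component; "
            "collect more data or use fewer bins"
        )
    Csub = C[np.ix_(scc, scc)]
    T = Csub / Csub.sum(axis=1, keepdims=True)
    pi = stationary_distribution(T)

    kT = KB_KCAL * temperature
    free = np.full(n_bins, np.nan)
    occupied = np.zeros(n_bins, dtype=bool)
    with np.errstate(divide="ignore"):
        f_scc = -kT * np.log(pi)
    f_scc -= np.nanmin(f_scc)
    for k, bin_idx in enumerate(scc):
        free[bin_idx] = f_scc[k]
        occupied[bin_idx] = True
    return PMFProfile(
        bin_centers=centers,
        free_energy=free,
        occupied=occupied,
        temperature=temperature,
        lag=lag,
        source=source,
        n_samples=n_samples,
    )


def convergence_segments(
    series: np.ndarray,
    k: int = 3,
    n_bins: int = 30,
    lag: int = 1,
    temperature: float = 310.0,
    burn_in: float = 0.10,
) -> list[tuple[str, PMFProfile]]:
    """PMF per contiguous k-th of the data plus the full-data PMF, all on
    a shared bin grid (labels: 'full', 'segment_1', ...)."""
    x = np.asarray(series, dtype=float)
    start = int(np.floor(burn_in * len(x)))
    body = x[start:]
    if len(body) < k * (lag + 1):
        raise ValueError(f"series too short to split into {k} segments")
    range_ = (float(body.min()), float(body.max()))
    out = [
        (
            "full",
            pmf_from_series(
                [body], n_bins, lag, temperature, burn_in=0.0,
                range_=range_, source="full",
            ),
        )
    ]
    for i, seg in enumerate(np.array_split(body, k), start=1):
        try:
            prof = pmf_from_series(
                [seg], n_bins, lag, temperature, burn_in=0.0,
                range_=range_, source=f"segment_{i}",
            )
        except ValueError as exc:
            raise ValueError(f"segment {i}: {exc}") from exc
        out.append((f"segment_{i}", prof))
    return out
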