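"""Global (whole-segment) coupling: equal-time Pearson matrices and networks.

For one pair of systems (two muscles, or heart/respiration against one
muscle) the coupling matrix holds the zero-lag Pearson coefficient between
every pair of band-power (or rate) time series: 10 x 10 = 100 values per
muscle pair, 1 x 10 = 10 per rate-muscle pair.  Matrices are averaged
element-wise across participants, and mapped into a multiplex network
whose nodes are (system, frequency band) pairs and whose links carry the
coupling strength plus a configurable strength class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .bandpower import BandPowerSeries
from .config import LINK_CLASS_LABELS, LINK_CLASS_PRESETS
from .rates import RateSeries
from .recording import SegmentLabel

__all__ = [
    "CouplingMatrix",
    "Link",
    "NetworkMap",
    "coupling_matrix",
    "best_lag",
    "group_average",
    "build_network",
    "mean_link_strength",
]

MIN_OVERLAP = 10


@dataclass
class CouplingMatrix:
    """Pearson coupling coefficients for one system pair and segment."""

    pair_id: tuple[str, str]
    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray            # shape (n_rows, n_cols), entries in [-1, 1]
    lag: float = 0.0
    segment: SegmentLabel | None = None
    n_participants: int = 1
    cell_counts: np.ndarray | None = None   # per-cell participant counts after averaging

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("matrix shape does not match its labels")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.abs(finite).max() > 1 + 1e-9:
            raise ValueError("correlation entries must lie in [-1, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _series_list(x) -> list:
    if isinstance(x, (BandPowerSeries, RateSeries)):
        return [x]
    return list(x)


def _label(series) -> str:
    if isinstance(series, RateSeries):
        return series.kind.upper()
    return series.band_label


def _system(series) -> str:
    if isinstance(series, RateSeries):
        return "Heart" if series.kind == "hr" else "Respiration"
    return series.muscle_id


def _stack(series_list, step: float) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack series sharing one uniform grid into (indices, values, labels)."""
    idx_ref = None
    rows = []
    labels = []
    for s in series_list:
        if abs(s.step - step) > 1e-9:
            raise ValueError("all series entering one matrix must share the same step")
        idx = np.round(s.times / step).astype(int)
        if idx_ref is None:
            idx_ref = idx
        rows.append((idx, s.values))
        labels.append(_label(s))
    # use the intersection of all index grids
    common = rows[0][0]
    for idx, _ in rows[1:]:
        common = np.intersect1d(common, idx)
    mat = np.empty((len(rows), common.size))
    for i, (idx, vals) in enumerate(rows):
        pos = np.searchsorted(idx, common)
        mat[i] = vals[pos]
    return common, mat, labels


def _pearson_rows(a: np.ndarray, b: np.ndarray, row_labels, col_labels) -> np.ndarray:
    """Row-by-row Pearson matrix between two (n, T) stacks."""
    t = a.shape[1]
    for mat, labels, side in ((a, row_labels, "row"), (b, col_labels, "column")):
        sd = mat.std(axis=1, ddof=1)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise ValueError(f"zero-variance series in {side} band {labels[dead[0]]!r}")
    az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, ddof=1, keepdims=True)
    bz = (b - b.mean(axis=1, keepdims=True)) / b.std(axis=1, ddof=1, keepdims=True)
    return np.clip(az @ bz.T / (t - 1), -1.0, 1.0)


def coupling_matrix(a, b, lag: float = 0.0, segment: SegmentLabel | None = None) -> CouplingMatrix:
    """Equal-time Pearson matrix between two sets of series at a given lag.

    Entry (m, k) correlates ``a_m(t)`` with ``b_k(t + lag)``; lags are in
    seconds and must be multiples of the series step.  Series are trimmed
    to their common time support; an overlap below 10 points is an error.
    """
    a_list, b_list = _series_list(a), _series_list(b)
    step = a_list[0].step
    lag_steps = int(round(lag / step))
    if abs(lag_steps * step - lag) > 1e-9:
        raise ValueError(f"lag {lag} s is not a multiple of the series step {step} s")

    ia, amat, row_labels = _stack(a_list, step)
    ib, bmat, col_labels = _stack(b_list, step)
    # b shifted by lag: b value at grid index i is paired with a at i - lag_steps
    common = np.intersect1d(ia, ib - lag_steps)
    if common.size < MIN_OVERLAP:
        raise ValueError(f"series overlap of {common.size} points is below {MIN_OVERLAP}")
    asel = amat[:, np.searchsorted(ia, common)]
    bsel = bmat[:, np.searchsorted(ib, common + lag_steps)]
    values = _pearson_rows(asel, bsel, row_labels, col_labels)
    return CouplingMatrix(
        pair_id=(_system(a_list[0]), _system(b_list[0])),
        row_labels=row_labels, col_labels=col_labels,
        values=values, lag=lag, segment=segment,
    )


def best_lag(a, b, lag_candidates) -> tuple[float, float]:
    """Scan lag candidates and return ``(lag, r)`` maximising the correlation.

    Ties (within 1e-12) are broken toward the smallest \\|lag\\|, then the
    negative lag before the positive one.
    """
    results = []
    for lag in lag_candidates:
        r = float(coupling_matrix(a, b, lag=lag).values[0, 0])
        results.append((lag, r))
    best_r = max(r for _, r in results)
    contenders = [(lag, r) for lag, r in results if r >= best_r - 1e-12]
    lag, r = min(contenders, key=lambda lr: (abs(lr[0]), 0 if lr[0] < 0 else 1))
    return lag, r


def group_average(matrices: list[CouplingMatrix]) -> CouplingMatrix:
    """Element-wise mean of per-participant matrices (NaN cells mean-ignored).

    All inputs must share pair_id, labels and lag; the participant count
    per cell is recorded in ``cell_counts``.
    """
    if not matrices:
        raise ValueError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.shape != first.shape or m.row_labels != first.row_labels \
                or m.col_labels != first.col_labels:
            raise ValueError("matrix shape/label mismatch in group averaging")
        if m.pair_id != first.pair_id or m.lag != first.lag:
            raise ValueError("pair_id/lag mismatch in group averaging")
    stack = np.stack([m.values for m in matrices])
    counts = np.isfinite(stack).sum(axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return CouplingMatrix(
        pair_id=first.pair_id, row_labels=list(first.row_labels),
        col_labels=list(first.col_labels), values=mean, lag=first.lag,
        segment=first.segment, n_participants=len(matrices), cell_counts=counts,
    )


# ---------------------------------------------------------------------------
# network maps
# ---------------------------------------------------------------------------

@dataclass
class Link:
    source: tuple[str, str]
    target: tuple[str, str]
    strength: float
    class_label: str
    significant: bool = True


@dataclass
class NetworkMap:
    """Multiplex node-link structure over (system, band) nodes."""

    nodes: list[tuple[str, str]]
    links: list[Link]
    class_thresholds: tuple[float, ...]
    class_labels: tuple[str, ...] = LINK_CLASS_LABELS

    @property
    def n_links(self) -> int:
        return len(self.links)

    def significant_links(self) -> list[Link]:
        return [l for l in self.links if l.significant]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for system, band in self.nodes:
            g.add_node(f"{system}:{band}", system=system, band=band)
        for l in self.links:
            g.add_edge(
                f"{l.source[0]}:{l.source[1]}", f"{l.target[0]}:{l.target[1]}",
                strength=float(l.strength), class_label=l.class_label,
                significant=bool(l.significant),
            )
        return g


def classify_strength(
    r: float,
    thresholds: tuple[float, ...],
    labels: tuple[str, ...] = LINK_CLASS_LABELS,
) -> str:
    """Assign a link-strength class; below the lowest breakpoint -> 'below-threshold'."""
    if len(labels) != len(thresholds):
        raise ValueError("need one label per breakpoint")
    if not np.isfinite(r) or r <= thresholds[0]:
        return "below-threshold"
    cls = labels[0]
    for th, lab in zip(thresholds, labels):
        if r > th:
            cls = lab
    return cls


def build_network(
    matrices: list[CouplingMatrix],
    thresholds: str | tuple[float, ...] = "methods",
    labels: tuple[str, ...] = LINK_CLASS_LABELS,
) -> NetworkMap:
    """Map coupling matrices into one multiplex network (one sub-network per pair).

    ``thresholds`` is either an ordered tuple of strictly increasing
    breakpoints or the name of a shipped preset.
    """
    if isinstance(thresholds, str):
        thresholds = LINK_CLASS_PRESETS[thresholds]
    thresholds = tuple(float(t) for t in thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("class breakpoints must be strictly increasing")

    nodes: list[tuple[str, str]] = []
    seen = set()
    links: list[Link] = []
    for mat in matrices:
        sys_a, sys_b = mat.pair_id
        for side, labels_side in ((sys_a, mat.row_labels), (sys_b, mat.col_labels)):
            for band in labels_side:
                node = (side, band)
                if node not in seen:
                    seen.add(node)
                    nodes.append(node)
        for i, row in enumerate(mat.row_labels):
            for j, col in enumerate(mat.col_labels):
                r = float(mat.values[i, j])
                links.append(Link(
                    source=(sys_a, row), target=(sys_b, col), strength=r,
                    class_label=classify_strength(r, thresholds, labels),
                ))
    return NetworkMap(nodes=nodes, links=links, class_thresholds=thresholds,
                      class_labels=labels)


def mean_link_strength(matrix: CouplingMatrix) -> float:
    """Average link strength over all cells of one sub-network matrix."""
    return float(np.nanmean(matrix.values))
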