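"""Discrete-time survival head: time grid, probabilities, curves, losses.

The model outputs a single probability vector per subject over (event,
time-bin) cells via one softmax.  With a single event type (death, K = 1)
and five percentile-derived cut points, the vector has 6 cells: one per
in-horizon bin plus a beyond-horizon cell.  The cumulative incidence
function (CIF) is the running sum of in-horizon cells, and the survival
function is its complement, S(t) = 1 − CIF(t).

The beyond-horizon cell is an explicit design choice: a pure softmax over
the five in-horizon bins would force S at the last cut point to zero, which
cannot represent late-censored subjects.

Training uses the two-part DeepHit-style objective: a discrete likelihood
term handling right censoring plus a pairwise ranking penalty on CIF values.
The loss functions accept either plain numpy arrays or autodiff
:class:`~gliosurv.autodiff.Tensor` batches, so the same code path is used for
evaluation and for gradient-based training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor

__all__ = [
    "TimeGrid",
    "DiscreteSurvivalOutput",
    "SurvivalCurve",
    "build_time_grid",
    "discretize_time",
    "softmax_probabilities",
    "cif",
    "survival_function",
    "interpolate_monthly",
    "likelihood_loss",
    "ranking_loss",
    "total_loss",
    "DAYS_PER_MONTH",
    "PERCENTILES",
]

DAYS_PER_MONTH = 30.44
PERCENTILES = (10.0, 30.0, 50.0, 70.0, 90.0)


@dataclass(frozen=True)
class TimeGrid:
    """Five increasing cut points (days) defining right-closed bins
    (cut_{m-1}, cut_m], with cut_0 = 0, plus an implicit beyond-horizon bin."""

    cut_points: tuple[float, ...]
    month_days: float = DAYS_PER_MONTH

    def __post_init__(self):
        cp = tuple(float(c) for c in self.cut_points)
        if len(cp) < 1 or any(c <= 0 for c in cp) or any(
            b <= a for a, b in zip(cp, cp[1:])
        ):
            raise ValueError("cut points must be positive and strictly increasing")
        object.__setattr__(self, "cut_points", cp)

    @property
    def n_bins(self) -> int:
        return len(self.cut_points)

    @property
    def t_max(self) -> float:
        return self.cut_points[-1]

    @property
    def n_cells(self) -> int:
        """Output cells = in-horizon bins + beyond-horizon cell (K = 1)."""
        return self.n_bins + 1

    def months(self) -> np.ndarray:
        """Integer months covered by the grid horizon."""
        return np.arange(1, int(np.floor(self.t_max / self.month_days)) + 1)


@dataclass
class DiscreteSurvivalOutput:
    """Per-subject softmax probabilities over the (event, bin) cells.

    ``y`` has shape (n_subjects, n_bins + 1); the last column is the
    beyond-horizon cell.  Rows sum to 1.
    """

    y: np.ndarray
    grid: TimeGrid

    def __post_init__(self):
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.y.shape[1] != self.grid.n_cells:
            raise ValueError(
                f"expected {self.grid.n_cells} cells, got {self.y.shape[1]}"
            )
        if np.any(self.y < -1e-9):
            raise ValueError("probabilities must be nonnegative")
        if np.max(np.abs(self.y.sum(axis=1) - 1.0)) > 1e-6:
            raise ValueError("rows must sum to 1 within 1e-6")

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]


@dataclass
class SurvivalCurve:
    """Survival probabilities at the grid cut points and at integer months."""

    grid_survival: np.ndarray  # (n, n_bins)
    monthly: np.ndarray  # (n, n_months)
    grid: TimeGrid = field(repr=False, default=None)


def build_time_grid(training_times, month_days: float = DAYS_PER_MONTH) -> TimeGrid:
    """Cut points at the {10, 30, 50, 70, 90}th percentiles of the observed
    training times (events and censored pooled), linear-interpolation
    quantiles."""
    t = np.asarray(training_times, dtype=float)
    if t.size < 10:
        raise ValueError("need at least 10 training subjects to build the grid")
    if np.any(t < 0):
        raise ValueError("negative survival times")
    cuts = np.quantile(t, np.asarray(PERCENTILES) / 100.0, method="linear")
    distinct = np.unique(cuts)
    if distinct.size < 3:
        raise ValueError("degenerate training times: fewer than 3 distinct cut points")
    return TimeGrid(tuple(distinct) if distinct.size < cuts.size else tuple(cuts),
                    month_days=month_days)


def discretize_time(t, grid: TimeGrid) -> np.ndarray:
    """Map continuous times (days) to bin indices 0..n_bins-1, or ``n_bins``
    for the beyond-horizon bin.  Bins are right-closed: bin m covers
    (cut_{m-1}, cut_m]; t = 0 falls in the first bin."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative time")
    edges = np.asarray(grid.cut_points)
    # first bin whose cut point is >= t; t beyond the last cut -> n_bins
    idx = np.searchsorted(edges, t, side="left")
    return idx if idx.shape else int(idx)


def softmax_probabilities(logits, grid: TimeGrid) -> DiscreteSurvivalOutput:
    """Max-subtracted softmax over the output cells."""
    z = np.atleast_2d(np.asarray(logits, dtype=float))
    if not np.all(np.isfinite(z)):
        raise ValueError("logits must be finite")
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return DiscreteSurvivalOutput(e / e.sum(axis=1, keepdims=True), grid)


def cif(out: DiscreteSurvivalOutput, bin_index=None) -> np.ndarray:
    """Cumulative incidence F̂(m) = Σ_{m' ≤ m} y_{1,m'} over in-horizon bins.

    Without ``bin_index`` returns the full (n, n_bins) matrix; with it,
    the per-subject CIF at that bin (scalar index or one per subject).
    """
    F = np.cumsum(out.y[:, : out.grid.n_bins], axis=1)
    if bin_index is None:
        return F
    b = np.asarray(bin_index)
    if b.ndim == 0:
        return F[:, int(b)]
    return F[np.arange(F.shape[0]), b]


def survival_function(out: DiscreteSurvivalOutput) -> SurvivalCurve:
    """S at each cut point, S(cut_m) = 1 − F̂(m), plus monthly interpolation."""
    S = 1.0 - cif(out)
    S = np.clip(S, 0.0, 1.0)
    monthly = interpolate_monthly(S, out.grid)
    return SurvivalCurve(grid_survival=S, monthly=monthly, grid=out.grid)


def interpolate_monthly(grid_survival: np.ndarray, grid: TimeGrid) -> np.ndarray:
    """Linear interpolation of S between (0, 1.0) and the cut-point values,
    sampled at integer months (month = ``grid.month_days`` days)."""
    S = np.atleast_2d(np.asarray(grid_survival, dtype=float))
    xs = np.concatenate([[0.0], grid.cut_points])
    months = grid.months() * grid.month_days
    out = np.empty((S.shape[0], months.size))
    for i in range(S.shape[0]):
        ys = np.concatenate([[1.0], S[i]])
        out[i] = np.interp(months, xs, ys)
    return out


# --------------------------------------------------------------------- losses

_CLAMP = 1e-12


def _cif_tensor(y: Tensor, n_bins: int) -> Tensor:
    """CIF matrix from a probability Tensor via lower-triangular matmul."""
    L = np.tril(np.ones((n_bins, n_bins)))
    return y[:, :n_bins] @ Tensor(L.T)


def likelihood_loss(y, bins, events, grid: TimeGrid):
    """Discrete negative log-likelihood with right censoring.

    Event subjects contribute −log y at their event bin (the beyond cell if
    the event falls past the horizon); censored subjects contribute
    −log S(bin) = −log Σ_{m > bin} y (beyond-horizon censorings reduce to
    −log y_beyond).  Probabilities are clamped at 1e−12 inside the logs.
    """
    bins = np.asarray(bins, dtype=int)
    events = np.asarray(events, dtype=int)
    n_bins = grid.n_bins
    is_tensor = isinstance(y, Tensor)
    yt = y if is_tensor else Tensor(np.atleast_2d(np.asarray(y, dtype=float)))
    n = yt.shape[0]
    idx = np.arange(n)

    # event term: y at the subject's cell (bin index == n_bins -> beyond cell)
    cell = np.minimum(bins, n_bins)
    y_at = yt[idx, cell]
    # censoring term: S(bin) = sum of cells strictly after the bin, incl. the
    # beyond cell; censored past the horizon reduces to y_beyond alone
    thr = np.minimum(bins + 1, n_bins)
    tail_mask = (np.arange(n_bins + 1)[None, :] >= thr[:, None]).astype(float)
    surv_at = (yt * Tensor(tail_mask)).sum(axis=1)

    ev = events.astype(float)
    term = (
        Tensor(ev) * y_at.clamp_min(_CLAMP).log()
        + Tensor(1.0 - ev) * surv_at.clamp_min(_CLAMP).log()
    )
    loss = -term.mean()
    return loss if is_tensor else float(loss.item())


def ranking_loss(y, bins, events, grid: TimeGrid, sigma: float = 0.1):
    """Pairwise ranking penalty over acceptable pairs.

    A pair (i, j) is acceptable when subject i has an observed event and
    bin_i < bin_j.  Each pair contributes η(F̂_i(bin_i) − F̂_j(bin_i)) with
    η(d) = exp(−d/σ); the loss is the mean over acceptable pairs, 0 when
    there are none.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    bins = np.asarray(bins, dtype=int)
    events = np.asarray(events, dtype=int)
    n_bins = grid.n_bins
    is_tensor = isinstance(y, Tensor)
    yt = y if is_tensor else Tensor(np.atleast_2d(np.asarray(y, dtype=float)))

    ii, jj = np.meshgrid(np.arange(len(bins)), np.arange(len(bins)), indexing="ij")
    acceptable = (events[ii] == 1) & (bins[ii] < bins[jj])
    i_idx, j_idx = ii[acceptable], jj[acceptable]
    if i_idx.size == 0:
        return Tensor(0.0) if is_tensor else 0.0
    F = _cif_tensor(yt, n_bins)
    b = np.minimum(bins[i_idx], n_bins - 1)  # event bins are < n_bins for acceptable i
    d = F[i_idx, b] - F[j_idx, b]
    loss = (d * (-1.0 / sigma)).exp().mean()
    return loss if is_tensor else float(loss.item())


def total_loss(l1, l2, lambda_rank: float = 0.5):
    """Two-part objective: likelihood + λ · ranking."""
    if lambda_rank < 0:
        raise ValueError("lambda_rank must be nonnegative")
    return l1 + lambda_rank * l2
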