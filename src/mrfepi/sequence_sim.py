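"""MRF-EPI fingerprint simulation and dictionary construction.

The acquisition plays a train of spoiled gradient-echo readouts with a
variable flip angle, echo time and repetition time per time point; each
tissue (T1, T2*, B1+ efficiency) traces a characteristic 35-point signal
evolution ("fingerprint").  Under ideal spoiling the evolution is the
standard recursion

    s_i      = Mz_i * sin(b1 * fa_i) * exp(-TE_i / T2*)
    Mz_{i+1} = M0 + (Mz_i * cos(b1 * fa_i) - M0) * exp(-TR_i / T1)

starting from thermal equilibrium Mz_0 = M0.  Dictionaries enumerate a
geometric T1/T2* grid (constant fractional spacing, 2% by default) times
a linear B1+ grid, drop non-physical entries with T1 < T2*, and store
unit-norm magnitude fingerprints for inner-product matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionSchedule",
    "TissueParams",
    "GridSpec",
    "Fingerprint",
    "Dictionary",
    "DictionarySplit",
    "make_schedule",
    "schedule_from_file",
    "simulate_fingerprint",
    "simulate_fingerprints",
    "make_geometric_grid",
    "make_linear_grid",
    "generate_dictionary",
    "split_by_range",
    "split_by_increment",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionSchedule:
    """Per-time-point pulse parameters of one MRF-EPI slice."""

    flip_angle_deg: np.ndarray
    te_ms: np.ndarray
    tr_ms: np.ndarray

    def __post_init__(self):
        for name in ("flip_angle_deg", "te_ms", "tr_ms"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        fa, te, tr = self.flip_angle_deg, self.te_ms, self.tr_ms
        if not (fa.shape == te.shape == tr.shape) or fa.ndim != 1 or fa.size < 1:
            raise ValueError("schedule sequences must be 1D and of equal length >= 1")
        if np.any(fa <= 0) or np.any(fa > 180):
            raise ValueError("flip angles must lie in (0, 180] degrees")
        if np.any(te <= 0):
            raise ValueError("echo times must be positive")
        if np.any(tr <= te):
            raise ValueError("every TR must exceed its TE")

    @property
    def n_timepoints(self) -> int:
        return self.flip_angle_deg.size


@dataclass(frozen=True)
class TissueParams:
    t1_ms: float
    t2s_ms: float
    b1_eff: float = 1.0

    def __post_init__(self):
        if not (self.t1_ms > 0 and self.t2s_ms > 0):
            raise ValueError("relaxation times must be positive")
        if not np.isfinite([self.t1_ms, self.t2s_ms, self.b1_eff]).all():
            raise ValueError("tissue parameters must be finite")
        if self.b1_eff < 0:
            raise ValueError("B1+ efficiency must be non-negative")


@dataclass(frozen=True)
class GridSpec:
    """Dictionary parameter grid: geometric T1/T2* axes, linear B1+ axis."""

    t1_min_ms: float = 100.0
    t1_max_ms: float = 4000.0
    t2s_min_ms: float = 10.0
    t2s_max_ms: float = 3000.0
    increment_frac: float = 0.02
    b1_min: float = 0.6
    b1_max: float = 1.4
    b1_step: float = 0.05
    exclude_t1_lt_t2s: bool = True

    def __post_init__(self):
        if not (0 < self.t1_min_ms <= self.t1_max_ms and 0 < self.t2s_min_ms <= self.t2s_max_ms):
            raise ValueError("grid bounds must satisfy 0 < min <= max")
        if not 0 < self.increment_frac < 1:
            raise ValueError("increment_frac must be in (0, 1)")
        if self.b1_step <= 0 or self.b1_min <= 0 or self.b1_max < self.b1_min:
            raise ValueError("invalid B1+ grid")

    def t1_grid(self) -> np.ndarray:
        return make_geometric_grid(self.t1_min_ms, self.t1_max_ms, self.increment_frac)

    def t2s_grid(self) -> np.ndarray:
        return make_geometric_grid(self.t2s_min_ms, self.t2s_max_ms, self.increment_frac)

    def b1_grid(self) -> np.ndarray:
        return make_linear_grid(self.b1_min, self.b1_max, self.b1_step)


@dataclass(frozen=True)
class Fingerprint:
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=np.float64))
        if not np.isfinite(self.values).all():
            raise ValueError("fingerprint values must be finite")
        if self.normalized and abs(np.linalg.norm(self.values) - 1.0) > 1e-9:
            raise ValueError("fingerprint flagged normalized but L2 norm is not 1")

    def normalize(self) -> "Fingerprint":
        norm = np.linalg.norm(self.values)
        if norm == 0:
            raise ValueError("cannot normalize a zero fingerprint")
        return Fingerprint(self.values / norm, normalized=True)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class Dictionary:
    """Simulated fingerprint dictionary.

    ``params`` holds (t1_ms, t2s_ms, b1) per row; ``signals`` the matching
    unit-norm fingerprints.  ``t1_index``/``t2s_index``/``b1_index`` are the
    positions of each entry on its grid axis, kept for increment splitting.
    """

    params: np.ndarray            # (N, 3)
    signals: np.ndarray           # (N, n_timepoints), unit L2 rows
    schedule: AcquisitionSchedule
    grid: GridSpec
    t1_index: np.ndarray = field(default=None, repr=False)
    t2s_index: np.ndarray = field(default=None, repr=False)
    b1_index: np.ndarray = field(default=None, repr=False)

    def __len__(self) -> int:
        return self.params.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.signals.shape[1]

    def entry(self, index: int) -> TissueParams:
        t1, t2s, b1 = self.params[index]
        return TissueParams(t1_ms=float(t1), t2s_ms=float(t2s), b1_eff=float(b1))


@dataclass(frozen=True)
class DictionarySplit:
    train_indices: np.ndarray
    valid_indices: np.ndarray

    def __post_init__(self):
        tr = np.asarray(self.train_indices, dtype=np.int64)
        va = np.asarray(self.valid_indices, dtype=np.int64)
        object.__setattr__(self, "train_indices", tr)
        object.__setattr__(self, "valid_indices", va)
        if np.intersect1d(tr, va).size:
            raise ValueError("train and validation indices overlap")


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

_DEFAULT_FA = (34.0, 86.0)
_DEFAULT_TE = (21.0, 81.5)
_DEFAULT_TR = (3530.0, 6570.0)


def make_schedule(
    n_timepoints: int = 35,
    fa_range_deg: tuple[float, float] = _DEFAULT_FA,
    te_range_ms: tuple[float, float] = _DEFAULT_TE,
    tr_range_ms: tuple[float, float] = _DEFAULT_TR,
    pattern: str = "linear_up",
) -> AcquisitionSchedule:
    """Build a schedule spanning the given ranges.

    ``linear_up`` interpolates each parameter from its low to high bound
    across the time points; ``linear_down`` runs high to low.  Site-specific
    schedules are loaded with :func:`schedule_from_file` (pattern
    ``custom`` points there).
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")
    if pattern == "custom":
        raise ValueError("pattern 'custom' requires schedule_from_file(path)")
    if pattern not in ("linear_up", "linear_down"):
        raise ValueError(f"unknown pattern {pattern!r}")

    def ramp(lo: float, hi: float) -> np.ndarray:
        vals = np.linspace(lo, hi, n_timepoints)
        return vals[::-1].copy() if pattern == "linear_down" else vals

    return AcquisitionSchedule(
        flip_angle_deg=ramp(*fa_range_deg),
        te_ms=ramp(*te_range_ms),
        tr_ms=ramp(*tr_range_ms),
    )


def schedule_from_file(path) -> AcquisitionSchedule:
    """Read a whitespace/comma-delimited 3-column file: FA(deg), TE(ms), TR(ms)."""
    table = np.loadtxt(path, delimiter=None, comments="#", dtype=np.float64, ndmin=2)
    if table.ndim != 2 or table.shape[1] != 3:
        raise ValueError("schedule file must have 3 columns: flip_angle_deg, te_ms, tr_ms")
    return AcquisitionSchedule(table[:, 0], table[:, 1], table[:, 2])


# ---------------------------------------------------------------------------
# Bloch simulation
# ---------------------------------------------------------------------------

def simulate_fingerprints(
    schedule: AcquisitionSchedule,
    t1_ms: np.ndarray,
    t2s_ms: np.ndarray,
    b1_eff: np.ndarray,
    m0: float = 1.0,
    n_prep_cycles: int = 0,
) -> np.ndarray:
    """Vectorized spoiled-GRE Bloch recursion over arrays of tissue parameters.

    Returns magnitude signals of shape ``(len(t1_ms), n_timepoints)``, not
    normalized.  ``n_prep_cycles`` > 0 replays the schedule that many times
    before recording, driving the magnetization toward its steady state.
    """
    t1 = np.atleast_1d(np.asarray(t1_ms, dtype=np.float64))
    t2s = np.atleast_1d(np.asarray(t2s_ms, dtype=np.float64))
    b1 = np.atleast_1d(np.asarray(b1_eff, dtype=np.float64))
    if not (t1.shape == t2s.shape == b1.shape):
        raise ValueError("parameter arrays must share a shape")
    if np.any(t1 <= 0) or np.any(t2s <= 0):
        raise ValueError("relaxation times must be positive")
    if not (np.isfinite(t1).all() and np.isfinite(t2s).all() and np.isfinite(b1).all()):
        raise ValueError("tissue parameters must be finite")

    fa_rad = np.deg2rad(schedule.flip_angle_deg)
    te, tr = schedule.te_ms, schedule.tr_ms
    n = schedule.n_timepoints

    alpha = np.outer(b1, fa_rad)                     # (V, n)
    sin_a, cos_a = np.sin(alpha), np.cos(alpha)
    e_te = np.exp(-te[None, :] / t2s[:, None])       # (V, n)
    e_tr = np.exp(-tr[None, :] / t1[:, None])        # (V, n)

    signals = np.empty((t1.size, n), dtype=np.float64)
    mz = np.full(t1.size, float(m0))
    for cycle in range(n_prep_cycles + 1):
        record = cycle == n_prep_cycles
        for i in range(n):
            if record:
                signals[:, i] = mz * sin_a[:, i] * e_te[:, i]
            mz = m0 + (mz * cos_a[:, i] - m0) * e_tr[:, i]
    return np.abs(signals)


def simulate_fingerprint(
    schedule: AcquisitionSchedule,
    params: TissueParams,
    m0: float = 1.0,
    n_prep_cycles: int = 0,
) -> Fingerprint:
    """Simulate one magnitude fingerprint (not normalized)."""
    if not (np.isfinite(m0) and m0 > 0):
        raise ValueError("m0 must be positive and finite")
    values = simulate_fingerprints(
        schedule,
        np.array([params.t1_ms]),
        np.array([params.t2s_ms]),
        np.array([params.b1_eff]),
        m0=m0,
        n_prep_cycles=n_prep_cycles,
    )[0]
    return Fingerprint(values, normalized=False)


# ---------------------------------------------------------------------------
# grids and dictionaries
# ---------------------------------------------------------------------------

def make_geometric_grid(lo: float, hi: float, increment_frac: float) -> np.ndarray:
    """Values lo*(1+f)^k for k = 0, 1, ... while the value stays <= hi."""
    if not (0 < lo <= hi):
        raise ValueError("need 0 < lo <= hi")
    if increment_frac <= 0:
        raise ValueError("increment_frac must be positive")
    ratio = 1.0 + increment_frac
    # count via logs, then guard the boundary against rounding either way
    n = int(np.floor(np.log(hi / lo) / np.log(ratio))) + 1
    grid = lo * ratio ** np.arange(n + 1)
    grid = grid[grid <= hi * (1 + 1e-12)]
    return grid


def make_linear_grid(lo: float, hi: float, step: float) -> np.ndarray:
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def generate_dictionary(schedule: AcquisitionSchedule, grid: GridSpec) -> Dictionary:
    """Enumerate the grid, simulate and L2-normalize every fingerprint."""
    t1_axis, t2s_axis, b1_axis = grid.t1_grid(), grid.t2s_grid(), grid.b1_grid()
    i1, i2, i3 = np.meshgrid(
        np.arange(t1_axis.size), np.arange(t2s_axis.size), np.arange(b1_axis.size),
        indexing="ij",
    )
    i1, i2, i3 = i1.ravel(), i2.ravel(), i3.ravel()
    t1, t2s, b1 = t1_axis[i1], t2s_axis[i2], b1_axis[i3]

    if grid.exclude_t1_lt_t2s:
        keep = t1 >= t2s
        i1, i2, i3 = i1[keep], i2[keep], i3[keep]
        t1, t2s, b1 = t1[keep], t2s[keep], b1[keep]
    if t1.size == 0:
        raise ValueError("grid specification produced zero dictionary entries")

    signals = simulate_fingerprints(schedule, t1, t2s, b1)
    norms = np.linalg.norm(signals, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("grid produced an identically zero fingerprint")
    signals /= norms

    return Dictionary(
        params=np.column_stack([t1, t2s, b1]),
        signals=signals,
        schedule=schedule,
        grid=grid,
        t1_index=i1,
        t2s_index=i2,
        b1_index=i3,
    )


# ---------------------------------------------------------------------------
# training/validation splits
# ---------------------------------------------------------------------------

def split_by_range(
    dictionary: Dictionary,
    t1_train: tuple[float, float] = (500.0, 2500.0),
    t2s_train: tuple[float, float] = (50.0, 1500.0),
) -> DictionarySplit:
    """Train on entries inside the closed T1 x T2* box; validate on the rest.

    This split probes extrapolation: the validation entries lie outside the
    relaxation-time ranges the model ever sees in training.
    """
    t1, t2s = dictionary.params[:, 0], dictionary.params[:, 1]
    in_box = (
        (t1 >= t1_train[0]) & (t1 <= t1_train[1])
        & (t2s >= t2s_train[0]) & (t2s <= t2s_train[1])
    )
    train = np.flatnonzero(in_box)
    valid = np.flatnonzero(~in_box)
    if train.size == 0:
        raise ValueError("range split produced an empty training set")
    if valid.size == 0:
        warnings.warn("range split covers the whole dictionary; validation set is empty")
    return DictionarySplit(train, valid)


def split_by_increment(dictionary: Dictionary, interval: int) -> DictionarySplit:
    """Train on every ``interval``-th grid value along both relaxation axes.

    Keeping T1 and T2* grid indices that are multiples of ``interval``
    yields a coarser geometric grid with effective fractional increment
    (1+f)^interval - 1 (e.g. 2% sampled at interval 2 gives ~4.04%).  All
    remaining entries form the validation set; B1+ is not subsampled.
    """
    if interval < 1:
        raise ValueError("interval must be >= 1")
    if dictionary.t1_index is None or dictionary.t2s_index is None:
        raise ValueError("dictionary lacks grid indices; regenerate with generate_dictionary")
    n1 = int(dictionary.t1_index.max()) + 1
    n2 = int(dictionary.t2s_index.max()) + 1
    if interval > max(n1, n2):
        raise ValueError(f"interval {interval} exceeds grid length {max(n1, n2)}")
    on_subgrid = (dictionary.t1_index % interval == 0) & (dictionary.t2s_index % interval == 0)
    return DictionarySplit(np.flatnonzero(on_subgrid), np.flatnonzero(~on_subgrid))
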