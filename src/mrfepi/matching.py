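"""Inner-product dictionary matching and the empirical noise machinery.

Matching is the reference reconstruction: each voxel's fingerprint is
L2-normalized and compared with every unit-norm dictionary fingerprint by
dot product (cosine similarity); the best-scoring entry's (T1, T2*, B1+)
becomes the voxel estimate.  The residual between the scanned and the
matched signal measures the per-voxel SNR (in dB) and, pooled over
voxels, forms the noise bank used to corrupt training signals for the
stage-I denoiser.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_sim import Dictionary, Fingerprint, TissueParams

__all__ = [
    "BaselineStack",
    "MatchResult",
    "NoiseBank",
    "match_signal",
    "match_stack",
    "compute_snr",
    "extract_noise_bank",
    "sample_noise",
]

_CHUNK_ROWS = 20000  # dictionary rows per scoring block (bounds the scratch matmul)


@dataclass
class BaselineStack:
    """One slice of the MRF baseline scan: (X, Y, n_timepoints) plus mask."""

    data: np.ndarray
    brain_mask: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.brain_mask = np.asarray(self.brain_mask).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("stack data must be (X, Y, n_timepoints)")
        if self.brain_mask.shape != self.data.shape[:2]:
            raise ValueError("mask shape must match the stack's spatial dims")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]


@dataclass
class MatchResult:
    t1_map: np.ndarray
    t2s_map: np.ndarray
    b1_map: np.ndarray
    score_map: np.ndarray
    index_map: np.ndarray          # -1 outside mask / unmatched
    n_unmatched: int = 0


@dataclass
class NoiseBank:
    """Signed residual vectors (scan - matched entry) in normalized-signal units."""

    residuals: np.ndarray                       # (M, n_timepoints)
    source_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.residuals = np.atleast_2d(np.asarray(self.residuals, dtype=np.float64))
        if not np.isfinite(self.residuals).all():
            raise ValueError("residuals must be finite")

    @property
    def pooled_values(self) -> np.ndarray:
        """All M*n scalar amplitudes with their temporal order discarded."""
        return self.residuals.ravel()

    def __len__(self) -> int:
        return self.residuals.shape[0]


def _as_signal(query) -> np.ndarray:
    if isinstance(query, Fingerprint):
        return query.values
    return np.asarray(query, dtype=np.float64)


def match_signal(query, dictionary: Dictionary) -> tuple[TissueParams, float, int]:
    """Return the dictionary entry with maximal inner product to the query.

    The query is L2-normalized first, so matching is scale-invariant.
    Ties break toward the lowest row index.
    """
    q = _as_signal(query)
    if q.size != dictionary.n_timepoints:
        raise ValueError("query length does not match the dictionary")
    norm = np.linalg.norm(q)
    if norm == 0:
        raise ValueError("zero-norm query cannot be matched")
    scores = dictionary.signals @ (q / norm)
    index = int(np.argmax(scores))
    return dictionary.entry(index), float(scores[index]), index


def match_stack(stack: BaselineStack, dictionary: Dictionary) -> MatchResult:
    """Voxel-wise inner-product matching inside the brain mask.

    Unmatched voxels (zero-norm signals) and everything outside the mask
    are written as 0 in the parameter maps and -1 in the index map.
    """
    if stack.n_timepoints != dictionary.n_timepoints:
        raise ValueError("stack and dictionary disagree on n_timepoints")
    x, y, n = stack.data.shape
    shape = (x, y)
    t1_map = np.zeros(shape)
    t2s_map = np.zeros(shape)
    b1_map = np.zeros(shape)
    score_map = np.zeros(shape)
    index_map = np.full(shape, -1, dtype=np.int64)

    voxels = stack.data[stack.brain_mask]                    # (V, n)
    norms = np.linalg.norm(voxels, axis=1)
    matched = norms > 0
    n_unmatched = int((~matched).sum())
    if matched.any():
        queries = voxels[matched] / norms[matched, None]
        best_idx, best_score = _argmax_scores(queries, dictionary.signals)
        vi = np.flatnonzero(stack.brain_mask.ravel())[matched]
        rows, cols = np.unravel_index(vi, shape)
        t1_map[rows, cols] = dictionary.params[best_idx, 0]
        t2s_map[rows, cols] = dictionary.params[best_idx, 1]
        b1_map[rows, cols] = dictionary.params[best_idx, 2]
        score_map[rows, cols] = best_score
        index_map[rows, cols] = best_idx
    return MatchResult(t1_map, t2s_map, b1_map, score_map, index_map, n_unmatched)


def _argmax_scores(queries: np.ndarray, signals: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Chunked argmax of queries @ signals.T preserving lowest-index ties."""
    v = queries.shape[0]
    best_idx = np.zeros(v, dtype=np.int64)
    best_score = np.full(v, -np.inf)
    q32 = queries.astype(np.float64)
    for start in range(0, signals.shape[0], _CHUNK_ROWS):
        block = signals[start : start + _CHUNK_ROWS]
        scores = q32 @ block.T
        local = np.argmax(scores, axis=1)
        local_best = scores[np.arange(v), local]
        improved = local_best > best_score        # strict: earlier rows win ties
        best_idx[improved] = local[improved] + start
        best_score[improved] = local_best[improved]
    return best_idx, best_score


def compute_snr(s, n) -> float:
    """Eq.-style SNR in dB: 10*log10(sum s_i^2 / sum n_i^2).

    Returns +inf when the residual has zero energy.
    """
    s = _as_signal(s)
    n = _as_signal(n)
    if s.shape != n.shape:
        raise ValueError("signal and residual lengths differ")
    es = float(np.sum(s * s))
    if es == 0:
        raise ValueError("signal has zero energy; SNR undefined")
    en = float(np.sum(n * n))
    if en == 0:
        return np.inf
    return 10.0 * np.log10(es / en)


def extract_noise_bank(
    stack: BaselineStack, dictionary: Dictionary, source_meta: dict | None = None
) -> tuple[NoiseBank, np.ndarray]:
    """Match the stack, collect residuals and compute the per-voxel SNR map.

    Residual = normalized scan signal - matched (unit-norm) dictionary
    signal.  The SNR map holds dB values inside the mask (+inf where the
    residual vanishes) and 0 outside.
    """
    result = match_stack(stack, dictionary)
    x, y, _ = stack.data.shape
    snr_map = np.zeros((x, y))
    rows, cols = np.nonzero(stack.brain_mask & (result.index_map >= 0))
    if rows.size == 0:
        raise ValueError("no matchable voxels inside the mask")
    signals = stack.data[rows, cols]
    scans = signals / np.linalg.norm(signals, axis=1, keepdims=True)
    matched = dictionary.signals[result.index_map[rows, cols]]
    residuals = scans - matched
    energy_s = np.sum(matched * matched, axis=1)
    energy_n = np.sum(residuals * residuals, axis=1)
    with np.errstate(divide="ignore"):
        snr_map[rows, cols] = 10.0 * np.log10(energy_s / energy_n)
    bank = NoiseBank(residuals, source_meta=source_meta or {})
    return bank, snr_map


def sample_noise(
    bank: NoiseBank,
    n_timepoints: int,
    mode: str = "pooled_iid",
    rng: np.random.Generator | int | None = None,
    size: int | None = None,
) -> np.ndarray:
    """Draw residual vectors from the bank.

    ``pooled_iid`` draws each time point independently (with replacement)
    from the pooled scalar amplitudes; ``permuted_vector`` draws a stored
    residual row and shuffles its temporal order.  ``size=None`` returns a
    single (n_timepoints,) vector, otherwise (size, n_timepoints).
    """
    if len(bank) == 0 or bank.residuals.size == 0:
        raise ValueError("noise bank is empty")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    m = 1 if size is None else size
    if mode == "pooled_iid":
        out = rng.choice(bank.pooled_values, size=(m, n_timepoints), replace=True)
    elif mode == "permuted_vector":
        if bank.residuals.shape[1] != n_timepoints:
            raise ValueError("stored residual length differs from n_timepoints")
        picks = rng.integers(0, len(bank), size=m)
        out = bank.residuals[picks].copy()
        out = rng.permuted(out, axis=1)
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return out[0] if size is None else out
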