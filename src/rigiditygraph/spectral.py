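"""Eigen-analysis of rigidity graphs: mode similarity, windowed mean-graph
statistics, prominent modes, and mechanical hotspots.

Mode bookkeeping follows the convention of descending eigenvalues; the
"mean-modes" are eigenvectors of the window-averaged graph K̄, their
"content" in a window is the largest |dot product| with that window's
eigenvectors, and a mode is *prominent* when its strength sits above the
Tukey upper fence of the eigenvalue distribution and its averaged content is
in the configured top quantile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graphs import RigidityGraph

logger = logging.getLogger(__name__)

#: Default squared-eigenvector-weight threshold for hotspot residues.
NU_C2 = 0.1


@dataclass
class SpectralResult:
    """Full spectrum, eigenvalues descending, eigenvectors as columns.

    A deterministic sign convention is applied: the largest-magnitude
    component of each eigenvector is made positive (ties broken by the
    first such index).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def n(self) -> int:
        return len(self.eigenvalues)

    def mode(self, alpha: int) -> np.ndarray:
        """Eigenvector of mode ``alpha`` (0-based, descending eigenvalue)."""
        return self.eigenvectors[:, alpha]


def eigendecompose(graph: RigidityGraph | np.ndarray,
                   matrix_kind: str = "K") -> SpectralResult:
    """Eigendecompose a rigidity graph's L (=D−A) or K (=D+A) operator.

    A raw symmetric matrix may be passed instead of a graph, in which case
    ``matrix_kind`` is ignored.
    """
    if isinstance(graph, RigidityGraph):
        if matrix_kind == "K":
            M = graph.signless_laplacian
        elif matrix_kind == "L":
            M = graph.laplacian
        else:
            raise ValueError(f"matrix_kind must be 'L' or 'K', got {matrix_kind!r}")
    else:
        M = np.asarray(graph, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("non-finite matrix entries")
    if not np.allclose(M, M.T):
        raise ValueError("matrix must be symmetric")
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # sign convention: largest-|component| entry positive
    lead = np.argmax(np.abs(evecs), axis=0)
    signs = np.sign(evecs[lead, np.arange(evecs.shape[1])])
    signs[signs == 0] = 1.0
    return SpectralResult(evals, evecs * signs)


def mode_similarity(compared: SpectralResult, reference: SpectralResult,
                    alpha: int) -> tuple[float, int]:
    """Similarity r_α = max_β |ν_β · ν_α^ref| and the attaining mode β_max.

    The absolute dot product makes the measure invariant to eigenvector sign
    flips; ties are broken by the smaller β.
    """
    if compared.n != reference.n:
        raise ValueError("spectra have different dimensions")
    dots = np.abs(compared.eigenvectors.T @ reference.mode(alpha))
    beta = int(np.argmax(dots))
    return float(dots[beta]), beta


def mode_similarities(compared: SpectralResult,
                      reference: SpectralResult) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`mode_similarity` over all reference modes."""
    if compared.n != reference.n:
        raise ValueError("spectra have different dimensions")
    M = np.abs(compared.eigenvectors.T @ reference.eigenvectors)
    return M.max(axis=0), M.argmax(axis=0)


def mean_graph(windows: list[RigidityGraph] | list[np.ndarray]
               ) -> RigidityGraph | np.ndarray:
    """Entrywise arithmetic mean of per-window graphs.

    Accepts either :class:`RigidityGraph` objects (averaged on the adjacency;
    degree-derived operators commute with the average since D is linear in A)
    or raw symmetric matrices such as per-window K operators, in which case a
    plain matrix is returned.
    """
    if not windows:
        raise ValueError("need at least one window")
    is_graph = isinstance(windows[0], RigidityGraph)
    mats = [w.adjacency if isinstance(w, RigidityGraph) else np.asarray(w, float)
            for w in windows]
    shape = mats[0].shape
    if any(m.shape != shape for m in mats):
        raise ValueError("window graphs have mismatched shapes")
    A = np.mean(mats, axis=0)
    if is_graph:
        first = windows[0]
        return RigidityGraph(A, first.group, first.subset, window="mean")
    return A


@dataclass
class MeanModeStats:
    """Windowed statistics of a fluctuating rigidity graph.

    ``contents`` is the (n_windows, N) matrix of per-window mean-mode
    contents r_n^α′; ``mean_contents`` their window average ⟨r^α′⟩.
    """

    mean: RigidityGraph | np.ndarray
    spectrum: SpectralResult          # of K̄ (or L̄)
    contents: np.ndarray
    mean_contents: np.ndarray
    matrix_kind: str = "K"

    @property
    def n_windows(self) -> int:
        return self.contents.shape[0]

    @property
    def strengths(self) -> np.ndarray:
        """Mean-mode coupling strengths λ^α′."""
        return self.spectrum.eigenvalues


def mean_mode_content(windows: list[RigidityGraph] | list[np.ndarray],
                      matrix_kind: str = "K") -> MeanModeStats:
    """Mean graph, mean-modes, and their per-window contents.

    Degenerate mean-mode eigenvalues are logged: the similarity still takes
    the max over individual eigenvectors, but contents within a degenerate
    subspace are basis-dependent.
    """
    gbar = mean_graph(windows)
    spec = eigendecompose(gbar, matrix_kind)
    lam = spec.eigenvalues
    if len(lam) > 1:
        gaps = np.abs(np.diff(lam))
        scale = max(np.abs(lam).max(), 1.0)
        if np.any(gaps < 1e-10 * scale):
            logger.info("degenerate mean-mode eigenvalues detected")
    rows = []
    for w in windows:
        spec_n = eigendecompose(w, matrix_kind)
        r, _ = mode_similarities(spec_n, spec)
        rows.append(r)
    contents = np.array(rows)
    return MeanModeStats(gbar, spec, contents, contents.mean(axis=0),
                         matrix_kind)


@dataclass
class ProminentModeSet:
    """Prominent mean-modes and their hotspot residues (0-based indices)."""

    modes: list[int]
    hotspots: dict[int, list[int]] = field(default_factory=dict)
    strength_fence: float = np.nan
    content_threshold: float = np.nan
    nu_c2: float = NU_C2

    def __contains__(self, alpha: int) -> bool:
        return alpha in self.modes

    def all_hotspots(self) -> set[int]:
        return set().union(*self.hotspots.values()) if self.hotspots else set()


def prominent_mode_indices(strengths: np.ndarray, mean_contents: np.ndarray,
                           content_quantile: float = 0.75
                           ) -> tuple[list[int], float, float]:
    """Indices passing both the Tukey-fence strength criterion (strict >)
    and the content quantile criterion (≥ the empirical quantile).

    Quantiles use linear interpolation between order statistics.  Returns
    (indices, strength fence, content threshold).
    """
    strengths = np.asarray(strengths, dtype=float)
    mean_contents = np.asarray(mean_contents, dtype=float)
    if strengths.shape != mean_contents.shape:
        raise ValueError("strength/content lists differ in length")
    if len(strengths) < 4:
        raise ValueError("need at least 4 modes to form quartiles")
    q1, q3 = np.quantile(strengths, [0.25, 0.75])
    fence = q3 + 1.5 * (q3 - q1)
    c_thr = float(np.quantile(mean_contents, content_quantile))
    idx = np.nonzero((strengths > fence) & (mean_contents >= c_thr))[0]
    return [int(i) for i in idx], float(fence), c_thr


def hotspot_residues(mode: np.ndarray, nu_c2: float = NU_C2) -> list[int]:
    """Residues with squared eigenvector weight ν_I² ≥ ν_c²."""
    mode = np.asarray(mode, dtype=float)
    return [int(i) for i in np.nonzero(mode ** 2 >= nu_c2)[0]]


def select_prominent_modes(stats: MeanModeStats,
                           content_quantile: float = 0.75,
                           nu_c2: float = NU_C2) -> ProminentModeSet:
    """Prominent modes of a windowed graph series, with per-mode hotspots.

    The content quantile defaults to the top 25% (use 0.68 for side-chain
    graphs, whose contents fluctuate more).
    """
    idx, fence, c_thr = prominent_mode_indices(
        stats.strengths, stats.mean_contents, content_quantile)
    hotspots = {a: hotspot_residues(stats.spectrum.mode(a), nu_c2) for a in idx}
    return ProminentModeSet(idx, hotspots, fence, c_thr, nu_c2)


def mode_table(stats: MeanModeStats, prominent: ProminentModeSet) -> pd.DataFrame:
    """Per-mode summary (1-based mode index) ready for TSV export."""
    n = stats.spectrum.n
    return pd.DataFrame({
        "mode": np.arange(1, n + 1),
        "strength": stats.strengths,
        "mean_content": stats.mean_contents,
        "prominent": [a in prominent.modes for a in range(n)],
        "hotspots": [
            ";".join(str(r + 1) for r in prominent.hotspots.get(a, []))
            for a in range(n)
        ],
    })
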