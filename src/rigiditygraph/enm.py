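"""Elastic-network construction and fluctuation-matching of spring constants.

The model is a set of harmonic springs on CG sites.  Normal-mode analysis is
realised as an eigendecomposition of the 3N×3N Hessian; because equilibrium
fluctuations of a classical harmonic system are mass-independent, the site
covariance is C = k_B·T·H⁺ with the rigid-body null space excluded.  The
predicted variance of an inter-site distance uses the first-order projection
⟨δl_ij²⟩ = êᵀ(C_ii + C_jj − 2 C_ij)ê along the equilibrium separation ê.

Spring constants are learned by self-consistent iteration: each spring's k is
nudged by the inverse-variance residual between target and model,
k ← max(0, k + α·k_B·T·(1/⟨δl²⟩_target − 1/⟨δl²⟩_model)), which for an
isolated pair is exactly a (damped) Newton step on k = k_B·T/⟨δl²⟩.
Redundant springs are driven to k = 0 and can be removed by trimming,
followed by a refit on the retained set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import graphs
from .constants import kT
from .core import (NONSKELETON, SKELETON1, BsENM, CGModel, FluctuationTargets,
                   Spring)

__all__ = [
    "build_initial_model", "build_bsenm0", "enm_hessian", "enm_covariance",
    "enm_distance_fluctuations", "fluctuation_matching_round",
    "trim_and_refit", "learn_bsenm", "MatchingReport",
    "write_model", "read_model",
]


class NetworkRankError(ValueError):
    """The Hessian null space is larger than the rigid-body space."""


def _rigid_mode_count(coords: np.ndarray) -> int:
    """Dimension of the rigid-body space: 6, or 5 for collinear geometries."""
    n = coords.shape[0]
    center = coords.mean(axis=0)
    x = coords - center
    gens = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        gens.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        gens.append(np.cross(np.broadcast_to(e, (n, 3)), x).ravel())
    G = np.array(gens)
    s = np.linalg.svd(G, compute_uv=False)
    return int(np.sum(s > 1e-8 * max(s[0], 1.0)))


def build_initial_model(cg: CGModel, lc: float, k0: float = 1.0,
                        targets: FluctuationTargets | None = None,
                        temperature: float = 300.0,
                        classify: bool = True) -> BsENM:
    """Seed a spring network: one spring per pair with l0 < lc, all k = k0.

    When fluctuation ``targets`` are supplied, spring rest lengths (and the
    pair selection) come from the targets' window-averaged distances rather
    than the single equilibrium frame.
    """
    if lc <= 0:
        raise ValueError("cutoff must be positive")
    if targets is not None:
        sel = targets.l0 < lc
        pairs = targets.pairs[sel]
        l0 = targets.l0[sel]
    else:
        ii, jj = np.triu_indices(cg.n_sites, k=1)
        d = np.linalg.norm(cg.coords[ii] - cg.coords[jj], axis=1)
        sel = d < lc
        pairs = np.column_stack([ii, jj])[sel]
        l0 = d[sel]
    if len(pairs) == 0:
        raise ValueError(f"no site pairs within cutoff {lc} Å")
    springs = [Spring(int(i), int(j), float(d), float(k0))
               for (i, j), d in zip(pairs, l0)]
    model = BsENM(cg.sites, springs, cg.coords.copy(), temperature)
    if classify:
        graphs.classify_model(model)
    return model


def build_bsenm0(cg: CGModel, lc: float, temperature: float = 300.0) -> BsENM:
    """Topology-only reference network: every within-cutoff spring has k = 1."""
    return build_initial_model(cg, lc, k0=1.0, temperature=temperature)


def _pair_geometry(coords: np.ndarray, pairs: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Unit separation vectors ê and distances for site pairs."""
    d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-8):
        bad = pairs[r < 1e-8][0]
        raise ValueError(f"coincident sites {tuple(bad)} joined by a spring")
    return d / r[:, None], r


def _assemble_hessian(n: int, pairs: np.ndarray, e: np.ndarray,
                      k: np.ndarray) -> np.ndarray:
    B = k[:, None, None] * e[:, :, None] * e[:, None, :]
    H4 = np.zeros((n, n, 3, 3))
    i, j = pairs[:, 0], pairs[:, 1]
    np.add.at(H4, (i, i), B)
    np.add.at(H4, (j, j), B)
    np.add.at(H4, (i, j), -B)
    np.add.at(H4, (j, i), -B)
    return H4.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)


def enm_hessian(model: BsENM) -> np.ndarray:
    """3N×3N Hessian of the harmonic network at its equilibrium geometry.

    Each spring contributes −k·ê êᵀ off-diagonal and +k·ê êᵀ on the two
    diagonal blocks, with ê the unit vector along the equilibrium separation.
    """
    pairs = model.spring_pairs()
    k = model.stiffnesses()
    if len(pairs) == 0:
        return np.zeros((3 * model.n_sites, 3 * model.n_sites))
    e, _ = _pair_geometry(model.coords, pairs)
    return _assemble_hessian(model.n_sites, pairs, e, k)


def enm_covariance(model: BsENM) -> np.ndarray:
    """Thermal site covariance C = k_B·T·H⁺ (rigid-body modes excluded)."""
    H = enm_hessian(model)
    evals, evecs = np.linalg.eigh(H)
    top = evals[-1]
    if top <= 0:
        raise NetworkRankError("network has no stiffness (all k = 0?)")
    zero = evals < 1e-8 * top
    n_rigid = _rigid_mode_count(model.coords)
    n_zero = int(zero.sum())
    if n_zero != n_rigid:
        raise NetworkRankError(
            f"{n_zero} zero modes found, expected {n_rigid}; the spring "
            "network is disconnected or degenerate"
        )
    V = evecs[:, ~zero]
    lam = evals[~zero]
    return kT(model.temperature) * (V / lam) @ V.T


def enm_distance_fluctuations(model: BsENM,
                              pairs: np.ndarray | None = None,
                              covariance: np.ndarray | None = None) -> np.ndarray:
    """Predicted distance variance ⟨δl²⟩ (Å²) for site pairs.

    Defaults to the model's spring pairs.  A precomputed covariance may be
    passed to amortise the eigendecomposition.
    """
    if pairs is None:
        pairs = model.spring_pairs()
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    C = covariance if covariance is not None else enm_covariance(model)
    n = model.n_sites
    C4 = C.reshape(n, 3, n, 3).transpose(0, 2, 1, 3)
    i, j = pairs[:, 0], pairs[:, 1]
    d = model.coords[i] - model.coords[j]
    r = np.linalg.norm(d, axis=1)
    if np.any(r < 1e-8):
        raise ValueError("coincident sites in requested pair")
    e = d / r[:, None]
    M = C4[i, i] + C4[j, j] - 2.0 * C4[i, j]
    return np.einsum("pa,pab,pb->p", e, M, e)


@dataclass
class MatchingReport:
    """Outcome of one self-consistent fluctuation-matching round."""

    iterations: int
    converged: bool
    max_rel_mismatch: float
    k: np.ndarray
    predicted: np.ndarray
    target: np.ndarray
    n_zero: int
    alpha_final: float
    history: list[float] = field(default_factory=list)


def _align_targets(model: BsENM, targets: FluctuationTargets) -> np.ndarray:
    lookup = targets.as_dict()
    var = np.empty(len(model.springs))
    for n, s in enumerate(model.springs):
        if s.pair not in lookup:
            raise ValueError(f"no fluctuation target for spring pair {s.pair}")
        var[n] = lookup[s.pair][1]
    if np.any(var <= 0):
        raise ValueError("every spring needs a positive target variance")
    return var


class _FastPredictor:
    """Amortised per-iteration variance prediction for a fixed topology."""

    def __init__(self, model: BsENM):
        self.n = model.n_sites
        self.pairs = model.spring_pairs()
        self.e, _ = _pair_geometry(model.coords, self.pairs)
        self.kBT = kT(model.temperature)
        self.n_rigid = _rigid_mode_count(model.coords)

    def variances(self, k: np.ndarray) -> np.ndarray:
        H = _assemble_hessian(self.n, self.pairs, self.e, k)
        evals, evecs = np.linalg.eigh(H)
        top = evals[-1]
        if top <= 0:
            raise NetworkRankError("network has no stiffness")
        zero = evals < 1e-8 * top
        if int(zero.sum()) != self.n_rigid:
            raise NetworkRankError(
                f"{int(zero.sum())} zero modes, expected {self.n_rigid}: "
                "spring network disconnected or degenerate"
            )
        V = evecs[:, ~zero].reshape(self.n, 3, -1)
        lam = evals[~zero]
        # per-pair mode amplitudes g = ê·(V_i − V_j); ⟨δl²⟩ = kBT Σ g²/λ
        D = V[self.pairs[:, 0]] - V[self.pairs[:, 1]]
        g = np.einsum("pa,pam->pm", self.e, D)
        return self.kBT * (g ** 2 / lam).sum(axis=1)


def fluctuation_matching_round(model: BsENM, targets: FluctuationTargets,
                               alpha: float = 0.5, tol: float = 1e-6,
                               max_iter: int = 3000, n_guard: int = 10,
                               clamp_rel: float = 0.5,
                               clamp_abs: float = 1.0
                               ) -> tuple[BsENM, MatchingReport]:
    """Iterate the inverse-variance update until the distance variances match.

    Convergence: the maximum relative mismatch |⟨δl²⟩_model − target| / target
    over springs with k > 0 falls below ``tol``.  Two stabilisers tame the
    coupled-spring dynamics: each step is clamped to a trust region of
    max(clamp_rel·k, clamp_abs·α) per spring, and if the mismatch fails to
    improve on its best value for ``n_guard`` consecutive iterations the
    iterate is reset to the best state with α halved.  If α underflows the
    round returns unconverged at the best state seen.
    """
    v_target = _align_targets(model, targets)
    predictor = _FastPredictor(model)
    alpha0 = alpha
    k = model.stiffnesses().copy()
    kBT = kT(model.temperature)
    history: list[float] = []
    converged = False
    best_mismatch = np.inf
    best_k = k.copy()
    stall = 0
    it = 0
    v_model = predictor.variances(k)
    for it in range(1, max_iter + 1):
        active = k > 0
        if not np.any(active):
            raise NetworkRankError("all spring constants reached zero")
        mismatch = float(np.max(np.abs(v_model[active] - v_target[active])
                                / v_target[active]))
        history.append(mismatch)
        if mismatch < best_mismatch:
            best_mismatch = mismatch
            best_k = k.copy()
            stall = 0
        else:
            stall += 1
            if stall >= n_guard:
                alpha *= 0.5
                stall = 0
                if alpha < 1e-12:
                    break
                k = best_k.copy()
                v_model = predictor.variances(k)
                continue
        if mismatch <= tol:
            converged = True
            break
        step = alpha * kBT * (1.0 / v_target - 1.0 / v_model)
        limit = np.maximum(clamp_rel * k, clamp_abs * alpha / alpha0)
        k = np.maximum(0.0, k + np.clip(step, -limit, limit))
        v_model = predictor.variances(k)
    if not converged:
        k = best_k
        v_model = predictor.variances(k)
    final = model.with_stiffnesses(k)
    report = MatchingReport(
        iterations=it, converged=converged,
        max_rel_mismatch=best_mismatch if not converged else history[-1],
        k=k, predicted=v_model, target=v_target,
        n_zero=int(np.sum(k == 0.0)), alpha_final=alpha, history=history,
    )
    return final, report


def trim_and_refit(model: BsENM, targets: FluctuationTargets,
                   k_min: float = 1e-3,
                   **match_kwargs) -> tuple[BsENM, MatchingReport]:
    """Drop springs with k < k_min and rerun the matching on the survivors.

    Skeleton-1 springs are never trimmed (they carry chain connectivity).
    Raises if trimming would disconnect the network.
    """
    kept = [s for s in model.springs
            if s.category == SKELETON1 or s.k >= k_min]
    if not kept:
        raise ValueError("trimming removed every spring; lower k_min")
    trimmed = BsENM(model.sites, [Spring(s.i, s.j, s.l0, s.k, s.category)
                                  for s in kept],
                    model.coords.copy(), model.temperature)
    try:
        enm_covariance(trimmed)
    except NetworkRankError as err:
        raise NetworkRankError(
            f"trimming at k_min={k_min} disconnects the network; "
            "use a lower k_min"
        ) from err
    return fluctuation_matching_round(trimmed, targets, **match_kwargs)


def learn_bsenm(window, lc: float = 7.8, k0: float = 1.0,
                temperature: float = 300.0, k_min: float = 1e-3,
                trim: bool = True, **match_kwargs):
    """End-to-end learning from one CG trajectory window.

    Computes fluctuation targets for all within-cutoff pairs, seeds the
    network at k0, runs a matching round and (optionally) connectivity
    trimming with a refit.  Returns (model, round1_report, round2_report);
    the last element is None when ``trim`` is False.
    """
    from .mapping import compute_fluctuation_targets

    targets = compute_fluctuation_targets(window, cutoff=lc)
    cg = window.mean_structure()
    model = build_initial_model(cg, lc, k0=k0, targets=targets,
                                temperature=temperature)
    model, rep1 = fluctuation_matching_round(model, targets, **match_kwargs)
    if not trim:
        return model, rep1, None
    model, rep2 = trim_and_refit(model, targets, k_min=k_min, **match_kwargs)
    return model, rep1, rep2


# -- file I/O -------------------------------------------------------------

def model_frame(model: BsENM) -> pd.DataFrame:
    resi = [s.residue_index for s in model.sites]
    return pd.DataFrame({
        "i": [s.i for s in model.springs],
        "j": [s.j for s in model.springs],
        "residue_i": [resi[s.i] + 1 for s in model.springs],
        "residue_j": [resi[s.j] + 1 for s in model.springs],
        "category": [s.category for s in model.springs],
        "l0": [s.l0 for s in model.springs],
        "k": [s.k for s in model.springs],
    })


def write_model(model: BsENM, path: str | Path,
                metadata: dict | None = None) -> None:
    """Spring list as TSV plus a JSON sidecar with run metadata."""
    path = Path(path)
    model_frame(model).to_csv(path, sep="\t", index=False)
    meta = {"temperature": model.temperature, "n_sites": model.n_sites,
            "n_springs": len(model.springs)}
    meta.update(metadata or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_model(path: str | Path, sites, coords,
               temperature: float = 300.0) -> BsENM:
    df = pd.read_csv(path, sep="\t")
    springs = [Spring(int(r.i), int(r.j), float(r.l0), float(r.k), str(r.category))
               for r in df.itertuples()]
    return BsENM(sites, springs, np.asarray(coords, dtype=float), temperature)
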