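"""Reference networks and Gaussian pseudo-trajectories for testing.

The generator builds a compact, self-avoiding CG chain with realistic
spacing (3.8 Å between consecutive backbone positions, N/O sites split along
the local tangent, one side-chain site per residue), wires every
within-cutoff site pair with a spring, and draws the spring constants from
the study conditions: strong skeleton springs, heavy-tailed (shifted Lomax)
non-skeleton springs with a distance-dependent zero probability — longer
contacts are rarer and weaker, which is what makes the learned network
progressively sparser with distance.

Because the reference network is known exactly, every downstream stage can
be tested against analytic answers: the site covariance k_B·T·H⁺, the
per-pair distance variances, and, for windowed statistics, a series of
perturbed networks with one planted dominant edge whose residues must come
out as hotspots of a prominent mode.

Frames are drawn i.i.d. from the network's Gaussian ensemble (rigid-body
modes given zero variance).  Fluctuation matching consumes only variances,
so the missing temporal autocorrelation is irrelevant to its correctness;
window-level fluctuations are instead emulated by explicit, independent
multiplicative noise on the spring constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import enm, graphs
from .constants import DEFAULT_CUTOFF, DEFAULT_TEMPERATURE
from .core import (BACKBONE, NONSKELETON, SIDECHAIN, BsENM, CGModel, CGSite,
                   CGTrajectory, FluctuationTargets, Spring)

#: Residue-name palette (no GLY/CYS: every fixture residue has a side-chain
#: site and no disulfide chemistry unless requested explicitly).
_PALETTE = ("ALA", "VAL", "LEU", "ILE", "SER", "THR", "ASP", "GLU", "ASN",
            "GLN", "LYS", "ARG", "PHE", "TYR", "TRP", "MET", "HIS", "PRO")


@dataclass(frozen=True)
class FixtureSpec:
    """Everything that determines a fixture byte-for-byte (given the seed)."""

    n_residues: int = 30
    seed: int = 0
    #: chain layout: "globule" (compact self-avoiding coil, the default for
    #: anything involving dynamics) or "helix" (ideal α-helix, whose banded,
    #: translation-regular contact map is the clean setting for chain-mode
    #: comparisons)
    topology: str = "globule"
    lc: float = DEFAULT_CUTOFF
    temperature: float = DEFAULT_TEMPERATURE
    #: uniform stiffness ranges for skeleton springs (kcal/mol/Å²)
    skeleton1_k: tuple[float, float] = (10.0, 50.0)
    skeleton2_k: tuple[float, float] = (5.0, 20.0)
    #: shifted-Lomax parameters for non-skeleton stiffnesses
    lomax_shape: float = 2.2
    lomax_scale: float = 1.0
    k_floor: float = 0.05
    #: mean probability that a within-cutoff non-skeleton pair has no spring;
    #: the actual probability grows linearly with pair distance
    zero_fraction: float = 0.2
    distance_dependent_zeros: bool = True
    frames_per_window: int = 10000
    n_windows: int = 10


@dataclass
class ReferenceENM:
    """A spring network with known constants plus its analytic statistics."""

    model: BsENM
    covariance: np.ndarray           # k_B·T·H⁺, (3N, 3N)
    targets: FluctuationTargets     # analytic l0/⟨δl²⟩ for every spring pair
    spec: FixtureSpec

    @property
    def nonzero_pairs(self) -> set[tuple[int, int]]:
        return {s.pair for s in self.model.springs if s.k > 0}

    @property
    def zero_pairs(self) -> set[tuple[int, int]]:
        return {s.pair for s in self.model.springs if s.k == 0}


def _compact_chain(n: int, rng: np.random.Generator,
                   step: float = 3.8, min_sep: float = 3.9) -> np.ndarray:
    """Self-avoiding walk at protein-like packing density.

    The confinement radius scales as 2.8·N^(1/3) Å (globular-protein
    density); a strong centering bias plus a hard wall keeps the fold
    compact, so the resulting contact network braces the chain and the
    lowest internal modes stay stiff — a floppy coil would put the Gaussian
    ensemble outside the small-fluctuation regime the analytic distance
    statistics assume.
    """
    radius = 2.8 * n ** (1.0 / 3.0)
    for _ in range(500):  # restart loop
        pos = np.zeros((n, 3))
        ok = True
        for i in range(1, n):
            placed = False
            for _ in range(500):
                direction = rng.normal(size=3)
                direction += 0.9 * (-pos[i - 1]) / radius  # confinement bias
                direction /= np.linalg.norm(direction)
                cand = pos[i - 1] + step * direction
                if i > 1 and np.min(np.linalg.norm(pos[:i - 1] - cand, axis=1)) < min_sep:
                    continue
                if np.linalg.norm(cand) > 1.15 * radius:
                    continue
                pos[i] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return pos
    raise RuntimeError("failed to place a self-avoiding chain")


def _ideal_helix(n: int, radius: float = 2.3, rise: float = 1.5,
                 twist_deg: float = 100.0) -> np.ndarray:
    """Backbone positions of an ideal α-helix (Cα-like parameters)."""
    theta = np.deg2rad(twist_deg) * np.arange(n)
    return np.column_stack([radius * np.cos(theta),
                            radius * np.sin(theta),
                            rise * np.arange(n)])


def _chain_sites(pos: np.ndarray, rng: np.random.Generator,
                 resnames: list[str]) -> tuple[list[CGSite], np.ndarray]:
    n = len(pos)
    sites: list[CGSite] = []
    coords = []
    k = 0
    for i in range(n):
        prev_i = max(i - 1, 0)
        next_i = min(i + 1, n - 1)
        t = pos[next_i] - pos[prev_i]
        t /= np.linalg.norm(t)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(t @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        n1 = np.cross(t, ref)
        n1 /= np.linalg.norm(n1)
        n2 = np.cross(t, n1)
        phi = rng.uniform(0, 2 * np.pi)
        jitter = rng.normal(scale=0.15, size=(3, 3))
        site_pos = {
            "N": pos[i] - 1.2 * t + jitter[0],
            "O": pos[i] + 1.2 * t + jitter[1],
            "SC": pos[i] + 2.4 * (np.cos(phi) * n1 + np.sin(phi) * n2) + jitter[2],
        }
        for name, cls in (("N", BACKBONE), ("O", BACKBONE), ("SC", SIDECHAIN)):
            src = name if name != "SC" else "COM"
            sites.append(CGSite(k, i, "A", cls, src, resnames[i]))
            coords.append(site_pos[name])
            k += 1
    return sites, np.array(coords)


def _draw_stiffness(spring: Spring, spec: FixtureSpec,
                    rng: np.random.Generator) -> float:
    if spring.category == "skeleton1":
        return float(rng.uniform(*spec.skeleton1_k))
    if spring.category == "skeleton2":
        return float(rng.uniform(*spec.skeleton2_k))
    p_zero = spec.zero_fraction
    if spec.distance_dependent_zeros:
        p_zero = np.clip(spec.zero_fraction * 2.0 * spring.l0 / spec.lc, 0.0, 0.95)
    if rng.uniform() < p_zero:
        return 0.0
    u = rng.uniform()
    lomax_draw = spec.lomax_scale * ((1.0 - u) ** (-1.0 / spec.lomax_shape) - 1.0)
    return float(spec.k_floor + lomax_draw)


def make_reference_enm(spec: FixtureSpec | None = None, **kwargs) -> ReferenceENM:
    """Build a reference network and its analytic fluctuation statistics.

    Keyword arguments override :class:`FixtureSpec` fields.  Raises after a
    bounded number of resampling attempts if a connected, full-rank network
    cannot be drawn (never observed at the default settings).
    """
    if spec is None:
        spec = FixtureSpec(**kwargs)
    elif kwargs:
        raise ValueError("pass either a FixtureSpec or keyword overrides")
    if spec.n_residues < 4:
        raise ValueError("need at least 4 residues")
    rng = np.random.default_rng(spec.seed)
    resnames = [str(_PALETTE[i]) for i in rng.integers(0, len(_PALETTE),
                                                       spec.n_residues)]
    if spec.topology not in ("globule", "helix"):
        raise ValueError(f"unknown topology {spec.topology!r}")
    for _ in range(20):
        if spec.topology == "helix":
            pos = _ideal_helix(spec.n_residues)
        else:
            pos = _compact_chain(spec.n_residues, rng)
        sites, coords = _chain_sites(pos, rng, resnames)
        cg = CGModel(sites, coords)
        model = enm.build_initial_model(cg, spec.lc, k0=1.0,
                                        temperature=spec.temperature)
        for s in model.springs:
            s.k = _draw_stiffness(s, spec, rng)
        try:
            C = enm.enm_covariance(model)
        except enm.NetworkRankError:
            continue  # disconnected draw; resample geometry
        var = enm.enm_distance_fluctuations(model, covariance=C)
        targets = FluctuationTargets(model.spring_pairs(),
                                     np.array([s.l0 for s in model.springs]),
                                     var)
        return ReferenceENM(model, C, targets, spec)
    raise RuntimeError("could not draw a connected reference network")


def sample_enm_trajectory(ref: ReferenceENM | BsENM, frames: int,
                          seed: int = 0) -> CGTrajectory:
    """Draw i.i.d. Gaussian frames from the network's thermal ensemble.

    Frames have mean = equilibrium coordinates and covariance k_B·T·H⁺;
    rigid-body modes carry zero variance, so coordinates stay bounded and
    distance statistics are unaffected.  At T → 0 every frame equals the
    equilibrium structure.
    """
    if frames < 2:
        raise ValueError("need at least 2 frames")
    model = ref.model if isinstance(ref, ReferenceENM) else ref
    rng = np.random.default_rng(seed)
    if model.temperature == 0.0:
        disp = np.zeros((frames, 3 * model.n_sites))
    else:
        C = (ref.covariance if isinstance(ref, ReferenceENM)
             else enm.enm_covariance(model))
        evals, evecs = np.linalg.eigh(C)
        evals = np.clip(evals, 0.0, None)
        factor = evecs * np.sqrt(evals)
        z = rng.standard_normal((frames, factor.shape[1]))
        disp = z @ factor.T
    coords = model.coords[None] + disp.reshape(frames, model.n_sites, 3)
    return CGTrajectory(list(model.sites), coords)


@dataclass
class WindowSeries:
    """Per-window perturbed networks with one planted dominant edge."""

    models: list[BsENM]
    planted_residues: tuple[int, int]
    planted_spring: int           # index into each model's spring list
    planted_k: float
    reference: ReferenceENM

    def window_graphs(self, group: str = "ALL") -> list[np.ndarray]:
        """Non-skeleton signless Laplacians K_n of every window."""
        return [graphs.residue_graph(m, group, "nonskeleton", w).signless_laplacian
                for w, m in enumerate(self.models)]


def make_window_series(ref: ReferenceENM, n_windows: int = 20,
                       perturbation: float = 0.3, seed: int = 0,
                       planted_factor: float = 6.0) -> WindowSeries:
    """Emulate window-to-window network fluctuations.

    Every non-planted spring constant is multiplied by independent lognormal
    noise exp(N(0, σ²)) per window (σ = ``perturbation``).  One sequence-
    distant non-skeleton spring is planted: held constant across windows at
    ``planted_factor`` × the 99th percentile of the non-skeleton constants,
    so prominent-mode and hotspot detection have a known answer.
    """
    if n_windows < 2:
        raise ValueError("need at least 2 windows")
    rng = np.random.default_rng(seed)
    model = ref.model
    resi = np.array([s.residue_index for s in model.sites])
    nonskel = [(idx, s) for idx, s in enumerate(model.springs)
               if s.category == NONSKELETON and s.k > 0
               and resi[s.i] != resi[s.j]]
    if not nonskel:
        raise ValueError("reference has no non-skeleton springs to plant on")
    sep = [abs(resi[s.i] - resi[s.j]) for _, s in nonskel]
    planted_idx, planted = nonskel[int(np.argmax(sep))]
    k_ns = np.array([s.k for _, s in nonskel])
    planted_k = planted_factor * float(np.quantile(k_ns, 0.99))

    k_ref = model.stiffnesses()
    models = []
    for _ in range(n_windows):
        noise = np.exp(rng.normal(0.0, perturbation, size=k_ref.shape))
        k_n = k_ref * noise if perturbation > 0 else k_ref.copy()
        k_n[planted_idx] = planted_k
        models.append(model.with_stiffnesses(k_n))
    return WindowSeries(models,
                        (int(resi[planted.i]), int(resi[planted.j])),
                        planted_idx, planted_k, ref)
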