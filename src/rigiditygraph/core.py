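"""Core data containers for the coarse-grained elastic-network pipeline.

The coarse-grained (CG) representation places up to three sites per residue:
two backbone sites (amide nitrogen, carbonyl oxygen) and one side-chain site
(a representative heavy atom or the side-chain heavy-atom center of mass).
Single-site hetero residues (structural ions, ligands) are appended as extra
residues so they participate in the interaction network like any other node.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Site classes.
BACKBONE = "backbone"
SIDECHAIN = "sidechain"

#: Spring categories.
SKELETON1 = "skeleton1"
SKELETON2 = "skeleton2"
NONSKELETON = "nonskeleton"
DISULFIDE = "disulfide"

SPRING_CATEGORIES = (SKELETON1, SKELETON2, NONSKELETON, DISULFIDE)


@dataclass(frozen=True)
class CGSite:
    """One coarse-grained site.

    ``residue_index`` runs sequentially (0-based) over all chains in file
    order, with hetero residues (ions, bound ligand chains) counted as
    additional residues.  ``source`` records the atom the site sits on, or
    ``"COM"`` for a side-chain center of mass.
    """

    site_index: int
    residue_index: int
    chain_id: str
    site_class: str
    source: str
    resname: str = ""

    def __post_init__(self):
        if self.site_class not in (BACKBONE, SIDECHAIN):
            raise ValueError(f"unknown site_class {self.site_class!r}")


@dataclass
class CGModel:
    """A CG topology with a single coordinate set (Å)."""

    sites: list[CGSite]
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sites), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} != ({len(self.sites)}, 3)"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite CG coordinates")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_residues(self) -> int:
        return max(s.residue_index for s in self.sites) + 1

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([s.residue_index for s in self.sites], dtype=int)

    @property
    def site_classes(self) -> np.ndarray:
        return np.array([s.site_class for s in self.sites])


@dataclass
class CGTrajectory:
    """Per-frame CG coordinates: ``coords`` has shape (n_frames, n_sites, 3).

    ``frame_interval`` is informational (time units between saved frames).
    """

    sites: list[CGSite]
    coords: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (len(self.sites), 3):
            raise ValueError(
                f"coords shape {self.coords.shape} incompatible with "
                f"{len(self.sites)} sites"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite trajectory coordinates")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def frame(self, t: int) -> CGModel:
        return CGModel(self.sites, self.coords[t])

    def mean_structure(self) -> CGModel:
        """Frame-averaged coordinates as a CGModel."""
        return CGModel(self.sites, self.coords.mean(axis=0))


@dataclass
class FluctuationTargets:
    """Per-pair mean distance l0 (Å) and distance variance ⟨δl²⟩ (Å²)."""

    pairs: np.ndarray  # (m, 2) int, i < j
    l0: np.ndarray
    var: np.ndarray

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.l0 = np.asarray(self.l0, dtype=float)
        self.var = np.asarray(self.var, dtype=float)
        if not (len(self.pairs) == len(self.l0) == len(self.var)):
            raise ValueError("pairs/l0/var length mismatch")
        if np.any(self.pairs[:, 0] == self.pairs[:, 1]):
            raise ValueError("self-pair in targets")
        self.pairs = np.sort(self.pairs, axis=1)
        keys = list(map(tuple, self.pairs))
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate pairs in targets")
        if np.any(self.l0 <= 0):
            raise ValueError("non-positive mean distance")
        if np.any(self.var < 0):
            raise ValueError("negative variance")

    def as_dict(self) -> dict[tuple[int, int], tuple[float, float]]:
        return {
            (int(i), int(j)): (float(a), float(b))
            for (i, j), a, b in zip(self.pairs, self.l0, self.var)
        }


@dataclass
class Spring:
    """A harmonic spring between CG sites i and j.

    ``k`` is the stiffness in kcal·mol⁻¹·Å⁻²; ``l0`` the rest length in Å.
    The category (skeleton1/skeleton2/nonskeleton/disulfide) is fixed at
    construction from residue separation and chemistry.
    """

    i: int
    j: int
    l0: float
    k: float
    category: str = NONSKELETON

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("spring endpoints coincide")
        if self.i > self.j:
            self.i, self.j = self.j, self.i
        if self.k < 0:
            raise ValueError("negative stiffness")
        if self.category not in SPRING_CATEGORIES:
            raise ValueError(f"unknown spring category {self.category!r}")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass
class BsENM:
    """A backbone/side-chain elastic network: springs on CG sites.

    ``coords`` are the equilibrium site coordinates (Å) used for normal-mode
    analysis; classical equilibrium fluctuations are mass-independent, so no
    masses are carried.
    """

    sites: list[CGSite]
    springs: list[Spring]
    coords: np.ndarray
    temperature: float = 300.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sites), 3):
            raise ValueError("equilibrium coords shape mismatch")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite equilibrium coordinates")
        pairs = [s.pair for s in self.springs]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate spring pairs")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_residues(self) -> int:
        return max(s.residue_index for s in self.sites) + 1

    def spring_pairs(self) -> np.ndarray:
        return np.array([s.pair for s in self.springs], dtype=int).reshape(-1, 2)

    def stiffnesses(self) -> np.ndarray:
        return np.array([s.k for s in self.springs], dtype=float)

    def with_stiffnesses(self, k: np.ndarray) -> "BsENM":
        """Copy of the model with spring constants replaced."""
        k = np.asarray(k, dtype=float)
        if k.shape != (len(self.springs),):
            raise ValueError("stiffness vector length mismatch")
        springs = [replace(s, k=float(ki)) for s, ki in zip(self.springs, k)]
        return BsENM(self.sites, springs, self.coords.copy(), self.temperature)
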