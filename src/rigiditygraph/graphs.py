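"""Spring classification and inter-residue rigidity graphs.

Springs are classified by residue separation (skeleton-1: within a residue or
between nearest sequence neighbours; skeleton-2: second-nearest neighbours;
everything else non-skeleton), by chemistry (cysteine Sγ–Sγ at covalent
distance = disulfide), and by the site classes of their endpoints (BB/BS/SS).

The inter-residue adjacency sums spring constants over all CG-site springs
linking two residues: A_IJ = Σ_{i∈I, j∈J} k_ij.  The degree matrix D holds
row sums, and the derived operators are the Laplacian L = D − A and the
signless Laplacian K = D + A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (BACKBONE, DISULFIDE, NONSKELETON, SIDECHAIN, SKELETON1,
                   SKELETON2, BsENM, CGSite, Spring)

logger = logging.getLogger(__name__)

GROUPS = ("ALL", "BB", "BS", "SS")
SUBSETS = ("all", "skeleton", "nonskeleton", "disulfide")

#: Sγ–Sγ rest lengths below this (Å) are covalent disulfide bonds.
DISULFIDE_CUTOFF = 2.5


@dataclass(frozen=True)
class SpringClass:
    skeleton_rank: int | None  # 1, 2, or None
    chem: str                  # "disulfide" | "ordinary"
    group: str                 # "BB" | "BS" | "SS"

    @property
    def category(self) -> str:
        if self.chem == DISULFIDE:
            return DISULFIDE
        if self.skeleton_rank == 1:
            return SKELETON1
        if self.skeleton_rank == 2:
            return SKELETON2
        return NONSKELETON


def spring_group(site_i: CGSite, site_j: CGSite) -> str:
    """BB / BS / SS from the two endpoint site classes."""
    bb = (site_i.site_class == BACKBONE) + (site_j.site_class == BACKBONE)
    return {2: "BB", 1: "BS", 0: "SS"}[bb]


def classify_spring(i: int, j: int, l0: float, sites: list[CGSite],
                    disulfide_cutoff: float = DISULFIDE_CUTOFF) -> SpringClass:
    """Classify one site pair.

    Inter-chain pairs are always non-skeleton (chains are not sequence
    neighbours).  A Sγ–Sγ pair between two cysteines below the covalent
    cutoff is a disulfide.
    """
    si, sj = sites[i], sites[j]
    group = spring_group(si, sj)

    if (si.resname == "CYS" and sj.resname == "CYS"
            and si.source == "SG" and sj.source == "SG"
            and si.residue_index != sj.residue_index
            and l0 < disulfide_cutoff):
        return SpringClass(None, DISULFIDE, group)

    if si.chain_id == sj.chain_id:
        sep = abs(si.residue_index - sj.residue_index)
        if sep <= 1:
            return SpringClass(1, "ordinary", group)
        if sep == 2:
            return SpringClass(2, "ordinary", group)
    return SpringClass(None, "ordinary", group)


def classify_model(model: BsENM,
                   disulfide_cutoff: float = DISULFIDE_CUTOFF) -> BsENM:
    """Return the model with every spring's category (re)assigned in place."""
    for s in model.springs:
        s.category = classify_spring(s.i, s.j, s.l0, model.sites,
                                     disulfide_cutoff).category
    return model


@dataclass
class RigidityGraph:
    """Weighted inter-residue graph for one interaction group/subset."""

    adjacency: np.ndarray
    group: str = "ALL"
    subset: str = "nonskeleton"
    window: int | str | None = None

    def __post_init__(self):
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(A < 0) or np.any(np.diag(A) != 0):
            raise ValueError("adjacency needs non-negative weights, zero diagonal")
        self.adjacency = A

    @property
    def n_residues(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        """Node strengths k_II (row sums of A)."""
        return self.adjacency.sum(axis=1)

    @property
    def degree_matrix(self) -> np.ndarray:
        return np.diag(self.degrees)

    @property
    def laplacian(self) -> np.ndarray:
        """L = D − A."""
        return self.degree_matrix - self.adjacency

    @property
    def signless_laplacian(self) -> np.ndarray:
        """K = D + A (positive semidefinite)."""
        return self.degree_matrix + self.adjacency


def _spring_in_subset(spring: Spring, subset: str) -> bool:
    if subset == "all":
        return True
    if subset == "skeleton":
        return spring.category in (SKELETON1, SKELETON2)
    if subset == "nonskeleton":
        return spring.category == NONSKELETON
    if subset == "disulfide":
        return spring.category == DISULFIDE
    raise ValueError(f"unknown subset {subset!r}")


def residue_graph(model: BsENM, group: str = "ALL",
                  subset: str = "nonskeleton",
                  window: int | str | None = None) -> RigidityGraph:
    """Sum spring constants into an inter-residue adjacency matrix.

    Disulfide springs never enter the ``nonskeleton`` subset (they are
    covalent, not non-bonded couplings).  An empty selection yields a zero
    graph with a logged warning.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    n = model.n_residues
    resi = np.array([s.residue_index for s in model.sites])
    A = np.zeros((n, n))
    used = 0
    for s in model.springs:
        if not _spring_in_subset(s, subset):
            continue
        if group != "ALL" and spring_group(model.sites[s.i], model.sites[s.j]) != group:
            continue
        I, J = resi[s.i], resi[s.j]
        if I == J:
            continue  # intra-residue springs carry no inter-residue edge
        A[I, J] += s.k
        A[J, I] += s.k
        used += 1
    if used == 0:
        logger.warning("empty spring selection for group=%s subset=%s", group, subset)
    return RigidityGraph(A, group, subset, window)


def contact_graph(model0: BsENM, window: int | str | None = None) -> RigidityGraph:
    """Residue contact-count graph of a topology-only network (all k = 1).

    m_IJ counts within-cutoff CG site pairs between residues I and J; the
    degree m_II is the residue contact number.
    """
    ones = model0.with_stiffnesses(np.ones(len(model0.springs)))
    return residue_graph(ones, "ALL", "all", window)


def sparsity_profile(model: BsENM, bin_width: float = 0.5,
                     subset: str = "all", k_min: float = 1e-3) -> pd.DataFrame:
    """Fraction of springs retaining k ≥ k_min per rest-length bin.

    ``k_min`` separates surviving springs from those driven to (numerical)
    zero by the matching iterations; the default matches the connectivity
    trimming threshold.  Returns a DataFrame with bin edges/centers, the
    pair count, the surviving count, and the retained fraction (NaN for
    empty bins).
    """
    springs = [s for s in model.springs if _spring_in_subset(s, subset)]
    if not springs:
        raise ValueError("no springs in requested subset")
    l0 = np.array([s.l0 for s in springs])
    k = np.array([s.k for s in springs])
    lo = np.floor(l0.min() / bin_width) * bin_width
    hi = np.ceil(l0.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    idx = np.clip(np.digitize(l0, edges) - 1, 0, len(edges) - 2)
    n_pairs = np.bincount(idx, minlength=len(edges) - 1)
    n_pos = np.bincount(idx, weights=(k >= k_min).astype(float),
                        minlength=len(edges) - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_pairs > 0, n_pos / np.maximum(n_pairs, 1), np.nan)
    return pd.DataFrame({
        "bin_left": edges[:-1],
        "bin_center": 0.5 * (edges[:-1] + edges[1:]),
        "n_pairs": n_pairs.astype(int),
        "n_positive": n_pos.astype(int),
        "fraction_positive": frac,
    })


def bs_contribution_ledger(model: BsENM) -> pd.DataFrame:
    """Per-residue split of non-skeleton BS strength by the entry site class.

    For each residue I, sums the BS spring constants entering through I's
    backbone sites versus through its side-chain site; the two parts sum to
    I's BS degree.  Used to decide whether a residue participates in a
    backbone–side-chain mode via its backbone or its side chain.
    """
    n = model.n_residues
    bb = np.zeros(n)
    sc = np.zeros(n)
    for s in model.springs:
        if s.category != NONSKELETON:
            continue
        si, sj = model.sites[s.i], model.sites[s.j]
        if spring_group(si, sj) != "BS" or si.residue_index == sj.residue_index:
            continue
        for site in (si, sj):
            if site.site_class == BACKBONE:
                bb[site.residue_index] += s.k
            else:
                sc[site.residue_index] += s.k
    return pd.DataFrame({"backbone_strength": bb, "sidechain_strength": sc})


def edge_list(graph: RigidityGraph) -> pd.DataFrame:
    """Upper-triangle edges as a tidy table (1-based residue labels)."""
    I, J = np.nonzero(np.triu(graph.adjacency, k=1))
    return pd.DataFrame({
        "I": I + 1, "J": J + 1,
        "k_IJ": graph.adjacency[I, J],
        "group": graph.group, "subset": graph.subset,
    })


def write_edge_list(graph: RigidityGraph, path) -> None:
    edge_list(graph).to_csv(path, sep="\t", index=False)


def read_edge_list(path, n_residues: int | None = None) -> RigidityGraph:
    df = pd.read_csv(path, sep="\t")
    n = n_residues or int(max(df["I"].max(), df["J"].max()))
    A = np.zeros((n, n))
    for r in df.itertuples():
        A[int(r.I) - 1, int(r.J) - 1] += r.k_IJ
        A[int(r.J) - 1, int(r.I) - 1] += r.k_IJ
    group = df["group"].iloc[0] if "group" in df and len(df) else "ALL"
    subset = df["subset"].iloc[0] if "subset" in df and len(df) else "nonskeleton"
    return RigidityGraph(A, str(group), str(subset))
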