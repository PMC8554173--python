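"""Atomic-to-CG mapping, trajectory windowing, and fluctuation targets.

Each amino acid contributes two backbone sites (amide N, carbonyl O) plus one
side-chain site; glycine has no side-chain site.  Polar/charged side chains
use a representative interacting atom, hydrophobic ones the center of mass of
their heavy atoms.  Structures and trajectories are read through MDAnalysis,
so every format it understands (PDB, GRO, DCD, XTC, ...) works here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BACKBONE, SIDECHAIN, CGModel, CGSite, CGTrajectory, FluctuationTargets


class MappingError(ValueError):
    """A residue cannot be mapped onto CG sites."""


#: Atom names considered part of the backbone (heavy atoms + common H names).
_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "OT1", "OT2", "O1", "O2"}

#: Solvent / counter-ion residue names silently dropped from the mapping.
_SOLVENT = {"HOH", "TIP3", "TIP", "TP3", "WAT", "SOL", "SPC",
            "NA", "SOD", "CL", "CLA", "K", "POT", "CS", "RB"}

#: Standard amino-acid residue names (incl. CHARMM histidine variants).
_AMINO = {"ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
          "HSD", "HSE", "HSP", "ILE", "LEU", "LYS", "MET", "PHE", "PRO",
          "SER", "THR", "TRP", "TYR", "VAL"}

COM_RULE = "COM"


@dataclass(frozen=True)
class SideChainRule:
    """Either a named representative atom or a heavy-atom center of mass."""

    kind: str  # "atom" | "com"
    atom: str | None = None

    def __post_init__(self):
        if self.kind not in ("atom", "com"):
            raise ValueError(f"unknown side-chain rule kind {self.kind!r}")
        if self.kind == "atom" and not self.atom:
            raise ValueError("atom rule requires an atom name")


def _default_side_rules() -> dict[str, SideChainRule]:
    rep = {
        "ALA": "CB", "SER": "OG", "THR": "OG1", "CYS": "SG", "TYR": "OH",
        "ASP": "CG", "GLU": "CD", "ASN": "CG", "GLN": "CD", "HIS": "NE2",
        "HSD": "NE2", "HSE": "NE2", "HSP": "NE2", "LYS": "NZ", "ARG": "CZ",
    }
    com = ["VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO"]
    rules = {r: SideChainRule("atom", a) for r, a in rep.items()}
    rules.update({r: SideChainRule("com") for r in com})
    return rules


@dataclass
class MappingTable:
    """Per-residue-type CG mapping rules.

    ``side_rules`` maps residue names to side-chain rules; glycine is absent
    (no heavy side-chain atom).  ``ion_resnames`` become single-site residues.
    ``fallback_com`` maps unknown (ligand) residues to a single heavy-atom
    center-of-mass site instead of raising.
    """

    backbone_n: str = "N"
    backbone_o: str = "O"
    side_rules: dict[str, SideChainRule] = field(default_factory=_default_side_rules)
    ion_resnames: set[str] = field(default_factory=lambda: {"CAL", "CA2", "ZN", "ZN2", "MG", "MN", "FE"})
    fallback_com: bool = False

    def __post_init__(self):
        if "GLY" in self.side_rules:
            raise ValueError("glycine must not have a side-chain rule")

    # -- serialisation ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "backbone_n": self.backbone_n,
            "backbone_o": self.backbone_o,
            "fallback_com": self.fallback_com,
            "ions": sorted(self.ion_resnames),
            "side_chains": {
                r: (rule.atom if rule.kind == "atom" else COM_RULE)
                for r, rule in sorted(self.side_rules.items())
            },
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MappingTable":
        doc = yaml.safe_load(Path(path).read_text())
        rules = {}
        for resname, value in doc.get("side_chains", {}).items():
            if value == COM_RULE:
                rules[resname.upper()] = SideChainRule("com")
            else:
                rules[resname.upper()] = SideChainRule("atom", str(value))
        kwargs = dict(
            backbone_n=doc.get("backbone_n", "N"),
            backbone_o=doc.get("backbone_o", "O"),
            fallback_com=bool(doc.get("fallback_com", False)),
        )
        if rules:
            kwargs["side_rules"] = rules
        if "ions" in doc:
            kwargs["ion_resnames"] = {str(x).upper() for x in doc["ions"]}
        return cls(**kwargs)


def default_mapping_table() -> MappingTable:
    return MappingTable()


def _is_hydrogen(atom) -> bool:
    name = atom.name.strip()
    if name[:1].isdigit():
        name = name[1:]
    return name[:1].upper() == "H"


def _heavy_sidechain_atoms(residue):
    return [
        a for a in residue.atoms
        if a.name.strip().upper() not in _BACKBONE_ATOMS and not _is_hydrogen(a)
    ]


@dataclass
class _SiteDef:
    """Resolved atom indices + weights for one CG site (internal)."""

    atom_indices: np.ndarray
    weights: np.ndarray  # normalised
    site: CGSite


def _chain_of(residue) -> str:
    seg = getattr(residue, "segid", "") or ""
    try:
        chain = residue.atoms.chainIDs[0]
    except (AttributeError, IndexError):
        chain = ""
    return str(chain or seg or "A").strip() or "A"


def _resolve_sites(atoms, table: MappingTable) -> list[_SiteDef]:
    """Build the per-site atom index/weight lists for an AtomGroup."""
    defs: list[_SiteDef] = []
    site_index = 0
    residue_index = 0
    for residue in atoms.residues:
        resname = residue.resname.strip().upper()
        if resname in _SOLVENT:
            continue
        chain = _chain_of(residue)
        names = {a.name.strip().upper(): a.ix for a in residue.atoms}

        def _single(atom_name, site_class, source=None):
            if atom_name not in names:
                raise MappingError(
                    f"residue {resname} {residue.resid}: required atom "
                    f"{atom_name!r} missing"
                )
            return _SiteDef(
                np.array([names[atom_name]]),
                np.array([1.0]),
                CGSite(0, 0, chain, site_class, source or atom_name, resname),
            )

        def _com(site_class):
            heavy = _heavy_sidechain_atoms(residue)
            if not heavy:
                raise MappingError(
                    f"residue {resname} {residue.resid}: no heavy atoms for COM site"
                )
            masses = []
            for a in heavy:
                try:
                    m = float(a.mass)
                except Exception:
                    m = 0.0
                masses.append(m if m > 0 else 1.0)
            w = np.asarray(masses, dtype=float)
            return _SiteDef(
                np.array([a.ix for a in heavy]),
                w / w.sum(),
                CGSite(0, 0, chain, site_class, COM_RULE, resname),
            )

        if resname in _AMINO:
            new = [
                _single(table.backbone_n, BACKBONE),
                _single(table.backbone_o, BACKBONE),
            ]
            rule = table.side_rules.get(resname)
            if rule is not None:
                if rule.kind == "atom":
                    new.append(_single(rule.atom, SIDECHAIN))
                else:
                    new.append(_com(SIDECHAIN))
        elif resname in table.ion_resnames:
            ion_atom = residue.atoms[0]
            new = [_SiteDef(
                np.array([ion_atom.ix]), np.array([1.0]),
                CGSite(0, 0, chain, SIDECHAIN, ion_atom.name.strip(), resname),
            )]
        elif table.fallback_com:
            new = [_com(SIDECHAIN)]
        else:
            raise MappingError(
                f"residue {resname} {residue.resid}: no mapping rule "
                "(enable fallback_com or extend the table)"
            )

        for d in new:
            d.site = CGSite(site_index, residue_index, d.site.chain_id,
                            d.site.site_class, d.site.source, d.site.resname)
            site_index += 1
            defs.append(d)
        residue_index += 1
    if not defs:
        raise MappingError("no mappable residues found")
    return defs


def _apply(defs: list[_SiteDef], positions: np.ndarray) -> np.ndarray:
    out = np.empty((len(defs), 3))
    for n, d in enumerate(defs):
        out[n] = d.weights @ positions[d.atom_indices]
    return out


def map_structure(atoms, mapping_table: MappingTable | None = None) -> CGModel:
    """Map one all-atom structure (MDAnalysis Universe/AtomGroup) to CG sites."""
    table = mapping_table or default_mapping_table()
    group = atoms.atoms
    defs = _resolve_sites(group, table)
    coords = _apply(defs, group.universe.atoms.positions)
    return CGModel([d.site for d in defs], coords)


def map_trajectory(atoms, mapping_table: MappingTable | None = None,
                   frame_interval: float = 1.0) -> CGTrajectory:
    """Map every frame of an all-atom trajectory to CG coordinates.

    The mapping is frame-local: frame t is mapped exactly as
    :func:`map_structure` would map it in isolation.
    """
    table = mapping_table or default_mapping_table()
    group = atoms.atoms
    u = group.universe
    defs = _resolve_sites(group, table)
    frames = []
    for _ in u.trajectory:
        frames.append(_apply(defs, u.atoms.positions))
    return CGTrajectory([d.site for d in defs], np.stack(frames), frame_interval)


def split_windows(traj: CGTrajectory, window_frames: int) -> list[CGTrajectory]:
    """Cut a trajectory into consecutive non-overlapping windows.

    A trailing partial window is dropped so window statistics stay
    homogeneous.  Raises if the trajectory is shorter than one window.
    """
    if window_frames < 2:
        raise ValueError("window_frames must be >= 2")
    n = traj.n_frames // window_frames
    if n == 0:
        raise ValueError(
            f"trajectory of {traj.n_frames} frames shorter than one window "
            f"({window_frames} frames)"
        )
    return [
        CGTrajectory(traj.sites,
                     traj.coords[w * window_frames:(w + 1) * window_frames],
                     traj.frame_interval)
        for w in range(n)
    ]


def _pair_distances(coords: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    d = coords[:, pairs[:, 0]] - coords[:, pairs[:, 1]]
    return np.linalg.norm(d, axis=-1)


def candidate_pairs(traj: CGTrajectory, cutoff: float) -> np.ndarray:
    """Unordered site pairs whose frame-averaged distance is below ``cutoff``."""
    n = traj.n_sites
    ii, jj = np.triu_indices(n, k=1)
    pairs = np.column_stack([ii, jj])
    mean_d = _pair_distances(traj.coords, pairs).mean(axis=0)
    return pairs[mean_d < cutoff]


def compute_fluctuation_targets(window: CGTrajectory,
                                pairs: np.ndarray | None = None,
                                cutoff: float | None = None) -> FluctuationTargets:
    """Per-pair mean distance and population variance over a window.

    ``pairs`` may be given explicitly; otherwise they are selected by the
    frame-averaged distance being below ``cutoff``.
    """
    if window.n_frames < 2:
        raise ValueError("need at least 2 frames for fluctuation targets")
    if pairs is None:
        if cutoff is None:
            raise ValueError("provide pairs or a cutoff")
        pairs = candidate_pairs(window, cutoff)
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    dists = _pair_distances(window.coords, pairs)
    if np.any(dists < 1e-8):
        bad = pairs[np.any(dists < 1e-8, axis=0)][0]
        raise ValueError(f"zero inter-site distance for pair {tuple(bad)}")
    l0 = dists.mean(axis=0)
    var = np.mean((dists - l0) ** 2, axis=0)  # population variance
    return FluctuationTargets(pairs, l0, var)


# -- file I/O -------------------------------------------------------------

def site_table(sites: list[CGSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site_index": [s.site_index for s in sites],
            "residue_index": [s.residue_index for s in sites],
            "chain": [s.chain_id for s in sites],
            "site_class": [s.site_class for s in sites],
            "source": [s.source for s in sites],
            "resname": [s.resname for s in sites],
        }
    )


def write_site_table(sites: list[CGSite], path: str | Path) -> None:
    site_table(sites).to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> list[CGSite]:
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "resname": str})
    return [
        CGSite(int(r.site_index), int(r.residue_index), str(r.chain),
               str(r.site_class), str(r.source), str(r.resname))
        for r in df.itertuples()
    ]


def write_cg_pdb(traj: CGTrajectory | CGModel, path: str | Path) -> None:
    """Write CG coordinates as a (multi-model) PDB via MDAnalysis."""
    import MDAnalysis as mda

    if isinstance(traj, CGModel):
        traj = CGTrajectory(traj.sites, traj.coords[None])
    sites = traj.sites
    n_res = max(s.residue_index for s in sites) + 1
    u = mda.Universe.empty(
        n_atoms=len(sites), n_residues=n_res,
        atom_resindex=[s.residue_index for s in sites],
        residue_segindex=[0] * n_res, trajectory=True,
    )
    u.add_TopologyAttr("name", [
        s.source if s.source != COM_RULE else "SC" for s in sites
    ])
    resnames = [""] * n_res
    for s in sites:
        resnames[s.residue_index] = s.resname or "UNK"
    u.add_TopologyAttr("resname", resnames)
    u.add_TopologyAttr("resid", list(range(1, n_res + 1)))
    u.load_new(traj.coords.astype(np.float32), order="fac")
    with mda.Writer(str(path), n_atoms=len(sites), multiframe=traj.n_frames > 1) as w:
        for _ in u.trajectory:
            w.write(u.atoms)


def write_targets(targets: FluctuationTargets, path: str | Path) -> None:
    pd.DataFrame(
        {"i": targets.pairs[:, 0], "j": targets.pairs[:, 1],
         "l0": targets.l0, "var": targets.var}
    ).to_csv(path, sep="\t", index=False)


def read_targets(path: str | Path) -> FluctuationTargets:
    df = pd.read_csv(path, sep="\t")
    return FluctuationTargets(df[["i", "j"]].to_numpy(), df["l0"].to_numpy(),
                              df["var"].to_numpy())
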