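"""Shared fixtures: small synthetic reference networks and learned models.

Everything is generated programmatically from seeded specs; nothing is read
from disk.  Heavier artefacts (learned models) are session-scoped so the
expensive fluctuation-matching runs once.
"""

import numpy as np
import pytest

import rigiditygraph as rg
from rigiditygraph import enm


@pytest.fixture(scope="session")
def small_ref():
    """12-residue compact-globule reference network."""
    return rg.make_reference_enm(n_residues=12, seed=3)


@pytest.fixture(scope="session")
def helix_ref():
    """30-residue ideal-helix reference (graph-topology tests)."""
    return rg.make_reference_enm(n_residues=30, seed=11, topology="helix")


@pytest.fixture(scope="session")
def standard_ref():
    """30-residue compact-globule reference: the standard study fixture."""
    return rg.make_reference_enm(n_residues=30, seed=11)


@pytest.fixture(scope="session")
def learned_standard(standard_ref):
    """Network learned from the standard reference's analytic targets.

    Returns (round-1 model, trimmed model, reference).
    """
    ref = standard_ref
    cg = rg.CGModel(ref.model.sites, ref.model.coords)
    model = enm.build_initial_model(cg, ref.spec.lc, k0=1.0,
                                    targets=ref.targets)
    fit, rep1 = enm.fluctuation_matching_round(model, ref.targets)
    assert rep1.converged
    trimmed, rep2 = enm.trim_and_refit(fit, ref.targets)
    assert rep2.converged
    return fit, trimmed, ref


@pytest.fixture(scope="session")
def learned_small(small_ref):
    """Spring network learned from the small reference's analytic targets.

    Returns (round-1 model, trimmed model, reference).
    """
    cg = rg.CGModel(small_ref.model.sites, small_ref.model.coords)
    model = enm.build_initial_model(cg, small_ref.spec.lc, k0=1.0,
                                    targets=small_ref.targets)
    fit, rep1 = enm.fluctuation_matching_round(model, small_ref.targets)
    assert rep1.converged
    trimmed, rep2 = enm.trim_and_refit(fit, small_ref.targets)
    assert rep2.converged
    return fit, trimmed, small_ref


def make_peptide_universe(residues, n_frames=1, displace=None):
    """Build an in-memory all-atom MDAnalysis Universe for mapping tests.

    ``residues`` is a list of (resname, {atom_name: xyz}) tuples;
    ``displace`` optionally gives a per-frame rigid shift applied to frame t.
    """
    import MDAnalysis as mda

    n_atoms = sum(len(a) for _, a in residues)
    u = mda.Universe.empty(
        n_atoms=n_atoms,
        n_residues=len(residues),
        atom_resindex=np.repeat(np.arange(len(residues)),
                                [len(a) for _, a in residues]),
        residue_segindex=[0] * len(residues),
        trajectory=True,
    )
    u.add_TopologyAttr("name", [n for _, atoms in residues for n in atoms])
    u.add_TopologyAttr("resname", [rn for rn, _ in residues])
    u.add_TopologyAttr("resid", list(range(1, len(residues) + 1)))
    u.add_TopologyAttr("mass", [12.0] * n_atoms)
    base = np.array([xyz for _, atoms in residues for xyz in atoms.values()],
                    dtype=np.float32)
    frames = []
    for t in range(n_frames):
        shift = np.zeros(3, dtype=np.float32)
        if displace is not None:
            shift = np.asarray(displace(t), dtype=np.float32)
        frames.append(base + shift)
    u.load_new(np.stack(frames), order="fac")
    return u


ALA_ATOMS = {
    "N": (0.0, 0.0, 0.0), "CA": (1.5, 0.0, 0.0), "C": (2.2, 1.3, 0.0),
    "O": (3.4, 1.4, 0.0), "CB": (2.1, -0.9, 1.1), "HB1": (2.5, -1.8, 0.7),
}

GLY_ATOMS = {
    "N": (5.0, 0.0, 0.0), "CA": (6.5, 0.0, 0.0), "C": (7.2, 1.3, 0.0),
    "O": (8.4, 1.4, 0.0),
}
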