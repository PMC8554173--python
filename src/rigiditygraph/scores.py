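"""Per-residue rigidity scores and hotspot location classification.

Each residue gets a *characteristic mode* per rigidity graph: the prominent
mode where it carries the most weight, provided that weight is significant
(ν_I² ≥ ν_c²); otherwise the non-prominent mode where it carries the most
weight.  The rigidity score is then κ_I = ⟨r_{I′}⟩·λ_{I′} — the mode's
mechanical strength weighted by its averaged content.  Backbone and
side-chain scores combine the BB/BS/SS graphs:

    κ_I^B = max(κ_I^BB, κ_I^BS)   with κ^BS counted only if the residue
                                  enters its BS mode through its backbone,
    κ_I^S = max(κ_I^SS, κ_I^BS)   with κ^BS counted only via the side chain.

Glycine has no side-chain site; its κ^S is reported as a configured minimal
placeholder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import BACKBONE, NONSKELETON, SIDECHAIN, BsENM
from .graphs import residue_graph, spring_group
from .spectral import (NU_C2, MeanModeStats, ProminentModeSet,
                       mean_mode_content, select_prominent_modes)

LOCATION_CLASSES = ("interior", "periphery", "loop")


def read_ss_labels(path) -> str:
    """Read per-residue H/E/L labels from a text file.

    Accepts one label per line or a single concatenated line; anything that
    is not H or E (e.g. DSSP's G/I/T/S/B/-) is reduced to L.
    """
    from pathlib import Path

    raw = "".join(Path(path).read_text().split())
    reduced = "".join(c if c in "HE" else "L" for c in raw.upper())
    if not reduced:
        raise ValueError(f"no labels found in {path}")
    return reduced


def characteristic_mode(residue: int, stats: MeanModeStats,
                        prominent: ProminentModeSet,
                        nu_c2: float = NU_C2) -> int:
    """The mode that best represents a residue (0-based index).

    Prominent modes are preferred when the residue's squared weight there
    reaches ν_c²; otherwise the best non-prominent mode is used.  Argmax
    ties break toward the smaller mode index.
    """
    weights = stats.spectrum.eigenvectors[residue, :] ** 2
    in_prom = np.zeros(len(weights), dtype=bool)
    in_prom[list(prominent.modes)] = True
    if in_prom.any():
        pi = int(np.flatnonzero(in_prom)[np.argmax(weights[in_prom])])
        if weights[pi] >= nu_c2:
            return pi
    if not (~in_prom).any():
        raise ValueError(
            f"residue {residue}: every mode is prominent and none passes "
            "the weight threshold; no fallback mode exists"
        )
    rest = np.flatnonzero(~in_prom)
    return int(rest[np.argmax(weights[rest])])


def residue_score(residue: int, mode: int, stats: MeanModeStats) -> float:
    """κ_I = ⟨r_{I′}⟩ · λ_{I′} for the residue's characteristic mode."""
    return float(stats.mean_contents[mode] * stats.strengths[mode])


def _bs_mode_side(model: BsENM, residue: int, mode_hotspots: list[int]
                  ) -> tuple[float, float]:
    """Split residue I's non-skeleton BS strength toward a mode's hotspot
    partners into (backbone, side-chain) entry parts.

    Falls back to all BS springs incident to I when no hotspot partner is
    connected.
    """
    partners = set(mode_hotspots) - {residue}

    def _accumulate(restrict: bool) -> tuple[float, float]:
        bb = sc = 0.0
        for s in model.springs:
            if s.category != NONSKELETON or s.k <= 0:
                continue
            si, sj = model.sites[s.i], model.sites[s.j]
            if spring_group(si, sj) != "BS":
                continue
            ri, rj = si.residue_index, sj.residue_index
            if ri == rj:
                continue
            if ri == residue:
                mine, other = si, rj
            elif rj == residue:
                mine, other = sj, ri
            else:
                continue
            if restrict and other not in partners:
                continue
            if mine.site_class == BACKBONE:
                bb += s.k
            else:
                sc += s.k
        return bb, sc

    bb, sc = _accumulate(restrict=True)
    if bb + sc == 0.0:
        bb, sc = _accumulate(restrict=False)
    return bb, sc


def combine_scores(kappa_bb: float, kappa_bs: float, kappa_ss: float,
                   bs_backbone_strength: float, bs_sidechain_strength: float,
                   is_glycine: bool = False, glycine_placeholder: float = 0.0,
                   backbone_fraction_threshold: float = 0.5
                   ) -> tuple[float, float]:
    """Backbone and side-chain scores (κ^B, κ^S) for one residue.

    The BS score competes for the backbone (side-chain) slot only when at
    least ``backbone_fraction_threshold`` of the residue's BS strength toward
    its characteristic-mode partners enters via backbone (side-chain) sites.
    """
    total = bs_backbone_strength + bs_sidechain_strength
    if total > 0:
        f_bb = bs_backbone_strength / total
        via_backbone = f_bb >= backbone_fraction_threshold
        via_sidechain = (1.0 - f_bb) >= backbone_fraction_threshold
    else:
        via_backbone = via_sidechain = False
    kappa_b = max(kappa_bb, kappa_bs if via_backbone else 0.0)
    if is_glycine:
        return kappa_b, glycine_placeholder
    kappa_s = max(kappa_ss, kappa_bs if via_sidechain else 0.0)
    return kappa_b, kappa_s


def classify_location(residue: int, ss_labels: str | list[str],
                      margin: int = 3) -> str:
    """Locate a residue relative to secondary-structure elements.

    ``ss_labels`` is one H/E/L character per residue.  ``interior``: inside a
    helix/strand and more than ``margin`` residues from both of its ends;
    ``periphery``: within ``margin`` residues of an element boundary, inside
    or outside; ``loop``: otherwise.
    """
    labels = list(ss_labels)
    if not 0 <= residue < len(labels):
        raise ValueError("residue index outside label range")
    elements = []
    start = None
    for i, c in enumerate(labels + ["L"]):
        in_el = c in ("H", "E")
        if in_el and start is None:
            start = i
        elif not in_el and start is not None:
            elements.append((start, i - 1))
            start = None
    if not elements:
        return "loop"
    for lo, hi in elements:
        if lo <= residue <= hi:
            if min(residue - lo, hi - residue) > margin:
                return "interior"
            return "periphery"
    dist = min(min(abs(residue - lo), abs(residue - hi)) for lo, hi in elements)
    return "periphery" if dist <= margin else "loop"


@dataclass
class GraphScores:
    """Per-group intermediate results used to assemble the score table."""

    stats: MeanModeStats
    prominent: ProminentModeSet
    char_mode: np.ndarray
    kappa: np.ndarray


def _score_group(windows_K, content_quantile: float, nu_c2: float,
                 n_residues: int) -> GraphScores:
    stats = mean_mode_content(windows_K, matrix_kind="K")
    prominent = select_prominent_modes(stats, content_quantile, nu_c2)
    modes = np.array([characteristic_mode(I, stats, prominent, nu_c2)
                      for I in range(n_residues)])
    kappa = np.array([residue_score(I, m, stats)
                      for I, m in zip(range(n_residues), modes)])
    return GraphScores(stats, prominent, modes, kappa)


def residue_score_table(window_models: list[BsENM],
                        content_quantiles: dict[str, float] | None = None,
                        nu_c2: float = NU_C2,
                        ss_labels: str | None = None,
                        margin: int = 3,
                        glycine_placeholder: float = 0.0) -> pd.DataFrame:
    """Full scoring pipeline over a series of per-window spring networks.

    Builds the non-skeleton BB/BS/SS rigidity graphs for every window,
    extracts prominent modes and characteristic modes, and combines the
    per-graph scores into κ^B and κ^S.  The BS entry-side bookkeeping uses
    the window-averaged model.  Returns one row per residue (1-based labels).
    """
    if not window_models:
        raise ValueError("need at least one window model")
    quantiles = {"BB": 0.75, "BS": 0.75, "SS": 0.68}
    quantiles.update(content_quantiles or {})
    ref = window_models[0]
    n = ref.n_residues
    if ss_labels is not None and len(list(ss_labels)) != n:
        raise ValueError(
            f"{len(list(ss_labels))} secondary-structure labels for {n} residues"
        )

    groups: dict[str, GraphScores] = {}
    for group in ("BB", "BS", "SS"):
        Ks = [residue_graph(m, group, "nonskeleton", window=w).signless_laplacian
              for w, m in enumerate(window_models)]
        groups[group] = _score_group(Ks, quantiles[group], nu_c2, n)

    # window-averaged spring model for the BS contribution ledger
    k_mean = np.mean([m.stiffnesses() for m in window_models], axis=0)
    mean_model = ref.with_stiffnesses(k_mean)

    has_sidechain = np.zeros(n, dtype=bool)
    resnames = [""] * n
    chains = [""] * n
    for s in ref.sites:
        resnames[s.residue_index] = s.resname
        chains[s.residue_index] = s.chain_id
        if s.site_class == SIDECHAIN:
            has_sidechain[s.residue_index] = True
    is_glycine = np.array([(rn == "GLY") or not hs
                           for rn, hs in zip(resnames, has_sidechain)])

    hotspots = set()
    for g in groups.values():
        hotspots |= g.prominent.all_hotspots()

    rows = []
    for I in range(n):
        bs_mode = int(groups["BS"].char_mode[I])
        bs_hot = groups["BS"].prominent.hotspots.get(bs_mode, [])
        bb_str, sc_str = _bs_mode_side(mean_model, I, bs_hot)
        kb, ks = combine_scores(
            groups["BB"].kappa[I], groups["BS"].kappa[I], groups["SS"].kappa[I],
            bb_str, sc_str, is_glycine=bool(is_glycine[I]),
            glycine_placeholder=glycine_placeholder,
        )
        row = {
            "residue": I + 1, "chain": chains[I], "resname": resnames[I],
            "kappa_BB": groups["BB"].kappa[I],
            "kappa_BS": groups["BS"].kappa[I],
            "kappa_SS": (np.nan if is_glycine[I] else groups["SS"].kappa[I]),
            "kappa_B": kb, "kappa_S": ks,
            "char_mode_BB": int(groups["BB"].char_mode[I]) + 1,
            "char_mode_BS": bs_mode + 1,
            "char_mode_SS": int(groups["SS"].char_mode[I]) + 1,
            "glycine": bool(is_glycine[I]),
            "hotspot": I in hotspots,
        }
        if ss_labels is not None:
            row["location"] = classify_location(I, ss_labels, margin)
        rows.append(row)
    return pd.DataFrame(rows)


def hotspot_band(table: pd.DataFrame) -> dict[str, float]:
    """Descriptive hotspot band boundaries in the κ^B–κ^S plane.

    The minimum κ^B and κ^S over hotspot residues (glycines excluded on the
    side-chain axis); a summary of where hotspots live, not a classifier.
    """
    hot = table[table["hotspot"]]
    if hot.empty:
        return {"kappa_B_min": np.nan, "kappa_S_min": np.nan}
    non_gly = hot[~hot["glycine"]]
    return {
        "kappa_B_min": float(hot["kappa_B"].min()),
        "kappa_S_min": float(non_gly["kappa_S"].min()) if len(non_gly) else np.nan,
    }
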