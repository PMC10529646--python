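"""Per-residue dynamic features from pre-aligned coordinate ensembles.

The channel is a homotetramer; dynamic features are computed per residue of
the monomer and averaged over the four symmetric copies. Two quantities are
extracted from a frames × atoms × 3 Cα ensemble:

* RMSF_i = sqrt(mean_f |r_i(f) − ⟨r_i⟩|²), the positional fluctuation (Å);
* anchor covariance rows C_aj = ⟨Δr_a · Δr_j⟩ (Å²), the scalar dot-product
  covariance between a chosen anchor residue (e.g. the pore-lining A316 or
  the pore-helix V278) and every residue j — either within the anchor's own
  monomer ("intra") or in the adjacent monomers ("neighbor", both ring
  neighbors averaged). Optional normalization gives the dimensionless
  cross-correlation C_aj/sqrt(C_aa·C_jj) in [−1, 1].

Frames must be pre-aligned upstream; no superposition is performed here.
SASA fractions and secondary structure are ingested as annotations, not
computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class CoordinateEnsemble:
    """Pre-aligned ensemble of per-residue (Cα) coordinates.

    ``residue_ids`` is a list of (chain, position) labels, one per atom
    column; every chain must carry an identical set of positions.
    """

    coords: np.ndarray  # (F, N, 3) in Å
    residue_ids: list[tuple[str, int]]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (F, N, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("need at least 2 frames")
        if self.coords.shape[1] != len(self.residue_ids):
            raise ValueError("residue_ids length must match coords")
        by_chain = self.positions_by_chain()
        sets = [tuple(v) for v in by_chain.values()]
        if len(set(sets)) != 1:
            raise ValueError("every chain must have an identical residue-position set")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def chains(self) -> list[str]:
        seen: list[str] = []
        for c, _ in self.residue_ids:
            if c not in seen:
                seen.append(c)
        return seen

    def positions_by_chain(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for c, p in self.residue_ids:
            out.setdefault(c, []).append(p)
        return {c: sorted(v) for c, v in out.items()}

    def index_of(self, chain: str, position: int) -> int:
        try:
            return self.residue_ids.index((chain, position))
        except ValueError:
            raise KeyError(f"residue ({chain}, {position}) not in ensemble") from None


def compute_rmsf(ens: CoordinateEnsemble, monomer_average: bool = True) -> pd.Series:
    """Per-residue RMSF (Å); averaged over symmetric chains by default.

    Returns a Series indexed by monomer position (or by (chain, position)
    when ``monomer_average`` is false).
    """
    disp = ens.coords - ens.coords.mean(axis=0, keepdims=True)
    rmsf = np.sqrt(np.mean(np.sum(disp**2, axis=2), axis=0))  # (N,)
    if not monomer_average:
        idx = pd.MultiIndex.from_tuples(ens.residue_ids, names=["chain", "position"])
        return pd.Series(rmsf, index=idx, name="rmsf_A")
    positions = ens.positions_by_chain()[ens.chains[0]]
    acc = np.zeros(len(positions))
    for c in ens.chains:
        cols = [ens.index_of(c, p) for p in positions]
        acc += rmsf[cols]
    return pd.Series(acc / len(ens.chains), index=pd.Index(positions, name="position"),
                     name="rmsf_A")


def compute_anchor_covariance(
    ens: CoordinateEnsemble,
    anchors: Sequence[int],
    mode: str = "intra",
    normalize: bool = False,
) -> pd.DataFrame:
    """Scalar covariance rows ⟨Δr_a·Δr_j⟩ for each anchor position.

    ``mode="intra"`` pairs the anchor with residues of its own chain;
    ``mode="neighbor"`` with residues of both ring-adjacent chains
    (averaged). Rows are averaged across the symmetric (anchor-chain,
    target-chain) pairs. With ``normalize=True`` values are divided by
    sqrt(C_aa·C_jj); zero-variance residues make normalization undefined and
    raise.

    Returns a DataFrame: one row per anchor (index = anchor position),
    columns = monomer positions.
    """
    if mode not in ("intra", "neighbor"):
        raise ValueError("mode must be 'intra' or 'neighbor'")
    chains = ens.chains
    if mode == "neighbor" and len(chains) < 2:
        raise ValueError("neighbor mode needs at least 2 chains")
    positions = ens.positions_by_chain()[chains[0]]
    for a in anchors:
        for c in chains:
            ens.index_of(c, a)  # raises KeyError if absent

    disp = ens.coords - ens.coords.mean(axis=0, keepdims=True)  # (F, N, 3)
    F = ens.n_frames
    col_idx = {c: np.array([ens.index_of(c, p) for p in positions]) for c in chains}

    def cov_row(anchor_chain: str, anchor_pos: int, target_chain: str) -> np.ndarray:
        da = disp[:, ens.index_of(anchor_chain, anchor_pos), :]  # (F, 3)
        dj = disp[:, col_idx[target_chain], :]  # (F, n, 3)
        return np.einsum("fk,fjk->j", da, dj) / F

    out = {}
    var = None
    if normalize:
        var = np.sum(disp**2, axis=(0, 2)) / F  # per-atom ⟨|Δr|²⟩
        if np.any(var[np.concatenate(list(col_idx.values()))] == 0):
            raise ValueError("normalization undefined: zero-variance residue in ensemble")
    for a in anchors:
        acc = np.zeros(len(positions))
        n_pairs = 0
        for ci, c in enumerate(chains):
            if mode == "intra":
                targets = [c]
            else:
                targets = [chains[(ci - 1) % len(chains)], chains[(ci + 1) % len(chains)]]
                targets = list(dict.fromkeys(targets))  # 2 chains: single neighbor
            for tch in targets:
                row = cov_row(c, a, tch)
                if normalize:
                    va = var[ens.index_of(c, a)]
                    vj = var[col_idx[tch]]
                    if va == 0:
                        raise ValueError(f"normalization undefined: anchor {a} has zero variance")
                    row = row / np.sqrt(va * vj)
                acc += row
                n_pairs += 1
        out[a] = acc / n_pairs
    df = pd.DataFrame(out).T
    df.index.name = "anchor"
    df.columns = pd.Index(positions, name="position")
    return df


EXPOSURE_CLASSES = ("WATER", "LIPID", "BORDER", "BURIED")

#: neighbor-search radius for exposure classification, Å
EXPOSURE_CUTOFF_A = 5.0


def classify_exposure(
    residue_coords: np.ndarray,
    residue_positions: Sequence[int],
    water_coords: np.ndarray,
    lipid_coords: np.ndarray,
    cutoff: float = EXPOSURE_CUTOFF_A,
) -> pd.Series:
    """Classify residues by proximity to solvent and membrane.

    A residue within ``cutoff`` of any water atom is WATER-exposed, within
    ``cutoff`` of any lipid atom LIPID-exposed, both makes it BORDER
    (membrane interface) and neither BURIED. ``residue_coords`` may be
    (n, 3) single-atom or a list of per-residue atom arrays.
    """
    water = np.asarray(water_coords, float).reshape(-1, 3)
    lipid = np.asarray(lipid_coords, float).reshape(-1, 3)
    if water.size == 0 and lipid.size == 0:
        raise ValueError("cannot classify exposure: no water or lipid atoms present")
    wtree = cKDTree(water) if water.size else None
    ltree = cKDTree(lipid) if lipid.size else None

    def near(tree, pts) -> bool:
        if tree is None:
            return False
        d, _ = tree.query(pts, k=1)
        return bool(np.min(d) <= cutoff)

    labels = []
    for res in residue_coords:
        pts = np.asarray(res, float).reshape(-1, 3)
        w, l = near(wtree, pts), near(ltree, pts)
        labels.append("BORDER" if (w and l) else "WATER" if w else "LIPID" if l else "BURIED")
    return pd.Series(labels, index=pd.Index(residue_positions, name="position"),
                     name="exposure_class")


def dynamic_feature_table(
    ens: CoordinateEnsemble,
    anchors: Sequence[int],
    anchor_names: Sequence[str] | None = None,
    normalize: bool = False,
) -> pd.DataFrame:
    """Assemble the per-position dynamics block: RMSF plus intra- and
    neighbor-monomer covariance rows for each anchor."""
    rmsf = compute_rmsf(ens)
    names = list(anchor_names) if anchor_names else [f"pos{a}" for a in anchors]
    if len(names) != len(anchors):
        raise ValueError("anchor_names must match anchors")
    blocks = {"rmsf_A": rmsf}
    for a, nm in zip(anchors, names):
        blocks[f"cov_{nm}_intra"] = compute_anchor_covariance(ens, [a], "intra", normalize).loc[a]
        if len(ens.chains) >= 2:
            blocks[f"cov_{nm}_neighbor"] = compute_anchor_covariance(ens, [a], "neighbor", normalize).loc[a]
    return pd.DataFrame(blocks)
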