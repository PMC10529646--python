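"""Synthetic inputs for the BK-channel gating pipeline.

Real inputs to the pipeline are expensive to produce: per-mutation folding
energies come from structure-based ΔΔG protocols on the open and closed
cryo-EM conformations, dynamic features from a 100 ns membrane MD trajectory,
and the ΔV1/2 labels from three decades of patch-clamp work. This module
generates stand-ins for every one of those inputs with the *statistical*
structure the downstream analysis relies on:

* nonuniform positional coverage (mutations concentrate in a designated
  "transmembrane" subset of positions);
* a configurable fraction (default 0.23) of mutations with |ΔV1/2| > 50 mV,
  mirroring the curated experimental dataset;
* a minority of saturated records whose G-V curve could not be measured;
* a planted monotone relationship between a sparse subset of energy terms
  and the true ΔV1/2, passed through a saturating nonlinearity so that tree
  ensembles can recover it while linear baselines underfit;
* 4-fold chain symmetry in coordinate ensembles, with a prescribed
  per-residue fluctuation-amplitude profile and inter-residue couplings.

No attempt is made to emulate an actual molecular force field; values only
carry the declared statistical structure.

All randomness is drawn from ``numpy.random.default_rng`` seeded from the
config; per-mutation latent energies use hashed sub-seeds ``(seed, tag,
position, mutant index)`` so that any subset of mutations — including the
full single-mutation scan — receives identical values regardless of request
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .energetics import EnergyTable
from .ephys import MutationRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Rosetta-style energy-term vocabulary used by the generator. ``ref`` is
#: emitted with identical open/closed contributions so its ΔΔΔG is constant
#: (exactly zero) across mutations — downstream pruning must remove it.
DEFAULT_TERMS: tuple[str, ...] = (
    "fa_atr",
    "fa_rep",
    "fa_sol",
    "fa_elec",
    "fa_mpsolv",
    "fa_dun",
    "hbond_sc",
    "hbond_bb_sc",
    "omega",
    "p_aa_pp",
    "ref",
)

# sub-stream tags (kept < 2**16 so [seed, tag, ...] seed lists stay small ints)
_TAG_DATASET = 11
_TAG_ENERGY = 13
_TAG_CALIBRATE = 17
_TAG_ENSEMBLE = 19
_TAG_GV = 23
_TAG_ANNOT = 29
_TAG_WT = 31


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults mirror the curated experimental dataset: 473 labeled single
    mutations, ~23% of them with |ΔV1/2| > 50 mV, a small minority saturated
    (unmeasurably large shift), coverage concentrated on transmembrane
    positions, and tetrameric (4-fold) ensembles.
    """

    n_positions: int = 200
    n_mutations: int = 473
    frac_large_shift: float = 0.23
    frac_saturated: float = 0.04
    frac_duplicate: float = 0.05
    frac_nonzero_calcium: float = 0.03
    tm_fraction: float = 0.35
    tm_weight: float = 0.80
    signal_features: tuple[str, ...] = ("fa_sol", "fa_atr", "fa_elec", "fa_mpsolv")
    noise_sd: float = 10.0  # mV, replicate-level noise on ΔV1/2
    large_shift_mV: float = 50.0
    n_chains: int = 4
    n_frames: int = 100
    gv_noise_sd: float = 0.0  # SD of additive noise on G/Gmax points
    seed: int = 0
    terms: tuple[str, ...] = DEFAULT_TERMS

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_large_shift <= 1.0:
            raise ValueError("frac_large_shift must be in [0, 1]")
        if not 0.0 <= self.frac_saturated <= 1.0:
            raise ValueError("frac_saturated must be in [0, 1]")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        missing = set(self.signal_features) - set(self.terms)
        if missing:
            raise ValueError(f"signal features not in term vocabulary: {sorted(missing)}")


# ---------------------------------------------------------------------------
# latent model: per-mutation energy perturbations and the planted signal
# ---------------------------------------------------------------------------

_SIGNAL_SD = 2.0   # REU, SD of signal-term ΔΔΔG contributions
_NOISE_TERM_SD = 1.5  # REU, SD of non-signal terms
_INTERACTION = 1.0  # weight of the pairwise interaction between the first two signal terms
_SATURATION_U0 = 3.5  # REU, softness of the saturating nonlinearity


def wt_sequence(config: SyntheticConfig) -> str:
    """Deterministic wild-type sequence of length ``n_positions`` (1-based positions)."""
    rng = np.random.default_rng([config.seed, _TAG_WT])
    return "".join(rng.choice(list(AA20), size=config.n_positions))


def tm_positions(config: SyntheticConfig) -> np.ndarray:
    """Positions designated as transmembrane: a contiguous block starting at 1/5 of the chain."""
    n_tm = max(1, int(round(config.tm_fraction * config.n_positions)))
    start = config.n_positions // 5
    return np.arange(start + 1, min(start + n_tm, config.n_positions) + 1)


def _mutation_energy_row(config: SyntheticConfig, position: int, mut_aa: str) -> np.ndarray:
    """Latent per-term ΔΔΔG (REU) for one mutation; independent of request order."""
    rng = np.random.default_rng([config.seed, _TAG_ENERGY, position, AA20.index(mut_aa)])
    row = np.empty(len(config.terms))
    signal = set(config.signal_features)
    for k, term in enumerate(config.terms):
        if term == "ref":
            row[k] = 0.0
        elif term in signal:
            row[k] = rng.normal(0.0, _SIGNAL_SD)
        else:
            row[k] = rng.normal(0.0, _NOISE_TERM_SD)
    return row


def _signal_value(config: SyntheticConfig, row: np.ndarray) -> float:
    """Planted saturating-additive signal u -> tanh(u / u0)."""
    idx = [config.terms.index(t) for t in config.signal_features]
    x = row[idx]
    u = float(np.sum(x))
    if len(idx) >= 2:
        u += _INTERACTION * x[0] * x[1]
    return float(np.tanh(u / _SATURATION_U0))


def _signal_scale(config: SyntheticConfig) -> float:
    """mV per unit of saturated signal, calibrated so that the population
    fraction of *observed* |ΔV1/2| > large_shift_mV equals frac_large_shift.

    Calibration draws a fixed 20 000-mutation reference sample (signal plus
    measurement noise) from its own sub-stream and root-finds the scale, so
    the scale depends on the config but not on which mutations end up in the
    labeled dataset. Calibrating on the noisy observable matters: the
    saturating nonlinearity piles density just above any fixed quantile of
    the noise-free signal, so noise would otherwise push the realized
    fraction systematically below the target.
    """
    if config.frac_large_shift <= 0.0:
        return config.large_shift_mV  # arbitrary benign scale; nothing exceeds threshold by design
    rng = np.random.default_rng([config.seed, _TAG_CALIBRATE])
    k = len(config.signal_features)
    x = rng.normal(0.0, _SIGNAL_SD, size=(20_000, k))
    u = x.sum(axis=1)
    if k >= 2:
        u = u + _INTERACTION * x[:, 0] * x[:, 1]
    g = np.tanh(u / _SATURATION_U0)
    eps = rng.normal(0.0, config.noise_sd, size=g.shape)
    q = 1.0 - config.frac_large_shift

    def realized(scale: float) -> float:
        return float(np.quantile(np.abs(scale * g + eps), q))

    lo, hi = 1e-6, 10.0 * config.large_shift_mV
    while realized(hi) < config.large_shift_mV and hi < 1e6:
        hi *= 2.0
    for _ in range(80):  # bisection; realized() is monotone in scale
        mid = 0.5 * (lo + hi)
        if realized(mid) < config.large_shift_mV:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def true_delta_v(config: SyntheticConfig, position: int, mut_aa: str) -> float:
    """Noise-free planted ΔV1/2 (mV) for a mutation — the generative truth."""
    row = _mutation_energy_row(config, position, mut_aa)
    return _signal_scale(config) * _signal_value(config, row)


# ---------------------------------------------------------------------------
# labeled mutation dataset
# ---------------------------------------------------------------------------

def generate_mutation_dataset(config: SyntheticConfig) -> list[MutationRecord]:
    """Sample a labeled mutation dataset with the configured coverage structure.

    Returns raw (uncurated) records: duplicates from independent sources,
    saturated records carrying flags instead of numbers, and a few records at
    non-zero Ca2+ that curation must drop. Deterministic in ``config.seed``.
    """
    cfg = config
    if cfg.n_mutations > 19 * cfg.n_positions:
        raise ValueError(
            f"n_mutations={cfg.n_mutations} exceeds the {19 * cfg.n_positions} "
            f"distinct single mutations available on {cfg.n_positions} positions"
        )
    rng = np.random.default_rng([cfg.seed, _TAG_DATASET])
    seq = wt_sequence(cfg)
    tm = set(tm_positions(cfg).tolist())

    positions = np.arange(1, cfg.n_positions + 1)
    weights = np.array([cfg.tm_weight / len(tm) if p in tm else
                        (1.0 - cfg.tm_weight) / (cfg.n_positions - len(tm)) for p in positions])
    weights /= weights.sum()

    chosen: list[tuple[int, str]] = []
    seen: set[tuple[int, str]] = set()
    while len(chosen) < cfg.n_mutations:
        pos = int(rng.choice(positions, p=weights))
        wt = seq[pos - 1]
        mut = str(rng.choice([a for a in AA20 if a != wt]))
        if (pos, mut) in seen:
            continue
        seen.add((pos, mut))
        chosen.append((pos, mut))

    scale = _signal_scale(cfg)
    dv_true = np.array([scale * _signal_value(cfg, _mutation_energy_row(cfg, p, m))
                        for p, m in chosen])
    dv_obs = dv_true + rng.normal(0.0, cfg.noise_sd, size=len(chosen))

    # saturation: the top-|ΔV| records are unmeasurable; direction follows the sign
    n_sat = int(round(cfg.frac_saturated * cfg.n_mutations))
    sat_idx = set(np.argsort(-np.abs(dv_obs))[:n_sat].tolist())

    records: list[MutationRecord] = []
    for i, (pos, mut) in enumerate(chosen):
        primary = bool(rng.random() < 0.5)
        source = "cui_lab" if primary else f"lit:ref{int(rng.integers(86, 110))}"
        if i in sat_idx:
            records.append(MutationRecord(seq[pos - 1], pos, mut, float("nan"),
                                          source=source,
                                          saturated="high" if dv_obs[i] > 0 else "low"))
        else:
            records.append(MutationRecord(seq[pos - 1], pos, mut, float(dv_obs[i]),
                                          source=source))

    # duplicate reports of the same mutation from an independent source
    n_dup = int(round(cfg.frac_duplicate * cfg.n_mutations))
    dup_pool = [i for i in range(len(chosen)) if i not in sat_idx]
    for i in rng.choice(dup_pool, size=min(n_dup, len(dup_pool)), replace=False):
        pos, mut = chosen[i]
        records.append(MutationRecord(seq[pos - 1], pos, mut,
                                      float(dv_obs[i] + rng.normal(0.0, 8.0)),
                                      source=f"lit:ref{int(rng.integers(86, 110))}"))

    # a few higher-Ca2+ measurements that must be excluded from modeling
    n_ca = int(round(cfg.frac_nonzero_calcium * cfg.n_mutations))
    for i in rng.choice(dup_pool, size=min(n_ca, len(dup_pool)), replace=False):
        pos, mut = chosen[i]
        records.append(MutationRecord(seq[pos - 1], pos, mut,
                                      float(dv_obs[i] + rng.normal(0.0, 15.0)),
                                      source="lit:ca", calcium_uM=10.0))
    return records


def true_delta_v_table(config: SyntheticConfig, records: Iterable[MutationRecord]) -> pd.Series:
    """Generative-truth ΔV1/2 for each distinct mutation ID in ``records``."""
    out: dict[str, float] = {}
    for r in records:
        if r.mutation_id not in out:
            out[r.mutation_id] = true_delta_v(config, r.position, r.mut_aa)
    return pd.Series(out, name="true_dV_mV")


# ---------------------------------------------------------------------------
# per-conformation energy tables
# ---------------------------------------------------------------------------

def _parse_mutation_id(mid: str) -> tuple[str, int, str]:
    wt, pos, mut = mid[0], mid[1:-1], mid[-1]
    if wt not in AA20 or mut not in AA20 or not pos.isdigit():
        raise ValueError(f"malformed mutation ID: {mid!r}")
    return wt, int(pos), mut


def generate_energy_tables(
    config: SyntheticConfig, mutation_ids: Sequence[str]
) -> dict[tuple[str, str], EnergyTable]:
    """Per-term folding-energy tables for WT and each mutant in both states.

    Keys are ``(entity, conformation)`` with conformation in {"open",
    "closed"}. Construction guarantees the per-term ΔΔΔG of each mutant
    equals its latent planted row exactly (within squash linearity), and
    that WT self-mutations evaluate to exactly zero.
    """
    if len(mutation_ids) == 0:
        raise ValueError("mutation_ids must be nonempty")
    cfg = config
    seq = wt_sequence(cfg)
    rng = np.random.default_rng([cfg.seed, _TAG_ENERGY, 0])
    terms = list(cfg.terms)
    wt_open = dict(zip(terms, rng.normal(0.0, 2.0, len(terms))))
    wt_closed = dict(zip(terms, rng.normal(0.0, 2.0, len(terms))))
    if "ref" in wt_closed:
        # the reference energy depends only on sequence composition, never on
        # conformation, so it must cancel exactly even through the squashing
        wt_closed["ref"] = wt_open["ref"]

    out: dict[tuple[str, str], EnergyTable] = {
        ("WT", "open"): EnergyTable("WT", "open", wt_open),
        ("WT", "closed"): EnergyTable("WT", "closed", wt_closed),
    }
    for mid in mutation_ids:
        wt, pos, mut = _parse_mutation_id(mid)
        if not 1 <= pos <= cfg.n_positions:
            raise KeyError(f"unknown mutation ID {mid!r}: position outside 1..{cfg.n_positions}")
        if seq[pos - 1] != wt:
            raise KeyError(f"unknown mutation ID {mid!r}: WT residue at {pos} is {seq[pos - 1]}")
        if wt == mut:
            # WT self-mutation: identical copies of the WT tables
            out[(mid, "open")] = EnergyTable(mid, "open", dict(wt_open))
            out[(mid, "closed")] = EnergyTable(mid, "closed", dict(wt_closed))
            continue
        row = _mutation_energy_row(cfg, pos, mut)
        stab_rng = np.random.default_rng([cfg.seed, _TAG_ENERGY, pos, AA20.index(mut), 1])
        stab = stab_rng.normal(0.0, 1.0, len(terms))  # state-independent stability shift
        mo = {t: wt_open[t] + stab[k] + row[k] for k, t in enumerate(terms)}
        mc = {t: wt_closed[t] + stab[k] for k, t in enumerate(terms)}
        if "ref" in mc:
            mc["ref"] = mo["ref"]
        out[(mid, "open")] = EnergyTable(mid, "open", mo)
        out[(mid, "closed")] = EnergyTable(mid, "closed", mc)
    return out


# ---------------------------------------------------------------------------
# coordinate ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSpec:
    """Ground truth of a generated ensemble, for closed-form checks."""

    amplitude: np.ndarray  # per-residue target RMSF, Å (length n_positions)
    couplings: tuple[tuple[int, int, float], ...]  # (pos_i, pos_j, rho) within each chain


def default_amplitude(config: SyntheticConfig) -> np.ndarray:
    """Smooth per-residue RMSF profile between 0.5 and 2.0 Å (loops more mobile)."""
    i = np.arange(config.n_positions)
    return 1.25 + 0.75 * np.sin(2.0 * np.pi * i / max(config.n_positions, 1) * 3.0)


def default_couplings(config: SyntheticConfig) -> tuple[tuple[int, int, float], ...]:
    a = max(1, config.n_positions // 3)
    b = max(1, (2 * config.n_positions) // 3)
    return ((a, min(a + 5, config.n_positions), 0.6),
            (b, min(b + 7, config.n_positions), 0.5))


def generate_ensemble(
    config: SyntheticConfig,
    amplitude: np.ndarray | None = None,
    couplings: Sequence[tuple[int, int, float]] | None = None,
):
    """Pre-aligned synthetic tetramer ensemble of Cα positions.

    Each chain is a copy of the same backbone trace rotated about the z axis
    (exact ``n_chains``-fold symmetry of residue labels). Frame-to-frame
    displacements are zero-mean Gaussians with per-axis SD ``amplitude/√3``,
    so the expected RMSF of residue i is ``amplitude[i]``. For each coupling
    ``(i, j, rho)``, residues i and j within a chain share a latent Gaussian
    so that E[⟨Δr_i·Δr_j⟩] = rho * amplitude_i * amplitude_j.

    Returns a :class:`~bkgating.dynamics.CoordinateEnsemble` plus the
    :class:`EnsembleSpec` ground truth.
    """
    from .dynamics import CoordinateEnsemble

    cfg = config
    n = cfg.n_positions
    amp = default_amplitude(cfg) if amplitude is None else np.asarray(amplitude, float)
    if amp.shape != (n,):
        raise ValueError(f"amplitude profile must have length {n}")
    if np.any(amp < 0):
        raise ValueError("amplitude must be nonnegative")
    coup = tuple(default_couplings(cfg) if couplings is None else couplings)
    for (i, j, rho) in coup:
        if not (1 <= i <= n and 1 <= j <= n):
            raise ValueError(f"coupling positions ({i},{j}) outside 1..{n}")
        if not -1.0 <= rho <= 1.0:
            raise ValueError("coupling rho must be in [-1, 1]")

    rng = np.random.default_rng([cfg.seed, _TAG_ENSEMBLE])
    # base chain trace: gentle helix so chains don't overlap
    t = np.linspace(0, 4 * np.pi, n)
    base = np.stack([18.0 + 3.0 * np.cos(t), 3.0 * np.sin(t), np.linspace(0, 1.5 * n, n)], axis=1)

    sigma = amp / np.sqrt(3.0)
    F, C = cfg.n_frames, cfg.n_chains
    coords = np.empty((F, C * n, 3))
    residue_ids: list[tuple[str, int]] = []
    chains = [chr(ord("A") + c) for c in range(C)]
    for c in range(C):
        theta = 2.0 * np.pi * c / C
        rot = np.array([[np.cos(theta), -np.sin(theta), 0.0],
                        [np.sin(theta), np.cos(theta), 0.0],
                        [0.0, 0.0, 1.0]])
        mean = base @ rot.T
        eps = rng.normal(size=(F, n, 3))
        for (i, j, rho) in coup:
            if rho == 0.0:
                continue
            shared = rng.normal(size=(F, 3))
            s = np.sqrt(abs(rho))
            r = np.sqrt(1.0 - abs(rho))
            eps[:, i - 1, :] = r * eps[:, i - 1, :] + s * shared
            eps[:, j - 1, :] = r * eps[:, j - 1, :] + np.sign(rho) * s * shared
        coords[:, c * n:(c + 1) * n, :] = mean[None, :, :] + sigma[None, :, None] * eps
        residue_ids.extend((chains[c], p) for p in range(1, n + 1))

    ens = CoordinateEnsemble(coords=coords, residue_ids=residue_ids)
    return ens, EnsembleSpec(amplitude=amp, couplings=coup)


# ---------------------------------------------------------------------------
# G-V curves
# ---------------------------------------------------------------------------

DEFAULT_VOLTAGE_GRID = np.arange(-100.0, 301.0, 20.0)


def generate_gv_curves(
    config: SyntheticConfig,
    true_params: Mapping[str, tuple[float, float]],
    voltages: np.ndarray | None = None,
    n_patches: int = 3,
) -> pd.DataFrame:
    """Sample normalized conductance points on a Boltzmann curve per patch.

    ``true_params`` maps mutant_id -> (V1/2 [mV], slope b [mV]). Points are
    G/Gmax = 1/(1+exp((V1/2 - V)/b)) plus N(0, gv_noise_sd) noise. Returns a
    long table (mutant_id, patch_id, voltage_mV, g_over_gmax).
    """
    v = DEFAULT_VOLTAGE_GRID if voltages is None else np.asarray(voltages, float)
    rng = np.random.default_rng([config.seed, _TAG_GV])
    rows = []
    for mutant_id, (v_half, b) in true_params.items():
        if b <= 0:
            raise ValueError(f"slope b must be positive for {mutant_id} (got {b})")
        if not -300.0 <= v_half <= 400.0:
            raise ValueError(f"V1/2 out of range for {mutant_id} (got {v_half})")
        for p in range(n_patches):
            g = 1.0 / (1.0 + np.exp((v_half - v) / b))
            if config.gv_noise_sd > 0:
                g = g + rng.normal(0.0, config.gv_noise_sd, size=v.shape)
            for vi, gi in zip(v, g):
                rows.append((mutant_id, f"{mutant_id}_p{p + 1}", float(vi), float(gi)))
    return pd.DataFrame(rows, columns=["mutant_id", "patch_id", "voltage_mV", "g_over_gmax"])


# ---------------------------------------------------------------------------
# per-residue annotations
# ---------------------------------------------------------------------------

SS_CLASSES = ("H", "E", "C")
EXPOSURE_CLASSES = ("WATER", "LIPID", "BORDER", "BURIED")


def generate_annotations(config: SyntheticConfig) -> pd.DataFrame:
    """Per-position structural/sequence annotations the pipeline ingests.

    Columns: position, ss_class (H/E/C), exposure_class, pore_lining (0/1),
    sasa_pct (percent of a fully exposed reference), conservation (0..1).
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, _TAG_ANNOT])
    tm = set(tm_positions(cfg).tolist())
    pos = np.arange(1, cfg.n_positions + 1)
    ss = np.where(np.isin(pos, list(tm)), "H",
                  rng.choice(SS_CLASSES, size=cfg.n_positions, p=[0.35, 0.2, 0.45]))
    exposure = []
    for p in pos:
        if p in tm:
            exposure.append(str(rng.choice(["LIPID", "BORDER", "BURIED"], p=[0.5, 0.25, 0.25])))
        else:
            exposure.append(str(rng.choice(["WATER", "BURIED"], p=[0.7, 0.3])))
    pore = np.zeros(cfg.n_positions, dtype=int)
    tm_arr = sorted(tm)
    if tm_arr:
        core = tm_arr[len(tm_arr) // 2: len(tm_arr) // 2 + max(1, len(tm_arr) // 6)]
        pore[np.array(core) - 1] = 1
    sasa = np.clip(rng.normal(np.where([p in tm for p in pos], 25.0, 55.0), 15.0), 0.0, 100.0)
    cons = np.clip(rng.beta(2.0, 2.0, size=cfg.n_positions), 0.0, 1.0)
    return pd.DataFrame({
        "position": pos,
        "ss_class": ss,
        "exposure_class": exposure,
        "pore_lining": pore,
        "sasa_pct": np.round(sasa, 2),
        "conservation": np.round(cons, 4),
    })


def enumerate_single_mutations(sequence: str) -> list[str]:
    """All 19·L single-mutation IDs of ``sequence`` (1-based positions)."""
    return [f"{wt}{i}{m}" for i, wt in enumerate(sequence, start=1) for m in AA20 if m != wt]
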