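"""Electrophysiology stage: Boltzmann G-V fits, ΔV1/2, and dataset curation.

The voltage dependence of channel opening is summarized by fitting the
two-parameter Boltzmann function

    G(V)/Gmax = 1 / (1 + exp((V1/2 - V) / b))

to normalized conductance-voltage points from each patch. ``V1/2`` (mV) is
the half-activation voltage and ``b`` (mV) the slope factor; the equivalent
gating charge z is absorbed into b = kT/(ze) and never fitted separately.
A mutation's functional effect is the shift ΔV1/2 = V1/2(mutant) - V1/2(WT).

Curation turns heterogeneous per-source records into one modeling row per
mutation: only nominal 0 μM Ca2+ measurements are kept, saturated (out of
measurable range) records receive the dataset's extreme flag values
(+370 / -300 mV), duplicate reports are reconciled (primary-lab value when
reports agree within 20 mV, mean otherwise), and finally a bounded tanh
squashing caps |ΔV1/2| below 200 mV so that a handful of extreme shifts do
not dominate the regression loss.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: flag values assigned to saturated records: the largest shifts in the dataset
FLAG_HIGH_MV = 370.0
FLAG_LOW_MV = -300.0

#: squashing bound on |ΔV1/2|
DELTA_V_MAX_MV = 200.0

#: duplicate reports within this spread are considered consistent
DUPLICATE_SPREAD_MV = 20.0


@dataclass(frozen=True)
class MutationRecord:
    """One reported mutation measurement (possibly one of several per mutation)."""

    wt_aa: str
    position: int
    mut_aa: str
    delta_v_half: float  # mV; NaN when saturated
    source: str = "unknown"
    saturated: str = "none"  # none | high | low
    calcium_uM: float = 0.0

    def __post_init__(self) -> None:
        if self.wt_aa not in VALID_AA or self.mut_aa not in VALID_AA:
            raise ValueError(f"unknown residue letter in {self.wt_aa}{self.position}{self.mut_aa}")
        if self.position < 1:
            raise ValueError("position must be 1-based positive")
        if self.saturated not in ("none", "high", "low"):
            raise ValueError(f"bad saturation flag {self.saturated!r}")

    @property
    def mutation_id(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"

    @property
    def is_wt_baseline(self) -> bool:
        return self.wt_aa == self.mut_aa


@dataclass
class GVCurve:
    """Normalized conductance-voltage points for one patch."""

    voltages: np.ndarray  # mV, strictly increasing
    conductance_ratios: np.ndarray  # G/Gmax; noisy values slightly outside [0,1] allowed
    patch_id: str = ""
    mutant_id: str = ""

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, float)
        self.conductance_ratios = np.asarray(self.conductance_ratios, float)
        if self.voltages.shape != self.conductance_ratios.shape:
            raise ValueError("voltages and conductance_ratios must have equal length")
        if self.voltages.size < 4:
            raise ValueError("need at least 4 G-V points")
        if np.any(np.diff(self.voltages) <= 0):
            raise ValueError("voltages must be strictly increasing")


@dataclass(frozen=True)
class BoltzmannFit:
    v_half: float  # mV
    slope_b: float  # mV
    v_half_sem: float = 0.0
    slope_sem: float = 0.0
    n_patches: int = 1

    def __post_init__(self) -> None:
        if self.slope_b <= 0:
            raise ValueError("slope_b must be positive")
        if self.v_half_sem < 0 or self.slope_sem < 0:
            raise ValueError("SEMs must be nonnegative")


def boltzmann(v: np.ndarray, v_half: float, b: float) -> np.ndarray:
    """G/Gmax of the two-parameter Boltzmann function."""
    return 1.0 / (1.0 + np.exp((v_half - v) / b))


def _initial_v_half(curve: GVCurve) -> float:
    """Linear interpolation of the half-maximum crossing (robust fit start)."""
    v, g = curve.voltages, curve.conductance_ratios
    above = g >= 0.5
    if above.all() or (~above).all():
        return float(v[np.argmin(np.abs(g - 0.5))])
    i = int(np.argmax(above)) if not above[0] else int(np.argmax(~above))
    i = max(i, 1)
    g0, g1 = g[i - 1], g[i]
    if g1 == g0:
        return float(v[i])
    return float(v[i - 1] + (0.5 - g0) * (v[i] - v[i - 1]) / (g1 - g0))


def fit_boltzmann(curve: GVCurve, init: tuple[float, float] | None = None) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit of one G-V curve.

    Initialization: V1/2 from the interpolated half-maximum crossing and
    b = 25 mV unless ``init`` is given. Bounds: V1/2 in [-300, 400] mV,
    b in (0, 200] mV. Standard errors come from the fit covariance.
    """
    p0 = init if init is not None else (_initial_v_half(curve), 25.0)
    try:
        popt, pcov = curve_fit(
            boltzmann, curve.voltages, curve.conductance_ratios,
            p0=p0, bounds=([-300.0, 1e-6], [400.0, 200.0]), maxfev=10000,
        )
    except RuntimeError as e:  # pragma: no cover - scipy message varies
        raise RuntimeError(f"Boltzmann fit failed for patch {curve.patch_id!r}: {e}") from e
    v_half, b = float(popt[0]), float(popt[1])
    if b <= 0:
        raise RuntimeError(f"non-positive slope fitted for patch {curve.patch_id!r}")
    perr = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    sem = np.where(np.isfinite(perr), perr, 0.0)
    return BoltzmannFit(v_half, b, float(sem[0]), float(sem[1]), n_patches=1)


def aggregate_patches(fits: list[BoltzmannFit]) -> BoltzmannFit:
    """Average fits across patches of one mutant; SEM = sample SD / sqrt(n).

    A single patch is returned unchanged with SEM defined as zero.
    """
    if not fits:
        raise ValueError("no fits to aggregate")
    if len(fits) == 1:
        return replace(fits[0], v_half_sem=0.0, slope_sem=0.0, n_patches=1)
    v = np.array([f.v_half for f in fits])
    b = np.array([f.slope_b for f in fits])
    n = len(fits)
    return BoltzmannFit(
        float(v.mean()), float(b.mean()),
        float(v.std(ddof=1) / math.sqrt(n)), float(b.std(ddof=1) / math.sqrt(n)),
        n_patches=n,
    )


def compute_delta_v(mutant: BoltzmannFit, wt: BoltzmannFit) -> tuple[float, float]:
    """ΔV1/2 = mutant − WT, with SEMs propagated in quadrature."""
    dv = mutant.v_half - wt.v_half
    sem = math.hypot(mutant.v_half_sem, wt.v_half_sem)
    return float(dv), float(sem)


def delta_v_per_patch(mutant_fits: list[BoltzmannFit], wt: BoltzmannFit) -> tuple[float, float]:
    """Patch-wise ΔV averaging: mean over per-patch (mutant − WT) shifts.

    With a single shared WT reference this equals aggregate-then-subtract for
    the mean, but the SEM reflects patch-to-patch spread of the shift itself.
    """
    if not mutant_fits:
        raise ValueError("no mutant fits")
    shifts = np.array([f.v_half - wt.v_half for f in mutant_fits])
    n = len(shifts)
    sem = float(shifts.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return float(shifts.mean()), sem


def squash_delta_v(dv: float, v_max: float = DELTA_V_MAX_MV) -> float:
    """Bounded tanh squashing s(x) = v_max·tanh(x/v_max).

    Odd, strictly monotone, |s| < v_max; nearly the identity for
    |x| ≲ 100 mV at the default bound.
    """
    if v_max <= 0:
        raise ValueError("v_max must be positive")
    if not np.isfinite(dv):
        raise ValueError("dv must be finite")
    return float(v_max * math.tanh(dv / v_max))


def curate_dataset(
    records: list[MutationRecord],
    primary_source_tag: str = "cui_lab",
    v_max: float = DELTA_V_MAX_MV,
    spread_mV: float = DUPLICATE_SPREAD_MV,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reduce raw records to one modeling row per mutation.

    Rules, in order: keep only 0 μM Ca2+ records; saturated records take the
    flag values +370 / -300 mV (conflicting directions for one mutation are
    an error); duplicates with spread <= ``spread_mV`` keep the primary-source
    value when present (mean of primaries if several) else the mean, spread
    > ``spread_mV`` always the mean; squashing is applied last.

    Returns ``(table, audit)``: the curated table (one row per mutation) and
    an audit log tracing every output row to its input records.
    """
    kept = [r for r in records if r.calcium_uM == 0.0]
    groups: dict[str, list[MutationRecord]] = {}
    for r in kept:
        groups.setdefault(r.mutation_id, []).append(r)

    rows, audit = [], []
    for mid in groups:
        grp = groups[mid]
        sat_dirs = {r.saturated for r in grp if r.saturated != "none"}
        if len(sat_dirs) > 1:
            srcs = sorted(r.source for r in grp if r.saturated != "none")
            raise ValueError(f"conflicting saturation directions for {mid}: sources {srcs}")
        if sat_dirs:
            direction = sat_dirs.pop()
            dv = FLAG_HIGH_MV if direction == "high" else FLAG_LOW_MV
            rule = f"saturated-{direction}-flag"
        else:
            vals = np.array([r.delta_v_half for r in grp], float)
            if len(vals) == 1:
                dv, rule = float(vals[0]), "single"
            else:
                spread = float(vals.max() - vals.min())
                primaries = [r.delta_v_half for r in grp if r.source == primary_source_tag]
                if spread <= spread_mV and primaries:
                    dv, rule = float(np.mean(primaries)), "duplicate-primary"
                else:
                    dv = float(vals.mean())
                    rule = "duplicate-mean-small-spread" if spread <= spread_mV else "duplicate-mean-large-spread"
        r0 = grp[0]
        saturated = "none" if not sat_dirs and all(r.saturated == "none" for r in grp) else \
            next((r.saturated for r in grp if r.saturated != "none"), "none")
        rows.append({
            "mutation": mid, "wt_aa": r0.wt_aa, "position": r0.position, "mut_aa": r0.mut_aa,
            "dV_mV": dv, "dV_squashed_mV": squash_delta_v(dv, v_max),
            "saturated": saturated, "n_records": len(grp),
        })
        audit.append({
            "mutation": mid, "rule": rule, "n_records": len(grp),
            "sources": ";".join(r.source for r in grp),
            "raw_values": ";".join("NA" if not np.isfinite(r.delta_v_half) else f"{r.delta_v_half:.3f}" for r in grp),
            "final_dV_mV": dv,
        })

    table = pd.DataFrame(rows).sort_values(["position", "mutation"]).reset_index(drop=True)
    if not table.empty and table["mutation"].duplicated().any():  # defensive; grouping prevents this
        raise AssertionError("curated table has duplicate mutation IDs")
    return table, pd.DataFrame(audit)
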