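"""Conformational-pair energy scoring: per-term and total ΔΔΔG.

A mutation's bias on the open-closed gating equilibrium is quantified from
four folding-energy evaluations (WT/mutant × open/closed conformation):

    ΔΔΔG = (ΔG_fold^open − ΔG_fold^closed)_mutant − (ΔG_fold^open − ΔG_fold^closed)_WT

Positive ΔΔΔG destabilizes the open state relative to WT. Because the score
function is pairwise additive the same formula applies per energy term,
giving a decomposition into physical contributions (dispersion, repulsion,
solvation, membrane transfer, ...).

Raw scores are squashed with a bounded tanh, s(x) = Emax·tanh(x/Emax) with
Emax = 50 REU, *before* differencing, so unphysically large clash energies
cannot dominate the differences. ΔΔΔG itself is stored unsquashed.
Squashing of inputs deliberately breaks exact per-term additivity of the
total outside the linear regime (|score| ≲ 25 REU).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: bound of the score squashing, Rosetta energy units
E_MAX_REU = 50.0

CONFORMATIONS = ("open", "closed")


@dataclass
class EnergyTable:
    """Per-term folding energy of one entity (WT or a mutant) in one conformation."""

    entity: str
    conformation: str
    terms: dict[str, float]
    total: float | None = None  # defaults to the sum of terms

    def __post_init__(self) -> None:
        if self.conformation not in CONFORMATIONS:
            raise ValueError(f"conformation must be one of {CONFORMATIONS}")
        if not self.terms:
            raise ValueError("terms must be nonempty")
        s = float(sum(self.terms.values()))
        if self.total is None:
            self.total = s
        elif abs(self.total - s) > 1e-6:
            raise ValueError(
                f"total {self.total} differs from term sum {s} for {self.entity}/{self.conformation}"
            )


@dataclass
class DddgRecord:
    mutation_id: str
    terms: dict[str, float]
    total: float


def squash_score(score: float, e_max: float = E_MAX_REU) -> float:
    """s(x) = e_max·tanh(x/e_max); bounded in (−e_max, e_max)."""
    if e_max <= 0:
        raise ValueError("e_max must be positive")
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    return float(e_max * math.tanh(score / e_max))


def _check_vocab(tables: Sequence[EnergyTable]) -> list[str]:
    vocabs = [set(t.terms) for t in tables]
    common = vocabs[0]
    if any(v != common for v in vocabs[1:]):
        sym = set()
        for v in vocabs[1:]:
            sym |= common ^ v
        raise ValueError(f"mismatched term vocabularies; symmetric difference: {sorted(sym)}")
    # stable order: as declared in the first table
    return list(tables[0].terms)


def compute_dddg(
    wt_open: EnergyTable,
    wt_closed: EnergyTable,
    mut_open: EnergyTable,
    mut_closed: EnergyTable,
    squash: bool = True,
    squash_terms: bool = True,
    e_max: float = E_MAX_REU,
) -> DddgRecord:
    """Evaluate ΔΔΔG per term and in total for one mutation.

    When ``squash`` is true, input scores are squashed before differencing;
    ``squash_terms=False`` restricts squashing to the totals only. The total
    ΔΔΔG is computed from the (squashed) table totals, not by summing
    per-term ΔΔΔGs, so the two agree only in the linear regime.
    """
    order = _check_vocab([wt_open, wt_closed, mut_open, mut_closed])

    def s(x: float, is_term: bool) -> float:
        if not squash or (is_term and not squash_terms):
            return float(x)
        return squash_score(x, e_max)

    terms = {
        t: (s(mut_open.terms[t], True) - s(mut_closed.terms[t], True))
        - (s(wt_open.terms[t], True) - s(wt_closed.terms[t], True))
        for t in order
    }
    total = (s(mut_open.total, False) - s(mut_closed.total, False)) \
        - (s(wt_open.total, False) - s(wt_closed.total, False))
    return DddgRecord(mut_open.entity, terms, float(total))


def dddg_matrix(
    tables: Mapping[tuple[str, str], EnergyTable],
    mutations: Iterable[str],
    wt_positions: Mapping[int, str] | None = None,
    squash: bool = True,
    squash_terms: bool = True,
    e_max: float = E_MAX_REU,
) -> tuple[pd.DataFrame, list[str]]:
    """ΔΔΔG records for every requested mutation plus WT self-mutation baselines.

    ``tables`` is keyed by ``(entity, conformation)`` and must contain the WT
    pair. ``wt_positions`` maps position -> WT residue; when given, one
    baseline row (e.g. A316A, exactly zero by construction) is emitted per
    position. Mutations whose tables are absent are reported in the second
    return value, never silently skipped.

    Returns a wide DataFrame indexed by mutation ID (term columns + 'total')
    and the list of missing mutation IDs.
    """
    if ("WT", "open") not in tables or ("WT", "closed") not in tables:
        raise ValueError("WT tables for both conformations are required")
    wt_o, wt_c = tables[("WT", "open")], tables[("WT", "closed")]

    rows: dict[str, dict[str, float]] = {}
    missing: list[str] = []
    for mid in mutations:
        if (mid, "open") not in tables or (mid, "closed") not in tables:
            missing.append(mid)
            continue
        rec = compute_dddg(wt_o, wt_c, tables[(mid, "open")], tables[(mid, "closed")],
                           squash=squash, squash_terms=squash_terms, e_max=e_max)
        rows[mid] = {**rec.terms, "total": rec.total}

    if wt_positions is not None:
        for pos, aa in wt_positions.items():
            mid = f"{aa}{pos}{aa}"
            rec = compute_dddg(wt_o, wt_c, wt_o, wt_c,
                               squash=squash, squash_terms=squash_terms, e_max=e_max)
            rows[mid] = {**rec.terms, "total": rec.total}

    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "mutation"
    return df, missing
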