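"""Readers and writers for the pipeline's table and structure formats.

Tabular formats are plain CSV/TSV (comma or tab, UTF-8, header row):

* mutation table: ``mutation, dV_mV, source, saturated, calcium_uM``;
* G-V points: TSV ``mutant_id, patch_id, voltage_mV, g_over_gmax``;
* energy tables: long CSV ``entity, conformation, term, score_REU``;
* ΔΔΔG: wide CSV, one row per mutation, one column per term plus total;
* per-residue features/annotations: CSV keyed by ``position``.

Coordinate ensembles round-trip through multi-model PDB (Cα pseudo-atoms,
one MODEL per frame) via Biopython; per-residue score maps are written into
the B-factor column of a single-model PDB.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser, PDBIO
from Bio.PDB.Structure import Structure
from Bio.PDB.Model import Model
from Bio.PDB.Chain import Chain
from Bio.PDB.Residue import Residue
from Bio.PDB.Atom import Atom

from .energetics import CONFORMATIONS, EnergyTable
from .ephys import VALID_AA, MutationRecord

MUTATION_COLUMNS = ["mutation", "dV_mV", "source", "saturated", "calcium_uM"]


def parse_mutation_string(s: str) -> tuple[str, int, str]:
    """Split e.g. 'L235F' into ('L', 235, 'F'); raises on malformed input."""
    s = s.strip()
    if len(s) < 3 or s[0] not in VALID_AA or s[-1] not in VALID_AA or not s[1:-1].isdigit():
        raise ValueError(f"malformed mutation string {s!r}")
    return s[0], int(s[1:-1]), s[-1]


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Parse and validate a mutation table (CSV or TSV by extension).

    Saturated records may leave ``dV_mV`` empty. Errors name the offending
    line number.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    if list(df.columns) != MUTATION_COLUMNS:
        if len(df.columns) != len(set(df.columns)):
            raise ValueError(f"{path}: duplicated header column")
        raise ValueError(f"{path}: expected columns {MUTATION_COLUMNS}, got {list(df.columns)}")
    records = []
    for i, row in df.iterrows():
        line = i + 2  # 1-based, after the header
        try:
            wt, pos, mut = parse_mutation_string(str(row["mutation"]))
            sat = (row["saturated"] or "none").strip() if isinstance(row["saturated"], str) else "none"
            dv_raw = row["dV_mV"]
            dv = float("nan") if (not isinstance(dv_raw, str) or dv_raw.strip() == "") \
                else float(dv_raw)
            if sat == "none" and not np.isfinite(dv):
                raise ValueError("missing dV_mV on an unsaturated record")
            records.append(MutationRecord(
                wt, pos, mut, dv,
                source=str(row["source"]).strip(),
                saturated=sat,
                calcium_uM=float(row["calcium_uM"]),
            ))
        except (ValueError, KeyError) as e:
            raise ValueError(f"{path}, line {line}: {e}") from e
    return records


def write_mutation_table(records: Sequence[MutationRecord], path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.DataFrame({
        "mutation": [r.mutation_id for r in records],
        "dV_mV": ["" if not np.isfinite(r.delta_v_half) else f"{r.delta_v_half:.4f}"
                  for r in records],
        "source": [r.source for r in records],
        "saturated": [r.saturated for r in records],
        "calcium_uM": [r.calcium_uM for r in records],
    })
    df.to_csv(path, sep=sep, index=False)


# -- G-V points --------------------------------------------------------------

GV_COLUMNS = ["mutant_id", "patch_id", "voltage_mV", "g_over_gmax"]


def read_gv_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != GV_COLUMNS:
        raise ValueError(f"{path}: expected columns {GV_COLUMNS}, got {list(df.columns)}")
    return df


def write_gv_table(df: pd.DataFrame, path: str | Path) -> None:
    df[GV_COLUMNS].to_csv(path, sep="\t", index=False)


# -- energy tables -----------------------------------------------------------

def read_energy_tables(path: str | Path) -> dict[tuple[str, str], EnergyTable]:
    """Long CSV (entity, conformation, term, score_REU) -> EnergyTable map."""
    df = pd.read_csv(path)
    expected = ["entity", "conformation", "term", "score_REU"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    out: dict[tuple[str, str], EnergyTable] = {}
    for (entity, conf), grp in df.groupby(["entity", "conformation"], sort=False):
        if conf not in CONFORMATIONS:
            raise ValueError(f"{path}: unknown conformation {conf!r} for {entity}")
        out[(entity, conf)] = EnergyTable(entity, conf,
                                          dict(zip(grp["term"], grp["score_REU"].astype(float))))
    return out


def write_energy_tables(tables: Mapping[tuple[str, str], EnergyTable],
                        path: str | Path) -> None:
    rows = [
        {"entity": t.entity, "conformation": t.conformation, "term": term, "score_REU": score}
        for t in tables.values() for term, score in t.terms.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# -- ensembles: multi-model PDB ----------------------------------------------

def write_ensemble_pdb(ens, path: str | Path) -> None:
    """Write a CoordinateEnsemble as a multi-model Cα-only PDB file."""
    structure = Structure("ens")
    for f in range(ens.n_frames):
        model = Model(f, serial_num=f + 1)
        chains: dict[str, Chain] = {}
        for i, (chain_id, pos) in enumerate(ens.residue_ids):
            if chain_id not in chains:
                chains[chain_id] = Chain(chain_id)
                model.add(chains[chain_id])
            res = Residue((" ", pos, " "), "ALA", "")
            atom = Atom("CA", ens.coords[f, i], 0.0, 1.0, " ", " CA ", i + 1, "C")
            res.add(atom)
            chains[chain_id].add(res)
        structure.add(model)
    io = PDBIO()
    io.set_structure(structure)
    io.save(str(path))


def read_ensemble_pdb(path: str | Path):
    """Read a multi-model Cα PDB back into a CoordinateEnsemble."""
    from .dynamics import CoordinateEnsemble

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PDB numbering warnings on pseudo-structures
        structure = PDBParser(QUIET=True).get_structure("ens", str(path))
    models = list(structure)
    if len(models) < 2:
        raise ValueError(f"{path}: need at least 2 MODEL records")
    residue_ids: list[tuple[str, int]] = []
    frames = []
    for mi, model in enumerate(models):
        ids, xyz = [], []
        for chain in model:
            for res in chain:
                ca = res["CA"]
                ids.append((chain.id, res.id[1]))
                xyz.append(ca.coord)
        if mi == 0:
            residue_ids = ids
        elif ids != residue_ids:
            raise ValueError(f"{path}: residue layout differs between models")
        frames.append(np.asarray(xyz, float))
    return CoordinateEnsemble(coords=np.stack(frames), residue_ids=residue_ids)


def write_bfactor_pdb(
    structure_path: str | Path, values: Mapping[int, float], out_path: str | Path,
    strict: bool = False,
) -> None:
    """Write a copy of a PDB with per-residue values in the B-factor column.

    ``values`` maps residue position -> value; untouched residues get 0.
    Values are clamped to the fixed-width PDB field range [-999.99, 999.99].
    ``strict`` errors when a value's position is absent from the structure.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(structure_path))
    model = next(iter(structure))
    present = {res.id[1] for chain in model for res in chain}
    missing = set(values) - present
    if strict and missing:
        raise ValueError(f"positions not in structure: {sorted(missing)}")
    for chain in model:
        for res in chain:
            b = float(np.clip(values.get(res.id[1], 0.0), -999.99, 999.99))
            for atom in res:
                atom.bfactor = b
    io = PDBIO()
    io.set_structure(model)
    io.save(str(out_path))


def read_bfactor_map(path: str | Path) -> dict[int, float]:
    """Per-residue B-factor (first atom per residue) from a PDB file."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    out: dict[int, float] = {}
    for chain in next(iter(structure)):
        for res in chain:
            atom = next(iter(res))
            out.setdefault(res.id[1], float(atom.bfactor))
    return out
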