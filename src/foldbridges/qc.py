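"""Domain-quality filters applied before scoring and calibration.

Three rules: drop domains with an ASTRAL aerospaci quality score below 0.4,
drop domains whose coordinate files contain only C-alpha atoms, and drop
domains with one or more chain breaks (successive C-alpha atoms further
than 4.3 A apart).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_AEROSPACI_MIN = 0.4
DEFAULT_GAP_THRESHOLD = 4.3  # Angstrom; strictly greater counts as a break


@dataclass(frozen=True)
class DomainRecord:
    domain_id: str
    scop_class: str
    fold: str
    superfamily: str = ""
    family: str = ""
    aerospaci: float = float("nan")
    calpha_only: bool = False
    has_chain_break: bool = False

    def __post_init__(self):
        prefix = self.fold.split(".")[0]
        if prefix != self.scop_class:
            raise ValueError(
                f"fold {self.fold!r} does not match class {self.scop_class!r}"
            )


def filter_by_quality(
    records: pd.DataFrame, aerospaci_min: float = DEFAULT_AEROSPACI_MIN
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove records with aerospaci < aerospaci_min.

    Returns (retained, rejection_log); the log states the rule applied per
    removal.  A missing aerospaci value is an error, never a silent pass.
    """
    if "aerospaci" not in records.columns:
        raise ValueError("records lack an 'aerospaci' column")
    if records["aerospaci"].isna().any():
        bad = records.loc[records["aerospaci"].isna(), "domain_id"].tolist()
        raise ValueError(f"aerospaci missing for domains: {bad[:10]}")
    reject = records["aerospaci"] < aerospaci_min
    log = records.loc[reject, ["domain_id", "aerospaci"]].copy()
    log["rule"] = [
        f"aerospaci {v} < {aerospaci_min}" for v in log["aerospaci"]
    ]
    return records.loc[~reject].reset_index(drop=True), log.reset_index(drop=True)


def detect_chain_breaks(
    coords: np.ndarray, gap_threshold: float = DEFAULT_GAP_THRESHOLD
) -> list[int]:
    """Indices i where consecutive C-alpha atoms i, i+1 are > gap_threshold apart."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be an (n, 3) array of C-alpha positions")
    if coords.shape[0] < 2:
        warnings.warn("fewer than 2 residues; no chain breaks assessable")
        return []
    gaps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
    return np.flatnonzero(gaps > gap_threshold).tolist()


def read_calpha_coordinates(pdb_path) -> tuple[np.ndarray, bool]:
    """C-alpha coordinates and a C-alpha-only flag from a PDB file.

    Parsed with Bio.PDB; the first altloc is taken and residue order is
    honoured as given.  ``calpha_only`` is True when no residue carries any
    heavy atom besides CA.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("domain", str(pdb_path))
    coords = []
    calpha_only = True
    for model in structure:
        for chain in model:
            for residue in chain:
                atoms = {a.get_name(): a for a in residue}
                if any(name != "CA" for name in atoms):
                    calpha_only = False
                if "CA" in atoms:
                    coords.append(atoms["CA"].get_coord())
        break  # first model only
    return np.asarray(coords, dtype=float), calpha_only


def qc_domain(pdb_path, gap_threshold: float = DEFAULT_GAP_THRESHOLD) -> dict:
    """QC verdict for one coordinate file.

    A domain is flagged for omission when it is C-alpha-only or has at least
    one chain break.
    """
    coords, calpha_only = read_calpha_coordinates(pdb_path)
    breaks = detect_chain_breaks(coords, gap_threshold)
    return {
        "n_residues": int(coords.shape[0]),
        "calpha_only": calpha_only,
        "chain_breaks": breaks,
        "keep": (not calpha_only) and not breaks,
    }


def apply_qc(
    records: pd.DataFrame,
    coordinate_dir=None,
    aerospaci_min: float = DEFAULT_AEROSPACI_MIN,
    gap_threshold: float = DEFAULT_GAP_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full QC pass: aerospaci filter plus structural checks when coordinates exist.

    ``coordinate_dir`` may hold ``<domain_id>.pdb`` files; domains without a
    file skip the structural checks.  Returns (retained, rejection_log).
    """
    retained, log = filter_by_quality(records, aerospaci_min)
    if coordinate_dir is None:
        return retained, log
    import pathlib

    cdir = pathlib.Path(coordinate_dir)
    drop = []
    extra = []
    for row in retained.itertuples(index=False):
        path = cdir / f"{row.domain_id}.pdb"
        if not path.exists():
            continue
        verdict = qc_domain(path, gap_threshold)
        if not verdict["keep"]:
            drop.append(row.domain_id)
            rule = (
                "calpha-only coordinates"
                if verdict["calpha_only"]
                else f"chain break(s) at {verdict['chain_breaks']} (> {gap_threshold} A)"
            )
            extra.append({"domain_id": row.domain_id, "aerospaci": getattr(row, "aerospaci", np.nan), "rule": rule})
    retained = retained[~retained["domain_id"].isin(drop)].reset_index(drop=True)
    log = pd.concat([log, pd.DataFrame(extra, columns=["domain_id", "aerospaci", "rule"])], ignore_index=True)
    return retained, log
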