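"""HDX-MS peptide-table utilities.

Implements the peptide inclusion criteria used for hydrogen/deuterium
exchange analysis of protein-membrane binding, sequence-coverage
computation over the retained peptides, and per-peptide deuterium
uptake differences between states (e.g. apo versus membrane-bound).
Decreased uptake in the presence of membranes indicates protection —
a candidate membrane-binding region.

Threshold boundaries are inclusive: "a minimum intensity of 5000"
admits exactly 5000 and "a maximum MH+ error of 5 ppm" admits exactly
5.  No spectral processing happens here; inputs are vendor-style state
exports as CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

log = logging.getLogger("guvkin")


@dataclass
class HDXPeptide:
    """One identified peptide and its per-state deuterium uptake.

    ``start``/``end`` are 1-based inclusive residue numbers;
    ``uptake`` maps (state, exposure_s) -> deuterons.
    """

    protein: str
    sequence: str
    start: int
    end: int
    max_intensity: float
    products_per_aa: float
    mh_error_ppm: float
    n_identifications: int
    uptake: Dict[Tuple[str, float], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad residue range {self.start}-{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} != span "
                f"{self.end - self.start + 1} for {self.sequence!r}"
            )
        if self.products_per_aa < 0:
            raise ValueError("products_per_aa must be >= 0")
        mx = self.max_uptake
        for key, val in self.uptake.items():
            if val < 0 or val > mx + 1e-9:
                raise ValueError(
                    f"uptake {val} outside [0, {mx}] for {self.sequence!r} at {key}"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def max_uptake(self) -> int:
        """Theoretical maximum exchangeable amides.

        The N-terminal residue back-exchanges instantly and prolines
        carry no amide hydrogen, so the maximum is
        length - 1 - (prolines after the first position).
        """
        return self.length - 1 - self.sequence[1:].count("P")


@dataclass
class FilterCriteria:
    """Peptide inclusion thresholds (all boundaries inclusive)."""

    min_intensity: float = 5000.0
    min_length: int = 5
    min_products_per_aa: float = 0.1
    max_mh_error_ppm: float = 5.0
    min_identifications: int = 2
    n_files: int = 3

    def __post_init__(self) -> None:
        if min(
            self.min_intensity, self.min_length, self.min_products_per_aa,
            self.max_mh_error_ppm, self.min_identifications,
        ) <= 0:
            raise ValueError("all thresholds must be positive")


def filter_peptides(
    peptides: Sequence[HDXPeptide], criteria: Optional[FilterCriteria] = None
) -> Tuple[List[HDXPeptide], List[Tuple[HDXPeptide, List[str]]]]:
    """Split peptides into kept and rejected-with-reasons.

    A peptide is kept iff it meets every criterion; each rejected
    peptide is returned with the full list of violated criteria.
    """
    criteria = criteria or FilterCriteria()
    kept: List[HDXPeptide] = []
    rejected: List[Tuple[HDXPeptide, List[str]]] = []
    for p in peptides:
        reasons = []
        if p.max_intensity < criteria.min_intensity:
            reasons.append("intensity")
        if p.length < criteria.min_length:
            reasons.append("length")
        if p.products_per_aa < criteria.min_products_per_aa:
            reasons.append("products_per_aa")
        if abs(p.mh_error_ppm) > criteria.max_mh_error_ppm:
            reasons.append("mh_error")
        if p.n_identifications < criteria.min_identifications:
            reasons.append("identifications")
        if reasons:
            rejected.append((p, reasons))
        else:
            kept.append(p)
    log.info("kept %d / %d peptides", len(kept), len(peptides))
    return kept, rejected


def sequence_coverage(peptides: Sequence[HDXPeptide], protein_length: int) -> float:
    """Percent of residues covered by the union of peptide spans."""
    covered = set()
    for p in peptides:
        if p.end > protein_length:
            raise ValueError(
                f"peptide {p.sequence!r} ends at {p.end} > protein length {protein_length}"
            )
        covered.update(range(p.start, p.end + 1))
    return 100.0 * len(covered) / protein_length


@dataclass
class UptakeDifference:
    """Per-exposure uptake difference (state_b - state_a) of one peptide."""

    peptide: HDXPeptide
    state_a: str
    state_b: str
    differences: Dict[float, float]  # exposure_s -> delta deuterons
    classification: str  # "protected" | "deprotected" | "no change"


def uptake_difference(
    peptide: HDXPeptide,
    state_a: str,
    state_b: str,
    delta_da: float = 0.5,
    min_exposures: int = 1,
) -> UptakeDifference:
    """Uptake differences between two states over shared exposures.

    The peptide is classified "protected" when the difference drops
    below ``-delta_da`` at >= ``min_exposures`` exposures (state_b
    exchanges less — e.g. shielded by membrane binding), "deprotected"
    for the symmetric case, else "no change".  The numeric threshold is
    an explicit configuration choice, 0.5 Da by default.
    """
    exp_a = {e for s, e in peptide.uptake if s == state_a}
    exp_b = {e for s, e in peptide.uptake if s == state_b}
    shared = sorted(exp_a & exp_b)
    if not shared:
        raise ValueError(
            f"no shared exposures between {state_a!r} and {state_b!r}"
        )
    diffs = {
        e: peptide.uptake[(state_b, e)] - peptide.uptake[(state_a, e)] for e in shared
    }
    n_prot = sum(1 for d in diffs.values() if d < -delta_da)
    n_deprot = sum(1 for d in diffs.values() if d > delta_da)
    if n_prot >= min_exposures and n_prot >= n_deprot:
        cls = "protected"
    elif n_deprot >= min_exposures:
        cls = "deprotected"
    else:
        cls = "no change"
    return UptakeDifference(peptide, state_a, state_b, diffs, cls)


# ---------------------------------------------------------------------------
# CSV dialect


PEPTIDE_COLUMNS = [
    "protein", "sequence", "start", "end",
    "max_intensity", "products_per_aa", "mh_error_ppm", "n_identifications",
]
UPTAKE_COLUMNS = ["protein", "start", "end", "state", "exposure_s", "uptake_da"]


def read_peptides_csv(
    path: Union[str, Path], uptake_path: Optional[Union[str, Path]] = None
) -> List[HDXPeptide]:
    """Read a peptide table, optionally joined with a long uptake table."""
    df = pd.read_csv(path)
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    uptake_by_key: Dict[Tuple[str, int, int], Dict[Tuple[str, float], float]] = {}
    if uptake_path is not None:
        up = pd.read_csv(uptake_path)
        for row in up.itertuples(index=False):
            key = (str(row.protein), int(row.start), int(row.end))
            uptake_by_key.setdefault(key, {})[(str(row.state), float(row.exposure_s))] = float(
                row.uptake_da
            )
    peptides = []
    for row in df.itertuples(index=False):
        key = (str(row.protein), int(row.start), int(row.end))
        peptides.append(
            HDXPeptide(
                protein=str(row.protein),
                sequence=str(row.sequence),
                start=int(row.start),
                end=int(row.end),
                max_intensity=float(row.max_intensity),
                products_per_aa=float(row.products_per_aa),
                mh_error_ppm=float(row.mh_error_ppm),
                n_identifications=int(row.n_identifications),
                uptake=uptake_by_key.get(key, {}),
            )
        )
    return peptides


def peptides_to_frame(peptides: Sequence[HDXPeptide]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein": p.protein, "sequence": p.sequence,
                "start": p.start, "end": p.end,
                "max_intensity": p.max_intensity,
                "products_per_aa": p.products_per_aa,
                "mh_error_ppm": p.mh_error_ppm,
                "n_identifications": p.n_identifications,
            }
            for p in peptides
        ],
        columns=PEPTIDE_COLUMNS,
    )
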