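"""Absolute protein quantification via a spike-in calibration curve.

Label-free protein signals are divided by the protein's average
molecular weight (normalizing for the number of peptides longer
proteins yield), spike-in standard amounts (fmol) are converted to
molecule counts via Avogadro's number, and an ordinary least-squares
line of log10(signal/MW) on log10(molecules) is fitted to the
standards. Inverting that line converts any protein's MW-normalized
signal into molecules, and division by the number of cells analysed
gives copies per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass
from scipy import stats

AVOGADRO = 6.02214076e23

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_N_CELLS = 1_200_000  # cells labelled per pull-down reaction


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS fit of log10(signal/MW) on log10(molecules)."""

    slope: float
    intercept: float
    r_squared: float
    points: tuple[tuple[float, float], ...]  # (log10_molecules, log10_signal_per_mw)

    @property
    def n_points(self) -> int:
        return len(self.points)


def protein_mw(sequence: str) -> float:
    """Average (not monoisotopic) molecular weight in Daltons."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    bad = set(sequence) - _STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)!r}")
    return float(_pmass.calculate_mass(sequence=sequence, average=True))


def mw_normalize(lfq_signal: float, mw_da: float) -> float:
    """Signal per Dalton: LFQ signal divided by molecular weight."""
    if mw_da <= 0:
        raise ValueError("mw_da must be positive")
    if lfq_signal < 0:
        raise ValueError("lfq_signal must be non-negative")
    return lfq_signal / mw_da


def amount_to_molecules(amount_fmol: float) -> float:
    """Molecule count of an amount in femtomoles."""
    if amount_fmol < 0:
        raise ValueError("amount must be non-negative")
    return amount_fmol * 1e-15 * AVOGADRO


def fit_calibration(
    signal_per_mw,
    molecules,
    min_points: int = 3,
) -> CalibrationCurve:
    """Fit the log-log calibration line to spike-in standard points."""
    y = np.log10(np.asarray(signal_per_mw, dtype=float))
    x = np.log10(np.asarray(molecules, dtype=float))
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("signals and molecule counts must be positive and finite")
    if x.size != y.size:
        raise ValueError("signal and molecule arrays must have equal length")
    if x.size < min_points:
        raise ValueError(f"need at least {min_points} standard points, got {x.size}")
    if np.allclose(x, x[0]):
        raise ValueError("molecule counts must not all be equal")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        points=tuple(zip(x.tolist(), y.tolist())),
    )


def copies_per_cell(
    signals: pd.Series,
    curve: CalibrationCurve,
    mw_table: dict[str, float] | pd.Series,
    n_cells: int = DEFAULT_N_CELLS,
) -> pd.DataFrame:
    """Convert linear LFQ protein signals into molecules and copies per cell.

    ``signals`` maps accession to a linear LFQ value (e.g. the mean over
    the biotin replicates). Inverting the calibration line:
    log10(molecules) = (log10(signal/MW) − intercept) / slope.
    Proteins lacking an MW (or with non-positive signal) are excluded
    with a warning.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; cannot invert")
    if n_cells < 1:
        raise ValueError("n_cells must be positive")
    mw = pd.Series(mw_table, dtype=float)
    rows = []
    excluded = []
    for acc, signal in signals.items():
        w = mw.get(acc, np.nan)
        if not np.isfinite(w) or w <= 0 or not np.isfinite(signal) or signal <= 0:
            excluded.append(acc)
            continue
        spm = mw_normalize(float(signal), float(w))
        log10_mol = (np.log10(spm) - curve.intercept) / curve.slope
        mol = 10.0 ** log10_mol
        rows.append((acc, spm, mol, mol / n_cells))
    if excluded:
        warnings.warn(
            f"{len(excluded)} protein(s) excluded from absolute quantification "
            f"(missing MW or non-positive signal), e.g. {excluded[:3]}",
            stacklevel=2,
        )
    out = pd.DataFrame(
        rows, columns=["accession", "signal_per_mw", "molecules", "copies_per_cell"]
    ).set_index("accession")
    out.attrs["n_cells"] = n_cells
    out.attrs["excluded"] = excluded
    return out


def top_n_abundant(table: pd.DataFrame, n: int = 30) -> pd.DataFrame:
    """The n most abundant proteins by copies per cell (ties by accession)."""
    if table.empty:
        raise ValueError("copy-number table is empty")
    ordered = table.sort_index().sort_values(
        "copies_per_cell", ascending=False, kind="mergesort"
    )
    return ordered.head(n)
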