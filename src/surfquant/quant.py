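"""Cross-run MS1 label-free quantification from extracted ion chromatograms.

Every peptide ion identified in at least one LC-MS run is quantified in
every sample by extracting its XIC (±7 ppm, ±1.5 min by default) from
each run's MS1 feature map and integrating the peak nearest the
identification retention time. Peptide areas are summed into protein
quantities, which can then be normalized (median-of-totals scaling,
log2, per-sample median centring).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_PPM = 7.0
DEFAULT_RT_HALF_WINDOW_MIN = 1.5
DEFAULT_EXPECTANCY_MAX = 0.05

#: a peak boundary is placed at the first local minimum at or below this
#: fraction of the apex intensity
PEAK_BOUNDARY_FRACTION = 0.05


@dataclass(frozen=True)
class PeptideIon:
    """One identified peptide ion, the unit of XIC quantification."""

    peptide: str
    charge: int
    mz: float
    rt: float
    expectancy: float
    accessions: frozenset[str]

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("mz must be positive")
        if self.rt < 0:
            raise ValueError("rt must be non-negative")
        if not self.accessions:
            raise ValueError("accessions must be non-empty")

    @property
    def is_unique(self) -> bool:
        return len(self.accessions) == 1


@dataclass
class Xic:
    """Extracted ion chromatogram of one ion in one run."""

    ion: PeptideIon
    run_id: str
    times: np.ndarray
    intensities: np.ndarray
    window: tuple[float, float, float, float]  # mz_lo, mz_hi, rt_lo, rt_hi
    area: float | None = None


@dataclass
class ProteinQuantMatrix:
    """Proteins x samples: linear summed peptide areas and, after
    :func:`normalize`, a log2-centred layer; per-protein metadata
    (n_peptides, has_unique_peptide, mw_da)."""

    linear: pd.DataFrame
    meta: pd.DataFrame
    log2: pd.DataFrame | None = None


def ppm_window(mz: float, ppm: float) -> tuple[float, float]:
    """Inclusive mass window mz ± mz * ppm * 1e-6."""
    if mz <= 0:
        raise ValueError("mz must be positive")
    if ppm < 0:
        raise ValueError("ppm must be non-negative")
    half = mz * ppm * 1e-6
    return mz - half, mz + half


def extract_xic(
    feature_map: pd.DataFrame,
    ion: PeptideIon,
    ppm: float = DEFAULT_PPM,
    rt_half_window_min: float = DEFAULT_RT_HALF_WINDOW_MIN,
    run_id: str = "",
) -> Xic:
    """Collect in-window centroids into a time-ordered trace.

    Centroids sharing a scan time inside the m/z window are summed to a
    single intensity. An empty window yields an empty trace.
    """
    mz_lo, mz_hi = ppm_window(ion.mz, ppm)
    rt_lo, rt_hi = ion.rt - rt_half_window_min, ion.rt + rt_half_window_min
    mask = (
        feature_map["mz"].to_numpy() >= mz_lo
    ) & (feature_map["mz"].to_numpy() <= mz_hi)
    t = feature_map["rt_min"].to_numpy()[mask]
    inten = feature_map["intensity"].to_numpy()[mask]
    rt_mask = (t >= rt_lo) & (t <= rt_hi)
    t, inten = t[rt_mask], inten[rt_mask]
    if t.size:
        order = np.argsort(t, kind="mergesort")
        t, inten = t[order], inten[order]
        # collapse duplicate scan times
        uniq, idx = np.unique(t, return_inverse=True)
        summed = np.bincount(idx, weights=inten)
        t, inten = uniq, summed
    return Xic(
        ion=ion,
        run_id=run_id,
        times=t,
        intensities=inten,
        window=(mz_lo, mz_hi, rt_lo, rt_hi),
    )


def _integrate_trace(
    times: np.ndarray, intensities: np.ndarray, target_rt: float
) -> float | None:
    """Trapezoid area of the peak whose apex is nearest ``target_rt``."""
    n = times.size
    if n < 2 or not np.any(intensities > 0):
        return None
    y = intensities
    # local maxima (plateau edges count once)
    is_max = np.ones(n, dtype=bool)
    is_max[1:] &= y[1:] >= y[:-1]
    is_max[:-1] &= y[:-1] >= y[1:]
    is_max &= y > 0
    apex_candidates = np.flatnonzero(is_max)
    if apex_candidates.size == 0:
        return None
    apex = apex_candidates[np.argmin(np.abs(times[apex_candidates] - target_rt))]
    floor = PEAK_BOUNDARY_FRACTION * y[apex]
    lo = apex
    while lo > 0:
        lo -= 1
        if y[lo] <= floor and (lo == 0 or y[lo - 1] >= y[lo]):
            break
    hi = apex
    while hi < n - 1:
        hi += 1
        if y[hi] <= floor and (hi == n - 1 or y[hi + 1] >= y[hi]):
            break
    if hi == lo:
        return None
    return float(np.trapezoid(y[lo : hi + 1], times[lo : hi + 1]))


def integrate_peak(xic: Xic) -> float | None:
    """Area (intensity · min) under the XIC peak nearest the ID RT.

    Peak boundaries sit at the first local minima at or below 5% of the
    apex, or at the trace ends. Empty or single-point traces give
    ``None`` (missing).
    """
    area = _integrate_trace(xic.times, xic.intensities, xic.ion.rt)
    xic.area = area
    return area


def _fast_run_index(feature_map: pd.DataFrame):
    """Pre-sort a run's centroids by m/z for binary-search extraction."""
    mz = feature_map["mz"].to_numpy()
    order = np.argsort(mz, kind="mergesort")
    return (
        mz[order],
        feature_map["rt_min"].to_numpy()[order],
        feature_map["intensity"].to_numpy()[order],
    )


def quantify_across_runs(
    identifications: pd.DataFrame,
    feature_maps: dict[str, pd.DataFrame],
    design: pd.DataFrame,
    ppm: float = DEFAULT_PPM,
    rt_half_window_min: float = DEFAULT_RT_HALF_WINDOW_MIN,
    expectancy_max: float = DEFAULT_EXPECTANCY_MAX,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify the union of accepted ions in every sample.

    Ions are accepted when expectancy < ``expectancy_max``; duplicates of
    the same (peptide, charge) across runs collapse to one row whose
    reference m/z and RT come from the best-scoring identification
    (match-between-runs). Cells with no integrable peak are NaN.

    Returns ``(matrix, ion_meta)``: the peptide x sample area matrix
    indexed by (peptide, charge), and per-ion metadata (mz, rt,
    expectancy, accessions, is_unique).
    """
    missing_runs = set(identifications["run_id"]) - set(feature_maps)
    if missing_runs:
        raise ValueError(f"no feature map for run(s): {sorted(missing_runs)}")
    extra = set(identifications["run_id"]) - set(design["run_id"])
    if extra:
        raise ValueError(f"run(s) absent from design: {sorted(extra)}")

    ids = identifications[identifications["expectancy"] < expectancy_max]
    best = (
        ids.sort_values(["expectancy", "run_id"], kind="mergesort")
        .drop_duplicates(subset=["peptide", "charge"], keep="first")
        .sort_values(["peptide", "charge"], kind="mergesort")
        .reset_index(drop=True)
    )

    run_index = {
        rid: _fast_run_index(fm)
        for rid, fm in feature_maps.items()
        if rid in set(design["run_id"])
    }
    samples = design["sample_id"].tolist()
    sample_run = dict(zip(design["sample_id"], design["run_id"]))

    values = np.full((len(best), len(samples)), np.nan)
    for i, row in best.iterrows():
        mz_lo = row["mz_observed"] * (1 - ppm * 1e-6)
        mz_hi = row["mz_observed"] * (1 + ppm * 1e-6)
        rt_lo = row["rt_min"] - rt_half_window_min
        rt_hi = row["rt_min"] + rt_half_window_min
        for j, sid in enumerate(samples):
            mz_s, rt_s, in_s = run_index[sample_run[sid]]
            a = np.searchsorted(mz_s, mz_lo, side="left")
            b = np.searchsorted(mz_s, mz_hi, side="right")
            if a == b:
                continue
            t, inten = rt_s[a:b], in_s[a:b]
            m = (t >= rt_lo) & (t <= rt_hi)
            if not m.any():
                continue
            t, inten = t[m], inten[m]
            order = np.argsort(t, kind="mergesort")
            t, inten = t[order], inten[order]
            uniq, idx = np.unique(t, return_inverse=True)
            inten = np.bincount(idx, weights=inten)
            area = _integrate_trace(uniq, inten, row["rt_min"])
            if area is not None:
                values[i, j] = area

    index = pd.MultiIndex.from_frame(best[["peptide", "charge"]])
    matrix = pd.DataFrame(values, index=index, columns=samples)
    ion_meta = best.set_index(index)[
        ["mz_observed", "rt_min", "expectancy", "accessions", "is_unique"]
    ]
    return matrix, ion_meta


def rollup_proteins(
    peptide_matrix: pd.DataFrame,
    ion_meta: pd.DataFrame,
    mw_table: dict[str, float] | pd.Series | None = None,
    min_peptides: int = 2,
) -> ProteinQuantMatrix:
    """Sum peptide areas into protein quantities.

    Proteins with fewer than ``min_peptides`` distinct peptide sequences
    are dropped. Shared peptides contribute to every mapped protein;
    ``has_unique_peptide`` records whether at least one peptide maps to
    that protein alone (a later reporting gate, not a quantification
    filter). Proteins absent from ``mw_table`` keep a NaN MW with a
    warning and are excluded downstream from absolute quantification.
    """
    if mw_table is None:
        mw_table = {}
    mw_table = dict(mw_table) if not isinstance(mw_table, dict) else mw_table

    acc_lists = ion_meta["accessions"].astype(str).str.split(";")
    is_unique = (acc_lists.map(len) == 1).to_numpy()

    long = peptide_matrix.copy()
    long["accession"] = acc_lists.to_numpy()
    long["__is_unique"] = is_unique
    long = long.reset_index().explode("accession")

    sample_cols = list(peptide_matrix.columns)
    grouped = long.groupby("accession", sort=True)
    n_pep = grouped["peptide"].nunique()
    keep = n_pep[n_pep >= min_peptides].index
    sums = grouped[sample_cols].sum(min_count=1).loc[keep]
    has_unique = grouped["__is_unique"].any().loc[keep]

    mw = pd.Series(
        [mw_table.get(a, np.nan) for a in keep], index=keep, dtype=float
    )
    if mw_table and mw.isna().any():
        missing = sorted(mw.index[mw.isna()])
        warnings.warn(
            f"no molecular weight for {len(missing)} protein(s) "
            f"(e.g. {missing[:3]}); excluded from absolute quantification",
            stacklevel=2,
        )
    meta = pd.DataFrame(
        {
            "n_peptides": n_pep.loc[keep],
            "has_unique_peptide": has_unique,
            "mw_da": mw,
        }
    )
    return ProteinQuantMatrix(linear=sums, meta=meta)


def normalize(matrix: ProteinQuantMatrix) -> ProteinQuantMatrix:
    """Fill the log2-centred layer.

    Each sample is scaled by median(sample totals) / (its total), zeros
    and missing stay missing, values are log2-transformed, and each
    sample's median is subtracted so per-sample medians are exactly 0.
    """
    linear = matrix.linear
    totals = linear.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"sample(s) with non-positive total signal: {bad}")
    scaled = linear * (totals.median() / totals)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.log2(scaled.where(scaled > 0))
    log2 = log2 - log2.median(axis=0)
    return ProteinQuantMatrix(linear=linear, meta=matrix.meta, log2=log2)
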