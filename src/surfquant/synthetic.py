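"""Synthetic surfaceomics experiments with known ground truth.

Emulates a biotin-vs-mock pull-down experiment measured by single-shot
DDA LC-MS: a proteome of surface proteins (enriched in biotin samples),
nonspecific bead binders (equal in both arms), cytoplasmic leakage
(small positive effect), and a dynamic-range spike-in standard mix.
Each tryptic peptide elutes as a symmetric triangular peak on a fixed
scan grid; per-sample peptide areas carry multiplicative lognormal
noise; identifications are present in at least one run so the cross-run
matching stage is exercised.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

AVOGADRO = 6.02214076e23

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")
# residues used when drawing random peptide bodies: no K/R (cleavage sites)
# and no P (would suppress an upstream cleavage site)
_BODY_AA = sorted(_STANDARD_AA - set("KRP"))

#: detectability constant for spike-in standards: signal = molecules * MW / 1e3
STANDARD_SIGNAL_PER_MW = 1e-3


def _default_standard_points() -> list[tuple[str, float]]:
    """Eight standards log-uniform over five decades of amount (fmol)."""
    fmols = np.logspace(np.log10(0.5), np.log10(5e4), 8)
    return [(f"STD{i + 1}", float(f)) for i, f in enumerate(fmols)]


@dataclass
class SyntheticConfig:
    """Parameters of a simulated biotin/mock surfaceomics experiment.

    Defaults reflect a typical small-cell-number pull-down study:
    four biological replicates per arm, ~10 tryptic peptides per
    protein, lognormal protein abundances spanning a few decades,
    5% multiplicative feature noise, and a strong (Log2FC = 2)
    biotin enrichment of the true surface proteins.
    """

    n_proteins: int = 200
    surface_fraction: float = 0.3
    bead_binder_fraction: float = 0.5
    leakage_fraction: float = 0.2
    enrichment_log2fc: float = 2.0
    leakage_log2fc: float = 0.2  # below the 0.5 reporting cut by design
    abundance_log10_mean: float = 6.0
    abundance_log10_sd: float = 1.0
    noise_cv: float = 0.05
    peptides_per_protein_mean: float = 10.0
    rt_jitter_sd_min: float = 0.1
    missing_rate: float = 0.0
    n_replicates_biotin: int = 4
    n_replicates_mock: int = 4
    standard_points: list[tuple[str, float]] = field(
        default_factory=_default_standard_points
    )
    seed: int = 0
    # chromatography / identification plumbing
    peak_base_min: float = 0.4  # full base width of the triangular peak
    scan_interval_min: float = 0.05
    rt_range_min: tuple[float, float] = (5.0, 60.0)
    id_rate: float = 0.7  # chance a present feature is also identified in a run
    cell_line: str = "AML1"

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        for name in ("surface_fraction", "bead_binder_fraction", "leakage_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.surface_fraction + self.bead_binder_fraction + self.leakage_fraction > 1 + 1e-12:
            raise ValueError("compartment fractions must sum to at most 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.peptides_per_protein_mean <= 0:
            raise ValueError("peptides_per_protein_mean must be positive")
        if self.rt_jitter_sd_min < 0:
            raise ValueError("rt_jitter_sd_min must be non-negative")
        if self.n_replicates_biotin < 1 or self.n_replicates_mock < 1:
            raise ValueError("replicate counts must be positive")
        if not self.standard_points:
            raise ValueError("standard_points must not be empty")
        fmols = [f for _, f in self.standard_points]
        if any(f <= 0 for f in fmols):
            raise ValueError("standard amounts must be strictly positive")
        if len(set(fmols)) == 1 and len(fmols) > 1:
            raise ValueError("standard amounts must not all be equal")


@dataclass
class GroundTruth:
    """Latent quantities the pipeline estimates.

    proteins: accession, compartment, base_abundance, true_log2fc,
        true_molecules (standards only, else NaN), mw_da, n_peptides.
    peptides: accession, peptide, charge, mz, base_rt_min, weight.
    areas: long table (peptide, charge, sample_id, run_id, area,
        expected_area, apex_rt_min, present) — ``area`` is the realized
        (noise-applied) area encoded in the feature map; ``expected_area``
        the noiseless expectation.
    """

    proteins: pd.DataFrame
    peptides: pd.DataFrame
    areas: pd.DataFrame


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    truth: GroundTruth
    feature_maps: dict[str, pd.DataFrame]  # run_id -> (rt_min, mz, intensity)
    identifications: pd.DataFrame
    design: pd.DataFrame
    ontology: list[tuple[str, str, set[str]]]  # (term, description, members)
    standards: pd.DataFrame  # accession, fmol
    sequences: dict[str, str]  # accession -> amino-acid sequence


# ---------------------------------------------------------------------------
# tryptic digestion and peptide physics
# ---------------------------------------------------------------------------

def digest(protein_sequence: str, max_missed: int = 0) -> list[str]:
    """In-silico tryptic digest: cleave after K or R unless followed by P.

    Returns the unique peptides carrying 0..max_missed internal missed
    cleavage sites, ordered by missed-cleavage count then position.
    The concatenation of the 0-missed peptides reproduces the input.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be non-negative")
    bad = set(protein_sequence) - _STANDARD_AA
    if bad:
        raise ValueError(
            f"sequence contains non-standard residues: {sorted(bad)!r}"
        )
    if not protein_sequence:
        return []
    # fragment boundaries of the fully cleaved digest
    cuts = [0]
    for i, aa in enumerate(protein_sequence[:-1]):
        if aa in "KR" and protein_sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(protein_sequence))
    fragments = [
        protein_sequence[a:b] for a, b in zip(cuts[:-1], cuts[1:])
    ]
    out: list[str] = []
    seen: set[str] = set()
    for m in range(max_missed + 1):
        for i in range(len(fragments) - m):
            pep = "".join(fragments[i : i + m + 1])
            if pep not in seen:
                seen.add(pep)
                out.append(pep)
    return out


def peptide_mz(peptide: str, charge: int) -> float:
    """Monoisotopic m/z of a peptide ion: (M + z * proton) / z."""
    if not peptide:
        raise ValueError("peptide must be non-empty")
    bad = set(peptide) - _STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residues: {sorted(bad)!r}")
    if charge < 1:
        raise ValueError("charge must be at least 1")
    return float(_pmass.fast_mass(peptide, charge=charge))


def _charge_from_sequence(peptide: str) -> int:
    """Deterministic 2+/3+ assignment from a stable sequence hash."""
    h = int(hashlib.sha1(peptide.encode()).hexdigest(), 16)
    return 2 + (h % 2)


def _lognormal_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def _noise_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = _lognormal_sigma(cv)
    return np.exp(rng.normal(0.0, sigma, size=size) - 0.5 * sigma * sigma)


# ---------------------------------------------------------------------------
# experiment simulation
# ---------------------------------------------------------------------------

#: minimum m/z separation between distinct peptide ions, so that XIC
#: windows (±7 ppm) never capture signal from a neighbouring ion
_MIN_MZ_SEPARATION_PPM = 25.0


def _random_peptide(
    rng: np.random.Generator, seen: set[str], mz_taken: list[float]
) -> tuple[str, int, float]:
    """A unique tryptic peptide: 6-15 non-K/R/P residues ending in K or R.

    Rejects candidates whose ion m/z falls within 25 ppm of an already
    generated ion, keeping every simulated XIC interference-free.
    """
    import bisect

    while True:
        length = int(rng.integers(6, 16))
        body = "".join(rng.choice(_BODY_AA, size=length - 1))
        pep = body + ("K" if rng.random() < 0.5 else "R")
        if pep in seen:
            continue
        z = _charge_from_sequence(pep)
        mz = peptide_mz(pep, z)
        i = bisect.bisect_left(mz_taken, mz)
        tol = mz * _MIN_MZ_SEPARATION_PPM * 1e-6
        if i > 0 and mz - mz_taken[i - 1] < tol:
            continue
        if i < len(mz_taken) and mz_taken[i] - mz < tol:
            continue
        seen.add(pep)
        mz_taken.insert(i, mz)
        return pep, z, mz


def simulate_experiment(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a complete biotin/mock experiment with ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_proteins
    n_surface = round(n * config.surface_fraction)
    n_cyto = round(n * config.leakage_fraction)
    n_bead = n - n_surface - n_cyto
    if n_bead < 0:
        raise ValueError("compartment fractions leave no room for bead binders")

    accessions = (
        [f"SP{i + 1:04d}" for i in range(n_surface)]
        + [f"CY{i + 1:04d}" for i in range(n_cyto)]
        + [f"BB{i + 1:04d}" for i in range(n_bead)]
    )
    compartments = (
        ["surface"] * n_surface + ["cytoplasmic"] * n_cyto + ["bead_binder"] * n_bead
    )
    log2fcs = (
        [config.enrichment_log2fc] * n_surface
        + [config.leakage_log2fc] * n_cyto
        + [0.0] * n_bead
    )
    abundances = 10.0 ** rng.normal(
        config.abundance_log10_mean, config.abundance_log10_sd, size=n
    )
    molecules = [math.nan] * n

    # spike-in standards: identical in both arms, signal = molecules * MW / 1e3
    std_rows = []
    for label, fmol in config.standard_points:
        accessions.append(label)
        compartments.append("standard")
        log2fcs.append(0.0)
        std_rows.append((label, float(fmol)))
    standards = pd.DataFrame(std_rows, columns=["accession", "fmol"])

    # peptides per protein (standards included so they flow through LFQ)
    seen_peps: set[str] = set()
    mz_taken: list[float] = []
    pep_rows = []
    sequences: dict[str, str] = {}
    n_peps_per_protein: dict[str, int] = {}
    for acc in accessions:
        n_pep = max(2, int(rng.poisson(config.peptides_per_protein_mean)))
        peps = [_random_peptide(rng, seen_peps, mz_taken) for _ in range(n_pep)]
        sequences[acc] = "".join(p for p, _, _ in peps)
        n_peps_per_protein[acc] = n_pep
        weights = np.exp(rng.normal(0.0, 0.5, size=n_pep))  # ionization efficiency
        for (pep, z, mz), w in zip(peps, weights):
            pep_rows.append(
                (
                    acc,
                    pep,
                    z,
                    mz,
                    float(rng.uniform(*config.rt_range_min)),
                    float(w),
                )
            )
    peptides = pd.DataFrame(
        pep_rows,
        columns=["accession", "peptide", "charge", "mz", "base_rt_min", "weight"],
    )

    # abundances for standards from amount and sequence MW
    std_abund = []
    for label, fmol in config.standard_points:
        mw = float(_pmass.calculate_mass(sequence=sequences[label], average=True))
        mol = fmol * 1e-15 * AVOGADRO
        std_abund.append(mol * mw * STANDARD_SIGNAL_PER_MW)
        molecules.append(mol)
    base_abundance = np.concatenate([abundances, np.array(std_abund)])

    mw_da = np.array(
        [
            float(_pmass.calculate_mass(sequence=sequences[acc], average=True))
            for acc in accessions
        ]
    )
    proteins = pd.DataFrame(
        {
            "accession": accessions,
            "compartment": compartments,
            "base_abundance": base_abundance,
            "true_log2fc": log2fcs,
            "true_molecules": molecules,
            "mw_da": mw_da,
            "n_peptides": [n_peps_per_protein[a] for a in accessions],
        }
    )

    # design: one LC-MS run per sample
    design_rows = []
    for grp, nrep in (
        ("biotin", config.n_replicates_biotin),
        ("mock", config.n_replicates_mock),
    ):
        for r in range(1, nrep + 1):
            sid = f"{grp}_{r}"
            design_rows.append((sid, f"run_{sid}", grp, config.cell_line, r))
    design = pd.DataFrame(
        design_rows, columns=["sample_id", "run_id", "group", "cell_line", "replicate"]
    )

    prot_lfc = dict(zip(proteins["accession"], proteins["true_log2fc"]))
    prot_ab = dict(zip(proteins["accession"], proteins["base_abundance"]))

    n_pep_total = len(peptides)
    n_samples = len(design)
    is_biotin = (design["group"] == "biotin").to_numpy()

    base_area = (
        peptides["weight"].to_numpy()
        * np.array([prot_ab[a] for a in peptides["accession"]])
    )
    lfc = np.array([prot_lfc[a] for a in peptides["accession"]])
    expected = base_area[:, None] * np.where(is_biotin[None, :], 2.0 ** lfc[:, None], 1.0)
    noise = _noise_factors(rng, config.noise_cv, (n_pep_total, n_samples))
    areas = expected * noise

    # per-run retention-time jitter, snapped to the scan grid so the
    # sampled triangle integrates exactly by the trapezoid rule
    dt = config.scan_interval_min
    jitter = rng.normal(0.0, config.rt_jitter_sd_min, size=(n_pep_total, n_samples))
    apex_rt = peptides["base_rt_min"].to_numpy()[:, None] + jitter
    apex_rt = np.round(apex_rt / dt) * dt

    # missingness: feature absent in a run; every peptide kept in >=1 run
    present = rng.random((n_pep_total, n_samples)) >= config.missing_rate
    none_present = ~present.any(axis=1)
    if none_present.any():
        keep_col = rng.integers(0, n_samples, size=int(none_present.sum()))
        present[np.flatnonzero(none_present), keep_col] = True

    run_ids = design["run_id"].to_numpy()
    sample_ids = design["sample_id"].to_numpy()

    area_rows = pd.DataFrame(
        {
            "peptide": np.repeat(peptides["peptide"].to_numpy(), n_samples),
            "charge": np.repeat(peptides["charge"].to_numpy(), n_samples),
            "accession": np.repeat(peptides["accession"].to_numpy(), n_samples),
            "sample_id": np.tile(sample_ids, n_pep_total),
            "run_id": np.tile(run_ids, n_pep_total),
            "area": areas.ravel(),
            "expected_area": expected.ravel(),
            "apex_rt_min": apex_rt.ravel(),
            "present": present.ravel(),
        }
    )

    # triangular elution profiles on the scan grid
    half = config.peak_base_min / 2.0
    k = int(round(half / dt))
    offsets = np.arange(-k, k + 1) * dt
    shape = 1.0 - np.abs(offsets) / half  # zero at both ends
    feature_maps: dict[str, pd.DataFrame] = {}
    mz_all = peptides["mz"].to_numpy()
    for j, rid in enumerate(run_ids):
        sel = present[:, j]
        apex = apex_rt[sel, j]
        amp = areas[sel, j] / half  # triangle area = apex_intensity * half
        times = apex[:, None] + offsets[None, :]
        intens = amp[:, None] * shape[None, :]
        fmap = pd.DataFrame(
            {
                "rt_min": np.round(times.ravel(), 6),
                "mz": np.repeat(mz_all[sel], len(offsets)),
                "intensity": intens.ravel(),
            }
        )
        # zero-intensity peak ends are kept: the sampled triangle then
        # integrates exactly under the trapezoid rule
        feature_maps[rid] = fmap.sort_values(
            ["rt_min", "mz"], kind="mergesort", ignore_index=True
        )

    # identification tables: per run, only where the feature is present;
    # each peptide identified in at least one run
    identified = present & (rng.random((n_pep_total, n_samples)) < config.id_rate)
    no_id = ~identified.any(axis=1)
    for i in np.flatnonzero(no_id):
        cols = np.flatnonzero(present[i])
        identified[i, cols[rng.integers(0, len(cols))]] = True
    ppm_err = rng.normal(0.0, 1.5, size=(n_pep_total, n_samples)).clip(-5, 5)
    id_rows = []
    for i in range(n_pep_total):
        for j in np.flatnonzero(identified[i]):
            id_rows.append(
                (
                    run_ids[j],
                    peptides.at[i, "peptide"],
                    int(peptides.at[i, "charge"]),
                    mz_all[i] * (1.0 + ppm_err[i, j] * 1e-6),
                    apex_rt[i, j],
                    float(rng.uniform(1e-4, 0.04)),
                    peptides.at[i, "accession"],
                    1,
                )
            )
    identifications = pd.DataFrame(
        id_rows,
        columns=[
            "run_id",
            "peptide",
            "charge",
            "mz_observed",
            "rt_min",
            "expectancy",
            "accessions",
            "is_unique",
        ],
    )

    # ontology: the two informative compartment terms plus decoys
    surface_set = set(proteins.loc[proteins["compartment"] == "surface", "accession"])
    cyto_set = set(proteins.loc[proteins["compartment"] == "cytoplasmic", "accession"])
    ontology: list[tuple[str, str, set[str]]] = [
        ("cell surface", "true surface proteins", surface_set),
        ("cytoplasm", "cytoplasmic leakage proteins", cyto_set),
    ]
    non_std = [a for a in accessions if not a.startswith("STD")]
    for d in range(10):
        size = int(rng.integers(5, min(41, max(6, len(non_std)))))
        members = set(rng.choice(non_std, size=size, replace=False))
        ontology.append((f"decoy_{d + 1:02d}", "random decoy term", members))

    truth = GroundTruth(proteins=proteins, peptides=peptides, areas=area_rows)
    return SyntheticDataset(
        config=config,
        truth=truth,
        feature_maps=feature_maps,
        identifications=identifications,
        design=design,
        ontology=ontology,
        standards=standards,
        sequences=sequences,
    )


def simulate_standard_readings(
    standard_points: list[tuple[str, float]] | None = None,
    noise_cv: float = 0.2,
    n_draws: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated replicate signal readings for a dynamic-range standard mix.

    Signals follow the generator's standard model (signal proportional to
    molecules x MW / 1e3) with multiplicative lognormal noise per draw;
    draws are averaged in linear space. MW values are drawn log-uniform
    over a realistic 15-150 kDa range.

    Returns a table (accession, fmol, molecules, mw_da, signal) ready for
    :func:`surfquant.absquant.fit_calibration`.
    """
    if standard_points is None:
        standard_points = _default_standard_points()
    rng = np.random.default_rng(seed)
    rows = []
    for label, fmol in standard_points:
        mol = fmol * 1e-15 * AVOGADRO
        mw = 10.0 ** rng.uniform(np.log10(15e3), np.log10(150e3))
        draws = mol * mw * STANDARD_SIGNAL_PER_MW * _noise_factors(
            rng, noise_cv, n_draws
        )
        rows.append((label, fmol, mol, mw, float(np.mean(draws))))
    return pd.DataFrame(
        rows, columns=["accession", "fmol", "molecules", "mw_da", "signal"]
    )


# ---------------------------------------------------------------------------
# on-disk dialect
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write a dataset as plain-text files; re-reading reproduces it."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": directory / "proteins.fasta",
        "gmt": directory / "ontology.gmt",
        "identifications": directory / "identifications.tsv",
        "features": directory / "features.csv",
        "design": directory / "design.tsv",
        "standards": directory / "standards.tsv",
        "truth_proteins": directory / "truth_proteins.tsv",
        "truth_peptides": directory / "truth_peptides.tsv",
        "truth_areas": directory / "truth_areas.tsv",
    }
    with open(paths["fasta"], "w") as fh:
        for acc, seq in dataset.sequences.items():
            fh.write(f">{acc}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    with open(paths["gmt"], "w") as fh:
        for term, desc, members in dataset.ontology:
            fh.write("\t".join([term, desc] + sorted(members)) + "\n")
    dataset.identifications.to_csv(paths["identifications"], sep="\t", index=False)
    feats = pd.concat(
        [fmap.assign(run_id=rid) for rid, fmap in dataset.feature_maps.items()],
        ignore_index=True,
    )[["run_id", "rt_min", "mz", "intensity"]]
    feats.to_csv(paths["features"], index=False)
    dataset.design.to_csv(paths["design"], sep="\t", index=False)
    dataset.standards.to_csv(paths["standards"], sep="\t", index=False)
    dataset.truth.proteins.to_csv(paths["truth_proteins"], sep="\t", index=False)
    dataset.truth.peptides.to_csv(paths["truth_peptides"], sep="\t", index=False)
    dataset.truth.areas.to_csv(paths["truth_areas"], sep="\t", index=False)
    return paths


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_feature_maps(path: str | Path) -> dict[str, pd.DataFrame]:
    feats = pd.read_csv(path)
    return {
        rid: grp[["rt_min", "mz", "intensity"]].reset_index(drop=True)
        for rid, grp in feats.groupby("run_id", sort=False)
    }


def read_dataset(directory: str | Path) -> SyntheticDataset:
    """Reconstruct a written dataset (config is not round-tripped)."""
    from .enrichment import read_gmt

    directory = Path(directory)
    sequences = read_fasta(directory / "proteins.fasta")
    ontology = [
        (a.term, a.description, set(a.members))
        for a in read_gmt(directory / "ontology.gmt")
    ]
    truth = GroundTruth(
        proteins=pd.read_csv(directory / "truth_proteins.tsv", sep="\t"),
        peptides=pd.read_csv(directory / "truth_peptides.tsv", sep="\t"),
        areas=pd.read_csv(directory / "truth_areas.tsv", sep="\t"),
    )
    return SyntheticDataset(
        config=None,  # type: ignore[arg-type]
        truth=truth,
        feature_maps=read_feature_maps(directory / "features.csv"),
        identifications=pd.read_csv(directory / "identifications.tsv", sep="\t"),
        design=pd.read_csv(directory / "design.tsv", sep="\t"),
        ontology=ontology,
        standards=pd.read_csv(directory / "standards.tsv", sep="\t"),
        sequences=sequences,
    )
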