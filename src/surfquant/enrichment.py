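"""Subcellular-localization enrichment scoring of screened protein sets.

Hypergeometric over-representation analysis (ORA) against GMT gene
sets, a weighted Kolmogorov-Smirnov running-sum GSEA with set-membership
permutation nulls, the per-term delta-enrichment statistic (difference
of annotated proportions between labelled and unlabelled proteins), the
surface:cytoplasm hit-count ratio, and Venn/UpSet-style exclusive
overlap summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import bh_adjust

DEFAULT_MIN_SET_SIZE = 3
DEFAULT_MAX_SET_SIZE = 350


@dataclass(frozen=True)
class OntologyAnnotation:
    term: str
    description: str
    members: frozenset[str]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"term {self.term!r} has no members")


def read_gmt(path: str | Path) -> list[OntologyAnnotation]:
    """Parse a GMT file: term <tab> description <tab> member...

    Duplicate members within a line are stored once; a line with fewer
    than three fields raises an error naming the line number.
    """
    annotations = []
    seen_terms = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            term, desc, *members = fields
            if term in seen_terms:
                raise ValueError(f"{path}: line {lineno}: duplicate term {term!r}")
            seen_terms.add(term)
            annotations.append(
                OntologyAnnotation(term, desc, frozenset(m for m in members if m))
            )
    return annotations


def ora(
    hits: set[str],
    universe: set[str],
    sets: list[OntologyAnnotation],
    min_size: int = DEFAULT_MIN_SET_SIZE,
    max_size: int = DEFAULT_MAX_SET_SIZE,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``hits`` within ``universe``.

    Term membership is intersected with the universe before the size
    filter; retained terms are scored by the upper tail P(X >= k) and
    BH-adjusted across terms. Columns: term, description, k, K, n, N,
    gene_ratio, p, p_adj.
    """
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    n, big_n = len(hits), len(universe)
    rows = []
    for ann in sets:
        members = ann.members & universe
        big_k = len(members)
        if not (min_size <= big_k <= max_size):
            continue
        k = len(members & hits)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append(
            (
                ann.term,
                ann.description,
                k,
                big_k,
                n,
                big_n,
                k / n if n else np.nan,
                min(p, 1.0),
            )
        )
    out = pd.DataFrame(
        rows, columns=["term", "description", "k", "K", "n", "N", "gene_ratio", "p"]
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def _enrichment_score(
    stat: np.ndarray, hit: np.ndarray, weight: float
) -> float:
    """Maximum-magnitude deviation of the weighted KS running sum."""
    w = np.abs(stat) ** weight * hit
    total = w.sum()
    if total == 0:  # degenerate: fall back to unweighted increments
        w = hit.astype(float)
        total = w.sum()
    n_miss = (~hit.astype(bool)).sum()
    running = np.cumsum(w / total - (~hit.astype(bool)) / n_miss)
    return float(running[np.argmax(np.abs(running))])


def gsea(
    ranked: pd.Series,
    sets: list[OntologyAnnotation],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-set enrichment on a ranked protein list.

    ``ranked`` maps protein id to a real statistic; proteins are sorted
    by decreasing statistic (ties broken by id). The null permutes set
    membership (same set size, ``n_perm`` draws); NES divides ES by the
    mean |null ES| of matching sign and the empirical p carries +1
    smoothing. Terms with no overlap, or covering the whole ranked
    list, are skipped as degenerate.
    """
    if ranked.index.duplicated().any():
        raise ValueError("duplicate protein ids in ranked list")
    if not np.isfinite(ranked.to_numpy(dtype=float)).all():
        raise ValueError("ranking statistics must be finite")
    order = sorted(ranked.index, key=lambda g: (-ranked[g], g))
    stat = ranked.loc[order].to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(order)}
    n = len(order)
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for ann in sets:
        idx = np.array(sorted(pos[g] for g in ann.members if g in pos), dtype=int)
        k = idx.size
        if k == 0 or k == n:
            continue
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        es = _enrichment_score(stat, hit, weight)
        if k not in null_cache:
            null = np.empty(n_perm)
            for b in range(n_perm):
                perm_hit = np.zeros(n, dtype=bool)
                perm_hit[rng.choice(n, size=k, replace=False)] = True
                null[b] = _enrichment_score(stat, perm_hit, weight)
            null_cache[k] = null
        null = null_cache[k]
        same_sign = null * np.sign(es) > 0 if es != 0 else np.ones(n_perm, bool)
        denom = np.abs(null[same_sign]).mean() if same_sign.any() else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        n_extreme = int(np.sum(same_sign & (np.abs(null) >= abs(es))))
        p = (1 + n_extreme) / (1 + int(same_sign.sum()))
        rows.append((ann.term, ann.description, k, es, nes, min(p, 1.0)))
    out = pd.DataFrame(
        rows, columns=["term", "description", "size", "ES", "NES", "p"]
    )
    out["p_adj"] = bh_adjust(out["p"].to_numpy()) if len(out) else []
    return out


def delta_enrichment(
    term_members: set[str] | frozenset[str],
    labelled: set[str],
    unlabelled: set[str],
    mode: str = "difference",
) -> float:
    """Contrast of the annotated proportion between labelled and
    unlabelled proteins for one term.

    ``difference`` (default): p_labelled − p_unlabelled;
    ``ratio``: p_labelled / p_unlabelled (inf when only the labelled
    side is annotated, NaN when neither is).
    """
    if labelled & unlabelled:
        raise ValueError("labelled and unlabelled sets must be disjoint")
    if not labelled or not unlabelled:
        raise ValueError("labelled and unlabelled sets must be non-empty")
    p_lab = len(term_members & labelled) / len(labelled)
    p_unl = len(term_members & unlabelled) / len(unlabelled)
    if mode == "difference":
        return p_lab - p_unl
    if mode == "ratio":
        if p_unl == 0:
            return float("inf") if p_lab > 0 else float("nan")
        return p_lab / p_unl
    raise ValueError(f"unknown mode {mode!r}")


def surface_to_cytoplasm_ratio(
    significant: set[str],
    surface_members: set[str] | frozenset[str],
    cytoplasm_members: set[str] | frozenset[str],
) -> float:
    """Count ratio |sig ∩ surface| / |sig ∩ cytoplasm|.

    Returns inf when only the cytoplasm count is zero and NaN (0/0,
    undefined) when both are.
    """
    n_surf = len(significant & surface_members)
    n_cyto = len(significant & cytoplasm_members)
    if n_cyto == 0:
        return float("inf") if n_surf > 0 else float("nan")
    return n_surf / n_cyto


def overlap_summary(named_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Exclusive-intersection (UpSet-style) counts for >= 2 named sets.

    Each row is one non-empty exclusive region (proteins in exactly
    that combination of sets); counts partition the union and the
    percentages are relative to the union size.
    """
    if len(named_sets) < 2:
        raise ValueError("need at least two sets")
    names = list(named_sets)
    union = set().union(*named_sets.values())
    regions: dict[tuple[str, ...], int] = {}
    for protein in union:
        combo = tuple(n for n in names if protein in named_sets[n])
        regions[combo] = regions.get(combo, 0) + 1
    rows = []
    for r in range(len(names), 0, -1):
        for combo in combinations(names, r):
            if combo in regions:
                count = regions[combo]
                rows.append(
                    (
                        "&".join(combo),
                        len(combo),
                        count,
                        100.0 * count / len(union) if union else np.nan,
                    )
                )
    return pd.DataFrame(rows, columns=["region", "degree", "count", "pct_of_union"])
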