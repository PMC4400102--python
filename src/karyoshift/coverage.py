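"""Coverage-based detection of differentiated sex-linked Muller elements.

A fully differentiated X is present in one copy in males and two in
females, so X-linked scaffolds show half male genomic coverage: their
log2(male/female depth) sits one unit below the autosomal peak.  The
pipeline (i) keeps scaffolds longer than a length floor with positive depth
in both sexes, (ii) anchors the autosomal log2(M/F) peak (``a_coord``) at
the maximum of a kernel density estimate — or at the second-highest peak
for genomes where sex-linked scaffolds are the majority — (iii) flags X
candidates within [a_coord - 1.1, a_coord - 0.9] and Z candidates within
[a_coord + 0.9, a_coord + 1.1], and (iv) tests each Muller element for
over-representation among candidates with a one-sided Fisher exact test
(default alpha 0.01, no multiple-testing correction across the six
elements).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assignment import EXCLUDED_TIE, UNASSIGNED

DEPTH_COLUMNS = ("scaffold_id", "length_bp", "male_depth", "female_depth")


@dataclass
class CoverageRatioTable:
    """Retained scaffolds with their log2(M/F) depth ratios.

    ``dropped_short`` counts scaffolds at or below the length floor;
    ``dropped_zero_depth`` counts scaffolds with zero depth in either sex
    (their log ratio is undefined).
    """

    table: pd.DataFrame  # scaffold_id, length_bp, element?, log2_mf
    min_length_bp: int = 1000
    dropped_short: int = 0
    dropped_zero_depth: int = 0

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class PeakEstimate:
    """Autosomal log2(M/F) anchor: the density peak of the ratio distribution."""

    a_coord: float
    mode_rank: str  # primary | secondary
    grid: np.ndarray = field(repr=False, default=None)
    density: np.ndarray = field(repr=False, default=None)


@dataclass
class ElementEnrichmentResult:
    """Fisher over-representation of one element among sex-linked candidates."""

    element: str
    n_scaffolds: int
    n_candidates: int
    expected_candidates: float
    odds_ratio: float
    fisher_p: float
    verdict: str  # sex_linked | not_sex_linked
    partial: bool = False  # high candidate fraction without a significant call


def build_ratio_table(
    records: pd.DataFrame, min_length_bp: int = 1000
) -> CoverageRatioTable:
    """Filter scaffolds and compute log2(male/female) depth per scaffold.

    Retains scaffolds strictly longer than ``min_length_bp`` with positive
    depth in both sexes; dropped scaffolds are tallied, not raised.
    """
    df = records.copy()
    short = df["length_bp"] <= min_length_bp
    df = df[~short]
    zero = (df["male_depth"] <= 0) | (df["female_depth"] <= 0)
    dropped_zero = int(zero.sum())
    df = df[~zero].copy()
    df["log2_mf"] = np.log2(df["male_depth"] / df["female_depth"])
    return CoverageRatioTable(
        table=df.reset_index(drop=True),
        min_length_bp=min_length_bp,
        dropped_short=int(short.sum()),
        dropped_zero_depth=dropped_zero,
    )


def _local_maxima(density: np.ndarray) -> np.ndarray:
    """Indices of local maxima on the grid, endpoints included."""
    d = density
    left = np.r_[True, d[1:] >= d[:-1]]
    right = np.r_[d[:-1] >= d[1:], True]
    idx = np.flatnonzero(left & right)
    # collapse flat plateaus to their first index
    keep = np.r_[True, np.diff(idx) > 1] if idx.size else np.array([], dtype=bool)
    return idx[keep]


def estimate_autosomal_peak(
    table: CoverageRatioTable, mode_rank: str = "primary", grid_points: int = 512
) -> PeakEstimate:
    """Locate the autosomal log2(M/F) peak by Gaussian KDE.

    Silverman-bandwidth Gaussian kernel evaluated on a fixed grid spanning
    the data range; ``mode_rank="secondary"`` returns the local maximum with
    the second-highest density (for genomes whose largest peak is the sex
    chromosome itself).  Requires at least 20 retained scaffolds.
    """
    if mode_rank not in ("primary", "secondary"):
        raise ValueError(f"unknown mode_rank {mode_rank!r}")
    values = table.table["log2_mf"].to_numpy(dtype=float)
    if values.size < 20:
        raise ValueError(
            f"need >= 20 retained scaffolds to anchor the autosomal peak, got {values.size}"
        )
    if np.ptp(values) == 0.0:  # point mass: KDE is singular, the peak is the value
        v = float(values[0])
        grid = np.array([v])
        return PeakEstimate(a_coord=v, mode_rank="primary", grid=grid, density=np.array([1.0]))
    kde = stats.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), grid_points)
    density = kde(grid)
    maxima = _local_maxima(density)
    order = maxima[np.argsort(density[maxima])[::-1]]
    if mode_rank == "secondary":
        if order.size < 2:
            raise ValueError("secondary peak requested but the density has a single maximum")
        idx = order[1]
    else:
        idx = order[0]
    return PeakEstimate(a_coord=float(grid[idx]), mode_rank=mode_rank, grid=grid, density=density)


def classify_candidates(
    table: CoverageRatioTable,
    peak: PeakEstimate,
    window_low: float = 0.9,
    window_high: float = 1.1,
) -> pd.DataFrame:
    """Flag scaffolds whose log2(M/F) falls in the hemizygosity windows.

    X candidates lie in the closed interval [a_coord - window_high,
    a_coord - window_low]; Z candidates mirror it above the peak.  The two
    windows never overlap (window_low > 0), so the flags are exclusive.

    Returns the ratio table with a ``candidate`` column in
    {X_candidate, Z_candidate, none}.
    """
    df = table.table.copy()
    a = peak.a_coord
    r = df["log2_mf"]
    is_x = (r >= a - window_high) & (r <= a - window_low)
    is_z = (r >= a + window_low) & (r <= a + window_high)
    df["candidate"] = np.select([is_x, is_z], ["X_candidate", "Z_candidate"], default="none")
    return df


def test_element_enrichment(
    candidates: pd.DataFrame,
    alpha: float = 0.01,
    side: str = "X",
    partial_threshold: float = 0.25,
) -> list[ElementEnrichmentResult]:
    """Per-element one-sided Fisher test for candidate over-representation.

    For each element with >= 1 assigned scaffold, a 2x2 table (this element
    vs the rest) x (candidate vs not) is tested one-sided for an excess of
    candidates; elements with p < alpha are called sex-linked.  Scaffolds
    labelled UNASSIGNED/EXCLUDED_TIE are excluded.  Elements whose candidate
    fraction exceeds ``partial_threshold`` without reaching significance are
    annotated as partial — a reporting convention for partially sex-linked
    elements, not a test.
    """
    flag = f"{side}_candidate"
    df = candidates[~candidates["element"].isin([UNASSIGNED, EXCLUDED_TIE])]
    df = df[df["element"].notna()]
    total = len(df)
    results: list[ElementEnrichmentResult] = []
    if total == 0:
        return results
    total_cand = int((df["candidate"] == flag).sum())
    overall = total_cand / total
    for element, sub in df.groupby("element", sort=True):
        n = len(sub)
        k = int((sub["candidate"] == flag).sum())
        table = np.array([[k, n - k], [total_cand - k, (total - n) - (total_cand - k)]])
        odds, p = stats.fisher_exact(table, alternative="greater")
        verdict = "sex_linked" if p < alpha else "not_sex_linked"
        results.append(
            ElementEnrichmentResult(
                element=str(element),
                n_scaffolds=n,
                n_candidates=k,
                expected_candidates=n * overall,
                odds_ratio=float(odds),
                fisher_p=float(p),
                verdict=verdict,
                partial=(verdict == "not_sex_linked" and n > 0 and k / n > partial_threshold),
            )
        )
    return results


test_element_enrichment.__test__ = False  # statistical test, not a pytest case


def detect_sexlinked_elements(
    depth: pd.DataFrame,
    assignments: pd.DataFrame | None = None,
    element_column: str = "assigned_element",
    min_length_bp: int = 1000,
    mode_rank: str = "primary",
    alpha: float = 0.01,
    side: str = "X",
    window_low: float = 0.9,
    window_high: float = 1.1,
) -> tuple[list[ElementEnrichmentResult], pd.DataFrame, PeakEstimate]:
    """End-to-end coverage detection: ratio table, peak, windows, Fisher.

    ``depth`` needs scaffold_id/length_bp/male_depth/female_depth and either
    an ``element`` column or an ``assignments`` table to merge one in.
    Returns (per-element results, per-scaffold candidate table, peak).
    """
    df = depth.copy()
    if assignments is not None:
        df = df.merge(
            assignments[["scaffold_id", element_column]].rename(
                columns={element_column: "element"}
            ),
            on="scaffold_id",
            how="left",
        )
        df["element"] = df["element"].fillna(UNASSIGNED)
    elif "element" not in df.columns:
        raise ValueError("depth table lacks an element column and no assignments given")
    ratios = build_ratio_table(df, min_length_bp=min_length_bp)
    peak = estimate_autosomal_peak(ratios, mode_rank=mode_rank)
    cand = classify_candidates(ratios, peak, window_low=window_low, window_high=window_high)
    results = test_element_enrichment(cand, alpha=alpha, side=side)
    return results, cand, peak


def enrichment_frame(results: list[ElementEnrichmentResult]) -> pd.DataFrame:
    """Results as a flat table (for enrichment.tsv)."""
    return pd.DataFrame(
        [
            {
                "element": r.element,
                "n_scaffolds": r.n_scaffolds,
                "n_candidates": r.n_candidates,
                "expected_candidates": r.expected_candidates,
                "odds_ratio": r.odds_ratio,
                "fisher_p": r.fisher_p,
                "verdict": r.verdict,
                "partial": r.partial,
            }
            for r in results
        ]
    )


def read_depth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(DEPTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"depth table missing columns: {sorted(missing)}")
    return df
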