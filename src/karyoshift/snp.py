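"""SNP calling from allele-count pileups and detection of young
(neo-) sex chromosomes via male SNP excess.

On a nascent X-Y pair the chromosomes are still similar enough that Y
reads co-map onto X scaffolds, so fixed X-Y differences appear as
heterozygous sites in males only: the fraction of SNPs contributed by the
male sample rises above the autosomal ~0.5.  A fully degenerate old X
shows no such excess (Y reads no longer map).  The caller applies a
depth-proportional threshold: a site needs depth >= 6, and a SNP is
called when at least two distinct alleles each reach 0.3 x coverage —
so the cut-off scales with depth, keeping calls largely
coverage-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assignment import EXCLUDED_TIE, UNASSIGNED

BASES = ("A", "C", "G", "T")
PILEUP_COLUMNS = ("scaffold_id", "pos") + BASES


@dataclass
class YoungSexLinkResult:
    """Rank-sum comparison of one element's per-scaffold male SNP fraction
    against the autosomal reference."""

    element: str
    n_focal: int
    n_reference: int
    median_focal_fraction: float
    autosomal_median: float
    shift: float
    rank_test_p: float
    verdict: str  # young_sex_linked | none | untestable
    excess_sex: str = "male"


def call_snps(
    sites: pd.DataFrame, min_depth: int = 6, allele_fraction: float = 0.3
) -> pd.DataFrame:
    """Apply the depth and allele-fraction rule to a pileup.

    Sites with total depth < ``min_depth`` are dropped; a retained site is a
    SNP iff at least two distinct alleles each have count >=
    ``allele_fraction`` x depth (real-valued comparison, >=).

    Returns the retained sites with ``depth`` and boolean ``is_snp`` columns.
    Negative allele counts raise ValueError.
    """
    counts = sites.loc[:, list(BASES)].to_numpy()
    if counts.size and counts.min() < 0:
        raise ValueError("negative allele counts in pileup")
    depth = counts.sum(axis=1)
    keep = depth >= min_depth
    counts = counts[keep]
    depth = depth[keep]
    out = sites.loc[keep].copy()
    out["depth"] = depth
    threshold = allele_fraction * depth[:, None]
    out["is_snp"] = (counts >= threshold).sum(axis=1) >= 2
    return out.reset_index(drop=True)


def summarize_scaffold_snps(
    male_calls: pd.DataFrame,
    female_calls: pd.DataFrame,
    scaffold_lengths: pd.DataFrame,
    assignments: pd.DataFrame | None = None,
    element_column: str = "assigned_element",
    min_total_snps: int = 1,
) -> pd.DataFrame:
    """Per-scaffold SNP counts, densities and male SNP fraction.

    ``scaffold_lengths`` needs scaffold_id and length_bp; the element label
    is merged from ``assignments`` when given.  male_fraction =
    male_snps / (male_snps + female_snps), undefined (NaN, ``defined`` False)
    when the total falls below ``min_total_snps``.
    """
    def _counts(calls: pd.DataFrame, name: str) -> pd.Series:
        if calls.empty:
            return pd.Series(dtype=np.int64, name=name)
        return calls[calls["is_snp"]].groupby("scaffold_id").size().rename(name)

    df = scaffold_lengths[["scaffold_id", "length_bp"]].copy()
    df = df.merge(_counts(male_calls, "male_snps"), on="scaffold_id", how="left")
    df = df.merge(_counts(female_calls, "female_snps"), on="scaffold_id", how="left")
    df[["male_snps", "female_snps"]] = (
        df[["male_snps", "female_snps"]].fillna(0).astype(np.int64)
    )
    total = df["male_snps"] + df["female_snps"]
    with np.errstate(invalid="ignore"):
        df["male_fraction"] = np.where(total > 0, df["male_snps"] / total.replace(0, 1), np.nan)
    df.loc[total == 0, "male_fraction"] = np.nan
    df["defined"] = total >= min_total_snps
    kb = df["length_bp"] / 1000.0
    df["male_snp_density_kb"] = df["male_snps"] / kb
    df["female_snp_density_kb"] = df["female_snps"] / kb
    if assignments is not None:
        df = df.merge(
            assignments[["scaffold_id", element_column]].rename(
                columns={element_column: "element"}
            ),
            on="scaffold_id",
            how="left",
        )
        df["element"] = df["element"].fillna(UNASSIGNED)
    return df


def detect_young_sexlink(
    summaries: pd.DataFrame,
    focal_elements: list[str] | None = None,
    reference_elements: list[str] | None = None,
    alpha: float = 0.01,
    min_shift: float = 0.05,
    excess_sex: str = "male",
    min_scaffolds: int = 10,
) -> list[YoungSexLinkResult]:
    """Test elements for an excess of heterogametic-sex SNPs.

    For each focal element, the per-scaffold male SNP fractions are compared
    one-sided (greater) against the pooled autosomal reference with a
    Mann-Whitney rank-sum test; for ZW systems (``excess_sex="female"``) the
    female fraction 1 - male_fraction is tested instead.  An element is
    called young_sex_linked iff p < alpha AND the median shift is at least
    ``min_shift`` — the shift guard keeps statistically significant but
    biologically negligible offsets from being flagged.  Groups with fewer
    than ``min_scaffolds`` defined scaffolds are marked untestable.
    """
    df = summaries[summaries["defined"] & summaries["male_fraction"].notna()]
    df = df[~df["element"].isin([UNASSIGNED, EXCLUDED_TIE])]
    elements = sorted(df["element"].dropna().unique())
    if focal_elements is None:
        focal_elements = elements

    frac = df["male_fraction"] if excess_sex == "male" else 1.0 - df["male_fraction"]
    df = df.assign(_frac=frac)
    results: list[YoungSexLinkResult] = []
    for element in focal_elements:
        # default reference: every other element (leave-one-out autosomal pool)
        ref_set = (
            reference_elements
            if reference_elements is not None
            else [e for e in elements if e != element]
        )
        ref = df[df["element"].isin(ref_set)]["_frac"].to_numpy()
        foc = df[df["element"] == element]["_frac"].to_numpy()
        base = YoungSexLinkResult(
            element=element, n_focal=foc.size, n_reference=ref.size,
            median_focal_fraction=float(np.median(foc)) if foc.size else np.nan,
            autosomal_median=float(np.median(ref)) if ref.size else np.nan,
            shift=np.nan, rank_test_p=np.nan, verdict="untestable",
            excess_sex=excess_sex,
        )
        if foc.size < min_scaffolds or ref.size < min_scaffolds:
            results.append(base)
            continue
        shift = base.median_focal_fraction - base.autosomal_median
        _, p = stats.mannwhitneyu(foc, ref, alternative="greater")
        base.shift = float(shift)
        base.rank_test_p = float(p)
        base.verdict = (
            "young_sex_linked" if (p < alpha and shift >= min_shift) else "none"
        )
        results.append(base)
    return results


def young_sexlink_frame(results: list[YoungSexLinkResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def read_pileup(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pileup missing columns: {sorted(missing)}")
    return df
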