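"""Dosage-compensation and sex-biased-expression statistics.

Whether the single X of the heterogametic sex is transcriptionally
compensated is read off two ratio analyses on FPKM tables:

* male/female (M/F) ratios within a tissue — a compensated X centres near
  the autosomes, an uncompensated X sits two-fold lower in males;
* current/ancestral (C/A) ratios per sex — each gene's expression on the
  extant X divided by its pre-sex-linkage level, proxied by the ortholog's
  autosomal expression in an outgroup.

Both analyses quantile-normalize the two samples, take per-gene ratios,
recentre by the autosomal median (so the autosomal control is exactly 1),
and summarize per chromosome class with the boxplot-notch CI
(median +/- 1.57 x IQR / sqrt(n)) and a two-sided Mann-Whitney test of X
vs autosomes.  Genes below 1 FPKM in both samples of a comparison are
excluded.  Separately, S7-style testis-bias classes use fixed 3-fold
(strongly testis-biased) and 10-fold (testis-specific) cut-offs against
four reference samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class RatioSummary:
    """Per-chromosome-class summary of log2 expression ratios."""

    chromosome_class: str  # X | autosome
    n_genes: int
    median_log2_ratio: float
    ci_half_width: float  # 1.57 * IQR / sqrt(n), log2 units
    rank_test_p: float  # two-sided, X vs autosomes (NaN for the reference class)

    @property
    def median_ratio(self) -> float:
        return float(2.0 ** self.median_log2_ratio)

    def ci_ratio(self) -> tuple[float, float]:
        """Notch CI on the ratio scale."""
        return (
            float(2.0 ** (self.median_log2_ratio - self.ci_half_width)),
            float(2.0 ** (self.median_log2_ratio + self.ci_half_width)),
        )


def pairwise_expression_filter(
    a: np.ndarray, b: np.ndarray, min_fpkm: float = 1.0
) -> np.ndarray:
    """Mask of genes retained for a two-sample comparison.

    A gene is dropped only when its FPKM is strictly below ``min_fpkm`` in
    BOTH samples: requiring joint failure keeps genuinely sample-specific
    genes (e.g. testis-specific ones silent elsewhere) in the analysis.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return ~((a < min_fpkm) & (b < min_fpkm))


def quantile_normalize(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample quantile normalization (preprocessCore-style).

    The rank-k value of each output equals the mean of the two inputs'
    rank-k order statistics; tied input values receive the average of their
    tied ranks' reference values.  With no ties the two outputs have
    identical multisets, and the transform is idempotent.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("quantile_normalize expects two 1-D vectors of equal length")
    if a.size == 0:
        return a.copy(), b.copy()
    ref = (np.sort(a) + np.sort(b)) / 2.0

    def _one(x: np.ndarray) -> np.ndarray:
        r = stats.rankdata(x, method="average") - 1.0  # 0-based, half-integer at ties
        lo = np.floor(r).astype(int)
        hi = np.ceil(r).astype(int)
        return (ref[lo] + ref[hi]) / 2.0

    return _one(a), _one(b)


def _notch_summary(log2_ratios: np.ndarray, cls: str, p: float) -> RatioSummary:
    q1, q3 = np.percentile(log2_ratios, [25, 75])  # type-7 linear interpolation
    iqr = q3 - q1
    return RatioSummary(
        chromosome_class=cls,
        n_genes=log2_ratios.size,
        median_log2_ratio=float(np.median(log2_ratios)),
        ci_half_width=float(1.57 * iqr / np.sqrt(log2_ratios.size)),
        rank_test_p=p,
    )


def _ratio_analysis(
    numer: np.ndarray, denom: np.ndarray, is_x: np.ndarray, min_fpkm: float
) -> tuple[list[RatioSummary], pd.DataFrame]:
    """Shared core of the M/F and C/A analyses."""
    numer = np.asarray(numer, dtype=float)
    denom = np.asarray(denom, dtype=float)
    is_x = np.asarray(is_x, dtype=bool)
    keep = pairwise_expression_filter(numer, denom, min_fpkm)
    numer, denom, is_x = numer[keep], denom[keep], is_x[keep]
    if numer.size == 0 or not (~is_x).any():
        raise ValueError("ratio analysis needs at least one retained autosomal gene")
    qn_n, qn_d = quantile_normalize(numer, denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = qn_n / qn_d
    ok = np.isfinite(ratio) & (ratio > 0)
    ratio, is_x, kept_idx = ratio[ok], is_x[ok], np.flatnonzero(keep)[ok]
    # recentre by the autosomal median ratio; done in log2 space so the
    # autosomal median lands at exactly 1 for even sample sizes too
    log2r = np.log2(ratio)
    log2r = log2r - np.median(log2r[~is_x])
    x_vals, a_vals = log2r[is_x], log2r[~is_x]
    if x_vals.size and a_vals.size:
        _, p = stats.mannwhitneyu(x_vals, a_vals, alternative="two-sided")
    else:
        p = np.nan
    summaries = [_notch_summary(a_vals, "autosome", np.nan)]
    if x_vals.size:
        summaries.append(_notch_summary(x_vals, "X", float(p)))
    per_gene = pd.DataFrame(
        {"index": kept_idx, "log2_ratio": log2r, "chromosome_class":
         np.where(is_x, "X", "autosome")}
    )
    return summaries, per_gene


def mf_ratio_analysis(
    male_fpkm: np.ndarray,
    female_fpkm: np.ndarray,
    is_x: np.ndarray,
    min_fpkm: float = 1.0,
) -> tuple[list[RatioSummary], pd.DataFrame]:
    """Male/female expression ratios for one tissue, X vs autosomes.

    Inputs are paired per gene.  Returns ([autosome summary, X summary],
    per-gene table of recentred log2(M/F)); after recentring the autosomal
    median ratio is exactly 1 (log2 = 0).
    """
    return _ratio_analysis(male_fpkm, female_fpkm, is_x, min_fpkm)


def current_ancestral_analysis(
    pairs: pd.DataFrame, sex: str, min_fpkm: float = 1.0
) -> tuple[list[RatioSummary], pd.DataFrame]:
    """Current/ancestral expression ratios for one sex, X vs autosomes.

    ``pairs`` is a 1:1 ortholog table with columns ``current_<sex>``,
    ``ancestral_<sex>`` and boolean ``is_x``; the ancestral value proxies
    the gene's expression before its element became sex-linked.
    """
    cur = pairs[f"current_{sex}"].to_numpy(dtype=float)
    anc = pairs[f"ancestral_{sex}"].to_numpy(dtype=float)
    return _ratio_analysis(cur, anc, pairs["is_x"].to_numpy(), min_fpkm)


def build_ortholog_pairs(
    expression: pd.DataFrame,
    ancestral: pd.DataFrame,
    orthologs: pd.DataFrame,
    tissue: str,
    x_elements: list[str],
) -> pd.DataFrame:
    """Assemble the C/A analysis table from long-format expression tables.

    ``expression``/``ancestral`` are long tables (gene_id, tissue, sex,
    fpkm); ``orthologs`` maps focal_gene -> ref_gene with the reference
    element used as the chromosome-class proxy.
    """
    def _wide(df: pd.DataFrame, key: str) -> pd.DataFrame:
        sub = df[df["tissue"] == tissue]
        return sub.pivot_table(index="gene_id", columns="sex", values="fpkm").rename(
            columns={"male": f"{key}_male", "female": f"{key}_female"}
        )

    cur = _wide(expression, "current")
    anc = _wide(ancestral, "ancestral")
    out = orthologs.merge(cur, left_on="focal_gene", right_index=True)
    out = out.merge(anc, left_on="ref_gene", right_index=True)
    out["is_x"] = out["ref_element"].isin(x_elements)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# sex-bias classification
# ---------------------------------------------------------------------------

MF_CATEGORIES = (
    "female_specific", "strongly_female", "female_biased", "unbiased",
    "male_biased", "strongly_male", "male_specific",
)

#: the five samples required by the testis-bias rules
TESTIS_RULE_SAMPLES = ("testis", "male_head", "female_head", "female_body", "ovary")


def classify_mf_bias(
    male_fpkm: np.ndarray,
    female_fpkm: np.ndarray,
    fold_biased: float = 2.0,
    fold_strong: float = 5.0,
    min_fpkm: float = 1.0,
) -> np.ndarray:
    """Per-gene male/female bias category from one tissue's paired FPKM.

    A gene expressed (>= min_fpkm) in exactly one sex is sex-specific;
    otherwise the M/F fold change is binned at ``fold_biased`` and
    ``fold_strong`` (>= convention).  The fold cut-offs are conventions of
    this package, exposed as parameters.
    """
    m = np.asarray(male_fpkm, dtype=float)
    f = np.asarray(female_fpkm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = m / f
    out = np.full(m.shape, "unbiased", dtype=object)
    out[(m >= min_fpkm) & (f < min_fpkm)] = "male_specific"
    out[(f >= min_fpkm) & (m < min_fpkm)] = "female_specific"
    both = (m >= min_fpkm) & (f >= min_fpkm)
    out[both & (ratio >= fold_strong)] = "strongly_male"
    out[both & (ratio >= fold_biased) & (ratio < fold_strong)] = "male_biased"
    out[both & (ratio <= 1.0 / fold_strong)] = "strongly_female"
    out[both & (ratio <= 1.0 / fold_biased) & (ratio > 1.0 / fold_strong)] = "female_biased"
    return out


def classify_testis_bias(samples: pd.DataFrame) -> np.ndarray:
    """Testis-bias category per gene from the five reference samples.

    ``samples`` must carry columns testis, male_head, female_head,
    female_body, ovary (FPKM).  A gene is strongly_testis_biased when testis
    expression is at least 3-fold higher than EACH of the other four
    samples, and testis_specific at 10-fold (>= comparisons); specificity
    implies the strong-bias criterion.
    """
    missing = set(TESTIS_RULE_SAMPLES) - set(samples.columns)
    if missing:
        raise ValueError(f"testis-bias rules need samples: {sorted(missing)}")
    testis = samples["testis"].to_numpy(dtype=float)
    others = samples[list(TESTIS_RULE_SAMPLES[1:])].to_numpy(dtype=float)
    max_other = others.max(axis=1)
    out = np.full(testis.shape, "none", dtype=object)
    out[testis >= 3.0 * max_other] = "strongly_testis_biased"
    out[testis >= 10.0 * max_other] = "testis_specific"
    return out


def compare_bias_proportions(
    categories: np.ndarray, is_x: np.ndarray, biased_set: set[str]
) -> tuple[float, float, float]:
    """X vs autosome proportion of genes in ``biased_set``.

    Returns (proportion on X, proportion on autosomes, chi-square p); the
    p-value is a Pearson chi-square on the 2x2 table, NaN when a margin is
    empty.
    """
    categories = np.asarray(categories, dtype=object)
    is_x = np.asarray(is_x, dtype=bool)
    biased = np.isin(categories, list(biased_set))
    nx, na = int(is_x.sum()), int((~is_x).sum())
    bx, ba = int(biased[is_x].sum()), int(biased[~is_x].sum())
    px = bx / nx if nx else np.nan
    pa = ba / na if na else np.nan
    table = np.array([[bx, nx - bx], [ba, na - ba]])
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return px, pa, float("nan")
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return px, pa, float(p)


def summaries_frame(summaries: list[RatioSummary], **extra) -> pd.DataFrame:
    rows = []
    for s in summaries:
        lo, hi = s.ci_ratio()
        rows.append(
            {
                "chromosome_class": s.chromosome_class,
                "n_genes": s.n_genes,
                "median_log2_ratio": s.median_log2_ratio,
                "median_ratio": s.median_ratio,
                "ci_half_width_log2": s.ci_half_width,
                "ci_ratio_low": lo,
                "ci_ratio_high": hi,
                "rank_test_p": s.rank_test_p,
                **extra,
            }
        )
    return pd.DataFrame(rows)


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "tissue", "sex", "fpkm"} - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns: {sorted(missing)}")
    return df
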