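"""Seeded synthetic genomes with planted sex-chromosome scenarios.

Every downstream stage of the pipeline (element assignment, coverage-based
detection, SNP-based detection, dosage analysis) is tested against data from
this module, which plants a known karyotype and records the ground truth.

The generator emulates the *downstream summaries* of a male/female
resequencing study of a non-model fly — per-scaffold depth tables,
per-site allele-count pileups, gene-hit tables and FPKM matrices — not the
reads themselves.  Scenarios per Muller element:

``autosomal``
    two copies in both sexes.
``diff_X`` / ``diff_Z``
    fully differentiated sex chromosome: one copy in the heterogametic sex
    (males for X, females for Z), two in the other.
``neo_X(d)``
    young neo-sex chromosome at differentiation level ``d`` in [0, 1].  The
    heterogametic-sex depth multiplier is (1 - d/2): at d=0 the Y homolog
    still cross-maps and depth is equal; at d=1 male depth is halved.
    Divergent X-Y sites appear as extra male-only heterozygous sites.
``partial_sexlinked(q)``
    a fraction q of the element's scaffolds are fully sex-linked, the rest
    autosomal (a partially sex-linked element).

All randomness flows from one integer seed through numpy SeedSequence
spawn keys, so each generator can be re-run independently and the whole
suite is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ELEMENTS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F")

# substream ids for the counter-based seed scheme
_STREAM_GENOME = 0
_STREAM_DEPTH = 1
_STREAM_PILEUP = 2
_STREAM_HITS = 3
_STREAM_EXPR = 4


class ConfigError(ValueError):
    """Raised when a ScenarioConfig violates its invariants."""


@dataclass(frozen=True)
class ElementScenario:
    """Planted evolutionary state of one Muller element.

    kind: one of autosomal / diff_X / diff_Z / neo_X / partial_sexlinked.
    d: differentiation level for neo_X (0 = undifferentiated, 1 = full).
    q: sex-linked fraction of scaffolds for partial_sexlinked.
    """

    kind: str = "autosomal"
    d: float = 0.0
    q: float = 0.0

    _KINDS = ("autosomal", "diff_X", "diff_Z", "neo_X", "partial_sexlinked")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ConfigError(f"unknown scenario kind {self.kind!r}")
        if not (0.0 <= self.d <= 1.0 and 0.0 <= self.q <= 1.0):
            raise ConfigError("scenario parameters d and q must lie in [0, 1]")

    @classmethod
    def parse(cls, text: str) -> "ElementScenario":
        """Parse 'neo_X:0.3' / 'partial_sexlinked:0.5' / 'diff_X' strings."""
        kind, _, arg = text.partition(":")
        kind = kind.strip()
        if kind == "neo_X" and arg:
            return cls(kind="neo_X", d=float(arg))
        if kind == "partial_sexlinked" and arg:
            return cls(kind="partial_sexlinked", q=float(arg))
        return cls(kind=kind)


def _default_proportions() -> dict[str, float]:
    # five large elements plus the small dot (F)
    return {"A": 0.21, "B": 0.21, "C": 0.21, "D": 0.21, "E": 0.11, "F": 0.05}


@dataclass
class ScenarioConfig:
    """Full description of a planted study: genome, depth, SNP and
    expression parameters.

    Depth is reads per base per diploid copy-pair; a fully differentiated
    X-linked scaffold therefore averages depth_mean/2 in males.
    depth_dispersion is the negative-binomial overdispersion (variance =
    m + dispersion * m^2); 0 gives the Poisson limit.
    """

    n_scaffolds: int = 2000
    element_proportions: dict[str, float] = field(default_factory=_default_proportions)
    # lognormal law for scaffold lengths: (mean, sd) of ln(length), floor in bp
    scaffold_length_law: tuple[float, float, float] = (8.0, 0.6, 500.0)
    per_element_scenario: dict[str, ElementScenario] = field(default_factory=dict)
    heterogamety: str = "XY"  # XY | ZW | none
    depth_mean: float = 20.0
    depth_dispersion: float = 0.02
    base_het_rate: float = 1e-3  # heterozygous sites / bp / sex
    xy_divergence_rate: float = 0.0  # extra male-only variant rate on neo_X
    retained_homology: float = 1.0  # fraction of divergent sites still cross-mapping
    seq_error_rate: float = 0.0
    hit_noise_rate: float = 0.0
    genes_per_bp: float = 1e-4  # 1 gene / 10 kb
    low_score_fraction: float = 0.1  # gene hits planted at/below the score-50 cut
    compensation_mode: str = "male_up"  # male_up | female_down | none
    sexbias_fractions: tuple[float, float] = (0.1, 0.1)  # (testis-specific, ovary-biased)
    expr_log_mean: float = 3.0  # ln-FPKM location of the ancestral expression law
    expr_log_sd: float = 1.0
    expr_noise_sd: float = 0.25  # multiplicative lognormal measurement noise (ln units)
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        props = self.element_proportions
        if set(props) - set(ELEMENTS):
            raise ConfigError(f"unknown elements in proportions: {set(props) - set(ELEMENTS)}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigError("element_proportions must sum to 1")
        if any(not (0.0 <= p <= 1.0) for p in props.values()):
            raise ConfigError("element proportions must lie in [0, 1]")
        if self.n_scaffolds < 0:
            raise ConfigError("n_scaffolds must be non-negative")
        if self.depth_mean <= 0:
            raise ConfigError("depth_mean must be positive")
        if self.depth_dispersion < 0:
            raise ConfigError("depth_dispersion must be non-negative")
        if self.heterogamety not in ("XY", "ZW", "none"):
            raise ConfigError(f"unknown heterogamety {self.heterogamety!r}")
        if self.compensation_mode not in ("male_up", "female_down", "none"):
            raise ConfigError(f"unknown compensation_mode {self.compensation_mode!r}")
        scen = self.per_element_scenario
        if set(scen) - set(ELEMENTS):
            raise ConfigError("per_element_scenario keys must be Muller elements")
        n_diff_x = sum(1 for s in scen.values() if s.kind == "diff_X")
        n_diff_z = sum(1 for s in scen.values() if s.kind == "diff_Z")
        # multi-element X/Z systems exist (e.g. multiple fused elements) but
        # must be asked for explicitly
        if self.heterogamety == "XY" and n_diff_z:
            raise ConfigError("diff_Z scenario requires ZW heterogamety")
        if self.heterogamety == "ZW" and n_diff_x:
            raise ConfigError("diff_X scenario requires XY heterogamety")
        if not (0.0 <= self.hit_noise_rate <= 1.0):
            raise ConfigError("hit_noise_rate must lie in [0, 1]")
        tf, of = self.sexbias_fractions
        if not (0.0 <= tf <= 1.0 and 0.0 <= of <= 1.0 and tf + of <= 1.0):
            raise ConfigError("sexbias_fractions must be fractions with sum <= 1")

    def scenario_for(self, element: str) -> ElementScenario:
        return self.per_element_scenario.get(element, ElementScenario())

    def rng(self, stream: int) -> np.random.Generator:
        ss = np.random.SeedSequence(entropy=int(self.seed), spawn_key=(stream,))
        return np.random.default_rng(ss)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["per_element_scenario"] = {
            k: dataclasses.asdict(v) for k, v in self.per_element_scenario.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        scen = d.get("per_element_scenario") or {}
        parsed = {}
        for k, v in scen.items():
            if isinstance(v, str):
                parsed[k] = ElementScenario.parse(v)
            elif isinstance(v, dict):
                parsed[k] = ElementScenario(**v)
            else:
                parsed[k] = v
        d["per_element_scenario"] = parsed
        if "scaffold_length_law" in d:
            d["scaffold_length_law"] = tuple(d["scaffold_length_law"])
        if "sexbias_fractions" in d:
            d["sexbias_fractions"] = tuple(d["sexbias_fractions"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Planted ground truth: per-scaffold element and copy numbers, per-gene
    element, per-gene expression class."""

    scaffolds: pd.DataFrame  # scaffold_id, length_bp, element, male_cn, female_cn, neo, d
    genes: pd.DataFrame | None = None  # gene_id, scaffold_id, element
    expression_classes: pd.DataFrame | None = None  # gene_id, expr_class

    def copy_number(self, sex: str) -> np.ndarray:
        return self.scaffolds["male_cn" if sex == "male" else "female_cn"].to_numpy()


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(config: ScenarioConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw scaffolds: Muller element by multinomial sampling, lengths
    lognormal with a floor, planted copy numbers per the element scenarios.

    Returns (scaffold table, truth).  The scaffold table carries
    scaffold_id, length_bp and true_element; the truth additionally records
    copy numbers per sex and the neo-X differentiation level.
    """
    config.validate()
    rng = config.rng(_STREAM_GENOME)
    n = int(config.n_scaffolds)

    elems = np.array(ELEMENTS)
    probs = np.array([config.element_proportions.get(e, 0.0) for e in ELEMENTS])
    element = rng.choice(elems, size=n, p=probs / probs.sum()) if n else np.array([], dtype=object)

    mu, sd, floor = config.scaffold_length_law
    lengths = np.maximum(np.round(rng.lognormal(mu, sd, size=n)), floor).astype(np.int64)

    het = config.heterogamety
    male_cn = np.full(n, 2.0)
    female_cn = np.full(n, 2.0)
    neo = np.zeros(n, dtype=bool)
    dlevel = np.zeros(n)
    for e in ELEMENTS:
        mask = element == e
        if not mask.any():
            continue
        scen = config.scenario_for(e)
        if scen.kind == "diff_X":
            male_cn[mask] = 1.0
        elif scen.kind == "diff_Z":
            female_cn[mask] = 1.0
        elif scen.kind == "neo_X":
            # Y reads still cross-map: effective male copy number 2(1 - d/2)
            neo[mask] = True
            dlevel[mask] = scen.d
            if het == "ZW":
                female_cn[mask] = 2.0 * (1.0 - scen.d / 2.0)
            else:
                male_cn[mask] = 2.0 * (1.0 - scen.d / 2.0)
        elif scen.kind == "partial_sexlinked":
            idx = np.flatnonzero(mask)
            k = int(round(scen.q * idx.size))
            chosen = rng.choice(idx, size=k, replace=False) if k else np.array([], dtype=int)
            if het == "ZW":
                female_cn[chosen] = 1.0
            else:
                male_cn[chosen] = 1.0

    ids = np.array([f"scf{i:06d}" for i in range(n)], dtype=object)
    scaffolds = pd.DataFrame(
        {"scaffold_id": ids, "length_bp": lengths, "true_element": element}
    )
    truth_df = pd.DataFrame(
        {
            "scaffold_id": ids,
            "length_bp": lengths,
            "element": element,
            "male_cn": male_cn,
            "female_cn": female_cn,
            "neo": neo,
            "d": dlevel,
        }
    )
    return scaffolds, SyntheticTruth(scaffolds=truth_df)


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------

def _overdispersed_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts with var = m + dispersion*m^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_depth(
    genome: pd.DataFrame, truth: SyntheticTruth, config: ScenarioConfig
) -> pd.DataFrame:
    """Per-scaffold mean depth per sex: negative-binomial read-base totals
    divided by scaffold length.  Expected depth is
    depth_mean * copy_number / 2 — an X-linked scaffold averages half depth
    in males.

    Returns a table with scaffold_id, length_bp, male_depth, female_depth.
    """
    rng = config.rng(_STREAM_DEPTH)
    t = truth.scaffolds
    lengths = t["length_bp"].to_numpy(dtype=float)
    out = {"scaffold_id": t["scaffold_id"].to_numpy(), "length_bp": t["length_bp"].to_numpy()}
    for sex in ("male", "female"):
        cn = truth.copy_number(sex)
        mean_bases = config.depth_mean * (cn / 2.0) * lengths
        counts = _overdispersed_counts(rng, mean_bases, config.depth_dispersion)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"{sex}_depth"] = np.where(lengths > 0, counts / lengths, 0.0)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# pileups
# ---------------------------------------------------------------------------

_BASES = np.array(["A", "C", "G", "T"])


def simulate_pileups(
    genome: pd.DataFrame, truth: SyntheticTruth, config: ScenarioConfig
) -> dict[str, pd.DataFrame]:
    """Variant-site pileups per sex (homozygous sites carry no signal for
    the SNP caller and are omitted).

    Heterozygous sites arrive at base_het_rate per bp per sex; scaffolds on a
    young neo-X additionally receive male-only sites at
    xy_divergence_rate * retained_homology per bp (fixed X-Y differences that
    appear heterozygous in males because X and Y reads co-map).  Site depth
    follows the same overdispersed law as the coverage table, scaled by copy
    number; allele counts at a het site are Binomial(depth, 0.5) between two
    distinct bases.  Optional uniform sequencing error adds a third allele.

    Returns {"male": DataFrame, "female": DataFrame} with columns
    scaffold_id, pos, A, C, G, T (1-based positions).
    """
    rng = config.rng(_STREAM_PILEUP)
    t = truth.scaffolds
    lengths = t["length_bp"].to_numpy(dtype=float)
    neo = t["neo"].to_numpy()
    het_sex = "female" if config.heterogamety == "ZW" else "male"
    out: dict[str, pd.DataFrame] = {}
    for sex in ("male", "female"):
        rate = np.full(len(t), config.base_het_rate)
        if sex == het_sex:
            rate = rate + neo * config.xy_divergence_rate * config.retained_homology
        n_sites = rng.poisson(rate * lengths)
        scaf_idx = np.repeat(np.arange(len(t)), n_sites)
        total = int(n_sites.sum())
        if total == 0:
            out[sex] = pd.DataFrame(
                {"scaffold_id": [], "pos": [], "A": [], "C": [], "G": [], "T": []}
            ).astype({"pos": np.int64, "A": np.int64, "C": np.int64, "G": np.int64, "T": np.int64})
            continue
        pos = (rng.random(total) * np.repeat(lengths, n_sites)).astype(np.int64) + 1
        cn = truth.copy_number(sex)[scaf_idx]
        depth = _overdispersed_counts(
            rng, config.depth_mean * cn / 2.0, config.depth_dispersion
        )
        alt = rng.binomial(depth, 0.5)
        ref = depth - alt
        # pick two distinct bases per site
        b1 = rng.integers(0, 4, size=total)
        b2 = (b1 + rng.integers(1, 4, size=total)) % 4
        counts = np.zeros((total, 4), dtype=np.int64)
        rows = np.arange(total)
        counts[rows, b1] = ref
        counts[rows, b2] = alt
        if config.seq_error_rate > 0:
            nerr = rng.binomial(depth, config.seq_error_rate)
            b3 = rng.integers(0, 4, size=total)
            np.add.at(counts, (rows, b3), nerr)
        df = pd.DataFrame(
            {
                "scaffold_id": t["scaffold_id"].to_numpy()[scaf_idx],
                "pos": pos,
                "A": counts[:, 0],
                "C": counts[:, 1],
                "G": counts[:, 2],
                "T": counts[:, 3],
            }
        )
        out[sex] = df.sort_values(["scaffold_id", "pos"], kind="mergesort").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# gene hits
# ---------------------------------------------------------------------------

def simulate_gene_hits(
    genome: pd.DataFrame, truth: SyntheticTruth, config: ScenarioConfig
) -> pd.DataFrame:
    """Reference-gene hits on scaffolds, emulating translated-alignment hit
    tables: genes arrive Poisson-proportional to scaffold length (default
    1 gene / 10 kb), carry the scaffold's true element flipped to a wrong one
    with probability hit_noise_rate, and a low_score_fraction of hits score
    at or below the score-50 filter.

    Updates truth.genes with the planted gene -> element map (true labels of
    the genes that pass the score filter).
    """
    rng = config.rng(_STREAM_HITS)
    t = truth.scaffolds
    n_genes = rng.poisson(config.genes_per_bp * t["length_bp"].to_numpy(dtype=float))
    scaf_idx = np.repeat(np.arange(len(t)), n_genes)
    total = int(n_genes.sum())
    elem_index = {e: i for i, e in enumerate(ELEMENTS)}
    true_elem_idx = np.array([elem_index[e] for e in t["element"]], dtype=int)[scaf_idx] \
        if total else np.array([], dtype=int)
    flip = rng.random(total) < config.hit_noise_rate
    offset = rng.integers(1, len(ELEMENTS), size=total)
    label_idx = np.where(flip, (true_elem_idx + offset) % len(ELEMENTS), true_elem_idx)
    low = rng.random(total) < config.low_score_fraction
    score = np.where(low, rng.uniform(5.0, 50.0, size=total), rng.uniform(50.5, 300.0, size=total))
    gene_ids = np.array([f"gene{i:06d}" for i in range(total)], dtype=object)
    hits = pd.DataFrame(
        {
            "query_gene_id": gene_ids,
            "scaffold_id": t["scaffold_id"].to_numpy()[scaf_idx] if total else [],
            "score": np.round(score, 2),
            "gene_element": np.array(ELEMENTS, dtype=object)[label_idx] if total else [],
        }
    )
    truth.genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "scaffold_id": hits["scaffold_id"].to_numpy(),
            "element": np.array(ELEMENTS, dtype=object)[true_elem_idx] if total else [],
        }
    )
    return hits


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

TISSUES = ("whole_body", "head", "gonad")
_SOMATIC = {"whole_body", "head"}


def _x_factor(sex: str, tissue: str, mode: str, het_sex: str) -> float:
    """Current/ancestral expression multiplier for a fully sex-linked gene."""
    if sex == het_sex:
        # hemizygous: one copy -> 0.5, somatic compensation may restore it
        if tissue in _SOMATIC and mode == "male_up":
            return 1.0
        return 0.5
    # homogametic sex keeps two copies; female_down halves them
    if mode == "female_down":
        return 0.5
    return 1.0


def simulate_expression(
    truth: SyntheticTruth, config: ScenarioConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Current and ancestral (proto-sex-chromosome) FPKM per gene.

    Ancestral expression is lognormal per gene, shared across sexes; current
    expression applies the hemizygosity/compensation multipliers on sex-linked
    genes and plants testis-specific and ovary-biased genes per
    sexbias_fractions.  Gonad expression is never compensated.  All observed
    values carry multiplicative lognormal measurement noise.

    Returns (expression, ancestral_expression, orthologs): long tables with
    gene_id, tissue, sex, fpkm (ancestral keyed by ref_gene ids) and the 1:1
    ortholog map (focal_gene, ref_gene, ref_element).
    """
    if truth.genes is None:
        raise ValueError("simulate_gene_hits must run before simulate_expression")
    rng = config.rng(_STREAM_EXPR)
    genes = truth.genes.reset_index(drop=True)
    n = len(genes)
    het_sex = "female" if config.heterogamety == "ZW" else "male"

    base = rng.lognormal(config.expr_log_mean, config.expr_log_sd, size=n)

    # sex-linkage status of each gene = its scaffold's planted copy numbers
    scaf = truth.scaffolds.set_index("scaffold_id")
    het_cn = scaf["female_cn" if het_sex == "female" else "male_cn"]
    linked = (het_cn.reindex(genes["scaffold_id"]).to_numpy() < 2.0)

    tf, of = config.sexbias_fractions
    u = rng.random(n)
    expr_class = np.where(u < tf, "testis_specific", np.where(u < tf + of, "ovary_biased", "unbiased"))

    gonad_factor = {  # multiplier on the sex-specific gonad sample
        "testis_specific": {"male": 20.0, "female": 0.05},
        "ovary_biased": {"male": 1.0, "female": 5.0},
        "unbiased": {"male": 1.0, "female": 1.0},
    }

    cur_rows, anc_rows = [], []
    for tissue in TISSUES:
        for sex in ("male", "female"):
            xf = _x_factor(sex, tissue, config.compensation_mode, het_sex)
            mean = base * np.where(linked, xf, 1.0)
            if tissue == "gonad":
                bias = np.array([gonad_factor[c][sex] for c in expr_class])
                mean = mean * bias
            noise = rng.lognormal(0.0, config.expr_noise_sd, size=n)
            anc_noise = rng.lognormal(0.0, config.expr_noise_sd, size=n)
            cur_rows.append(
                pd.DataFrame(
                    {"gene_id": genes["gene_id"], "tissue": tissue, "sex": sex,
                     "fpkm": mean * noise}
                )
            )
            anc_mean = base.copy()
            if tissue == "gonad":
                anc_mean = anc_mean * np.array([gonad_factor[c][sex] for c in expr_class])
            anc_rows.append(
                pd.DataFrame(
                    {"gene_id": "ref_" + genes["gene_id"], "tissue": tissue, "sex": sex,
                     "fpkm": anc_mean * anc_noise}
                )
            )
    expression = pd.concat(cur_rows, ignore_index=True)
    ancestral = pd.concat(anc_rows, ignore_index=True)
    orthologs = pd.DataFrame(
        {
            "focal_gene": genes["gene_id"],
            "ref_gene": "ref_" + genes["gene_id"],
            "ref_element": genes["element"],
        }
    )
    truth.expression_classes = pd.DataFrame(
        {"gene_id": genes["gene_id"], "expr_class": expr_class, "sex_linked": linked}
    )
    return expression, ancestral, orthologs


# ---------------------------------------------------------------------------
# convenience bundle + disk I/O
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """All tables for one simulated study."""

    config: ScenarioConfig
    truth: SyntheticTruth
    scaffolds: pd.DataFrame
    depth: pd.DataFrame
    pileups: dict[str, pd.DataFrame]
    gene_hits: pd.DataFrame
    expression: pd.DataFrame
    ancestral_expression: pd.DataFrame
    orthologs: pd.DataFrame


def simulate_study(config: ScenarioConfig) -> SyntheticStudy:
    """Run all five generators in dependency order."""
    scaffolds, truth = simulate_genome(config)
    depth = simulate_depth(scaffolds, truth, config)
    pileups = simulate_pileups(scaffolds, truth, config)
    hits = simulate_gene_hits(scaffolds, truth, config)
    expression, ancestral, orthologs = simulate_expression(truth, config)
    return SyntheticStudy(
        config=config, truth=truth, scaffolds=scaffolds, depth=depth,
        pileups=pileups, gene_hits=hits, expression=expression,
        ancestral_expression=ancestral, orthologs=orthologs,
    )


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write all study tables as TSV plus the truth/config as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kw = dict(sep="\t", index=False)
    study.scaffolds.to_csv(outdir / "scaffolds.tsv", **kw)
    study.depth.to_csv(outdir / "depth.tsv", **kw)
    for sex, df in study.pileups.items():
        df.to_csv(outdir / f"pileup_{sex}.tsv", **kw)
    study.gene_hits.to_csv(outdir / "gene_hits.tsv", **kw)
    study.expression.to_csv(outdir / "expression.tsv", **kw)
    study.ancestral_expression.to_csv(outdir / "ancestral_expression.tsv", **kw)
    study.orthologs.to_csv(outdir / "orthologs.tsv", **kw)
    truth = {
        "scaffolds": study.truth.scaffolds.to_dict(orient="list"),
        "config": study.config.to_dict(),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1, default=str))
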