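"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the library's own code paths: the
Fisher oracle sums hypergeometric probabilities from exact binomial
coefficients, the SNP oracle re-applies the calling rule literally to
enumerated compositions, and the parsimony oracle enumerates every
internal-state assignment.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import pandas as pd
import pytest

import karyoshift as ks


# ---------------------------------------------------------------------------
# scenario fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def diffx_config() -> ks.ScenarioConfig:
    """2,000-scaffold genome with the dot element (F) as a differentiated X."""
    return ks.ScenarioConfig(
        per_element_scenario={"F": ks.ElementScenario("diff_X")}, seed=1
    )


@pytest.fixture(scope="session")
def diffx_study(diffx_config) -> ks.SyntheticStudy:
    return ks.simulate_study(diffx_config)


@pytest.fixture(scope="session")
def diffx_assignments(diffx_study) -> pd.DataFrame:
    return ks.assign_scaffold_elements(ks.filter_hits(diffx_study.gene_hits))


# ---------------------------------------------------------------------------
# Fisher oracle: one-sided over-representation p as an exact tail sum
# ---------------------------------------------------------------------------

def fisher_greater_oracle(k: int, n1: int, k_total: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(n, k_total, n1), from exact
    binomial coefficients (2x2 table: k of n1 element scaffolds are
    candidates, k_total of n overall)."""
    denom = math.comb(n, k_total)
    lo = k
    hi = min(n1, k_total)
    total = Fraction(0)
    for j in range(lo, hi + 1):
        total += Fraction(math.comb(n1, j) * math.comb(n - n1, k_total - j), denom)
    return float(total)


# ---------------------------------------------------------------------------
# SNP-caller oracle: literal rule on an explicit composition
# ---------------------------------------------------------------------------

def snp_rule_oracle(counts: tuple[int, int, int, int],
                    min_depth: int = 6, allele_fraction: float = 0.3):
    """(kept, is_snp) by direct application of the printed rule."""
    depth = sum(counts)
    if depth < min_depth:
        return False, False
    n_alleles = sum(1 for c in counts if c >= allele_fraction * depth and c > 0)
    return True, n_alleles >= 2


def compositions(total_max: int, parts: int = 4):
    """All non-negative integer compositions with sum <= total_max."""
    for total in range(total_max + 1):
        for cuts in itertools.combinations(range(total + parts - 1), parts - 1):
            comp = []
            prev = -1
            for c in cuts:
                comp.append(c - prev - 1)
                prev = c
            comp.append(total + parts - 2 - prev)
            yield tuple(comp)


# ---------------------------------------------------------------------------
# parsimony oracle: exhaustive minimum over internal-state assignments
# ---------------------------------------------------------------------------

def parsimony_bruteforce(tree, tip_state: dict, states: tuple) -> int:
    """Minimal number of state changes over ALL internal assignments."""
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    leaves = {id(nd): tip_state[nd.taxon.label] for nd in tree.leaf_node_iter()}
    best = None
    for assign in itertools.product(states, repeat=len(internals)):
        state = dict(leaves)
        for nd, s in zip(internals, assign):
            state[id(nd)] = s
        cost = 0
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None and state[id(nd)] != state[id(nd.parent_node)]:
                cost += 1
        if best is None or cost < best:
            best = cost
    return best


def all_rooted_topologies(tips: tuple[str, ...]):
    """Every rooted (possibly multifurcating) topology on the labeled tips,
    as Newick strings."""
    def build(labels: tuple[str, ...]) -> list[str]:
        if len(labels) == 1:
            return [labels[0]]
        out = []
        for parts in set_partitions(labels):
            if len(parts) < 2:
                continue
            for combo in itertools.product(*(build(tuple(p)) for p in parts)):
                out.append("(" + ",".join(combo) + ")")
        return out

    return [s + ";" for s in build(tips)]


def set_partitions(items):
    """All partitions of a sequence into non-empty blocks."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part
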