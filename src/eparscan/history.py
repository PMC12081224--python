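"""History of the NAHR events: origin counts, rate, expansion, HWE.

Minimum-origin counting uses irreversible (gain-only, no-loss) parsimony:
each junction type defines a presence/absence character on the tips of
the haplogroup tree, and because a Y-linked gain is never lost again, the
minimum number of independent NAHR events explaining the character is the
number of maximal subtrees whose tips are all present.  A loss-permitting
model would collapse every pattern to a single ancestral gain and is
deliberately not offered.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .trees import Clade, HaplogroupTree

__all__ = [
    "OriginTable",
    "MinOriginsResult",
    "RateInputs",
    "HWEResult",
    "min_origins",
    "branch_generations_and_rate",
    "expansion_fold",
    "hwe_x_test",
]


@dataclass
class OriginTable:
    """Per-sample (lineage tip, junction type) annotations on a tree."""

    assignments: Mapping[str, tuple[str, str]]  # sample -> (tip, type_id)
    tree: HaplogroupTree

    def presence_by_type(self) -> dict[str, set[str]]:
        presence: dict[str, set[str]] = {}
        for sample, (tip, type_id) in self.assignments.items():
            if tip not in self.tree:
                raise KeyError(f"sample {sample!r} placed on unknown tip {tip!r}")
            presence.setdefault(type_id, set()).add(tip)
        return presence


@dataclass
class MinOriginsResult:
    count: int
    gains: list[tuple[str, str]]  # (junction type, gain branch label)

    def per_type(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for type_id, _ in self.gains:
            out[type_id] = out.get(type_id, 0) + 1
        return out


def min_origins(table: OriginTable) -> MinOriginsResult:
    """Minimum independent gains over all junction types.

    For each type, presence is marked on every tip carrying at least one
    sample of that type; the minimal gain set under gain-only parsimony
    places one gain above each maximal all-present subtree.  The total is
    the sum over types, and the gain branches are reported.
    """
    if not table.assignments:
        raise ValueError("origin table is empty")
    gains: list[tuple[str, str]] = []
    for type_id, present in sorted(table.presence_by_type().items()):
        for branch in _maximal_present_subtrees(table.tree.root, present):
            gains.append((type_id, branch))
    return MinOriginsResult(count=len(gains), gains=gains)


def _maximal_present_subtrees(root: Clade, present: set[str]) -> list[str]:
    """Labels of nodes heading maximal subtrees with every tip present."""
    gains: list[str] = []
    memo: dict[int, bool] = {}  # node id -> every tip below is present

    def fill(node: Clade) -> bool:
        if node.is_tip:
            memo[id(node)] = node.label in present
        else:
            results = [fill(child) for child in node.children]
            memo[id(node)] = all(results)
        return memo[id(node)]

    fill(root)

    def collect(node: Clade) -> None:
        if memo[id(node)]:
            gains.append(node.label)
            return
        for child in node.children:
            collect(child)

    if memo[id(root)]:
        return [root.label]
    collect(root)
    return gains


# ---------------------------------------------------------------------------
# NAHR formation rate


@dataclass
class RateInputs:
    """Branch-generation bookkeeping for the NAHR rate estimate.

    ``s_total`` SNPs across the reference MSY phylogeny with a mean of
    ``s_tip_mean`` SNPs from root to tip imply ``s_total / s_tip_mean``
    tip-depth units of branch length; scaling by TMRCA in generations
    gives the total generations surveyed by the phylogeny.
    """

    s_total: float
    s_tip_mean: float
    tmrca_years: float
    gen_years: float = 31.0
    n_events: int = 0

    def validate(self) -> None:
        for name in ("s_total", "s_tip_mean", "tmrca_years", "gen_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.s_tip_mean > self.s_total:
            raise ValueError("mean root-to-tip SNPs cannot exceed the total")
        if self.n_events < 0:
            raise ValueError("n_events must be non-negative")


def branch_generations_and_rate(inputs: RateInputs) -> tuple[float, float]:
    """Total generations in the phylogeny and the per-generation NAHR rate.

    generations = (s_total / s_tip_mean) * (tmrca_years / gen_years);
    rate = n_events / generations.  Both are returned unrounded.
    """
    inputs.validate()
    generations = (inputs.s_total / inputs.s_tip_mean) * (
        inputs.tmrca_years / inputs.gen_years
    )
    return generations, inputs.n_events / generations


def expansion_fold(
    current_freq: float, founder_carriers: int, founder_pop: int
) -> float:
    """Fold change of carrier frequency since the founding event."""
    if founder_pop <= 0:
        raise ValueError("founder_pop must be positive")
    if founder_carriers < 1:
        raise ValueError("at least one founder carrier is required")
    if not 0.0 <= current_freq <= 1.0:
        raise ValueError("current_freq must be a proportion")
    return current_freq / (founder_carriers / founder_pop)


# ---------------------------------------------------------------------------
# X-linked Hardy-Weinberg test


@dataclass
class HWEResult:
    q_hat: float
    expected_male_carriers: float
    expected_het_females: float
    expected_hom_females: float
    chi_square: float
    df: int
    p_value: float


def hwe_x_test(
    n_male_carriers: int,
    n_males: int,
    n_het_females: int,
    n_hom_females: int,
    n_females: int,
) -> HWEResult:
    """Joint male/female Hardy-Weinberg test for an X-linked allele.

    The allele frequency is estimated from the pooled X chromosomes
    (males carry one, females two); expected counts are q*n for
    hemizygous male carriers and 2q(1-q)*n / q^2*n for heterozygous and
    homozygous females.  The chi-square sums over the five phenotype
    cells (two male, three female) with df = 2: five cells minus the two
    sex totals minus one estimated parameter.
    """
    if n_males <= 0 or n_females <= 0:
        raise ValueError("sample totals must be positive")
    if n_male_carriers > n_males or n_het_females + n_hom_females > n_females:
        raise ValueError("carrier counts exceed sample totals")
    q = (n_male_carriers + n_het_females + 2 * n_hom_females) / (
        n_males + 2 * n_females
    )
    expected = np.array([
        q * n_males,
        (1 - q) * n_males,
        2 * q * (1 - q) * n_females,
        q * q * n_females,
        (1 - q) ** 2 * n_females,
    ])
    observed = np.array([
        n_male_carriers,
        n_males - n_male_carriers,
        n_het_females,
        n_hom_females,
        n_females - n_het_females - n_hom_females,
    ], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(
            expected > 0, (observed - expected) ** 2 / expected, 0.0
        )
    chi_square = float(terms.sum())
    df = 2
    return HWEResult(
        q_hat=q,
        expected_male_carriers=float(expected[0]),
        expected_het_females=float(expected[2]),
        expected_hom_females=float(expected[3]),
        chi_square=chi_square,
        df=df,
        p_value=float(stats.chi2.sf(chi_square, df)),
    )
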