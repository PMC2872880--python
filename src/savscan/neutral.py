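"""Neutral expectation for ESR change categories under random mutation.

Enumerates every single-base substitution of every k-mer (for hexamers:
4096 x 6 positions x 3 alternative bases = 73,728 permutations), weights
each by the empirical proportion of that ordered base substitution among
polarized variants, and accumulates the weight into the change category
of the (wild, mutant) k-mer pair. The result is the distribution of
change categories expected if variants arose with no selection on
splicing, against which observed category tallies are compared with
Yates-corrected chi-square tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .changes import ChangeCategory, FOUR_CATEGORIES, NINE_CATEGORIES
from .motifs import ESRMotifSet
from .variants import PolarizedVariant

__all__ = [
    "SubstitutionBias",
    "ExpectedChangeDistribution",
    "substitution_bias",
    "expected_change_distribution",
    "compare_to_expected",
]

_BASES = "ACGT"
SUBSTITUTIONS: tuple[tuple[str, str], ...] = tuple(
    (a, d) for a in _BASES for d in _BASES if a != d
)


@dataclass(frozen=True)
class SubstitutionBias:
    """Proportions of the 12 ordered single-base substitutions."""

    proportions: Mapping[tuple[str, str], float]

    def __post_init__(self) -> None:
        keys = set(self.proportions)
        if keys != set(SUBSTITUTIONS):
            raise ValueError(f"bias must cover exactly the 12 ordered substitutions, got {len(keys)}")
        if any(p < 0 for p in self.proportions.values()):
            raise ValueError("substitution proportions must be >= 0")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"substitution proportions must sum to 1, got {total!r}")

    def __getitem__(self, key: tuple[str, str]) -> float:
        return self.proportions[key]

    @classmethod
    def uniform(cls) -> "SubstitutionBias":
        return cls({s: 1.0 / 12.0 for s in SUBSTITUTIONS})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"substitution": f"{a}>{d}", "proportion": self.proportions[(a, d)]}
            for a, d in SUBSTITUTIONS
        ]
        return pd.DataFrame(rows)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubstitutionBias":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        props = {}
        for _, row in df.iterrows():
            anc, der = str(row["substitution"]).replace("->", ">").split(">")
            props[(anc.strip().upper(), der.strip().upper())] = float(row["proportion"])
        return cls(props)


def substitution_bias(variants: Iterable[PolarizedVariant]) -> SubstitutionBias:
    """Empirical ancestral->derived substitution proportions."""
    counts = {s: 0 for s in SUBSTITUTIONS}
    n = 0
    for v in variants:
        counts[(v.ancestral, v.derived)] += 1
        n += 1
    if n == 0:
        raise ValueError("substitution_bias requires at least one variant")
    return SubstitutionBias({s: c / n for s, c in counts.items()})


@dataclass(frozen=True)
class ExpectedChangeDistribution:
    """Expected proportions of change categories under neutrality."""

    set_name: str
    proportions: Mapping[ChangeCategory, float]
    permutation_count: int
    bias: SubstitutionBias
    unlabeled_scheme: bool = False

    @property
    def categories(self) -> tuple[ChangeCategory, ...]:
        return FOUR_CATEGORIES if self.unlabeled_scheme else NINE_CATEGORIES

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": [c.label for c in self.categories],
                "expected_proportion": [self.proportions[c] for c in self.categories],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def expected_change_distribution(
    motif_set: ESRMotifSet, bias: SubstitutionBias
) -> ExpectedChangeDistribution:
    """Enumerate all single-base k-mer mutations, bias-weighted.

    Every k-mer is counted once (uniform k-mer background); each
    (k-mer, position, alternative base) triple contributes the bias
    proportion of its substitution to the category of the (wild,
    mutant) classification pair. For hexamers the triple count is
    4096 x 6 x 3 = 73,728.
    """
    k = motif_set.k
    labels = {
        "".join(kmer): motif_set.classify("".join(kmer))
        for kmer in itertools.product(_BASES, repeat=k)
    }
    weights: dict[ChangeCategory, float] = {}
    permutations = 0
    for kmer, wild_label in labels.items():
        for pos in range(k):
            orig = kmer[pos]
            for alt in _BASES:
                if alt == orig:
                    continue
                mutant = kmer[:pos] + alt + kmer[pos + 1 :]
                cat = ChangeCategory(wild_label, labels[mutant])
                weights[cat] = weights.get(cat, 0.0) + bias[(orig, alt)]
                permutations += 1
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("bias assigns zero weight to every enumerated substitution")
    categories = FOUR_CATEGORIES if motif_set.unlabeled else NINE_CATEGORIES
    proportions = {c: weights.get(c, 0.0) / total for c in categories}
    return ExpectedChangeDistribution(
        set_name=motif_set.name,
        proportions=proportions,
        permutation_count=permutations,
        bias=bias,
        unlabeled_scheme=motif_set.unlabeled,
    )


def compare_to_expected(
    observed: Mapping[ChangeCategory, int],
    expected: ExpectedChangeDistribution,
) -> pd.DataFrame:
    """Per-category chi-square (Yates) test of observed vs expected.

    For each category, a 2x2 table of category-vs-rest counts (observed
    row, and the expected proportions scaled to the observed total) is
    tested with continuity correction. When the expected proportion is
    zero but the category was observed, the ratio is infinite and an
    exact binomial test is reported instead.
    """
    total = sum(observed.get(c, 0) for c in expected.categories)
    if total < 1:
        raise ValueError("observed counts must total at least 1")
    rows = []
    for cat in expected.categories:
        obs = observed.get(cat, 0)
        p_exp = expected.proportions[cat]
        obs_prop = obs / total
        if p_exp == 0.0:
            ratio = float("inf") if obs > 0 else float("nan")
            pval = stats.binomtest(obs, total, p=0.0, alternative="greater").pvalue
            stat = float("nan")
        else:
            ratio = obs_prop / p_exp
            table = [
                [obs, total - obs],
                [total * p_exp, total * (1.0 - p_exp)],
            ]
            stat, pval, _, _ = stats.chi2_contingency(table, correction=True)
        rows.append(
            {
                "category": cat.label,
                "observed": obs,
                "observed_proportion": obs_prop,
                "expected_proportion": p_exp,
                "ratio": ratio,
                "chi2_yates": stat,
                "p_value": pval,
            }
        )
    return pd.DataFrame(rows)
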