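"""Segregation-ratio tests, co-segregation tables, and phenotype frequencies.

The segregation test is a Pearson chi-square goodness-of-fit against an
expected Mendelian ratio (1:3 for a single recessive locus), df = 1, without
continuity correction by default; Yates' correction is available behind a
flag and can only raise the p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

PHENOTYPES = ("mutant", "wt")


@dataclass
class SegregationResult:
    n_mut: int
    n_wt: int
    ratio: tuple[int, int]
    chi2: float
    df: int
    p_value: float
    yates: bool


@dataclass
class CosegregationTable:
    table: pd.DataFrame  # phenotype x genotype counts
    n: int
    #: mutant-phenotype plants not homozygous for the tested allele — these
    #: would break a causal interpretation
    causality_breaking: int
    #: homozygous plants with wild-type phenotype — suppression candidates
    suppression_candidates: int


def segregation_test(
    n_mut: int,
    n_wt: int,
    ratio: tuple[int, int] = (1, 3),
    yates: bool = False,
) -> SegregationResult:
    """Chi-square goodness-of-fit of observed mutant:wild-type counts.

    ``ratio`` is (mutant, wild-type) expectation, e.g. (1, 3) for a
    monogenic recessive trait in an F2.
    """
    n = n_mut + n_wt
    if n <= 0:
        raise ValueError("total count must be > 0")
    a, b = ratio
    if a <= 0 or b <= 0:
        raise ValueError("ratio components must be > 0")
    if n_mut < 0 or n_wt < 0:
        raise ValueError("counts must be non-negative")
    exp_mut = n * a / (a + b)
    exp_wt = n * b / (a + b)
    correction = 0.5 if yates else 0.0
    chi2 = sum(
        (max(abs(obs - exp) - correction, 0.0)) ** 2 / exp
        for obs, exp in ((n_mut, exp_mut), (n_wt, exp_wt))
    )
    p = float(stats.chi2.sf(chi2, df=1))
    return SegregationResult(
        n_mut=n_mut, n_wt=n_wt, ratio=ratio, chi2=float(chi2), df=1,
        p_value=p, yates=yates,
    )


def cosegregation_report(records: Iterable[tuple[str, str]]) -> CosegregationTable:
    """Cross-tabulate (phenotype, genotype) records.

    Phenotypes must be "mutant" or "wt"; genotypes are free categorical
    labels where any label starting with "hom" marks homozygosity for the
    tested (deletion) allele.  Flags the two biologically meaningful
    discordance counts: mutant-phenotype plants that are not homozygous, and
    homozygous plants that look wild type (candidate suppression).
    """
    rows = list(records)
    for pheno, geno in rows:
        if pheno not in PHENOTYPES:
            raise ValueError(f"unknown phenotype label {pheno!r} (expected mutant/wt)")
        if not isinstance(geno, str) or not geno:
            raise ValueError(f"invalid genotype label {geno!r}")
    df = pd.DataFrame(rows, columns=["phenotype", "genotype"])
    table = pd.crosstab(df["phenotype"], df["genotype"]) if rows else pd.DataFrame()

    def is_hom(geno: str) -> bool:
        return geno.startswith("hom") and not geno.startswith("hom-wt") \
            and not geno.startswith("hom_wt")

    breaking = sum(1 for p, g in rows if p == "mutant" and not is_hom(g))
    suppression = sum(1 for p, g in rows if p == "wt" and is_hom(g))
    return CosegregationTable(
        table=table, n=len(rows),
        causality_breaking=breaking, suppression_candidates=suppression,
    )


def phenotype_frequencies(
    counts: dict[str, int] | Sequence[tuple[str, int]],
    n_families: int,
) -> pd.DataFrame:
    """Phenotype-class counts as percentages of screened families.

    Percent is 100 * count / n_families rounded to two decimals for display;
    the unrounded fraction is kept alongside.
    """
    if n_families <= 0:
        raise ValueError("n_families must be > 0")
    items = list(counts.items()) if isinstance(counts, dict) else list(counts)
    rows = []
    for name, count in items:
        if count < 0 or count > n_families:
            raise ValueError(f"count for {name!r} must be in [0, {n_families}]")
        frac = count / n_families
        rows.append({
            "phenotype": name, "count": count,
            "percent": round(100.0 * frac, 2), "fraction": frac,
        })
    return pd.DataFrame(rows)
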