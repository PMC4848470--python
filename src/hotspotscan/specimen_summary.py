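"""Specimen-table summary statistics (species mapping means, heterozygosity
ranges, between-species mapping comparison, heterozygosity–latitude
association).

Rounding is half-up at the printed number of decimals; the reference specimen
(whose reads built the reference genome, so its mapping fractions are ~100%)
is excluded from mapping means and comparisons by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats

from .core_io import SpecimenRecord


def _round_half_up(x: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def species_mean(
    records: list[SpecimenRecord],
    field: str,
    species: str,
    exclude_reference: bool = False,
    round_to: int | None = None,
) -> float:
    values = [
        getattr(r, field)
        for r in records
        if r.species == species and not (exclude_reference and r.is_reference)
    ]
    if not values:
        raise ValueError(f"no matching records for species {species!r}")
    mean = float(np.mean(values))
    return _round_half_up(mean, round_to) if round_to is not None else mean


def field_range(
    records: list[SpecimenRecord], field: str, round_to: int | None = None
) -> tuple[float, float]:
    if not records:
        raise ValueError("no records")
    values = [getattr(r, field) for r in records]
    lo, hi = min(values), max(values)
    if round_to is not None:
        lo, hi = _round_half_up(lo, round_to), _round_half_up(hi, round_to)
    return lo, hi


@dataclass
class ComparisonStats:
    """Two-sample t-test in both pooled-variance and Welch flavours. The
    one-sided alternative is 'first group larger'."""

    group_sizes: tuple[int, int]
    means: tuple[float, float]
    t_pooled: float
    df_pooled: float
    p_pooled_two_sided: float
    p_pooled_one_sided: float
    t_welch: float
    df_welch: float
    p_welch_two_sided: float
    p_welch_one_sided: float
    degenerate: bool = False


def compare_species_mapping(
    records: list[SpecimenRecord],
    field: str = "mapped_noncoding_pct",
    species_pair: tuple[str, str] | None = None,
    exclude_reference: bool = True,
) -> ComparisonStats:
    """Between-species comparison of a mapping fraction.

    The first species of the pair (default: the species of the reference
    specimen) is the group expected to map better."""
    species = sorted({r.species for r in records})
    if species_pair is None:
        ref = [r.species for r in records if r.is_reference]
        first = ref[0] if ref else species[0]
        second = next(s for s in species if s != first)
        species_pair = (first, second)
    g1 = [getattr(r, field) for r in records
          if r.species == species_pair[0] and not (exclude_reference and r.is_reference)]
    g2 = [getattr(r, field) for r in records
          if r.species == species_pair[1] and not (exclude_reference and r.is_reference)]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs >= 2 non-reference specimens")
    a, b = np.asarray(g1, float), np.asarray(g2, float)

    degenerate = a.var(ddof=1) == 0 and b.var(ddof=1) == 0
    if degenerate:
        if np.mean(a) == np.mean(b):
            t = 0.0
            two = one = 1.0
        else:
            warnings.warn("zero pooled variance with distinct means; p reported as 0 limit")
            t = float("inf") if np.mean(a) > np.mean(b) else float("-inf")
            two = one = 0.0
        df_p = len(a) + len(b) - 2
        return ComparisonStats((len(a), len(b)), (float(a.mean()), float(b.mean())),
                               t, df_p, two, one, t, df_p, two, one, degenerate=True)

    pooled = stats.ttest_ind(a, b, equal_var=True)
    welch = stats.ttest_ind(a, b, equal_var=False)
    one_sided = lambda res: float(res.pvalue / 2) if res.statistic > 0 else float(1 - res.pvalue / 2)
    return ComparisonStats(
        group_sizes=(len(a), len(b)),
        means=(float(a.mean()), float(b.mean())),
        t_pooled=float(pooled.statistic), df_pooled=float(pooled.df),
        p_pooled_two_sided=float(pooled.pvalue), p_pooled_one_sided=one_sided(pooled),
        t_welch=float(welch.statistic), df_welch=float(welch.df),
        p_welch_two_sided=float(welch.pvalue), p_welch_one_sided=one_sided(welch),
    )


@dataclass
class AssociationStats:
    n: int
    pearson_r: float
    pearson_t: float
    pearson_p_two_sided: float
    pearson_p_one_sided: float   # alternative: negative association
    spearman_rho: float
    spearman_p_two_sided: float


def het_latitude_association(
    records: list[SpecimenRecord],
    het_field: str = "het_pct",
) -> AssociationStats:
    """Correlation between heterozygosity and collection latitude (Pearson with
    t-test p-values, plus Spearman rank correlation)."""
    pts = [(r.latitude, getattr(r, het_field)) for r in records]
    if len(pts) < 3:
        raise ValueError("need >= 3 records with latitude")
    lat = np.array([p[0] for p in pts])
    het = np.array([p[1] for p in pts])
    if lat.std() == 0 or het.std() == 0:
        raise ValueError("zero variance in latitude or heterozygosity")
    pear = stats.pearsonr(lat, het)
    r = float(pear.statistic)
    n = len(pts)
    t = r * np.sqrt((n - 2) / (1 - r * r)) if abs(r) < 1 else float("inf") * np.sign(r)
    one_sided = float(stats.t.cdf(t, df=n - 2))  # mass below: negative association
    spear = stats.spearmanr(lat, het)
    return AssociationStats(
        n=n, pearson_r=r, pearson_t=float(t),
        pearson_p_two_sided=float(pear.pvalue), pearson_p_one_sided=one_sided,
        spearman_rho=float(spear.statistic), spearman_p_two_sided=float(spear.pvalue),
    )
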