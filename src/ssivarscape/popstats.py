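"""Heterozygosity, homozygous-fraction and spontaneous-mutation statistics.

Genomic heterozygosity is the count of heterozygous SNPs divided by the
covered bases of the sequenced sample; the founder mutation rate is the count
of homozygous differences divided by covered bases.  In the selfed progeny a
population-level spontaneous mutation is a site where strictly more than a
threshold number of lines (default 20) carry a genotype incompatible with the
founders.  Two discordance predicates are provided:

* ``shared-hom`` (default): candidate sites are those where both founders are
  homozygous for the same allele G; a line is discordant if it has a confident
  call different from G/G.  This avoids counting legitimate segregants at
  founder-heterozygous sites, where a quarter of selfed lines match neither
  founder genotype.
* ``novel-allele``: any site; a line is discordant if its call contains an
  allele present in neither founder genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MutationCallParams", "genomic_heterozygosity", "class_fraction",
    "fold_change", "homozygous_fraction", "expected_hom_fraction",
    "detect_population_mutations", "mutation_rate", "per_line_mutation_rates",
]


@dataclass(frozen=True)
class MutationCallParams:
    min_discordant_lines: int = 20   # strict >
    min_covered_lines: int = 20
    predicate: str = "shared-hom"    # or "novel-allele"

    def __post_init__(self) -> None:
        if self.min_discordant_lines < 1:
            raise ValueError("min_discordant_lines must be >= 1")
        if self.predicate not in ("shared-hom", "novel-allele"):
            raise ValueError("predicate must be 'shared-hom' or 'novel-allele'")


def genomic_heterozygosity(n_het: int, covered_bases: int) -> float:
    """Heterozygous SNP count divided by covered bases."""
    if covered_bases <= 0:
        raise ValueError("covered_bases must be > 0")
    return n_het / covered_bases


def class_fraction(class_count: int, total_count: int) -> float:
    """Percentage share of one SNP class in the total."""
    if total_count <= 0:
        raise ValueError("total_count must be > 0")
    return 100.0 * class_count / total_count


def fold_change(rate_a: float, rate_b: float) -> float:
    if rate_b <= 0:
        raise ValueError("denominator rate must be > 0")
    return rate_a / rate_b


def expected_hom_fraction(g: int) -> float:
    """Expected homozygous fraction at founder-heterozygous sites after g
    selfing generations: 1 - 2^-g (0.5 at g=1, 0.75 at g=2)."""
    if g < 0:
        raise ValueError("g must be >= 0")
    return 1.0 - 2.0 ** (-g)


def homozygous_fraction(calls: np.ndarray) -> float:
    """Observed homozygous fraction among a line's called genotypes.

    ``calls`` uses the bin/site codes 0=aa, 1=ab, 2=bb, -1 missing, restricted
    to founder-heterozygous markers.
    """
    calls = np.asarray(calls)
    called = calls >= 0
    if not called.any():
        raise ValueError("no called sites")
    return float(((calls == 0) | (calls == 2))[called].sum() / called.sum())


def detect_population_mutations(
    gt1: np.ndarray,
    gt2: np.ndarray,
    recipient_gt: np.ndarray,
    variant_gt: np.ndarray,
    params: MutationCallParams = MutationCallParams(),
) -> pd.DataFrame:
    """Sites where more than the threshold number of lines contradict the founders.

    ``gt1``/``gt2`` are (n_lines, n_sites) allele-code arrays of the lines'
    called genotypes (-1 missing); ``recipient_gt`` and ``variant_gt`` are
    (n_sites, 2) founder genotypes.  Returns a frame (site_index,
    n_discordant, n_called) of reported sites.
    """
    gt1 = np.asarray(gt1)
    gt2 = np.asarray(gt2)
    recipient_gt = np.asarray(recipient_gt)
    variant_gt = np.asarray(variant_gt)
    if (recipient_gt < 0).any() or (variant_gt < 0).any():
        raise ValueError("founder genotype missing at some site")
    n_lines, n_sites = gt1.shape
    called = (gt1 >= 0) & (gt2 >= 0)

    if params.predicate == "shared-hom":
        rec_hom = recipient_gt[:, 0] == recipient_gt[:, 1]
        var_hom = variant_gt[:, 0] == variant_gt[:, 1]
        candidate = rec_hom & var_hom & (recipient_gt[:, 0] == variant_gt[:, 0])
        g = recipient_gt[:, 0]
        discordant = called & ((gt1 != g[None, :]) | (gt2 != g[None, :]))
        discordant &= candidate[None, :]
    else:
        founder = np.stack([recipient_gt[:, 0], recipient_gt[:, 1],
                            variant_gt[:, 0], variant_gt[:, 1]], axis=1)
        novel1 = (gt1[:, :, None] != founder[None, :, :]).all(axis=2)
        novel2 = (gt2[:, :, None] != founder[None, :, :]).all(axis=2)
        discordant = called & (novel1 | novel2)
        candidate = np.ones(n_sites, dtype=bool)

    n_called = called.sum(axis=0)
    n_disc = discordant.sum(axis=0)
    report = candidate & (n_called >= params.min_covered_lines) \
        & (n_disc > params.min_discordant_lines)
    return pd.DataFrame({
        "site_index": np.flatnonzero(report),
        "n_discordant": n_disc[report],
        "n_called": n_called[report],
    })


def mutation_rate(n_mutation_sites: int, covered_bases: int) -> float:
    """Spontaneous-mutation site count divided by covered bases."""
    if covered_bases <= 0:
        raise ValueError("covered_bases must be > 0")
    return n_mutation_sites / covered_bases


def per_line_mutation_rates(
    discordant_by_line: np.ndarray, covered_sites_by_line: np.ndarray
) -> np.ndarray:
    """Per-line rates: discordant calls at reported sites over the line's
    observed-site count (sites with at least one read)."""
    covered = np.asarray(covered_sites_by_line, dtype=float)
    out = np.full(covered.shape, np.nan)
    ok = covered > 0
    out[ok] = np.asarray(discordant_by_line, dtype=float)[ok] / covered[ok]
    return out
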