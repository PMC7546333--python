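"""Founder site filtering and variant-vs-recipient genotype classification.

A variant site is classified relative to a homozygous recipient genotype R/R:

* ``NON_VARIANT``  — sample R/R;
* ``HOMO_SNP``     — sample X/X with X != R (a fixed, homozygous difference);
* ``HETERO_SNP``   — sample R/X (carries the recipient allele plus one other);
* ``MUTATION_SNP`` — sample X/Y with both alleles differing from R;
* ``UNCLASSIFIED`` — the recipient itself is heterozygous, so the trichotomy
  does not apply and the site is excluded from the comparison.

Filtering follows the resequencing pipeline's rules: per-sample attribute
thresholds (mapping quality strictly above 20, depth within [1, 300], copy
number strictly below 2) and removal of variant calls closer than 5 bp to a
neighbouring call (both members of a too-close pair are dropped — the rule is
symmetric).  Pairwise depth gates are applied when comparing two samples:
homozygous variant genotypes need depth > 2, heterozygous ones depth > 6.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import GenomeLayout, encode_base

__all__ = [
    "SiteClass", "FilterThresholds", "CDSModel",
    "filter_single_sample", "filter_pairwise", "filter_pairwise_table",
    "classify_relative", "classify_sites", "tally", "snp_density",
    "annotate_coding_effect",
]


class SiteClass(str, enum.Enum):
    NON_VARIANT = "non_variant"
    HOMO_SNP = "homo_snp"
    HETERO_SNP = "hetero_snp"
    MUTATION_SNP = "mutation_snp"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class FilterThresholds:
    """Strictness conventions: mapq and pair depths are strict >, depth bounds
    inclusive, copy number strict <, adjacency strict >."""

    mapq_min: int = 20
    depth_min: int = 1
    depth_max: int = 300
    min_adjacent_gap: int = 5
    copy_number_max: float = 2.0
    pair_hom_depth_min: int = 2
    pair_het_depth_min: int = 6

    def __post_init__(self) -> None:
        if self.depth_min > self.depth_max:
            raise ValueError("depth_min must not exceed depth_max")
        for name in ("mapq_min", "depth_min", "min_adjacent_gap",
                     "copy_number_max", "pair_hom_depth_min", "pair_het_depth_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def filter_single_sample(
    calls: pd.DataFrame, thresholds: FilterThresholds = FilterThresholds()
) -> pd.DataFrame:
    """Apply per-sample site filters to a (chrom, pos)-sorted call table.

    Attribute rules first (mapq > 20, 1 <= depth <= 300, copy number < 2),
    then the adjacency rule among the survivors: any call whose nearest
    surviving neighbour on the same chromosome is <= 5 bp away is removed,
    together with that neighbour.  The operation is idempotent.
    """
    required = {"chrom", "pos", "depth", "mapq", "copy_number"}
    missing = required - set(calls.columns)
    if missing:
        raise ValueError(f"call table lacks columns: {sorted(missing)}")
    if len(calls) == 0:
        return calls.copy()
    if (calls["depth"] < 0).any():
        raise ValueError("negative depth")
    order = calls.sort_values(["chrom", "pos"], kind="stable").index
    if not (order == calls.index).all():
        raise ValueError("calls must be sorted by (chrom, pos)")

    t = thresholds
    keep = (
        (calls["mapq"] > t.mapq_min)
        & (calls["depth"] >= t.depth_min)
        & (calls["depth"] <= t.depth_max)
        & (calls["copy_number"] < t.copy_number_max)
    )
    surv = calls[keep]
    if len(surv) == 0:
        return surv.copy()
    pos = surv["pos"].to_numpy()
    same_chrom_prev = surv["chrom"].to_numpy()[1:] == surv["chrom"].to_numpy()[:-1]
    gap = np.diff(pos)
    close_pair = same_chrom_prev & (gap <= t.min_adjacent_gap)
    crowded = np.zeros(len(surv), dtype=bool)
    crowded[:-1] |= close_pair
    crowded[1:] |= close_pair
    return surv[~crowded].copy()


def filter_pairwise(
    recipient_call: pd.Series,
    variant_call: pd.Series,
    thresholds: FilterThresholds = FilterThresholds(),
) -> bool:
    """Depth gate for a recipient/variant call pair at one position."""
    if (recipient_call["chrom"], recipient_call["pos"]) != (
            variant_call["chrom"], variant_call["pos"]):
        raise ValueError("recipient and variant calls are at different positions")
    a1, a2 = variant_call["gt1"], variant_call["gt2"]
    if a1 < 0 or a2 < 0 or pd.isna(a1) or pd.isna(a2):
        return False
    t = thresholds
    if a1 == a2:
        return variant_call["depth"] > t.pair_hom_depth_min
    return variant_call["depth"] > t.pair_het_depth_min


def filter_pairwise_table(
    variant_calls: pd.DataFrame, thresholds: FilterThresholds = FilterThresholds()
) -> pd.DataFrame:
    """Vectorised pairwise depth gate over a variant call table
    (columns gt1, gt2, depth; missing genotype coded as -1)."""
    t = thresholds
    gt1 = variant_calls["gt1"].to_numpy()
    gt2 = variant_calls["gt2"].to_numpy()
    depth = variant_calls["depth"].to_numpy()
    called = (gt1 >= 0) & (gt2 >= 0)
    hom = called & (gt1 == gt2)
    keep = np.where(
        hom, depth > t.pair_hom_depth_min,
        called & (depth > t.pair_het_depth_min))
    return variant_calls[keep].copy()


def _as_code(allele) -> int:
    if isinstance(allele, str):
        return encode_base(allele)
    code = int(allele)
    if not 0 <= code <= 3:
        raise ValueError(f"allele code {code} outside 0..3 (A,C,G,T)")
    return code


def classify_relative(recipient_gt, sample_gt) -> SiteClass:
    """Classify one sample genotype against the recipient genotype.

    Genotypes are unordered pairs, given as 2-character strings ("AG"),
    2-tuples of bases, or 2-tuples of integer codes.
    """
    r1, r2 = (_as_code(a) for a in recipient_gt)
    s1, s2 = (_as_code(a) for a in sample_gt)
    if r1 != r2:
        return SiteClass.UNCLASSIFIED
    r = r1
    if s1 == r and s2 == r:
        return SiteClass.NON_VARIANT
    if s1 == s2:
        return SiteClass.HOMO_SNP
    if s1 == r or s2 == r:
        return SiteClass.HETERO_SNP
    return SiteClass.MUTATION_SNP


def classify_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Vectorised classification of a site table with integer allele columns
    rec1, rec2 (recipient) and var1, var2 (sample); adds a ``site_class``
    column holding the class values (comparable to :class:`SiteClass`)."""
    rec1 = sites["rec1"].to_numpy()
    rec2 = sites["rec2"].to_numpy()
    s1 = sites["var1"].to_numpy()
    s2 = sites["var2"].to_numpy()
    out = np.full(len(sites), SiteClass.UNCLASSIFIED.value, dtype=object)
    hom_rec = rec1 == rec2
    r = rec1
    out[hom_rec & (s1 == r) & (s2 == r)] = SiteClass.NON_VARIANT.value
    out[hom_rec & (s1 == s2) & (s1 != r)] = SiteClass.HOMO_SNP.value
    het = s1 != s2
    out[hom_rec & het & ((s1 == r) | (s2 == r))] = SiteClass.HETERO_SNP.value
    out[hom_rec & het & (s1 != r) & (s2 != r)] = SiteClass.MUTATION_SNP.value
    result = sites.copy()
    result["site_class"] = out
    return result


_TALLY_CLASSES = [SiteClass.HOMO_SNP, SiteClass.HETERO_SNP, SiteClass.MUTATION_SNP]


def tally(classified: pd.DataFrame, layout: GenomeLayout) -> pd.DataFrame:
    """Per-chromosome and total counts of each SNP class.

    ``snp_number`` counts homo- plus hetero- plus mutation-SNPs (non-variant
    and unclassified sites are not SNPs relative to the recipient).  The last
    row, labelled ``Total``, sums the chromosome rows.
    """
    known = set(layout.names)
    bad = set(classified["chrom"].unique()) - known
    if bad:
        raise ValueError(f"chromosomes not in layout: {sorted(bad)}")
    rows = []
    for name in layout.names:
        sub = classified[classified["chrom"] == name]
        counts = {c.value: int((sub["site_class"] == c).sum()) for c in _TALLY_CLASSES}
        counts["snp_number"] = sum(counts.values())
        rows.append({"chrom": name, **counts})
    table = pd.DataFrame(rows)
    total = table.drop(columns="chrom").sum()
    total["chrom"] = "Total"
    return pd.concat([table, total.to_frame().T], ignore_index=True)[
        ["chrom", "snp_number", "homo_snp", "hetero_snp", "mutation_snp"]]


def snp_density(count: int, covered_bases: int) -> float:
    """SNPs per kilobase of covered sequence."""
    if covered_bases <= 0:
        raise ValueError("covered_bases must be > 0")
    return 1000.0 * count / covered_bases


# ---------------------------------------------------------------------------
# Coding-effect annotation
# ---------------------------------------------------------------------------


@dataclass
class CDSModel:
    """A coding sequence as ordered genomic exon intervals (1-based inclusive).

    Exons are given in genomic order; on the minus strand the coding sequence
    is the reverse complement of their concatenation.  Total length must be a
    multiple of 3.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def coding_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


def _revcomp_code(code: int) -> int:
    return {0: 3, 1: 2, 2: 1, 3: 0}[code]  # A<->T, C<->G


_CODON_TABLE: dict[str, str] = {}


def _translate_codon(codon: str) -> str:
    if not _CODON_TABLE:
        from Bio.Seq import Seq
        for b1 in "ACGT":
            for b2 in "ACGT":
                for b3 in "ACGT":
                    c = b1 + b2 + b3
                    _CODON_TABLE[c] = str(Seq(c).translate())
    return _CODON_TABLE[codon]


def annotate_coding_effect(
    chrom: str,
    pos: int,
    ref_base: str,
    alt_base: str,
    gene_models: list[CDSModel],
    reference: dict[str, str],
) -> str:
    """Classify a substitution as synonymous / non_synonymous / non_coding.

    The reference and mutated codons are translated with the standard genetic
    code (reverse-complemented on the minus strand).  A site overlapping
    several coding models is non-synonymous if it changes the protein of any.
    """
    if chrom not in reference:
        raise ValueError(f"chromosome {chrom!r} not in reference")
    seq = reference[chrom].upper()
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside reference ({len(seq)} bp)")
    if seq[pos - 1] != ref_base.upper():
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: expected {seq[pos - 1]}, got {ref_base}")

    effects = []
    for model in gene_models:
        if model.chrom != chrom:
            continue
        if model.coding_length() % 3 != 0:
            raise ValueError(f"{model.gene_id}: CDS length not divisible by 3")
        offset = 0
        cds_index = None
        for start, end in model.exons:
            if start <= pos <= end:
                cds_index = offset + (pos - start)
                break
            offset += end - start + 1
        if cds_index is None:
            continue
        cds = "".join(seq[s - 1:e] for s, e in model.exons)
        if model.strand == "-":
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            cds = "".join(comp[b] for b in reversed(cds))
            cds_index = len(cds) - 1 - cds_index
            ref_c, alt_c = comp[ref_base.upper()], comp[alt_base.upper()]
        else:
            ref_c, alt_c = ref_base.upper(), alt_base.upper()
        codon_start = (cds_index // 3) * 3
        within = cds_index - codon_start
        ref_codon = cds[codon_start:codon_start + 3]
        if ref_codon[within] != ref_c:
            raise ValueError(f"{model.gene_id}: CDS/reference inconsistency at {chrom}:{pos}")
        alt_codon = ref_codon[:within] + alt_c + ref_codon[within + 1:]
        effects.append(
            "synonymous" if _translate_codon(ref_codon) == _translate_codon(alt_codon)
            else "non_synonymous")
    if not effects:
        return "non_coding"
    return "non_synonymous" if "non_synonymous" in effects else "synonymous"
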