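"""Readers and writers for the pipeline's standard formats.

Conventions: VCF positions are 1-based (recipient genotype unphased, variant
genotype phased with the non-recipient allele on the second haplotype); bins
are 1-based half-open [start, end) internally and are converted to 0-based
half-open on BED export by subtracting one from both edges, which preserves
lengths.  Every TSV/BED written here carries a comment header recording the
tool version, the seed and a configuration hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from . import __version__
from .simulate import BASES, GenomeLayout, FounderPair, MISSING, decode_base, encode_base
from .binmap import MISSING_CODE
from .sites import CDSModel

GT_CODE_TO_CHAR = {0: "A", 1: "H", 2: "B", MISSING_CODE: "-"}
GT_CHAR_TO_CODE = {v: k for k, v in GT_CODE_TO_CHAR.items()}


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = yaml.safe_dump(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(seed: int | None, cfg_hash: str | None) -> list[str]:
    parts = [f"ssivarscape v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash:
        parts.append(f"config_hash={cfg_hash}")
    return ["# " + " | ".join(parts)]


def write_tsv(df: pd.DataFrame, path, seed: int | None = None,
              cfg_hash: str | None = None, index: bool = False) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for line in _header_lines(seed, cfg_hash):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_founders_vcf(
    founders: FounderPair,
    layout: GenomeLayout,
    path,
    seed: int | None = None,
    depth: int = 30,
    mapq: int = 60,
    copy_number: float = 1.0,
) -> None:
    """Write recipient + variant genotypes as a two-sample VCF.

    The simulator does not model founder read depth, so constant per-site
    DP/MQ/CN attributes are attached; user-supplied VCFs carry their own.
    """
    header = pysam.VariantHeader()
    for c in layout.chromosomes:
        header.contigs.add(c.name, length=c.length_bp)
    header.info.add("CN", 1, "Float", "Copy number of the surrounding region")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("MQ", 1, "Integer", "Mapping quality")
    if seed is not None:
        header.add_line(f"##ssivarscape_seed={seed}")
    header.add_line(f"##source=ssivarscape-{__version__}")
    header.add_sample("recipient")
    header.add_sample("variant")

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in founders.sites.itertuples(index=False):
            ref_code = int(row.ref)
            alleles = [ref_code]
            for code in (row.rec1, row.rec2, row.var1, row.var2):
                if int(code) not in alleles:
                    alleles.append(int(code))
            rec = vcf.new_record(
                contig=row.chrom, start=int(row.pos) - 1,
                alleles=tuple(decode_base(a) for a in alleles))
            rec.info["CN"] = copy_number
            idx = {a: i for i, a in enumerate(alleles)}
            rec.samples["recipient"]["GT"] = (idx[int(row.rec1)], idx[int(row.rec2)])
            rec.samples["recipient"].phased = False
            rec.samples["variant"]["GT"] = (idx[int(row.var1)], idx[int(row.var2)])
            rec.samples["variant"].phased = True
            for s in ("recipient", "variant"):
                rec.samples[s]["DP"] = depth
                rec.samples[s]["MQ"] = mapq
            vcf.write(rec)


def read_genotypes_vcf(path) -> dict[str, pd.DataFrame]:
    """Per-sample site-call tables from a VCF.

    Returns {sample: DataFrame(chrom, pos, ref, gt1, gt2, depth, mapq,
    copy_number)} with allele integer codes (missing -1).  Records whose REF
    or a called ALT allele is not a single A/C/G/T base are rejected with the
    record's line context.
    """
    out: dict[str, list] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for s in samples:
            out[s] = []
        for i, rec in enumerate(vcf.fetch() if vcf.index else vcf, start=1):
            try:
                allele_codes = []
                for a in rec.alleles:
                    if a is None or len(a) != 1 or a.upper() not in BASES:
                        raise ValueError(f"non-SNP allele {a!r}")
                    allele_codes.append(encode_base(a))
                cn = float(rec.info.get("CN", 1.0))
                for s in samples:
                    sm = rec.samples[s]
                    gt = sm.get("GT", (None, None))
                    g1 = allele_codes[gt[0]] if gt and gt[0] is not None else MISSING
                    g2 = allele_codes[gt[1]] if gt and len(gt) > 1 and gt[1] is not None else MISSING
                    out[s].append((rec.contig, rec.pos, allele_codes[0], g1, g2,
                                   int(sm.get("DP") or 0), int(sm.get("MQ") or 0), cn))
            except Exception as exc:  # noqa: BLE001 - reported with context
                raise ValueError(f"malformed VCF record #{i} at "
                                 f"{rec.contig}:{rec.pos}: {exc}") from exc
    cols = ["chrom", "pos", "ref", "gt1", "gt2", "depth", "mapq", "copy_number"]
    return {s: pd.DataFrame(rows, columns=cols) for s, rows in out.items()}


# ---------------------------------------------------------------------------
# BED / bin map
# ---------------------------------------------------------------------------


def write_bins_bed(bins: pd.DataFrame, path, seed: int | None = None,
                   cfg_hash: str | None = None) -> None:
    """Bins to BED: 0-based half-open, converted from internal 1-based
    half-open by subtracting 1 from both start and end (lengths preserved)."""
    bed = pd.DataFrame({
        "chrom": bins["chrom"],
        "start": bins["start"] - 1,
        "end": bins["end"] - 1,
        "name": bins["label"] if "label" in bins else bins["bin_id"].map("bin{}".format),
    })
    with open(path, "w") as fh:
        for line in _header_lines(seed, cfg_hash):
            fh.write(line + "\n")
        bed.to_csv(fh, sep="\t", index=False, header=False)


def read_bins_bed(path, layout: GenomeLayout | None = None) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", comment="#", header=None,
                      names=["chrom", "start", "end", "name"])
    bins = pd.DataFrame({
        "bin_id": bed["name"].str.removeprefix("bin").astype(int),
        "label": bed["name"],
        "chrom": bed["chrom"],
        "start": bed["start"] + 1,
        "end": bed["end"] + 1,
    })
    bins["length"] = bins["end"] - bins["start"]
    return bins


def write_bin_matrix(matrix: pd.DataFrame, path, seed: int | None = None,
                     cfg_hash: str | None = None) -> None:
    """Lines x bins genotype matrix with A/H/B/- codes."""
    chars = matrix.replace(GT_CODE_TO_CHAR)
    write_tsv(chars, path, seed, cfg_hash, index=True)


def read_bin_matrix(path) -> pd.DataFrame:
    chars = read_tsv(path, index_col=0)
    chars.columns = chars.columns.astype(int)
    return chars.apply(lambda col: col.map(GT_CHAR_TO_CODE)).astype(np.int8)


# ---------------------------------------------------------------------------
# Gene models and reference sequence
# ---------------------------------------------------------------------------


def read_gene_models(gff_path) -> list[CDSModel]:
    """CDS models from a GFF3 file (CDS features grouped by Parent/ID)."""
    import gffutils

    db = gffutils.create_db(str(gff_path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    grouped: dict[str, CDSModel] = {}
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        parent = feat.attributes.get("Parent", feat.attributes.get("ID", [feat.id]))[0]
        model = grouped.get(parent)
        if model is None:
            model = CDSModel(gene_id=parent, chrom=feat.seqid, strand=feat.strand, exons=[])
            grouped[parent] = model
        model.exons.append((feat.start, feat.end))
    return list(grouped.values())


def read_reference_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------------------
# Misc structured outputs
# ---------------------------------------------------------------------------


def write_json_report(report: dict, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_default)
        fh.write("\n")


def write_truth_set(truth, path, seed: int | None = None) -> None:
    """Truth set as a structured JSON text file."""
    payload = {
        "seed": truth.seed,
        "config": {k: (v if not isinstance(v, list) else [vars(q) for q in v])
                   for k, v in vars(truth.config).items()},
        "site_kind": truth.site_kind.tolist(),
        "crossovers": truth.crossovers.to_dict(orient="list"),
        "population_mutations": truth.population_mutations.to_dict(orient="list"),
        "mutation_carriers": {str(k): v.tolist() for k, v in truth.mutation_carriers.items()},
        "qtls": truth.qtls.to_dict(orient="list"),
    }
    write_json_report(payload, path)
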