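"""End-to-end pipeline: simulate -> classify -> binmap -> stats -> scan.

Every stage is a plain function over the library's containers; the driver
wires them together from a :class:`RunConfig`, writes each stage's artifacts
and collects a run report.  Identical configuration and seed yield identical
artifacts and report.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .binmap import (
    AA, AB, BB, MISSING_CODE, CallParams, WindowParams, bin_genotypes,
    build_bins, build_genetic_map, call_genotypes, detect_breakpoints,
    map_size, window_states,
)
from .popstats import (
    MutationCallParams, class_fraction, detect_population_mutations,
    expected_hom_fraction, fold_change, genomic_heterozygosity,
    homozygous_fraction, mutation_rate,
)
from .qtl import ScanParams, permutation_threshold, scan_profile, select_cofactors, summarize
from .simulate import (
    GenomeLayout, SimulationConfig, QTLSpec, rice_layout, self_population,
    simulate_founders, simulate_observations, simulate_traits,
)
from .sites import SiteClass, classify_sites, tally

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All pipeline parameters; read from a YAML mapping with one block per
    module (sim, call, window, mutation, scan) plus layout and global keys."""

    seed: int = 0
    out_dir: str = "ssivarscape_out"
    # Either a bp scale applied to the 12-chromosome rice-like layout, or an
    # explicit chromosome list [(name, length_bp, genetic_length_cM), ...].
    # The genetic map is kept full length, so the scale trades physical
    # window resolution against runtime (see docs/methods.md).
    layout_scale: float = 0.05
    layout_chromosomes: list | None = None
    log_level: str = "INFO"
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    call: CallParams = field(default_factory=CallParams)
    window: WindowParams = field(default_factory=WindowParams)
    mutation: MutationCallParams = field(default_factory=MutationCallParams)
    scan: ScanParams = field(default_factory=ScanParams)

    def layout(self) -> GenomeLayout:
        if self.layout_chromosomes:
            return GenomeLayout.from_spec(self.layout_chromosomes)
        return rice_layout(self.layout_scale)

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = {k: v for k, v in raw.items()
                  if k in ("seed", "out_dir", "layout_scale",
                           "layout_chromosomes", "log_level")}
        sim_raw = dict(raw.get("sim", {}))
        qtls = [QTLSpec(**q) for q in sim_raw.pop("qtls", [])]
        kwargs["sim"] = SimulationConfig(qtls=qtls, **sim_raw)
        kwargs["call"] = CallParams(**raw.get("call", {}))
        kwargs["window"] = WindowParams(**raw.get("window", {}))
        kwargs["mutation"] = MutationCallParams(**raw.get("mutation", {}))
        kwargs["scan"] = ScanParams(**raw.get("scan", {}))
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Population genotyping glue: observations -> calls -> windows -> bins -> map
# ---------------------------------------------------------------------------


def genotype_population(
    observations: pd.DataFrame,
    founders,
    layout: GenomeLayout,
    call_params: CallParams = CallParams(),
    window_params: WindowParams = WindowParams(),
    map_function: str = "kosambi",
) -> dict:
    """Run the whole bin-map construction from sparse allele counts.

    Markers are the sites where the recipient is homozygous and the variant
    heterozygous; allele a is the recipient allele, allele b the variant's
    other allele.  Sites with total population depth at or below the
    threshold are excluded before calling.
    """
    sites = founders.sites
    marker = founders.marker_mask()
    midx = np.flatnonzero(marker)
    msites = sites.iloc[midx].reset_index(drop=True)
    rec = msites["rec1"].to_numpy(np.int8)
    v1 = msites["var1"].to_numpy(np.int8)
    v2 = msites["var2"].to_numpy(np.int8)
    b_allele = np.where(v1 == rec, v2, v1).astype(np.int8)

    key = msites["chrom"].astype(str) + ":" + msites["pos"].astype(str)
    marker_of = pd.Series(np.arange(len(msites)), index=key)
    obs_key = observations["chrom"].astype(str) + ":" + observations["pos"].astype(str)
    mrow = obs_key.map(marker_of)
    obs = observations[mrow.notna()].copy()
    obs["marker"] = mrow[mrow.notna()].astype(int).to_numpy()

    count_cols = obs[["n_A", "n_C", "n_G", "n_T"]].to_numpy()
    m = obs["marker"].to_numpy()
    n_a = count_cols[np.arange(len(obs)), rec[m]]
    n_b = count_cols[np.arange(len(obs)), b_allele[m]]
    obs["n_a"] = n_a
    obs["n_b"] = n_b
    obs["obs_depth"] = count_cols.sum(axis=1)

    # population-depth site filter (strict >)
    pop_depth = np.zeros(len(msites), dtype=np.int64)
    np.add.at(pop_depth, m, obs["obs_depth"].to_numpy())
    keep_site = pop_depth > call_params.min_population_depth
    obs = obs[keep_site[obs["marker"].to_numpy()]].copy()

    _, calls = call_genotypes(obs["n_a"].to_numpy(), obs["n_b"].to_numpy(), call_params)
    obs["call"] = calls

    # per-line sliding windows (founder-allele read fraction) over the line's
    # observed marker sites
    mpos = msites["pos"].to_numpy()
    mchrom = msites["chrom"].to_numpy()
    line_segments: dict[str, dict[str, tuple[list, np.ndarray]]] = {}
    breakpoints_by_chrom: dict[str, list] = {c: [] for c in layout.names}
    for line_id, sub in obs.groupby("line_id", sort=True):
        per_chrom = {}
        sub = sub.sort_values("marker")
        mk = sub["marker"].to_numpy()
        cc = mchrom[mk]
        for chrom in pd.unique(cc):
            sel = cc == chrom
            pos_c = mpos[mk[sel]]
            states = window_states(sub["n_a"].to_numpy()[sel],
                                   sub["n_b"].to_numpy()[sel], window_params)
            if states.size == 0:
                per_chrom[chrom] = ([], np.empty(0, dtype=np.int64))
                continue
            centers = pos_c[window_params.window // 2:
                            window_params.window // 2 + states.size]
            segments, bps = detect_breakpoints(states, centers, window_params)
            # the threshold-offset correction can overshoot near chromosome
            # ends; clamp into the chromosome
            bps = np.clip(bps, 2, layout.chromosome(chrom).length_bp)
            per_chrom[chrom] = (segments, bps)
            breakpoints_by_chrom[chrom].extend(bps.tolist())
        line_segments[line_id] = per_chrom

    bins = build_bins({c: np.array(v, dtype=np.int64)
                       for c, v in breakpoints_by_chrom.items()}, layout)
    matrix = bin_genotypes(line_segments, bins)
    gmap = build_genetic_map(matrix, bins, function=map_function)
    return {
        "markers": msites.assign(b_allele=b_allele),
        "observations": obs,
        "line_segments": line_segments,
        "bins": bins,
        "matrix": matrix,
        "genetic_map": gmap,
        "map_size_cM": map_size(gmap),
    }


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages, write artifacts under ``config.out_dir`` and return
    the run report (also written as report.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.as_dict()
    # hash only the scientific parameters, not output locations
    cfg_hash = sio.config_hash({k: v for k, v in cfg_dict.items() if k != "out_dir"})
    seed = config.seed
    rng = np.random.default_rng(seed)
    layout = config.layout()
    report: dict = {"seed": seed, "config_hash": cfg_hash,
                    "config": cfg_dict, "layout_total_bp": layout.total_bp,
                    "layout_total_cM": layout.total_cM}

    def stage(name):
        logger.info("stage %s", name)

    # --- simulate ---------------------------------------------------------
    try:
        stage("simulate")
        config.sim.seed = seed
        founders, kinds = simulate_founders(layout, config.sim, rng)
        population, truth = self_population(founders, layout, config.sim, rng, kinds)
        traits = simulate_traits(population, config.sim, rng, truth)
        observations = simulate_observations(population, config.sim, rng)
        sio.write_founders_vcf(founders, layout, out / "founders.vcf", seed)
        sio.write_tsv(observations, out / "observations.tsv", seed, cfg_hash)
        sio.write_tsv(traits, out / "traits.tsv", seed, cfg_hash)
        sio.write_truth_set(truth, out / "truth.json", seed)
    except Exception as exc:
        raise PipelineError("simulate", exc) from exc

    # --- classify ---------------------------------------------------------
    try:
        stage("classify")
        classified = classify_sites(founders.sites)
        table = tally(classified, layout)
        sio.write_tsv(classified, out / "site_classes.tsv", seed, cfg_hash)
        sio.write_tsv(table, out / "class_tally.tsv", seed, cfg_hash)
        covered = layout.total_bp  # simulated founders are fully covered
        # total genomic heterozygosity of each founder (all het sites / bases)
        n_het_rec = int((founders.sites["rec1"] != founders.sites["rec2"]).sum())
        n_het_var_total = int(founders.variant_is_het().sum())
        # variant-vs-recipient SNP classes
        n_het_rel = int((classified["site_class"] == SiteClass.HETERO_SNP).sum())
        n_hom_rel = int((classified["site_class"] == SiteClass.HOMO_SNP).sum())
        het_rec = genomic_heterozygosity(n_het_rec, covered)
        het_var = genomic_heterozygosity(n_het_var_total, covered)
        report["classify"] = {
            "covered_bases": covered,
            "recipient_heterozygosity": het_rec,
            "variant_heterozygosity": het_var,
            "variant_mutation_rate": mutation_rate(n_hom_rel, covered),
            "heterozygosity_fold_change": fold_change(het_var, het_rec)
            if n_het_rec else None,
            "hetero_snp_fraction_pct": class_fraction(
                n_het_rel, n_het_rel + n_hom_rel) if n_het_rel + n_hom_rel else None,
            "tally_total": int(table.loc[table["chrom"] == "Total", "snp_number"].iloc[0]),
        }
    except Exception as exc:
        raise PipelineError("classify", exc) from exc

    # --- binmap -----------------------------------------------------------
    try:
        stage("binmap")
        geno = genotype_population(observations, founders, layout,
                                   config.call, config.window)
        bins, matrix, gmap = geno["bins"], geno["matrix"], geno["genetic_map"]
        sio.write_bins_bed(bins, out / "bins.bed", seed, cfg_hash)
        sio.write_bin_matrix(matrix, out / "bin_matrix.tsv", seed, cfg_hash)
        sio.write_tsv(gmap, out / "genetic_map.tsv", seed, cfg_hash)
        report["binmap"] = {
            "n_markers": len(geno["markers"]),
            "n_bins": len(bins),
            "map_size_cM": geno["map_size_cM"],
            "observed_pair_fraction": float(
                len(observations) / (population.n_lines * founders.n_sites))
            if founders.n_sites else 0.0,
            "mean_observed_depth": float(observations[
                ["n_A", "n_C", "n_G", "n_T"]].to_numpy().sum(axis=1).mean())
            if len(observations) else 0.0,
        }
    except Exception as exc:
        raise PipelineError("binmap", exc) from exc

    # --- stats ------------------------------------------------------------
    try:
        stage("stats")
        codes = matrix.to_numpy()
        hom_fracs = []
        het_fracs = []
        for row in codes:
            called = row >= 0
            if called.any():
                hom_fracs.append(homozygous_fraction(row))
                het_fracs.append(float((row[called] == AB).mean()))
        g = config.sim.selfing_generations
        # single-site confident calls at candidate (shared-homozygous) sites
        mut_report = _population_mutations_from_observations(
            observations, founders, config.call, config.mutation)
        report["stats"] = {
            "mean_homozygous_fraction_pct": 100.0 * float(np.mean(hom_fracs))
            if hom_fracs else None,
            "expected_homozygous_fraction_pct": 100.0 * expected_hom_fraction(g),
            "mean_line_bin_heterozygosity_pct": 100.0 * float(np.mean(het_fracs))
            if het_fracs else None,
            "n_population_mutation_sites": int(len(mut_report)),
            "population_mutation_rate": mutation_rate(len(mut_report), layout.total_bp),
        }
        sio.write_tsv(mut_report, out / "population_mutations.tsv", seed, cfg_hash)
    except Exception as exc:
        raise PipelineError("stats", exc) from exc

    # --- scan -------------------------------------------------------------
    try:
        stage("scan")
        trait_name = config.sim.trait_name
        y = traits.set_index("line_id").loc[matrix.index, trait_name].to_numpy(float)
        bin_cm = gmap["cM"].to_numpy()
        cof = select_cofactors(y, matrix, bins, bin_cm, config.scan)
        profile = scan_profile(y, matrix, bins, bin_cm, cof, config.scan)
        perm_rng = np.random.default_rng(seed + 1)
        perm_thr = permutation_threshold(y, matrix, config.scan, perm_rng)
        thr = max(config.scan.lod_report_threshold, 0.0)
        hits = summarize(profile, thr, bins, bin_cm, config.scan, trait_name)
        sio.write_tsv(profile, out / f"lod_profile_{trait_name}.tsv", seed, cfg_hash)
        sio.write_tsv(hits, out / f"qtl_hits_{trait_name}.tsv", seed, cfg_hash)
        prof_bins = profile.merge(bins, on="bin_id")
        chrom_peaks = {}
        for chrom, sub in prof_bins.groupby("chrom"):
            sub = sub[np.isfinite(sub["lod"])]
            if len(sub):
                peak = sub.loc[sub["lod"].idxmax()]
                chrom_peaks[chrom] = {
                    "bin_id": int(peak["bin_id"]), "lod": float(peak["lod"]),
                    "r2_pct": float(100 * peak["r2"]),
                    "start": int(peak["start"]), "end": int(peak["end"])}
        report["scan"] = {
            "chrom_peaks": chrom_peaks,
            "trait": trait_name,
            "cofactors": cof,
            "permutation_threshold": perm_thr,
            "report_threshold": thr,
            "n_hits": int(len(hits)),
            "hits": hits.to_dict(orient="records"),
        }
    except Exception as exc:
        raise PipelineError("scan", exc) from exc

    sio.write_json_report(report, out / "report.json")
    return report


def _population_mutations_from_observations(
    observations: pd.DataFrame,
    founders,
    call_params: CallParams,
    mut_params: MutationCallParams,
) -> pd.DataFrame:
    """Single-site genotype calls at every founder site, then the population
    discordance predicate."""
    sites = founders.sites
    if len(observations) == 0:
        return pd.DataFrame(columns=["site_index", "chrom", "pos",
                                     "n_discordant", "n_called"])
    key = sites["chrom"].astype(str) + ":" + sites["pos"].astype(str)
    site_of = pd.Series(np.arange(len(sites)), index=key)
    obs_key = observations["chrom"].astype(str) + ":" + observations["pos"].astype(str)
    si = obs_key.map(site_of).to_numpy()
    counts = observations[["n_A", "n_C", "n_G", "n_T"]].to_numpy()

    # Call the two most plausible alleles at each observation: allele a is the
    # recipient allele; allele b the best-supported other allele.
    rec1 = sites["rec1"].to_numpy(np.int8)
    a_allele = rec1[si.astype(int)]
    masked = counts.copy()
    masked[np.arange(len(masked)), a_allele] = -1
    b_allele = masked.argmax(axis=1).astype(np.int8)
    n_a = counts[np.arange(len(counts)), a_allele]
    n_b = counts[np.arange(len(counts)), b_allele]
    _, calls = call_genotypes(n_a, n_b, call_params)

    line_ids = sorted(observations["line_id"].unique())
    line_of = {l: i for i, l in enumerate(line_ids)}
    li = observations["line_id"].map(line_of).to_numpy()
    n_lines, n_sites = len(line_ids), len(sites)
    gt1 = np.full((n_lines, n_sites), -1, dtype=np.int8)
    gt2 = np.full((n_lines, n_sites), -1, dtype=np.int8)
    called = calls >= 0
    gt1[li[called], si[called].astype(int)] = np.where(
        calls[called] == BB, b_allele[called], a_allele[called])
    gt2[li[called], si[called].astype(int)] = np.where(
        calls[called] == AA, a_allele[called], b_allele[called])

    rec_gt = sites[["rec1", "rec2"]].to_numpy(np.int8)
    var_gt = sites[["var1", "var2"]].to_numpy(np.int8)
    rep = detect_population_mutations(gt1, gt2, rec_gt, var_gt, mut_params)
    rep = rep.assign(chrom=sites["chrom"].to_numpy()[rep["site_index"]],
                     pos=sites["pos"].to_numpy()[rep["site_index"]])
    return rep[["site_index", "chrom", "pos", "n_discordant", "n_called"]]
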