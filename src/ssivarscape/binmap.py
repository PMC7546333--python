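"""Genotype calling, breakpoint detection, bin maps and genetic distances.

The F2 lines are observed at a few percent of the marker sites and roughly
3x depth, so genotypes are called per site from allele counts with a Bayesian
posterior (F2 priors 1:2:1; calls require posterior > 0.95), sites with total
population depth at or below 40 are excluded, and a sliding window over each
line's observed sites smooths the sparse calls into chromosome segments.
Runs of identical window states form segments, short runs are absorbed into
their longer neighbour, and a recombination breakpoint is placed at the
midpoint between the flanking informative sites.  The union of all lines'
breakpoints partitions each chromosome into bins (half-open [start, end),
1-based), every line is constant within every bin by construction, and
adjacent-bin recombination fractions estimated by EM give the genetic map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GenomeLayout

logger = logging.getLogger(__name__)

#: Genotype codes: aa = homozygous recipient allele, bb = homozygous
#: non-recipient allele, ab heterozygous; -1 missing.
AA, AB, BB = 0, 1, 2
MISSING_CODE = -1

F2_PRIORS = (0.25, 0.5, 0.25)


@dataclass(frozen=True)
class CallParams:
    """Single-site genotype-calling thresholds."""

    base_error: float = 0.01
    posterior_threshold: float = 0.95
    min_population_depth: int = 40  # strict >, applied as a per-site filter

    def __post_init__(self) -> None:
        if not 0.0 <= self.base_error < 0.5:
            raise ValueError("base_error must lie in [0, 0.5)")
        if not 0.5 <= self.posterior_threshold < 1.0:
            raise ValueError("posterior_threshold must lie in [0.5, 1)")


@dataclass(frozen=True)
class WindowParams:
    """Sliding-window smoothing parameters.

    The window spans ``window`` consecutive observed sites of one line and
    needs at least ``min_called`` confident genotype calls; ``hom_threshold``
    is the fraction of alleles from one founder haplotype required to call
    the window homozygous; runs shorter than ``min_run`` windows are absorbed
    by the longer flanking run.
    """

    window: int = 15
    step: int = 1
    hom_threshold: float = 0.9
    min_called: int = 5
    min_run: int = 2

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0.5 < self.hom_threshold <= 1.0:
            raise ValueError("hom_threshold must lie in (0.5, 1]")


@dataclass
class GenotypePosterior:
    p_aa: float
    p_ab: float
    p_bb: float
    call: int  # AA/AB/BB or MISSING_CODE


def call_genotypes(
    n_a: np.ndarray,
    n_b: np.ndarray,
    params: CallParams = CallParams(),
    priors: tuple[float, float, float] = F2_PRIORS,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior genotype probabilities and calls from founder-allele counts.

    Likelihoods: aa (1-e)^na e^nb, bb e^na (1-e)^nb, ab (1/2)^(na+nb);
    posterior proportional to prior times likelihood.  A call is made only if
    the maximum posterior exceeds the threshold; zero-count sites are missing.
    Returns (posteriors with shape (n, 3), calls int8).
    """
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    if (n_a < 0).any() or (n_b < 0).any():
        raise ValueError("negative allele counts")
    # a floor keeps 0 * log(0) well-defined at base_error = 0; any count of
    # the discordant allele then sends the homozygous likelihood to zero
    e = max(params.base_error, 1e-300)
    log_e = np.log(e)
    log_1e = np.log1p(-e)
    log_half = np.log(0.5)
    ll = np.stack([
        n_a * log_1e + n_b * log_e,
        (n_a + n_b) * log_half,
        n_a * log_e + n_b * log_1e,
    ], axis=1)
    ll = ll + np.log(np.asarray(priors))
    # normalise in log space; guard the e=0 / all -inf corner
    mx = ll.max(axis=1, keepdims=True)
    finite = np.isfinite(mx[:, 0])
    post = np.zeros_like(ll)
    if finite.any():
        w = np.exp(ll[finite] - mx[finite])
        post[finite] = w / w.sum(axis=1, keepdims=True)
    calls = np.where(
        post.max(axis=1) > params.posterior_threshold,
        post.argmax(axis=1), MISSING_CODE).astype(np.int8)
    calls[(n_a + n_b) == 0] = MISSING_CODE
    return post, calls


def call_genotype(
    n_a: int, n_b: int,
    params: CallParams = CallParams(),
    priors: tuple[float, float, float] = F2_PRIORS,
) -> GenotypePosterior:
    """Scalar convenience wrapper around :func:`call_genotypes`."""
    post, calls = call_genotypes(np.array([n_a]), np.array([n_b]), params, priors)
    return GenotypePosterior(*post[0], int(calls[0]))


def filter_population_depth(
    site_depth: np.ndarray, params: CallParams = CallParams()
) -> np.ndarray:
    """Mask of sites whose total read depth across the population is > threshold."""
    return np.asarray(site_depth) > params.min_population_depth


# ---------------------------------------------------------------------------
# Sliding windows and breakpoints
# ---------------------------------------------------------------------------


def window_states(
    n_a: np.ndarray, n_b: np.ndarray, params: WindowParams = WindowParams()
) -> np.ndarray:
    """Window genotype along one line's ordered sites from founder-allele counts.

    Each window of ``window`` consecutive sites is summarised by the fraction
    f_b of non-recipient alleles among its informative alleles:
    f_b <= 1-hom -> aa, f_b >= hom -> bb, otherwise ab.  Windows with fewer
    than ``min_called`` informative sites (n_a + n_b > 0) are missing.

    At the paper's ~3x depth the counts are read alleles; for known genotype
    calls use :func:`window_states_from_calls`, which contributes two alleles
    per called site so f_b reduces to (# b alleles) / (2 x called sites).
    Returns one state per window (length n - window + 1).
    """
    n_a = np.asarray(n_a, dtype=np.int64)
    n_b = np.asarray(n_b, dtype=np.int64)
    if n_a.shape != n_b.shape:
        raise ValueError("n_a and n_b must align")
    W = params.window
    n = len(n_a)
    if n < W:
        return np.empty(0, dtype=np.int8)
    informative = (n_a + n_b) > 0
    csum_a = np.concatenate([[0], np.cumsum(n_a)])
    csum_b = np.concatenate([[0], np.cumsum(n_b)])
    csum_i = np.concatenate([[0], np.cumsum(informative)])
    wa = csum_a[W:] - csum_a[:-W]
    wb = csum_b[W:] - csum_b[:-W]
    wi = csum_i[W:] - csum_i[:-W]
    states = np.full(n - W + 1, MISSING_CODE, dtype=np.int8)
    ok = wi >= params.min_called
    with np.errstate(invalid="ignore", divide="ignore"):
        f_b = np.where(ok & (wa + wb > 0), wb / np.maximum(wa + wb, 1), np.nan)
    eps = 1e-12  # keeps exact-boundary fractions (e.g. 3/30 vs 1-0.9) stable
    states[ok & (f_b <= 1 - params.hom_threshold + eps)] = AA
    states[ok & (f_b >= params.hom_threshold - eps)] = BB
    mid = ok & (f_b > 1 - params.hom_threshold + eps) & (f_b < params.hom_threshold - eps)
    states[mid] = AB
    return states


def _calls_to_allele_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    calls = np.asarray(calls)
    called = calls >= 0
    n_b = np.where(called, calls, 0).astype(np.int64)  # code == # b alleles
    n_a = np.where(called, 2 - calls, 0).astype(np.int64)
    return n_a, n_b


def window_states_from_calls(
    calls: np.ndarray, params: WindowParams = WindowParams()
) -> np.ndarray:
    """Window states over per-site genotype calls (AA/AB/BB, missing -1)."""
    n_a, n_b = _calls_to_allele_counts(calls)
    return window_states(n_a, n_b, params)


def window_genotype(calls: np.ndarray, params: WindowParams = WindowParams()) -> int:
    """State of a single window (the genotype calls of exactly one window)."""
    p = WindowParams(window=max(len(calls), 1), step=params.step,
                     hom_threshold=params.hom_threshold,
                     min_called=params.min_called, min_run=params.min_run)
    out = window_states_from_calls(np.asarray(calls), p)
    return int(out[0]) if out.size else MISSING_CODE


def detect_breakpoints(
    states: np.ndarray,
    centers_bp: np.ndarray,
    params: WindowParams = WindowParams(),
) -> tuple[list[tuple[int, int, int]], np.ndarray]:
    """Segments and breakpoint positions from ordered window states.

    ``centers_bp`` gives the physical position of each window's central site.
    Maximal runs of identical non-missing states form segments; runs shorter
    than ``min_run`` are reassigned to the longer flanking run; a breakpoint
    sits at the midpoint between the last supporting site of one segment and
    the first of the next, corrected for the window-threshold crossing
    offset: a window of W sites switches into a heterozygous state once
    roughly 2W(1-hom_threshold) of its sites lie past the true crossover and
    into a homozygous state only after W(2 hom_threshold - 1) sites do, so
    the raw midpoint systematically extends heterozygous segments by a few
    sites; subtracting that offset makes the estimate unbiased under uniform
    crossover placement.  Returns ([(state, start_bp, end_bp), ...],
    breakpoints array); zero segments if every window is missing.
    """
    states = np.asarray(states)
    centers_bp = np.asarray(centers_bp)
    if states.shape != centers_bp.shape:
        raise ValueError("states and centers_bp must align")
    keep = states >= 0
    s = states[keep]
    c = centers_bp[keep]
    if s.size == 0:
        return [], np.empty(0, dtype=np.int64)

    # compress into runs [state, start index, end index] over the kept windows
    runs: list[list[int]] = []
    for i, st in enumerate(s):
        if runs and runs[-1][0] == st:
            runs[-1][2] = i
        else:
            runs.append([int(st), i, i])

    def run_len(r):  # in windows
        return r[2] - r[1] + 1

    changed = True
    while changed and len(runs) > 1:
        changed = False
        for i, r in enumerate(runs):
            if run_len(r) >= params.min_run:
                continue
            left = runs[i - 1] if i > 0 else None
            right = runs[i + 1] if i < len(runs) - 1 else None
            if left is None and right is None:
                continue
            if right is None or (left is not None and run_len(left) >= run_len(right)):
                target = left
            else:
                target = right
            r[0] = target[0]
            # merge equal-state neighbours
            merged: list[list[int]] = []
            for q in runs:
                if merged and merged[-1][0] == q[0]:
                    merged[-1][2] = q[2]
                else:
                    merged.append(q)
            runs = merged
            changed = True
            break

    segments = [(r[0], int(c[r[1]]), int(c[r[2]])) for r in runs]

    # threshold-crossing site counts for the window statistic
    W = params.window
    hom = params.hom_threshold
    k_enter_het = np.floor(2 * W * (1 - hom) + 1e-9) + 1
    k_enter_hom = np.ceil(W * (2 * hom - 1) - 1e-9)
    breakpoints = []
    prev_bp = -np.inf
    for i in range(len(runs) - 1):
        left, right = runs[i], runs[i + 1]
        li, rj = left[2], right[1]          # kept-window indices flanking the change
        midpoint = (c[li] + c[rj]) / 2.0
        spacing = (c[rj] - c[li]) / max(rj - li, 1)
        if right[0] == AB:                  # hom -> het, flips early
            k_star = k_enter_het
        elif left[0] == AB:                 # het -> hom, flips late
            k_star = k_enter_hom
        else:                               # hom -> hom (rare direct change)
            k_star = np.ceil(W * hom - 1e-9)
        offset_sites = (k_star - 1.0) - W / 2.0
        bp = int(round(midpoint - offset_sites * spacing))
        bp = int(max(bp, prev_bp + 1))      # keep breakpoints strictly increasing
        prev_bp = bp
        breakpoints.append(bp)
    return segments, np.array(breakpoints, dtype=np.int64)


# ---------------------------------------------------------------------------
# Bins
# ---------------------------------------------------------------------------


def build_bins(
    breakpoints_by_chrom: dict[str, np.ndarray], layout: GenomeLayout
) -> pd.DataFrame:
    """Partition each chromosome at the union of all lines' breakpoints.

    Bins are 1-based half-open [start, end) tiling [1, length+1); a
    chromosome with k unique breakpoints yields k+1 bins.  Bin ids number
    bins consecutively genome-wide, matching the ``binN`` labels of the map.
    """
    rows = []
    bin_id = 0
    for chrom in layout.chromosomes:
        bps = np.unique(np.asarray(breakpoints_by_chrom.get(chrom.name, []), dtype=np.int64))
        if bps.size and (bps.min() < 1 or bps.max() > chrom.length_bp):
            raise ValueError(f"breakpoint outside {chrom.name}")
        bps = bps[(bps > 1) & (bps <= chrom.length_bp)]
        edges = np.concatenate([[1], bps, [chrom.length_bp + 1]])
        for start, end in zip(edges[:-1], edges[1:]):
            bin_id += 1
            rows.append({"bin_id": bin_id, "label": f"bin{bin_id}",
                         "chrom": chrom.name, "start": int(start), "end": int(end)})
    bins = pd.DataFrame(rows)
    bins["length"] = bins["end"] - bins["start"]
    return bins


def bin_genotypes(
    line_segments: dict[str, dict[str, tuple[list, np.ndarray]]],
    bins: pd.DataFrame,
) -> pd.DataFrame:
    """Lines x bins genotype matrix from per-line chromosome segments.

    ``line_segments[line_id][chrom]`` is the (segments, breakpoints) pair from
    :func:`detect_breakpoints`.  Each line's first/last segment is extended to
    the chromosome ends; a bin takes the state of the segment containing its
    midpoint (each line's breakpoints are bin edges, so bins never straddle a
    segment boundary).  Chromosomes without any window state are missing.
    """
    bin_mid = ((bins["start"] + bins["end"]) // 2).to_numpy()
    bin_chrom = bins["chrom"].to_numpy()
    out = {}
    for line_id, per_chrom in line_segments.items():
        row = np.full(len(bins), MISSING_CODE, dtype=np.int8)
        for chrom, (segments, breakpoints) in per_chrom.items():
            if not segments:
                continue
            mask = bin_chrom == chrom
            region = np.searchsorted(breakpoints, bin_mid[mask], side="right")
            states = np.array([seg[0] for seg in segments], dtype=np.int8)
            row[mask] = states[region]
        out[line_id] = row
    matrix = pd.DataFrame.from_dict(out, orient="index",
                                    columns=bins["bin_id"].to_numpy())
    matrix.index.name = "line_id"
    return matrix


# ---------------------------------------------------------------------------
# Recombination fractions and map distances
# ---------------------------------------------------------------------------

# Known recombinant-gamete counts per two-locus genotype cell (coupling F2);
# the double heterozygote (1,1) is a mixture handled in the E-step.
_KNOWN_R = np.array([[0, 1, 2],
                     [1, -1, 1],
                     [2, 1, 0]], dtype=float)


def estimate_rf(
    genotypes_i: np.ndarray,
    genotypes_j: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> float:
    """Maximum-likelihood recombination fraction for two codominant F2 loci.

    EM over the 3x3 genotype table in coupling phase: every cell determines
    its recombinant-gamete count except the double heterozygote, which arises
    from two parental gametes with probability (1-r)^2 / ((1-r)^2 + r^2) and
    from two recombinant gametes otherwise.
    """
    gi = np.asarray(genotypes_i)
    gj = np.asarray(genotypes_j)
    mask = (gi >= 0) & (gj >= 0)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least 2 lines with both genotypes called")
    counts = np.zeros((3, 3))
    np.add.at(counts, (gi[mask], gj[mask]), 1)
    n11 = counts[1, 1]
    known = float((counts * np.where(_KNOWN_R < 0, 0, _KNOWN_R)).sum())
    r = 0.25
    for _ in range(max_iter):
        e11 = 2 * r * r / (r * r + (1 - r) ** 2)
        new = (known + n11 * e11) / (2 * n)
        new = min(max(new, 0.0), 0.5)
        if abs(new - r) < tol:
            r = new
            break
        r = new
    return float(r)


def to_centimorgans(r: float, function: str = "kosambi") -> float:
    """Map a recombination fraction to a distance in centimorgans."""
    if not 0 <= r < 0.5:
        raise ValueError("r must lie in [0, 0.5)")
    if function == "haldane":
        return -50.0 * np.log1p(-2.0 * r)
    if function == "kosambi":
        return 25.0 * np.log((1 + 2 * r) / (1 - 2 * r))
    raise ValueError(f"unknown mapping function {function!r}")


def from_centimorgans(d: float, function: str = "kosambi") -> float:
    """Inverse mapping function: distance in cM back to a recombination fraction."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    if function == "haldane":
        return 0.5 * (1.0 - np.exp(-d / 50.0))
    if function == "kosambi":
        return 0.5 * np.tanh(d / 50.0)
    raise ValueError(f"unknown mapping function {function!r}")


def build_genetic_map(
    matrix: pd.DataFrame,
    bins: pd.DataFrame,
    function: str = "kosambi",
    max_r: float = 0.495,
) -> pd.DataFrame:
    """Genetic map over the bin partition: adjacent recombination fractions and
    cumulative cM per chromosome.

    Adjacent r-hat estimates are clipped to ``max_r`` before conversion so a
    noisy unlinked-looking pair cannot contribute an infinite distance; pairs
    with too few doubly-called lines contribute zero and are flagged NaN in
    the ``r_prev`` column.
    """
    gmap = bins.copy()
    r_prev = np.full(len(bins), np.nan)
    cm = np.zeros(len(bins))
    cols = list(matrix.columns)
    for chrom in gmap["chrom"].unique():
        idx = np.flatnonzero((gmap["chrom"] == chrom).to_numpy())
        running = 0.0
        for prev, cur in zip(idx[:-1], idx[1:]):
            ci = matrix[cols[prev]].to_numpy()
            cj = matrix[cols[cur]].to_numpy()
            try:
                r = estimate_rf(ci, cj)
            except ValueError:
                r = np.nan
            r_prev[cur] = r
            if np.isfinite(r):
                running += to_centimorgans(min(r, max_r), function)
            cm[cur] = running
    gmap["r_prev"] = r_prev
    gmap["cM"] = cm
    return gmap


def map_size(gmap: pd.DataFrame) -> float:
    """Total map length: sum of terminal cumulative distances per chromosome."""
    if len(gmap) == 0:
        return 0.0
    return float(gmap.groupby("chrom", sort=False)["cM"].max().sum())
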