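"""Regression-based composite-interval-mapping approximation over bin genotypes.

Bins from a dense recombination bin map act as markers, so interval stepping
between markers adds nothing and each bin is tested directly by comparing two
nested least-squares fits: the null model (intercept plus background
cofactors) and the full model adding the tested bin's additive code
x in {-1, 0, +1} and dominance code z = 1[heterozygote] — two degrees of
freedom, matching a codominant F2 design.  For a bin fitted on n complete
cases, LOD = (n/2) log10(RSS0/RSS1), and the explained variance share obeys
R^2 = 1 - 10^(-2 LOD / n).  Background cofactors come from a forward
selection over bins, and cofactors within an exclusion distance of the tested
bin are dropped from both models.  Genome-wide significance is calibrated by
permuting trait values across lines and taking a quantile of the permutation
maximum-LOD distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binmap import MISSING_CODE

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanParams:
    cofactor_lod_enter: float = 3.0
    cofactor_exclusion_cM: float = 10.0
    n_permutations: int = 1000
    alpha: float = 0.05
    lod_report_threshold: float = 3.5
    min_lines: int = 10
    max_cofactors: int = 10
    support_drop: float = 1.5

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")


def lod_from_r2(r2: float, n: int) -> float:
    """LOD score implied by a variance share R^2 at sample size n."""
    if not 0 <= r2 < 1:
        raise ValueError("r2 must lie in [0, 1)")
    return -(n / 2.0) * np.log10(1.0 - r2)


def r2_from_lod(lod: float, n: int) -> float:
    """Variance share implied by a LOD score at sample size n."""
    return 1.0 - 10.0 ** (-2.0 * lod / n)


def _design_columns(codes: np.ndarray) -> np.ndarray:
    """Additive and dominance columns for genotype codes 0/1/2."""
    x = codes.astype(float) - 1.0
    z = (codes == 1).astype(float)
    return np.column_stack([x, z])


class CollinearBin(ValueError):
    """Raised when the tested bin adds no rank to the cofactor design."""


def fit_bin(
    y: np.ndarray,
    codes: np.ndarray,
    cofactor_codes: np.ndarray | None = None,
    min_lines: int = 10,
) -> tuple[float, float, int]:
    """LOD, R^2 and complete-case count for one tested bin.

    Lines missing the trait, the tested bin, or any cofactor genotype are
    dropped.  Raises :class:`CollinearBin` when the bin's columns lie in the
    span of the cofactor design.
    """
    y = np.asarray(y, dtype=float)
    codes = np.asarray(codes)
    mask = ~np.isnan(y) & (codes != MISSING_CODE)
    if cofactor_codes is not None and cofactor_codes.size:
        cofactor_codes = np.atleast_2d(cofactor_codes)
        if cofactor_codes.shape[0] != y.shape[0]:
            cofactor_codes = cofactor_codes.T
        mask &= (cofactor_codes != MISSING_CODE).all(axis=1)
    n = int(mask.sum())
    if n < min_lines:
        raise ValueError(f"only {n} complete lines (need >= {min_lines})")
    yy = y[mask]
    X0 = np.ones((n, 1))
    if cofactor_codes is not None and cofactor_codes.size:
        for j in range(cofactor_codes.shape[1]):
            X0 = np.hstack([X0, _design_columns(cofactor_codes[mask, j])])
    X1 = np.hstack([X0, _design_columns(codes[mask])])
    rank0 = np.linalg.matrix_rank(X0)
    rank1 = np.linalg.matrix_rank(X1)
    if rank1 <= rank0:
        raise CollinearBin("tested bin is collinear with the cofactor design")
    rss0 = float(np.sum((yy - X0 @ np.linalg.lstsq(X0, yy, rcond=None)[0]) ** 2))
    rss1 = float(np.sum((yy - X1 @ np.linalg.lstsq(X1, yy, rcond=None)[0]) ** 2))
    if rss0 <= 0:
        return 0.0, 0.0, n
    if rss1 <= 0:
        return np.inf, 1.0, n
    lod = (n / 2.0) * np.log10(rss0 / rss1)
    r2 = 1.0 - rss1 / rss0
    return float(max(lod, 0.0)), float(max(r2, 0.0)), n


def scan_profile(
    y: np.ndarray,
    matrix: pd.DataFrame,
    bins: pd.DataFrame,
    bin_cm: np.ndarray | None = None,
    cofactors: list[int] | None = None,
    params: ScanParams = ScanParams(),
) -> pd.DataFrame:
    """LOD profile over all bins; cofactors near the tested bin are omitted.

    ``matrix`` is lines x bins (columns = bin_id); ``bin_cm`` gives each bin's
    genetic position (cumulative cM within its chromosome) and is required
    when cofactors are used.  Bins that cannot be fitted get NaN.
    """
    cofactors = list(cofactors or [])
    bin_ids = list(matrix.columns)
    id_to_col = {b: i for i, b in enumerate(bin_ids)}
    chrom = bins.set_index("bin_id").loc[bin_ids, "chrom"].to_numpy()
    if cofactors and bin_cm is None:
        raise ValueError("bin_cm is required when cofactors are given")
    codes_all = matrix.to_numpy()
    rows = []
    for i, b in enumerate(bin_ids):
        use = cofactors
        if cofactors:
            use = [
                c for c in cofactors
                if c != b and not (
                    chrom[id_to_col[c]] == chrom[i]
                    and abs(bin_cm[id_to_col[c]] - bin_cm[i]) <= params.cofactor_exclusion_cM)
            ]
        cof = codes_all[:, [id_to_col[c] for c in use]] if use else None
        try:
            lod, r2, n = fit_bin(y, codes_all[:, i], cof, params.min_lines)
        except CollinearBin:
            logger.info("bin %s skipped: collinear with cofactors", b)
            lod, r2, n = np.nan, np.nan, 0
        except ValueError:
            lod, r2, n = np.nan, np.nan, 0
        rows.append({"bin_id": b, "lod": lod, "r2": r2, "n": n})
    return pd.DataFrame(rows)


def select_cofactors(
    y: np.ndarray,
    matrix: pd.DataFrame,
    bins: pd.DataFrame,
    bin_cm: np.ndarray,
    params: ScanParams = ScanParams(),
) -> list[int]:
    """Forward selection of background bins.

    Repeatedly add the bin with the highest LOD against the current model
    while that LOD exceeds ``cofactor_lod_enter``; deterministic, ties broken
    by (chrom, start) order, i.e. by ascending bin id.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).all():
        return []
    selected: list[int] = []
    ordered = bins.sort_values(["chrom", "start"])["bin_id"].tolist()
    codes_all = matrix.to_numpy()
    col_of = {b: i for i, b in enumerate(matrix.columns)}
    for _ in range(params.max_cofactors):
        # candidates are scored against the full current model (no exclusion
        # window here — that rule applies only when profiling the final scan)
        cof = codes_all[:, [col_of[c] for c in selected]] if selected else None
        best, best_lod = None, -np.inf
        for b in ordered:  # fixed order makes ties deterministic
            if b in selected:
                continue
            try:
                lod, _, _ = fit_bin(y, codes_all[:, col_of[b]], cof, params.min_lines)
            except (CollinearBin, ValueError):
                continue
            if np.isfinite(lod) and lod > best_lod:
                best, best_lod = b, float(lod)
        if best is None or best_lod <= params.cofactor_lod_enter:
            break
        selected.append(best)
    return selected


def permutation_threshold(
    y: np.ndarray,
    matrix: pd.DataFrame,
    params: ScanParams = ScanParams(),
    rng: np.random.Generator | None = None,
) -> float:
    """Genome-wide LOD threshold from the permutation null.

    Trait values are permuted across lines ``n_permutations`` times; the
    threshold is the (1 - alpha) quantile of the per-permutation maximum LOD
    over all bins (no cofactors, matching standard single-locus calibration).
    """
    rng = rng or np.random.default_rng()
    y = np.asarray(y, dtype=float)
    keep = ~np.isnan(y)
    y = y[keep]
    codes = matrix.to_numpy()[keep]
    n_lines = len(y)
    perms = np.empty((n_lines, params.n_permutations))
    for k in range(params.n_permutations):
        perms[:, k] = y[rng.permutation(n_lines)]
    max_lod = np.zeros(params.n_permutations)
    for j in range(codes.shape[1]):
        cj = codes[:, j]
        mask = cj != MISSING_CODE
        n = int(mask.sum())
        if n < params.min_lines:
            continue
        D = np.column_stack([np.ones(n), *_design_columns(cj[mask]).T])
        Q, _ = np.linalg.qr(D)
        Yb = perms[mask]
        tot = (Yb ** 2).sum(axis=0)
        rss0 = tot - Yb.sum(axis=0) ** 2 / n
        proj = Q.T @ Yb
        rss1 = tot - (proj ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            lod = np.where(rss1 > 0, (n / 2.0) * np.log10(rss0 / rss1), np.inf)
        np.maximum(max_lod, np.nan_to_num(lod, nan=0.0), out=max_lod)
    return float(np.quantile(max_lod, 1.0 - params.alpha))


def summarize(
    profile: pd.DataFrame,
    threshold: float,
    bins: pd.DataFrame,
    bin_cm: np.ndarray,
    params: ScanParams = ScanParams(),
    trait: str = "trait",
) -> pd.DataFrame:
    """QTL hits: LOD maxima above threshold, separated by the exclusion distance.

    Each hit reports the peak bin's coordinates and length, its LOD and R^2
    in percent, and a support interval of contiguous bins within
    ``support_drop`` LOD of the peak.
    """
    columns = ["trait", "chrom", "peak_bin", "start", "end", "bin_length",
               "lod", "r2_pct", "support_start", "support_end"]
    if len(profile) == 0:
        return pd.DataFrame(columns=columns)
    merged = profile.merge(bins, on="bin_id")
    merged["cm"] = bin_cm
    ok = merged[np.isfinite(merged["lod"]) & (merged["lod"] > threshold)]
    hits = []
    taken: list[tuple[str, float]] = []
    for _, row in ok.sort_values("lod", ascending=False).iterrows():
        if any(c == row["chrom"] and abs(p - row["cm"]) < params.cofactor_exclusion_cM
               for c, p in taken):
            continue
        taken.append((row["chrom"], row["cm"]))
        same = merged[merged["chrom"] == row["chrom"]].reset_index(drop=True)
        pi = int(same.index[same["bin_id"] == row["bin_id"]][0])
        lo = hi = pi
        while lo > 0 and np.isfinite(same.loc[lo - 1, "lod"]) \
                and same.loc[lo - 1, "lod"] >= row["lod"] - params.support_drop:
            lo -= 1
        while hi < len(same) - 1 and np.isfinite(same.loc[hi + 1, "lod"]) \
                and same.loc[hi + 1, "lod"] >= row["lod"] - params.support_drop:
            hi += 1
        hits.append({
            "trait": trait, "chrom": row["chrom"], "peak_bin": int(row["bin_id"]),
            "start": int(row["start"]), "end": int(row["end"]),
            "bin_length": int(row["end"] - row["start"]),
            "lod": float(row["lod"]), "r2_pct": float(100.0 * row["r2"]),
            "support_start": int(same.loc[lo, "start"]),
            "support_end": int(same.loc[hi, "end"]),
        })
    out = pd.DataFrame(hits, columns=columns)
    return out.sort_values(["chrom", "start"]).reset_index(drop=True) if len(out) else out
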