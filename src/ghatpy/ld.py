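"""Linkage-disequilibrium structure and the effective number of markers.

Markers in LD carry redundant information, so a genome of ``m`` markers
behaves like a smaller number ``M_eff`` of independent "genotype blocks".
``M_eff`` calibrates the permutation null of the Ghat test (scale method).
Two estimators are provided:

``ld_decay``
    Bins pairwise genotype r-squared by inter-marker distance per
    chromosome, smooths the decay curve monotonically, finds the distance
    ``d*`` at which mean r2 drops below a threshold, and counts
    ``ceil(span / d*)`` segments per chromosome.

``simple_m``
    Eigenvalue criterion: per chromosome, the smallest number of leading
    eigenvalues of the marker correlation matrix whose sum reaches a set
    fraction (default 0.995) of the total; summed over chromosomes.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .datatypes import GenotypeMatrix, LDSummary, MarkerMap

logger = logging.getLogger(__name__)

__all__ = ["pairwise_r2", "ld_decay", "simple_m", "meff_from_corr"]


def _chrom_dosages(g: GenotypeMatrix, mmap: MarkerMap, chrom) -> tuple:
    """Imputed dosage block and positions for one chromosome."""
    mmap.check_matches(g)
    mask = mmap.chrom == str(chrom)
    if not mask.any():
        raise ValueError(f"chromosome {chrom!r} not present in map")
    X = g.dosages[:, mask].astype(np.float64)
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        r, c = np.where(np.isnan(X))
        X[r, c] = col_mean[c]
    return X, mmap.pos[mask], np.asarray(g.markers)[mask]


def pairwise_r2(g: GenotypeMatrix, mmap: MarkerMap, chrom,
                max_win_snp: int = 1000) -> pd.DataFrame:
    """Squared dosage correlation for marker pairs within a sliding window.

    Pairs are limited to at most ``max_win_snp`` intervening markers.
    Monomorphic markers are skipped (their correlation is undefined).
    Returns a DataFrame with columns ``marker_i, marker_j, distance, r2``.
    """
    X, pos, mids = _chrom_dosages(g, mmap, chrom)
    sd = X.std(axis=0)
    poly = sd > 0
    n_mono = int((~poly).sum())
    if n_mono:
        logger.info("chromosome %s: %d monomorphic markers skipped",
                    chrom, n_mono)
    X, pos, mids = X[:, poly], pos[poly], mids[poly]
    m = X.shape[1]
    if m < 2:
        warnings.warn(f"chromosome {chrom}: fewer than 2 polymorphic "
                      "markers; empty r2 table")
        return pd.DataFrame(columns=["marker_i", "marker_j", "distance",
                                     "r2"])
    Xs = (X - X.mean(axis=0)) / sd[poly]
    n = X.shape[0]
    frames = []
    for k in range(1, min(max_win_snp, m - 1) + 1):
        r = np.einsum("ij,ij->j", Xs[:, :-k], Xs[:, k:]) / n
        frames.append(pd.DataFrame({
            "marker_i": mids[:-k], "marker_j": mids[k:],
            "distance": pos[k:] - pos[:-k], "r2": r * r}))
    return pd.concat(frames, ignore_index=True)


def ld_decay(g: GenotypeMatrix, mmap: MarkerMap, max_win_snp: int = 1000,
             max_chr: int | None = None, max_r2: float = 0.03,
             n_bins: int = 100) -> LDSummary:
    """Effective marker number from the distance at which LD decays.

    Per chromosome, pairwise r2 is averaged in ``n_bins`` equal-width
    distance bins over the chromosome span, smoothed by isotonic
    (non-increasing) regression, and the smallest bin distance with
    smoothed mean r2 below ``max_r2`` becomes the independence distance
    ``d*``; the chromosome contributes ``ceil(span / d*)`` segments.  If LD
    never decays below the threshold the chromosome counts as a single
    segment.
    """
    if not 0 < max_r2 < 1:
        raise ValueError("max_r2 must be in (0, 1)")
    chroms = pd.unique(mmap.chrom)
    if max_chr is not None:
        chroms = chroms[:max_chr]
    per_chrom_rows = []
    decay_rows = []
    m_eff = 0
    for chrom in chroms:
        tab = pairwise_r2(g, mmap, chrom, max_win_snp=max_win_snp)
        pos = mmap.pos[mmap.chrom == str(chrom)]
        mask_m = int((mmap.chrom == str(chrom)).sum())
        span = float(pos.max() - pos.min())
        if len(tab) == 0 or span <= 0:
            segments, d_star = 1, np.nan
        else:
            edges = np.linspace(0, max(span, tab["distance"].max()),
                                n_bins + 1)
            centers = 0.5 * (edges[:-1] + edges[1:])
            idx = np.clip(np.digitize(tab["distance"], edges) - 1,
                          0, n_bins - 1)
            sums = np.bincount(idx, weights=tab["r2"], minlength=n_bins)
            counts = np.bincount(idx, minlength=n_bins)
            filled = counts > 0
            iso = IsotonicRegression(increasing=False)
            smooth = iso.fit_transform(centers[filled],
                                       sums[filled] / counts[filled],
                                       sample_weight=counts[filled])
            for c_, s_, n_ in zip(centers[filled], smooth, counts[filled]):
                decay_rows.append({"chrom": chrom, "distance": c_,
                                   "mean_r2": s_, "n_pairs": int(n_)})
            below = np.flatnonzero(smooth < max_r2)
            if len(below) == 0:
                warnings.warn(f"chromosome {chrom}: mean r2 never falls "
                              f"below {max_r2}; counting 1 segment")
                segments, d_star = 1, np.nan
            else:
                d_star = float(centers[filled][below[0]])
                segments = max(int(np.ceil(span / max(d_star, 1e-12))), 1)
                # a chromosome cannot carry more independent segments than
                # markers
                segments = min(segments, int(mask_m))
        per_chrom_rows.append({"chrom": chrom, "span": span,
                               "d_star": d_star, "segments": segments})
        m_eff += segments
    return LDSummary(m_eff=int(m_eff), method="ld_decay",
                     per_chrom=pd.DataFrame(per_chrom_rows),
                     decay=pd.DataFrame(decay_rows),
                     params={"max_win_snp": max_win_snp, "max_r2": max_r2,
                             "n_bins": n_bins})


def meff_from_corr(corr: np.ndarray, var_fraction: float = 0.995) -> int:
    """Smallest number of leading eigenvalues reaching ``var_fraction`` of
    the total eigenvalue sum."""
    vals = np.linalg.eigvalsh(corr)
    return _meff_from_eigvals(vals, var_fraction)


def _meff_from_eigvals(vals: np.ndarray, var_fraction: float) -> int:
    vals = np.sort(np.clip(vals, 0.0, None))[::-1]
    total = vals.sum()
    if total <= 0:
        raise ValueError("degenerate correlation matrix")
    cum = np.cumsum(vals) / total
    return int(np.searchsorted(cum, var_fraction - 1e-12) + 1)


def simple_m(g: GenotypeMatrix, mmap: MarkerMap,
             var_fraction: float = 0.995,
             block_size: int = 2000) -> LDSummary:
    """simpleM effective marker number.

    Chromosomes longer than ``block_size`` markers are split into
    contiguous blocks whose per-block counts are summed, keeping the
    eigendecompositions tractable at high marker density.
    """
    if not 0 < var_fraction <= 1:
        raise ValueError("var_fraction must be in (0, 1]")
    chroms = pd.unique(mmap.chrom)
    rows = []
    m_eff = 0
    for chrom in chroms:
        X, _, _ = _chrom_dosages(g, mmap, chrom)
        sd = X.std(axis=0)
        poly = sd > 0
        n_mono = int((~poly).sum())
        if n_mono:
            logger.info("chromosome %s: %d monomorphic markers dropped "
                        "from simpleM", chrom, n_mono)
        X = X[:, poly]
        m_chr = X.shape[1]
        if m_chr == 0:
            raise ValueError(f"chromosome {chrom}: no polymorphic markers")
        Xs = (X - X.mean(axis=0)) / sd[poly]
        n = X.shape[0]
        n_blocks = int(np.ceil(m_chr / block_size))
        bounds = np.linspace(0, m_chr, n_blocks + 1).astype(int)
        chrom_meff = 0
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            B = np.ascontiguousarray(Xs[:, b0:b1], dtype=np.float32)
            corr = (B.T @ B) / n
            chrom_meff += _meff_from_eigvals(
                np.linalg.eigvalsh(corr).astype(np.float64), var_fraction)
        rows.append({"chrom": chrom, "m": m_chr, "m_eff": chrom_meff})
        m_eff += chrom_meff
    return LDSummary(m_eff=int(m_eff), method="simpleM",
                     per_chrom=pd.DataFrame(rows),
                     params={"var_fraction": var_fraction,
                             "block_size": block_size})
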