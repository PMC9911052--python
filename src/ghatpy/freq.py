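"""Allele frequencies per group and the change between two time points."""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import FreqChange, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["allele_frequencies", "frequency_change"]


def allele_frequencies(g: GenotypeMatrix, group_label=None) -> np.ndarray:
    """Counted-allele frequency per marker within one sample group.

    Frequency = (sum of non-missing dosages) / (2 x number of non-missing
    calls); individuals are weighted equally.  Markers with no non-missing
    call in the group come back as NaN.
    """
    sub = g.subset_group(group_label) if group_label is not None else g
    dos = sub.dosages
    called = np.isfinite(dos)
    n_called = called.sum(axis=0)
    total = np.where(called, dos, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, total / (2.0 * n_called), np.nan)
    return freq


def frequency_change(g: GenotypeMatrix, early, late) -> FreqChange:
    """Per-marker delta = freq(late) - freq(early).

    Positive delta means the counted allele rose in frequency; combined with
    positive effects this drives the Ghat statistic positive (selection
    favouring trait-increasing alleles).  Markers with a missing frequency
    in either group get delta = NaN and are excluded downstream.
    """
    if early == late:
        raise ValueError("early and late groups must differ")
    g_early = g.subset_group(early)
    g_late = g.subset_group(late)
    f_early = allele_frequencies(g_early)
    f_late = allele_frequencies(g_late)
    n_early = np.isfinite(g_early.dosages).sum(axis=0)
    n_late = np.isfinite(g_late.dosages).sum(axis=0)
    delta = f_late - f_early
    n_missing = int(np.sum(~np.isfinite(delta)))
    if n_missing:
        logger.info("%d markers lack calls in one group; delta set missing",
                    n_missing)
    return FreqChange(marker=g.markers, delta=delta, freq_early=f_early,
                      freq_late=f_late, n_early=n_early, n_late=n_late,
                      counted_allele=g.counted_allele)
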