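"""Core containers shared across the package.

Genotypes are diploid allele dosages in {0, 1, 2} (count of the per-marker
``counted_allele``); missing calls are ``NaN``.  All downstream statistics are
invariant under a joint orientation flip of any marker (dosage -> 2 - dosage,
effect -> -effect, frequency change -> -change), and the containers carry the
orientation so that flips can be applied consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "MarkerMap",
    "EffectEstimates",
    "FreqChange",
    "LDSummary",
    "GhatResult",
]


def _as_str_array(values: Sequence) -> np.ndarray:
    return np.asarray([str(v) for v in values], dtype=object)


@dataclass
class GenotypeMatrix:
    """Individuals x markers allele-dosage matrix with sample metadata.

    Parameters
    ----------
    samples
        Unique sample identifiers, length ``n``.
    markers
        Unique marker identifiers, length ``m``, in map order.
    dosages
        ``n x m`` float array; entries in {0, 1, 2} or NaN for missing.
    group
        Per-sample label (generation number, registration year, ...).
    counted_allele
        Per-marker identifier of the allele whose copies are counted.
    """

    samples: np.ndarray
    markers: np.ndarray
    dosages: np.ndarray
    group: np.ndarray | None = None
    counted_allele: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = _as_str_array(self.samples)
        self.markers = _as_str_array(self.markers)
        self.dosages = np.asarray(self.dosages, dtype=np.float32)
        if self.dosages.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids are not unique")
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker ids are not unique")
        finite = self.dosages[np.isfinite(self.dosages)]
        # fractional values in [0, 2] are allowed so mean-imputed matrices
        # remain valid; file readers separately enforce integer {0,1,2} codes
        if finite.size and (finite.min() < 0.0 or finite.max() > 2.0):
            bad = finite[(finite < 0.0) | (finite > 2.0)]
            raise ValueError(
                f"dosages must lie in [0, 2] or be missing; found e.g. {bad[:5]}"
            )
        if self.group is not None:
            self.group = np.asarray(self.group)
            if len(self.group) != len(self.samples):
                raise ValueError("group labels do not match sample count")
        if self.counted_allele is None:
            self.counted_allele = _as_str_array(["A"] * len(self.markers))
        else:
            self.counted_allele = _as_str_array(self.counted_allele)
            if len(self.counted_allele) != len(self.markers):
                raise ValueError("counted_allele does not match marker count")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def subset_group(self, label) -> "GenotypeMatrix":
        """Rows whose group label equals ``label``."""
        if self.group is None:
            raise ValueError("genotype matrix carries no group labels")
        mask = self.group == label
        if not mask.any():
            raise ValueError(f"group label {label!r} selects no samples")
        return GenotypeMatrix(
            samples=self.samples[mask],
            markers=self.markers,
            dosages=self.dosages[mask],
            group=self.group[mask],
            counted_allele=self.counted_allele,
        )

    def flip_markers(self, marker_ids: Sequence[str],
                     new_alleles: Sequence[str] | None = None) -> "GenotypeMatrix":
        """Reorient markers: dosage -> 2 - dosage, counted allele renamed."""
        idx = {m: i for i, m in enumerate(self.markers)}
        dos = self.dosages.copy()
        alleles = self.counted_allele.copy()
        for k, mid in enumerate(marker_ids):
            j = idx[str(mid)]
            dos[:, j] = 2.0 - dos[:, j]
            alleles[j] = (str(new_alleles[k]) if new_alleles is not None
                          else f"flip({alleles[j]})")
        return replace(self, dosages=dos, counted_allele=alleles)


@dataclass
class MarkerMap:
    """Per-marker chromosome and position (bp or cM, declared per file)."""

    marker: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    units: str = "cM"

    def __post_init__(self) -> None:
        self.marker = _as_str_array(self.marker)
        self.chrom = _as_str_array(self.chrom)
        self.pos = np.asarray(self.pos, dtype=float)
        if not (len(self.marker) == len(self.chrom) == len(self.pos)):
            raise ValueError("map columns have unequal lengths")
        if len(set(self.marker)) != len(self.marker):
            raise ValueError("map marker ids are not unique")

    def __len__(self) -> int:
        return len(self.marker)

    def sort(self) -> "MarkerMap":
        """Stable sort by (chromosome, position)."""
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        return MarkerMap(self.marker[order], self.chrom[order],
                         self.pos[order], self.units)

    def check_matches(self, g: GenotypeMatrix) -> None:
        if len(self) != g.n_markers or not (self.marker == g.markers).all():
            raise ValueError("marker map does not match genotype marker order")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"marker": self.marker, "chrom": self.chrom,
                             "pos": self.pos})


@dataclass
class EffectEstimates:
    """Per-marker allele-substitution effects with their orientation.

    ``alpha[j]`` is the estimated additive effect (trait units per copy of
    ``counted_allele[j]``).  ``params`` records the estimation method's
    hyperparameters and fitted variance components for reproducibility.
    """

    marker: np.ndarray
    alpha: np.ndarray
    method: str = "external"
    counted_allele: np.ndarray | None = None
    inclusion_prob: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.marker = _as_str_array(self.marker)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if len(self.marker) != len(self.alpha):
            raise ValueError("marker and alpha lengths differ")
        if not np.isfinite(self.alpha).all():
            raise ValueError("non-finite effect estimates")
        if self.counted_allele is None:
            self.counted_allele = _as_str_array(["A"] * len(self.marker))
        else:
            self.counted_allele = _as_str_array(self.counted_allele)

    def __len__(self) -> int:
        return len(self.marker)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"marker": self.marker, "alpha": self.alpha})
        if self.inclusion_prob is not None:
            df["inclusion_prob"] = self.inclusion_prob
        return df


@dataclass
class FreqChange:
    """Counted-allele frequency change between an early and a late group."""

    marker: np.ndarray
    delta: np.ndarray
    freq_early: np.ndarray
    freq_late: np.ndarray
    n_early: np.ndarray
    n_late: np.ndarray
    counted_allele: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.marker = _as_str_array(self.marker)
        for name in ("delta", "freq_early", "freq_late"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.n_early = np.asarray(self.n_early, dtype=int)
        self.n_late = np.asarray(self.n_late, dtype=int)
        # externally supplied change vectors may carry delta without the
        # underlying frequencies; consistency is only checkable where all
        # three are present
        ok = (np.isfinite(self.delta) & np.isfinite(self.freq_early)
              & np.isfinite(self.freq_late))
        if not np.allclose(self.delta[ok],
                           (self.freq_late - self.freq_early)[ok], atol=1e-8):
            raise ValueError("delta must equal freq_late - freq_early")
        fin = np.concatenate([self.freq_early[np.isfinite(self.freq_early)],
                              self.freq_late[np.isfinite(self.freq_late)]])
        if fin.size and (fin.min() < -1e-9 or fin.max() > 1 + 1e-9):
            raise ValueError("frequencies outside [0, 1]")
        if self.counted_allele is None:
            self.counted_allele = _as_str_array(["A"] * len(self.marker))
        else:
            self.counted_allele = _as_str_array(self.counted_allele)

    def __len__(self) -> int:
        return len(self.marker)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "marker": self.marker, "freq_early": self.freq_early,
            "freq_late": self.freq_late, "delta": self.delta,
            "n_early": self.n_early, "n_late": self.n_late,
        })


@dataclass
class LDSummary:
    """Effective number of independent genome segments and how it was found."""

    m_eff: int
    method: str
    per_chrom: pd.DataFrame
    decay: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.m_eff < 1:
            raise ValueError("m_eff must be >= 1")


@dataclass
class GhatResult:
    """Outcome of the Ghat permutation test."""

    ghat: float
    p_value: float
    method: str
    perms: int
    m: int
    null_mean: float
    null_sd: float
    seed: int
    num_eff: int | None = None
    blocksize: int | None = None
    p_empirical: float | None = None
    alpha_level: float = 0.05
    ci_level: float = 0.95
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    @property
    def direction(self) -> str:
        if self.p_value < self.alpha_level:
            if self.ghat > 0:
                return "positive"
            if self.ghat < 0:
                return "negative"
        return "none"

    def to_dict(self) -> dict:
        d = {
            "ghat": self.ghat, "p_value": self.p_value, "method": self.method,
            "perms": self.perms, "m": self.m, "num_eff": self.num_eff,
            "blocksize": self.blocksize, "null_mean": self.null_mean,
            "null_sd": self.null_sd, "p_empirical": self.p_empirical,
            "direction": self.direction, "alpha_level": self.alpha_level,
            "ci_level": self.ci_level, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "seed": self.seed,
        }
        return d
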