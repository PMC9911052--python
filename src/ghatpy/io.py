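"""Readers and writers for genotypes, maps, phenotypes and result vectors.

Supported genotype formats
--------------------------
delimited
    Comma- or tab-separated; first column sample id, optional second column
    ``group``, remaining columns one marker each (header row of marker
    ids); entries 0/1/2, missing coded ``NA`` or empty.
vcf
    VCF 4.x via cyvcf2; only biallelic SNPs are retained and the dosage is
    the ALT-allele count (phased and unphased genotypes are treated
    identically).
plink_raw
    The PLINK ``--recode A`` dosage export: whitespace-separated with
    FID/IID/PAT/MAT/SEX/PHENOTYPE followed by one ``SNP_countedallele``
    column per marker.

All readers enforce integer {0, 1, 2} codes; a {-1, 0, 1} coding is
rejected rather than silently rescaled.
"""

from __future__ import annotations

import logging
from collections import namedtuple
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import EffectEstimates, FreqChange, GenotypeMatrix, MarkerMap

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes", "write_genotypes", "write_vcf",
    "read_map", "write_map", "read_phenotypes",
    "read_effects", "read_change", "write_effects", "write_change",
    "impute_missing", "align_effects_and_change", "AlignedVectors",
]


def _check_codes(values: np.ndarray, path) -> None:
    finite = values[np.isfinite(values)]
    bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))]
    if bad.size:
        raise ValueError(
            f"{path}: genotype codes must be 0/1/2 or NA; found "
            f"{sorted(set(bad.tolist()))[:5]} (a -1/0/1 coding is not "
            "rescaled automatically)")


def _read_delimited_genotypes(path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep=None, engine="python",
                         na_values=["NA", ""], dtype=str)
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse delimited genotypes "
                         f"({exc})") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a sample column plus markers")
    sample_col = df.columns[0]
    group = None
    marker_cols = list(df.columns[1:])
    if marker_cols and marker_cols[0].lower() == "group":
        group = df[marker_cols[0]].to_numpy()
        marker_cols = marker_cols[1:]
    if not marker_cols:
        raise ValueError(f"{path}: no marker columns found")
    try:
        dos = df[marker_cols].astype(float).to_numpy()
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric genotype entry "
                         f"({exc})") from exc
    _check_codes(dos, path)
    return GenotypeMatrix(samples=df[sample_col].astype(str).to_numpy(),
                          markers=marker_cols, dosages=dos, group=group)


def _read_vcf_genotypes(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    markers, alleles, rows = [], [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        gt = np.asarray(v.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        rows.append(gt)
        markers.append(v.ID if v.ID not in (None, ".")
                       else f"{v.CHROM}:{v.POS}")
        alleles.append(v.ALT[0])
    vcf.close()
    if n_skipped:
        logger.info("%s: %d non-biallelic-SNP records skipped", path,
                    n_skipped)
    if not rows:
        raise ValueError(f"{path}: no biallelic SNP records")
    return GenotypeMatrix(samples=samples, markers=markers,
                          dosages=np.array(rows).T, counted_allele=alleles)


def _read_plink_raw(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep=r"\s+", na_values=["NA"])
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if not set(meta).issubset(df.columns):
        raise ValueError(f"{path}: missing PLINK .raw header columns")
    marker_cols = [c for c in df.columns if c not in meta]
    markers, alleles = [], []
    for c in marker_cols:
        name, _, allele = c.rpartition("_")
        if not name:
            name, allele = c, "?"
        markers.append(name)
        alleles.append(allele)
    dos = df[marker_cols].to_numpy(dtype=float)
    _check_codes(dos, path)
    return GenotypeMatrix(samples=df["IID"].astype(str).to_numpy(),
                          markers=markers, dosages=dos,
                          counted_allele=alleles)


def read_genotypes(path, format: str = "delimited") -> GenotypeMatrix:
    """Read a genotype matrix; ``format`` in {delimited, vcf, plink_raw}."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    readers = {"delimited": _read_delimited_genotypes,
               "vcf": _read_vcf_genotypes,
               "plink_raw": _read_plink_raw}
    if format not in readers:
        raise ValueError(f"unknown genotype format {format!r}; expected one "
                         f"of {sorted(readers)}")
    return readers[format](path)


def write_genotypes(g: GenotypeMatrix, path, sep: str = ",") -> None:
    df = pd.DataFrame(g.dosages, columns=g.markers)
    df = df.map(lambda x: "" if not np.isfinite(x)
                else (str(int(x)) if float(x).is_integer()
                      else repr(float(x))))
    if g.group is not None:
        df.insert(0, "group", g.group)
    df.insert(0, "sample", g.samples)
    df.to_csv(path, sep=sep, index=False)


def write_vcf(g: GenotypeMatrix, mmap: MarkerMap, path) -> None:
    """Minimal VCF 4.2 export (GT only, REF=A, ALT=counted allele base)."""
    mmap.check_matches(g)
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        for chrom in pd.unique(mmap.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        # positions are written as integer bp; cM maps are scaled by 1e4
        pos_int = np.maximum(np.round(mmap.pos * (1e4 if mmap.units == "cM"
                                                  else 1)).astype(int), 1)
        for j, mid in enumerate(g.markers):
            alt = g.counted_allele[j]
            if alt not in ("A", "C", "G", "T") or alt == "A":
                alt = "C"
            cells = [gt_code.get(float(x), "./.") if np.isfinite(x) else "./."
                     for x in g.dosages[:, j]]
            fh.write(f"{mmap.chrom[j]}\t{pos_int[j]}\t{mid}\tA\t{alt}\t.\t"
                     f"PASS\t.\tGT\t" + "\t".join(cells) + "\n")


def read_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep=None, engine="python")
    need = {"marker", "chrom", "pos"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: map needs columns {sorted(need)}")
    units = df["units"].iloc[0] if "units" in df.columns else "cM"
    return MarkerMap(marker=df["marker"].astype(str).to_numpy(),
                     chrom=df["chrom"].astype(str).to_numpy(),
                     pos=df["pos"].to_numpy(dtype=float), units=units)


def write_map(mmap: MarkerMap, path, sep: str = ",") -> None:
    df = mmap.to_frame()
    df["units"] = mmap.units
    df.to_csv(path, sep=sep, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    """Long-format phenotype table: sample, trait, value (+ covariates)."""
    df = pd.read_csv(path, sep=None, engine="python")
    need = {"sample", "trait", "value"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: phenotypes need columns {sorted(need)}")
    if df.duplicated(subset=["sample", "trait"]).any():
        raise ValueError(f"{path}: more than one value per (sample, trait)")
    df["sample"] = df["sample"].astype(str)
    return df


def _read_two_col(path, value_col):
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need (marker, {value_col}) columns")
    cols = list(df.columns)
    marker = df[cols[0]].astype(str).to_numpy()
    value = df[value_col if value_col in cols else cols[1]].to_numpy(float)
    allele = (df["counted_allele"].astype(str).to_numpy()
              if "counted_allele" in cols else None)
    return marker, value, allele


def read_effects(path) -> EffectEstimates:
    marker, alpha, allele = _read_two_col(path, "alpha")
    return EffectEstimates(marker=marker, alpha=alpha,
                           counted_allele=allele)


def read_change(path) -> FreqChange:
    marker, delta, allele = _read_two_col(path, "delta")
    nan = np.full(len(marker), np.nan)
    return FreqChange(marker=marker, delta=delta, freq_early=nan,
                      freq_late=nan, n_early=np.zeros(len(marker), int),
                      n_late=np.zeros(len(marker), int),
                      counted_allele=allele)


def write_effects(eff: EffectEstimates, path, sep: str = ",") -> None:
    eff.to_frame().to_csv(path, sep=sep, index=False)


def write_change(change: FreqChange, path, sep: str = ",") -> None:
    change.to_frame().to_csv(path, sep=sep, index=False)


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the marker's mean over non-missing calls.

    Fully missing markers cannot be imputed and raise an error naming them.
    """
    dos = g.dosages.astype(np.float64)
    missing = ~np.isfinite(dos)
    if not missing.any():
        return g
    n_called = (~missing).sum(axis=0)
    dead = np.asarray(g.markers)[n_called == 0]
    if dead.size:
        raise ValueError("markers with no non-missing calls cannot be "
                         f"imputed: {', '.join(map(str, dead[:10]))}")
    col_mean = np.nansum(np.where(missing, 0.0, dos), axis=0) / n_called
    r, c = np.where(missing)
    dos[r, c] = col_mean[c]
    return GenotypeMatrix(samples=g.samples, markers=g.markers,
                          dosages=dos, group=g.group,
                          counted_allele=g.counted_allele)


AlignedVectors = namedtuple("AlignedVectors", ["marker", "alpha", "delta"])


def align_effects_and_change(effects: EffectEstimates,
                             change: FreqChange) -> AlignedVectors:
    """Match effect and change vectors by marker id and orientation.

    Markers present in only one input are dropped (with a logged count);
    where the two inputs count opposite alleles the effect is sign-flipped
    onto the change's orientation, which leaves Ghat unchanged.  The output
    follows the change vector's (map) order.
    """
    eff_pos = {m: i for i, m in enumerate(effects.marker)}
    keep = [(j, eff_pos[m]) for j, m in enumerate(change.marker)
            if m in eff_pos]
    if not keep:
        raise ValueError("no marker ids shared between effects and change")
    n_drop = (len(change.marker) - len(keep)
              + len(effects.marker) - len(keep))
    if n_drop:
        logger.info("%d markers present in only one input dropped", n_drop)
    cj = np.array([k[0] for k in keep])
    ej = np.array([k[1] for k in keep])
    alpha = effects.alpha[ej].astype(float).copy()
    delta = change.delta[cj].astype(float)
    ea = effects.counted_allele[ej]
    ca = change.counted_allele[cj]
    mismatch = ea != ca
    bad = mismatch & ((ea == "") | (ca == ""))
    if bad.any():
        raise ValueError("conflicting counted alleles with no allele "
                         "information to flip on: "
                         f"{change.marker[cj][bad][:5]}")
    if mismatch.any():
        logger.info("%d markers reoriented (effect sign flipped)",
                    int(mismatch.sum()))
        alpha[mismatch] = -alpha[mismatch]
    return AlignedVectors(marker=change.marker[cj], alpha=alpha,
                          delta=delta)
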