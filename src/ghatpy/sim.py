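"""Forward-in-time simulator of divergently selected diploid populations.

The design mirrors a common livestock-breeding validation scheme: a neutral
historical phase (random-mating Wright-Fisher drift with recombination)
builds up linkage disequilibrium from a linkage-equilibrium start; a marker
panel is then ascertained among common loci, and two seed-paired populations
are bred from identical founders for ``n_breeding_generations`` — population
A under random mating, population B under truncation selection on phenotype.

Recombination follows Haldane's model: crossovers per chromosome per meiosis
are Poisson with mean equal to the map length in Morgans, placed uniformly,
with no interference.  Phenotypes are additive: the sum of QTL dosages times
effects plus Gaussian noise scaled so that narrow-sense heritability matches
the configured value in the founder generation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .datatypes import GenotypeMatrix, MarkerMap

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "FounderPop",
    "SimulatedStudy",
    "desk_scale",
    "simulate_founders",
    "evolve",
    "simulate_pair",
    "scan_study",
    "run_table1_group",
]


@dataclass
class SimConfig:
    """Parameters of one simulated breeding study.

    Defaults reproduce the baseline regime of the validation design: a
    genome of 100-cM chromosomes, 100 historical drift generations, 20
    breeding generations, a trait with h2 = 0.5 controlled by 150 QTL, and a
    marker panel of common (MAF >= 0.05) loci.
    """

    n_chrom: int = 30
    chrom_length_cm: float = 100.0
    n_hist_generations: int = 100
    hist_n: int = 100          # historical (effective) population size
    n_breeding_generations: int = 20
    n: int = 400               # individuals per breeding generation
    h2: float = 0.5
    n_qtl: int = 150
    n_markers: int = 10020
    selection: str = "none"    # {"none", "truncation"} for single-pop runs
    selected_fraction: float = 0.2
    maf_min: float = 0.05      # marker ascertainment threshold
    pool_factor: float = 2.5   # simulated loci per ascertained locus
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.h2 <= 1:
            raise ValueError("h2 must be in (0, 1]")
        if not 0 < self.selected_fraction <= 1:
            raise ValueError("selected_fraction must be in (0, 1]")
        if self.selection not in ("none", "truncation"):
            raise ValueError(f"unknown selection mode {self.selection!r}")
        if self.n_qtl < 1 or self.n_markers < 1:
            raise ValueError("n_qtl and n_markers must be positive")


def desk_scale(**overrides) -> SimConfig:
    """Desk-scale preset: 5 chromosomes, 2,000 markers, n = 400.

    A reduced genome used throughout the test suite in place of the full
    30-chromosome design; all fields can be overridden.
    """
    base = dict(n_chrom=5, n_markers=2000, n=400, h2=0.5, n_qtl=150)
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class FounderPop:
    """Historical population at the end of the drift phase."""

    haplotypes: np.ndarray      # (2 * hist_n, n_loci) uint8
    chrom: np.ndarray           # per-locus chromosome index
    pos_cm: np.ndarray          # per-locus position within chromosome, cM
    p_init: np.ndarray          # initialization frequencies of the draw

    @property
    def freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


@dataclass
class SimulatedStudy:
    """One population's full breeding history plus the simulation truth."""

    config: SimConfig
    tag: str                               # "A_unselected" or "B_selected"
    marker_map: MarkerMap
    qtl_chrom: np.ndarray
    qtl_pos_cm: np.ndarray
    qtl_effects: np.ndarray                # scaled true effects
    dosages: list = field(default_factory=list)       # per-gen (n, m) int8
    phenotypes: list = field(default_factory=list)    # per-gen (n,) float
    breeding_values: list = field(default_factory=list)
    qtl_freqs: list = field(default_factory=list)     # per-gen (n_qtl,)

    @property
    def n_generations(self) -> int:
        return len(self.dosages)

    def genotype_matrix(self, generations=None) -> GenotypeMatrix:
        """Stack the requested generations into one labelled matrix."""
        if generations is None:
            generations = range(self.n_generations)
        generations = list(generations)
        dos = np.concatenate([self.dosages[g] for g in generations])
        group = np.concatenate([
            np.full(len(self.dosages[g]), g) for g in generations])
        samples = [f"{self.tag}_g{g}_i{i}"
                   for g in generations
                   for i in range(len(self.dosages[g]))]
        return GenotypeMatrix(samples=samples, markers=self.marker_map.marker,
                              dosages=dos.astype(np.float32), group=group)

    def phenotype_vector(self, generations=None) -> np.ndarray:
        if generations is None:
            generations = range(self.n_generations)
        return np.concatenate([self.phenotypes[g] for g in generations])


# ---------------------------------------------------------------------------
# Meiosis kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _meiosis_kernel(parent_haps, parents, chrom_starts, pos_morgan,
                    chrom_len_morgan, seed, out):   # pragma: no cover - jit
    """Fill ``out`` (2*n_children x L) with recombinant gametes.

    ``parents`` is (n_children, 2); gamete ``2*i + k`` comes from parent
    ``parents[i, k]``.  Crossover pattern per chromosome: Poisson(length in
    Morgans) breakpoints, uniform positions, alternating parental phase with
    a fair random starting phase (Haldane, no interference).
    """
    np.random.seed(seed)
    n_children = parents.shape[0]
    n_chrom = chrom_starts.shape[0] - 1
    for i in range(n_children):
        for k in range(2):
            p = parents[i, k]
            row = 2 * i + k
            for c in range(n_chrom):
                s = chrom_starts[c]
                e = chrom_starts[c + 1]
                phase = np.random.randint(0, 2)
                n_x = np.random.poisson(chrom_len_morgan)
                if n_x == 0:
                    for j in range(s, e):
                        out[row, j] = parent_haps[2 * p + phase, j]
                else:
                    xpos = np.sort(np.random.uniform(0.0, chrom_len_morgan,
                                                     n_x))
                    j = s
                    for b in range(n_x):
                        x = xpos[b]
                        while j < e and pos_morgan[j] < x:
                            out[row, j] = parent_haps[2 * p + phase, j]
                            j += 1
                        phase = 1 - phase
                    while j < e:
                        out[row, j] = parent_haps[2 * p + phase, j]
                        j += 1


def _draw_parent_pairs(rng, n_children, pool):
    """Two distinct parents per child, uniform over ``pool`` indices."""
    k = len(pool)
    if k < 2:
        raise ValueError("fewer than 2 candidate parents remain")
    a = rng.integers(0, k, size=n_children)
    b = rng.integers(0, k - 1, size=n_children)
    b = b + (b >= a)
    return np.column_stack([pool[a], pool[b]]).astype(np.int64)


def _reproduce(haps, parents, chrom_starts, pos_morgan, chrom_len_m, rng):
    out = np.empty((2 * parents.shape[0], haps.shape[1]), dtype=np.uint8)
    seed = int(rng.integers(0, 2**31 - 1))
    _meiosis_kernel(haps, parents, chrom_starts, pos_morgan,
                    float(chrom_len_m), seed, out)
    return out


# ---------------------------------------------------------------------------
# Historical phase and ascertainment
# ---------------------------------------------------------------------------

def _init_genome(cfg: SimConfig, rng) -> tuple[np.ndarray, np.ndarray]:
    """Random locus positions: chromosome index and within-chrom cM."""
    n_loci = int(np.ceil(cfg.pool_factor * (cfg.n_markers + cfg.n_qtl)))
    chrom = rng.integers(0, cfg.n_chrom, size=n_loci)
    pos = rng.uniform(0.0, cfg.chrom_length_cm, size=n_loci)
    order = np.lexsort((pos, chrom))
    return chrom[order], pos[order]


def simulate_founders(cfg: SimConfig, rng=None) -> FounderPop:
    """Drift-only history: random mating for ``n_hist_generations``.

    Haplotypes start in linkage equilibrium with per-locus frequencies drawn
    uniform on (0, 1); drift and recombination then shape LD.  With
    ``n_hist_generations=0`` the returned population is the initialization
    draw itself.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chrom, pos = _init_genome(cfg, rng)
    p_init = rng.uniform(0.0, 1.0, size=len(pos))
    haps = (rng.random((2 * cfg.hist_n, len(pos))) < p_init).astype(np.uint8)
    chrom_starts = np.searchsorted(chrom, np.arange(cfg.n_chrom + 1))
    pos_morgan = pos / 100.0
    chrom_len_m = cfg.chrom_length_cm / 100.0
    pool = np.arange(cfg.hist_n)
    for _ in range(cfg.n_hist_generations):
        parents = _draw_parent_pairs(rng, cfg.hist_n, pool)
        haps = _reproduce(haps, parents, chrom_starts, pos_morgan,
                          chrom_len_m, rng)
    return FounderPop(haplotypes=haps, chrom=chrom, pos_cm=pos,
                      p_init=p_init)


def _ascertain(cfg: SimConfig, founders: FounderPop, rng):
    """Pick marker and QTL loci from the post-drift standing variation.

    Markers: uniform draw among loci with MAF >= ``maf_min`` (array-like
    ascertainment of common variants).  QTL: uniform among the remaining
    polymorphic loci.  Returns (marker_idx, qtl_idx) in genome order.
    """
    p = founders.freqs
    maf = np.minimum(p, 1 - p)
    common = np.flatnonzero(maf >= cfg.maf_min)
    if len(common) < cfg.n_markers:
        raise RuntimeError(
            f"only {len(common)} loci with MAF >= {cfg.maf_min}; "
            f"need {cfg.n_markers}")
    marker_idx = np.sort(rng.choice(common, size=cfg.n_markers,
                                    replace=False))
    taken = np.zeros(len(p), dtype=bool)
    taken[marker_idx] = True
    poly = np.flatnonzero((maf > 0) & ~taken)
    if len(poly) < cfg.n_qtl:
        raise RuntimeError(
            f"only {len(poly)} polymorphic non-marker loci; "
            f"need {cfg.n_qtl} QTL")
    qtl_idx = np.sort(rng.choice(poly, size=cfg.n_qtl, replace=False))
    return marker_idx, qtl_idx


# ---------------------------------------------------------------------------
# Breeding phase
# ---------------------------------------------------------------------------

def _dosages(haps: np.ndarray, cols: np.ndarray) -> np.ndarray:
    sub = haps[:, cols]
    return (sub[0::2, :] + sub[1::2, :]).astype(np.int8)


def evolve(cfg: SimConfig, gen0_haps, founders: FounderPop, marker_idx,
           qtl_idx, qtl_effects, sigma_e, selection: str, rng,
           tag: str, gen0_phenotypes=None) -> SimulatedStudy:
    """Breed forward for ``n_breeding_generations`` from given founders.

    ``selection='none'``: parents uniform among the generation.
    ``selection='truncation'``: parents uniform among the top
    ``selected_fraction`` by phenotype.  Per-generation marker dosages,
    phenotypes and true breeding values are recorded for generations
    0 .. n_breeding_generations inclusive.
    """
    chrom_starts = np.searchsorted(founders.chrom,
                                   np.arange(cfg.n_chrom + 1))
    pos_morgan = founders.pos_cm / 100.0
    chrom_len_m = cfg.chrom_length_cm / 100.0

    mids = [f"M{c}_{i}" for i, c in enumerate(founders.chrom[marker_idx])]
    marker_map = MarkerMap(marker=mids,
                           chrom=founders.chrom[marker_idx].astype(str),
                           pos=founders.pos_cm[marker_idx], units="cM")
    study = SimulatedStudy(config=cfg, tag=tag, marker_map=marker_map,
                           qtl_chrom=founders.chrom[qtl_idx],
                           qtl_pos_cm=founders.pos_cm[qtl_idx],
                           qtl_effects=qtl_effects)

    haps = gen0_haps
    n = cfg.n
    n_sel = max(int(round(cfg.selected_fraction * n)), 2)
    for g in range(cfg.n_breeding_generations + 1):
        qtl_dos = _dosages(haps, qtl_idx).astype(np.float32)
        bv = qtl_dos @ qtl_effects.astype(np.float32)
        if g == 0 and gen0_phenotypes is not None:
            y = gen0_phenotypes
        else:
            y = bv + sigma_e * rng.standard_normal(n)
        study.dosages.append(_dosages(haps, marker_idx))
        study.phenotypes.append(np.asarray(y, dtype=float))
        study.breeding_values.append(bv.astype(float))
        study.qtl_freqs.append(qtl_dos.mean(axis=0) / 2.0)
        if g == cfg.n_breeding_generations:
            break
        if selection == "truncation":
            pool = np.argsort(y)[-n_sel:]
        else:
            pool = np.arange(n)
        parents = _draw_parent_pairs(rng, n, pool)
        haps = _reproduce(haps, parents, chrom_starts, pos_morgan,
                          chrom_len_m, rng)
    return study


def _setup_pair(cfg: SimConfig, max_retries: int = 5):
    """Shared history for a seed-paired A/B study: founders, panel, gen 0."""
    for attempt in range(max_retries):
        seed = cfg.seed if attempt == 0 else cfg.seed + 990_000_001 + attempt
        rng = np.random.default_rng([seed, 0])
        try:
            founders = simulate_founders(cfg, rng)
            marker_idx, qtl_idx = _ascertain(cfg, founders, rng)
            break
        except RuntimeError as exc:
            warnings.warn(f"founder draw {attempt} rejected ({exc}); "
                          "resampling")
    else:
        raise RuntimeError("could not ascertain a marker panel after "
                           f"{max_retries} founder draws")

    # restrict the breeding phase to the ascertained panel (markers + QTL);
    # loci outside the panel cannot influence anything downstream
    panel = np.sort(np.concatenate([marker_idx, qtl_idx]))
    founders = FounderPop(haplotypes=np.ascontiguousarray(
                              founders.haplotypes[:, panel]),
                          chrom=founders.chrom[panel],
                          pos_cm=founders.pos_cm[panel],
                          p_init=founders.p_init[panel])
    marker_idx = np.searchsorted(panel, marker_idx)
    qtl_idx = np.searchsorted(panel, qtl_idx)

    chrom_starts = np.searchsorted(founders.chrom,
                                   np.arange(cfg.n_chrom + 1))
    parents = _draw_parent_pairs(rng, cfg.n, np.arange(cfg.hist_n))
    gen0 = _reproduce(founders.haplotypes, parents, chrom_starts,
                      founders.pos_cm / 100.0,
                      cfg.chrom_length_cm / 100.0, rng)

    # scale QTL effects so that founder-generation additive variance is h2
    # and residual variance 1 - h2 (phenotypic variance ~ 1)
    raw = rng.standard_normal(cfg.n_qtl)
    qtl_dos = _dosages(gen0, qtl_idx).astype(np.float64)
    var_bv = np.var(qtl_dos @ raw)
    if var_bv <= 0:
        raise RuntimeError("founder QTL panel carries no additive variance")
    effects = raw * np.sqrt(cfg.h2 / var_bv)
    sigma_e = float(np.sqrt(1.0 - cfg.h2))
    gen0_pheno = (qtl_dos @ effects
                  + sigma_e * rng.standard_normal(cfg.n))
    return founders, marker_idx, qtl_idx, effects, sigma_e, gen0, gen0_pheno


def simulate_pair(cfg: SimConfig) -> tuple[SimulatedStudy, SimulatedStudy]:
    """Seed-paired unselected (A) / truncation-selected (B) populations.

    Both populations share founders, marker/QTL panel, generation-0
    haplotypes and generation-0 phenotypes; their histories diverge only
    through the selection step and the per-population RNG streams that feed
    it.
    """
    (founders, marker_idx, qtl_idx, effects, sigma_e,
     gen0, gen0_pheno) = _setup_pair(cfg)
    pop_a = evolve(cfg, gen0, founders, marker_idx, qtl_idx, effects,
                   sigma_e, "none", np.random.default_rng([cfg.seed, 1]),
                   "A_unselected", gen0_phenotypes=gen0_pheno)
    pop_b = evolve(cfg, gen0, founders, marker_idx, qtl_idx, effects,
                   sigma_e, "truncation",
                   np.random.default_rng([cfg.seed, 2]),
                   "B_selected", gen0_phenotypes=gen0_pheno)
    return pop_a, pop_b


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Single population under ``cfg.selection``."""
    (founders, marker_idx, qtl_idx, effects, sigma_e,
     gen0, gen0_pheno) = _setup_pair(cfg)
    tag = "B_selected" if cfg.selection == "truncation" else "A_unselected"
    stream = 2 if cfg.selection == "truncation" else 1
    return evolve(cfg, gen0, founders, marker_idx, qtl_idx, effects,
                  sigma_e, cfg.selection,
                  np.random.default_rng([cfg.seed, stream]), tag,
                  gen0_phenotypes=gen0_pheno)


# ---------------------------------------------------------------------------
# Study-level Ghat scan and the parameter-sweep harness
# ---------------------------------------------------------------------------

def scan_study(study: SimulatedStudy, estimator: str = "rrblup",
               early_gen: int | None = None, late_gen: int | None = None,
               train_per_gen: int | None = None, perms: int = 1000,
               var_fraction: float = 0.995, seed: int = 0,
               estimator_kwargs: dict | None = None):
    """Run the full Ghat pipeline on one simulated population.

    Effects are estimated from all recorded generations (the whole
    population unless ``train_per_gen`` requests a per-generation random
    subsample), the frequency change is taken between ``early_gen`` and
    ``late_gen`` (default: 5 generations before the last, and the last),
    the effective marker number comes from the simpleM eigenvalue criterion
    on the contrast samples, and the scale-method permutation test is
    applied.
    """
    from .effects import fit_bayesc, fit_rrblup
    from .freq import frequency_change
    from .ghat import ghat_test
    from .ld import simple_m

    rng = np.random.default_rng(seed)
    n_gen = study.n_generations
    if late_gen is None:
        late_gen = n_gen - 1
    if early_gen is None:
        early_gen = late_gen - 5

    # training design: all generations, optional per-generation subsample
    dos_parts, y_parts = [], []
    for g in range(n_gen):
        dos = study.dosages[g]
        y = study.phenotypes[g]
        if train_per_gen is not None and train_per_gen < len(y):
            pick = rng.choice(len(y), size=train_per_gen, replace=False)
            dos, y = dos[pick], y[pick]
        dos_parts.append(dos)
        y_parts.append(y)
    z_train = np.concatenate(dos_parts).astype(np.float32)
    y_train = np.concatenate(y_parts)

    kwargs = dict(estimator_kwargs or {})
    if estimator == "rrblup":
        kwargs.setdefault("subsample_seed", int(rng.integers(0, 2**31 - 1)))
        eff = fit_rrblup(z_train, y_train, marker_ids=study.marker_map.marker,
                         **kwargs)
    elif estimator == "bayesc":
        kwargs.setdefault("seed", int(rng.integers(0, 2**31 - 1)))
        eff = fit_bayesc(z_train, y_train,
                         marker_ids=study.marker_map.marker, **kwargs)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    g_all = study.genotype_matrix(generations=[early_gen, late_gen])
    change = frequency_change(g_all, early=early_gen, late=late_gen)
    ld = simple_m(g_all, study.marker_map, var_fraction=var_fraction)
    res = ghat_test(eff.alpha, change.delta, method="scale", perms=perms,
                    num_eff=ld.m_eff, seed=int(rng.integers(0, 2**31 - 1)))
    return res


def run_table1_group(group: str, levels, reps: int,
                     estimator: str = "rrblup", alpha: float = 0.01,
                     seed: int = 0, base_config: SimConfig | None = None,
                     scan_kwargs: dict | None = None,
                     populations=("A_unselected", "B_selected")):
    """Parameter sweep over paired selected/unselected populations.

    ``group`` names the varied parameter: ``sample_size``, ``heritability``,
    ``n_qtl`` or ``marker_density``; ``levels`` are its values.  For every
    level and replicate a seed-paired A/B study is simulated, the Ghat scan
    runs on both populations, and the per-replicate p-values are collected.
    Returns a pandas DataFrame with one row per (level, replicate,
    population).
    """
    import pandas as pd

    field_by_group = {"sample_size": "n", "heritability": "h2",
                      "n_qtl": "n_qtl", "marker_density": "n_markers"}
    if group not in field_by_group:
        raise ValueError(f"unknown sweep group {group!r}")
    fld = field_by_group[group]
    if base_config is None:
        base_config = desk_scale()
    scan_kwargs = dict(scan_kwargs or {})

    ss = np.random.SeedSequence(seed)
    rows = []
    n_failed = 0
    for level in levels:
        for rep in range(reps):
            child = ss.spawn(1)[0]
            rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
            cfg_kwargs = {f.name: getattr(base_config, f.name)
                          for f in base_config.__dataclass_fields__.values()}
            cfg_kwargs[fld] = level
            cfg_kwargs["seed"] = rep_seed
            cfg = SimConfig(**cfg_kwargs)
            try:
                pop_a, pop_b = simulate_pair(cfg)
                for pop, tag in ((pop_a, "A_unselected"),
                                 (pop_b, "B_selected")):
                    if tag not in populations:
                        continue
                    res = scan_study(pop, estimator=estimator,
                                     seed=rep_seed, **scan_kwargs)
                    rows.append({"group": group, "level": level, "rep": rep,
                                 "population": tag, "ghat": res.ghat,
                                 "p_value": res.p_value,
                                 "num_eff": res.num_eff,
                                 "significant": res.p_value < alpha})
            except RuntimeError as exc:
                n_failed += 1
                logger.warning("replicate dropped (level=%s rep=%d): %s",
                               level, rep, exc)
    if n_failed:
        logger.warning("%d replicates dropped in sweep %s", n_failed, group)
    out = pd.DataFrame(rows)
    out.attrs["n_failed"] = n_failed
    out.attrs["alpha"] = alpha
    return out
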