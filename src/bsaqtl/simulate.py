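"""Synthetic data generator for F2 bulked-segregant sequencing experiments.

Emulates the study design the downstream scan assumes: a biparental
Cabriolet x Darmor cross selfed to a large F2 population (720 lines by
default), genotyped in silico at tens of thousands of informative variant
positions on the 19 *Brassica napus* chromosomes; a treatment-dependent
flowering-time phenotype (six-week vernalization, VERN, versus none, NVERN)
right-censored at 170 days; extreme ~5% phenotypic-tail DNA bulks; and
per-sample allele read counts at ~30x mean depth with sequencing error.

Model summary
-------------
* Meiosis: crossovers per chromosome are Poisson with mean equal to the
  chromosome's genetic length in Morgans, placed uniformly on the cM scale
  (Haldane model, no interference).  A gamete starts from a random parental
  phase and switches at each crossover; an F2 line is the sum of two
  independent gametes, giving Cabriolet-allele dosages in {0, 1, 2} that
  segregate 1:2:1.
* Phenotype: days to flowering = treatment baseline + per-locus additive and
  dominance effects + Gaussian noise, right-censored at ``censor_days``
  (plants not flowering by then receive the censor value, the DNF score).
* Reads: per-variant depth is Poisson(mean_depth); the Cabriolet read count
  is Binomial(depth, f(1-e) + (1-f)e) where f is the bulk's Cabriolet allele
  frequency and e a symmetric per-read allele-flip error rate.

Every operation is deterministic given its integer seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "BNAPUS_CHROMOSOMES",
    "VERN",
    "NVERN",
    "QTLLocus",
    "QTLModel",
    "F2GenotypeMatrix",
    "BulkDefinition",
    "default_qtl_model",
    "snap_model_to_map",
    "build_variant_map",
    "simulate_gametes",
    "simulate_f2_genotypes",
    "simulate_phenotypes",
    "select_bulks",
    "simulate_allele_counts",
]

#: The 19 chromosomes of allotetraploid B. napus (A and C subgenomes).
BNAPUS_CHROMOSOMES = tuple(f"A{i:02d}" for i in range(1, 11)) + tuple(
    f"C{i:02d}" for i in range(1, 10)
)

VERN = "VERN"
NVERN = "NVERN"
_TREATMENTS = (VERN, NVERN)

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# variant map
# ---------------------------------------------------------------------------

def build_variant_map(
    n_chromosomes: int = 19,
    variants_per_chromosome: int = 2000,
    chromosome_length_bp: int = 30_000_000,
    map_length_cM: float = 100.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw an informative-variant catalogue for a biparental cross.

    Physical positions are uniform on each chromosome then sorted; genetic
    positions are proportional to physical position (uniform recombination),
    so ``position_cM = position_bp * map_length_cM / chromosome_length_bp``.
    Parental alleles are distinct random bases at every position.

    Returns a DataFrame with columns ``chromosome``, ``position_bp`` (1-based),
    ``position_cM``, ``cab_allele``, ``dar_allele``, sorted by chromosome then
    position.
    """
    if n_chromosomes <= 0 or variants_per_chromosome <= 0:
        raise ConfigError("chromosome and variant counts must be positive")
    if chromosome_length_bp <= 0 or map_length_cM <= 0:
        raise ConfigError("chromosome_length_bp and map_length_cM must be positive")
    if variants_per_chromosome > chromosome_length_bp:
        raise ConfigError("more variants requested than base pairs available")

    if n_chromosomes == len(BNAPUS_CHROMOSOMES):
        chrom_names = BNAPUS_CHROMOSOMES
    else:
        chrom_names = tuple(f"chr{i:02d}" for i in range(1, n_chromosomes + 1))

    rng = np.random.default_rng(seed)
    frames = []
    for chrom in chrom_names:
        pos = np.unique(rng.integers(1, chromosome_length_bp + 1, size=variants_per_chromosome))
        while pos.size < variants_per_chromosome:  # collisions are rare at realistic densities
            extra = rng.integers(1, chromosome_length_bp + 1,
                                 size=variants_per_chromosome - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        cab = rng.integers(0, 4, size=pos.size)
        dar = (cab + rng.integers(1, 4, size=pos.size)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chromosome": chrom,
                    "position_bp": pos,
                    "position_cM": pos * (map_length_cM / chromosome_length_bp),
                    "cab_allele": _BASES[cab],
                    "dar_allele": _BASES[dar],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _validate_variant_map(variant_map: pd.DataFrame) -> None:
    required = {"chromosome", "position_bp", "position_cM", "cab_allele", "dar_allele"}
    missing = required - set(variant_map.columns)
    if missing:
        raise DataError(f"variant map lacks columns: {sorted(missing)}")
    if len(variant_map) == 0:
        raise DataError("variant map is empty")


# ---------------------------------------------------------------------------
# meiosis / F2 genotypes
# ---------------------------------------------------------------------------

@dataclass
class F2GenotypeMatrix:
    """Cabriolet-allele dosages (0/1/2) for F2 lines at mapped variants.

    ``dosage`` is an int8 array of shape (n_lines, n_variants) whose columns
    align with the rows of ``variant_map``.
    """

    dosage: np.ndarray
    line_ids: list[str]
    variant_map: pd.DataFrame

    @property
    def n_lines(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def line_index(self, line_ids) -> np.ndarray:
        lookup = {lid: i for i, lid in enumerate(self.line_ids)}
        try:
            return np.array([lookup[lid] for lid in line_ids], dtype=np.intp)
        except KeyError as exc:
            raise DataError(f"unknown line id: {exc.args[0]!r}") from None


def simulate_gametes(variant_map: pd.DataFrame, n_gametes: int, seed: int = 0) -> np.ndarray:
    """Simulate gametes under the Haldane (no-interference) crossover model.

    Returns a uint8 array of shape (n_gametes, n_variants): 1 where the
    gamete carries the Cabriolet allele.  Crossover counts per chromosome are
    Poisson with mean (cM span)/100; positions are uniform on the cM scale.
    """
    _validate_variant_map(variant_map)
    if n_gametes < 1:
        raise ConfigError("n_gametes must be >= 1")
    rng = np.random.default_rng(seed)
    out = np.empty((n_gametes, len(variant_map)), dtype=np.uint8)
    col = 0
    for _, block in variant_map.groupby("chromosome", sort=False):
        cM = block["position_cM"].to_numpy(dtype=float)
        span = cM[-1] - cM[0]
        start = rng.integers(0, 2, size=n_gametes).astype(np.uint8)
        n_x = rng.poisson(span / 100.0, size=n_gametes)
        sl = slice(col, col + cM.size)
        for g in range(n_gametes):
            if n_x[g] == 0:
                out[g, sl] = start[g]
            else:
                cuts = np.sort(rng.uniform(cM[0], cM[-1], size=n_x[g]))
                flips = np.searchsorted(cuts, cM, side="left")
                out[g, sl] = (start[g] + flips) % 2
        col += cM.size
    return out


def simulate_f2_genotypes(variant_map: pd.DataFrame, n_lines: int, seed: int = 0) -> F2GenotypeMatrix:
    """Simulate an F2 population: each line is the sum of two independent gametes."""
    _validate_variant_map(variant_map)
    if n_lines < 1:
        raise ConfigError("n_lines must be >= 1")
    gametes = simulate_gametes(variant_map, 2 * n_lines, seed=seed)
    dosage = (gametes[::2].astype(np.int8) + gametes[1::2].astype(np.int8))
    line_ids = [f"L{i + 1:04d}" for i in range(n_lines)]
    return F2GenotypeMatrix(dosage=dosage, line_ids=line_ids, variant_map=variant_map)


# ---------------------------------------------------------------------------
# phenotype model
# ---------------------------------------------------------------------------

@dataclass
class QTLLocus:
    """One causal locus with treatment-specific effects in days.

    ``additive`` is half the difference between the two homozygote means
    (positive values delay flowering in Darmor homozygotes); ``dominance``
    is the heterozygote deviation from the homozygote midpoint.
    """

    chromosome: str
    position_bp: int
    additive: dict[str, float]
    dominance: dict[str, float] = field(default_factory=dict)


@dataclass
class QTLModel:
    """Treatment-dependent flowering-time model with right censoring."""

    loci: list[QTLLocus]
    baseline: dict[str, float]
    noise_sd: float = 8.0
    censor_days: int = 170

    def __post_init__(self) -> None:
        if self.censor_days <= 0:
            raise ConfigError("censor_days must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


def default_qtl_model(noise_sd: float = 8.0, censor_days: int = 170,
                      chromosome: str = "A02") -> QTLModel:
    """Two-locus model calibrated to the parental flowering means.

    Homozygous-Cabriolet lines average 42.92 d under VERN and 78 d under
    NVERN; homozygous-Darmor lines average 71.25 d under VERN and exceed the
    170-day censor under NVERN (DNF).  The major locus sits at the FLC-like
    position on A02 (dominant toward lateness without vernalization), the
    minor at the FT-like position 6.2 Mbp downstream.
    """
    return QTLModel(
        loci=[
            QTLLocus(chromosome, 136_553,
                     additive={VERN: 11.165, NVERN: 28.0},
                     dominance={VERN: 0.0, NVERN: 15.0}),
            QTLLocus(chromosome, 6_375_504,
                     additive={VERN: 3.0, NVERN: 22.0},
                     dominance={VERN: 0.0, NVERN: 0.0}),
        ],
        baseline={VERN: 57.085, NVERN: 128.0},
        noise_sd=noise_sd,
        censor_days=censor_days,
    )


def snap_model_to_map(model: QTLModel, variant_map: pd.DataFrame) -> QTLModel:
    """Move each causal locus to the nearest mapped variant on its chromosome."""
    _validate_variant_map(variant_map)
    loci = []
    for locus in model.loci:
        block = variant_map.loc[variant_map["chromosome"] == locus.chromosome, "position_bp"]
        if block.empty:
            raise DataError(f"no variants on chromosome {locus.chromosome!r}")
        pos = block.to_numpy()
        loci.append(replace(locus, position_bp=int(pos[np.argmin(np.abs(pos - locus.position_bp))])))
    return replace(model, loci=loci)


def simulate_phenotypes(
    genotypes: F2GenotypeMatrix,
    qtl_model: QTLModel,
    treatment: str,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate flowering times (days) under one treatment.

    Returns a DataFrame with columns ``line_id``, ``treatment``,
    ``flowering_days`` and ``censored``.  Raw values exceeding
    ``censor_days`` are stored as the censor value with ``censored`` True
    (the DNF convention).
    """
    if treatment not in _TREATMENTS:
        raise ConfigError(f"treatment must be one of {_TREATMENTS}, got {treatment!r}")
    vm = genotypes.variant_map
    days = np.full(genotypes.n_lines, qtl_model.baseline[treatment], dtype=float)
    for locus in qtl_model.loci:
        hit = np.flatnonzero(
            (vm["chromosome"].to_numpy() == locus.chromosome)
            & (vm["position_bp"].to_numpy() == locus.position_bp)
        )
        if hit.size == 0:
            raise DataError(
                f"causal locus {locus.chromosome}:{locus.position_bp} is not in the variant map"
            )
        dosage = genotypes.dosage[:, hit[0]].astype(float)
        a = locus.additive.get(treatment, 0.0)
        d = locus.dominance.get(treatment, 0.0)
        # dosage counts Cabriolet alleles; Darmor homozygote (dosage 0) is +a
        days += a * (1.0 - dosage) + d * (dosage == 1)
    if qtl_model.noise_sd > 0:
        days += np.random.default_rng(seed).normal(0.0, qtl_model.noise_sd, size=days.size)
    censored = days >= qtl_model.censor_days
    days = np.where(censored, float(qtl_model.censor_days), days)
    return pd.DataFrame(
        {
            "line_id": genotypes.line_ids,
            "treatment": treatment,
            "flowering_days": days,
            "censored": censored,
        }
    )


# ---------------------------------------------------------------------------
# bulk selection
# ---------------------------------------------------------------------------

@dataclass
class BulkDefinition:
    """Membership of the early- and late-flowering DNA bulks."""

    early_lines: list[str]
    late_lines: list[str]
    fraction: float = 0.05

    def __post_init__(self) -> None:
        if set(self.early_lines) & set(self.late_lines):
            raise DataError("early and late bulks must be disjoint")


def _take_tail(df: pd.DataFrame, size: int, ascending: bool, rng: np.random.Generator) -> list[str]:
    """Lines in one phenotypic tail; ties at the boundary broken by seeded sampling."""
    if size <= 0:
        return []
    days = df["flowering_days"].to_numpy()
    order = np.argsort(days, kind="stable")
    if not ascending:
        order = order[::-1]
    if size >= len(df):
        return df["line_id"].tolist()
    boundary = days[order[size - 1]]
    if ascending:
        definite = order[days[order] < boundary]
        tied = order[days[order] == boundary]
    else:
        definite = order[days[order] > boundary]
        tied = order[days[order] == boundary]
    need = size - definite.size
    sampled = rng.choice(tied, size=need, replace=False)
    idx = np.concatenate([definite, sampled])
    return df["line_id"].to_numpy()[idx].tolist()


def select_bulks(phenotypes: pd.DataFrame, fraction: float = 0.05, seed: int = 0) -> BulkDefinition:
    """Select the extreme phenotypic tails as early/late bulks.

    Bulk size is round(fraction * n).  Censored (DNF) lines are eligible only
    for the late bulk.  When lines tied at a bulk boundary exceed the
    remaining capacity — for instance more DNF lines than late-bulk slots —
    members are drawn among the tied lines by seeded uniform sampling.  The
    two bulks are always disjoint.
    """
    if len(phenotypes) == 0:
        raise DataError("phenotype table is empty")
    if not 0 < fraction < 0.5:
        raise ConfigError("fraction must lie in (0, 0.5)")
    size = round(fraction * len(phenotypes))
    rng = np.random.default_rng(seed)

    late = _take_tail(phenotypes, min(size, len(phenotypes)), ascending=False, rng=rng)
    eligible_early = phenotypes[
        (~phenotypes["censored"]) & (~phenotypes["line_id"].isin(late))
    ]
    if len(eligible_early) == 0:
        early: list[str] = []
    else:
        early = _take_tail(eligible_early, min(size, len(eligible_early)), ascending=True, rng=rng)
    return BulkDefinition(early_lines=early, late_lines=late, fraction=fraction)


# ---------------------------------------------------------------------------
# read-count model
# ---------------------------------------------------------------------------

def simulate_allele_counts(
    source,
    lines=None,
    variant_map: pd.DataFrame | None = None,
    mean_depth: float = 30.0,
    error_rate: float = 0.001,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate pooled short-read allele counts at every mapped variant.

    ``source`` is either an :class:`F2GenotypeMatrix` (a bulk or the whole
    population; restrict with ``lines``) or one of the strings
    ``"cabriolet"`` / ``"darmor"`` for a parental sample (which requires
    ``variant_map``).  Per variant, depth ~ Poisson(mean_depth) and the
    Cabriolet read count ~ Binomial(depth, f(1-e) + (1-f)e) with f the pool's
    Cabriolet allele frequency and e the symmetric allele-flip error rate.

    Returns a DataFrame aligned row-for-row with the variant map, columns
    ``chromosome``, ``position_bp``, ``cab_allele``, ``dar_allele``,
    ``cab_count``, ``dar_count``.
    """
    if mean_depth <= 0:
        raise ConfigError("mean_depth must be positive")
    if not 0 <= error_rate < 0.5:
        raise ConfigError("error_rate must lie in [0, 0.5)")

    if isinstance(source, str):
        if variant_map is None:
            raise ConfigError("parental simulation requires a variant_map")
        _validate_variant_map(variant_map)
        vm = variant_map
        if source.lower() == "cabriolet":
            f = np.ones(len(vm))
        elif source.lower() == "darmor":
            f = np.zeros(len(vm))
        else:
            raise ConfigError(f"unknown parent {source!r}")
    elif isinstance(source, F2GenotypeMatrix):
        vm = source.variant_map
        dosage = source.dosage
        if lines is not None:
            dosage = dosage[source.line_index(lines)]
        f = dosage.mean(axis=0) / 2.0
    else:
        raise ConfigError("source must be an F2GenotypeMatrix or a parent name")

    rng = np.random.default_rng(seed)
    depth = rng.poisson(mean_depth, size=len(vm))
    p = f * (1.0 - error_rate) + (1.0 - f) * error_rate
    cab = rng.binomial(depth, p)
    return pd.DataFrame(
        {
            "chromosome": vm["chromosome"].to_numpy(),
            "position_bp": vm["position_bp"].to_numpy(),
            "cab_allele": vm["cab_allele"].to_numpy(),
            "dar_allele": vm["dar_allele"].to_numpy(),
            "cab_count": cab,
            "dar_count": depth - cab,
        }
    )
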