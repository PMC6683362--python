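"""Synthetic cohorts with the statistical structure of a hybridogenetic system.

The generator emulates a RAD-style SNP matrix for a mixed population of
*P. lessonae* (LL), *P. ridibundus* (RR, hemiclonal) and hybrid
*P.* kl. *esculentus* frogs (LR, and optionally triploid LLR/LRR), plus
a microsatellite peak table, so every downstream stage can be exercised
against a known truth table.

Diagnostic loci carry a fixed L allele on the lessonae genome and a
fixed R allele on the ridibundus genome.  Allele read depths at those
loci are multinomial over {L, R} with probabilities proportional to
genome dosage (LR 1:1, LLR 2:1, LRR 1:2), perturbed by a symmetric
sequencing-error mass.  Non-diagnostic loci carry a shared major allele
in every group and model heterozygosity as a single per-class
probability: a coalescent-free simplification that preserves exactly the
features the analysis consumes (the heterozygosity contrast between
hemiclones, sexual parentals and hybrids, and the identifiability of the
planted diagnostic panel).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import GenotypeMatrix, PeakTable, PopAssignment, PopulationMap, TaxonHint

__all__ = [
    "SimConfig",
    "TruthTable",
    "simulate_cohort",
    "MicrosatLocus",
    "PeakSimConfig",
    "default_microsat_loci",
    "simulate_peak_table",
    "DOSAGE_P_L",
]

CLASSES = ("LL", "RR", "LR", "LLR", "LRR")

#: probability that a read at a diagnostic locus carries the L allele,
#: proportional to L-genome dosage
DOSAGE_P_L: dict[str, float] = {
    "LL": 1.0,
    "RR": 0.0,
    "LR": 0.5,
    "LLR": 2.0 / 3.0,
    "LRR": 1.0 / 3.0,
}

_BASES = np.array(["A", "C", "G", "T"])


@dataclasses.dataclass
class TruthTable:
    """Ground-truth class, sex and population per simulated sample."""

    records: pd.DataFrame  # columns: sample, true_class, sex, population

    def class_of(self, sample_id: str) -> str:
        row = self.records.loc[self.records["sample"] == sample_id]
        return str(row["true_class"].iloc[0])

    def classes(self) -> dict[str, str]:
        return dict(zip(self.records["sample"], self.records["true_class"]))

    def write(self, path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.records.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "TruthTable":
        return cls(pd.read_csv(path, sep="\t", comment="#"))


@dataclasses.dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults mirror the study system: a matrix of 2521 SNPs containing
    376 fully species-diagnostic loci, a reference group of lessonae
    (LL) and a small hemiclonal ridibundus (RR) group beside the hybrid
    majority, sequenced at moderate, overdispersed RAD depth.  The
    per-class heterozygosity rates at non-diagnostic loci default to the
    study's observed contrasts (lessonae ~0.07, hybrids higher overall
    because every diagnostic locus is heterozygous in them, hemiclonal
    ridibundus ~0.02).
    """

    n_per_class: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"LL": 20, "RR": 5, "LR": 30, "LLR": 0, "LRR": 0}
    )
    n_loci_total: int = 2521
    n_diagnostic: int = 376
    depth_mean: float = 20.0
    depth_dispersion: float | str = 5.0  # negative-binomial size, or "poisson"
    seq_error: float = 0.01
    missing_rate: float = 0.1
    residual_het: float = 0.02  # hemiclonal RR, off-panel
    parental_het: float = 0.07  # sexual LL, off-panel
    hybrid_het: float = 0.05  # LR/LLR/LRR, off-panel
    triploid_coding: bool = False  # write triploid GT strings for LLR/LRR truth
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.n_per_class) - set(CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown classes in n_per_class: {sorted(unknown)}")
        if sum(self.n_per_class.values()) <= 0:
            raise ConfigurationError("cohort must contain at least one individual")
        if not (0 <= self.n_diagnostic <= self.n_loci_total):
            raise ConfigurationError("need 0 <= n_diagnostic <= n_loci_total")
        if not (0.0 <= self.seq_error < 0.5):
            raise ConfigurationError("seq_error must lie in [0, 0.5)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        for name in ("residual_het", "parental_het", "hybrid_het"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.depth_dispersion != "poisson" and not float(self.depth_dispersion) > 0:
            raise ConfigurationError("depth_dispersion must be positive or 'poisson'")


def _draw_depths(rng: np.random.Generator, config: SimConfig, size: int) -> np.ndarray:
    if config.depth_dispersion == "poisson":
        return rng.poisson(config.depth_mean, size=size)
    k = float(config.depth_dispersion)
    p = k / (k + config.depth_mean)
    return rng.negative_binomial(k, p, size=size)


def _offpanel_het_rate(config: SimConfig, cls: str) -> float:
    if cls == "LL":
        return config.parental_het
    if cls == "RR":
        return config.residual_het
    return config.hybrid_het


def simulate_cohort(config: SimConfig) -> tuple[GenotypeMatrix, PopulationMap, TruthTable]:
    """Simulate a genotype matrix with allele depths, a population map and
    the truth table.  Identical config (including seed) gives identical
    output."""
    rng = np.random.default_rng(config.seed)
    n_loci = config.n_loci_total

    locus_ids = [f"tag{i:05d}:1" for i in range(n_loci)]
    diag_idx = np.sort(
        rng.choice(n_loci, size=config.n_diagnostic, replace=False)
    )
    is_diag = np.zeros(n_loci, dtype=bool)
    is_diag[diag_idx] = True

    # two distinct bases per locus; at diagnostic loci the reference allele
    # is randomly the L- or the R-specific one
    ref_base = _BASES[rng.integers(0, 4, size=n_loci)]
    alt_base = np.array(
        [rng.choice([b for b in _BASES if b != r]) for r in ref_base]
    )
    l_is_ref = rng.random(n_loci) < 0.5  # meaningful at diagnostic loci only
    l_allele = np.where(l_is_ref, ref_base, alt_base)
    r_allele = np.where(l_is_ref, alt_base, ref_base)
    alleles = {
        locus_ids[i]: (str(ref_base[i]), str(alt_base[i])) for i in range(n_loci)
    }

    samples: list[tuple[str, str]] = []  # (sample_id, class)
    for cls in CLASSES:
        for j in range(int(config.n_per_class.get(cls, 0))):
            samples.append((f"{cls}_{j:03d}", cls))

    populations = {"LL": "north", "RR": "south"}
    genotypes: dict[str, dict[str, tuple[str, ...]]] = {}
    depths: dict[str, dict[str, dict[str, int]]] = {}
    truth_rows = []
    assignments: dict[str, PopAssignment] = {}
    hybrid_counter = 0

    for sample_id, cls in samples:
        if cls in populations:
            pop = populations[cls]
        else:
            # hybrids split evenly over the two demes
            pop = "north" if hybrid_counter % 2 == 0 else "south"
            hybrid_counter += 1
        sex = "M" if rng.random() < 0.5 else "F"
        hint = {
            "LL": TaxonHint.LL_REF,
            "RR": TaxonHint.RR_REF,
        }.get(cls, TaxonHint.UNKNOWN)
        assignments[sample_id] = PopAssignment(pop, hint)
        truth_rows.append((sample_id, cls, sex, pop))

        p_l = DOSAGE_P_L[cls]
        p_l_obs = p_l * (1.0 - config.seq_error) + (1.0 - p_l) * config.seq_error

        total = _draw_depths(rng, config, n_loci)
        d_l = rng.binomial(total, p_l_obs)
        d_r = total - d_l
        het_offpanel = rng.random(n_loci) < _offpanel_het_rate(config, cls)
        missing = rng.random(n_loci) < config.missing_rate

        calls: dict[str, tuple[str, ...]] = {}
        dd: dict[str, dict[str, int]] = {}
        for i in range(n_loci):
            if missing[i]:
                continue
            locus = locus_ids[i]
            if is_diag[i]:
                la, ra = str(l_allele[i]), str(r_allele[i])
                if cls == "LL":
                    calls[locus] = (la, la)
                elif cls == "RR":
                    calls[locus] = (ra, ra)
                elif config.triploid_coding and cls == "LLR":
                    calls[locus] = (la, la, ra)
                elif config.triploid_coding and cls == "LRR":
                    calls[locus] = (la, ra, ra)
                else:
                    calls[locus] = (la, ra)
                dd[locus] = {la: int(d_l[i]), ra: int(d_r[i])}
            else:
                rb, ab = str(ref_base[i]), str(alt_base[i])
                calls[locus] = (rb, ab) if het_offpanel[i] else (rb, rb)
        genotypes[sample_id] = calls
        depths[sample_id] = dd

    gm = GenotypeMatrix(
        [s for s, _ in samples], locus_ids, alleles, genotypes, depths, validate=False
    )
    pm = PopulationMap(assignments)
    truth = TruthTable(
        pd.DataFrame(truth_rows, columns=["sample", "true_class", "sex", "population"])
    )
    return gm, pm, truth


def planted_panel(config: SimConfig) -> pd.DataFrame:
    """The diagnostic panel implied by a config, for parameter-recovery
    tests: columns locus, l_allele, r_allele.  Re-derives the same draws
    as :func:`simulate_cohort` from the seed."""
    rng = np.random.default_rng(config.seed)
    n_loci = config.n_loci_total
    locus_ids = [f"tag{i:05d}:1" for i in range(n_loci)]
    diag_idx = np.sort(rng.choice(n_loci, size=config.n_diagnostic, replace=False))
    ref_base = _BASES[rng.integers(0, 4, size=n_loci)]
    alt_base = np.array([rng.choice([b for b in _BASES if b != r]) for r in ref_base])
    l_is_ref = rng.random(n_loci) < 0.5
    l_allele = np.where(l_is_ref, ref_base, alt_base)
    r_allele = np.where(l_is_ref, alt_base, ref_base)
    rows = [
        (locus_ids[i], str(l_allele[i]), str(r_allele[i])) for i in diag_idx
    ]
    return pd.DataFrame(rows, columns=["locus", "l_allele", "r_allele"])


# ---------------------------------------------------------------------------
# Microsatellite peak simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MicrosatLocus:
    """A co-amplifying L/R diagnostic microsatellite locus.

    ``efficiency`` scales the per-copy amplification of each allele;
    unlisted alleles amplify at efficiency 1.
    """

    locus_id: str
    l_alleles: tuple[int, ...]
    r_alleles: tuple[int, ...]
    efficiency: Mapping[int, float] = dataclasses.field(default_factory=dict)

    def eff(self, allele: int) -> float:
        return float(self.efficiency.get(allele, 1.0))


def default_microsat_loci() -> list[MicrosatLocus]:
    """Three loci shaped like the study's markers: one clean locus with a
    single fixed R allele and several L alleles, plus two messier loci."""
    return [
        MicrosatLocus("Rica1b5", l_alleles=(122, 123, 127, 145), r_alleles=(137,)),
        MicrosatLocus("Res16", l_alleles=(119, 123, 131), r_alleles=(127,)),
        MicrosatLocus("Rica2a34", l_alleles=(98, 102, 110), r_alleles=(106,)),
    ]


@dataclasses.dataclass
class PeakSimConfig:
    n_per_class: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"LR": 20, "LLR": 0, "LRR": 0}
    )
    loci: tuple[MicrosatLocus, ...] = dataclasses.field(
        default_factory=lambda: tuple(default_microsat_loci())
    )
    base_height: float = 1000.0
    sigma: float = 0.1  # lognormal noise on each peak
    null_prob: float = 0.0  # per-(sample, locus, allele) dropout
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        if not (0.0 <= self.null_prob < 1.0):
            raise ConfigurationError("null_prob must lie in [0, 1)")
        unknown = set(self.n_per_class) - set(CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown classes: {sorted(unknown)}")


def simulate_peak_table(config: PeakSimConfig) -> tuple[PeakTable, TruthTable]:
    """Simulate microsatellite peaks.

    Each genome copy draws one allele from its lineage's allele list;
    the height of allele *a* is
    ``base_height * efficiency(a) * copy_number(a) * exp(N(0, sigma^2))``.
    Null alleles (dropout) emit no record.  LLR individuals whose two L
    copies drew distinct alleles produce tri-allelic patterns.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    truth_rows = []
    for cls in CLASSES:
        n = int(config.n_per_class.get(cls, 0))
        for j in range(n):
            sample_id = f"{cls}_{j:03d}"
            sex = "M" if rng.random() < 0.5 else "F"
            truth_rows.append((sample_id, cls, sex, "sim"))
            for locus in config.loci:
                copies: list[int] = []
                for lineage in cls:  # class string spells the genome copies
                    pool = locus.l_alleles if lineage == "L" else locus.r_alleles
                    copies.append(int(pool[rng.integers(0, len(pool))]))
                counts: dict[int, int] = {}
                for a in copies:
                    counts[a] = counts.get(a, 0) + 1
                for a in sorted(counts):
                    if config.null_prob > 0 and rng.random() < config.null_prob:
                        continue
                    noise = (
                        float(np.exp(rng.normal(0.0, config.sigma)))
                        if config.sigma > 0
                        else 1.0
                    )
                    height = config.base_height * locus.eff(a) * counts[a] * noise
                    rows.append((sample_id, locus.locus_id, a, height))
    if not rows:
        raise ValidationError("peak simulation produced no records (empty cohort?)")
    pt = PeakTable(pd.DataFrame(rows, columns=["sample", "locus", "allele", "height"]))
    truth = TruthTable(
        pd.DataFrame(truth_rows, columns=["sample", "true_class", "sex", "population"])
    )
    return pt, truth
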