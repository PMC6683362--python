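"""Ploidy inference from per-allele sequencing depths at diagnostic loci.

In an LR diploid hybrid the L- and R-specific alleles of a diagnostic
locus are present in one copy each, so their read depths should be
roughly equal and the per-locus coverage ratio max/min should tend
towards 1.  In LLR and LRR triploids one allele sits on two genome
copies and should be sequenced about twice as deeply, pushing the ratio
towards 2.  This module computes the per-locus ratios and their
per-individual summaries (the ratio statistic of the field), classifies
ploidy with a guard band, and offers a binomial-likelihood companion
call that is reported alongside the ratio heuristic, never overriding
it.

Note that the expectation of max/min at finite depth exceeds its
infinite-depth limit: sampling noise only ever inflates the statistic
(at per-locus depth ~100 a true diploid averages ~1.1x).  The pooled
ratio, computed on depths summed over loci, suppresses this bias.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .diagnostics import DiagnosticPanel
from .errors import ConfigurationError
from .io import GenotypeMatrix

__all__ = [
    "PloidyCall",
    "LocusDepth",
    "DosageProfile",
    "locus_coverage_ratio",
    "individual_dosage_profile",
    "classify_ploidy",
    "dosage_likelihood_call",
    "LikelihoodCall",
    "dosage_report",
]

log = logging.getLogger(__name__)

DIPLOID_LR = "DIPLOID_LR"
TRIPLOID_LLR = "TRIPLOID_LLR"
TRIPLOID_LRR = "TRIPLOID_LRR"
UNDETERMINED = "UNDETERMINED"

PloidyCall = str

#: expected fraction of reads carrying the L allele, per class
_CLASS_P_L = {DIPLOID_LR: 0.5, TRIPLOID_LLR: 2.0 / 3.0, TRIPLOID_LRR: 1.0 / 3.0}


@dataclasses.dataclass(frozen=True)
class LocusDepth:
    locus_id: str
    depth_l: int
    depth_r: int

    @property
    def ratio(self) -> float:
        return locus_coverage_ratio(self.depth_l, self.depth_r)


def locus_coverage_ratio(depth_a: int, depth_b: int) -> float:
    """Ratio of the higher allele coverage to the lower, always >= 1."""
    if depth_a < 1 or depth_b < 1:
        raise ValueError("both allele depths must be >= 1 for a coverage ratio")
    hi, lo = max(depth_a, depth_b), min(depth_a, depth_b)
    return hi / lo


@dataclasses.dataclass
class DosageProfile:
    """Depth-ratio statistics of one individual over a diagnostic panel.

    ``mean_ratio`` averages the per-locus max/min ratios (the statistic
    as the field reports it); ``pooled_ratio`` is max/min of the depths
    summed over loci (lower variance, lower finite-depth bias);
    ``mean_log2_lr`` is signed and carries the direction of any dosage
    imbalance (positive = L in excess = LLR-like).
    """

    sample_id: str
    records: list[LocusDepth]
    n_loci_used: int
    mean_ratio: float | None
    pooled_ratio: float | None
    mean_log2_lr: float | None
    call: PloidyCall


def individual_dosage_profile(
    gm: GenotypeMatrix,
    panel: DiagnosticPanel,
    sample_id: str,
    min_depth_per_allele: int = 3,
    min_loci: int = 20,
    diploid_max: float = 1.4,
    triploid_min: float = 1.7,
) -> DosageProfile:
    """Dosage statistics for one sample over the panel.

    Only panel loci where the sample's called genotype contains both
    oriented alleles and both allele depths reach
    ``min_depth_per_allele`` are used (a heterozygote with a zero-depth
    allele is indistinguishable from allelic dropout, so such loci are
    excluded rather than imputed).  Fewer than ``min_loci`` usable loci
    gives an UNDETERMINED call.
    """
    if sample_id not in set(gm.sample_ids):
        raise ConfigurationError(f"sample {sample_id!r} not in matrix")
    if len(panel) == 0:
        raise ConfigurationError("panel is empty")
    records: list[LocusDepth] = []
    for entry in panel:
        call = gm.genotype(sample_id, entry.locus_id)
        if call is None or not {entry.l_allele, entry.r_allele} <= set(call):
            continue
        dd = gm.depths_at(sample_id, entry.locus_id)
        if dd is None:
            continue
        d_l = int(dd.get(entry.l_allele, 0))
        d_r = int(dd.get(entry.r_allele, 0))
        if d_l < min_depth_per_allele or d_r < min_depth_per_allele:
            continue
        records.append(LocusDepth(entry.locus_id, d_l, d_r))

    n = len(records)
    if n == 0:
        profile = DosageProfile(sample_id, records, 0, None, None, None, UNDETERMINED)
        return profile
    ratios = np.array([r.ratio for r in records])
    sum_l = sum(r.depth_l for r in records)
    sum_r = sum(r.depth_r for r in records)
    profile = DosageProfile(
        sample_id=sample_id,
        records=records,
        n_loci_used=n,
        mean_ratio=float(ratios.mean()),
        pooled_ratio=max(sum_l, sum_r) / min(sum_l, sum_r),
        mean_log2_lr=float(
            np.mean([math.log2(r.depth_l / r.depth_r) for r in records])
        ),
        call=UNDETERMINED,
    )
    if n < min_loci:
        log.info(
            "sample %s: only %d usable panel loci (< %d), call UNDETERMINED",
            sample_id,
            n,
            min_loci,
        )
        return profile
    profile.call = classify_ploidy(profile, diploid_max=diploid_max, triploid_min=triploid_min)
    return profile


def classify_ploidy(
    profile: DosageProfile,
    diploid_max: float = 1.4,
    triploid_min: float = 1.7,
) -> PloidyCall:
    """Threshold the mean per-locus ratio into diploid / triploid calls.

    The guard band (UNDETERMINED between ``diploid_max`` and
    ``triploid_min``) avoids forcing borderline calls; for triploid-band
    ratios the direction (LLR vs LRR) comes from the sign of
    ``mean_log2_lr``.
    """
    if diploid_max >= triploid_min:
        raise ConfigurationError("need diploid_max < triploid_min")
    if profile.mean_ratio is None:
        return UNDETERMINED
    if profile.mean_ratio <= diploid_max:
        return DIPLOID_LR
    if profile.mean_ratio >= triploid_min:
        if profile.mean_log2_lr is None or profile.mean_log2_lr == 0.0:
            return UNDETERMINED
        return TRIPLOID_LLR if profile.mean_log2_lr > 0 else TRIPLOID_LRR
    return UNDETERMINED


@dataclasses.dataclass(frozen=True)
class LikelihoodCall:
    logliks: dict[str, float]  # class -> summed binomial log-likelihood
    ml_class: PloidyCall


def dosage_likelihood_call(profile: DosageProfile, error: float = 0.0) -> LikelihoodCall:
    """Maximum-likelihood dosage class from per-locus binomial depths.

    For each class the L-read probability is the dosage fraction
    (1/2, 2/3 or 1/3) shrunk towards 1/2 by the sequencing-error mass
    ``error``; the log-likelihood sums ``Binom(d_L; d_L + d_R, p)`` over
    the usable loci.  Reported alongside the ratio heuristic as a
    companion call.
    """
    if not (0.0 <= error < 0.5):
        raise ConfigurationError("error must lie in [0, 0.5)")
    if not profile.records:
        return LikelihoodCall({}, UNDETERMINED)
    d_l = np.array([r.depth_l for r in profile.records])
    tot = np.array([r.depth_l + r.depth_r for r in profile.records])
    logliks = {}
    for cls, p in _CLASS_P_L.items():
        p_obs = p * (1.0 - error) + (1.0 - p) * error
        logliks[cls] = float(stats.binom.logpmf(d_l, tot, p_obs).sum())
    ml = max(logliks, key=logliks.get)
    return LikelihoodCall(logliks, ml)


def dosage_report(
    gm: GenotypeMatrix,
    panel: DiagnosticPanel,
    samples: list[str] | None = None,
    min_depth_per_allele: int = 3,
    min_loci: int = 20,
    diploid_max: float = 1.4,
    triploid_min: float = 1.7,
    likelihood_error: float = 0.01,
) -> pd.DataFrame:
    """Per-sample dosage summary table."""
    rows = []
    for sample in samples if samples is not None else gm.sample_ids:
        prof = individual_dosage_profile(
            gm,
            panel,
            sample,
            min_depth_per_allele=min_depth_per_allele,
            min_loci=min_loci,
            diploid_max=diploid_max,
            triploid_min=triploid_min,
        )
        lik = dosage_likelihood_call(prof, error=likelihood_error)
        rows.append(
            (
                sample,
                prof.n_loci_used,
                prof.mean_ratio,
                prof.pooled_ratio,
                prof.mean_log2_lr,
                prof.call,
                lik.ml_class,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "n_loci_used",
            "mean_ratio",
            "pooled_ratio",
            "mean_log2_lr",
            "call",
            "ml_class",
        ],
    )
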