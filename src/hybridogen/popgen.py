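"""Population summaries: observed heterozygosity and a diagnostic-locus
hybrid index.

The hybrid index is a deliberately simple stand-in for Bayesian
admixture assignment: over the called diagnostic-panel loci of one
individual it measures the fractions of L/R-heterozygous,
homozygous-L and homozygous-R genotypes, which separate the parental
species (LL, RR) from hybrids (LR) cleanly because the panel is fixed
between the parental genomes.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping

import pandas as pd

from .diagnostics import DiagnosticPanel
from .errors import ConfigurationError, ValidationError
from .io import GenotypeMatrix, PopulationMap

__all__ = ["HybridIndexResult", "hybrid_index", "hybrid_index_report", "observed_heterozygosity"]

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class HybridIndexResult:
    sample_id: str
    n_panel_called: int
    frac_het: float
    frac_hom_l: float
    frac_hom_r: float
    taxon_call: str  # LL, LR, RR or AMBIGUOUS


def hybrid_index(
    gm: GenotypeMatrix,
    panel: DiagnosticPanel,
    sample_id: str,
    pure_min: float = 0.9,
    het_min: float = 0.9,
) -> HybridIndexResult:
    """Classify one sample from its diagnostic-panel genotype fractions.

    ``taxon_call`` is LL/RR when the homozygous fraction for that genome
    reaches ``pure_min``, LR when the L/R-heterozygous fraction reaches
    ``het_min``, otherwise AMBIGUOUS.  The thresholds default below 1 to
    tolerate genotyping error and missing data.
    """
    if len(panel) == 0:
        raise ConfigurationError("panel is empty")
    n_het = n_l = n_r = 0
    for entry in panel:
        call = gm.genotype(sample_id, entry.locus_id)
        if call is None:
            continue
        distinct = set(call)
        if {entry.l_allele, entry.r_allele} <= distinct:
            n_het += 1
        elif distinct == {entry.l_allele}:
            n_l += 1
        elif distinct == {entry.r_allele}:
            n_r += 1
        # calls involving off-panel alleles are not informative and are skipped
    n = n_het + n_l + n_r
    if n == 0:
        return HybridIndexResult(sample_id, 0, 0.0, 0.0, 0.0, "AMBIGUOUS")
    f_het, f_l, f_r = n_het / n, n_l / n, n_r / n
    if f_l >= pure_min:
        call = "LL"
    elif f_r >= pure_min:
        call = "RR"
    elif f_het >= het_min:
        call = "LR"
    else:
        call = "AMBIGUOUS"
    return HybridIndexResult(sample_id, n, f_het, f_l, f_r, call)


def hybrid_index_report(
    gm: GenotypeMatrix,
    panel: DiagnosticPanel,
    samples: list[str] | None = None,
    pure_min: float = 0.9,
    het_min: float = 0.9,
) -> pd.DataFrame:
    rows = [
        dataclasses.astuple(
            hybrid_index(gm, panel, s, pure_min=pure_min, het_min=het_min)
        )
        for s in (samples if samples is not None else gm.sample_ids)
    ]
    return pd.DataFrame(
        rows,
        columns=["sample", "n_panel_called", "frac_het", "frac_hom_l", "frac_hom_r", "taxon_call"],
    )


def observed_heterozygosity(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    taxon_calls: Mapping[str, str],
    min_n: int = 5,
    loci: list[str] | None = None,
) -> pd.DataFrame:
    """Average observed heterozygosity per (population, taxon) group.

    Per individual, H_o is the fraction of heterozygous genotypes among
    its called loci (all loci by default, or a restricted set such as
    the diagnostic panel via ``loci``); groups then average over their
    individuals.  Groups with fewer than ``min_n`` individuals are
    omitted, with a logged note.
    """
    if gm.n_loci == 0 or gm.n_samples == 0:
        raise ValidationError("empty genotype matrix")
    locus_list = loci if loci is not None else gm.locus_ids
    rows = []
    for sample in gm.sample_ids:
        if sample not in pm:
            continue
        n_called = n_het = 0
        for locus in locus_list:
            het = gm.is_het(sample, locus)
            if het is None:
                continue
            n_called += 1
            n_het += int(het)
        if n_called == 0:
            continue
        rows.append(
            (
                pm.population(sample),
                taxon_calls.get(sample, "UNKNOWN"),
                sample,
                n_het / n_called,
            )
        )
    df = pd.DataFrame(rows, columns=["population", "taxon", "sample", "h_ind"])
    groups = []
    for (pop, taxon), grp in df.groupby(["population", "taxon"], sort=True):
        if len(grp) < min_n:
            log.info("group (%s, %s) has n=%d < %d; omitted", pop, taxon, len(grp), min_n)
            continue
        groups.append((pop, taxon, len(grp), float(grp["h_ind"].mean())))
    return pd.DataFrame(groups, columns=["population", "taxon", "n", "h_obs"])
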