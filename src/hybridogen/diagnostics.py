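"""Discovery of species-diagnostic loci from parental reference panels.

A locus is diagnostic when the two parental reference groups (LL and RR)
are fixed for different alleles — an allele-frequency difference of 1.0
— among their non-missing genotype calls.  Each panel entry is oriented:
the allele fixed in the LL references is the L allele, the allele fixed
in the RR references the R allele.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterator

import pandas as pd

from .errors import ConfigurationError
from .io import GenotypeMatrix, PopulationMap, TaxonHint

__all__ = ["PanelEntry", "DiagnosticPanel", "find_diagnostic_loci", "panel_coverage_report"]

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class PanelEntry:
    locus_id: str
    l_allele: str
    r_allele: str
    n_ll_called: int
    n_rr_called: int

    def __post_init__(self) -> None:
        if self.l_allele == self.r_allele:
            raise ConfigurationError(
                f"panel entry {self.locus_id}: L and R alleles are identical"
            )


@dataclasses.dataclass
class DiagnosticPanel:
    """Oriented set of diagnostic loci, sorted by locus id."""

    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.locus_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[PanelEntry]:
        return iter(self.entries)

    def loci(self) -> list[str]:
        return [e.locus_id for e in self.entries]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(e) for e in self.entries],
            columns=["locus_id", "l_allele", "r_allele", "n_ll_called", "n_rr_called"],
        )

    def write(self, path: str | Path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.as_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "DiagnosticPanel":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"l_allele": str, "r_allele": str})
        return cls(
            [
                PanelEntry(
                    str(r.locus_id),
                    str(r.l_allele),
                    str(r.r_allele),
                    int(r.n_ll_called),
                    int(r.n_rr_called),
                )
                for r in df.itertuples(index=False)
            ]
        )


def _fixed_allele(calls: list[tuple[str, ...]]) -> str | None:
    """The single allele all calls are homozygous for, else None."""
    seen: set[str] = set()
    for call in calls:
        seen.update(call)
        if len(seen) > 1:
            return None
    return next(iter(seen)) if seen else None


def find_diagnostic_loci(
    gm: GenotypeMatrix,
    pm: PopulationMap,
    min_ref_called: int = 3,
    require_biallelic: bool = True,
) -> DiagnosticPanel:
    """Scan all loci for fixed L/R differences between the reference groups.

    A locus enters the panel iff, among non-missing reference calls, all
    LL references are homozygous for one allele, all RR references for a
    different allele, and each group has at least ``min_ref_called``
    called samples.  Hybrid and UNKNOWN samples are ignored: they are
    the inference targets.
    """
    in_matrix = set(gm.sample_ids)
    ll_refs = [s for s in pm.samples_with_hint(TaxonHint.LL_REF) if s in in_matrix]
    rr_refs = [s for s in pm.samples_with_hint(TaxonHint.RR_REF) if s in in_matrix]
    if not ll_refs or not rr_refs:
        raise ConfigurationError(
            "diagnostic discovery needs at least one LL_REF and one RR_REF sample "
            f"present in the matrix (got {len(ll_refs)} LL, {len(rr_refs)} RR)"
        )

    entries: list[PanelEntry] = []
    for locus in gm.locus_ids:
        if require_biallelic and len(gm.alleles.get(locus, ())) != 2:
            continue
        ll_calls = [c for c in (gm.genotype(s, locus) for s in ll_refs) if c is not None]
        rr_calls = [c for c in (gm.genotype(s, locus) for s in rr_refs) if c is not None]
        if len(ll_calls) < min_ref_called or len(rr_calls) < min_ref_called:
            continue
        a = _fixed_allele(ll_calls)
        b = _fixed_allele(rr_calls)
        if a is None or b is None or a == b:
            continue
        entries.append(PanelEntry(locus, a, b, len(ll_calls), len(rr_calls)))
    if not entries:
        log.warning(
            "no diagnostic loci found (%d LL refs, %d RR refs, min_ref_called=%d)",
            len(ll_refs),
            len(rr_refs),
            min_ref_called,
        )
    return DiagnosticPanel(entries)


def panel_coverage_report(gm: GenotypeMatrix, panel: DiagnosticPanel) -> pd.DataFrame:
    """Per-sample counts of panel loci with called genotypes and with
    usable (both-allele) depths; used to flag samples too sparse for a
    dosage call."""
    if len(panel) == 0:
        raise ConfigurationError("panel is empty")
    rows = []
    for sample in gm.sample_ids:
        n_called = 0
        n_depth = 0
        for entry in panel:
            call = gm.genotype(sample, entry.locus_id)
            if call is None:
                continue
            n_called += 1
            dd = gm.depths_at(sample, entry.locus_id)
            if dd and entry.l_allele in dd and entry.r_allele in dd:
                n_depth += 1
        rows.append((sample, n_called, n_depth))
    return pd.DataFrame(rows, columns=["sample", "n_called", "n_with_depths"])
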