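"""Readers, writers and the shared data model.

The pipeline touches three plain-text formats: VCF 4.2 (``GT`` plus
per-allele ``AD`` depths) for the SNP matrix, a tab-separated population
map, and a tab-separated microsatellite peak table.  Loci are identified
as ``CHROM:POS`` (1-based, following the VCF standard) and alleles are
plain strings, so SNP bases and microsatellite fragment sizes share one
representation.

Triploid genotype strings (``0/0/1``) are accepted on read so that
simulated triploid truth files round-trip, even though real RAD exports
are diploid-coded.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import pysam

from .errors import FormatError, ValidationError

__all__ = [
    "GenotypeMatrix",
    "PopulationMap",
    "PopAssignment",
    "TaxonHint",
    "PeakTable",
    "read_vcf_with_depths",
    "write_vcf",
    "read_population_map",
    "write_population_map",
    "read_peak_table",
    "write_peak_table",
]


class TaxonHint(str, enum.Enum):
    """A priori taxon label attached to a sample in the population map.

    ``LL_REF`` / ``RR_REF`` mark the parental reference panels (here the
    *P. lessonae* and *P. ridibundus* groups) used to discover
    species-diagnostic loci; everything else is ``UNKNOWN`` and is an
    inference target.
    """

    LL_REF = "LL_REF"
    RR_REF = "RR_REF"
    UNKNOWN = "UNKNOWN"


@dataclasses.dataclass(frozen=True)
class PopAssignment:
    population: str
    taxon_hint: TaxonHint = TaxonHint.UNKNOWN


@dataclasses.dataclass
class PopulationMap:
    """Maps each sample to a population and an optional reference label."""

    assignments: dict[str, PopAssignment]

    def __len__(self) -> int:
        return len(self.assignments)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.assignments

    def population(self, sample_id: str) -> str:
        return self.assignments[sample_id].population

    def taxon_hint(self, sample_id: str) -> TaxonHint:
        return self.assignments[sample_id].taxon_hint

    def samples_with_hint(self, hint: TaxonHint) -> list[str]:
        return [s for s, a in self.assignments.items() if a.taxon_hint == hint]


class GenotypeMatrix:
    """Samples x loci genotype calls with optional per-allele read depths.

    Parameters
    ----------
    sample_ids, locus_ids:
        Ordered, duplicate-free identifiers.
    alleles:
        ``locus_id -> tuple of registered allele strings`` (reference
        allele first, by convention of the VCF writer).
    genotypes:
        ``sample_id -> locus_id -> tuple of called alleles``.  A missing
        call is simply an absent key.  Calls are unordered multisets; a
        diploid heterozygote is ``("A", "G")``, a triploid call has
        three entries.
    depths:
        ``sample_id -> locus_id -> {allele: read depth}``, optional.
    """

    def __init__(
        self,
        sample_ids: Iterable[str],
        locus_ids: Iterable[str],
        alleles: Mapping[str, tuple[str, ...]],
        genotypes: Mapping[str, Mapping[str, tuple[str, ...]]],
        depths: Mapping[str, Mapping[str, Mapping[str, int]]] | None = None,
        validate: bool = True,
    ) -> None:
        self.sample_ids = list(sample_ids)
        self.locus_ids = list(locus_ids)
        self.alleles = {l: tuple(a) for l, a in alleles.items()}
        self._genotypes = {s: dict(g) for s, g in genotypes.items()}
        self._depths = (
            {s: {l: dict(d) for l, d in per.items()} for s, per in depths.items()}
            if depths
            else {}
        )
        if validate:
            self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def genotype(self, sample_id: str, locus_id: str) -> tuple[str, ...] | None:
        """Called alleles at (sample, locus), or ``None`` when missing."""
        return self._genotypes.get(sample_id, {}).get(locus_id)

    def depths_at(self, sample_id: str, locus_id: str) -> dict[str, int] | None:
        """Per-allele read depths at (sample, locus), or ``None``."""
        return self._depths.get(sample_id, {}).get(locus_id)

    def is_het(self, sample_id: str, locus_id: str) -> bool | None:
        call = self.genotype(sample_id, locus_id)
        if call is None:
            return None
        return len(set(call)) > 1

    def called_loci(self, sample_id: str) -> list[str]:
        return [l for l in self.locus_ids if l in self._genotypes.get(sample_id, {})]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        if len(set(self.locus_ids)) != len(self.locus_ids):
            raise ValidationError("duplicate locus identifiers")
        locus_set = set(self.locus_ids)
        for locus in self.alleles:
            if locus not in locus_set:
                raise ValidationError(f"alleles registered for unknown locus {locus!r}")
        sample_set = set(self.sample_ids)
        for sample, calls in self._genotypes.items():
            if sample not in sample_set:
                raise ValidationError(f"genotypes for unknown sample {sample!r}")
            for locus, call in calls.items():
                registered = set(self.alleles.get(locus, ()))
                if not set(call) <= registered:
                    raise ValidationError(
                        f"call {call} at {sample}/{locus} uses unregistered alleles"
                    )
        for sample, per in self._depths.items():
            for locus, dd in per.items():
                registered = set(self.alleles.get(locus, ()))
                if not set(dd) <= registered:
                    raise ValidationError(
                        f"depths at {sample}/{locus} reference unregistered alleles"
                    )
                if any(int(v) < 0 for v in dd.values()):
                    raise ValidationError(f"negative depth at {sample}/{locus}")


@dataclasses.dataclass
class PeakTable:
    """Microsatellite peak heights, one record per visible peak.

    Columns: ``sample``, ``locus``, ``allele`` (fragment size in bp) and
    ``height`` (absorbance units, strictly positive).  Absent peaks are
    absent records, never zero heights.
    """

    records: pd.DataFrame

    COLUMNS = ("sample", "locus", "allele", "height")

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"peak table missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        df["allele"] = df["allele"].astype(int)
        df["height"] = df["height"].astype(float)
        if (df["height"] <= 0).any():
            bad = df.loc[df["height"] <= 0].iloc[0]
            raise ValidationError(
                f"non-positive peak height for {bad['sample']}/{bad['locus']}/{bad['allele']}"
            )
        if df.duplicated(subset=["sample", "locus", "allele"]).any():
            raise ValidationError("duplicate (sample, locus, allele) peak records")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def peaks_for(self, sample_id: str, locus_id: str) -> pd.DataFrame:
        df = self.records
        return df.loc[(df["sample"] == sample_id) & (df["locus"] == locus_id)]

    def sample_locus_pairs(self) -> list[tuple[str, str]]:
        return list(
            self.records[["sample", "locus"]].drop_duplicates().itertuples(index=False, name=None)
        )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _split_locus_id(locus_id: str) -> tuple[str, int]:
    chrom, _, pos = locus_id.rpartition(":")
    if not chrom:
        raise ValidationError(f"locus id {locus_id!r} is not CHROM:POS")
    return chrom, int(pos)


def read_vcf_with_depths(path: str | Path, require_depths: bool = False) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    ``GT`` is required; ``AD`` (per-allele depths, reference first) is
    required only when ``require_depths`` is set.  Missing genotypes
    (``./.``) are stored as missing with no depth requirement; diploid
    and triploid GT strings are both accepted.
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    if "GT" not in vf.header.formats:
        raise FormatError(f"{path}: VCF has no GT FORMAT field")
    if require_depths and "AD" not in vf.header.formats:
        raise FormatError(f"{path}: AD FORMAT field required but absent")

    sample_ids = list(vf.header.samples)
    locus_ids: list[str] = []
    alleles: dict[str, tuple[str, ...]] = {}
    genotypes: dict[str, dict[str, tuple[str, ...]]] = {s: {} for s in sample_ids}
    depths: dict[str, dict[str, dict[str, int]]] = {s: {} for s in sample_ids}
    seen = set()
    for i, rec in enumerate(vf, start=1):
        try:
            locus = f"{rec.chrom}:{rec.pos}"
            if locus in seen:
                raise ValidationError(f"{path}: duplicate site {locus}")
            seen.add(locus)
            site_alleles = tuple(rec.alleles)
            locus_ids.append(locus)
            alleles[locus] = site_alleles
            for s in sample_ids:
                sm = rec.samples[s]
                gt = sm.get("GT")
                if gt is None or any(a is None for a in gt):
                    continue
                genotypes[s][locus] = tuple(site_alleles[a] for a in gt)
                ad = sm.get("AD")
                if ad is not None and not all(v is None for v in ad):
                    depths[s][locus] = {
                        site_alleles[j]: int(v)
                        for j, v in enumerate(ad)
                        if v is not None
                    }
                elif require_depths:
                    raise FormatError(
                        f"{path}: AD missing for called genotype {s} at {locus}"
                    )
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: malformed VCF record {i}: {exc}") from exc
    vf.close()
    return GenotypeMatrix(sample_ids, locus_ids, alleles, genotypes, depths)


def write_vcf(gm: GenotypeMatrix, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    """Write a :class:`GenotypeMatrix` as VCF 4.2 with GT and AD fields."""
    path = Path(path)
    chroms: list[str] = []
    for locus in gm.locus_ids:
        chrom, _ = _split_locus_id(locus)
        if not chroms or chroms[-1] != chrom:
            chroms.append(chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for line in header_lines:
            fh.write(f"##{line}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Per-allele read depths (ref first)">\n'
        )
        for chrom in dict.fromkeys(chroms):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for locus in gm.locus_ids:
            chrom, pos = _split_locus_id(locus)
            site_alleles = gm.alleles[locus]
            ref, alts = site_alleles[0], site_alleles[1:]
            index = {a: i for i, a in enumerate(site_alleles)}
            fields = [
                chrom,
                str(pos),
                ".",
                ref,
                ",".join(alts) if alts else ".",
                ".",
                ".",
                ".",
                "GT:AD",
            ]
            for s in gm.sample_ids:
                call = gm.genotype(s, locus)
                if call is None:
                    fields.append("./.:.")
                    continue
                gt = "/".join(str(i) for i in sorted(index[a] for a in call))
                dd = gm.depths_at(s, locus)
                if dd is None:
                    ad = "."
                else:
                    ad = ",".join(str(int(dd.get(a, 0))) for a in site_alleles)
                fields.append(f"{gt}:{ad}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Population map
# ---------------------------------------------------------------------------

def read_population_map(path: str | Path) -> PopulationMap:
    """Read a TSV with columns ``sample``, ``population`` and optionally
    ``taxon_hint`` (defaulting to UNKNOWN)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("sample", "population"):
        if col not in df.columns:
            raise FormatError(f"{path}: population map needs a {col!r} column")
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise ValidationError(f"{path}: duplicate sample {dup!r}")
    allowed = {h.value for h in TaxonHint}
    assignments: dict[str, PopAssignment] = {}
    for row in df.itertuples(index=False):
        token = getattr(row, "taxon_hint", TaxonHint.UNKNOWN.value)
        if pd.isna(token):
            token = TaxonHint.UNKNOWN.value
        if token not in allowed:
            raise ValidationError(
                f"{path}: unknown taxon_hint {token!r} for sample {row.sample!r}; "
                f"allowed: {sorted(allowed)}"
            )
        assignments[row.sample] = PopAssignment(row.population, TaxonHint(token))
    return PopulationMap(assignments)


def write_population_map(pm: PopulationMap, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("sample\tpopulation\ttaxon_hint\n")
        for sample, a in pm.assignments.items():
            fh.write(f"{sample}\t{a.population}\t{a.taxon_hint.value}\n")


# ---------------------------------------------------------------------------
# Peak table
# ---------------------------------------------------------------------------

def read_peak_table(path: str | Path) -> PeakTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PeakTable.COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: peak table missing columns {missing}")
    return PeakTable(df)


def write_peak_table(pt: PeakTable, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pt.records.to_csv(fh, sep="\t", index=False)
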