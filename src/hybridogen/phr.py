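"""Microsatellite peak-height-ratio (PHR) triploid detection.

At a co-amplifying L/R diagnostic microsatellite, the height of an
allele's absorbance peak grows with its copy number, so in triploids the
duplicated genome's allele is amplified in roughly double quantity.
Because amplification efficiency also depends on allele size and primer
mismatches, raw ratios are only comparable within a genotype, against
ranges calibrated on individuals of known ploidy.  The statistic is

    PHR = log10(H_R / H_L)

where ``H_R`` and ``H_L`` are the heights of the R- and L-specific
peaks.  Base 10 keeps the copy-number-2 signal at +/- 0.301,
commensurate with published calibration ranges; the base is
configurable.  Individuals with three distinct peaks are flagged
tri-allelic (direct triploid evidence) and receive no PHR class; loci
showing a single peak (possible null allele) are uninformative.
"""

from __future__ import annotations

import dataclasses
import math
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, ValidationError

__all__ = [
    "PhrRange",
    "CalibrationRanges",
    "load_calibration",
    "default_calibration_path",
    "PHRResult",
    "compute_phr",
    "detect_triallelic",
    "classify_phr",
    "phr_report",
    "OUT_OF_RANGE",
]

OUT_OF_RANGE = "OUT_OF_RANGE"


@dataclasses.dataclass(frozen=True)
class PhrRange:
    cls: str  # LLR, LR or LRR
    phr_min: float
    phr_max: float
    mean: float | None = None

    def __post_init__(self) -> None:
        if self.phr_min > self.phr_max:
            raise ValidationError(f"{self.cls}: phr_min > phr_max")
        if self.mean is not None and not (self.phr_min <= self.mean <= self.phr_max):
            raise ValidationError(f"{self.cls}: mean outside [phr_min, phr_max]")

    def contains(self, value: float) -> bool:
        return self.phr_min <= value <= self.phr_max


@dataclasses.dataclass
class CalibrationRanges:
    """Disjoint closed PHR intervals per genotype class for one
    (locus, genotype) calibration set."""

    ranges: dict[str, PhrRange]

    def __post_init__(self) -> None:
        items = sorted(self.ranges.values(), key=lambda r: r.phr_min)
        for lo, hi in zip(items, items[1:]):
            if hi.phr_min <= lo.phr_max:
                raise ConfigurationError(
                    f"calibration ranges overlap: {lo.cls} and {hi.cls}"
                )

    def classify(self, value: float) -> str:
        for r in self.ranges.values():
            if r.contains(value):
                return r.cls
        return OUT_OF_RANGE


def default_calibration_path() -> Path:
    return Path(str(resources.files("hybridogen").joinpath("data/phr_calibration.tsv")))


def load_calibration(path: str | Path | None = None) -> dict[tuple[str, str], CalibrationRanges]:
    """Load calibration TSV (locus, genotype, class, phr_min, phr_max,
    mean) into per-(locus, genotype) range sets; disjointness is checked
    on load."""
    path = Path(path) if path is not None else default_calibration_path()
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"locus", "genotype", "class", "phr_min", "phr_max"}
    if not needed <= set(df.columns):
        raise ConfigurationError(f"{path}: calibration needs columns {sorted(needed)}")
    out: dict[tuple[str, str], CalibrationRanges] = {}
    for (locus, genotype), grp in df.groupby(["locus", "genotype"], sort=True):
        ranges = {}
        for _, row in grp.iterrows():
            mean = row.get("mean")
            mean = None if pd.isna(mean) else float(mean)
            ranges[str(row["class"])] = PhrRange(
                str(row["class"]), float(row["phr_min"]), float(row["phr_max"]), mean
            )
        out[(str(locus), str(genotype))] = CalibrationRanges(ranges)
    return out


@dataclasses.dataclass
class PHRResult:
    """PHR outcome for one sample x locus peak pattern."""

    sample_id: str
    locus_id: str
    l_allele: int | None
    r_allele: int | None
    h_l: float | None
    h_r: float | None
    phr: float | None
    triallelic: bool
    pattern: str  # "LR", "single_peak", "triallelic", "no_informative_peaks"
    phr_class: str | None = None
    warnings: tuple[str, ...] = ()


def detect_triallelic(peaks: pd.DataFrame) -> bool:
    """True iff the sample x locus slice shows >= 3 distinct allele sizes."""
    return peaks["allele"].nunique() >= 3


def compute_phr(
    peaks: pd.DataFrame,
    l_alleles: set[int],
    r_alleles: set[int],
    sample_id: str = "",
    locus_id: str = "",
    base: float = 10.0,
) -> PHRResult:
    """PHR for one sample x locus peak-table slice.

    A PHR is computed iff exactly one L-specific and one R-specific peak
    are present and the pattern is not tri-allelic.  Peaks whose allele
    is in neither set are ignored with a warning recorded on the result.
    """
    if peaks.empty:
        raise ValidationError("empty peak slice")
    if base <= 0 or base == 1.0:
        raise ConfigurationError("log base must be positive and != 1")
    warnings = []
    alleles = peaks["allele"].astype(int)
    known = peaks.loc[alleles.isin(l_alleles | r_alleles)]
    for a in sorted(set(alleles) - (l_alleles | r_alleles)):
        warnings.append(f"peak allele {a} in neither L nor R set; ignored")
    triallelic = detect_triallelic(peaks)
    l_peaks = known.loc[known["allele"].isin(l_alleles)]
    r_peaks = known.loc[known["allele"].isin(r_alleles)]

    result = PHRResult(
        sample_id=sample_id,
        locus_id=locus_id,
        l_allele=None,
        r_allele=None,
        h_l=None,
        h_r=None,
        phr=None,
        triallelic=triallelic,
        pattern="no_informative_peaks",
        warnings=tuple(warnings),
    )
    if triallelic:
        result.pattern = "triallelic"
        return result
    if len(l_peaks) == 1 and len(r_peaks) == 1:
        h_l = float(l_peaks["height"].iloc[0])
        h_r = float(r_peaks["height"].iloc[0])
        result.l_allele = int(l_peaks["allele"].iloc[0])
        result.r_allele = int(r_peaks["allele"].iloc[0])
        result.h_l = h_l
        result.h_r = h_r
        result.phr = math.log(h_r / h_l, base)
        result.pattern = "LR"
    elif len(known) == 1:
        # homozygous pattern or null allele on the other genome
        result.pattern = "single_peak"
    return result


def classify_phr(phr: float, ranges: CalibrationRanges) -> str:
    """The unique calibrated class whose closed interval contains
    ``phr``, else OUT_OF_RANGE."""
    return ranges.classify(phr)


def phr_report(
    peak_table,
    msat_panel: dict[str, tuple[set[int], set[int]]],
    calibration: dict[tuple[str, str], CalibrationRanges] | None = None,
    base: float = 10.0,
) -> pd.DataFrame:
    """PHR results for every sample x locus pair in a peak table.

    ``msat_panel`` maps locus id to its (L-allele set, R-allele set).
    When a calibration entry exists for (locus, "L/R" genotype) the PHR
    class is attached.
    """
    rows = []
    for sample, locus in peak_table.sample_locus_pairs():
        if locus not in msat_panel:
            continue
        l_set, r_set = msat_panel[locus]
        res = compute_phr(
            peak_table.peaks_for(sample, locus), l_set, r_set, sample, locus, base=base
        )
        if res.phr is not None and calibration is not None:
            genotype = f"{res.l_allele}/{res.r_allele}"
            cal = calibration.get((locus, genotype))
            if cal is not None:
                res.phr_class = classify_phr(res.phr, cal)
        rows.append(
            (
                sample,
                locus,
                res.l_allele,
                res.r_allele,
                res.h_l,
                res.h_r,
                res.phr,
                res.pattern,
                res.triallelic,
                res.phr_class,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sample",
            "locus",
            "l_allele",
            "r_allele",
            "h_l",
            "h_r",
            "phr",
            "pattern",
            "triallelic",
            "phr_class",
        ],
    )
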