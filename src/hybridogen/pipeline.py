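"""End-to-end orchestration: diagnose -> dosage -> PHR -> population
summaries, with reproducible, headered report files.

Every output TSV starts with a comment header carrying the package
version, the seed and a hash of the effective configuration, so a rerun
with identical config produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .diagnostics import DiagnosticPanel, find_diagnostic_loci, panel_coverage_report
from .dosage import dosage_report
from .errors import ConfigurationError
from .io import (
    GenotypeMatrix,
    PopulationMap,
    read_peak_table,
    read_population_map,
    read_vcf_with_depths,
)
from .phr import load_calibration, phr_report
from .popgen import hybrid_index_report, observed_heterozygosity

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineResult"]


@dataclasses.dataclass
class RunConfig:
    """All stage parameters of a pipeline run."""

    vcf: str
    popmap: str
    outdir: str
    peaks: str | None = None
    msat_panel: str | None = None  # TSV: locus, l_alleles (comma), r_alleles (comma)
    calibration: str | None = None
    min_ref_called: int = 3
    require_biallelic: bool = True
    min_depth_per_allele: int = 3
    min_loci: int = 20
    diploid_max: float = 1.4
    triploid_min: float = 1.7
    likelihood_error: float = 0.01
    pure_min: float = 0.9
    het_min: float = 0.9
    min_n: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    _PATH_FIELDS = ("vcf", "popmap", "outdir", "peaks", "msat_panel", "calibration")

    def digest(self) -> str:
        """Hash of the analysis parameters (paths excluded, so moving the
        same run elsewhere keeps the digest stable)."""
        params = {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if k not in self._PATH_FIELDS
        }
        payload = json.dumps(params, sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclasses.dataclass
class PipelineResult:
    outdir: Path
    summary: dict
    panel: DiagnosticPanel


def _read_msat_panel(path: str | Path) -> dict[str, tuple[set[int], set[int]]]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    needed = {"locus", "l_alleles", "r_alleles"}
    if not needed <= set(df.columns):
        raise ConfigurationError(f"{path}: microsat panel needs columns {sorted(needed)}")
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.locus)] = (
            {int(a) for a in str(row.l_alleles).split(",")},
            {int(a) for a in str(row.r_alleles).split(",")},
        )
    return out


def _write_tsv(df, path: Path, header: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run all applicable stages and write the report bundle.

    Produces ``panel.tsv``, ``dosage.tsv``, ``hybrid_index.tsv``,
    ``heterozygosity.tsv``, optionally ``phr.tsv``, and ``summary.json``.
    An empty diagnostic panel skips the dosage and hybrid-index stages
    with an explicit notice in the summary.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = [
        f"hybridogen {__version__}",
        f"seed={config.seed} config={config.digest()}",
    ]

    gm: GenotypeMatrix = read_vcf_with_depths(config.vcf, require_depths=False)
    pm: PopulationMap = read_population_map(config.popmap)

    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "n_samples": gm.n_samples,
        "n_loci": gm.n_loci,
        "notices": [],
    }

    panel = find_diagnostic_loci(
        gm,
        pm,
        min_ref_called=config.min_ref_called,
        require_biallelic=config.require_biallelic,
    )
    panel.write(outdir / "panel.tsv", header_lines=header)
    summary["n_diagnostic_loci"] = len(panel)

    if len(panel) == 0:
        notice = "diagnostic panel is empty; dosage and hybrid-index stages skipped"
        log.warning(notice)
        summary["notices"].append(notice)
        summary["taxon_counts"] = {}
        summary["ploidy_counts"] = {}
    else:
        coverage = panel_coverage_report(gm, panel)
        _write_tsv(coverage, outdir / "panel_coverage.tsv", header)

        hi = hybrid_index_report(
            gm, panel, pure_min=config.pure_min, het_min=config.het_min
        )
        _write_tsv(hi, outdir / "hybrid_index.tsv", header)
        taxon_calls = dict(zip(hi["sample"], hi["taxon_call"]))
        summary["taxon_counts"] = (
            hi["taxon_call"].value_counts().sort_index().to_dict()
        )

        dos = dosage_report(
            gm,
            panel,
            min_depth_per_allele=config.min_depth_per_allele,
            min_loci=config.min_loci,
            diploid_max=config.diploid_max,
            triploid_min=config.triploid_min,
            likelihood_error=config.likelihood_error,
        )
        _write_tsv(dos, outdir / "dosage.tsv", header)
        hybrids = dos.loc[[taxon_calls.get(s) == "LR" for s in dos["sample"]]]
        summary["ploidy_counts"] = (
            hybrids["call"].value_counts().sort_index().to_dict()
        )
        summary["ploidy_counts_ml"] = (
            hybrids["ml_class"].value_counts().sort_index().to_dict()
        )

        het = observed_heterozygosity(gm, pm, taxon_calls, min_n=config.min_n)
        _write_tsv(het, outdir / "heterozygosity.tsv", header)
        summary["heterozygosity_groups"] = len(het)

    if config.peaks is not None:
        if config.msat_panel is None:
            raise ConfigurationError("peaks given without msat_panel allele assignments")
        pt = read_peak_table(config.peaks)
        msat = _read_msat_panel(config.msat_panel)
        calibration = load_calibration(config.calibration)
        phr_df = phr_report(pt, msat, calibration)
        _write_tsv(phr_df, outdir / "phr.tsv", header)
        informative = phr_df.loc[phr_df["phr_class"].notna()]
        summary["phr_class_counts"] = (
            informative["phr_class"].value_counts().sort_index().to_dict()
        )
        summary["n_triallelic"] = int(phr_df["triallelic"].sum())

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(outdir, summary, panel)
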