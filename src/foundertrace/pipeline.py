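"""End-to-end analysis pipeline and report assembly.

Ties the stages together in the order a founder-variant analysis runs:
load phased genotypes -> resolve focal carriers -> shared-core detection
on common SNVs -> rare-variant tagging on the unfiltered sites -> optional
clinical comparison and renal survival.  Every output records the exact
run configuration so a report bundle can be reproduced from its own
summary file.
"""

from __future__ import annotations

import json
import math
import sys
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .clinstats import (
    clinical_comparison,
    km_curve,
    logrank,
    survival_records_from_frame,
)
from .haplotype_io import (
    CarrierSet,
    HaplotypeMatrix,
    focal_carriers,
    read_phased_vcf,
    read_sample_list,
)
from .rare_tagging import background_sites, select_rare_window, tag_report
from .shared_core import SharedCoreAnalysis, match_matrix, shared_core_analysis
from .variants import VariantRecord


@dataclass
class RunConfig:
    """Configuration of one pipeline run (thresholds default to the
    standard haplotype-analysis settings: common SNPs at MAF > 5% with
    missingness < 1%; rare tags below 0.5% in a 1 Mb window; exact
    consensus matching, tolerance 0)."""

    vcf: str
    focal: str  # chrom:pos:ref:alt
    out_dir: str
    region: tuple[str, int, int] | None = None
    pheno: str | None = None
    one_per_family: str | None = None
    maf_min: float = 0.05
    missing_max: float = 0.01
    rare_max: float = 0.005
    window_bp: int = 1_000_000
    tolerance: int = 0
    assume_phased_hom: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("maf_min", "missing_max", "rare_max"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0,1), got {v}")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")


def _log(msg: str) -> None:
    print(f"[foundertrace] {msg}", file=sys.stderr)


def _common_snv_matrix(
    full: HaplotypeMatrix, config: RunConfig, focal: VariantRecord
) -> HaplotypeMatrix:
    """Common-variant view: biallelic SNVs passing the MAF/missingness
    filters, plus the focal site itself."""
    snv = HaplotypeMatrix(
        samples=list(full.samples),
        alleles=full.alleles[
            :,
            [
                j
                for j, s in enumerate(full.sites)
                if (len(s.ref) == 1 and len(s.alt) == 1) or s.matches(focal)
            ],
        ],
        sites=[
            s
            for s in full.sites
            if (len(s.ref) == 1 and len(s.alt) == 1) or s.matches(focal)
        ],
    )
    return snv.filtered(config.maf_min, config.missing_max, keep=focal)


def shared_core_report(analysis: SharedCoreAnalysis) -> dict:
    core = analysis.core
    lo, hi = analysis.extent_span_bp
    return {
        "core_interval": [core.core_left, core.core_right],
        "core_n_sites": int(core.core_site_indices.size),
        "core_alleles": core.core_alleles.astype(int).tolist(),
        "background_matches": core.background_matches,
        "background_total": core.background_total,
        "frequency_text": core.frequency_text,
        "extent_span_bp_min": lo,
        "extent_span_bp_max": hi,
        "n_carriers": analysis.consensus.n_carriers,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Writes into ``out_dir``: summary.json (config echo + all results),
    extents.tsv, match_matrix.tsv (carriers x sites consensus agreement),
    rare_tags.tsv, and clinstats.json when a phenotype table is given.
    Returns the summary dict.
    """
    config.validate()
    focal = VariantRecord.from_id(config.focal)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    _log(f"loading {config.vcf}")
    full = read_phased_vcf(
        config.vcf,
        region=config.region,
        maf_min=0.0,
        assume_phased_hom=config.assume_phased_hom,
    )
    _log(f"{full.n_samples} samples x {full.n_sites} sites loaded")
    carriers = focal_carriers(full, focal)
    _log(f"{len(carriers)} heterozygous carriers of {focal.vcf_id}")

    common = _common_snv_matrix(full, config, focal)
    _log(f"{common.n_sites} common SNVs after filtering")
    analysis = shared_core_analysis(common, carriers, config.tolerance)

    extents = pd.DataFrame(
        [
            {
                "carrier": e.carrier,
                "left_pos": e.left_pos,
                "right_pos": e.right_pos,
                "span_bp": e.span_bp,
                "n_sites": e.n_sites,
            }
            for e in analysis.extents
        ]
    )
    extents.to_csv(out / "extents.tsv", sep="\t", index=False)

    mm = match_matrix(common, carriers, analysis.consensus)
    pd.DataFrame(
        mm,
        index=carriers.sample_ids,
        columns=[s.pos for s in common.sites],
    ).to_csv(out / "match_matrix.tsv", sep="\t", index_label="carrier")

    one_per_family = (
        read_sample_list(config.one_per_family) if config.one_per_family else None
    )
    rare_sites = select_rare_window(
        background_sites(full, carriers),
        focal,
        window_bp=config.window_bp,
        freq_max=config.rare_max,
    )
    tags = tag_report(full, carriers, rare_sites, one_per_family)
    tag_frame = pd.DataFrame(
        [
            {
                "variant": t.site.vcf_id,
                "background_with": t.result.table.c,
                "background_without": t.result.table.d,
                "carriers_with": t.result.table.a,
                "carriers_total": t.result.table.a + t.result.table.b,
                # None rather than IEEE inf: keeps the JSON strict
                "odds_ratio": (
                    t.result.odds_ratio
                    if math.isfinite(t.result.odds_ratio)
                    else None
                ),
                "p_two_sided": t.result.p_two_sided,
                "p_one_sided_enrichment": t.result.p_one_sided_enrichment,
                "p_bonferroni": t.p_bonferroni,
            }
            for t in tags
        ]
    )
    tag_frame.to_csv(out / "rare_tags.tsv", sep="\t", index=False)

    summary = {
        "tool": "foundertrace",
        "version": __version__,
        "config": asdict(config),
        "n_samples": full.n_samples,
        "n_sites_loaded": full.n_sites,
        "n_common_snvs": common.n_sites,
        "carriers": [list(c) for c in carriers.carriers],
        "shared_core": shared_core_report(analysis),
        "rare_tags": tag_frame.to_dict(orient="records"),
    }

    if config.pheno:
        summary["clinstats"] = clinstats_report(
            pd.read_csv(config.pheno, sep="\t"), carriers
        )
        with open(out / "clinstats.json", "w") as fh:
            json.dump(summary["clinstats"], fh, indent=1)
            fh.write("\n")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
        fh.write("\n")
    _log(f"report written to {out}")
    return summary


def clinstats_report(pheno: pd.DataFrame, carriers: CarrierSet | list[str]) -> dict:
    """Clinical comparison + renal survival report.

    Carrier-vs-background Welch/Fisher comparisons over the whole table;
    Kaplan-Meier renal survival and a log-rank test between sexes within
    the carrier group; chi-square of hypertension (SBP >= 140 or
    DBP >= 90) against kidney failure within carriers.
    """
    from .clinstats import chi_square_2x2
    from .rare_tagging import ContingencyTable

    carrier_ids = (
        carriers.sample_ids if isinstance(carriers, CarrierSet) else list(carriers)
    )
    report: dict = {
        "comparison": clinical_comparison(pheno, carrier_ids).to_dict(
            orient="records"
        )
    }
    carr = pheno[pheno["sample"].astype(str).isin(set(carrier_ids))]
    if {"age", "event"} <= set(carr.columns) and len(carr) > 0:
        records = survival_records_from_frame(carr)
        km = km_curve(records)
        report["renal_survival"] = {
            "n": len(records),
            "events": int(carr["event"].sum()),
            "median_age": km.median,
        }
        if carr["sex"].nunique() == 2 and carr["event"].sum() > 0:
            stat, p = logrank(records)
            report["logrank_by_sex"] = {"statistic": stat, "p": p}
        if {"sbp", "dbp"} <= set(carr.columns):
            htn = (carr["sbp"] >= 140) | (carr["dbp"] >= 90)
            ev = carr["event"].astype(bool)
            table = ContingencyTable(
                int((htn & ev).sum()),
                int((htn & ~ev).sum()),
                int((~htn & ev).sum()),
                int((~htn & ~ev).sum()),
            )
            try:
                stat, p = chi_square_2x2(table)
                report["hypertension_vs_failure"] = {
                    "table": [table.a, table.b, table.c, table.d],
                    "chi2": stat,
                    "p": p,
                }
            except ValueError:
                pass
    return report
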