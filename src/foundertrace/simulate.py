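"""Founder-descent cohort simulator.

Generates the statistical structure a founder variant leaves in
population data, providing ground truth for every downstream stage:

* one founder haplotype carrying the focal variant;
* carriers descending from the founder ``g`` generations back, each
  retaining an ancestral segment around the focal site whose one-sided
  genetic length is Exponential with mean ``1/g`` Morgans (Haldane model,
  no interference; expected one-sided length 100/g cM), truncated at the
  region edges;
* a background pool of haplotypes, by default with independent sites at
  their allele frequencies (an optional pool-mosaic mode provides crude
  linkage disequilibrium);
* rare tagging variants planted on the founder haplotype and segregating
  at a low background frequency elsewhere;
* clinical covariates with a renal-survival endpoint (age at renal
  replacement therapy, censored otherwise).

Each carrier's segment is drawn independently — a star-shaped genealogy
from the founder, the simplest model consistent with apparently unrelated
pedigrees.  A fixed seed gives byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .haplotype_io import HaplotypeMatrix, Site, _site_stats
from .variants import VariantRecord


class SimConfigError(ValueError):
    pass


@dataclass
class FounderSimConfig:
    """Parameters of the founder-cohort generator.

    Defaults emulate a chr16-like chromosome with the focal site at
    ~20.36 Mb, nine carriers descending from a founder ten generations
    back, 2500 background samples (5000 background haplotypes), 400
    common sites with allele frequencies Uniform(0.05, 0.5), and four
    rare tagging variants at 0.3% background frequency all riding the
    founder haplotype, under a uniform 1 cM/Mb map.
    """

    generations: int = 10
    n_carriers: int = 9
    n_background: int = 2500  # background samples; 2 haplotypes each
    chrom: str = "16"
    region_start: int = 1
    region_end: int = 90_000_000  # half-open
    focal_pos: int = 20_360_000
    focal_ref: str = "ATCTGCCCCGAAG"
    focal_alt: str = "ACCGCCTCCT"
    cm_per_mb: float = 1.0
    n_common_sites: int = 400
    common_freq_range: tuple[float, float] = (0.05, 0.5)
    n_rare_tags: int = 4
    rare_tag_freq: float = 0.003
    tag_on_founder_prob: float = 1.0
    tag_window_bp: int = 1_000_000
    genotype_error_rate: float = 0.0
    background_mode: str = "independent"  # or "mosaic"
    mosaic_pool_size: int = 50
    mosaic_switch_prob: float = 0.05

    def validate(self) -> None:
        if self.generations < 1:
            raise SimConfigError("generations must be >= 1")
        if not (self.region_start <= self.focal_pos < self.region_end):
            raise SimConfigError("focal position must lie inside the region")
        lo, hi = self.common_freq_range
        if not (0 < lo <= hi < 1):
            raise SimConfigError("common frequencies must be inside (0,1)")
        if not 0 < self.rare_tag_freq < 1:
            raise SimConfigError("rare tag frequency must be inside (0,1)")
        if not 0 <= self.tag_on_founder_prob <= 1:
            raise SimConfigError("tag_on_founder_prob must be in [0,1]")
        if self.cm_per_mb < 0:
            raise SimConfigError("cM/Mb rate must be >= 0")
        if self.background_mode not in ("independent", "mosaic"):
            raise SimConfigError(f"unknown mode {self.background_mode!r}")
        if self.n_carriers < 1 or self.n_background < 0:
            raise SimConfigError("need >= 1 carrier and >= 0 background")

    @property
    def focal(self) -> VariantRecord:
        return VariantRecord(
            self.chrom, self.focal_pos, self.focal_ref, self.focal_alt
        )


@dataclass
class FounderSimTruth:
    """Ground truth of one simulated cohort.

    ``segments`` are the carriers' true ancestral intervals in bp
    (truncated at the region edges, always containing the focal site);
    ``one_sided_morgans`` keeps the raw untruncated exponential draws per
    carrier so recombination-model checks are free of edge effects.
    """

    founder_alleles: np.ndarray
    segments: list[tuple[int, int]]
    one_sided_morgans: list[tuple[float, float]]
    tag_positions: list[int]
    carrier_ids: list[str]
    focal: VariantRecord
    seed: int
    config: FounderSimConfig

    def to_json(self, path: str) -> None:
        payload = {
            "seed": self.seed,
            "focal": self.focal.vcf_id,
            "carrier_ids": self.carrier_ids,
            "segments": [[int(a), int(b)] for a, b in self.segments],
            "one_sided_morgans": [
                [float(l), float(r)] for l, r in self.one_sided_morgans
            ],
            "tag_positions": [int(p) for p in self.tag_positions],
            "founder_alleles": self.founder_alleles.astype(int).tolist(),
            "config": asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    def segment_intersection(self) -> tuple[int, int]:
        return (
            max(a for a, _ in self.segments),
            min(b for _, b in self.segments),
        )


def _draw_positions(
    rng: np.random.Generator, n: int, lo: int, hi: int, taken: set[int]
) -> np.ndarray:
    """n distinct positions in [lo, hi), avoiding ``taken``."""
    out: set[int] = set()
    while len(out) < n:
        draw = rng.integers(lo, hi, size=n - len(out))
        out.update(int(p) for p in draw if int(p) not in taken)
    return np.array(sorted(out), dtype=np.int64)


class _BackgroundDrawer:
    """Draws one background haplotype; independent sites or pool mosaic."""

    def __init__(
        self, config: FounderSimConfig, freqs: np.ndarray, rng: np.random.Generator
    ):
        self.freqs = freqs
        self.rng = rng
        self.pool: np.ndarray | None = None
        if config.background_mode == "mosaic":
            self.pool = (
                rng.random((config.mosaic_pool_size, freqs.size)) < freqs
            ).astype(np.int8)
            self.switch = config.mosaic_switch_prob

    def __call__(self) -> np.ndarray:
        if self.pool is None:
            return (self.rng.random(self.freqs.size) < self.freqs).astype(np.int8)
        m = self.pool.shape[0]
        switches = self.rng.random(self.freqs.size) < self.switch
        switches[0] = True
        choice = self.rng.integers(0, m, size=self.freqs.size)
        donor = np.maximum.accumulate(
            np.where(switches, np.arange(self.freqs.size), -1)
        )
        return self.pool[choice[donor], np.arange(self.freqs.size)]


def simulate_founder_cohort(
    config: FounderSimConfig, seed: int
) -> tuple[HaplotypeMatrix, FounderSimTruth]:
    """Simulate a phased cohort of carriers plus background samples.

    Carriers are listed first in the matrix (``carrier_01`` ...), each
    heterozygous for the focal variant on haplotype 0; the focal haplotype
    equals the founder haplotype inside the carrier's ancestral segment
    and fresh background draws outside it.  Genotyping errors (if enabled)
    flip non-focal alleles independently at the configured rate.
    """
    config.validate()
    rng = np.random.default_rng(seed)

    # --- site map -------------------------------------------------------
    taken = {config.focal_pos}
    tag_lo = max(config.region_start, config.focal_pos - config.tag_window_bp // 2)
    tag_hi = min(config.region_end, config.focal_pos + config.tag_window_bp // 2)
    tag_pos = _draw_positions(rng, config.n_rare_tags, tag_lo, tag_hi, taken)
    taken.update(int(p) for p in tag_pos)
    common_pos = _draw_positions(
        rng, config.n_common_sites, config.region_start, config.region_end, taken
    )

    positions = np.concatenate(([config.focal_pos], tag_pos, common_pos))
    kind = np.concatenate(
        (
            ["focal"],
            ["tag"] * len(tag_pos),
            ["common"] * len(common_pos),
        )
    )
    order = np.argsort(positions, kind="stable")
    positions, kind = positions[order], kind[order]
    m = positions.size
    focal_j = int(np.flatnonzero(kind == "focal")[0])

    lo, hi = config.common_freq_range
    freqs = np.where(
        kind == "common",
        rng.uniform(lo, hi, size=m),
        np.where(kind == "tag", config.rare_tag_freq, 0.0),
    )

    # --- founder haplotype ---------------------------------------------
    founder = (rng.random(m) < freqs).astype(np.int8)
    tag_mask = kind == "tag"
    rides = rng.random(int(tag_mask.sum())) < config.tag_on_founder_prob
    founder[tag_mask] = np.where(rides, 1, founder[tag_mask]).astype(np.int8)
    founder[focal_j] = 1

    draw_background = _BackgroundDrawer(config, freqs, rng)
    bp_per_morgan = 100.0 / config.cm_per_mb * 1e6 if config.cm_per_mb > 0 else None

    # --- carriers -------------------------------------------------------
    n_car = config.n_carriers
    carrier_ids = [f"carrier_{i + 1:02d}" for i in range(n_car)]
    rows: list[np.ndarray] = []
    segments: list[tuple[int, int]] = []
    morgans: list[tuple[float, float]] = []
    for _ in range(n_car):
        left_m = rng.exponential(1.0 / config.generations)
        right_m = rng.exponential(1.0 / config.generations)
        morgans.append((left_m, right_m))
        if bp_per_morgan is None:  # cM/Mb = 0: no recombination at all
            a, b = config.region_start, config.region_end - 1
        else:
            a = max(config.region_start, int(config.focal_pos - left_m * bp_per_morgan))
            b = min(config.region_end - 1, int(config.focal_pos + right_m * bp_per_morgan))
        segments.append((a, b))
        inside = (positions >= a) & (positions <= b)
        focal_hap = np.where(inside, founder, draw_background()).astype(np.int8)
        other_hap = draw_background()
        other_hap[focal_j] = 0
        rows.append(focal_hap)
        rows.append(other_hap)

    # --- background samples --------------------------------------------
    background_ids = [f"bg_{i + 1:04d}" for i in range(config.n_background)]
    for _ in range(config.n_background):
        for _k in range(2):
            hap = draw_background()
            hap[focal_j] = 0
            rows.append(hap)

    alleles = np.stack(rows, axis=0)
    if config.genotype_error_rate > 0:
        flip = rng.random(alleles.shape) < config.genotype_error_rate
        flip[:, focal_j] = False  # focal genotype assumed validated
        alleles = np.where(flip, 1 - alleles, alleles).astype(np.int8)

    ref_alt = [
        (config.focal_ref, config.focal_alt) if kind[j] == "focal" else ("A", "C")
        for j in range(m)
    ]
    sites = []
    for j in range(m):
        alt_freq, miss = _site_stats(alleles[:, j])
        sites.append(
            Site(config.chrom, int(positions[j]), ref_alt[j][0], ref_alt[j][1], alt_freq, miss)
        )
    matrix = HaplotypeMatrix(
        samples=carrier_ids + background_ids, alleles=alleles, sites=sites
    )
    truth = FounderSimTruth(
        founder_alleles=founder,
        segments=segments,
        one_sided_morgans=morgans,
        tag_positions=[int(p) for p in positions[kind == "tag"]],
        carrier_ids=carrier_ids,
        focal=config.focal,
        seed=seed,
        config=config,
    )
    return matrix, truth


@dataclass
class ClinicalSimConfig:
    """Phenotype generator settings.

    Carrier defaults emulate an autosomal-dominant tubulointerstitial
    nephropathy cohort: kidney-failure ages Normal(52, 10) truncated to
    [30, 80], raised blood pressure, reduced kidney function (higher
    creatinine), no excess gout, and serum urate indistinguishable from
    background.  ``carrier_effect`` scales every carrier shift; at 0 the
    carriers are drawn from the background model exactly (null for
    type-I-error checks).
    """

    failure_age_mean: float = 52.0
    failure_age_sd: float = 10.0
    failure_age_bounds: tuple[float, float] = (30.0, 80.0)
    background_event_hazard: float = 0.0015  # per year of adult life
    censor_age_range: tuple[float, float] = (40.0, 85.0)
    sbp_background: tuple[float, float] = (144.2, 24.1)
    dbp_background: tuple[float, float] = (86.4, 13.5)
    sbp_carrier_shift: float = 19.4
    dbp_carrier_shift: float = 12.9
    creatinine_log_mean: float = -0.12  # ~0.89 mg/dL background median
    creatinine_log_sd: float = 0.18
    creatinine_carrier_log_shift: float = 0.28
    acr_log_mean: float = 0.2  # mg/mmol
    acr_log_sd: float = 0.8
    acr_carrier_log_shift: float = 0.5
    urate_mean: float = 309.0
    urate_sd: float = 80.0
    male_fraction: float = 0.543
    gout_background_rate: float = 0.021


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    out = np.empty(size)
    done = 0
    while done < size:
        draw = rng.normal(mean, sd, size=size - done)
        keep = draw[(draw >= lo) & (draw <= hi)]
        out[done : done + keep.size] = keep
        done += keep.size
    return out


def simulate_clinical(
    n: int,
    n_carriers: int,
    seed: int,
    carrier_effect: float = 1.0,
    config: ClinicalSimConfig | None = None,
    carrier_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate a per-sample phenotype table with a renal-survival endpoint.

    Returns a frame with columns sample, carrier, sex, age (years at renal
    replacement therapy or censoring), event, creatinine_mg_dl, acr, sbp,
    dbp, urate, gout.  The first ``n_carriers`` samples are carriers (IDs
    can be supplied to match a genotype simulation).
    """
    if n < 1 or not 0 <= n_carriers <= n:
        raise SimConfigError("need 1 <= n and 0 <= n_carriers <= n")
    cfg = config or ClinicalSimConfig()
    rng = np.random.default_rng(seed)
    carrier = np.zeros(n, dtype=bool)
    carrier[:n_carriers] = True
    eff = float(carrier_effect)

    sex = np.where(rng.random(n) < cfg.male_fraction, "male", "female")
    censor_age = rng.uniform(*cfg.censor_age_range, size=n)
    # Background event model: constant low hazard from age 20.
    bg_event_age = 20.0 + rng.exponential(
        1.0 / cfg.background_event_hazard, size=n
    )
    failure_age = _truncated_normal(
        rng,
        cfg.failure_age_mean,
        cfg.failure_age_sd,
        *cfg.failure_age_bounds,
        size=n,
    )
    event_age = np.where(carrier & (eff > 0), failure_age, bg_event_age)
    event = event_age <= censor_age
    time = np.where(event, event_age, censor_age)

    shift = np.where(carrier, eff, 0.0)
    sbp = rng.normal(*cfg.sbp_background, size=n) + shift * cfg.sbp_carrier_shift
    dbp = rng.normal(*cfg.dbp_background, size=n) + shift * cfg.dbp_carrier_shift
    creat = np.exp(
        rng.normal(cfg.creatinine_log_mean, cfg.creatinine_log_sd, size=n)
        + shift * cfg.creatinine_carrier_log_shift
    )
    acr = np.exp(
        rng.normal(cfg.acr_log_mean, cfg.acr_log_sd, size=n)
        + shift * cfg.acr_carrier_log_shift
    )
    urate = rng.normal(cfg.urate_mean, cfg.urate_sd, size=n)
    gout_rate = np.where(carrier & (eff > 0), 0.0, cfg.gout_background_rate)
    gout = rng.random(n) < gout_rate

    if carrier_ids is not None and len(carrier_ids) != n_carriers:
        raise SimConfigError("carrier_ids length must equal n_carriers")
    ids = list(carrier_ids) if carrier_ids else [
        f"carrier_{i + 1:02d}" for i in range(n_carriers)
    ]
    ids += [f"bg_{i + 1:04d}" for i in range(n - n_carriers)]

    return pd.DataFrame(
        {
            "sample": ids,
            "carrier": carrier.astype(int),
            "sex": sex,
            "age": np.round(time, 4),
            "event": event.astype(int),
            "creatinine_mg_dl": np.round(creat, 4),
            "acr": np.round(acr, 4),
            "sbp": np.round(sbp, 2),
            "dbp": np.round(dbp, 2),
            "urate": np.round(urate, 2),
            "gout": gout.astype(int),
        }
    )


def write_pheno_tsv(pheno: pd.DataFrame, path: str) -> None:
    pheno.to_csv(path, sep="\t", index=False)
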