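"""Synthetic tumour cohorts, expression matrices and siRNA screens.

The generator emulates the statistical structure that the amplicon-driver
analysis assumes, so every downstream stage is testable without external
data:

* a BAC-style tiling of a reduced genome with clone-level log2 ratios that
  are piecewise-constant per sample (0 for diploid, a per-event gain
  amplitude, and a per-event amplification amplitude inside a planted
  recurrent amplicon) plus Gaussian probe noise, isolated outlier spikes
  and germline-polymorphic clones with sample-random shifts;
* clinical annotations (grade, ER, PR, HER2, subtype) in which the planted
  amplification is enriched in grade III / ER-negative samples via
  logistic weighting of the amplification probability;
* gene expression where planted driver genes respond linearly to their
  true copy-number value and all other genes are independent of copy
  number, with detection P-values marking a configurable undetected set;
* an siRNA viability screen over a small cell-line panel in which driver
  siRNAs are lethal only in amplified lines (with a configurable number of
  effective pool oligos, plus an optional off-target decoy whose pool is
  lethal but only one oligo validates), and dose-response curves with
  lower true SF50 in amplified lines for a CDK2-inhibitor analogue.

All randomness flows from one seeded generator with spawned sub-streams
per data product, so identical seed + config gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = ["SimConfig", "SimTruth", "ScreenTruth", "CohortData", "draw_clinical",
           "simulate_cohort", "simulate_screen"]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_chrom_sizes() -> dict[str, int]:
    # reduced genome: the amplicon chromosome at its real length plus seven
    # 35 Mb autosome stand-ins, tiled at the same ~150 kb clone spacing
    sizes = {f"chr{c}": 35_000_000 for c in (1, 3, 5, 8, 11, 13, 17)}
    sizes["chr19"] = 59_130_000
    return sizes


def _default_amplicon() -> list[tuple[str, int, int]]:
    # emulates a 5.1 Mb recurrent amplicon at 27.8-32.9 Mb on one chromosome
    return [("chr19", 27_800_000, 32_900_000)]


def _default_odds() -> dict[str, float]:
    return {"grade3": 20.0, "er_neg": 5.5}


@dataclass
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults reproduce the cohort scale of the analysis this package
    implements: 313 samples, a 16/313 amplification prevalence enriched in
    grade III / ER-negative tumours, amplification amplitudes well above
    the 0.45 log2 threshold, gains in the 0.08-0.45 band, and a clone count
    scaled to 2,000 (the full-genome platform had ~31,367 clones; the
    reduced genome keeps the same probe spacing regime).
    """

    n_samples: int = 313
    n_clones: int = 2_000
    chrom_sizes: dict[str, int] = field(default_factory=_default_chrom_sizes)
    amplicon_intervals: list[tuple[str, int, int]] = field(default_factory=_default_amplicon)
    amplicon_prevalence: float = 16 / 313
    amp_log2: tuple[float, float] = (0.6, 1.2)
    gain_log2: tuple[float, float] = (0.1, 0.4)
    noise_sd: float = 0.12
    outlier_rate: float = 0.005
    outlier_magnitude: tuple[float, float] = (1.5, 3.0)
    polymorphic_fraction: float = 0.01
    polymorphic_shift: tuple[float, float] = (0.2, 0.6)
    n_background_gains: int = 2
    n_background_losses: int = 1
    grade3_rate: float = 204 / 313
    er_neg_rate: float = 144 / 313
    her2_pos_rate: float = 64 / 313
    enrichment_odds: dict[str, float] = field(default_factory=_default_odds)
    # expression
    n_genes: int = 120
    n_amplicon_genes: int = 9
    n_driver_genes: int = 6
    n_undetected_genes: int = 1
    driver_beta: float = 4.0
    expression_noise_sd: float = 1.0
    baseline_range: tuple[float, float] = (6.0, 10.0)
    # screen
    n_cell_lines: int = 8
    n_amplified_lines: int = 2
    screen_replicates: int = 3
    screen_cv: float = 0.1
    driver_kill: float = 0.6
    plk1_kill: float = 0.8
    n_effective_oligos: int = 3
    include_decoy: bool = False
    # dose-response
    drug: str = "AZD5438"
    doses: tuple[float, ...] = (1e-4, 1e-5, 1e-6, 1e-7, 1e-8, 1e-9)
    sf50_amplified: float = 5e-8
    sf50_not_amplified: float = 2e-6
    dr_hill: float = 1.0
    dr_top: float = 1.0
    dr_bottom: float = 0.02
    dr_noise_sd: float = 0.05
    dr_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("amplicon_prevalence", "outlier_rate", "polymorphic_fraction",
                     "grade3_rate", "er_neg_rate", "her2_pos_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("amp_log2", "gain_log2", "outlier_magnitude", "polymorphic_shift"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigError(f"{name} must be a positive (low, high) range")
        if self.noise_sd < 0 or self.expression_noise_sd < 0:
            raise ConfigError("noise sds must be non-negative")
        self.amplicon_intervals = [tuple(iv) for iv in self.amplicon_intervals]
        for chrom, start, end in self.amplicon_intervals:
            if chrom not in self.chrom_sizes:
                raise ConfigError(f"amplicon chromosome {chrom} not in chrom_sizes")
            if not (0 <= start < end <= self.chrom_sizes[chrom]):
                raise ConfigError(
                    f"amplicon interval {chrom}:{start}-{end} outside the declared chromosome"
                )
        if self.n_driver_genes + self.n_undetected_genes > self.n_amplicon_genes:
            raise ConfigError("drivers + undetected genes exceed amplicon gene count")
        if self.n_amplified_lines < 1 or self.n_cell_lines - self.n_amplified_lines < 1:
            raise ConfigError("need >= 1 amplified and >= 1 non-amplified cell line")
        if self.screen_replicates < 2 or self.dr_replicates < 2:
            raise ConfigError("need >= 2 replicate wells per condition")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["amplicon_intervals"] = [list(iv) for iv in self.amplicon_intervals]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("amp_log2", "gain_log2", "outlier_magnitude", "polymorphic_shift",
                    "baseline_range", "doses"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "amplicon_intervals" in d:
            d["amplicon_intervals"] = [tuple(iv) for iv in d["amplicon_intervals"]]
        return cls(**d)


@dataclass
class SimTruth:
    """Ground truth aligned 1:1 with the emitted cohort tables."""

    sample_amplified: pd.Series  # bool per sample
    clone_values: pd.DataFrame  # true (noise-free) clone x sample log2 means
    polymorphic_clones: list[str]
    outlier_mask: pd.DataFrame  # bool clone x sample, planted spikes
    genes: pd.DataFrame  # symbol, chrom, start, end, driver, beta, undetected
    amp_amplitudes: pd.Series  # drawn amplification amplitude per amplified sample


@dataclass
class ScreenTruth:
    cell_line_amplified: dict[str, bool]
    driver_genes: list[str]
    decoy_gene: str | None
    expected_survival: pd.DataFrame  # cell_line x target expected pool survival
    sf50_true: dict[str, float]  # per cell line (single drug)


@dataclass
class CohortData:
    clone_table: pd.DataFrame
    expression: pd.DataFrame
    detection_p: pd.DataFrame
    annotations: pd.DataFrame
    genes: pd.DataFrame
    truth: SimTruth


# ---------------------------------------------------------------------------


def _tile_genome(config: SimConfig) -> pd.DataFrame:
    """Evenly tile each chromosome with clones, proportional to its size."""
    sizes = config.chrom_sizes
    total = sum(sizes.values())
    alloc = {c: int(config.n_clones * s / total) for c, s in sizes.items()}
    short = config.n_clones - sum(alloc.values())
    for c in list(sizes)[:short]:
        alloc[c] += 1
    rows = []
    i = 0
    for chrom, size in sizes.items():
        n = alloc[chrom]
        spacing = size / n
        # tiling-path array: clones abut, leaving no uncovered gaps
        for k in range(n):
            start = int(k * spacing)
            end = int((k + 1) * spacing) if k < n - 1 else size
            rows.append((f"CL{i:05d}", chrom, start, end))
            i += 1
    return pd.DataFrame(rows, columns=["clone_id", "chrom", "start", "end"])


def draw_clinical(
    config: SimConfig, rng: np.random.Generator, n: int | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw clinical annotations and amplification flags for n samples.

    The amplification probability is a logistic function of grade III and
    ER-negative status with the configured enrichment odds; the intercept
    is calibrated so the marginal probability over the drawn covariates
    equals ``amplicon_prevalence``.
    """
    n = config.n_samples if n is None else n
    samples = [f"S{i:04d}" for i in range(n)]
    grade3 = rng.random(n) < config.grade3_rate
    er_neg = rng.random(n) < config.er_neg_rate
    her2_pos = rng.random(n) < config.her2_pos_rate
    pr_pos = np.where(er_neg, rng.random(n) < 0.15, rng.random(n) < 0.85)
    subtype = np.where(her2_pos, "HER2", np.where(er_neg, "ER-/HER2-", "ER+/HER2-"))

    prev = config.amplicon_prevalence
    if prev <= 0.0:
        p = np.zeros(n)
    elif prev >= 1.0:
        p = np.ones(n)
    else:
        lin = (
            np.log(config.enrichment_odds.get("grade3", 1.0)) * grade3
            + np.log(config.enrichment_odds.get("er_neg", 1.0)) * er_neg
        )
        b0 = brentq(lambda b: expit(b + lin).mean() - prev, -30.0, 30.0, xtol=1e-12)
        p = expit(b0 + lin)
    amplified = rng.random(n) < p

    annotations = pd.DataFrame(
        {
            "sample_id": samples,
            "grade": np.where(grade3, "III", "I/II"),
            "er": np.where(er_neg, "negative", "positive"),
            "pr": np.where(pr_pos, "positive", "negative"),
            "her2": np.where(her2_pos, "positive", "negative"),
            "subtype": subtype,
        }
    ).set_index("sample_id")
    return annotations, pd.Series(amplified, index=samples, name="amplified")


def _plant_genes(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Gene annotations: amplicon genes inside the first planted interval,
    the rest spread over the remaining genome."""
    chrom0, a_start, a_end = config.amplicon_intervals[0]
    rows = []
    na = config.n_amplicon_genes
    span = a_end - a_start
    for k in range(na):
        glen = int(rng.integers(8_000, 80_000))
        centre = a_start + int((k + 0.5) * span / na)
        rows.append((f"AMPG{k + 1}", chrom0, centre - glen // 2, centre + glen // 2))
    n_bg = config.n_genes - na
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    for k in range(n_bg):
        ci = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
        chrom = chroms[ci]
        glen = int(rng.integers(8_000, 80_000))
        while True:
            start = int(rng.integers(0, config.chrom_sizes[chrom] - glen))
            inside = any(
                c == chrom and start < e and start + glen > s
                for c, s, e in config.amplicon_intervals
            )
            if not inside:
                break
        rows.append((f"GENE{k:04d}", chrom, start, start + glen))
    genes = pd.DataFrame(rows, columns=["symbol", "chrom", "start", "end"])
    driver = np.zeros(len(genes), dtype=bool)
    driver[: config.n_driver_genes] = True  # first amplicon genes are drivers
    undetected = np.zeros(len(genes), dtype=bool)
    undetected[na - config.n_undetected_genes : na] = True
    genes["amplicon"] = np.arange(len(genes)) < na
    genes["driver"] = driver
    genes["beta"] = np.where(driver, config.driver_beta, 0.0)
    genes["undetected"] = undetected
    return genes


def _gene_true_cn(genes: pd.DataFrame, clones: pd.DataFrame, true_vals: np.ndarray) -> np.ndarray:
    """Median true clone value over clones overlapping each gene (genes x samples)."""
    out = np.zeros((len(genes), true_vals.shape[1]))
    chroms = clones["chrom"].to_numpy()
    starts = clones["start"].to_numpy()
    ends = clones["end"].to_numpy()
    for gi, g in enumerate(genes.itertuples(index=False)):
        hit = (chroms == g.chrom) & (starts < g.end) & (ends > g.start)
        if hit.any():
            out[gi] = np.median(true_vals[hit], axis=0)
    return out


def simulate_cohort(config: SimConfig) -> CohortData:
    """Generate the full synthetic tumour cohort.

    Returns the clone log2-ratio table (clone metadata + one column per
    sample), the expression and detection-P matrices (gene x sample), the
    clinical annotation table, the gene annotations, and the ground truth.
    """
    root = np.random.default_rng(config.seed)
    rng_clin, rng_cnv, rng_noise, rng_expr, _rng_screen = root.spawn(5)

    clones = _tile_genome(config)
    n_clones = len(clones)
    annotations, amplified = draw_clinical(config, rng_clin)
    samples = list(annotations.index)
    n = len(samples)

    chroms = clones["chrom"].to_numpy()
    cstart = clones["start"].to_numpy()
    cend = clones["end"].to_numpy()

    true_vals = np.zeros((n_clones, n))
    amp_amplitude = pd.Series(np.nan, index=samples)
    amp_flags = amplified.to_numpy()
    for si in np.flatnonzero(amp_flags):
        amp = float(rng_cnv.uniform(*config.amp_log2))
        amp_amplitude.iloc[si] = amp
        for chrom, s, e in config.amplicon_intervals:
            hit = (chroms == chrom) & (cstart < e) & (cend > s)
            true_vals[hit, si] = amp

    # background gains and losses: piecewise-constant events per sample
    for si in range(n):
        for kind, count in (("gain", config.n_background_gains), ("loss", config.n_background_losses)):
            for _ in range(count):
                first = int(rng_cnv.integers(0, n_clones))
                length = int(rng_cnv.integers(2, 21))
                idx = np.arange(first, min(first + length, n_clones))
                idx = idx[chroms[idx] == chroms[first]]  # stay on one chromosome
                amp = float(rng_cnv.uniform(*config.gain_log2))
                if kind == "loss":
                    amp = -amp
                free = idx[true_vals[idx, si] == 0.0]  # never overwrite the amplicon
                true_vals[free, si] = amp

    # polymorphic clones: sample-random +- shift, listed in a sidecar
    eligible = np.ones(n_clones, dtype=bool)
    for chrom, s, e in config.amplicon_intervals:
        eligible &= ~((chroms == chrom) & (cstart < e) & (cend > s))
    n_poly = int(round(config.polymorphic_fraction * n_clones))
    poly_idx = rng_cnv.choice(np.flatnonzero(eligible), size=n_poly, replace=False) if n_poly else np.array([], dtype=int)
    poly_idx.sort()
    poly_shift = np.zeros((n_clones, n))
    if n_poly:
        signs = rng_cnv.choice([-1.0, 1.0], size=(n_poly, n))
        mags = rng_cnv.uniform(*config.polymorphic_shift, size=(n_poly, n))
        poly_shift[poly_idx] = signs * mags

    noise = rng_noise.normal(0.0, config.noise_sd, size=(n_clones, n)) if config.noise_sd > 0 else 0.0
    spike_mask = rng_noise.random((n_clones, n)) < config.outlier_rate
    spikes = np.zeros((n_clones, n))
    if spike_mask.any():
        k = int(spike_mask.sum())
        spikes[spike_mask] = (
            rng_noise.choice([-1.0, 1.0], size=k) * rng_noise.uniform(*config.outlier_magnitude, size=k)
        )

    ratios = true_vals + poly_shift + noise + spikes
    clone_table = pd.concat(
        [clones, pd.DataFrame(ratios, columns=samples, index=clones.index)], axis=1
    )

    # expression
    genes = _plant_genes(config, rng_expr)
    gene_cn_true = _gene_true_cn(genes, clones, true_vals)
    baseline = rng_expr.uniform(*config.baseline_range, size=len(genes))
    expr = (
        baseline[:, None]
        + genes["beta"].to_numpy()[:, None] * gene_cn_true
        + rng_expr.normal(0.0, config.expression_noise_sd, size=(len(genes), n))
    )
    detp = rng_expr.uniform(0.0, 0.005, size=(len(genes), n))
    undet = genes["undetected"].to_numpy()
    detp[undet] = rng_expr.uniform(0.02, 1.0, size=(int(undet.sum()), n))
    expression = pd.DataFrame(expr, index=genes["symbol"], columns=samples)
    detection_p = pd.DataFrame(detp, index=genes["symbol"], columns=samples)

    truth = SimTruth(
        sample_amplified=amplified,
        clone_values=pd.DataFrame(true_vals, index=clones["clone_id"], columns=samples),
        polymorphic_clones=list(clones["clone_id"].iloc[poly_idx]),
        outlier_mask=pd.DataFrame(spike_mask, index=clones["clone_id"], columns=samples),
        genes=genes,
        amp_amplitudes=amp_amplitude,
    )
    return CohortData(
        clone_table=clone_table,
        expression=expression,
        detection_p=detection_p,
        annotations=annotations,
        genes=genes,
        truth=truth,
    )


# ---------------------------------------------------------------------------


def simulate_screen(
    config: SimConfig,
    genes: pd.DataFrame | None = None,
    cell_lines: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, ScreenTruth]:
    """Generate the siRNA screen and dose-response tables.

    ``genes`` defaults to the planted amplicon gene table (symbol + driver
    flag).  Per well, viability = line base luminescence x survival effect
    x (1 + N(0, cv)).  Driver-gene siRNAs reduce survival only in
    amplified lines (pool and the first ``n_effective_oligos`` oligos);
    PLK1 is lethal everywhere; siCON has effect 1.  The optional decoy is
    a non-driver whose pool is lethal in amplified lines but only one
    oligo is effective, so deconvolution must reject it.
    """
    root = np.random.default_rng(config.seed)
    _c, _v, _n, _e, rng = root.spawn(5)

    if genes is None:
        names = [f"AMPG{k + 1}" for k in range(config.n_amplicon_genes)]
        driver = [k < config.n_driver_genes for k in range(config.n_amplicon_genes)]
        genes = pd.DataFrame({"symbol": names, "driver": driver})
    elif "amplicon" in genes.columns:
        # only the genes mapping to the amplicon are taken into the screen
        genes = genes.loc[genes["amplicon"]].reset_index(drop=True)
    if cell_lines is None:
        cell_lines = [f"LINE_A{i + 1}" for i in range(config.n_amplified_lines)] + [
            f"LINE_N{i + 1}" for i in range(config.n_cell_lines - config.n_amplified_lines)
        ]
    amplified = {
        line: i < config.n_amplified_lines for i, line in enumerate(cell_lines)
    }
    if not any(amplified.values()) or all(amplified.values()):
        raise ConfigError("need >= 1 amplified and >= 1 non-amplified cell line")

    drivers = list(genes.loc[genes["driver"], "symbol"])
    non_drivers = list(genes.loc[~genes["driver"], "symbol"])
    decoy = non_drivers[0] if (config.include_decoy and non_drivers) else None

    def effect(target: str, oligo: str, line_amp: bool) -> float:
        if target in ("siCON1", "siCON2"):
            return 1.0
        if target == "PLK1":
            return 1.0 - config.plk1_kill
        if not line_amp:
            return 1.0
        if target in drivers:
            if oligo == "pool" or (oligo.isdigit() and int(oligo) <= config.n_effective_oligos):
                return 1.0 - config.driver_kill
            return 1.0
        if decoy is not None and target == decoy:
            if oligo == "pool" or oligo == "1":
                return 1.0 - 0.8 * config.driver_kill
            return 1.0
        return 1.0

    base = {line: float(rng.uniform(8e4, 1.2e5)) for line in cell_lines}
    rows = []
    targets = list(genes["symbol"]) + ["PLK1", "siCON1", "siCON2"]
    for line in cell_lines:
        for target in targets:
            oligos = ["pool", "1", "2", "3", "4"] if target in set(genes["symbol"]) else ["pool"]
            for oligo in oligos:
                eff = effect(target, oligo, amplified[line])
                for rep in range(1, config.screen_replicates + 1):
                    mult = 1.0 + (rng.normal(0.0, config.screen_cv) if config.screen_cv > 0 else 0.0)
                    rows.append(
                        dict(cell_line=line, target=target, oligo=oligo, replicate=rep,
                             luminescence=max(base[line] * eff * mult, 1.0))
                    )
    screen = pd.DataFrame(rows)

    exp_surv = pd.DataFrame(
        [[effect(t, "pool", amplified[l]) for t in targets] for l in cell_lines],
        index=cell_lines, columns=targets,
    )

    dr_rows = []
    sf50_true = {}
    # absolute-50% survival dose of the true curve (differs from the midpoint
    # whenever bottom > 0 or top != 1)
    ratio = (config.dr_top - config.dr_bottom) / (0.5 - config.dr_bottom) - 1.0
    for line in cell_lines:
        mid = config.sf50_amplified if amplified[line] else config.sf50_not_amplified
        sf50_true[line] = mid * ratio ** (1.0 / config.dr_hill)
        for dose in config.doses:
            mean = config.dr_bottom + (config.dr_top - config.dr_bottom) / (
                1.0 + 10.0 ** (config.dr_hill * (np.log10(dose) - np.log10(mid)))
            )
            for rep in range(1, config.dr_replicates + 1):
                obs = mean + (rng.normal(0.0, config.dr_noise_sd) if config.dr_noise_sd > 0 else 0.0)
                dr_rows.append(
                    dict(cell_line=line, drug=config.drug, dose_M=dose, replicate=rep,
                         viability=max(obs, 0.0))
                )
    dose_response = pd.DataFrame(dr_rows)

    truth = ScreenTruth(
        cell_line_amplified=amplified,
        driver_genes=drivers,
        decoy_gene=decoy,
        expected_survival=exp_surv,
        sf50_true=sf50_true,
    )
    return screen, dose_response, truth
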