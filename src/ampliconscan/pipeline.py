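"""End-to-end pipeline: preprocess -> segment -> call states -> regions ->
integrate -> associate -> screen.

``analyze_cohort`` is the in-memory engine; ``run_pipeline`` is the
file-oriented wrapper that reads a :class:`PipelineConfig`, writes every
stage output (TSV/BED/JSON) plus a run manifest, and logs clone/sample
counts after each filter so the platform-style bookkeeping ("N clones
after polymorphic filtering") is reproducible.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as asio
from .association import AssociationResult, chi_square, collapse_levels, crosstab, fisher_exact_2x2
from .integration import detection_filter, gene_cn, overexpressed_when_amplified
from .screen import fit_sf50, selective_lethality, survival_fractions, welch_t
from .segmentation import CbsParams, segment_cohort
from .states import (
    STATE_CODES,
    AMPLIFICATION,
    StateThresholds,
    call_states,
    recurrent_cores,
    sample_amplified_intervals,
    smallest_region_of_amplification,
)

logger = logging.getLogger("ampliconscan")

__all__ = ["PipelineConfig", "CohortResults", "parse_locus", "analyze_cohort",
           "table1_associations", "analyze_screen", "analyze_dose_response",
           "run_pipeline"]


def parse_locus(locus: str) -> tuple[str, int, int]:
    """Parse "chrom:start-end" (bp, 0-based half-open)."""
    try:
        chrom, span = locus.split(":")
        start, end = (int(x.replace(",", "")) for x in span.split("-"))
    except ValueError as exc:
        raise ValueError(f"cannot parse locus {locus!r}; expected chrom:start-end") from exc
    if start >= end:
        raise ValueError(f"locus start must be < end in {locus!r}")
    return chrom, start, end


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; round-trips through YAML."""

    clone_table: str
    outdir: str = "ampliconscan_out"
    polymorphic: str | None = None
    genes_bed: str | None = None
    expression: str | None = None
    detection_p: str | None = None
    annotations: str | None = None
    screen: str | None = None
    dose_response: str | None = None
    locus: str = "chr19:27800000-32900000"
    loss_below: float = -0.08
    gain_low: float = 0.08
    amp_above: float = 0.45
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 10_000
    cbs_min_width: int = 2
    outlier_k: float = 3.0
    integration_alpha: float = 0.05
    screen_alpha: float = 0.05
    amplified_lines: list[str] = field(default_factory=list)
    seed: int = 0

    def thresholds(self) -> StateThresholds:
        return StateThresholds(self.loss_below, self.gain_low, self.amp_above)

    def cbs_params(self) -> CbsParams:
        return CbsParams(self.cbs_alpha, self.cbs_n_perm, self.cbs_min_width, self.seed)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)


@dataclass
class CohortResults:
    smoothed: pd.DataFrame  # clone meta + per-sample smoothed values
    segments: pd.DataFrame
    states: pd.DataFrame  # clone x sample codes, indexed by clone_id
    clone_meta: pd.DataFrame
    amplified: pd.Series  # bool per sample: >= 1 amplified clone in the locus
    prevalence: float
    per_sample_regions: dict
    cores: list
    sra: object | None = None
    sra_genes: pd.DataFrame | None = None
    integration: pd.DataFrame | None = None
    association: pd.DataFrame | None = None


def analyze_cohort(
    clone_df: pd.DataFrame,
    locus: tuple[str, int, int],
    cbs: CbsParams = CbsParams(),
    thresholds: StateThresholds = StateThresholds(),
    outlier_k: float = 3.0,
    polymorphic: list[str] | None = None,
    genes: pd.DataFrame | None = None,
    expression: pd.DataFrame | None = None,
    detection_p: pd.DataFrame | None = None,
    annotations: pd.DataFrame | None = None,
    integration_alpha: float = 0.05,
) -> CohortResults:
    """Run segmentation, state calling, region detection and (optionally)
    expression integration and clinical association on one cohort."""
    samples = [c for c in clone_df.columns if c not in ("clone_id", "chrom", "start", "end")]
    logger.info("cohort: %d clones x %d samples", len(clone_df), len(samples))
    smoothed, seg_df, _profiles = segment_cohort(
        clone_df, samples, cbs, outlier_k=outlier_k, polymorphic=polymorphic
    )
    logger.info("segmentation: %d clones retained, %d segments", len(smoothed), len(seg_df))

    clone_meta = smoothed[["clone_id", "chrom", "start", "end"]]
    states = call_states(smoothed[samples], thresholds)
    states.index = pd.Index(clone_meta["clone_id"], name="clone_id")

    chrom, lstart, lend = locus
    in_locus = (
        (clone_meta["chrom"] == chrom)
        & (clone_meta["start"] < lend)
        & (clone_meta["end"] > lstart)
    ).to_numpy()
    amp_code = STATE_CODES[AMPLIFICATION]
    amplified = pd.Series(
        (states.to_numpy()[in_locus] == amp_code).any(axis=0), index=samples, name="amplified"
    )
    prevalence = float(amplified.mean())
    logger.info("locus %s:%d-%d amplified in %d/%d samples (%.1f%%)",
                chrom, lstart, lend, int(amplified.sum()), len(samples), 100 * prevalence)

    per_sample_regions = {
        s: sample_amplified_intervals(clone_meta, states[s].to_numpy(), s) for s in samples
    }
    cores = recurrent_cores(clone_meta, states)
    sra = sra_genes = None
    if amplified.any():
        amp_regions = {s: r for s, r in per_sample_regions.items() if amplified[s]}
        sra, sra_genes = smallest_region_of_amplification(amp_regions, locus, genes, cores)

    integration = None
    if genes is not None and expression is not None:
        if detection_p is not None:
            expression = detection_filter(expression, detection_p)
            logger.info("detection filter: %d probes retained", len(expression))
        cn_vals, cn_states = gene_cn(smoothed, genes, thresholds)
        integration = overexpressed_when_amplified(cn_vals, cn_states, expression, integration_alpha)
        logger.info("integration: %d genes tested, %d overexpressed-when-amplified",
                    int(integration["tested"].sum()),
                    int(integration["overexpressed_when_amplified"].sum()))

    association = None
    if annotations is not None:
        association = table1_associations(annotations, amplified)

    return CohortResults(
        smoothed=smoothed, segments=seg_df, states=states, clone_meta=clone_meta,
        amplified=amplified, prevalence=prevalence,
        per_sample_regions=per_sample_regions, cores=cores, sra=sra, sra_genes=sra_genes,
        integration=integration, association=association,
    )


_FACTORS = [
    ("grade", ["I/II", "III"], "fisher"),
    ("er", ["positive", "negative"], "fisher"),
    ("pr", ["positive", "negative"], "fisher"),
    ("her2", ["positive", "negative"], "fisher"),
    ("subtype", ["ER-/HER2-", "HER2", "ER+/HER2-"], "chi-square"),
]


def table1_associations(annotations: pd.DataFrame, amplified: pd.Series) -> pd.DataFrame:
    """Amplification vs clinical factors, in the layout of a cohort table.

    2-level factors use Fisher's exact test; the 3-level subtype uses the
    chi-square test, plus a Fisher test of ER-/HER2- vs the pooled other
    subtypes.  Output is tidy: one row per factor level with counts and
    the factor-level P.
    """
    rows = []
    for factor, levels, test in _FACTORS:
        if factor not in annotations.columns:
            continue
        present = [l for l in levels if (annotations[factor] == l).any()]
        if len(present) < 2:
            continue
        table = crosstab(annotations, amplified, factor, level_order=present)
        res: AssociationResult = (
            fisher_exact_2x2(table) if test == "fisher" and len(present) == 2 else chi_square(table)
        )
        for i, level in enumerate(present):
            n_amp, n_not = int(table.counts[i, 0]), int(table.counts[i, 1])
            rows.append(
                dict(factor=factor, level=level, n_amplified=n_amp, n_not_amplified=n_not,
                     pct_amplified=100.0 * n_amp / max(n_amp + n_not, 1),
                     test=res.test, statistic=res.statistic, p=res.p)
            )
        if factor == "subtype" and "ER-/HER2-" in present and len(present) == 3:
            coll = collapse_levels(table, ["ER-/HER2-"], label_rest="other subtypes")
            fres = fisher_exact_2x2(coll)
            for i, level in enumerate(coll.rows):
                n_amp, n_not = int(coll.counts[i, 0]), int(coll.counts[i, 1])
                rows.append(
                    dict(factor="subtype_collapsed", level=level, n_amplified=n_amp,
                         n_not_amplified=n_not,
                         pct_amplified=100.0 * n_amp / max(n_amp + n_not, 1),
                         test=fres.test, statistic=fres.statistic, p=fres.p)
                )
    return pd.DataFrame(rows)


def analyze_screen(
    screen: pd.DataFrame, amplified_lines: dict[str, bool], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Survival fractions and per-gene selective-lethality calls."""
    fractions = survival_fractions(screen)
    calls = selective_lethality(fractions, amplified_lines, alpha=alpha)
    call_df = pd.DataFrame(
        [
            dict(gene=c.gene, t=c.t, p=c.p, mean_sf_amplified=c.mean_amplified,
                 mean_sf_not_amplified=c.mean_not_amplified, selective=c.selective,
                 n_oligos_significant=c.n_oligos_significant, validated=c.validated)
            for c in calls
        ]
    )
    return fractions, call_df


def analyze_dose_response(
    dose_response: pd.DataFrame, amplified_lines: dict[str, bool]
) -> tuple[pd.DataFrame, dict]:
    """Per cell line logistic fit + SF50; group comparison on log10 SF50."""
    rows = []
    for (line, drug), grp in dose_response.groupby(["cell_line", "drug"], sort=False):
        means = grp.groupby("dose_M")["viability"].mean()
        fit = fit_sf50(means.index.to_numpy(), means.to_numpy(), cell_line=line, drug=drug)
        rows.append(
            dict(cell_line=line, drug=drug, amplified=bool(amplified_lines.get(line, False)),
                 bottom=fit.bottom, top=fit.top, hill=fit.hill, ec50=fit.ec50,
                 sf50_M=fit.sf50, sf50_extrapolated=fit.sf50_extrapolated)
        )
    fits = pd.DataFrame(rows)
    comparison: dict = {}
    ok = fits["sf50_M"].notna()
    amp = fits["amplified"] & ok
    non = ~fits["amplified"] & ok
    if amp.sum() >= 2 and non.sum() >= 2:
        t, p = welch_t(
            np.log10(fits.loc[amp, "sf50_M"].to_numpy(dtype=float)),
            np.log10(fits.loc[non, "sf50_M"].to_numpy(dtype=float)),
        )
        comparison = dict(
            t=t, p=p,
            geomean_sf50_amplified=float(10 ** np.log10(fits.loc[amp, "sf50_M"]).mean()),
            geomean_sf50_not_amplified=float(10 ** np.log10(fits.loc[non, "sf50_M"]).mean()),
        )
    return fits, comparison


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> CohortResults:
    """Run every configured stage from files and write all outputs.

    Deterministic given the seed: running twice with the same config
    produces byte-identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {
        k: getattr(config, k)
        for k in ("clone_table", "polymorphic", "genes_bed", "expression",
                  "detection_p", "annotations", "screen", "dose_response")
        if getattr(config, k)
    }
    for name, path in inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"{name}: {path} does not exist")

    clone_df = asio.read_clone_table(config.clone_table)
    polymorphic = asio.read_polymorphic_list(config.polymorphic) if config.polymorphic else None
    genes = asio.read_genes_bed(config.genes_bed) if config.genes_bed else None
    expression = asio.read_matrix(config.expression, "symbol") if config.expression else None
    detection_p = asio.read_matrix(config.detection_p, "symbol") if config.detection_p else None
    annotations = asio.read_annotations(config.annotations) if config.annotations else None

    results = analyze_cohort(
        clone_df, parse_locus(config.locus), cbs=config.cbs_params(),
        thresholds=config.thresholds(), outlier_k=config.outlier_k,
        polymorphic=polymorphic, genes=genes, expression=expression,
        detection_p=detection_p, annotations=annotations,
        integration_alpha=config.integration_alpha,
    )

    asio.write_matrix(results.smoothed.set_index("clone_id"), outdir / "smoothed.tsv", "clone_id")
    asio.write_table(results.segments, outdir / "segments.tsv")
    asio.write_matrix(results.states, outdir / "states.tsv", "clone_id")
    asio.write_regions_bed(results.cores, outdir / "cores.bed")
    if results.sra is not None:
        asio.write_regions_bed([results.sra], outdir / "sra.bed")
    summary = {
        "locus": config.locus,
        "n_samples": int(len(results.amplified)),
        "n_clones_retained": int(len(results.smoothed)),
        "amplified_samples": sorted(results.amplified.index[results.amplified]),
        "n_amplified": int(results.amplified.sum()),
        "prevalence_percent": round(100.0 * results.prevalence, 1),
        "sra_genes": list(results.sra_genes["symbol"]) if results.sra_genes is not None else None,
    }
    asio.write_json(summary, outdir / "summary.json")
    if results.integration is not None:
        asio.write_table(results.integration.reset_index(), outdir / "integration.tsv")
    if results.association is not None:
        asio.write_table(results.association, outdir / "association.tsv")

    if config.screen:
        screen = asio.read_screen_table(config.screen)
        lines = sorted(screen["cell_line"].unique())
        amp_lines = {l: l in set(config.amplified_lines) for l in lines}
        fractions, calls = analyze_screen(screen, amp_lines, alpha=config.screen_alpha)
        asio.write_table(fractions, outdir / "survival_fractions.tsv")
        asio.write_table(calls, outdir / "selective_lethality.tsv")
    if config.dose_response:
        dr = asio.read_dose_response(config.dose_response)
        lines = sorted(dr["cell_line"].unique())
        amp_lines = {l: l in set(config.amplified_lines) for l in lines}
        fits, comparison = analyze_dose_response(dr, amp_lines)
        asio.write_table(fits, outdir / "sf50.tsv")
        if comparison:
            asio.write_json(comparison, outdir / "sf50_comparison.json")

    from . import __version__

    manifest = {
        "version": __version__,
        "parameters": config.to_dict(),
        "input_sha256": {k: _sha256(v) for k, v in inputs.items()},
        "n_samples": int(len(results.amplified)),
        "n_clones_retained": int(len(results.smoothed)),
    }
    asio.write_json(manifest, outdir / "manifest.json")
    return results
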