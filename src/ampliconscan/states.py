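"""Categorical copy-number states, amplified regions and FISH classification.

CBS-smoothed log2 ratios are mapped to four states using fixed thresholds
empirically validated for BAC-array data: loss (< -0.08), no-change, gain
(0.08..0.45, roughly 3-5 copies) and amplification (> 0.45, more than 5
copies).  Boundary values +-0.08 are assigned away from no-change, and 0.45
to gain, so each value has exactly one deterministic state.

Region operations summarise the per-clone states: per-sample amplified
intervals, recurrent amplification cores across a cohort, and the smallest
region of amplification (SRA) at a queried locus, whose gene content is the
candidate-driver list.  FISH signal counts are classified with the
counting rule used to validate array calls: amplified when more than half
of neoplastic nuclei carry large signal clusters or > 5 signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StateThresholds",
    "AmpliconRegion",
    "STATE_CODES",
    "call_state",
    "call_states",
    "sample_amplified_intervals",
    "recurrent_cores",
    "smallest_region_of_amplification",
    "classify_fish",
]

LOSS, NO_CHANGE, GAIN, AMPLIFICATION = "loss", "no-change", "gain", "amplification"
STATE_CODES = {LOSS: -1, NO_CHANGE: 0, GAIN: 1, AMPLIFICATION: 2}


@dataclass(frozen=True)
class StateThresholds:
    """Smoothed-log2 cutoffs for the categorical states."""

    loss_below: float = -0.08
    gain_low: float = 0.08
    amp_above: float = 0.45

    def __post_init__(self) -> None:
        if not self.loss_below < self.gain_low < self.amp_above:
            raise ValueError("need loss_below < gain_low < amp_above")


@dataclass
class AmpliconRegion:
    """A genomic interval amplified in one or more samples."""

    chrom: str
    start: int
    end: int
    samples: list[str]
    recurrence: float  # fraction of cohort supporting the region

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and self.end > start


def call_state(value: float, thresholds: StateThresholds = StateThresholds()) -> str | None:
    """Map one smoothed value to a state; NaN -> None (missing)."""
    if value is None or not np.isfinite(value):
        return None
    if value <= thresholds.loss_below:
        return LOSS
    if value > thresholds.amp_above:
        return AMPLIFICATION
    if value >= thresholds.gain_low:
        return GAIN
    return NO_CHANGE


def call_states(
    values: np.ndarray | pd.DataFrame, thresholds: StateThresholds = StateThresholds()
):
    """Vectorised state coding: -1 loss, 0 no-change, 1 gain, 2 amplification.

    NaNs propagate (float output with NaN for missing).
    """
    v = np.asarray(values, dtype=float) if not isinstance(values, pd.DataFrame) else values.to_numpy(dtype=float)
    out = np.zeros(v.shape, dtype=float)
    out[v <= thresholds.loss_below] = -1
    out[v >= thresholds.gain_low] = 1
    out[v > thresholds.amp_above] = 2
    out[~np.isfinite(v)] = np.nan
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (first, last) inclusive index pairs."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, ends)]


def sample_amplified_intervals(
    clone_meta: pd.DataFrame, states: np.ndarray, sample_id: str
) -> list[AmpliconRegion]:
    """Maximal runs of consecutively amplified clones for one sample.

    ``clone_meta`` holds clone_id/chrom/start/end in genome order; ``states``
    is the sample's per-clone state code vector.
    """
    regions: list[AmpliconRegion] = []
    chroms = clone_meta["chrom"].to_numpy()
    starts = clone_meta["start"].to_numpy()
    ends = clone_meta["end"].to_numpy()
    st = np.asarray(states, dtype=float)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for a, b in _runs(st[idx] == STATE_CODES[AMPLIFICATION]):
            regions.append(
                AmpliconRegion(
                    chrom=str(chrom),
                    start=int(starts[idx[a]]),
                    end=int(ends[idx[b]]),
                    samples=[sample_id],
                    recurrence=np.nan,
                )
            )
    return regions


def recurrent_cores(
    clone_meta: pd.DataFrame,
    state_matrix: pd.DataFrame,
    min_fraction: float | None = None,
    min_probes: int = 2,
) -> list[AmpliconRegion]:
    """Maximal runs of clones amplified in >= min_fraction of the cohort.

    ``state_matrix`` is clone x sample state codes.  The default
    ``min_fraction`` requires two amplified samples (the minimum for
    "recurrent").  Each core is annotated with its supporting samples
    (those with >= 1 amplified clone inside the core).
    """
    n_samples = state_matrix.shape[1]
    if n_samples == 0:
        raise ValueError("empty cohort")
    if min_fraction is None:
        min_fraction = 2.0 / n_samples
    amp = state_matrix.to_numpy() == STATE_CODES[AMPLIFICATION]
    freq = amp.mean(axis=1)
    cores: list[AmpliconRegion] = []
    chroms = clone_meta["chrom"].to_numpy()
    starts = clone_meta["start"].to_numpy()
    ends = clone_meta["end"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        for a, b in _runs(freq[idx] >= min_fraction):
            if b - a + 1 < min_probes:
                continue
            gidx = idx[a : b + 1]
            support = amp[gidx].any(axis=0)
            cores.append(
                AmpliconRegion(
                    chrom=str(chrom),
                    start=int(starts[gidx[0]]),
                    end=int(ends[gidx[-1]]),
                    samples=[c for c, s in zip(state_matrix.columns, support) if s],
                    recurrence=float(support.mean()),
                )
            )
    return cores


def smallest_region_of_amplification(
    per_sample_regions: dict[str, list[AmpliconRegion]],
    locus: tuple[str, int, int],
    genes: pd.DataFrame | None = None,
    cores: list[AmpliconRegion] | None = None,
) -> tuple[AmpliconRegion, pd.DataFrame | None]:
    """Intersect per-sample amplified intervals overlapping a locus.

    Each qualifying sample contributes the minimal interval spanning its
    amplified clones that overlap the locus; the SRA is the intersection of
    these spans.  If the intersection is empty the highest-recurrence core
    overlapping the locus is returned instead (with a warning).  Genes
    overlapping the result are listed in genomic order.
    """
    import warnings

    chrom, lstart, lend = locus
    spans: list[tuple[int, int]] = []
    supporting: list[str] = []
    for sample, regions in per_sample_regions.items():
        hits = [r for r in regions if r.overlaps(chrom, lstart, lend)]
        if hits:
            spans.append((min(r.start for r in hits), max(r.end for r in hits)))
            supporting.append(sample)
    if not spans:
        raise ValueError(f"no sample amplified at locus {chrom}:{lstart}-{lend}")
    start = max(s for s, _ in spans)
    end = min(e for _, e in spans)
    if start < end:
        sra = AmpliconRegion(chrom, start, end, supporting, len(supporting) / max(len(per_sample_regions), 1))
    else:
        warnings.warn(
            "per-sample amplified intervals do not intersect; "
            "falling back to the highest-recurrence core",
            stacklevel=2,
        )
        candidates = [c for c in (cores or []) if c.overlaps(chrom, lstart, lend)]
        if not candidates:
            raise ValueError("empty intersection and no core overlapping the locus")
        sra = max(candidates, key=lambda c: c.recurrence)
    contained = None
    if genes is not None:
        hit = (genes["chrom"] == sra.chrom) & (genes["start"] < sra.end) & (genes["end"] > sra.start)
        contained = genes.loc[hit].sort_values(["start", "end"]).reset_index(drop=True)
    return sra, contained


def classify_fish(
    counts: np.ndarray,
    clusters: np.ndarray | None = None,
    cells_threshold: float = 0.5,
) -> str:
    """Classify per-nucleus FISH signal counts for one case.

    Amplified when the fraction of nuclei with a large signal cluster or
    more than 5 signals exceeds ``cells_threshold``; otherwise gain when the
    median count is 3-5 copies; otherwise no-change (two copies per
    nucleus).
    """
    c = np.asarray(counts)
    if c.size == 0:
        raise ValueError("empty FISH observation")
    if np.any(c < 0):
        raise ValueError("negative signal count")
    clus = np.zeros(c.shape, dtype=bool) if clusters is None else np.asarray(clusters, dtype=bool)
    high = clus | (c > 5)
    if high.mean() > cells_threshold:
        return AMPLIFICATION
    med = float(np.median(c))
    if 3.0 <= med <= 5.0:
        return GAIN
    return NO_CHANGE
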