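"""aCGH preprocessing and circular binary segmentation (CBS).

Input is a table of clone-level normalised log2 ratios (tumour vs pooled
reference DNA), ordered along the genome.  Preprocessing removes isolated
outlier probes by their deviation from genomic neighbours (in units of the
genome-wide MAD), drops known polymorphic clones, and rescales each sample
so its genome-wide MAD matches a common target, preserving the overall log2
scale on which the categorical thresholds are defined.

Segmentation is a from-scratch CBS: each stretch of probes is treated as a
circle; over all arc boundaries ``i < j`` the two-sample pooled-variance
t-statistic comparing the arc ``(i, j]`` against its complement is
maximised, the maximum is referred to a permutation null, and significant
arcs are split recursively.  Per-clone "smoothed" values are the means of
the segment owning each clone.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

MAD_CONSTANT = 1.4826  # consistency constant: MAD * 1.4826 estimates sigma for Gaussians

__all__ = [
    "CbsParams",
    "Segment",
    "CopyNumberProfile",
    "mad",
    "max_t_arc",
    "cbs_segment",
    "remove_outliers",
    "rescale_mad",
    "cohort_target_mad",
    "filter_polymorphic",
    "make_profile",
    "segment_profile",
    "segment_cohort",
]


def mad(values: np.ndarray) -> float:
    """Genome-wide median absolute deviation, scaled by 1.4826."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("MAD of empty array")
    return MAD_CONSTANT * float(np.median(np.abs(v - np.median(v))))


@dataclass(frozen=True)
class CbsParams:
    """Tuning parameters of the CBS permutation test.

    alpha
        Significance level for accepting a split (permutation P <= alpha).
    n_perm
        Number of random permutations forming the null distribution of
        max |T|.  P-values use the (b + 1)/(k + 1) correction, so the
        smallest attainable P is 1/(n_perm + 1).
    min_width
        Minimum number of probes in a tested arc and in its complement.
    seed
        Base seed; each tested stretch derives its own permutation stream
        from (seed, offset, length) so results do not depend on recursion
        order or on ``alpha``.
    """

    alpha: float = 0.01
    n_perm: int = 10_000
    min_width: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.min_width < 1:
            raise ValueError("min_width must be >= 1")


@dataclass
class Segment:
    """A constant-mean run of clones produced by CBS (indices inclusive).

    ``n_probes`` counts the probes the mean was computed from; when indices
    refer to the full clone table it can be smaller than the index span
    (excluded clones inside the segment are not counted).
    """

    first: int
    last: int
    mean: float
    chrom: str = ""
    n_probes: int = -1

    def __post_init__(self) -> None:
        if self.n_probes < 0:
            self.n_probes = self.last - self.first + 1


@njit(cache=True)
def _max_t2_scan(x, min_width):  # pragma: no cover - executed via numba
    """Return (i, j, t2) maximising the squared arc t-statistic.

    Arc is x[i+1 .. j] inclusive; the complement wraps circularly.  Both arc
    and complement must hold >= min_width probes.  Ties resolve to the
    smallest i, then smallest j (strict > update in ascending scan order).
    Zero pooled variance with distinct means maps to t2 = 1e300.
    """
    n = x.shape[0]
    S = np.empty(n + 1)
    Q = np.empty(n + 1)
    S[0] = 0.0
    Q[0] = 0.0
    for t in range(n):
        S[t + 1] = S[t] + x[t]
        Q[t + 1] = Q[t] + x[t] * x[t]
    tot_s = S[n]
    tot_q = Q[n]
    best = -1.0
    bi = -1
    bj = -1
    for i in range(n - 1):
        for j in range(i + 1, n):
            m1 = j - i
            m2 = n - m1
            if m1 < min_width or m2 < min_width:
                continue
            s1 = S[j + 1] - S[i + 1]
            q1 = Q[j + 1] - Q[i + 1]
            mean1 = s1 / m1
            mean2 = (tot_s - s1) / m2
            ss1 = q1 - s1 * s1 / m1
            ss2 = (tot_q - q1) - (tot_s - s1) * (tot_s - s1) / m2
            if ss1 < 0.0:
                ss1 = 0.0
            if ss2 < 0.0:
                ss2 = 0.0
            pooled = (ss1 + ss2) / (n - 2)
            d = mean1 - mean2
            if pooled <= 1e-300:
                t2 = 1e300 if d * d > 1e-300 else 0.0
            else:
                t2 = d * d / (pooled * (1.0 / m1 + 1.0 / m2))
            if t2 > best:
                best = t2
                bi = i
                bj = j
    return bi, bj, best


@njit(cache=True)
def _perm_exceedances(x, min_width, t2_obs, n_perm, alpha, stop_b, seed):  # pragma: no cover
    """Count permutations whose max t2 reaches t2_obs, stopping sequentially.

    Three stopping rules (all leave the split decision p = (b+1)/(k+1) <=
    alpha consistent for any arc whose permutation P is not within
    sampling error of alpha):

    * b >= stop_b: the full-run P-value is guaranteed > alpha (exact
      no-split stop);
    * b >= 10 and (b+1) > 4*alpha*(k+1): the exceedance rate is already
      far above alpha (heuristic no-split stop);
    * b >= 25 and (b+1) > alpha*(k+1): sequential (Besag-Clifford style)
      stop once enough exceedances have accrued with the rate above alpha;
    * at checkpoints k in {100, 200, ...}: (b+1) <= alpha*(k+1), the
      running P-value is already at or below alpha (split stop).

    Returns (b, k) with k permutations evaluated.
    """
    np.random.seed(seed)
    n = x.shape[0]
    y = x.copy()
    b = 0
    k = 0
    thresh = t2_obs * (1.0 - 1e-12)
    for _ in range(n_perm):
        # Fisher-Yates shuffle
        for t in range(n - 1, 0, -1):
            r = np.random.randint(0, t + 1)
            tmp = y[t]
            y[t] = y[r]
            y[r] = tmp
        _, _, t2 = _max_t2_scan(y, min_width)
        k += 1
        if t2 >= thresh:
            b += 1
            if b >= stop_b:
                break
            if b >= 10 and (b + 1) > 4.0 * alpha * (k + 1):
                break
            if b >= 25 and (b + 1) > alpha * (k + 1):
                break
        if k % 100 == 0 and (b + 1) <= alpha * (k + 1):
            break
    return b, k


def max_t_arc(values: np.ndarray, min_width: int = 2) -> tuple[int, int, float]:
    """Best circular-arc split of ``values``: (i, j, |T|).

    The arc is values[i+1 .. j]; splitting inserts change-points after index
    i and after index j.  |T| is the pooled-variance two-sample t-statistic.
    """
    x = np.ascontiguousarray(values, dtype=np.float64)
    if x.shape[0] < 2 * min_width:
        raise ValueError("need at least 2*min_width values")
    i, j, t2 = _max_t2_scan(x, min_width)
    return int(i), int(j), math.sqrt(t2) if t2 < 1e299 else math.inf


def _node_seed(base_seed: int, offset: int, length: int) -> int:
    # Deterministic per-stretch stream, independent of recursion order/alpha.
    h = (base_seed * 2654435761 + offset * 40503 + length * 69069 + 12345) % (2**31 - 1)
    return int(h)


def cbs_segment(values: np.ndarray, params: CbsParams, _offset: int = 0) -> list[Segment]:
    """Segment one chromosome's ordered log2 ratios.

    Recursively splits at the most significant circular arc while the
    permutation P-value (b+1)/(k+1) is <= params.alpha.  A 3-way split at an
    interior arc can leave flanking pieces shorter than ``min_width``; those
    are emitted as-is (min_width constrains tested arcs, not emitted
    flanks).  Adjacent segments with equal means (within 1e-12) are merged.
    """
    x = np.ascontiguousarray(values, dtype=np.float64)
    n = x.shape[0]
    if n == 0:
        return []
    if n < 2 * params.min_width:
        return [Segment(0, n - 1, float(np.mean(x)))]

    i, j, t2 = _max_t2_scan(x, params.min_width)
    if i < 0 or t2 <= 0.0:
        return [Segment(0, n - 1, float(np.mean(x)))]

    # b must stay below ceil(alpha*(n_perm+1)) for P=(b+1)/(n_perm+1) <= alpha
    stop_b = int(math.floor(params.alpha * (params.n_perm + 1)))
    if stop_b < 1:
        stop_b = 1
    b, k = _perm_exceedances(
        x, params.min_width, t2, params.n_perm,
        params.alpha, stop_b, _node_seed(params.seed, _offset, n),
    )
    p = (b + 1) / (k + 1)
    if p > params.alpha or b >= stop_b:
        return [Segment(0, n - 1, float(np.mean(x)))]

    pieces: list[tuple[int, int]] = []
    if i >= 0:
        pieces.append((0, i))
    pieces.append((i + 1, j))
    if j < n - 1:
        pieces.append((j + 1, n - 1))
    # arc (i, j] with i >= 0 always leaves a left flank [0, i]
    segments: list[Segment] = []
    for lo, hi in pieces:
        sub = cbs_segment(x[lo : hi + 1], params, _offset=_offset + lo)
        for s in sub:
            segments.append(Segment(s.first + lo, s.last + lo, s.mean))

    # merge adjacent equal-mean segments
    merged: list[Segment] = []
    for s in segments:
        if merged and abs(merged[-1].mean - s.mean) < 1e-12:
            prev = merged.pop()
            w1, w2 = prev.n_probes, s.n_probes
            merged.append(
                Segment(prev.first, s.last, (prev.mean * w1 + s.mean * w2) / (w1 + w2))
            )
        else:
            merged.append(s)
    return merged


# ---------------------------------------------------------------------------
# profiles and preprocessing


@dataclass
class CopyNumberProfile:
    """One sample's ordered clones with raw, excluded and smoothed values."""

    sample_id: str
    clones: pd.DataFrame  # columns clone_id, chrom, start, end; genome-sorted
    values: np.ndarray
    excluded: np.ndarray  # bool; outlier/polymorphic, dropped from segmentation
    smoothed: np.ndarray | None = None
    imputed: np.ndarray | None = None  # bool; smoothed value imputed for excluded clones
    segments: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.clones)
        if len(self.values) != n or len(self.excluded) != n:
            raise ValueError("values/excluded must align with clones")


def make_profile(clone_df: pd.DataFrame, sample: str) -> CopyNumberProfile:
    """Build a profile from a clone table (clone_id, chrom, start, end, samples...)."""
    values = clone_df[sample].to_numpy(dtype=float)
    return CopyNumberProfile(
        sample_id=sample,
        clones=clone_df[["clone_id", "chrom", "start", "end"]].reset_index(drop=True),
        values=values,
        excluded=~np.isfinite(values),
    )


def remove_outliers(profile: CopyNumberProfile, k: float = 3.0) -> CopyNumberProfile:
    """Flag probes deviating from both genomic neighbours by > k * MAD.

    The MAD is the genome-wide (1.4826-scaled) median absolute deviation of
    all retained ratios.  Neighbours are the adjacent retained clones on the
    same chromosome; chromosome ends are compared to their single
    neighbour.  Flagged clones are excluded from segmentation input.
    """
    retained = ~profile.excluded
    if retained.sum() == 0:
        raise ValueError("degenerate profile: no retained clones")
    m = mad(profile.values[retained])
    excluded = profile.excluded.copy()
    chroms = profile.clones["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero((chroms == chrom) & retained)
        if idx.size < 2:
            continue
        x = profile.values[idx]
        d_prev = np.abs(np.diff(x, prepend=np.nan))
        d_next = np.abs(np.diff(x, append=np.nan))
        jump_prev = d_prev > k * m
        jump_next = d_next > k * m
        flag = np.where(
            np.isnan(d_prev), jump_next, np.where(np.isnan(d_next), jump_prev, jump_prev & jump_next)
        )
        excluded[idx[flag]] = True
    if excluded.all():
        raise ValueError("degenerate profile: all clones flagged as outliers")
    return replace(profile, excluded=excluded)


def rescale_mad(profile: CopyNumberProfile, target_mad: float | None) -> CopyNumberProfile:
    """Rescale ratios so the sample's genome-wide MAD equals ``target_mad``.

    ``target_mad=None`` is single-sample mode: no rescaling is performed.
    """
    if target_mad is None:
        return profile
    sample_mad = mad(profile.values[~profile.excluded])
    if sample_mad == 0.0:
        raise ValueError(f"sample {profile.sample_id}: MAD is zero, cannot rescale")
    if target_mad <= 0.0:
        raise ValueError("target_mad must be positive")
    return replace(profile, values=profile.values * (target_mad / sample_mad))


def cohort_target_mad(profiles: list[CopyNumberProfile]) -> float:
    """Cohort-median target: median of per-sample genome-wide MADs.

    Using the cohort median preserves the overall log2 scale on which the
    -0.08 / 0.08 / 0.45 state thresholds are defined.
    """
    return float(np.median([mad(p.values[~p.excluded]) for p in profiles]))


def filter_polymorphic(clone_df: pd.DataFrame, polymorphic: list[str]) -> pd.DataFrame:
    """Drop listed (germline-polymorphic) clones from the table entirely."""
    known = set(clone_df["clone_id"])
    unknown = [c for c in polymorphic if c not in known]
    if unknown:
        warnings.warn(
            f"{len(unknown)} polymorphic clone id(s) not in table, ignored: "
            + ", ".join(unknown[:5]),
            stacklevel=2,
        )
    keep = ~clone_df["clone_id"].isin(polymorphic)
    return clone_df.loc[keep].reset_index(drop=True)


def segment_profile(profile: CopyNumberProfile, params: CbsParams) -> CopyNumberProfile:
    """Run CBS per chromosome on the retained clones of one sample.

    Excluded clones receive the smoothed value of the segment spanning
    their coordinates (nearest segment at chromosome edges) and are marked
    imputed.
    """
    n = len(profile.clones)
    smoothed = np.full(n, np.nan)
    imputed = np.zeros(n, dtype=bool)
    segments: list[Segment] = []
    chroms = profile.clones["chrom"].to_numpy()
    starts = profile.clones["start"].to_numpy()
    retained = ~profile.excluded
    for chrom in pd.unique(chroms):
        on_chrom = chroms == chrom
        idx = np.flatnonzero(on_chrom & retained)
        if idx.size == 0:
            continue
        segs = cbs_segment(profile.values[idx], params)
        bounds = []  # (start_bp of first clone, end_bp of last clone, mean)
        for s in segs:
            gidx = idx[s.first : s.last + 1]
            smoothed[gidx] = s.mean
            segments.append(
                Segment(int(gidx[0]), int(gidx[-1]), s.mean, chrom=str(chrom),
                        n_probes=s.n_probes)
            )
            bounds.append((starts[gidx[0]], starts[gidx[-1]], s.mean))
        # impute excluded clones from the spanning (or nearest) segment
        for e in np.flatnonzero(on_chrom & ~retained):
            pos = starts[e]
            val = bounds[0][2]
            for lo, hi, mean_ in bounds:
                if pos >= lo:
                    val = mean_
                if pos <= hi:
                    break
            smoothed[e] = val
            imputed[e] = True
    return replace(profile, smoothed=smoothed, imputed=imputed, segments=segments)


def segment_cohort(
    clone_df: pd.DataFrame,
    samples: list[str],
    params: CbsParams,
    outlier_k: float = 3.0,
    polymorphic: list[str] | None = None,
    rescale: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, list[CopyNumberProfile]]:
    """Full preprocessing + segmentation for a cohort.

    Returns (smoothed clone x sample matrix with clone metadata, per-sample
    segment table, profiles).  With a single sample or ``rescale=False`` no
    MAD rescaling is applied.
    """
    if polymorphic:
        clone_df = filter_polymorphic(clone_df, polymorphic)
    profiles = [remove_outliers(make_profile(clone_df, s), k=outlier_k) for s in samples]
    if rescale and len(profiles) > 1:
        target = cohort_target_mad(profiles)
        # a zero cohort target (noise-free data) leaves the scale untouched
        if target > 0:
            profiles = [rescale_mad(p, target) for p in profiles]
    profiles = [segment_profile(p, params) for p in profiles]

    smoothed = pd.concat(
        [
            clone_df[["clone_id", "chrom", "start", "end"]].reset_index(drop=True),
            pd.DataFrame({p.sample_id: p.smoothed for p in profiles}),
        ],
        axis=1,
    )
    rows = []
    starts = clone_df["start"].to_numpy()
    ends = clone_df["end"].to_numpy()
    for p in profiles:
        for s in p.segments:
            rows.append(
                {
                    "sample": p.sample_id,
                    "chrom": s.chrom,
                    "start": int(starts[s.first]),
                    "end": int(ends[s.last]),
                    "n_probes": s.n_probes,
                    "mean": s.mean,
                }
            )
    seg_df = pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "n_probes", "mean"])
    return smoothed, seg_df, profiles
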