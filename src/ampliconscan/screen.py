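"""siRNA viability-screen analysis and dose-response SF50 estimation.

Survival fractions are mean target-well viability divided by mean
non-targeting-control (siCON) viability on the same cell line/plate.
Selective lethality of a silenced gene is a Welch two-sample t-test of
pool-level survival fractions between amplified and non-amplified cell
lines, validated by pool deconvolution: at least two of the four
individual oligonucleotides must be individually significant in the same
direction (lower survival in amplified lines), guarding against off-target
pool effects.

Dose-response curves follow a four-parameter logistic in log10 dose;
SF50 is the dose at which fitted survival crosses 0.5 absolute (the
published definition), which for asymmetric fits differs from the curve
midpoint (also reported, as ec50).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SurvivalFraction",
    "SelectiveLethality",
    "DoseResponseFit",
    "survival_fractions",
    "welch_t",
    "selective_lethality",
    "logistic_survival",
    "fit_sf50",
    "qpcr_normalize",
]

CONTROL_TARGETS = ("siCON", "siCON1", "siCON2")


@dataclass
class SurvivalFraction:
    cell_line: str
    target: str
    oligo: str
    value: float
    sem: float
    n: int


@dataclass
class SelectiveLethality:
    gene: str
    t: float
    p: float
    mean_amplified: float
    mean_not_amplified: float
    selective: bool
    oligo_p: dict[str, float] = field(default_factory=dict)
    n_oligos_significant: int = 0
    validated: bool = False


def survival_fractions(screen: pd.DataFrame) -> pd.DataFrame:
    """Per (cell_line, target, oligo) survival fraction relative to siCON.

    ``screen`` columns: cell_line, target, oligo, replicate, luminescence.
    The divisor is the mean luminescence over all siCON wells of the same
    cell line; its replicate variance is propagated into the SEM by the
    delta method.  A cell line without siCON wells is an error.
    """
    required = {"cell_line", "target", "oligo", "luminescence"}
    if not required <= set(screen.columns):
        raise ValueError(f"screen table must have columns {sorted(required)}")
    out = []
    for line, plate in screen.groupby("cell_line", sort=False):
        con = plate.loc[plate["target"].isin(CONTROL_TARGETS), "luminescence"].to_numpy(dtype=float)
        if con.size == 0:
            raise ValueError(f"cell line {line}: no siCON control wells")
        con_mean = con.mean()
        con_cv2 = (con.var(ddof=1) / con.size) / con_mean**2 if con.size > 1 else 0.0
        for (target, oligo), grp in plate.groupby(["target", "oligo"], sort=False):
            lum = grp["luminescence"].to_numpy(dtype=float)
            if lum.size < 2:
                raise ValueError(
                    f"cell line {line}, target {target}, oligo {oligo}: "
                    "need >= 2 replicate wells"
                )
            value = lum.mean() / con_mean
            tgt_cv2 = (lum.var(ddof=1) / lum.size) / lum.mean() ** 2
            out.append(
                dict(cell_line=line, target=target, oligo=str(oligo),
                     survival_fraction=value,
                     sem=value * float(np.sqrt(tgt_cv2 + con_cv2)),
                     n=int(lum.size))
            )
    return pd.DataFrame(out)


def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance two-sided t-test: (t, P).

    With a zero-variance group of n = 2 the Welch denominator can collapse;
    the pooled-variance (Student) test is used as a documented fallback for
    exact within-group ties.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 observations per group")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        t, p = stats.ttest_ind(a, b, equal_var=True)
        return float(t), float(p)
    if a.var(ddof=1) == 0.0 or b.var(ddof=1) == 0.0:
        t, p = stats.ttest_ind(a, b, equal_var=True)
        return float(t), float(p)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def selective_lethality(
    fractions: pd.DataFrame,
    amplified: dict[str, bool],
    alpha: float = 0.05,
    pool_label: str = "pool",
) -> list[SelectiveLethality]:
    """Pool-level selective-lethality call with oligo deconvolution.

    For each non-control gene: Welch t-test of pool survival fractions
    between amplified and non-amplified cell lines; ``selective`` when
    P < alpha and amplified-line mean survival is lower.  ``validated``
    additionally requires >= 2 individual oligos each significant in the
    same direction.
    """
    frac = fractions[~fractions["target"].isin(CONTROL_TARGETS)]
    results = []
    for gene, grp in frac.groupby("target", sort=False):
        is_amp = grp["cell_line"].map(amplified).astype(bool)
        pool = grp[grp["oligo"] == pool_label]
        pa = pool.loc[is_amp[pool.index], "survival_fraction"].to_numpy()
        pn = pool.loc[~is_amp[pool.index], "survival_fraction"].to_numpy()
        if pa.size < 2 or pn.size < 2:
            raise ValueError(f"gene {gene}: need >= 2 cell lines per group")
        t, p = welch_t(pa, pn)
        sel = bool(p < alpha and pa.mean() < pn.mean())
        oligo_p: dict[str, float] = {}
        n_sig = 0
        for oligo, ogrp in grp[grp["oligo"] != pool_label].groupby("oligo", sort=False):
            oa = ogrp.loc[is_amp[ogrp.index], "survival_fraction"].to_numpy()
            on = ogrp.loc[~is_amp[ogrp.index], "survival_fraction"].to_numpy()
            if oa.size < 2 or on.size < 2:
                continue
            ot, op = welch_t(oa, on)
            oligo_p[str(oligo)] = op
            if op < alpha and oa.mean() < on.mean():
                n_sig += 1
        results.append(
            SelectiveLethality(
                gene=str(gene), t=t, p=p,
                mean_amplified=float(pa.mean()), mean_not_amplified=float(pn.mean()),
                selective=sel, oligo_p=oligo_p, n_oligos_significant=n_sig,
                validated=bool(sel and n_sig >= 2),
            )
        )
    return results


def logistic_survival(dose: np.ndarray, bottom: float, top: float, hill: float, log10_mid: float) -> np.ndarray:
    """Four-parameter logistic: survival as a function of molar dose."""
    ld = np.log10(np.asarray(dose, dtype=float))
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (ld - log10_mid)))


@dataclass
class DoseResponseFit:
    cell_line: str
    drug: str
    bottom: float
    top: float
    hill: float
    log10_mid: float
    sf50: float | None  # molar; None when the curve never crosses 0.5
    sf50_extrapolated: bool
    ec50: float  # curve midpoint, for comparison with the absolute-50% SF50
    rss: float


def fit_sf50(
    doses: np.ndarray,
    survival: np.ndarray,
    cell_line: str = "",
    drug: str = "",
) -> DoseResponseFit:
    """Least-squares logistic fit and absolute-50% survival dose.

    Bounds: top in [0.8, 1.2], bottom in [0, 0.5], |hill| in [0.05, 10];
    both hill signs are tried (multi-start) and the lower residual wins.
    SF50 solves fitted survival = 0.5; it is flagged extrapolated outside
    the dosed range and None when the fitted curve does not cross 0.5.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(survival, dtype=float)
    ok = np.isfinite(d) & np.isfinite(y) & (d > 0)
    d, y = d[ok], y[ok]
    if np.unique(d).size < 4:
        raise ValueError("need >= 4 distinct positive dose points")
    ld = np.log10(d)

    def residuals(theta: np.ndarray) -> np.ndarray:
        bottom, top, hill, lmid = theta
        return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (ld - lmid))) - y

    lo = [0.0, 0.8, -10.0, ld.min() - 3.0]
    hi = [0.5, 1.2, 10.0, ld.max() + 3.0]
    best = None
    mid0 = float(np.median(ld))
    for hill0 in (1.0, -1.0, 3.0):
        theta0 = np.array([max(0.0, min(0.5, y.min())), min(1.2, max(0.8, y.max())), hill0, mid0])
        theta0 = np.clip(theta0, lo, hi)
        try:
            res = optimize.least_squares(
                residuals, theta0, bounds=(lo, hi), xtol=1e-8, ftol=1e-8, gtol=1e-8
            )
        except ValueError:
            continue
        if best is None or res.cost < best.cost - 1e-15:
            best = res
    if best is None:
        raise RuntimeError("dose-response fit failed from all starts")
    bottom, top, hill, lmid = (float(v) for v in best.x)
    if abs(hill) < 0.05:
        hill = 0.05 if hill >= 0 else -0.05

    sf50 = None
    extrapolated = False
    ratio = (top - bottom) / (0.5 - bottom) - 1.0 if 0.5 > bottom else -1.0
    if top > 0.5 > bottom and ratio > 0:
        l50 = lmid + np.log10(ratio) / hill
        sf50 = float(10.0 ** l50)
        extrapolated = bool(l50 < ld.min() - 1e-9 or l50 > ld.max() + 1e-9)
    return DoseResponseFit(
        cell_line=cell_line, drug=drug, bottom=bottom, top=top, hill=hill,
        log10_mid=lmid, sf50=sf50, sf50_extrapolated=extrapolated,
        ec50=float(10.0 ** lmid), rss=float(2.0 * best.cost),
    )


def qpcr_normalize(
    target: float,
    reference: dict[str, float],
    target_control: float | None = None,
    reference_control: dict[str, float] | None = None,
) -> dict[str, float]:
    """Standard-curve qRT-PCR normalisation against reference genes.

    Normalised expression = target quantity / geometric mean of the
    reference quantities (TFRC and MRPL19 in the assay this emulates).
    Given the matched siCON condition, knockdown = 1 - silenced/control on
    the normalised scale.
    """
    quantities = [target, *reference.values()]
    if target_control is not None:
        quantities += [target_control, *(reference_control or {}).values()]
    if any(q is None or q <= 0 for q in quantities):
        raise ValueError("all qPCR quantities must be positive")
    geo = float(np.exp(np.mean(np.log(list(reference.values())))))
    normalized = target / geo
    out = {"normalized": normalized}
    if target_control is not None:
        geo_c = float(np.exp(np.mean(np.log(list((reference_control or reference).values())))))
        out["normalized_control"] = target_control / geo_c
        out["knockdown"] = 1.0 - normalized / out["normalized_control"]
    return out
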