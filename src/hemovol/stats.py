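"""Agreement statistics for method comparison.

Relative error, Bland-Altman limits of agreement, a one-sided Wilcoxon
signed-rank test (exact by enumeration for small n), Spearman rank
correlation, ordinary least squares, Cohen's kappa, and the volume-based
surgical decision rules.

Sign convention: paired differences are always ``m1 - m2`` with m1 the
planimetry (reference) method, so a comparator that overestimates shows up
as a *negative* Bland-Altman bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedVolumes",
    "BlandAltmanResult",
    "AgreementResult",
    "DecisionRule",
    "relative_error",
    "bland_altman",
    "wilcoxon_one_sided",
    "spearman_rho",
    "ols_fit",
    "cohens_kappa",
    "surgical_decision",
]


@dataclass(frozen=True)
class PairedVolumes:
    """Volumes of the same regions measured by two methods (cm^3)."""

    m1: np.ndarray
    m2: np.ndarray
    region_ids: tuple | None = None

    def __post_init__(self) -> None:
        m1 = np.asarray(self.m1, dtype=float)
        m2 = np.asarray(self.m2, dtype=float)
        if m1.shape != m2.shape or m1.ndim != 1:
            raise ValueError("m1 and m2 must be 1D arrays of equal length")
        object.__setattr__(self, "m1", m1)
        object.__setattr__(self, "m2", m2)

    def __len__(self) -> int:
        return len(self.m1)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False)  # per-pair means, for plotting
    diffs: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class AgreementResult:
    table: np.ndarray
    p_observed: float
    p_chance: float
    kappa: float


@dataclass(frozen=True)
class DecisionRule:
    """Volume thresholds (cm^3) triggering surgical evacuation.

    EDH: evacuation at >= 30 regardless of location. IPH: >= 30 on the
    frontal or temporal lobe, >= 50 elsewhere. Inclusive thresholds.
    """

    edh_threshold: float = 30.0
    iph_frontal_temporal_threshold: float = 30.0
    iph_other_threshold: float = 50.0

    def __post_init__(self) -> None:
        if min(
            self.edh_threshold,
            self.iph_frontal_temporal_threshold,
            self.iph_other_threshold,
        ) <= 0:
            raise ValueError("thresholds must be positive")


def relative_error(reference: float, estimate: float) -> float:
    """``|reference - estimate| / reference``.

    Against phantoms the reference is the exact volume; against clinical
    masks the planimetry volume stands in as the benchmark.
    """
    if reference <= 0:
        raise ValueError("reference volume must be positive")
    return abs(reference - estimate) / reference


def bland_altman(p: PairedVolumes) -> BlandAltmanResult:
    """Bias and 95% limits of agreement of the differences ``m1 - m2``.

    Limits are ``bias +/- 1.96 * SD`` with the sample (n-1) standard
    deviation.
    """
    if len(p) < 2:
        raise ValueError("need at least 2 pairs")
    d = p.m1 - p.m2
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(p.m1 + p.m2) / 2.0,
        diffs=d,
    )


_EXACT_N_MAX = 15


def _signed_ranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))  # average ranks for ties
    return d, ranks


def wilcoxon_one_sided(p: PairedVolumes, alternative: str) -> tuple[float, float]:
    """One-sided Wilcoxon signed-rank test on paired volumes.

    ``alternative="m1_greater"`` tests whether m1's volumes are located
    higher than m2's (and vice versa). Zero differences are dropped. For
    n <= 15 the p-value is exact, from the full enumeration of the 2^n
    equally likely sign assignments of the ranked |d|; beyond that a normal
    approximation with tie correction and a 0.5 continuity correction is
    used. Returns ``(W+, p)`` where W+ is the sum of ranks of positive
    differences.
    """
    if alternative not in ("m1_greater", "m2_greater"):
        raise ValueError("alternative must be 'm1_greater' or 'm2_greater'")
    d, ranks = _signed_ranks(p.m1 - p.m2)
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero: no information")
    if n < 5:
        raise ValueError("need at least 5 nonzero differences")
    w_plus = float(ranks[d > 0].sum())
    # m2_greater predicts small W+; flip to the complementary statistic so
    # both branches compute an upper-tail probability
    w = w_plus if alternative == "m1_greater" else float(ranks.sum()) - w_plus

    if n <= _EXACT_N_MAX:
        signs = np.indices((2,) * n).reshape(n, -1).T.astype(float)  # all 2^n patterns
        w_all = signs @ ranks
        p_val = float((w_all >= w - 1e-9).mean())
    else:
        mu = ranks.sum() / 2.0
        var = (ranks**2).sum() / 4.0  # equals n(n+1)(2n+1)/24 - tie correction
        z = (w - mu - 0.5) / np.sqrt(var)
        p_val = float(sps.norm.sf(z))
    return w_plus, p_val


def spearman_rho(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1D vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rho undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def ols_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line; returns (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant x: slope undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def cohens_kappa(table: np.ndarray) -> AgreementResult:
    """Chance-corrected agreement from a k x k contingency table of counts."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("table must be square")
    if np.any(t < 0) or t.sum() <= 0:
        raise ValueError("counts must be non-negative with a positive total")
    total = t.sum()
    p_o = float(np.trace(t) / total)
    p_e = float((t.sum(axis=1) * t.sum(axis=0)).sum() / total**2)
    if p_e >= 1.0 - 1e-15:
        if p_o >= 1.0 - 1e-15:
            return AgreementResult(t, p_o, p_e, 1.0)
        raise ValueError("chance agreement is 1: kappa undefined")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(t, p_o, p_e, float(kappa))


def surgical_decision(
    volume_cm3: float,
    hemorrhage_type: str,
    location: str = "other",
    rule: DecisionRule = DecisionRule(),
) -> str:
    """Volume-based evacuation decision: ``"surgery"`` or ``"observation"``."""
    if volume_cm3 < 0:
        raise ValueError("volume must be non-negative")
    htype = hemorrhage_type.upper()
    loc = location.lower()
    if htype == "EDH":
        threshold = rule.edh_threshold
    elif htype == "IPH":
        if loc in ("frontal", "temporal"):
            threshold = rule.iph_frontal_temporal_threshold
        elif loc == "other":
            threshold = rule.iph_other_threshold
        else:
            raise ValueError(f"unknown location {location!r}")
    else:
        raise ValueError(f"unknown hemorrhage type {hemorrhage_type!r}")
    return "surgery" if volume_cm3 >= threshold else "observation"
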