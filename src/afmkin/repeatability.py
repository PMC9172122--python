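"""Between-session variability (sigma) and standard error of measurement.

The design has three marker applications per subject: A1 and A2 by tester
A and B1 by tester B.  Intra-tester pairs are (A1, A2); inter-tester
pairs are (A1, B1).  For curves, the two-measurement standard deviation
(|a - b| / sqrt(2)) is computed at each percent of the gait cycle and
averaged over the cycle, giving one variability value (sigma) per subject
and angle; scalars (static angles, ROM) skip the time average.  The SEM
is the square root of the error variance (mean within-pair variance
across subjects).  Group summaries use a Shapiro-Wilk normality test to
choose between mean +/- SD and median [IQR]; both are always retained.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import AfmError

_SQRT2 = np.sqrt(2.0)


def pair_sigma(a, b) -> float:
    """Two-measurement SD (n-1 denominator), time-averaged for curves.

    ``a`` and ``b`` are either scalars (static angle, ROM) or normalized
    curves of equal length; per-point SD = |a - b| / sqrt(2), averaged
    over the cycle.  NaN points (e.g. hallux frontal) are skipped.
    """
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise AfmError("paired measurements differ in length")
    d = np.abs(a - b) / _SQRT2
    ok = np.isfinite(d)
    if not np.any(ok):
        raise AfmError("no finite paired samples")
    return float(np.mean(d[ok]))


def sem(pairs: Sequence[Tuple[np.ndarray, np.ndarray]], *,
        aggregate: str = "pointwise") -> float:
    """Standard error of measurement across subjects (degrees).

    Each element of ``pairs`` is one subject's two measurements (scalars
    or equal-length curves).  With ``aggregate='pointwise'`` (default) the
    error variance is computed per time point — mean over subjects of the
    within-pair variance d^2/2 — the SEM taken as its square root, and
    then averaged over the cycle, mirroring the sigma computation.
    ``aggregate='time_first'`` averages each subject's within-pair
    variance over the cycle before pooling.
    """
    if len(pairs) < 2:
        raise AfmError("SEM needs at least two subjects")
    d2 = []
    for a, b in pairs:
        a = np.atleast_1d(np.asarray(a, dtype=float))
        b = np.atleast_1d(np.asarray(b, dtype=float))
        if a.shape != b.shape:
            raise AfmError("paired measurements differ in length")
        d2.append((a - b) ** 2 / 2.0)
    d2 = np.array(d2)                       # (subjects, points)
    if aggregate == "pointwise":
        err_var = np.nanmean(d2, axis=0)    # per-point error variance
        return float(np.nanmean(np.sqrt(err_var)))
    if aggregate == "time_first":
        return float(np.sqrt(np.nanmean(d2)))
    raise ValueError(f"unknown aggregation {aggregate!r}")


@dataclasses.dataclass
class GroupSummary:
    """Distribution-aware summary of per-subject sigmas."""

    mean: float
    sd: float
    median: float
    iqr: float
    shapiro_p: float
    normal: bool

    @property
    def preferred(self) -> str:
        """Formatted per the normality outcome."""
        if self.normal:
            return f"{self.mean:.1f} ± {self.sd:.1f}°"
        return f"{self.median:.1f} [{self.iqr:.1f}°]"


def summarize(sigmas: Sequence[float], alpha: float = 0.05) -> GroupSummary:
    """Shapiro-Wilk at ``alpha``; non-normal samples are reported as
    median [IQR], normal ones as mean +/- SD.  Both are retained."""
    x = np.asarray(sigmas, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 3:
        raise AfmError("group summary needs at least three subjects")
    if np.ptp(x) == 0:
        p, normal = 1.0, True
    else:
        _, p = stats.shapiro(x)
        normal = p >= alpha
    q75, q25 = np.percentile(x, [75, 25])
    return GroupSummary(
        mean=float(np.mean(x)), sd=float(np.std(x, ddof=1)),
        median=float(np.median(x)), iqr=float(q75 - q25),
        shapiro_p=float(p), normal=bool(normal),
    )


@dataclasses.dataclass
class Measurement:
    """One marker application: normalized mean curves plus static angles
    and ROM, keyed by (angle name, plane)."""

    curves: Dict[Tuple[str, str], np.ndarray]
    static: Dict[Tuple[str, str], float]
    rom: Dict[Tuple[str, str], float]


@dataclasses.dataclass
class RepeatabilityResult:
    """Per-angle sigma (per subject), SEM, and group summaries, for each
    of the three quantities (curve, static, ROM)."""

    sigmas: Dict[str, Dict[Tuple[str, str], List[float]]]
    sems: Dict[str, Dict[Tuple[str, str], float]]
    summaries: Dict[str, Dict[Tuple[str, str], GroupSummary]]


def evaluate_pairs(first: Sequence[Measurement], second: Sequence[Measurement],
                   *, aggregate: str = "pointwise",
                   summarize_groups: bool = True) -> RepeatabilityResult:
    """Sigma/SEM for a list of subjects' measurement pairs.

    ``first[i]`` and ``second[i]`` are the two measurements of subject i
    (A1/A2 for intra-tester, A1/B1 for inter-tester).
    """
    if len(first) != len(second) or not first:
        raise AfmError("need equally many first and second measurements")
    keys = [k for k in first[0].curves if k in second[0].curves]
    sigmas = {q: {k: [] for k in keys} for q in ("curve", "static", "rom")}
    pair_data = {q: {k: [] for k in keys} for q in ("curve", "static", "rom")}
    for m1, m2 in zip(first, second):
        for k in keys:
            for q, x1, x2 in (("curve", m1.curves[k], m2.curves[k]),
                              ("static", m1.static.get(k), m2.static.get(k)),
                              ("rom", m1.rom.get(k), m2.rom.get(k))):
                if x1 is None or x2 is None:
                    continue
                sigmas[q][k].append(pair_sigma(x1, x2))
                pair_data[q][k].append((np.atleast_1d(x1), np.atleast_1d(x2)))
    sems = {
        q: {k: sem(v, aggregate=aggregate) for k, v in pair_data[q].items() if len(v) >= 2}
        for q in pair_data
    }
    summaries = {}
    if summarize_groups:
        for q in sigmas:
            summaries[q] = {}
            for k, v in sigmas[q].items():
                if len(v) >= 3:
                    summaries[q][k] = summarize(v)
    return RepeatabilityResult(sigmas, sems, summaries)
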