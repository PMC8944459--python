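"""Automatic fuzzy-domain construction and fuzzification of clinical variables.

A *fuzzy domain* partitions the observed range of one parameter (a vital sign,
an ABG field, a therapy duration in days, ...) into five overlapping linguistic
subsets F1..F5: two shoulder trapezoids at the extremes and three triangles in
between, every adjacent pair sharing an overlap of width ``h``.  The geometry is
derived entirely from population statistics of the parameter rather than from
expert-curated ranges:

1. the raw observations are trimmed to the central (or lower, for nonnegative
   duration-like variables) mass covering at least 95% of observations;
2. the trimmed minimum ``m``, maximum ``M`` and median anchor the domain, with
   the medium triangle centered on the trimmed median and spanning one third of
   the trimmed range;
3. the overlap half-width ``h`` defaults to half the standard deviation of the
   trimmed values.

Fuzzification evaluates the five membership functions at a raw value and
assigns the single category with the highest degree (ties to the lower
category); the reserved code 0 marks absent data and is never produced from a
numeric value.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "THERAPY_LABELS",
    "MONITORING_LABELS",
    "LIMIT_NAMES",
    "ParameterStats",
    "TrimmedTable",
    "FuzzyDomain",
    "trim_95",
    "build_domain",
    "domain_from_observations",
    "membership",
    "fuzzify",
    "plot_domain",
    "save_domains",
    "load_domains",
    "round_half_away",
]

#: Linguistic vocabulary for therapy-duration parameters (days of therapy).
THERAPY_LABELS: tuple[str, ...] = ("ultra-short", "short", "medium", "long", "ultra-long")
#: Linguistic vocabulary for bedside monitoring parameters.
MONITORING_LABELS: tuple[str, ...] = ("very low", "low", "medium", "high", "very high")

#: Canonical order of the ten domain limits, left edge to right edge.
LIMIT_NAMES: tuple[str, ...] = ("VLL", "LL", "VLH", "NL", "LH", "HL", "NH", "VHL", "HH", "VHH")


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (report convention; internal math stays full precision)."""
    q = 10.0**decimals
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


@dataclass(frozen=True)
class ParameterStats:
    """Population summary of one parameter over its non-null observations."""

    parameter_id: str
    n_obs: int
    mean: float
    sd: float
    minimum: float
    maximum: float
    median: float

    @classmethod
    def from_values(cls, parameter_id: str, values: Iterable[float]) -> "ParameterStats":
        arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            raise ValueError("no observations")
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        return cls(
            parameter_id=parameter_id,
            n_obs=int(arr.size),
            mean=float(arr.mean()),
            sd=sd,
            minimum=float(arr.min()),
            maximum=float(arr.max()),
            median=float(np.median(arr)),
        )


@dataclass(frozen=True)
class TrimmedTable:
    """The "95% table": observed values retained after tail trimming.

    ``m``/``M`` are the trimmed minimum/maximum, ``median_t``/``sd_t`` the
    median and standard deviation recomputed on retained values only, and
    ``coverage`` the fraction of raw observations retained (>= the requested
    coverage by construction).  ``degenerate`` flags constant retained data
    (m == M), which domain construction rejects.
    """

    parameter_id: str
    m: float
    M: float
    median_t: float
    sd_t: float
    coverage: float
    value_frequencies: dict[float, int] = field(repr=False)
    degenerate: bool = False


def trim_95(
    observations: Iterable[float],
    mode: str = "central",
    coverage: float = 0.95,
    parameter_id: str = "",
) -> TrimmedTable:
    """Trim a distribution to the observed values covering >= ``coverage`` of its mass.

    Cutoffs are always placed at observed values, never interpolated.  Scanning
    the observed values in increasing order, the lower cutoff is the first
    value at which the cumulative frequency reaches the lower-tail threshold
    (0 in ``upper`` mode, (1-coverage)/2 in ``central`` mode) and the upper
    cutoff the first value at which it reaches the upper threshold; both
    cutoff values are retained.

    Parameters
    ----------
    observations
        Raw values; NaNs are dropped.
    mode
        ``"upper"`` trims the top tail only (for nonnegative duration-like
        variables whose minimum is meaningful), ``"central"`` trims
        (1-coverage)/2 from each tail (for monitoring vitals).
    """
    if mode not in ("upper", "central"):
        raise ValueError(f"unknown trim mode {mode!r} (expected 'upper' or 'central')")
    arr = np.asarray(list(observations) if not isinstance(observations, np.ndarray) else observations, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("no observations")

    values, counts = np.unique(arr, return_counts=True)
    cum = np.cumsum(counts) / arr.size
    eps = 1e-12
    if mode == "upper":
        m = float(values[0])
        M = float(values[np.searchsorted(cum, coverage - eps)])
    else:
        alpha = (1.0 - coverage) / 2.0
        m = float(values[np.searchsorted(cum, alpha - eps)])
        M = float(values[np.searchsorted(cum, 1.0 - alpha - eps)])

    retained = arr[(arr >= m) & (arr <= M)]
    sd_t = float(retained.std(ddof=1)) if retained.size > 1 else 0.0
    keep = (values >= m) & (values <= M)
    return TrimmedTable(
        parameter_id=parameter_id,
        m=m,
        M=M,
        median_t=float(np.median(retained)),
        sd_t=sd_t,
        coverage=float(retained.size / arr.size),
        value_frequencies={float(v): int(c) for v, c in zip(values[keep], counts[keep])},
        degenerate=bool(m == M),
    )


@dataclass(frozen=True)
class FuzzyDomain:
    """One parameter's fuzzy domain: ten limits, overlap half-width and labels.

    Limits in left-to-right order are VLL < LL < VLH <= NL < LH < HL < NH <=
    VHL < HH < VHH.  F1 is the left shoulder (plateau up to LL, ramp down to
    VLH), F2/F3/F4 are symmetric triangles on [LL, LH], [NL, NH], [HL, HH],
    and F5 the right shoulder (ramp up across [VHL, HH], plateau beyond).
    """

    parameter_id: str
    labels: tuple[str, ...]
    m: float
    M: float
    median_t: float
    h: float
    VLL: float
    LL: float
    VLH: float
    NL: float
    LH: float
    HL: float
    NH: float
    VHL: float
    HH: float
    VHH: float
    sd_t: float | None = None
    overlap_rule: str = "half_sd"

    def limits(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in LIMIT_NAMES}

    def membership(self, x):
        return membership(self, x)

    def fuzzify(self, x):
        return fuzzify(self, x)

    def to_dict(self) -> dict:
        return {
            "parameter_id": self.parameter_id,
            "labels": list(self.labels),
            "m": self.m,
            "M": self.M,
            "median_t": self.median_t,
            "sd_t": self.sd_t,
            "h": self.h,
            "overlap_rule": self.overlap_rule,
            "limits": self.limits(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FuzzyDomain":
        return cls(
            parameter_id=d["parameter_id"],
            labels=tuple(d["labels"]),
            m=d["m"],
            M=d["M"],
            median_t=d["median_t"],
            sd_t=d.get("sd_t"),
            h=d["h"],
            overlap_rule=d.get("overlap_rule", "half_sd"),
            **{name: d["limits"][name] for name in LIMIT_NAMES},
        )


def build_domain(
    m: float,
    M: float,
    median_t: float,
    h: float,
    labels: Sequence[str] = MONITORING_LABELS,
    parameter_id: str = "",
    sd_t: float | None = None,
    clamp_median: bool = False,
    overlap_rule: str = "half_sd",
) -> FuzzyDomain:
    """Build a five-subset fuzzy domain from trimmed-range statistics.

    The medium triangle spans one third of the trimmed range [m, M] and is
    centered on the trimmed median; the shoulders sit at the range edges; every
    adjacent pair of subsets overlaps by ``2h`` (half-width ``h``)::

        VLL = m - h     LL  = m + h      VLH = m + 2h
        NL  = median_t - (M - m)/6       LH  = NL + h
        NH  = median_t + (M - m)/6       HL  = NH - h
        VHL = M - 2h    HH  = M - h      VHH = M + h

    ``clamp_median`` pulls a median too close to a range edge into the interval
    where the limits stay ordered (used by the automatic pipeline; direct calls
    raise instead).
    """
    for name, v in (("m", m), ("M", M), ("median_t", median_t), ("h", h)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite")
    if m == M:
        raise ValueError("degenerate range")
    if m > M:
        raise ValueError(f"m={m} exceeds M={M}")
    R = M - m
    if h <= 0:
        raise ValueError("overlap half-width must be positive")
    if h >= R / 6.0:
        raise ValueError("overlap too wide for range")
    if len(labels) != 5:
        raise ValueError("exactly five subset labels required")

    if clamp_median:
        lo = m + 2.0 * h + R / 6.0
        hi = M - 2.0 * h - R / 6.0
        median_t = min(max(median_t, lo), hi)
    if not (m <= median_t <= M):
        raise ValueError(f"median_t={median_t} outside [{m}, {M}]")

    NL = median_t - R / 6.0
    NH = median_t + R / 6.0
    limits = {
        "VLL": m - h,
        "LL": m + h,
        "VLH": m + 2.0 * h,
        "NL": NL,
        "LH": NL + h,
        "HL": NH - h,
        "NH": NH,
        "VHL": M - 2.0 * h,
        "HH": M - h,
        "VHH": M + h,
    }
    # Ordering: strict everywhere except where a shoulder ramp may touch the
    # medium triangle (VLH == NL, NH == VHL are legitimate boundary geometries).
    touch_ok = {("VLH", "NL"), ("NH", "VHL")}
    seq = [(name, limits[name]) for name in LIMIT_NAMES]
    for (na, va), (nb, vb) in zip(seq, seq[1:]):
        if (na, nb) in touch_ok:
            # touching geometries are legitimate; tolerate rounding at the joint
            ok = va <= vb + 1e-9 * max(1.0, abs(va), abs(vb))
        else:
            ok = va < vb
        if not ok:
            raise ValueError(
                f"domain limits not monotone ({na}={va:g} !< {nb}={vb:g}); "
                "median too close to a range edge — use clamp_median or adjust h"
            )

    return FuzzyDomain(
        parameter_id=parameter_id,
        labels=tuple(labels),
        m=m,
        M=M,
        median_t=median_t,
        sd_t=sd_t,
        h=h,
        overlap_rule=overlap_rule,
        **limits,
    )


def domain_from_observations(
    parameter_id: str,
    values: Iterable[float],
    mode: str = "central",
    coverage: float = 0.95,
    overlap_rule: str = "half_sd",
    labels: Sequence[str] = MONITORING_LABELS,
) -> FuzzyDomain:
    """Trim a raw distribution and build its fuzzy domain in one step.

    ``overlap_rule`` is ``"half_sd"`` (h = sd of the trimmed table / 2) or
    ``"fixed:<value>"``.  When the requested h would invert the closed forms
    (h >= range/6) the builder falls back to h = range/12 and records the
    substitution in ``overlap_rule``.
    """
    table = trim_95(values, mode=mode, coverage=coverage, parameter_id=parameter_id)
    if table.degenerate:
        raise ValueError(f"constant parameter {parameter_id!r}: cannot build a fuzzy domain")
    if overlap_rule == "half_sd":
        h = table.sd_t / 2.0
    elif overlap_rule.startswith("fixed:"):
        h = float(overlap_rule.split(":", 1)[1])
    else:
        raise ValueError(f"unknown overlap rule {overlap_rule!r}")
    R = table.M - table.m
    rule = overlap_rule
    if not (0.0 < h < R / 6.0):
        h = R / 12.0
        rule = f"{overlap_rule}->range_twelfth"
    return build_domain(
        table.m,
        table.M,
        table.median_t,
        h,
        labels=labels,
        parameter_id=parameter_id,
        sd_t=table.sd_t,
        clamp_median=True,
        overlap_rule=rule,
    )


def membership(domain: FuzzyDomain, x) -> np.ndarray:
    """Degrees of membership of ``x`` in the five subsets, shape ``(..., 5)``.

    Values beyond the domain edges clamp: mu1 = 1 below VLL, mu5 = 1 above VHH.
    Raises on NaN input (absent data is handled by :func:`fuzzify`, not here).
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        # +/- inf clamp like any out-of-range value; NaN is an error
        if np.any(np.isnan(arr)):
            raise ValueError("non-finite value")
        arr = np.clip(arr, domain.VLL - 1.0, domain.VHH + 1.0)
    d = domain
    mu = np.zeros(arr.shape + (5,), dtype=float)
    mu[..., 0] = np.where(arr <= d.LL, 1.0, np.clip((d.VLH - arr) / (d.VLH - d.LL), 0.0, 1.0))
    for i, (a, b) in enumerate(((d.LL, d.LH), (d.NL, d.NH), (d.HL, d.HH)), start=1):
        peak = 0.5 * (a + b)
        up = (arr - a) / (peak - a)
        down = (b - arr) / (b - peak)
        mu[..., i] = np.clip(np.minimum(up, down), 0.0, 1.0)
    mu[..., 4] = np.where(arr >= d.HH, 1.0, np.clip((arr - d.VHL) / (d.HH - d.VHL), 0.0, 1.0))
    return mu


def fuzzify(domain: FuzzyDomain, x):
    """Assign a value (or array) to a single category code.

    Missing (None/NaN) -> 0.  Otherwise the category with the highest degree
    of membership, ties broken to the lower category index; this reproduces
    the ">0.5 in an overlap" assignment wherever a membership exceeds 0.5 and
    extends it deterministically elsewhere.  Total on the reals: values below
    VLL map to 1, above VHH to 5.
    """
    scalar = np.ndim(x) == 0
    arr = np.asarray(x, dtype=float)
    if scalar:
        arr = arr.reshape(1)
    out = np.zeros(arr.shape, dtype=np.int64)
    finite = ~np.isnan(arr)
    if finite.any():
        mu = membership(domain, arr[finite])
        out[finite] = 1 + np.argmax(mu, axis=-1)
    return int(out[0]) if scalar else out


def plot_domain(domain: FuzzyDomain, path: str | Path | None = None, n_points: int = 600):
    """Render the five membership shapes over [VLL, VHH]; overlaps are shaded.

    Returns the matplotlib figure; writes to ``path`` (PNG/SVG by extension)
    when given.
    """
    if not isinstance(domain, FuzzyDomain):
        raise ValueError("plot_domain requires a FuzzyDomain")
    import matplotlib.pyplot as plt

    xs = np.linspace(domain.VLL, domain.VHH, n_points)
    mu = membership(domain, xs)
    fig, ax = plt.subplots(figsize=(8, 3.2))
    for i in range(5):
        ax.plot(xs, mu[:, i], label=f"F{i + 1} ({domain.labels[i]})")
    for a, b in ((domain.LL, domain.VLH), (domain.NL, domain.LH), (domain.HL, domain.NH), (domain.VHL, domain.HH)):
        ax.axvspan(a, b, color="grey", alpha=0.15)
    ax.set_xlabel(domain.parameter_id or "value")
    ax.set_ylabel("membership")
    ax.set_ylim(-0.02, 1.05)
    ax.legend(loc="center left", bbox_to_anchor=(1.0, 0.5), fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig


def save_domains(domains: Mapping[str, FuzzyDomain], path: str | Path) -> None:
    payload = {name: dom.to_dict() for name, dom in domains.items()}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_domains(path: str | Path) -> dict[str, FuzzyDomain]:
    payload = json.loads(Path(path).read_text())
    return {name: FuzzyDomain.from_dict(d) for name, d in payload.items()}
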