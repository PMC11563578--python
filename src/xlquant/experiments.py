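"""Study-level analyses: mixing series, swap concordance, change calls.

Three validation designs recur in 2-plex isobaric qCLMS:

* a **mixing series** — one labeled digest pair combined at known 127:126
  ratios (e.g. 10:1 ... 1:10); observed log2 ratios regressed on expected
  log2 ratios should give slope ~1;
* a **label-swap** pair of experiments — conditions exchange channels
  between experiment I and II, so a genuine abundance change appears with
  anti-correlated sign in the two experiments, while a labeling or handling
  artifact does not;
* a **null comparison** — identical samples in both channels; the spread of
  site ratios around 0 calibrates what "no change" looks like.

Change calls use a fold threshold in both experiments with the
direction-consistency requirement implied by the swap design.  Sites seen in
only one experiment are never called changed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .ident import SiteKey
from .quant import SiteQuant

__all__ = [
    "MixingDesign", "MixingEvalResult", "SwapPair", "ChangeCall",
    "evaluate_mixing", "swap_join", "classify_changes",
    "ratio_distribution_summary",
]


@dataclass(frozen=True)
class MixingDesign:
    """Sample labels and their expected 127:126 intensity ratios."""

    levels: Tuple[Tuple[str, float], ...] = (
        ("10:1", 10.0), ("5:1", 5.0), ("1:1", 1.0), ("1:5", 0.2), ("1:10", 0.1),
    )

    def __post_init__(self) -> None:
        for label, r in self.levels:
            if r <= 0:
                raise ValueError(f"expected ratio for {label!r} must be > 0")

    def expected_log2(self) -> Dict[str, float]:
        return {label: math.log2(r) for label, r in self.levels}


@dataclass
class MixingEvalResult:
    """OLS of observed vs expected log2(127/126) plus per-level summaries."""

    slope: float
    intercept: float
    r_squared: float
    per_level: pd.DataFrame  # label, expected_log2, n, mean, sd


def evaluate_mixing(
    quants_per_sample: Dict[str, Sequence[float]],
    design: MixingDesign = MixingDesign(),
) -> MixingEvalResult:
    """Regress observed log2 ratios on the design's expected log2 ratios.

    ``quants_per_sample`` maps sample label -> observed log2(127/126) values
    (per site or per spectrum, as the caller prefers). Requires >= 2 distinct
    expected levels (otherwise no slope is defined).
    """
    expected = design.expected_log2()
    xs: List[float] = []
    ys: List[float] = []
    rows = []
    for label, values in quants_per_sample.items():
        if label not in expected:
            raise KeyError(f"sample {label!r} not present in the mixing design")
        e = expected[label]
        vals = np.asarray(list(values), dtype=float)
        vals = vals[~np.isnan(vals)]
        xs.extend([e] * len(vals))
        ys.extend(vals)
        rows.append({
            "label": label, "expected_log2": e, "n": len(vals),
            "mean": float(vals.mean()) if len(vals) else float("nan"),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        })
    if len({round(x, 12) for x in xs}) < 2:
        raise ValueError("mixing evaluation needs >= 2 distinct expected levels")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.allclose(y, y[0]):
        # degenerate: constant observations; slope 0 through the constant
        slope, intercept, r2 = 0.0, float(y[0]), 0.0
    else:
        fit = stats.linregress(x, y)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    return MixingEvalResult(slope, intercept, r2, pd.DataFrame(rows))


@dataclass(frozen=True)
class SwapPair:
    """One site's ratios across the two swap experiments.

    ``presence`` is "both", "I_only" or "II_only"; ratios are in the shared
    orientation (log2(126/127)).
    """

    key: SiteKey
    link_class: str
    ratio_i: Optional[float]
    ratio_ii: Optional[float]
    presence: str


@dataclass
class SwapJoinResult:
    pairs: List[SwapPair]
    n_both: int
    n_i_only: int
    n_ii_only: int
    slope: Optional[float]
    intercept: Optional[float]
    r_squared: Optional[float]
    slope_stderr: Optional[float]


def swap_join(
    exp1: Sequence[SiteQuant], exp2: Sequence[SiteQuant]
) -> SwapJoinResult:
    """Outer-join two experiments on site key; fit OLS over shared sites.

    Both inputs must use the same ratio orientation. The fit (slope,
    intercept, R^2) uses only sites quantified in both experiments — the
    "green dots"; with no shared sites the fit is None (flagged by
    ``n_both == 0``).
    """
    orientations = {s.orientation for s in list(exp1) + list(exp2)}
    if len(orientations) > 1:
        raise ValueError(f"mixed ratio orientations across experiments: {orientations}")
    d1 = {s.key: s for s in exp1}
    d2 = {s.key: s for s in exp2}
    pairs: List[SwapPair] = []
    for key in list(d1) + [k for k in d2 if k not in d1]:
        s1, s2 = d1.get(key), d2.get(key)
        ref = s1 or s2
        presence = "both" if (s1 and s2) else ("I_only" if s1 else "II_only")
        pairs.append(SwapPair(
            key=key,
            link_class=ref.link_class,
            ratio_i=s1.mean_ratio if s1 else None,
            ratio_ii=s2.mean_ratio if s2 else None,
            presence=presence,
        ))
    both = [p for p in pairs if p.presence == "both"]
    slope = intercept = r2 = stderr = None
    if len(both) >= 2:
        x = np.array([p.ratio_i for p in both])
        y = np.array([p.ratio_ii for p in both])
        if not (np.allclose(x, x[0]) or np.allclose(y, y[0])):
            fit = stats.linregress(x, y)
            slope, intercept = float(fit.slope), float(fit.intercept)
            r2, stderr = float(fit.rvalue**2), float(fit.stderr)
    return SwapJoinResult(
        pairs=pairs,
        n_both=len(both),
        n_i_only=sum(p.presence == "I_only" for p in pairs),
        n_ii_only=sum(p.presence == "II_only" for p in pairs),
        slope=slope, intercept=intercept, r_squared=r2, slope_stderr=stderr,
    )


@dataclass(frozen=True)
class ChangeCall:
    """Per-site verdict at a fold threshold.

    changed: |log2 ratio| >= log2(fold) in BOTH experiments with opposite
    signs (the swap design anti-correlates genuine changes);
    inconsistent: above threshold in both but same-signed;
    one_experiment_only: seen once — above-threshold singletons are flagged
    via ``single_above_threshold`` but never called changed;
    unchanged: everything else.
    """

    key: SiteKey
    link_class: str
    call: str
    fold: float
    single_above_threshold: bool = False


def classify_changes(
    pairs: Sequence[SwapPair], fold: float = 2.0
) -> List[ChangeCall]:
    """Apply the twofold-in-both-experiments rule to joined swap pairs."""
    if fold <= 1:
        raise ValueError(f"fold threshold must exceed 1, got {fold}")
    cut = math.log2(fold)
    calls = []
    for p in pairs:
        if p.presence != "both":
            r = p.ratio_i if p.ratio_i is not None else p.ratio_ii
            calls.append(ChangeCall(
                p.key, p.link_class, "one_experiment_only", fold,
                single_above_threshold=abs(r) >= cut,
            ))
            continue
        above = abs(p.ratio_i) >= cut and abs(p.ratio_ii) >= cut
        if not above:
            call = "unchanged"
        elif p.ratio_i * p.ratio_ii < 0:
            call = "changed"
        else:
            call = "inconsistent"
        calls.append(ChangeCall(p.key, p.link_class, call, fold))
    return calls


def ratio_distribution_summary(
    sites: Sequence[SiteQuant], window: float = 0.5
) -> pd.DataFrame:
    """Fraction of sites with |mean log2 ratio| <= window, per link class.

    Mirrors the null-comparison readout (most ratios within ±0.5 when
    nothing changes). Rows: one per link class present, plus "overall".
    """
    if not sites:
        raise ValueError("ratio distribution summary needs >= 1 site")
    df = pd.DataFrame({
        "link_class": [s.link_class for s in sites],
        "within": [abs(s.mean_ratio) <= window for s in sites],
    })
    rows = []
    for cls, sub in df.groupby("link_class", sort=True):
        rows.append({"link_class": cls, "n": len(sub),
                     "fraction_within": float(sub["within"].mean())})
    rows.append({"link_class": "overall", "n": len(df),
                 "fraction_within": float(df["within"].mean())})
    return pd.DataFrame(rows)


def swap_pairs_to_frame(result: SwapJoinResult, calls: Sequence[ChangeCall] = ()) -> pd.DataFrame:
    """Swap-pair table, optionally annotated with change calls."""
    call_by_key = {c.key: c for c in calls}
    return pd.DataFrame(
        {
            "site": str(p.key),
            "link_class": p.link_class,
            "ratio_exp1": p.ratio_i,
            "ratio_exp2": p.ratio_ii,
            "presence": p.presence,
            "call": call_by_key[p.key].call if p.key in call_by_key else "",
        }
        for p in result.pairs
    )
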