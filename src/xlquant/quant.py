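"""Reporter-ion quantification: extraction, impurity correction, aggregation.

The 2-plex measurement model: each identified MS2 spectrum carries two
reporter peaks near 126.128 and 127.131 m/z.  Observed intensities I = (I126,
I127) are a mixture of the true channel signals A = (A126, A127) through the
2x2 purity matrix M (column j = how channel j's true signal distributes over
the observed channels):

    M @ A = I,   M = [[0.90754, 0.01], [0.09246, 0.90724]]  (default lot)

The 126 channel bleeds upward via natural 13C abundance; the 127 channel
bleeds downward via incomplete (99%) 13C enrichment.  Correction solves the
linear system; per-spectrum log2 ratios of the corrected intensities are then
averaged per modified site (monolink) or pair of crosslinked sites, which is
the method's site-level quantity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ident import AnyID, SiteKey, link_class, site_key
from .masschem import REPORTER_126, REPORTER_127
from .spectra import SpectraRun, Spectrum, peaks_in_window

__all__ = [
    "PurityMatrix", "DEFAULT_PURITY", "ReporterIntensities", "QuantRecord",
    "SiteQuant", "extract_reporters", "correct_impurity", "log2_ratio",
    "quantify", "aggregate_sites", "recenter", "interference_scan",
    "sites_to_frame", "records_to_frame",
]


@dataclass(frozen=True)
class PurityMatrix:
    """2x2 channel-purity matrix; column j = distribution of channel j's
    true signal across observed channels (rows = observed 126, 127)."""

    values: Tuple[Tuple[float, float], Tuple[float, float]]

    def __post_init__(self) -> None:
        m = np.asarray(self.values, dtype=float)
        if m.shape != (2, 2):
            raise ValueError("purity matrix must be 2x2")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError("purity entries must lie in [0, 1]")
        if np.any(m.sum(axis=0) > 1 + 1e-9):
            raise ValueError("purity column sums must be <= 1")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("purity matrix is singular")

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


#: Reagent-lot purity values shipped as the default.
DEFAULT_PURITY = PurityMatrix(((0.90754, 0.01), (0.09246, 0.90724)))

IDENTITY_PURITY = PurityMatrix(((1.0, 0.0), (0.0, 1.0)))


@dataclass(frozen=True)
class ReporterIntensities:
    """Raw and corrected channel intensities for one spectrum."""

    i126: float
    i127: float
    a126: Optional[float] = None
    a127: Optional[float] = None
    status: str = "ok"  # ok | missing126 | missing127 | both_missing |
    #                     nonpositive_after_correction


def extract_reporters(
    s: Spectrum, tol: float = 0.005, unit: str = "Da", mode: str = "sum"
) -> ReporterIntensities:
    """Raw (I126, I127): per channel, the sum (or max) of peak intensities
    within ±tol of the channel's theoretical m/z; 0 when no peak."""
    if mode not in ("sum", "max"):
        raise ValueError(f"mode must be 'sum' or 'max', got {mode!r}")
    out = []
    for channel in (REPORTER_126, REPORTER_127):
        peaks = peaks_in_window(s, channel.mz, tol, unit)
        if not peaks:
            out.append(0.0)
        elif mode == "sum":
            out.append(sum(p.intensity for p in peaks))
        else:
            out.append(max(p.intensity for p in peaks))
    i126, i127 = out
    if i126 <= 0 and i127 <= 0:
        status = "both_missing"
    elif i126 <= 0:
        status = "missing126"
    elif i127 <= 0:
        status = "missing127"
    else:
        status = "ok"
    return ReporterIntensities(i126, i127, status=status)


def correct_impurity(
    raw: ReporterIntensities | Tuple[float, float],
    purity: PurityMatrix = DEFAULT_PURITY,
) -> ReporterIntensities:
    """Solve M @ A = I for the true channel intensities.

    Equivalent (to numerical precision) to the closed forms obtained by
    eliminating one channel from the 2x2 system; with the default matrix,
    A126 = (I126 - I127*0.01102)/0.906521 and
    A127 = (I127 - I126*0.10188)/0.906221.
    A non-positive corrected channel is flagged, not clamped: clamping to
    zero would fabricate infinite ratios downstream.
    """
    if isinstance(raw, tuple):
        raw = ReporterIntensities(*raw)
    if raw.i126 < 0 or raw.i127 < 0:
        raise ValueError("raw intensities must be non-negative")
    a = np.linalg.solve(purity.matrix, np.array([raw.i126, raw.i127]))
    status = raw.status
    if status == "ok" and (a[0] <= 0 or a[1] <= 0):
        status = "nonpositive_after_correction"
    return replace(raw, a126=float(a[0]), a127=float(a[1]), status=status)


def closed_form_correction(
    i126: float, i127: float, purity: PurityMatrix = DEFAULT_PURITY
) -> Tuple[float, float]:
    """Gaussian elimination of the 2x2 system in closed form.

    Returned coefficients reduce, for the default matrix, to
    (I126 - I127*0.01102)/0.906521 and (I127 - I126*0.10188)/0.906221.
    Used as the independent route in tests against the linear solve.
    """
    (m11, m12), (m21, m22) = purity.values
    a126 = (i126 - i127 * (m12 / m22)) / (m11 - m12 * m21 / m22)
    a127 = (i127 - i126 * (m21 / m11)) / (m22 - m12 * m21 / m11)
    return a126, a127


def log2_ratio(
    corrected: ReporterIntensities, orientation: str = "127/126"
) -> Optional[float]:
    """log2 of the requested corrected-channel quotient; None (never ±inf)
    when either corrected channel is missing or non-positive."""
    if orientation not in ("127/126", "126/127"):
        raise ValueError(f"orientation must be '127/126' or '126/127', got {orientation!r}")
    a126, a127 = corrected.a126, corrected.a127
    if a126 is None or a127 is None or a126 <= 0 or a127 <= 0:
        return None
    r = a127 / a126 if orientation == "127/126" else a126 / a127
    return math.log2(r)


@dataclass(frozen=True)
class QuantRecord:
    """Per-spectrum quantification outcome tied to an identification."""

    run_id: str
    scan: int
    key: SiteKey
    link_class: str
    intensities: ReporterIntensities
    ratio: Optional[float]  # log2, in the declared orientation
    orientation: str
    engines: frozenset = frozenset()


@dataclass
class SiteQuant:
    """Aggregated ratio for one site (monolink) or site pair (crosslink)."""

    key: SiteKey
    link_class: str
    n_spectra: int
    mean_ratio: float
    sd_ratio: float
    orientation: str
    engines: frozenset = frozenset()


def quantify(
    run: SpectraRun,
    ids: Sequence[AnyID],
    tol: float = 0.005,
    unit: str = "Da",
    purity: PurityMatrix = DEFAULT_PURITY,
    orientation: str = "127/126",
    mode: str = "sum",
    include_decoys: bool = False,
) -> List[QuantRecord]:
    """Extract, correct and ratio the reporters of every identified spectrum.

    IDs whose scans are absent from the run are counted and warned about,
    never fatal.
    """
    by_scan = run.by_scan()
    records: List[QuantRecord] = []
    missing = 0
    for ident in ids:
        if ident.decoy and not include_decoys:
            continue
        s = by_scan.get(ident.scan)
        if s is None or ident.run_id != run.run_id:
            missing += 1
            continue
        raw = extract_reporters(s, tol, unit, mode)
        corr = correct_impurity(raw, purity)
        records.append(
            QuantRecord(
                run_id=ident.run_id,
                scan=ident.scan,
                key=site_key(ident),
                link_class=link_class(site_key(ident)),
                intensities=corr,
                ratio=log2_ratio(corr, orientation),
                orientation=orientation,
                engines=ident.engines,
            )
        )
    if missing:
        warnings.warn(f"{missing} identification(s) had no matching scan", stacklevel=2)
    return records


def aggregate_sites(records: Iterable[QuantRecord]) -> List[SiteQuant]:
    """Average the per-spectrum log2 ratios of every site key.

    The site mean is the arithmetic mean of contributing spectra's log2
    ratios (spectra without a ratio are excluded); SD is the sample standard
    deviation (0 for a single spectrum).
    """
    groups: Dict[SiteKey, List[QuantRecord]] = {}
    order: List[SiteKey] = []
    for rec in records:
        if rec.ratio is None:
            continue
        if rec.key not in groups:
            order.append(rec.key)
        groups.setdefault(rec.key, []).append(rec)
    out = []
    for key in order:
        recs = groups[key]
        ratios = np.array([r.ratio for r in recs])
        engines = frozenset().union(*(r.engines for r in recs))
        out.append(
            SiteQuant(
                key=key,
                link_class=recs[0].link_class,
                n_spectra=len(recs),
                mean_ratio=float(ratios.mean()),
                sd_ratio=float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
                orientation=recs[0].orientation,
                engines=engines,
            )
        )
    return out


def recenter(
    sites: Sequence[SiteQuant],
    selector,
    target: float = 0.0,
    mode: str = "median",
) -> Tuple[List[SiteQuant], float]:
    """Shift the mean ratios of a selected group; leave the rest untouched.

    ``selector`` is a predicate over :class:`SiteQuant`.  ``mode="median"``
    shifts the group so its median equals ``target`` (used e.g. to re-center
    one protein's intralinks when input stoichiometry differs between
    channels); ``mode="offset"`` adds the fixed ``target`` to the group.
    Returns (new sites, shift applied).
    """
    chosen = [s for s in sites if selector(s)]
    if not chosen:
        raise ValueError("re-centering selector matched no sites")
    if mode == "median":
        shift = target - float(np.median([s.mean_ratio for s in chosen]))
    elif mode == "offset":
        shift = target
    else:
        raise ValueError(f"mode must be 'median' or 'offset', got {mode!r}")
    out = []
    for s in sites:
        if selector(s):
            s = SiteQuant(s.key, s.link_class, s.n_spectra,
                          s.mean_ratio + shift, s.sd_ratio, s.orientation,
                          s.engines)
        out.append(s)
    return out, shift


def interference_percent(count: int, total: int) -> float:
    """Percent of spectra affected, to 2 decimals (NaN for an empty run).

    The exact rounding used by :func:`interference_scan` when reporting, so
    worked examples can be checked against the same code path.
    """
    return round(100.0 * count / total, 2) if total else float("nan")


def interference_scan(
    run: SpectraRun,
    targets: Sequence[float] = (REPORTER_126.mz, REPORTER_127.mz),
    tol: float = 40.0,
    unit: str = "ppm",
    ms_level: int = 2,
) -> pd.DataFrame:
    """Count spectra containing any peak within the window of each target m/z.

    A spectrum counts once per target.  Percent = 100 * count / total spectra
    at the requested MS level, reported to 2 decimals; with an empty run the
    percent is NaN (flagged by ``total == 0``).
    """
    spectra = [s for s in run if s.ms_level == ms_level]
    total = len(spectra)
    rows = []
    for t in targets:
        count = sum(1 for s in spectra if peaks_in_window(s, t, tol, unit))
        percent = interference_percent(count, total)
        rows.append({"target_mz": t, "count": count, "total": total,
                     "percent": percent})
    return pd.DataFrame(rows)


def records_to_frame(records: Sequence[QuantRecord]) -> pd.DataFrame:
    """Per-spectrum detail table."""
    return pd.DataFrame(
        {
            "run": r.run_id,
            "scan": r.scan,
            "site": str(r.key),
            "link_class": r.link_class,
            "I126": r.intensities.i126,
            "I127": r.intensities.i127,
            "A126": r.intensities.a126,
            "A127": r.intensities.a127,
            "status": r.intensities.status,
            f"log2_{r.orientation.replace('/', '_')}": r.ratio,
        }
        for r in records
    )


def sites_to_frame(sites: Sequence[SiteQuant]) -> pd.DataFrame:
    """Site-level quantification table."""
    return pd.DataFrame(
        {
            "site": str(s.key),
            "link_class": s.link_class,
            "n_spectra": s.n_spectra,
            "mean_log2_ratio": s.mean_ratio,
            "sd_log2_ratio": s.sd_ratio,
            "orientation": s.orientation,
            "engines": ";".join(sorted(s.engines)),
        }
        for s in sites
    )
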