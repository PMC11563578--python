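"""Crosslink/monolink identification model, parsers, fragments and validation.

Search engines (pLink2, Nexus, Comet) identify Qlinker-modified spectra; this
module parses their outputs into a unified model, canonicalizes crosslink
sites into order-insensitive keys, generates theoretical b/y fragment ladders
(crosslinked partner treated as a fixed mass, since the linker is
non-MS-cleavable), and applies the spectrum-quality rule: a match is accepted
when each peptide shows at least four consecutive b or y ions and the
majority of observed fragment-ion intensity is annotated.

Two input dialects are supported:

* ``interchange_tsv`` — the package's own format with columns
  run, scan, type{mono|xl}, pepA, linkA, protA, resA, pepB, linkB, protB,
  resB, score, engine, decoy.
* ``plink2_csv`` — pLink2 filtered spectra CSV (Title, Peptide like
  ``SEQA(3)-SEQB(5)``, Proteins like ``ProtA (123)-ProtB (45)``).

Residue numbering is 1-based in peptides and proteins (``Rpb1:K15`` style).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, replace as _dc_replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import masschem
from .masschem import (
    AMINO_ACID_MASSES,
    PROTON_MASS,
    WATER,
    monoisotopic_mass,
    qlinker_deltas,
    tolerance_window,
)
from .spectra import Spectrum

__all__ = [
    "PeptideForm", "MonolinkID", "CrosslinkID", "SiteKey", "ValidationReport",
    "ParseIssue", "parse_ids", "merge_engines", "site_key",
    "theoretical_fragments", "validate_spectrum",
]

QLINKER_CROSSLINK, QLINKER_MONOLINK = qlinker_deltas()
_WATER_MASS = monoisotopic_mass(WATER)


@dataclass(frozen=True)
class PeptideForm:
    """A peptide with positioned modifications and the linker-bearing residue.

    ``modifications`` maps 1-based residue positions to added masses (Da);
    ``link_position`` is the 1-based index of the Qlinker-bearing residue.
    """

    sequence: str
    link_position: int
    modifications: Tuple[Tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        if not (1 <= self.link_position <= len(self.sequence)):
            raise ValueError(
                f"link position {self.link_position} outside peptide "
                f"{self.sequence!r} (length {len(self.sequence)})"
            )
        for pos, _ in self.modifications:
            if not (1 <= pos <= len(self.sequence)):
                raise ValueError(f"modification position {pos} outside peptide")

    @property
    def mass(self) -> float:
        """Neutral mass including positioned modifications (no linker)."""
        return masschem.peptide_mass(
            self.sequence, (m for _, m in self.modifications)
        )


ProteinSite = Tuple[str, int]  # (protein name, 1-based residue number)


@dataclass(frozen=True)
class _BaseID:
    run_id: str
    scan: int
    engines: frozenset = frozenset()
    score: float = 0.0
    decoy: bool = False


@dataclass(frozen=True)
class MonolinkID(_BaseID):
    peptide: PeptideForm = None  # type: ignore[assignment]
    site: ProteinSite = None  # type: ignore[assignment]

    @property
    def peptides(self) -> Tuple[PeptideForm, ...]:
        return (self.peptide,)


@dataclass(frozen=True)
class CrosslinkID(_BaseID):
    alpha: PeptideForm = None  # type: ignore[assignment]
    beta: PeptideForm = None  # type: ignore[assignment]
    site_alpha: ProteinSite = None  # type: ignore[assignment]
    site_beta: ProteinSite = None  # type: ignore[assignment]

    @property
    def peptides(self) -> Tuple[PeptideForm, ...]:
        return (self.alpha, self.beta)


AnyID = Union[MonolinkID, CrosslinkID]


@dataclass(frozen=True)
class SiteKey:
    """Canonical site identity: one residue (monolink) or an unordered pair.

    Crosslink pairs are stored lexicographically by (protein, residue) so
    that equality is order-insensitive.
    """

    sites: Tuple[ProteinSite, ...]

    def __post_init__(self) -> None:
        if len(self.sites) not in (1, 2):
            raise ValueError("a site key holds one or two protein sites")
        object.__setattr__(self, "sites", tuple(sorted(self.sites)))

    @property
    def is_crosslink(self) -> bool:
        return len(self.sites) == 2

    def __str__(self) -> str:
        return "--".join(f"{p}:{r}" for p, r in self.sites)

    @classmethod
    def from_string(cls, text: str) -> "SiteKey":
        sites = []
        for part in text.split("--"):
            prot, res = part.rsplit(":", 1)
            sites.append((prot, int(res)))
        return cls(tuple(sites))


def site_key(ident: AnyID) -> SiteKey:
    """Canonical :class:`SiteKey` for an identification."""
    if isinstance(ident, MonolinkID):
        if ident.site is None:
            raise ValueError("monolink lacks a protein site")
        return SiteKey((ident.site,))
    if ident.site_alpha is None or ident.site_beta is None:
        raise ValueError("crosslink lacks protein sites")
    return SiteKey((ident.site_alpha, ident.site_beta))


def link_class(key: SiteKey) -> str:
    """monolink / intralink (same protein) / interlink (two proteins)."""
    if not key.is_crosslink:
        return "monolink"
    return "intralink" if key.sites[0][0] == key.sites[1][0] else "interlink"


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

@dataclass
class ParseIssue:
    row: int
    message: str


INTERCHANGE_COLUMNS = [
    "run", "scan", "type", "pepA", "linkA", "protA", "resA",
    "pepB", "linkB", "protB", "resB", "score", "engine", "decoy",
]


def parse_ids(
    path: str | Path,
    dialect: str = "interchange_tsv",
    issues: Optional[List[ParseIssue]] = None,
) -> List[AnyID]:
    """Parse an identification table into Monolink/Crosslink IDs.

    Unparseable rows are collected into ``issues`` (if given) and skipped;
    the run continues.  Decoy rows are flagged, not dropped.
    """
    path = Path(path)
    if dialect == "interchange_tsv":
        return _parse_interchange(path, issues)
    if dialect == "plink2_csv":
        return _parse_plink2(path, issues)
    raise ValueError(f"unknown dialect {dialect!r}")


def _record_issue(issues: Optional[List[ParseIssue]], row: int, msg: str) -> None:
    if issues is not None:
        issues.append(ParseIssue(row, msg))


def _parse_interchange(path: Path, issues: Optional[List[ParseIssue]]) -> List[AnyID]:
    ids: List[AnyID] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for rownum, row in enumerate(reader, start=2):
            try:
                ids.append(_interchange_row(row))
            except (ValueError, KeyError, TypeError) as exc:
                _record_issue(issues, rownum, str(exc))
    return ids


def _interchange_row(row: Dict[str, str]) -> AnyID:
    engines = frozenset(e for e in row.get("engine", "").split(";") if e)
    common = dict(
        run_id=row["run"],
        scan=int(row["scan"]),
        engines=engines,
        score=float(row.get("score") or 0.0),
        decoy=(row.get("decoy", "0").strip().lower() in ("1", "true", "yes")),
    )
    pep_a = PeptideForm(row["pepA"], int(row["linkA"]))
    site_a = (row["protA"], int(row["resA"]))
    if row["type"] == "mono":
        return MonolinkID(peptide=pep_a, site=site_a, **common)
    if row["type"] == "xl":
        pep_b = PeptideForm(row["pepB"], int(row["linkB"]))
        site_b = (row["protB"], int(row["resB"]))
        return CrosslinkID(
            alpha=pep_a, beta=pep_b, site_alpha=site_a, site_beta=site_b, **common
        )
    raise ValueError(f"unknown id type {row['type']!r}")


_PLINK_PEPTIDE = re.compile(r"^([A-Z]+)\((\d+)\)-([A-Z]+)\((\d+)\)$")
_PLINK_MONO = re.compile(r"^([A-Z]+)\((\d+)\)$")
_PLINK_PROTEIN = re.compile(r"^(.+?)\s*\((\d+)\)-(.+?)\s*\((\d+)\)")
_PLINK_PROT_MONO = re.compile(r"^(.+?)\s*\((\d+)\)")


def _parse_plink2(path: Path, issues: Optional[List[ParseIssue]]) -> List[AnyID]:
    """Read a pLink2 spectra CSV (crosslink or monolink flavor)."""
    ids: List[AnyID] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for rownum, row in enumerate(reader, start=2):
            try:
                ids.append(_plink2_row(row))
            except (ValueError, KeyError, AttributeError) as exc:
                _record_issue(issues, rownum, str(exc))
    return ids


def _plink2_row(row: Dict[str, str]) -> AnyID:
    title = row["Title"]
    # Titles follow "run.scan.scan.charge[.dta]"
    parts = title.split(".")
    run_id, scan = parts[0], int(parts[1])
    score = float(row.get("Score") or row.get("Evalue") or 0.0)
    common = dict(run_id=run_id, scan=scan, engines=frozenset({"pLink2"}),
                  score=score, decoy=False)
    pep = row["Peptide"]
    m = _PLINK_PEPTIDE.match(pep)
    if m:
        seq_a, link_a, seq_b, link_b = m.group(1), int(m.group(2)), m.group(3), int(m.group(4))
        pm = _PLINK_PROTEIN.match(row["Proteins"])
        if not pm:
            raise ValueError(f"cannot parse Proteins field {row['Proteins']!r}")
        return CrosslinkID(
            alpha=PeptideForm(seq_a, link_a),
            beta=PeptideForm(seq_b, link_b),
            site_alpha=(pm.group(1).strip(), int(pm.group(2))),
            site_beta=(pm.group(3).strip(), int(pm.group(4))),
            **common,
        )
    m = _PLINK_MONO.match(pep)
    if m:
        pm = _PLINK_PROT_MONO.match(row["Proteins"])
        if not pm:
            raise ValueError(f"cannot parse Proteins field {row['Proteins']!r}")
        return MonolinkID(
            peptide=PeptideForm(m.group(1), int(m.group(2))),
            site=(pm.group(1).strip(), int(pm.group(2))),
            **common,
        )
    raise ValueError(f"cannot parse Peptide field {pep!r}")


def write_interchange(ids: Sequence[AnyID], path: str | Path) -> None:
    """Write identifications in the interchange TSV dialect."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(INTERCHANGE_COLUMNS)
        for i in ids:
            if isinstance(i, MonolinkID):
                row = [i.run_id, i.scan, "mono", i.peptide.sequence,
                       i.peptide.link_position, i.site[0], i.site[1],
                       "", "", "", ""]
            else:
                row = [i.run_id, i.scan, "xl", i.alpha.sequence,
                       i.alpha.link_position, i.site_alpha[0], i.site_alpha[1],
                       i.beta.sequence, i.beta.link_position,
                       i.site_beta[0], i.site_beta[1]]
            row += [f"{i.score:g}", ";".join(sorted(i.engines)), int(i.decoy)]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# Merging engines
# ---------------------------------------------------------------------------

def merge_engines(*idsets: Iterable[AnyID]) -> List[AnyID]:
    """Combine identification lists from several engines.

    One record per (run, scan) when engines agree on the site key (engine
    sets are unioned, the best score kept); conflicting site keys for one
    scan are all kept and can be found via duplicate (run, scan) pairs.
    Idempotent: merging a merged list is a no-op.
    """
    grouped: Dict[Tuple[str, int, SiteKey], AnyID] = {}
    order: List[Tuple[str, int, SiteKey]] = []
    for ids in idsets:
        for ident in ids:
            k = (ident.run_id, ident.scan, site_key(ident))
            if k in grouped:
                prev = grouped[k]
                grouped[k] = _replace_engines(
                    prev if prev.score >= ident.score else ident,
                    prev.engines | ident.engines,
                )
            else:
                grouped[k] = ident
                order.append(k)
    return [grouped[k] for k in order]


def _replace_engines(ident: AnyID, engines: frozenset) -> AnyID:
    return _dc_replace(ident, engines=engines)


def ambiguous_scans(ids: Sequence[AnyID]) -> Dict[Tuple[str, int], List[AnyID]]:
    """Scans carrying more than one distinct site key after merging."""
    by_scan: Dict[Tuple[str, int], List[AnyID]] = {}
    for ident in ids:
        by_scan.setdefault((ident.run_id, ident.scan), []).append(ident)
    return {k: v for k, v in by_scan.items() if len(v) > 1}


# ---------------------------------------------------------------------------
# Theoretical fragments and spectrum validation
# ---------------------------------------------------------------------------

def theoretical_fragments(
    ident: AnyID,
    charges: Sequence[int] = (1, 2),
    include_linker: bool = True,
) -> List[Tuple[str, float]]:
    """(label, m/z) for all b_i / y_i ions of each peptide in the ID.

    For a monolink the monolink delta sits on the link residue.  For a
    crosslink the partner peptide plus the crosslink delta is treated as a
    fixed mass on the linked residue of the chain being fragmented (the
    linker is non-MS-cleavable, so no stub ions are produced).
    """
    out: List[Tuple[str, float]] = []
    peptides = ident.peptides
    for pi, pep in enumerate(peptides):
        label = "AB"[pi] if len(peptides) > 1 else ""
        extra = dict(pep.modifications)
        if include_linker:
            add = extra.get(pep.link_position, 0.0)
            if isinstance(ident, MonolinkID):
                add += QLINKER_MONOLINK.delta_mass
            else:
                partner = peptides[1 - pi]
                add += QLINKER_CROSSLINK.delta_mass + partner.mass
            extra[pep.link_position] = add
        seq = pep.sequence
        n = len(seq)
        residue_masses = [
            AMINO_ACID_MASSES[aa] + extra.get(i + 1, 0.0)
            for i, aa in enumerate(seq)
        ]
        prefix = 0.0
        b_neutral = []
        for i in range(n - 1):
            prefix += residue_masses[i]
            b_neutral.append(prefix)
        total = sum(residue_masses)
        for z in charges:
            for i, bm in enumerate(b_neutral, start=1):
                out.append((f"b{label}{i}+{z}", (bm + z * PROTON_MASS) / z))
            for i in range(1, n):
                ym = total - b_neutral[n - 1 - i] + _WATER_MASS
                out.append((f"y{label}{i}+{z}", (ym + z * PROTON_MASS) / z))
    return out


@dataclass
class ValidationReport:
    """Per-peptide consecutive-run lengths and annotated-intensity fraction.

    ``passed`` is true when every peptide shows a b-run >= 4 or a y-run >= 4
    and at least ``majority_threshold`` of the observed fragment-ion
    intensity is annotated.
    """

    b_runs: Tuple[int, ...]
    y_runs: Tuple[int, ...]
    annotated_fraction: float
    passed: bool
    min_run: int = 4
    majority_threshold: float = 0.5


def _longest_run(hits: Sequence[bool]) -> int:
    best = cur = 0
    for h in hits:
        cur = cur + 1 if h else 0
        best = max(best, cur)
    return best


def validate_spectrum(
    ident: AnyID,
    spectrum: Spectrum,
    frag_tol_ppm: float = 20.0,
    charges: Sequence[int] = (1, 2),
    min_run: int = 4,
    majority_threshold: float = 0.5,
    exclude_reporter_region: bool = True,
) -> ValidationReport:
    """Annotate a spectrum against its ID's fragment ladder and apply the
    acceptance rule (>=4 consecutive b or y ions per peptide, majority of
    observed ion intensity annotated).

    ``exclude_reporter_region`` removes peaks below 132 m/z (reporter ions
    and immonium region) from the annotated-fraction denominator, since
    reporter intensity is not backbone fragmentation.
    """
    frags = theoretical_fragments(ident, charges)
    annotated_idx: set = set()
    matched: Dict[str, bool] = {}
    for label, mz in frags:
        low, high = tolerance_window(mz, frag_tol_ppm, "ppm")
        i = int(np.searchsorted(spectrum.mz, low, side="left"))
        j = int(np.searchsorted(spectrum.mz, high, side="right"))
        if j > i:
            matched[label] = True
            annotated_idx.update(range(i, j))
        else:
            matched.setdefault(label, False)

    peptides = ident.peptides
    b_runs, y_runs = [], []
    for pi, pep in enumerate(peptides):
        plabel = "AB"[pi] if len(peptides) > 1 else ""
        n = len(pep.sequence)
        b_hits = [
            any(matched.get(f"b{plabel}{i}+{z}", False) for z in charges)
            for i in range(1, n)
        ]
        y_hits = [
            any(matched.get(f"y{plabel}{i}+{z}", False) for z in charges)
            for i in range(1, n)
        ]
        b_runs.append(_longest_run(b_hits))
        y_runs.append(_longest_run(y_hits))

    weights = spectrum.intensity
    if exclude_reporter_region:
        keep = spectrum.mz >= 132.0
    else:
        keep = np.ones(len(spectrum), dtype=bool)
    total = float(weights[keep].sum())
    ann_mask = np.zeros(len(spectrum), dtype=bool)
    if annotated_idx:
        ann_mask[sorted(annotated_idx)] = True
    annotated = float(weights[ann_mask & keep].sum())
    frac = annotated / total if total > 0 else 0.0

    runs_ok = all(
        max(b, y) >= min_run for b, y in zip(b_runs, y_runs)
    )
    passed = runs_ok and frac >= majority_threshold
    return ValidationReport(
        tuple(b_runs), tuple(y_runs), frac, passed, min_run, majority_threshold
    )
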