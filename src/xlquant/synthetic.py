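"""Seeded synthetic qCLMS datasets: spectra + identifications + ground truth.

The generator inverts the quantification model so every pipeline stage is
testable without instrument data.  For each configured site it draws true
channel intensities honoring the site's log2(127/126) ratio, forward-mixes
them through the 2x2 purity matrix into raw reporter peaks at the theoretical
reporter m/z, emits the b/y fragment ladder of the (tryptic) Qlinker-modified
peptide, sprinkles noise peaks, and writes matched identification rows — so
the quant pipeline, run on the emitted data, should recover the configured
site ratios exactly (no noise) or within sampling error (with noise).

Peptides come from a bundled toy proteome (synthetic sequences under familiar
subunit names, e.g. Rpb1..Rpb12, TBP, TOA1, TOA2) so site keys look realistic
without any downloads; peptide bounds follow tryptic cleavage after K/R with
the linker-bearing lysine treated as uncleavable.

Everything is a pure function of the config, including its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .ident import (
    AnyID,
    CrosslinkID,
    MonolinkID,
    PeptideForm,
    SiteKey,
    link_class,
    theoretical_fragments,
    write_interchange,
)
from .masschem import PROTON_MASS, REPORTER_126, REPORTER_127
from .quant import DEFAULT_PURITY, PurityMatrix
from .spectra import SpectraRun, Spectrum, write_json_run, write_mzml

__all__ = [
    "SimSite", "SimConfig", "GroundTruth", "load_toy_proteome",
    "random_sites", "simulate_run", "simulate_swap", "simulate_background_run",
    "write_dataset",
]


def load_toy_proteome() -> Dict[str, str]:
    """Bundled synthetic toy proteome: protein name -> sequence."""
    text = (resources.files("xlquant") / "data" / "toy_proteome.fasta").read_text()
    seqs: Dict[str, str] = {}
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            seqs[name] = ""
        elif name:
            seqs[name] += line.strip()
    return seqs


def _tryptic_bounds(seq: str, kpos: int) -> Tuple[int, int]:
    """[start, end] 1-based bounds of the tryptic peptide containing the
    linker-bearing lysine at ``kpos``; the modified K itself is uncleavable."""
    start = 1
    for i in range(kpos - 1, 0, -1):  # cleavage after residue i (1-based)
        if seq[i - 1] in "KR":
            start = i + 1
            break
    end = len(seq)
    for j in range(kpos + 1, len(seq) + 1):
        if seq[j - 1] in "KR":
            end = j
            break
    return start, end


def _peptide_for_site(proteome: Mapping[str, str], site: Tuple[str, int]) -> PeptideForm:
    protein, resnum = site
    if protein not in proteome:
        raise KeyError(f"protein {protein!r} not in the proteome")
    seq = proteome[protein]
    if not (1 <= resnum <= len(seq)) or seq[resnum - 1] != "K":
        raise ValueError(f"site {protein}:{resnum} is not a lysine")
    start, end = _tryptic_bounds(seq, resnum)
    return PeptideForm(seq[start - 1 : end], resnum - start + 1)


@dataclass(frozen=True)
class SimSite:
    """One quantifiable site with its ground-truth ratio and spectrum count."""

    key: SiteKey
    true_log2_ratio: float  # log2(127/126)
    n_spectra: int = 1

    def __post_init__(self) -> None:
        if self.n_spectra < 0:
            raise ValueError("spectra count must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults emulate a clean 2-plex reporter run.

    Intensities are log-normal (median ~5e4 counts); the site ratio is
    applied multiplicatively to the 127 channel; ``ratio_noise_sd`` adds
    per-spectrum Gaussian scatter (log2 units) around the site's true ratio
    before forward mixing.  Noise peaks avoid the reporter windows unless
    ``interference_fraction`` > 0, which plants a peak inside a randomly
    chosen reporter window in that fraction of spectra.
    """

    sites: Tuple[SimSite, ...]
    seed: int = 0
    base_intensity_mu: float = math.log(5e4)  # log-space mean
    base_intensity_sigma: float = 0.6  # log-space sd
    purity: PurityMatrix = DEFAULT_PURITY
    n_noise_peaks: int = 30
    noise_intensity_mu: float = math.log(300.0)
    noise_intensity_sigma: float = 1.0
    ladder_completeness: float = 1.0
    reporter_dropout: float = 0.0
    ratio_noise_sd: float = 0.0
    interference_fraction: float = 0.0
    run_id: str = "sim"

    def __post_init__(self) -> None:
        for name in ("ladder_completeness", "reporter_dropout", "interference_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ratio_noise_sd < 0 or self.base_intensity_sigma < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.n_noise_peaks < 0:
            raise ValueError("n_noise_peaks must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually emitted, keyed for later comparison."""

    site_ratio: Dict[SiteKey, float]  # configured true log2(127/126)
    spectrum_truth: Dict[int, Tuple[float, float, float]]  # scan -> (A126, A127, ratio)


_REPORTER_MZS = (REPORTER_126.mz, REPORTER_127.mz)
_REPORTER_GUARD = 0.02  # Da half-width kept free of noise peaks


def random_sites(
    n: int,
    true_ratios: Sequence[float],
    n_spectra: int,
    seed: int = 0,
    classes: Sequence[str] = ("monolink", "intralink", "interlink"),
    proteome: Optional[Mapping[str, str]] = None,
) -> Tuple[SimSite, ...]:
    """Draw ``n`` distinct lysine sites from the toy proteome, cycling through
    ``true_ratios`` and ``classes``."""
    proteome = dict(proteome or load_toy_proteome())
    rng = np.random.default_rng(seed)
    lysines = [
        (name, i + 1)
        for name, seq in sorted(proteome.items())
        for i, aa in enumerate(seq)
        if aa == "K" and 1 < i + 1 < len(seq)
    ]
    rng.shuffle(lysines)
    sites: List[SimSite] = []
    used: set = set()
    pool = iter(lysines)
    while len(sites) < n:
        cls = classes[len(sites) % len(classes)]
        ratio = float(true_ratios[len(sites) % len(true_ratios)])
        try:
            a = next(pool)
        except StopIteration as exc:
            raise ValueError("toy proteome exhausted; request fewer sites") from exc
        if cls == "monolink":
            key = SiteKey((a,))
        else:
            partner = None
            for b in lysines:
                if b == a or (a, b) in used or (b, a) in used:
                    continue
                same = b[0] == a[0]
                if cls == "intralink" and same and abs(b[1] - a[1]) > 6:
                    partner = b
                    break
                if cls == "interlink" and not same:
                    partner = b
                    break
            if partner is None:
                continue
            used.add((a, partner))
            key = SiteKey((a, partner))
        if key in {s.key for s in sites}:
            continue
        sites.append(SimSite(key, ratio, n_spectra))
    return tuple(sites)


def _make_id(
    proteome: Mapping[str, str], site: SimSite, run_id: str, scan: int
) -> AnyID:
    key = site.key
    if not key.is_crosslink:
        return MonolinkID(
            run_id=run_id, scan=scan, engines=frozenset({"sim"}), score=1.0,
            peptide=_peptide_for_site(proteome, key.sites[0]), site=key.sites[0],
        )
    return CrosslinkID(
        run_id=run_id, scan=scan, engines=frozenset({"sim"}), score=1.0,
        alpha=_peptide_for_site(proteome, key.sites[0]),
        beta=_peptide_for_site(proteome, key.sites[1]),
        site_alpha=key.sites[0], site_beta=key.sites[1],
    )


def simulate_run(
    cfg: SimConfig, proteome: Optional[Mapping[str, str]] = None
) -> Tuple[SpectraRun, List[AnyID], GroundTruth]:
    """Emit (spectra, matching identifications, ground truth) for a config."""
    proteome = dict(proteome or load_toy_proteome())
    rng = np.random.default_rng(cfg.seed)
    M = cfg.purity.matrix
    spectra: List[Spectrum] = []
    ids: List[AnyID] = []
    truth = GroundTruth({}, {})
    scan = 0
    for site in cfg.sites:
        truth.site_ratio[site.key] = site.true_log2_ratio
        template = _make_id(proteome, site, cfg.run_id, 0)
        frag_mzs = np.array([mz for _, mz in theoretical_fragments(template, charges=(1,))])
        prec_mass = sum(p.mass for p in template.peptides)
        if site.key.is_crosslink:
            from .ident import QLINKER_CROSSLINK

            prec_mass += QLINKER_CROSSLINK.delta_mass
        else:
            from .ident import QLINKER_MONOLINK

            prec_mass += QLINKER_MONOLINK.delta_mass
        z = 3
        prec_mz = (prec_mass + z * PROTON_MASS) / z
        for _ in range(site.n_spectra):
            scan += 1
            r = site.true_log2_ratio + (
                rng.normal(0.0, cfg.ratio_noise_sd) if cfg.ratio_noise_sd else 0.0
            )
            base = rng.lognormal(cfg.base_intensity_mu, cfg.base_intensity_sigma)
            a = np.array([base, base * 2.0**r])
            i_obs = M @ a
            mzs: List[float] = []
            ints: List[float] = []
            dropped = None
            if cfg.reporter_dropout and rng.random() < cfg.reporter_dropout:
                dropped = int(rng.integers(2))
            for ch in range(2):
                if ch != dropped:
                    mzs.append(_REPORTER_MZS[ch])
                    ints.append(float(i_obs[ch]))
            keep = (
                rng.random(frag_mzs.size) < cfg.ladder_completeness
                if cfg.ladder_completeness < 1.0
                else np.ones(frag_mzs.size, dtype=bool)
            )
            for mz in frag_mzs[keep]:
                mzs.append(float(mz))
                ints.append(float(rng.lognormal(cfg.base_intensity_mu - 2.3, 0.5)))
            for _ in range(cfg.n_noise_peaks):
                while True:
                    nmz = float(rng.uniform(100.0, 1500.0))
                    if all(abs(nmz - t) > _REPORTER_GUARD for t in _REPORTER_MZS):
                        break
                mzs.append(nmz)
                ints.append(float(rng.lognormal(cfg.noise_intensity_mu, cfg.noise_intensity_sigma)))
            if cfg.interference_fraction and rng.random() < cfg.interference_fraction:
                t = _REPORTER_MZS[int(rng.integers(2))]
                mzs.append(t + float(rng.uniform(-0.002, 0.002)))
                ints.append(float(rng.lognormal(cfg.noise_intensity_mu, cfg.noise_intensity_sigma)))
            spectra.append(Spectrum(
                run_id=cfg.run_id, scan=scan, ms_level=2,
                precursor_mz=prec_mz, precursor_charge=z,
                rt=float(scan) * 1.5, mz=mzs, intensity=ints,
            ))
            ids.append(replace(template, scan=scan))
            truth.spectrum_truth[scan] = (float(a[0]), float(a[1]), float(r))
    return SpectraRun(cfg.run_id, spectra), ids, truth


def simulate_swap(
    cfg: SimConfig,
    changed_effects: Mapping[SiteKey, float],
    proteome: Optional[Mapping[str, str]] = None,
) -> Tuple[
    Tuple[SpectraRun, List[AnyID], GroundTruth],
    Tuple[SpectraRun, List[AnyID], GroundTruth],
]:
    """Two label-swapped experiments from one site panel.

    ``changed_effects`` maps a site key to its log2(126/127) effect in
    experiment I; the swap flips the channel assignment, so in experiment II
    the same site carries the opposite effect.  Sites not listed are
    unchanged (true ratio 0 plus the configured noise).  ``cfg.sites`` ratios
    are ignored; the effect map is the single source of truth.
    """
    def with_ratios(exp_sign: float, seed_offset: int, run_id: str) -> SimConfig:
        sites = tuple(
            # generator ratios are log2(127/126) = -log2(126/127)
            replace(s, true_log2_ratio=-exp_sign * changed_effects.get(s.key, 0.0))
            for s in cfg.sites
        )
        return replace(cfg, sites=sites, seed=cfg.seed + seed_offset, run_id=run_id)

    exp1 = simulate_run(with_ratios(+1.0, 0, cfg.run_id + "_I"), proteome)
    exp2 = simulate_run(with_ratios(-1.0, 1, cfg.run_id + "_II"), proteome)
    return exp1, exp2


def simulate_background_run(
    n_spectra: int,
    planted: Mapping[float, int] = (),
    seed: int = 0,
    n_peaks: int = 40,
    run_id: str = "background",
) -> SpectraRun:
    """A run of plain (non-reporter) MS2 spectra for interference scans.

    ``planted`` maps a target m/z to the number of spectra that should carry
    a peak within 0.002 Da of it; all other peaks avoid every planted target
    by a wide margin.
    """
    planted = dict(planted)
    rng = np.random.default_rng(seed)
    targets = list(planted)
    carriers: Dict[float, set] = {
        t: set(rng.choice(n_spectra, size=planted[t], replace=False))
        for t in targets
    }
    spectra = []
    for i in range(n_spectra):
        mzs: List[float] = []
        ints: List[float] = []
        for _ in range(n_peaks):
            while True:
                mz = float(rng.uniform(100.0, 1500.0))
                if all(abs(mz - t) > 0.05 for t in (*targets, *_REPORTER_MZS)):
                    break
            mzs.append(mz)
            ints.append(float(rng.lognormal(math.log(1e3), 1.0)))
        for t in targets:
            if i in carriers[t]:
                mzs.append(t + float(rng.uniform(-0.002, 0.002)))
                ints.append(float(rng.lognormal(math.log(1e3), 1.0)))
        spectra.append(Spectrum(run_id=run_id, scan=i + 1, ms_level=2,
                                mz=mzs, intensity=ints))
    return SpectraRun(run_id, spectra)


def write_dataset(
    run: SpectraRun,
    ids: Sequence[AnyID],
    truth: GroundTruth,
    outdir: str | Path,
    spectra_format: str = "mzML",
) -> Dict[str, Path]:
    """Write spectra (mzML or JSON), interchange-TSV IDs and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    if spectra_format == "mzML":
        paths["spectra"] = outdir / f"{run.run_id}.mzML"
        write_mzml(run, paths["spectra"])
    elif spectra_format == "json":
        paths["spectra"] = outdir / f"{run.run_id}.json"
        write_json_run(run, paths["spectra"])
    else:
        raise ValueError(f"unknown spectra format {spectra_format!r}")
    paths["ids"] = outdir / f"{run.run_id}.ids.tsv"
    write_interchange(ids, paths["ids"])
    paths["truth"] = outdir / f"{run.run_id}.truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("site\tlink_class\ttrue_log2_127_126\n")
        for key, ratio in truth.site_ratio.items():
            fh.write(f"{key}\t{link_class(key)}\t{ratio:g}\n")
    return paths
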