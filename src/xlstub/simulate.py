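"""Ground-truthed synthetic crosslinking-MS data.

Generates random protein databases with reversed-sequence decoys, samples
crosslinked tryptic peptide pairs, and emits MS2 (and optionally MS3)
spectra with known peak identities. The generator emulates the contrast
between acquisition modes: stepped HCD produces rich backbone
fragmentation with moderately intense stub doublets in a single MS2 scan,
while low-energy CID preferentially cleaves the crosslinker (dominant stub
doublets, sparse backbone fragments) and relies on MS3 scans triggered on
doublet peak pairs for sequence information.

Every spectrum comes with a ground-truth record (true pair, which doublets
were emitted, which backbone cleavage slots were emitted) and with a
candidate list for the downstream scoring step: the true pair plus random
target/decoy pairs standing in for the random matches a search engine
would consider. All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chem import (
    BS3,
    DSSO,
    CrosslinkedPair,
    CrosslinkerSpec,
    Peptide,
    peptide_mass,
    theoretical_fragments,
    tryptic_digest,
)
from .constants import ISOTOPE_SPACING, MONO_RESIDUE_MASSES, H2O, mz_from_neutral
from .io import ProteinRecord, Spectrum

__all__ = [
    "SimulationConfig",
    "Candidate",
    "ScanTruth",
    "Ms3Truth",
    "SimulationResult",
    "generate_protein_db",
    "generate_decoy_db",
    "simulate_crosslinked_spectra",
    "simulate_cid_ms3_run",
    "simulate_fdr_records",
]

DECOY_PREFIX = "REV_"

#: Acquisition-mode presets: (backbone_fragment_prob, stub_intensity_scale).
#: sHCD mixes collision energies in one scan, so backbone fragments are
#: frequent and stubs only moderately dominant; low-energy CID is applied to
#: cleave the crosslinker, so stubs dominate and backbone fragments are sparse.
_ACQUISITION_PRESETS = {
    "sHCD": (0.7, 3.0),
    "CID_MS2": (0.35, 10.0),
    "CID_MS2_MS3": (0.35, 10.0),
}


@dataclass
class SimulationConfig:
    seed: int
    n_proteins: int = 20
    protein_length: int = 300
    crosslinker: CrosslinkerSpec = DSSO
    n_csms: int = 200
    acquisition: str = "sHCD"
    doublet_emission_prob: float = 0.9
    backbone_fragment_prob: float | None = None  # None -> acquisition preset
    stub_intensity_scale: float | None = None  # None -> acquisition preset
    plus_p_emission_prob: float = 0.2
    noise_peaks_per_spectrum: int = 30
    noise_intensity_mu: float = 0.5  # lognormal parameters of noise peaks
    noise_intensity_sigma: float = 0.8
    ms3_trigger_top_n: int = 4
    ms3_backbone_prob: float = 0.9
    ms3_doublet_ppm_tol: float = 10.0
    false_trigger_prob: float = 0.0  # chance of one spurious MS3 per MS2 scan
    n_random_candidates: int = 3
    n_linear_spectra: int = 0
    n_xl_mod_linear_spectra: int = 0
    n_noncovalent_spectra: int = 0
    peptide_length_range: tuple[int, int] = (6, 30)
    max_missed_cleavages: int = 2
    mz_range: tuple[float, float] = (150.0, 1800.0)

    def __post_init__(self):
        if self.acquisition not in _ACQUISITION_PRESETS:
            raise ValueError(f"unknown acquisition mode {self.acquisition!r}")
        for p in (self.doublet_emission_prob, self.plus_p_emission_prob, self.ms3_backbone_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        preset = _ACQUISITION_PRESETS[self.acquisition]
        if self.backbone_fragment_prob is None:
            self.backbone_fragment_prob = preset[0]
        if self.stub_intensity_scale is None:
            self.stub_intensity_scale = preset[1]


@dataclass(frozen=True)
class Candidate:
    """One pair a search would score for a scan; the generator marks the true one."""

    pair: CrosslinkedPair
    is_true: bool = False
    noncovalent_flag: bool = False


@dataclass
class ScanTruth:
    scan_id: str
    kind: str  # 'csm' | 'linear' | 'xl_mod_linear' | 'noncovalent'
    pair: CrosslinkedPair | None = None
    doublet_emitted: dict[str, bool] = field(default_factory=dict)
    emitted_slots: set[tuple[str, str, int]] = field(default_factory=set)  # (owner, series, index)
    stub_pion_mzs: dict[tuple[str, str], float] = field(default_factory=dict)  # (owner, label) -> mz


@dataclass(frozen=True)
class Ms3Truth:
    scan_id: str
    parent_scan_id: str
    intended_owner: str | None  # None = false trigger
    stub_label: str | None


@dataclass
class SimulationResult:
    config: SimulationConfig
    targets: list[ProteinRecord]
    decoys: list[ProteinRecord]
    spectra: list[Spectrum]
    truths: list[ScanTruth]
    candidates: dict[str, list[Candidate]]
    ms3_truths: list[Ms3Truth] = field(default_factory=list)


# Background amino-acid frequencies with K/R tuned so tryptic peptides land
# mostly in the 6-30 residue band (cut density ~0.13 per residue).
_AA = np.array(list(MONO_RESIDUE_MASSES))
_AA_W = np.array([0.08 if a == "K" else 0.05 if a == "R" else 0.87 / 18 for a in _AA])
_AA_W /= _AA_W.sum()


def generate_protein_db(n_proteins: int, protein_length: int, rng: np.random.Generator) -> list[ProteinRecord]:
    """Random target proteins whose tryptic digest yields 6-30mer peptides."""
    records = []
    for i in range(n_proteins):
        seq = "".join(rng.choice(_AA, size=protein_length, p=_AA_W))
        records.append(ProteinRecord(f"P{i:04d}", seq, is_decoy=False))
    return records


def generate_decoy_db(targets: list[ProteinRecord], prefix: str = DECOY_PREFIX) -> list[ProteinRecord]:
    """One reversed-sequence decoy per target (composition-preserving involution)."""
    return [ProteinRecord(prefix + t.accession, t.sequence[::-1], is_decoy=True) for t in targets]


def _linkable_peptides(
    records: list[ProteinRecord], config: SimulationConfig
) -> list[tuple[Peptide, list[int]]]:
    """Digest a database and keep peptides with at least one reactive residue."""
    xl = config.crosslinker
    out = []
    for rec in records:
        for pep in tryptic_digest(
            rec.sequence,
            max_missed=config.max_missed_cleavages,
            length_range=config.peptide_length_range,
            accession=rec.accession,
            is_decoy=rec.is_decoy,
        ):
            sites = [i for i, aa in enumerate(pep.sequence, start=1) if aa in xl.reactive_sites]
            if sites:
                out.append((pep, sites))
    return out


def _envelope(mz: float, charge: int, intensity: float) -> list[tuple[float, float]]:
    """A 3-peak isotope envelope with decreasing intensities, mono first."""
    z = max(charge, 1)
    return [(mz + k * ISOTOPE_SPACING / z, intensity * r) for k, r in enumerate((1.0, 0.45, 0.15))]


def _noise_peaks(config: SimulationConfig, rng: np.random.Generator, n: int | None = None) -> list[tuple[float, float]]:
    n = config.noise_peaks_per_spectrum if n is None else n
    lo, hi = config.mz_range
    mzs = rng.uniform(lo, hi, size=n)
    intens = rng.lognormal(config.noise_intensity_mu, config.noise_intensity_sigma, size=n)
    return list(zip(mzs.tolist(), intens.tolist()))


def _draw_pair(
    pool: list[tuple[Peptide, list[int]]],
    rng: np.random.Generator,
    xl: CrosslinkerSpec,
    charge: int,
    distinct_proteins: bool = False,
) -> CrosslinkedPair:
    while True:
        ia, ib = rng.integers(0, len(pool), size=2)
        pa, sa = pool[ia]
        pb, sb = pool[ib]
        if pa.sequence == pb.sequence:
            continue
        if distinct_proteins and pa.protein_accessions == pb.protein_accessions:
            continue
        return CrosslinkedPair(
            alpha=pa,
            beta=pb,
            link_site_alpha=int(sa[rng.integers(0, len(sa))]),
            link_site_beta=int(sb[rng.integers(0, len(sb))]),
            crosslinker=xl,
            precursor_charge=charge,
        )


def _emit_linear_peaks(
    pep: Peptide, prob: float, scale: float, rng: np.random.Generator, mod_delta: float = 0.0
) -> list[tuple[float, float]]:
    """b/y peaks (charge 1, with envelopes) of a linear peptide, per-slot Bernoulli."""
    residues = [MONO_RESIDUE_MASSES[aa] for aa in pep.sequence]
    prefix = np.cumsum(residues)
    total = prefix[-1] + mod_delta
    peaks = []
    L = len(pep)
    for i in range(1, L):
        for neutral in (prefix[i - 1], total - prefix[L - i - 1] + H2O):
            if rng.random() < prob:
                peaks.extend(_envelope(mz_from_neutral(float(neutral), 1), 1, scale * rng.lognormal(2.0, 0.6)))
    return peaks


def simulate_crosslinked_spectra(
    config: SimulationConfig,
    targets: list[ProteinRecord] | None = None,
    decoys: list[ProteinRecord] | None = None,
) -> SimulationResult:
    """Simulate an acquisition run of crosslinked-peptide MS2 spectra.

    For each simulated CSM two target peptides are crosslinked at random
    reactive sites and peaks are emitted as follows: the intact-peptide
    stub doublet of each peptide with probability ``doublet_emission_prob``
    (intensity boosted by ``stub_intensity_scale``); each backbone b/y slot
    independently with probability ``backbone_fragment_prob`` — link-site
    slots as a cleaved-stub variant (or +P for a non-cleavable reagent),
    plus an extra +P variant with ``plus_p_emission_prob``; a 3-peak
    isotope envelope per fragment; and uniform-m/z noise peaks. Optional
    linear-peptide, crosslinker-modified-linear, and noncovalent
    (co-isolated peptide) scans exercise the MS3 and prefilter paths.
    """
    rng = np.random.default_rng(config.seed)
    if targets is None:
        targets = generate_protein_db(config.n_proteins, config.protein_length, rng)
    if decoys is None:
        decoys = generate_decoy_db(targets)
    xl = config.crosslinker

    target_pool = _linkable_peptides(targets, config)
    full_pool = target_pool + _linkable_peptides(decoys, config)
    if len(target_pool) < 2:
        raise ValueError("database too small: fewer than two linkable peptides")

    spectra: list[Spectrum] = []
    truths: list[ScanTruth] = []
    candidates: dict[str, list[Candidate]] = {}
    scan_no = 0

    def random_candidates(charge: int, n: int) -> list[Candidate]:
        return [Candidate(_draw_pair(full_pool, rng, xl, charge)) for _ in range(n)]

    for _ in range(config.n_csms):
        scan_no += 1
        scan_id = f"MS2_{scan_no:05d}"
        charge = int(rng.integers(3, 5))
        pair = _draw_pair(target_pool, rng, xl, charge, distinct_proteins=True)
        truth = ScanTruth(scan_id=scan_id, kind="csm", pair=pair)

        theo = {
            (f.owner, f.series, f.index, f.stub_state): f.mz
            for f in theoretical_fragments(pair, max_fragment_charge=1)
        }
        peaks: list[tuple[float, float]] = []

        for owner in ("alpha", "beta"):
            pep = pair.peptide(owner)
            site = max(pair.link_site(owner), 1)
            L = len(pep)

            emitted = bool(rng.random() < config.doublet_emission_prob) and xl.cleavable
            truth.doublet_emitted[owner] = emitted
            if xl.cleavable:
                for label in xl.doublet_pair:
                    truth.stub_pion_mzs[(owner, label)] = theo[(owner, "P", 0, label)]
                if emitted:
                    base = config.stub_intensity_scale * rng.lognormal(2.0, 0.6)
                    for label in xl.doublet_pair:
                        mz = theo[(owner, "P", 0, label)]
                        peaks.extend(_envelope(mz, 1, base * rng.uniform(0.5, 1.0)))

            for series in ("b", "y"):
                for i in range(1, L):
                    if rng.random() >= config.backbone_fragment_prob:
                        continue
                    contains = (site <= i) if series == "b" else (site >= L - i + 1)
                    inten = rng.lognormal(2.0, 0.6)
                    if not contains:
                        mz = theo[(owner, series, i, None)]
                        peaks.extend(_envelope(mz, 1, inten))
                    else:
                        if xl.cleavable:
                            label = xl.doublet_pair[int(rng.integers(0, 2))]
                            peaks.extend(_envelope(theo[(owner, series, i, label)], 1, inten))
                            if rng.random() < config.plus_p_emission_prob:
                                peaks.extend(
                                    _envelope(theo[(owner, series, i, "+P")], 1, inten * 0.5)
                                )
                        else:
                            peaks.extend(_envelope(theo[(owner, series, i, "+P")], 1, inten))
                    truth.emitted_slots.add((owner, series, i))

        peaks.extend(_noise_peaks(config, rng))
        spectra.append(
            Spectrum(
                scan_id=scan_id,
                ms_level=2,
                precursor_mz=pair.precursor_mz,
                precursor_charge=charge,
                peaks=peaks,
            )
        )
        truths.append(truth)
        candidates[scan_id] = [Candidate(pair, is_true=True)] + random_candidates(
            charge, config.n_random_candidates
        )

    # Non-crosslinked parent scans (linear, crosslinker-modified linear,
    # noncovalently associated peptide pairs) for MS3 statistics and the
    # gas-phase-association prefilter.
    extra = (
        [("linear", 0.0)] * config.n_linear_spectra
        + [("xl_mod_linear", xl.hydrolyzed_mod)] * config.n_xl_mod_linear_spectra
        + [("noncovalent", None)] * config.n_noncovalent_spectra
    )
    for kind, mod_delta in extra:
        scan_no += 1
        scan_id = f"MS2_{scan_no:05d}"
        charge = int(rng.integers(2, 4))
        if kind == "noncovalent":
            pair = _draw_pair(target_pool, rng, xl, charge, distinct_proteins=True)
            peaks = _emit_linear_peaks(pair.alpha, 0.8, 1.0, rng) + _emit_linear_peaks(
                pair.beta, 0.8, 1.0, rng
            )
            precursor = mz_from_neutral(peptide_mass(pair.alpha) + peptide_mass(pair.beta), charge)
            cands = [Candidate(pair, is_true=False, noncovalent_flag=True)]
            truths.append(ScanTruth(scan_id=scan_id, kind=kind, pair=pair))
        else:
            pep, _ = target_pool[int(rng.integers(0, len(target_pool)))]
            peaks = _emit_linear_peaks(pep, 0.8, 1.0, rng, mod_delta=mod_delta)
            precursor = mz_from_neutral(peptide_mass(pep) + mod_delta, charge)
            cands = random_candidates(charge, config.n_random_candidates)
            truths.append(ScanTruth(scan_id=scan_id, kind=kind))
        peaks.extend(_noise_peaks(config, rng))
        spectra.append(
            Spectrum(
                scan_id=scan_id,
                ms_level=2,
                precursor_mz=precursor,
                precursor_charge=charge,
                peaks=peaks,
            )
        )
        candidates[scan_id] = cands

    return SimulationResult(
        config=config,
        targets=targets,
        decoys=decoys,
        spectra=spectra,
        truths=truths,
        candidates=candidates,
    )


def simulate_cid_ms3_run(config: SimulationConfig, result: SimulationResult) -> SimulationResult:
    """Append instrument-style MS3 scans to a CID run.

    Mirrors the acquisition logic rather than the ground truth: the MS2 peak
    list is scanned for peak pairs separated by the signature doublet mass
    difference (per charge 1..2, within ``ms3_doublet_ppm_tol``), up to
    ``ms3_trigger_top_n`` doublets are selected by intensity, and an MS3
    scan is emitted on the more intense peak of each. Where the selected
    peak is a true intact-peptide stub peak, the MS3 contains backbone
    fragments of the released stub-bearing linear peptide; coincidental
    (false) triggers — including the optional injected ones — yield
    noise-only MS3 scans. Truth records the intended target of every MS3.
    """
    rng = np.random.default_rng(config.seed + 1)
    xl = config.crosslinker
    if not xl.cleavable:
        return result
    delta = xl.doublet_delta
    truth_by_scan = {t.scan_id: t for t in result.truths}

    ms3_spectra: list[Spectrum] = []
    ms3_truths: list[Ms3Truth] = []
    ms3_no = 0

    from .annotate import deisotope  # deferred: avoids a module cycle at import time

    for spec in [s for s in result.spectra if s.ms_level == 2]:
        truth = truth_by_scan[spec.scan_id]
        dpeaks = deisotope(spec, ppm_tol=config.ms3_doublet_ppm_tol, max_charge=3)
        mzs = np.array([p.mono_mz for p in dpeaks])
        charges = np.array([p.charge for p in dpeaks])
        intens = np.array([p.summed_intensity for p in dpeaks])

        # instrument-style doublet scan on the deisotoped peak list
        found: list[tuple[float, float, int]] = []  # (pair intensity, selected mz, charge)
        for z in (1, 2):
            targets_mz = mzs + delta / z
            for i in range(len(mzs)):
                if charges[i] not in (0, z):
                    continue
                tol = targets_mz[i] * config.ms3_doublet_ppm_tol * 1e-6
                lo = np.searchsorted(mzs, targets_mz[i] - tol)
                hi = np.searchsorted(mzs, targets_mz[i] + tol)
                for j in range(lo, hi):
                    if charges[j] not in (0, z):
                        continue
                    inten = max(intens[i], intens[j])
                    sel = mzs[i] if intens[i] >= intens[j] else mzs[j]
                    found.append((float(inten), float(sel), z))
        found.sort(key=lambda t: -t[0])

        selected = []
        seen_mz: list[float] = []
        for inten, sel, z in found:
            if len(selected) >= config.ms3_trigger_top_n:
                break
            if any(abs(sel - s) < 0.05 for s in seen_mz):
                continue
            selected.append((sel, z))
            seen_mz.append(sel)
        if rng.random() < config.false_trigger_prob and len(mzs):
            selected.append((float(mzs[rng.integers(0, len(mzs))]), 1))

        for sel_mz, z in selected:
            ms3_no += 1
            scan_id = f"MS3_{ms3_no:05d}"
            intended_owner, intended_label = None, None
            if truth.pair is not None:
                for (owner, label), mz in truth.stub_pion_mzs.items():
                    if abs(sel_mz - mz) <= mz * config.ms3_doublet_ppm_tol * 1e-6:
                        intended_owner, intended_label = owner, label
                        break
            peaks: list[tuple[float, float]] = []
            if intended_owner is not None:
                pep = truth.pair.peptide(intended_owner)
                site = max(truth.pair.link_site(intended_owner), 1)
                stub = xl.stub_masses[intended_label]
                residues = [MONO_RESIDUE_MASSES[aa] for aa in pep.sequence]
                residues[site - 1] += stub
                prefix = np.cumsum(residues)
                total = prefix[-1]
                L = len(pep)
                for i in range(1, L):
                    for neutral in (prefix[i - 1], total - prefix[L - i - 1] + H2O):
                        if rng.random() < config.ms3_backbone_prob:
                            peaks.extend(
                                _envelope(mz_from_neutral(float(neutral), 1), 1, rng.lognormal(2.0, 0.6))
                            )
            peaks.extend(_noise_peaks(config, rng, n=config.noise_peaks_per_spectrum // 2))
            if not peaks:
                peaks = _noise_peaks(config, rng, n=max(config.noise_peaks_per_spectrum // 2, 1))
            ms3_spectra.append(
                Spectrum(
                    scan_id=scan_id,
                    ms_level=3,
                    precursor_mz=sel_mz,
                    precursor_charge=z,
                    peaks=peaks,
                    parent_scan_id=spec.scan_id,
                    selected_precursor_mz=sel_mz,
                )
            )
            ms3_truths.append(Ms3Truth(scan_id, spec.scan_id, intended_owner, intended_label))

    result.spectra = result.spectra + ms3_spectra
    result.ms3_truths = ms3_truths
    return result


def simulate_fdr_records(
    seed: int,
    n_true: int = 500,
    n_false: int = 2000,
    true_score_loc: float = 1.2,
    true_score_scale: float = 0.25,
    false_score_loc: float = 0.4,
    false_score_scale: float = 0.2,
    decoy_database_ratio: float = 1.0,
):
    """Score-level CSM records with known true/false composition.

    True identifications are target-target by construction; false (random)
    matches draw each peptide independently from the combined target+decoy
    pool, so with an equal-size decoy database they are TT/TD/DD in
    1:2:1 proportion and TD - DD estimates the false TT count. Scores are
    normal with overlapping true and false distributions so that a 5% FDR
    threshold falls inside the data. All records are heteromeric.
    """
    from .fdr import CSMRecord

    rng = np.random.default_rng(seed)
    letters = np.array(list("ACDEFGHILMNPQSTVWY"))

    def make_record(i: int, score: float, a_decoy: bool, b_decoy: bool, is_true: bool) -> CSMRecord:
        seq_a = "K" + "".join(rng.choice(letters, size=7))
        seq_b = "K" + "".join(rng.choice(letters, size=7))
        pa = Peptide(seq_a, frozenset({("REV_" if a_decoy else "") + f"PA{i}"}), is_decoy=a_decoy)
        pb = Peptide(seq_b, frozenset({("REV_" if b_decoy else "") + f"PB{i}"}), is_decoy=b_decoy)
        pair = CrosslinkedPair(pa, pb, 1, 1, DSSO, precursor_charge=3)
        return CSMRecord(
            scan_id=f"sim{i}",
            pair=pair,
            score=max(score, 0.0),
            delta_score=score,
            matched_fragments_alpha=5,
            matched_fragments_beta=5,
            is_true=is_true,
        )

    records = []
    for i in range(n_true):
        records.append(make_record(i, rng.normal(true_score_loc, true_score_scale), False, False, True))
    p_decoy = decoy_database_ratio / (1.0 + decoy_database_ratio)
    for j in range(n_false):
        a_dec = bool(rng.random() < p_decoy)
        b_dec = bool(rng.random() < p_decoy)
        records.append(
            make_record(n_true + j, rng.normal(false_score_loc, false_score_scale), a_dec, b_dec, False)
        )
    return records
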