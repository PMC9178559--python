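"""Spectrum annotation: deisotoping, intensity ranks, ppm fragment matching.

Observed peaks are first collapsed into deisotoped peaks (monoisotopic m/z,
charge, summed intensity), ranked by intensity, and then matched against
theoretical fragments within a ppm tolerance. All doublet-rank statistics
downstream operate on deisotoped ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import TheoreticalFragment
from .constants import ISOTOPE_SPACING, ppm_error
from .io import Spectrum

__all__ = ["DeisotopedPeak", "FragmentMatch", "deisotope", "assign_ranks", "match_fragments"]


@dataclass
class DeisotopedPeak:
    mono_mz: float
    charge: int  # 0 = undetermined (singleton, no envelope found)
    summed_intensity: float
    member_peak_indices: list[int] = field(default_factory=list)
    rank: int = 0  # 1 = most intense; assigned by assign_ranks


@dataclass(frozen=True)
class FragmentMatch:
    fragment: TheoreticalFragment
    peak: DeisotopedPeak
    ppm_error: float
    ambiguous: bool = False


def deisotope(
    spectrum: Spectrum,
    ppm_tol: float = 15.0,
    max_charge: int = 4,
    isotope_ppm_tol: float | None = None,
) -> list[DeisotopedPeak]:
    """Collapse isotope envelopes by greedy clustering from intense seeds.

    Seeds are visited in order of decreasing intensity. For each seed the
    charge 1..max_charge yielding the longest chain of peaks at
    seed + k * 1.0033548378/z (within the isotope tolerance, with
    non-increasing intensity, each step taking the candidate nearest the
    exact isotope position) wins; chain members are consumed. The seed —
    the first and most intense member — is reported as the monoisotopic
    peak. Peaks with no envelope pass through as singletons with charge 0.

    ``isotope_ppm_tol`` is the window for the isotope-position test. It
    defaults to min(ppm_tol, 5 ppm): systematic calibration error cancels
    in the difference of two peaks from one scan, so envelope spacing is
    measured far more precisely than absolute fragment mass, and a loose
    matching tolerance must not let clusters chain across co-isolated
    isobaric fragments.

    Total intensity is conserved: the summed intensities of the output
    equal the summed raw intensities.
    """
    if isotope_ppm_tol is None:
        isotope_ppm_tol = min(ppm_tol, 5.0)
    mzs = np.array([p[0] for p in spectrum.peaks])
    intens = np.array([p[1] for p in spectrum.peaks])
    n = len(mzs)
    used = np.zeros(n, dtype=bool)
    out: list[DeisotopedPeak] = []

    for seed in np.argsort(-intens, kind="stable"):
        if used[seed]:
            continue
        best_chain: list[int] = []
        best_z = 0
        for z in range(1, max_charge + 1):
            chain = [int(seed)]
            last_int = intens[seed]
            k = 1
            while True:
                target = mzs[seed] + k * ISOTOPE_SPACING / z
                tol = target * isotope_ppm_tol * 1e-6
                lo = np.searchsorted(mzs, target - tol)
                hi = np.searchsorted(mzs, target + tol)
                cand = [
                    j
                    for j in range(lo, hi)
                    if not used[j] and j not in chain and intens[j] <= last_int
                ]
                if not cand:
                    break
                # prefer the candidate closest to the exact isotope position:
                # spacing is the most precise envelope signal, and this keeps
                # a co-eluting isobaric mono from being swallowed as an isotope
                j = min(cand, key=lambda j: (abs(mzs[j] - target), -intens[j]))
                chain.append(j)
                last_int = intens[j]
                k += 1
            if len(chain) > len(best_chain):
                best_chain, best_z = chain, z
        if len(best_chain) >= 2:
            used[best_chain] = True
            out.append(
                DeisotopedPeak(
                    mono_mz=float(mzs[seed]),
                    charge=best_z,
                    summed_intensity=float(intens[best_chain].sum()),
                    member_peak_indices=sorted(best_chain),
                )
            )
        else:
            used[seed] = True
            out.append(
                DeisotopedPeak(
                    mono_mz=float(mzs[seed]),
                    charge=0,
                    summed_intensity=float(intens[seed]),
                    member_peak_indices=[int(seed)],
                )
            )
    out.sort(key=lambda p: p.mono_mz)
    return out


def assign_ranks(peaks: list[DeisotopedPeak]) -> list[DeisotopedPeak]:
    """Assign intensity ranks in place: 1 = most intense; ties broken by lower m/z."""
    order = sorted(range(len(peaks)), key=lambda i: (-peaks[i].summed_intensity, peaks[i].mono_mz))
    for rank, i in enumerate(order, start=1):
        peaks[i].rank = rank
    return peaks


def match_fragments(
    peaks: list[DeisotopedPeak],
    fragments: list[TheoreticalFragment],
    ppm_tol: float,
) -> list[FragmentMatch]:
    """Match each theoretical fragment to its nearest compatible observed peak.

    A peak is compatible when its charge equals the fragment charge or is
    undetermined (0). Among compatible peaks within ppm_tol the one with
    the smallest |ppm error| wins (ties: higher intensity). One peak may
    satisfy several isobaric fragments; such matches are flagged ambiguous.
    """
    if ppm_tol <= 0:
        raise ValueError("ppm tolerance must be positive")
    if not peaks or not fragments:
        return []
    peak_mzs = np.array([p.mono_mz for p in peaks])
    order = np.argsort(peak_mzs)
    sorted_mzs = peak_mzs[order]

    raw: list[tuple[int, int, float]] = []  # (fragment idx, peak idx, ppm)
    for fi, frag in enumerate(fragments):
        tol = frag.mz * ppm_tol * 1e-6
        lo = np.searchsorted(sorted_mzs, frag.mz - tol)
        hi = np.searchsorted(sorted_mzs, frag.mz + tol)
        best = None
        for oi in range(lo, hi):
            p = peaks[order[oi]]
            if p.charge not in (0, frag.charge):
                continue
            err = ppm_error(p.mono_mz, frag.mz)
            key = (abs(err), -p.summed_intensity)
            if best is None or key < best[0]:
                best = (key, int(order[oi]), err)
        if best is not None:
            raw.append((fi, best[1], best[2]))

    peak_hits: dict[int, int] = {}
    for _, pi, _ in raw:
        peak_hits[pi] = peak_hits.get(pi, 0) + 1
    return [
        FragmentMatch(fragments[fi], peaks[pi], err, ambiguous=peak_hits[pi] > 1)
        for fi, pi, err in raw
    ]
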