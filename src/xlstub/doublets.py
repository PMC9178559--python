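"""Signature doublet detection and conservative sequence coverage.

A cleaved crosslinker leaves complementary stub species on each peptide;
the two most frequently observed stubs form a fixed-mass-difference doublet
of intact-peptide (P-ion) peaks. A doublet is called for a peptide when
both P-ion stub variants named by the crosslinker's doublet pair are
matched at the same charge; the rank of the more intense of the two peaks
is the rank of the whole doublet.

Sequence coverage is computed conservatively: the fraction of the 2(L-1)
possible (series, cleavage position) slots — one N-terminal and one
C-terminal fragment between every adjacent residue pair — that have at
least one matched fragment, regardless of stub state, charge or loss.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotate import FragmentMatch
from .chem import CrosslinkedPair, Peptide

__all__ = [
    "DoubletCall",
    "CoverageResult",
    "detect_doublets",
    "csm_doublet_class",
    "doublet_rank_curve",
    "sequence_coverage",
    "doublet_prevalence_summary",
]


@dataclass(frozen=True)
class DoubletCall:
    owner: str  # 'alpha' | 'beta'
    labels: tuple[str, str]
    charge: int
    peak_ranks: tuple[int, int]
    peak_mzs: tuple[float, float] = (0.0, 0.0)

    @property
    def doublet_rank(self) -> int:
        """Rank of the more intense doublet peak (smaller number = more intense)."""
        return min(self.peak_ranks)


@dataclass(frozen=True)
class CoverageResult:
    """Per-peptide fragment coverage, total and split by fragment category.

    All fractions share the denominator 2(L-1). ``link_site`` restricts the
    numerator to link-site-containing fragments; ``stub_only`` and
    ``plus_p`` further split those into cleaved-stub and intact-partner
    (+P) evidence.
    """

    owner: str
    total: float
    linear: float
    link_site: float
    stub_only: float
    plus_p: float


def detect_doublets(matches: list[FragmentMatch], pair: CrosslinkedPair) -> list[DoubletCall]:
    """Call signature doublets from annotated P-ion stub matches.

    For each (peptide, charge) a call is emitted iff both doublet-pair stub
    variants of the intact-peptide ion matched. Non-cleavable crosslinkers
    yield no calls.
    """
    xl = pair.crosslinker
    if not xl.cleavable:
        return []
    lo, hi = xl.doublet_pair
    found: dict[tuple[str, int, str], FragmentMatch] = {}
    for m in matches:
        f = m.fragment
        if f.series == "P" and f.stub_state in (lo, hi):
            key = (f.owner, f.charge, f.stub_state)
            prev = found.get(key)
            if prev is None or m.peak.rank < prev.peak.rank:
                found[key] = m
    calls = []
    for owner in ("alpha", "beta"):
        for charge in sorted({c for (o, c, _) in found if o == owner}):
            a = found.get((owner, charge, lo))
            b = found.get((owner, charge, hi))
            if a is not None and b is not None:
                calls.append(
                    DoubletCall(
                        owner=owner,
                        labels=(lo, hi),
                        charge=charge,
                        peak_ranks=(a.peak.rank, b.peak.rank),
                        peak_mzs=(a.peak.mono_mz, b.peak.mono_mz),
                    )
                )
    return calls


def csm_doublet_class(calls: list[DoubletCall]) -> int:
    """0, 1 or 2: number of distinct peptides of one CSM with a detected doublet."""
    return len({c.owner for c in calls})


def best_doublet_rank(calls: list[DoubletCall]) -> int | None:
    """Best (smallest) doublet rank across all calls of one CSM."""
    return min((c.doublet_rank for c in calls), default=None)


def doublet_rank_curve(best_ranks: list[int], cutoffs: list[int]) -> list[float]:
    """Cumulative fraction of doublet-containing CSMs with best rank <= each cutoff."""
    if not best_ranks:
        return []
    n = len(best_ranks)
    return [sum(r <= c for r in best_ranks) / n for c in cutoffs]


def sequence_coverage(matches: list[FragmentMatch], peptide_length: int, owner: str) -> CoverageResult:
    """Conservative fragment sequence coverage for one peptide of a CSM.

    A cleavage position counts once per series no matter how many stub,
    loss or charge variants matched there. P ions carry no backbone
    cleavage information and are excluded.
    """
    L = peptide_length
    if L < 2:
        raise ValueError("sequence coverage undefined for peptides shorter than 2 residues")
    denom = 2 * (L - 1)

    slots: dict[str, set] = {"total": set(), "linear": set(), "link_site": set(),
                             "stub_only": set(), "plus_p": set()}
    for m in matches:
        f = m.fragment
        if f.owner != owner or f.series not in ("b", "y"):
            continue
        slot = (f.series, f.index)
        slots["total"].add(slot)
        if not f.contains_link_site:
            slots["linear"].add(slot)
        else:
            slots["link_site"].add(slot)
            if f.stub_state == "+P":
                slots["plus_p"].add(slot)
            elif f.stub_state is not None:
                slots["stub_only"].add(slot)
    return CoverageResult(
        owner=owner,
        total=len(slots["total"]) / denom,
        linear=len(slots["linear"]) / denom,
        link_site=len(slots["link_site"]) / denom,
        stub_only=len(slots["stub_only"]) / denom,
        plus_p=len(slots["plus_p"]) / denom,
    )


def doublet_prevalence_summary(doublet_classes: list[int]) -> dict[str, float]:
    """Fractions of CSMs containing at least one, and both, peptide doublets."""
    n = len(doublet_classes)
    if n == 0:
        return {"at_least_one": 0.0, "both": 0.0, "n": 0}
    return {
        "at_least_one": sum(c >= 1 for c in doublet_classes) / n,
        "both": sum(c == 2 for c in doublet_classes) / n,
        "n": n,
    }
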