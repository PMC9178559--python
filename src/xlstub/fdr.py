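"""CSM scoring, pre-FDR quality filters, and grouped target-decoy FDR.

The CSM score is a deliberately simple, declared statistic: the fraction of
total deisotoped spectrum intensity explained by matched fragments plus the
mean fragment sequence coverage of the two peptides (range [0, 2]). FDR is
estimated on unique CSMs with the classical cleavable-crosslink target-decoy
estimator FDR = max(0, TD - DD) / TT, separately for self (both peptides
from one protein) and heteromeric matches, since random heteromeric matches
are far more abundant in a quadratic search space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import DeisotopedPeak, FragmentMatch
from .chem import CrosslinkedPair
from .doublets import CoverageResult, sequence_coverage

__all__ = [
    "CSMRecord",
    "FdrGroupResult",
    "score_csm",
    "make_csm_record",
    "prefilter_csms",
    "estimate_fdr_grouped",
    "passing_csms",
    "doublet_filter_comparison",
    "normalize_scores_to_fdr_cutoff",
    "cleavability_comparison",
]


@dataclass
class CSMRecord:
    scan_id: str
    pair: CrosslinkedPair
    score: float
    delta_score: float
    matched_fragments_alpha: int
    matched_fragments_beta: int
    doublet_class: int = 0
    best_doublet_rank: int | None = None
    coverage: tuple[CoverageResult, CoverageResult] | None = None
    is_noncovalent_flagged: bool = False
    is_true: bool | None = None  # ground truth when known (simulations)

    @property
    def td_class(self) -> str:
        a, b = self.pair.alpha.is_decoy, self.pair.beta.is_decoy
        if not a and not b:
            return "TT"
        if a and b:
            return "DD"
        return "TD"

    @property
    def self_or_heteromeric(self) -> str:
        strip = lambda accs: {a.removeprefix("REV_") for a in accs}
        shared = strip(self.pair.alpha.protein_accessions) & strip(self.pair.beta.protein_accessions)
        return "self" if shared else "heteromeric"


def score_csm(
    matches: list[FragmentMatch],
    peaks: list[DeisotopedPeak],
    pair: CrosslinkedPair,
) -> float:
    """Declared simple CSM score in [0, 2].

    Explained-intensity fraction (distinct matched deisotoped peaks over
    total deisotoped intensity) plus the mean total sequence coverage of
    the two peptides.
    """
    total = sum(p.summed_intensity for p in peaks)
    matched_ids = {id(m.peak) for m in matches}
    explained = sum(p.summed_intensity for p in peaks if id(p) in matched_ids)
    frac = explained / total if total > 0 else 0.0
    cov_a = sequence_coverage(matches, len(pair.alpha), "alpha").total
    cov_b = sequence_coverage(matches, len(pair.beta), "beta").total
    return frac + 0.5 * (cov_a + cov_b)


def make_csm_record(
    scan_id: str,
    pair: CrosslinkedPair,
    matches: list[FragmentMatch],
    peaks: list[DeisotopedPeak],
    delta_score: float = 0.0,
    doublet_class: int = 0,
    best_doublet_rank: int | None = None,
    is_noncovalent_flagged: bool = False,
    is_true: bool | None = None,
) -> CSMRecord:
    """Assemble a CSMRecord from an annotation result."""
    def n_matched(owner):
        return len({(m.fragment.series, m.fragment.index)
                    for m in matches if m.fragment.owner == owner})

    return CSMRecord(
        scan_id=scan_id,
        pair=pair,
        score=score_csm(matches, peaks, pair),
        delta_score=delta_score,
        matched_fragments_alpha=n_matched("alpha"),
        matched_fragments_beta=n_matched("beta"),
        doublet_class=doublet_class,
        best_doublet_rank=best_doublet_rank,
        coverage=(
            sequence_coverage(matches, len(pair.alpha), "alpha"),
            sequence_coverage(matches, len(pair.beta), "beta"),
        ),
        is_noncovalent_flagged=is_noncovalent_flagged,
        is_true=is_true,
    )


def prefilter_csms(
    csms: list[CSMRecord],
    min_fragments: int = 3,
    min_delta_fraction: float = 0.15,
    min_length: int = 6,
) -> list[CSMRecord]:
    """Pre-FDR quality filter.

    Keeps CSMs with at least ``min_fragments`` matched fragments for BOTH
    peptides, a delta score strictly above ``min_delta_fraction`` of the
    match score, both peptide lengths >= ``min_length``, no peptide shared
    between two or more proteins, and no noncovalent (gas-phase
    association) flag. Idempotent.
    """
    out = []
    for r in csms:
        if r.matched_fragments_alpha < min_fragments or r.matched_fragments_beta < min_fragments:
            continue
        if not r.delta_score > min_delta_fraction * r.score:
            continue
        if len(r.pair.alpha) < min_length or len(r.pair.beta) < min_length:
            continue
        if len(r.pair.alpha.protein_accessions) > 1 or len(r.pair.beta.protein_accessions) > 1:
            continue
        if r.is_noncovalent_flagged:
            continue
        out.append(r)
    return out


@dataclass
class FdrGroupResult:
    group: str  # 'self' | 'heteromeric'
    threshold_score: float
    counts: tuple[int, int, int]  # (TT, TD, DD) at threshold
    achieved_fdr: float
    degenerate: bool = False  # no targets in group

    @property
    def n_passing_tt(self) -> int:
        return self.counts[0]


def _unique_csms(csms: list[CSMRecord]) -> list[CSMRecord]:
    best: dict[tuple, CSMRecord] = {}
    for r in csms:
        k = r.pair.key()
        if k not in best or r.score > best[k].score:
            best[k] = r
    return list(best.values())


def estimate_fdr_grouped(
    csms: list[CSMRecord],
    level: float = 0.05,
    unique: bool = True,
) -> dict[str, FdrGroupResult]:
    """Grouped target-decoy FDR on unique CSMs.

    Within each group (self / heteromeric) thresholds are scanned in
    descending score order; FDR(t) = max(0, TD - DD) / TT over records with
    score >= t, monotonized by a running minimum from the high-score end
    (so adding lower-scoring records can only raise the estimate). The
    threshold is the lowest score whose monotonized FDR is <= ``level``.
    """
    records = _unique_csms(csms) if unique else list(csms)
    out: dict[str, FdrGroupResult] = {}
    for group in ("self", "heteromeric"):
        recs = [r for r in records if r.self_or_heteromeric == group]
        if not recs:
            continue
        recs.sort(key=lambda r: -r.score)
        tt = np.cumsum([r.td_class == "TT" for r in recs])
        td = np.cumsum([r.td_class == "TD" for r in recs])
        dd = np.cumsum([r.td_class == "DD" for r in recs])
        if tt[-1] == 0:
            out[group] = FdrGroupResult(group, float("inf"), (0, 0, 0), 0.0, degenerate=True)
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            fdr = np.where(tt > 0, np.maximum(0, td - dd) / np.maximum(tt, 1), np.inf)
        qv = np.minimum.accumulate(fdr[::-1])[::-1]  # non-decreasing down the score list
        ok = np.nonzero(qv <= level)[0]
        if len(ok) == 0:
            out[group] = FdrGroupResult(group, float("inf"), (0, 0, 0), 0.0)
            continue
        i = int(ok[-1])
        out[group] = FdrGroupResult(
            group=group,
            threshold_score=recs[i].score,
            counts=(int(tt[i]), int(td[i]), int(dd[i])),
            achieved_fdr=float(qv[i]),
        )
    return out


def passing_csms(
    csms: list[CSMRecord],
    results: dict[str, FdrGroupResult],
    unique: bool = True,
) -> list[CSMRecord]:
    """Records at or above their group's FDR threshold."""
    records = _unique_csms(csms) if unique else list(csms)
    out = []
    for r in records:
        res = results.get(r.self_or_heteromeric)
        if res is not None and not res.degenerate and r.score >= res.threshold_score:
            out.append(r)
    return out


def fdr_curve(csms: list[CSMRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(score thresholds descending, raw FDR at each threshold) for one group."""
    recs = sorted(csms, key=lambda r: -r.score)
    scores = np.array([r.score for r in recs])
    tt = np.cumsum([r.td_class == "TT" for r in recs])
    td = np.cumsum([r.td_class == "TD" for r in recs])
    dd = np.cumsum([r.td_class == "DD" for r in recs])
    fdr = np.maximum(0, td - dd) / np.maximum(tt, 1)
    return scores, fdr


def doublet_filter_comparison(csms: list[CSMRecord], level: float = 0.05) -> dict:
    """Heteromeric yield with and without the peptide-doublet prefilter.

    The filtered condition keeps only CSMs with at least one detected
    peptide doublet before re-estimating FDR. Returns passing TT counts,
    thresholds, TT/TD score distributions, and FDR-vs-threshold curves for
    both conditions.
    """
    het = [r for r in _unique_csms(csms) if r.self_or_heteromeric == "heteromeric"]
    filtered = [r for r in het if r.doublet_class >= 1]

    def condition(recs):
        res = estimate_fdr_grouped(recs, level, unique=False).get("heteromeric")
        scores_tt = [r.score for r in recs if r.td_class == "TT"]
        scores_td = [r.score for r in recs if r.td_class == "TD"]
        thr_scores, fdr = fdr_curve(recs)
        return {
            "n_passing_tt": 0 if res is None or res.degenerate else res.n_passing_tt,
            "threshold": None if res is None else res.threshold_score,
            "scores_tt": scores_tt,
            "scores_td": scores_td,
            "fdr_curve": (thr_scores, fdr),
        }

    return {"unfiltered": condition(het), "doublet_filtered": condition(filtered)}


def normalize_scores_to_fdr_cutoff(
    csms: list[CSMRecord], level: float = 0.10
) -> dict[str, np.ndarray]:
    """Scores divided by their group's FDR threshold (threshold maps to 1.0)."""
    results = estimate_fdr_grouped(csms, level)
    out = {}
    for group, res in results.items():
        if res.degenerate or res.threshold_score in (0.0, float("inf")):
            raise ValueError(f"cannot normalize: no usable threshold for group {group}")
        scores = np.array([r.score for r in _unique_csms(csms) if r.self_or_heteromeric == group])
        out[group] = scores / res.threshold_score
    return out


def cleavability_comparison(
    stub_aware: list[CSMRecord],
    stub_blind: list[CSMRecord],
    level: float = 0.05,
) -> dict:
    """Passing heteromeric CSMs for stub-aware vs stub-blind (noncleavable) annotation.

    Both record sets come from annotating the same spectra against the same
    pairs; the stub-blind run excludes cleaved-stub fragments from matching
    and scoring, mimicking a search that treats the crosslinker as
    noncleavable.
    """
    def yield_of(recs):
        res = estimate_fdr_grouped(recs, level).get("heteromeric")
        return 0 if res is None or res.degenerate else res.n_passing_tt

    return {"stub_aware": yield_of(stub_aware), "stub_blind": yield_of(stub_blind)}
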