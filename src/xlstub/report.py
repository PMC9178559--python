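"""Figure-panel-style summary tables.

Each function returns a tidy DataFrame mirroring one panel of the standard
cleavable-crosslinker evaluation: doublet prevalence and rank curves,
paired sequence-coverage comparisons between acquisition runs (matched on
the unique CSM key and tested with a two-sided Wilcoxon signed-rank test),
MS3 trigger statistics, doublet-prefilter FDR comparisons, and
fragment-category coverage splits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .doublets import doublet_prevalence_summary, doublet_rank_curve
from .fdr import CSMRecord, cleavability_comparison, doublet_filter_comparison, normalize_scores_to_fdr_cutoff

__all__ = [
    "doublet_prevalence_table",
    "rank_curve_table",
    "common_csms",
    "paired_coverage_table",
    "trigger_summary_table",
    "doublet_filter_table",
    "coverage_categories_table",
    "normalized_score_table",
    "cleavability_table",
]

DEFAULT_RANK_CUTOFFS = [1, 2, 3, 5, 10, 20, 50, 100]


def doublet_prevalence_table(runs: dict[str, list[CSMRecord]]) -> pd.DataFrame:
    """Fraction of TT CSMs per run containing >=1 and both peptide doublets."""
    rows = []
    for label, records in runs.items():
        classes = [r.doublet_class for r in records if r.td_class == "TT"]
        s = doublet_prevalence_summary(classes)
        rows.append({"run": label, "at_least_one": s["at_least_one"], "both": s["both"], "n": s["n"]})
    return pd.DataFrame(rows)


def rank_curve_table(
    runs: dict[str, list[CSMRecord]], cutoffs: list[int] | None = None
) -> pd.DataFrame:
    """Cumulative fraction of doublet-containing CSMs passing each rank cutoff."""
    cutoffs = cutoffs or DEFAULT_RANK_CUTOFFS
    rows = []
    for label, records in runs.items():
        ranks = [r.best_doublet_rank for r in records if r.best_doublet_rank is not None]
        curve = doublet_rank_curve(ranks, cutoffs)
        for c, f in zip(cutoffs, curve):
            rows.append({"run": label, "rank_cutoff": c, "cumulative_fraction": f, "n": len(ranks)})
    return pd.DataFrame(rows)


def common_csms(a: list[CSMRecord], b: list[CSMRecord]) -> list[tuple[CSMRecord, CSMRecord]]:
    """CSMs identified in both runs, matched on (peptides, link sites, charge)."""
    index = {r.pair.key(): r for r in a}
    return [(index[r.pair.key()], r) for r in b if r.pair.key() in index]


def _better_worse(record: CSMRecord) -> tuple[float, float]:
    ca, cb = record.coverage[0].total, record.coverage[1].total
    return max(ca, cb), min(ca, cb)


def paired_coverage_table(runs: dict[str, list[CSMRecord]]) -> pd.DataFrame:
    """Better/worse-peptide coverage of common CSMs across runs, with Wilcoxon tests.

    Coverage differs between the two peptides of a CSM; they are reported
    as the better- and worse-fragmenting peptide. P-values compare each
    pair of runs on the common CSMs by a two-sided Wilcoxon signed-rank
    test, separately for the better and worse peptide.
    """
    labels = list(runs)
    keysets = [{r.pair.key() for r in runs[l]} for l in labels]
    common = set.intersection(*keysets) if keysets else set()
    rows = []
    per_run: dict[str, dict[str, np.ndarray]] = {}
    for label in labels:
        recs = [r for r in runs[label] if r.pair.key() in common and r.coverage]
        recs.sort(key=lambda r: r.pair.key())
        better = np.array([_better_worse(r)[0] for r in recs])
        worse = np.array([_better_worse(r)[1] for r in recs])
        per_run[label] = {"better": better, "worse": worse}
        rows.append(
            {
                "run": label,
                "n_common": len(recs),
                "median_better": float(np.median(better)) if len(better) else np.nan,
                "median_worse": float(np.median(worse)) if len(worse) else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    tests = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            for side in ("better", "worse"):
                x, y = per_run[la][side], per_run[lb][side]
                if len(x) and np.any(x - y):
                    p = float(stats.wilcoxon(x, y).pvalue)
                else:
                    p = np.nan
                tests.append({"run_a": la, "run_b": lb, "peptide": side, "wilcoxon_p": p})
    table.attrs["wilcoxon"] = pd.DataFrame(tests)
    return table


def trigger_summary_table(ms3_eval: dict) -> pd.DataFrame:
    """Proportions of CSMs with 0/1/2 correct MS3 triggers + MS3-per-MS2 by parent type."""
    s = ms3_eval["summary"]
    rows = [
        {"metric": f"csm_correct_triggers_{k}", "value": v}
        for k, v in s["correct_trigger_proportions"].items()
    ]
    rows += [
        {"metric": f"mean_ms3_per_ms2_{kind}", "value": v} for kind, v in s["mean_ms3_per_ms2"].items()
    ]
    return pd.DataFrame(rows)


def doublet_filter_table(records: list[CSMRecord], level: float = 0.05) -> pd.DataFrame:
    """Heteromeric yield at FDR with vs without the doublet prefilter."""
    comp = doublet_filter_comparison(records, level)
    rows = []
    for cond, d in comp.items():
        rows.append(
            {
                "condition": cond,
                "n_passing_tt": d["n_passing_tt"],
                "threshold": d["threshold"],
                "n_tt": len(d["scores_tt"]),
                "n_td": len(d["scores_td"]),
            }
        )
    return pd.DataFrame(rows)


def coverage_categories_table(records: list[CSMRecord]) -> pd.DataFrame:
    """Median coverage by fragment category (all / linear / link-site / stub / +P)."""
    cats = ("total", "linear", "link_site", "stub_only", "plus_p")
    vals = {c: [] for c in cats}
    for r in records:
        if not r.coverage:
            continue
        for cov in r.coverage:
            for c in cats:
                vals[c].append(getattr(cov, c))
    return pd.DataFrame(
        [
            {"category": c, "median_coverage": float(np.median(v)) if v else np.nan, "n_peptides": len(v)}
            for c, v in vals.items()
        ]
    )


def normalized_score_table(records: list[CSMRecord], level: float = 0.10) -> pd.DataFrame:
    """Scores normalized to the group score cutoff at the given FDR level."""
    rows = []
    for group, scores in normalize_scores_to_fdr_cutoff(records, level).items():
        for s in scores:
            rows.append({"group": group, "normalized_score": float(s)})
    return pd.DataFrame(rows)


def cleavability_table(
    stub_aware: list[CSMRecord], stub_blind: list[CSMRecord], level: float = 0.05
) -> pd.DataFrame:
    comp = cleavability_comparison(stub_aware, stub_blind, level)
    return pd.DataFrame(
        [{"mode": k, "heteromeric_csms_passing": v} for k, v in comp.items()]
    )
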