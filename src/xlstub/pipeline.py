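"""End-to-end orchestration: annotate, score, evaluate doublets/MS3, run FDR.

The annotation step plays the role of the search engine's rescoring stage:
for every MS2 scan it deisotopes the peaks, scores each candidate peptide
pair (the generator's stand-in for a search candidate list), keeps the best
as the CSM with a delta score against the runner-up, and attaches doublet
calls and per-peptide coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotate import DeisotopedPeak, FragmentMatch, assign_ranks, deisotope, match_fragments
from .chem import CrosslinkedPair, CrosslinkerSpec, Peptide, theoretical_fragments
from .doublets import best_doublet_rank, csm_doublet_class, detect_doublets, sequence_coverage
from .fdr import CSMRecord, estimate_fdr_grouped, make_csm_record, passing_csms, prefilter_csms, score_csm
from .io import CSM_TABLE_COLUMNS, Spectrum
from .ms3 import classify_ms3_trigger, combined_coverage, stub_peptide_fragments, trigger_summary
from .simulate import Candidate, SimulationConfig, SimulationResult, simulate_cid_ms3_run, simulate_crosslinked_spectra

__all__ = [
    "ScanAnnotation",
    "annotate_run",
    "evaluate_ms3_run",
    "records_to_table",
    "run_simulated_pipeline",
]


@dataclass
class ScanAnnotation:
    """Best-candidate annotation of one MS2 scan."""

    record: CSMRecord
    pair: CrosslinkedPair
    matches: list[FragmentMatch]
    peaks: list[DeisotopedPeak]


def annotate_run(
    spectra: list[Spectrum],
    candidates: dict[str, list[Candidate]],
    ppm_tol: float = 15.0,
    max_fragment_charge: int | None = None,
    include_stub_fragments: bool = True,
    deisotope_max_charge: int = 4,
    truths: dict[str, CrosslinkedPair] | None = None,
) -> dict[str, ScanAnnotation]:
    """Annotate and score every MS2 scan against its candidate pairs.

    Returns the best-scoring candidate per scan as a CSMRecord (delta score
    = gap to the second-best candidate), together with the matches and
    deisotoped peaks needed for MS3 evaluation. ``include_stub_fragments=
    False`` runs the stub-blind (noncleavable) annotation mode.
    """
    out: dict[str, ScanAnnotation] = {}
    for spec in spectra:
        if spec.ms_level != 2:
            continue
        cands = candidates.get(spec.scan_id)
        if not cands:
            continue
        peaks = assign_ranks(deisotope(spec, ppm_tol, deisotope_max_charge))
        scored = []
        for cand in cands:
            frags = theoretical_fragments(
                cand.pair,
                max_fragment_charge=max_fragment_charge,
                include_stub_fragments=include_stub_fragments,
            )
            matches = match_fragments(peaks, frags, ppm_tol)
            scored.append((score_csm(matches, peaks, cand.pair), cand, matches))
        scored.sort(key=lambda t: -t[0])
        best_score, best_cand, best_matches = scored[0]
        second = scored[1][0] if len(scored) > 1 else 0.0
        calls = detect_doublets(best_matches, best_cand.pair) if include_stub_fragments else []
        is_true = None
        if truths is not None:
            true_pair = truths.get(spec.scan_id)
            is_true = true_pair is not None and best_cand.pair.key() == true_pair.key()
        record = make_csm_record(
            scan_id=spec.scan_id,
            pair=best_cand.pair,
            matches=best_matches,
            peaks=peaks,
            delta_score=best_score - second,
            doublet_class=csm_doublet_class(calls),
            best_doublet_rank=best_doublet_rank(calls),
            is_noncovalent_flagged=best_cand.noncovalent_flag,
            is_true=is_true,
        )
        out[spec.scan_id] = ScanAnnotation(record, best_cand.pair, best_matches, peaks)
    return out


def evaluate_ms3_run(
    spectra: list[Spectrum],
    annotations: dict[str, ScanAnnotation],
    crosslinker: CrosslinkerSpec,
    linear_candidates: list[Peptide] | None = None,
    ppm_tol: float = 20.0,
    ms3_match_ppm_tol: float = 15.0,
    parent_kinds: dict[str, str] | None = None,
) -> dict:
    """Classify all MS3 scans and compute combined MS2+MS3 coverage.

    For every MS3 scan the selected precursor is compared against the
    parent CSM's matched intact-peptide stub fragments (20 ppm default);
    correctly-triggered scans are annotated against the released
    stub-bearing linear peptide and their matched cleavage slots are
    unioned into the parent peptide's coverage.
    """
    ms3_by_parent: dict[str, list[Spectrum]] = {}
    for s in spectra:
        if s.ms_level == 3:
            if s.parent_scan_id is None or not any(
                t.scan_id == s.parent_scan_id for t in spectra if t.ms_level == 2
            ):
                raise ValueError(f"MS3 scan {s.scan_id}: dangling parent link {s.parent_scan_id}")
            ms3_by_parent.setdefault(s.parent_scan_id, []).append(s)

    per_parent = []
    combined: dict[str, dict[str, float]] = {}
    classifications: dict[str, list] = {}
    for spec in spectra:
        if spec.ms_level != 2:
            continue
        ann = annotations.get(spec.scan_id)
        kind = (parent_kinds or {}).get(spec.scan_id, "csm" if ann else "noise")
        children = ms3_by_parent.get(spec.scan_id, [])
        cls = []
        ms3_matches: dict[str, list[FragmentMatch]] = {"alpha": [], "beta": []}
        for ms3 in children:
            c = classify_ms3_trigger(
                ms3,
                ann.matches if ann else [],
                linear_candidates=linear_candidates,
                crosslinker=crosslinker,
                ppm_tol=ppm_tol,
            )
            cls.append(c)
            if c.outcome == "correct_stub" and ann is not None:
                frags = stub_peptide_fragments(ann.pair, c.matched_owner, c.stub_label)
                peaks = assign_ranks(deisotope(ms3, ms3_match_ppm_tol))
                ms3_matches[c.matched_owner].extend(match_fragments(peaks, frags, ms3_match_ppm_tol))
        per_parent.append({"parent_kind": kind, "classifications": cls})
        classifications[spec.scan_id] = cls
        if ann is not None and kind == "csm":
            combined[spec.scan_id] = {
                owner: combined_coverage(
                    ann.matches, ms3_matches[owner], len(ann.pair.peptide(owner)), owner
                ).total
                for owner in ("alpha", "beta")
            }

    return {
        "summary": trigger_summary(per_parent),
        "combined_coverage": combined,
        "classifications": classifications,
    }


def records_to_table(records: list[CSMRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "scan_id": r.scan_id,
                "alpha_sequence": r.pair.alpha.sequence,
                "beta_sequence": r.pair.beta.sequence,
                "alpha_mods": r.pair.alpha.mod_string(),
                "beta_mods": r.pair.beta.mod_string(),
                "alpha_accessions": ";".join(sorted(r.pair.alpha.protein_accessions)),
                "beta_accessions": ";".join(sorted(r.pair.beta.protein_accessions)),
                "link_site_alpha": r.pair.link_site_alpha,
                "link_site_beta": r.pair.link_site_beta,
                "precursor_charge": r.pair.precursor_charge,
                "score": r.score,
                "delta_score": r.delta_score,
                "alpha_is_decoy": r.pair.alpha.is_decoy,
                "beta_is_decoy": r.pair.beta.is_decoy,
                "td_class": r.td_class,
                "self_or_heteromeric": r.self_or_heteromeric,
                "matched_fragments_alpha": r.matched_fragments_alpha,
                "matched_fragments_beta": r.matched_fragments_beta,
                "doublet_class": r.doublet_class,
                "best_doublet_rank": r.best_doublet_rank if r.best_doublet_rank is not None else "",
                "coverage_alpha": r.coverage[0].total if r.coverage else 0.0,
                "coverage_beta": r.coverage[1].total if r.coverage else 0.0,
                "is_noncovalent_flagged": r.is_noncovalent_flagged,
            }
        )
    return pd.DataFrame(rows, columns=CSM_TABLE_COLUMNS)


def coverage_table(annotations: dict[str, ScanAnnotation]) -> pd.DataFrame:
    """Per-peptide coverage categories of every annotated CSM (one row per peptide)."""
    from .io import COVERAGE_TABLE_COLUMNS

    rows = []
    for sid, a in annotations.items():
        for cov in a.record.coverage or ():
            rows.append(
                {
                    "scan_id": sid,
                    "owner": cov.owner,
                    "total": cov.total,
                    "linear": cov.linear,
                    "link_site": cov.link_site,
                    "stub_only": cov.stub_only,
                    "plus_p": cov.plus_p,
                }
            )
    return pd.DataFrame(rows, columns=COVERAGE_TABLE_COLUMNS)


def records_from_table(df: pd.DataFrame, crosslinker: CrosslinkerSpec) -> list[CSMRecord]:
    """Rebuild CSMRecords from a CSM table (inverse of records_to_table).

    Coverage is restored as totals only; category splits live in the
    separate per-peptide coverage table. Variable modifications are not
    rebuilt into typed objects, so unique-CSM keys of reloaded records are
    comparable across runs (both serialize mods the same way) but not with
    in-memory records carrying mods.
    """
    from .doublets import CoverageResult

    records = []
    for row in df.itertuples(index=False):
        pa = Peptide(
            row.alpha_sequence,
            frozenset(a for a in str(row.alpha_accessions).split(";") if a),
            is_decoy=bool(row.alpha_is_decoy),
        )
        pb = Peptide(
            row.beta_sequence,
            frozenset(a for a in str(row.beta_accessions).split(";") if a),
            is_decoy=bool(row.beta_is_decoy),
        )
        pair = CrosslinkedPair(
            pa, pb, int(row.link_site_alpha), int(row.link_site_beta), crosslinker,
            precursor_charge=int(row.precursor_charge),
        )
        rank = pd.to_numeric(row.best_doublet_rank, errors="coerce")
        records.append(
            CSMRecord(
                scan_id=str(row.scan_id),
                pair=pair,
                score=float(row.score),
                delta_score=float(row.delta_score),
                matched_fragments_alpha=int(row.matched_fragments_alpha),
                matched_fragments_beta=int(row.matched_fragments_beta),
                doublet_class=int(row.doublet_class),
                best_doublet_rank=None if pd.isna(rank) else int(rank),
                coverage=(
                    CoverageResult("alpha", float(row.coverage_alpha), 0, 0, 0, 0),
                    CoverageResult("beta", float(row.coverage_beta), 0, 0, 0, 0),
                ),
                is_noncovalent_flagged=bool(row.is_noncovalent_flagged),
            )
        )
    return records


CANDIDATE_TABLE_COLUMNS = [
    "scan_id",
    "alpha_sequence",
    "beta_sequence",
    "alpha_accessions",
    "beta_accessions",
    "alpha_start",
    "beta_start",
    "link_site_alpha",
    "link_site_beta",
    "precursor_charge",
    "alpha_is_decoy",
    "beta_is_decoy",
    "is_true",
    "noncovalent_flag",
]


def candidates_to_table(candidates: dict[str, list[Candidate]]) -> pd.DataFrame:
    rows = []
    for sid, cands in candidates.items():
        for c in cands:
            p = c.pair
            rows.append(
                {
                    "scan_id": sid,
                    "alpha_sequence": p.alpha.sequence,
                    "beta_sequence": p.beta.sequence,
                    "alpha_accessions": ";".join(sorted(p.alpha.protein_accessions)),
                    "beta_accessions": ";".join(sorted(p.beta.protein_accessions)),
                    "alpha_start": p.alpha.start_position,
                    "beta_start": p.beta.start_position,
                    "link_site_alpha": p.link_site_alpha,
                    "link_site_beta": p.link_site_beta,
                    "precursor_charge": p.precursor_charge,
                    "alpha_is_decoy": p.alpha.is_decoy,
                    "beta_is_decoy": p.beta.is_decoy,
                    "is_true": c.is_true,
                    "noncovalent_flag": c.noncovalent_flag,
                }
            )
    return pd.DataFrame(rows, columns=CANDIDATE_TABLE_COLUMNS)


def candidates_from_table(df: pd.DataFrame, crosslinker: CrosslinkerSpec) -> dict[str, list[Candidate]]:
    missing = [c for c in CANDIDATE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"candidate table missing column(s): {missing}")
    out: dict[str, list[Candidate]] = {}
    for row in df.itertuples(index=False):
        pa = Peptide(
            row.alpha_sequence,
            frozenset(a for a in str(row.alpha_accessions).split(";") if a),
            start_position=int(row.alpha_start),
            is_decoy=bool(row.alpha_is_decoy),
        )
        pb = Peptide(
            row.beta_sequence,
            frozenset(a for a in str(row.beta_accessions).split(";") if a),
            start_position=int(row.beta_start),
            is_decoy=bool(row.beta_is_decoy),
        )
        pair = CrosslinkedPair(
            pa, pb, int(row.link_site_alpha), int(row.link_site_beta), crosslinker,
            precursor_charge=int(row.precursor_charge),
        )
        out.setdefault(str(row.scan_id), []).append(
            Candidate(pair, is_true=bool(row.is_true), noncovalent_flag=bool(row.noncovalent_flag))
        )
    return out


def run_simulated_pipeline(
    config: SimulationConfig,
    fdr_level: float = 0.05,
    ppm_tol: float = 15.0,
    prefilter: bool = True,
) -> dict:
    """Simulate a run and push it through annotation, doublets, MS3 and FDR.

    Returns the simulation result, per-scan annotations, CSM records (pre-
    and post-filter), grouped FDR results and the passing records — the
    building blocks for all report tables.
    """
    sim = simulate_crosslinked_spectra(config)
    if config.acquisition == "CID_MS2_MS3":
        sim = simulate_cid_ms3_run(config, sim)

    truths = {t.scan_id: t.pair for t in sim.truths if t.pair is not None and t.kind == "csm"}
    annotations = annotate_run(sim.spectra, sim.candidates, ppm_tol=ppm_tol, truths=truths)
    records = [a.record for a in annotations.values()]
    filtered = prefilter_csms(records) if prefilter else list(records)
    fdr_results = estimate_fdr_grouped(filtered, fdr_level)
    passing = passing_csms(filtered, fdr_results)

    ms3_eval = None
    if any(s.ms_level == 3 for s in sim.spectra):
        kinds = {t.scan_id: ("csm" if t.kind == "csm" else t.kind) for t in sim.truths}
        ms3_eval = evaluate_ms3_run(
            sim.spectra, annotations, config.crosslinker, parent_kinds=kinds
        )

    return {
        "simulation": sim,
        "annotations": annotations,
        "records": records,
        "filtered_records": filtered,
        "fdr_results": fdr_results,
        "passing": passing,
        "ms3_eval": ms3_eval,
    }
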