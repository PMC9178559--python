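"""MS3 trigger evaluation and combined MS2+MS3 sequence coverage.

In CID-MS2/MS3 acquisition the instrument fragments the crosslinked
precursor with low-energy CID (cleaving the crosslinker rather than the
backbone), detects signature doublet peak pairs, and triggers MS3 scans on
selected doublet peaks to sequence the released stub-bearing linear
peptides. This module checks whether each MS3 precursor actually
corresponds to a stub fragment of an identified crosslinked peptide, and
merges fragment evidence from correctly-triggered MS3 scans into the
parent CSM's sequence coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotate import FragmentMatch
from .chem import (
    CrosslinkedPair,
    CrosslinkerSpec,
    Peptide,
    TheoreticalFragment,
    peptide_mass,
)
from .constants import H2O, MONO_RESIDUE_MASSES, mz_from_neutral
from .doublets import CoverageResult, sequence_coverage
from .io import Spectrum

__all__ = [
    "TriggerClassification",
    "classify_ms3_trigger",
    "trigger_summary",
    "combined_coverage",
    "stub_peptide_fragments",
]


@dataclass(frozen=True)
class TriggerClassification:
    ms3_scan_id: str
    outcome: str  # correct_stub | linear_peptide | crosslinker_modified_linear | unmatched
    matched_owner: str | None = None  # alpha | beta
    stub_label: str | None = None
    ppm_error: float | None = None


def classify_ms3_trigger(
    ms3: Spectrum,
    parent_annotation: list[FragmentMatch],
    linear_candidates: list[Peptide] | None = None,
    crosslinker: CrosslinkerSpec | None = None,
    ppm_tol: float = 20.0,
    max_charge: int = 4,
) -> TriggerClassification:
    """Classify an MS3 scan by what its selected precursor actually was.

    ``correct_stub`` — the MS3 precursor m/z matches a matched intact-peptide
    (P-ion) stub fragment of either peptide of the parent CSM within
    ``ppm_tol``. Failing that, the precursor is compared against the masses
    of the provided linear peptides, plain (``linear_peptide``) or carrying
    a hydrolyzed/amidated crosslinker (``crosslinker_modified_linear``);
    otherwise ``unmatched``.
    """
    if ms3.ms_level != 3:
        raise ValueError(f"scan {ms3.scan_id} is not an MS3 scan")
    sel = ms3.selected_precursor_mz

    best = None
    for m in parent_annotation:
        f = m.fragment
        if f.series != "P" or f.stub_state in (None, "+P"):
            continue
        err = (sel - f.mz) / f.mz * 1e6
        if abs(err) <= ppm_tol and (best is None or abs(err) < abs(best[2])):
            best = (f.owner, f.stub_state, err)
    if best is not None:
        return TriggerClassification(ms3.scan_id, "correct_stub", best[0], best[1], best[2])

    if linear_candidates:
        mod_deltas = [0.0]
        outcomes = ["linear_peptide"]
        if crosslinker is not None:
            mod_deltas += [crosslinker.hydrolyzed_mod, crosslinker.amidated_mod]
            outcomes += ["crosslinker_modified_linear", "crosslinker_modified_linear"]
        for pep in linear_candidates:
            base = peptide_mass(pep)
            for delta, outcome in zip(mod_deltas, outcomes):
                for z in range(1, max_charge + 1):
                    theo = mz_from_neutral(base + delta, z)
                    err = (sel - theo) / theo * 1e6
                    if abs(err) <= ppm_tol:
                        return TriggerClassification(ms3.scan_id, outcome, None, None, err)
    return TriggerClassification(ms3.scan_id, "unmatched")


def trigger_summary(per_parent: list[dict]) -> dict:
    """Summarize MS3 triggering over MS2 parent scans.

    ``per_parent`` holds one dict per MS2 scan with keys ``parent_kind``
    ('csm', 'linear', 'xl_mod_linear' or 'noise') and ``classifications``
    (the TriggerClassifications of its MS3 children). Returns the
    proportions of CSM parents with 0/1/2 peptides correctly triggered and
    the mean number of MS3 scans per MS2 by parent kind.
    """
    csm_counts = {0: 0, 1: 0, 2: 0}
    ms3_counts: dict[str, list[int]] = {}
    for entry in per_parent:
        kind = entry["parent_kind"]
        cls = entry["classifications"]
        ms3_counts.setdefault(kind, []).append(len(cls))
        if kind == "csm":
            owners = {c.matched_owner for c in cls if c.outcome == "correct_stub"}
            csm_counts[min(len(owners), 2)] += 1
    n_csm = sum(csm_counts.values())
    proportions = {k: (v / n_csm if n_csm else 0.0) for k, v in csm_counts.items()}
    mean_ms3 = {k: sum(v) / len(v) for k, v in ms3_counts.items()}
    return {"correct_trigger_proportions": proportions, "mean_ms3_per_ms2": mean_ms3, "n_csm": n_csm}


def stub_peptide_fragments(
    pair: CrosslinkedPair,
    owner: str,
    stub_label: str,
    max_fragment_charge: int = 2,
) -> list[TheoreticalFragment]:
    """Theoretical b/y ions of one released stub-bearing linear peptide.

    MS3 precursors are linear peptides carrying a crosslinker stub at the
    link site, so MS3 annotation reuses the backbone fragment model with
    the stub mass as a fixed modification at the link site.
    """
    pep = pair.peptide(owner)
    site = max(pair.link_site(owner), 1)
    stub_mass = pair.crosslinker.stub_masses[stub_label]
    L = len(pep)
    mods_at: dict[int, float] = {}
    for mod in pep.modifications:
        p = max(mod.position, 1)
        mods_at[p] = mods_at.get(p, 0.0) + mod.mass_delta
    mods_at[site] = mods_at.get(site, 0.0) + stub_mass

    prefix, prefix_sums = 0.0, []
    for i, aa in enumerate(pep.sequence, start=1):
        prefix += MONO_RESIDUE_MASSES[aa] + mods_at.get(i, 0.0)
        prefix_sums.append(prefix)
    total = prefix_sums[-1]

    frags = []
    for i in range(1, L):
        for series, neutral in (("b", prefix_sums[i - 1]), ("y", total - prefix_sums[L - i - 1] + H2O)):
            contains = (site <= i) if series == "b" else (site >= L - i + 1)
            for z in range(1, max_fragment_charge + 1):
                frags.append(
                    TheoreticalFragment(
                        owner=owner,
                        series=series,
                        index=i,
                        stub_state=stub_label if contains else None,
                        neutral_loss=None,
                        charge=z,
                        mz=mz_from_neutral(neutral, z),
                        contains_link_site=contains,
                    )
                )
    return frags


def combined_coverage(
    ms2_matches: list[FragmentMatch],
    ms3_matches: list[FragmentMatch],
    peptide_length: int,
    owner: str,
) -> CoverageResult:
    """Coverage of one peptide from the MS2 scan plus its correct MS3 scans.

    The matched (series, position) sets are unioned over the parent MS2
    annotation and all MS3 scans correctly assigned to this peptide; the
    denominator stays 2(L-1). Never lower than the MS2-only coverage.
    """
    return sequence_coverage(list(ms2_matches) + list(ms3_matches), peptide_length, owner)
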