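"""Peak-list and table I/O.

MGF reading/writing (with a TITLE-token convention to link MS3 scans to
their parent MS2 scans, since standard MGF has no MS3 linkage field), FASTA
databases with decoy-prefix detection, CSM result tables as TSV, and global
ppm mass recalibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .constants import CANONICAL_RESIDUES

__all__ = [
    "Spectrum",
    "ProteinRecord",
    "MgfParseError",
    "parse_mgf",
    "serialize_mgf",
    "read_fasta",
    "write_fasta",
    "recalibrate_spectra",
    "write_csm_table",
    "read_csm_table",
    "CSM_TABLE_COLUMNS",
]


class MgfParseError(ValueError):
    pass


@dataclass
class Spectrum:
    """One MS2 or MS3 scan: precursor info plus an mz-sorted peak list."""

    scan_id: str
    ms_level: int
    precursor_mz: float
    precursor_charge: int
    peaks: list[tuple[float, float]]
    parent_scan_id: str | None = None
    selected_precursor_mz: float | None = None
    retention_time: float | None = None

    def __post_init__(self):
        if self.ms_level not in (2, 3):
            raise ValueError(f"ms_level must be 2 or 3, got {self.ms_level}")
        if self.ms_level == 3 and (self.parent_scan_id is None or self.selected_precursor_mz is None):
            raise ValueError("MS3 spectrum requires parent_scan_id and selected_precursor_mz")
        self.peaks = sorted(self.peaks)
        for mz, inten in self.peaks:
            if mz <= 0 or inten < 0:
                raise ValueError(f"invalid peak ({mz}, {inten})")


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"empty sequence for {self.accession}")


def _parse_title_tokens(title: str) -> dict[str, str]:
    out = {}
    for tok in title.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def parse_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF peak list.

    The TITLE line may carry ``scan=<id> mslevel=<n> parent=<id>
    selected_mz=<x>`` tokens (our MS3-linkage convention); a block without
    them is treated as an MS2 scan with a generated scan id.
    """
    spectra: list[Spectrum] = []
    in_block = False
    headers: dict[str, str] = {}
    peaks: list[tuple[float, float]] = []
    block_index = 0

    def finish():
        if "PEPMASS" not in headers:
            raise MgfParseError(f"block {block_index}: missing PEPMASS")
        pepmass = float(headers["PEPMASS"].split()[0])
        charge = 0
        if "CHARGE" in headers:
            c = headers["CHARGE"].strip()
            sign = -1 if c.endswith("-") else 1
            charge = sign * int(c.rstrip("+-"))
        tokens = _parse_title_tokens(headers.get("TITLE", ""))
        ms_level = int(tokens.get("mslevel", 2))
        rt = float(headers["RTINSECONDS"]) if "RTINSECONDS" in headers else None
        spectra.append(
            Spectrum(
                scan_id=tokens.get("scan", f"scan{block_index}"),
                ms_level=ms_level,
                precursor_mz=pepmass,
                precursor_charge=charge,
                peaks=peaks,
                parent_scan_id=tokens.get("parent"),
                selected_precursor_mz=float(tokens["selected_mz"]) if "selected_mz" in tokens else None,
                retention_time=rt,
            )
        )

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                in_block, headers, peaks = True, {}, []
                block_index += 1
            elif line == "END IONS":
                finish()
                in_block = False
            elif in_block:
                if "=" in line and not line[0].isdigit():
                    k, v = line.split("=", 1)
                    headers[k] = v
                else:
                    parts = line.split()
                    try:
                        peaks.append((float(parts[0]), float(parts[1])))
                    except (ValueError, IndexError) as e:
                        raise MgfParseError(f"line {lineno}: bad peak line {line!r}") from e
    return spectra


def serialize_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    """Write spectra as MGF; round-trips all Spectrum fields through parse_mgf."""
    with open(path, "w") as fh:
        for s in spectra:
            tokens = [f"scan={s.scan_id}", f"mslevel={s.ms_level}"]
            if s.parent_scan_id is not None:
                tokens.append(f"parent={s.parent_scan_id}")
            if s.selected_precursor_mz is not None:
                tokens.append(f"selected_mz={s.selected_precursor_mz!r}")
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={' '.join(tokens)}\n")
            fh.write(f"PEPMASS={s.precursor_mz!r}\n")
            if s.precursor_charge:
                sign = "-" if s.precursor_charge < 0 else "+"
                fh.write(f"CHARGE={abs(s.precursor_charge)}{sign}\n")
            if s.retention_time is not None:
                fh.write(f"RTINSECONDS={s.retention_time!r}\n")
            for mz, inten in s.peaks:
                fh.write(f"{mz!r} {inten!r}\n")
            fh.write("END IONS\n")


def read_fasta(path: str | Path, decoy_prefix: str = "REV_") -> list[ProteinRecord]:
    """Read a protein FASTA; accessions starting with the decoy prefix are decoys.

    Records with non-canonical residues are rejected with an error naming
    the accession.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().strip()
        bad = set(seq) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(f"record {rec.id}: non-canonical residue(s) {sorted(bad)}")
        records.append(ProteinRecord(rec.id, seq, is_decoy=rec.id.startswith(decoy_prefix)))
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession}\n{rec.sequence}\n")


def recalibrate_spectra(
    spectra: list[Spectrum], ms1_ppm_shift: float, ms2_ppm_shift: float
) -> list[Spectrum]:
    """Remove a global systematic mass error.

    A measured spectrum with a systematic error of ``s`` ppm has every m/z
    too high by a factor (1 + s*1e-6); recalibration multiplies precursor
    m/z by (1 - ms1_ppm_shift*1e-6) and fragment m/z by
    (1 - ms2_ppm_shift*1e-6). Intensities are unchanged.
    """
    import math

    if not (math.isfinite(ms1_ppm_shift) and math.isfinite(ms2_ppm_shift)):
        raise ValueError("ppm shifts must be finite")
    f1 = 1.0 - ms1_ppm_shift * 1e-6
    f2 = 1.0 - ms2_ppm_shift * 1e-6
    out = []
    for s in spectra:
        out.append(
            replace(
                s,
                precursor_mz=s.precursor_mz * f1,
                selected_precursor_mz=(
                    None if s.selected_precursor_mz is None else s.selected_precursor_mz * f2
                ),
                peaks=[(mz * f2, inten) for mz, inten in s.peaks],
            )
        )
    return out


CSM_TABLE_COLUMNS = [
    "scan_id",
    "alpha_sequence",
    "beta_sequence",
    "alpha_mods",
    "beta_mods",
    "alpha_accessions",
    "beta_accessions",
    "link_site_alpha",
    "link_site_beta",
    "precursor_charge",
    "score",
    "delta_score",
    "alpha_is_decoy",
    "beta_is_decoy",
    "td_class",
    "self_or_heteromeric",
    "matched_fragments_alpha",
    "matched_fragments_beta",
    "doublet_class",
    "best_doublet_rank",
    "coverage_alpha",
    "coverage_beta",
    "is_noncovalent_flagged",
]

#: Per-peptide coverage split by fragment category; written next to the CSM
#: table by the annotate stage so category panels are recomputable from files.
COVERAGE_TABLE_COLUMNS = [
    "scan_id",
    "owner",
    "total",
    "linear",
    "link_site",
    "stub_only",
    "plus_p",
]


def write_csm_table(df: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in CSM_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CSM table missing column(s): {missing}")
    df.to_csv(path, sep="\t", index=False)


def read_csm_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={c: str for c in ("scan_id", "alpha_mods", "beta_mods", "alpha_accessions", "beta_accessions")},
        keep_default_na=False,
        na_values=[],
    )
    missing = [c for c in CSM_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"CSM table missing column(s): {missing}")
    for col in ("alpha_is_decoy", "beta_is_decoy", "is_noncovalent_flagged"):
        df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
    for col in ("link_site_alpha", "link_site_beta", "precursor_charge",
                "matched_fragments_alpha", "matched_fragments_beta", "doublet_class"):
        df[col] = df[col].astype(int)
    for col in ("score", "delta_score", "coverage_alpha", "coverage_beta"):
        df[col] = df[col].astype(float)
    df["best_doublet_rank"] = pd.to_numeric(df["best_doublet_rank"], errors="coerce")
    return df
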