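"""Peptide and crosslinker chemistry.

In-silico tryptic digestion, monoisotopic mass arithmetic, variable
modification enumeration, crosslinker specifications (DSSO, DSBU, BS3) and
theoretical fragment generation for crosslinked peptide pairs.

A cleavable crosslinker such as DSSO fragments in the mass spectrometer,
leaving a short "stub" on each peptide. DSSO cleaves asymmetrically into an
alkene (A) and a sulfenic acid (S) stub; S commonly loses water to form the
unsaturated thiol (T). The two most frequently observed stubs per peptide,
A and T, differ by a fixed mass and form the signature doublet used for
peptide-mass inference and MS3 triggering.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from .constants import (
    CANONICAL_RESIDUES,
    H2O,
    MONO_RESIDUE_MASSES,
    NH3,
    CH3SOH,
    mz_from_neutral,
)

__all__ = [
    "CrosslinkerSpec",
    "Modification",
    "ModificationRule",
    "Peptide",
    "CrosslinkedPair",
    "TheoreticalFragment",
    "DSSO",
    "DSBU",
    "BS3",
    "CROSSLINKERS",
    "tryptic_digest",
    "peptide_mass",
    "enumerate_variable_mods",
    "theoretical_fragments",
    "search_space_size",
    "STANDARD_VARIABLE_MODS",
]


@dataclass(frozen=True)
class CrosslinkerSpec:
    """Chemistry of a (possibly MS-cleavable) crosslinker.

    ``stub_masses`` maps stub labels to the mass left on a peptide after
    in-spectrometer cleavage; ``doublet_pair`` names the two stub species
    whose mass difference defines the signature doublet. ``linker_mass`` is
    the intact spacer mass added when both peptides stay connected (for a
    cleavable reagent this equals the sum of the two complementary stubs).
    """

    name: str
    linker_mass: float
    hydrolyzed_mod: float
    amidated_mod: float
    stub_masses: dict[str, float] = field(default_factory=dict)
    doublet_pair: tuple[str, str] | None = None
    reactive_sites: frozenset[str] = frozenset("KSTY")
    links_nterm: bool = True

    @property
    def cleavable(self) -> bool:
        return bool(self.stub_masses)

    @property
    def doublet_delta(self) -> float:
        """Mass difference between the two doublet stub species (Da)."""
        if not self.doublet_pair:
            raise ValueError(f"{self.name} has no signature doublet")
        lo, hi = self.doublet_pair
        return self.stub_masses[hi] - self.stub_masses[lo]

    def __post_init__(self):
        if self.cleavable:
            if self.doublet_pair is None:
                raise ValueError("cleavable crosslinker needs a doublet_pair")
            if self.doublet_delta <= 0:
                raise ValueError("doublet_delta must be positive")


#: Disuccinimidyl sulfoxide. Stubs: alkene (A), sulfenic acid (S), and
#: unsaturated thiol (T = S - H2O). Signature doublet A/T, ~32 Da apart.
DSSO = CrosslinkerSpec(
    name="DSSO",
    stub_masses={"A": 54.01056, "S": 103.99320, "T": 85.98264},
    doublet_pair=("A", "T"),
    linker_mass=54.01056 + 103.99320,
    hydrolyzed_mod=176.01433,
    amidated_mod=175.03031,
)

#: Disuccinimidyl dibutyric urea; cleaves into A and B stubs.
DSBU = CrosslinkerSpec(
    name="DSBU",
    stub_masses={"A": 85.05276, "B": 111.032028},
    doublet_pair=("A", "B"),
    linker_mass=85.05276 + 111.032028,
    hydrolyzed_mod=214.095357,
    amidated_mod=213.11134,
)

#: Bis(sulfosuccinimidyl)suberate — non-cleavable: no stubs, no doublet.
BS3 = CrosslinkerSpec(
    name="BS3",
    stub_masses={},
    doublet_pair=None,
    linker_mass=156.07864 - H2O,
    hydrolyzed_mod=156.07864,
    amidated_mod=155.09463,
)

CROSSLINKERS = {"DSSO": DSSO, "DSBU": DSBU, "BS3": BS3}


@dataclass(frozen=True)
class Modification:
    """A mass modification at a residue position (0 = protein/peptide N-terminus)."""

    position: int
    mass_delta: float
    label: str = ""


@dataclass(frozen=True)
class ModificationRule:
    """A variable modification with its residue specificity.

    ``residues`` is the set of amino-acid letters the modification may sit
    on; ``nterm`` additionally allows the protein N-terminus (position 0).
    """

    label: str
    mass_delta: float
    residues: frozenset[str]
    nterm: bool = False


STANDARD_VARIABLE_MODS = [
    ModificationRule("ox", 15.994915, frozenset("M")),
    ModificationRule("deam", 0.984016, frozenset("NQ")),
    ModificationRule("methyl", 14.015650, frozenset("ED")),
]


def crosslinker_mod_rules(xl: CrosslinkerSpec) -> list[ModificationRule]:
    """Hydrolyzed (-OH) and amidated (-NH2) dead-end crosslinker mods (Lys + protein N-term)."""
    return [
        ModificationRule(f"{xl.name}-OH", xl.hydrolyzed_mod, frozenset("K"), nterm=True),
        ModificationRule(f"{xl.name}-NH2", xl.amidated_mod, frozenset("K"), nterm=True),
    ]


@dataclass(frozen=True)
class Peptide:
    sequence: str
    protein_accessions: frozenset[str] = frozenset()
    start_position: int = 1  # 1-based position in the parent protein
    modifications: tuple[Modification, ...] = ()
    is_decoy: bool = False
    missed_cleavages: int = 0

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError("empty peptide")
        bad = set(self.sequence) - CANONICAL_RESIDUES
        if bad:
            raise ValueError(f"non-canonical residue(s) {sorted(bad)} in {self.sequence}")
        for m in self.modifications:
            if not 0 <= m.position <= len(self.sequence):
                raise ValueError(f"modification position {m.position} outside peptide")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def is_protein_nterm(self) -> bool:
        return self.start_position == 1

    def mod_string(self) -> str:
        return ";".join(f"{m.position}:{m.label or m.mass_delta:+}" for m in self.modifications)


def peptide_mass(peptide: Peptide) -> float:
    """Neutral monoisotopic mass: residues + H2O + modification deltas."""
    try:
        m = sum(MONO_RESIDUE_MASSES[aa] for aa in peptide.sequence)
    except KeyError as e:  # pragma: no cover - blocked by Peptide validation
        raise ValueError(f"unknown residue {e.args[0]}") from e
    return m + H2O + sum(mod.mass_delta for mod in peptide.modifications)


def tryptic_digest(
    sequence: str,
    max_missed: int = 2,
    length_range: tuple[int, int] | None = None,
    accession: str = "",
    is_decoy: bool = False,
) -> list[Peptide]:
    """Tryptic peptides of a protein: cleave after K/R unless followed by P.

    Returns all peptides with 0..max_missed missed cleavages, optionally
    restricted to a length range, with their 1-based start positions.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    # cut points: index i means a cut between sequence[i-1] and sequence[i]
    cuts = [0]
    for i in range(1, len(sequence)):
        if sequence[i - 1] in "KR" and sequence[i] != "P":
            cuts.append(i)
    cuts.append(len(sequence))

    peptides = []
    accs = frozenset([accession]) if accession else frozenset()
    for a in range(len(cuts) - 1):
        for missed in range(max_missed + 1):
            b = a + 1 + missed
            if b >= len(cuts):
                break
            seq = sequence[cuts[a] : cuts[b]]
            if length_range and not (length_range[0] <= len(seq) <= length_range[1]):
                continue
            peptides.append(
                Peptide(
                    sequence=seq,
                    protein_accessions=accs,
                    start_position=cuts[a] + 1,
                    is_decoy=is_decoy,
                    missed_cleavages=missed,
                )
            )
    return peptides


def enumerate_variable_mods(
    peptide: Peptide,
    mod_catalog: list[ModificationRule],
    max_mods: int = 1,
) -> list[Peptide]:
    """The unmodified peptide plus every variant with up to ``max_mods`` variable mods.

    With the conventional ``max_mods=1`` this is the unmodified form plus one
    variant per (rule, eligible site). N-terminal rules apply at position 0
    only when the peptide is the protein N-terminal peptide.
    """
    sites: list[Modification] = []
    for rule in mod_catalog:
        if rule.nterm and peptide.is_protein_nterm:
            sites.append(Modification(0, rule.mass_delta, rule.label))
        for i, aa in enumerate(peptide.sequence, start=1):
            if aa in rule.residues:
                sites.append(Modification(i, rule.mass_delta, rule.label))

    out = [peptide]
    for k in range(1, max_mods + 1):
        for combo in itertools.combinations(sites, k):
            positions = [m.position for m in combo]
            if len(set(positions)) < len(positions):
                continue
            out.append(replace(peptide, modifications=peptide.modifications + tuple(combo)))
    return out


@dataclass(frozen=True)
class CrosslinkedPair:
    """Two peptides joined by a crosslinker at specific residues.

    Link sites are 1-based residue positions; 0 denotes the protein
    N-terminus (only valid for a protein N-terminal peptide).
    """

    alpha: Peptide
    beta: Peptide
    link_site_alpha: int
    link_site_beta: int
    crosslinker: CrosslinkerSpec
    precursor_charge: int = 3

    def __post_init__(self):
        for pep, site in ((self.alpha, self.link_site_alpha), (self.beta, self.link_site_beta)):
            if site == 0:
                if not (self.crosslinker.links_nterm and pep.is_protein_nterm):
                    raise ValueError("N-terminal link on a non-N-terminal peptide")
            elif not 1 <= site <= len(pep):
                raise ValueError(f"link site {site} outside peptide {pep.sequence}")
            elif pep.sequence[site - 1] not in self.crosslinker.reactive_sites:
                raise ValueError(
                    f"residue {pep.sequence[site - 1]}{site} is not a "
                    f"{self.crosslinker.name} reactive site"
                )

    def peptide(self, owner: str) -> Peptide:
        return self.alpha if owner == "alpha" else self.beta

    def link_site(self, owner: str) -> int:
        return self.link_site_alpha if owner == "alpha" else self.link_site_beta

    @property
    def pair_mass(self) -> float:
        return peptide_mass(self.alpha) + peptide_mass(self.beta) + self.crosslinker.linker_mass

    @property
    def precursor_mz(self) -> float:
        return mz_from_neutral(self.pair_mass, self.precursor_charge)

    def key(self) -> tuple:
        """Unique-CSM key: peptide sequences + mods, link sites, precursor charge."""
        a = (self.alpha.sequence, self.alpha.mod_string(), self.link_site_alpha)
        b = (self.beta.sequence, self.beta.mod_string(), self.link_site_beta)
        return (min(a, b), max(a, b), self.precursor_charge)


@dataclass(frozen=True)
class TheoreticalFragment:
    """One predicted ion of a crosslinked peptide pair.

    ``series`` is 'b', 'y' or 'P' (intact peptide); ``index`` the cleavage
    ordinal (0 for P ions). ``stub_state`` is None for plain backbone
    fragments, a stub label for cleaved-crosslinker fragments, or '+P' for
    fragments still attached via the intact linker to the whole partner
    peptide.
    """

    owner: str  # 'alpha' | 'beta'
    series: str  # 'b' | 'y' | 'P'
    index: int
    stub_state: str | None
    neutral_loss: str | None
    charge: int
    mz: float
    contains_link_site: bool

    def label(self) -> str:
        stub = "" if self.stub_state is None else f"+{self.stub_state.lstrip('+')}"
        loss = "" if self.neutral_loss is None else f"-{self.neutral_loss}"
        name = "P" if self.series == "P" else f"{self.series}{self.index}"
        return f"{self.owner[0]}.{name}{stub}{loss}^{self.charge}"


_LOSSES = {"H2O": H2O, "NH3": NH3, "CH3SOH": CH3SOH}


def _fragment_contains_site(series: str, index: int, site: int, length: int) -> bool:
    s = max(site, 1)  # N-terminal link behaves like a link on residue 1
    if series == "b":
        return s <= index
    return s >= length - index + 1  # y


def theoretical_fragments(
    pair: CrosslinkedPair,
    max_fragment_charge: int | None = None,
    losses_enabled: bool = False,
    include_stub_fragments: bool = True,
) -> list[TheoreticalFragment]:
    """All theoretical b-, y- and intact-peptide (P) ions for a crosslinked pair.

    Backbone fragments that do not span the link site carry plain masses.
    Fragments spanning the link site are emitted once per stub label (for a
    cleavable crosslinker) and once as '+P' — the plain fragment mass plus
    the intact linker and the whole partner peptide. P ions (intact peptide
    + stub) are emitted per stub label; for the doublet-pair labels these
    are the signature doublet species.

    ``include_stub_fragments=False`` treats the crosslinker as noncleavable:
    only plain and +P fragments are generated (stub-blind search mode).
    """
    if max_fragment_charge is None:
        max_fragment_charge = max(1, min(3, pair.precursor_charge - 1))
    xl = pair.crosslinker
    emit_stubs = include_stub_fragments and xl.cleavable

    frags: list[TheoreticalFragment] = []

    def emit(owner, series, index, stub, neutral, contains):
        losses = [None]
        if losses_enabled and series != "P":
            losses.extend(["H2O", "NH3"])
            if stub in ("S", "T"):
                losses.append("CH3SOH")
        for loss in losses:
            m = neutral - (_LOSSES[loss] if loss else 0.0)
            for z in range(1, max_fragment_charge + 1):
                frags.append(
                    TheoreticalFragment(
                        owner=owner,
                        series=series,
                        index=index,
                        stub_state=stub,
                        neutral_loss=loss,
                        charge=z,
                        mz=mz_from_neutral(m, z),
                        contains_link_site=contains,
                    )
                )

    for owner in ("alpha", "beta"):
        pep = pair.peptide(owner)
        other = pair.beta if owner == "alpha" else pair.alpha
        site = pair.link_site(owner)
        L = len(pep)
        other_mass = peptide_mass(other)
        residue_masses = [MONO_RESIDUE_MASSES[aa] for aa in pep.sequence]
        mods_at = {}
        for mod in pep.modifications:
            mods_at[max(mod.position, 1)] = mods_at.get(max(mod.position, 1), 0.0) + mod.mass_delta

        prefix = 0.0
        prefix_sums = []
        for i in range(1, L + 1):
            prefix += residue_masses[i - 1] + mods_at.get(i, 0.0)
            prefix_sums.append(prefix)
        total = prefix_sums[-1]

        for i in range(1, L):
            b_neutral = prefix_sums[i - 1]
            y_neutral = total - prefix_sums[L - i - 1] + H2O
            for series, neutral in (("b", b_neutral), ("y", y_neutral)):
                contains = _fragment_contains_site(series, i, site, L)
                if not contains:
                    emit(owner, series, i, None, neutral, False)
                else:
                    if emit_stubs:
                        for label, sm in xl.stub_masses.items():
                            emit(owner, series, i, label, neutral + sm, True)
                    emit(owner, series, i, "+P", neutral + xl.linker_mass + other_mass, True)

        if emit_stubs:
            pep_neutral = total + H2O
            for label, sm in xl.stub_masses.items():
                emit(owner, "P", 0, label, pep_neutral + sm, True)

    return frags


def search_space_size(n: int) -> int:
    """Number of crosslinked peptide pair candidates from n linear peptides: (n^2+n)/2."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return (n * n + n) // 2
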