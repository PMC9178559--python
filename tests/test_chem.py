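"""Digestion, mass arithmetic, crosslinker chemistry and fragment generation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xlstub.chem import (
    BS3,
    DSBU,
    DSSO,
    CrosslinkedPair,
    Modification,
    ModificationRule,
    Peptide,
    crosslinker_mod_rules,
    enumerate_variable_mods,
    peptide_mass,
    search_space_size,
    theoretical_fragments,
    tryptic_digest,
)
from xlstub.constants import H2O, MONO_RESIDUE_MASSES, PROTON, NH3

AA = sorted(MONO_RESIDUE_MASSES)


def digest_oracle(sequence, max_missed):
    """Exhaustive enumeration: every substring whose ends are valid cut points."""
    cuts = [0] + [i for i in range(1, len(sequence)) if sequence[i - 1] in "KR" and sequence[i] != "P"]
    cuts.append(len(sequence))
    out = set()
    for a, b in itertools.combinations(range(len(cuts)), 2):
        if b - a - 1 <= max_missed:
            out.add(sequence[cuts[a] : cuts[b]])
    return out


class TestDigest:
    @pytest.mark.parametrize(
        "seq,missed,expected",
        [
            ("MKRA", 0, {"MK", "R", "A"}),
            ("MKRA", 2, {"MK", "R", "A", "MKR", "RA", "MKRA"}),
            ("AAAA", 2, {"AAAA"}),
            ("AKPA", 0, {"AKPA"}),  # no cleavage before proline
        ],
    )
    def test_examples(self, seq, missed, expected):
        assert {p.sequence for p in tryptic_digest(seq, missed)} == expected

    def test_matches_enumeration_oracle_on_random_proteins(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(AA, size=60))
            for missed in (0, 1, 2):
                got = {p.sequence for p in tryptic_digest(seq, missed)}
                assert got == digest_oracle(seq, missed)

    def test_start_positions_and_length_filter(self):
        peps = tryptic_digest("MKRAAK", 0, length_range=(2, 10))
        assert {(p.sequence, p.start_position) for p in peps} == {("MK", 1), ("AAK", 4)}


class TestMass:
    def test_glycylglycine(self):
        assert peptide_mass(Peptide("GG")) == pytest.approx(132.05349, abs=1e-4)

    def test_carbamidomethyl_cysteine(self):
        plain = peptide_mass(Peptide("C"))
        cam = peptide_mass(Peptide("C", modifications=(Modification(1, 57.021464, "cam"),)))
        assert cam - plain == pytest.approx(57.021464, abs=1e-9)

    def test_oxidation_delta(self):
        pep = Peptide("AMA")
        ox = Peptide("AMA", modifications=(Modification(2, 15.994915, "ox"),))
        assert peptide_mass(ox) - peptide_mass(pep) == pytest.approx(15.994915)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValueError, match="X"):
            Peptide("AXA")


class TestVariableMods:
    OX = ModificationRule("ox", 15.994915, frozenset("M"))

    def test_single_site(self):
        assert len(enumerate_variable_mods(Peptide("AMA"), [self.OX])) == 2

    def test_crosslinker_deadend_mods_on_lysine(self):
        rules = crosslinker_mod_rules(DSSO)
        forms = enumerate_variable_mods(Peptide("AKA", start_position=7), rules)
        assert len(forms) == 3  # unmodified + OH and NH2 at K2
        deltas = sorted(sum(m.mass_delta for m in f.modifications) for f in forms)
        assert deltas == pytest.approx([0.0, 175.03031, 176.01433])

    def test_nterm_site_only_on_protein_nterminal_peptide(self):
        rules = crosslinker_mod_rules(DSSO)
        nterm = enumerate_variable_mods(Peptide("AKA", start_position=1), rules)
        assert len(nterm) == 5  # K2 and position 0, two mods each

    def test_at_most_one_mod(self):
        forms = enumerate_variable_mods(Peptide("MM"), [self.OX])
        assert len(forms) == 3  # none, M1, M2 -- never both
        assert max(len(f.modifications) for f in forms) == 1


class TestFragments:
    def test_link_site_containment_and_stub_variants(self, dsso_pair):
        frags = theoretical_fragments(dsso_pair, max_fragment_charge=1)
        by = lambda **kw: [
            f for f in frags if all(getattr(f, k) == v for k, v in kw.items())
        ]
        # alpha = AKAR linked at K2: b1 does not span the link
        (b1,) = by(owner="alpha", series="b", index=1)
        assert b1.stub_state is None and not b1.contains_link_site
        # y3 = KAR spans the link: A, S, T stubs and one +P variant
        y3 = by(owner="alpha", series="y", index=3)
        assert {f.stub_state for f in y3} == {"A", "S", "T", "+P"}
        assert all(f.contains_link_site for f in y3)

    def test_p_ion_mz(self, dsso_pair):
        frags = theoretical_fragments(dsso_pair, max_fragment_charge=1)
        (pa,) = [f for f in frags if f.owner == "alpha" and f.series == "P" and f.stub_state == "A"]
        M = peptide_mass(dsso_pair.alpha)
        assert pa.mz == pytest.approx(M + 54.01056 + 1.0072765, abs=1e-4)

    def test_stub_mass_differences(self, dsso_pair):
        frags = theoretical_fragments(dsso_pair, max_fragment_charge=1)
        y3 = {f.stub_state: f.mz for f in frags if f.owner == "alpha" and f.series == "y" and f.index == 3}
        assert y3["T"] - y3["A"] == pytest.approx(31.97208, abs=1e-5)
        assert y3["S"] - y3["T"] == pytest.approx(H2O, abs=1e-4)

    def test_one_plus_p_per_link_fragment_none_elsewhere(self, dsso_pair):
        frags = [f for f in theoretical_fragments(dsso_pair, max_fragment_charge=1) if f.series != "P"]
        for (owner, series, index), group in itertools.groupby(
            sorted(frags, key=lambda f: (f.owner, f.series, f.index)),
            key=lambda f: (f.owner, f.series, f.index),
        ):
            group = list(group)
            n_plus_p = sum(f.stub_state == "+P" for f in group)
            if group[0].contains_link_site:
                assert n_plus_p == 1
            else:
                assert n_plus_p == 0

    def test_noncleavable_has_no_stubs(self):
        pair = CrosslinkedPair(Peptide("AKAR"), Peptide("KRFESA"), 2, 1, BS3)
        states = {f.stub_state for f in theoretical_fragments(pair)}
        assert states == {None, "+P"}

    def test_invalid_link_site_rejected(self):
        with pytest.raises(ValueError):
            CrosslinkedPair(Peptide("AKAR"), Peptide("KRFESA"), 3, 1, DSSO)  # A3 not reactive
        with pytest.raises(ValueError):
            CrosslinkedPair(Peptide("AKAR"), Peptide("KRFESA"), 9, 1, DSSO)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.data())
    def test_complementarity(self, data):
        """b_i + y_(L-i) neutral masses sum to the peptide mass plus link constants."""
        seq = data.draw(st.text(alphabet=AA, min_size=3, max_size=12))
        sites = [i for i, aa in enumerate(seq, 1) if aa in "KSTY"]
        if not sites:
            seq += "K"
            sites = [len(seq)]
        site = data.draw(st.sampled_from(sites))
        pair = CrosslinkedPair(Peptide(seq), Peptide("KGGR"), site, 1, DSSO)
        frags = {
            (f.series, f.index, f.stub_state): f.mz
            for f in theoretical_fragments(pair, max_fragment_charge=1)
            if f.owner == "alpha"
        }
        M = peptide_mass(pair.alpha)
        L = len(seq)
        for i in range(1, L):
            for stub, delta in (("A", DSSO.stub_masses["A"]), ("S", DSSO.stub_masses["S"])):
                b = frags.get(("b", i, None), frags.get(("b", i, stub)))
                y = frags.get(("y", L - i, None), frags.get(("y", L - i, stub)))
                total = (b - PROTON) + (y - PROTON)
                assert total == pytest.approx(M + delta, abs=1e-6)


class TestCrosslinkerSpecs:
    @pytest.mark.parametrize("xl", [DSSO, DSBU])
    def test_printed_mod_masses_consistent_with_stub_sums(self, xl):
        assert xl.hydrolyzed_mod == pytest.approx(xl.linker_mass + H2O, abs=1e-4)
        assert xl.amidated_mod == pytest.approx(xl.linker_mass + NH3, abs=1e-4)

    def test_bs3_not_cleavable(self):
        assert not BS3.cleavable
        with pytest.raises(ValueError):
            BS3.doublet_delta


class TestSearchSpace:
    @pytest.mark.parametrize("n,expected", [(0, 0), (1, 1), (3, 6), (1000, 500500)])
    def test_closed_form(self, n, expected):
        assert search_space_size(n) == expected

    def test_matches_pair_enumeration(self):
        for n in range(8):
            pairs = {frozenset((i, j)) if i != j else (i,) for i in range(n) for j in range(i, n)}
            assert search_space_size(n) == len(pairs)
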