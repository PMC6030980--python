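"""Fragment generation: series arithmetic, cross-link rule, neutral losses."""

import numpy as np
import pytest

import oracle
from conftest import random_crosslinked_psm, random_peptide
from speclink import (
    AnnotationSettings,
    CrossLinkedPSM,
    Peptide,
    Tolerance,
    apply_neutral_losses,
    generate_fragments,
    parse_sequence,
    peptide_neutral_mass,
)


def frag_map(fragments):
    return {
        (f.peptide_id, f.series, f.index, f.charge, f.loss): f for f in fragments
    }


def by_settings(**kwargs):
    defaults = dict(
        tolerance=Tolerance(10.0, "ppm"),
        ion_types=frozenset({"b", "y"}),
        max_fragment_charge=1,
        losses_enabled=False,
    )
    defaults.update(kwargs)
    return AnnotationSettings(**defaults)


class TestLinearSeries:
    def test_b2_and_y1_of_peptide(self):
        psm = CrossLinkedPSM(peptides=(Peptide("PEPTIDE"),), precursor_charge=2)
        frags = frag_map(generate_fragments(psm, by_settings()))
        assert frags[("alpha", "b", 2, 1, None)].mz == pytest.approx(227.10263, abs=1e-4)
        assert frags[("alpha", "y", 1, 1, None)].mz == pytest.approx(148.06043, abs=1e-4)

    def test_against_independent_series_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            seq = random_peptide(rng)
            psm = CrossLinkedPSM(peptides=(Peptide(seq),), precursor_charge=2)
            frags = frag_map(generate_fragments(psm, by_settings()))
            for i in range(1, len(seq)):
                assert frags[("alpha", "b", i, 1, None)].neutral_mass == pytest.approx(
                    oracle.b_ion(seq, i), abs=1e-4
                )
                assert frags[("alpha", "y", i, 1, None)].neutral_mass == pytest.approx(
                    oracle.y_ion(seq, i), abs=1e-4
                )

    def test_c_z_offsets_from_b_y(self):
        psm = CrossLinkedPSM(peptides=(Peptide("PEPTIDEK"),), precursor_charge=2)
        frags = frag_map(
            generate_fragments(psm, by_settings(ion_types=frozenset("bcyz")))
        )
        for i in range(1, 8):
            b = frags[("alpha", "b", i, 1, None)].neutral_mass
            c = frags[("alpha", "c", i, 1, None)].neutral_mass
            y = frags[("alpha", "y", i, 1, None)].neutral_mass
            z = frags[("alpha", "z", i, 1, None)].neutral_mass
            assert c - b == pytest.approx(oracle.AMMONIA, abs=1e-6)
            assert y - z == pytest.approx(oracle.AMMONIA, abs=1e-6)

    def test_z_radical_convention_adds_hydrogen(self):
        psm = CrossLinkedPSM(peptides=(Peptide("PEPTIDEK"),), precursor_charge=2)
        classical = frag_map(
            generate_fragments(psm, by_settings(ion_types=frozenset("z")))
        )
        radical = frag_map(
            generate_fragments(
                psm, by_settings(ion_types=frozenset("z"), z_radical=True)
            )
        )
        for key, frag in classical.items():
            assert radical[key].neutral_mass - frag.neutral_mass == pytest.approx(
                1.00783, abs=1e-5
            )

    def test_single_residue_peptide_has_no_backbone_ions(self):
        psm = CrossLinkedPSM(peptides=(Peptide("K"),), precursor_charge=2)
        assert generate_fragments(psm, by_settings()) == []

    def test_empty_ion_types_yield_empty_list(self):
        psm = CrossLinkedPSM(peptides=(Peptide("PEPTIDE"),), precursor_charge=2)
        assert generate_fragments(psm, by_settings(ion_types=frozenset())) == []

    def test_invalid_charge_range_rejected(self):
        with pytest.raises(ValueError):
            by_settings(max_fragment_charge=0)

    def test_charges_capped_by_precursor(self):
        psm = CrossLinkedPSM(peptides=(Peptide("PEPTIDE"),), precursor_charge=2)
        frags = generate_fragments(psm, by_settings(max_fragment_charge=5))
        assert {f.charge for f in frags} == {1, 2}

    def test_complementarity_of_prefix_and_suffix_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            seq = random_peptide(rng)
            pep = Peptide(seq)
            total = peptide_neutral_mass(pep)
            psm = CrossLinkedPSM(peptides=(pep,), precursor_charge=2)
            frags = frag_map(
                generate_fragments(psm, by_settings(ion_types=frozenset("bcyz")))
            )
            n = len(seq)
            for i in range(1, n):
                b = frags[("alpha", "b", i, 1, None)].neutral_mass
                y = frags[("alpha", "y", n - i, 1, None)].neutral_mass
                assert b + y == pytest.approx(total, abs=1e-6)
                c = frags[("alpha", "c", i, 1, None)].neutral_mass
                z = frags[("alpha", "z", n - i, 1, None)].neutral_mass
                assert c + z == pytest.approx(total, abs=1e-6)

    def test_mz_strictly_increases_with_index_within_series(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            seq = random_peptide(rng)
            psm = CrossLinkedPSM(peptides=(Peptide(seq),), precursor_charge=3)
            frags = generate_fragments(
                psm, by_settings(ion_types=frozenset("by"), max_fragment_charge=2)
            )
            for series in "by":
                for z in (1, 2):
                    mzs = [
                        f.mz
                        for f in sorted(frags, key=lambda f: f.index)
                        if f.series == series and f.charge == z
                    ]
                    assert all(a < b for a, b in zip(mzs, mzs[1:]))

    def test_modification_belongs_to_fragment_containing_residue(self, registry):
        pep, _ = parse_sequence("PEPTMoxIDE", registry)
        psm = CrossLinkedPSM(peptides=(pep,), precursor_charge=2)
        plain = frag_map(
            generate_fragments(
                CrossLinkedPSM(peptides=(Peptide("PEPTMIDE"),), precursor_charge=2),
                by_settings(),
            )
        )
        modded = frag_map(generate_fragments(psm, by_settings()))
        for key, frag in modded.items():
            _pid, series, index, _z, _loss = key
            covers = index >= 5 if series == "b" else index >= 4  # M at position 5 of 8
            expected = plain[key].neutral_mass + (15.99491 if covers else 0.0)
            assert frag.neutral_mass == pytest.approx(expected, abs=1e-6)


class TestCrossLinked:
    def test_linked_y1_carries_linker_plus_partner(self):
        pa, la = parse_sequence("GK#")
        pb, lb = parse_sequence("GK#")
        psm = CrossLinkedPSM(
            peptides=(pa, pb), link_positions=(la, lb),
            crosslinker_mass=138.06808, precursor_charge=3,
        )
        frags = frag_map(generate_fragments(psm, by_settings()))
        y1a = frags[("alpha", "y", 1, 1, None)]
        assert y1a.contains_link
        expected = oracle.ion_mz(
            oracle.residue_mass("K") + oracle.WATER + 138.06808
            + oracle.peptide_mass("GK"), 1,
        )
        assert y1a.mz == pytest.approx(expected, abs=1e-4)
        # b1 (G alone) does not span the link
        assert not frags[("alpha", "b", 1, 1, None)].contains_link

    def test_precursor_is_both_peptides_plus_linker(self):
        rng = np.random.default_rng(1)
        psm = random_crosslinked_psm(rng)
        frags = generate_fragments(
            psm, by_settings(ion_types=frozenset({"precursor"}))
        )
        expected = (
            peptide_neutral_mass(psm.peptides[0])
            + peptide_neutral_mass(psm.peptides[1])
            + psm.crosslinker_mass
        )
        assert all(
            f.neutral_mass == pytest.approx(expected, abs=1e-6) for f in frags
        )
        assert any(f.charge == psm.precursor_charge for f in frags)

    def test_crosslink_equals_linear_with_partner_mass_modification(self, registry):
        """A cross-linked peptide fragments like the same linear peptide
        carrying (linker + partner) as a modification at the link site."""
        rng = np.random.default_rng(21)
        settings = by_settings(
            ion_types=frozenset("bcyz"), max_fragment_charge=2, losses_enabled=True
        )
        for _ in range(10):
            psm = random_crosslinked_psm(rng)
            for side in (0, 1):
                pep = psm.peptides[side]
                partner = psm.peptides[1 - side]
                shift = psm.crosslinker_mass + peptide_neutral_mass(partner)
                registry.register("xl", shift)
                linear = CrossLinkedPSM(
                    peptides=(
                        Peptide(
                            pep.sequence,
                            pep.mods + ((psm.link_positions[side], registry["xl"]),),
                        ),
                    ),
                    precursor_charge=psm.precursor_charge,
                )
                pid = "alpha" if side == 0 else "beta"
                xl_frags = {
                    (f.series, f.index, f.charge, f.loss): f.mz
                    for f in apply_neutral_losses(
                        generate_fragments(psm, settings), psm, True
                    )
                    if f.peptide_id == pid and f.series != "precursor"
                }
                lin_frags = {
                    (f.series, f.index, f.charge, f.loss): f.mz
                    for f in apply_neutral_losses(
                        generate_fragments(linear, settings), linear, True
                    )
                    if f.series != "precursor"
                }
                assert xl_frags.keys() == lin_frags.keys()
                for key, mz in xl_frags.items():
                    assert mz == pytest.approx(lin_frags[key], rel=1e-9)


class TestNeutralLosses:
    def test_water_loss_added_for_loss_prone_residue(self):
        psm = CrossLinkedPSM(peptides=(Peptide("PE"),), precursor_charge=2)
        frags = generate_fragments(psm, by_settings())
        augmented = apply_neutral_losses(frags, psm, True)
        losses = frag_map(augmented)
        b1 = losses[("alpha", "b", 1, 1, None)]
        assert ("alpha", "b", 1, 1, "H2O") not in losses  # P alone: no loss
        y1 = losses[("alpha", "y", 1, 1, None)]
        y1_loss = losses[("alpha", "y", 1, 1, "H2O")]
        assert y1.neutral_mass - y1_loss.neutral_mass == pytest.approx(
            18.01056, abs=1e-4
        )

    def test_ammonia_loss_for_rknq(self):
        psm = CrossLinkedPSM(peptides=(Peptide("GKG"),), precursor_charge=2)
        augmented = frag_map(
            apply_neutral_losses(generate_fragments(psm, by_settings()), psm, True)
        )
        assert ("alpha", "b", 2, 1, "NH3") in augmented
        assert ("alpha", "b", 1, 1, "NH3") not in augmented

    def test_no_losses_for_inert_residues(self):
        psm = CrossLinkedPSM(peptides=(Peptide("GGG"),), precursor_charge=2)
        frags = generate_fragments(psm, by_settings())
        assert apply_neutral_losses(frags, psm, True) == frags

    def test_disabled_is_identity(self):
        psm = CrossLinkedPSM(peptides=(Peptide("PESTER"),), precursor_charge=2)
        frags = generate_fragments(psm, by_settings())
        assert apply_neutral_losses(frags, psm, False) == frags

    def test_base_fragments_retained_and_single_loss_only(self):
        psm = CrossLinkedPSM(peptides=(Peptide("SKSK"),), precursor_charge=2)
        frags = generate_fragments(psm, by_settings())
        augmented = apply_neutral_losses(frags, psm, True)
        assert set(frags) <= set(augmented)
        assert all(f.loss in (None, "H2O", "NH3") for f in augmented)
        # no double-loss variants: each loss variant differs from its base by
        # exactly one water or ammonia
        assert not any("H2O" in str(f.loss) and "NH3" in str(f.loss) for f in augmented)


class TestTolerance:
    @pytest.mark.parametrize(
        "text,value,unit",
        [("10ppm", 10.0, "ppm"), ("0.02Da", 0.02, "Da"), ("5PPM", 5.0, "ppm"),
         (" 0.5 da ", 0.5, "Da")],
    )
    def test_parse_forms(self, text, value, unit):
        tol = Tolerance.parse(text)
        assert tol.value == value and tol.unit == unit

    @pytest.mark.parametrize("text", ["10", "ppm", "-3ppm", "0ppm", "10mmu"])
    def test_invalid_forms_rejected(self, text):
        with pytest.raises(ValueError):
            Tolerance.parse(text)

    def test_window_scales_with_mz_for_ppm_only(self):
        assert Tolerance(10, "ppm").window_da(500.0) == pytest.approx(0.005)
        assert Tolerance(0.02, "Da").window_da(500.0) == 0.02
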